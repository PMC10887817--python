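"""Per-locus and per-group marker diversity statistics.

For allele frequencies :math:`p_i` at a locus:

* GD (Nei's gene diversity / expected heterozygosity)
  :math:`GD = 1 - \\sum_i p_i^2`;
* PIC (Botstein's polymorphism information content)
  :math:`PIC = 1 - \\sum_i p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`
  (always <= GD, equality only for monomorphic loci; at most 0.375 for a
  biallelic locus, attained at p = 0.5);
* Ho, the observed fraction of heterozygous calls;
* MAF, the frequency of the second-most-frequent allele;
* inbreeding coefficient :math:`F = 1 - Ho/GD` (1 exactly when a
  polymorphic locus shows no heterozygote, as expected for inbred lines;
  undefined for monomorphic loci and then reported as NaN, never 0).

Group summaries add the polymorphic-marker count (>= 2 alleles observed
within the group) and a group-level F computed as 1 - mean(Ho)/mean(GD)
over the group's polymorphic loci (ratio of means — robust when many loci
are nearly monomorphic within a group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, SampleMeta, ValidationError

__all__ = [
    "LocusStats", "PanelSummary", "allele_freqs", "pic", "gd", "ho",
    "inbreeding_f", "locus_stats", "panel_summary", "group_summary",
]

_HIST_BINS = np.linspace(0.0, 0.55, 12)  # 0.05-wide bins covering [0, 0.55]


@dataclass
class LocusStats:
    locus_id: str
    allele_freqs: dict[str, float]
    maf: float
    pic: float
    ho: float
    gd: float
    inbreeding_f: float  # NaN when GD == 0
    n_called: int


@dataclass
class PanelSummary:
    per_locus: pd.DataFrame  # one row per locus, LocusStats columns
    means: dict[str, float]
    histograms: dict[str, np.ndarray] = field(default_factory=dict)
    frac_maf_040_050: float = 0.0
    frac_pic_gt_030: float = 0.0
    n_pic_lt_020: int = 0
    n_inbreeding_one: int = 0


def allele_freqs(
    matrix: GenotypeMatrix, locus: str
) -> tuple[dict[str, float], int]:
    """Allele frequencies at a locus plus the number of called samples.

    Each non-missing diploid call contributes two allele observations.
    """
    counts: dict[str, int] = {}
    n_called = 0
    for code in matrix.data[locus]:
        if code == MISSING:
            continue
        n_called += 1
        for ch in code:
            counts[ch] = counts.get(ch, 0) + 1
    total = 2 * n_called
    freqs = {a: c / total for a, c in sorted(counts.items())} if total else {}
    return freqs, n_called


def pic(freqs: Sequence[float]) -> float:
    p = np.asarray(list(freqs), dtype=float)
    if p.size and abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("allele frequencies must sum to 1")
    s2 = float(np.sum(p**2))
    cross = (float(np.sum(p**2)) ** 2 - float(np.sum(p**4))) / 2.0
    return 1.0 - s2 - 2.0 * cross


def gd(freqs: Sequence[float], n_called: int | None = None,
       unbiased: bool = False) -> float:
    """Nei's gene diversity; ``unbiased=True`` applies the 2n/(2n-1)
    small-sample correction (off by default)."""
    p = np.asarray(list(freqs), dtype=float)
    if p.size and abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("allele frequencies must sum to 1")
    d = 1.0 - float(np.sum(p**2))
    if unbiased:
        if not n_called:
            raise ValidationError("unbiased GD needs n_called")
        d *= (2 * n_called) / (2 * n_called - 1)
    return d


def ho(matrix: GenotypeMatrix, locus: str) -> float:
    col = matrix.data[locus]
    called = col[col != MISSING]
    if called.empty:
        return float("nan")
    return float((called.str[0] != called.str[1]).mean())


def inbreeding_f(ho_value: float, gd_value: float) -> float:
    """F = 1 - Ho/GD; NaN for monomorphic loci (GD = 0)."""
    if gd_value <= 0:
        return float("nan")
    return 1.0 - ho_value / gd_value


def locus_stats(matrix: GenotypeMatrix, locus: str) -> LocusStats:
    freqs, n_called = allele_freqs(matrix, locus)
    ordered = sorted(freqs.values(), reverse=True)
    maf = ordered[1] if len(ordered) > 1 else 0.0
    p = list(freqs.values())
    gd_v = gd(p) if p else 0.0
    pic_v = pic(p) if p else 0.0
    ho_v = ho(matrix, locus) if n_called else float("nan")
    return LocusStats(
        locus_id=locus,
        allele_freqs=freqs,
        maf=maf,
        pic=pic_v,
        ho=ho_v,
        gd=gd_v,
        inbreeding_f=inbreeding_f(ho_v, gd_v) if n_called else float("nan"),
        n_called=n_called,
    )


def _stats_frame(matrix: GenotypeMatrix) -> pd.DataFrame:
    rows = []
    for locus in matrix.loci:
        s = locus_stats(matrix, locus)
        rows.append(
            {
                "locus_id": s.locus_id, "maf": s.maf, "pic": s.pic,
                "ho": s.ho, "gd": s.gd, "inbreeding_f": s.inbreeding_f,
                "n_called": s.n_called,
                "n_alleles": len(s.allele_freqs),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def panel_summary(matrix: GenotypeMatrix) -> PanelSummary:
    """Per-locus statistics plus panel-wide means and distributions."""
    if matrix.n_loci == 0:
        raise ValidationError("panel_summary needs at least one locus")
    df = _stats_frame(matrix)
    means = {
        k: float(np.nanmean(df[k].to_numpy(dtype=float)))
        for k in ("maf", "pic", "ho", "gd")
    }
    hists = {
        k: np.histogram(
            df[k].to_numpy(dtype=float)[~np.isnan(df[k].to_numpy(dtype=float))],
            bins=_HIST_BINS,
        )[0]
        for k in ("maf", "pic", "ho", "gd")
    }
    n = len(df)
    return PanelSummary(
        per_locus=df,
        means=means,
        histograms=hists,
        frac_maf_040_050=float(((df.maf >= 0.4) & (df.maf <= 0.5)).sum() / n),
        frac_pic_gt_030=float((df.pic > 0.3).sum() / n),
        n_pic_lt_020=int((df.pic < 0.2).sum()),
        n_inbreeding_one=int((df.inbreeding_f == 1.0).sum()),
    )


@dataclass
class GroupSummary:
    summary: PanelSummary
    n_samples: int
    n_polymorphic: int
    group_inbreeding_f: float  # 1 - mean(Ho)/mean(GD) over polymorphic loci


def group_summary(
    matrix: GenotypeMatrix,
    meta: Sequence[SampleMeta],
    group_by: str = "subpopulation",
    allow_unlabeled: bool = False,
) -> dict[str, GroupSummary]:
    """Diversity statistics within each group of samples.

    ``group_by`` is a SampleMeta field (population, subpopulation, species,
    fruit_shape).  Every matrix sample must be labelled unless
    ``allow_unlabeled`` (unlabelled samples are then excluded).
    """
    labels: dict[str, str | None] = {}
    for m in meta:
        v = getattr(m, group_by)
        labels[m.sample_id] = v.value if hasattr(v, "value") else v
    groups: dict[str, list[str]] = {}
    for s in matrix.samples:
        lab = labels.get(s)
        if lab is None:
            if allow_unlabeled:
                continue
            raise ValidationError(f"sample {s} has no {group_by} label")
        groups.setdefault(lab, []).append(s)
    out: dict[str, GroupSummary] = {}
    for lab in sorted(groups):
        sub = matrix.subset_samples(groups[lab])
        summ = panel_summary(sub)
        poly = summ.per_locus[summ.per_locus.n_alleles >= 2]
        if len(poly) and float(poly.gd.mean()) > 0:
            f = 1.0 - float(np.nanmean(poly.ho)) / float(poly.gd.mean())
        else:
            f = float("nan")
        out[lab] = GroupSummary(
            summary=summ,
            n_samples=sub.n_samples,
            n_polymorphic=int((summ.per_locus.n_alleles >= 2).sum()),
            group_inbreeding_f=f,
        )
    return out
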