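"""Minimal discriminating SNP sets and core-germplasm selection.

A pair of samples is *resolved* by a locus when both calls are present and
the unordered genotypes differ (a missing call never resolves anything).
Finding the smallest locus subset resolving every resolvable pair is set
cover, so the screen is the classic greedy: repeatedly take the locus
resolving the most still-unresolved pairs, breaking ties by higher gene
diversity and then panel order, until no locus adds a new pair.  Pairs no
locus in the whole panel separates (duplicate fingerprints) are reported
explicitly rather than silently dropped.

Core lines are the most central members of each subpopulation: samples
ranked by ascending mean pairwise genotype-difference count to the rest of
their subpopulation, with the top fraction (default 10%, round-half-up,
floor of one line per subpopulation) selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity_stats import locus_stats
from .io_formats import MISSING, GenotypeMatrix, SampleMeta, ValidationError
from .relatedness import DiffMatrix

__all__ = [
    "CoreSetResult", "CoreLineResult", "greedy_core_snps",
    "saturation_curve", "pair_guarantee_stats", "select_core_lines",
]


@dataclass
class CoreSetResult:
    selected: list[str]                    # loci, selection order
    newly_resolved: list[int]              # per step, strictly positive
    cumulative_fraction: list[float]       # of resolvable pairs
    unresolved_pairs: list[tuple[str, str]]  # unresolvable by full panel
    n_pairs: int
    n_resolvable: int
    pair_min_diff_histogram: dict[int, int] = field(default_factory=dict)


@dataclass
class CoreLineResult:
    ranking: dict[str, list[str]]   # subpop -> sample_ids, ascending mean diff
    selected: dict[str, list[str]]  # subpop -> chosen core lines
    fraction: float


def _pair_index(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _resolution_masks(matrix: GenotypeMatrix) -> tuple[list[int], int]:
    """Per locus, a bitmask over sample pairs it resolves; plus pair count."""
    vals = matrix.values()
    n = matrix.n_samples
    pairs = _pair_index(n)
    masks: list[int] = []
    for j in range(vals.shape[1]):
        col = vals[:, j]
        m = 0
        for b, (i, k) in enumerate(pairs):
            ci, ck = col[i], col[k]
            if ci != MISSING and ck != MISSING and ci != ck:
                m |= 1 << b
        masks.append(m)
    return masks, len(pairs)


def greedy_core_snps(matrix: GenotypeMatrix) -> CoreSetResult:
    """Greedy minimum-set screen for loci that distinguish all samples."""
    if matrix.n_samples < 2:
        raise ValidationError("greedy_core_snps needs >= 2 samples")
    loci = matrix.loci
    masks, n_pairs = _resolution_masks(matrix)
    full = 0
    for m in masks:
        full |= m
    n_resolvable = bin(full).count("1")
    gd_by_locus = {l: locus_stats(matrix, l).gd for l in loci}

    covered = 0
    selected: list[str] = []
    newly: list[int] = []
    cumulative: list[float] = []
    remaining = list(range(len(loci)))
    while covered != full:
        best = None
        for idx in remaining:
            gain = bin(masks[idx] & ~covered).count("1")
            if gain == 0:
                continue
            key = (-gain, -gd_by_locus[loci[idx]], idx)
            if best is None or key < best[0]:
                best = (key, idx, gain)
        if best is None:
            break
        _, idx, gain = best
        covered |= masks[idx]
        remaining.remove(idx)
        selected.append(loci[idx])
        newly.append(gain)
        cumulative.append(
            bin(covered).count("1") / n_resolvable if n_resolvable else 1.0
        )

    samples = matrix.samples
    pairs = _pair_index(len(samples))
    unresolved = [
        (samples[i], samples[j])
        for b, (i, j) in enumerate(pairs)
        if not (full >> b) & 1
    ]
    sel_idx = [loci.index(l) for l in selected]
    hist: dict[int, int] = {}
    for b in range(n_pairs):
        k = sum(1 for idx in sel_idx if (masks[idx] >> b) & 1)
        hist[k] = hist.get(k, 0) + 1
    return CoreSetResult(
        selected=selected,
        newly_resolved=newly,
        cumulative_fraction=cumulative,
        unresolved_pairs=unresolved,
        n_pairs=n_pairs,
        n_resolvable=n_resolvable,
        pair_min_diff_histogram=dict(sorted(hist.items())),
    )


def saturation_curve(
    matrix: GenotypeMatrix, ordered_loci: Sequence[str]
) -> pd.DataFrame:
    """Resolved-pair and distinct-fingerprint counts per locus prefix.

    For each prefix length k of ``ordered_loci``: the number of sample
    pairs differing at >= 1 of the first k loci (missing calls excluded
    from resolution), and the number of distinct k-locus genotype strings
    with missing kept as its own symbol (a printable fingerprint).
    """
    for l in ordered_loci:
        if l not in matrix.loci:
            raise ValidationError(f"locus {l} not in matrix")
    sub = matrix.subset_loci(list(ordered_loci))
    masks, n_pairs = _resolution_masks(sub)
    vals = sub.values()
    rows = [{"k": 0, "resolved_pairs": 0, "distinct_combinations": 1}]
    covered = 0
    for k in range(1, len(ordered_loci) + 1):
        covered |= masks[k - 1]
        combos = {"|".join(row[:k]) for row in vals}
        rows.append(
            {
                "k": k,
                "resolved_pairs": bin(covered).count("1"),
                "distinct_combinations": len(combos),
            }
        )
    return pd.DataFrame(rows).set_index("k")


def pair_guarantee_stats(
    matrix: GenotypeMatrix, snp_set: Sequence[str], k: int = 2
) -> float:
    """Fraction of sample pairs differing at >= k of the selected loci.

    The denominator is restricted to pairs with at least one comparable
    selected locus.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    sub = matrix.subset_loci(list(snp_set))
    vals = sub.values()
    n = sub.n_samples
    num = den = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = (vals[i] != MISSING) & (vals[j] != MISSING)
            if not both.any():
                continue
            den += 1
            if int((both & (vals[i] != vals[j])).sum()) >= k:
                num += 1
    if den == 0:
        raise ValidationError("no comparable pairs for the selected loci")
    return num / den


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_core_lines(
    diff: DiffMatrix,
    meta: Sequence[SampleMeta],
    fraction: float = 0.10,
    group_by: str = "subpopulation",
) -> CoreLineResult:
    """Pick each subpopulation's most central lines.

    Members are ranked by ascending mean pairwise difference count to the
    other members of the same group (ties by sample_id); the top
    max(1, round_half_up(fraction * n)) are selected.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    labels: dict[str, str | None] = {}
    for m in meta:
        v = getattr(m, group_by)
        labels[m.sample_id] = v.value if hasattr(v, "value") else v
    groups: dict[str, list[int]] = {}
    for idx, s in enumerate(diff.sample_ids):
        lab = labels.get(s)
        if lab is None:
            raise ValidationError(f"sample {s} has no {group_by} label")
        groups.setdefault(lab, []).append(idx)
    ranking: dict[str, list[str]] = {}
    selected: dict[str, list[str]] = {}
    for lab in sorted(groups):
        members = groups[lab]
        ids = [diff.sample_ids[i] for i in members]
        if len(members) == 1:
            ranking[lab] = ids
            selected[lab] = ids
            continue
        sub = diff.n_diff[np.ix_(members, members)]
        mean_diff = sub.sum(axis=1) / (len(members) - 1)
        order = sorted(range(len(members)),
                       key=lambda t: (mean_diff[t], ids[t]))
        ranking[lab] = [ids[t] for t in order]
        n_sel = max(1, _round_half_up(fraction * len(members)))
        selected[lab] = ranking[lab][:n_sel]
    return CoreLineResult(ranking=ranking, selected=selected,
                          fraction=fraction)
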