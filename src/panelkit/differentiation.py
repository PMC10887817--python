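"""Population differentiation: pairwise Weir–Cockerham Fst and AMOVA.

Fst uses the Weir & Cockerham (1984) theta estimator: per locus and per
allele the among-population (a), among-individual-within-population (b)
and within-individual (c) variance components are computed from sample
allele frequencies, observed heterozygosities and sample sizes; the
multi-locus estimate is the ratio of sums, theta = sum(a) / sum(a+b+c),
over all loci with defined components.  Values are reported unclamped
(slightly negative estimates near zero differentiation are meaningful).

AMOVA partitions allelic variance across a nested design with four
strata — between populations, between subpopulations within populations,
between samples within subpopulations, within samples — treating each
diploid individual as two allele draws (the within-samples stratum is the
intra-individual, i.e. heterozygosity, variance).  The allele-level
distance is 0/1 per locus mismatch, so every sum of squares reduces to
allele-count algebra: for a group carrying n called alleles with
frequencies p at a locus, SS among its alleles is (n/2)(1 - sum p^2);
hierarchical stratum SS are differences of these within-group sums between
successive partitions.  Variance components are obtained by equating
observed to expected mean squares, with expected-SS coefficients computed
exactly for the (generally unbalanced) nested design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, SampleMeta, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["FstMatrix", "AmovaTable", "wc_theta", "pairwise_fst", "amova"]


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    group_labels: list[str]
    values: np.ndarray  # symmetric, NaN diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_labels,
                            columns=self.group_labels)


def _group_calls(
    matrix: GenotypeMatrix,
    meta: Sequence[SampleMeta],
    group_by: str,
) -> dict[str, GenotypeMatrix]:
    labels: dict[str, str | None] = {}
    for m in meta:
        v = getattr(m, group_by)
        labels[m.sample_id] = v.value if hasattr(v, "value") else v
    groups: dict[str, list[str]] = {}
    for s in matrix.samples:
        lab = labels.get(s)
        if lab is None:
            raise ValidationError(f"sample {s} has no {group_by} label")
        groups.setdefault(lab, []).append(s)
    return {lab: matrix.subset_samples(ids) for lab, ids in groups.items()}


def _locus_components(
    columns: list[pd.Series],
) -> tuple[float, float, float] | None:
    """WC84 a, b, c summed over alleles for one locus across r groups.

    ``columns`` holds each group's genotype codes at the locus.  Returns
    None when the locus is undefined (a group with no calls, average
    sample size <= 1, or monomorphic across all groups).
    """
    r = len(columns)
    n = np.zeros(r)
    freq: list[dict[str, float]] = []
    het: list[dict[str, float]] = []
    alleles: set[str] = set()
    for g, col in enumerate(columns):
        called = col[col != MISSING]
        n[g] = len(called)
        if n[g] == 0:
            return None
        counts: dict[str, int] = {}
        hets: dict[str, int] = {}
        for code in called:
            for ch in code:
                counts[ch] = counts.get(ch, 0) + 1
            if code[0] != code[1]:
                for ch in set(code):
                    hets[ch] = hets.get(ch, 0) + 1
        freq.append({a: c / (2 * n[g]) for a, c in counts.items()})
        het.append({a: h / n[g] for a, h in hets.items()})
        alleles.update(counts)
    if len(alleles) < 2:
        return None
    nbar = n.mean()
    if nbar <= 1:
        return None
    ntot = n.sum()
    nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in sorted(alleles):
        p = np.array([f.get(allele, 0.0) for f in freq])
        h = np.array([hh.get(allele, 0.0) for hh in het])
        pbar = float((n * p).sum() / ntot)
        s2 = float((n * (p - pbar) ** 2).sum() / ((r - 1) * nbar))
        hbar = float((n * h).sum() / ntot)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta(
    matrix: GenotypeMatrix,
    meta: Sequence[SampleMeta],
    group_by: str = "subpopulation",
    groups: Sequence[str] | None = None,
) -> float:
    """Multi-locus Weir–Cockerham theta across the given groups."""
    by_group = _group_calls(matrix, meta, group_by)
    if groups is not None:
        by_group = {g: by_group[g] for g in groups}
    if len(by_group) < 2:
        raise ValidationError("wc_theta needs >= 2 groups")
    for lab, sub in by_group.items():
        if sub.n_samples < 15:
            logger.warning("group %s has only %d samples", lab, sub.n_samples)
    labs = list(by_group)
    a_tot = d_tot = 0.0
    for locus in matrix.loci:
        comp = _locus_components([by_group[l].data[locus] for l in labs])
        if comp is None:
            continue
        a, b, c = comp
        a_tot += a
        d_tot += a + b + c
    if d_tot == 0:
        raise ValidationError("no informative loci for theta")
    return a_tot / d_tot


def pairwise_fst(
    matrix: GenotypeMatrix,
    meta: Sequence[SampleMeta],
    group_by: str = "subpopulation",
) -> FstMatrix:
    """Pairwise multi-locus theta between every pair of groups."""
    by_group = _group_calls(matrix, meta, group_by)
    labels = sorted(by_group)
    if len(labels) < 2:
        raise ValidationError("pairwise_fst needs >= 2 groups")
    k = len(labels)
    vals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            theta = wc_theta(matrix, meta, group_by,
                             groups=[labels[i], labels[j]])
            vals[i, j] = vals[j, i] = theta
    return FstMatrix(labels, vals)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaTable:
    table: pd.DataFrame  # indexed by stratum, incl. Total row
    degenerate: bool = False

    STRATA = (
        "Between populations",
        "Between subpopulations within populations",
        "Between samples within subpopulations",
        "Within samples",
    )


def _ss_within(groups: list[list[int]], enc: np.ndarray) -> float:
    """SS among alleles within each group, summed over groups and loci.

    For a group holding n called alleles with counts c_k at a locus, the
    sum of squared deviations equals the mean pairwise 0/1 distance form
    (1/n) * #differing pairs = (n/2)(1 - sum p_k^2); this depends only on
    the allele counts, so no haplotype-phase assignment is needed.
    """
    total = 0.0
    for members in groups:
        counts = enc[members].sum(axis=0).astype(float)  # loci x alleles
        n_alleles = counts.sum(axis=1)  # called alleles per locus
        ok = n_alleles > 0
        sum_p2 = np.ones_like(n_alleles)
        sum_p2[ok] = (counts[ok] ** 2).sum(axis=1) / n_alleles[ok] ** 2
        total += float(np.sum(n_alleles[ok] / 2 * (1 - sum_p2[ok])))
    return total


def _encode_allele_counts(matrix: GenotypeMatrix) -> np.ndarray:
    """samples x loci x alleles array of per-genotype allele counts
    (all zero for missing calls)."""
    vals = matrix.values()
    n, L = vals.shape
    per_locus = [sorted({ch for c in vals[:, j] if c != MISSING
                         for ch in c}) for j in range(L)]
    width = max((len(a) for a in per_locus), default=1) or 1
    enc = np.zeros((n, L, width), dtype=np.int16)
    for j in range(L):
        idx = {a: k for k, a in enumerate(per_locus[j])}
        for i in range(n):
            c = vals[i, j]
            if c == MISSING:
                continue
            enc[i, j, idx[c[0]]] += 1
            enc[i, j, idx[c[1]]] += 1
    return enc


def _f_coeff(partition: list[list[int]], clusters: list[list[int]]) -> float:
    """Expected-SS coefficient of one variance component for SS within the
    groups of ``partition``.

    Both arguments list individual indices; each individual contributes two
    allele units.  For clusters nested within (or equal to) the partition
    groups the coefficient is A - sum_g (sum_{C in g} n_C^2)/n_g with sizes
    in allele units; when the partition is instead nested within the
    clusters, group means absorb the cluster effect and the coefficient
    is 0.
    """
    a_total = 2 * sum(len(g) for g in partition)
    acc = 0.0
    for members in partition:
        n_g = 2 * len(members)
        gset = set(members)
        for cl in clusters:
            inter = gset.intersection(cl)
            if not inter:
                continue
            if len(inter) != len(cl):  # cluster coarser than the partition
                return 0.0
            acc += (2 * len(cl)) ** 2 / n_g
    return a_total - acc


def amova(
    matrix: GenotypeMatrix,
    meta: Sequence[SampleMeta],
) -> AmovaTable:
    """Hierarchical AMOVA over populations / subpopulations / samples.

    Missing calls are excluded per locus from the sums of squares; the
    design coefficients use the full sample sizes.  Negative variance
    components are retained as estimated.
    """
    by_id = {m.sample_id: m for m in meta}
    samples = matrix.samples
    for s in samples:
        m = by_id.get(s)
        if m is None or m.population is None or m.subpopulation is None:
            raise ValidationError(
                f"sample {s} lacks population/subpopulation labels"
            )
    n = len(samples)
    pops = sorted({by_id[s].population for s in samples})
    subs = sorted({(by_id[s].population, by_id[s].subpopulation)
                   for s in samples})
    pop_groups = [[i for i, s in enumerate(samples)
                   if by_id[s].population == p] for p in pops]
    sub_groups = [[i for i, s in enumerate(samples)
                   if (by_id[s].population, by_id[s].subpopulation) == ps]
                  for ps in subs]
    ind_groups = [[i] for i in range(n)]
    total_group = [list(range(n))]

    enc = _encode_allele_counts(matrix)
    ss_w = {
        "total": _ss_within(total_group, enc),
        "pop": _ss_within(pop_groups, enc),
        "sub": _ss_within(sub_groups, enc),
        "ind": _ss_within(ind_groups, enc),
    }
    ss = np.array([
        ss_w["total"] - ss_w["pop"],   # between populations
        ss_w["pop"] - ss_w["sub"],     # between subpops within pops
        ss_w["sub"] - ss_w["ind"],     # between samples within subpops
        ss_w["ind"],                   # within samples
    ])
    df = np.array([
        len(pops) - 1,
        len(subs) - len(pops),
        n - len(subs),
        n,
    ], dtype=float)

    # Expected-SS coefficients: rows follow the strata, columns the
    # variance components (population, subpopulation, sample, within).
    # For a partition P, E[SS_within(P)] = sum_v sigma_v^2 * f(P, v); the
    # unit-level (within-sample) coefficient is A - #groups since each
    # allele is its own cluster (sum_{C in g} n_C^2 = n_g).
    partitions = [total_group, pop_groups, sub_groups, ind_groups]

    def coeff_row(partition):
        row = np.zeros(4)
        for level, cl in enumerate((pop_groups, sub_groups, ind_groups)):
            row[level] = _f_coeff(partition, cl)
        row[3] = 2 * n - len(partition)
        return row

    rows = [coeff_row(p) for p in partitions]
    coeff = np.array([
        rows[0] - rows[1],
        rows[1] - rows[2],
        rows[2] - rows[3],
        rows[3],
    ])

    if float(ss.sum()) == 0.0:
        table = pd.DataFrame(
            {
                "df": np.append(df, df.sum()),
                "sum_sq": np.zeros(5),
                "mean_sq": np.full(5, np.nan),
                "variance_component": np.zeros(5),
                "pct_variation": np.full(5, np.nan),
            },
            index=list(AmovaTable.STRATA) + ["Total"],
        )
        return AmovaTable(table, degenerate=True)

    keep = df > 0
    sigma = np.zeros(4)
    sigma[keep] = np.linalg.solve(coeff[np.ix_(keep, keep)], ss[keep])
    if np.any(sigma < 0):
        logger.info("negative AMOVA variance component retained as estimated")
    total_var = sigma.sum()
    pct = sigma / total_var * 100 if total_var > 0 else np.full(4, np.nan)
    ms = np.where(df > 0, ss / np.maximum(df, 1), np.nan)
    table = pd.DataFrame(
        {
            "df": np.append(df, df.sum()),
            "sum_sq": np.append(ss, ss.sum()),
            "mean_sq": np.append(ms, ss.sum() / df.sum()),
            "variance_component": np.append(sigma, total_var),
            "pct_variation": np.append(pct, np.nansum(pct)),
        },
        index=list(AmovaTable.STRATA) + ["Total"],
    )
    return AmovaTable(table, degenerate=False)
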