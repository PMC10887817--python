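"""Pairwise genotype differences, neighbor-joining trees and PCA.

The pairwise comparison counts, for every pair of samples, the loci where
both calls are present and the (unordered) genotypes differ; missing calls
are null and excluded from both the difference and the comparable count.
The NJ tree is built on the normalised proportion d = n_diff/n_comparable,
which removes the bias that unequal comparable-locus counts would otherwise
introduce.  Note this proportion is a per-pair Hamming fraction over
per-pair locus sets: when comparable sets differ between pairs it need not
satisfy the triangle inequality, which NJ does not require.

PCA codes biallelic loci as panel-wide-minor-allele dosage (0/1/2),
multi-allelic loci one-hot by per-allele dosage, mean-imputes missing
cells per locus, centres columns, and eigendecomposes via SVD.  Component
signs are fixed so each component's largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, ValidationError

__all__ = [
    "DiffMatrix", "TreeResult", "PCAResult",
    "pairwise_diff", "normalized_distance", "nj_tree", "code_and_pca",
]


@dataclass
class DiffMatrix:
    sample_ids: list[str]
    n_diff: np.ndarray        # symmetric int, zero diagonal
    n_comparable: np.ndarray  # symmetric int

    def to_frame(self, which: str = "n_diff") -> pd.DataFrame:
        arr = getattr(self, which)
        return pd.DataFrame(arr, index=self.sample_ids,
                            columns=self.sample_ids)

    def mean_diff_to_others(self) -> pd.Series:
        """Per sample, mean n_diff to every other sample."""
        n = len(self.sample_ids)
        if n < 2:
            raise ValidationError("need >= 2 samples")
        sums = self.n_diff.sum(axis=1)  # diagonal is 0
        return pd.Series(sums / (n - 1), index=self.sample_ids)


@dataclass
class TreeResult:
    newick: str
    leaf_labels: list[str]


@dataclass
class PCAResult:
    sample_ids: list[str]
    coordinates: np.ndarray        # samples x components
    explained_variance: np.ndarray  # fractions, sum <= 1


def _encode_columns(matrix: GenotypeMatrix) -> np.ndarray:
    """Integer-encode genotype codes per locus; missing -> -1."""
    vals = matrix.values()
    out = np.empty(vals.shape, dtype=np.int32)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        codes, inv = np.unique(col, return_inverse=True)
        enc = inv.astype(np.int32)
        miss = np.flatnonzero(codes == MISSING)
        if miss.size:
            enc[enc == miss[0]] = -1
        out[:, j] = enc
    return out


def pairwise_diff(matrix: GenotypeMatrix) -> DiffMatrix:
    """Count differing genotypes and comparable loci for every sample pair."""
    if matrix.n_samples < 2:
        raise ValidationError("pairwise_diff needs >= 2 samples")
    enc = _encode_columns(matrix)
    n = enc.shape[0]
    present = enc >= 0
    n_diff = np.zeros((n, n), dtype=np.int64)
    n_comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = present[i] & present[i + 1:]
        diff = both & (enc[i] != enc[i + 1:])
        n_comp[i, i + 1:] = both.sum(axis=1)
        n_diff[i, i + 1:] = diff.sum(axis=1)
    n_diff += n_diff.T
    n_comp += n_comp.T
    np.fill_diagonal(n_comp, matrix.n_loci)
    return DiffMatrix(matrix.samples, n_diff, n_comp)


def normalized_distance(diff: DiffMatrix) -> np.ndarray:
    """Proportion of comparable loci that differ, per pair, in [0, 1]."""
    n = len(diff.sample_ids)
    comp = diff.n_comparable.astype(float)
    off = ~np.eye(n, dtype=bool)
    if np.any(comp[off] == 0):
        i, j = np.argwhere((comp == 0) & off)[0]
        raise ValidationError(
            f"no comparable loci between {diff.sample_ids[i]} and "
            f"{diff.sample_ids[j]}"
        )
    d = np.zeros((n, n))
    d[off] = diff.n_diff[off] / comp[off]
    return d


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(distances: np.ndarray, labels: list[str]) -> TreeResult:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimising Q is joined at each step; exact ties are broken by
    the lexicographic order of the joined subtrees' smallest leaf labels.
    Negative branch lengths are clamped to 0 with the deficit moved onto
    the sister edge, preserving the pair's summed length.  The result is
    the standard unrooted tree, written with a trifurcating root.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValidationError("nj_tree needs >= 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("distance matrix must be square symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValidationError("distance matrix diagonal must be zero")
    if len(labels) != n:
        raise ValidationError("labels must match matrix size")

    newicks = [_escape(l) for l in labels]
    minleaf = list(labels)  # smallest leaf label per active node (tie rule)
    active = list(range(n))
    d = d.copy()

    def clamp(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        return max(bi, 0.0), max(bj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b],
                       *sorted((minleaf[active[a]], minleaf[active[b]])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        bi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        bj = dij - bi
        bi, bj = clamp(bi, bj)
        # distances from the new node u to every other active node
        du = {}
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            du[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        # reuse slot i for the merged node
        first, second = sorted(
            [(minleaf[i], newicks[i], bi), (minleaf[j], newicks[j], bj)]
        )
        newicks[i] = (f"({first[1]}:{first[2]:.10g},"
                      f"{second[1]}:{second[2]:.10g})")
        minleaf[i] = first[0]
        for k, v in du.items():
            d[i, k] = d[k, i] = max(v, 0.0)
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final star
    bi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    parts = sorted(
        [(minleaf[i], newicks[i], max(bi, 0.0)),
         (minleaf[j], newicks[j], max(bj, 0.0)),
         (minleaf[k], newicks[k], max(bk, 0.0))]
    )
    newick = ("(" + ",".join(f"{p[1]}:{p[2]:.10g}" for p in parts) + ");")
    return TreeResult(newick=newick, leaf_labels=list(labels))


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Genotype coding and PCA
# ---------------------------------------------------------------------------

def code_dosage(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Numeric coding of the genotype matrix for PCA.

    Biallelic locus -> one column counting the panel-wide minor allele
    (0/1/2).  Multi-allelic locus -> one column per allele.  Missing calls
    become NaN (mean-imputed downstream); monomorphic loci yield a single
    constant column.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    from .diversity_stats import allele_freqs  # local import avoids a cycle

    for locus in matrix.loci:
        freqs, _ = allele_freqs(matrix, locus)
        alleles = sorted(freqs, key=lambda a: (freqs[a], a))
        col = matrix.data[locus]
        if len(alleles) <= 2:
            counted = alleles[0] if alleles else "A"  # minor allele
            vals = np.array(
                [np.nan if c == MISSING else float(c.count(counted))
                 for c in col]
            )
            cols.append(vals)
            names.append(locus)
        else:
            for a in alleles:
                vals = np.array(
                    [np.nan if c == MISSING else float(c.count(a))
                     for c in col]
                )
                cols.append(vals)
                names.append(f"{locus}:{a}")
    return np.column_stack(cols), names


def code_and_pca(matrix: GenotypeMatrix, n_components: int = 3) -> PCAResult:
    """Principal component analysis of dosage-coded genotypes."""
    if matrix.n_samples < 2 or matrix.n_loci < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 loci")
    x, _ = code_dosage(matrix)
    col_means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    inds = np.where(np.isnan(x))
    x[inds] = col_means[inds[1]]
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    var = s**2
    total = var.sum()
    evr = (var[:k] / total) if total > 0 else np.zeros(k)
    coords = u[:, :k] * s[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(k):
        if s[c] == 0:
            continue
        idx = int(np.argmax(np.abs(vt[c])))
        if vt[c, idx] < 0:
            coords[:, c] = -coords[:, c]
    return PCAResult(matrix.samples, coords, np.asarray(evr))
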