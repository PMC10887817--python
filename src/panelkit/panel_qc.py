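"""Perfect-SNP panel quality control.

A candidate locus enters the final panel only if it passes five filters,
with strict comparisons exactly as stated by each criterion:

1. minor allele frequency  > ``min_maf``   (default 0.4);
2. missing rate            < ``max_missing`` (default 0.2);
3. observed heterozygosity < ``max_het``   (default 0.2);
4. no other known variant within ``flank_bp`` (default 100 bp, boundary
   inclusive: a neighbour at exactly 100 bp fails) on either side — clean
   flanks are what make a locus amenable to robust multiplex amplicon
   primers;
5. exactly two alleles observed.

MAF here is computed from genotype calls (two allele observations per
non-missing diploid call); missing rate is over all samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .io_formats import GenotypeMatrix, ValidationError, VariantCatalog
from .diversity_stats import allele_freqs, ho

logger = logging.getLogger(__name__)

__all__ = ["PanelCriteria", "LocusQC", "locus_qc", "apply_panel_filter",
           "panel_spacing"]


@dataclass(frozen=True)
class PanelCriteria:
    min_maf: float = 0.4
    max_missing: float = 0.2
    max_het: float = 0.2
    flank_bp: int = 100
    required_allele_count: int = 2

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_missing", "max_het"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.flank_bp < 0:
            raise ValidationError("flank_bp must be >= 0")


@dataclass
class LocusQC:
    locus_id: str
    maf: float
    missing_rate: float
    het_rate: float
    n_alleles: int
    flank_clean: bool
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failure_reasons


def _flank_clean(
    catalog: VariantCatalog, locus_id: str, flank_bp: int
) -> bool:
    loc = catalog[locus_id]
    positions = catalog.neighbor_positions.get(loc.chromosome)
    if positions is None or len(positions) == 0:
        return True
    lo = np.searchsorted(positions, loc.position - flank_bp, side="left")
    hi = np.searchsorted(positions, loc.position + flank_bp, side="right")
    in_window = positions[lo:hi]
    # the locus itself does not count as its own neighbour
    return len(in_window[in_window != loc.position]) == 0


def locus_qc(
    matrix: GenotypeMatrix,
    catalog: VariantCatalog,
    criteria: PanelCriteria = PanelCriteria(),
) -> list[LocusQC]:
    """Evaluate the five panel filters for every locus of the matrix.

    Raises if a matrix locus is absent from the catalog (the flank filter
    is then undefined).
    """
    out: list[LocusQC] = []
    n_samples = matrix.n_samples
    for locus in matrix.loci:
        if locus not in catalog:
            raise ValidationError(f"locus {locus} missing from catalog")
        freqs, n_called = allele_freqs(matrix, locus)
        ordered = sorted(freqs.values(), reverse=True)
        maf = ordered[1] if len(ordered) > 1 else 0.0
        missing_rate = 1.0 - (n_called / n_samples) if n_samples else 1.0
        het_rate = ho(matrix, locus) if n_called else 0.0
        n_alleles = len(freqs)
        clean = _flank_clean(catalog, locus, criteria.flank_bp)
        reasons = []
        if not maf > criteria.min_maf:
            reasons.append("maf")
        if not missing_rate < criteria.max_missing:
            reasons.append("missing")
        if not het_rate < criteria.max_het:
            reasons.append("het")
        if not clean:
            reasons.append("flank")
        if n_alleles != criteria.required_allele_count:
            reasons.append("n_alleles")
        out.append(
            LocusQC(locus, maf, missing_rate, het_rate, n_alleles, clean,
                    reasons)
        )
    return out


def apply_panel_filter(
    matrix: GenotypeMatrix, qc: list[LocusQC]
) -> GenotypeMatrix:
    """Restrict the matrix to QC-passed loci, preserving locus order."""
    status = {q.locus_id: q.passed for q in qc}
    missing = [l for l in matrix.loci if l not in status]
    if missing:
        raise ValidationError(f"QC does not cover loci: {missing[:5]}")
    keep = [l for l in matrix.loci if status[l]]
    if not keep:
        logger.warning("no locus passed panel QC; returning empty panel")
    return matrix.subset_loci(keep)


def panel_spacing(catalog: VariantCatalog) -> dict:
    """Per-chromosome marker counts and mean adjacent-marker distances.

    The global mean is over all adjacent pairs pooled across chromosomes;
    chromosomes with a single marker contribute no pairs and report a
    spacing of None.
    """
    by_chrom: dict[str, list[int]] = {}
    for loc in catalog.loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc.position)
    per_chrom = {}
    all_gaps: list[int] = []
    for chrom, positions in sorted(by_chrom.items()):
        positions = sorted(positions)
        gaps = list(np.diff(positions))
        per_chrom[chrom] = {
            "count": len(positions),
            "mean_distance": float(np.mean(gaps)) if gaps else None,
        }
        all_gaps.extend(int(g) for g in gaps)
    return {
        "per_chromosome": per_chrom,
        "mean_distance": float(np.mean(all_gaps)) if all_gaps else None,
        "n_markers": len(catalog.loci),
    }
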