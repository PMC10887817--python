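"""Diploid genotype calling from per-allele read counts.

Targeted amplicon panels sequence each locus to very high depth (around
1000x in the regime this toolkit targets), so genotypes are called directly
from allele read frequencies rather than from base-quality likelihoods.
The rule: alleles with the highest and second-highest read counts are the
major and minor alleles; a locus is homozygous when the major-allele read
frequency exceeds ``hom_major_freq`` (default 0.7), and heterozygous when
both major and minor frequencies exceed ``het_min_freq`` (default 0.35).
Count patterns satisfying neither rule (e.g. major 0.65, minor 0.30) fall
in an ambiguous zone and are reported missing rather than guessed, as is
anything below the configurable depth floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import (
    MISSING,
    AlleleCountsTable,
    GenotypeMatrix,
    ValidationError,
)

__all__ = ["CallThresholds", "GenotypeCall", "call_genotype", "call_matrix"]


@dataclass(frozen=True)
class CallThresholds:
    """Frequency thresholds and depth floor for read-count genotype calls.

    ``hom_major_freq``
        a call is homozygous when major-allele frequency strictly exceeds
        this (default 0.7);
    ``het_min_freq``
        a call is heterozygous when both top-two allele frequencies strictly
        exceed this (default 0.35);
    ``min_depth``
        total-read floor below which the call is missing (default 20; the
        high-depth regime makes this a formality, but amplicon dropout
        happens).
    """

    hom_major_freq: float = 0.7
    het_min_freq: float = 0.35
    min_depth: int = 20

    def __post_init__(self) -> None:
        if not (0.5 < self.hom_major_freq <= 1.0):
            raise ValidationError("hom_major_freq must be in (0.5, 1]")
        if not (0.0 < self.het_min_freq <= 0.5):
            raise ValidationError("het_min_freq must be in (0, 0.5]")
        if self.min_depth < 0:
            raise ValidationError("min_depth must be >= 0")


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call: an unordered allele pair or missing, plus depth."""

    alleles: tuple[str, str] | None
    depth: int

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def code(self) -> str:
        if self.alleles is None:
            return MISSING
        a, b = sorted(self.alleles)
        return a + b


def call_genotype(
    counts: dict[str, int], thresholds: CallThresholds = CallThresholds()
) -> GenotypeCall:
    """Call one (sample, locus) genotype from its allele read counts.

    Frequencies are computed over all observed alleles, not just the top
    two, so contamination or a stray third allele depresses both the major
    and minor frequencies and pushes borderline calls to missing.  Ties in
    the top-two ranking are broken alphabetically; the heterozygous call is
    an unordered pair, so the tie rule only affects labelling.
    """
    for allele, c in counts.items():
        if c < 0:
            raise ValidationError(f"negative count for allele {allele!r}")
    total = sum(counts.values())
    if total < thresholds.min_depth or total == 0:
        return GenotypeCall(None, total)
    # sort by (-count, allele): deterministic major/minor labelling
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    major, major_n = ranked[0]
    major_freq = major_n / total
    if major_freq > thresholds.hom_major_freq:
        return GenotypeCall((major, major), total)
    if len(ranked) > 1:
        minor, minor_n = ranked[1]
        minor_freq = minor_n / total
        if (major_freq > thresholds.het_min_freq
                and minor_freq > thresholds.het_min_freq):
            a, b = sorted((major, minor))
            return GenotypeCall((a, b), total)
    return GenotypeCall(None, total)


def call_matrix(
    table: AlleleCountsTable,
    thresholds: CallThresholds = CallThresholds(),
) -> GenotypeMatrix:
    """Call every (sample, locus) record of a read-count table.

    The output grid covers all samples x all loci seen anywhere in the
    table; loci with no record for a sample are missing for that sample.
    """
    samples = table.samples
    loci = table.loci
    grid = pd.DataFrame(
        MISSING, index=pd.Index(samples, name="sample_id"), columns=loci,
        dtype=str,
    )
    for (sample, locus), counts in table.iter_records():
        grid.loc[sample, locus] = call_genotype(counts, thresholds).code
    return GenotypeMatrix(grid)
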