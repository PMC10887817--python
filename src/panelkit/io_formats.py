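"""External representations of the pipeline's objects.

Formats handled here:

* per-allele read-count TSV (``sample_id  locus_id  allele  read_count``),
  the raw output of a targeted amplicon-sequencing genotyping run;
* fingerprint CSV — a samples x loci matrix of two-letter genotype codes
  (``AA``, ``AG``, missing ``--``), the marker-fingerprint convention;
* multi-sample VCF 4.x (import via cyvcf2, export as plain text);
* sample-metadata TSV (species / population / subpopulation / fruit shape);
* variant-catalog TSV (panel locus positions) plus an optional genome-wide
  variant-position TSV used for flanking-region QC;
* newick trees and a JSON run manifest.

Coordinates are 1-based inclusive throughout (VCF convention).  Genotypes
are unordered allele pairs: heterozygote codes are normalised to sorted
allele order on ingest (``GA`` == ``AG``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "--"
VALID_ALLELES = frozenset("ACGT")


class ParseError(ValueError):
    """Malformed input file (carries the offending line where known)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class LocusRole(str, Enum):
    BACKGROUND = "background"
    FOREGROUND = "foreground"


class FruitShape(str, Enum):
    BLOCKY = "blocky"
    WIDE_HORN = "wide_horn"
    NARROW_HORN = "narrow_horn"
    LINEAR = "linear"
    OTHER = "other"


@dataclass(frozen=True)
class LocusDef:
    """A panel locus: position, reference/alternate alleles and its role.

    ``role`` distinguishes background (diversity) markers from foreground
    trait markers; it is annotation only and never filters computations.
    """

    locus_id: str
    chromosome: str
    position: int  # 1-based bp
    ref_allele: str
    alt_alleles: tuple[str, ...]
    role: LocusRole = LocusRole.BACKGROUND

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"{self.locus_id}: position must be >= 1")
        alleles = (self.ref_allele, *self.alt_alleles)
        if len(set(alleles)) != len(alleles):
            raise ValidationError(f"{self.locus_id}: alleles must be distinct")
        for a in alleles:
            if a not in VALID_ALLELES:
                raise ValidationError(f"{self.locus_id}: bad allele {a!r}")


@dataclass
class VariantCatalog:
    """Panel loci plus, per chromosome, sorted positions of all known
    variants (panel candidates and everything else) for flank checks."""

    loci: list[LocusDef]
    neighbor_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_pos: set[tuple[str, int]] = set()
        for loc in self.loci:
            if loc.locus_id in seen_ids:
                raise ValidationError(f"duplicate locus_id {loc.locus_id}")
            key = (loc.chromosome, loc.position)
            if key in seen_pos:
                raise ValidationError(f"duplicate position {key}")
            seen_ids.add(loc.locus_id)
            seen_pos.add(key)
        self.loci = sorted(self.loci, key=lambda l: (l.chromosome, l.position))
        self.neighbor_positions = {
            c: np.unique(np.asarray(p, dtype=np.int64))
            for c, p in self.neighbor_positions.items()
        }

    def __getitem__(self, locus_id: str) -> LocusDef:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    def __contains__(self, locus_id: str) -> bool:
        return any(l.locus_id == locus_id for l in self.loci)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    species: str = ""
    population: str | None = None
    subpopulation: str | None = None
    fruit_shape: FruitShape | None = None

    def __post_init__(self) -> None:
        if self.subpopulation is not None and self.population is None:
            raise ValidationError(
                f"{self.sample_id}: subpopulation given without population"
            )


def normalize_code(code: str) -> str:
    """Normalise a two-letter genotype code to sorted allele order.

    ``"GA"`` -> ``"AG"``; the missing code passes through unchanged.
    """
    if code == MISSING:
        return MISSING
    if len(code) != 2 or any(ch not in VALID_ALLELES for ch in code):
        raise ValidationError(f"invalid genotype code {code!r}")
    a, b = sorted(code)
    return a + b


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid genotype calls — the pipeline's central object.

    Cells hold normalised two-letter codes or ``"--"``.  Sample and locus
    order are meaningful and preserved by every operation.
    """

    data: pd.DataFrame  # index: sample_id, columns: locus_id, dtype: str

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate locus ids")
        norm = self.data.map(normalize_code)
        self.data = norm.astype(str)

    # -- basic accessors ----------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    @property
    def n_loci(self) -> int:
        return len(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype="U2")

    def alleles_at(self, locus_id: str) -> list[str]:
        """Distinct alleles observed in non-missing calls, sorted."""
        col = self.data[locus_id]
        alleles: set[str] = set()
        for code in col:
            if code != MISSING:
                alleles.update(code)
        return sorted(alleles)

    def allele_dict(self) -> dict[str, list[str]]:
        return {l: self.alleles_at(l) for l in self.loci}

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data.loc[list(sample_ids)].copy())

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data[list(locus_ids)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.data.equals(other.data)


# ---------------------------------------------------------------------------
# Read-count tables
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountsTable:
    """Per (sample, locus) read counts for each observed allele."""

    df: pd.DataFrame  # columns: sample_id, locus_id, allele, read_count

    def __post_init__(self) -> None:
        required = ["sample_id", "locus_id", "allele", "read_count"]
        if list(self.df.columns)[:4] != required:
            raise ValidationError(f"counts table must have columns {required}")
        if (self.df["read_count"] < 0).any():
            bad = self.df[self.df["read_count"] < 0].iloc[0]
            raise ValidationError(
                f"negative read_count for ({bad.sample_id}, {bad.locus_id}, "
                f"{bad.allele})"
            )
        if self.df.duplicated(["sample_id", "locus_id", "allele"]).any():
            bad = self.df[
                self.df.duplicated(["sample_id", "locus_id", "allele"])
            ].iloc[0]
            raise ValidationError(
                f"duplicate row for ({bad.sample_id}, {bad.locus_id}, "
                f"{bad.allele})"
            )

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.df["locus_id"]))

    def n_records(self) -> int:
        return len(self.df.groupby(["sample_id", "locus_id"], sort=False))

    def counts_for(self, sample_id: str, locus_id: str) -> dict[str, int]:
        sub = self.df[
            (self.df["sample_id"] == sample_id)
            & (self.df["locus_id"] == locus_id)
        ]
        return dict(zip(sub["allele"], sub["read_count"].astype(int)))

    def iter_records(self):
        """Yield ((sample_id, locus_id), {allele: count})."""
        for key, grp in self.df.groupby(["sample_id", "locus_id"], sort=False):
            yield key, dict(zip(grp["allele"], grp["read_count"].astype(int)))


def read_counts_table(path: str | Path) -> AlleleCountsTable:
    """Read a per-allele read-count TSV.

    Absent alleles are implicitly count 0 (a record only lists observed
    alleles).  Duplicate (sample, locus, allele) rows are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"sample_id": str, "locus_id": str, "allele": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse counts TSV: {exc}") from exc
    required = ["sample_id", "locus_id", "allele", "read_count"]
    if list(df.columns)[: len(required)] != required:
        raise ParseError(f"{path}: expected columns {required}")
    counts = pd.to_numeric(df["read_count"], errors="coerce")
    if counts.isna().any() or (counts % 1 != 0).any():
        # +2: 1-based line numbers, plus the header line
        line = int(np.flatnonzero(counts.isna() | (counts % 1 != 0))[0]) + 2
        raise ParseError(f"{path}: line {line}: read_count is not an integer")
    df["read_count"] = counts.astype(np.int64)
    for a in df["allele"]:
        if a not in VALID_ALLELES:
            raise ParseError(f"{path}: invalid allele {a!r}")
    return AlleleCountsTable(df[required].copy())


def write_counts_table(table: AlleleCountsTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fingerprint matrices
# ---------------------------------------------------------------------------

def read_fingerprint_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a fingerprint CSV (first column sample_id, one column per locus,
    two-letter genotype codes, missing ``--``)."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: fingerprint CSV needs sample_id + loci")
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return GenotypeMatrix(df)


def write_fingerprint_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def import_vcf(path: str | Path) -> GenotypeMatrix:
    """Import genotype calls from a multi-sample VCF (plain or bgzipped).

    ``./.`` becomes missing; phased separators are treated as unphased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    columns: list[list[str]] = []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        locus_id = var.ID if var.ID not in (None, ".") else (
            f"{var.CHROM}_{var.POS}"
        )
        col = []
        for gt in var.genotypes:
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col.append(MISSING)
            else:
                col.append(normalize_code(alleles[a] + alleles[b]))
        loci.append(locus_id)
        columns.append(col)
    vcf.close()
    data = pd.DataFrame(
        dict(zip(loci, columns)), index=pd.Index(samples, name="sample_id")
    )
    if not loci:
        raise ParseError(f"{path}: VCF contains no variant records")
    return GenotypeMatrix(data)


def export_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    catalog: VariantCatalog | None = None,
) -> None:
    """Write the matrix as a minimal VCF 4.2 text file.

    With a catalog, CHROM/POS/REF come from it; otherwise loci are placed on
    a synthetic chromosome at consecutive positions with the alphabetically
    first observed allele as REF.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    vals = matrix.values()
    for j, locus in enumerate(matrix.loci):
        observed = matrix.alleles_at(locus)
        if catalog is not None and locus in catalog:
            loc = catalog[locus]
            chrom, pos, ref = loc.chromosome, loc.position, loc.ref_allele
            alts = list(dict.fromkeys(list(loc.alt_alleles)
                                      + [a for a in observed if a != ref]))
        else:
            chrom, pos = "chrUn", j + 1
            ref = observed[0] if observed else "A"
            alts = [a for a in observed if a != ref]
        alleles = [ref] + alts
        idx = {a: i for i, a in enumerate(alleles)}
        gts = []
        for code in vals[:, j]:
            if code == MISSING:
                gts.append("./.")
            else:
                gts.append(f"{idx[code[0]]}/{idx[code[1]]}")
        alt_field = ",".join(alts) if alts else "."
        lines.append(
            f"{chrom}\t{pos}\t{locus}\t{ref}\t{alt_field}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Metadata and catalogs
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata TSV needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id in metadata")
    out = []
    for _, row in df.iterrows():
        shape = row.get("fruit_shape", "")
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                species=row.get("species", ""),
                population=row.get("population") or None,
                subpopulation=row.get("subpopulation") or None,
                fruit_shape=FruitShape(shape) if shape else None,
            )
        )
    return out


def write_metadata(meta: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "species": m.species,
            "population": m.population or "",
            "subpopulation": m.subpopulation or "",
            "fruit_shape": m.fruit_shape.value if m.fruit_shape else "",
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(
    path: str | Path, variants_path: str | Path | None = None
) -> VariantCatalog:
    """Read a panel-catalog TSV (locus_id, chromosome, position, ref_allele,
    alt_alleles comma-separated, role) plus an optional genome-wide variant
    position TSV (chromosome, position) for the flank check.

    When no variant file is given, neighbor positions default to the panel
    loci themselves.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    loci = [
        LocusDef(
            locus_id=r["locus_id"],
            chromosome=r["chromosome"],
            position=int(r["position"]),
            ref_allele=r["ref_allele"],
            alt_alleles=tuple(a for a in r["alt_alleles"].split(",") if a),
            role=LocusRole(r.get("role") or "background"),
        )
        for _, r in df.iterrows()
    ]
    neighbors: dict[str, list[int]] = {}
    if variants_path is not None:
        vdf = pd.read_csv(Path(variants_path), sep="\t", dtype=str)
        for _, r in vdf.iterrows():
            neighbors.setdefault(r["chromosome"], []).append(int(r["position"]))
    else:
        for loc in loci:
            neighbors.setdefault(loc.chromosome, []).append(loc.position)
    return VariantCatalog(
        loci=loci,
        neighbor_positions={c: np.array(p) for c, p in neighbors.items()},
    )


def write_catalog(catalog: VariantCatalog, path: str | Path) -> None:
    rows = [
        {
            "locus_id": l.locus_id,
            "chromosome": l.chromosome,
            "position": l.position,
            "ref_allele": l.ref_allele,
            "alt_alleles": ",".join(l.alt_alleles),
            "role": l.role.value,
        }
        for l in catalog.loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_variant_positions(catalog: VariantCatalog, path: str | Path) -> None:
    rows = [
        {"chromosome": c, "position": int(p)}
        for c, arr in sorted(catalog.neighbor_positions.items())
        for p in arr
    ]
    pd.DataFrame(rows, columns=["chromosome", "position"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Results export
# ---------------------------------------------------------------------------

def write_newick(newick: str, path: str | Path) -> None:
    if not newick.endswith(";"):
        newick += ";"
    Path(path).write_text(newick + "\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def export_results(tables: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write named result objects into ``out_dir`` with deterministic layouts.

    DataFrames -> ``<name>.csv``; newick strings (keys ending ``_tree``) ->
    ``<name>.nwk``; anything JSON-serialisable -> ``<name>.json``.
    Returns the written paths in deterministic (sorted-name) order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        obj = tables[name]
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p)
        elif isinstance(obj, str) and name.endswith("_tree"):
            p = out_dir / f"{name}.nwk"
            write_newick(obj, p)
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                    default=_json_default) + "\n")
        written.append(p)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
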