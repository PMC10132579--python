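"""Readers and writers for the genotype and phenotype formats the pipeline touches.

Two genotype codings are supported:

* ``PHASED_VCF`` — diploid genotype call strings (``"0|0"``, ``"1|1"``,
  ``".|."``; unphased ``/`` separators are accepted everywhere) read from a
  VCF whose records carry a structural-variant type (``SVTYPE`` INFO key or a
  symbolic ALT such as ``<INV>``).
* ``INTEGER_CODED`` — marker matrices coded 1 / 0 / −1 (homozygous reference,
  heterozygous, homozygous alternate) as distributed for transposable-element
  and SNP panels.

Call strings are preserved verbatim on read; all interpretation (one-hot
encoding, dosage conversion) happens downstream. Marker order is file order
throughout — no re-sorting by coordinate is ever applied, because downstream
consumers are order-sensitive and file order is reproducible.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "Coding",
    "VariantRecord",
    "RawGenotypeTable",
    "PhenotypeTable",
    "AlignedDataset",
    "VCFParseError",
    "read_sv_vcf",
    "read_integer_coded_table",
    "read_phenotype_table",
    "align_dataset",
    "subsample_markers",
]

#: Spellings that mean "missing" in integer-coded tables.
MISSING_TOKENS = {"", "NA", ".", "NaN", "nan"}


class VariantClass(str, enum.Enum):
    INV = "INV"
    DUP = "DUP"
    DEL = "DEL"
    SNP = "SNP"
    INDEL = "INDEL"
    TE = "TE"


class Coding(str, enum.Enum):
    PHASED_VCF = "PHASED_VCF"
    INTEGER_CODED = "INTEGER_CODED"


class VCFParseError(ValueError):
    """Malformed VCF content; the message names the offending line number."""


@dataclass
class VariantRecord:
    """One marker: identity, locus, variant class and the per-accession calls."""

    marker_id: str
    chrom: str
    pos: int  # 1-based, as read from the VCF
    variant_class: VariantClass
    calls: dict[str, str]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class RawGenotypeTable:
    """Accession x marker call matrix with a coding tag.

    ``calls`` is a DataFrame indexed by accession with one column per marker:
    genotype strings for ``PHASED_VCF``, floats in {1, 0, -1, NaN} for
    ``INTEGER_CODED``. ``chrom`` / ``pos`` / ``variant_classes`` are
    per-marker metadata (``None`` for coded tables, which carry neither
    coordinates nor SV types).
    """

    accessions: list[str]
    marker_ids: list[str]
    coding: Coding
    calls: pd.DataFrame
    chrom: list[str] | None = None
    pos: list[int] | None = None
    variant_classes: list[VariantClass] | None = None
    n_cleaned: int = 0  # coded cells outside {1,0,-1} replaced by missing

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession IDs")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker IDs")
        if self.calls.shape != (len(self.accessions), len(self.marker_ids)):
            raise ValueError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.marker_ids)} markers"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def records(self) -> list[VariantRecord]:
        """Materialise per-marker VariantRecords (PHASED_VCF tables only)."""
        if self.coding is not Coding.PHASED_VCF:
            raise ValueError("records() is only defined for PHASED_VCF tables")
        assert self.chrom is not None and self.pos is not None
        assert self.variant_classes is not None
        return [
            VariantRecord(
                marker_id=m,
                chrom=self.chrom[j],
                pos=self.pos[j],
                variant_class=self.variant_classes[j],
                calls=dict(zip(self.accessions, self.calls.iloc[:, j])),
            )
            for j, m in enumerate(self.marker_ids)
        ]

    def subset_markers(self, indices: list[int] | np.ndarray) -> "RawGenotypeTable":
        idx = list(indices)
        return RawGenotypeTable(
            accessions=list(self.accessions),
            marker_ids=[self.marker_ids[j] for j in idx],
            coding=self.coding,
            calls=self.calls.iloc[:, idx].copy(),
            chrom=[self.chrom[j] for j in idx] if self.chrom is not None else None,
            pos=[self.pos[j] for j in idx] if self.pos is not None else None,
            variant_classes=(
                [self.variant_classes[j] for j in idx]
                if self.variant_classes is not None
                else None
            ),
            n_cleaned=self.n_cleaned,
        )

    def subset_accessions(self, accessions: list[str]) -> "RawGenotypeTable":
        missing = set(accessions) - set(self.accessions)
        if missing:
            raise KeyError(f"accessions not in table: {sorted(missing)}")
        return RawGenotypeTable(
            accessions=list(accessions),
            marker_ids=list(self.marker_ids),
            coding=self.coding,
            calls=self.calls.loc[list(accessions)].copy(),
            chrom=self.chrom,
            pos=self.pos,
            variant_classes=self.variant_classes,
            n_cleaned=self.n_cleaned,
        )

    def equals(self, other: "RawGenotypeTable") -> bool:
        """Content equality (ignores the cleaning counter)."""
        if (
            self.accessions != other.accessions
            or self.marker_ids != other.marker_ids
            or self.coding != other.coding
            or self.chrom != other.chrom
            or self.pos != other.pos
            or self.variant_classes != other.variant_classes
        ):
            return False
        if self.coding is Coding.INTEGER_CODED:
            a = self.calls.to_numpy(dtype=float)
            b = other.calls.to_numpy(dtype=float)
            return bool(
                np.all((a == b) | (np.isnan(a) & np.isnan(b)))
            )
        return bool((self.calls.to_numpy() == other.calls.to_numpy()).all())


@dataclass
class PhenotypeTable:
    """A single quantitative trait keyed by accession ID."""

    trait_name: str
    values: dict[str, float]  # NaN marks a missing measurement
    units: str = ""

    def __post_init__(self) -> None:
        for acc, v in self.values.items():
            if v is not None and not math.isnan(v) and not math.isfinite(v):
                raise ValueError(f"non-finite trait value for accession {acc!r}")

    def non_missing(self) -> dict[str, float]:
        return {a: v for a, v in self.values.items() if not math.isnan(v)}


@dataclass
class AlignedDataset:
    """Genotypes and phenotypes restricted to shared accessions, same order."""

    table: RawGenotypeTable
    phenotype: PhenotypeTable

    def __post_init__(self) -> None:
        pheno_accs = list(self.phenotype.values.keys())
        if self.table.accessions != pheno_accs:
            raise ValueError("genotype and phenotype accession order differ")
        if any(math.isnan(v) for v in self.phenotype.values.values()):
            raise ValueError("aligned phenotype contains missing values")

    @property
    def accessions(self) -> list[str]:
        return self.table.accessions

    @property
    def y(self) -> np.ndarray:
        return np.asarray(
            [self.phenotype.values[a] for a in self.accessions], dtype=float
        )


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

_SYMBOLIC_ALT = {"<INV>": VariantClass.INV, "<DUP>": VariantClass.DUP,
                 "<DEL>": VariantClass.DEL}
_SVTYPE_MAP = {"INV": VariantClass.INV, "DUP": VariantClass.DUP,
               "DEL": VariantClass.DEL, "SNP": VariantClass.SNP,
               "INDEL": VariantClass.INDEL, "TE": VariantClass.TE}


def _resolve_variant_class(ref: str, alt: str, info: str) -> VariantClass | None:
    for kv in info.split(";"):
        if kv.startswith("SVTYPE="):
            return _SVTYPE_MAP.get(kv.split("=", 1)[1].upper())
    if alt in _SYMBOLIC_ALT:
        return _SYMBOLIC_ALT[alt]
    return None


def read_sv_vcf(path: str, delimiter: str = "\t") -> RawGenotypeTable:
    """Read a (possibly SV-annotated) VCF into a :class:`RawGenotypeTable`.

    Only the GT subfield of FORMAT is consumed; call strings (including the
    ``|`` vs ``/`` separator and missing spellings) are preserved verbatim.
    Records whose variant class cannot be resolved from SVTYPE or a symbolic
    ALT fall back to SNP (single-base REF and ALT) or INDEL, with a warning.
    """
    accessions: list[str] | None = None
    marker_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    classes: list[VariantClass] = []
    columns: list[list[str]] = []
    seen_ids: set[str] = set()
    n_fallback = 0

    with open(path) as fh:
        first = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if first:
                if not line.startswith("##fileformat=VCF"):
                    raise VCFParseError(
                        f"line 1: missing ##fileformat=VCF header (got {line[:40]!r})"
                    )
                first = False
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split(delimiter)
                if len(fields) < 10 or fields[8] != "FORMAT":
                    raise VCFParseError(
                        f"line {lineno}: #CHROM header lacks FORMAT/sample columns"
                    )
                accessions = fields[9:]
                continue
            if accessions is None:
                raise VCFParseError(f"line {lineno}: data line before #CHROM header")
            fields = line.split(delimiter)
            if len(fields) != 9 + len(accessions):
                raise VCFParseError(
                    f"line {lineno}: expected {9 + len(accessions)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, vid, ref, alt, _qual, _filt, info, fmt = fields[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VCFParseError(f"line {lineno}: POS {pos_s!r} is not an integer")
            if pos < 1:
                raise VCFParseError(f"line {lineno}: POS must be >= 1, got {pos}")
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise VCFParseError(f"line {lineno}: FORMAT has no GT subfield")
            gt_idx = fmt_keys.index("GT")

            vclass = _resolve_variant_class(ref, alt, info)
            if vclass is None:
                vclass = (
                    VariantClass.SNP
                    if len(ref) == 1 and len(alt) == 1 and alt not in (".",)
                    else VariantClass.INDEL
                )
                n_fallback += 1
                logger.warning(
                    "line %d: unresolvable variant class, falling back to %s",
                    lineno, vclass.value,
                )
            marker_id = vid if vid not in (".", "") else f"{chrom}:{pos}"
            if marker_id in seen_ids:  # VCF IDs are not guaranteed unique
                k = 2
                while f"{marker_id}_{k}" in seen_ids:
                    k += 1
                marker_id = f"{marker_id}_{k}"
            seen_ids.add(marker_id)

            calls = []
            for s, sample_field in zip(accessions, fields[9:]):
                parts = sample_field.split(":")
                if gt_idx >= len(parts):
                    raise VCFParseError(
                        f"line {lineno}: sample {s} lacks GT subfield"
                    )
                calls.append(parts[gt_idx])
            marker_ids.append(marker_id)
            chroms.append(chrom)
            positions.append(pos)
            classes.append(vclass)
            columns.append(calls)

    if accessions is None:
        raise VCFParseError("no #CHROM header found")
    if n_fallback:
        logger.warning("%d record(s) required a variant-class fallback", n_fallback)
    data = (
        pd.DataFrame(
            np.asarray(columns, dtype=object).T,
            index=accessions, columns=marker_ids,
        )
        if columns
        else pd.DataFrame(index=accessions, columns=marker_ids, dtype=object)
    )
    return RawGenotypeTable(
        accessions=list(accessions),
        marker_ids=marker_ids,
        coding=Coding.PHASED_VCF,
        calls=data,
        chrom=chroms,
        pos=positions,
        variant_classes=classes,
    )


# ---------------------------------------------------------------------------
# Integer-coded tables
# ---------------------------------------------------------------------------

def read_integer_coded_table(
    path: str,
    delimiter: str = "\t",
    orientation: str = "accessions_as_rows",
) -> RawGenotypeTable:
    """Read a 1/0/−1 coded marker matrix.

    The file has one header row of marker IDs (first cell names the accession
    column) and one row per accession; ``orientation="markers_as_rows"``
    reads the transpose. Cells outside {1, 0, −1} — including ``NA``, ``.``
    and empty — become missing; values that are neither missing spellings nor
    valid codes are counted and reported via ``n_cleaned`` with a warning.
    """
    if orientation not in ("accessions_as_rows", "markers_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"empty genotype table: {path}")
    rows = [ln.split(delimiter) for ln in lines]
    width = len(rows[0])
    for i, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row at line {i} ({len(r)} fields, expected {width})"
            )
    header = rows[0][1:]
    row_ids = [r[0] for r in rows[1:]]
    n_cleaned = 0
    values = np.full((len(rows) - 1, len(header)), np.nan)
    for i, r in enumerate(rows[1:]):
        for j, cell in enumerate(r[1:]):
            tok = cell.strip()
            if tok in MISSING_TOKENS:
                continue
            try:
                v = float(tok)
            except ValueError:
                v = None
            if v in (1.0, 0.0, -1.0):
                values[i, j] = v
            else:
                n_cleaned += 1
    if n_cleaned:
        logger.warning(
            "%s: %d cell(s) outside {1,0,-1} treated as missing", path, n_cleaned
        )
    if orientation == "markers_as_rows":
        values = values.T
        accessions, marker_ids = header, row_ids
    else:
        accessions, marker_ids = row_ids, header
    return RawGenotypeTable(
        accessions=list(accessions),
        marker_ids=list(marker_ids),
        coding=Coding.INTEGER_CODED,
        calls=pd.DataFrame(values, index=accessions, columns=marker_ids),
        n_cleaned=n_cleaned,
    )


def read_phenotype_table(
    path: str,
    trait: str,
    delimiter: str = ",",
    id_column: str | int = 0,
    units: str = "",
) -> PhenotypeTable:
    """Read one trait column from a delimited phenotype table.

    Non-numeric cells become missing. Requesting an absent trait raises an
    error that names the traits actually present.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if isinstance(id_column, int):
        id_col = df.columns[id_column]
    else:
        id_col = id_column
        if id_col not in df.columns:
            raise KeyError(f"id column {id_col!r} not in {list(df.columns)}")
    if trait not in df.columns:
        available = [c for c in df.columns if c != id_col]
        raise KeyError(
            f"trait {trait!r} not found; available traits: {available}"
        )
    values: dict[str, float] = {}
    for acc, cell in zip(df[id_col], df[trait]):
        try:
            v = float(cell)
        except (TypeError, ValueError):
            v = float("nan")
        values[str(acc)] = v
    return PhenotypeTable(trait_name=trait, values=values, units=units)


def align_dataset(
    table: RawGenotypeTable, phenotype: PhenotypeTable
) -> AlignedDataset:
    """Restrict genotypes and phenotype to shared accessions with observed trait.

    Accession order follows the genotype table. Accessions missing from
    either side, or with a missing trait value, are dropped (counts logged).
    """
    if table.n_accessions == 0:
        raise ValueError("empty genotype table")
    observed = phenotype.non_missing()
    shared = [a for a in table.accessions if a in observed]
    if not shared:
        raise ValueError(
            "no accession is present in both the genotype table and the "
            "phenotype table with a non-missing trait value"
        )
    n_missing_pheno = sum(
        1 for a in table.accessions if a in phenotype.values and a not in observed
    )
    logger.info(
        "align: kept %d accessions (dropped %d genotyped-only, %d with missing "
        "phenotype, %d phenotyped-only)",
        len(shared),
        table.n_accessions - len(shared) - n_missing_pheno,
        n_missing_pheno,
        len(phenotype.values) - sum(1 for a in phenotype.values if a in table.accessions),
    )
    sub = table.subset_accessions(shared)
    pheno = PhenotypeTable(
        trait_name=phenotype.trait_name,
        values={a: observed[a] for a in shared},
        units=phenotype.units,
    )
    return AlignedDataset(table=sub, phenotype=pheno)


def subsample_markers(
    table: RawGenotypeTable, k: int, seed: int = 0
) -> RawGenotypeTable:
    """Uniform random marker subsample without replacement, original order kept."""
    if k > table.n_markers:
        raise ValueError(f"k={k} exceeds marker count {table.n_markers}")
    if k < 1:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(table.n_markers, size=k, replace=False))
    return table.subset_markers(idx)
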