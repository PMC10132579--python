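"""One-hot encoding of genotype calls into the 3D input tensor.

Three fixed-width schemes are supported, matching the marker panels:

* ``SV6`` (width 6) — structural variants, one reference/alternate channel
  pair per SV type in the order INV, DUP, DEL::

      0|0 (INV) -> [1,0,0,0,0,0]     1|1 (INV) -> [0,1,0,0,0,0]
      0|0 (DUP) -> [0,0,1,0,0,0]     1|1 (DUP) -> [0,0,0,1,0,0]
      0|0 (DEL) -> [0,0,0,0,1,0]     1|1 (DEL) -> [0,0,0,0,0,1]
      .|. (missing)               -> [0,0,0,0,0,0]

* ``CODED3`` (width 3) — integer-coded TE/SNP markers::

      1 (1/1) -> [1,0,0]    0 (0/1) -> [0,1,0]    -1 (0/0) -> [0,0,1]
      missing (./.)         -> [0,0,0]

* ``PHASED_BIALLELIC2`` (width 2) — phased biallelic SNPs/indels:
  ``0|0 -> [1,0]``, ``1|1 -> [0,1]``, missing ``-> [0,0]``.

Every encoded fiber is one-hot or all-zero; the all-zero vector is reserved
for missing or unmappable calls. Heterozygous diploid calls have no channel
in the SV6 and PHASED_BIALLELIC2 schemes (the source panels are inbred lines
with homozygous calls only), so they encode as all-zero and are counted in a
warning tally rather than silently widening the scheme. Genotypes with any
allele index above 1 are likewise treated as missing.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Coding, RawGenotypeTable, VariantClass

logger = logging.getLogger(__name__)

__all__ = [
    "SchemeId",
    "OneHotScheme",
    "GenotypeTensor",
    "scheme_width",
    "encode_sv_call",
    "encode_coded_call",
    "encode_phased_biallelic",
    "build_tensor",
    "save_tensor",
    "load_tensor",
]

_SV_TYPES = (VariantClass.INV, VariantClass.DUP, VariantClass.DEL)


class SchemeId(str, enum.Enum):
    SV6 = "SV6"
    CODED3 = "CODED3"
    PHASED_BIALLELIC2 = "PHASED_BIALLELIC2"


_WIDTHS = {SchemeId.SV6: 6, SchemeId.CODED3: 3, SchemeId.PHASED_BIALLELIC2: 2}


def scheme_width(scheme_id: SchemeId | str) -> int:
    """Number of one-hot channels of a scheme (SV6→6, CODED3→3, biallelic→2)."""
    try:
        return _WIDTHS[SchemeId(scheme_id)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown scheme id {scheme_id!r}") from None


def _parse_diploid(call: str) -> tuple[int, int] | None:
    """Parse a diploid GT string to allele indices; ``None`` if missing.

    Accepts both ``|`` and ``/`` separators and haploid-style single-allele
    strings (treated as homozygous). Any ``.`` allele means missing.
    """
    if call is None:
        return None
    s = str(call).strip()
    sep = "|" if "|" in s else "/"
    parts = s.split(sep)
    if len(parts) == 1:
        parts = [s, s]
    if len(parts) != 2:
        raise ValueError(f"cannot parse genotype call {call!r}")
    alleles = []
    for p in parts:
        p = p.strip()
        if p == "." or p == "":
            return None
        try:
            alleles.append(int(p))
        except ValueError:
            raise ValueError(f"cannot parse genotype call {call!r}") from None
    return alleles[0], alleles[1]


@dataclass(frozen=True)
class OneHotScheme:
    """A fixed one-hot mapping from (call, variant class) to a binary vector."""

    scheme_id: SchemeId

    @property
    def width(self) -> int:
        return scheme_width(self.scheme_id)

    def encode(
        self,
        call,
        variant_class: VariantClass | None = None,
        warnings: dict | None = None,
    ) -> np.ndarray:
        if self.scheme_id is SchemeId.SV6:
            return encode_sv_call(call, variant_class, warnings)
        if self.scheme_id is SchemeId.CODED3:
            return encode_coded_call(call)
        return encode_phased_biallelic(call, warnings)


def _warn(warnings: dict | None, key: str) -> None:
    if warnings is not None:
        warnings[key] = warnings.get(key, 0) + 1


def encode_sv_call(
    call: str,
    variant_class: VariantClass,
    warnings: dict | None = None,
) -> np.ndarray:
    """Encode one SV genotype call as a length-6 one-hot vector.

    Channel pairs are (ref, alt) per SV type in the fixed order INV, DUP,
    DEL. Missing, heterozygous and multi-allelic calls map to all-zero
    (the latter two bump warning counters).
    """
    vclass = VariantClass(variant_class)
    if vclass not in _SV_TYPES:
        raise ValueError(
            f"variant class {vclass.value} has no SV6 channel; use the "
            "PHASED_BIALLELIC2 scheme for SNP/indel markers"
        )
    vec = np.zeros(6, dtype=np.uint8)
    alleles = _parse_diploid(call)
    if alleles is None:
        return vec
    a, b = alleles
    if a != b:
        _warn(warnings, "heterozygous")
        return vec
    if a > 1:
        _warn(warnings, "multiallelic")
        return vec
    base = 2 * _SV_TYPES.index(vclass)
    vec[base + (1 if a == 1 else 0)] = 1
    return vec


def encode_coded_call(code) -> np.ndarray:
    """Encode an integer code: 1 (1/1)→[1,0,0], 0 (0/1)→[0,1,0], −1 (0/0)→[0,0,1].

    Missing (``None``/NaN) encodes as [0,0,0]. Any other value is an error —
    the table reader is responsible for cleaning stray codes.
    """
    vec = np.zeros(3, dtype=np.uint8)
    if code is None:
        return vec
    v = float(code)
    if np.isnan(v):
        return vec
    if v == 1.0:
        vec[0] = 1
    elif v == 0.0:
        vec[1] = 1
    elif v == -1.0:
        vec[2] = 1
    else:
        raise ValueError(f"integer code {code!r} outside {{1, 0, -1, missing}}")
    return vec


def encode_phased_biallelic(call: str, warnings: dict | None = None) -> np.ndarray:
    """Encode a biallelic call: 0|0→[1,0], 1|1→[0,1], missing/het→[0,0]."""
    vec = np.zeros(2, dtype=np.uint8)
    alleles = _parse_diploid(call)
    if alleles is None:
        return vec
    a, b = alleles
    if a != b:
        _warn(warnings, "heterozygous")
        return vec
    if a > 1:
        _warn(warnings, "multiallelic")
        return vec
    vec[a] = 1
    return vec


@dataclass
class GenotypeTensor:
    """The 3D one-hot input array: accessions x markers x channels."""

    data: np.ndarray  # (x, y, z) binary
    accession_ids: list[str]
    marker_ids: list[str]
    scheme_id: SchemeId
    warnings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x, y, z = self.data.shape
        if z != scheme_width(self.scheme_id):
            raise ValueError(
                f"channel count {z} does not match scheme width "
                f"{scheme_width(self.scheme_id)}"
            )
        if x != len(self.accession_ids) or y != len(self.marker_ids):
            raise ValueError("tensor shape does not match id lists")
        fiber_sums = self.data.sum(axis=2)
        if fiber_sums.max(initial=0) > 1:
            raise ValueError("tensor fibers must be one-hot or all-zero")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def subset_accessions(self, indices) -> "GenotypeTensor":
        idx = np.asarray(indices)
        return GenotypeTensor(
            data=self.data[idx],
            accession_ids=[self.accession_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            scheme_id=self.scheme_id,
            warnings=dict(self.warnings),
        )


def build_tensor(
    table: RawGenotypeTable, scheme: OneHotScheme | SchemeId | str
) -> GenotypeTensor:
    """One-hot encode a whole genotype table into the 3D input tensor.

    Scheme and table coding must match (SV6 / PHASED_BIALLELIC2 need genotype
    strings, CODED3 needs integer codes). Under SV6, markers whose class is
    not INV/DUP/DEL are dropped with a logged count.
    """
    if not isinstance(scheme, OneHotScheme):
        scheme = OneHotScheme(SchemeId(scheme))
    sid = scheme.scheme_id
    if sid is SchemeId.CODED3 and table.coding is not Coding.INTEGER_CODED:
        raise ValueError("CODED3 requires an INTEGER_CODED table")
    if sid in (SchemeId.SV6, SchemeId.PHASED_BIALLELIC2) and (
        table.coding is not Coding.PHASED_VCF
    ):
        raise ValueError(f"{sid.value} requires a PHASED_VCF table")

    warnings: dict = {}
    marker_ids = list(table.marker_ids)
    classes = table.variant_classes
    keep = list(range(len(marker_ids)))
    if sid is SchemeId.SV6:
        assert classes is not None
        keep = [j for j in keep if classes[j] in _SV_TYPES]
        dropped = len(marker_ids) - len(keep)
        if dropped:
            logger.warning(
                "build_tensor: dropped %d non-INV/DUP/DEL marker(s) for SV6",
                dropped,
            )
            warnings["dropped_markers"] = dropped
    x = table.n_accessions
    y = len(keep)
    z = scheme.width
    if x == 0 or y == 0:
        raise ValueError("cannot build an empty tensor")
    data = np.zeros((x, y, z), dtype=np.uint8)
    raw = table.calls.to_numpy()
    for col, j in enumerate(keep):
        vclass = classes[j] if classes is not None else None
        for i in range(x):
            data[i, col] = scheme.encode(raw[i, j], vclass, warnings)
    if warnings.get("heterozygous"):
        logger.warning(
            "build_tensor: %d heterozygous call(s) encoded as missing",
            warnings["heterozygous"],
        )
    return GenotypeTensor(
        data=data,
        accession_ids=list(table.accessions),
        marker_ids=[marker_ids[j] for j in keep],
        scheme_id=sid,
        warnings=warnings,
    )


def save_tensor(tensor: GenotypeTensor, path: str | Path) -> tuple[Path, Path]:
    """Persist a tensor as <path>.npy plus a JSON sidecar; round trip is exact."""
    path = Path(path)
    npy = path.with_suffix(".npy")
    sidecar = path.with_suffix(".json")
    np.save(npy, tensor.data)
    sidecar.write_text(
        json.dumps(
            {
                "accession_ids": tensor.accession_ids,
                "marker_ids": tensor.marker_ids,
                "scheme_id": tensor.scheme_id.value,
                "warnings": tensor.warnings,
            }
        )
    )
    return npy, sidecar


def load_tensor(path: str | Path) -> GenotypeTensor:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return GenotypeTensor(
        data=data,
        accession_ids=meta["accession_ids"],
        marker_ids=meta["marker_ids"],
        scheme_id=SchemeId(meta["scheme_id"]),
        warnings=meta.get("warnings", {}),
    )
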