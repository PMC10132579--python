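"""Synthetic genotype and phenotype generator with known additive architecture.

Two genotype models mirror the two marker panels the pipeline consumes:

* ``PHASED_SV`` — inbred-line (fully homozygous) phased SV calls: each
  accession carries ``"1|1"`` at marker j with probability ``p_j`` (the
  alternate-allele frequency, drawn uniformly per marker) and ``"0|0"``
  otherwise. SV types (INV/DUP/DEL) are assigned by a configurable mix.
  Heterozygotes never occur, matching the selfing species the SV panel
  comes from.
* ``CODED`` — integer-coded markers with Hardy-Weinberg genotype
  frequencies: code 1 (hom reference) with probability ``(1-p_j)^2``,
  0 (het) with ``2 p_j (1-p_j)`` and -1 (hom alternate) with ``p_j^2``.

Calls are masked to missing at a configurable rate. Phenotypes are strictly
additive: a sparse set of causal markers receives N(0, 1) effects, genetic
values are the dosage-weighted sums, and Gaussian noise is scaled so that
``Var(g) / Var(y)`` equals the requested heritability in expectation. The
generator returns the full ground truth (causal ids, effects, genetic
values) so recovery is measurable. There is no linkage disequilibrium,
population structure, epistasis or genotype-environment interaction.

A single global seed is split into per-stage substreams (frequencies,
genotypes, missingness, SV types, causal choice, effects, noise), so the
same genotypes can be reused across phenotype replicates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Coding,
    PhenotypeTable,
    RawGenotypeTable,
    VariantClass,
)

__all__ = [
    "GenotypeScheme",
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "write_fixtures",
]


class GenotypeScheme(str, enum.Enum):
    PHASED_SV = "PHASED_SV"
    CODED = "CODED"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic genotype/phenotype generator."""

    n_accessions: int = 400
    n_markers: int = 500
    scheme: GenotypeScheme = GenotypeScheme.PHASED_SV
    sv_type_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # INV, DUP, DEL
    alt_allele_freq_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    n_causal: int = 30
    heritability: float = 0.8
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.alt_allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"degenerate allele-frequency range ({lo}, {hi})")
        if abs(sum(self.sv_type_mix) - 1.0) > 1e-9:
            raise ValueError("sv_type_mix proportions must sum to 1")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(cfg: SimConfig) -> RawGenotypeTable:
    """Draw a genotype table under the configured scheme; deterministic per seed."""
    rng_freq, rng_geno, rng_miss, rng_type = _substreams(cfg.seed, 4)
    n, m = cfg.n_accessions, cfg.n_markers
    lo, hi = cfg.alt_allele_freq_range
    p = rng_freq.uniform(lo, hi, size=m)
    missing_mask = rng_miss.random((n, m)) < cfg.missing_rate

    if cfg.scheme is GenotypeScheme.PHASED_SV:
        alt = rng_geno.random((n, m)) < p
        calls = np.where(alt, "1|1", "0|0").astype(object)
        calls[missing_mask] = ".|."
        type_pool = (VariantClass.INV, VariantClass.DUP, VariantClass.DEL)
        sv_types = [
            type_pool[i]
            for i in rng_type.choice(3, size=m, p=list(cfg.sv_type_mix))
        ]
        marker_ids = [f"sv_{j:05d}" for j in range(m)]
        df = pd.DataFrame(
            calls, index=[f"acc_{i:04d}" for i in range(n)], columns=marker_ids
        )
        return RawGenotypeTable(
            accessions=list(df.index),
            marker_ids=marker_ids,
            coding=Coding.PHASED_VCF,
            calls=df,
            chrom=["1"] * m,
            pos=[1000 * (j + 1) for j in range(m)],
            variant_classes=list(sv_types),
        )

    # CODED: Hardy-Weinberg genotype frequencies on the 1/0/-1 convention
    u = rng_geno.random((n, m))
    hom_ref = (1.0 - p) ** 2
    het = 2.0 * p * (1.0 - p)
    codes = np.where(u < hom_ref, 1.0, np.where(u < hom_ref + het, 0.0, -1.0))
    codes[missing_mask] = np.nan
    marker_ids = [f"te_{j:05d}" for j in range(m)]
    df = pd.DataFrame(
        codes, index=[f"acc_{i:04d}" for i in range(n)], columns=marker_ids
    )
    return RawGenotypeTable(
        accessions=list(df.index),
        marker_ids=marker_ids,
        coding=Coding.INTEGER_CODED,
        calls=df,
    )


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype."""

    causal_ids: list[str]
    effects: np.ndarray  # full-length; exactly zero on non-causal markers
    genetic_values: np.ndarray
    sigma2_e: float
    heritability: float


def simulate_phenotypes(
    table: RawGenotypeTable, cfg: SimConfig
) -> tuple[PhenotypeTable, SimTruth]:
    """Additive phenotypes ``y = g + e`` with ``Var(g)/Var(y) = h2`` in expectation.

    Genetic values use alternate-allele dosages (missing calls mean-imputed,
    as downstream consumers do); noise variance is
    ``Var(g) (1 - h2) / h2``.
    """
    from .baselines import to_dosage

    rng_causal, rng_eff, rng_noise = _substreams(cfg.seed + 1_000_003, 3)
    m = table.n_markers
    causal_idx = np.sort(rng_causal.choice(m, size=cfg.n_causal, replace=False))
    beta = np.zeros(m)
    beta[causal_idx] = rng_eff.normal(0.0, 1.0, size=cfg.n_causal)
    Z = to_dosage(table).Z
    g = Z @ beta
    var_g = float(g.var())
    if var_g == 0.0:
        raise ValueError("no causal variation: Var(g) = 0")
    h2 = cfg.heritability
    sigma2_e = var_g * (1.0 - h2) / h2
    e = rng_noise.normal(0.0, math.sqrt(sigma2_e), size=len(g))
    y = g + e
    pheno = PhenotypeTable(
        trait_name=cfg.trait_name,
        values={a: float(v) for a, v in zip(table.accessions, y)},
    )
    truth = SimTruth(
        causal_ids=[table.marker_ids[j] for j in causal_idx],
        effects=beta,
        genetic_values=g,
        sigma2_e=sigma2_e,
        heritability=h2,
    )
    return pheno, truth


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_SV_ALT = {VariantClass.INV: "<INV>", VariantClass.DUP: "<DUP>",
           VariantClass.DEL: "<DEL>"}


def write_fixtures(
    table: RawGenotypeTable,
    phenotype: PhenotypeTable,
    out_dir: str | Path,
    basename: str = "sim",
) -> dict[str, Path]:
    """Write a table + phenotype to disk in the formats the readers consume.

    PHASED_VCF tables become a minimal VCF (SVTYPE INFO, GT-only FORMAT),
    INTEGER_CODED tables a TSV, phenotypes a CSV. Reading the files back
    reproduces the inputs exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if table.coding is Coding.PHASED_VCF:
        vcf = out_dir / f"{basename}.vcf"
        with open(vcf, "w") as fh:
            fh.write(_VCF_HEADER)
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(table.accessions)
                + "\n"
            )
            raw = table.calls.to_numpy()
            assert table.chrom is not None and table.pos is not None
            assert table.variant_classes is not None
            for j, mid in enumerate(table.marker_ids):
                vclass = table.variant_classes[j]
                if vclass in _SV_ALT:
                    ref, alt = "N", _SV_ALT[vclass]
                    info = f"SVTYPE={vclass.value}"
                elif vclass is VariantClass.SNP:
                    ref, alt, info = "A", "T", "."
                else:
                    ref, alt, info = "AT", "A", f"SVTYPE={vclass.value}"
                row = [
                    table.chrom[j], str(table.pos[j]), mid, ref, alt,
                    ".", ".", info, "GT",
                ] + [str(c) for c in raw[:, j]]
                fh.write("\t".join(row) + "\n")
        paths["genotypes"] = vcf
    else:
        tsv = out_dir / f"{basename}_coded.tsv"
        with open(tsv, "w") as fh:
            fh.write("accession\t" + "\t".join(table.marker_ids) + "\n")
            raw = table.calls.to_numpy(dtype=float)
            for i, acc in enumerate(table.accessions):
                cells = [
                    "NA" if np.isnan(v) else str(int(v)) for v in raw[i]
                ]
                fh.write(acc + "\t" + "\t".join(cells) + "\n")
        paths["genotypes"] = tsv

    pheno_csv = out_dir / f"{basename}_phenotypes.csv"
    with open(pheno_csv, "w") as fh:
        fh.write(f"accession_id,{phenotype.trait_name}\n")
        for acc, v in phenotype.values.items():
            fh.write(f"{acc},{'' if math.isnan(v) else repr(v)}\n")
    paths["phenotypes"] = pheno_csv
    return paths
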