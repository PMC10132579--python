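import numpy as np
import pytest
from hypothesis import settings

import novgmdeep as ng

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


FIXTURE_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t1000\tsv1\tN\t<INV>\t.\t.\tSVTYPE=INV\tGT\t0|0\t1|1\t.|.
1\t5000\tsv2\tN\t<DEL>\t.\t.\tSVTYPE=DEL\tGT\t1|1\t0|0\t0|0
"""


@pytest.fixture
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(FIXTURE_VCF)
    return path


@pytest.fixture
def coded_table_file(tmp_path):
    path = tmp_path / "coded.tsv"
    path.write_text(
        "accession\tm1\tm2\tm3\n"
        "accA\t1\t0\t-1\n"
        "accB\t0\t0\t1\n"
    )
    return path


@pytest.fixture(scope="session")
def small_sim():
    """A small phased-SV simulated dataset shared across tests (read-only)."""
    cfg = ng.SimConfig(
        n_accessions=60, n_markers=50, n_causal=10, heritability=0.8, seed=42
    )
    table = ng.simulate_genotypes(cfg)
    pheno, truth = ng.simulate_phenotypes(table, cfg)
    y = np.asarray([pheno.values[a] for a in table.accessions])
    return cfg, table, pheno, truth, y


@pytest.fixture(scope="session")
def small_tensor(small_sim):
    _, table, _, _, y = small_sim
    return ng.build_tensor(table, "SV6"), y
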