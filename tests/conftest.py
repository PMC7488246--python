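import numpy as np
import pandas as pd
import pytest

import pigsnp as pg


@pytest.fixture(scope="session")
def small_config():
    """A small but structured cohort: 3 regions, LD blocks, 5 causal SNPs."""
    return pg.SimulationConfig(
        n_samples_per_region=60,
        regions=("Caucasus", "EuropeanRussia", "WestSiberia"),
        n_snps=400,
        n_causal=5,
        ld_block_size=5,
        missing_rate=0.02,
        populations_per_region=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return pg.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(small_cohort, tmp_path_factory):
    """The small cohort written to disk (VCF + phenotype TSV + manifest)."""
    gm, ph, man = small_cohort
    out = tmp_path_factory.mktemp("cohort")
    paths = pg.write_dataset(gm, ph, man, out)
    return paths


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t50.0\t.\tDP=10\tGT\t0/0\t0/1\t1/1
1\t200\t.\tC\tT\t40.0\t.\tDP=10\tGT\t1/1\t1/1\t0/0
1\t300\t.\tG\tA\t100.0\t.\tDP=5\tGT\t0/0\t0/0\t0/1
1\t400\t.\tT\tC\t90.0\t.\tDP=30\tGT\t0|1\t./.\t1|1
1\t500\t.\tA\tC,G\t90.0\t.\tDP=30\tGT\t0/1\t0/2\t1/1
2\t100\t.\tAT\tA\t90.0\t.\tDP=30\tGT\t0/0\t0/1\t0/0
2\t200\t.\tG\tC\t80.0\t.\tDP=25\tGT\t1/0\t0/0\t0/0
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    """Hand-written VCF exercising QC boundaries, phasing, missingness,
    multiallelic and indel lines."""
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture()
def toy_phenotypes(tmp_path):
    table = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "population": ["P1", "P1", "P2"],
            "region": ["R1", "R1", "R2"],
            "eye_grade": [0, 2, 4],
            "hair_grade": [1, 3, 4],
        }
    )
    path = tmp_path / "pheno.tsv"
    table.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(202409)
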