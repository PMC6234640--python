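import numpy as np
import pytest
from hypothesis import settings

import riskdrift as rd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=8>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5\ts6
1\t100\trs1\tA\tG\t.\t.\tAA=A\tGT\t0|1\t1|1\t0|0\t0|1\t1|1\t0|0
1\t200\trs2\tC\tT\t.\t.\tAA=t|||\tGT\t0|0\t0|1\t1|1\t0|0\t0|1\t1|1
1\t300\trs3\tG\tA\t.\t.\tAA=N\tGT\t0|0\t0|0\t0|0\t0|0\t0|0\t0|0
8\t100000000\trs4\tG\tC\t.\t.\tAA=G\tGT\t0|1\t0|0\t0|0\t0|0\t1|1\t0|0
1\t500\trs5\tT\tA\t.\t.\tAA=T\tGT\t0|1\t0|0\t1|1\t0|0\t0|0\t0|1
"""

#: population assignment for the fixture VCF's six samples
VCF_POPS = {"s1": "AFR", "s2": "AFR", "s3": "AMR", "s4": "EAS", "s5": "EUR", "s6": "SAS"}


@pytest.fixture()
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture(scope="session")
def demo_panel():
    """Synthetic bottleneck panel with EUR-ascertained SYNTH array flags."""
    demo = rd.DemographyParams(n_snps=30_000, seed=42)
    panel = rd.build_panel(demo)
    return rd.ascertain_array_subset(panel, rng=np.random.default_rng([42, 1]))


@pytest.fixture(scope="session")
def small_panel():
    """A small panel for fast exact-arithmetic tests."""
    demo = rd.DemographyParams(n_snps=500, seed=5)
    return rd.build_panel(demo)


@pytest.fixture(scope="session")
def disease_table(demo_panel):
    return rd.synthesize_disease_table(demo_panel, n_loci=600, rng=np.random.default_rng(9))


@pytest.fixture(scope="session")
def genotypes(demo_panel, disease_table):
    """HW genotypes for the disease loci only (40 individuals per population)."""
    sub = demo_panel.replace(
        demo_panel.df[demo_panel.df["id"].isin(disease_table["id"])], note="disease loci"
    )
    return rd.simulate_genotypes(
        sub, {p: 40 for p in rd.POPULATIONS}, rng=np.random.default_rng(17)
    )
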