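import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TOY_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=q10,Description="Quality below 10">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t100\t.\tA\tG\t.\tPASS\t.
chr1\t200\t.\tC\tT\t.\tq10\t.
chr1\t300\t.\tG\tA\t.\tPASS\t.
"""

MIXED_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t100\t.\tA\tG,T\t.\tPASS\t.
chr1\t400\t.\tAT\tA\t.\tPASS\t.
chr1\t500\t.\tC\tCGG\t.\tPASS\t.
chr1\t600\t.\tAT\tGC\t.\tPASS\t.
chr1\t700\t.\tT\tC\t.\t.\t.
"""

TOY_MAF = """\
Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tTumor_Sample_Barcode\tVariant_Type
GENE1\tchr1\t1000\tC\tT\tS1\tSNP
GENE2\tchr1\t2000\tG\tA\tS1\tSNP
GENE3\tchr2\t500\tT\tG\tS1\tSNP
GENE4\tchr1\t1500\tA\tC\tS2\tSNP
GENE5\tchr3\t900\tC\tA\tS2\tSNP
GENE6\tchr1\t3000\tTA\t-\tS2\tDEL
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def mixed_vcf(tmp_path):
    path = tmp_path / "mixed.vcf"
    path.write_text(MIXED_VCF)
    return path


@pytest.fixture
def toy_maf(tmp_path):
    path = tmp_path / "toy.maf"
    path.write_text(TOY_MAF)
    return path


@pytest.fixture
def chrom_sizes_file(tmp_path):
    path = tmp_path / "sizes.tsv"
    path.write_text("chr1\t100000\nchr2\t80000\nchr3\t60000\n")
    return path


@pytest.fixture
def random_fasta(tmp_path):
    """100-kb uniform-random single-chromosome FASTA."""
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
    path = tmp_path / "ref.fa"
    with open(path, "w") as fh:
        fh.write(">chrR\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    return path, seq
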