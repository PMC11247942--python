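import numpy as np
import pytest

from rectalresponse import synthetic_cohort as syn

MAF_HEADER = ("Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
              "Tumor_Seq_Allele2\tVariant_Classification\t"
              "Tumor_Sample_Barcode\tt_depth\tAF\n")


def make_maf(path, rows):
    """Write a MAF file from (gene, chrom, pos, ref, alt, class, sample,
    depth, af) tuples; None depth/af become empty fields."""
    with open(path, "w") as fh:
        fh.write("# synthetic fixture\n")
        fh.write(MAF_HEADER)
        for r in rows:
            fields = [str(x) if x is not None else "" for x in r]
            fh.write("\t".join(fields) + "\n")
    return path


@pytest.fixture
def tiny_maf(tmp_path):
    rows = [
        ("TP53", "17", 7578406, "C", "T", "Missense_Mutation", "S1", 120, 0.42),
        ("TP53", "17", 7577120, "G", "A", "Nonsense_Mutation", "S1", 95, 0.31),
        ("APC", "5", 112175240, "G", "T", "Missense_Mutation", "S2", 80, 0.25),
        ("KRAS", "12", 25398284, "C", "A", "Missense_Mutation", "S2", 20, 0.50),
        ("POLE", "12", 133250250, "T", "C", "Missense_Mutation", "S3", 60, 0.05),
        ("MLH1", "3", 37067240, "A", "G", "Silent", "S3", 90, 0.33),
        ("MSH3", "5", 79970915, "C", "G", "Missense_Mutation", "S3", None, None),
    ]
    return make_maf(tmp_path / "tiny.maf", rows)


@pytest.fixture(scope="session")
def paperlike_cohort():
    params = syn.preset("paperlike", seed=20240917)
    return syn.simulate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(11)
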