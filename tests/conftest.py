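import numpy as np
import pytest

from podabc import genotype_io as gio


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_ped_map(tmp_path):
    """Hand-written 3-sample, 2-SNP PED/MAP pair with a known code matrix.

    SNP rs1 (chr1:1000, alleles A/G) and rs2 (chr1:2000, alleles C/T);
    sample s3 is missing at rs2.  With A1 = lexicographically smaller
    allele, the expected A1-count matrix is [[2, 0], [1, 1], [0, MISSING]].
    """
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    map_.write_text("1 rs1 0 1000\n1 rs2 0 2000\n")
    ped.write_text(
        "F1 s1 0 0 0 -9 A A T T\n"
        "F1 s2 0 0 0 -9 A G C T\n"
        "F2 s3 0 0 0 -9 G G 0 0\n")
    expected = np.array([[2, 0], [1, 1], [0, gio.MISSING]], dtype=np.int8)
    return ped, map_, expected


def make_dataset(geno, breeds=None, groups=None, **kw):
    """Small helper: dataset from an integer matrix with default breeds."""
    geno = np.asarray(geno, dtype=np.int8)
    if breeds is None:
        breeds = ["POP"] * geno.shape[0]
    if groups is None:
        groups = {b: "other" for b in breeds}
    return gio.from_arrays(geno, breeds, groups, **kw)
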