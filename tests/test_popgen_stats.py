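"""Diversity and differentiation statistics against hand and simulation
oracles."""

import numpy as np
import pytest

from podabc import popgen_stats as ps
from podabc.genotype_io import MISSING, from_arrays

from conftest import make_dataset


def two_breed_dataset(counts_a, counts_b, n_a, n_b):
    """Dataset with exact per-breed A1 allele counts at each SNP."""
    cols = []
    for ca, cb in zip(counts_a, counts_b):
        col = np.concatenate([_col(ca, n_a), _col(cb, n_b)])
        cols.append(col)
    g = np.column_stack(cols).astype(np.int8)
    return make_dataset(g, breeds=["A"] * n_a + ["B"] * n_b,
                        groups={"A": "other", "B": "other"})


def _col(count, n):
    col = np.zeros(n, dtype=np.int8)
    col[: count // 2] = 2
    if count % 2:
        col[count // 2] = 1
    return col


class TestHeterozygosity:
    def test_hand_computed_fixture(self):
        # 5 samples x 3 SNPs, worked out by direct counting
        g = np.array([[0, 1, 2],
                      [1, 1, 2],
                      [1, 1, 2],
                      [2, 1, MISSING],
                      [0, 1, 2]], dtype=np.int8)
        ds = make_dataset(g)
        ho_m, ho_s, he_m, he_s = ps.heterozygosity(ds, "POP")
        # Ho per SNP: 2/5, 5/5, 0/4 ; p per SNP: 0.4, 0.5, 1.0
        ho = np.array([0.4, 1.0, 0.0])
        he = np.array([2 * .4 * .6, 0.5, 0.0])
        assert ho_m == pytest.approx(ho.mean())
        assert ho_s == pytest.approx(ho.std())
        assert he_m == pytest.approx(he.mean())
        assert he_s == pytest.approx(he.std())

    def test_all_heterozygote_column(self):
        ds = make_dataset(np.ones((6, 1), dtype=np.int8))
        assert ps.heterozygosity(ds, "POP")[0] == 1.0

    def test_he_half_at_p_half(self):
        ds = make_dataset(np.array([[0], [2]], dtype=np.int8))
        assert ps.heterozygosity(ds, "POP")[2] == pytest.approx(0.5)

    def test_unbiased_correction_factor(self):
        ds = make_dataset(np.array([[0], [2]], dtype=np.int8))
        he = ps.heterozygosity(ds, "POP", unbiased=True)[2]
        assert he == pytest.approx(0.5 * 4 / 3)


class TestMeanMaf:
    def test_monomorphic_zero_and_half(self):
        ds = make_dataset(np.array([[2, 0], [2, 2]], dtype=np.int8))
        m, s = ps.mean_maf(ds, "POP")
        assert m == pytest.approx((0.0 + 0.5) / 2)

    def test_folding(self):
        # p = 0.75 must report MAF 0.25
        ds = make_dataset(np.array([[2], [2], [1], [1]], dtype=np.int8))
        assert ps.mean_maf(ds, "POP")[0] == pytest.approx(0.25)


def test_allele_relabelling_invariance(rng):
    g = rng.binomial(2, rng.uniform(0.1, 0.9, 30)[None, :],
                     size=(25, 30)).astype(np.int8)
    ds = make_dataset(g)
    flipped = make_dataset(2 - g)
    for fn in (ps.heterozygosity, ps.mean_maf):
        np.testing.assert_allclose(fn(ds, "POP"), fn(flipped, "POP"))


class TestIbsDistance:
    def test_identical_and_opposite(self):
        g = np.array([[0, 0, 0], [0, 0, 0], [2, 2, 2]], dtype=np.int8)
        d = ps.ibs_distance(make_dataset(g))
        assert d.matrix[0, 1] == 0.0
        assert d.matrix[0, 2] == 1.0

    def test_brute_force_counts(self, rng):
        g = rng.integers(0, 3, size=(3, 8)).astype(np.int8)
        g[0, 2] = MISSING
        d = ps.ibs_distance(make_dataset(g)).matrix
        for i in range(3):
            for j in range(i + 1, 3):
                shares, cnt = 0, 0
                for k in range(8):
                    if g[i, k] == MISSING or g[j, k] == MISSING:
                        continue
                    shares += 2 - abs(int(g[i, k]) - int(g[j, k]))
                    cnt += 1
                assert d[i, j] == pytest.approx(1 - shares / (2 * cnt))

    def test_symmetry_zero_diagonal(self, rng):
        g = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
        d = ps.ibs_distance(make_dataset(g))
        np.testing.assert_allclose(d.matrix, d.matrix.T)
        np.testing.assert_allclose(np.diag(d.matrix), 0.0)


class TestReynolds:
    def test_identical_frequencies_frequency_mode_zero(self):
        ds = two_breed_dataset([10, 6], [10, 6], 10, 10)
        assert ps.reynolds_distance(ds, "A", "B", unbiased=False) == 0.0

    def test_fixed_difference_is_one(self):
        ds = two_breed_dataset([20, 20], [0, 0], 10, 10)
        assert ps.reynolds_distance(ds, "A", "B") == pytest.approx(1.0)

    def test_two_snp_toy_matches_hand_formula(self):
        n1, n2 = 10, 8
        ca, cb = [14, 5], [4, 9]
        ds = two_breed_dataset(ca, cb, n1, n2)
        num = den = 0.0
        for j in range(2):
            p1, p2 = ca[j] / (2 * n1), cb[j] / (2 * n2)
            h1 = 2 * n1 * 2 * p1 * (1 - p1) / (2 * n1 - 1)
            h2 = 2 * n2 * 2 * p2 * (1 - p2) / (2 * n2 - 1)
            hsum = n1 * h1 + n2 * h2
            al = (p1 - p2) ** 2 - (n1 + n2) * hsum / (4 * n1 * n2 * (n1 + n2 - 1))
            bl = (4 * n1 * n2 - n1 - n2) * hsum / (4 * n1 * n2 * (n1 + n2 - 1))
            num += al
            den += al + bl
        assert ps.reynolds_distance(ds, "A", "B") == pytest.approx(num / den)

    def test_linearized_form(self):
        ds = two_breed_dataset([14, 5], [4, 9], 10, 8)
        theta = ps.reynolds_distance(ds, "A", "B")
        lin = ps.reynolds_distance(ds, "A", "B", linearized=True)
        assert lin == pytest.approx(-np.log(1 - theta))


class TestHudsonFst:
    def test_identical_populations_near_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 400)
        g = rng.binomial(2, np.tile(p, (60, 1))).astype(np.int8)
        ds = make_dataset(g, breeds=["A"] * 30 + ["B"] * 30,
                          groups={"A": "other", "B": "other"})
        assert abs(ps.hudson_fst(ds, "A", "B")) < 0.02

    def test_fixed_difference_is_one(self):
        ds = two_breed_dataset([20, 20], [0, 0], 10, 10)
        assert ps.hudson_fst(ds, "A", "B") == pytest.approx(1.0)

    def test_toy_matches_hand_formula(self):
        n1, n2 = 10, 8
        ca, cb = [14, 5], [4, 9]
        ds = two_breed_dataset(ca, cb, n1, n2)
        num = den = 0.0
        for j in range(2):
            p1, p2 = ca[j] / 20, cb[j] / 16
            num += ((p1 - p2) ** 2 - p1 * (1 - p1) / 19 - p2 * (1 - p2) / 15)
            den += p1 * (1 - p2) + p2 * (1 - p1)
        assert ps.hudson_fst(ds, "A", "B") == pytest.approx(num / den)


def test_differentiation_vanishes_as_frequencies_converge(rng):
    p = rng.uniform(0.3, 0.7, 500)
    prev_rey, prev_fst = 1.0, 1.0
    for delta in (0.3, 0.15, 0.05, 0.0):
        pa = np.clip(p + delta, 0, 1)
        ga = rng.binomial(2, np.tile(pa, (40, 1))).astype(np.int8)
        gb = rng.binomial(2, np.tile(p, (40, 1))).astype(np.int8)
        ds = make_dataset(np.vstack([ga, gb]),
                          breeds=["A"] * 40 + ["B"] * 40,
                          groups={"A": "other", "B": "other"})
        rey = ps.reynolds_distance(ds, "A", "B")
        fst = ps.hudson_fst(ds, "A", "B")
        assert rey <= prev_rey + 0.02 and fst <= prev_fst + 0.02
        prev_rey, prev_fst = rey, fst
    assert abs(prev_rey) < 0.02 and abs(prev_fst) < 0.02


class TestF3:
    def test_target_equals_source_near_zero(self):
        ds = two_breed_dataset([30, 40], [10, 60], 50, 50)
        g3 = ds.genotypes[:50]          # copy of breed A as the target
        g = np.vstack([ds.genotypes, g3])
        ds3 = make_dataset(g, breeds=["A"] * 50 + ["B"] * 50 + ["T"] * 50,
                           groups={"A": "other", "B": "other", "T": "other"})
        assert abs(ps.f3_statistic(ds3, "T", "A", "B")) < 0.01

    def test_mixture_frequencies_negative(self):
        # pT exactly midway between diverged sources: (pT-pA)(pT-pB) < 0
        n = 40
        ca = [int(0.2 * 2 * n)] * 6
        cb = [int(0.8 * 2 * n)] * 6
        ct = [int(0.5 * 2 * n)] * 6
        cols = [np.concatenate([_col(a, n), _col(b, n), _col(t, n)])
                for a, b, t in zip(ca, cb, ct)]
        ds = make_dataset(np.column_stack(cols),
                          breeds=["A"] * n + ["B"] * n + ["T"] * n,
                          groups={"A": "other", "B": "other", "T": "other"})
        assert ps.f3_statistic(ds, "T", "A", "B") < -0.05

    def test_independent_drift_positive(self):
        n = 40
        cols = [np.concatenate([_col(int(0.5 * 2 * n), n),
                                _col(int(0.5 * 2 * n), n),
                                _col(int(0.95 * 2 * n), n)])
                for _ in range(6)]
        ds = make_dataset(np.column_stack(cols),
                          breeds=["A"] * n + ["B"] * n + ["T"] * n,
                          groups={"A": "other", "B": "other", "T": "other"})
        assert ps.f3_statistic(ds, "T", "A", "B") > 0.05


class TestNeiDistance:
    def test_identical_zero(self):
        ds = two_breed_dataset([10, 6], [10, 6], 10, 10)
        assert ps.nei_distance(ds, "A", "B") == pytest.approx(0.0)

    def test_increases_with_divergence(self):
        near = two_breed_dataset([10, 6], [12, 8], 10, 10)
        far = two_breed_dataset([10, 6], [20, 18], 10, 10)
        assert (ps.nei_distance(far, "A", "B")
                > ps.nei_distance(near, "A", "B"))


# ---------------------------------------------------------------------------
# LD-based Ne trajectory (msprime as the independent simulation oracle)
# ---------------------------------------------------------------------------

def _msprime_dataset(n_dip, ne, seed, length=2e7, recomb=1e-8, mu=6e-8):
    import msprime

    ts = msprime.sim_ancestry(samples=n_dip, population_size=ne,
                              sequence_length=length,
                              recombination_rate=recomb, random_seed=seed)
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 1,
                               model=msprime.BinaryMutationModel())
    g = ts.genotype_matrix()            # sites x haplotypes
    geno = (g[:, 0::2] + g[:, 1::2]).T.astype(np.int8)
    pos = np.array([int(s.position) + 1 for s in ts.sites()])
    keep = np.concatenate([[True], np.diff(pos) > 0])
    geno, pos = geno[:, keep], pos[keep]
    p = geno.mean(axis=0) / 2
    common = np.minimum(p, 1 - p) >= 0.05
    geno, pos = geno[:, common], pos[common]
    m = geno.shape[1]
    return from_arrays(geno, ["POP"] * n_dip, {"POP": "other"},
                       chrom=np.array(["1"] * m, dtype=object), pos_bp=pos)


@pytest.mark.parametrize("ne", [200])
def test_ne_trajectory_recovers_constant_size(ne):
    """Within a factor of two of the true constant N for the recent bins."""
    ds = _msprime_dataset(50, ne, seed=11)
    traj = ps.ne_trajectory(ds, "POP")
    est = traj.point_estimate()
    assert np.isfinite(est)
    assert ne / 2 <= est <= ne * 2


def test_ne_trajectory_scales_with_true_size():
    e1 = ps.ne_trajectory(_msprime_dataset(50, 100, seed=5), "POP"
                          ).point_estimate()
    e2 = ps.ne_trajectory(_msprime_dataset(50, 200, seed=7), "POP"
                          ).point_estimate()
    assert 1.3 <= e2 / e1 <= 3.0


def test_ne_trajectory_empty_bin_flagged(rng):
    # two SNPs far apart: only one coarse bin is populated
    g = rng.binomial(2, 0.5, size=(30, 2)).astype(np.int8)
    ds = make_dataset(g, chrom=np.array(["1", "1"], dtype=object),
                      pos_bp=np.array([1000, 2_000_000]))
    traj = ps.ne_trajectory(ds, "POP")
    assert any(b.n_snp_pairs == 0 and np.isnan(b.ne_hat) for b in traj.bins)
    assert [b.generations_ago for b in traj.bins] == sorted(
        b.generations_ago for b in traj.bins)


def test_diversity_summary_table(rng):
    from podabc.scenario_sim import hw_fixture

    ds = hw_fixture(rng.uniform(0.1, 0.9, 50), 20, rng)
    df = ps.diversity_summary(ds)
    assert set(df.columns) >= {"breed", "n", "Ho_mean", "He_mean", "MAF_mean"}
    assert (df["n"] == 20).all()
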