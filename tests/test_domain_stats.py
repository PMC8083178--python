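import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicontacts import HiCMap, SyntheticSpec, generate_map
from hicontacts.domain_stats import (
    DomainMatrix,
    aggregate,
    call_domain_interactions,
    fit_dispersion,
    hypergeom_pvalue,
    nbinom_pvalue,
    poisson_pvalue,
)
from hicontacts.hic_io import Domain
from hicontacts.synthetic import PlantedBlock

from oracles import hypergeom_tail, nbinom_tail, poisson_tail


def _domains(bin_ranges, res=10_000, chrom="chr1"):
    return [
        Domain(chrom, lo * res, (hi + 1) * res).assign_bins(res)
        for lo, hi in bin_ranges
    ]


def _dm_with(M):
    """DomainMatrix straight from a given symmetric count matrix."""
    n = M.shape[0]
    doms = _domains([(i, i) for i in range(n)])
    return DomainMatrix(domains=doms, raw=np.asarray(M, dtype=float))


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------

def test_aggregate_block_sums():
    hic = HiCMap("chr1", 10_000, np.ones((4, 4)))
    dm = aggregate(hic, _domains([(0, 1), (2, 3)]))
    np.testing.assert_array_equal(dm.M, [[4, 4], [4, 4]])


def test_aggregate_single_domain_grand_sum(small_map):
    dm = aggregate(small_map, _domains([(0, 4)]))
    assert dm.M[0, 0] == int(round(small_map.matrix.sum()))


def test_aggregate_gap_bin_excluded():
    hic = HiCMap("chr1", 10_000, np.ones((5, 5)))
    dm = aggregate(hic, _domains([(0, 1), (3, 4)]))   # bin 2 uncovered
    np.testing.assert_array_equal(dm.M, [[4, 4], [4, 4]])
    assert dm.raw.sum() == 16   # 9 of the 25 cells dropped


def test_aggregate_empty_domains():
    hic = HiCMap("chr1", 10_000, np.ones((4, 4)))
    with pytest.raises(ValueError, match="empty"):
        aggregate(hic, [])


def test_aggregate_conservation_integer_identity():
    rng = np.random.default_rng(12)
    m = rng.integers(0, 20, size=(30, 30)).astype(float)
    m = np.triu(m) + np.triu(m, 1).T
    hic = HiCMap("chr1", 10_000, m)
    ranges = [(0, 9), (10, 19), (20, 29)]
    dm = aggregate(hic, _domains(ranges))
    assert dm.raw.sum() == m.sum()
    assert dm.K.sum() == dm.M.sum()   # sum_i K_i == sum_ij M[i,j]
    assert dm.T == (dm.M.sum() + np.trace(dm.M)) // 2


def test_aggregate_domain_outside_map():
    hic = HiCMap("chr1", 10_000, np.ones((4, 4)))
    with pytest.raises(ValueError, match="outside"):
        aggregate(hic, _domains([(0, 5)]))


# ---------------------------------------------------------------------------
# hypergeometric
# ---------------------------------------------------------------------------

def test_hypergeom_spec_example():
    # T=20, K_i=5, K_j=4, k=3 -> 155/4845
    M = np.array([[2, 3, 0], [3, 0, 1], [0, 1, 14]])
    dm = _dm_with(M)
    assert (dm.T, dm.K[0], dm.K[1], dm.M[0, 1]) == (20, 5, 4, 3)
    assert hypergeom_pvalue(dm, 0, 1) == pytest.approx(155 / 4845, rel=1e-12)


def test_hypergeom_zero_count_is_one():
    M = np.array([[4, 0], [0, 6]])
    assert hypergeom_pvalue(_dm_with(M), 0, 1) == 1.0


def test_hypergeom_oracle_grid():
    rng = np.random.default_rng(21)
    for _ in range(200):
        n = 3
        M = np.triu(rng.integers(0, 8, (n, n)))
        M = M + np.triu(M, 1).T
        dm = _dm_with(M.astype(float))
        if dm.T == 0 or dm.T > 60:
            continue
        for i in range(n):
            for j in range(i + 1, n):
                Ki, Kj = int(dm.K[i]), int(dm.K[j])
                if Ki == 0 or Kj == 0 or Ki + Kj > dm.T:
                    continue
                expected = hypergeom_tail(int(dm.M[i, j]), dm.T, Ki, Kj)
                assert hypergeom_pvalue(dm, i, j) == pytest.approx(expected, rel=1e-12)


def test_hypergeom_monotone_in_k():
    from scipy import stats
    prev = 1.1
    for k in range(0, 6):
        p = float(stats.hypergeom.sf(k - 1, 40, 10, 12))
        assert p <= prev
        prev = p


# ---------------------------------------------------------------------------
# Poisson / NB
# ---------------------------------------------------------------------------

def test_poisson_spec_examples():
    M = np.array([[0, 2, 0], [2, 0, 2], [0, 2, 88]])
    dm = _dm_with(M)
    # K0=2, K1=4, T=92
    assert _lam(dm, 0, 1) == pytest.approx(2 * 4 / (2 * 92))
    # closed-form spot checks against the partial-sum oracle
    assert poisson_tail(2, 1.0) == pytest.approx(1 - 2 / np.e, rel=1e-12)
    assert poisson_tail(4, 4.0) == pytest.approx(0.5665298796332912, rel=1e-12)


def _lam(dm, i, j):
    return float(dm.K[i]) * float(dm.K[j]) / (2.0 * dm.T)


def test_poisson_zero_count_is_one():
    M = np.array([[4, 0], [0, 6]])
    assert poisson_pvalue(_dm_with(M), 0, 1) == 1.0


def test_poisson_matches_oracle():
    rng = np.random.default_rng(22)
    for _ in range(100):
        M = np.triu(rng.integers(0, 6, (3, 3)))
        M = M + np.triu(M, 1).T
        dm = _dm_with(M.astype(float))
        if dm.T == 0:
            continue
        for i in range(3):
            for j in range(i + 1, 3):
                lam = _lam(dm, i, j)
                if lam == 0:
                    continue
                expected = poisson_tail(int(dm.M[i, j]), lam)
                assert poisson_pvalue(dm, i, j) == pytest.approx(expected, rel=1e-10)


def test_nbinom_zero_dispersion_equals_poisson():
    M = np.array([[2, 3, 1], [3, 4, 2], [1, 2, 6]]).astype(float)
    dm = _dm_with(M)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        assert nbinom_pvalue(dm, i, j, 0.0) == poisson_pvalue(dm, i, j)
        assert nbinom_pvalue(dm, i, j, -1.0) == poisson_pvalue(dm, i, j)


def test_nbinom_closed_form_at_k1():
    # mu=2, phi=0.5 -> r=2, p_nb=1/2; P(X>=1) = 1 - (1/2)^2 = 0.75
    from scipy import stats
    assert float(stats.nbinom.sf(0, 2.0, 0.5)) == pytest.approx(0.75, rel=1e-12)
    assert nbinom_tail(1, 2.0, 0.5) == pytest.approx(0.75, rel=1e-12)


def test_nbinom_matches_oracle():
    from scipy import stats
    for r, p_nb in [(2.0, 0.5), (5.0, 0.3), (0.7, 0.8)]:
        for k in range(0, 8):
            assert float(stats.nbinom.sf(k - 1, r, p_nb)) == \
                pytest.approx(nbinom_tail(k, r, p_nb), rel=1e-10)


def test_nbinom_converges_to_poisson():
    M = np.array([[2, 3, 1], [3, 4, 2], [1, 2, 6]]).astype(float)
    dm = _dm_with(M)
    for i, j in [(0, 1), (1, 2)]:
        assert abs(nbinom_pvalue(dm, i, j, 1e-6) - poisson_pvalue(dm, i, j)) < 1e-4


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=1, max_value=15), st.integers(min_value=1, max_value=15))
def test_pvalues_monotone_in_k(Ki, Kj):
    """All three tests are monotone non-increasing in the observed count."""
    from scipy import stats
    T = 40
    lam = Ki * Kj / (2 * T)
    prev_h = prev_p = prev_n = 1.1
    for k in range(0, min(Ki, Kj) + 1):
        ph = float(stats.hypergeom.sf(k - 1, T, min(Ki, T), min(Kj, T)))
        pp = float(stats.poisson.sf(k - 1, lam))
        pn = float(stats.nbinom.sf(k - 1, 2.0, 2.0 / (2.0 + lam)))
        assert ph <= prev_h + 1e-15
        assert pp <= prev_p + 1e-15
        assert pn <= prev_n + 1e-15
        prev_h, prev_p, prev_n = ph, pp, pn


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _poisson_dm(seed, n=50, phi=0.0):
    """Simulate M from the product null with optional NB overdispersion."""
    rng = np.random.default_rng(seed)
    base = rng.integers(50, 150, n).astype(float)
    T = base.sum() / 2
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mu = base[i] * base[j] / (2 * T)
            if phi <= 0:
                M[i, j] = rng.poisson(mu)
            else:
                r = 1.0 / phi
                M[i, j] = rng.negative_binomial(r, r / (r + mu))
            M[j, i] = M[i, j]
    return _dm_with(M)


def test_dispersion_zero_on_poisson_data():
    dm = _poisson_dm(seed=31, n=50)   # 1225 pairs
    assert fit_dispersion(dm) < 0.05


def test_dispersion_recovers_nb():
    dm = _poisson_dm(seed=32, n=60, phi=0.5)
    assert fit_dispersion(dm) == pytest.approx(0.5, abs=0.1)


def test_dispersion_constant_clipped_to_zero():
    M = np.full((6, 6), 4.0)
    assert fit_dispersion(_dm_with(M)) >= 0.0


def test_dispersion_too_few_pairs():
    M = np.ones((3, 3))
    with pytest.raises(ValueError, match="Poisson"):
        fit_dispersion(_dm_with(M))


# ---------------------------------------------------------------------------
# call_domain_interactions
# ---------------------------------------------------------------------------

def _block_scenario(seed):
    n_bins = 120
    ranges = [(k * 10, k * 10 + 9) for k in range(12)]
    # flat decay (gamma=0): the marginal-product null is exact-model here
    block = PlantedBlock(ranges[1], ranges[8], fold=10.0)
    spec = SyntheticSpec(n_bins=n_bins, seed=seed, shape=2.0, gamma=0.0, blocks=[block])
    hic, _ = generate_map(spec, chromosome="chrB", resolution=10_000)
    return hic, _domains(ranges, chrom="chrB")


@pytest.mark.parametrize("test_name", ["hypergeometric", "poisson", "nbinom"])
def test_planted_block_called_all_tests(test_name):
    hic, doms = _block_scenario(seed=41)
    cs = call_domain_interactions(hic, doms, test=test_name, alpha=0.01)
    assert any((c.i, c.j) == (1, 8) for c in cs.calls)


def test_uniform_map_no_hypergeom_calls():
    for seed in (51, 52, 53):
        spec = SyntheticSpec(n_bins=200, seed=seed, shape=2.0, gamma=0.0)
        hic, _ = generate_map(spec, resolution=10_000)
        doms = _domains([(k * 10, k * 10 + 9) for k in range(20)], chrom="chrS")
        cs = call_domain_interactions(hic, doms, test="hypergeometric", alpha=0.01)
        assert len(cs) == 0


def test_alpha_one_returns_all_pairs():
    hic, doms = _block_scenario(seed=41)
    cs = call_domain_interactions(hic, doms, test="poisson", alpha=1.0)
    n = len(doms)
    assert len(cs) == n * (n - 1) // 2


def test_unknown_test_name():
    hic, doms = _block_scenario(seed=41)
    with pytest.raises(ValueError, match="unknown test"):
        call_domain_interactions(hic, doms, test="gaussian")


def test_min_separation_excludes_adjacent():
    hic, doms = _block_scenario(seed=41)
    cs = call_domain_interactions(hic, doms, test="poisson", alpha=1.0, min_separation=1)
    assert all(c.j - c.i > 1 for c in cs.calls)
    assert np.isnan(cs.p_matrix[0, 1])


def test_q_ge_p_and_symmetric_matrices():
    hic, doms = _block_scenario(seed=41)
    cs = call_domain_interactions(hic, doms, test="hypergeometric", alpha=0.05)
    iu = np.triu_indices(len(doms), 1)
    p, q = cs.p_matrix[iu], cs.q_matrix[iu]
    assert (q >= p - 1e-15).all()
    np.testing.assert_array_equal(cs.p_matrix, cs.p_matrix.T)
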