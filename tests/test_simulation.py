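"""Dataset generation: batch layout, frequencies, fold change, coordinates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scpowersim as sp


# -- batch assignment -------------------------------------------------------

def test_distribute_samples_balances_cases_and_controls():
    cases = [f"case{i}" for i in range(4)]
    ctrls = [f"ctrl{i}" for i in range(4)]
    bm = sp.distribute_samples(cases, ctrls, 2)
    for batch in set(bm.values()):
        members = [s for s, b in bm.items() if b == batch]
        assert sum(m.startswith("case") for m in members) == 2
        assert sum(m.startswith("ctrl") for m in members) == 2


def test_distribute_samples_four_per_batch():
    cases = [f"case{i}" for i in range(50)]
    ctrls = [f"ctrl{i}" for i in range(50)]
    bm = sp.distribute_samples(cases, ctrls, 25)
    sizes = np.unique(list(bm.values()), return_counts=True)[1]
    assert set(sizes) == {4}


def test_distribute_samples_too_many_batches_errors():
    with pytest.raises(ValueError):
        sp.distribute_samples(["a", "b"], ["c"], 5)


def test_distribute_sample_per_batch_bijection():
    samples = [f"s{i}" for i in range(100)]
    bm = sp.distribute_sample_per_batch(samples)
    assert len(set(bm.values())) == 100
    sizes = np.unique(list(bm.values()), return_counts=True)[1]
    assert set(sizes) == {1}
    assert sp.distribute_sample_per_batch(["only"]) == {"only": "batch000"}


def test_distribute_split_sample_mixes_batches():
    samples = [f"s{i}" for i in range(100)]
    bm, parents = sp.distribute_split_sample(samples, 4, 100)
    assert len(bm) == 400
    # each batch holds 4 units from 4 distinct samples
    by_batch = {}
    for unit, batch in bm.items():
        by_batch.setdefault(batch, []).append(parents[unit])
    for members in by_batch.values():
        assert len(members) == 4 and len(set(members)) == 4
    # exhaustive scan: units of one sample never share a batch
    by_sample = {}
    for unit, parent in parents.items():
        by_sample.setdefault(parent, []).append(bm[unit])
    for batches in by_sample.values():
        assert len(set(batches)) == len(batches)


def test_distribute_split_sample_single_subsample_is_round_robin():
    samples = [f"s{i}" for i in range(8)]
    bm, parents = sp.distribute_split_sample(samples, 1, 2)
    assert set(bm) == set(samples)  # unit ids collapse to sample ids
    sizes = np.unique(list(bm.values()), return_counts=True)[1]
    assert set(sizes) == {4}


# -- cluster frequency profiles --------------------------------------------

def test_cf_profiles_zero_scale_identical(small_params, rng):
    prof = sp.sample_cf_profiles(small_params.mean_logfreq,
                                 small_params.logfreq_cov, 0.0,
                                 [f"s{i}" for i in range(5)], rng)
    expected = np.exp(small_params.mean_logfreq)
    expected /= expected.sum()
    for row in prof.to_numpy():
        np.testing.assert_allclose(row, expected, atol=1e-12)


def test_cf_profiles_sum_to_one(small_params, rng):
    prof = sp.sample_cf_profiles(small_params.mean_logfreq,
                                 small_params.logfreq_cov, 1.5,
                                 [f"s{i}" for i in range(50)], rng)
    np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-12)
    assert (prof.to_numpy() >= 0).all()


def test_cf_profiles_log_covariance_monte_carlo(rng):
    """Pre-normalisation, log draws carry covariance logfreq_cov * cf_scale."""
    mu = np.log(np.array([0.5, 0.3, 0.2]))
    cov = np.array([[0.09, 0.02, -0.01],
                    [0.02, 0.16, 0.03],
                    [-0.01, 0.03, 0.04]])
    scale = 0.7
    draws = rng.multivariate_normal(mu, cov * scale, size=10_000, method="svd")
    emp = np.cov(draws, rowvar=False)
    frob = np.linalg.norm(emp - cov * scale) / np.linalg.norm(cov * scale)
    assert frob <= 0.10


def test_cf_profiles_non_psd_errors(rng):
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
    with pytest.raises(ValueError, match="positive semidefinite"):
        sp.sample_cf_profiles(np.log([0.5, 0.5]), bad, 1.0, ["s1"], rng)


# -- fold change ------------------------------------------------------------

def test_fold_change_identity():
    p = np.array([0.2, 0.3, 0.5])
    np.testing.assert_allclose(sp.induce_fold_change(p, 0, 1.0), p)


def test_fold_change_worked_example():
    p = np.array([0.2, 0.3, 0.5])
    out = sp.induce_fold_change(p, 0, 2.0)
    np.testing.assert_allclose(out, [0.4, 0.225, 0.375])
    # brute-force renormalisation oracle
    expected = np.array([0.4, 0.3, 0.5])
    expected[1:] *= (1 - 0.4) / expected[1:].sum()
    np.testing.assert_allclose(out, expected)


def test_fold_change_cap():
    p = np.array([0.3, 0.4, 0.3])
    out = sp.induce_fold_change(p, 0, 5.0)
    assert out[0] == 1.0
    np.testing.assert_allclose(out[1:], 0.0)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
       st.floats(0.0, 10.0), st.integers(0, 7))
def test_fold_change_sums_to_one(raw, fc, tidx):
    p = np.asarray(raw) / np.sum(raw)
    tidx = tidx % len(p)
    out = sp.induce_fold_change(p, tidx, fc)
    assert abs(out.sum() - 1.0) < 1e-12
    assert (out >= -1e-15).all()
    assert out[tidx] == pytest.approx(min(fc * p[tidx], 1.0))


# -- allocation -------------------------------------------------------------

def test_allocate_even_split():
    np.testing.assert_array_equal(sp.allocate_cells([0.5, 0.5], 100), [50, 50])


def test_allocate_largest_remainder_tie_break():
    out = sp.allocate_cells([1 / 3, 1 / 3, 1 / 3], 100)
    np.testing.assert_array_equal(out, [34, 33, 33])
    # brute-force largest-remainder oracle
    exact = np.full(3, 100 / 3)
    base = np.floor(exact).astype(int)
    order = np.argsort(-(exact - base), kind="stable")
    base[order[: 100 - base.sum()]] += 1
    np.testing.assert_array_equal(out, base)


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=10),
       st.integers(0, 5000))
def test_allocate_conserves_total(raw, n):
    p = np.asarray(raw) / np.sum(raw)
    out = sp.allocate_cells(p, n)
    assert out.sum() == n
    assert (out >= 0).all()


# -- shifts and coordinates -------------------------------------------------

def test_shift_zero_scale_exact_zero(rng):
    out = sp.sample_shift(np.array([1.0, 2.0, 3.0]), 0.0, rng)
    np.testing.assert_array_equal(out, 0.0)


def test_shift_variance_monte_carlo(rng):
    diag = np.array([0.5, 2.0])
    scale = 1.5
    draws = np.array([sp.sample_shift(diag, scale, rng) for _ in range(20_000)])
    np.testing.assert_allclose(draws.var(axis=0), diag * scale, rtol=0.10)
    # independence across coordinates
    assert abs(np.corrcoef(draws.T)[0, 1]) < 0.05


def test_pc_coords_degenerate_at_centroid(rng):
    mu = np.array([1.0, -1.0, 2.0])
    out = sp.sample_pc_coords(mu, np.zeros(3), np.zeros(3), np.zeros((3, 3)),
                              10, rng)
    np.testing.assert_allclose(out, np.tile(mu, (10, 1)), atol=1e-5)


def test_pc_coords_moments_monte_carlo(rng):
    mu = np.array([2.0, -3.0])
    b = np.array([0.5, 0.0])
    s = np.array([0.0, -0.5])
    cov = np.array([[1.0, 0.3], [0.3, 0.5]])
    out = sp.sample_pc_coords(mu, b, s, cov, 50_000, rng)
    se = np.sqrt(np.diag(cov) / 50_000)
    np.testing.assert_allclose(out.mean(axis=0), mu + b + s, atol=3 * se.max())
    emp = np.cov(out, rowvar=False)
    assert np.linalg.norm(emp - cov) / np.linalg.norm(cov) <= 0.10


# -- whole-dataset generation ----------------------------------------------

def test_simulate_conserves_counts(small_params):
    design = sp.StudyDesign(n_case=2, n_control=2, cells_per_sample=100,
                            n_batches=2, seed=3)
    ds = sp.simulate_dataset(small_params, design)
    assert ds.n_cells == 400
    counts = {s: (ds.samples == s).sum() for s in set(ds.samples)}
    assert set(counts.values()) == {100}
    for s in set(ds.samples):
        assert len(set(ds.conditions[ds.samples == s])) == 1


def test_simulate_exact_fold_change_at_zero_cf_scale(small_params):
    target = small_params.cluster_labels[1]
    design = sp.StudyDesign(n_case=5, n_control=5, cells_per_sample=200,
                            n_batches=2, cf_scale=0.0, fold_change=4.0,
                            target_cluster=target, seed=9)
    prof = sp.sample_cf_profiles(small_params.mean_logfreq,
                                 small_params.logfreq_cov, 0.0,
                                 ["x"], np.random.default_rng(0)).to_numpy()[0]
    induced = sp.induce_fold_change(prof, 1, 4.0)
    ratio = induced[1] / prof[1]
    assert ratio == pytest.approx(4.0, abs=1e-12)
    # after integer allocation the realised ratio is within 1/cells_per_sample
    ds = sp.simulate_dataset(small_params, design)
    case_f = np.mean([(ds.origin_clusters[ds.samples == s] == target).mean()
                      for s in set(ds.samples[ds.conditions == "case"])])
    ctrl_f = np.mean([(ds.origin_clusters[ds.samples == s] == target).mean()
                      for s in set(ds.samples[ds.conditions == "control"])])
    assert abs(case_f - 4.0 * ctrl_f) <= 4.0 / design.cells_per_sample


def test_simulate_deterministic_under_seed(small_params):
    design = sp.StudyDesign(n_case=2, n_control=2, cells_per_sample=50,
                            n_batches=2, seed=21)
    a = sp.simulate_dataset(small_params, design)
    b = sp.simulate_dataset(small_params, design)
    np.testing.assert_array_equal(a.embeddings, b.embeddings)
    assert list(a.samples) == list(b.samples)
    assert a.target_cluster == b.target_cluster
    design2 = sp.StudyDesign(n_case=2, n_control=2, cells_per_sample=50,
                             n_batches=2, seed=22)
    c = sp.simulate_dataset(small_params, design2)
    assert not np.array_equal(a.embeddings, c.embeddings)


def test_simulate_no_shift_scales_identical_distributions(small_params):
    """b_scale=s_scale=0: coordinates of a cluster look the same across
    batches (two-sample test does not reject beyond nominal)."""
    from scipy import stats
    design = sp.StudyDesign(n_case=4, n_control=4, cells_per_sample=300,
                            n_batches=2, b_scale=0.0, s_scale=0.0, seed=17)
    ds = sp.simulate_dataset(small_params, design)
    label = small_params.cluster_labels[0]
    mask = ds.origin_clusters == label
    batches = sorted(set(ds.batches))
    x = ds.embeddings[mask & (ds.batches == batches[0]), 0]
    y = ds.embeddings[mask & (ds.batches == batches[1]), 0]
    assert stats.ks_2samp(x, y).pvalue > 0.01
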