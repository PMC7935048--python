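"""State clustering, fraction rates, centroid matching and FNC vectorization."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fbconn import (
    BandedConnectivity,
    FilterDesignSpec,
    ObservationMatrix,
    WindowSpec,
    assemble_observations,
    build_bank_from_edges,
    centroid_similarity,
    cluster_states,
    devectorize_fnc,
    elbow_curve,
    fraction_rates,
    match_states,
    vectorize_fnc,
)


def make_obs(values, subjects=None, bands=None, times=None):
    n = values.shape[0]
    return ObservationMatrix(
        values=values,
        subjects=np.asarray(subjects if subjects is not None else ["s"] * n),
        bands=np.asarray(bands if bands is not None else np.zeros(n, int)),
        times=np.asarray(times if times is not None else np.arange(n)),
    )


@pytest.fixture(scope="module")
def toy_bank():
    spec = FilterDesignSpec(sampling_hz=1.0, n_bands=2)
    return build_bank_from_edges([(0.0, 0.025), (0.025, 0.075)], spec)


def make_banded(rng, bank, subject, n_bands=2, n_t=140, n_p=6):
    n_c = int((1 + np.sqrt(1 + 8 * n_p)) / 2)
    iu, ju = np.triu_indices(n_c, 1)
    return BandedConnectivity(
        values=rng.standard_normal((n_bands, n_t, n_p)),
        bank=bank,
        window=WindowSpec(5),
        pair_index=list(zip(iu.tolist(), ju.tolist())),
        time_offset=5,
        tr_seconds=1.0,
        subject_id=subject,
    )


# ---------------------------------------------------------------------------
# vectorization
# ---------------------------------------------------------------------------

def test_vectorize_round_trip_and_pair_count(rng):
    m = rng.standard_normal((47, 47))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    v = vectorize_fnc(m)
    assert v.shape == (1081,)
    back = devectorize_fnc(v, diagonal=1.0)
    assert np.allclose(back, m)
    assert np.array_equal(vectorize_fnc(back), v)


def test_vectorize_3x3_hand_case():
    m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    assert np.array_equal(vectorize_fnc(m), [1.0, 2.0, 3.0])
    assert np.array_equal(devectorize_fnc([1.0, 2.0, 3.0]), m)
    assert np.array_equal(np.diag(devectorize_fnc([1.0, 2.0, 3.0], diagonal=1.0)), np.ones(3))


def test_vectorize_rejects_asymmetry_and_bad_length():
    with pytest.raises(ValueError, match="symmetric"):
        vectorize_fnc(np.array([[0.0, 1.0], [0.5, 0.0]]))
    with pytest.raises(ValueError, match="pair count"):
        devectorize_fnc(np.arange(4.0))


@settings(max_examples=20, derandomize=True)
@given(st.integers(2, 12), st.integers(0, 10**6))
def test_vectorize_devectorize_identity(n, seed):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((n, n))
    m = m + m.T
    np.fill_diagonal(m, 0.0)
    assert np.array_equal(devectorize_fnc(vectorize_fnc(m)), m)


# ---------------------------------------------------------------------------
# observation assembly
# ---------------------------------------------------------------------------

def test_assemble_shape_and_row_order(rng, toy_bank):
    banded = [make_banded(rng, toy_bank, s) for s in ("s01", "s02")]
    obs = assemble_observations(banded)
    assert obs.values.shape == (2 * 2 * 140, 6)
    # deterministic (subject, band, time) ordering and indexing round trip
    for row in rng.integers(0, obs.n_rows, size=50):
        b = banded[0 if obs.subjects[row] == "s01" else 1]
        assert np.array_equal(
            obs.values[row], b.values[obs.bands[row], obs.times[row]]
        )
    first = obs.n_rows // 2
    assert np.all(obs.subjects[:first] == "s01")
    assert np.all(np.diff(obs.bands[:first]) >= 0)


def test_assemble_single_band_row_count(rng, toy_bank):
    b = make_banded(rng, toy_bank, "solo", n_bands=2)
    b.values = b.values[:1]
    obs = assemble_observations([b])
    assert obs.n_rows == 140


def test_assemble_drops_missing_rows_and_counts(rng, toy_bank):
    b = make_banded(rng, toy_bank, "s01")
    b.values[0, 3, 2] = np.nan
    b.values[1, 7, 0] = np.nan
    obs = assemble_observations([b])
    assert obs.n_dropped == 2
    assert obs.n_rows == 2 * 140 - 2


def test_assemble_rejects_mismatched_pair_order(rng, toy_bank):
    b1 = make_banded(rng, toy_bank, "s01")
    b2 = make_banded(rng, toy_bank, "s02")
    b2.pair_index = list(reversed(b2.pair_index))
    with pytest.raises(ValueError, match="pair"):
        assemble_observations([b1, b2])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_k1_centroid_is_grand_mean(rng):
    obs = make_obs(rng.standard_normal((200, 5)))
    model = cluster_states(obs, k=1, replicates=2, seed=0)
    assert np.allclose(model.centroids[0], obs.values.mean(axis=0))


def test_well_separated_blobs_recovered_exactly(rng):
    centres = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 10], [-10, -10, -10]], float)
    truth = rng.integers(0, 4, size=400)
    obs = make_obs(centres[truth] + 0.05 * rng.standard_normal((400, 3)))
    model = cluster_states(obs, k=4, replicates=5, seed=1)
    # perfect partition up to label permutation
    joint = pd.crosstab(truth, model.labels).to_numpy()
    assert (joint > 0).sum() == 4


def test_inertia_matches_brute_force_recomputation(rng):
    obs = make_obs(rng.standard_normal((300, 4)))
    model = cluster_states(obs, k=3, replicates=5, seed=2)
    recomputed = np.sum((obs.values - model.centroids[model.labels]) ** 2)
    assert model.inertia == pytest.approx(recomputed, rel=1e-9)


def test_clustering_is_reproducible_under_fixed_seed(rng):
    obs = make_obs(rng.standard_normal((250, 4)))
    a = cluster_states(obs, k=4, replicates=6, seed=11)
    b = cluster_states(obs, k=4, replicates=6, seed=11)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.centroids, b.centroids)


def test_states_ordered_by_descending_occupancy(rng):
    centres = np.array([[10.0, 0.0], [-10.0, 0.0]])
    truth = np.array([0] * 30 + [1] * 170)
    obs = make_obs(centres[truth] + 0.1 * rng.standard_normal((200, 2)))
    model = cluster_states(obs, k=2, replicates=3, seed=0)
    counts = np.bincount(model.labels)
    assert counts[0] >= counts[1]


def test_k_exceeding_rows_raises(rng):
    obs = make_obs(rng.standard_normal((5, 2)))
    with pytest.raises(ValueError, match="k=10"):
        cluster_states(obs, k=10, replicates=2, seed=0)


def test_elbow_inertia_non_increasing_and_zero_at_distinct_rows(rng):
    vals = rng.standard_normal((60, 3))
    obs = make_obs(vals)
    curve = elbow_curve(obs, [1, 2, 3, 4, 5, 6], replicates=3, seed=4)
    assert np.all(np.diff(curve["inertia"]) <= 1e-9)
    distinct = make_obs(np.unique(vals, axis=0)[:8])
    full = elbow_curve(distinct, [8], replicates=2, seed=0)
    assert full["inertia"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_elbow_sharpest_drop_at_true_k(rng):
    centres = np.array([[20, 0], [0, 20], [-20, 0], [0, -20]], float)
    truth = rng.integers(0, 4, size=300)
    obs = make_obs(centres[truth] + 0.2 * rng.standard_normal((300, 2)))
    curve = elbow_curve(obs, [1, 2, 3, 4, 5, 6], replicates=4, seed=7)
    inertia = curve["inertia"].to_numpy()
    drops = inertia[:-1] - inertia[1:]          # drop achieved moving to k+1
    assert np.argmax(drops / inertia[:-1] > 0.9) == 2   # going from k=3 to k=4


# ---------------------------------------------------------------------------
# fraction rates
# ---------------------------------------------------------------------------

def test_fraction_rates_conservation_and_degenerate_case(rng):
    n = 400
    obs = make_obs(
        rng.standard_normal((n, 3)),
        subjects=np.repeat(["s01", "s02"], n // 2),
        bands=np.tile(np.repeat([0, 1], n // 4), 2),
    )
    model = cluster_states(obs, k=3, replicates=3, seed=0)
    table = fraction_rates(model, obs)
    sums = table.per_band.groupby(["subject", "band"])["fraction"].sum()
    assert np.allclose(sums, 1.0, atol=1e-12)
    assert table.per_band["fraction"].between(0, 1).all()

    # all observations in one state
    model.labels[:] = 1
    table1 = fraction_rates(model, obs)
    piv = table1.overall.pivot(index="subject", columns="state", values="fraction")
    assert np.allclose(piv[1], 1.0) and np.allclose(piv.drop(columns=1), 0.0)


def test_uniform_random_labels_give_uniform_fractions(rng):
    n, k = 80000, 8
    obs = make_obs(np.zeros((n, 1)))
    from fbconn import StateModel

    labels = rng.integers(0, k, size=n)
    model = StateModel(k=k, centroids=np.zeros((k, 1)), labels=labels,
                       inertia=0.0, replicates=0)
    table = fraction_rates(model, obs)
    p = 1 / k
    ci = 4 * np.sqrt(p * (1 - p) / n)
    assert np.all(np.abs(table.overall["fraction"] - p) < ci)


# ---------------------------------------------------------------------------
# centroid similarity / matching
# ---------------------------------------------------------------------------

def test_centroid_similarity_identity_sign_and_oracle(rng):
    a = rng.standard_normal((4, 15))
    sim = centroid_similarity(a, a)
    assert np.allclose(np.diag(sim), 1.0)
    assert np.allclose(np.diag(centroid_similarity(a, -a)), -1.0)
    for i in range(4):
        for j in range(4):
            assert sim[i, j] == pytest.approx(np.corrcoef(a[i], a[j])[0, 1], abs=1e-12)


def test_centroid_similarity_zero_variance_gives_missing(rng, caplog):
    a = rng.standard_normal((2, 6))
    b = np.vstack([np.ones(6), rng.standard_normal(6)])
    with caplog.at_level("WARNING", logger="fbconn"):
        sim = centroid_similarity(a, b)
    assert np.isnan(sim[:, 0]).all()
    assert np.isfinite(sim[:, 1]).all()


def test_match_states_recovers_permutation_and_sign(rng):
    ref = rng.standard_normal((5, 20))
    perm = np.array([3, 0, 4, 1, 2])
    est = ref[perm]
    assignment, corr = match_states(est, ref)
    assert np.array_equal(est[assignment], ref)
    assert np.allclose(corr, 1.0)

    est_flip = ref.copy()
    est_flip[2] = -est_flip[2]
    _, corr = match_states(est_flip, ref)
    assert corr[2] == pytest.approx(-1.0)
    assert np.allclose(np.delete(corr, 2), 1.0)


def test_match_states_equals_exhaustive_search(rng):
    est = rng.standard_normal((4, 10))
    ref = rng.standard_normal((4, 10))
    _, matched = match_states(est, ref)
    sim = centroid_similarity(ref, est)
    best = max(
        sum(sim[r, p[r]] for r in range(4)) for p in permutations(range(4))
    )
    assert matched.sum() == pytest.approx(best, abs=1e-8)


def test_match_states_size_mismatch(rng):
    with pytest.raises(ValueError, match="equally many"):
        match_states(rng.standard_normal((3, 5)), rng.standard_normal((4, 5)))
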