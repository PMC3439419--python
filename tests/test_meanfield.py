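import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from opinioncusp import meanfield as mf
from opinioncusp.microdynamics import CONV_SECOND, receive_message
from opinioncusp.states import N_STATES, STATE_INDEX, all_states

STATES = all_states()


def brute_force_step_single(n, media=None):
    """Independent oracle: accumulate the single-message map pair by pair
    through the rule primitives, without the transition tensor."""
    n = np.asarray(n, float)
    if media is None:
        q, scale = n, 1.0
    else:
        q, scale = n + media.rates, 1.0 + media.total
    out = np.zeros(N_STATES)
    for r in STATES:
        for s in STATES:
            out[STATE_INDEX[receive_message(r, s)]] += (
                n[STATE_INDEX[r]] * q[STATE_INDEX[s]] / scale
            )
    return out / out.sum()


composition_st = arrays(
    float, N_STATES, elements=st.floats(0.01, 1.0)
).map(lambda v: v / v.sum())


# --- compositions and averages ---------------------------------------------

def test_as_composition_rejects_bad_input():
    with pytest.raises(ValueError):
        mf.as_composition([0.5, 0.5])
    with pytest.raises(ValueError):
        mf.as_composition([0.3] * 7)
    with pytest.raises(ValueError):
        mf.as_composition([1.2, -0.2, 0, 0, 0, 0, 0])


@pytest.mark.parametrize(
    "fractions,expected",
    [
        ({"APP": 1.0}, (1.0, 1.0, 1.0)),
        ({"CMM": 0.5, "CPP": 0.5}, (0.0, 0.0, 0.0)),
        ({"CMM": 0.6, "AMM": 0.2, "A0P": 0.2}, (0.4, -0.8, -0.6)),
    ],
)
def test_averages(fractions, expected):
    comp = mf.composition_from_labels(fractions)
    assert mf.averages(comp) == pytest.approx(expected)


# --- step maps --------------------------------------------------------------

def test_consensus_is_fixed_under_both_modes():
    for lab in ("CMM", "C00", "CPP"):
        n = mf.composition_from_labels({lab: 1.0})
        np.testing.assert_allclose(mf.step_single(n), n, atol=1e-15)
        np.testing.assert_allclose(mf.step_conversation(n), n, atol=1e-15)


def test_step_single_worked_example():
    n = mf.composition_from_labels({"CMM": 0.5, "A0P": 0.5})
    expected = mf.composition_from_labels({"CMM": 0.25, "AMM": 0.25, "A0P": 0.5})
    np.testing.assert_allclose(mf.step_single(n), expected, atol=1e-15)


def test_step_single_with_media_worked_example():
    n = mf.composition_from_labels({"C00": 1.0})
    media = mf.MediaSource.from_labels({"CPP": 1.0})
    expected = mf.composition_from_labels({"C00": 0.5, "CPP": 0.5})
    np.testing.assert_allclose(mf.step_single(n, media), expected, atol=1e-15)


@given(composition_st)
@settings(deadline=None, max_examples=60)
def test_simplex_conservation(n):
    for mode in mf.MODES:
        for media in (None, mf.MediaSource.from_labels({"CPP": 0.2, "APP": 0.1})):
            out = mf.step(n, mode, media)
            assert abs(out.sum() - 1.0) < 1e-12
            assert np.all(out >= 0)


@given(composition_st)
@settings(deadline=None, max_examples=60)
def test_mirror_equivariance_of_step_maps(n):
    media = mf.MediaSource.from_labels({"CPP": 0.3, "AMM": 0.1})
    for mode in mf.MODES:
        lhs = mf.mirror_composition(mf.step(n, mode, media))
        rhs = mf.step(mf.mirror_composition(n), mode, media.mirrored())
        np.testing.assert_allclose(lhs, rhs, atol=1e-14)


def test_table_driven_step_equals_rule_driven_oracle(random_compositions):
    media = mf.MediaSource.from_labels({"CPP": 0.25})
    for n in random_compositions:
        np.testing.assert_allclose(
            mf.step_single(n), brute_force_step_single(n), atol=1e-14
        )
        np.testing.assert_allclose(
            mf.step_single(n, media), brute_force_step_single(n, media), atol=1e-14
        )


def test_conversation_step_equals_pairwise_accumulation(random_compositions):
    for n in random_compositions[:20]:
        out = np.zeros(N_STATES)
        for i in range(N_STATES):
            for j in range(N_STATES):
                out[CONV_SECOND[i, j]] += n[i] * n[j]
        np.testing.assert_allclose(mf.step_conversation(n), out / out.sum(),
                                   atol=1e-14)


@pytest.mark.parametrize("a", np.arange(0.05, 0.46, 0.05))
def test_balanced_minority_family_is_stationary_in_both_modes(a):
    n = np.zeros(N_STATES)
    n[0], n[3], n[5] = 1 - 2 * a, a, a  # CMM, AMM, A0P
    for comp in (n, mf.mirror_composition(n)):
        for mode in mf.MODES:
            assert np.abs(mf.step(comp, mode) - comp).sum() < 1e-14


def test_calm_only_closure_under_single_messages():
    n = mf.composition_from_labels({"CMM": 0.3, "C00": 0.5, "CPP": 0.2})
    media = mf.MediaSource.from_labels({"CPP": 0.4})
    for media_case in (None, media):
        out = mf.step_single(n, media_case)
        assert np.all(out[3:] == 0)


def test_conversation_mode_depletes_the_uninformed_calm_state():
    n = mf.composition_from_labels({"CMM": 0.3, "C00": 0.5, "CPP": 0.2})
    _, final, converged, _ = mf.iterate(n, "conversation", record=False)
    assert converged
    assert final[1] < 1e-8  # n_C00 -> 0
    n = mf.composition_from_labels({"C00": 1.0})
    np.testing.assert_allclose(mf.step_conversation(n), n, atol=1e-15)


# --- iteration --------------------------------------------------------------

def test_iterate_consensus_converges_immediately():
    n = mf.composition_from_labels({"CPP": 1.0})
    traj, final, converged, used = mf.iterate(n, "single")
    assert converged and used == 1
    np.testing.assert_allclose(final, n)


def test_iterate_interior_calm_fixed_point_is_stationary():
    n = mf.composition_from_labels({"CMM": 1 / 3, "C00": 1 / 3, "CPP": 1 / 3})
    np.testing.assert_allclose(mf.step_single(n), n, atol=1e-15)


def test_iterate_records_trajectory_on_the_simplex(negative_lean):
    traj, final, converged, used = mf.iterate(negative_lean, "single")
    assert converged
    sums = traj.compositions.sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    assert np.all(traj.compositions >= 0)
    assert traj.compositions.shape == (used + 1, N_STATES)
    df = traj.to_frame()
    assert list(df.columns[:2]) == ["tick", "n_CMM"]


def test_iterate_nonconvergence_sets_flag(negative_lean):
    _, _, converged, used = mf.iterate(negative_lean, "single", max_iter=3)
    assert not converged and used == 3


# --- fixed points and stability ---------------------------------------------

def test_calm_only_fixed_points_single_mode():
    results = mf.calm_only_fixed_points("single")
    by_class = {}
    for comp, rep in results:
        assert len(rep.eigenvalues) == 2
        by_class.setdefault(rep.classification, []).append(comp)
    attractors = by_class["attractor"]
    assert len(attractors) == 2
    for comp in attractors:
        assert comp.max() == pytest.approx(1.0)  # the two consensus states
    (saddle,) = by_class["saddle"]
    np.testing.assert_allclose(saddle[:3], 1 / 3, atol=1e-8)
    (_, rep), = [(c, r) for c, r in results if r.classification == "saddle"]
    mods = np.abs(rep.eigenvalues)
    assert mods.min() < 1 < mods.max()  # tangent eigenvalues straddle 1
    # the all-uninformed point is fixed too, but repelling
    assert "repeller" in by_class


def test_calm_only_conversation_edge_is_stationary():
    results = mf.calm_only_fixed_points("conversation", grid=10)
    for comp, _ in results:
        assert np.abs(mf.step_conversation(comp) - comp).sum() < 1e-12


def test_jacobian_classifications():
    pure_cmm = mf.composition_from_labels({"CMM": 1.0})
    # consensus sits at the end of a fixed-point continuum: marginal in
    # the full 7-state space
    rep = mf.jacobian(pure_cmm, "single")
    assert len(rep.eigenvalues) == 6
    assert rep.moduli.max() <= 1 + 1e-6
    family = mf.composition_from_labels({"CMM": 0.6, "AMM": 0.2, "A0P": 0.2})
    rep = mf.jacobian(family, "single")
    assert rep.classification == "marginal"
    assert np.any(np.abs(rep.moduli - 1) < 1e-4)
    mirrored = mf.jacobian(mf.mirror_composition(family), "single")
    assert mirrored.classification == rep.classification


def test_jacobian_rejects_off_simplex_points():
    with pytest.raises(ValueError):
        mf.jacobian(np.full(7, 0.2))


# --- families, sampling, basins ---------------------------------------------

def test_classify_family_examples():
    assert mf.classify_family(
        mf.composition_from_labels({"CMM": 0.6, "AMM": 0.2, "A0P": 0.2})
    ) == mf.FAMILY_MINUS
    assert mf.classify_family(
        mf.composition_from_labels({"CPP": 1.0})
    ) == mf.FAMILY_PLUS
    assert mf.classify_family(
        mf.composition_from_labels({"C00": 1.0})
    ) == mf.NEUTRAL_CALM
    assert mf.classify_family(
        mf.composition_from_labels({"CMM": 0.5, "CPP": 0.5})
    ) == mf.OTHER  # not stationary under the single-message map


def test_uniform_simplex_sampler():
    rng = np.random.default_rng(11)
    draws = mf.sample_uniform_composition(rng, 100_000)
    assert draws.shape == (100_000, 7)
    np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(draws >= 0)
    # flat Dirichlet: per-coordinate mean 1/7, sd of the mean ~ 4e-4
    np.testing.assert_allclose(draws.mean(axis=0), 1 / 7, atol=3e-3)
    again = mf.sample_uniform_composition(np.random.default_rng(11), 100_000)
    np.testing.assert_array_equal(draws, again)


def test_basin_frequencies_small_run_is_mirror_balanced():
    freqs = mf.basin_frequencies(n_samples=400, seed=5)
    assert sum(freqs.values()) == pytest.approx(1.0)
    assert freqs[mf.FAMILY_MINUS] > 0.35
    assert freqs[mf.FAMILY_PLUS] > 0.35
    assert abs(freqs[mf.FAMILY_MINUS] - freqs[mf.FAMILY_PLUS]) < 0.12
    again = mf.basin_frequencies(n_samples=400, seed=5)
    assert freqs == again  # seeded reproducibility


# --- media scans -------------------------------------------------------------

def test_media_scan_requires_grid(negative_lean):
    with pytest.raises(ValueError):
        mf.media_scan(negative_lean, mf.MediaSource.from_labels({"CPP": 1}), [])


def test_media_scan_records_and_critical_rate(negative_lean):
    media = mf.MediaSource.from_labels({"CPP": 1.0})
    scan = mf.media_scan(negative_lean, media, [0.02, 0.3], "single")
    assert len(scan.records) == 2
    assert scan.records[0]["avg_O"] < 0 < scan.records[1]["avg_O"]
    assert 0.02 < scan.critical_rate < 0.3
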