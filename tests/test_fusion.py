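import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from typoclust.fusion import (EPS, FusionConfig, ModelOutput, entropy, fuse,
                              fuse_type1, fuse_type2, fuse_type3, fuse_type4)


def test_entropy_maximum_at_half():
    assert entropy(0.5) == pytest.approx(np.log(2))


def test_entropy_clipped_limits():
    assert entropy(0.0) == pytest.approx(0.0, abs=1e-9)
    assert entropy(1.0) == pytest.approx(0.0, abs=1e-9)


def test_entropy_symmetry():
    for p in np.arange(0.1, 1.0, 0.1):
        assert entropy(p) == pytest.approx(entropy(1 - p))


def test_entropy_rejects_out_of_range():
    with pytest.raises(ValueError):
        entropy(1.2)
    with pytest.raises(ValueError):
        ModelOutput(np.array([-0.1, 0.5]))


# --- type 1 ---------------------------------------------------------------

def test_type1_endpoints_reproduce_each_model():
    pp = np.array([0.9, 0.2, 0.6])
    pg = np.array([0.1, 0.8, 0.4])
    assert (fuse_type1(pp, pg, 0.0)[1] == (pp >= 0.5)).all()
    assert (fuse_type1(pp, pg, 1.0)[1] == (pg >= 0.5)).all()


def test_type1_midpoint_threshold_rule():
    p, lab = fuse_type1(np.array([0.8]), np.array([0.2]), 0.5)
    assert p[0] == pytest.approx(0.5)
    assert lab[0] == 1  # >= 0.5 goes positive


def test_type1_alpha_out_of_range_raises():
    with pytest.raises(ValueError):
        fuse_type1(np.array([0.5]), np.array([0.5]), 1.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1),
       st.lists(st.floats(0, 1), min_size=2, max_size=6).map(sorted))
def test_type1_monotone_interpolation(pp, pg, alphas):
    fused = [fuse_type1(np.array([pp]), np.array([pg]), a)[0][0] for a in alphas]
    diffs = np.diff(fused)
    if pg >= pp:
        assert np.all(diffs >= -1e-12)
    else:
        assert np.all(diffs <= 1e-12)
    assert all(min(pp, pg) - 1e-12 <= f <= max(pp, pg) + 1e-12 for f in fused)


# --- type 2 ---------------------------------------------------------------

def test_type2_prefers_confident_model():
    out = fuse_type2(ModelOutput([0.9]), ModelOutput([0.55]))
    assert out[0] == 1  # h(0.9) < h(0.55) -> personalized label
    out = fuse_type2(ModelOutput([0.5]), ModelOutput([1.0]))
    assert out[0] == 1  # general is maximally confident


def test_type2_tie_goes_to_personalized():
    out = fuse_type2(ModelOutput([0.3]), ModelOutput([0.3]))
    assert out[0] == 0
    out = fuse_type2(ModelOutput([0.7]), ModelOutput([0.3]))  # equal entropies
    assert out[0] == 1  # personalized label wins the tie


# --- type 3 ---------------------------------------------------------------

def test_type3_equal_entropies_average_probabilities():
    p, lab = fuse_type3(ModelOutput([0.7]), ModelOutput([0.3]))
    assert p[0] == pytest.approx(0.5)
    assert lab[0] == 1


def test_type3_confident_model_dominates():
    p, lab = fuse_type3(ModelOutput([1.0]), ModelOutput([0.4]))
    assert p[0] == pytest.approx(1.0, abs=1e-6)
    assert lab[0] == 1


def test_type3_hand_computed_example():
    p, lab = fuse_type3(ModelOutput([0.9]), ModelOutput([0.4]))
    h_p, h_g = entropy(0.9), entropy(0.4)
    assert h_p == pytest.approx(0.3251, abs=1e-4)
    assert h_g == pytest.approx(0.6730, abs=1e-4)
    assert p[0] == pytest.approx(0.7372, abs=1e-4)
    assert lab[0] == 1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
def test_type3_is_convex_combination(pp, pg):
    p, _ = fuse_type3(ModelOutput([pp]), ModelOutput([pg]))
    assert min(pp, pg) - 1e-9 <= p[0] <= max(pp, pg) + 1e-9


# --- type 4 ---------------------------------------------------------------

@pytest.mark.parametrize("a,b,expect", [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 1)])
def test_type4_or_truth_table(a, b, expect):
    assert fuse_type4([a], [b])[0] == expect


def test_type4_rejects_non_binary():
    with pytest.raises(ValueError):
        fuse_type4([0.5], [1])


def test_type4_never_decreases_recall(rng):
    y = rng.integers(0, 2, 200)
    lp = rng.integers(0, 2, 200)
    lg = rng.integers(0, 2, 200)
    fused = fuse_type4(lp, lg)
    pos = y == 1
    recall = lambda pred: (pred[pos] == 1).mean()
    assert recall(fused) >= max(recall(lp), recall(lg))


# --- dispatch and aggregation --------------------------------------------

def test_dispatch_validates_config():
    out_p, out_g = ModelOutput([0.8]), ModelOutput([0.3])
    assert fuse(out_p, out_g, FusionConfig("type4"))[0] == 1
    with pytest.raises(ValueError, match="alpha"):
        fuse(out_p, out_g, FusionConfig("type1"))
    with pytest.raises(ValueError, match="strategy"):
        FusionConfig("type9").validate()


def test_window_probs_aggregate_to_stimulus_means():
    out = ModelOutput.from_window_probs([0.2, 0.4, 0.9, 0.7],
                                        ["s1", "s1", "s0", "s0"])
    np.testing.assert_allclose(out.probabilities, [0.8, 0.3])
    np.testing.assert_array_equal(out.labels, [1, 0])
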