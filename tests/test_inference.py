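"""Two-stage inference: set-likelihood ranking, NNLS reconstruction against a
brute-force oracle, and the residual-based ternary decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sersmix.inference import (
    InferenceConfig,
    ReconstructionResult,
    build_prototypes,
    candidate_sets,
    missing_ratio,
    nnls_reconstruct,
    rank_binary,
    refine,
    residual_gain,
    set_likelihood,
)
from sersmix.spectra import COMPONENTS


# ---- stage 1: set likelihood ----------------------------------------

def test_symmetric_probabilities_tie_all_pairs():
    p = np.array([0.5, 0.5, 0.5])
    scores = {S: set_likelihood(p, S) for S in candidate_sets("pairs_only")}
    vals = list(scores.values())
    assert all(v == pytest.approx(3 * np.log(0.5)) for v in vals)


def test_set_likelihood_direct_arithmetic():
    p = np.array([0.9, 0.8, 0.1])
    expected = np.log(0.9) + np.log(0.8) + np.log(1 - 0.1)
    assert set_likelihood(p, ("A", "B")) == pytest.approx(expected)
    assert expected == pytest.approx(-0.4339, abs=5e-5)


def test_saturated_probabilities_clamped():
    p = np.array([1.0, 1.0, 0.0])
    score = set_likelihood(p, ("A", "B"), eps=1e-7)
    assert score == pytest.approx(3 * np.log(1 - 1e-7), abs=1e-12)
    others = [set_likelihood(p, S, eps=1e-7)
              for S in candidate_sets("pairs_only") if S != ("A", "B")]
    assert all(score > o for o in others)


def test_empty_candidate_set_rejected():
    with pytest.raises(ValueError):
        set_likelihood(np.array([0.5, 0.5, 0.5]), ())


def test_rank_binary_picks_dominant_pair():
    S, scores = rank_binary(np.array([0.95, 0.9, 0.05]), InferenceConfig())
    assert S == ("A", "B")
    assert set(scores) == {"AB", "AC", "BC"}


def test_rank_binary_tie_breaks_lexicographically():
    S, _ = rank_binary(np.array([0.5, 0.5, 0.5]), InferenceConfig())
    assert S == ("A", "B")


def test_unified_mode_lets_singleton_win():
    cfg = InferenceConfig(candidate_mode="unified")
    S, _ = rank_binary(np.array([0.99, 0.01, 0.01]), cfg)
    assert S == ("A",)


@settings(deadline=None, max_examples=200)
@given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3))
def test_rank_binary_equals_brute_force(probs):
    p = np.array(probs)
    for mode in ("pairs_only", "unified"):
        cfg = InferenceConfig(candidate_mode=mode)
        S, scores = rank_binary(p, cfg)
        cands = candidate_sets(mode)
        brute = [set_likelihood(p, c, cfg.prob_clamp) for c in cands]
        assert scores["".join(S)] == pytest.approx(max(brute))


# ---- prototypes and NNLS --------------------------------------------

def test_prototypes_are_classwise_means():
    feats = {
        "A": np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]),
        "B": np.array([[4.0, 4.0, 4.0]]),
        "C": np.array([[0.0, 1.0, 0.0], [0.0, 3.0, 0.0]]),
    }
    protos = build_prototypes(feats)
    np.testing.assert_allclose(protos["A"], [2.0, 2.0, 2.0])
    np.testing.assert_allclose(protos["B"], [4.0, 4.0, 4.0])
    np.testing.assert_allclose(protos["C"], [0.0, 2.0, 0.0])


def test_prototypes_require_all_classes():
    with pytest.raises(ValueError, match="C"):
        build_prototypes({"A": np.ones((1, 3)), "B": np.ones((1, 3))})


def test_nnls_recovers_exact_nonnegative_combination():
    rng = np.random.default_rng(0)
    protos = {c: rng.random(32) for c in COMPONENTS}
    x = 0.5 * protos["A"] + 0.5 * protos["B"]
    res = nnls_reconstruct(x, protos, ("A", "B"))
    np.testing.assert_allclose(res.beta, [0.5, 0.5], atol=1e-10)
    assert res.e == pytest.approx(0.0, abs=1e-18)


def test_nnls_clamps_to_boundary_for_anticorrelated_input():
    protos = {"A": np.array([1.0, 0.0]), "B": np.array([0.0, 1.0]),
              "C": np.array([1.0, 1.0])}
    x = np.array([-1.0, -1.0])
    res = nnls_reconstruct(x, protos, COMPONENTS)
    np.testing.assert_allclose(res.beta, 0.0)
    assert res.e == pytest.approx(float(x @ x))


def test_nnls_rejects_nonfinite_input():
    protos = {c: np.ones(4) for c in COMPONENTS}
    with pytest.raises(ValueError):
        nnls_reconstruct(np.array([1.0, np.nan, 0.0, 0.0]), protos, ("A",))


def test_nnls_matches_grid_search_oracle():
    """Reconstruction error equals a dense grid search over beta within grid
    resolution, on random small instances."""
    rng = np.random.default_rng(7)
    grid = np.linspace(0.0, 2.0, 81)
    for _ in range(20):
        protos = {c: rng.random(16) for c in COMPONENTS}
        x = rng.random(16) * 1.5
        res = nnls_reconstruct(x, protos, ("A", "B"))
        P = np.column_stack([protos["A"], protos["B"]])
        B1, B2 = np.meshgrid(grid, grid, indexing="ij")
        combos = np.stack([B1.ravel(), B2.ravel()])
        errs = ((x[:, None] - P @ combos) ** 2).sum(axis=0)
        e_grid = errs.min()
        assert res.e <= e_grid + 1e-12
        h = grid[1] - grid[0]
        curvature = np.linalg.norm(P, 2) ** 2
        assert e_grid - res.e <= curvature * (2 * h) ** 2


def test_nnls_nesting_supports():
    rng = np.random.default_rng(8)
    for _ in range(50):
        protos = {c: rng.random(16) for c in COMPONENTS}
        x = rng.random(16)
        e_bin = nnls_reconstruct(x, protos, ("A", "B")).e
        e_tri = nnls_reconstruct(x, protos, COMPONENTS).e
        assert e_tri <= e_bin + 1e-12


# ---- stage 2: residual gain, missing ratio, decision ----------------

def test_residual_gain_values():
    assert residual_gain(0.5, 0.5) == 0.0
    assert residual_gain(0.5, 0.0) == 1.0
    assert residual_gain(0.10, 0.08) == pytest.approx(0.2)
    assert residual_gain(0.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        residual_gain(-0.1, 0.0)


def test_missing_ratio_values():
    tri = ReconstructionResult(tuple(COMPONENTS), np.array([0.4, 0.4, 0.2]), 0.0)
    assert missing_ratio(tri, ("A", "B")) == pytest.approx(0.2)
    tri0 = ReconstructionResult(tuple(COMPONENTS), np.array([0.5, 0.5, 0.0]), 0.0)
    assert missing_ratio(tri0, ("A", "B")) == 0.0
    tri1 = ReconstructionResult(tuple(COMPONENTS), np.array([0.0, 0.0, 1.0]), 0.0)
    assert missing_ratio(tri1, ("A", "B")) == 1.0
    allz = ReconstructionResult(tuple(COMPONENTS), np.zeros(3), 0.0)
    assert missing_ratio(allz, ("A", "B")) == 0.0


def test_missing_ratio_validates_supports():
    tri = ReconstructionResult(("A", "B"), np.array([0.5, 0.5]), 0.0)
    with pytest.raises(ValueError):
        missing_ratio(tri, ("A", "B"))
    full = ReconstructionResult(tuple(COMPONENTS), np.ones(3), 0.0)
    with pytest.raises(ValueError):
        missing_ratio(full, ("A",))


def _decision(g, rho, cfg=InferenceConfig()):
    return "ternary" if (g >= cfg.tau_g and rho >= cfg.tau_rho) else "binary"


@pytest.mark.parametrize("g,rho,expected", [
    (0.05, 0.10, "ternary"),   # both thresholds exceeded
    (0.05, 0.05, "binary"),    # missing-component ratio too small
    (0.01, 0.50, "binary"),    # residual gain too small
    (0.01, 0.01, "binary"),
    (0.040, 0.080, "ternary"),  # boundary: rule is >=
])
def test_decision_rule_quadrants(g, rho, expected):
    assert _decision(g, rho) == expected


def test_decision_rule_monotone_in_g_and_rho():
    grid = np.linspace(0, 0.5, 26)
    cfg = InferenceConfig()
    for g in grid:
        for rho in grid:
            if _decision(g, rho, cfg) == "ternary":
                assert _decision(min(g + 0.1, 1.0), rho, cfg) == "ternary"
                assert _decision(g, min(rho + 0.1, 1.0), cfg) == "ternary"


def test_refine_end_to_end_upgrade_and_retain():
    rng = np.random.default_rng(9)
    protos = {c: rng.random(64) for c in COMPONENTS}
    cfg = InferenceConfig()
    # true ternary composition: refinement upgrades
    x3 = 0.4 * protos["A"] + 0.4 * protos["B"] + 0.3 * protos["C"]
    rep = refine(x3, ("A", "B"), protos, cfg)
    assert rep.refined and rep.category == "ABC"
    assert rep.e_tri <= rep.e_bin
    # true binary composition: refinement retains the pair
    x2 = 0.5 * protos["A"] + 0.5 * protos["B"]
    rep2 = refine(x2, ("A", "B"), protos, cfg)
    assert not rep2.refined and rep2.category == "AB"
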