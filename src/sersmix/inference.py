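"""Two-stage mixture inference.

Stage 1 ranks candidate component sets by a set-likelihood score computed
from the evidence branch's presence probabilities,

    Score(S) = sum_{k in S} log p_k + sum_{k not in S} log(1 - p_k),

and selects the best-scoring candidate.  In ``pairs_only`` mode the
candidates are the three binary sets {AB, AC, BC}; in ``unified`` mode the
three singletons compete as well (used for seven-category validation).

Stage 2 decides whether the winning pair should be upgraded to the ternary
category.  The spectrum is reconstructed by nonnegative least squares against
class-mean prototype spectra under both the binary and the ternary
hypothesis; with squared-L2 residuals e_bin >= e_tri (NNLS over a superset
support never fits worse), the relative residual gain and the
missing-component weight ratio

    g = (e_bin - e_tri) / e_bin,      rho = beta_missing / sum(beta)

trigger the upgrade iff ``g >= tau_g`` and ``rho >= tau_rho``.  The ternary
category never competes in stage 1; it is reachable only through this
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls as _lawson_hanson_nnls

from .spectra import COMPONENTS, set_to_category


@dataclass
class InferenceConfig:
    tau_g: float = 0.040
    tau_rho: float = 0.080
    prob_clamp: float = 1e-7
    candidate_mode: str = "pairs_only"   # or "unified"
    residual_metric: str = "squared_l2"

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_g < 1.0) or not (0.0 < self.tau_rho < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if not (0.0 < self.prob_clamp < 0.5):
            raise ValueError("prob_clamp must lie in (0, 0.5)")
        if self.candidate_mode not in ("pairs_only", "unified"):
            raise ValueError(f"unknown candidate mode {self.candidate_mode!r}")
        if self.residual_metric not in ("squared_l2", "l2"):
            raise ValueError(f"unknown residual metric {self.residual_metric!r}")


@dataclass
class ReconstructionResult:
    support: tuple[str, ...]
    beta: np.ndarray
    e: float


@dataclass
class RefinementReport:
    decision: tuple[str, ...]
    stage1_scores: dict[str, float]
    S_bin: tuple[str, ...] | None = None
    g: float | None = None
    rho: float | None = None
    e_bin: float | None = None
    e_tri: float | None = None
    beta_tri: np.ndarray | None = None
    refined: bool = False

    @property
    def category(self) -> str:
        return set_to_category(self.decision)


def candidate_sets(mode: str, components: Sequence[str] = COMPONENTS) -> list[tuple[str, ...]]:
    """Ordered stage-1 candidate list (lexicographic; ties resolve to the
    earliest entry).  The full set is never a stage-1 candidate."""
    pairs = [tuple(c) for c in combinations(components, 2)]
    if mode == "pairs_only":
        return pairs
    singles = [(c,) for c in components]
    return sorted(singles + pairs)


def set_likelihood(p: np.ndarray, S: Sequence[str], eps: float = 1e-7,
                   components: Sequence[str] = COMPONENTS) -> float:
    """Log set-likelihood of component set ``S`` under probabilities ``p``."""
    S = set(S)
    if not S:
        raise ValueError("candidate set must be non-empty")
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    score = 0.0
    for k, comp in enumerate(components):
        score += np.log(p[k]) if comp in S else np.log(1.0 - p[k])
    return float(score)


def rank_binary(p: np.ndarray, cfg: InferenceConfig) -> tuple[tuple[str, ...], dict[str, float]]:
    """Best-scoring stage-1 candidate plus all candidate scores.

    Candidates are pre-sorted lexicographically and the comparison is strict,
    so exact ties resolve to the lexicographically smallest set.
    """
    scores: dict[str, float] = {}
    best: tuple[str, ...] | None = None
    best_score = -np.inf
    for S in candidate_sets(cfg.candidate_mode):
        sc = set_likelihood(p, S, cfg.prob_clamp)
        scores[set_to_category(S)] = sc
        if sc > best_score:
            best, best_score = S, sc
    return best, scores


def build_prototypes(features_by_class: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Class-wise mean spectra of the pure training features."""
    missing = [c for c in COMPONENTS if c not in features_by_class
               or len(np.atleast_2d(features_by_class[c])) == 0]
    if missing:
        raise ValueError(f"missing pure training spectra for class(es) {missing}")
    return {
        c: np.atleast_2d(np.asarray(features_by_class[c], dtype=float)).mean(axis=0)
        for c in COMPONENTS
    }


def nnls_reconstruct(x: np.ndarray, prototypes: Mapping[str, np.ndarray],
                     support: Sequence[str],
                     metric: str = "squared_l2") -> ReconstructionResult:
    """Nonnegative least-squares fit of ``x`` on the prototypes in ``support``."""
    support = tuple(sorted(set(support)))
    if not support:
        raise ValueError("support must be non-empty")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input spectrum")
    P = np.column_stack([prototypes[c] for c in support])
    beta, rnorm = _lawson_hanson_nnls(P, x)
    e = float(rnorm**2) if metric == "squared_l2" else float(rnorm)
    return ReconstructionResult(support, beta, e)


def residual_gain(e_bin: float, e_tri: float) -> float:
    """Relative residual improvement of the ternary over the binary fit."""
    if e_bin < 0 or e_tri < 0:
        raise ValueError("residuals must be nonnegative")
    if e_bin == 0:
        return 0.0
    return (e_bin - e_tri) / e_bin


def missing_ratio(tri_result: ReconstructionResult, S_bin: Sequence[str]) -> float:
    """Ternary-fit weight share of the component absent from the binary set."""
    if set(tri_result.support) != set(COMPONENTS):
        raise ValueError("ternary result must have full support")
    missing = set(COMPONENTS) - set(S_bin)
    if len(missing) != 1:
        raise ValueError("binary set must lack exactly one component")
    total = float(tri_result.beta.sum())
    if total == 0:
        return 0.0
    idx = tri_result.support.index(next(iter(missing)))
    return float(tri_result.beta[idx]) / total


def refine(x: np.ndarray, S_bin: Sequence[str], prototypes: Mapping[str, np.ndarray],
           cfg: InferenceConfig,
           stage1_scores: Mapping[str, float] | None = None) -> RefinementReport:
    """Residual-based ternary refinement of a binary stage-1 prediction."""
    S_bin = tuple(sorted(S_bin))
    rec_bin = nnls_reconstruct(x, prototypes, S_bin, cfg.residual_metric)
    rec_tri = nnls_reconstruct(x, prototypes, COMPONENTS, cfg.residual_metric)
    # NNLS nesting: widening the nonnegative support can never fit worse
    # (tiny negative slack tolerated for solver round-off)
    assert rec_tri.e <= rec_bin.e + 1e-9 * max(1.0, rec_bin.e), "NNLS nesting violated"
    g = residual_gain(rec_bin.e, min(rec_tri.e, rec_bin.e))
    rho = missing_ratio(rec_tri, S_bin)
    upgrade = g >= cfg.tau_g and rho >= cfg.tau_rho
    return RefinementReport(
        decision=tuple(COMPONENTS) if upgrade else S_bin,
        stage1_scores=dict(stage1_scores or {}),
        S_bin=S_bin,
        g=g,
        rho=rho,
        e_bin=rec_bin.e,
        e_tri=rec_tri.e,
        beta_tri=rec_tri.beta,
        refined=upgrade,
    )


def infer_from_proba(p: np.ndarray, x: np.ndarray,
                     prototypes: Mapping[str, np.ndarray],
                     cfg: InferenceConfig) -> RefinementReport:
    """Both inference stages, starting from evidence probabilities."""
    S1, scores = rank_binary(p, cfg)
    if len(S1) == 1:
        # unified mode: singleton winners are final pure predictions
        return RefinementReport(decision=S1, stage1_scores=scores)
    return refine(x, S1, prototypes, cfg, scores)


def infer(x: np.ndarray, model, prototypes: Mapping[str, np.ndarray],
          cfg: InferenceConfig | None = None) -> RefinementReport:
    """End-to-end inference for one preprocessed spectrum."""
    if cfg is None:
        cfg = InferenceConfig()
    x = np.asarray(x, dtype=float)
    p = model.predict_proba(x[None, :])[0]
    return infer_from_proba(p, x, prototypes, cfg)
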