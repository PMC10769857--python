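"""Two-state all-rates-different Markov (Mk/ARD) engine and null calibration.

A gene's history on the tree is modelled as a continuous-time Markov chain
with a gain rate q01 (absent -> present) and a loss rate q10 per unit branch
length. The module provides the pruning likelihood, maximum-likelihood rate
fitting, exact endpoint simulation, and the false-discovery calibration:
simulate every gene independently under its fitted rates, re-run the whole
predictability screen, and measure how much of it survives by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._tree import Phylogeny
from .config import PipelineConfig, derive_seed
from .pangenome_matrix import PAMatrix, PAPSet, collapse_patterns, filter_by_frequency

log = logging.getLogger(__name__)

_RATE_BOUNDS = (1e-8, 1e3)  # per unit branch length


@dataclass
class RateModel2:
    """Fitted two-state ARD model for one gene/PAP."""

    q01: float
    q10: float
    root_p1: float
    log_likelihood: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0 or (self.q01 == 0 and self.q10 == 0):
            raise ValueError("rates must be non-negative and not both zero")
        if not (0.0 <= self.root_p1 <= 1.0):
            raise ValueError("root_p1 must lie in [0, 1]")

    @property
    def stationary_p1(self) -> float:
        return self.q01 / (self.q01 + self.q10)


def transition_probabilities(q01: float, q10: float, t) -> np.ndarray:
    """Exact 2-state transition matrix P(t) = exp(Qt).

    Returns an array of shape ``(..., 2, 2)`` for scalar or vector ``t``:
    ``P[..., i, j]`` is the probability of ending in state j given state i.
    """
    t = np.asarray(t, dtype=float)
    s = q01 + q10
    if s == 0:
        eye = np.zeros(t.shape + (2, 2))
        eye[..., 0, 0] = eye[..., 1, 1] = 1.0
        return eye
    e = np.exp(-s * t)
    p01 = (q01 / s) * (1.0 - e)
    p10 = (q10 / s) * (1.0 - e)
    P = np.empty(t.shape + (2, 2))
    P[..., 0, 0] = 1.0 - p01
    P[..., 0, 1] = p01
    P[..., 1, 0] = p10
    P[..., 1, 1] = 1.0 - p10
    return P


# --------------------------------------------------------------------------- #
# Likelihood
# --------------------------------------------------------------------------- #
def mk_log_likelihood(tree: Phylogeny, states, q01: float, q10: float,
                      root_p1: float) -> float:
    """Felsenstein pruning log-likelihood of binary tip states.

    The root is weighted by ``(1 - root_p1, root_p1)``. Impossible data
    (e.g. mixed states on a zero-length tree) return ``-inf``.
    """
    RateModel2(q01, q10, root_p1, 0.0)  # validate parameters
    states = np.asarray(states, dtype=int)
    if states.shape != (tree.n_tips,):
        raise ValueError("one state per tip required")
    P = transition_probabilities(q01, q10, tree.blen)
    L = np.zeros((tree.n_nodes, 2))
    L[np.arange(tree.n_tips), states] = 1.0
    logscale = 0.0
    left, right = tree.left, tree.right
    for v in tree.internal_nodes():
        l, r = left[v], right[v]
        Lv = (P[l] @ L[l]) * (P[r] @ L[r])
        m = Lv.max()
        if m <= 0.0:
            return -np.inf
        L[v] = Lv / m
        logscale += np.log(m)
    total = (1.0 - root_p1) * L[tree.root, 0] + root_p1 * L[tree.root, 1]
    if total <= 0.0:
        return -np.inf
    return float(np.log(total) + logscale)


def fit_ard(tree: Phylogeny, states, root_policy="stationary",
            n_starts: int = 4) -> RateModel2:
    """Maximum-likelihood gain/loss rates by bounded multi-start search.

    ``root_policy`` is ``"stationary"`` (root probability follows
    q01/(q01+q10), re-evaluated during the search) or a fixed probability.
    Constant traits are inestimable and raise ``ValueError``.
    """
    states = np.asarray(states, dtype=int)
    k = states.sum()
    if k == 0 or k == states.size:
        raise ValueError("cannot fit rates to a constant trait")

    def root_p1(q01, q10):
        if root_policy == "stationary":
            return q01 / (q01 + q10)
        return float(root_policy)

    def neg_ll(x):
        q01, q10 = np.exp(x)
        return -mk_log_likelihood(tree, states, q01, q10, root_p1(q01, q10))

    # moment-flavoured initial guess: changes needed per unit tree length
    from .phylo_signal import fitch_parsimony
    base = max(fitch_parsimony(tree, states), 1) / max(tree.total_length(), 1e-12)
    prev = k / states.size
    starts = []
    for f in (1.0, 0.2, 5.0, 25.0)[:n_starts]:
        q01 = np.clip(base * f * prev * 2, *_RATE_BOUNDS)
        q10 = np.clip(base * f * (1 - prev) * 2, *_RATE_BOUNDS)
        starts.append(np.log([q01, q10]))

    lb, ub = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])
    best, converged = None, False
    for x0 in starts:
        res = minimize(neg_ll, x0, method="L-BFGS-B",
                       bounds=[(lb, ub), (lb, ub)],
                       options={"ftol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    q01, q10 = np.exp(best.x)
    return RateModel2(float(q01), float(q10), root_p1(q01, q10),
                      log_likelihood=-float(best.fun), converged=converged)


# --------------------------------------------------------------------------- #
# Simulation
# --------------------------------------------------------------------------- #
def simulate_mk_many(tree: Phylogeny, q01, q10, root_p1,
                     rng: np.random.Generator) -> np.ndarray:
    """Simulate many independent genes at once.

    ``q01``, ``q10`` and ``root_p1`` are vectors (one entry per gene); the
    return value has shape ``(n_genes, n_tips)``. Branch endpoints are drawn
    from the exact transition matrix, so no event-level simulation is needed.
    """
    q01 = np.atleast_1d(np.asarray(q01, dtype=float))
    q10 = np.atleast_1d(np.asarray(q10, dtype=float))
    root_p1 = np.atleast_1d(np.asarray(root_p1, dtype=float))
    G = q01.size
    s = q01 + q10
    states = np.zeros((tree.n_nodes, G), dtype=np.uint8)
    states[tree.root] = rng.random(G) < root_p1
    for v in range(tree.n_nodes - 2, -1, -1):  # preorder: parents first
        t = tree.blen[v]
        e = np.exp(-s * t)
        p_gain = np.where(s > 0, (q01 / np.where(s > 0, s, 1.0)) * (1 - e), 0.0)
        p_stay = np.where(s > 0, (q01 + q10 * e) / np.where(s > 0, s, 1.0), 1.0)
        par = states[tree.parent[v]]
        p1 = np.where(par == 1, p_stay, p_gain)
        states[v] = rng.random(G) < p1
    return states[: tree.n_tips].T.copy()


def simulate_mk(tree: Phylogeny, model: RateModel2, seed: int = 0) -> np.ndarray:
    """Binary tip states for one gene under the given rate model."""
    rng = np.random.default_rng(seed)
    return simulate_mk_many(tree, [model.q01], [model.q10],
                            [model.root_p1], rng)[0]


def fit_rates_for_paps(tree: Phylogeny, paps: PAPSet,
                       root_policy="stationary") -> list[RateModel2]:
    """fit_ard for every PAP, aligned to the tree's tip order."""
    order = [tree.tip_index[g] for g in paps.genome_ids]
    models = []
    for pap in paps.paps:
        tip_states = np.zeros(tree.n_tips, dtype=int)
        tip_states[order] = pap.pattern
        models.append(fit_ard(tree, tip_states, root_policy=root_policy))
    return models


# --------------------------------------------------------------------------- #
# False-discovery calibration
# --------------------------------------------------------------------------- #
def null_fdr_screen(tree: Phylogeny, paps: PAPSet, config: PipelineConfig,
                    n_sims: int | None = None,
                    models: list[RateModel2] | None = None) -> dict:
    """Re-run the predictability screen on phylogeny-constrained null data.

    Every PAP is simulated independently under its (given or fitted) ARD
    model; each replicate is filtered, collapsed and screened like real
    data, and D is evaluated only for the F1-passing PAPs. Returns per-
    replicate fractions of PAPs passing the F1 gate alone and the F1+D
    gates; the latter is the false-discovery calibration.
    """
    from .phylo_signal import signal_screen
    from .rf_predict import run_predictability_screen

    if n_sims is None:
        n_sims = config.n_null_sims
    if models is None:
        log.info("fitting ARD rates for %d PAPs", len(paps))
        models = fit_rates_for_paps(tree, paps)
    if len(models) != len(paps):
        raise ValueError("one rate model per PAP required")
    q01 = np.array([m.q01 for m in models])
    q10 = np.array([m.q10 for m in models])
    root_p1 = np.array([m.root_p1 for m in models])

    frac_f1, frac_both, n_analysed = [], [], []
    for rep in range(n_sims):
        rng = np.random.default_rng(derive_seed(config.seed, "nullsim", rep))
        sim = simulate_mk_many(tree, q01, q10, root_p1, rng)  # (G, n_tips)
        matrix = PAMatrix(list(tree.tip_labels),
                          [f"sim{rep:03d}_{i:05d}" for i in range(sim.shape[0])],
                          sim.T)
        matrix = filter_by_frequency(matrix, config.rare_min, config.common_max)
        sim_paps, _ = collapse_patterns(matrix)
        rep_config = config.replace(seed=derive_seed(config.seed, "nullrep", rep))
        records, _ = run_predictability_screen(sim_paps, rep_config)
        n_total = len(records)
        passing_f1 = [r.pattern_id for r in records if r.predictable]
        signals = signal_screen(tree, sim_paps, rep_config,
                                pattern_ids=passing_f1)
        n_both = int(((signals["D"] > config.d_min) & signals["valid"]).sum())
        frac_f1.append(len(passing_f1) / n_total if n_total else 0.0)
        frac_both.append(n_both / n_total if n_total else 0.0)
        n_analysed.append(n_total)
        log.info("null replicate %d: %d/%d pass F1, %d pass F1+D",
                 rep, len(passing_f1), n_total, n_both)
    return {
        "fraction_f1": frac_f1,
        "fraction_f1_and_d": frac_both,
        "n_paps": n_analysed,
        "mean": float(np.mean(frac_both)) if frac_both else np.nan,
        "min": float(np.min(frac_both)) if frac_both else np.nan,
        "max": float(np.max(frac_both)) if frac_both else np.nan,
    }


def rates_to_frame(paps: PAPSet, models: list[RateModel2]) -> pd.DataFrame:
    return pd.DataFrame({
        "pattern_id": paps.pattern_ids,
        "q01": [m.q01 for m in models],
        "q10": [m.q10 for m in models],
        "root_p1": [m.root_p1 for m in models],
        "loglik": [m.log_likelihood for m in models],
        "converged": [m.converged for m in models],
    }).set_index("pattern_id")
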