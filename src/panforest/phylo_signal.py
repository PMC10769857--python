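"""Phylogenetic distribution of binary traits: Fitch parsimony and the
Fritz-Purvis D statistic.

D locates an observed trait between two reference points: the expected
clumping of a phylogenetically random trait (tip shuffles, D = 1) and of a
trait produced by thresholding a Brownian character evolved on the tree
(D = 0). Traits with D > 0 are at most Brownian-clumped; the pipeline uses
D > 0 together with a minimum parsimony score to exclude genes whose
apparent associations could be explained by shared ancestry alone.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._tree import Phylogeny, from_dendropy
from .config import PipelineConfig, derive_seed
from .pangenome_matrix import PAPSet

log = logging.getLogger(__name__)

__all__ = [
    "prepare_tree", "fitch_parsimony", "sister_clade_changes",
    "d_statistic", "signal_screen", "passes_signal", "DStatResult",
]


@dataclass
class DStatResult:
    pattern_id: str
    d_obs: float
    mean_d_r: float           # permutation (phylogenetically random) null mean
    mean_d_b: float           # Brownian-threshold null mean
    D: float
    parsimony: int
    n_permutations: int
    valid: bool = True
    reason: str = ""


# --------------------------------------------------------------------------- #
# Tree preparation
# --------------------------------------------------------------------------- #
def prepare_tree(newick_text: str, genome_ids, seed: int = 0) -> Phylogeny:
    """Parse, prune, midpoint-root and binarise a Newick tree.

    Tips not present in ``genome_ids`` are pruned with a log message; a
    genome missing from the tree is a hard error. Polytomies are resolved
    deterministically (seeded) with zero-length branches, and missing branch
    lengths are replaced by 1.0 with a warning.
    """
    dtree = dendropy.Tree.get(data=newick_text, schema="newick",
                              preserve_underscores=True)
    tip_labels = {l.taxon.label for l in dtree.leaf_node_iter() if l.taxon}
    genomes = list(genome_ids)
    missing = sorted(set(genomes) - tip_labels)
    if missing:
        raise ValueError(f"genomes absent from the tree: {missing}")
    extra = sorted(tip_labels - set(genomes))
    if extra:
        log.info("pruning %d tree tips absent from the matrix: %s",
                 len(extra), extra[:10])
        dtree.retain_taxa_with_labels(genomes)

    n_missing_len = 0
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            n_missing_len += 1
    if n_missing_len:
        warnings.warn(f"{n_missing_len} branches without length set to 1.0",
                      stacklevel=2)

    dtree.encode_bipartitions()
    dtree.reroot_at_midpoint(update_bipartitions=True)
    # the midpoint can land exactly on a tip node, in which case dendropy
    # promotes that tip to the root; restore it as a zero-length child
    if dtree.seed_node.taxon is not None:
        tip = dendropy.Node(taxon=dtree.seed_node.taxon, edge_length=0.0)
        dtree.seed_node.taxon = None
        dtree.seed_node.add_child(tip)
    dtree.resolve_polytomies(limit=2, update_bipartitions=False,
                             rng=random.Random(seed))
    dtree.suppress_unifurcations()
    for edge in dtree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return from_dendropy(dtree)


# --------------------------------------------------------------------------- #
# Parsimony
# --------------------------------------------------------------------------- #
def fitch_parsimony(tree: Phylogeny, states) -> int | np.ndarray:
    """Fitch small-parsimony count of 0/1 state changes.

    ``states`` is aligned to ``tree.tip_labels``; a 2-D array of shape
    ``(n_tips, k)`` scores k traits at once and returns an array.
    """
    states = np.asarray(states)
    squeeze = states.ndim == 1
    S = states.reshape(tree.n_tips, -1)
    if S.shape[0] != tree.n_tips:
        raise ValueError("one state per tip required")
    if not np.isin(S, (0, 1)).all():
        raise ValueError("states must be 0 or 1 for every tip")
    sets = np.zeros((tree.n_nodes, S.shape[1]), dtype=np.uint8)
    sets[: tree.n_tips] = np.uint8(1) << S.astype(np.uint8)
    changes = np.zeros(S.shape[1], dtype=np.int64)
    left, right = tree.left, tree.right
    for v in tree.internal_nodes():
        a, b = sets[left[v]], sets[right[v]]
        inter = a & b
        union = a | b
        empty = inter == 0
        sets[v] = np.where(empty, union, inter)
        changes += empty
    return int(changes[0]) if squeeze else changes


# --------------------------------------------------------------------------- #
# Sister-clade differences and D
# --------------------------------------------------------------------------- #
def sister_clade_changes(tree: Phylogeny, tip_values) -> float | np.ndarray:
    """Sum over internal nodes of |left daughter - right daughter| where
    internal values are the unweighted means of the two daughters,
    estimated tips-to-root."""
    vals = np.asarray(tip_values, dtype=float)
    squeeze = vals.ndim == 1
    V = np.zeros((tree.n_nodes, vals.reshape(tree.n_tips, -1).shape[1]))
    V[: tree.n_tips] = vals.reshape(tree.n_tips, -1)
    d = np.zeros(V.shape[1])
    left, right = tree.left, tree.right
    for v in tree.internal_nodes():
        a, b = V[left[v]], V[right[v]]
        d += np.abs(a - b)
        V[v] = 0.5 * (a + b)
    return float(d[0]) if squeeze else d


def _brownian_threshold_traits(tree: Phylogeny, k: int, n_sims: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Simulate Brownian values on the tree and threshold so the k largest
    tip values are scored 1. Zero-length branches get a small epsilon
    variance; rank ties are broken by seeded jitter."""
    eps = 1e-8 * max(tree.height(), 1e-300)
    sd = np.sqrt(np.maximum(tree.blen, eps))
    noise = rng.standard_normal((tree.n_nodes, n_sims)) * sd[:, None]
    vals = np.zeros((tree.n_nodes, n_sims))
    parent = tree.parent
    for v in range(tree.n_nodes - 2, -1, -1):  # preorder: parents first
        vals[v] = vals[parent[v]] + noise[v]
    tips = vals[: tree.n_tips]
    tips = tips + rng.standard_normal(tips.shape) * 1e-12
    order = np.argpartition(-tips, k - 1, axis=0)[:k]
    traits = np.zeros_like(tips, dtype=np.uint8)
    np.put_along_axis(traits, order, np.uint8(1), axis=0)
    return traits


def d_statistic(tree: Phylogeny, states, n_permutations: int = 1000,
                seed: int = 0, pattern_id: str = "") -> DStatResult:
    """Fritz-Purvis D for one binary trait.

    ``d_obs`` is scaled between the mean sister-clade change sum of
    ``n_permutations`` tip shuffles (random expectation) and of the same
    number of Brownian-threshold simulations with matched prevalence:
    ``D = (d_obs - mean_d_b) / (mean_d_r - mean_d_b)``.
    """
    states = np.asarray(states, dtype=np.uint8)
    if states.shape != (tree.n_tips,):
        raise ValueError("one binary state per tip required")
    k = int(states.sum())
    if k == 0 or k == tree.n_tips:
        return DStatResult(pattern_id, np.nan, np.nan, np.nan, np.nan,
                           0, n_permutations, valid=False,
                           reason="constant trait")
    rng = np.random.default_rng(seed)
    d_obs = float(sister_clade_changes(tree, states))
    perms = rng.permuted(
        np.repeat(states[:, None], n_permutations, axis=1), axis=0)
    d_r = sister_clade_changes(tree, perms)
    brown = _brownian_threshold_traits(tree, k, n_permutations, rng)
    d_b = sister_clade_changes(tree, brown)
    mean_d_r = float(d_r.mean())
    mean_d_b = float(d_b.mean())
    pars = fitch_parsimony(tree, states)
    denom = mean_d_r - mean_d_b
    if abs(denom) < 1e-9 * max(1.0, abs(mean_d_r)):
        return DStatResult(pattern_id, d_obs, mean_d_r, mean_d_b, np.nan,
                           pars, n_permutations, valid=False,
                           reason="degenerate null separation")
    D = (d_obs - mean_d_b) / denom
    return DStatResult(pattern_id, d_obs, mean_d_r, mean_d_b, D, pars,
                       n_permutations)


def passes_signal(result: DStatResult, config: PipelineConfig) -> bool:
    """Gate applied to predicted (target) PAPs: D strictly above ``d_min``
    and at least ``parsimony_min`` state changes on the tree."""
    return bool(result.valid and result.D > config.d_min
                and result.parsimony >= config.parsimony_min)


def signal_screen(tree: Phylogeny, paps: PAPSet, config: PipelineConfig,
                  pattern_ids=None) -> pd.DataFrame:
    """One DStatResult row per PAP (optionally restricted to
    ``pattern_ids``), with a boolean ``pass`` column.

    Degenerate traits yield a failed pass flag, not an exception.
    """
    order = [tree.tip_index[g] for g in paps.genome_ids]
    wanted = paps.pattern_ids if pattern_ids is None else list(pattern_ids)
    rows = []
    for pid in wanted:
        pap = paps.by_id[pid]
        tip_states = np.zeros(tree.n_tips, dtype=np.uint8)
        tip_states[order] = pap.pattern
        res = d_statistic(tree, tip_states, config.n_d_permutations,
                          seed=derive_seed(config.seed, "dstat", pid),
                          pattern_id=pid)
        rows.append({
            "pattern_id": pid, "d_obs": res.d_obs, "mean_d_r": res.mean_d_r,
            "mean_d_b": res.mean_d_b, "D": res.D, "parsimony": res.parsimony,
            "valid": res.valid, "pass": passes_signal(res, config),
        })
        if not res.valid:
            log.info("PAP %s excluded from the D filter: %s", pid, res.reason)
    df = pd.DataFrame(rows, columns=["pattern_id", "d_obs", "mean_d_r",
                                     "mean_d_b", "D", "parsimony", "valid",
                                     "pass"])
    return df.set_index("pattern_id")
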