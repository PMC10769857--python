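"""Directed gene-interaction network and ecological edge classification.

Edges point from a predictor PAP to a predicted PAP and carry the Gini
importance as weight. Only edges whose target passed both the dual-class F1
gate and the phylogenetic-distribution gate (D, parsimony) survive; the
predictor side is exempt. Polarity is read off the conditional frequency of
the target given the predictor (co-occurrence vs avoidance), and edges are
then sorted into putative mutualisms, commensalisms and competitions, in
that order of precedence with commensalism first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .pangenome_matrix import PAPSet, pap_conditional_frequencies
from .rf_predict import PredictionRecord

log = logging.getLogger(__name__)

CO_OCCURRENCE = "co-occurrence"
AVOIDANCE = "avoidance"


@dataclass(frozen=True)
class RelationshipEdge:
    source: str   # predictor PAP
    target: str   # predicted PAP
    gini: float
    polarity: str  # co-occurrence | avoidance
    category: str = "uncategorized"
    host: str | None = None       # filled for commensal edges
    commensal: str | None = None


# --------------------------------------------------------------------------- #
# Edge construction
# --------------------------------------------------------------------------- #
def build_edges(records: list[PredictionRecord], signals: pd.DataFrame,
                paps: PAPSet, config: PipelineConfig) -> list[RelationshipEdge]:
    """Keep predictor->target links with Gini >= ``gini_min`` (inclusive)
    whose target passes the F1 and D/parsimony gates, and assign polarity.

    ``signals`` must contain a ``pass`` column for (at least) every
    predictable target; missing rows are a hard error. Edges whose
    conditional frequencies tie exactly are dropped and logged.
    """
    edges: list[RelationshipEdge] = []
    n_tied = 0
    for rec in records:
        if not rec.predictable:
            continue
        if rec.pattern_id not in signals.index:
            raise KeyError(f"no signal-screen row for PAP {rec.pattern_id!r}")
        if not bool(signals.loc[rec.pattern_id, "pass"]):
            continue
        target_pap = paps.by_id[rec.pattern_id]
        for src, gini in rec.importances.items():
            if gini < config.gini_min:
                continue
            freq = pap_conditional_frequencies(target_pap, paps.by_id[src])
            p1 = freq["p_target_given_source_present"]
            p0 = freq["p_target_given_source_absent"]
            if p1 is None or p0 is None or p1 == p0:
                n_tied += 1
                continue
            polarity = CO_OCCURRENCE if p1 > p0 else AVOIDANCE
            edges.append(RelationshipEdge(src, rec.pattern_id, float(gini),
                                          polarity))
    if n_tied:
        log.info("dropped %d edges with tied or undefined conditional "
                 "frequencies", n_tied)
    edges.sort(key=lambda e: (e.target, e.source))
    return edges


# --------------------------------------------------------------------------- #
# Categorisation
# --------------------------------------------------------------------------- #
def _commensal_roles(pid_a: str, pid_b: str, paps: PAPSet,
                     config: PipelineConfig) -> tuple[str, str] | None:
    """Test the commensalism rule for an unordered pair.

    The host is the more prevalent pattern. It must be present in at least
    ``commensal_host_cover`` of the genomes carrying the commensal, and its
    frequency among genomes lacking the commensal must be at least
    ``commensal_presence_ratio`` of its overall frequency (both inclusive).
    Returns (host, commensal) or None.
    """
    a, b = paps.by_id[pid_a], paps.by_id[pid_b]
    if a.prevalence == b.prevalence:
        return None
    host, comm = (a, b) if a.prevalence > b.prevalence else (b, a)
    freq = pap_conditional_frequencies(host, comm)
    cover = freq["p_target_given_source_present"]
    without = freq["p_target_given_source_absent"]
    if cover is None or without is None:
        return None
    if cover >= config.commensal_host_cover and \
            without >= config.commensal_presence_ratio * host.prevalence:
        return host.pattern_id, comm.pattern_id
    return None


def categorize_relationships(edges: list[RelationshipEdge], paps: PAPSet,
                             config: PipelineConfig) -> list[RelationshipEdge]:
    """Assign mutually exclusive categories with precedence
    commensalism > mutualism > competition.

    Mutualism requires qualifying co-occurrence edges in both directions
    (hence both endpoints passed the target gates); with
    ``config.mutual_ratio`` set, the two Gini weights must additionally agree
    within that max/min ratio. Every qualifying avoidance edge not claimed
    above is a competition; remaining edges stay uncategorized.
    """
    by_pair = {(e.source, e.target): e for e in edges}
    out = []
    for e in edges:
        if e.polarity == AVOIDANCE:
            out.append(replace(e, category="competition"))
            continue
        roles = _commensal_roles(e.source, e.target, paps, config)
        if roles is not None:
            out.append(replace(e, category="commensalism",
                               host=roles[0], commensal=roles[1]))
            continue
        recip = by_pair.get((e.target, e.source))
        if recip is not None and recip.polarity == CO_OCCURRENCE:
            if config.mutual_ratio is not None:
                lo, hi = sorted((e.gini, recip.gini))
                if lo <= 0 or hi / lo > config.mutual_ratio:
                    out.append(e)
                    continue
            out.append(replace(e, category="mutualism"))
            continue
        out.append(e)
    return out


def apply_exclusion_list(edges: list[RelationshipEdge],
                         excluded_pattern_ids) -> list[RelationshipEdge]:
    """Drop every edge touching an excluded pattern (e.g. gene families
    flagged as artefactually split during pangenome construction)."""
    excluded = set(excluded_pattern_ids)
    touched = {e.source for e in edges} | {e.target for e in edges}
    unknown = excluded - touched
    if unknown:
        log.warning("%d excluded ids not present in the network: %s",
                    len(unknown), sorted(unknown)[:10])
    kept = [e for e in edges
            if e.source not in excluded and e.target not in excluded]
    log.info("exclusion list removed %d of %d edges",
             len(edges) - len(kept), len(edges))
    return kept


# --------------------------------------------------------------------------- #
# Summaries and export
# --------------------------------------------------------------------------- #
@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    component_sizes: list[int]
    component_sizes_cooccurrence: list[int]
    component_sizes_avoidance: list[int]
    pagerank: dict[str, float]
    category_counts: dict[str, int]


def _digraph(edges: list[RelationshipEdge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.source, e.target, gini=e.gini, polarity=e.polarity,
                   category=e.category)
    return g


def network_summary(edges: list[RelationshipEdge]) -> NetworkSummary:
    """Connected components (overall and per polarity) and Gini-weighted
    PageRank (damping 0.85, convergence 1e-10) of the directed network."""
    if not edges:
        return NetworkSummary(0, 0, [], [], [], {}, {})
    g = _digraph(edges)

    def comp_sizes(sub_edges):
        if not sub_edges:
            return []
        u = _digraph(sub_edges).to_undirected()
        return sorted((len(c) for c in nx.connected_components(u)),
                      reverse=True)

    pagerank = nx.pagerank(g, alpha=0.85, weight="gini", tol=1e-10,
                           max_iter=1000)
    counts: dict[str, int] = {}
    for e in edges:
        counts[e.category] = counts.get(e.category, 0) + 1
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        component_sizes=comp_sizes(edges),
        component_sizes_cooccurrence=comp_sizes(
            [e for e in edges if e.polarity == CO_OCCURRENCE]),
        component_sizes_avoidance=comp_sizes(
            [e for e in edges if e.polarity == AVOIDANCE]),
        pagerank=pagerank,
        category_counts=counts,
    )


def edges_to_frame(edges: list[RelationshipEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.source, e.target, e.gini, e.polarity, e.category,
          e.host or "", e.commensal or "") for e in edges],
        columns=["source", "target", "gini", "polarity", "category",
                 "host", "commensal"])


def write_graphml(edges: list[RelationshipEdge], paps: PAPSet,
                  signals: pd.DataFrame, metrics: pd.DataFrame, path) -> None:
    """GraphML export with node attributes for external visualisation."""
    g = _digraph(edges)
    summary = network_summary(edges)
    for node in g.nodes:
        attrs = {"prevalence": float(paps.by_id[node].prevalence),
                 "pagerank": float(summary.pagerank.get(node, 0.0))}
        if node in signals.index:
            attrs["D"] = float(signals.loc[node, "D"])
            attrs["parsimony"] = int(signals.loc[node, "parsimony"])
        if node in metrics.index:
            attrs["predictable"] = bool(metrics.loc[node, "predictable"])
        g.nodes[node].update(attrs)
    nx.write_graphml(g, path)
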