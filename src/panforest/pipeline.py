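"""End-to-end orchestration: matrix -> PAPs -> forests -> D filter -> network."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._tree import Phylogeny
from .config import PipelineConfig
from .interaction_network import (NetworkSummary, RelationshipEdge,
                                  apply_exclusion_list, build_edges,
                                  categorize_relationships, edges_to_frame,
                                  network_summary)
from .pangenome_matrix import (CollapseMap, PAMatrix, PAPSet,
                               collapse_patterns, filter_by_frequency)
from .phylo_signal import prepare_tree, signal_screen
from .rf_predict import PredictionRecord, run_predictability_screen, records_to_frame

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    papset: PAPSet
    collapse_map: CollapseMap
    records: list[PredictionRecord]
    metrics: pd.DataFrame
    signals: pd.DataFrame
    edges: list[RelationshipEdge]
    summary: NetworkSummary
    report: dict

    def serialize(self) -> str:
        """A canonical text rendering of all outputs (used for determinism
        checks and audit dumps)."""
        parts = [
            "## metrics", self.metrics.to_csv(),
            "## signals", self.signals.to_csv(),
            "## edges", edges_to_frame(self.edges).to_csv(index=False),
            "## pagerank",
            "\n".join(f"{k}\t{v:.12g}"
                      for k, v in sorted(self.summary.pagerank.items())),
            "## components", repr(self.summary.component_sizes),
            "## categories", repr(sorted(self.summary.category_counts.items())),
        ]
        return "\n".join(parts)


def run_pipeline(matrix: PAMatrix, tree, config: PipelineConfig,
                 excluded_pattern_ids=(), compute_d: str = "predictable",
                 prefiltered: bool = False) -> PipelineResult:
    """Run the whole screen on a presence-absence matrix and a phylogeny.

    ``tree`` is a Newick string or a prepared ``Phylogeny``. With
    ``compute_d="predictable"`` (the default) the D statistic is evaluated
    only for PAPs that passed the dual-class F1 gate - the only place the
    result feeds into - while ``"all"`` screens every PAP.
    """
    if not prefiltered:
        matrix = filter_by_frequency(matrix, config.rare_min, config.common_max)
    papset, cmap = collapse_patterns(matrix)
    if isinstance(tree, Phylogeny):
        missing = set(matrix.genome_ids) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"genomes absent from the tree: {sorted(missing)}")
        if set(tree.tip_labels) != set(matrix.genome_ids):
            tree = prepare_tree(tree.to_newick(), matrix.genome_ids,
                                seed=config.seed)
    else:
        tree = prepare_tree(tree, matrix.genome_ids, seed=config.seed)

    records, metrics = run_predictability_screen(papset, config)
    if compute_d == "all":
        wanted = None
    elif compute_d == "predictable":
        wanted = [r.pattern_id for r in records if r.predictable]
    else:
        raise ValueError("compute_d must be 'predictable' or 'all'")
    signals = signal_screen(tree, papset, config, pattern_ids=wanted)

    edges = build_edges(records, signals, papset, config)
    if excluded_pattern_ids:
        edges = apply_exclusion_list(edges, excluded_pattern_ids)
    edges = categorize_relationships(edges, papset, config)
    summary = network_summary(edges)

    n_predictable = int(sum(r.predictable for r in records))
    n_pass_both = int(signals["pass"].sum())
    report = {
        "n_genomes": matrix.n_genomes,
        "n_genome_classes": len(set(cmap.genome_to_class.values())),
        "n_genes_after_filter": matrix.n_genes,
        "n_paps": len(papset),
        "n_predictable": n_predictable,
        "n_predictable_with_d_pass": n_pass_both,
        "fraction_predictable_with_d_pass":
            n_pass_both / len(papset) if len(papset) else float("nan"),
        "n_edges": len(edges),
        "category_counts": summary.category_counts,
    }
    log.info("pipeline report: %s", report)
    return PipelineResult(config, papset, cmap, records, metrics, signals,
                          edges, summary, report)
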