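"""Edge construction, ecological categorisation, and network summaries."""

import numpy as np
import pandas as pd
import pytest

from panforest import (PipelineConfig, apply_exclusion_list, build_edges,
                       categorize_relationships, collapse_patterns,
                       edges_to_frame, network_summary)
from panforest.interaction_network import (AVOIDANCE, CO_OCCURRENCE,
                                           RelationshipEdge, _commensal_roles)
from panforest.rf_predict import ClassMetrics, PredictionRecord

from conftest import matrix_from_columns


def make_papset(cols):
    return collapse_patterns(matrix_from_columns(
        {g: np.asarray(v, dtype=np.uint8) for g, v in cols.items()}))[0]


def record(pid, importances, predictable=True):
    metrics = ClassMetrics(tp=5, fp=0, fn=0, tn=5)
    return PredictionRecord(pid, metrics, importances, predictable)


def signal_frame(rows):
    df = pd.DataFrame(
        [{"pattern_id": pid, "D": 0.5, "parsimony": 10, "valid": True,
          "pass": ok} for pid, ok in rows.items()])
    return df.set_index("pattern_id")


@pytest.fixture
def simple_world():
    # t co-occurs with s (and is perfectly predicted by it); u avoids t
    n = 40
    t = np.r_[np.ones(20), np.zeros(20)]
    s = t.copy()
    s[0] = 0   # nearly identical, distinct PAP
    u = 1 - t
    u[-1] = 0
    paps = make_papset({"t": t, "s": s, "u": u})
    return paps


def test_build_edges_gini_threshold_and_polarity(simple_world):
    config = PipelineConfig()
    records = [record("PAP:t", {"PAP:s": 0.5, "PAP:u": 0.01}),
               record("PAP:s", {"PAP:t": 0.009}, predictable=False)]
    signals = signal_frame({"PAP:t": True})
    edges = build_edges(records, signals, simple_world, config)
    # gini exactly at the threshold is kept; unpredictable targets drop out
    assert {(e.source, e.target) for e in edges} == \
        {("PAP:s", "PAP:t"), ("PAP:u", "PAP:t")}
    by_src = {e.source: e for e in edges}
    assert by_src["PAP:s"].polarity == CO_OCCURRENCE
    assert by_src["PAP:u"].polarity == AVOIDANCE


def test_build_edges_requires_signal_pass_and_rows(simple_world):
    config = PipelineConfig()
    records = [record("PAP:t", {"PAP:s": 0.5})]
    edges = build_edges(records, signal_frame({"PAP:t": False}),
                        simple_world, config)
    assert edges == []
    with pytest.raises(KeyError, match="PAP:t"):
        build_edges(records, signal_frame({"PAP:s": True}),
                    simple_world, config)


def test_build_edges_drops_ties():
    # source independent of target: conditional frequencies tie exactly
    t = [1, 1, 0, 0, 1, 1, 0, 0]
    s = [1, 0, 1, 0, 1, 0, 1, 0]
    paps = make_papset({"t": t, "s": s})
    config = PipelineConfig()
    records = [record("PAP:t", {"PAP:s": 0.9})]
    edges = build_edges(records, signal_frame({"PAP:t": True}), paps, config)
    assert edges == []


# --------------------------------------------------------------------------- #
# Commensalism rule (worked threshold case)
# --------------------------------------------------------------------------- #
def commensal_table(n_host_without: int):
    """90 genomes; commensal in 40, host in the 40 plus ``n_host_without``
    of the remaining 50. Host prevalence with n_host_without=5 is 50%, and
    5/50 = 10% of commensal-absent genomes carry the host: exactly 20% of
    the host's overall prevalence - the worked boundary case."""
    n = 90
    comm = np.r_[np.ones(40), np.zeros(50)]
    host = np.r_[np.ones(40 + n_host_without), np.zeros(n - 40 - n_host_without)]
    return make_papset({"host": host, "comm": comm})


def test_commensal_worked_threshold_inclusive():
    config = PipelineConfig()
    paps = commensal_table(5)     # host 45/90 = 50%; 5/50 = 10% = 0.20 * 50%
    roles = _commensal_roles("PAP:host", "PAP:comm", paps, config)
    assert roles == ("PAP:host", "PAP:comm")
    # argument order must not matter
    assert _commensal_roles("PAP:comm", "PAP:host", paps, config) == roles


def test_commensal_below_threshold_rejected():
    config = PipelineConfig()
    paps = commensal_table(4)     # 4/50 = 8% < 20% of 48.9% -> no commensalism
    assert _commensal_roles("PAP:host", "PAP:comm", paps, config) is None


def test_commensal_requires_cover():
    # host misses one commensal genome: cover 39/40 = 97.5% < 99%
    comm = np.r_[np.ones(40), np.zeros(50)]
    host = comm.copy()
    host[0] = 0
    host[40:50] = 1
    paps = make_papset({"host": host, "comm": comm})
    assert _commensal_roles("PAP:host", "PAP:comm", paps,
                            PipelineConfig()) is None


def test_commensal_equal_prevalence_undecidable():
    t = [1, 1, 0, 0]
    s = [1, 0, 1, 0]
    paps = make_papset({"a": t, "b": s})
    assert _commensal_roles("PAP:a", "PAP:b", paps, PipelineConfig()) is None


# --------------------------------------------------------------------------- #
# Categorisation precedence
# --------------------------------------------------------------------------- #
def test_categorize_mutualism_needs_reciprocity(simple_world):
    config = PipelineConfig()
    e_st = RelationshipEdge("PAP:s", "PAP:t", 0.5, CO_OCCURRENCE)
    e_ts = RelationshipEdge("PAP:t", "PAP:s", 0.4, CO_OCCURRENCE)
    out = categorize_relationships([e_st, e_ts], simple_world, config)
    assert all(e.category == "mutualism" for e in out)
    out_one = categorize_relationships([e_st], simple_world, config)
    assert out_one[0].category == "uncategorized"


def test_categorize_avoidance_is_competition(simple_world):
    out = categorize_relationships(
        [RelationshipEdge("PAP:u", "PAP:t", 0.3, AVOIDANCE)],
        simple_world, PipelineConfig())
    assert out[0].category == "competition"


def test_categorize_commensal_takes_precedence():
    paps = commensal_table(5)
    config = PipelineConfig()
    edges = [RelationshipEdge("PAP:host", "PAP:comm", 0.5, CO_OCCURRENCE),
             RelationshipEdge("PAP:comm", "PAP:host", 0.5, CO_OCCURRENCE)]
    out = categorize_relationships(edges, paps, config)
    # reciprocal co-occurrence, but the commensal rule matches first
    assert all(e.category == "commensalism" for e in out)
    assert all(e.host == "PAP:host" and e.commensal == "PAP:comm" for e in out)


def test_mutual_ratio_option(simple_world):
    config = PipelineConfig(mutual_ratio=2.0)
    e_st = RelationshipEdge("PAP:s", "PAP:t", 0.5, CO_OCCURRENCE)
    e_ts = RelationshipEdge("PAP:t", "PAP:s", 0.1, CO_OCCURRENCE)
    out = categorize_relationships([e_st, e_ts], simple_world, config)
    assert all(e.category == "uncategorized" for e in out)


# --------------------------------------------------------------------------- #
# Exclusion, summary, export
# --------------------------------------------------------------------------- #
def test_apply_exclusion_list():
    edges = [RelationshipEdge("A", "B", 0.5, CO_OCCURRENCE),
             RelationshipEdge("B", "C", 0.5, CO_OCCURRENCE),
             RelationshipEdge("C", "D", 0.5, AVOIDANCE)]
    kept = apply_exclusion_list(edges, ["B"])
    assert [(e.source, e.target) for e in kept] == [("C", "D")]
    kept2 = apply_exclusion_list(edges, ["nope"])   # warns, removes nothing
    assert len(kept2) == 3


def test_network_summary_chain_pagerank_oracle():
    edges = [RelationshipEdge("A", "B", 1.0, CO_OCCURRENCE, "mutualism"),
             RelationshipEdge("B", "C", 2.0, CO_OCCURRENCE, "mutualism"),
             RelationshipEdge("D", "E", 1.0, AVOIDANCE, "competition")]
    s = network_summary(edges)
    assert s.n_nodes == 5 and s.n_edges == 3
    assert s.component_sizes == [3, 2]
    assert s.component_sizes_cooccurrence == [3]
    assert s.component_sizes_avoidance == [2]
    assert s.category_counts == {"mutualism": 2, "competition": 1}
    # independent PageRank oracle: power iteration with dangling-mass spread
    nodes = ["A", "B", "C", "D", "E"]
    W = np.zeros((5, 5))
    W[0, 1] = 1.0   # A->B
    W[1, 2] = 2.0   # B->C
    W[3, 4] = 1.0   # D->E
    row = W.sum(axis=1)
    pr = np.full(5, 0.2)
    for _ in range(500):
        new = np.full(5, 0.15 / 5)
        for i in range(5):
            if row[i] > 0:
                new += 0.85 * pr[i] * W[i] / row[i]
            else:
                new += 0.85 * pr[i] / 5
        pr = new
    for i, node in enumerate(nodes):
        assert s.pagerank[node] == pytest.approx(pr[i], abs=1e-6)


def test_network_summary_empty_and_frame():
    s = network_summary([])
    assert s.n_nodes == 0 and s.pagerank == {}
    df = edges_to_frame([RelationshipEdge("A", "B", 0.5, CO_OCCURRENCE,
                                          "commensalism", host="A",
                                          commensal="B")])
    assert list(df.columns) == ["source", "target", "gini", "polarity",
                                "category", "host", "commensal"]
    assert df.loc[0, "host"] == "A"
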