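"""Tree simulation, joint gain/loss modules, planted benchmarks."""

import numpy as np
import pytest

from panforest import (ModuleSpec, generate_benchmark, rates_for_events,
                       simulate_gene_orders, simulate_mk_many, simulate_module,
                       simulate_tree, truth_to_frame)
from panforest.synthetic_data import (_evolve_branch, _flip_rates,
                                      _stationary, commensalism_module,
                                      competition_module, mutualism_module)

from conftest import star_like_tree


# --------------------------------------------------------------------------- #
# Trees
# --------------------------------------------------------------------------- #
def test_simulate_tree_contract():
    t = simulate_tree(4, seed=1)
    assert t.n_tips == 4 and t.n_nodes == 7
    assert t.height() == pytest.approx(1.0)
    assert (t.blen[:-1] >= 0).all()
    assert t.tip_labels == [f"g{i:04d}" for i in range(4)]
    assert simulate_tree(16, seed=9).to_newick() == \
        simulate_tree(16, seed=9).to_newick()
    assert simulate_tree(8, "coalescent", seed=2).n_tips == 8
    with pytest.raises(ValueError, match="at least 3"):
        simulate_tree(2)
    with pytest.raises(ValueError, match="unknown tree model"):
        simulate_tree(8, "foo")


def n_cherries(tree):
    left, right = tree.left, tree.right
    return sum(1 for v in tree.internal_nodes()
               if left[v] < tree.n_tips and right[v] < tree.n_tips)


def test_yule_cherry_fraction():
    # under the Yule model the expected cherries/tips ratio approaches 1/3;
    # Monte-Carlo check within 3 standard errors
    n, reps = 40, 200
    fracs = [n_cherries(simulate_tree(n, seed=s)) / n for s in range(reps)]
    mean = np.mean(fracs)
    se = np.std(fracs, ddof=1) / np.sqrt(reps)
    assert abs(mean - 1 / 3) < 3 * se + 1 / n   # 1/n: finite-size bias slack


def test_rates_for_events():
    q01, q10 = rates_for_events(tree_length=10.0, events=12.0, prevalence=0.3)
    assert q01 / (q01 + q10) == pytest.approx(0.3)        # stationarity
    s = q01 + q10
    assert 2 * 10.0 * s * 0.3 * 0.7 == pytest.approx(12.0)  # event count
    with pytest.raises(ValueError):
        rates_for_events(10.0, 5.0, 1.0)


# --------------------------------------------------------------------------- #
# Modules
# --------------------------------------------------------------------------- #
def test_module_spec_validation():
    ones = np.ones((2, 2))
    with pytest.raises(ValueError, match="exceeds the joint-state guard"):
        ModuleSpec("m", [f"g{i}" for i in range(13)], np.ones(13), np.ones(13),
                   np.ones((13, 13)), np.ones((13, 13)), "null")
    with pytest.raises(ValueError, match="non-negative"):
        ModuleSpec("m", ["a", "b"], [1, -1], [1, 1], ones, ones, "null")
    with pytest.raises(ValueError, match=r"\(m, m\)"):
        ModuleSpec("m", ["a", "b"], [1, 1], [1, 1], np.ones((3, 3)), ones,
                   "null")


def test_flip_rates_and_stationary_independent_case():
    # with all multipliers 1 the stationary law factorises per gene
    spec = ModuleSpec("m", ["a", "b"], [1.0, 2.0], [3.0, 2.0],
                      np.ones((2, 2)), np.ones((2, 2)), "null")
    rates = _flip_rates(spec)
    assert rates.shape == (4, 2)
    assert rates[0b00, 0] == 1.0 and rates[0b01, 0] == 3.0
    pi = _stationary(rates)
    pa, pb = 1.0 / 4.0, 2.0 / 4.0
    expect = [(1 - pa) * (1 - pb), pa * (1 - pb), (1 - pa) * pb, pa * pb]
    assert np.allclose(pi, expect, atol=1e-6)


def test_evolve_branch_event_count_linearity():
    # Gillespie event counts grow linearly with branch length
    spec = ModuleSpec("m", ["a"], [5.0], [5.0], np.ones((1, 1)),
                      np.ones((1, 1)), "null")
    rates = _flip_rates(spec)
    rng = np.random.default_rng(0)
    t = 10.0     # ~50 events per call at total rate 5
    n_calls = 200
    mean_t = np.mean([_evolve_branch(0, t, rates, rng)[1]
                      for _ in range(n_calls)])
    mean_2t = np.mean([_evolve_branch(0, 2 * t, rates, rng)[1]
                       for _ in range(n_calls)])
    assert mean_2t / mean_t == pytest.approx(2.0, rel=0.05)


def test_uncoupled_module_matches_independent_simulation():
    # multipliers = 1: per-gene marginals match the independent two-state
    # simulator within 3 SE (star-like tree, so tips are exactly i.i.d.)
    tree = star_like_tree(4, 10.0)
    alpha, beta = 1.0, 2.0
    spec = ModuleSpec("m", ["a", "b"], [alpha, alpha], [beta, beta],
                      np.ones((2, 2)), np.ones((2, 2)), "null")
    reps = 500
    tot, n = 0, 0
    for r in range(reps):
        tips = simulate_module(tree, spec, seed=r)
        tot += tips.sum()
        n += tips.size
    rng = np.random.default_rng(1)
    ind = simulate_mk_many(tree, np.full(2 * reps, alpha),
                           np.full(2 * reps, beta),
                           np.full(2 * reps, alpha / (alpha + beta)), rng)
    p = ind.mean()
    se = np.sqrt(p * (1 - p) * (1 / n + 1 / ind.size))
    assert abs(tot / n - p) < 3 * se


def test_strict_commensal_construction():
    # B cannot be gained and is lost 100x faster when A is absent
    # moderate host turnover: the only A-absent-B-present lineage time is the
    # short lag after a host loss, which scales with the host's event count
    tree = simulate_tree(32, seed=5)
    a_rates = rates_for_events(tree.total_length(), 10.0, 0.6)
    b_rates = rates_for_events(tree.total_length(), 40.0, 0.8)
    gain_mult = np.ones((2, 2))
    loss_mult = np.ones((2, 2))
    gain_mult[1, 0] = 1e6          # B gains essentially only when A present
    loss_mult[1, 0] = 1e-2         # i.e. loss x100 when A absent
    spec = ModuleSpec("c", ["A", "B"], [a_rates[0], b_rates[0] / 1e6],
                      [a_rates[1], b_rates[1] * 1e2],
                      gain_mult, loss_mult, "commensalism")
    n_ab = n_b = 0
    for r in range(100):
        tips = simulate_module(tree, spec, seed=r)
        n_b += tips[1].sum()
        n_ab += (tips[0] & tips[1]).sum()
    assert n_b > 0
    assert n_ab / n_b >= 0.99      # P(A present | B present)


def test_strong_competition_construction():
    tree = simulate_tree(32, seed=6)
    q = rates_for_events(tree.total_length(), 40.0, 0.5)
    spec = ModuleSpec("x", ["A", "B"], [q[0], q[0]], [q[1], q[1]],
                      gain_mult=np.zeros((2, 2)),
                      loss_mult=np.full((2, 2), 100.0),
                      category="competition")
    joint = total = 0
    for r in range(100):
        tips = simulate_module(tree, spec, seed=r)
        joint += (tips[0] & tips[1]).sum()
        total += tips.shape[1]
    assert joint / total < 0.01


def test_module_factories_have_declared_structure():
    tree = simulate_tree(64, seed=4)
    rng = np.random.default_rng(0)
    mut = mutualism_module("mut001", tree, rng)
    assert (mut.gain_mult[0, 1] > 1) and (mut.loss_mult[0, 1] < 1)
    com = commensalism_module("com001", tree, rng)
    # the host's rates ignore the dependent; the dependent needs the host
    assert com.gain_mult[0, 1] == 1 and com.loss_mult[0, 1] == 1
    assert com.gain_mult[1, 0] > 100 and com.loss_mult[1, 0] < 1
    cmp_ = competition_module("cmp001", tree, rng)
    assert (cmp_.gain_mult[0, 1] < 1) and (cmp_.loss_mult[0, 1] > 1)


# --------------------------------------------------------------------------- #
# Benchmarks
# --------------------------------------------------------------------------- #
def test_benchmark_bookkeeping(small_benchmark):
    b = small_benchmark
    coupled = b.truth.coupled_genes()
    assert len(b.truth.pairs) == 4                    # 2 + 1 + 1 modules
    assert len(coupled) == 8
    # truth covers every matrix column exactly once
    assert set(b.matrix.gene_ids) == coupled | set(b.truth.null_genes)
    assert not (coupled & set(b.truth.null_genes))
    prev = b.matrix.prevalence()
    assert ((prev >= 0.05) & (prev <= 0.95)).all()
    assert set(b.truth.null_rates) == set(b.truth.null_genes)
    frame = truth_to_frame(b.truth)
    assert len(frame) == len(b.truth.pairs) + len(b.truth.null_genes)


def test_benchmark_byte_reproducible():
    a = generate_benchmark(n_tips=32, n_null_genes=20, n_mutualism=1,
                           n_commensal=1, n_competition=0, seed=11)
    b = generate_benchmark(n_tips=32, n_null_genes=20, n_mutualism=1,
                           n_commensal=1, n_competition=0, seed=11)
    assert a.matrix.gene_ids == b.matrix.gene_ids
    assert np.array_equal(a.matrix.values, b.matrix.values)
    assert a.tree.to_newick() == b.tree.to_newick()
    assert a.truth.pairs == b.truth.pairs
    c = generate_benchmark(n_tips=32, n_null_genes=20, n_mutualism=1,
                           n_commensal=1, n_competition=0, seed=12)
    assert not np.array_equal(
        np.sort(a.matrix.values, axis=None), np.sort(c.matrix.values, axis=None)) \
        or a.tree.to_newick() != c.tree.to_newick()


def test_benchmark_pure_null():
    b = generate_benchmark(n_tips=16, n_null_genes=25, n_mutualism=0,
                           n_commensal=0, n_competition=0, seed=1)
    assert b.truth.pairs == []
    assert b.matrix.n_genes == len(b.truth.null_genes)


def test_simulate_gene_orders(small_benchmark):
    df = simulate_gene_orders(small_benchmark, p_linked=1.0, seed=0)
    m = small_benchmark.matrix
    for genome, grp in df.groupby("genome"):
        pos = np.sort(grp["position"].to_numpy())
        assert np.array_equal(pos, np.arange(len(pos)))
        row = m.values[m.genome_ids.index(genome)]
        assert len(grp) == int(row.sum())
    # with p_linked=1 every co-present planted pair is adjacent (circular)
    one = df[df["genome"] == m.genome_ids[0]].set_index("gene")["position"]
    n = len(one)
    for a, b, _cat in small_benchmark.truth.pairs:
        if a in one.index and b in one.index:
            d = abs(int(one[a]) - int(one[b]))
            assert min(d, n - d) == 1
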