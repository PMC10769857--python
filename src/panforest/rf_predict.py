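"""Per-PAP supervised predictability screening.

For every presence-absence pattern, a random forest is trained to predict it
from all other PAPs over the deduplicated genome rows, on a stratified 75/25
split drawn independently per PAP. A pattern counts as accurately predicted
when the F1 score of both the present and the absent class reaches the
configured minimum on the held-out test set, and the Gini (mean decrease in
impurity) importances of the predictor PAPs are retained for network
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._tree import Phylogeny
from .config import PipelineConfig, derive_seed
from .pangenome_matrix import PAMatrix, PAPSet, collapse_patterns, filter_by_frequency

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Splitting
# --------------------------------------------------------------------------- #
@dataclass
class SplitSpec:
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def stratified_split(n_genomes: int, target, train_frac: float,
                     seed: int) -> SplitSpec | None:
    """Stratified train/test partition of genome indices.

    The training set holds ``round(train_frac * N)`` genomes, allocated to the
    two target classes by largest remainder so each class's train share stays
    within one genome of its overall proportion (every class keeps at least
    one genome on each side). Returns ``None`` when either class has fewer
    than two genomes - such PAPs are skipped and logged by the caller.
    """
    target = np.asarray(target).astype(bool)
    if target.size != n_genomes:
        raise ValueError("target length must equal the number of genomes")
    n1 = int(target.sum())
    n0 = n_genomes - n1
    if n1 < 2 or n0 < 2:
        return None
    n_train = round(train_frac * n_genomes)
    q1, q0 = train_frac * n1, train_frac * n0
    k1, k0 = math.floor(q1), math.floor(q0)
    while k1 + k0 < n_train:  # largest remainder; ties go to the larger class
        f1, f0 = q1 - k1, q0 - k0
        if f1 > f0 or (f1 == f0 and n1 >= n0):
            k1 += 1
        else:
            k0 += 1
    k1 = min(max(k1, 1), n1 - 1)
    k0 = min(max(n_train - k1, 1), n0 - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genomes)
    ones = order[target[order]]
    zeros = order[~target[order]]
    train = np.sort(np.concatenate([ones[:k1], zeros[:k0]]))
    test = np.sort(np.concatenate([ones[k1:], zeros[k0:]]))
    return SplitSpec(train, test, seed)


# --------------------------------------------------------------------------- #
# Metrics
# --------------------------------------------------------------------------- #
@dataclass
class ClassMetrics:
    """Test-set confusion counts and derived metrics, present = positive."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float = field(init=False)
    precision_present: float = field(init=False)
    recall_present: float = field(init=False)
    f1_present: float = field(init=False)
    precision_absent: float = field(init=False)
    recall_absent: float = field(init=False)
    f1_absent: float = field(init=False)
    undefined: bool = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        total = tp + fp + fn + tn
        self.accuracy = (tp + tn) / total if total else np.nan
        self.precision_present = tp / (tp + fp) if (tp + fp) else np.nan
        self.recall_present = tp / (tp + fn) if (tp + fn) else np.nan
        self.precision_absent = tn / (tn + fn) if (tn + fn) else np.nan
        self.recall_absent = tn / (tn + fp) if (tn + fp) else np.nan
        self.f1_present = _f1(self.precision_present, self.recall_present)
        self.f1_absent = _f1(self.precision_absent, self.recall_absent)
        self.undefined = bool(np.isnan([
            self.accuracy, self.precision_present, self.recall_present,
            self.f1_present, self.precision_absent, self.recall_absent,
            self.f1_absent,
        ]).any())


def _f1(precision: float, recall: float) -> float:
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        return np.nan
    return 2 * precision * recall / (precision + recall)


@dataclass
class PredictionRecord:
    pattern_id: str
    metrics: ClassMetrics | None
    importances: dict[str, float]
    predictable: bool
    skipped: bool = False
    skip_reason: str = ""


# --------------------------------------------------------------------------- #
# Fitting
# --------------------------------------------------------------------------- #
def fit_and_score_pap(paps: PAPSet, target_id: str, config: PipelineConfig,
                      _X: np.ndarray | None = None) -> PredictionRecord:
    """Train and evaluate the forest for one target PAP.

    The target is excluded from its own feature set. ``_X`` lets callers pass
    the precomputed (genomes x PAPs) float32 design matrix when screening
    many PAPs. Ties in the forest's averaged vote at exactly 0.5 resolve to
    the absent class.
    """
    ids = paps.pattern_ids
    t = ids.index(target_id)
    X_all = _X if _X is not None else _design_matrix(paps)
    y = X_all[:, t].astype(np.uint8)
    X = np.delete(X_all, t, axis=1)
    feature_ids = ids[:t] + ids[t + 1:]

    seed = derive_seed(config.seed, "rf", target_id)
    split = stratified_split(X.shape[0], y, config.train_frac, seed)
    if split is None:
        log.info("PAP %s skipped: a class has fewer than 2 genomes", target_id)
        return PredictionRecord(target_id, None, {}, False, skipped=True,
                                skip_reason="single-class or near-constant target")
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features="sqrt",
        criterion="gini",
        bootstrap=config.bootstrap,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X[split.train_idx], y[split.train_idx])
    pred = rf.predict(X[split.test_idx])
    truth = y[split.test_idx].astype(bool)
    pred = pred.astype(bool)
    metrics = ClassMetrics(
        tp=int(np.sum(truth & pred)), fp=int(np.sum(~truth & pred)),
        fn=int(np.sum(truth & ~pred)), tn=int(np.sum(~truth & ~pred)),
    )
    importances = {fid: float(w)
                   for fid, w in zip(feature_ids, rf.feature_importances_)}
    predictable = (not metrics.undefined
                   and metrics.f1_present >= config.f1_min
                   and metrics.f1_absent >= config.f1_min)
    return PredictionRecord(target_id, metrics, importances, bool(predictable))


def _design_matrix(paps: PAPSet) -> np.ndarray:
    """(deduplicated genomes) x PAPs float32 matrix for the forests."""
    return np.ascontiguousarray(paps.matrix(collapsed=True).T,
                                dtype=np.float32)


def run_predictability_screen(paps: PAPSet, config: PipelineConfig
                              ) -> tuple[list[PredictionRecord], pd.DataFrame]:
    """Fit one forest per PAP and collect metrics.

    Returns the full records (with importances) and a tidy metrics table.
    Skipped PAPs appear as analysed-but-unpredictable rows with a flag so
    denominators stay explicit.
    """
    if len(paps) < 2:
        return [], records_to_frame([])
    X = _design_matrix(paps)
    records = [fit_and_score_pap(paps, pid, config, _X=X)
               for pid in paps.pattern_ids]
    n_pred = sum(r.predictable for r in records)
    log.info("screen: %d/%d PAPs predictable (dual-class F1 >= %.2f)",
             n_pred, len(records), config.f1_min)
    return records, records_to_frame(records)


_METRIC_FIELDS = ["accuracy", "precision_present", "recall_present",
                  "f1_present", "precision_absent", "recall_absent",
                  "f1_absent", "tp", "fp", "fn", "tn"]


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"pattern_id": r.pattern_id, "predictable": r.predictable,
               "skipped": r.skipped}
        for f in _METRIC_FIELDS:
            row[f] = getattr(r.metrics, f) if r.metrics is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows, columns=["pattern_id", "predictable", "skipped"]
                      + _METRIC_FIELDS)
    return df.set_index("pattern_id") if len(df) else df


def importances_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    """Sparse three-column (target, source, gini) importance table."""
    rows = [(r.pattern_id, src, g)
            for r in records for src, g in sorted(r.importances.items()) if g > 0]
    return pd.DataFrame(rows, columns=["target", "source", "gini"])


# --------------------------------------------------------------------------- #
# Stability and downsampling experiments
# --------------------------------------------------------------------------- #
def repeat_stability(paps: PAPSet, config: PipelineConfig,
                     n_repeats: int = 100) -> pd.DataFrame:
    """Repeat the whole screen with fresh splits and tally, per PAP, how
    often it comes out predictable (always / never / sometimes)."""
    counts = {pid: 0 for pid in paps.pattern_ids}
    for rep in range(n_repeats):
        rep_config = config.replace(seed=derive_seed(config.seed, "repeat", rep))
        records, _ = run_predictability_screen(paps, rep_config)
        for r in records:
            counts[r.pattern_id] += int(r.predictable)
    df = pd.DataFrame({
        "pattern_id": list(counts),
        "n_predictable": list(counts.values()),
        "n_repeats": n_repeats,
    }).set_index("pattern_id")
    df["outcome"] = np.select(
        [df.n_predictable == n_repeats, df.n_predictable == 0],
        ["always", "never"], default="sometimes")
    return df


def downsample_screen(matrix: PAMatrix, tree: Phylogeny,
                      config: PipelineConfig,
                      fractions=(0.5, 0.25, 0.1, 0.05),
                      repeats: int = 10) -> pd.DataFrame:
    """Sensitivity of the screen to dataset size.

    For each retained fraction of genomes (sampled without replacement,
    seeded) the matrix is re-filtered, re-collapsed and fully re-screened,
    including the D filter on the subsampled tree. ``matrix`` is the
    unfiltered (or frequency-filtered) presence-absence matrix.
    """
    from .phylo_signal import signal_screen

    rows = []
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise ValueError("fractions must lie in (0, 1]")
        for rep in range(repeats):
            rng = np.random.default_rng(
                derive_seed(config.seed, "downsample", frac, rep))
            n_keep = max(2, int(round(frac * matrix.n_genomes)))
            keep = np.sort(rng.choice(matrix.n_genomes, n_keep, replace=False)) \
                if n_keep < matrix.n_genomes else np.arange(matrix.n_genomes)
            sub = PAMatrix([matrix.genome_ids[i] for i in keep],
                           list(matrix.gene_ids), matrix.values[keep])
            sub = filter_by_frequency(sub, config.rare_min, config.common_max)
            if sub.n_genes == 0:
                rows.append({"fraction": frac, "repeat": rep,
                             "n_paps_analysed": 0,
                             "n_predictable_with_D_pass": 0})
                continue
            sub_paps, _ = collapse_patterns(sub)
            sub_config = config.replace(
                seed=derive_seed(config.seed, "downsample_run", frac, rep))
            records, _ = run_predictability_screen(sub_paps, sub_config)
            sub_tree = _subsample_tree(tree, sub.genome_ids, sub_config.seed)
            passing = [r.pattern_id for r in records if r.predictable]
            signals = signal_screen(sub_tree, sub_paps, sub_config,
                                    pattern_ids=passing)
            n_pass = int(signals["pass"].sum())
            rows.append({"fraction": frac, "repeat": rep,
                         "n_paps_analysed": len(records),
                         "n_predictable_with_D_pass": n_pass})
    return pd.DataFrame(rows)


def _subsample_tree(tree: Phylogeny, genome_ids, seed: int) -> Phylogeny:
    from .phylo_signal import prepare_tree
    return prepare_tree(tree.to_newick(), genome_ids, seed=seed)
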