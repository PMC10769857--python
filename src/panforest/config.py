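"""Pipeline configuration and deterministic seed derivation."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict


@dataclass
class PipelineConfig:
    """Thresholds and sizes shared across the pipeline stages.

    Defaults correspond to the standard analysis settings: accessory genes
    are those present in 1-99% of genomes (boundaries kept), random forests
    use 1,000 trees of depth 16 on a 75/25 stratified split, a gene counts as
    accurately predicted when the F1 score of both the present and the absent
    class reaches 0.9 on the test set, edges need a Gini importance of at
    least 0.01, and predicted genes must show a Fritz-Purvis D above 0 with a
    Fitch parsimony score of at least 8 changes on the tree.
    """

    rare_min: float = 0.01
    common_max: float = 0.99
    train_frac: float = 0.75
    n_trees: int = 1000
    max_depth: int = 16
    f1_min: float = 0.90
    gini_min: float = 0.01
    d_min: float = 0.0          # exclusive: pass requires D > d_min
    parsimony_min: int = 8
    commensal_host_cover: float = 0.99
    commensal_presence_ratio: float = 0.20
    n_null_sims: int = 100
    n_d_permutations: int = 1000
    seed: int = 0
    bootstrap: bool = True      # genome bootstrap per tree in the forest
    mutual_ratio: float | None = None  # optional max/min Gini ratio for mutualism

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_min < self.common_max < 1.0):
            raise ValueError("need 0 < rare_min < common_max < 1")
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("need 0 < train_frac < 1")
        for name in ("n_trees", "max_depth", "parsimony_min",
                     "n_null_sims", "n_d_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("f1_min", "gini_min", "commensal_host_cover",
                     "commensal_presence_ratio"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **kw) -> "PipelineConfig":
        d = asdict(self)
        d.update(kw)
        return PipelineConfig(**d)


def derive_seed(master: int, *tokens) -> int:
    """A stable sub-seed from a master seed and context tokens.

    Hash-based so that e.g. adding one PAP to a screen does not shift the
    random stream of every other PAP. Always below 2**31.
    """
    payload = repr((int(master),) + tuple(tokens)).encode()
    digest = hashlib.blake2b(payload, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
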