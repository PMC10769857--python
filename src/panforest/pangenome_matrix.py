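"""Presence-absence matrices and their collapse into unique patterns (PAPs).

The pipeline operates on a binary genomes x gene-families matrix. Gene
families sharing an identical presence-absence column are collapsed into one
presence-absence pattern (PAP), and genomes with identical rows are collapsed
to a single representative for model fitting, while the full genome list is
retained for prevalence and category calculations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ROARY_META_COLUMNS = 14  # fixed metadata columns before the genome columns


# --------------------------------------------------------------------------- #
# Types
# --------------------------------------------------------------------------- #
@dataclass
class PAMatrix:
    """Binary genomes x gene-families matrix. 1 = present, 0 = absent."""

    genome_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # uint8, shape (n_genomes, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.genome_ids), len(self.gene_ids)):
            raise ValueError("matrix shape inconsistent with identifier lists")
        for kind, ids in (("genome", self.genome_ids), ("gene", self.gene_ids)):
            dups = _duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {kind} identifiers: {sorted(dups)}")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def prevalence(self) -> np.ndarray:
        """Fraction of genomes carrying each gene."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids,
                            columns=self.gene_ids)


@dataclass
class PAP:
    """One unique presence-absence pattern and the genes that share it."""

    pattern_id: str
    pattern: np.ndarray          # uint8 over the full genome list
    members: list[str]
    prevalence: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a PAP must have at least one member gene")


@dataclass
class PAPSet:
    """All PAPs of a matrix plus the genome-deduplication bookkeeping."""

    genome_ids: list[str]
    paps: list[PAP]
    rep_indices: np.ndarray        # columns of the deduplicated genome rows
    genome_classes: dict[str, str]  # genome_id -> genome class id
    by_id: dict[str, PAP] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.by_id = {p.pattern_id: p for p in self.paps}
        if len(self.by_id) != len(self.paps):
            raise ValueError("duplicate pattern ids")

    def __len__(self) -> int:
        return len(self.paps)

    @property
    def pattern_ids(self) -> list[str]:
        return [p.pattern_id for p in self.paps]

    def matrix(self, collapsed: bool = False) -> np.ndarray:
        """Patterns stacked as a (n_paps, n_genomes) array.

        With ``collapsed=True`` only one representative genome per identical
        row is kept -- the modelling view used by the random forests.
        """
        if not self.paps:
            n = len(self.rep_indices) if collapsed else len(self.genome_ids)
            return np.zeros((0, n), dtype=np.uint8)
        full = np.stack([p.pattern for p in self.paps])
        return full[:, self.rep_indices] if collapsed else full


@dataclass
class CollapseMap:
    gene_to_pattern: dict[str, str]
    genome_to_class: dict[str, str]


# --------------------------------------------------------------------------- #
# IO
# --------------------------------------------------------------------------- #
def read_presence_absence(path, dialect: str | None = None,
                          meta_columns: int = ROARY_META_COLUMNS) -> PAMatrix:
    """Read a gene presence-absence table.

    ``dialect`` is ``"rtab"`` (tab-delimited, genes in rows, cells 0/1) or
    ``"roary_csv"`` (quoted CSV with gene names in cells; any non-empty
    genome cell maps to 1, an empty cell to 0). When omitted the dialect is
    sniffed from the header line.
    """
    if dialect is None:
        with open(path) as fh:
            header = fh.readline()
        dialect = "rtab" if "\t" in header else "roary_csv"
    if dialect == "rtab":
        return _read_rtab(path)
    if dialect == "roary_csv":
        return _read_roary_csv(path, meta_columns)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_rtab(path) -> PAMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    genome_ids = [str(g) for g in df.columns]
    raw = df.to_numpy()
    values = np.zeros(raw.shape, dtype=np.uint8)
    for cell_value in ("0", "1"):
        values[raw == cell_value] = int(cell_value)
    bad = ~np.isin(raw, ("0", "1"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary cell {raw[i, j]!r} for gene {gene_ids[i]!r} "
            f"in genome {genome_ids[j]!r}"
        )
    # rows are genes in the file; the in-memory convention is genomes x genes
    return PAMatrix(genome_ids, gene_ids, values.T)


def _read_roary_csv(path, meta_columns: int) -> PAMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] <= meta_columns:
        raise ValueError(
            f"expected genome columns after {meta_columns} metadata columns"
        )
    gene_ids = [str(g) for g in df.iloc[:, 0]]
    genome_ids = [str(g) for g in df.columns[meta_columns:]]
    cells = df.iloc[:, meta_columns:].to_numpy()
    values = (cells != "").astype(np.uint8)
    return PAMatrix(genome_ids, gene_ids, values.T)


def write_rtab(matrix: PAMatrix, path) -> None:
    df = pd.DataFrame(matrix.values.T, index=pd.Index(matrix.gene_ids, name="Gene"),
                      columns=matrix.genome_ids)
    df.to_csv(path, sep="\t")


def write_collapse_map(cmap: CollapseMap, gene_path, genome_path) -> None:
    pd.DataFrame(sorted(cmap.gene_to_pattern.items()),
                 columns=["gene", "pattern_id"]).to_csv(
        gene_path, sep="\t", index=False)
    pd.DataFrame(sorted(cmap.genome_to_class.items()),
                 columns=["genome", "genome_class"]).to_csv(
        genome_path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# Filtering and collapsing
# --------------------------------------------------------------------------- #
def filter_by_frequency(matrix: PAMatrix, rare_min: float = 0.01,
                        common_max: float = 0.99) -> PAMatrix:
    """Drop genes present in fewer than ``rare_min`` or more than
    ``common_max`` of genomes; exactly-at-boundary genes are kept.

    Comparisons are exact rationals on genome counts so that e.g. a gene in
    3 of 300 genomes (exactly 1%) survives regardless of float rounding.
    """
    if not (0.0 < rare_min < common_max < 1.0):
        raise ValueError("need 0 < rare_min < common_max < 1")
    n = matrix.n_genomes
    lo = Fraction(str(rare_min)) * n
    hi = Fraction(str(common_max)) * n
    counts = matrix.values.sum(axis=0)
    keep = np.array([lo <= int(c) <= hi for c in counts])
    if not keep.any():
        warnings.warn("no genes survive the frequency filter", stacklevel=2)
    return PAMatrix(
        list(matrix.genome_ids),
        [g for g, k in zip(matrix.gene_ids, keep) if k],
        matrix.values[:, keep],
    )


def collapse_patterns(matrix: PAMatrix) -> tuple[PAPSet, CollapseMap]:
    """Collapse identical gene columns into PAPs and identical genome rows
    into genome classes.

    The pattern id is deterministic: ``PAP:`` plus the lexicographically
    smallest member gene id. Genome class ids follow the same rule with a
    ``GC:`` prefix.
    """
    cols: dict[bytes, list[str]] = {}
    col_vec: dict[bytes, np.ndarray] = {}
    for j, gene in enumerate(matrix.gene_ids):
        key = matrix.values[:, j].tobytes()
        cols.setdefault(key, []).append(gene)
        col_vec[key] = matrix.values[:, j]
    paps = []
    gene_to_pattern = {}
    for key, members in cols.items():
        members = sorted(members)
        pid = "PAP:" + members[0]
        vec = col_vec[key]
        paps.append(PAP(pid, vec.copy(), members, float(vec.mean())))
        for g in members:
            gene_to_pattern[g] = pid
    paps.sort(key=lambda p: p.pattern_id)

    rows: dict[bytes, list[int]] = {}
    for i in range(matrix.n_genomes):
        rows.setdefault(matrix.values[i].tobytes(), []).append(i)
    genome_to_class = {}
    rep_indices = []
    for idxs in rows.values():
        rep = min(idxs, key=lambda i: matrix.genome_ids[i])
        cid = "GC:" + matrix.genome_ids[rep]
        rep_indices.append(rep)
        for i in idxs:
            genome_to_class[matrix.genome_ids[i]] = cid
    rep_indices = np.array(sorted(rep_indices), dtype=np.intp)

    papset = PAPSet(list(matrix.genome_ids), paps, rep_indices, genome_to_class)
    if len(rep_indices) < matrix.n_genomes:
        log.info("collapsed %d genomes into %d unique rows",
                 matrix.n_genomes, len(rep_indices))
    return papset, CollapseMap(gene_to_pattern, genome_to_class)


def expand_patterns(papset: PAPSet, cmap: CollapseMap,
                    gene_ids: list[str]) -> PAMatrix:
    """Reconstruct the filtered matrix from its PAPs (inverse of collapse)."""
    values = np.stack(
        [papset.by_id[cmap.gene_to_pattern[g]].pattern for g in gene_ids],
        axis=1,
    )
    return PAMatrix(list(papset.genome_ids), list(gene_ids), values)


# --------------------------------------------------------------------------- #
# Conditional frequencies
# --------------------------------------------------------------------------- #
def pap_conditional_frequencies(target: PAP | np.ndarray,
                                source: PAP | np.ndarray) -> dict:
    """2x2 contingency of a target pattern against a source pattern.

    Returns joint counts and ``p_target``, ``p_target_given_source_present``
    and ``p_target_given_source_absent``; a zero denominator yields ``None``
    for the corresponding frequency rather than an error.
    """
    t = target.pattern if isinstance(target, PAP) else np.asarray(target)
    s = source.pattern if isinstance(source, PAP) else np.asarray(source)
    if t.shape != s.shape:
        raise ValueError("patterns cover different genome lists")
    t = t.astype(bool)
    s = s.astype(bool)
    n11 = int(np.sum(t & s))
    n10 = int(np.sum(t & ~s))
    n01 = int(np.sum(~t & s))
    n00 = int(np.sum(~t & ~s))
    n = t.size
    return {
        "n11": n11, "n10": n10, "n01": n01, "n00": n00,
        "p_target": n and (n11 + n10) / n,
        "p_target_given_source_present":
            (n11 / (n11 + n01)) if (n11 + n01) else None,
        "p_target_given_source_absent":
            (n10 / (n10 + n00)) if (n10 + n00) else None,
    }


def _duplicates(items) -> set:
    seen, dups = set(), set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups
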