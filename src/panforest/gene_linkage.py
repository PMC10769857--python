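"""Physical linkage between associated genes, measured in gene counts.

Distances are ordinal differences between gene positions on a replicon
(adjacent genes are 1 apart); on circular replicons the shorter way around
is taken. Pairs co-resident in a genome but on different replicons (e.g.
chromosome vs plasmid) are tallied separately as cross-element pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class GeneOrderTable:
    """Per-genome, per-replicon gene order.

    ``table`` columns: genome, replicon, circular (0/1), gene, position.
    Positions on each replicon must be a permutation of 0..n-1; a gene family
    may appear several times (multi-copy) and on several replicons.
    """

    table: pd.DataFrame
    _placements: dict = field(init=False, repr=False)
    _replicons: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = ["genome", "replicon", "circular", "gene", "position"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene-order table lacks columns {missing}")
        self._replicons = {}
        for (genome, replicon), grp in self.table.groupby(["genome", "replicon"]):
            pos = np.sort(grp["position"].to_numpy())
            if not np.array_equal(pos, np.arange(len(pos))):
                raise ValueError(
                    f"positions on {genome}/{replicon} are not a permutation "
                    f"of 0..{len(pos) - 1}")
            circ = set(grp["circular"].astype(int))
            if len(circ) != 1:
                raise ValueError(
                    f"inconsistent circular flag on {genome}/{replicon}")
            self._replicons[(genome, replicon)] = (len(pos), circ.pop() == 1)
        self._placements = {}
        for row in self.table.itertuples(index=False):
            self._placements.setdefault((row.genome, row.gene), []).append(
                (row.replicon, int(row.position)))

    @property
    def genomes(self) -> list[str]:
        return sorted(self.table["genome"].unique())

    def placements(self, genome: str, gene: str) -> list[tuple[str, int]]:
        return self._placements.get((genome, gene), [])


def read_gene_orders(path) -> GeneOrderTable:
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "replicon": str,
                                            "gene": str})
    return GeneOrderTable(df)


def circular_distance(pos_a: int, pos_b: int, n_genes: int,
                      circular: bool = True) -> int:
    """Gene-count distance between two positions on one replicon."""
    if not (0 <= pos_a < n_genes and 0 <= pos_b < n_genes):
        raise ValueError(
            f"positions {pos_a}, {pos_b} out of range for {n_genes} genes")
    d = abs(pos_a - pos_b)
    return min(d, n_genes - d) if circular else d


def pair_linkage_profile(gene_a: str, gene_b: str, orders: GeneOrderTable,
                         near_max: int = 10, far_min: int = 21,
                         matrix=None) -> dict:
    """Per-genome minimum distance between two gene families.

    For each genome carrying both genes, the minimum distance over all copy
    placements on shared replicons is recorded; co-resident pairs with no
    shared replicon count as cross-element. Summary fractions report how
    many co-replicon pairs sit within ``near_max`` genes and at or beyond
    ``far_min`` genes. When a presence-absence ``matrix`` is supplied,
    genomes where it asserts presence but the order table has no placement
    are skipped with a warning.
    """
    expected = None
    if matrix is not None:
        cols = {g: j for j, g in enumerate(matrix.gene_ids)}
        rows = {g: i for i, g in enumerate(matrix.genome_ids)}
        expected = (cols, rows)
    distances: dict[str, int] = {}
    cross_element = 0
    for genome in orders.genomes:
        pa = orders.placements(genome, gene_a)
        pb = orders.placements(genome, gene_b)
        if expected is not None:
            cols, rows = expected
            for gene, placed in ((gene_a, pa), (gene_b, pb)):
                if (not placed and gene in cols and genome in rows
                        and matrix.values[rows[genome], cols[gene]] == 1):
                    log.warning("gene %s present in matrix but missing from "
                                "order table of genome %s; genome skipped",
                                gene, genome)
        if not pa or not pb:
            continue
        best = None
        shared = False
        for rep_a, pos_a in pa:
            for rep_b, pos_b in pb:
                if rep_a != rep_b:
                    continue
                shared = True
                n, circ = orders._replicons[(genome, rep_a)]
                d = circular_distance(pos_a, pos_b, n, circ)
                best = d if best is None else min(best, d)
        if shared:
            distances[genome] = best
        else:
            cross_element += 1
    vals = np.array(list(distances.values()))
    n_co = len(vals)
    return {
        "distances": distances,
        "cross_element": cross_element,
        "n_coreplicon": n_co,
        "frac_near": float(np.mean(vals <= near_max)) if n_co else np.nan,
        "frac_far": float(np.mean(vals >= far_min)) if n_co else np.nan,
    }


def linkage_table(pairs, orders: GeneOrderTable, **kw) -> pd.DataFrame:
    """``pair_linkage_profile`` over many (gene_a, gene_b) pairs."""
    rows = []
    for a, b in pairs:
        prof = pair_linkage_profile(a, b, orders, **kw)
        med = (float(np.median(list(prof["distances"].values())))
               if prof["distances"] else np.nan)
        rows.append({"gene_a": a, "gene_b": b,
                     "n_coreplicon": prof["n_coreplicon"],
                     "cross_element": prof["cross_element"],
                     "median_distance": med,
                     "frac_near": prof["frac_near"],
                     "frac_far": prof["frac_far"]})
    return pd.DataFrame(rows)
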