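"""Expression-pattern classification of ohnolog gene pairs.

Ohnologs are gene duplicates retained from the teleost whole-genome
duplication.  Expression is binarized per cell (TPM strictly greater
than 1), each pair's cells are partitioned into only-A / only-B / both /
none, and the pair is classified by a fixed decision tree:

* NotExpressed — neither member expressed in most cells
  (n_none > 300 at study scale);
* XOR — members used in mutually exclusive cells
  (both_min_diff = min(n_onlyA, n_onlyB) - n_both > 15);
* Single — one member carries essentially all usage
  (|n_exprA - n_exprB| > 60, breadths counting co-expressing cells);
* Mixed — everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OHNOLOG_CLASSES = ("NotExpressed", "XOR", "Single", "Mixed")


@dataclass(frozen=True)
class OhnologThresholds:
    """Decision-tree thresholds, tuned for a ~363-cell dataset."""

    not_expressed_cells: int = 300
    xor_both_min_diff: int = 15
    single_difference: int = 60
    expression_cutoff: float = 1.0
    # alternative reading of the NotExpressed rule: each member individually
    # expressed in no more than `not_expressed_cells` cells
    per_gene_not_expressed: bool = False

    def __post_init__(self) -> None:
        if min(self.not_expressed_cells, self.xor_both_min_diff, self.single_difference) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class OhnologPairRecord:
    gene_a: str
    gene_b: str
    n_only_a: int
    n_only_b: int
    n_both: int
    n_none: int
    both_min_diff: int
    pair_class: str


def binarize(matrix: pd.DataFrame, cutoff: float = 1.0) -> pd.DataFrame:
    """Expressed / not expressed per cell: strictly greater than ``cutoff``."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    return matrix > cutoff


def count_pair(binary: pd.DataFrame, gene_a: str, gene_b: str) -> tuple[int, int, int, int]:
    """(n_onlyA, n_onlyB, n_both, n_none) over all cells."""
    for g in (gene_a, gene_b):
        if g not in binary.columns:
            raise KeyError(f"unknown gene {g!r}")
    a = binary[gene_a].to_numpy(bool)
    b = binary[gene_b].to_numpy(bool)
    n_both = int((a & b).sum())
    n_only_a = int((a & ~b).sum())
    n_only_b = int((b & ~a).sum())
    n_none = int((~a & ~b).sum())
    return n_only_a, n_only_b, n_both, n_none


def classify_pair(
    counts: tuple[int, int, int, int],
    n_cells: int,
    thresholds: OhnologThresholds = OhnologThresholds(),
) -> str:
    """Apply the decision tree NotExpressed -> XOR -> Single -> Mixed."""
    n_only_a, n_only_b, n_both, n_none = counts
    if n_only_a + n_only_b + n_both + n_none != n_cells:
        raise ValueError("pair counts do not sum to the number of cells")
    n_expr_a = n_only_a + n_both
    n_expr_b = n_only_b + n_both
    if thresholds.per_gene_not_expressed:
        # literal per-gene reading: neither member expressed in more than
        # `not_expressed_cells` cells
        not_expressed = max(n_expr_a, n_expr_b) <= thresholds.not_expressed_cells
    else:
        not_expressed = n_none > thresholds.not_expressed_cells
    if not_expressed:
        return "NotExpressed"
    if min(n_only_a, n_only_b) - n_both > thresholds.xor_both_min_diff:
        return "XOR"
    if abs(n_expr_a - n_expr_b) > thresholds.single_difference:
        return "Single"
    return "Mixed"


def classify_all(
    matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    thresholds: OhnologThresholds = OhnologThresholds(),
) -> tuple[pd.DataFrame, dict[str, int], list[tuple[str, str]]]:
    """Classify every resolvable pair; report skipped pairs and a class tally.

    ``pairs`` needs columns ``gene_a`` and ``gene_b``; pairs with a
    member absent from the matrix are skipped and reported.
    """
    if len(pairs) == 0:
        raise ValueError("empty ohnolog pair list")
    binary = binarize(matrix, thresholds.expression_cutoff)
    n_cells = len(matrix)
    records: list[OhnologPairRecord] = []
    skipped: list[tuple[str, str]] = []
    for ga, gb in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        if ga not in binary.columns or gb not in binary.columns:
            skipped.append((ga, gb))
            continue
        counts = count_pair(binary, ga, gb)
        records.append(
            OhnologPairRecord(
                gene_a=ga,
                gene_b=gb,
                n_only_a=counts[0],
                n_only_b=counts[1],
                n_both=counts[2],
                n_none=counts[3],
                both_min_diff=min(counts[0], counts[1]) - counts[2],
                pair_class=classify_pair(counts, n_cells, thresholds),
            )
        )
    table = pd.DataFrame([r.__dict__ for r in records])
    tally = {c: int((table["pair_class"] == c).sum()) for c in OHNOLOG_CLASSES}
    return table, tally, skipped
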