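"""Cell/gene quality control, spike-in stripping, and TPM renormalization.

Conventions follow the study design: a gene is "expressed" in a cell when
its value is strictly greater than the cutoff (default 1 TPM); QC
thresholds are exclusive, so a cell with exactly the minimum read count
or expressed-gene count is retained; after spike-in stripping each
cell's endogenous values are rescaled to sum to one million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import SPIKE_PREFIX

TPM_TARGET = 1_000_000.0


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every cell."""


@dataclass(frozen=True)
class QcThresholds:
    """Exclusive lower bounds for cell QC.

    ``min_reads``/``min_genes`` mirror the sequencing-depth and
    library-complexity cut used on real plates (50,000 paired reads and
    1,000 expressed genes at genome scale); on synthetic data with a few
    hundred genes a scaled ``min_genes`` is used instead.
    """

    min_reads: int = 50_000
    min_genes: int = 1_000
    expressed_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.min_reads <= 0 or self.min_genes <= 0 or self.expressed_cutoff <= 0:
            raise ValueError("QC thresholds must be positive")


def spikein_mask(matrix: pd.DataFrame, prefix: str = SPIKE_PREFIX) -> pd.Series:
    """Boolean per-gene flag: True for spike-in control transcripts."""
    return pd.Series(
        matrix.columns.str.startswith(prefix), index=matrix.columns, name="spike_in"
    )


def expressed_gene_count(
    values: pd.Series | np.ndarray, cutoff: float = 1.0
) -> int:
    """Number of genes with expression strictly above ``cutoff`` in one cell."""
    arr = np.asarray(values, float)
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")
    return int((arr > cutoff).sum())


def filter_cells(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop cells failing either QC threshold.

    A cell is excluded when its paired read count is below
    ``thresholds.min_reads`` or its expressed-gene count (strictly
    greater than the expression cutoff, spike-ins included) is below
    ``thresholds.min_genes``; equality passes.  Returns the retained
    matrix and metadata plus a report listing every excluded cell with
    its reasons.
    """
    missing = matrix.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing for cells: {list(missing[:5])}")
    counts = (matrix.values > thresholds.expressed_cutoff).sum(axis=1)
    reads = meta.loc[matrix.index, "read_count"].to_numpy()
    low_reads = reads < thresholds.min_reads
    low_genes = counts < thresholds.min_genes
    drop = low_reads | low_genes
    reasons = []
    for i in np.flatnonzero(drop):
        why = []
        if low_reads[i]:
            why.append(f"reads {reads[i]} < {thresholds.min_reads}")
        if low_genes[i]:
            why.append(f"expressed genes {counts[i]} < {thresholds.min_genes}")
        reasons.append((matrix.index[i], "; ".join(why)))
    report = pd.DataFrame(reasons, columns=["cell", "reason"]).set_index("cell")
    keep = matrix.index[~drop]
    if len(keep) == 0:
        raise EmptyResultError("all cells excluded by QC thresholds")
    return matrix.loc[keep], meta.loc[keep], report


def strip_spikeins_and_rescale(
    matrix: pd.DataFrame, prefix: str = SPIKE_PREFIX
) -> pd.DataFrame:
    """Remove spike-in columns and rescale each cell to one million TPM."""
    spikes = spikein_mask(matrix, prefix)
    endo = matrix.loc[:, ~spikes.values]
    sums = endo.sum(axis=1)
    dead = sums.index[sums <= 0]
    if len(dead):
        raise EmptyResultError(
            f"cells with zero endogenous signal cannot be rescaled: {list(dead[:5])}"
        )
    return endo.div(sums, axis=0) * TPM_TARGET


def filter_genes(
    matrix: pd.DataFrame, min_tpm: float = 1.0, min_cells: int = 3
) -> pd.DataFrame:
    """Keep genes expressed above ``min_tpm`` in at least ``min_cells`` cells."""
    n_expressing = (matrix.values > min_tpm).sum(axis=0)
    keep = n_expressing >= min_cells
    if not keep.any():
        import warnings

        warnings.warn("gene filter removed every gene", stacklevel=2)
    return matrix.loc[:, keep]


def mrna_content_proxy(matrix: pd.DataFrame, prefix: str = SPIKE_PREFIX) -> pd.Series:
    """Endogenous-to-spike-in signal ratio per cell.

    Spike-ins enter each well at a fixed amount, so this ratio tracks the
    cell's endogenous mRNA content.  Computed on the matrix *before*
    spike-in stripping.
    """
    spikes = spikein_mask(matrix, prefix)
    if not spikes.any():
        raise ValueError("no spike-in columns found; cannot form content proxy")
    spike_sum = matrix.loc[:, spikes.values].sum(axis=1)
    if (spike_sum <= 0).any():
        bad = spike_sum.index[spike_sum <= 0]
        raise ValueError(f"zero spike-in signal in cells: {list(bad[:5])}")
    endo_sum = matrix.loc[:, ~spikes.values].sum(axis=1)
    return (endo_sum / spike_sum).rename("mrna_content")


def run_qc(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    min_tpm: float = 1.0,
    min_cells: int = 3,
    prefix: str = SPIKE_PREFIX,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full QC stage: cell filter, spike-in strip + rescale, gene filter.

    Returns the processed endogenous matrix, the retained metadata and a
    stage report with counts and the per-cell content proxy.
    """
    kept, meta_kept, cell_report = filter_cells(matrix, meta, thresholds)
    content = mrna_content_proxy(kept, prefix)
    rescaled = strip_spikeins_and_rescale(kept, prefix)
    final = filter_genes(rescaled, min_tpm=min_tpm, min_cells=min_cells)
    report = {
        "cells_in": int(matrix.shape[0]),
        "cells_retained": int(final.shape[0]),
        "cells_excluded": cell_report.to_dict()["reason"],
        "genes_in": int(matrix.shape[1]),
        "genes_retained": int(final.shape[1]),
        "mrna_content": content,
    }
    return final, meta_kept, report
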