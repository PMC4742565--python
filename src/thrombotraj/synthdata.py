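"""Synthetic single-cell datasets with known ground truth.

The generator emulates the statistical structure of index-sorted
cd41:EGFP kidney-marrow cells: a one-dimensional differentiation
continuum through five states (1a, 1b, 2, 3, 4) plus a small
high-FSC/SSC outlier group; a bimodal EGFP-like fluorescence covariate
increasing along the continuum; monotone marker genes (cd41-like,
EGFP-like); three dynamic trend groups (up-then-down, monotone-down,
up-then-plateau); per-state marker programs; declining endogenous mRNA
content and expressed-gene count along the continuum; constant spike-in
transcripts; Bernoulli dropout on top of log-normal noise; and planted
ohnolog pairs realizing each expression-pattern class.

Expression values are TPM-like relative abundances on an arbitrary raw
scale; downstream QC renormalizes each cell's endogenous values to sum
to one million.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import SPIKE_PREFIX

GENE_CLASSES = (
    "flat",
    "group_I",
    "group_II",
    "group_III",
    "marker",
    "state_marker",
    "ohnolog",
    "spike_in",
)
STATE_NAMES = ("1a", "1b", "2", "3", "4")
OHNOLOG_CLASSES = ("NotExpressed", "XOR", "Single", "Mixed")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic world.

    Defaults describe the study-scale scenario: 363 index-sorted cells,
    ~500 endogenous genes, 20 spike-ins, five differentiation states and
    a ~1% outlier group.  Amplitudes are on the natural-log expression
    scale; ``noise_sd`` is the log-scale dispersion; dropout probability
    grows linearly along the continuum, which makes the expressed-gene
    count decline with differentiation; ``content_decay`` scales all
    endogenous means down by ``exp(-content_decay * t)``, emulating the
    loss of total mRNA content in mature cells.
    """

    n_cells: int = 363
    n_genes: int = 500
    n_spikeins: int = 20
    n_states: int = 5
    state_proportions: tuple[float, ...] = (0.22, 0.20, 0.20, 0.18, 0.20)
    outlier_fraction: float = 0.008
    n_markers: int = 2
    n_trend_genes: int = 35  # per trend group I / II / III
    n_state_markers: int = 25  # per state
    n_ohnolog_pairs: int = 3  # per ohnolog class
    marker_amplitude: float = 5.0
    trend_amplitude: float = 5.0
    state_marker_amplitude: float = 5.0
    state_marker_baseline: float = -4.0  # off-state log-mean offset from base
    state_marker_width: float = 0.25  # fraction of the state's span on t
    state_spread: float = 0.15  # within-state pseudotime s.d. (state-span units)
    outlier_signature_frac: float = 0.20  # fraction of genes in the signature
    outlier_signature_amplitude: float = 7.0
    base_logmean: float = 3.0
    content_decay: float = 2.0
    dropout_base: float = 0.05
    dropout_slope: float = 0.20
    dropout_jitter: float = 0.05  # per-cell capture-efficiency s.d.
    mature_dropout_extra: float = 0.15  # focused program of the last state
    noise_sd: float = 0.30
    fluor_slope: float = 2.0
    fluor_jump: float = 1.4
    fluor_noise_sd: float = 0.25
    group1_peak: float = 0.30
    group1_width: float = 0.16
    group1_baseline: float = -3.0  # cell-cycle program: sharp fold, low bulk
    group3_onset: float = 0.30
    group3_rate: float = 0.07
    group3_baseline: float = -3.0  # effector program: sharp fold, low bulk
    mean_reads: float = 1.0e6
    seed: int = 5

    def __post_init__(self) -> None:
        if len(self.state_proportions) != self.n_states:
            raise ValueError(
                f"need {self.n_states} state proportions, got "
                f"{len(self.state_proportions)}"
            )
        if not np.isclose(sum(self.state_proportions), 1.0):
            raise ValueError("state proportions must sum to 1")
        if any(p <= 0 for p in self.state_proportions):
            raise ValueError("state proportions must be positive")
        for name in ("n_cells", "n_genes", "n_spikeins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_base <= 1.0:
            raise ValueError("dropout_base must be a probability")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")

    @property
    def n_planted(self) -> int:
        """Number of non-flat endogenous genes implied by the parameters."""
        return (
            self.n_markers
            + 3 * self.n_trend_genes
            + self.n_states * self.n_state_markers
            + 2 * 4 * self.n_ohnolog_pairs
        )


@dataclass
class SyntheticTruth:
    """Ground truth: per-cell pseudotime/state, per-gene class, pair classes."""

    cells: pd.DataFrame  # index cell_id; columns pseudotime, state
    genes: pd.DataFrame  # index gene_id; columns gene_class
    ohnolog_pairs: pd.DataFrame  # columns gene_a, gene_b, true_class
    params: GeneratorParams = field(repr=False, default=None)

    @property
    def marker_gene(self) -> str:
        """Identifier of the planted cd41-like monotone marker."""
        return "cd41-like"


def _state_edges(proportions: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(proportions)])


def _assign_states(t: np.ndarray, proportions: np.ndarray) -> np.ndarray:
    edges = _state_edges(proportions)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(proportions) - 1)
    return np.asarray(STATE_NAMES)[idx]


def _gene_table(params: GeneratorParams) -> pd.DataFrame:
    """Lay out gene identifiers and classes; flat genes fill the remainder."""
    if params.n_planted > params.n_genes:
        raise ValueError(
            f"n_genes={params.n_genes} too small for {params.n_planted} planted genes"
        )
    rows: list[tuple[str, str]] = [("cd41-like", "marker"), ("EGFP-like", "marker")]
    for grp in ("I", "II", "III"):
        rows += [
            (f"trend{grp}_{i:03d}", f"group_{grp}") for i in range(params.n_trend_genes)
        ]
    for s in STATE_NAMES[: params.n_states]:
        rows += [
            (f"state{s}_marker_{i:02d}", "state_marker")
            for i in range(params.n_state_markers)
        ]
    for cls in OHNOLOG_CLASSES:
        for i in range(params.n_ohnolog_pairs):
            rows += [
                (f"ohno_{cls}_{i}_a", "ohnolog"),
                (f"ohno_{cls}_{i}_b", "ohnolog"),
            ]
    n_flat = params.n_genes - len(rows)
    rows += [(f"gene_{i:04d}", "flat") for i in range(n_flat)]
    rows += [(f"{SPIKE_PREFIX}{i:05d}", "spike_in") for i in range(params.n_spikeins)]
    return pd.DataFrame(rows, columns=["gene_id", "gene_class"]).set_index("gene_id")


def _logmean_curves(
    params: GeneratorParams, genes: pd.DataFrame, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell x per-gene log-scale mean (endogenous genes only; no decay)."""
    n = len(t)
    mu = np.zeros((n, len(genes)))
    base = params.base_logmean
    amp = params.trend_amplitude
    edges = _state_edges(np.asarray(params.state_proportions))
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = params.state_marker_width * np.diff(edges)
    for j, (gid, cls) in enumerate(genes["gene_class"].items()):
        if cls == "marker":
            mu[:, j] = base - params.marker_amplitude / 2 + params.marker_amplitude * t
        elif cls == "group_I":
            peak = params.group1_peak + rng.normal(0, 0.03)
            mu[:, j] = (
                base
                + params.group1_baseline
                + amp * np.exp(-((t - peak) ** 2) / (2 * params.group1_width**2))
            )
        elif cls == "group_II":
            # translation/ribosome-like: abundant early, monotone decline —
            # these genes carry much of the total-mRNA-content trend
            mu[:, j] = base + amp * (0.5 - t)
        elif cls == "group_III":
            onset = params.group3_onset + rng.normal(0, 0.03)
            sig = 1.0 / (1.0 + np.exp(-(t - onset) / params.group3_rate))
            mu[:, j] = base + params.group3_baseline + amp * sig
        elif cls == "state_marker":
            s = gid.split("_")[0].removeprefix("state")
            k = STATE_NAMES.index(s)
            # silent off-state, moderate abundance in-state: strong log-fold
            # contrast without letting these genes dominate per-cell totals
            mu[:, j] = (
                base
                + params.state_marker_baseline
                + params.state_marker_amplitude
                * np.exp(-((t - centers[k]) ** 2) / (2 * widths[k] ** 2))
            )
        elif cls == "flat":
            mu[:, j] = base + rng.normal(0, 1.0)
        # ohnolog / spike_in columns are filled elsewhere
    return mu


def _ohnolog_masks(
    cls: str, n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Binary expressed/not-expressed masks for both members of one pair.

    Patterns are chosen so the decision-tree classifier at default
    thresholds (NotExpressed n_none > 300, XOR both_min_diff > 15,
    Single expression-breadth gap > 60) recovers the class exactly at
    the default 363-cell scale.
    """
    order = rng.permutation(n_cells)
    a = np.zeros(n_cells, bool)
    b = np.zeros(n_cells, bool)
    if cls == "NotExpressed":
        a[order[:4]] = True
        b[order[4:8]] = True  # n_none = n_cells - 8 > 300
    elif cls == "XOR":
        half = int(0.42 * n_cells)
        a[order[:half]] = True
        b[order[half : 2 * half]] = True
        both = order[2 * half : 2 * half + 3]
        a[both] = b[both] = True  # both_min_diff ~ half - 3 >> 15
    elif cls == "Single":
        wide = int(0.70 * n_cells)
        a[order[:wide]] = True
        b[order[: int(0.06 * n_cells)]] = True  # breadth gap ~ 0.64 n >> 60
    elif cls == "Mixed":
        broad = int(0.55 * n_cells)
        a[order[:broad]] = True
        b[order[int(0.10 * n_cells) : int(0.10 * n_cells) + broad]] = True
    else:  # pragma: no cover
        raise ValueError(cls)
    return a, b


def generate_dataset(
    params: GeneratorParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic index-sorted plate set.

    Returns
    -------
    matrix : DataFrame, cells x (n_genes + n_spikeins)
        Raw TPM-like non-negative values; spike-in columns carry the
        ``ERCC-`` prefix.
    meta : DataFrame indexed like ``matrix``
        Index-sort covariates: fluorescence, FSC, SSC, population label,
        paired read count, tissue, plate and well.
    truth : SyntheticTruth
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)

    n = params.n_cells
    n_out = int(round(params.outlier_fraction * n))
    props = np.asarray(params.state_proportions, float)
    # cells concentrate near state centres (discrete populations threaded on a
    # continuum): draw a state, then a pseudotime near its centre
    edges = _state_edges(props)
    state_idx = rng.choice(params.n_states, size=n, p=props)
    lo, hi = edges[state_idx], edges[state_idx + 1]
    centers = 0.5 * (lo + hi)
    t = np.clip(
        centers + rng.normal(0, params.state_spread, n) * (hi - lo),
        lo + 0.02 * (hi - lo),
        hi - 0.02 * (hi - lo),
    )
    order = np.argsort(t)
    t = t[order]
    states = _assign_states(t, props)
    # outliers replace a random subset of cells; they sit off the continuum
    out_idx = rng.choice(n, size=n_out, replace=False)
    states = states.astype(object)
    states[out_idx] = "outlier"
    for name in STATE_NAMES[: params.n_states]:
        if not np.any(states == name):
            raise ValueError(f"zero cells drawn in mandatory state {name}")

    cell_ids = [f"cell_{i:04d}" for i in range(n)]
    genes = _gene_table(params)
    endo = genes.index[genes["gene_class"] != "spike_in"]
    n_endo = len(endo)

    mu = _logmean_curves(params, genes.loc[endo], t, rng)
    # outlier cells: flat profile plus a shared strong signature on a
    # random subset of genes (macrophage-like), independent of pseudotime
    sig_genes = rng.choice(
        n_endo, size=max(20, int(params.outlier_signature_frac * n_endo)), replace=False
    )
    if n_out:
        mu[out_idx, :] = params.base_logmean + rng.normal(0, 0.3, size=(n_out, n_endo))
        mu[np.ix_(out_idx, sig_genes)] += params.outlier_signature_amplitude

    log_decay = -params.content_decay * t
    log_decay[out_idx] = -params.content_decay * 0.5
    vals = np.exp(
        mu + log_decay[:, None] + rng.normal(0, params.noise_sd, size=mu.shape)
    )

    # dropout rises along the continuum and jumps in the mature state, whose
    # focused transcriptional program expresses a smaller set of genes
    # per-cell capture-efficiency jitter: wells differ in lysis/RT efficiency,
    # which shifts every gene of a cell together (and survives renormalization
    # as compensatory inflation of the detected genes)
    per_cell_drop = (
        params.dropout_base
        + params.dropout_slope * t
        + rng.normal(0, params.dropout_jitter, n)
    )
    per_cell_drop[states == "4"] += params.mature_dropout_extra
    p_drop = np.clip(per_cell_drop, 0.0, 1.0)[:, None] * np.ones((1, n_endo))
    # dropout is expression-dependent: abundant transcripts are captured more
    # reliably, so the per-gene rate shrinks with the log-mean above baseline
    p_drop *= np.exp(-np.clip(mu - params.base_logmean, 0.0, None) / 2.0)
    # outliers run a different transcriptional program: their signature genes
    # are always on, half of the remaining genes are silent
    if n_out:
        p_drop[out_idx, :] = 0.5
        p_drop[np.ix_(out_idx, sig_genes)] = params.dropout_base
    # the high-abundance monotone markers (cd41/EGFP transgene analogues)
    # never drop out
    marker_cols = [j for j, g in enumerate(endo) if g in ("cd41-like", "EGFP-like")]
    p_drop[:, marker_cols] = 0.0
    vals[rng.uniform(size=vals.shape) < p_drop] = 0.0

    # planted ohnolog pairs overwrite their columns with exact patterns
    pair_rows = []
    col_of = {g: j for j, g in enumerate(endo)}
    for cls in OHNOLOG_CLASSES:
        for i in range(params.n_ohnolog_pairs):
            ga, gb = f"ohno_{cls}_{i}_a", f"ohno_{cls}_{i}_b"
            ma, mb = _ohnolog_masks(cls, n, rng)
            for g, m in ((ga, ma), (gb, mb)):
                col = np.zeros(n)
                col[m] = np.exp(
                    params.base_logmean + 1.0 + rng.normal(0, params.noise_sd, m.sum())
                )
                vals[:, col_of[g]] = col
            pair_rows.append((ga, gb, cls))

    spike = np.exp(
        params.base_logmean
        + rng.normal(0, 0.5, size=params.n_spikeins)[None, :]
        + rng.normal(0, params.noise_sd, size=(n, params.n_spikeins))
    )

    matrix = pd.DataFrame(
        np.hstack([vals, spike]), index=cell_ids, columns=genes.index
    )

    fluor = np.exp(
        params.fluor_slope * t
        + params.fluor_jump * (states == "4").astype(float)
        + rng.normal(0, params.fluor_noise_sd, n)
    )
    fluor[out_idx] = np.exp(
        params.fluor_slope + params.fluor_jump + rng.normal(0, params.fluor_noise_sd, n_out)
    )
    fsc = rng.normal(100, 12, n)
    ssc = rng.normal(80, 10, n)
    fsc[out_idx] = rng.normal(260, 15, n_out)
    ssc[out_idx] = rng.normal(220, 15, n_out)
    population = np.where(
        (states == "4") | (states == "outlier"), "EGFPhigh", "EGFPlow"
    )
    tissue = np.full(n, "kidney", object)
    # half of the mature (state 4) cells are drawn from circulation; their
    # expression distribution is identical, emulating the kidney/circulation twin
    mature = np.flatnonzero(states == "4")
    circ = rng.choice(mature, size=len(mature) // 2, replace=False)
    tissue[circ] = "circulation"

    meta = pd.DataFrame(
        {
            "fluorescence": fluor,
            "FSC": fsc,
            "SSC": ssc,
            "population": population,
            "read_count": np.round(
                rng.lognormal(np.log(params.mean_reads), 0.25, n)
            ).astype(int),
            "tissue": tissue,
            "plate": "plate_0",
            "well": [f"W{i:03d}" for i in range(n)],
        },
        index=cell_ids,
    )

    truth = SyntheticTruth(
        cells=pd.DataFrame({"pseudotime": t, "state": states}, index=cell_ids),
        genes=genes,
        ohnolog_pairs=pd.DataFrame(
            pair_rows, columns=["gene_a", "gene_b", "true_class"]
        ),
        params=params,
    )
    return matrix, meta, truth


def generate_qc_plate(
    params: GeneratorParams | None = None,
    n_failures: int = 5,
    min_reads: int = 50_000,
    min_genes: int = 150,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A plate where exactly ``n_failures`` wells fail both QC thresholds.

    Failed wells get a read count below ``min_reads`` and have expression
    zeroed on all but a few genes, so their expressed-gene count falls
    below ``min_genes``; all other wells pass both thresholds.
    """
    params = params or GeneratorParams()
    if n_failures > params.n_cells:
        raise ValueError("n_failures exceeds n_cells")
    matrix, meta, _ = generate_dataset(params)
    rng = np.random.default_rng(params.seed + 1)
    fail = rng.choice(params.n_cells, size=n_failures, replace=False)
    fail_ids = matrix.index[fail]
    keep_cols = rng.choice(matrix.shape[1], size=min(20, matrix.shape[1]), replace=False)
    zero_cols = np.setdiff1d(np.arange(matrix.shape[1]), keep_cols)
    matrix.iloc[fail, zero_cols] = 0.0
    meta.loc[fail_ids, "read_count"] = rng.integers(1_000, min_reads, n_failures)
    # make sure passing wells really pass
    ok = matrix.index.difference(fail_ids)
    meta.loc[ok, "read_count"] = meta.loc[ok, "read_count"].clip(lower=min_reads)
    return matrix, meta


def small_params(seed: int = 0, **overrides) -> GeneratorParams:
    """A reduced world for fast tests: fewer cells and genes, same structure."""
    base = dict(
        n_cells=120,
        n_genes=160,
        n_spikeins=8,
        n_trend_genes=8,
        n_state_markers=6,
        n_ohnolog_pairs=1,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorParams(**base)
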