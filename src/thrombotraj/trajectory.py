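"""ICA-composite pseudotime: latent factors, states, and cell ordering.

The ordering model assumes a non-branching differentiation continuum
observed through four independent latent factors: one explains
progression among EGFP-low cells ("within_small"), one the switch from
the EGFP-low toward the EGFP-high population ("difference"), one
progression among EGFP-high cells ("within_large"), and one isolates a
handful of outlier cells.  Cells are Ward-clustered in factor space into
six groups, the groups are named 1a, 1b, 2, 3, 4 and outlier, and
pseudotime is the lexicographic rank by (stage, stage factor,
fluorescence, cell id) with outliers set aside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import FastICA
from sklearn.manifold import TSNE

FACTOR_ROLES = ("within_small", "difference", "within_large", "outlier")
STAGE_ORDER = ("1a", "1b", "2", "3", "4")
# which oriented factor orders cells inside each stage (documented convention:
# the three-stage progression itself fixes no per-stage sort key)
STAGE_FACTOR = {
    "1a": "within_small",
    "1b": "within_small",
    "2": "within_small",
    "3": "difference",
    "4": "within_large",
}


@dataclass
class LatentFactors:
    """Cells x K independent factors plus role labels and orientation."""

    values: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)  # role -> column name

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def factor(self, role: str) -> pd.Series:
        return self.values[self.roles[role]]


def log1p_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log(TPM + 1) per entry, then z-score each gene (constant genes -> 0)."""
    x = np.log1p(matrix.to_numpy(float))
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=matrix.index, columns=matrix.columns)


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman needs two equal-length 1-D vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a zero-variance vector")
    return float(stats.spearmanr(x, y).statistic)


def _reconstruction_errors(x: np.ndarray, k_max: int, seed: int) -> np.ndarray:
    errs = np.empty(k_max)
    for k in range(1, k_max + 1):
        ica = FastICA(
            n_components=k, random_state=seed, whiten="unit-variance", max_iter=1000
        )
        s = ica.fit_transform(x)
        errs[k - 1] = np.linalg.norm(x - ica.inverse_transform(s))
    return errs


def choose_k(
    matrix: pd.DataFrame, k_max: int = 10, frac: float = 0.1, seed: int = 0
) -> int:
    """Elbow choice of the ICA component count.

    Computes the Frobenius reconstruction error for 1..k_max components
    and returns the largest k whose marginal error reduction still
    exceeds ``frac`` of the 1 -> 2 reduction; rank-1 data gives 1.
    """
    x = matrix.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("constant matrix: component count undefined")
    k_max = min(k_max, *x.shape)
    errs = _reconstruction_errors(x, k_max, seed)
    drops = -np.diff(errs)  # drops[i] = err(k=i+1) - err(k=i+2) reduction
    if len(drops) == 0 or drops[0] <= 0:
        return 1
    good = [k for k in range(2, k_max + 1) if drops[k - 2] > frac * drops[0]]
    return max(good, default=1)


def fit_ica(matrix: pd.DataFrame, k: int = 4, seed: int = 3984) -> LatentFactors:
    """Fit FastICA over cells on the log-standardized matrix.

    Rows are sorted by cell identifier first so the result does not
    depend on input row order.
    """
    ordered = matrix.sort_index()
    x = ordered.to_numpy(float)
    ica = FastICA(n_components=k, random_state=seed, whiten="unit-variance", max_iter=2000)
    sources = ica.fit_transform(x)
    cols = [f"IC{i+1}" for i in range(k)]
    values = pd.DataFrame(sources, index=ordered.index, columns=cols)
    return LatentFactors(values=values.loc[matrix.index])


def orient_factors(factors: LatentFactors, fluorescence: pd.Series) -> LatentFactors:
    """Flip factor signs so each correlates non-negatively with fluorescence."""
    import warnings

    fl = fluorescence.loc[factors.values.index].to_numpy(float)
    vals = factors.values.copy()
    for col in vals.columns:
        v = vals[col].to_numpy()
        if np.ptp(v) == 0:
            warnings.warn(f"factor {col} has zero variance; left unchanged", stacklevel=2)
            continue
        if stats.spearmanr(v, fl).statistic < 0:
            vals[col] = -v
    return LatentFactors(values=vals, roles=dict(factors.roles))


def assign_roles(factors: LatentFactors, fluorescence: pd.Series) -> LatentFactors:
    """Attach role labels to the factors.

    Heuristics: the outlier factor is the most heavy-tailed (highest
    excess kurtosis); among the rest, the difference factor correlates
    most with fluorescence; of the remaining two, the within_small
    factor carries relatively more variance in the low-fluorescence half
    of the cells, the within_large factor in the high half.
    """
    vals = factors.values
    fl = fluorescence.loc[vals.index].to_numpy(float)
    cols = list(vals.columns)
    kurt = {c: stats.kurtosis(vals[c]) for c in cols}
    roles: dict[str, str] = {"outlier": max(cols, key=kurt.get)}
    rest = [c for c in cols if c != roles["outlier"]]
    rho = {c: abs(stats.spearmanr(vals[c], fl).statistic) for c in rest}
    roles["difference"] = max(rest, key=rho.get)
    rest = [c for c in rest if c != roles["difference"]]
    low = fl <= np.median(fl)
    if len(rest) >= 2:
        def low_ratio(c):
            v = vals[c].to_numpy()
            return np.var(v[low]) / max(np.var(v[~low]), 1e-12)

        roles["within_small"] = max(rest, key=low_ratio)
        rest = [c for c in rest if c != roles["within_small"]]
    if rest:
        roles["within_large"] = rest[0]
    return LatentFactors(values=vals, roles=roles)


@dataclass
class ClusterAssignment:
    """Per-cell 6-way partition plus stage labels once assigned."""

    partition: pd.Series  # integer cluster index per cell
    stages: pd.Series | None = None  # labels in {1a,1b,2,3,4,outlier}


def cluster_cells(factors: LatentFactors, n_clusters: int = 6) -> ClusterAssignment:
    """Ward-linkage hierarchical partition of cells in factor space."""
    vals = factors.values
    if n_clusters > len(vals):
        raise ValueError("more clusters than cells")
    z = linkage(vals.to_numpy(float), method="ward")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterAssignment(
        partition=pd.Series(labels, index=vals.index, name="cluster")
    )


def label_clusters(
    assignment: ClusterAssignment,
    factors: LatentFactors,
    fluorescence: pd.Series,
) -> ClusterAssignment:
    """Name the six clusters 1a, 1b, 2, 3, 4 and outlier.

    The outlier group is the most isolated compact cluster in factor
    space: the one maximizing distance-to-nearest-centroid relative to
    its own spread (the planted outliers carry extreme loadings, but ICA
    may spread them over several factors, so isolation over the full
    factor space is the robust reading; ties go to the smaller cluster).
    The remaining clusters are ordered along the continuum by median
    fluorescence, with median position on the oriented difference factor
    as tie-break, then cluster size, then index.
    """
    part = assignment.partition
    fl = fluorescence.loc[part.index]
    diff = factors.factor("difference")
    ids = sorted(part.unique())
    vals = factors.values.to_numpy(float)
    cent = {c: vals[(part == c).to_numpy()].mean(axis=0) for c in ids}
    within = {
        c: np.sqrt(
            ((vals[(part == c).to_numpy()] - cent[c]) ** 2).sum(axis=1).mean()
        )
        + 1e-9
        for c in ids
    }
    iso = {
        c: min(np.linalg.norm(cent[c] - cent[o]) for o in ids if o != c)
        / within[c]
        for c in ids
    }
    sizes = {c: int((part == c).sum()) for c in ids}
    # the outlier group is small by construction; restrict to clusters well
    # below the average size, falling back to the smallest cluster when the
    # outliers were absorbed into a larger one
    small = [c for c in ids if sizes[c] <= 0.5 * len(part) / len(ids)]
    if small:
        outlier_cluster = max(small, key=lambda c: (iso[c], -sizes[c], -c))
    else:
        outlier_cluster = min(ids, key=lambda c: (sizes[c], -iso[c], c))
    rest = [c for c in ids if c != outlier_cluster]
    order = sorted(
        rest,
        key=lambda c: (
            float(fl[part == c].median()),
            float(diff[part == c].median()),
            -int((part == c).sum()),
            c,
        ),
    )
    naming = {c: STAGE_ORDER[i] for i, c in enumerate(order)}
    naming[outlier_cluster] = "outlier"
    stages = part.map(naming).rename("stage")
    return ClusterAssignment(partition=part, stages=stages)


def assemble_pseudotime(
    assignment: ClusterAssignment,
    factors: LatentFactors,
    fluorescence: pd.Series,
) -> pd.Series:
    """Composite pseudotime rank over non-outlier cells.

    Cells sort primarily by stage (1a < 1b < 2 < 3 < 4); within stages
    1a/1b/2 by the within_small factor, within stage 3 (the low-to-high
    switch) by the difference factor, within stage 4 by the within_large
    factor; ties break by fluorescence, then cell identifier.  Ranks are
    a bijection onto 0..n-1 over the ordered cells.
    """
    if assignment.stages is None:
        raise ValueError("stage labels missing; run label_clusters first")
    stages = assignment.stages
    keep = stages[stages != "outlier"].index
    rows = []
    for cell in keep:
        st = stages[cell]
        fac = factors.factor(STAGE_FACTOR[st])[cell]
        rows.append((STAGE_ORDER.index(st), float(fac), float(fluorescence[cell]), cell))
    rows.sort()
    ranks = pd.Series(
        {cell: i for i, (_, _, _, cell) in enumerate(rows)}, name="pseudotime_rank"
    )
    return ranks.loc[[c for c in keep]]


def order_cells(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    k: int = 4,
    n_clusters: int = 6,
    seed: int = 3984,
) -> tuple[pd.Series, ClusterAssignment, LatentFactors]:
    """Full ordering stage: ICA -> orient -> roles -> cluster -> pseudotime."""
    x = log1p_standardize(matrix)
    fl = meta.loc[matrix.index, "fluorescence"]
    factors = fit_ica(x, k=k, seed=seed)
    factors = orient_factors(factors, fl)
    factors = assign_roles(factors, fl)
    assignment = cluster_cells(factors, n_clusters=n_clusters)
    assignment = label_clusters(assignment, factors, fl)
    pseudotime = assemble_pseudotime(assignment, factors, fl)
    return pseudotime, assignment, factors


def embed_2d(
    factors: LatentFactors, perplexity: float = 75.0, seed: int = 254
) -> pd.DataFrame:
    """t-SNE depiction of the factor matrix; no downstream computation uses it."""
    import warnings

    n = len(factors.values)
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the number of cells")
    if n <= 3 * perplexity:
        warnings.warn("few cells relative to perplexity", stacklevel=2)
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(factors.values.to_numpy(float))
    return pd.DataFrame(emb, index=factors.values.index, columns=["tsne1", "tsne2"])


def regress_path(
    pseudotime: pd.Series, embedding: pd.DataFrame, n_points: int = 50, bandwidth: float = 0.05
) -> np.ndarray:
    """Kernel-smoothed trajectory through the 2-D embedding.

    Nadaraya-Watson regression of each embedding coordinate on the
    normalized pseudotime rank, evaluated on a uniform grid; returns an
    ordered (n_points x 2) polyline.
    """
    cells = pseudotime.index.intersection(embedding.index)
    t = pseudotime.loc[cells].rank().to_numpy(float)
    t = (t - t.min()) / max(t.max() - t.min(), 1.0)
    xy = embedding.loc[cells].to_numpy(float)
    grid = np.linspace(0, 1, n_points)
    w = np.exp(-((grid[:, None] - t[None, :]) ** 2) / (2 * bandwidth**2))
    w /= w.sum(axis=1, keepdims=True)
    return w @ xy
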