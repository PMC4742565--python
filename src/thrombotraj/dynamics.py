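"""Pseudotime-dynamic gene detection, trend grouping, and two-group tests.

Each gene's log(TPM+1) profile over pseudotime is scored by comparing
the exact marginal likelihoods of two zero-mean Gaussian processes on
the mean-centred profile: an RBF-kernel GP (expression may change
smoothly over pseudotime) and a constant-kernel GP (expression does not
change).  Genes whose log likelihood ratio exceeds a threshold are
"dynamic"; their standardized posterior-mean curves are Ward-clustered
into trend groups named I (up-then-down), II (monotone down) and III
(up-then-plateau).  A separate per-gene Gaussian likelihood-ratio test
with step-down Holm-Šidák correction compares two cell groups.

The RBF fit shares one eigendecomposition of the pseudotime kernel per
length-scale across all genes, which makes thousands of exact GP fits
cheap: with K = s2*K0(ls) + n2*I and K0 = Q diag(lam) Q',
log|K| and the quadratic form reduce to 1-D sums over eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster.hierarchy import fcluster, linkage

LOG2PI = np.log(2.0 * np.pi)
TREND_GROUPS = ("I", "II", "III")


def _normalize_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)
    rng = np.ptp(t)
    if rng == 0:
        raise ValueError("pseudotime has zero range")
    return (t - t.min()) / rng


class PseudotimeGP:
    """Shared exact-GP scaffolding over one pseudotime vector.

    Eigendecomposes the unit-variance RBF kernel on a grid of
    length-scales once; per-gene fits then only optimize the signal and
    noise variances on the eigen-spectrum.
    """

    def __init__(
        self,
        pseudotime: np.ndarray,
        lengthscales: np.ndarray | None = None,
        grid_size: int = 50,
    ):
        self.t = _normalize_time(np.asarray(pseudotime, float))
        self.n = len(self.t)
        if self.n < 10:
            raise ValueError("need at least 10 cells for GP fits")
        if lengthscales is None:
            lengthscales = np.geomspace(0.03, 1.0, 8)
        self.lengthscales = np.asarray(lengthscales, float)
        d2 = (self.t[:, None] - self.t[None, :]) ** 2
        self._eigs = []
        for ls in self.lengthscales:
            k0 = np.exp(-d2 / (2 * ls**2))
            lam, q = np.linalg.eigh(k0)
            self._eigs.append((np.clip(lam, 0.0, None), q))
        self.grid = np.linspace(0, 1, grid_size)
        self._cross = [
            np.exp(-((self.grid[:, None] - self.t[None, :]) ** 2) / (2 * ls**2))
            for ls in self.lengthscales
        ]

    def _fit_spectrum(
        self, lam: np.ndarray, a: np.ndarray, restarts: int = 2
    ) -> tuple[float, float, float]:
        """Max marginal log-likelihood over (signal, noise) variances.

        With K = c * (w * K0 + (1 - w) * I), the overall scale c has the
        closed-form optimum c* = quad/n, leaving a 1-D search over the
        signal share w in (0, 1); a bounded refinement follows the grid.
        """
        a2 = a**2
        n = self.n

        def nll_of_w(w: float) -> float:
            e = lam * w + (1.0 - w)
            c = max(float(np.mean(a2 / e)), 1e-10)
            return 0.5 * (float(np.sum(np.log(e))) + n * np.log(c) + n)

        ws = np.linspace(0.005, 0.995, 40)
        e = lam[None, :] * ws[:, None] + (1.0 - ws)[:, None]
        c = np.maximum((a2[None, :] / e).mean(axis=1), 1e-10)
        nlls = 0.5 * (np.log(e).sum(axis=1) + n * np.log(c) + n)
        i = int(np.argmin(nlls))
        lo, hi = ws[max(i - 1, 0)], ws[min(i + 1, len(ws) - 1)]
        res = optimize.minimize_scalar(
            nll_of_w, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5},
        )
        w, nll = (res.x, res.fun) if res.fun < nlls[i] else (ws[i], nlls[i])
        e_best = lam * w + (1.0 - w)
        c_best = max(float(np.mean(a2 / e_best)), 1e-10)
        loglik = -nll - 0.5 * n * LOG2PI
        return loglik, c_best * w, c_best * (1.0 - w)


def gp_loglik_rbf(
    pseudotime, y, restarts: int = 2, gp: PseudotimeGP | None = None
) -> tuple[float, np.ndarray]:
    """Best log marginal likelihood of the RBF-kernel GP on centred y.

    Optimizes signal variance, noise variance and (by grid) the
    length-scale; returns the log likelihood and the posterior mean on
    the shared pseudotime grid.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite expression values")
    gp = gp or PseudotimeGP(pseudotime)
    yc = y - y.mean()
    best = (-np.inf, None, None, None)
    for i, (lam, q) in enumerate(gp._eigs):
        a = q.T @ yc
        ll, s2, n2 = gp._fit_spectrum(lam, a, restarts=restarts)
        if ll > best[0]:
            best = (ll, i, s2, n2)
    ll, i, s2, n2 = best
    lam, q = gp._eigs[i]
    alpha = q @ ((q.T @ yc) / (s2 * lam + n2))
    mean_curve = y.mean() + s2 * (gp._cross[i] @ alpha)
    return float(ll), mean_curve


def gp_loglik_const(pseudotime, y, gp: PseudotimeGP | None = None) -> float:
    """Log marginal likelihood of the constant-kernel (no-change) GP.

    On the centred profile the constant kernel carries no signal, so the
    model reduces to i.i.d. noise with variance fitted in closed form
    (floored at 1e-8 to guard the zero-noise degeneracy).
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite expression values")
    n = len(y)
    yc = y - y.mean()
    n2 = max(float(np.mean(yc**2)), 1e-8)
    return float(-0.5 * n * (LOG2PI + np.log(n2) + 1.0))


@dataclass
class DynamicGeneResult:
    """Per-gene GP model comparison results plus trend labels."""

    table: pd.DataFrame  # index gene; loglik_rbf, loglik_const, log_ratio, dynamic
    curves: pd.DataFrame  # genes x grid posterior means (dynamic genes only)
    grid: np.ndarray
    threshold: float


def detect_dynamic_genes(
    matrix: pd.DataFrame,
    pseudotime: pd.Series,
    threshold: float = 5.0,
    restarts: int = 2,
) -> DynamicGeneResult:
    """GP likelihood-ratio screen for pseudotime-dependent genes.

    Fits both GPs to each gene's log(TPM+1) profile over the ordered
    cells and flags genes with log likelihood ratio above ``threshold``
    (default 5, calibrated so flat noise genes are rarely flagged).
    """
    cells = pseudotime.sort_values().index
    x = np.log1p(matrix.loc[cells].to_numpy(float))
    gp = PseudotimeGP(pseudotime.loc[cells].to_numpy(float))
    rows = []
    curves = {}
    for j, gene in enumerate(matrix.columns):
        y = x[:, j]
        ll_c = gp_loglik_const(None, y, gp=gp)
        if np.ptp(y) == 0:
            rows.append((gene, ll_c, ll_c, 0.0))
            continue
        ll_r, curve = gp_loglik_rbf(None, y, restarts=restarts, gp=gp)
        ll_r = max(ll_r, ll_c)  # RBF nests the noise-only model
        rows.append((gene, ll_r, ll_c, ll_r - ll_c))
        if ll_r - ll_c > threshold:
            curves[gene] = curve
    table = pd.DataFrame(
        rows, columns=["gene", "loglik_rbf", "loglik_const", "log_ratio"]
    ).set_index("gene")
    table["dynamic"] = table["log_ratio"] > threshold
    curve_df = pd.DataFrame(curves).T
    return DynamicGeneResult(
        table=table, curves=curve_df, grid=gp.grid, threshold=threshold
    )


def _trend_templates(grid: np.ndarray) -> dict[str, np.ndarray]:
    """Canonical standardized shapes of the three trend groups."""
    bump = np.exp(-((grid - 0.3) ** 2) / (2 * 0.16**2))  # up then down
    down = -grid  # monotone decrease
    plateau = 1.0 / (1.0 + np.exp(-(grid - 0.3) / 0.07))  # up then maintain
    return {"I": bump, "II": down, "III": plateau}


def cluster_trends(
    result: DynamicGeneResult, n_groups: int = 3, seed: int = 0
) -> pd.Series:
    """Ward-cluster standardized posterior-mean curves into trend groups.

    Each cluster is renamed I/II/III by the best correlation match of its
    mean curve to the canonical shapes: interior peak -> I, monotone
    decreasing -> II, rise-then-plateau -> III.  Clusters with identical
    mean curves therefore share a label; a degenerate (flat) mean curve
    gets the label "none".
    """
    curves = result.curves
    if len(curves) < n_groups:
        raise ValueError(
            f"only {len(curves)} dynamic genes; cannot form {n_groups} groups"
        )
    z = curves.sub(curves.mean(axis=1), axis=0)
    z = z.div(z.std(axis=1).replace(0.0, 1.0), axis=0)
    labels = fcluster(linkage(z.to_numpy(), method="ward"), t=n_groups, criterion="maxclust")
    templates = _trend_templates(result.grid)
    naming = {}
    for ci in range(1, n_groups + 1):
        mean_curve = z.to_numpy()[labels == ci].mean(axis=0)
        if np.ptp(mean_curve) == 0:
            naming[ci] = "none"
            continue
        sims = {
            name: np.corrcoef(mean_curve, tpl)[0, 1]
            for name, tpl in templates.items()
        }
        naming[ci] = max(sims, key=sims.get)
    return pd.Series(
        [naming[l] for l in labels], index=curves.index, name="trend_group"
    )


def holm_sidak(p) -> np.ndarray:
    """Step-down Šidák-adjusted p-values, returned in the input order.

    Sort ascending; adjusted_(i) = 1 - (1 - p_(i))^(m - i); enforce a
    running maximum along the sorted sequence; cap at 1.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class GroupComparisonResult:
    """Per-gene two-group likelihood-ratio test with Holm-Šidák control."""

    table: pd.DataFrame  # index gene; statistic, p_raw, p_adjusted, significant
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def compare_groups(
    matrix: pd.DataFrame,
    cells_a,
    cells_b,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Likelihood-ratio test of equal means per gene between two cell groups.

    Gaussian model on log(TPM+1): shared mean and variance versus
    separate group means with shared variance.  The likelihood-ratio
    statistic n*log(SS_total / SS_within) is asymptotically chi-square
    with 1 df; p-values use its exact finite-sample calibration via the
    monotone map to t² = (n-2)(SS_total/SS_within - 1) ~ F(1, n-2),
    which avoids the anti-conservative chi-square tail at these group
    sizes.  P-values are then Holm-Šidák adjusted across genes.
    """
    cells_a = pd.Index(cells_a)
    cells_b = pd.Index(cells_b)
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    xa = np.log1p(matrix.loc[cells_a].to_numpy(float))
    xb = np.log1p(matrix.loc[cells_b].to_numpy(float))
    n = len(cells_a) + len(cells_b)
    both = np.vstack([xa, xb])
    ss_total = ((both - both.mean(axis=0)) ** 2).sum(axis=0)
    ss_within = ((xa - xa.mean(axis=0)) ** 2).sum(axis=0) + (
        (xb - xb.mean(axis=0)) ** 2
    ).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(ss_total / ss_within)
        t2 = (n - 2) * (ss_total / ss_within - 1.0)
    stat = np.where(ss_total <= 0, 0.0, stat)  # constant gene: no evidence
    stat = np.nan_to_num(stat, nan=0.0, posinf=np.inf)
    t2 = np.where(ss_total <= 0, 0.0, t2)
    t2 = np.nan_to_num(t2, nan=0.0, posinf=np.inf)
    p_raw = stats.f.sf(t2, 1, n - 2)
    p_adj = holm_sidak(p_raw)
    table = pd.DataFrame(
        {
            "statistic": stat,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        },
        index=matrix.columns,
    )
    return GroupComparisonResult(table=table, alpha=alpha)
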