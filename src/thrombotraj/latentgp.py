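"""One-dimensional GP latent variable model for cross-validating pseudotime.

An independent ordering of the cells: each gene's log expression is
modelled as a draw from a zero-mean Gaussian process over an unobserved
one-dimensional latent coordinate shared by all genes (RBF kernel plus
white noise).  Latent coordinates and kernel hyperparameters are fitted
jointly by maximizing the exact GP marginal likelihood with a standard
normal prior on the coordinates (a MAP GPLVM — the deterministic
substitute for a variationally-inferred Bayesian GPLVM; the quantity of
interest downstream is only the induced cell *ordering*, which is
insensitive to this choice).  Orientation of the latent axis is
arbitrary until aligned to a reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectory import spearman


@dataclass
class LatentPosition:
    """Fitted 1-D latent coordinates and kernel hyperparameters."""

    coords: pd.Series
    signal_variance: float
    lengthscale: float
    noise_variance: float
    objective: float  # log posterior (marginal likelihood + latent prior)


def _select_genes(x: np.ndarray, n_genes: int) -> np.ndarray:
    """Columns of the ``n_genes`` highest-variance genes."""
    if x.shape[1] <= n_genes:
        return np.arange(x.shape[1])
    var = x.var(axis=0)
    return np.sort(np.argsort(var)[::-1][:n_genes])


def _neg_log_posterior(params: np.ndarray, s: np.ndarray, d: int) -> tuple[float, np.ndarray]:
    """Objective and gradient for (latent coords, log hyperparameters).

    s is the n x n inner-product matrix Y Y^T of the centred expression;
    the GP marginal over D independent gene dimensions gives
    -0.5 * [D log|K| + tr(K^-1 S)] with K = s2 * RBF(x; ls) + n2 * I,
    plus a N(0,1) prior on each latent coordinate.
    """
    n = s.shape[0]
    x = params[:n]
    log_s2, log_ls, log_n2 = params[n:]
    s2, ls, n2 = np.exp([log_s2, log_ls, log_n2])
    diff = x[:, None] - x[None, :]
    k_rbf = np.exp(-(diff**2) / (2 * ls**2))
    k = s2 * k_rbf + (n2 + 1e-8) * np.eye(n)
    try:
        cho = np.linalg.cholesky(k)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    k_inv = np.linalg.inv(cho.T) @ np.linalg.inv(cho)
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    quad = float(np.sum(k_inv * s))
    nll = 0.5 * (d * logdet + quad) + 0.5 * float(x @ x)
    # dL/dK for L = -0.5 (D log|K| + tr(K^-1 S)); grad of NLL is -dL/dK
    g_k = 0.5 * (d * k_inv - k_inv @ s @ k_inv)
    g_krbf = g_k * (s2 * k_rbf)
    grad_x = np.zeros(n)
    w = g_krbf * (-diff / ls**2)
    grad_x = 2.0 * w.sum(axis=1)  # symmetric double count of (i,j) and (j,i)
    grad_x += x  # prior
    grad_s2 = float(np.sum(g_k * (s2 * k_rbf)))
    grad_ls = float(np.sum(g_krbf * (diff**2 / ls**2)))
    grad_n2 = float(np.trace(g_k) * n2)
    return nll, np.concatenate([grad_x, [grad_s2, grad_ls, grad_n2]])


def fit_gplvm_1d(
    matrix: pd.DataFrame,
    n_genes: int = 500,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 800,
) -> LatentPosition:
    """Fit the 1-D MAP GPLVM on log(TPM+1) expression.

    Genes are reduced to the ``n_genes`` most variable and standardized;
    the latent coordinate is initialized from the first principal
    component (plus perturbations across restarts) and optimized jointly
    with the RBF hyperparameters by L-BFGS; the best restart wins.
    """
    x = np.log1p(matrix.to_numpy(float))
    x = x[:, _select_genes(x, n_genes)]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    n, d = x.shape
    s = x @ x.T
    # PC1 via the cell-cell Gram matrix (cheaper than the gene covariance)
    lam, vec = np.linalg.eigh(s)
    pc1 = vec[:, -1] * np.sqrt(max(lam[-1], 1e-12))
    pc1 = (pc1 - pc1.mean()) / max(pc1.std(), 1e-12)

    rng = np.random.default_rng(seed)
    best: LatentPosition | None = None
    last_err: Exception | None = None
    for r in range(restarts):
        x0 = pc1 if r == 0 else pc1 + rng.normal(0, 0.3, n)
        params0 = np.concatenate([x0, np.log([1.0, 1.0, 0.5])])
        # the latent prior fixes the coordinate scale, so the length-scale is
        # confined to a band around 1 to block the shrink-to-white-noise mode
        bounds = [(None, None)] * n + [
            (np.log(1e-3), np.log(1e3)),
            (np.log(1.0), np.log(2.0)),
            (np.log(1e-4), np.log(1e3)),
        ]
        res = optimize.minimize(
            _neg_log_posterior,
            params0,
            args=(s, d),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter},
        )
        if not np.isfinite(res.fun):
            last_err = RuntimeError(f"restart {r} diverged: {res.message}")
            continue
        s2, ls, n2 = np.exp(res.x[n:])
        cand = LatentPosition(
            coords=pd.Series(res.x[:n], index=matrix.index, name="gplvm_latent"),
            signal_variance=float(s2),
            lengthscale=float(ls),
            noise_variance=float(n2),
            objective=-float(res.fun),
        )
        if best is None or cand.objective > best.objective:
            best = cand
    if best is None:
        raise RuntimeError(f"GPLVM optimization failed on all restarts: {last_err}")
    return best


def align_orientation(latent: LatentPosition, reference: pd.Series) -> LatentPosition:
    """Flip the latent axis if it anti-correlates with the reference."""
    ref = reference.loc[latent.coords.index].to_numpy(float)
    if np.ptp(ref) == 0:
        raise ValueError("zero-variance reference; orientation undefined")
    if stats.spearmanr(latent.coords.to_numpy(), ref).statistic < 0:
        return LatentPosition(
            coords=-latent.coords,
            signal_variance=latent.signal_variance,
            lengthscale=latent.lengthscale,
            noise_variance=latent.noise_variance,
            objective=latent.objective,
        )
    return latent


def compare_orderings(a: pd.Series, b: pd.Series) -> float:
    """|Spearman| agreement between two orderings of the same cells."""
    common = a.index.intersection(b.index)
    if len(common) != len(a) or len(common) != len(b):
        raise ValueError("orderings cover different cell sets")
    return abs(spearman(a.loc[common].to_numpy(), b.loc[common].to_numpy()))
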