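"""Probabilistic PCA with EM over missing entries.

The model is the standard latent linear-Gaussian factor model with isotropic
noise,

    x = mu + W z + eps,   z ~ N(0, I_q),   eps ~ N(0, sigma^2 I_p),

whose maximum-likelihood solution on complete data is the top-q eigenbasis of
the sample covariance (Tipping & Bishop).  With missing entries the model is
fitted by expectation conditional maximization: the E-step computes, per row,
the posterior of the latent coordinate given that row's observed entries; the
CM-steps update mu, then W, then sigma^2 against the same expectations.  Each
conditional update maximizes the expected complete-data log-likelihood, so the
observed-data log-likelihood is non-decreasing across iterations.

Missing cells are imputed by their posterior predictive mean
mu_m + W_m E[z | x_obs]; observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PPCAModel", "fit_ppca", "impute", "scores", "variance_explained"]


@dataclass
class PPCAModel:
    mean: np.ndarray           # length-p
    loadings: np.ndarray       # p x q factor loading matrix W
    noise_variance: float      # sigma^2 > 0
    q: int
    converged: bool = False
    n_iter: int = 0
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.mean.shape[0]

    def principal_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal component directions and singular values of W.

        Columns are ordered by decreasing singular value (hence decreasing
        modelled variance) and sign-fixed so that each column's
        largest-magnitude entry is positive; this removes the rotation and
        sign indeterminacy of the factor parametrization.
        """
        u, s, _ = np.linalg.svd(self.loadings, full_matrices=False)
        for k in range(u.shape[1]):
            j = np.argmax(np.abs(u[:, k]))
            if u[j, k] < 0:
                u[:, k] = -u[:, k]
        return u, s


def _as_masked(data: np.ndarray, mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = ~np.isnan(data)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError("mask shape does not match data shape")
    return data, mask


def _estep(data, mask, mean, W, sigma2):
    """Batched posterior of z per row plus the observed-data log-likelihood.

    Uses W_o^T W_o = W^T diag(mask) W so all rows are handled in one stacked
    inverse, and the Woodbury/determinant-lemma forms for the likelihood.
    """
    n, p = data.shape
    q = W.shape[1]
    resid = np.where(mask, data - mean, 0.0)  # r with missing coords zeroed
    M = np.einsum("nj,ja,jb->nab", mask, W, W) + sigma2 * np.eye(q)
    Minv = np.linalg.inv(M)
    rhs = resid @ W  # n x q  (= W_o^T r)
    zhat = np.einsum("nab,nb->na", Minv, rhs)
    Sz = sigma2 * Minv
    n_obs = mask.sum(axis=1)
    _, logdetM = np.linalg.slogdet(M)
    logdet = (n_obs - q) * np.log(sigma2) + logdetM
    quad = ((resid * resid).sum(axis=1) - np.einsum("na,na->n", rhs, zhat)) / sigma2
    ll = float(-0.5 * np.sum(n_obs * np.log(2 * np.pi) + logdet + quad))
    return zhat, Sz, ll


def _observed_loglik(data, mask, mean, W, sigma2) -> float:
    """Exact observed-data log-likelihood of the PPCA model."""
    return _estep(data, mask, mean, W, sigma2)[2]


def fit_ppca(
    data: np.ndarray,
    q: int,
    mask: np.ndarray | None = None,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init: str = "svd",
) -> PPCAModel:
    """Fit the PPCA model by ECM on (possibly) incomplete data.

    ``mask`` marks observed cells; if omitted, NaN cells are treated as
    missing.  ``init="svd"`` (default) initializes deterministically from the
    SVD of the column-mean-imputed matrix; ``init="random"`` draws the initial
    loadings from a seeded standard normal.  Convergence is declared when the
    relative change of the observed-data log-likelihood drops below ``tol``.
    """
    data, mask = _as_masked(data, mask)
    n, p = data.shape
    if not (1 <= q < min(n, p)):
        raise ValueError(f"q must satisfy 1 <= q < min(n, p) = {min(n, p)}, got {q}")
    if not mask.any(axis=1).all():
        raise ValueError("every row must have at least one observed entry")
    if not mask.any(axis=0).all():
        raise ValueError("every column must have at least one observed entry")

    # deterministic initialization from the mean-imputed spectrum
    col_mean = np.array([data[mask[:, j], j].mean() for j in range(p)])
    filled = np.where(mask, data, col_mean)
    mean = col_mean.copy()
    centered = filled - mean
    if init == "random":
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((p, q))
        sigma2 = float(np.var(centered)) or 1.0
    else:
        u_f, s_f, _ = np.linalg.svd(centered, full_matrices=False)
        eigvals = s_f**2 / max(n - 1, 1)
        sigma2 = float(np.mean(eigvals[q:])) if eigvals.size > q else 0.0
        sigma2 = max(sigma2, 1e-6 * max(float(eigvals[0]), 1.0))
        # right singular vectors give the loading directions in feature space
        V = np.linalg.svd(centered, full_matrices=False)[2][:q].T
        scale = np.sqrt(np.maximum(eigvals[:q] - sigma2, 1e-12))
        W = V * scale

    trace: list[float] = []
    converged = False
    it = 0
    miss = ~mask
    for it in range(1, max_iter + 1):
        # ---- E-step at (mean, W, sigma2)
        zhat, Sz, ll = _estep(data, mask, mean, W, sigma2)
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                break

        resid_obs = np.where(mask, data - mean - zhat @ W.T, 0.0)

        # ---- CM-1: mean (W, sigma2 fixed at current values);
        # observed cells contribute x - W z, missing cells the old mean
        new_mean = mean + resid_obs.sum(axis=0) / n

        # ---- CM-2: loadings w_j' = Ezz^{-1} b_j with the shared moment matrix
        Ezz = Sz.sum(axis=0) + zhat.T @ zhat  # q x q
        centered_obs = np.where(mask, data - new_mean, 0.0)
        B = centered_obs.T @ zhat  # observed-cell term, p x q
        if miss.any():
            # E[(x_mj - mu'_j) z] = Sz w0_j + (mu0_j - mu'_j + z.w0_j) zhat
            Sz_miss = np.einsum("nj,nab->jab", miss, Sz)  # p x q x q
            B += np.einsum("jab,jb->ja", Sz_miss, W)
            drift = miss * ((mean - new_mean) + zhat @ W.T)  # n x p
            B += drift.T @ zhat
        new_W = np.linalg.solve(Ezz, B.T).T

        # ---- CM-3: noise variance — exact expected squared residual,
        # including posterior uncertainty of the latents and the missing cells
        R = np.where(mask, data - new_mean - zhat @ new_W.T, 0.0)
        total = float((R * R).sum())
        total += float(np.einsum("nj,nab,ja,jb->", mask, Sz, new_W, new_W))
        if miss.any():
            dW = W - new_W
            total += sigma2 * float(miss.sum())
            total += float(np.einsum("nj,nab,ja,jb->", miss, Sz, dW, dW))
            U = miss * ((mean - new_mean) + zhat @ dW.T)
            total += float((U * U).sum())
        new_sigma2 = max(total / (n * p), 1e-12)

        mean, W, sigma2 = new_mean, new_W, new_sigma2

    return PPCAModel(
        mean=mean,
        loadings=W,
        noise_variance=float(sigma2),
        q=q,
        converged=converged,
        n_iter=it,
        log_likelihood_trace=trace,
    )


def impute(model: PPCAModel, data: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Replace missing cells by their posterior predictive mean.

    A fully missing row falls back to the model mean.  Observed cells are
    returned bit-identical to the input.
    """
    data, mask = _as_masked(data, mask)
    n, p = data.shape
    if p != model.p:
        raise ValueError(f"data has {p} columns but model expects {model.p}")
    W, mean, sigma2 = model.loadings, model.mean, model.noise_variance
    if mask.all():
        return data.copy()
    zhat, _, _ = _estep(data, mask, mean, W, sigma2)
    return np.where(mask, data, mean + zhat @ W.T)


def scores(model: PPCAModel, data: np.ndarray) -> np.ndarray:
    """Posterior-mean latent coordinates on complete data.

    Coordinates are expressed in the canonical component basis (see
    :meth:`PPCAModel.principal_axes`): component k's score for row x is
    s_k / (s_k^2 + sigma^2) * u_k . (x - mean), so components are ordered by
    explained variance with a deterministic sign.
    """
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("scores require complete data; impute first")
    if data.shape[1] != model.p:
        raise ValueError("dimension mismatch")
    u, s = model.principal_axes()
    shrink = s / (s**2 + model.noise_variance)
    return (data - model.mean) @ u * shrink


def variance_explained(
    model: PPCAModel, data: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-component share of total variance on the completed data.

    The spectrum of the sample covariance of the completed matrix is the
    denominator-defining object: fraction k is eigenvalue k over the trace.
    Returns the top-q fractions (non-increasing, each in [0, 1]).
    """
    data, mask_arr = _as_masked(data, mask)
    completed = impute(model, data, mask_arr) if not mask_arr.all() else data
    centered = completed - completed.mean(axis=0)
    eigvals = np.linalg.svd(centered, compute_uv=False) ** 2
    fractions = eigvals / eigvals.sum()
    return fractions[: model.q]
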