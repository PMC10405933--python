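"""Bayesian kernel regression fit by Gibbs sampling.

The model is a Gaussian mixed model with an intercept, an optional
covariate regression block, any number of kernel-structured random
effects, and i.i.d. noise:

    y = mu 1 + X beta + sum_k u_k + eps,
    u_k ~ N(0, sigma_k^2 K_k),   eps ~ N(0, sigma^2 I),

with conjugate scaled-inverse-chi^2 priors on every variance and a
Gaussian prior with large fixed variance on beta. Each kernel effect is
sampled in the eigenbasis of the kernel restricted to the training rows
(eigenvalues below a relative 1e-10 are truncated), which makes the
conditional posterior of its coordinates diagonal: a full scan costs
O(n_train * rank) per kernel. Held-out predictions propagate through
the kernel's cross-covariance between held-out and training rows, so an
environment with no training data is predicted exactly as far as its
kernel relates it to observed environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EIG_TRUNC_RTOL = 1e-10
PSD_TOL = 1e-6


class ModelError(ValueError):
    pass


@dataclass
class McmcConfig:
    """Chain settings and prior hyper-parameters for the Gibbs sampler.

    ``prior_df`` is the scaled-inverse-chi^2 degrees of freedom shared
    by every variance; prior scales partition the training phenotypic
    variance across the random terms according to
    ``prior_variance_split`` (default: half to the residual, the other
    half equally among kernel terms).
    """

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    prior_df: float = 5.0
    prior_variance_split: tuple[float, ...] | None = None
    beta_prior_variance: float | None = None  # default: 1e3 * var(y_train)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_variance_split is not None:
            if sum(self.prior_variance_split) > 1.0 + 1e-12:
                raise ValueError("prior_variance_split fractions must sum to <= 1")


@dataclass
class FitResult:
    """Posterior summaries of one fit."""

    predictions: np.ndarray  # posterior-mean linear predictor, all n rows
    post_mu: float
    post_beta: np.ndarray  # empty when no covariate block
    post_var: dict  # {"term_0": ..., ..., "residual": ...}
    post_beta_sd: np.ndarray
    effects: list  # posterior-mean u_k, one n-vector per kernel term
    pred_sd: np.ndarray
    pred_mcse: np.ndarray  # batch-means Monte Carlo SE of the posterior mean
    n_kept: int
    seed: int
    train_mask: np.ndarray = field(repr=False, default=None)


def _prepare_term(K: np.ndarray, train: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Eigenbasis of K restricted to training rows plus all-row propagator.

    Returns ``(B_all, d, mean_diag)`` with ``B_all = K[:, train] U D^-1``
    so that ``u = B_all @ gamma`` restricted to training rows equals
    ``U @ gamma``.
    """
    K = np.asarray(K, dtype=float)
    Ktt = K[np.ix_(train, train)]
    Ktt = (Ktt + Ktt.T) / 2.0
    w, V = np.linalg.eigh(Ktt)
    scale = max(abs(w[-1]), 1.0)
    if w[0] < -PSD_TOL * scale:
        raise ModelError(f"kernel is not PSD beyond jitter tolerance (lambda_min={w[0]:.3e})")
    keep = w > EIG_TRUNC_RTOL * max(w[-1], 0.0)
    if not keep.any():
        raise ModelError("kernel has no positive eigenvalue on the training rows")
    d, U = w[keep], V[:, keep]
    B_all = K[:, train] @ (U / d)
    return B_all, d, float(np.mean(np.diag(Ktt)))


def fit_predict(
    y: np.ndarray,
    kernel_terms: list[np.ndarray] | None = None,
    covariates: np.ndarray | None = None,
    config: McmcConfig | None = None,
    fixed_variances: dict | None = None,
) -> FitResult:
    """Run the Gibbs sampler and return posterior means.

    ``y`` holds the response for all n observations with held-out
    entries set to NaN; they are never imputed, only predicted.
    ``fixed_variances`` (``{"term_0": v0, ..., "residual": ve}``) pins
    selected variance components, which turns the sampler into an exact
    BLUP solver up to Monte Carlo error — used for validation.
    """
    config = config or McmcConfig()
    y = np.asarray(y, dtype=float)
    train = np.isfinite(y)
    nt = int(train.sum())
    if nt == 0:
        raise ModelError("all observations are masked; nothing to train on")
    kernel_terms = kernel_terms or []
    fixed_variances = fixed_variances or {}

    values = getattr(covariates, "values", covariates)
    X = None if values is None else np.atleast_2d(np.asarray(values, dtype=float))
    q = 0 if X is None else X.shape[1]

    y_t = y[train]
    var_y = max(float(np.var(y_t, ddof=1)) if nt > 1 else 0.0, 1e-12)
    df = config.prior_df
    n_terms = len(kernel_terms)

    if config.prior_variance_split is not None:
        splits = list(config.prior_variance_split)
        if len(splits) != n_terms:
            raise ModelError(
                f"prior_variance_split has {len(splits)} fractions for {n_terms} kernel terms"
            )
        resid_split = max(1.0 - sum(splits), 0.05)
    else:
        splits = [0.5 / n_terms] * n_terms if n_terms else []
        resid_split = 0.5
    S_resid = var_y * resid_split * (df + 2.0) / df

    terms = []
    for k, K in enumerate(kernel_terms):
        if K.shape != (y.size, y.size):
            raise ModelError(f"kernel {k} has shape {K.shape}, expected ({y.size},) * 2")
        B_all, d, mean_diag = _prepare_term(K, train)
        S_k = var_y * splits[k] * (df + 2.0) / df / max(mean_diag, 1e-12)
        terms.append({"B": B_all, "U": B_all[train], "d": d, "S": S_k})

    rng = np.random.default_rng(config.seed)
    sigma2 = fixed_variances.get("residual", var_y / 2.0)
    sig_k = [fixed_variances.get(f"term_{k}", var_y / (2.0 * max(n_terms, 1))) for k in range(n_terms)]
    gammas = [np.zeros(t["d"].size) for t in terms]
    mu = float(y_t.mean())
    beta = np.zeros(q)
    if q:
        Xt = X[train]
        XtX = Xt.T @ Xt
        sigma_beta2 = config.beta_prior_variance or 1e3 * var_y

    resid = y_t - mu
    kept_preds, kept_beta, kept_mu = [], [], []
    kept_var = {f"term_{k}": [] for k in range(n_terms)}
    kept_var["residual"] = []
    kept_effects = [[] for _ in range(n_terms)]

    for it in range(config.n_iter):
        # intercept, flat prior
        r_mu = resid + mu
        mu = float(r_mu.mean() + rng.standard_normal() * np.sqrt(sigma2 / nt))
        resid = r_mu - mu

        # kernel effects in their eigenbases
        for k, t in enumerate(terms):
            U, d = t["U"], t["d"]
            u_t = U @ gammas[k]
            r_k = resid + u_t
            prec = 1.0 / sigma2 + 1.0 / (sig_k[k] * d)
            mean = (U.T @ r_k) / sigma2 / prec
            gammas[k] = mean + rng.standard_normal(d.size) / np.sqrt(prec)
            u_t = U @ gammas[k]
            resid = r_k - u_t
            if f"term_{k}" not in fixed_variances:
                ssq = float(np.sum(gammas[k] ** 2 / d))
                sig_k[k] = (df * t["S"] + ssq) / rng.chisquare(df + d.size)

        # covariate regression block
        if q:
            r_b = resid + Xt @ beta
            C = XtX / sigma2 + np.eye(q) / sigma_beta2
            L = np.linalg.cholesky(C)
            mean = np.linalg.solve(C, Xt.T @ r_b / sigma2)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(q))
            resid = r_b - Xt @ beta

        # residual variance
        if "residual" not in fixed_variances:
            sigma2 = (df * S_resid + float(resid @ resid)) / rng.chisquare(df + nt)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            pred = np.full(y.size, mu)
            for k, t in enumerate(terms):
                u_all = t["B"] @ gammas[k]
                pred += u_all
                kept_effects[k].append(u_all)
                kept_var[f"term_{k}"].append(sig_k[k])
            if q:
                pred += X @ beta
                kept_beta.append(beta.copy())
            kept_var["residual"].append(sigma2)
            kept_mu.append(mu)
            kept_preds.append(pred)

    draws = np.asarray(kept_preds)
    n_kept = draws.shape[0]
    pred_mean = draws.mean(axis=0)
    pred_sd = draws.std(axis=0, ddof=1) if n_kept > 1 else np.zeros(y.size)
    nb = min(25, n_kept)
    batches = np.array_split(draws, nb, axis=0)
    bm = np.stack([b.mean(axis=0) for b in batches])
    pred_mcse = bm.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros(y.size)

    beta_draws = np.asarray(kept_beta) if q else np.empty((n_kept, 0))
    return FitResult(
        predictions=pred_mean,
        post_mu=float(np.mean(kept_mu)),
        post_beta=beta_draws.mean(axis=0) if q else np.array([]),
        post_beta_sd=beta_draws.std(axis=0, ddof=1) if q and n_kept > 1 else np.zeros(q),
        post_var={k: float(np.mean(v)) for k, v in kept_var.items()},
        effects=[np.mean(e, axis=0) for e in kept_effects],
        pred_sd=pred_sd,
        pred_mcse=pred_mcse,
        n_kept=n_kept,
        seed=config.seed,
        train_mask=train,
    )


def blup_solve(
    y: np.ndarray, K: np.ndarray, sigma_u2: float, sigma_e2: float
) -> np.ndarray:
    """Closed-form mixed-model predictions at known variance components.

    GLS intercept plus BLUP of the kernel effect, used as the
    independent oracle against which the sampler is checked:
    ``V = sigma_u2 K_tt + sigma_e2 I``;
    ``u_hat = sigma_u2 K[:, t] V^{-1} (y_t - mu_hat)``.
    """
    y = np.asarray(y, dtype=float)
    train = np.isfinite(y)
    y_t = y[train]
    Ktt = K[np.ix_(train, train)]
    V = sigma_u2 * Ktt + sigma_e2 * np.eye(train.sum())
    Vinv_1 = np.linalg.solve(V, np.ones(train.sum()))
    mu_hat = float(Vinv_1 @ y_t / Vinv_1.sum())
    u_hat = sigma_u2 * K[:, train] @ np.linalg.solve(V, y_t - mu_hat)
    return mu_hat + u_hat
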