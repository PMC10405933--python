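"""Relationship and design matrices for kernel-based multi-environment GBLUP.

Builds the linear kernels of the prediction model: the genomic
relationship matrix ``K.g = Me Me'/p`` from standardized marker counts,
the environmental relationship matrix ``H.e = Xe Xe'/r`` from
standardized covariates, their observation-level expansions ``K.e``
(incidence-based) and ``K.ec`` (covariate-based), and the Hadamard
genotype-by-environment interaction kernels ``K.ge`` / ``K.gec``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import TrialData

logger = logging.getLogger(__name__)

SYM_RTOL = 1e-10
PSD_JITTER_MAX = 1e-8


class KernelError(ValueError):
    """Raised for degenerate inputs that cannot yield a valid kernel."""


@dataclass
class DesignMatrices:
    """One-hot incidence matrices aligned with one trait's observations.

    ``Ze`` is n x I (environments), ``Zg`` is n x J (genotypes); each row
    of either matrix has exactly one 1.
    """

    Ze: np.ndarray
    Zg: np.ndarray
    env_ids: list[str]
    genotype_ids: list[str]
    obs_env: np.ndarray  # per-observation environment index
    obs_genotype: np.ndarray  # per-observation genotype index

    @property
    def n_obs(self) -> int:
        return self.Ze.shape[0]

    @property
    def n_environments(self) -> int:
        return self.Ze.shape[1]


@dataclass
class KernelSet:
    """The symmetric PSD relationship matrices entering the model."""

    K_g: np.ndarray  # J x J genomic
    H_e: np.ndarray | None  # I x I environmental (None when no covariates used)
    K_e: np.ndarray  # n x n incidence-based environment kernel
    K_ec: np.ndarray | None  # n x n covariate-based environment kernel
    K_ge: np.ndarray  # n x n interaction with K_e
    K_gec: np.ndarray | None  # n x n interaction with K_ec


def build_design_matrices(trial: TrialData, trait_id: str) -> DesignMatrices:
    """One-hot environment and genotype incidence for one trait's rows."""
    obs = trial.trait_observations(trait_id)
    env_idx = obs["env_id"].map(trial.env_index).to_numpy()
    geno_idx = obs["genotype_id"].map(trial.genotype_index).to_numpy()
    n = len(obs)
    Ze = np.zeros((n, trial.n_environments))
    Zg = np.zeros((n, trial.n_genotypes))
    Ze[np.arange(n), env_idx] = 1.0
    Zg[np.arange(n), geno_idx] = 1.0
    return DesignMatrices(
        Ze=Ze,
        Zg=Zg,
        env_ids=list(trial.env_ids),
        genotype_ids=list(trial.genotype_ids),
        obs_env=env_idx,
        obs_genotype=geno_idx,
    )


def standardize_columns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to mean 0, sample (n-1) standard deviation 1.

    Zero-variance columns are dropped with a logged warning. Returns the
    standardized matrix and the indices of retained columns.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] < 2:
        raise KernelError("standardization needs at least 2 rows")
    sd = M.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0:
        raise KernelError("all columns are constant; nothing to standardize")
    if kept.size < M.shape[1]:
        dropped = np.setdiff1d(np.arange(M.shape[1]), kept)
        logger.warning("dropping %d zero-variance column(s): %s", dropped.size, dropped.tolist())
    Z = (M[:, kept] - M[:, kept].mean(axis=0)) / sd[kept]
    return Z, kept


def genomic_kernel(markers: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix ``Me Me' / p`` over standardized markers."""
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    if markers.shape[0] < 2:
        raise KernelError("genomic kernel needs at least 2 lines")
    try:
        Me, kept = standardize_columns(markers)
    except KernelError as exc:
        raise KernelError("no polymorphic marker available") from exc
    return ensure_psd(Me @ Me.T / kept.size)


def env_covariate_kernel(env_covariates: np.ndarray) -> np.ndarray:
    """Environmental relationship matrix ``Xe Xe' / r`` over standardized covariates."""
    X = np.atleast_2d(np.asarray(env_covariates, dtype=float))
    if X.shape[1] == 0:
        raise KernelError("no environmental covariates supplied")
    if X.shape[0] < 2:
        raise KernelError("environmental kernel needs at least 2 environments")
    Xe, kept = standardize_columns(X)
    return ensure_psd(Xe @ Xe.T / kept.size)


def observation_env_kernel(design: DesignMatrices, H_e: np.ndarray | None = None) -> np.ndarray:
    """Observation-level environment kernel.

    Without ``H_e``: the incidence kernel ``K.e = Ze Ze'/I``. With
    ``H_e``: the covariate-based kernel ``K.ec = Ze H.e Ze'``.
    """
    Ze = design.Ze
    if H_e is None:
        return Ze @ Ze.T / design.n_environments
    H_e = np.asarray(H_e, dtype=float)
    if H_e.shape != (design.n_environments, design.n_environments):
        raise KernelError(
            f"H_e has shape {H_e.shape}, expected ({design.n_environments},) * 2"
        )
    return Ze @ H_e @ Ze.T


def interaction_kernel(
    env_obs_kernel: np.ndarray, K_g: np.ndarray, design: DesignMatrices
) -> np.ndarray:
    """Hadamard genotype-by-environment kernel ``K_env (.) Zg K.g Zg'``."""
    env_obs_kernel = np.asarray(env_obs_kernel, dtype=float)
    K_g = np.asarray(K_g, dtype=float)
    Zg = design.Zg
    if K_g.shape != (Zg.shape[1], Zg.shape[1]):
        raise KernelError(f"K_g has shape {K_g.shape}, expected ({Zg.shape[1]},) * 2")
    if env_obs_kernel.shape != (Zg.shape[0], Zg.shape[0]):
        raise KernelError(
            f"env kernel has shape {env_obs_kernel.shape}, expected ({Zg.shape[0]},) * 2"
        )
    return env_obs_kernel * (Zg @ K_g @ Zg.T)


def ensure_psd(K: np.ndarray, jitter_max: float = PSD_JITTER_MAX) -> np.ndarray:
    """Symmetrize and, if needed, add a minimal diagonal jitter (<= jitter_max).

    A matrix whose smallest eigenvalue is below ``-jitter_max`` (relative
    to its scale) is rejected rather than repaired.
    """
    K = np.asarray(K, dtype=float)
    asym = np.abs(K - K.T).max(initial=0.0)
    scale = max(np.abs(K).max(initial=0.0), 1.0)
    if asym > SYM_RTOL * scale:
        raise KernelError(f"matrix is asymmetric beyond tolerance (max |K-K'| = {asym:.3e})")
    K = (K + K.T) / 2.0
    lam_min = float(np.linalg.eigvalsh(K)[0])
    if lam_min < -jitter_max * scale:
        raise KernelError(f"matrix is not PSD (lambda_min = {lam_min:.3e})")
    if lam_min < 0.0:
        jitter = -lam_min + np.finfo(float).eps * scale
        logger.debug("adding diagonal jitter %.3e to restore PSD", jitter)
        K = K + jitter * np.eye(K.shape[0])
    return K


def build_kernel_set(
    trial: TrialData,
    trait_id: str,
    selected_covariates: np.ndarray | None = None,
) -> tuple[KernelSet, DesignMatrices]:
    """Assemble every kernel of the model for one trait.

    ``selected_covariates`` restricts the columns entering ``H.e`` /
    ``K.ec`` / ``K.gec``; ``None`` uses all covariates, an empty
    selection yields ``H_e = K_ec = K_gec = None`` (callers fall back to
    the incidence-based kernels).
    """
    design = build_design_matrices(trial, trait_id)
    K_g = genomic_kernel(trial.markers)
    K_e = observation_env_kernel(design)
    K_ge = interaction_kernel(K_e, K_g, design)
    if selected_covariates is None:
        cov = trial.env_covariates
    else:
        cov = trial.env_covariates[:, np.asarray(selected_covariates, dtype=int)]
    if cov.shape[1] > 0:
        H_e = env_covariate_kernel(cov)
        K_ec = observation_env_kernel(design, H_e)
        K_gec = interaction_kernel(K_ec, K_g, design)
    else:
        H_e = K_ec = K_gec = None
    return (
        KernelSet(K_g=K_g, H_e=H_e, K_e=K_e, K_ec=K_ec, K_ge=K_ge, K_gec=K_gec),
        design,
    )
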