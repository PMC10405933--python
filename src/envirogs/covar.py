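"""Engineered covariate blocks for the fixed-regression term.

Environmental covariates are measured once per environment, so before
entering the observation-level model they are expanded with the
environment incidence matrix. Three engineered blocks are supported:
the expanded (selected) covariates themselves, their quadratic
augmentation [Xe | Xe^2], and the single sign-aligned average covariate
Xe.avg — each selected column is flipped so its *training* correlation
with the response is non-negative, then the per-environment mean over
the flipped columns is taken for all environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import DesignMatrices, standardize_columns
from .select import SelectionOutcome, pearson_columns

logger = logging.getLogger(__name__)


class CovariateError(ValueError):
    pass


@dataclass
class EngineeredCovariates:
    """An observation-level covariate block with its provenance."""

    values: np.ndarray  # n x q
    provenance: str  # Xe | Xe_avg | Xe2 | X_g_ec | none
    sign_flips: frozenset = frozenset()
    source_selection: SelectionOutcome | None = None
    column_sources: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return 0 if self.values is None else self.values.shape[1]


def expand_to_observations(env_covariates: np.ndarray, design: DesignMatrices) -> np.ndarray:
    """Repeat each environment's covariate row for its observations (Ze X)."""
    X = np.atleast_2d(np.asarray(env_covariates, dtype=float))
    if X.shape[0] != design.n_environments:
        raise CovariateError(
            f"covariates have {X.shape[0]} rows but design has {design.n_environments} environments"
        )
    return X[design.obs_env, :]


def signed_average(
    env_covariates_selected: np.ndarray,
    y_train: np.ndarray,
    design_train: DesignMatrices,
) -> tuple[np.ndarray, frozenset]:
    """Sign-align selected covariates on the training fold and average.

    Columns whose training correlation with the response is negative are
    multiplied by -1; the per-environment row mean of the flipped matrix
    (over *all* environments, training and held-out) is returned
    together with the set of flipped column positions. Zero training
    correlation leaves the sign unchanged.
    """
    X = np.atleast_2d(np.asarray(env_covariates_selected, dtype=float))
    if X.shape[1] == 0:
        raise CovariateError("signed_average needs at least one selected covariate")
    expanded_train = expand_to_observations(X, design_train)
    r = pearson_columns(expanded_train, y_train)
    flips = frozenset(np.flatnonzero(r < 0).tolist())
    signs = np.where(r < 0, -1.0, 1.0)
    x_avg = (X * signs).mean(axis=1)
    return x_avg, flips


def quadratic_augment(env_covariates_selected: np.ndarray) -> np.ndarray:
    """[Xe | Xe^2] on standardized covariates, squares re-standardized.

    Squared columns that come out constant (e.g. a symmetric +-c column)
    are dropped by the re-standardization with a warning.
    """
    X = np.atleast_2d(np.asarray(env_covariates_selected, dtype=float))
    if X.shape[1] == 0:
        raise CovariateError("quadratic_augment needs at least one selected covariate")
    Xs, _ = standardize_columns(X)
    squares = Xs**2
    sd = squares.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if keep.size < squares.shape[1]:
        logger.warning(
            "dropping %d constant squared column(s)", squares.shape[1] - keep.size
        )
    if keep.size:
        sq_std = (squares[:, keep] - squares[:, keep].mean(axis=0)) / sd[keep]
        return np.hstack([Xs, sq_std])
    return Xs
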