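"""Containers for multi-environment trial data.

A trial couples three matrices: a long-format phenotype table
(environment, genotype, trait, value), a marker matrix of minor-allele
counts coded 0/1/2 (lines x markers), and an environmental-covariate
matrix (environments x covariates). Designs may be unbalanced: a
genotype need not appear in every environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class TrialDataError(ValueError):
    """Raised when trial components are inconsistent with each other."""


OBS_COLUMNS = ("env_id", "genotype_id", "trait_id", "value")


@dataclass
class TrialData:
    """Phenotypes plus marker and environmental-covariate matrices.

    Parameters
    ----------
    observations
        Long-format table with columns ``env_id``, ``genotype_id``,
        ``trait_id`` and ``value`` (phenotype, arbitrary units).
    markers
        Integer matrix, lines x markers, entries in {0, 1, 2}.
    env_covariates
        Real matrix, environments x covariates, one row per distinct
        environment in ``env_ids`` order.
    env_ids, genotype_ids, trait_ids
        Level orderings; they define the row indices of the matrices and
        the columns of the incidence matrices built downstream.
    """

    observations: pd.DataFrame
    markers: np.ndarray
    env_covariates: np.ndarray
    env_ids: list[str]
    genotype_ids: list[str]
    trait_ids: list[str]
    marker_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observations = pd.DataFrame(self.observations).reset_index(drop=True)
        missing = [c for c in OBS_COLUMNS if c not in self.observations.columns]
        if missing:
            raise TrialDataError(f"observation table lacks columns {missing}")
        self.markers = np.asarray(self.markers)
        self.env_covariates = np.atleast_2d(np.asarray(self.env_covariates, dtype=float))
        if not self.marker_names:
            self.marker_names = [f"m{k}" for k in range(self.markers.shape[1])]
        if not self.covariate_names:
            self.covariate_names = [f"ec{k}" for k in range(self.env_covariates.shape[1])]
        self.validate()

    # -- index maps -------------------------------------------------------
    @property
    def env_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.env_ids)}

    @property
    def genotype_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.genotype_ids)}

    @property
    def n_environments(self) -> int:
        return len(self.env_ids)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    def validate(self) -> None:
        if not np.isin(self.markers, (0, 1, 2)).all():
            raise TrialDataError("marker matrix has entries outside {0, 1, 2}")
        if self.markers.shape[0] != len(self.genotype_ids):
            raise TrialDataError(
                f"marker rows ({self.markers.shape[0]}) != genotypes ({len(self.genotype_ids)})"
            )
        if self.env_covariates.shape[0] != len(self.env_ids):
            raise TrialDataError(
                "env_covariates must have exactly one row per environment: "
                f"{self.env_covariates.shape[0]} rows vs {len(self.env_ids)} environments"
            )
        env_set, geno_set = set(self.env_ids), set(self.genotype_ids)
        bad_env = set(self.observations["env_id"]) - env_set
        bad_geno = set(self.observations["genotype_id"]) - geno_set
        if bad_env or bad_geno:
            raise TrialDataError(
                f"observations reference unknown levels: envs {sorted(bad_env)}, "
                f"genotypes {sorted(map(str, bad_geno))[:5]}"
            )
        bad_trait = set(self.observations["trait_id"]) - set(self.trait_ids)
        if bad_trait:
            raise TrialDataError(f"observations reference unknown traits {sorted(bad_trait)}")

    def trait_observations(self, trait_id: str) -> pd.DataFrame:
        """Rows of the phenotype table for one trait, in stored order."""
        if trait_id not in self.trait_ids:
            raise TrialDataError(f"unknown trait {trait_id!r}; have {self.trait_ids}")
        return self.observations[self.observations["trait_id"] == trait_id].reset_index(drop=True)

    # -- plain-text round trip -------------------------------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "phenotype": out / "phenotype.csv",
            "markers": out / "markers.csv",
            "env_covariates": out / "env_covariates.csv",
        }
        self.observations.to_csv(paths["phenotype"], index=False)
        pd.DataFrame(self.markers, index=self.genotype_ids, columns=self.marker_names).to_csv(
            paths["markers"], index_label="genotype_id"
        )
        pd.DataFrame(
            self.env_covariates, index=self.env_ids, columns=self.covariate_names
        ).to_csv(paths["env_covariates"], index_label="env_id")
        return paths

    @classmethod
    def read(cls, pheno: str | Path, geno: str | Path, envcov: str | Path) -> "TrialData":
        obs = pd.read_csv(pheno, dtype={"env_id": str, "genotype_id": str, "trait_id": str})
        markers = pd.read_csv(geno, index_col=0)
        covs = pd.read_csv(envcov, index_col=0)
        return cls(
            observations=obs,
            markers=markers.to_numpy(),
            env_covariates=covs.to_numpy(dtype=float),
            env_ids=[str(e) for e in covs.index],
            genotype_ids=[str(g) for g in markers.index],
            trait_ids=sorted(obs["trait_id"].unique()),
            marker_names=[str(c) for c in markers.columns],
            covariate_names=[str(c) for c in covs.columns],
        )


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated trial.

    ``beta_true`` is in phenotype units per standardized covariate unit
    and is exactly zero outside ``informative_covariates``.
    """

    informative_covariates: np.ndarray
    beta_true: np.ndarray
    var_components_true: tuple[float, float, float, float]
    seed: int

    def __post_init__(self) -> None:
        self.informative_covariates = np.asarray(self.informative_covariates, dtype=int)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if any(v < 0 for v in self.var_components_true):
            raise ValueError("variance components must be non-negative")
        mask = np.zeros(self.beta_true.size, dtype=bool)
        mask[self.informative_covariates] = True
        if np.any(self.beta_true[~mask] != 0.0):
            raise ValueError("beta_true must be zero outside informative_covariates")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_covariates": self.informative_covariates.tolist(),
            "beta_true": self.beta_true.tolist(),
            "var_components_true": list(self.var_components_true),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            informative_covariates=np.asarray(payload["informative_covariates"], dtype=int),
            beta_true=np.asarray(payload["beta_true"], dtype=float),
            var_components_true=tuple(payload["var_components_true"]),
            seed=int(payload["seed"]),
        )
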