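"""Predictor registry, leakage-safe LOEO evaluation, and accuracy statistics.

Fifteen predictor configurations M0-M14 combine (a) incidence-based or
covariate-based environment kernels, (b) the genomic and Hadamard
interaction kernels, (c) an engineered covariate block (all covariates,
selected covariates, their squares, the sign-aligned average, or a joint
marker+covariate selection), and (d) a selection procedure (none, the
correlation threshold ladder, Boruta, or both). M0 is the no-covariate
baseline every relative efficiency refers to.

Evaluation is leave-one-environment-out: each fold masks all responses
of one environment; covariate selection, sign flips and the average
covariate are computed from the training rows of that fold only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import covar as _covar
from . import kernels as _kernels
from . import select as _select
from .data import TrialData
from .kernels import DesignMatrices
from .model import FitResult, McmcConfig, fit_predict

logger = logging.getLogger(__name__)

MODEL_IDS = tuple(f"M{k}" for k in range(15))


class BenchError(ValueError):
    pass


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class PredictorSpec:
    """One row of the predictor registry."""

    model_id: str
    kernel_components: tuple[str, ...]  # subset of K.e, K.ec, K.g, K.ge, K.gec
    covariate_block: str = "none"  # none | Xe | Xe2 | Xe_avg | X_g_ec
    selection: str = "none"  # none | correlation | boruta | corr_and_boruta
    tentative_included: bool = False
    marker_selection: bool = False  # Boruta over markers feeding K.g


REGISTRY: dict[str, PredictorSpec] = {
    "M0": PredictorSpec("M0", ("K.e", "K.g", "K.ge")),
    "M1": PredictorSpec("M1", ("K.e", "K.g", "K.ge"), "Xe", "none"),
    "M2": PredictorSpec("M2", ("K.ec", "K.g", "K.gec"), "none", "correlation"),
    "M3": PredictorSpec("M3", ("K.e", "K.g", "K.ge"), "Xe", "correlation"),
    "M4": PredictorSpec("M4", ("K.ec", "K.g", "K.gec"), "Xe", "correlation"),
    "M5": PredictorSpec("M5", ("K.e", "K.g", "K.ge"), "Xe2", "correlation"),
    "M6": PredictorSpec("M6", ("K.e", "K.g", "K.ge"), "Xe_avg", "correlation"),
    "M7": PredictorSpec("M7", ("K.ec", "K.g", "K.gec"), "Xe_avg", "correlation"),
    "M8": PredictorSpec("M8", ("K.ec", "K.g", "K.gec"), "Xe_avg", "corr_and_boruta"),
    "M9": PredictorSpec("M9", ("K.e", "K.ge"), "X_g_ec", "boruta"),
    "M10": PredictorSpec(
        "M10", ("K.e", "K.g", "K.ge"), "Xe", "boruta", tentative_included=True, marker_selection=True
    ),
    "M11": PredictorSpec("M11", ("K.ec", "K.g", "K.gec"), "Xe_avg", "boruta"),
    "M12": PredictorSpec("M12", ("K.ec", "K.g", "K.ge"), "Xe_avg", "boruta", tentative_included=True),
    "M13": PredictorSpec("M13", ("K.ec", "K.g", "K.gec"), "Xe_avg", "boruta", tentative_included=True),
    "M14": PredictorSpec("M14", ("K.ec", "K.g", "K.gec"), "Xe_avg", "boruta"),
}


@dataclass
class SelectorConfig:
    ladder: tuple[float, ...] = _select.DEFAULT_LADDER
    alpha: float = _select.DEFAULT_ALPHA
    max_runs: int = _select.DEFAULT_MAX_RUNS
    rf_params: dict | None = None


@dataclass
class AssembledPredictor:
    """Inputs for ``fit_predict`` plus the audit trail of their assembly."""

    model_id: str
    kernel_terms: list
    kernel_names: list
    covariates: _covar.EngineeredCovariates | None
    selections: dict
    fallbacks: list
    y_masked: np.ndarray
    design: DesignMatrices
    test_mask: np.ndarray


@dataclass
class MetricCell:
    """Accuracy of one model on one held-out environment of one trait."""

    trait: str
    env: str
    model_id: str
    nrmse: float
    cor: float
    b0: float
    b: float
    n_test: int
    dataset: str = ""


@dataclass
class ComparisonReport:
    summary: pd.DataFrame  # per-model aggregated metrics + RE columns
    env_wins: pd.DataFrame
    trait_wins: pd.DataFrame
    cells: pd.DataFrame


def _subset_design(design: DesignMatrices, mask: np.ndarray) -> DesignMatrices:
    return DesignMatrices(
        Ze=design.Ze[mask],
        Zg=design.Zg[mask],
        env_ids=design.env_ids,
        genotype_ids=design.genotype_ids,
        obs_env=design.obs_env[mask],
        obs_genotype=design.obs_genotype[mask],
    )


def _select_covariates(
    spec: PredictorSpec,
    features_train: np.ndarray,
    y_train: np.ndarray,
    cfg: SelectorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Run the spec'd selector(s) on training rows; return indices + outcomes."""
    outcomes: dict = {}
    if spec.selection == "none":
        return np.arange(features_train.shape[1]), outcomes
    if spec.selection in ("correlation", "corr_and_boruta"):
        out_c = _select.correlation_ladder_select(features_train, y_train, cfg.ladder)
        outcomes["correlation"] = out_c
        selected = out_c.selected
    if spec.selection in ("boruta", "corr_and_boruta"):
        out_b = _select.boruta_select(
            features_train,
            y_train,
            alpha=cfg.alpha,
            max_runs=cfg.max_runs,
            include_tentative=spec.tentative_included,
            rf_params=cfg.rf_params,
            seed=rng,
        )
        outcomes["boruta"] = out_b
        selected = out_b.selected
    if spec.selection == "corr_and_boruta":
        selected = np.intersect1d(outcomes["correlation"].selected, outcomes["boruta"].selected)
    return selected, outcomes


def build_predictor(
    model_id: str,
    trial: TrialData,
    trait: str,
    holdout_env: str,
    seed: int = 0,
    selector: SelectorConfig | None = None,
) -> AssembledPredictor:
    """Assemble kernels and covariate blocks for one LOEO fold of one model.

    Selection runs on training rows only. An empty covariate selection
    where K.ec/K.gec or a covariate block is required falls back to the
    incidence-based kernels / no block, with a logged flag.
    """
    if model_id not in REGISTRY:
        raise BenchError(f"unknown model {model_id!r}; valid ids are {MODEL_IDS}")
    spec = REGISTRY[model_id]
    cfg = selector or SelectorConfig()
    rng = np.random.default_rng(seed)

    design = _kernels.build_design_matrices(trial, trait)
    obs = trial.trait_observations(trait)
    y = obs["value"].to_numpy(dtype=float)
    if holdout_env not in trial.env_index:
        raise BenchError(f"unknown environment {holdout_env!r}")
    test_mask = design.obs_env == trial.env_index[holdout_env]
    if not test_mask.any():
        raise BenchError(f"environment {holdout_env!r} has no observations for trait {trait!r}")
    train_mask = ~test_mask
    y_train = y[train_mask]
    y_masked = y.copy()
    y_masked[test_mask] = np.nan
    fallbacks: list[str] = []

    # markers feeding K.g (optionally Boruta-selected on training rows)
    marker_cols = np.arange(trial.markers.shape[1])
    selections: dict = {}
    if spec.marker_selection:
        marker_obs = trial.markers[design.obs_genotype, :].astype(float)
        out_m = _select.boruta_select(
            marker_obs[train_mask],
            y_train,
            alpha=cfg.alpha,
            max_runs=cfg.max_runs,
            include_tentative=spec.tentative_included,
            rf_params=cfg.rf_params,
            seed=rng,
        )
        selections["markers"] = out_m
        if out_m.n_selected > 0:
            marker_cols = out_m.selected
        else:
            fallbacks.append("marker_selection_empty_using_all")
    K_g = _kernels.genomic_kernel(trial.markers[:, marker_cols])

    # covariate selection (observation-level features, training rows only)
    env_obs = _covar.expand_to_observations(trial.env_covariates, design)
    if spec.covariate_block == "X_g_ec":
        marker_obs = trial.markers[design.obs_genotype, :].astype(float)
        joint = np.hstack([marker_obs, env_obs])
        out_j = _select.boruta_select(
            joint[train_mask],
            y_train,
            alpha=cfg.alpha,
            max_runs=cfg.max_runs,
            include_tentative=spec.tentative_included,
            rf_params=cfg.rf_params,
            seed=rng,
            joint_space=True,
        )
        selections["joint"] = out_j
        p = trial.markers.shape[1]
        cov_sel = out_j.selected[out_j.selected >= p] - p
    else:
        cov_sel, outcomes = _select_covariates(spec, env_obs[train_mask], y_train, cfg, rng)
        selections.update(outcomes)

    # kernels
    K_e = _kernels.observation_env_kernel(design)
    Kg_obs = design.Zg @ K_g @ design.Zg.T
    need_cov_kernel = {"K.ec", "K.gec"} & set(spec.kernel_components)
    K_ec = None
    if need_cov_kernel:
        if cov_sel.size > 0:
            H_e = _kernels.env_covariate_kernel(trial.env_covariates[:, cov_sel])
            K_ec = _kernels.observation_env_kernel(design, H_e)
        else:
            fallbacks.append("empty_selection_K.ec_fallback_to_K.e")
    kernel_terms, kernel_names = [], []
    for name in spec.kernel_components:
        if name == "K.e":
            kernel_terms.append(K_e)
        elif name == "K.g":
            kernel_terms.append(Kg_obs)
        elif name == "K.ge":
            kernel_terms.append(K_e * Kg_obs)
        elif name == "K.ec":
            kernel_terms.append(K_ec if K_ec is not None else K_e)
        elif name == "K.gec":
            kernel_terms.append((K_ec if K_ec is not None else K_e) * Kg_obs)
        else:  # pragma: no cover - registry is static
            raise BenchError(f"unknown kernel component {name!r}")
        kernel_names.append(name)

    # covariate block
    block = None
    if spec.covariate_block == "Xe":
        if cov_sel.size > 0:
            Xs, kept = _kernels.standardize_columns(trial.env_covariates[:, cov_sel])
            block = _covar.EngineeredCovariates(
                values=_covar.expand_to_observations(Xs, design),
                provenance="Xe",
                column_sources=cov_sel[kept].tolist(),
            )
    elif spec.covariate_block == "Xe2":
        if cov_sel.size > 0:
            X2 = _covar.quadratic_augment(trial.env_covariates[:, cov_sel])
            block = _covar.EngineeredCovariates(
                values=_covar.expand_to_observations(X2, design),
                provenance="Xe2",
                column_sources=cov_sel.tolist(),
            )
    elif spec.covariate_block == "Xe_avg":
        if cov_sel.size > 0:
            Xsel, kept = _kernels.standardize_columns(trial.env_covariates[:, cov_sel])
            x_avg, flips = _covar.signed_average(Xsel, y_train, _subset_design(design, train_mask))
            block = _covar.EngineeredCovariates(
                values=_covar.expand_to_observations(x_avg[:, None], design),
                provenance="Xe_avg",
                sign_flips=flips,
                column_sources=cov_sel[kept].tolist(),
            )
    elif spec.covariate_block == "X_g_ec":
        if selections["joint"].n_selected > 0:
            sel = selections["joint"].selected
            Xj, kept = _kernels.standardize_columns(joint[:, sel])
            block = _covar.EngineeredCovariates(
                values=Xj,
                provenance="X_g_ec",
                source_selection=selections["joint"],
                column_sources=sel[kept].tolist(),
            )
    if spec.covariate_block != "none" and block is None:
        fallbacks.append(f"empty_selection_no_{spec.covariate_block}_block")
    if block is not None and spec.covariate_block != "X_g_ec":
        block.source_selection = selections.get("correlation") or selections.get("boruta")

    return AssembledPredictor(
        model_id=model_id,
        kernel_terms=kernel_terms,
        kernel_names=kernel_names,
        covariates=block,
        selections=selections,
        fallbacks=fallbacks,
        y_masked=y_masked,
        design=design,
        test_mask=test_mask,
    )


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def nrmse(observed: np.ndarray, predicted: np.ndarray, normalization: str = "mean") -> float:
    """Root mean squared error divided by |mean(observed)| (or sd(observed)).

    The mean normalization is the package default; see docs/methods.md
    for why, and the ``normalization="sd"`` switch for the alternative.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size or observed.size == 0:
        raise MetricError("observed and predicted must have equal, positive length")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if normalization == "mean":
        denom = abs(float(observed.mean()))
        if denom == 0.0:
            raise MetricError(
                "mean(observed) is zero: mean-normalized NRMSE is undefined; "
                "use normalization='sd'"
            )
    elif normalization == "sd":
        denom = float(observed.std(ddof=1)) if observed.size > 1 else 0.0
        if denom == 0.0:
            raise MetricError("sd(observed) is zero: sd-normalized NRMSE is undefined")
    else:
        raise MetricError(f"unknown normalization {normalization!r}")
    return rmse / denom


def cor_and_regression(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation plus |intercept| and |1 - slope| of observed ~ predicted."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size < 3 or np.std(predicted) == 0.0 or np.std(observed) == 0.0:
        return (np.nan, np.nan, np.nan)
    fit = stats.linregress(predicted, observed)
    return (float(fit.rvalue), abs(float(fit.intercept)), abs(1.0 - float(fit.slope)))


def relative_efficiency(metric_baseline: float, metric_model: float, kind: str) -> float:
    """Percent efficiency of a model relative to the no-covariate baseline.

    ``nrmse_like`` (also used for b0 and b): (baseline/model - 1) x 100,
    positive when the model's error is smaller. ``cor_like``:
    (model/baseline - 1) x 100, positive when the model correlates
    better.
    """
    if kind == "nrmse_like":
        if metric_model == 0.0:
            raise MetricError("model metric is zero; relative efficiency undefined")
        return (metric_baseline / metric_model - 1.0) * 100.0
    if kind == "cor_like":
        if metric_baseline == 0.0:
            raise MetricError("baseline metric is zero; relative efficiency undefined")
        return (metric_model / metric_baseline - 1.0) * 100.0
    raise MetricError(f"unknown kind {kind!r}")


def win_percentage(won: int, total: int) -> float:
    if total <= 0:
        raise MetricError("total must be positive")
    return won / total * 100.0


# ----------------------------------------------------------------------
# LOEO driver and report
# ----------------------------------------------------------------------

def loeo_run(
    trial: TrialData,
    traits: list[str] | None = None,
    models: tuple[str, ...] = MODEL_IDS,
    mcmc: McmcConfig | None = None,
    selector: SelectorConfig | None = None,
    seed: int = 0,
    normalization: str = "mean",
    dataset: str = "synthetic",
) -> list[MetricCell]:
    """Leave-one-environment-out evaluation of the requested models.

    One fold per environment with observations for the trait; per
    (fold, model) an independent seed stream is derived from the master
    seed, so adding a model never perturbs another model's results.
    """
    mcmc = mcmc or McmcConfig()
    traits = traits or trial.trait_ids
    cells: list[MetricCell] = []
    for ti, trait in enumerate(traits):
        obs = trial.trait_observations(trait)
        envs = [e for e in trial.env_ids if (obs["env_id"] == e).any()]
        if len(envs) < 2:
            raise BenchError(f"trait {trait!r} needs >= 2 environments with observations")
        for ei, env in enumerate(envs):
            for mi, model_id in enumerate(models):
                child = int(
                    np.random.SeedSequence([seed, ti, ei, mi]).generate_state(1)[0] % (2**31 - 1)
                )
                asm = build_predictor(model_id, trial, trait, env, seed=child, selector=selector)
                fit = fit_predict(
                    asm.y_masked,
                    asm.kernel_terms,
                    asm.covariates,
                    replace(mcmc, seed=child),
                )
                cells.append(
                    evaluate_fold(asm, fit, obs, trait, env, model_id, normalization, dataset)
                )
    return cells


def evaluate_fold(
    asm: AssembledPredictor,
    fit: FitResult,
    obs: pd.DataFrame,
    trait: str,
    env: str,
    model_id: str,
    normalization: str = "mean",
    dataset: str = "synthetic",
) -> MetricCell:
    observed = obs["value"].to_numpy(dtype=float)[asm.test_mask]
    predicted = fit.predictions[asm.test_mask]
    cell_nrmse = nrmse(observed, predicted, normalization)
    cor, b0, b = cor_and_regression(observed, predicted)
    return MetricCell(
        trait=trait,
        env=env,
        model_id=model_id,
        nrmse=cell_nrmse,
        cor=cor,
        b0=b0,
        b=b,
        n_test=int(asm.test_mask.sum()),
        dataset=dataset,
    )


def _pairwise_wins(table: pd.DataFrame) -> pd.DataFrame:
    """Strict-win counts per model from a cells x models NRMSE table.

    Ties count as a win for neither model, so for every pair
    wins(m, m') + wins(m', m) + ties = number of cells.
    """
    models = list(table.columns)
    n_cells = len(table)
    wins = {}
    for m in models:
        w = 0
        for m2 in models:
            if m2 == m:
                continue
            w += int((table[m] < table[m2]).sum())
        wins[m] = w
    total = n_cells * (len(models) - 1)
    out = pd.DataFrame({"won": pd.Series(wins)})
    out["total"] = total
    out["pct"] = [win_percentage(w, total) if total > 0 else np.nan for w in out["won"]]
    out.index.name = "model_id"
    return out


def win_table(cells: list[MetricCell] | pd.DataFrame, baseline: str = "M0") -> ComparisonReport:
    """Aggregate MetricCells into the per-model summary and win counts.

    Environment-level wins compare NRMSE per (trait, env) cell;
    trait-level wins compare per-trait mean NRMSE. Aggregated
    NRMSE/Cor/b0/b are unweighted means over cells, and relative
    efficiencies are computed against ``baseline`` on those aggregates.
    """
    df = cells if isinstance(cells, pd.DataFrame) else pd.DataFrame([vars(c) for c in cells])
    models = sorted(df["model_id"].unique(), key=lambda m: (len(m), m))
    grid = df.pivot_table(index=["trait", "env"], columns="model_id", values="nrmse")
    if grid.isna().any().any():
        gaps = [
            (idx, m) for idx, row in grid.iterrows() for m in models if pd.isna(row.get(m))
        ]
        raise BenchError(f"cells do not cover the full (trait, env) x model grid; missing {gaps}")
    env_wins = _pairwise_wins(grid[models])
    trait_grid = df.pivot_table(index="trait", columns="model_id", values="nrmse", aggfunc="mean")
    trait_wins = _pairwise_wins(trait_grid[models])

    agg = df.groupby("model_id")[["nrmse", "cor", "b0", "b"]].mean().loc[models]
    summary = agg.copy()
    if baseline in agg.index:
        base = agg.loc[baseline]
        summary["re_nrmse"] = [
            relative_efficiency(base["nrmse"], v, "nrmse_like") for v in agg["nrmse"]
        ]
        summary["re_cor"] = [
            relative_efficiency(base["cor"], v, "cor_like") if base["cor"] != 0 else np.nan
            for v in agg["cor"]
        ]
        for col in ("b0", "b"):
            summary[f"re_{col}"] = [
                relative_efficiency(base[col], v, "nrmse_like") if v != 0 else np.nan
                for v in agg[col]
            ]
    return ComparisonReport(summary=summary, env_wins=env_wins, trait_wins=trait_wins, cells=df)
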