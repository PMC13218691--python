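"""Metrics, calibration, stratification, triage and study harnesses.

Covers the four regression metrics (Pearson, RMSE, R^2, MAE), a
coverage-based calibration error for Gaussian predictive distributions,
quantile stratification of individuals by predicted potential score
(top 20% / middle 60% / bottom 20%), uncertainty triage (median split on
total predictive variance plus a reject-the-top-10% setting), module
ablation and hyperparameter sensitivity harnesses, and an
ordinary-least-squares reference baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.linear_model import LinearRegression, Ridge

from .graph import SimilarityGraph, build_similarity
from .network import ModelSpec, forward, mc_predict
from .preprocess import ProcessedDataset
from .simulate import INDICATORS, SimulationConfig
from .training import LossWeights, TrainConfig, train


@dataclass
class MetricsReport:
    pearson: float           # NaN when undefined (zero variance)
    rmse: float
    r2: float
    mae: float
    n: int


@dataclass
class StratificationReport:
    table: pd.DataFrame      # rows top/middle/bottom; mean & sd columns
    sizes: dict[str, int]


@dataclass
class TriageReport:
    table: pd.DataFrame      # rows all/low/high/excluded; rmse & mae
    median_variance: float
    exclusion_threshold: float
    n_excluded: int


def regression_metrics(y: np.ndarray, mu: np.ndarray) -> MetricsReport:
    """Pearson r, RMSE, R^2 (about mean of y), MAE."""
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    if len(y) != len(mu) or len(y) < 2:
        raise ValueError("y and mu must be equal-length with n >= 2")
    resid = y - mu
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    if y.std() == 0 or mu.std() == 0:
        warnings.warn("zero variance in y or mu: Pearson undefined",
                      stacklevel=2)
        pearson = float("nan")
    else:
        pearson = float(spstats.pearsonr(y, mu)[0])
    return MetricsReport(pearson=pearson, rmse=rmse, r2=r2, mae=mae, n=len(y))


DEFAULT_CAL_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


def calibration_error(y: np.ndarray, mu: np.ndarray, var_total: np.ndarray,
                      grid: tuple[float, ...] = DEFAULT_CAL_GRID) -> float:
    """Mean absolute central-interval coverage gap.

    For each nominal level q, the empirical coverage is the fraction of
    observations inside the central q-interval of N(mu_i, var_i); the
    error averages |coverage - q| over the grid.  Zero in the
    infinite-sample limit for a perfectly calibrated model.
    """
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    var = np.asarray(var_total, dtype=float).ravel()
    if len(y) < 20:
        raise ValueError("calibration needs n >= 20")
    if np.any(var <= 0):
        raise ValueError("variances must be strictly positive")
    if len(grid) == 0:
        raise ValueError("empty calibration grid")
    sd = np.sqrt(var)
    absz = np.abs(y - mu) / sd
    errs = []
    for q in grid:
        half = spstats.norm.ppf(0.5 + q / 2.0)
        cov = float(np.mean(absz <= half))
        errs.append(abs(cov - q))
    return float(np.mean(errs))


def stratify_by_prediction(mu: np.ndarray, truth_table: pd.DataFrame
                           ) -> StratificationReport:
    """Rank by predicted score (descending, stable) and cut 20/60/20.

    ``truth_table`` must carry a ``true_score`` column and may carry the
    three standardized indicator columns.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    n = len(mu)
    if n < 10:
        raise ValueError("stratification needs n >= 10")
    if len(truth_table) != n:
        raise ValueError("truth table / prediction length mismatch")
    order = np.argsort(-mu, kind="stable")
    n_top = n_bot = int(0.2 * n)
    groups = {"top": order[:n_top],
              "middle": order[n_top:n - n_bot],
              "bottom": order[n - n_bot:]}
    cols = [c for c in ("true_score", *INDICATORS) if c in truth_table.columns]
    rows = []
    for name, idx in groups.items():
        sub = truth_table.iloc[idx]
        row = {"group": name, "n": len(idx)}
        for c in cols:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=1))
        rows.append(row)
    return StratificationReport(
        table=pd.DataFrame(rows).set_index("group"),
        sizes={k: len(v) for k, v in groups.items()})


def _errors(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    resid = y - mu
    return float(np.sqrt(np.mean(resid ** 2))), float(np.mean(np.abs(resid)))


def uncertainty_triage(y: np.ndarray, mu: np.ndarray,
                       var_total: np.ndarray) -> TriageReport:
    """Error by uncertainty group: median split + top-10% exclusion."""
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    var = np.asarray(var_total, dtype=float).ravel()
    n = len(y)
    if n < 20:
        raise ValueError("triage needs n >= 20")
    order = np.argsort(var, kind="stable")
    half = n // 2
    low, high = order[:half], order[half:]
    n_excl = int(0.1 * n)
    kept = order[: n - n_excl]

    rows = []
    for name, idx in (("all", np.arange(n)), ("low", low), ("high", high),
                      ("excluded_top10", kept)):
        rmse, mae = _errors(y[idx], mu[idx])
        rows.append({"setting": name, "n": len(idx), "rmse": rmse, "mae": mae})
    return TriageReport(
        table=pd.DataFrame(rows).set_index("setting"),
        median_variance=float(np.median(var)),
        exclusion_threshold=float(var[order[n - n_excl]]) if n_excl else math.inf,
        n_excluded=n_excl)


# ---------------------------------------------------------------------------
# OLS reference baseline
# ---------------------------------------------------------------------------

def ols_baseline(dataset: ProcessedDataset) -> MetricsReport:
    """Least-squares fit on train, metrics on test (ridge 1e-6 if d >= n)."""
    Xtr, ytr, _ = dataset.matrices_for("train")
    Xte, yte, _ = dataset.matrices_for("test")
    if Xtr.shape[1] >= Xtr.shape[0]:
        model = Ridge(alpha=1e-6)
    else:
        model = LinearRegression()
    model.fit(Xtr, ytr)
    return regression_metrics(yte, model.predict(Xte))


# ---------------------------------------------------------------------------
# Packaged benchmark
# ---------------------------------------------------------------------------

def benchmark_config(seed: int = 42) -> SimulationConfig:
    """The packaged benchmark cohort: n=2000, p=200, h^2=0.5, with the
    nonlinear (epistatic) and heteroscedastic components enabled."""
    return SimulationConfig(
        n_individuals=2000, n_markers=200, n_blocks=20,
        within_block_rho=0.5, n_causal=60, heritability=0.5,
        hetero_coeff=1.0, epistasis_frac=0.25,
        historical_noise_sd=0.5, seed=seed)


def prepare_benchmark(seed: int = 42, features: str = "genotype-only"
                      ) -> tuple[ProcessedDataset, SimilarityGraph, np.ndarray]:
    """Simulate + preprocess the benchmark; build the train-row graph."""
    from .preprocess import preprocess_cohort
    from .simulate import simulate_cohort
    cohort = simulate_cohort(benchmark_config(seed))
    ds = preprocess_cohort(cohort, seed=seed, features=features)
    Xtr = ds.matrices_for("train")[0][:, :ds.n_genotype_cols]
    graph = build_similarity(Xtr, k=10, h="median")
    # ground-truth noise SD aligned to the test rows, for triage fixtures
    id_to_sd = dict(zip(cohort.ids, cohort.true_noise_sd))
    test_sd = np.array([id_to_sd[i] for i in
                        np.asarray(ds.ids)[ds.rows_for("test")]])
    return ds, graph, test_sd


# ---------------------------------------------------------------------------
# Ablation and sensitivity harnesses
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = ("full", "no_manifold", "no_planner", "no_uncertainty",
                     "no_constraint")


def _weights_for_variant(base: LossWeights, variant: str) -> LossWeights:
    return LossWeights(
        lambda_manifold=0.0 if variant == "no_manifold" else base.lambda_manifold,
        lambda_reward=0.0 if variant == "no_planner" else base.lambda_reward,
        lambda_constraint=0.0 if variant == "no_constraint"
        else base.lambda_constraint)


def ablation_suite(dataset: ProcessedDataset, base_spec: ModelSpec,
                   weights: LossWeights, config: TrainConfig,
                   train_graph: SimilarityGraph | None = None,
                   seeds: tuple[int, ...] = (42, 43, 44, 45, 46),
                   variants: tuple[str, ...] = ABLATION_VARIANTS
                   ) -> pd.DataFrame:
    """Train full model + structural ablations with identical seeds.

    Returns one row per (variant, seed) with the four test metrics; the
    ``no_uncertainty`` variant carries no variance-derived entries.
    """
    from .training import evaluate_on_split
    rows = []
    for variant in variants:
        spec = ModelSpec(**{**base_spec.to_dict(), "variant": variant})
        w = _weights_for_variant(weights, variant)
        for s in seeds:
            cfg = TrainConfig(epochs=config.epochs,
                              batch_size=config.batch_size, lr=config.lr,
                              weight_decay=config.weight_decay, seed=s,
                              mc_passes=config.mc_passes)
            params, _ = train(dataset, spec, w, cfg, train_graph)
            metrics = evaluate_on_split(params, spec, dataset, "test",
                                        T=cfg.mc_passes, seed=s)
            rows.append({"variant": variant, "seed": s, **metrics})
    return pd.DataFrame(rows)


DEFAULT_SENSITIVITY_GRIDS = {
    "embed_dim": (64, 128, 256),
    "encoder_depth": (2, 3, 4),
    "lambda_manifold": (0.01, 0.1, 1.0),
    "feature_noise_sd": (0.0, 0.05, 0.1),
}

_DEPTH_DIMS = {2: (128, 64), 3: (256, 128, 64), 4: (256, 128, 128, 64)}


def sensitivity_suite(dataset: ProcessedDataset, base_spec: ModelSpec,
                      weights: LossWeights, config: TrainConfig,
                      train_graph: SimilarityGraph | None = None,
                      grids: dict | None = None) -> pd.DataFrame:
    """One row per configuration across the four sensitivity axes."""
    from .preprocess import inject_feature_noise
    from .training import evaluate_on_split
    grids = grids if grids is not None else dict(DEFAULT_SENSITIVITY_GRIDS)
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("sensitivity grids must be non-empty")

    rows = []
    for axis, values in grids.items():
        for value in values:
            spec, w, ds = base_spec, weights, dataset
            if axis == "embed_dim":
                spec = ModelSpec(**{**base_spec.to_dict(),
                                    "embed_dim": int(value)})
            elif axis == "encoder_depth":
                spec = ModelSpec(**{**base_spec.to_dict(),
                                    "encoder_dims": _DEPTH_DIMS[int(value)]})
            elif axis == "lambda_manifold":
                w = LossWeights(lambda_manifold=float(value),
                                lambda_reward=weights.lambda_reward,
                                lambda_constraint=weights.lambda_constraint)
            elif axis == "feature_noise_sd":
                if value > 0:
                    Xn = inject_feature_noise(dataset.X, float(value),
                                              seed=config.seed,
                                              n_genotype_cols=dataset.n_genotype_cols)
                    ds = ProcessedDataset(
                        X=Xn, y=dataset.y, ids=dataset.ids,
                        indicators=dataset.indicators, params=dataset.params,
                        split=dataset.split,
                        n_genotype_cols=dataset.n_genotype_cols)
            else:
                raise ValueError(f"unknown sensitivity axis '{axis}'")
            params, _ = train(ds, spec, w, config, train_graph)
            metrics = evaluate_on_split(params, spec, ds, "test",
                                        T=config.mc_passes, seed=config.seed)
            rows.append({"axis": axis, "value": value, **metrics})
    return pd.DataFrame(rows)


def full_report(params: dict[str, np.ndarray], spec: ModelSpec,
                dataset: ProcessedDataset, T: int = 20, seed: int = 0) -> dict:
    """Test-split metrics + calibration + triage + stratification."""
    Xte, yte, ind_te = dataset.matrices_for("test")
    out = mc_predict(params, spec, Xte, T=T, seed=seed)
    metrics = regression_metrics(yte, out.mu)
    cal = calibration_error(yte, out.mu, out.var_total)
    triage = uncertainty_triage(yte, out.mu, out.var_total)
    truth = pd.DataFrame(ind_te, columns=list(INDICATORS))
    truth.insert(0, "true_score", yte)
    strat = stratify_by_prediction(out.mu, truth)
    return {"metrics": metrics, "calibration_error": cal,
            "triage": triage, "stratification": strat,
            "predictive": out}
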