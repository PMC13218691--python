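"""Cohort cleaning, normalization, splitting and target construction.

Pipeline order is fixed: ID-duplicate removal -> missing-cell removal ->
three-standard-deviation outlier removal on the assessment indicators
(statistics computed once over the post-missing rows, sample SD, no
re-iteration).  Normalization parameters are fitted on the training
partition only: genotype columns are min–max mapped to [0,1], indicator
columns are z-scored, and the continuous potential score is the
re-standardized mean of the three z-scored assessment indicators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (CohortTable, HIST_COLUMNS, INDICATORS, MISSING_TOKEN)


class CohortParseError(ValueError):
    pass


@dataclass
class NormalizationParams:
    geno_min: pd.Series
    geno_max: pd.Series
    indicator_mean: pd.Series        # assessment + historical columns
    indicator_sd: pd.Series
    target_mean: float
    target_sd: float

    def constant_columns(self) -> list[str]:
        return [c for c in self.geno_min.index
                if self.geno_max[c] == self.geno_min[c]]

    def to_dict(self) -> dict:
        return {
            "geno_min": self.geno_min.to_dict(),
            "geno_max": self.geno_max.to_dict(),
            "indicator_mean": self.indicator_mean.to_dict(),
            "indicator_sd": self.indicator_sd.to_dict(),
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            geno_min=pd.Series(d["geno_min"]),
            geno_max=pd.Series(d["geno_max"]),
            indicator_mean=pd.Series(d["indicator_mean"]),
            indicator_sd=pd.Series(d["indicator_sd"]),
            target_mean=float(d["target_mean"]),
            target_sd=float(d["target_sd"]),
        )


@dataclass
class SplitIndex:
    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int

    def to_dict(self) -> dict:
        return {"train": list(self.train), "validation": list(self.validation),
                "test": list(self.test), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SplitIndex":
        return cls(train=list(d["train"]), validation=list(d["validation"]),
                   test=list(d["test"]), seed=int(d["seed"]))


@dataclass
class CleaningReport:
    n_input: int = 0
    n_duplicates: int = 0
    n_missing: int = 0
    n_outliers: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_duplicates - self.n_missing - self.n_outliers


@dataclass
class ProcessedDataset:
    """Model-ready dataset: features X, potential score y, metadata.

    ``X`` concatenates min–max-normalized genotype columns with (unless
    ``features='genotype-only'``) z-scored historical indicator columns.
    ``indicators`` holds the z-scored assessment-time indicators used as
    planner targets and in stratification reports.
    """

    X: pd.DataFrame
    y: np.ndarray
    ids: np.ndarray
    indicators: pd.DataFrame
    params: NormalizationParams
    split: SplitIndex
    n_genotype_cols: int
    removals: CleaningReport | None = None

    def rows_for(self, part: str) -> np.ndarray:
        wanted = set(getattr(self.split, part))
        return np.array([i for i, s in enumerate(self.ids) if s in wanted])

    def matrices_for(self, part: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = self.rows_for(part)
        return (self.X.to_numpy(dtype=float)[idx], self.y[idx],
                self.indicators.to_numpy(dtype=float)[idx])


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _check_header(path: Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen = set()
    for tok in header:
        if tok in seen:
            raise CohortParseError(
                f"duplicated header column '{tok}' in {path}")
        seen.add(tok)
    if "id" not in header:
        raise CohortParseError(f"no 'id' column in {path}")
    return header


def read_cohort(genotype_path: str | Path, phenotype_path: str | Path,
                truth_path: str | Path | None = None
                ) -> tuple[CohortTable, list[str]]:
    """Inner-join the two files on id; return the cohort and dropped IDs."""
    genotype_path, phenotype_path = Path(genotype_path), Path(phenotype_path)
    _check_header(genotype_path)
    _check_header(phenotype_path)
    geno = pd.read_csv(genotype_path, sep="\t", na_values=[MISSING_TOKEN],
                       keep_default_na=False, dtype={"id": str})
    pheno = pd.read_csv(phenotype_path, sep="\t", na_values=[MISSING_TOKEN],
                        keep_default_na=False, dtype={"id": str})
    for col in INDICATORS:
        if col not in pheno.columns:
            raise CohortParseError(f"phenotype file lacks column '{col}'")

    shared = [i for i in geno["id"] if i in set(pheno["id"])]
    if not shared:
        raise CohortParseError("no overlapping IDs between genotype and "
                               "phenotype files")
    dropped = sorted((set(geno["id"]) | set(pheno["id"])) - set(shared))

    # preserve genotype-file row order for shared ids; align phenotypes to it
    geno_kept = geno[geno["id"].isin(set(shared))].reset_index(drop=True)
    pheno_idx = pheno.drop_duplicates("id").set_index("id")
    pheno_kept = pheno_idx.loc[geno_kept["id"].drop_duplicates(), :]
    # duplicated genotype ids keep their rows; phenotype rows repeat accordingly
    pheno_aligned = pheno_idx.loc[geno_kept["id"], :].reset_index()

    ids = geno_kept["id"].to_numpy()
    genotypes = geno_kept.drop(columns="id").astype(float)
    hist_cols = [c for c in HIST_COLUMNS if c in pheno_aligned.columns]
    phenotypes = pheno_aligned[list(INDICATORS)].astype(float)
    if hist_cols:
        historical = pheno_aligned[hist_cols].astype(float)
    else:
        historical = pd.DataFrame(index=phenotypes.index)

    gvalue = noise_sd = None
    if truth_path is not None:
        truth = pd.read_csv(truth_path, sep="\t", dtype={"id": str})
        truth = truth.set_index("id").loc[ids]
        gvalue = truth["true_genetic_value"].to_numpy(dtype=float)
        noise_sd = truth["true_noise_sd"].to_numpy(dtype=float)

    cohort = CohortTable(ids=ids, genotypes=genotypes.reset_index(drop=True),
                         phenotypes=phenotypes.reset_index(drop=True),
                         historical=historical.reset_index(drop=True),
                         true_genetic_value=gvalue, true_noise_sd=noise_sd)
    _ = pheno_kept  # alignment check only
    return cohort, dropped


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clean_cohort(cohort: CohortTable) -> tuple[CohortTable, CleaningReport]:
    """Duplicates -> missing -> 3-SD outliers, in that fixed order."""
    report = CleaningReport(n_input=cohort.n)

    # 1. duplicate IDs: keep first occurrence
    ids = pd.Series(cohort.ids)
    dup_mask = ids.duplicated(keep="first").to_numpy()
    report.n_duplicates = int(dup_mask.sum())
    report.removed_ids["duplicates"] = list(ids[dup_mask].unique())
    keep = ~dup_mask
    cohort = _subset(cohort, keep)

    # 2. rows with any missing genotype or phenotype (incl. historical) cell
    miss = cohort.genotypes.isna().any(axis=1).to_numpy()
    miss |= cohort.phenotypes.isna().any(axis=1).to_numpy()
    if cohort.historical.shape[1] > 0:
        miss |= cohort.historical.isna().any(axis=1).to_numpy()
    report.n_missing = int(miss.sum())
    report.removed_ids["missing"] = list(cohort.ids[miss])
    cohort = _subset(cohort, ~miss)

    # 3. single-pass 3-sample-SD rule per assessment indicator
    out = np.zeros(cohort.n, dtype=bool)
    for col in INDICATORS:
        v = cohort.phenotypes[col].to_numpy(dtype=float)
        mean, sd = v.mean(), v.std(ddof=1) if len(v) > 1 else 0.0
        if sd > 0:
            out |= np.abs(v - mean) > 3.0 * sd
    report.n_outliers = int(out.sum())
    report.removed_ids["outliers"] = list(cohort.ids[out])
    cohort = _subset(cohort, ~out)

    if cohort.n == 0:
        raise ValueError("cohort is empty after cleaning")
    return cohort, report


def _subset(cohort: CohortTable, mask: np.ndarray) -> CohortTable:
    return CohortTable(
        ids=cohort.ids[mask],
        genotypes=cohort.genotypes.loc[mask].reset_index(drop=True),
        phenotypes=cohort.phenotypes.loc[mask].reset_index(drop=True),
        historical=cohort.historical.loc[mask].reset_index(drop=True),
        true_genetic_value=None if cohort.true_genetic_value is None
        else cohort.true_genetic_value[mask],
        true_noise_sd=None if cohort.true_noise_sd is None
        else cohort.true_noise_sd[mask],
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_cohort(ids: np.ndarray | list[str], seed: int) -> SplitIndex:
    """8:1:1 split at the individual level; remainder rows go to test."""
    ids = np.asarray(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 individuals to split 8:1:1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train, n_val = int(0.8 * n), int(0.1 * n)
    order = ids[perm]
    return SplitIndex(train=list(order[:n_train]),
                      validation=list(order[n_train:n_train + n_val]),
                      test=list(order[n_train + n_val:]),
                      seed=seed)


# ---------------------------------------------------------------------------
# Normalization and target
# ---------------------------------------------------------------------------

def fit_normalizers(cohort: CohortTable, split: SplitIndex) -> NormalizationParams:
    """Fit min–max (genotypes) and z-score (indicators) on the train rows."""
    train_mask = np.isin(cohort.ids, np.asarray(split.train))
    geno = cohort.genotypes.loc[train_mask]
    pheno = pd.concat([cohort.phenotypes, cohort.historical], axis=1).loc[train_mask]

    means, sds = {}, {}
    for col in pheno.columns:
        v = pheno[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"indicator '{col}' has zero variance on the "
                             "training split; cohort is degenerate")
        means[col], sds[col] = float(v.mean()), float(sd)

    # potential score statistics (train rows, from z-scored assessment cols)
    zcols = [(cohort.phenotypes[c].to_numpy(dtype=float)[train_mask] - means[c])
             / sds[c] for c in INDICATORS]
    raw = np.mean(np.column_stack(zcols), axis=1)
    t_sd = raw.std(ddof=1)
    if t_sd == 0:
        raise ValueError("potential score has zero variance on the training split")

    return NormalizationParams(
        geno_min=geno.min(), geno_max=geno.max(),
        indicator_mean=pd.Series(means), indicator_sd=pd.Series(sds),
        target_mean=float(raw.mean()), target_sd=float(t_sd),
    )


def normalize_genotypes(geno: pd.DataFrame, params: NormalizationParams
                        ) -> pd.DataFrame:
    span = (params.geno_max - params.geno_min).replace(0, np.nan)
    out = (geno - params.geno_min) / span
    return out.fillna(0.0)          # constant train columns map to 0


def zscore_indicators(table: pd.DataFrame, params: NormalizationParams
                      ) -> pd.DataFrame:
    cols = [c for c in table.columns if c in params.indicator_mean.index]
    return (table[cols] - params.indicator_mean[cols]) / params.indicator_sd[cols]


def build_target(cohort: CohortTable, params: NormalizationParams) -> np.ndarray:
    """Potential score: re-standardized mean of the three z-scored indicators."""
    z = zscore_indicators(cohort.phenotypes, params)
    raw = z[list(INDICATORS)].to_numpy(dtype=float).mean(axis=1)
    return (raw - params.target_mean) / params.target_sd


def apply_normalizers(cohort: CohortTable, params: NormalizationParams,
                      split: SplitIndex, features: str = "genotype+historical",
                      removals: CleaningReport | None = None) -> ProcessedDataset:
    if features not in ("genotype+historical", "genotype-only"):
        raise ValueError(f"unknown feature mode '{features}'")
    geno_norm = normalize_genotypes(cohort.genotypes, params)
    parts = [geno_norm]
    if features == "genotype+historical" and cohort.historical.shape[1] > 0:
        parts.append(zscore_indicators(cohort.historical, params))
    X = pd.concat(parts, axis=1)
    y = build_target(cohort, params)
    indicators = zscore_indicators(cohort.phenotypes, params)[list(INDICATORS)]
    return ProcessedDataset(X=X, y=y, ids=cohort.ids, indicators=indicators,
                            params=params, split=split,
                            n_genotype_cols=geno_norm.shape[1],
                            removals=removals)


def preprocess_cohort(cohort: CohortTable, seed: int,
                      features: str = "genotype+historical"
                      ) -> ProcessedDataset:
    """clean -> split -> fit on train -> apply, in one call."""
    cleaned, report = clean_cohort(cohort)
    split = split_cohort(cleaned.ids, seed)
    params = fit_normalizers(cleaned, split)
    return apply_normalizers(cleaned, params, split, features, removals=report)


def inject_feature_noise(X: pd.DataFrame, sd: float, seed: int,
                         n_genotype_cols: int | None = None) -> pd.DataFrame:
    """Add i.i.d. N(0, sd^2) to genotype feature columns only."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    out = X.copy()
    ncols = X.shape[1] if n_genotype_cols is None else n_genotype_cols
    noise = rng.normal(0.0, sd, size=(X.shape[0], ncols))
    out.iloc[:, :ncols] = out.iloc[:, :ncols].to_numpy(dtype=float) + noise
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_processed(ds: ProcessedDataset, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = ds.X.copy()
    X.insert(0, "id", ds.ids)
    X.to_csv(out_dir / "X.tsv", sep="\t", index=False)
    pd.DataFrame({"id": ds.ids, "y": ds.y}).to_csv(
        out_dir / "y.tsv", sep="\t", index=False)
    ind = ds.indicators.copy()
    ind.insert(0, "id", ds.ids)
    ind.to_csv(out_dir / "indicators.tsv", sep="\t", index=False)
    meta = ds.params.to_dict()
    meta["n_genotype_cols"] = ds.n_genotype_cols
    with open(out_dir / "norm_params.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    with open(out_dir / "split.json", "w") as fh:
        json.dump(ds.split.to_dict(), fh, indent=1)
    with open(out_dir / "removals.log", "w") as fh:
        if ds.removals is None:
            fh.write("no cleaning report\n")
        else:
            r = ds.removals
            fh.write(f"input rows\t{r.n_input}\n")
            fh.write(f"duplicates removed\t{r.n_duplicates}\n")
            fh.write(f"missing removed\t{r.n_missing}\n")
            fh.write(f"outliers removed\t{r.n_outliers}\n")
            for rule, idlist in r.removed_ids.items():
                for rid in idlist:
                    fh.write(f"{rule}\t{rid}\n")


def read_processed(out_dir: str | Path) -> ProcessedDataset:
    out_dir = Path(out_dir)
    X = pd.read_csv(out_dir / "X.tsv", sep="\t", dtype={"id": str})
    ids = X["id"].to_numpy()
    X = X.drop(columns="id")
    y = pd.read_csv(out_dir / "y.tsv", sep="\t", dtype={"id": str})["y"].to_numpy()
    ind = pd.read_csv(out_dir / "indicators.tsv", sep="\t",
                      dtype={"id": str}).drop(columns="id")
    with open(out_dir / "norm_params.json") as fh:
        meta = json.load(fh)
    n_geno = int(meta.pop("n_genotype_cols"))
    params = NormalizationParams.from_dict(meta)
    with open(out_dir / "split.json") as fh:
        split = SplitIndex.from_dict(json.load(fh))
    return ProcessedDataset(X=X, y=y, ids=ids, indicators=ind, params=params,
                            split=split, n_genotype_cols=n_geno)
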