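"""Synthetic genotype–phenotype cohort simulator.

Generates cohorts with the statistical structure a polygenic prediction
framework assumes: LD-correlated dosage markers, an additive polygenic
signal shared across three physical-capability indicators (speed,
endurance, strength), optional heteroscedastic observation noise, an
earlier "historical" noisy measurement of each indicator, and injectable
data defects (duplicates, missing cells, planted outliers) for exercising
the cleaning pipeline.

Linkage disequilibrium is emulated by block-equicorrelated latent
Gaussians thresholded to dosages under Hardy–Weinberg proportions: within
a block every pair of latent variables shares correlation ``rho``, and
each marker's latent value is cut at the quantiles of its own allele
frequency so the marginal dosage distribution is Binomial(2, f).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

INDICATORS = ("speed", "endurance", "strength")
HIST_COLUMNS = tuple(f"hist_{c}" for c in INDICATORS)
MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort generator.

    Defaults describe the study conditions the package targets: a cohort
    of 5,000 individuals, 500 dosage markers in 50 LD blocks, moderate
    within-block correlation, 100 causal markers, heritability 0.5, one
    common genetic factor shared by all three indicators, mild
    heteroscedasticity, and historical records that are noisy earlier
    versions of the assessment-time indicators.
    """

    n_individuals: int = 5000
    n_markers: int = 500
    n_blocks: int = 50
    within_block_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 100
    heritability: float = 0.5
    shared_factor_loading: float = 1.0
    hetero_coeff: float = 0.5
    historical_noise_sd: float = 0.5
    epistasis_frac: float = 0.0
    defect_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_markers <= 0 or self.n_blocks <= 0:
            raise ValueError("n_individuals, n_markers and n_blocks must be positive")
        if self.n_blocks > self.n_markers:
            raise ValueError("n_blocks must not exceed n_markers")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.n_causal <= self.n_markers):
            raise ValueError("n_causal must lie in (0, n_markers]")
        if not (0.0 <= self.heritability <= 1.0):
            raise ValueError("heritability must lie in [0, 1]")
        if not (0.0 <= self.shared_factor_loading <= 1.0):
            raise ValueError("shared_factor_loading must lie in [0, 1]")
        if self.hetero_coeff < 0 or self.historical_noise_sd < 0:
            raise ValueError("hetero_coeff and historical_noise_sd must be >= 0")
        if not (0.0 <= self.epistasis_frac <= 1.0):
            raise ValueError("epistasis_frac must lie in [0, 1]")
        for r in self.defect_rates:
            if not (0.0 <= r < 1.0):
                raise ValueError("defect rates must lie in [0, 1)")


@dataclass
class CohortTable:
    """Row-aligned genotype + phenotype cohort.

    All blocks are aligned on ``ids``.  ``true_genetic_value`` and
    ``true_noise_sd`` are simulator ground truth (per-individual genetic
    value on the common-factor scale, and the observation-noise SD used
    for the indicators); they are hidden from models and only consumed by
    evaluation code.
    """

    ids: np.ndarray
    genotypes: pd.DataFrame            # n x p dosages, id-free
    phenotypes: pd.DataFrame           # columns speed/endurance/strength
    historical: pd.DataFrame           # columns hist_*
    true_genetic_value: np.ndarray | None = None
    true_noise_sd: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def copy(self) -> "CohortTable":
        return CohortTable(
            ids=self.ids.copy(),
            genotypes=self.genotypes.copy(),
            phenotypes=self.phenotypes.copy(),
            historical=self.historical.copy(),
            true_genetic_value=None if self.true_genetic_value is None
            else self.true_genetic_value.copy(),
            true_noise_sd=None if self.true_noise_sd is None
            else self.true_noise_sd.copy(),
        )


@dataclass
class DefectManifest:
    """Record of every planted defect (and nothing else)."""

    duplicate_ids: list[str] = field(default_factory=list)
    missing_genotype_cells: list[tuple[int, int]] = field(default_factory=list)
    missing_phenotype_cells: list[tuple[int, str]] = field(default_factory=list)
    outlier_cells: list[tuple[int, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.duplicate_ids or self.missing_genotype_cells
                    or self.missing_phenotype_cells or self.outlier_cells)


def _block_sizes(p: int, n_blocks: int) -> np.ndarray:
    """Near-equal contiguous block sizes summing to p."""
    base = p // n_blocks
    sizes = np.full(n_blocks, base, dtype=int)
    sizes[: p % n_blocks] += 1
    return sizes


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw an n x p dosage matrix with block-LD structure.

    Returns the dosage matrix (entries in {0,1,2}) and a marker metadata
    table (marker name, block index, allele frequency).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_markers
    sizes = _block_sizes(p, config.n_blocks)
    rho = config.within_block_rho
    lo, hi = config.maf_range

    freqs = rng.uniform(lo, hi, size=p)
    dosages = np.empty((n, p), dtype=np.int8)
    blocks = np.empty(p, dtype=int)

    col = 0
    for b, size in enumerate(sizes):
        # equicorrelated latent Gaussians: sqrt(rho)*shared + sqrt(1-rho)*own
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, size))
        latent = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own
        f = freqs[col:col + size]
        # Hardy-Weinberg cut points on the latent scale
        t0 = stats.norm.ppf((1.0 - f) ** 2)
        t1 = stats.norm.ppf((1.0 - f) ** 2 + 2.0 * f * (1.0 - f))
        d = np.zeros((n, size), dtype=np.int8)
        d[latent >= t0] = 1
        d[latent >= t1] = 2
        dosages[:, col:col + size] = d
        blocks[col:col + size] = b
        col += size

    markers = pd.DataFrame({
        "marker": [f"m{j:05d}" for j in range(p)],
        "block": blocks,
        "allele_freq": freqs,
    })
    return dosages, markers


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def simulate_phenotypes(genotypes: np.ndarray, config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the three indicators, historical records, and ground truth.

    The genetic value is additive over ``n_causal`` markers (plus an
    optional pairwise-product component carrying ``epistasis_frac`` of
    the genetic variance).  Each indicator combines a common genetic
    factor with an indicator-specific one (weight ``shared_factor_loading``
    on the variance scale) and is rescaled so that
    Var(genetic)/Var(total) equals the configured heritability.  Noise is
    heteroscedastic: SD_i = base_sd * (1 + hetero_coeff * z_i) with z_i a
    min-max-scaled dosage score on a designated marker subset.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, p = genotypes.shape
    h2 = config.heritability
    lam = config.shared_factor_loading

    # causal markers spread uniformly across the marker axis (hence blocks)
    causal = np.linspace(0, p - 1, config.n_causal).round().astype(int)
    causal = np.unique(causal)
    Xc = genotypes[:, causal].astype(float)

    def additive_factor() -> np.ndarray:
        beta = rng.standard_normal(len(causal))
        return _standardize(Xc @ beta)

    common = additive_factor()
    if config.epistasis_frac > 0:
        # rank-one pairwise epistasis: the square of the additive score
        # expands to beta_j*beta_k x_j x_k product terms.  Epistatic
        # variance is orthogonal to additive variance by definition, so
        # the additive direction is projected out before mixing.
        epi = _standardize(common ** 2)
        epi = _standardize(epi - (epi @ common / (common @ common)) * common)
        ef = config.epistasis_frac
        common = _standardize(math.sqrt(1 - ef) * common + math.sqrt(ef) * epi)

    # heteroscedastic driver: min-max scaled dosage sum on the last markers
    subset = genotypes[:, max(0, p - 10):].astype(float).sum(axis=1)
    rngmin, rngmax = subset.min(), subset.max()
    z = np.zeros(n) if rngmax == rngmin else (subset - rngmin) / (rngmax - rngmin)
    scale = 1.0 + config.hetero_coeff * z
    # base_sd chosen so the mean noise variance is (1 - h2)
    mean_sq = float(np.mean(scale ** 2))
    base_sd = math.sqrt((1.0 - h2) / mean_sq) if h2 < 1.0 else 0.0
    noise_sd = base_sd * scale

    pheno = {}
    for name in INDICATORS:
        specific = additive_factor()
        genetic = math.sqrt(lam) * common + math.sqrt(1.0 - lam) * specific
        genetic = _standardize(genetic) * math.sqrt(h2)
        noise = rng.standard_normal(n) * noise_sd
        pheno[name] = genetic + noise
    phenotypes = pd.DataFrame(pheno)

    hist = {}
    for name in INDICATORS:
        hist[f"hist_{name}"] = (phenotypes[name].to_numpy()
                                + rng.standard_normal(n) * config.historical_noise_sd)
    historical = pd.DataFrame(hist)

    true_genetic_value = _standardize(common) * math.sqrt(h2)
    return phenotypes, historical, true_genetic_value, noise_sd


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Full deterministic cohort draw: genotypes, phenotypes, truth."""
    rng = np.random.default_rng(config.seed)
    genotypes, markers = simulate_genotypes(config, rng)
    phenotypes, historical, gvalue, noise_sd = simulate_phenotypes(
        genotypes, config, rng)
    n = config.n_individuals
    ids = np.array([f"id{i:06d}" for i in range(n)])
    geno_df = pd.DataFrame(genotypes.astype(float),
                           columns=markers["marker"].tolist())
    cohort = CohortTable(ids=ids, genotypes=geno_df, phenotypes=phenotypes,
                         historical=historical, true_genetic_value=gvalue,
                         true_noise_sd=noise_sd)
    if any(r > 0 for r in config.defect_rates):
        cohort, _ = inject_data_defects(cohort, config)
    return cohort


def inject_data_defects(cohort: CohortTable, config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[CohortTable, DefectManifest]:
    """Plant duplicates, missing cells and outliers; return a manifest.

    Appends floor(dup_rate*n) exact duplicate rows (same ID), blanks
    floor(miss_rate*n*p) genotype cells and floor(miss_rate*n*3)
    phenotype cells, and replaces floor(outlier_rate*n) phenotype values
    with column mean + 10*SD.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    dup_rate, miss_rate, out_rate = config.defect_rates
    manifest = DefectManifest()
    out = cohort.copy()
    n, p = out.genotypes.shape

    n_dup = int(dup_rate * n)
    if n_dup > 0:
        rows = rng.choice(n, size=n_dup, replace=False)
        out.ids = np.concatenate([out.ids, out.ids[rows]])
        out.genotypes = pd.concat(
            [out.genotypes, out.genotypes.iloc[rows]], ignore_index=True)
        out.phenotypes = pd.concat(
            [out.phenotypes, out.phenotypes.iloc[rows]], ignore_index=True)
        out.historical = pd.concat(
            [out.historical, out.historical.iloc[rows]], ignore_index=True)
        if out.true_genetic_value is not None:
            out.true_genetic_value = np.concatenate(
                [out.true_genetic_value, out.true_genetic_value[rows]])
        if out.true_noise_sd is not None:
            out.true_noise_sd = np.concatenate(
                [out.true_noise_sd, out.true_noise_sd[rows]])
        manifest.duplicate_ids = list(cohort.ids[rows])

    n_miss_g = int(miss_rate * n * p)
    if n_miss_g > 0:
        flat = rng.choice(n * p, size=n_miss_g, replace=False)
        gv = out.genotypes.to_numpy(dtype=float)
        for idx in flat:
            i, j = divmod(int(idx), p)
            gv[i, j] = np.nan
            manifest.missing_genotype_cells.append((i, j))
        out.genotypes = pd.DataFrame(gv, columns=out.genotypes.columns)

    n_miss_p = int(miss_rate * n * 3)
    if n_miss_p > 0:
        flat = rng.choice(n * 3, size=n_miss_p, replace=False)
        for idx in flat:
            i, j = divmod(int(idx), 3)
            col = INDICATORS[j]
            out.phenotypes.iloc[i, out.phenotypes.columns.get_loc(col)] = np.nan
            manifest.missing_phenotype_cells.append((i, col))

    n_out = int(out_rate * n)
    if n_out > 0:
        rows = rng.choice(n, size=n_out, replace=False)
        for i in rows:
            col = INDICATORS[int(rng.integers(3))]
            series = out.phenotypes[col]
            extreme = float(series.mean() + 10.0 * series.std(ddof=1))
            out.phenotypes.iloc[int(i), out.phenotypes.columns.get_loc(col)] = extreme
            manifest.outlier_cells.append((int(i), col))

    return out, manifest


# ---------------------------------------------------------------------------
# Persistence: plain TSV with "NA" as the missing sentinel
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, out_dir: str | Path) -> dict[str, Path]:
    """Write genotypes.tsv, phenotypes.tsv and (if present) truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    geno = cohort.genotypes.copy()
    geno.insert(0, "id", cohort.ids)
    paths["genotypes"] = out_dir / "genotypes.tsv"
    geno.to_csv(paths["genotypes"], sep="\t", index=False, na_rep=MISSING_TOKEN)

    pheno = pd.concat([cohort.phenotypes, cohort.historical], axis=1)
    pheno.insert(0, "id", cohort.ids)
    paths["phenotypes"] = out_dir / "phenotypes.tsv"
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, na_rep=MISSING_TOKEN)

    if cohort.true_genetic_value is not None:
        truth = pd.DataFrame({
            "id": cohort.ids,
            "true_genetic_value": cohort.true_genetic_value,
            "true_noise_sd": cohort.true_noise_sd,
        })
        paths["truth"] = out_dir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False, na_rep=MISSING_TOKEN)
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["maf_range"] = list(d["maf_range"])
    d["defect_rates"] = list(d["defect_rates"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    if "defect_rates" in d:
        d["defect_rates"] = tuple(d["defect_rates"])
    return SimulationConfig(**d)
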