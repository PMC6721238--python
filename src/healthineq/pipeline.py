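"""End-to-end orchestration: validate, impute, rank, index, decompose.

The full analysis mirrors a standard concentration-index study of survey
micro-data: validate the input against the data dictionary, fit a per-stratum
interval regression to replace banded income with continuous predictions,
equivalise with the modified OECD scale and rescale to base-year prices,
compute weighted fractional ranks and Erreygers-corrected concentration
indices, compare indices across survey waves, and decompose each stratum's
inequality into covariate contributions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .concentration import compare_indices, weighted_fractional_rank
from .decomposition import ErreygersDecomposition
from .design import CATEGORIES, MODEL_COLUMNS, build_design, build_income_design
from .income import IntervalIncomeRegressor, equivalise_income, load_cpi_table
from .synthetic import DEFAULT_BAND_BOUNDS

__all__ = [
    "AnalysisConfig",
    "StratumResult",
    "load_and_validate",
    "descriptive_summary",
    "chi_square_test",
    "impute_equivalised_income",
    "analyze_stratum",
    "run_full_analysis",
]

logger = logging.getLogger("healthineq")

# variables cross-tabulated against outpatient use in the descriptive table
_DESCRIPTIVE_VARS = [
    "sex", "married_ever", "age_group", "education", "self_rated_health",
    "chronic_disease", "mobility_difficulty", "depress", "exercise_2wk",
    "region", "physician_band",
]


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    input_path: str
    output_dir: str
    strata: list = field(default_factory=lambda: [
        ("female", 2005), ("female", 2009), ("male", 2005), ("male", 2009)])
    variable_map: dict = field(default_factory=dict)
    income_band_bounds: tuple = DEFAULT_BAND_BOUNDS
    cpi_table_path: str | None = None
    cpi: dict = field(default_factory=dict)
    base_year: int = 2009
    cesd_cutoff: int = 10
    income_floor: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "income_band_bounds" in raw:
            raw["income_band_bounds"] = tuple(
                (float(lo), float(hi)) for lo, hi in raw["income_band_bounds"])
        if "strata" in raw:
            raw["strata"] = [(s, int(yr)) for s, yr in raw["strata"]]
        return cls(**raw)

    def cpi_lookup(self) -> dict[int, float]:
        if self.cpi:
            return {int(k): float(v) for k, v in self.cpi.items()}
        if self.cpi_table_path:
            return load_cpi_table(self.cpi_table_path)
        return {}

    def cpi_ratio(self, year: int) -> float:
        cpi = self.cpi_lookup()
        if not cpi:
            return 1.0
        if self.base_year not in cpi:
            raise ValueError(f"base_year {self.base_year} missing from CPI table")
        if year not in cpi:
            raise ValueError(f"survey year {year} missing from CPI table")
        return cpi[self.base_year] / cpi[year]


def load_and_validate(source, variable_map: dict | None = None) -> pd.DataFrame:
    """Load micro-data, enforce the data dictionary, listwise-delete missing.

    ``source`` is a CSV path or a DataFrame.  ``variable_map`` renames input
    columns (canonical name -> column name in the file).  Rows missing any
    model variable are dropped with a logged per-variable count, recorded in
    ``df.attrs['missing_counts']``.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if variable_map:
        df = df.rename(columns={v: k for k, v in variable_map.items()})
    missing_cols = [c for c in MODEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input is missing required columns: {missing_cols}")

    missing_counts = {}
    for col in MODEL_COLUMNS:
        n_miss = int(df[col].isna().sum())
        if n_miss:
            missing_counts[col] = n_miss
            logger.warning("column %r: %d missing values, rows listwise-deleted",
                           col, n_miss)
    before = len(df)
    df = df.dropna(subset=MODEL_COLUMNS).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no rows remain after listwise deletion")
    if before != len(df):
        logger.info("listwise deletion removed %d of %d rows", before - len(df), before)

    for col, allowed in CATEGORIES.items():
        if df[col].dtype.kind in "fi" and all(isinstance(a, int) for a in allowed):
            df[col] = df[col].astype(int)
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"column {col!r}, row {row}: illegal category {df[col].iloc[row]!r}; "
                f"allowed: {allowed}")
    for col in ("cesd_score", "household_adults", "household_children"):
        df[col] = df[col].astype(int)
    if (df["weight"] <= 0).any():
        raise ValueError("weights must be positive")
    if (df["household_adults"] < 1).any():
        raise ValueError("household_adults must be at least 1")
    df.attrs["missing_counts"] = missing_counts
    return df


def chi_square_test(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    table = np.asarray(counts, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def descriptive_summary(table: pd.DataFrame, year: int | None = None,
                        cesd_cutoff: int = 10, weighted: bool = False) -> pd.DataFrame:
    """Cross-tabulations of each covariate against outpatient use.

    Returns one row per variable category with (weighted or unweighted)
    counts, row percentages, and the variable-level Pearson chi-square
    statistic without continuity correction.
    """
    df = table if year is None else table[table["year"] == year]
    if len(df) == 0:
        raise ValueError(f"no records for year {year}")
    df = df.copy()
    df["depress"] = (df["cesd_score"] >= cesd_cutoff).astype(int)
    w = df["weight"].to_numpy() if weighted else np.ones(len(df))

    rows = []
    for var in _DESCRIPTIVE_VARS:
        cats = CATEGORIES.get(var, [0, 1])
        counts = np.zeros((len(cats), 2))
        for i, cat in enumerate(cats):
            in_cat = (df[var] == cat).to_numpy()
            for j, used in enumerate((1, 0)):
                counts[i, j] = w[in_cat & (df["outpatient_use"] == used).to_numpy()].sum()
        chi2, p = chi_square_test(counts)
        for i, cat in enumerate(cats):
            total = counts[i].sum()
            rows.append({
                "variable": var, "category": str(cat),
                "n_use": counts[i, 0], "n_nouse": counts[i, 1],
                "pct_use": 100.0 * counts[i, 0] / total if total else float("nan"),
                "pct_nouse": 100.0 * counts[i, 1] / total if total else float("nan"),
                "chi_square": chi2, "p_value": p,
            })
    return pd.DataFrame(rows)


@dataclass
class StratumResult:
    """All fitted objects for one (sex, year) stratum."""

    stratum: tuple
    n: int
    income_fit: IntervalIncomeRegressor
    equivalised_income: np.ndarray
    decomposition: ErreygersDecomposition

    @property
    def concentration(self):
        return self.decomposition.concentration_result_


def impute_equivalised_income(df: pd.DataFrame, band_bounds=DEFAULT_BAND_BOUNDS,
                              income_floor: float = 1.0, cpi_ratio: float = 1.0):
    """Interval regression on banded income, equivalised and price-adjusted.

    Returns ``(equivalised_income, fitted_regressor)``; the income design is
    age group, education and region.  Predictions condition on the observed
    band (truncated-normal mean), so within-band income information is kept.
    """
    bounds = np.array([band_bounds[b - 1] for b in df["income_band"]])
    X = build_income_design(df)
    fit = IntervalIncomeRegressor(income_floor=income_floor)
    fit.fit(X, bounds, sample_weight=df["weight"].to_numpy())
    income = fit.predict_conditional(X, bounds)
    equivalised = equivalise_income(income, df["household_adults"],
                                    df["household_children"])
    return equivalised * cpi_ratio, fit


def analyze_stratum(df: pd.DataFrame, band_bounds=DEFAULT_BAND_BOUNDS,
                    cesd_cutoff: int = 10, income_floor: float = 1.0,
                    cpi_ratio: float = 1.0, stratum=("all", None)) -> StratumResult:
    """Impute income, rank, and decompose inequality for one stratum."""
    w = df["weight"].to_numpy()
    equiv, income_fit = impute_equivalised_income(
        df, band_bounds, income_floor=income_floor, cpi_ratio=cpi_ratio)
    lpinco = np.log(np.maximum(equiv, income_floor))
    ranks = weighted_fractional_rank(equiv, w)
    X = build_design(df, lpinco, cesd_cutoff=cesd_cutoff)
    dec = ErreygersDecomposition().fit(
        X, df["outpatient_use"].to_numpy(), sample_weight=w, ranks=ranks)
    return StratumResult(stratum=stratum, n=len(df), income_fit=income_fit,
                         equivalised_income=np.asarray(equiv), decomposition=dec)


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full_analysis(config: AnalysisConfig) -> dict[str, Path]:
    """Run every stage and write the output tables; deterministic given seed.

    Outputs: ``table1_descriptives.csv``, ``table2_indices.csv``, one
    ``table3_decomposition_<sex>_<year>.csv`` per stratum, and ``run.log``.
    All results are computed before anything is written, so a failing stage
    leaves no partial outputs.
    """
    out_dir = Path(config.output_dir)
    df = load_and_validate(config.input_path, config.variable_map or None)

    years = sorted({yr for _, yr in config.strata})
    sexes = sorted({s for s, _ in config.strata})
    for sex, year in config.strata:
        if sex not in CATEGORIES["sex"] or year not in set(df["year"]):
            raise ValueError(f"unknown stratum {(sex, year)!r} for this input")

    descriptives = pd.concat(
        [descriptive_summary(df, year, config.cesd_cutoff).assign(year=year)
         for year in years], ignore_index=True)

    results: dict[tuple, StratumResult] = {}
    for sex, year in config.strata:
        sub = df[(df["sex"] == sex) & (df["year"] == year)].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"stratum {(sex, year)!r} is empty")
        logger.info("analyzing stratum sex=%s year=%s (n=%d)", sex, year, len(sub))
        results[(sex, year)] = analyze_stratum(
            sub, config.income_band_bounds, cesd_cutoff=config.cesd_cutoff,
            income_floor=config.income_floor, cpi_ratio=config.cpi_ratio(year),
            stratum=(sex, year))

    index_rows = []
    for sex in sexes:
        strata_years = [yr for s, yr in config.strata if s == sex]
        if len(strata_years) == 2:
            y0, y1 = sorted(strata_years)
            a = results[(sex, y0)].concentration
            b = results[(sex, y1)].concentration
            cmp_ = compare_indices(a, b)
            index_rows.append({
                "sex": sex,
                f"index_{y0}": a.corrected_value, f"se_{y0}": a.standard_error,
                f"index_{y1}": b.corrected_value, f"se_{y1}": b.standard_error,
                "difference": cmp_.difference, "difference_se": cmp_.difference_se,
                "z": cmp_.z_statistic, "p_value": cmp_.p_value,
            })
    indices = pd.DataFrame(index_rows)

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    p = out_dir / "table1_descriptives.csv"
    descriptives.to_csv(p, index=False)
    outputs["descriptives"] = p
    p = out_dir / "table2_indices.csv"
    indices.to_csv(p, index=False)
    outputs["indices"] = p
    for (sex, year), res in results.items():
        p = out_dir / f"table3_decomposition_{sex}_{year}.csv"
        table = res.decomposition.table_.copy()
        table["total_corrected_ci"] = res.decomposition.total_corrected_ci_
        table["residual"] = res.decomposition.residual_
        table.to_csv(p, index=False)
        outputs[f"decomposition_{sex}_{year}"] = p

    log_path = out_dir / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config_hash: {_config_hash(config)}\n")
        fh.write(f"n_input: {len(df)}\n")
        fh.write(f"missing_counts: {df.attrs.get('missing_counts', {})}\n")
        fh.write(f"numpy: {np.__version__}, pandas: {pd.__version__}\n")
        for (sex, year), res in results.items():
            c = res.concentration
            fh.write(f"stratum ({sex}, {year}): n={res.n} "
                     f"E={c.corrected_value:.6f} se={c.standard_error:.6f} "
                     f"income_converged={res.income_fit.converged_} "
                     f"probit_converged={res.decomposition.probit_.converged_}\n")
    outputs["log"] = log_path
    return outputs
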