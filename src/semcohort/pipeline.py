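"""Staged analysis pipeline over a cohort table.

Stages, in order: preprocess (log transform + complete cases), age
partial-correlation check, selenium/age quotient, three-factor CFA, full
second-order structural model, per-arm 48-month factor-score change
tests, cardiovascular-age regression, and the selenium-quartile
mortality test. Each stage emits a structured report carrying the seed
and config hash of the cohort it consumed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import (ARM_ACTIVE, ARM_NONE, ARM_PLACEBO, GeneratorConfig,
                     simulate_baseline, simulate_cohort, simulate_mortality)
from .errors import DataError, NumericDomainError
from .modelspecs import BIOMARKERS, cfa_model_text, structural_model_text
from .sem import CovMatrix, FitResult, factor_scores, fit, indirect_effects
from .sem.model import parse_model

_FIRST_ORDER = ("inflammation", "oxidative_stress", "fibrosis")


@dataclass
class StageReport:
    stage: str
    n: int
    statistics: dict
    seed: int | None = None
    config_hash: str | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"stage": self.stage, "n": self.n, "seed": self.seed,
                "config_hash": self.config_hash,
                "statistics": _jsonable(self.statistics),
                "warnings": list(self.warnings)}


@dataclass
class ContingencyTable2x2:
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    counts: np.ndarray  # 2x2, non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise DataError("contingency table must be 2x2 and non-negative")

    @property
    def margins(self) -> tuple[np.ndarray, np.ndarray]:
        return self.counts.sum(axis=1), self.counts.sum(axis=0)


def config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ----------------------------------------------------------------------
# stage 0: preprocessing
# ----------------------------------------------------------------------
def preprocess(cohort: pd.DataFrame) -> tuple[pd.DataFrame, StageReport]:
    """Natural-log transform of all biomarker concentrations plus
    selenium (as ``log_selenium``); listwise deletion of incomplete
    rows. Raises on non-positive concentrations, naming the row."""
    required = ["age_years", "selenium_ugL", *BIOMARKERS]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")
    table = cohort.copy()
    n_before = len(table)
    table = table.dropna(subset=required)
    for col in (*BIOMARKERS, "selenium_ugL"):
        bad = table.index[table[col] <= 0]
        if len(bad):
            raise DataError(
                f"non-positive concentration in column {col!r}, "
                f"row {int(bad[0])}")
    for col in BIOMARKERS:
        table[col] = np.log(table[col].astype(float))
    table["log_selenium"] = np.log(table["selenium_ugL"].astype(float))
    report = StageReport("preprocess", len(table), {
        "rows_in": n_before, "rows_dropped": n_before - len(table),
        "log_transformed": [*BIOMARKERS, "selenium_ugL->log_selenium"],
    })
    return table, report


# ----------------------------------------------------------------------
# stage 1: age partial-correlation check
# ----------------------------------------------------------------------
def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z."""
    denom = math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise NumericDomainError("degenerate correlation with covariate")
    return (r_xy - r_xz * r_yz) / denom


def _corr_p(r: float, n: int) -> float:
    r = min(max(r, -0.999999999), 0.999999999)
    t = r * math.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(abs(t), n - 2)


def age_partial_adjustment(table: pd.DataFrame,
                           variables: list[str] | None = None,
                           alpha: float = 0.05
                           ) -> tuple[pd.DataFrame, pd.DataFrame,
                                      float, StageReport]:
    """Raw vs age-partialled biomarker correlation matrices and the
    share of pairs whose sign and significance status (two-sided
    ``alpha``) are unchanged after partialling out age."""
    variables = list(variables) if variables else list(BIOMARKERS)
    if "age_years" not in table.columns:
        raise DataError("age_years column required")
    n = len(table)
    if n <= 3:
        raise DataError("need more than 3 rows")
    sub = table[variables + ["age_years"]].astype(float)
    if np.any(sub.std(axis=0).to_numpy() == 0):
        raise DataError("constant column in correlation input")
    corr = sub.corr().to_numpy()
    r = corr[:-1, :-1]
    rz = corr[:-1, -1]

    denom = np.sqrt(np.outer(1.0 - rz**2, 1.0 - rz**2))
    rp = (r - np.outer(rz, rz)) / denom
    np.fill_diagonal(rp, 1.0)

    k = len(variables)
    unchanged = 0
    total = 0
    for i in range(k):
        for j in range(i + 1, k):
            total += 1
            sig_raw = _corr_p(r[i, j], n) < alpha
            sig_par = _corr_p(rp[i, j], n - 1) < alpha
            same_sign = np.sign(r[i, j]) == np.sign(rp[i, j])
            if sig_raw == sig_par and (same_sign or not (sig_raw or sig_par)):
                unchanged += 1
    percent = 100.0 * unchanged / total
    raw = pd.DataFrame(r, index=variables, columns=variables)
    adj = pd.DataFrame(rp, index=variables, columns=variables)
    report = StageReport("age_partial_adjustment", n, {
        "percent_unchanged": percent, "pairs": total, "alpha": alpha})
    return raw, adj, percent, report


# ----------------------------------------------------------------------
# stage 2: selenium/age quotient
# ----------------------------------------------------------------------
def sel_age_quotient(table: pd.DataFrame
                     ) -> tuple[pd.DataFrame, StageReport]:
    """Add ``sel_age`` = selenium / age (raw scales) and report its
    correlations with selenium and age."""
    for col in ("selenium_ugL", "age_years"):
        if col not in table.columns:
            raise DataError(f"missing column {col!r}")
    if (table["age_years"] <= 0).any():
        raise DataError("non-positive age")
    out = table.copy()
    out["sel_age"] = out["selenium_ugL"] / out["age_years"]
    if out["selenium_ugL"].std() == 0:
        corr_sel = 1.0
    else:
        corr_sel = float(np.corrcoef(out["sel_age"],
                                     out["selenium_ugL"])[0, 1])
    corr_age = float(np.corrcoef(out["sel_age"], out["age_years"])[0, 1]) \
        if out["age_years"].std() > 0 else 0.0
    report = StageReport("sel_age_quotient", len(out), {
        "corr_with_selenium": corr_sel, "corr_with_age": corr_age})
    return out, report


# ----------------------------------------------------------------------
# stage 3/4: CFA and structural model
# ----------------------------------------------------------------------
def run_cfa_stage(table: pd.DataFrame, seed: int = 0) -> FitResult:
    """Three-factor CFA (correlated factors) on the 12 multi-indicator
    log biomarkers of the baseline occasion."""
    base = _baseline_slice(table)
    spec = parse_model(cfa_model_text())
    S = CovMatrix.from_data(base, list(spec.manifest_names))
    return fit(spec, S, n=len(base), seed=seed)


def run_sem_stage(table: pd.DataFrame, seed: int = 0) -> FitResult:
    """Full second-order structural model; requires the ``sel_age``
    quotient column (stage order is enforced)."""
    if "sel_age" not in table.columns:
        raise DataError("sel_age column missing: run sel_age_quotient "
                        "before the structural-model stage")
    base = _baseline_slice(table)
    spec = parse_model(structural_model_text())
    S = CovMatrix.from_data(base, list(spec.manifest_names))
    return fit(spec, S, n=len(base), seed=seed)


def _baseline_slice(table: pd.DataFrame) -> pd.DataFrame:
    if "occasion_months" in table.columns:
        return table[table["occasion_months"] == 0]
    return table


# ----------------------------------------------------------------------
# stage 5: arm-wise 48-month change tests
# ----------------------------------------------------------------------
def paired_t(differences: np.ndarray) -> tuple[float, float, int]:
    """Paired t statistic, two-sided p and n from per-subject paired
    differences."""
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise DataError("need at least two paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0, n
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p), n


def arm_change_tests(cohort: pd.DataFrame, fit_result: FitResult
                     ) -> tuple[dict, StageReport]:
    """Per-arm, per-factor paired t tests on factor-score differences
    (baseline minus 48 months, so an increase over time gives a negative
    T). Scores at both occasions come from the baseline-fitted model
    centered at baseline means."""
    if "occasion_months" not in cohort.columns:
        raise DataError("occasion_months column required")
    table, _ = preprocess(cohort)
    if "sel_age" in fit_result.spec.manifest_names \
            and "sel_age" not in table.columns:
        table, _ = sel_age_quotient(table)
    base = table[table["occasion_months"] == 0].set_index("subject_id")
    follow = table[table["occasion_months"] == 48].set_index("subject_id")
    common = base.index.intersection(follow.index)
    warnings = []
    dropped = (len(base) - len(common)) + (len(follow) - len(common))
    if dropped:
        warnings.append(f"{dropped} unmatched subject rows excluded")
    base, follow = base.loc[common], follow.loc[common]

    cols = [c for c in fit_result.spec.manifest_names if c in base.columns]
    center = base[cols].mean()
    # own-indicator scores: full-model Thomson weights mix highly
    # correlated factors, which would smear one factor's arm shift into
    # the others' change tests
    scores0 = factor_scores(fit_result, base, center=center,
                            own_indicators=True)
    scores1 = factor_scores(fit_result, follow, center=center,
                            own_indicators=True)

    results: dict[str, dict[str, dict]] = {}
    factor_names = [f for f, inds in fit_result.spec.factors
                    if len(inds) >= 2]
    for arm in sorted(set(base["arm"]) - {ARM_NONE}):
        mask = base["arm"] == arm
        results[arm] = {}
        for fac in factor_names:
            diff = (scores0.loc[mask.to_numpy(), fac].to_numpy()
                    - scores1.loc[mask.to_numpy(), fac].to_numpy())
            t, p, n_pairs = paired_t(diff)
            results[arm][fac] = {"t": t, "p": p, "n": n_pairs,
                                 "mean_change": float(-diff.mean())}
    report = StageReport("arm_change_tests", len(common),
                         {"results": results}, warnings=warnings)
    return results, report


# ----------------------------------------------------------------------
# stage 6: cardiovascular-age regression
# ----------------------------------------------------------------------
def cv_age_predictor(intercept: float, coef_selenium: float,
                     coef_ntprobnp: float, scale: str = "log"):
    """Pure predictor ``cv_age(selenium, ntprobnp)`` for given
    coefficients; ``scale`` in {raw, log} states how the two inputs are
    transformed before applying the linear form."""
    if scale not in ("raw", "log"):
        raise DataError(f"unknown scale {scale!r}")

    def predict(selenium, ntprobnp):
        s = np.log(selenium) if scale == "log" else np.asarray(selenium,
                                                               dtype=float)
        b = np.log(ntprobnp) if scale == "log" else np.asarray(ntprobnp,
                                                               dtype=float)
        return intercept + coef_selenium * s + coef_ntprobnp * b

    return predict


def cv_age_regression(table: pd.DataFrame, scale: str = "log"
                      ) -> tuple[dict, StageReport]:
    """OLS of age on selenium and NT-proBNP (log scale by default, per
    the preprocessing convention), with t statistics, the ANOVA block
    and a reusable predictor."""
    base = _baseline_slice(table)
    for col in ("age_years", "ntprobnp"):
        if col not in base.columns:
            raise DataError(f"missing column {col!r}")
    if scale == "log":
        sel = base["log_selenium"] if "log_selenium" in base.columns \
            else np.log(base["selenium_ugL"])
        # after preprocess() the ntprobnp column is already on log scale
        nt = base["ntprobnp"].astype(float)
    else:
        sel = base["selenium_ugL"].astype(float)
        nt = base["ntprobnp"].astype(float)
    design = pd.DataFrame({"const": 1.0, "selenium": sel, "ntprobnp": nt})
    y = base["age_years"].astype(float)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise DataError("rank-deficient design matrix")
    model = sm.OLS(y.to_numpy(), design.to_numpy()).fit()
    perfect = bool(model.ssr < 1e-12 * max(model.ess, 1.0))
    fitted = model.fittedvalues
    corr = float(np.corrcoef(y, fitted)[0, 1]) if np.std(fitted) > 0 else 0.0
    coefs = dict(zip(design.columns, model.params))
    stats_block = {
        "coefficients": coefs,
        "t_values": dict(zip(design.columns, model.tvalues)),
        "p_values": dict(zip(design.columns, model.pvalues)),
        "anova": {"f": float("inf") if perfect else float(model.fvalue),
                  "mean_square": float(model.mse_model),
                  "p": 0.0 if perfect else float(model.f_pvalue),
                  "perfect_fit": perfect},
        "corr_age_cv_age": corr,
        "scale": scale,
    }
    report = StageReport("cv_age_regression", int(model.nobs),
                         dict(stats_block))
    predictor = cv_age_predictor(coefs["const"], coefs["selenium"],
                                 coefs["ntprobnp"], scale=scale)
    stats_block["predictor"] = predictor
    return stats_block, report


# ----------------------------------------------------------------------
# stage 7: quartile mortality test
# ----------------------------------------------------------------------
def pearson_chi2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2
    table: sum over cells of (O - E)^2 / E."""
    obs = table.counts
    row, col = table.margins
    total = obs.sum()
    if total <= 0 or np.any(row == 0) or np.any(col == 0):
        raise NumericDomainError("degenerate contingency table")
    expected = np.outer(row, col) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def quartile_mortality_test(cohort: pd.DataFrame
                            ) -> tuple[ContingencyTable2x2, float, float,
                                       StageReport]:
    """Lowest vs highest baseline selenium quartile by 5-year CV death;
    Pearson chi-square with 1 df, no continuity correction."""
    base = _baseline_slice(cohort)
    for col in ("selenium_ugL", "cv_death_5y"):
        if col not in base.columns:
            raise DataError(f"missing column {col!r}")
    base = base.dropna(subset=["cv_death_5y"])
    n = len(base)
    if n < 8:
        raise DataError("need at least 8 subjects for quartiles")
    sel = base["selenium_ugL"].to_numpy()
    death = base["cv_death_5y"].to_numpy().astype(int)
    order = np.argsort(sel, kind="stable")
    quart = np.empty(n, dtype=int)
    quart[order] = (np.arange(n) * 4) // n
    counts = np.zeros((2, 2))
    for q, row in ((0, 0), (3, 1)):
        mask = quart == q
        if not mask.any():
            raise DataError(f"empty selenium quartile {q}")
        counts[row, 0] = death[mask].sum()
        counts[row, 1] = mask.sum() - death[mask].sum()
    table = ContingencyTable2x2(("lowest_quartile", "highest_quartile"),
                                ("cv_death", "survived"), counts)
    chi2, p = pearson_chi2(table)
    report = StageReport("quartile_mortality_test", n, {
        "counts": counts.astype(int).tolist(), "chi2": chi2, "p": p,
        "deaths_low": int(counts[0, 0]), "n_low": int(counts[0].sum()),
        "deaths_high": int(counts[1, 0]), "n_high": int(counts[1].sum())})
    return table, chi2, p, report


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------
def run_full_pipeline(config: GeneratorConfig) -> dict:
    """Execute every stage in order on a freshly simulated cohort and
    return an ordered, JSON-serializable report."""
    chash = config_hash(config)

    def stamp(report: StageReport) -> dict:
        report.seed = config.seed
        report.config_hash = chash
        return report.to_dict()

    stages: list[dict] = []
    cohort = simulate_cohort(config)
    stages.append(stamp(StageReport("simulate", len(cohort), {
        "mode": config.mode, "subjects": int(config.n_subjects)})))

    table, rep = preprocess(cohort[cohort["occasion_months"] == 0])
    stages.append(stamp(rep))

    _, _, percent, rep = age_partial_adjustment(table)
    stages.append(stamp(rep))

    table, rep = sel_age_quotient(table)
    stages.append(stamp(rep))

    cfa = run_cfa_stage(table, seed=config.seed)
    stages.append(stamp(StageReport("cfa", cfa.n, cfa.to_report())))

    sem_fit = run_sem_stage(table, seed=config.seed)
    sem_stats = sem_fit.to_report()
    if sem_fit.converged:
        sem_stats["indirect_effects"] = {
            target: indirect_effects(sem_fit, "sel_age", target).total
            for target in ("inflammation", "oxidative_stress", "fibrosis",
                           "myocardium")}
    stages.append(stamp(StageReport("sem", sem_fit.n, sem_stats)))

    if config.mode == "rct":
        changes, rep = arm_change_tests(cohort, sem_fit)
        stages.append(stamp(rep))

    cv_stats, rep = cv_age_regression(table)
    cv_stats = {k: v for k, v in cv_stats.items() if k != "predictor"}
    stages.append(stamp(rep))

    if config.mode == "rct":
        import dataclasses
        obs_config = dataclasses.replace(config, mode="observational")
        obs = simulate_baseline(obs_config)
        obs = simulate_mortality(obs_config, obs)
    else:
        obs = cohort
    _, chi2, p, rep = quartile_mortality_test(obs)
    stages.append(stamp(rep))

    return {"seed": config.seed, "config_hash": chash,
            "stages": stages}
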