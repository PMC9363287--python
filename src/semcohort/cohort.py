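"""Seeded synthetic-cohort generator.

Produces per-subject, per-occasion biomarker panels with the latent
structure the analysis pipeline assumes: three first-order factors plus
a single-indicator myocardium factor, a second-order
inflammation/oxidative-stress factor driven by the standardized
selenium/age quotient, age links on a configurable subset of markers,
autoregressive 48-month follow-up with arm shifts, and a binary 5-year
cardiovascular-death endpoint (per-arm rates in RCT mode, selenium-
quartile rates in observational mode).

All randomness flows from ``GeneratorConfig.seed`` through disjoint
``numpy`` generator streams, so a given config reproduces byte-identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .modelspecs import BIOMARKERS, FACTOR_INDICATORS, structural_model_text
from .sem.model import ModelSpec, parse_model
from .sem.params import ParameterSet, build_template

ARM_ACTIVE = "active"
ARM_PLACEBO = "placebo"
ARM_NONE = "none"

COHORT_COLUMNS = (
    "subject_id", "arm", "occasion_months", "age_years", "selenium_ugL",
    *BIOMARKERS, "cv_death_5y",
)

_FIRST_ORDER = ("inflammation", "oxidative_stress", "fibrosis", "myocardium")

_DEFAULT_SCALES = {
    "tnfr1": (7.6, 0.35), "tnfr2": (7.8, 0.40), "opg": (6.2, 0.35),
    "opn": (4.0, 0.45), "copeptin": (2.1, 0.60), "mrproadm": (-0.3, 0.30),
    "endostatin": (4.1, 0.30), "galectin3": (2.8, 0.35),
    "timp1": (4.6, 0.30), "cathepsin_s": (3.0, 0.35), "gdf15": (7.2, 0.55),
    "mmp1": (2.3, 0.70), "ntprobnp": (5.8, 1.10),
}


@dataclass
class GeneratorConfig:
    """Fully explicit, seeded parameterization of the synthetic cohort."""

    seed: int = 0
    mode: str = "rct"  # rct | observational
    n_active: int = 221
    n_placebo: int = 222
    n_observational: int = 668

    # standardized structural coefficients
    sel_to_io: float = -0.29
    io_to_fib: float = 0.74
    io_to_myo: float = 0.65
    second_order: dict = field(default_factory=lambda: {
        "inflammation": 0.80, "oxidative_stress": 0.98})
    construct_reliability: dict = field(default_factory=lambda: {
        "inflammation": 0.63, "oxidative_stress": 0.70, "fibrosis": 0.63})

    # demographics and exposure marginals
    age_mean: float = 77.1
    age_sd: float = 3.5
    age_min: float = 70.0
    age_max: float = 88.0
    selenium_mean: float = 67.1
    # chosen so the selenium/age quotient correlates ~0.84 with selenium
    # and ~-0.64 with age, as the analysis expects
    selenium_sd: float = 4.0
    selenium_age_corr: float = -0.13

    # target observed correlations with age per marker
    age_links: dict = field(default_factory=lambda: {
        "tnfr1": 0.25, "opn": 0.22, "copeptin": 0.18, "gdf15": 0.30,
        "endostatin": 0.18, "ntprobnp": 0.37})

    # 48-month dynamics
    retest_rho: dict = field(default_factory=lambda: {
        "inflammation": 0.57, "oxidative_stress": 0.67, "fibrosis": 0.76,
        "myocardium": 0.70})
    arm_effects: dict = field(default_factory=lambda: {
        "placebo": {"inflammation": 0.28, "oxidative_stress": 0.22,
                    "fibrosis": 0.0, "myocardium": 0.0},
        "active": {"inflammation": -0.25, "oxidative_stress": 0.0,
                   "fibrosis": -0.45, "myocardium": -0.20}})

    # 5-year mortality
    mortality_rate_active: float = 0.059
    mortality_rate_placebo: float = 0.126
    mortality_rate_quartile_low: float = 29 / 107
    mortality_rate_quartile_high: float = 16 / 111

    biomarker_scales: dict = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 _DEFAULT_SCALES.items()})
    keep_latents: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.mode not in ("rct", "observational"):
            raise ConfigError(f"mode: unknown mode {self.mode!r}")
        for key in ("mortality_rate_active", "mortality_rate_placebo",
                    "mortality_rate_quartile_low",
                    "mortality_rate_quartile_high"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key}: rate {v} outside [0, 1]")
        for fac, rho in self.retest_rho.items():
            if fac not in _FIRST_ORDER:
                raise ConfigError(f"retest_rho.{fac}: unknown factor")
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"retest_rho.{fac}: {rho} outside (-1, 1)")
        for fac, cr in self.construct_reliability.items():
            if not 0.0 < cr < 1.0:
                raise ConfigError(
                    f"construct_reliability.{fac}: {cr} outside (0, 1)")
        for marker in self.age_links:
            if marker not in BIOMARKERS:
                raise ConfigError(f"age_links.{marker}: unknown biomarker")
        for marker in self.biomarker_scales:
            if marker not in BIOMARKERS:
                raise ConfigError(
                    f"biomarker_scales.{marker}: unknown biomarker")
        missing = [m for m in BIOMARKERS if m not in self.biomarker_scales]
        if missing:
            raise ConfigError(f"biomarker_scales: missing markers {missing}")
        if self.age_min >= self.age_max:
            raise ConfigError("age_min must be below age_max")
        if self.age_sd <= 0 or self.selenium_sd <= 0:
            raise ConfigError("dispersions must be positive")
        if not -1.0 < self.selenium_age_corr < 1.0:
            raise ConfigError("selenium_age_corr outside (-1, 1)")
        for arm, effects in self.arm_effects.items():
            if arm not in (ARM_ACTIVE, ARM_PLACEBO):
                raise ConfigError(f"arm_effects.{arm}: unknown arm")
            for fac in effects:
                if fac not in _FIRST_ORDER:
                    raise ConfigError(f"arm_effects.{arm}.{fac}: unknown "
                                      "factor")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        import dataclasses
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict | None) -> "GeneratorConfig":
        raw = dict(raw or {})
        defaults = cls()
        known = set(defaults.to_dict())
        unknown = [k for k in raw if k not in known]
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        merged = defaults.to_dict()
        for key, value in raw.items():
            base = merged[key]
            if isinstance(base, dict):
                if not isinstance(value, dict):
                    raise ConfigError(f"{key}: expected a mapping")
                sub = dict(base)
                for k2, v2 in value.items():
                    if isinstance(sub.get(k2), dict):
                        sub[k2] = {**sub[k2], **v2}
                    else:
                        sub[k2] = v2
                merged[key] = sub
            else:
                if base is not None and not isinstance(
                        value, (type(base), int, float, bool, str)):
                    raise ConfigError(f"{key}: type mismatch")
                merged[key] = value
        return cls(**merged)

    def with_total_n(self, n: int) -> "GeneratorConfig":
        """Copy of this config scaled to ``n`` subjects (split evenly
        across arms in RCT mode)."""
        if self.mode == "rct":
            return replace(self, n_active=n // 2, n_placebo=n - n // 2)
        return replace(self, n_observational=n)

    @property
    def n_subjects(self) -> int:
        if self.mode == "rct":
            return self.n_active + self.n_placebo
        return self.n_observational


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------
def calibrate_loadings(cr_target: float, k: int) -> float:
    """Equal standardized loading reproducing a composite reliability
    ``cr_target`` over ``k`` indicators: lambda^2 = CR / (k (1-CR) + CR)."""
    if not 0.0 < cr_target < 1.0:
        raise ConfigError(f"construct reliability {cr_target} outside (0, 1)")
    if k < 2:
        raise ConfigError("need at least two indicators")
    return math.sqrt(cr_target / (k * (1.0 - cr_target) + cr_target))


def _indicator_loadings(config: GeneratorConfig) -> dict[str, float]:
    lam: dict[str, float] = {}
    for fac, inds in FACTOR_INDICATORS.items():
        if len(inds) == 1:
            lam[inds[0]] = 1.0
            continue
        value = calibrate_loadings(config.construct_reliability[fac],
                                   len(inds))
        for ind in inds:
            lam[ind] = value
    return lam


def build_generating_parameters(config: GeneratorConfig
                                ) -> tuple[ModelSpec, ParameterSet]:
    """Standardized generating parameter set for the full structural
    model; every latent has unit variance (disturbances are one minus the
    explained variance) and indicator cores have unit variance."""
    spec = parse_model(structural_model_text())
    params = build_template(spec)
    man_idx = {name: i for i, name in enumerate(spec.manifest_names)}
    lat_idx = {name: j for j, name in enumerate(spec.latent_names)}

    lam = _indicator_loadings(config)
    params.lam[:] = 0.0
    for fac, inds in FACTOR_INDICATORS.items():
        for ind in inds:
            params.lam[man_idx[ind], lat_idx[fac]] = lam[ind]
    params.lam[man_idx["sel_age"], lat_idx["sel_age"]] = 1.0

    params.beta[:] = 0.0
    for fac, weight in config.second_order.items():
        params.beta[lat_idx[fac], lat_idx["infl_ox"]] = weight
    params.beta[lat_idx["infl_ox"], lat_idx["sel_age"]] = config.sel_to_io
    params.beta[lat_idx["fibrosis"], lat_idx["infl_ox"]] = config.io_to_fib
    params.beta[lat_idx["myocardium"], lat_idx["infl_ox"]] = config.io_to_myo

    explained = {
        "infl_ox": config.sel_to_io ** 2,
        "inflammation": config.second_order["inflammation"] ** 2,
        "oxidative_stress": config.second_order["oxidative_stress"] ** 2,
        "fibrosis": config.io_to_fib ** 2,
        "myocardium": config.io_to_myo ** 2,
    }
    params.psi[:] = 0.0
    params.psi[lat_idx["sel_age"], lat_idx["sel_age"]] = 1.0
    for name, expl in explained.items():
        if expl >= 1.0:
            raise ConfigError(
                f"explained variance of {name} is {expl:.3f} >= 1; "
                "coefficients incompatible with unit latent variances")
        params.psi[lat_idx[name], lat_idx[name]] = 1.0 - expl

    for ind in BIOMARKERS:
        params.theta[man_idx[ind]] = 1.0 - lam[ind] ** 2
    params.theta[man_idx["sel_age"]] = 0.0
    return spec, params


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------
def _truncnorm_moments(config: GeneratorConfig) -> tuple[float, float]:
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    mean, var = stats.truncnorm.stats(a, b, loc=config.age_mean,
                                      scale=config.age_sd, moments="mv")
    return float(mean), float(np.sqrt(var))


def simulate_baseline(config: GeneratorConfig,
                      n: int | None = None) -> pd.DataFrame:
    """Baseline (occasion 0) cohort.

    Latents are driven by the standardized selenium/age quotient; age
    links are injected through the component of standardized age that is
    orthogonal to the quotient, so the exogenous structural path stays
    uncontaminated while observed marker-age correlations hit their
    configured targets.
    """
    if n is not None:
        config = config.with_total_n(n)
    n_sub = config.n_subjects
    rng = np.random.default_rng([config.seed, 11])

    if config.mode == "rct":
        arms = np.array([ARM_ACTIVE] * config.n_active
                        + [ARM_PLACEBO] * config.n_placebo)
        arms = rng.permutation(arms)
    else:
        arms = np.full(n_sub, ARM_NONE)

    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean,
                              scale=config.age_sd, size=n_sub,
                              random_state=rng)
    tmean, tsd = _truncnorm_moments(config)
    z_age = (age - tmean) / tsd

    r_sa = config.selenium_age_corr
    selenium = (config.selenium_mean + config.selenium_sd
                * (r_sa * z_age
                   + math.sqrt(1.0 - r_sa**2) * rng.standard_normal(n_sub)))
    selenium = np.maximum(selenium, 1.0)

    quotient = selenium / age
    z_q = (quotient - quotient.mean()) / quotient.std()
    rho_qa = float(np.corrcoef(z_q, z_age)[0, 1])
    z_perp = (z_age - rho_qa * z_q) / math.sqrt(1.0 - rho_qa**2)

    # latent layer (all unit variance by construction); the myocardium
    # factor is assembled below because its disturbance lives in the
    # joint unique-component vector
    psi_io = 1.0 - config.sel_to_io**2
    io = config.sel_to_io * z_q \
        + math.sqrt(psi_io) * rng.standard_normal(n_sub)

    factors: dict[str, np.ndarray] = {}
    for fac in ("inflammation", "oxidative_stress"):
        w = config.second_order[fac]
        factors[fac] = (w * io + math.sqrt(1.0 - w**2)
                        * rng.standard_normal(n_sub))
    factors["fibrosis"] = (config.io_to_fib * io
                           + math.sqrt(1.0 - config.io_to_fib**2)
                           * rng.standard_normal(n_sub))

    c_vec, l_chol = _unique_mixer(config, factors, io, z_age, rho_qa)
    w_draws = rng.standard_normal((n_sub, len(BIOMARKERS)))
    uniques = np.outer(z_perp, c_vec) + w_draws @ l_chol.T

    nt_pos = BIOMARKERS.index("ntprobnp")
    factors["myocardium"] = config.io_to_myo * io + uniques[:, nt_pos]

    lam = _indicator_loadings(config)
    cores: dict[str, np.ndarray] = {}
    for fac, inds in FACTOR_INDICATORS.items():
        for ind in inds:
            if ind == "ntprobnp":
                cores[ind] = factors["myocardium"]
            else:
                j = BIOMARKERS.index(ind)
                cores[ind] = lam[ind] * factors[fac] + uniques[:, j]

    data = {
        "subject_id": np.arange(1, n_sub + 1),
        "arm": arms,
        "occasion_months": np.zeros(n_sub, dtype=int),
        "age_years": age,
        "selenium_ugL": selenium,
    }
    for marker in BIOMARKERS:
        mu, sd = config.biomarker_scales[marker]
        data[marker] = np.exp(mu + sd * cores[marker])
    data["cv_death_5y"] = pd.array([pd.NA] * n_sub, dtype="Int64")
    frame = pd.DataFrame(data)

    if config.keep_latents:
        frame["_z_age"] = z_age
        frame["_z_q"] = z_q
        frame["_z_perp"] = z_perp
        frame["_f_infl_ox"] = io
        for fac in _FIRST_ORDER:
            frame[f"_f_{fac}"] = factors[fac]
        for j, marker in enumerate(BIOMARKERS):
            frame[f"_w_{marker}"] = w_draws[:, j]
    return frame


def _unique_mixer(config: GeneratorConfig, factors: dict[str, np.ndarray],
                  io: np.ndarray, z_age: np.ndarray, rho_qa: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Age coefficients ``c`` and mixing Cholesky ``L`` for the joint
    unique-component vector (measurement errors of the multi-indicator
    markers plus the myocardium disturbance).

    Each unique component is ``c_j z_perp + (L w)_j`` with total
    covariance exactly ``diag(unique variances)``: the shared age
    component is cancelled by negatively correlated noise (L L' =
    D - c c'), so observed marker-age correlations hit their targets
    while the marker covariance matrix keeps the pure factor structure.
    """
    lam = _indicator_loadings(config)
    kappa = math.sqrt(1.0 - rho_qa**2)  # corr(z_perp, z_age)
    rho_io_age = float(np.corrcoef(io, z_age)[0, 1])

    marker_factor = {ind: fac for fac, inds in FACTOR_INDICATORS.items()
                     for ind in inds}
    c_vec = np.zeros(len(BIOMARKERS))
    d_vec = np.empty(len(BIOMARKERS))
    for j, marker in enumerate(BIOMARKERS):
        fac = marker_factor[marker]
        if marker == "ntprobnp":
            d_vec[j] = 1.0 - config.io_to_myo**2
            rho_fa = config.io_to_myo * rho_io_age
            lam_j = 1.0
        else:
            d_vec[j] = 1.0 - lam[marker] ** 2
            rho_fa = float(np.corrcoef(factors[fac], z_age)[0, 1])
            lam_j = lam[marker]
        if marker in config.age_links:
            c_vec[j] = (config.age_links[marker]
                        - lam_j * rho_fa) / kappa
    mixing = np.diag(d_vec) - np.outer(c_vec, c_vec)
    try:
        l_chol = np.linalg.cholesky(mixing)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("age links too strong: unique-component "
                          "covariance not positive definite") from exc
    return c_vec, l_chol


def simulate_followup(config: GeneratorConfig,
                      baseline: pd.DataFrame) -> pd.DataFrame:
    """48-month follow-up: factor autoregression eta2 = rho eta1 +
    sqrt(1-rho^2) innovation + arm shift, with indicator unique errors
    autoregressed at the same factor-specific rho so factor-score
    test-retest correlations match the configured rho."""
    required = ([f"_f_{fac}" for fac in _FIRST_ORDER]
                + [f"_w_{m}" for m in BIOMARKERS]
                + ["_z_age", "_z_q", "_z_perp", "_f_infl_ox"])
    missing = [c for c in required if c not in baseline.columns]
    if missing:
        raise DataError("baseline table lacks generator state columns "
                        f"{missing}; regenerate with keep_latents=True")
    if baseline["subject_id"].duplicated().any():
        raise DataError("duplicate subject ids in baseline table")
    n_sub = len(baseline)
    rng = np.random.default_rng([config.seed, 22])

    z_age = baseline["_z_age"].to_numpy()
    z_q = baseline["_z_q"].to_numpy()
    z_perp = baseline["_z_perp"].to_numpy()
    rho_qa = float(np.corrcoef(z_q, z_age)[0, 1])
    arms = baseline["arm"].to_numpy()

    io = baseline["_f_infl_ox"].to_numpy()
    factors1 = {fac: baseline[f"_f_{fac}"].to_numpy()
                for fac in _FIRST_ORDER}
    c_vec, l_chol = _unique_mixer(config, factors1, io, z_age, rho_qa)

    factors2: dict[str, np.ndarray] = {}
    for fac in _FIRST_ORDER:
        rho = config.retest_rho[fac]
        shift = np.zeros(n_sub)
        for arm, effects in config.arm_effects.items():
            shift[arms == arm] = effects.get(fac, 0.0)
        factors2[fac] = (rho * factors1[fac]
                         + math.sqrt(1.0 - rho**2)
                         * rng.standard_normal(n_sub) + shift)

    # unique components autoregress at the factor-specific rho so that
    # factor-score retest correlations track the configured values
    w1 = np.column_stack([baseline[f"_w_{m}"].to_numpy()
                          for m in BIOMARKERS])
    marker_factor = {ind: fac for fac, inds in FACTOR_INDICATORS.items()
                     for ind in inds}
    rho_vec = np.array([config.retest_rho[marker_factor[m]]
                        for m in BIOMARKERS])
    w2 = (rho_vec[None, :] * w1
          + np.sqrt(1.0 - rho_vec**2)[None, :]
          * rng.standard_normal((n_sub, len(BIOMARKERS))))
    uniques2 = np.outer(z_perp, c_vec) + w2 @ l_chol.T

    lam = _indicator_loadings(config)
    cores2: dict[str, np.ndarray] = {}
    for fac, inds in FACTOR_INDICATORS.items():
        for ind in inds:
            if ind == "ntprobnp":
                cores2[ind] = factors2["myocardium"]
            else:
                j = BIOMARKERS.index(ind)
                cores2[ind] = lam[ind] * factors2[fac] + uniques2[:, j]

    frame = baseline[["subject_id", "arm", "age_years",
                      "selenium_ugL"]].copy()
    frame.insert(2, "occasion_months", 48)
    for marker in BIOMARKERS:
        mu, sd = config.biomarker_scales[marker]
        frame[marker] = np.exp(mu + sd * cores2[marker])
    frame["cv_death_5y"] = baseline["cv_death_5y"].to_numpy()
    if config.keep_latents:
        for fac in _FIRST_ORDER:
            frame[f"_f_{fac}"] = factors2[fac]
    return frame.reset_index(drop=True)


def score_retest_correlations(config: GeneratorConfig,
                              baseline: pd.DataFrame,
                              followup: pd.DataFrame) -> dict[str, float]:
    """Per-factor test-retest correlations of own-indicator regression
    factor scores on the log scale.

    Full-model Thomson scores blend in persistent cross-factor and
    exogenous components and therefore overstate retest stability; this
    diagnostic scores each multi-indicator factor from its own
    indicators only.
    """
    out: dict[str, float] = {}
    for fac, inds in FACTOR_INDICATORS.items():
        if len(inds) < 2:
            continue
        yb = np.log(baseline[list(inds)].to_numpy(dtype=float))
        yf = np.log(followup[list(inds)].to_numpy(dtype=float))
        s = np.cov(yb, rowvar=False)
        lam = calibrate_loadings(config.construct_reliability[fac],
                                 len(inds))
        cov_ey = lam * np.sqrt(np.diag(s))
        w = np.linalg.solve(s, cov_ey)
        sb = (yb - yb.mean(axis=0)) @ w
        sf = (yf - yb.mean(axis=0)) @ w
        out[fac] = float(np.corrcoef(sb, sf)[0, 1])
    return out


def simulate_mortality(config: GeneratorConfig,
                       cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill ``cv_death_5y`` with Bernoulli draws: per-arm rates in RCT
    mode, linearly interpolated selenium-quartile rates in observational
    mode."""
    rng = np.random.default_rng([config.seed, 33])
    out = cohort.copy()
    base = out[out["occasion_months"] == 0]
    if base.empty:
        raise DataError("cohort has no baseline (occasion 0) rows")

    if config.mode == "rct":
        rates = {ARM_ACTIVE: config.mortality_rate_active,
                 ARM_PLACEBO: config.mortality_rate_placebo}
        arm_vals = base["arm"].to_numpy()
        unknown = set(arm_vals) - set(rates)
        if unknown:
            raise DataError(f"rct mode requires arm in {sorted(rates)}; "
                            f"found {sorted(unknown)}")
        p = np.array([rates[a] for a in arm_vals])
    else:
        sel = base["selenium_ugL"].to_numpy()
        order = np.argsort(sel, kind="stable")
        quart = np.empty(len(sel), dtype=int)
        quart[order] = (np.arange(len(sel)) * 4) // len(sel)
        lo = config.mortality_rate_quartile_low
        hi = config.mortality_rate_quartile_high
        p = lo + (hi - lo) * quart / 3.0

    death = (rng.random(len(base)) < p).astype(int)
    mapping = dict(zip(base["subject_id"], death))
    out["cv_death_5y"] = pd.array(
        [mapping.get(sid, pd.NA) for sid in out["subject_id"]],
        dtype="Int64")
    return out


def simulate_cohort(config: GeneratorConfig,
                    n: int | None = None) -> pd.DataFrame:
    """Full cohort: baseline (+ follow-up in RCT mode) with mortality."""
    baseline = simulate_baseline(config, n=n)
    baseline = simulate_mortality(config, baseline)
    if config.mode != "rct":
        return baseline
    followup = simulate_followup(config, baseline)
    combined = pd.concat([baseline, followup], ignore_index=True)
    return combined
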