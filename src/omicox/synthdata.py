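"""Synthetic type-2-diabetes cohorts for case-cohort cardiovascular risk modelling.

Generates subject-level tables with the statistical structure the downstream
analysis assumes: eight clinical risk-factor covariates (the SCORE2-Diabetes
variable set), sparse sex-specific protein effects, weak metabolite and
polygenic-score effects, cross-feature rank correlations induced by a Gaussian
copula, Weibull proportional-hazards event times over a 10-year horizon,
exponential dropout, a case-cohort subsample (random sub-cohort plus all
cases), and missing-at-random masking.  Ground truth (per-sex coefficients,
linear predictors, true 10-year risks) is returned alongside the data so
recovery properties can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCORE2_VARIABLES",
    "CLINICAL_MARGINALS",
    "SimulationConfig",
    "GroundTruth",
    "SurvivalOutcome",
    "CaseCohortSample",
    "default_config",
    "generate_cohort",
    "draw_case_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
]

#: The eight clinical covariates of the base 10-year CVD risk model for
#: adults with T2D (sex is handled by stratification, not as a covariate).
SCORE2_VARIABLES = [
    "age", "smoking", "sbp", "tchol", "hdl", "age_diag", "hba1c", "egfr",
]

#: Marginal distributions used to map latent standard-normal scores onto
#: clinically plausible scales: mean/SD for continuous variables, prevalence
#: for current smoking.  Values chosen to resemble a T2D cohort aged 40-69.
CLINICAL_MARGINALS = {
    "age": (60.3, 6.6),
    "sbp": (144.5, 17.7),
    "tchol": (4.5, 1.0),
    "hdl": (1.2, 0.3),
    "age_diag": (55.0, 6.5),
    "hba1c": (51.8, 12.9),
    "egfr": (88.3, 16.1),
}
SMOKING_PREVALENCE = 0.107

# Per-SD log-hazard ratios of the clinical covariates, identical in both
# sexes; signs follow the epidemiology (higher HDL and eGFR protective).
_CLINICAL_EFFECTS = {
    "age": (0.45, 0.45),
    "smoking": (0.30, 0.30),
    "sbp": (0.25, 0.25),
    "tchol": (0.15, 0.15),
    "hdl": (-0.20, -0.20),
    "age_diag": (-0.15, -0.15),
    "hba1c": (0.20, 0.20),
    "egfr": (-0.15, -0.15),
}

# Sparse omics truth: a handful of proteins with sex-specific effects (some
# male-only, some female-only, one shared), male-only metabolite effects and
# a male-only polygenic-score effect.  Effects are per SD of the latent score.
_OMICS_EFFECTS = {
    "prot_010": (0.50, 0.00),
    "prot_011": (0.45, 0.00),
    "prot_012": (-0.40, 0.00),
    "prot_013": (0.35, 0.00),
    "prot_020": (0.00, 0.50),
    "prot_021": (0.00, 0.45),
    "prot_022": (0.00, -0.40),
    "prot_030": (0.45, 0.40),
    "met_1": (0.45, 0.00),
    "met_2": (0.35, 0.00),
    "prs": (0.30, 0.00),
}

# Default Spearman targets: one strong within-layer protein pair, moderate
# clinical structure, weak cross-layer links (all but the first <= 0.47).
_DEFAULT_CORRELATIONS = [
    ("prot_010", "prot_014", 0.64),
    ("age", "age_diag", 0.55),
    ("age", "sbp", 0.30),
    ("tchol", "hdl", 0.20),
    ("met_1", "met_2", 0.40),
    ("prot_030", "met_1", 0.30),
    ("prot_011", "met_2", 0.25),
    ("prot_010", "hba1c", 0.20),
    ("prot_010", "prs", 0.05),
]

# Per-variable missingness of the clinical covariates (fractions of subjects),
# plus modest protein missingness including one feature beyond the 20% QC
# threshold; two proteins carry left-censoring at the detection limit, one
# beyond the 25% QC threshold.
_DEFAULT_MISSINGNESS = {
    "hdl": 0.120,
    "hba1c": 0.069,
    "age_diag": 0.066,
    "egfr": 0.060,
    "tchol": 0.058,
    "smoking": 0.008,
    "sbp": 0.003,
    "prot_001": 0.22,
    "prot_002": 0.15,
}
_DEFAULT_LOD_QUANTILES = {
    "prot_003": 0.30,
    "prot_004": 0.10,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The defaults emulate the structure of the study population the analysis
    is designed for: a full T2D cohort of 2365 subjects from which a random
    sub-cohort of fraction 0.707 (~1672 subjects) is drawn and all cases are
    appended (~79 extra), yielding a case-cohort sample of ~1751 subjects
    with ~15.4% observed 10-year events; ~59.7% male; 150 protein columns,
    7 metabolites and one polygenic score.
    """

    n_full_cohort: int = 2365
    male_fraction: float = 0.597
    n_proteins: int = 150
    n_metabolites: int = 7
    include_prs: bool = True
    true_effects: dict = field(
        default_factory=lambda: {**_CLINICAL_EFFECTS, **_OMICS_EFFECTS}
    )
    correlation_spec: list = field(
        default_factory=lambda: list(_DEFAULT_CORRELATIONS)
    )
    weibull_shape: tuple = (1.3, 1.3)  # (male, female)
    #: If given, Weibull scales are used as-is; otherwise they are calibrated
    #: by bisection to the sex-specific incidence targets below.
    weibull_scale: tuple | None = None
    #: Target observed 10-year event fraction in the full cohort, per sex.
    #: The weighted mean (0.597*0.137 + 0.403*0.081 ~ 0.114) makes the default
    #: case-cohort sample land near 15.4% events.
    incidence_10y: tuple = (0.137, 0.081)
    censoring_rate: float = 0.008  # yearly dropout hazard
    horizon: float = 10.0
    subcohort_fraction: float = 1672.0 / 2365.0
    multiomics_fraction: float = 0.565
    missingness_rates: dict = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    lod_quantiles: dict = field(
        default_factory=lambda: dict(_DEFAULT_LOD_QUANTILES)
    )
    seed: int = 0

    def validate(self) -> None:
        for name, val in [
            ("male_fraction", self.male_fraction),
            ("subcohort_fraction", self.subcohort_fraction),
            ("multiomics_fraction", self.multiomics_fraction),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.n_full_cohort < 100:
            raise ValueError("n_full_cohort must be at least 100")
        for rate in self.missingness_rates.values():
            if not 0.0 <= rate < 1.0:
                raise ValueError("missingness rates must be in [0, 1)")

    def feature_names(self) -> list[str]:
        names = list(SCORE2_VARIABLES)
        names += [f"prot_{i:03d}" for i in range(1, self.n_proteins + 1)]
        names += [f"met_{i}" for i in range(1, self.n_metabolites + 1)]
        if self.include_prs:
            names.append("prs")
        return names


@dataclass
class GroundTruth:
    """Simulation truth for recovery tests."""

    true_beta: dict          # (sex, feature) -> per-SD log hazard ratio
    true_linear_predictor: np.ndarray
    true_10y_risk: np.ndarray
    weibull_shape: dict      # sex -> shape
    weibull_scale: dict      # sex -> scale
    lod_values: dict         # feature -> detection-limit value


@dataclass
class SurvivalOutcome:
    """Observed follow-up time (years) and event indicator."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time < 0):
            raise ValueError("negative follow-up time")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalOutcome":
        return cls(df["time_years"].to_numpy(), df["event"].to_numpy())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx])

    def __len__(self):
        return len(self.time)


@dataclass
class CaseCohortSample:
    """A random sub-cohort plus all cases outside it.

    ``alpha`` is the realized sub-cohort sampling fraction (sub-cohort size
    over full-cohort size), the quantity the Barlow weights invert.
    """

    data: pd.DataFrame
    outcome: SurvivalOutcome
    in_subcohort: np.ndarray
    is_case: np.ndarray
    alpha: float

    def __post_init__(self):
        self.in_subcohort = np.asarray(self.in_subcohort, dtype=bool)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"sampling fraction alpha must be in (0,1], got {self.alpha}")
        if not np.all(self.in_subcohort | self.is_case):
            raise ValueError("every retained subject must be in the sub-cohort or a case")

    def __len__(self):
        return len(self.data)


def default_config(**overrides) -> SimulationConfig:
    """The study-emulating default configuration, with field overrides."""
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# copula machinery


def _spearman_to_pearson(rho_s: float) -> float:
    # exact relation for the bivariate normal copula
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def build_latent_correlation(names: list[str], spec: list) -> np.ndarray:
    """Latent Pearson correlation matrix hitting the Spearman targets.

    Raises ``ValueError`` naming the offending pairs when the implied matrix
    is not positive definite.
    """
    idx = {n: i for i, n in enumerate(names)}
    p = len(names)
    corr = np.eye(p)
    for a, b, rho in spec:
        if a not in idx or b not in idx:
            continue  # pair refers to a feature not simulated at this size
        r = _spearman_to_pearson(rho)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        pairs = ", ".join(f"({a},{b},rho={rho})" for a, b, rho in spec)
        raise ValueError(
            "correlation_spec does not yield a positive-definite latent "
            f"correlation matrix; offending targets among: {pairs}"
        ) from None
    return corr


def _draw_latent(rng: np.random.Generator, n: int, corr: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(corr)
    return rng.standard_normal((n, corr.shape[0])) @ L.T


# ---------------------------------------------------------------------------
# event-time model


def _observed_event_probability(
    lp: np.ndarray, shape: float, scale: float, horizon: float, dropout: float
) -> np.ndarray:
    """P(event observed within the horizon) under Weibull PH + exponential dropout.

    Integrates f_T(t) * exp(-dropout * t) over (0, horizon] on a fixed grid;
    deterministic, used by the calibration bisection.
    """
    t = np.linspace(1e-6, horizon, 257)
    # baseline cumulative hazard and hazard
    H0 = (t / scale) ** shape
    h0 = (shape / scale) * (t / scale) ** (shape - 1.0)
    elp = np.exp(lp)[:, None]
    surv = np.exp(-H0[None, :] * elp)
    dens = h0[None, :] * elp * surv
    return np.trapezoid(dens * np.exp(-dropout * t)[None, :], t, axis=1)


def calibrate_weibull_scale(
    lp: np.ndarray,
    shape: float,
    target: float,
    horizon: float,
    dropout: float,
) -> float:
    """Bisection on the Weibull scale so mean observed event probability hits
    ``target`` for the supplied linear predictors."""
    lo, hi = 1.0, 1e5  # scale up -> fewer events
    f = lambda s: float(
        np.mean(_observed_event_probability(lp, shape, s, horizon, dropout))
    ) - target
    if f(lo) < 0:  # even the fastest scale cannot reach the target
        return lo
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# public operations


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SurvivalOutcome, GroundTruth]:
    """Simulate a full cohort under the configured copula + Weibull PH model.

    Returns the subject table (one row per subject, omics columns prefixed
    ``prot_``/``met_``, polygenic score as ``prs``), the survival outcome and
    the ground truth.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_full_cohort
    names = config.feature_names()

    corr = build_latent_correlation(names, config.correlation_spec)
    Z = _draw_latent(rng, n, corr)
    z = {name: Z[:, j] for j, name in enumerate(names)}

    male = rng.random(n) < config.male_fraction
    sex = np.where(male, "M", "F")

    # linear predictors on the latent (per-SD) scale
    lp = np.zeros(n)
    beta_map = {}
    for feat, (bm, bf) in config.true_effects.items():
        if feat not in z:
            continue
        lp += np.where(male, bm, bf) * z[feat]
        beta_map[("M", feat)] = float(bm)
        beta_map[("F", feat)] = float(bf)

    # per-sex Weibull baseline, calibrated or supplied
    shapes = {"M": config.weibull_shape[0], "F": config.weibull_shape[1]}
    scales = {}
    for s, is_s, target in [
        ("M", male, config.incidence_10y[0]),
        ("F", ~male, config.incidence_10y[1]),
    ]:
        if config.weibull_scale is not None:
            scales[s] = config.weibull_scale[0 if s == "M" else 1]
        else:
            scales[s] = calibrate_weibull_scale(
                lp[is_s], shapes[s], target, config.horizon, config.censoring_rate
            )

    # inverse-CDF event times: T = scale * (-log U / exp(lp))^(1/shape)
    u = rng.random(n)
    shape_vec = np.where(male, shapes["M"], shapes["F"])
    scale_vec = np.where(male, scales["M"], scales["F"])
    T = scale_vec * (-np.log(u) / np.exp(lp)) ** (1.0 / shape_vec)
    if config.censoring_rate > 0:
        C = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(np.minimum(T, C), config.horizon)
    event = (T <= C) & (T <= config.horizon)

    true_risk = 1.0 - np.exp(
        -((config.horizon / scale_vec) ** shape_vec) * np.exp(lp)
    )

    cols = {"id": np.arange(n), "sex": sex}
    for name in SCORE2_VARIABLES:
        if name == "smoking":
            # threshold the latent score at the prevalence quantile
            from scipy.stats import norm

            cols[name] = (z[name] > norm.ppf(1.0 - SMOKING_PREVALENCE)).astype(int)
        else:
            mu, sd = CLINICAL_MARGINALS[name]
            cols[name] = mu + sd * z[name]
    lod_values = {}
    for name in names:
        if name in SCORE2_VARIABLES:
            continue
        col = z[name]
        q = config.lod_quantiles.get(name)
        if q:
            lod = float(np.quantile(col, q))
            col = np.maximum(col, lod)  # left-censoring at the detection limit
            lod_values[name] = lod
        cols[name] = col
    cols["time_years"] = time
    cols["event"] = event.astype(int)
    cols["in_multiomics"] = (rng.random(n) < config.multiomics_fraction).astype(int)
    df = pd.DataFrame(cols)

    truth = GroundTruth(
        true_beta=beta_map,
        true_linear_predictor=lp,
        true_10y_risk=true_risk,
        weibull_shape=shapes,
        weibull_scale=scales,
        lod_values=lod_values,
    )
    outcome = SurvivalOutcome(time, event.astype(int))
    df.attrs["lod_values"] = lod_values
    return df, outcome, truth


def draw_case_cohort(
    cohort: pd.DataFrame,
    outcome: SurvivalOutcome,
    subcohort_fraction: float,
    seed: int,
) -> CaseCohortSample:
    """Random sub-cohort of the full cohort plus all cases outside it."""
    if not (0.0 < subcohort_fraction <= 1.0):
        raise ValueError("subcohort_fraction must be in (0, 1]")
    n = len(cohort)
    is_case_full = outcome.event.astype(bool)
    if not is_case_full.any():
        raise ValueError("case-cohort design undefined: cohort contains no cases")
    rng = np.random.default_rng(seed)
    n_sub = int(round(subcohort_fraction * n))
    sub_idx = rng.choice(n, size=n_sub, replace=False)
    in_sub_full = np.zeros(n, dtype=bool)
    in_sub_full[sub_idx] = True
    keep = in_sub_full | is_case_full
    alpha = n_sub / n

    data = cohort.loc[keep].reset_index(drop=True)
    data.attrs.update(cohort.attrs)
    data["in_subcohort"] = in_sub_full[keep].astype(int)
    return CaseCohortSample(
        data=data,
        outcome=outcome.subset(keep),
        in_subcohort=in_sub_full[keep],
        is_case=is_case_full[keep],
        alpha=alpha,
    )


_NEVER_MASKED = {"id", "sex", "time_years", "event", "in_subcohort", "in_multiomics"}


def _mar_probabilities(
    rate: float, age_z: np.ndarray, male: np.ndarray
) -> np.ndarray:
    """Masking probabilities depending only on the fully observed age and sex,
    with the intercept solved so the marginal rate matches the target."""
    from scipy.special import expit
    from scipy.optimize import brentq

    eta = 0.8 * age_z + 0.4 * male.astype(float)
    f = lambda a: float(np.mean(expit(a + eta))) - rate
    a = brentq(f, -30.0, 30.0)
    return expit(a + eta)


def inject_missingness(
    cohort: pd.DataFrame,
    rates: dict,
    mechanism: str = "MAR",
    seed: int = 0,
) -> pd.DataFrame:
    """Mask values at the given per-variable rates (MCAR or MAR-on-observables).

    Outcome, sex and design flags are never masked.  Under MAR, the masking
    probability depends only on age and sex, which remain fully observed.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    for var, rate in rates.items():
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"missingness rate for {var} must be in [0, 1)")
    out = cohort.copy()
    out.attrs.update(cohort.attrs)
    rng = np.random.default_rng(seed)
    age = cohort["age"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / age.std()
    male = (cohort["sex"] == "M").to_numpy()
    for var, rate in rates.items():
        if var in _NEVER_MASKED or var == "age" or var not in out.columns or rate == 0:
            continue
        if mechanism == "MCAR":
            p = np.full(len(out), rate)
        else:
            p = _mar_probabilities(rate, age_z, male)
        mask = rng.random(len(out)) < p
        col = out[var].astype(float).to_numpy()
        col[mask] = np.nan
        out[var] = col
    return out


# ---------------------------------------------------------------------------
# I/O


def write_cohort(
    cohort: pd.DataFrame,
    path: str | Path,
    truth: GroundTruth | None = None,
    sep: str = ",",
) -> None:
    """Write the subject table (CSV/TSV) and, optionally, a truth sidecar JSON."""
    path = Path(path)
    cohort.to_csv(path, sep=sep, index=False)
    if truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        payload = {
            "true_beta": {f"{s}:{f}": b for (s, f), b in truth.true_beta.items()},
            "true_linear_predictor": truth.true_linear_predictor.tolist(),
            "true_10y_risk": truth.true_10y_risk.tolist(),
            "weibull_shape": truth.weibull_shape,
            "weibull_scale": truth.weibull_scale,
            "lod_values": truth.lod_values,
        }
        sidecar.write_text(json.dumps(payload))


def read_cohort(path: str | Path, sep: str = ",") -> tuple[pd.DataFrame, SurvivalOutcome]:
    df = pd.read_csv(path, sep=sep)
    return df, SurvivalOutcome.from_frame(df)
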