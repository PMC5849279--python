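"""Synthetic cohort generation for the risk-score pipeline.

Genotypes are drawn under Hardy-Weinberg equilibrium at the panel's
modeled-allele frequencies, with one designated SNP pair (by default the two
key PITX2 variants rs2200733 / rs10033464) drawn from a two-locus haplotype
distribution with signed disequilibrium D, so their dosages can be negatively
correlated while the single-SNP marginals are preserved.  Covariates follow
the study cohort's margins (mean age 66.2 y truncated at the 40-year
inclusion bound, 38% male, 77% hypertensive, ...).  The AF outcome is
Bernoulli, either from per-quintile absolute rates or from a logistic model
on the score and covariates with an optionally calibrated intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .panel import GenotypeMatrix, GrsVector, SnpPanel, assign_quantiles, compute_grs, load_panel

__all__ = [
    "LdSpec",
    "CovariateSpec",
    "QuintileRatesModel",
    "LogisticModel",
    "SimConfig",
    "Cohort",
    "admissible_d_range",
    "default_ld",
    "population_grs_moments",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_outcome",
    "simulate_cohort",
]

BINARY_COVARIATES = ["male", "smoker", "diabetes", "hypertension", "prior_mi", "heart_failure"]
COVARIATE_COLUMNS = ["age", "male", "smoker", "bmi"] + BINARY_COVARIATES[2:]


def admissible_d_range(fa: float, fb: float) -> tuple[float, float]:
    """Bounds on haplotype D keeping all four haplotype frequencies in [0, 1]."""
    lo = max(-fa * fb, -(1 - fa) * (1 - fb))
    hi = min(fa * (1 - fb), (1 - fa) * fb)
    return lo, hi


@dataclass(frozen=True)
class LdSpec:
    """A single SNP pair in linkage disequilibrium, parameterized by signed D.

    D is the haplotype-frequency covariance between the two modeled alleles;
    dosage covariance is 2D under random haplotype pairing.
    """

    rsid_a: str
    rsid_b: str
    d: float


def default_ld(panel: SnpPanel) -> LdSpec | None:
    """Negative LD between the two key PITX2 SNPs at half the admissible magnitude.

    The study reports the direction (negative) but not the magnitude, so the
    default is deliberately mid-range; pass an explicit :class:`LdSpec` to
    override.  Returns None if either SNP is absent from the panel.
    """
    a, b = "rs2200733", "rs10033464"
    if a not in panel.rsids or b not in panel.rsids:
        return None
    lo, _ = admissible_d_range(float(panel.row(a)["freq"]), float(panel.row(b)["freq"]))
    return LdSpec(a, b, 0.5 * lo)


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal covariate distributions; defaults match the whole-cohort margins.

    ``age_mean``/``age_sd`` are the *target* post-truncation moments: the
    latent normal location is calibrated so the mean of the >= ``age_min``
    truncated distribution equals ``age_mean``.
    """

    age_mean: float = 66.2
    age_sd: float = 11.8
    age_min: float = 40.0
    male: float = 341 / 904
    smoker: float = 84 / 904
    bmi_mean: float = 29.6
    bmi_sd: float = 6.8
    diabetes: float = 201 / 904
    hypertension: float = 693 / 904
    prior_mi: float = 80 / 904
    heart_failure: float = 49 / 904

    def __post_init__(self) -> None:
        for name in BINARY_COVARIATES:
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name}={p} outside [0, 1]")

    def prevalence(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class QuintileRatesModel:
    """AF probability fixed per GRS quintile (quintiles of the simulated scores)."""

    rates: tuple[float, float, float, float, float] = (0.04, 0.06, 0.08, 0.10, 0.12)

    def __post_init__(self) -> None:
        if len(self.rates) != 5:
            raise ValueError("quintile_rates must have length 5")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise ValueError(f"quintile rates {self.rates} outside [0, 1]")


@dataclass(frozen=True)
class LogisticModel:
    """AF probability expit(b0 + b_grs*GRS + b_cov . x).

    If ``target_rate`` is set, the intercept is calibrated by root finding so
    the cohort's expected marginal event rate equals the target.
    """

    beta_grs: float
    intercept: float | None = None
    beta_cov: dict[str, float] = field(default_factory=dict)
    target_rate: float | None = None

    def __post_init__(self) -> None:
        if (self.intercept is None) == (self.target_rate is None):
            raise ValueError("specify exactly one of intercept / target_rate")


@dataclass(frozen=True)
class SimConfig:
    n_participants: int
    panel: SnpPanel = field(default_factory=lambda: load_panel("af12"))
    ld: LdSpec | None = None  # None -> default negative-D PITX2 pair
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    outcome: QuintileRatesModel | LogisticModel = field(default_factory=QuintileRatesModel)
    seed: int = 0

    def resolved_ld(self) -> LdSpec | None:
        return self.ld if self.ld is not None else default_ld(self.panel)


@dataclass(frozen=True)
class Cohort:
    """Genotypes joined to covariates, scores and the binary AF outcome."""

    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    grs: GrsVector
    af_event: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genotypes.participant_ids)
        if len(self.covariates) != n or len(self.af_event) != n:
            raise ValueError("genotypes, covariates and outcome lengths differ")
        ev = np.asarray(self.af_event, dtype=int)
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("af_event must be binary")
        object.__setattr__(self, "af_event", ev)

    @property
    def n(self) -> int:
        return len(self.af_event)

    @property
    def event_rate(self) -> float:
        return float(self.af_event.mean())

    def frame(self) -> pd.DataFrame:
        """Covariates + score + outcome as one analysis-ready table."""
        df = self.covariates.copy()
        df.insert(0, "participant_id", self.genotypes.participant_ids)
        df["grs"] = self.grs.score
        df["af_event"] = self.af_event
        return df


def population_grs_moments(panel: SnpPanel, ld: LdSpec | None = None) -> tuple[float, float]:
    """Closed-form (mean, sd) of the score under HWE: mean 2*sum(f*w),
    variance sum(w^2 * 2f(1-f)) plus 2*w_a*w_b*2D for the LD pair."""
    f, w = panel.freqs, panel.weights
    mean = 2.0 * float(f @ w)
    var = float((w**2 * 2.0 * f * (1.0 - f)).sum())
    if ld is not None:
        var += 2.0 * panel.weight(ld.rsid_a) * panel.weight(ld.rsid_b) * 2.0 * ld.d
    return mean, float(np.sqrt(var))


def _sample_ld_pair(
    fa: float, fb: float, d: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = admissible_d_range(fa, fb)
    if not lo <= d <= hi:
        raise ValueError(f"D={d} outside admissible range [{lo:.4g}, {hi:.4g}]")
    # Haplotype classes: (A,B), (A,b), (a,B), (a,b); two haplotypes per person.
    p = np.array(
        [fa * fb + d, fa * (1 - fb) - d, (1 - fa) * fb - d, (1 - fa) * (1 - fb) + d]
    )
    hap = rng.multinomial(2, p, size=n)
    dos_a = hap[:, 0] + hap[:, 1]
    dos_b = hap[:, 0] + hap[:, 2]
    return dos_a.astype(float), dos_b.astype(float)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """HWE dosages Binomial(2, freq) per SNP; the LD pair from its haplotype law."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    panel, n = config.panel, config.n_participants
    dosage = np.empty((n, len(panel)), dtype=float)
    ld = config.resolved_ld()
    ld_cols: dict[str, int] = {}
    if ld is not None:
        ld_cols = {ld.rsid_a: panel.rsids.index(ld.rsid_a), ld.rsid_b: panel.rsids.index(ld.rsid_b)}
        da, db = _sample_ld_pair(
            float(panel.row(ld.rsid_a)["freq"]), float(panel.row(ld.rsid_b)["freq"]), ld.d, n, rng
        )
        dosage[:, ld_cols[ld.rsid_a]] = da
        dosage[:, ld_cols[ld.rsid_b]] = db
    for j, (rsid, f) in enumerate(zip(panel.rsids, panel.freqs)):
        if rsid not in ld_cols:
            dosage[:, j] = rng.binomial(2, f, size=n)
    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    return GenotypeMatrix(ids, list(panel.rsids), dosage)


@lru_cache(maxsize=None)
def _truncnorm_loc(target_mean: float, sd: float, lower: float) -> float:
    """Latent normal location whose >=lower truncation has the target mean."""

    def gap(loc: float) -> float:
        a = (lower - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - target_mean

    return float(optimize.brentq(gap, target_mean - 5 * sd, target_mean + 5 * sd))


def simulate_covariates(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Independent margins: truncated-normal age (rejection sampled at the
    40-year inclusion bound), normal BMI, Bernoulli binaries."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spec, n = config.covariates, config.n_participants
    loc = _truncnorm_loc(spec.age_mean, spec.age_sd, spec.age_min)
    age = np.empty(0)
    while age.size < n:
        draw = rng.normal(loc, spec.age_sd, size=2 * (n - age.size) + 16)
        age = np.concatenate([age, draw[draw >= spec.age_min]])
    df = pd.DataFrame({"age": age[:n]})
    df["male"] = rng.binomial(1, spec.male, size=n)
    df["smoker"] = rng.binomial(1, spec.smoker, size=n)
    df["bmi"] = rng.normal(spec.bmi_mean, spec.bmi_sd, size=n)
    for name in ("diabetes", "hypertension", "prior_mi", "heart_failure"):
        df[name] = rng.binomial(1, spec.prevalence(name), size=n)
    return df


def _linear_predictor(model: LogisticModel, grs: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
    eta = model.beta_grs * grs
    for name, beta in model.beta_cov.items():
        eta = eta + beta * cov[name].to_numpy(dtype=float)
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    def gap(b0: float) -> float:
        return float(special.expit(b0 + eta).mean()) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"cannot calibrate intercept to marginal rate {target}")
    return float(optimize.brentq(gap, lo, hi))


def simulate_outcome(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    grs = assign_quantiles(compute_grs(genotypes, config.panel), 5)
    model = config.outcome
    if isinstance(model, QuintileRatesModel):
        prob = np.asarray(model.rates, dtype=float)[grs.quintile - 1]
    else:
        eta = _linear_predictor(model, grs.score, covariates)
        b0 = model.intercept if model.intercept is not None else _calibrate_intercept(
            eta, model.target_rate
        )
        prob = special.expit(b0 + eta)
    events = rng.binomial(1, prob)
    return Cohort(genotypes, covariates, grs, events)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Genotypes -> covariates -> outcome from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    gm = simulate_genotypes(config, rng)
    cov = simulate_covariates(config, rng)
    return simulate_outcome(gm, cov, config, rng)
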