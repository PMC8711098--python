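"""Synthetic hemodialysis-like cohorts and small multi-view test fixtures.

The private clinical cohort behind the dry-weight problem is described only
by its marginal summaries (mean ± sd per predictor, a 312/164 male/female
split) and by the per-predictor Pearson correlations with dry weight, with
BMI dominating (r ≈ 0.956) and gender next (|r| ≈ 0.45).  The generator
reproduces that structure mechanistically rather than via a copula:

* each continuous predictor is drawn from a normal matching the published
  mean ± sd, truncated at an invented physiologic floor (age ≥ 18 y,
  BMI ≥ 12, HR ≥ 30 /min, pressures ≥ 40 mmHg, dialysis vintage ≥ 0.25 y).
  The parent (loc, scale) is moment-matched so the *truncated* distribution
  has exactly the published mean and sd;
* gender is Bernoulli (female=1, male=0) and females get a lower BMI mean
  (the overall BMI mixture still matches the published 22.96 ± 2.95), which
  routes part of the gender–dry-weight correlation through BMI — published
  r values for BMI and gender are too large to coexist under independence;
* dry weight is built as BMI times a gender-dependent height-squared proxy
  (weight = BMI · height², and the two sexes differ in stature) plus small
  centered contributions of the remaining predictors and Gaussian noise of
  sd 1.3 kg, the scale of the irreducible error reported for this problem.

Coefficients were calibrated once, by simulation at large n, so that the
sample correlations reproduce the published sign pattern and the BMI and
gender magnitudes; they are frozen here as defaults.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .cohort import CLINICAL_FEATURES, DEFAULT_TARGET, CohortTable

#: Published marginal summaries (mean, sd) and invented physiologic floors.
_MARGINALS = {
    "age": (54.17, 14.22, 18.0),
    "bmi": (22.96, 2.95, 12.0),
    "heart_rate": (73.41, 8.92, 30.0),
    "dbp": (88.32, 19.56, 40.0),
    "sbp": (150.64, 29.36, 40.0),
    "years_dialysis": (5.97, 3.22, 0.25),
}


@dataclasses.dataclass
class FeatureSpec:
    """One continuous predictor: target mean/sd of its floor-truncated law."""

    mean: float
    sd: float
    floor: float | None = None

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("feature sd must be strictly positive")
        if self.floor is not None and self.floor >= self.mean:
            raise ValueError("floor must lie below the target mean")


def _default_features() -> dict[str, FeatureSpec]:
    return {k: FeatureSpec(*v) for k, v in _MARGINALS.items()}


@dataclasses.dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``target_coefficients`` holds the dry-weight construction:
    ``dw = bmi * (bmi_scale - female_penalty * female) + sum_f c_f * (f - mean_f)
    + N(0, noise_sd^2)``.  ``bmi_gender_gap`` is the male-minus-female BMI
    mean difference inside the mixture.
    """

    n: int = 476
    male_fraction: float = 312 / 476
    features: dict[str, FeatureSpec] = dataclasses.field(default_factory=_default_features)
    bmi_gender_gap: float = 2.2
    bmi_scale: float = 3.10
    female_penalty: float = 0.13
    minor_coefficients: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "age": -0.130,
            "heart_rate": 0.163,
            "dbp": -0.053,
            "sbp": -0.046,
            "years_dialysis": -0.270,
        }
    )
    noise_sd: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must lie in (0, 1)")
        if not self.noise_sd >= 0:
            raise ValueError("noise_sd must be non-negative")
        pf = 1.0 - self.male_fraction
        pm = self.male_fraction
        if self.features["bmi"].sd ** 2 <= pf * pm * self.bmi_gender_gap**2:
            raise ValueError("bmi_gender_gap too large for the BMI sd")


def _matched_parent(mean: float, sd: float, floor: float | None) -> tuple[float, float]:
    """Parent (loc, scale) whose floor-truncated normal has the given moments."""
    if floor is None or (floor - mean) / sd < -6.0:
        return mean, sd  # truncation negligible

    def resid(params):
        loc, scale = params
        scale = abs(scale)
        a = (floor - loc) / scale
        m, v = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    loc, scale = optimize.fsolve(resid, x0=[mean, sd], full_output=False)
    return float(loc), float(abs(scale))


def _draw_truncated(
    rng: np.random.Generator, mean: float, sd: float, floor: float | None, n: int
) -> np.ndarray:
    loc, scale = _matched_parent(mean, sd, floor)
    if floor is None:
        return rng.normal(loc, scale, n)
    a = (floor - loc) / scale
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=n,
                               random_state=rng)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a synthetic cohort; fully deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    female = (rng.random(n) >= spec.male_fraction).astype(float)

    cols: dict[str, np.ndarray] = {"gender": female}
    for name in ("age", "heart_rate", "dbp", "sbp", "years_dialysis"):
        fs = spec.features[name]
        cols[name] = _draw_truncated(rng, fs.mean, fs.sd, fs.floor, n)

    # gender-dependent BMI mixture with the published overall mean/sd
    bmi_spec = spec.features["bmi"]
    pf = 1.0 - spec.male_fraction
    pm = spec.male_fraction
    gap = spec.bmi_gender_gap
    within_sd = float(np.sqrt(bmi_spec.sd**2 - pf * pm * gap**2))
    mu_f = bmi_spec.mean - pm * gap
    mu_m = mu_f + gap
    bmi = np.where(
        female == 1.0,
        _draw_truncated(rng, mu_f, within_sd, bmi_spec.floor, n),
        _draw_truncated(rng, mu_m, within_sd, bmi_spec.floor, n),
    )
    cols["bmi"] = bmi

    dw = bmi * (spec.bmi_scale - spec.female_penalty * female)
    for name, coef in spec.minor_coefficients.items():
        dw = dw + coef * (cols[name] - spec.features[name].mean)
    dw = dw + rng.normal(0.0, spec.noise_sd, n)

    X = np.column_stack([cols[f] for f in CLINICAL_FEATURES])
    return CohortTable(X, dw[:, None], CLINICAL_FEATURES, [DEFAULT_TARGET])


def generate_multiview_fixture(
    n: int = 60,
    d: int = 3,
    q: int = 1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> CohortTable:
    """Small smooth-regression fixture for fast solver tests.

    ``X`` is uniform on [-1, 1]^d; the target is a sum of two Gaussian bumps
    (a smooth nonlinear surface an RBF expansion can represent) plus optional
    Gaussian noise.
    """
    if n < 10:
        raise ValueError("fixture needs n >= 10")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(n, d))
    c1 = np.full(d, 0.5)
    c2 = np.full(d, -0.5)
    y = (
        2.0 * np.exp(-np.sum((X - c1) ** 2, axis=1) / 0.8)
        - np.exp(-np.sum((X - c2) ** 2, axis=1) / 0.8)
    )
    Y = np.tile(y[:, None], (1, q)) + rng.normal(0.0, noise_sd, size=(n, q))
    names = [f"x{j}" for j in range(d)]
    targets = [f"y{j}" for j in range(q)] if q > 1 else ["y"]
    return CohortTable(X, Y, names, targets)
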