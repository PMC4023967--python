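"""Synthetic elderly-cohort generator.

Generates tabular cohorts of community-dwelling elderly adults: 16 clinical
features spanning five functional domains (subject characteristics, clinical
examination, clinical balance, cognitive performance, muscle strength) plus
the three laboratory gait balance-control outcomes (CoM-BoS distance,
CoMv-BoS displacement, BoS area).

The dependence structure is a three-latent-factor Gaussian model -- a global
balance-ability factor, a lower-limb strength factor, and a cognitive factor.
Each feature loads on the latents and carries independent unique variance;
the balance outcomes are monotone (optionally tanh-compressed) functions of
their own latent combinations plus noise, so a learnable nonlinear mapping
from clinical features to outcomes exists by construction.

Marginal calibration: published cohort descriptives report the mean (SD) of
each instrument *as recorded*, i.e. after the instrument's bounds and integer
granularity are applied (BBS cannot exceed 56, fall counts are non-negative
integers, ...).  Naively clipping and rounding a Gaussian would therefore
bias both moments -- the BBS ceiling sits only ~0.7 SD above the target mean.
The generator instead moment-matches the *underlying* Gaussian so that the
censored (and, for integer instruments, rounded) marginal reproduces the
configured mean and SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, SchemaError

__all__ = [
    "SubjectRecord",
    "BalanceOutcome",
    "MarginalSpec",
    "CohortParams",
    "FEATURE_NAMES",
    "OUTCOME_NAMES",
    "COHORT_COLUMNS",
    "DOMAINS",
    "generate_cohort",
    "generate_cohort_frame",
    "records_to_frame",
    "frame_to_records",
    "write_cohort",
    "read_cohort",
]

FEATURE_NAMES: tuple[str, ...] = (
    "age", "sex", "bmi",
    "fall_history", "n_medications", "visual_acuity", "hearing_impaired",
    "bbs", "tug", "abc",
    "tmt_b_minus_a", "gds", "slums",
    "strength_ankle_pf", "strength_knee_ext", "strength_hip_abd",
)

OUTCOME_NAMES: tuple[str, ...] = ("com_bos", "comv_bos", "bos_area")

COHORT_COLUMNS: tuple[str, ...] = ("subject_id",) + FEATURE_NAMES + OUTCOME_NAMES

#: the five clinical functional domains
DOMAINS: dict[str, tuple[str, ...]] = {
    "subject_characteristics": ("age", "sex", "bmi"),
    "clinical_examination": (
        "fall_history", "n_medications", "visual_acuity", "hearing_impaired",
    ),
    "clinical_balance": ("bbs", "tug", "abc"),
    "cognitive_performance": ("tmt_b_minus_a", "gds", "slums"),
    "muscle_strength": (
        "strength_ankle_pf", "strength_knee_ext", "strength_hip_abd",
    ),
}


@dataclass
class SubjectRecord:
    """One subject's clinical evaluation (16 scalar features once encoded)."""

    subject_id: str
    age: float            # years
    sex: int              # 0 = female, 1 = male
    bmi: float            # kg/m^2
    fall_history: int     # falls in the past year
    n_medications: int
    visual_acuity: float  # Snellen denominator (20/x)
    hearing_impaired: int
    bbs: int              # Berg Balance Scale, 0-56
    tug: float            # Timed Up and Go, s
    abc: float            # balance confidence, 0-100 %
    tmt_b_minus_a: float  # Trail Making B-A, s
    gds: int              # Geriatric Depression Scale, 0-15
    slums: int            # SLUMS cognitive screen, 0-30
    strength_ankle_pf: float  # Nm/(BW*BH)
    strength_knee_ext: float
    strength_hip_abd: float

    def feature_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


@dataclass
class BalanceOutcome:
    """Gait balance control measures at heel strike, real-world units."""

    com_bos: float   # cm
    comv_bos: float  # cm
    bos_area: float  # cm^2

    def as_vector(self) -> np.ndarray:
        return np.array([self.com_bos, self.comv_bos, self.bos_area])


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal for one variable.

    kind: 'continuous' (censored to [lower, upper]), 'integer' (rounded then
    censored), or 'bernoulli' (mean = probability of 1; sd ignored).
    """

    mean: float
    sd: float
    kind: str = "continuous"
    lower: float = -math.inf
    upper: float = math.inf


def _default_marginals() -> dict[str, MarginalSpec]:
    """Calibration constants: published cohort descriptives of 56 elderly adults."""
    return {
        "age": MarginalSpec(76.1, 6.5, "continuous", lower=60.0),
        "sex": MarginalSpec(22 / 56, 0.0, "bernoulli"),
        "bmi": MarginalSpec(27.4, 6.1, "continuous", lower=13.0),
        "fall_history": MarginalSpec(0.95, 1.35, "integer", lower=0),
        "n_medications": MarginalSpec(3.8, 3.2, "integer", lower=0),
        "visual_acuity": MarginalSpec(36.6, 11.7, "continuous", lower=10.0),
        "hearing_impaired": MarginalSpec(14 / 56, 0.0, "bernoulli"),
        "bbs": MarginalSpec(53.4, 3.8, "integer", lower=0, upper=56),
        "tug": MarginalSpec(9.0, 2.0, "continuous", lower=2.0),
        "abc": MarginalSpec(85.7, 13.6, "continuous", lower=0.0, upper=100.0),
        "tmt_b_minus_a": MarginalSpec(63.2, 63.0, "continuous", lower=0.0),
        "gds": MarginalSpec(1.6, 1.9, "integer", lower=0, upper=15),
        "slums": MarginalSpec(26.4, 3.3, "integer", lower=0, upper=30),
        "strength_ankle_pf": MarginalSpec(3.1, 2.3, "continuous", lower=0.0),
        "strength_knee_ext": MarginalSpec(3.8, 2.7, "continuous", lower=0.0),
        "strength_hip_abd": MarginalSpec(1.9, 1.6, "continuous", lower=0.0),
        # gait balance control outcomes (cm, cm, cm^2)
        "com_bos": MarginalSpec(3.8, 1.1, "continuous", lower=0.3),
        "comv_bos": MarginalSpec(19.3, 3.5, "continuous", lower=0.5),
        "bos_area": MarginalSpec(436.0, 88.0, "continuous", lower=50.0),
    }


# latent order: (balance ability, lower-limb strength, cognition)
def _default_feature_loadings() -> dict[str, tuple[float, float, float]]:
    return {
        "age": (-0.40, -0.30, -0.30),
        "sex": (0.0, 0.0, 0.0),
        "bmi": (-0.20, -0.20, 0.0),
        "fall_history": (-0.50, -0.10, 0.0),
        "n_medications": (-0.30, 0.0, -0.20),
        "visual_acuity": (-0.50, 0.0, 0.0),     # larger denominator = worse vision
        "hearing_impaired": (-0.20, 0.0, -0.10),
        "bbs": (0.80, 0.20, 0.0),
        "tug": (-0.70, -0.30, 0.0),
        "abc": (0.70, 0.0, 0.20),
        "tmt_b_minus_a": (0.0, 0.0, -0.70),
        "gds": (-0.20, 0.0, -0.50),
        "slums": (0.0, 0.0, 0.80),
        "strength_ankle_pf": (0.20, 0.70, 0.0),
        "strength_knee_ext": (0.15, 0.75, 0.0),
        "strength_hip_abd": (0.25, 0.70, 0.0),
    }


def _default_outcome_loadings() -> dict[str, tuple[float, float, float]]:
    return {
        "com_bos": (0.70, 0.40, 0.30),
        "comv_bos": (0.55, 0.55, 0.35),
        "bos_area": (0.45, 0.65, 0.25),
    }


@dataclass
class CohortParams:
    """Configuration of the synthetic cohort generator.

    ``outcome_noise_frac`` is the fraction of each outcome's (standardized)
    variance that is pure noise, i.e. unexplainable by the clinical latents;
    the default 0.15 leaves cross-validated correlations achievable by a
    model trained on a few dozen subjects in the 0.3-0.9 range typical of
    clinical-to-biomechanical mappings.
    """

    n_subjects: int = 56
    seed: int = 0
    marginals: dict[str, MarginalSpec] = field(default_factory=_default_marginals)
    feature_loadings: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_feature_loadings
    )
    outcome_loadings: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_outcome_loadings
    )
    outcome_noise_frac: float = 0.15
    nonlinear_outcomes: bool = True
    tanh_gain: float = 1.0  # gain of the latent->outcome saturating link

    def with_zero_loadings(self) -> "CohortParams":
        """Copy of the params with every loading zeroed (null cohort)."""
        zf = {k: (0.0, 0.0, 0.0) for k in self.feature_loadings}
        zo = {k: (0.0, 0.0, 0.0) for k in self.outcome_loadings}
        return replace(self, feature_loadings=zf, outcome_loadings=zo)


def _validate_params(params: CohortParams) -> None:
    if params.n_subjects < 2:
        raise ConfigurationError("n_subjects must be >= 2")
    if not 0.0 <= params.outcome_noise_frac <= 1.0:
        raise ConfigurationError("outcome_noise_frac must lie in [0, 1]")
    for name in FEATURE_NAMES + OUTCOME_NAMES:
        if name not in params.marginals:
            raise ConfigurationError(f"marginal spec missing for '{name}'")
    for table, keys in (
        (params.feature_loadings, FEATURE_NAMES),
        (params.outcome_loadings, OUTCOME_NAMES),
    ):
        for name in keys:
            lam = np.asarray(table.get(name, (0.0, 0.0, 0.0)), dtype=float)
            if lam.shape != (3,) or not np.all(np.isfinite(lam)):
                raise ConfigurationError(f"loadings for '{name}' must be 3 finite values")
            if table is params.feature_loadings and lam @ lam > 1.0:
                raise ConfigurationError(
                    f"feature '{name}': squared loading norm {lam @ lam:.3f} > 1 "
                    "leaves negative unique variance (dependence structure not PSD)"
                )
    for name, spec in params.marginals.items():
        if spec.sd < 0:
            raise ConfigurationError(f"negative SD for '{name}'")
        if spec.kind == "bernoulli" and not 0.0 <= spec.mean <= 1.0:
            raise ConfigurationError(f"bernoulli mean for '{name}' outside [0, 1]")
        if spec.lower >= spec.upper:
            raise ConfigurationError(f"empty support for '{name}'")


# ---------------------------------------------------------------------------
# moment matching of the underlying Gaussian to censored / rounded targets
# ---------------------------------------------------------------------------

def _censored_normal_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and SD of clip(X, lo, hi) with X ~ N(mu, sigma)."""
    a = (lo - mu) / sigma if math.isfinite(lo) else -math.inf
    b = (hi - mu) / sigma if math.isfinite(hi) else math.inf
    Phi_a = stats.norm.cdf(a) if math.isfinite(a) else 0.0
    Phi_b = stats.norm.cdf(b) if math.isfinite(b) else 1.0
    phi_a = stats.norm.pdf(a) if math.isfinite(a) else 0.0
    phi_b = stats.norm.pdf(b) if math.isfinite(b) else 0.0
    P = Phi_b - Phi_a
    # E[X 1(a<Z<b)] and E[X^2 1(a<Z<b)] for X = mu + sigma Z
    ez1 = phi_a - phi_b
    ez2 = P + (a * phi_a if math.isfinite(a) else 0.0) - (b * phi_b if math.isfinite(b) else 0.0)
    m_mid = mu * P + sigma * ez1
    m2_mid = mu * mu * P + 2 * mu * sigma * ez1 + sigma * sigma * ez2
    mean = m_mid
    m2 = m2_mid
    if math.isfinite(lo):
        mean += lo * Phi_a
        m2 += lo * lo * Phi_a
    if math.isfinite(hi):
        mean += hi * (1.0 - Phi_b)
        m2 += hi * hi * (1.0 - Phi_b)
    var = max(m2 - mean * mean, 0.0)
    return mean, math.sqrt(var)


def _rounded_censored_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and SD of clip(round(X), lo, hi) over its integer support."""
    k_lo = int(lo) if math.isfinite(lo) else int(math.floor(mu - 10 * sigma))
    k_hi = int(hi) if math.isfinite(hi) else int(math.ceil(mu + 10 * sigma))
    ks = np.arange(k_lo, k_hi + 1)
    upper_edges = stats.norm.cdf((ks + 0.5 - mu) / sigma)
    lower_edges = stats.norm.cdf((ks - 0.5 - mu) / sigma)
    p = upper_edges - lower_edges
    p[0] += lower_edges[0]        # censoring absorbs the tails
    p[-1] += 1.0 - upper_edges[-1]
    mean = float(ks @ p)
    var = float((ks.astype(float) ** 2) @ p - mean * mean)
    return mean, math.sqrt(max(var, 0.0))


def _match_marginal(spec: MarginalSpec) -> tuple[float, float]:
    """Find (mu, sigma) of the underlying Gaussian reproducing spec.mean/sd.

    Returns the identity (mean, sd) when the bounds are irrelevant
    (continuous variable with <1e-5 censored mass).
    """
    if spec.sd == 0.0:
        return spec.mean, 0.0
    moments = (
        _rounded_censored_moments if spec.kind == "integer"
        else _censored_normal_moments
    )
    if spec.kind == "continuous":
        lo_mass = stats.norm.cdf((spec.lower - spec.mean) / spec.sd)
        hi_mass = stats.norm.sf((spec.upper - spec.mean) / spec.sd)
        if lo_mass + hi_mass < 1e-5:
            return spec.mean, spec.sd

    def residual(x):
        mu, log_sigma = x
        m, s = moments(mu, math.exp(log_sigma), spec.lower, spec.upper)
        return [(m - spec.mean) / spec.sd, (s - spec.sd) / spec.sd]

    sol = optimize.least_squares(
        residual, x0=[spec.mean, math.log(spec.sd)], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if np.max(np.abs(sol.fun)) > 1e-6:
        raise ConfigurationError(
            f"cannot match mean={spec.mean}, sd={spec.sd} on "
            f"[{spec.lower}, {spec.upper}] ({spec.kind}); residual {sol.fun}"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _tanh_link_unit_variance(gain: float) -> float:
    """SD of tanh(gain*U), U ~ N(0,1), via Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / math.sqrt(2 * math.pi)
    g = np.tanh(gain * nodes)
    var = float(w @ g**2) - float(w @ g) ** 2
    return math.sqrt(var)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _standard_scores(params: CohortParams, rng: np.random.Generator):
    """Latent draws and per-variable standardized scores (unit marginal)."""
    n = params.n_subjects
    z = rng.standard_normal((n, 3))
    scores: dict[str, np.ndarray] = {}
    for name in FEATURE_NAMES:
        lam = np.asarray(params.feature_loadings.get(name, (0.0, 0.0, 0.0)))
        unique = math.sqrt(max(1.0 - float(lam @ lam), 0.0))
        scores[name] = z @ lam + unique * rng.standard_normal(n)
    for name in OUTCOME_NAMES:
        w = np.asarray(params.outcome_loadings.get(name, (0.0, 0.0, 0.0)))
        norm = math.sqrt(float(w @ w))
        if norm == 0.0:
            signal = np.zeros(n)
        else:
            t = (z @ w) / norm
            if params.nonlinear_outcomes:
                signal = np.tanh(params.tanh_gain * t)
                signal /= _tanh_link_unit_variance(params.tanh_gain)
            else:
                signal = t
        nf = params.outcome_noise_frac
        signal_w = math.sqrt(1.0 - nf) if norm > 0.0 else 0.0
        noise_w = math.sqrt(nf) if norm > 0.0 else 1.0
        scores[name] = signal_w * signal + noise_w * rng.standard_normal(n)
    return z, scores


def generate_cohort_frame(params: CohortParams) -> pd.DataFrame:
    """Generate a cohort as a DataFrame with the documented column schema."""
    _validate_params(params)
    rng = np.random.default_rng(params.seed)
    _, scores = _standard_scores(params, rng)

    cols: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i + 1:03d}" for i in range(params.n_subjects)])
    }
    for name in FEATURE_NAMES + OUTCOME_NAMES:
        spec = params.marginals[name]
        u = scores[name]
        if spec.kind == "bernoulli":
            # probit threshold keeps P(1)=p exactly under any loading
            cols[name] = (u < stats.norm.ppf(spec.mean)).astype(int)
            continue
        mu, sigma = _match_marginal(spec)
        x = mu + sigma * u
        x = np.clip(x, spec.lower, spec.upper)
        if spec.kind == "integer":
            x = np.clip(np.rint(x), spec.lower, spec.upper).astype(int)
        cols[name] = x

    frame = pd.DataFrame(cols, columns=list(COHORT_COLUMNS))
    # physical consistency: displacement along any ray cannot undercut the
    # minimum distance to the boundary
    bad = frame["comv_bos"] < frame["com_bos"]
    frame.loc[bad, "comv_bos"] = frame.loc[bad, "com_bos"] + 0.05
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[tuple[SubjectRecord, BalanceOutcome]]:
    out = []
    for _, row in frame.iterrows():
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            **{
                f: (int(row[f]) if f in ("sex", "fall_history", "n_medications",
                                         "hearing_impaired", "bbs", "gds", "slums")
                   else float(row[f]))
                for f in FEATURE_NAMES
            },
        )
        out.append((rec, BalanceOutcome(*(float(row[o]) for o in OUTCOME_NAMES))))
    return out


def records_to_frame(records: list[tuple[SubjectRecord, BalanceOutcome]]) -> pd.DataFrame:
    rows = []
    for rec, out in records:
        row = {"subject_id": rec.subject_id}
        row.update({f: getattr(rec, f) for f in FEATURE_NAMES})
        row.update({o: getattr(out, o) for o in OUTCOME_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def generate_cohort(params: CohortParams) -> list[tuple[SubjectRecord, BalanceOutcome]]:
    """Generate a seeded cohort of (clinical record, balance outcome) pairs."""
    return frame_to_records(generate_cohort_frame(params))


def write_cohort(frame_or_records, path) -> None:
    """Write a cohort to CSV with the documented 20-column header."""
    frame = (
        frame_or_records
        if isinstance(frame_or_records, pd.DataFrame)
        else records_to_frame(frame_or_records)
    )
    # repr gives the shortest digit string that parses back to the same float
    frame.to_csv(path, index=False, columns=list(COHORT_COLUMNS),
                 float_format=lambda x: repr(float(x)))


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the column schema."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"cohort schema mismatch: missing columns {missing}, unexpected {extra}"
        )
    return frame[list(COHORT_COLUMNS)]
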