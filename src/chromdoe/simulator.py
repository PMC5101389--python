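"""Synthetic HILIC retention simulator for moxonidine and its four impurities.

The generator emulates the screening study's measurement process: a smooth
ground-truth retention surface, Gaussian peaks of known plate count on a
noisy baseline, linear detector calibration with mild heteroscedastic noise,
spiked-placebo recovery samples and a tablet assay sample.

Ground truth
------------
Per compound, log10 k is a quadratic polynomial in the coded mobile-phase
factors (x1 = (%ACN − 75)/5, x2 = (pH − 3.5)/0.7, x3 = (buffer mM − 40)/20),
the same 10-term family the screening models use.  The shipped coefficient
set (``GROUND_TRUTH_VERSION`` 1) was solved offline against the study's
anchor observations:

* impurities A and B coelute (Rs = 0) at 70 % ACN / pH 2.8 at any buffer level,
* at 75 % ACN / pH 4.68 / 40 mM, C and D coelute while Rs(A/B) = 10.91,
* at the optimum 80 % ACN / pH 2.8 / 40 mM every pair is baseline-resolved
  (Rs ≥ 2) and the last peak elutes within 12 min,
* retention of moxonidine and impurities B, C, D rises monotonically with
  %ACN (the HILIC signature), while impurity A is dominated by pH with a
  negative correlation,
* a one-factor-at-a-time robustness screen (±0.5 % ACN, ±0.05 pH, ±2 °C,
  ±0.1 mL/min) moves areas < 5 % and retention times and resolutions < 3 %.

The study never published per-run retention data, so the surface is
constrained by these anchors rather than estimated; any surface satisfying
them is admissible and this one is shipped as a versioned constant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .doe import HILIC_FACTORS, DesignTable, to_coded


class ConditionError(ValueError):
    """Chromatographic conditions outside the admissible simulator range."""


# ----------------------------------------------------------------------
# compounds
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundProfile:
    """Identity and physicochemical constants of one analyte."""

    name: str
    pka: float
    logp: float
    role: str  # "API" or "impurity"


#: Moxonidine (the API) and its four pharmacopoeial impurities, with the
#: calculated pKa and log P constants used to reason about their behaviour.
COMPOUNDS: tuple[CompoundProfile, ...] = (
    CompoundProfile("moxonidine", pka=7.92, logp=1.77, role="API"),
    CompoundProfile("impurity_a", pka=7.06, logp=2.49, role="impurity"),
    CompoundProfile("impurity_b", pka=7.48, logp=1.60, role="impurity"),
    CompoundProfile("impurity_c", pka=7.17, logp=1.57, role="impurity"),
    CompoundProfile("impurity_d", pka=6.95, logp=2.01, role="impurity"),
)

COMPOUND_NAMES = tuple(c.name for c in COMPOUNDS)
COMPOUND_ROLES = {c.name: c.role for c in COMPOUNDS}

#: response-table column per compound
K_COLUMNS = {"moxonidine": "k_M", "impurity_a": "k_A", "impurity_b": "k_B",
             "impurity_c": "k_C", "impurity_d": "k_D"}

#: standard solution mixture, µg/mL (API at the 100 % test concentration,
#: impurities at their specification levels)
STANDARD_MIX_UG_ML = {"moxonidine": 100.0, "impurity_a": 0.5, "impurity_b": 0.5,
                      "impurity_c": 1.0, "impurity_d": 1.0}

#: nominal "100 %" spike level per compound, µg/mL
NOMINAL_100 = dict(STANDARD_MIX_UG_ML)

#: default calibration grids, µg/mL (9 levels for impurities, 6 for the API)
CALIBRATION_LEVELS = {
    "moxonidine": tuple(np.linspace(25.0, 150.0, 6)),
    "impurity_a": tuple(np.linspace(0.04, 0.6, 9)),
    "impurity_b": tuple(np.linspace(0.04, 0.6, 9)),
    "impurity_c": tuple(np.linspace(0.08, 1.2, 9)),
    "impurity_d": tuple(np.linspace(0.08, 1.2, 9)),
}


# ----------------------------------------------------------------------
# conditions and ground truth
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MethodConditions:
    """One isocratic operating point of the method."""

    acn_percent: float = 80.0
    ph: float = 2.8
    buffer_mm: float = 40.0
    temperature: float = 25.0
    flow: float = 1.0       # mL/min
    wavelength: float = 255.0  # nm

    RANGES = {"acn_percent": (60.0, 90.0), "ph": (2.0, 6.0),
              "buffer_mm": (5.0, 80.0), "flow": (0.5, 2.0)}

    def validate(self) -> None:
        for attr, (lo, hi) in self.RANGES.items():
            v = getattr(self, attr)
            if not lo <= v <= hi:
                raise ConditionError(f"{attr}={v} outside admissible range [{lo}, {hi}]")

    def coded(self) -> np.ndarray:
        return to_coded(
            [self.acn_percent, self.ph, self.buffer_mm], HILIC_FACTORS
        )


GROUND_TRUTH_VERSION = 1

# log10 k coefficients, term order (1, x1, x2, x3, x1², x2², x3², x1x2, x1x3, x2x3)
_LOGK_COEFFS = {
    "moxonidine": (0.4932017241, 0.10, 0.03, 0.0, 0.02, 0.0, 0.004, 0.015, 0.0, 0.0),
    "impurity_a": (0.3321580313, 0.02, -0.08, 0.0, 0.01, -0.015, 0.004, -0.02, 0.0, -0.01),
    "impurity_b": (0.3913243028, 0.0688979829, -0.0114634229, 0.01, 0.0025,
                   0.0257682886, 0.004, 0.005, 0.0, 0.0),
    "impurity_c": (0.5382492904, 0.105, 0.025, 0.0, 0.02, 0.003, 0.004, 0.018, 0.0, 0.0),
    "impurity_d": (0.5634985478, 0.107, 0.0102668480, 0.0, 0.02, 0.0028334240,
                   0.004, 0.014, 0.0, 0.0),
}

#: detector response factors (area units per µg/mL), one per compound — the
#: published calibration slopes of the method (their unit conventions differ
#: between the API and the impurities and are kept as printed).
RESPONSE_FACTORS = {"moxonidine": 29142.47, "impurity_a": 24.45681,
                    "impurity_b": 27.659, "impurity_c": 18.18141,
                    "impurity_d": 11.82117}


@dataclass
class RetentionGroundTruth:
    """The simulator's generative model for one instrument/method system."""

    logk_coeffs: dict[str, np.ndarray]
    t0: float = 2.05                 # dead time, min, at 1 mL/min
    plate_count: float = 10_000.0    # N; peak width w = 4 tR / sqrt(N)
    temp_sensitivity: float = -0.005  # Δlog10 k per °C away from 25 °C
    flow_exponent: float = 0.25      # tR ∝ flow^(−exponent), empirical damping
    sigma_logk: float = 0.01         # total run-to-run noise on log10 k
    noise_correlation: float = 0.95  # fraction of log-k noise variance shared
                                     # across co-injected compounds (system
                                     # drift moves all peaks together, so most
                                     # of it cancels in resolutions)
    response_factors: dict[str, float] = field(
        default_factory=lambda: dict(RESPONSE_FACTORS))
    baseline_sigma: float = 0.17     # detector baseline noise SD, area-units/min scale
    version: int = GROUND_TRUTH_VERSION

    def logk(self, name: str, coded: np.ndarray, temperature: float = 25.0) -> float:
        x1, x2, x3 = coded
        t = np.array([1.0, x1, x2, x3, x1 * x1, x2 * x2, x3 * x3,
                      x1 * x2, x1 * x3, x2 * x3])
        base = float(np.dot(self.logk_coeffs[name], t))
        return base + self.temp_sensitivity * (temperature - 25.0)

    def to_json_dict(self) -> dict:
        return {
            "version": self.version,
            "logk_coeffs": {k: list(map(float, v)) for k, v in self.logk_coeffs.items()},
            "t0": self.t0, "plate_count": self.plate_count,
            "temp_sensitivity": self.temp_sensitivity,
            "flow_exponent": self.flow_exponent, "sigma_logk": self.sigma_logk,
            "noise_correlation": self.noise_correlation,
            "response_factors": dict(self.response_factors),
            "baseline_sigma": self.baseline_sigma,
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "RetentionGroundTruth":
        return cls(
            logk_coeffs={k: np.asarray(v, dtype=float)
                         for k, v in payload["logk_coeffs"].items()},
            t0=payload["t0"], plate_count=payload["plate_count"],
            temp_sensitivity=payload["temp_sensitivity"],
            flow_exponent=payload["flow_exponent"], sigma_logk=payload["sigma_logk"],
            noise_correlation=payload.get("noise_correlation", 0.95),
            response_factors=dict(payload["response_factors"]),
            baseline_sigma=payload["baseline_sigma"],
            version=payload.get("version", GROUND_TRUTH_VERSION),
        )


def default_ground_truth() -> RetentionGroundTruth:
    """The shipped, anchor-calibrated ground truth (version 1)."""
    return RetentionGroundTruth(
        logk_coeffs={k: np.asarray(v) for k, v in _LOGK_COEFFS.items()}
    )


# ----------------------------------------------------------------------
# chromatographic observables
# ----------------------------------------------------------------------

def retention_factor(tr: float, t0: float) -> float:
    """k = (tR − t0) / t0."""
    if t0 <= 0:
        raise ValueError("dead time t0 must be > 0")
    if tr < t0:
        raise ValueError(f"tR={tr} earlier than dead time t0={t0}")
    return (tr - t0) / t0


def resolution(tr1: float, tr2: float, w1: float, w2: float) -> float:
    """Baseline-width resolution Rs = 2 |tR2 − tR1| / (w1 + w2)."""
    if w1 <= 0 or w2 <= 0:
        raise ValueError("peak widths must be > 0")
    return 2.0 * abs(tr2 - tr1) / (w1 + w2)


@dataclass
class ChromOutcome:
    """Observables of one simulated injection."""

    conditions: MethodConditions
    t0: float
    k: dict[str, float]
    tr: dict[str, float]
    width: dict[str, float]
    area: dict[str, float]
    height: dict[str, float]
    rs_ab: float
    rs_cd: float

    @property
    def last_peak_time(self) -> float:
        return max(self.tr.values())

    def as_response_row(self) -> dict[str, float]:
        row = {K_COLUMNS[name]: self.k[name] for name in COMPOUND_NAMES}
        row["Rs_AB"] = self.rs_ab
        row["Rs_CD"] = self.rs_cd
        return row


def simulate_retention(
    truth: RetentionGroundTruth,
    conditions: MethodConditions,
    noise: bool = False,
    seed: int | np.random.Generator | None = None,
    concentrations: dict[str, float] | None = None,
) -> ChromOutcome:
    """Simulate one injection at the given conditions.

    log10 k is read from the per-compound surface at the coded conditions
    (plus Gaussian run-to-run noise of SD ``sigma_logk`` when ``noise``);
    tR = t0_eff (1 + k) with t0_eff = t0 · flow^(−flow_exponent); widths come
    from the shared plate count; areas from the detector response factors and
    the injected concentrations (standard mixture by default).
    """
    conditions.validate()
    coded = conditions.coded()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = dict(STANDARD_MIX_UG_ML if concentrations is None else concentrations)

    t0_eff = truth.t0 * conditions.flow ** (-truth.flow_exponent)
    shared_noise = 0.0
    if noise:
        rho = truth.noise_correlation
        shared_noise = rng.normal(0.0, truth.sigma_logk * np.sqrt(rho))
        sigma_ind = truth.sigma_logk * np.sqrt(1.0 - rho)
    k: dict[str, float] = {}
    tr: dict[str, float] = {}
    width: dict[str, float] = {}
    area: dict[str, float] = {}
    height: dict[str, float] = {}
    for name in COMPOUND_NAMES:
        logk = truth.logk(name, coded, conditions.temperature)
        if noise:
            logk += shared_noise + rng.normal(0.0, sigma_ind)
        k[name] = 10.0 ** logk
        tr[name] = t0_eff * (1.0 + k[name])
        width[name] = 4.0 * tr[name] / np.sqrt(truth.plate_count)
        area[name] = truth.response_factors[name] * conc.get(name, 0.0)
        sigma_t = width[name] / 4.0
        height[name] = area[name] / (sigma_t * np.sqrt(2.0 * np.pi))

    rs_ab = resolution(tr["impurity_a"], tr["impurity_b"],
                       width["impurity_a"], width["impurity_b"])
    rs_cd = resolution(tr["impurity_c"], tr["impurity_d"],
                       width["impurity_c"], width["impurity_d"])
    return ChromOutcome(conditions=conditions, t0=t0_eff, k=k, tr=tr,
                        width=width, area=area, height=height,
                        rs_ab=rs_ab, rs_cd=rs_cd)


def generate_study(
    truth: RetentionGroundTruth,
    design: DesignTable,
    seed: int | None = None,
    noise: bool = True,
    base_conditions: MethodConditions | None = None,
) -> pd.DataFrame:
    """Run the in-silico analogue of the screening experiments.

    Each design run is decoded to actual conditions and injected once;
    the result is a response table (run_id, k_M, k_A, k_B, k_C, k_D,
    Rs_AB, Rs_CD) row-aligned with the design.
    """
    rng = np.random.default_rng(seed)
    base = base_conditions or MethodConditions()
    rows = []
    for run_id, actual in zip(design.run_ids, design.actual):
        cond = replace(base, acn_percent=float(actual[0]), ph=float(actual[1]),
                       buffer_mm=float(actual[2]))
        outcome = simulate_retention(truth, cond, noise=noise, seed=rng)
        row = {"run_id": int(run_id)}
        row.update(outcome.as_response_row())
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# detector-level generators
# ----------------------------------------------------------------------

def simulate_chromatogram(
    outcome: ChromOutcome,
    baseline_sigma: float,
    sampling_rate: float = 5.0,
    seed: int | None = None,
    duration: float | None = None,
    include: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Render an outcome as a sampled trace (time_min, signal).

    The trace is a sum of Gaussian peaks (height = area / (σ√(2π)),
    σ = width/4) plus white baseline noise; deterministic for a fixed seed.
    ``include=()`` yields a pure-noise (placebo/blank) trace.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = outcome.last_peak_time + 2.0
    t = np.arange(0.0, duration, 1.0 / (sampling_rate * 60.0))
    signal = np.zeros_like(t)
    names = COMPOUND_NAMES if include is None else include
    for name in names:
        sigma_t = outcome.width[name] / 4.0
        signal += outcome.height[name] * np.exp(
            -0.5 * ((t - outcome.tr[name]) / sigma_t) ** 2
        )
    if baseline_sigma > 0:
        signal = signal + rng.normal(0.0, baseline_sigma, size=t.shape)
    return pd.DataFrame({"time_min": t, "signal": signal})


@dataclass
class CalibrationSeries:
    """Replicate detector responses over a concentration grid."""

    compound: str
    levels: np.ndarray                # µg/mL, strictly increasing
    responses: np.ndarray             # (n_levels, n_reps) area units
    seed: int | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("calibration levels must be strictly increasing")

    def mean_responses(self) -> np.ndarray:
        return self.responses.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n_levels, n_reps = self.responses.shape
        return pd.DataFrame({
            "compound": self.compound,
            "level": np.repeat(self.levels, n_reps),
            "replicate": np.tile(np.arange(1, n_reps + 1), n_levels),
            "response": self.responses.ravel(),
        })


def simulate_calibration(
    compound: str,
    true_slope: float | None = None,
    true_intercept: float = 0.0,
    levels=None,
    n_reps: int = 3,
    noise_model: tuple[float, float] | None = None,
    seed: int | None = None,
) -> CalibrationSeries:
    """Generate a linear calibration series with mild heteroscedastic noise.

    response = slope · conc + intercept + ε with ε ~ N(0, σ0 + σrel · response);
    the default (σ0, σrel) is (0.3 % of the mid-level response, 0.5 %).
    Slope defaults to the compound's response factor; levels default to the
    method's calibration grid (9 impurity levels / 6 API levels).
    """
    if true_slope is None:
        true_slope = RESPONSE_FACTORS[compound]
    if levels is None:
        levels = CALIBRATION_LEVELS[compound]
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    clean = true_slope * levels + true_intercept
    if noise_model is None:
        mid = true_slope * float(np.median(levels)) + true_intercept
        noise_model = (0.003 * abs(mid), 0.005)
    sigma0, sigma_rel = noise_model
    sd = sigma0 + sigma_rel * np.abs(clean)
    responses = clean[:, None] + rng.normal(0.0, 1.0, size=(len(levels), n_reps)) * sd[:, None]
    return CalibrationSeries(compound=compound, levels=levels,
                             responses=responses, seed=seed)


#: spike levels per compound for accuracy/precision work, µg/mL
SPIKE_LEVELS = {
    "moxonidine": {"80%": 80.0, "100%": 100.0, "120%": 120.0},
    "impurity_a": {"LOQ": 0.04, "100%": 0.5, "120%": 0.6},
    "impurity_b": {"LOQ": 0.04, "100%": 0.5, "120%": 0.6},
    "impurity_c": {"LOQ": 0.08, "100%": 1.0, "120%": 1.2},
    "impurity_d": {"LOQ": 0.08, "100%": 1.0, "120%": 1.2},
}


def simulate_spiked_placebo(
    compound: str,
    levels: dict[str, float] | None = None,
    true_recovery_bias: float = 1.0,
    rsd_found: float | None = None,
    n_per_level: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spiked-placebo recovery samples: found = nominal · (bias + noise).

    Returns one row per replicate with compound, level label, nominal and
    found concentration (µg/mL).  ``rsd_found`` is the relative SD of the
    found concentrations (preparation + injection variability); the default
    is 0.6 % for the API (large, precisely integrated peak) and 1.2 % for
    the trace-level impurities.
    """
    if rsd_found is None:
        rsd_found = 0.006 if COMPOUND_ROLES.get(compound) == "API" else 0.012
    if levels is None:
        levels = SPIKE_LEVELS[compound]
    rng = np.random.default_rng(seed)
    rows = []
    for label, nominal in levels.items():
        found = nominal * (true_recovery_bias
                           + rng.normal(0.0, rsd_found, size=n_per_level))
        for rep, f in enumerate(found, start=1):
            rows.append({"compound": compound, "level": label, "replicate": rep,
                         "nominal_ug_ml": nominal, "found_ug_ml": float(f)})
    return pd.DataFrame(rows)


def simulate_tablet_sample(
    true_content_percent: dict[str, float],
    truth: RetentionGroundTruth | None = None,
    nominal_api_ug_ml: float = 100.0,
    rsd_response: float = 0.005,
    n_preparations: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Detector responses of a tablet preparation at 100 µg/mL API nominal.

    ``true_content_percent`` maps compound → content as % of the API nominal
    concentration (API label claim for moxonidine, impurity percentages for
    the rest; 0 means absent).  Responses follow the calibration response
    factors with multiplicative noise.
    """
    truth = truth or default_ground_truth()
    rng = np.random.default_rng(seed)
    rows = []
    for prep in range(1, n_preparations + 1):
        for name in COMPOUND_NAMES:
            pct = float(true_content_percent.get(name, 0.0))
            if pct < 0:
                raise ValueError("contents must be >= 0")
            conc = pct / 100.0 * nominal_api_ug_ml
            resp = truth.response_factors[name] * conc
            resp *= 1.0 + rng.normal(0.0, rsd_response)
            rows.append({"preparation": prep, "compound": name,
                         "true_conc_ug_ml": conc, "response": resp})
    return pd.DataFrame(rows)
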