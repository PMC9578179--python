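"""Quasi-static lung mechanics model and synthetic two-arm cohort generator.

The lung is treated as a single compartment whose quasi-static pressure–volume
relation has two regimes, mirroring the stress–strain curve of an elastic
material:

* an **elastic regime** below the elastic-limit volume ``v_el``, where mean
  airway pressure rises linearly above PEEP with elastance ``e1``
  (cmH2O/mL), and
* a **plastic regime** above ``v_el``, where the curve stiffens
  exponentially at rate ``alpha`` (1/mL) — the regime in which elastic
  fibres begin to fail and further pressure buys no recoverable volume.

The two regimes join with a continuous first derivative, so the model slope
is non-decreasing everywhere.  A deflation limb uses the same functional
family with the elastic elastance divided by a hysteresis factor ``h >= 1``
(deflation holds more volume at a given pressure); its hinge pressure is the
ground truth for expiratory-limb PEEP selection.

The cohort generator emulates a two-arm animal experiment: each subject gets
lung parameters drawn from an arm-specific range, an inflation and a
deflation super-syringe maneuver (1 mL steps to 14 mL by default), and one
draw per configured outcome variable.  Continuous outcomes are calibrated so
the generating distribution's median and upper quartile equal the configured
ones; ordinal histology items are produced per rater from a correlated
latent normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LungParams",
    "PVManeuver",
    "OutcomeSpec",
    "ArmSpec",
    "LungParamRanges",
    "CohortConfig",
    "AnimalRecord",
    "pv_inflation_model",
    "pv_deflation_model",
    "simulate_maneuver",
    "simulate_cohort",
    "draw_lung_params",
    "draw_outcome",
    "lognormal_shape",
    "default_outcome_specs",
    "default_cohort_config",
]

#: third quartile of the standard normal, used throughout the calibration
_Z75 = 0.6744897501960817

ARM_STANDARD = "standard"
ARM_INDIVIDUALIZED = "individualized"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LungParams:
    """Generative parameters of one virtual lung.

    Parameters
    ----------
    peep:
        Pressure at zero injected volume, cmH2O (the individualized PEEP the
        maneuver starts from).
    e1:
        Elastance of the elastic zone, cmH2O/mL.
    v_el:
        Elastic-limit volume above baseline, mL.
    alpha:
        Plastic stiffening rate, 1/mL.  ``alpha = 0`` degenerates to a
        straight-line extension of the elastic zone.
    sigma:
        Standard deviation of i.i.d. Gaussian read-off noise on each
        pressure sample, cmH2O.
    hysteresis:
        Deflation-limb compliance gain (dimensionless, >= 1): the deflation
        elastic zone uses elastance ``e1 / hysteresis``.
    """

    peep: float
    e1: float
    v_el: float
    alpha: float = 0.5
    sigma: float = 0.3
    hysteresis: float = 1.4

    def __post_init__(self) -> None:
        if self.peep < 0:
            raise ValueError("peep must be >= 0")
        if self.e1 <= 0:
            raise ValueError("e1 must be > 0")
        if self.v_el <= 0:
            raise ValueError("v_el must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.hysteresis < 1:
            raise ValueError("hysteresis must be >= 1")

    @property
    def dp_true(self) -> float:
        """True driving pressure at the elastic limit, ``e1 * v_el`` (cmH2O)."""
        return self.e1 * self.v_el


@dataclass(eq=False)
class PVManeuver:
    """One quasi-static pressure–volume maneuver.

    Volumes are injected mL above baseline (strictly increasing, starting at
    0); pressures are mean airway pressure in cmH2O.  ``limb`` records
    whether the samples were acquired while inflating or deflating; the
    stored order is always ascending in volume.
    """

    subject_id: str
    limb: str
    v: np.ndarray
    p: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.limb not in ("inflation", "deflation"):
            raise ValueError(f"limb must be 'inflation' or 'deflation', got {self.limb!r}")
        if self.v.ndim != 1 or self.v.shape != self.p.shape:
            raise ValueError("v and p must be 1-D arrays of equal length")
        if self.v.size < 5:
            raise ValueError("a maneuver needs at least 5 points")
        if self.v[0] != 0.0:
            raise ValueError("first volume must be 0 (baseline)")
        if not np.all(np.diff(self.v) > 0):
            raise ValueError("volumes must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("all pressures must be finite")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @classmethod
    def from_points(
        cls, subject_id: str, limb: str, points: Iterable[tuple[float, float]], step: float
    ) -> "PVManeuver":
        """Build a maneuver from (volume, pressure) pairs in any order."""
        pts = sorted((float(v), float(p)) for v, p in points)
        v = np.array([q[0] for q in pts])
        p = np.array([q[1] for q in pts])
        return cls(subject_id=subject_id, limb=limb, v=v, p=p, step=step)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.v.tolist(), self.p.tolist()))

    @property
    def n(self) -> int:
        return int(self.v.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PVManeuver):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.limb == other.limb
            and self.step == other.step
            and np.array_equal(self.v, other.v)
            and np.array_equal(self.p, other.p)
        )


# ---------------------------------------------------------------------------
# pressure–volume law


def _pv_model(peep: float, e1: float, v_el: float, alpha: float, v: np.ndarray) -> np.ndarray:
    elastic = peep + e1 * v
    dv = np.maximum(v - v_el, 0.0)
    if alpha == 0.0:
        plastic = peep + e1 * v_el + e1 * dv
    else:
        plastic = peep + e1 * v_el + (e1 / alpha) * np.expm1(alpha * dv)
    return np.where(v <= v_el, elastic, plastic)


def pv_inflation_model(params: LungParams, v):
    """Noise-free inflation pressure (cmH2O) at injected volume ``v`` (mL).

    Linear below the elastic limit, exponentially stiffening above it; the
    join is C1-continuous so the slope never decreases.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ValueError("volume must be >= 0")
    out = _pv_model(params.peep, params.e1, params.v_el, params.alpha, arr)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def pv_deflation_model(params: LungParams, v):
    """Noise-free deflation pressure at volume ``v``.

    Same two-regime family anchored at the same zero-volume pressure, with
    elastic elastance ``e1 / hysteresis`` — at any volume the deflation limb
    sits at or below the inflation limb, the classical P–V hysteresis loop.
    Its hinge pressure ``peep + (e1/h) * v_el`` marks derecruitment onset.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ValueError("volume must be >= 0")
    out = _pv_model(params.peep, params.e1 / params.hysteresis, params.v_el, params.alpha, arr)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def simulate_maneuver(
    params: LungParams,
    v_max: float = 14.0,
    step: float = 1.0,
    limb: str = "inflation",
    seed=None,
    subject_id: str = "sim",
) -> PVManeuver:
    """Simulate one super-syringe maneuver: volumes 0, step, ..., v_max.

    Gaussian noise of sd ``params.sigma`` is added independently to every
    pressure reading (including the zero-volume baseline).  Deflation limbs
    are sampled from ``v_max`` down to 0 and stored ascending.  The same
    ``seed`` always reproduces the same maneuver bit for bit.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if v_max < 3 * step:
        raise ValueError("v_max must be at least 3 steps")
    n_steps = v_max / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"v_max={v_max} is not an integer number of steps of {step}")
    n_steps = int(round(n_steps))
    v = np.arange(n_steps + 1, dtype=float) * step

    rng = np.random.default_rng(seed)
    if limb == "inflation":
        clean = pv_inflation_model(params, v)
        noise = rng.normal(0.0, params.sigma, size=v.size)
    elif limb == "deflation":
        clean = pv_deflation_model(params, v)
        # noise drawn in acquisition order (v_max down to 0), stored ascending
        noise = rng.normal(0.0, params.sigma, size=v.size)[::-1]
    else:
        raise ValueError(f"unknown limb {limb!r}")
    return PVManeuver(subject_id=subject_id, limb=limb, v=v, p=clean + noise, step=float(step))


# ---------------------------------------------------------------------------
# outcome specifications


@dataclass(frozen=True)
class ArmSpec:
    """Location/spread of one outcome in one arm: median and [p25, p75]."""

    median: float
    p25: float
    p75: float

    def __post_init__(self) -> None:
        if not (self.p25 <= self.median <= self.p75):
            raise ValueError(
                f"median must lie within [p25, p75]; got {self.median} vs "
                f"[{self.p25}, {self.p75}]"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome variable's generating family and per-arm calibration.

    ``family`` is one of ``lognormal`` (strictly positive, right-skewed,
    e.g. cytokine concentrations), ``normal`` (e.g. cell fractions) or
    ``ordinal`` (0–4 histology items, scored per rater from a correlated
    latent normal).
    """

    name: str
    family: str
    arms: Mapping[str, ArmSpec]

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal", "ordinal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "lognormal":
            for arm, a in self.arms.items():
                if a.median <= 0 or a.p25 <= 0 or a.p75 <= 0:
                    raise ValueError(
                        f"lognormal outcome {self.name!r}/{arm} requires strictly "
                        "positive median and quartiles"
                    )


def lognormal_shape(median: float, p75: float) -> tuple[float, float]:
    """Return (mu, sigma) of the lognormal with the given median and p75.

    mu = ln(median); sigma solves p75 = exp(mu + sigma * z_{0.75}).  The
    lower quartile is then implied (median**2 / p75) rather than free — a
    two-parameter lognormal cannot match three independent quantiles.
    """
    mu = math.log(median)
    sigma = (math.log(p75) - mu) / _Z75
    if sigma < 0:
        raise ValueError("p75 must be >= median for a lognormal calibration")
    return mu, sigma


def draw_outcome(spec: ArmSpec, family: str, rng: np.random.Generator, size=None):
    """Draw from the calibrated generating distribution of one arm."""
    if family == "lognormal":
        mu, sigma = lognormal_shape(spec.median, spec.p75)
        return rng.lognormal(mu, sigma, size=size)
    if family == "normal":
        sd = (spec.p75 - spec.p25) / (2 * _Z75)
        return rng.normal(spec.median, sd, size=size)
    raise ValueError(f"draw_outcome does not handle family {family!r}")


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass(frozen=True)
class LungParamRanges:
    """Uniform sampling ranges for per-animal lung parameters.

    The driving pressure at the elastic limit is drawn directly
    (``dp_target``) and converted to ``e1 = dp / v_el`` so the cohort's true
    DP distribution is controlled explicitly; the default 8–14 cmH2O span
    brackets the experimental arm's reported DP range.  PEEP is drawn from a
    small set of whole-cmH2O levels weighted toward 12, the typical
    individualized PEEP of this model.
    """

    dp_target: tuple[float, float] = (8.0, 14.0)
    v_el: tuple[float, float] = (5.0, 10.0)
    #: total plastic stiffening exponent alpha * (v_max - v_el) over the
    #: observable plastic range; 1.5–2.8 keeps end-of-maneuver elastance at
    #: 4.5–16x the elastic value and end pressures in a physiologic band
    #: (~25–55 cmH2O) wherever the elastic limit falls.
    gamma: tuple[float, float] = (1.5, 2.8)
    hysteresis: tuple[float, float] = (1.2, 1.8)
    sigma: float = 0.3
    peep_choices: tuple[float, ...] = (9.0, 10.0, 11.0, 12.0)
    peep_probs: tuple[float, ...] = (0.1, 0.2, 0.2, 0.5)

    def __post_init__(self) -> None:
        for name in ("dp_target", "v_el", "gamma", "hysteresis"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is inverted")
        if len(self.peep_choices) != len(self.peep_probs):
            raise ValueError("peep_choices and peep_probs must have equal length")
        if abs(sum(self.peep_probs) - 1.0) > 1e-9:
            raise ValueError("peep_probs must sum to 1")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a two-arm synthetic cohort."""

    n_per_arm: int = 10
    seed: int = 0
    arms: Mapping[str, LungParamRanges] = field(
        default_factory=lambda: {
            ARM_STANDARD: LungParamRanges(),
            ARM_INDIVIDUALIZED: LungParamRanges(),
        }
    )
    outcomes: Sequence[OutcomeSpec] = field(default_factory=lambda: default_outcome_specs())
    raters: tuple[str, ...] = ("rater_1", "rater_2")
    rater_correlation: float = 0.8
    v_max: float = 14.0
    step: float = 1.0
    weight_mean_g: float = 357.0
    weight_sd_g: float = 21.0
    fio2: float = 0.8

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if len(self.arms) != 2:
            raise ValueError("exactly two arms are required")
        if not 0 <= self.rater_correlation <= 1:
            raise ValueError("rater_correlation must be in [0, 1]")
        for spec in self.outcomes:
            missing = set(self.arms) - set(spec.arms)
            if missing:
                raise ValueError(f"outcome {spec.name!r} lacks specs for arms {sorted(missing)}")


@dataclass
class AnimalRecord:
    """One subject: arm, lung, maneuvers, outcome draws and ALI ratings."""

    subject_id: str
    arm: str
    weight_g: float
    params: LungParams
    inflation: PVManeuver
    deflation: PVManeuver
    outcomes: dict[str, float]
    ali_ratings: dict[str, dict[str, int]]


def default_outcome_specs() -> list[OutcomeSpec]:
    """Default two-arm outcome calibration (post-ventilation time point).

    Medians/IQRs follow the reported contrasts of the severe-ARDS rat
    experiment this generator emulates: BAL cytokines fall under
    individualized driving pressure, lymphocyte fraction falls, histological
    injury is roughly three times lower; gases barely move.
    """

    def spec(name, family, std, ind):
        return OutcomeSpec(
            name=name,
            family=family,
            arms={ARM_STANDARD: ArmSpec(*std), ARM_INDIVIDUALIZED: ArmSpec(*ind)},
        )

    return [
        spec("il6_pgml", "lognormal", (270, 230, 340), (155, 42, 210)),
        spec("tnfa_pgml", "lognormal", (292, 259, 305), (139, 110, 217)),
        spec("il1b_pgml", "lognormal", (563, 376, 732), (331, 311, 572)),
        spec("pao2_mmhg", "lognormal", (121, 109, 143), (137, 91, 181)),
        spec("paco2_mmhg", "lognormal", (75, 59, 90), (92, 68, 102)),
        spec("lactate_mmoll", "lognormal", (1.8, 1.0, 3.7), (2.0, 1.4, 3.9)),
        spec("lymphocytes_pct", "normal", (96, 95, 97), (79, 65, 90)),
        spec("monocytes_pct", "normal", (2, 1, 3), (3, 2, 5)),
        spec("pmn_pct", "normal", (2, 2, 3), (13, 2, 24)),
        spec("ali_congestion", "ordinal", (2, 1, 3), (1, 1, 2)),
        spec("ali_hemorrhage", "ordinal", (0, 0, 3), (0, 0, 1)),
        spec("ali_neutrophil_infiltration", "ordinal", (2, 1, 2.5), (1, 0, 1)),
        spec("ali_hyaline_membrane", "ordinal", (0, 0, 2), (0, 0, 1)),
    ]


#: ordinal spec name -> ALI item it scores
ALI_SPEC_ITEMS = {
    "ali_congestion": "congestion",
    "ali_hemorrhage": "hemorrhage",
    "ali_neutrophil_infiltration": "neutrophil_infiltration",
    "ali_hyaline_membrane": "hyaline_membrane",
}


def default_cohort_config(seed: int = 0, n_per_arm: int = 10) -> CohortConfig:
    return CohortConfig(seed=seed, n_per_arm=n_per_arm)


# ---------------------------------------------------------------------------
# cohort simulation


def draw_lung_params(
    ranges: LungParamRanges, rng: np.random.Generator, v_max: float = 14.0
) -> LungParams:
    """Draw one animal's lung parameters from uniform ranges.

    The driving pressure at the elastic limit and the total plastic
    stiffening exponent are drawn directly and converted to ``e1`` and
    ``alpha``, so the cohort's DP span and pressure scale are controlled
    explicitly.
    """
    v_el = rng.uniform(*ranges.v_el)
    dp = rng.uniform(*ranges.dp_target)
    gamma = rng.uniform(*ranges.gamma)
    peep = float(rng.choice(np.asarray(ranges.peep_choices), p=np.asarray(ranges.peep_probs)))
    tail = max(v_max - v_el, 1e-6)
    return LungParams(
        peep=peep,
        e1=dp / v_el,
        v_el=v_el,
        alpha=gamma / tail,
        sigma=ranges.sigma,
        hysteresis=rng.uniform(*ranges.hysteresis),
    )


def _draw_ordinal_ratings(
    spec: ArmSpec, raters: Sequence[str], rho: float, rng: np.random.Generator
) -> dict[str, int]:
    """Per-rater 0–4 scores from a shared latent normal with correlation rho."""
    sd = (spec.p75 - spec.p25) / (2 * _Z75)
    common = rng.normal()
    out = {}
    for rater in raters:
        z = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * rng.normal()
        score = spec.median + sd * z
        out[rater] = int(min(4, max(0, round(score))))
    return out


def simulate_cohort(config: CohortConfig) -> list[AnimalRecord]:
    """Generate a full two-arm cohort of :class:`AnimalRecord`.

    All randomness descends from ``config.seed`` through a spawned
    ``SeedSequence`` per animal (three substreams: parameters+outcomes,
    inflation maneuver, deflation maneuver), so adding animals or stages
    never perturbs earlier draws and equal configs give identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    records: list[AnimalRecord] = []
    arm_prefix = {ARM_STANDARD: "S", ARM_INDIVIDUALIZED: "I"}

    for arm, ranges in config.arms.items():
        for i in range(config.n_per_arm):
            child = root.spawn(1)[0]
            ss_draw, ss_inf, ss_def = child.spawn(3)
            rng = np.random.default_rng(ss_draw)

            params = draw_lung_params(ranges, rng, v_max=config.v_max)
            weight = max(1.0, rng.normal(config.weight_mean_g, config.weight_sd_g))
            sid = f"{arm_prefix.get(arm, arm[:1].upper())}{i + 1:02d}"

            inflation = simulate_maneuver(
                params, config.v_max, config.step, "inflation", seed=ss_inf, subject_id=sid
            )
            deflation = simulate_maneuver(
                params, config.v_max, config.step, "deflation", seed=ss_def, subject_id=sid
            )

            outcomes: dict[str, float] = {}
            ali: dict[str, dict[str, int]] = {r: {} for r in config.raters}
            for spec in config.outcomes:
                arm_spec = spec.arms[arm]
                if spec.family == "ordinal":
                    item = ALI_SPEC_ITEMS.get(spec.name, spec.name)
                    ratings = _draw_ordinal_ratings(
                        arm_spec, config.raters, config.rater_correlation, rng
                    )
                    for rater, score in ratings.items():
                        ali[rater][item] = score
                else:
                    outcomes[spec.name] = float(draw_outcome(arm_spec, spec.family, rng))

            # cell fractions sum to 100% of the counted population
            frac_keys = [k for k in outcomes if k.endswith("_pct")]
            if len(frac_keys) >= 2:
                vals = np.array([max(0.0, outcomes[k]) for k in frac_keys])
                total = vals.sum()
                if total > 0:
                    vals = vals * 100.0 / total
                for k, val in zip(frac_keys, vals):
                    outcomes[k] = float(val)

            records.append(
                AnimalRecord(
                    subject_id=sid,
                    arm=arm,
                    weight_g=float(weight),
                    params=params,
                    inflation=inflation,
                    deflation=deflation,
                    outcomes=outcomes,
                    ali_ratings=ali,
                )
            )
    return records
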