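"""Synthetic aging-cohort generator calibrated to sex x genotype group statistics.

Emulates a cross-sectional frailty study of four mouse groups (male/female x
3xTg-AD/wild-type): each mouse receives one frailty assessment at a random
age, its item scores are drawn so that the expected FI follows a group
exponential trajectory f(age) = min(f0 * exp(m * age/10), ceiling), and its
death day is drawn from a Gompertz hazard scaled up by current expected
frailty, left-truncated at the assessment age.  Heavy censoring and
unknown-vital-status records reproduce the bookkeeping of real husbandry
data.

Calibration works backwards from published group summaries:

* the latent trajectory rate is root-found so that the *estimand* of the
  downstream ln-FI-on-age least-squares regression equals the target rate of
  deficit accumulation (the log of a noisy FI is biased low, more so at
  young ages where FI is small, so the naive trajectory rate would be
  over-recovered by 4-7%);
* the trajectory intercept f0 comes analytically from the target mean FI of
  mice assessed at 300-600 days of age (uniform age in the band);
* the Gompertz baseline hazard is root-found so that the unconditional mean
  lifespan matches the target, using the exact discrete survival curve of
  the day-stepped death process as the integration oracle.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import brentq

from .fi_core import (
    DEFAULT_TEMP_REF,
    DEFAULT_WEIGHT_REF,
    ConfigurationError,
    Genotype,
    ItemCatalog,
    ItemMode,
    MouseAssessment,
    Sex,
    default_catalog,
)

__all__ = [
    "VitalStatus",
    "GroupParams",
    "GroupTargets",
    "CohortRecord",
    "CalibrationError",
    "FI_FLOOR",
    "expected_fi",
    "expected_ln_fi",
    "expected_loglinear_slope",
    "mean_lifespan",
    "simulate_assessment",
    "simulate_fi_values",
    "simulate_death",
    "simulate_death_days",
    "calibrate_group",
    "simulate_cohort",
    "default_group_targets",
    "default_groups",
]

#: Floor applied to FI scores of 0 before taking logs: half the smallest
#: whole-deficit contribution on the 31-item instrument, 1/(2*31).
FI_FLOOR = 1.0 / 62.0


class CalibrationError(RuntimeError):
    """Root-finding for a calibration target failed."""


class VitalStatus(str, enum.Enum):
    DIED = "died"
    CENSORED = "censored"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GroupTargets:
    """Published summaries one sex x genotype group is calibrated against."""

    slope: float  # rate of deficit accumulation, ln FI per 10 days
    band_mean: float  # mean FI of mice assessed at 300-600 days
    mean_lifespan: float  # mean death day, uncensored, days


@dataclass(frozen=True)
class GroupParams:
    """Full simulator calibration for one sex x genotype group.

    ``m`` is the latent trajectory rate actually driving expected FI
    (per 10 days of age on the natural-log scale); ``targets.slope`` is the
    regression slope the group is calibrated to reproduce.  ``beta`` is the
    log-hazard increment per unit FI, so mortality tracks frailty.
    """

    sex: Sex
    genotype: Genotype
    m: float  # latent ln-FI trajectory rate per 10 days
    f0: float  # expected FI at age 0
    lambda0: float  # Gompertz baseline hazard, per day
    gamma: float  # Gompertz shape, per day
    beta: float  # log-hazard per unit FI
    age_range: tuple[int, int]  # assessment ages, uniform integer days
    p_cens: float  # probability follow-up is censored
    p_unknown: float = 0.0  # probability vital status is lost
    f_ceiling: float = 0.70  # submaximal FI limit
    fi_floor: float = FI_FLOOR
    weight_ref: tuple[float, float] = DEFAULT_WEIGHT_REF
    temp_ref: tuple[float, float] = DEFAULT_TEMP_REF
    targets: Optional[GroupTargets] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        if self.m <= 0:
            raise ConfigurationError(f"m must be positive, got {self.m}")
        if not 0 < self.f0 < self.f_ceiling <= 1:
            raise ConfigurationError(
                f"need 0 < f0 < f_ceiling <= 1, got f0={self.f0}, "
                f"f_ceiling={self.f_ceiling}"
            )
        if self.lambda0 <= 0 or self.gamma < 0:
            raise ConfigurationError("need lambda0 > 0 and gamma >= 0")
        if not 0 <= self.p_cens < 1:
            raise ConfigurationError(f"p_cens must lie in [0, 1), got {self.p_cens}")
        if not 0 <= self.p_unknown < 1:
            raise ConfigurationError("p_unknown must lie in [0, 1)")

    @property
    def label(self) -> str:
        sex = "male" if self.sex is Sex.MALE else "female"
        return f"{sex}_{self.genotype.value.lower()}"


@dataclass
class CohortRecord:
    """One simulated mouse: frailty assessment joined to vital status."""

    assessment: MouseAssessment
    status: VitalStatus
    death_day: Optional[int] = None
    censor_day: Optional[int] = None

    def __post_init__(self) -> None:
        self.status = VitalStatus(self.status)
        a = self.assessment.age_at_fi
        if self.status is VitalStatus.DIED:
            if self.death_day is None or self.censor_day is not None:
                raise ConfigurationError(
                    f"mouse {self.mouse_id!r}: DIED needs death_day only"
                )
            if self.death_day < a:
                raise ConfigurationError(
                    f"mouse {self.mouse_id!r}: death_day {self.death_day} "
                    f"precedes assessment age {a}"
                )
        elif self.status is VitalStatus.CENSORED:
            if self.censor_day is None or self.death_day is not None:
                raise ConfigurationError(
                    f"mouse {self.mouse_id!r}: CENSORED needs censor_day only"
                )
            if self.censor_day < a:
                raise ConfigurationError(
                    f"mouse {self.mouse_id!r}: censor_day {self.censor_day} "
                    f"precedes assessment age {a}"
                )
        else:
            if self.death_day is not None or self.censor_day is not None:
                raise ConfigurationError(
                    f"mouse {self.mouse_id!r}: UNKNOWN status cannot carry "
                    f"death_day or censor_day"
                )

    @property
    def mouse_id(self) -> str:
        return self.assessment.mouse_id

    @property
    def age_at_fi(self) -> int:
        return self.assessment.age_at_fi

    @property
    def sex(self) -> Sex:
        return self.assessment.sex

    @property
    def genotype(self) -> Genotype:
        return self.assessment.genotype


# ---------------------------------------------------------------------------
# Expected trajectory and its exact ln-FI transform
# ---------------------------------------------------------------------------


def expected_fi(age, params: GroupParams):
    """Expected FI at an age: min(f0 * exp(m * age/10), f_ceiling)."""
    age = np.asarray(age, dtype=float)
    # clip the exponent at the ceiling so extreme ages cannot overflow
    log_cap = np.log(params.f_ceiling / params.f0)
    f = params.f0 * np.exp(np.minimum(params.m * age / 10.0, log_cap))
    return np.minimum(f, params.f_ceiling)


def _item_counts(catalog: ItemCatalog) -> tuple[int, int]:
    return len(catalog.ordinal_items), len(catalog.z_items)


def expected_ln_fi(
    f, fi_floor: float = FI_FLOOR, n_ordinal: int = 29, n_z: int = 2
):
    """Exact E[ln max(FI, floor)] when expected FI is ``f``.

    Under the item-noise mechanism, the FI numerator is 0.5 * X + 0.25 * Y
    with X ~ Binomial(2 * n_ordinal, f) and Y ~ Binomial(4 * n_z, f), so the
    expectation is a finite sum over the joint support.  This is the oracle
    the slope calibration inverts.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    n_items = n_ordinal + n_z
    x = np.arange(2 * n_ordinal + 1)
    y = np.arange(4 * n_z + 1)
    fi = (0.5 * x[:, None] + 0.25 * y[None, :]) / n_items
    ln_fi = np.log(np.maximum(fi, fi_floor))
    px = stats.binom.pmf(x[None, :], 2 * n_ordinal, f[:, None])  # (nf, nx)
    py = stats.binom.pmf(y[None, :], 4 * n_z, f[:, None])  # (nf, ny)
    out = np.einsum("ax,xy,ay->a", px, ln_fi, py)
    return out if out.size > 1 else float(out[0])


def _f0_from_band_mean(m: float, band_mean: float, band=(300.0, 600.0)) -> float:
    """Invert the band-mean integral of f0 * exp(m*t/10) over uniform age."""
    lo, hi = band
    k = m / 10.0
    if abs(k) < 1e-12:
        return band_mean
    return band_mean * (hi - lo) * k / (np.exp(hi * k) - np.exp(lo * k))


def expected_loglinear_slope(
    m: float,
    band_mean: float,
    age_range: tuple[int, int],
    fi_floor: float = FI_FLOOR,
    f_ceiling: float = 0.70,
    n_ordinal: int = 29,
    n_z: int = 2,
) -> float:
    """Estimand of OLS(ln FI ~ age/10) for a latent trajectory rate ``m``.

    Evaluates the exact E[ln FI] at every integer assessment age in the
    range (ages are drawn uniformly on integers) and returns the population
    least-squares slope.  Because ln is concave and FI is noisy, this
    exceeds ``m``; calibration chooses ``m`` so it hits the target slope.
    """
    ages = np.arange(age_range[0], age_range[1] + 1, dtype=float)
    f0 = _f0_from_band_mean(m, band_mean)
    f = np.minimum(f0 * np.exp(m * ages / 10.0), f_ceiling)
    ey = expected_ln_fi(f, fi_floor, n_ordinal, n_z)
    x = ages / 10.0
    xc = x - x.mean()
    return float(xc @ (ey - ey.mean()) / (xc @ xc))


# ---------------------------------------------------------------------------
# Item-level assessment simulation
# ---------------------------------------------------------------------------


def _z_bin_indices(catalog: ItemCatalog) -> list[dict[float, int]]:
    """Map each achievable quarter score to a bin index, per z-binned item."""
    maps = []
    for it in catalog.z_items:
        lookup: dict[float, int] = {}
        for j in range(5):
            s = j / 4.0
            try:
                lookup[s] = list(it.bin_scores).index(s)
            except ValueError:
                raise ConfigurationError(
                    f"simulator needs quarter scores in bin_scores of item "
                    f"{it.name!r}; got {tuple(it.bin_scores)}"
                ) from None
        maps.append(lookup)
    return maps


def _draw_scores(f: np.ndarray, n_ordinal: int, n_z: int, rng) -> tuple:
    """Draw per-item scores with expectation ``f`` per mouse.

    Ordinal item: 0.5 * Binomial(2, f) (support {0, 0.5, 1}); z-binned item:
    0.25 * Binomial(4, f) (support {0, .25, .5, .75, 1}).  Both have
    expectation f, so E[FI] = f exactly.
    """
    n = f.shape[0]
    ordinal = rng.binomial(2, f[:, None], size=(n, n_ordinal)) * 0.5
    zq = rng.binomial(4, f[:, None], size=(n, n_z))  # quarter counts, 0..4
    return ordinal, zq


def _raw_from_bin(
    zq_col: np.ndarray, item, score_to_bin: dict[float, int], rng
) -> np.ndarray:
    """Emit raw measurements whose |z| falls inside the bin for each score."""
    edges = np.asarray(item.bin_edges, dtype=float)
    lows = np.concatenate([[0.0], edges])
    highs = np.concatenate([edges, [edges[-1] + 1.0]])
    k = np.array([score_to_bin[j / 4.0] for j in range(5)])[zq_col]
    z = lows[k] + (highs[k] - lows[k]) * rng.uniform(
        np.nextafter(0.0, 1.0), 1.0, size=zq_col.shape
    )
    sign = rng.choice([-1.0, 1.0], size=zq_col.shape)
    return item.ref_mean + sign * z * item.ref_sd


def simulate_assessment(
    age: int,
    params: GroupParams,
    rng: np.random.Generator,
    catalog: Optional[ItemCatalog] = None,
    mouse_id: str = "sim",
) -> MouseAssessment:
    """Simulate one mouse's assessment at a given age.

    Every item score has expectation f = expected_fi(age), and the raw
    weight/temperature measurements are placed inside the |z| bin mapping to
    the drawn score, so re-scoring the assessment reproduces the drawn FI
    exactly and E[FI] = f.
    """
    if catalog is None:
        catalog = default_catalog()
    lo, hi = params.age_range
    if not lo <= age <= hi:
        raise ConfigurationError(
            f"age {age} outside the group's assessment range [{lo}, {hi}]"
        )
    f = np.array([float(expected_fi(age, params))])
    n_ordinal, n_z = _item_counts(catalog)
    ordinal, zq = _draw_scores(f, n_ordinal, n_z, rng)
    bin_maps = _z_bin_indices(catalog)
    raws = [
        float(_raw_from_bin(zq[:, j], it, bin_maps[j], rng)[0])
        for j, it in enumerate(catalog.z_items)
    ]
    weight = raws[0] if len(raws) > 0 else None
    temperature = raws[1] if len(raws) > 1 else None
    return MouseAssessment(
        mouse_id=mouse_id,
        sex=params.sex,
        genotype=params.genotype,
        age_at_fi=int(age),
        ordinal_scores={
            it.name: float(ordinal[0, j])
            for j, it in enumerate(catalog.ordinal_items)
        },
        weight=weight,
        temperature=temperature,
    )


def simulate_fi_values(
    ages: np.ndarray,
    params: GroupParams,
    rng: np.random.Generator,
    catalog: Optional[ItemCatalog] = None,
) -> np.ndarray:
    """Vectorised fast path: draw the FI each mouse would score.

    Identical in distribution to scoring full simulated assessments (the
    raw-measurement round trip is exact by construction); used where only
    the aggregate FI matters.
    """
    if catalog is None:
        catalog = default_catalog()
    n_ordinal, n_z = _item_counts(catalog)
    f = np.asarray(expected_fi(np.asarray(ages, dtype=float), params))
    ordinal, zq = _draw_scores(np.atleast_1d(f), n_ordinal, n_z, rng)
    total = ordinal.sum(axis=1) + 0.25 * zq.sum(axis=1)
    return total / (n_ordinal + n_z)


# ---------------------------------------------------------------------------
# Frailty-dependent Gompertz mortality
# ---------------------------------------------------------------------------


def _log_survival_grid(params: GroupParams, tol: float = 1e-12) -> np.ndarray:
    """log S(t) of the day-stepped death process at t = 0, 1, ..., H.

    The continuous hazard h(t) = lambda0 * exp(gamma*t + beta*f(t)) is
    discretised to daily death probabilities p_u = 1 - exp(-h(u + 1/2));
    the grid extends until survival is numerically exhausted, so both
    calibration sums and sampling see the same process.
    """
    horizon = 4096
    while True:
        t_mid = np.arange(horizon) + 0.5
        f = expected_fi(t_mid, params)
        h = params.lambda0 * np.exp(params.gamma * t_mid + params.beta * f)
        # daily death prob p_u = 1 - exp(-h), so log per-day survival = -h
        log_s = np.concatenate([[0.0], -np.cumsum(h)])
        if np.exp(log_s[-1]) < tol or horizon >= 2**20:
            return log_s
        horizon *= 4


def mean_lifespan(params: GroupParams) -> float:
    """Exact mean death day of the day-stepped process (E[T] = sum_t S(t))."""
    return float(np.exp(_log_survival_grid(params)[:-1]).sum())


def simulate_death_days(
    entry_ages: np.ndarray,
    params: GroupParams,
    rng: np.random.Generator,
    log_s: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw death days conditional on survival to each entry age.

    Inverse-transform sampling on the discrete survival curve: the death day
    d satisfies S(d)/S(a) < U <= S(d-1)/S(a), which is day-stepped thinning
    of the frailty-scaled Gompertz hazard, left-truncated at entry.
    """
    if log_s is None:
        log_s = _log_survival_grid(params)
    a = np.asarray(entry_ages, dtype=int)
    if np.any(a < 0):
        raise ConfigurationError("entry ages must be non-negative")
    if np.any(a >= len(log_s) - 1):
        raise ConfigurationError("entry age beyond the survival horizon")
    u = rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=a.shape)
    target = log_s[a] + np.log(u)
    d = np.searchsorted(-log_s, -target, side="right")
    return np.minimum(d, len(log_s) - 1).astype(int)


def simulate_death(
    age_at_fi: int, params: GroupParams, rng: np.random.Generator
) -> int:
    """Draw one death day, conditional on being alive at the assessment."""
    return int(simulate_death_days(np.array([age_at_fi]), params, rng)[0])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibrate_group(
    targets: GroupTargets,
    *,
    sex: Sex,
    genotype: Genotype,
    age_range: tuple[int, int],
    p_cens: float,
    p_unknown: float = 0.0,
    gamma: float = 0.005,
    beta: float = 4.0,
    f_ceiling: float = 0.70,
    fi_floor: float = FI_FLOOR,
    weight_ref: tuple[float, float] = DEFAULT_WEIGHT_REF,
    temp_ref: tuple[float, float] = DEFAULT_TEMP_REF,
    n_ordinal: int = 29,
    n_z: int = 2,
) -> GroupParams:
    """Solve the free trajectory and hazard parameters from group targets.

    The latent rate ``m`` makes the ln-FI regression estimand equal the
    target slope; ``f0`` then follows analytically from the 300-600 day
    band mean; ``lambda0`` is root-found so the unconditional mean death
    day matches the target mean lifespan.
    """
    if targets.band_mean >= f_ceiling:
        raise CalibrationError(
            f"band mean {targets.band_mean} must lie below the FI ceiling "
            f"{f_ceiling}"
        )
    if min(targets.slope, targets.band_mean, targets.mean_lifespan) <= 0:
        raise CalibrationError("calibration targets must be positive")

    def slope_gap(m: float) -> float:
        return (
            expected_loglinear_slope(
                m, targets.band_mean, age_range, fi_floor, f_ceiling,
                n_ordinal, n_z,
            )
            - targets.slope
        )

    lo, hi = 0.3 * targets.slope, 1.5 * targets.slope
    try:
        m_latent = brentq(slope_gap, lo, hi, xtol=1e-9)
    except ValueError as exc:
        raise CalibrationError(
            f"no latent rate in [{lo:.4g}, {hi:.4g}] reproduces slope "
            f"{targets.slope} (gap at ends: {slope_gap(lo):+.4g}, "
            f"{slope_gap(hi):+.4g})"
        ) from exc

    f0 = _f0_from_band_mean(m_latent, targets.band_mean)

    def mean_gap(log10_lam: float) -> float:
        p = GroupParams(
            sex=sex, genotype=genotype, m=m_latent, f0=f0,
            lambda0=10.0 ** log10_lam, gamma=gamma, beta=beta,
            age_range=age_range, p_cens=p_cens, p_unknown=p_unknown,
            f_ceiling=f_ceiling, fi_floor=fi_floor,
            weight_ref=weight_ref, temp_ref=temp_ref,
        )
        return mean_lifespan(p) - targets.mean_lifespan

    try:
        log10_lam = brentq(mean_gap, -9.0, -0.5, xtol=1e-10)
    except ValueError as exc:
        raise CalibrationError(
            f"no baseline hazard in [1e-9, 10^-0.5]/day reproduces mean "
            f"lifespan {targets.mean_lifespan} d (gap at ends: "
            f"{mean_gap(-9.0):+.4g}, {mean_gap(-0.5):+.4g})"
        ) from exc

    return GroupParams(
        sex=sex, genotype=genotype, m=m_latent, f0=f0,
        lambda0=10.0 ** log10_lam, gamma=gamma, beta=beta,
        age_range=age_range, p_cens=p_cens, p_unknown=p_unknown,
        f_ceiling=f_ceiling, fi_floor=fi_floor,
        weight_ref=weight_ref, temp_ref=temp_ref, targets=targets,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def simulate_cohort(
    groups: Sequence[GroupParams],
    n_per_group: int,
    seed: int,
    catalog: Optional[ItemCatalog] = None,
    age_range: Optional[tuple[int, int]] = None,
) -> list[CohortRecord]:
    """Simulate a full cross-sectional cohort, deterministically per seed.

    Per mouse: assessment age uniform on the group's integer age range
    (or an override, e.g. to restrict to one age band); item scores drawn
    around the expected trajectory; death day drawn left-truncated at the
    assessment; vital status lost with probability p_unknown, otherwise
    censored with probability p_cens at a uniform day between assessment
    and death.
    """
    if n_per_group <= 0:
        raise ConfigurationError("n_per_group must be positive")
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(seed)
    n_ordinal, n_z = _item_counts(catalog)
    bin_maps = _z_bin_indices(catalog)
    records: list[CohortRecord] = []
    for params in groups:
        lo, hi = age_range if age_range is not None else params.age_range
        ages = rng.integers(max(lo, 1), hi + 1, size=n_per_group)
        f = np.asarray(expected_fi(ages.astype(float), params))
        ordinal, zq = _draw_scores(f, n_ordinal, n_z, rng)
        raws = np.column_stack(
            [
                _raw_from_bin(zq[:, j], it, bin_maps[j], rng)
                for j, it in enumerate(catalog.z_items)
            ]
        )
        death = simulate_death_days(ages, params, rng)
        u_unknown = rng.random(n_per_group) < params.p_unknown
        u_cens = rng.random(n_per_group) < params.p_cens
        censor_draw = rng.integers(ages + 1, death + 1)

        ordinal_names = [it.name for it in catalog.ordinal_items]
        for i in range(n_per_group):
            assessment = MouseAssessment(
                mouse_id=f"{params.label}_{i:05d}",
                sex=params.sex,
                genotype=params.genotype,
                age_at_fi=int(ages[i]),
                ordinal_scores={
                    name: float(ordinal[i, j])
                    for j, name in enumerate(ordinal_names)
                },
                weight=float(raws[i, 0]) if n_z > 0 else None,
                temperature=float(raws[i, 1]) if n_z > 1 else None,
            )
            if u_unknown[i]:
                rec = CohortRecord(assessment, VitalStatus.UNKNOWN)
            elif u_cens[i]:
                rec = CohortRecord(
                    assessment, VitalStatus.CENSORED,
                    censor_day=int(censor_draw[i]),
                )
            else:
                rec = CohortRecord(
                    assessment, VitalStatus.DIED, death_day=int(death[i])
                )
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Shipped default calibration
# ---------------------------------------------------------------------------


def _load_default_config() -> dict:
    with resources.files("mcfi.data").joinpath("default_groups.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_group_targets() -> dict[str, dict]:
    """Raw target blocks of the shipped group configuration."""
    return _load_default_config()["groups"]


@functools.lru_cache(maxsize=1)
def default_groups() -> dict[str, GroupParams]:
    """The four shipped group calibrations (male/female x TG/WT), solved.

    Calibration is performed on load from the published targets in
    ``data/default_groups.yaml``; results are cached per process.
    """
    cfg = _load_default_config()
    out: dict[str, GroupParams] = {}
    for label, g in cfg["groups"].items():
        targets = GroupTargets(
            slope=float(g["slope"]),
            band_mean=float(g["band_mean"]),
            mean_lifespan=float(g["mean_lifespan"]),
        )
        out[label] = calibrate_group(
            targets,
            sex=Sex(g["sex"]),
            genotype=Genotype(g["genotype"]),
            age_range=tuple(g["age_range"]),
            p_cens=float(g["p_cens"]),
            p_unknown=float(g.get("p_unknown", 0.0)),
            gamma=float(cfg.get("gamma", 0.005)),
            beta=float(cfg.get("beta", 4.0)),
            f_ceiling=float(cfg.get("f_ceiling", 0.70)),
            fi_floor=float(cfg.get("fi_floor", FI_FLOOR)),
        )
    return out
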