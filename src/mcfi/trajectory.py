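"""Deficit-accumulation trajectory statistics.

The rate of deficit accumulation is the slope of ordinary least squares of
ln FI on age, with age expressed in 10-day units; FI scores of zero are
floored at half the smallest whole-deficit contribution (1/62 on the 31-item
instrument) before the log.  Group means are also summarised in three age
bands (0-300, 300-600, 600+ days), rates are compared across groups with an
ANCOVA-style interaction test, and factorial effects of sex, genotype and
age band are tested with Type III analysis of variance.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cohort_sim import FI_FLOOR
from .fi_core import ConfigurationError, ValidationError

__all__ = [
    "SlopeFit",
    "BandSummary",
    "SlopeComparison",
    "AnovaTerm",
    "PairwiseContrast",
    "DEFAULT_BANDS",
    "fit_loglinear",
    "band_means",
    "compare_slopes",
    "factorial_anova",
]

logger = logging.getLogger("mcfi")

#: Age bands, half-open [lo, hi) days, partitioning [0, inf).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 300.0),
    (300.0, 600.0),
    (600.0, float("inf")),
)


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of ln FI on age/10 for one group."""

    group: str
    n: int
    slope: float  # ln FI per 10 days of age
    intercept: float  # ln FI at age 0
    pearson_r: float
    p_value: float
    slope_se: float

    def ci95(self) -> tuple[float, float]:
        """95% confidence interval for the slope (t distribution, n-2 df)."""
        half = stats.t.ppf(0.975, self.n - 2) * self.slope_se
        return (self.slope - half, self.slope + half)


@dataclass(frozen=True)
class BandSummary:
    """Mean FI of one group inside one age band."""

    group: str
    band: tuple[float, float]
    n: int
    mean_fi: Optional[float]
    sem: Optional[float]


@dataclass(frozen=True)
class PairwiseContrast:
    group_a: str
    group_b: str
    estimate: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class SlopeComparison:
    """ANCOVA-style test that deficit-accumulation rates differ by group."""

    interaction_F: float
    df_num: int
    df_den: int
    p_value: float
    slopes: dict[str, float]  # per-group slope from the interaction model
    pairwise: tuple[PairwiseContrast, ...]


@dataclass(frozen=True)
class AnovaTerm:
    term: str
    F: float
    df_num: float
    df_den: float
    p_value: float


def _floor_log_fi(fi: np.ndarray, fi_floor: float) -> np.ndarray:
    fi = np.asarray(fi, dtype=float)
    if np.any(fi < 0) or np.any(fi > 1):
        raise ValidationError("FI values must lie in [0, 1]")
    if fi_floor <= 0:
        raise ConfigurationError("fi_floor must be positive")
    return np.log(np.maximum(fi, fi_floor))


def fit_loglinear(
    ages: Sequence[float],
    fis: Sequence[float],
    group: str = "",
    fi_floor: float = FI_FLOOR,
) -> SlopeFit:
    """Estimate the rate of deficit accumulation for one group.

    OLS of ln(max(FI, floor)) on age/10; the Pearson correlation and its
    two-sided p-value (t distribution, n-2 df) describe the same linear
    association.
    """
    ages = np.asarray(ages, dtype=float)
    fis = np.asarray(fis, dtype=float)
    if ages.shape != fis.shape:
        raise ValidationError("ages and FI values must have equal length")
    n = ages.size
    if n < 3:
        raise ValidationError(f"group {group!r}: need >= 3 assessments, got {n}")
    if np.any(ages <= 0):
        raise ValidationError(f"group {group!r}: ages must be positive")
    if np.ptp(ages) == 0:
        raise ValidationError(
            f"group {group!r}: zero age variance, slope undefined"
        )
    y = _floor_log_fi(fis, fi_floor)
    x = ages / 10.0
    if np.ptp(y) == 0:
        # flat response: slope and correlation are exactly zero, p = 1
        return SlopeFit(group, n, 0.0, float(y[0]), 0.0, 1.0, 0.0)
    res = stats.linregress(x, y)
    return SlopeFit(
        group=group,
        n=n,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
    )


def _validate_bands(bands: Sequence[tuple[float, float]]) -> None:
    for lo, hi in bands:
        if not lo < hi:
            raise ConfigurationError(f"band ({lo}, {hi}) is empty")
    ordered = sorted(bands)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if lo2 < hi1:
            raise ConfigurationError(
                f"bands ({lo1}, {hi1}) and ({lo2}, {hi2}) overlap"
            )


def band_label(band: tuple[float, float]) -> str:
    lo, hi = band
    return f"{lo:g}+" if np.isinf(hi) else f"{lo:g}-{hi:g}"


def assign_band(
    ages, bands: Sequence[tuple[float, float]] = DEFAULT_BANDS
) -> pd.Series:
    """Label each age with its half-open [lo, hi) band."""
    _validate_bands(bands)
    ages = pd.Series(np.asarray(ages, dtype=float))
    out = pd.Series(pd.NA, index=ages.index, dtype="object")
    for band in bands:
        lo, hi = band
        out[(ages >= lo) & (ages < hi)] = band_label(band)
    return out


def band_means(
    df: pd.DataFrame,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    group_col: str = "group",
    age_col: str = "age_at_fi",
    fi_col: str = "fi",
) -> list[BandSummary]:
    """Per group x age-band mean FI with SEM and count.

    Empty cells are reported with n = 0 and absent mean, mirroring cohorts
    where a short-lived group contributes no old-age assessments.
    """
    _validate_bands(bands)
    out: list[BandSummary] = []
    for group, sub in df.groupby(group_col, sort=True):
        ages = sub[age_col].to_numpy(dtype=float)
        fis = sub[fi_col].to_numpy(dtype=float)
        for band in bands:
            lo, hi = band
            mask = (ages >= lo) & (ages < hi)
            n = int(mask.sum())
            if n == 0:
                out.append(BandSummary(str(group), band, 0, None, None))
                continue
            vals = fis[mask]
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None
            out.append(BandSummary(str(group), band, n, float(vals.mean()), sem))
    return out


def band_means_frame(summaries: Sequence[BandSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "band": [band_label(s.band) for s in summaries],
            "n": [s.n for s in summaries],
            "mean_fi": [s.mean_fi for s in summaries],
            "sem": [s.sem for s in summaries],
        }
    )


def compare_slopes(
    df: pd.DataFrame,
    fi_floor: float = FI_FLOOR,
    group_col: str = "group",
    age_col: str = "age_at_fi",
    fi_col: str = "fi",
) -> SlopeComparison:
    """Test whether deficit-accumulation rates differ across groups.

    Fits ln FI ~ group + age/10 + group:age/10 and compares it against the
    common-slope model by an extra-sum-of-squares F test (the ANCOVA
    homogeneity-of-slopes test).  Pairwise slope differences are tested on
    the interaction-model covariance with Bonferroni adjustment.
    """
    groups = sorted(df[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups to compare slopes")
    work = pd.DataFrame(
        {
            "g": df[group_col].astype(str).to_numpy(),
            "x": df[age_col].to_numpy(dtype=float) / 10.0,
            "y": _floor_log_fi(df[fi_col].to_numpy(), fi_floor),
        }
    )
    for g in groups:
        if (work["g"] == g).sum() < 3:
            raise ValidationError(f"group {g!r}: need >= 3 assessments")
        if np.ptp(work.loc[work["g"] == g, "x"]) == 0:
            raise ValidationError(f"group {g!r}: zero age variance")

    full = smf.ols("y ~ C(g) * x", data=work).fit()
    reduced = smf.ols("y ~ C(g) + x", data=work).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValidationError("singular design in the group x age model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp_tab = sm.stats.anova_lm(reduced, full)
    F = float(cmp_tab["F"].iloc[1])
    df_num = int(cmp_tab["df_diff"].iloc[1])
    df_den = int(full.df_resid)
    p = float(cmp_tab["Pr(>F)"].iloc[1])

    # per-group slope = base age coefficient + that group's interaction term
    base = groups[0]
    slopes: dict[str, float] = {}
    contrasts: dict[str, np.ndarray] = {}
    names = list(full.model.exog_names)
    k = len(names)
    x_ix = names.index("x")
    for g in groups:
        vec = np.zeros(k)
        vec[x_ix] = 1.0
        if g != base:
            vec[names.index(f"C(g)[T.{g}]:x")] = 1.0
        contrasts[g] = vec
        slopes[g] = float(vec @ full.params.to_numpy())

    pairs = list(itertools.combinations(groups, 2))
    pairwise = []
    for a, b in pairs:
        vec = contrasts[a] - contrasts[b]
        tt = full.t_test(vec)
        p_raw = float(tt.pvalue)
        pairwise.append(
            PairwiseContrast(
                group_a=a,
                group_b=b,
                estimate=float(np.squeeze(tt.effect)),
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * len(pairs)),
            )
        )
    return SlopeComparison(
        interaction_F=F,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        slopes=slopes,
        pairwise=tuple(pairwise),
    )


def factorial_anova(
    df: pd.DataFrame,
    response: str = "fi",
    factors: Sequence[str] = ("sex", "genotype", "age_band"),
    posthoc: bool = False,
) -> tuple[list[AnovaTerm], list[PairwiseContrast]]:
    """Factorial ANOVA with Type III sums of squares, sum-to-zero contrasts.

    Tests main effects and all interactions of the given factors on the
    response.  Interaction terms whose factor-level combinations include an
    empty cell are dropped with a warning (their Type III test is not
    estimable).  With ``posthoc=True``, all pairwise cell-mean contrasts are
    tested against the model's residual variance with Bonferroni adjustment.
    """
    work = df[[response, *factors]].copy()
    for f in factors:
        work[f] = work[f].astype(str)
        if work[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 observed levels")

    def term_formula(subset: Sequence[str]) -> str:
        return ":".join(f"C({f}, Sum)" for f in subset)

    # build all main effects + interactions, dropping terms with empty cells
    terms: list[str] = []
    for order in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, order):
            cells = work.groupby(list(subset), observed=False).size()
            full_size = int(np.prod([work[f].nunique() for f in subset]))
            if len(cells) < full_size or (cells == 0).any():
                logger.warning(
                    "dropping term %s: empty factor-level cell(s)",
                    "*".join(subset),
                )
                continue
            terms.append(term_formula(subset))
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=work).fit()
    if np.ptp(work[response].to_numpy(dtype=float)) == 0:
        # constant response: every F is exactly 0
        results = [
            AnovaTerm(t, 0.0, np.nan, float(model.df_resid), 1.0) for t in terms
        ]
        return results, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=3)
    results = []
    for t in terms:
        row = table.loc[t]
        results.append(
            AnovaTerm(
                term=t.replace("C(", "").replace(", Sum)", ""),
                F=float(row["F"]),
                df_num=float(row["df"]),
                df_den=float(model.df_resid),
                p_value=float(row["PR(>F)"]),
            )
        )

    contrasts: list[PairwiseContrast] = []
    if posthoc:
        cell = work.groupby(list(factors), observed=False)[response].agg(
            ["mean", "count"]
        )
        cell = cell[cell["count"] > 0]
        mse = float(model.mse_resid)
        dfr = float(model.df_resid)
        labels = ["/".join(map(str, ix if isinstance(ix, tuple) else (ix,)))
                  for ix in cell.index]
        pairs = list(itertools.combinations(range(len(cell)), 2))
        for i, j in pairs:
            mi, ni = cell["mean"].iloc[i], cell["count"].iloc[i]
            mj, nj = cell["mean"].iloc[j], cell["count"].iloc[j]
            se = np.sqrt(mse * (1.0 / ni + 1.0 / nj))
            tstat = (mi - mj) / se if se > 0 else 0.0
            p_raw = float(2 * stats.t.sf(abs(tstat), dfr)) if se > 0 else 1.0
            contrasts.append(
                PairwiseContrast(
                    group_a=labels[i],
                    group_b=labels[j],
                    estimate=float(mi - mj),
                    p_raw=p_raw,
                    p_adjusted=min(1.0, p_raw * len(pairs)),
                )
            )
    return results, contrasts
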