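"""Frailty-index scoring for the 31-item mouse clinical frailty instrument.

The frailty index (FI) operationalises deficit accumulation: each of 31
non-invasive clinical items is scored for the presence of an age-related
deficit, and the FI is the sum of item scores divided by the number of items
assessed, giving a dimensionless score in [0, 1].  Twenty-nine items are
ordinal (0 absent, 0.5 mild, 1 severe); body weight and surface temperature
are scored by how many reference standard deviations the measurement lies
from a young-adult reference mean.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

__all__ = [
    "Severity",
    "ItemMode",
    "Sex",
    "Genotype",
    "FrailtyStratum",
    "ItemDef",
    "ItemCatalog",
    "MouseAssessment",
    "FIResult",
    "ValidationError",
    "ConfigurationError",
    "ORDINAL_SCORES",
    "DEFAULT_BIN_EDGES",
    "DEFAULT_BIN_SCORES",
    "FI_CUTOFF",
    "score_ordinal_item",
    "score_z_binned",
    "compute_fi",
    "stratify_fi",
    "default_catalog",
]


class ValidationError(ValueError):
    """A datum violates the instrument's domain (bad score, bad level...)."""


class ConfigurationError(ValueError):
    """The catalog or run configuration is internally inconsistent."""


class Severity(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    SEVERE = "severe"


class ItemMode(str, enum.Enum):
    ORDINAL = "ordinal"
    Z_BINNED = "z_binned"


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"


class Genotype(str, enum.Enum):
    TG = "TG"  # 3xTg-AD triple-transgenic
    WT = "WT"  # wild-type control


class FrailtyStratum(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


#: Allowed scores for an ordinal item: deficit absent, mild, severe.
ORDINAL_SCORES = (0.0, 0.5, 1.0)

#: Default |z| bin edges (in reference SDs) and per-bin scores for the two
#: measured items (weight, surface temperature).  A measurement within 1 SD
#: of the reference mean scores 0; each further SD adds 0.25 up to 1.
DEFAULT_BIN_EDGES = (1.0, 2.0, 3.0, 4.0)
DEFAULT_BIN_SCORES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Clinical cutoff separating low from high frailty.
FI_CUTOFF = 0.21

_SEVERITY_SCORE = {Severity.NONE: 0.0, Severity.MILD: 0.5, Severity.SEVERE: 1.0}


@dataclass(frozen=True)
class ItemDef:
    """One item of the frailty instrument.

    Ordinal items need only a name and system grouping.  Z-binned items carry
    the young-adult reference statistics (``ref_mean``/``ref_sd`` in grams or
    degrees C) and the |z|-to-score bin map.
    """

    name: str
    system: str
    mode: ItemMode = ItemMode.ORDINAL
    ref_mean: Optional[float] = None
    ref_sd: Optional[float] = None
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
    bin_scores: Sequence[float] = DEFAULT_BIN_SCORES

    def __post_init__(self) -> None:
        if self.mode is ItemMode.Z_BINNED:
            if self.ref_mean is None or self.ref_sd is None:
                raise ConfigurationError(
                    f"z-binned item {self.name!r} needs ref_mean and ref_sd"
                )
            if self.ref_sd <= 0:
                raise ConfigurationError(
                    f"z-binned item {self.name!r} has ref_sd {self.ref_sd} <= 0"
                )
            _validate_bins(self.name, self.bin_edges, self.bin_scores)


def _validate_bins(name: str, edges: Sequence[float], scores: Sequence[float]) -> None:
    if len(scores) != len(edges) + 1:
        raise ConfigurationError(
            f"item {name!r}: need len(bin_scores) == len(bin_edges) + 1, "
            f"got {len(scores)} and {len(edges)}"
        )
    if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
        raise ConfigurationError(f"item {name!r}: bin_edges must be strictly ascending")
    if any(b > a for a, b in zip(scores[1:], scores[:-1])):
        raise ConfigurationError(f"item {name!r}: bin_scores must be non-decreasing")
    if scores[0] != 0 or scores[-1] > 1:
        raise ConfigurationError(
            f"item {name!r}: bin_scores must start at 0 and end <= 1"
        )


@dataclass(frozen=True)
class ItemCatalog:
    """The full instrument definition: an ordered list of items.

    The default catalog has 31 items — 29 ordinal plus weight and surface
    temperature — matching the published mouse clinical frailty instrument.
    Labs can substitute their own item names and reference statistics via a
    YAML file; only scores, never item semantics, enter any computation.
    """

    items: tuple[ItemDef, ...]

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate item names: {dupes}")
        if not self.items:
            raise ConfigurationError("catalog has no items")

    @property
    def ordinal_items(self) -> tuple[ItemDef, ...]:
        return tuple(it for it in self.items if it.mode is ItemMode.ORDINAL)

    @property
    def z_items(self) -> tuple[ItemDef, ...]:
        return tuple(it for it in self.items if it.mode is ItemMode.Z_BINNED)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_yaml(cls, path) -> "ItemCatalog":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ItemCatalog":
        items = []
        for entry in raw["items"]:
            mode = ItemMode(entry.get("mode", "ordinal"))
            items.append(
                ItemDef(
                    name=entry["name"],
                    system=entry.get("system", ""),
                    mode=mode,
                    ref_mean=entry.get("ref_mean"),
                    ref_sd=entry.get("ref_sd"),
                    bin_edges=tuple(entry.get("bin_edges", DEFAULT_BIN_EDGES)),
                    bin_scores=tuple(entry.get("bin_scores", DEFAULT_BIN_SCORES)),
                )
            )
        return cls(items=tuple(items))

    def to_dict(self) -> dict:
        out = []
        for it in self.items:
            d: dict = {"name": it.name, "system": it.system, "mode": it.mode.value}
            if it.mode is ItemMode.Z_BINNED:
                d.update(
                    ref_mean=it.ref_mean,
                    ref_sd=it.ref_sd,
                    bin_edges=list(it.bin_edges),
                    bin_scores=list(it.bin_scores),
                )
            out.append(d)
        return {"items": out}


# The 29 ordinal items of the mouse clinical frailty instrument, grouped by
# body system, plus the two measured items appended by default_catalog().
_DEFAULT_ORDINAL_ITEMS: tuple[tuple[str, str], ...] = (
    ("alopecia", "integument"),
    ("loss_of_fur_colour", "integument"),
    ("dermatitis", "integument"),
    ("loss_of_whiskers", "integument"),
    ("coat_condition", "integument"),
    ("tumours", "musculoskeletal"),
    ("distended_abdomen", "musculoskeletal"),
    ("kyphosis", "musculoskeletal"),
    ("tail_stiffening", "musculoskeletal"),
    ("gait_disorders", "musculoskeletal"),
    ("tremor", "musculoskeletal"),
    ("forelimb_grip_loss", "musculoskeletal"),
    ("body_condition", "musculoskeletal"),
    ("vestibular_disturbance", "vestibulocochlear_auditory"),
    ("hearing_loss", "vestibulocochlear_auditory"),
    ("cataracts", "ocular_nasal"),
    ("corneal_opacity", "ocular_nasal"),
    ("eye_discharge", "ocular_nasal"),
    ("microphthalmia", "ocular_nasal"),
    ("vision_loss", "ocular_nasal"),
    ("menace_reflex_loss", "ocular_nasal"),
    ("nasal_discharge", "ocular_nasal"),
    ("malocclusions", "digestive_urogenital"),
    ("rectal_prolapse", "digestive_urogenital"),
    ("urogenital_prolapse", "digestive_urogenital"),
    ("diarrhea", "digestive_urogenital"),
    ("breathing_abnormality", "respiratory"),
    ("mouse_grimace", "discomfort"),
    ("piloerection", "discomfort"),
)

#: Placeholder young-adult reference statistics for the measured items; the
#: cohort simulator uses these same values so simulated raw measurements
#: round-trip through the scorer.  Real labs supply their own.
DEFAULT_WEIGHT_REF = (31.0, 3.0)  # grams
DEFAULT_TEMP_REF = (36.5, 0.5)  # degrees C


def default_catalog() -> ItemCatalog:
    """The shipped 31-item catalog: 29 ordinal items + weight + temperature."""
    items = [ItemDef(name=n, system=s) for n, s in _DEFAULT_ORDINAL_ITEMS]
    items.append(
        ItemDef(
            name="weight",
            system="measured",
            mode=ItemMode.Z_BINNED,
            ref_mean=DEFAULT_WEIGHT_REF[0],
            ref_sd=DEFAULT_WEIGHT_REF[1],
        )
    )
    items.append(
        ItemDef(
            name="temperature",
            system="measured",
            mode=ItemMode.Z_BINNED,
            ref_mean=DEFAULT_TEMP_REF[0],
            ref_sd=DEFAULT_TEMP_REF[1],
        )
    )
    return ItemCatalog(items=tuple(items))


@dataclass
class MouseAssessment:
    """One mouse's single cross-sectional frailty assessment.

    ``ordinal_scores`` maps ordinal item name to a score in {0, 0.5, 1} or
    ``None`` for a missing (not-assessed) item; ``weight``/``temperature``
    are raw measurements (grams, degrees C) or ``None`` if missing.
    """

    mouse_id: str
    sex: Sex
    genotype: Genotype
    age_at_fi: int
    ordinal_scores: dict[str, Optional[float]] = field(default_factory=dict)
    weight: Optional[float] = None
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.genotype = Genotype(self.genotype)
        if self.age_at_fi <= 0:
            raise ValidationError(
                f"mouse {self.mouse_id!r}: age_at_fi must be positive, "
                f"got {self.age_at_fi}"
            )
        for name, score in self.ordinal_scores.items():
            if score is not None and score not in ORDINAL_SCORES:
                raise ValidationError(
                    f"mouse {self.mouse_id!r}, item {name!r}: ordinal score "
                    f"must be one of {ORDINAL_SCORES}, got {score}"
                )


@dataclass(frozen=True)
class FIResult:
    """A computed frailty index: score, items assessed, per-item breakdown."""

    fi: float
    n_assessed: int
    per_item_scores: dict[str, float]


def score_ordinal_item(severity: Severity | str, item: str = "") -> float:
    """Score one ordinal deficit: absent -> 0, mild -> 0.5, severe -> 1."""
    try:
        sev = Severity(severity)
    except ValueError:
        raise ValidationError(
            f"item {item or '<unnamed>'!r}: unrecognized severity {severity!r}; "
            f"expected one of {[s.value for s in Severity]}"
        ) from None
    return _SEVERITY_SCORE[sev]


def score_z_binned(
    value: float,
    ref_mean: float,
    ref_sd: float,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    bin_scores: Sequence[float] = DEFAULT_BIN_SCORES,
) -> float:
    """Score a measured item by |z| distance from the young-adult reference.

    z = |value - ref_mean| / ref_sd; the score is ``bin_scores[k]`` where
    ``k`` counts the edges strictly below z.  A z sitting exactly on an edge
    falls in the lower bin.
    """
    if ref_sd <= 0:
        raise ConfigurationError(f"ref_sd must be positive, got {ref_sd}")
    _validate_bins("<z-binned>", bin_edges, bin_scores)
    z = abs(value - ref_mean) / ref_sd
    k = sum(1 for e in bin_edges if e < z)
    return bin_scores[k]


def compute_fi(assessment: MouseAssessment, catalog: ItemCatalog) -> FIResult:
    """Compute the frailty index: sum of scores over items assessed.

    Missing items are excluded from numerator and denominator alike, the
    standard deficit-accumulation convention, so the FI remains a proportion
    of assessed deficits.
    """
    # The two measured items bind positionally: first z-binned item takes the
    # weight measurement, second the temperature, whatever they are named.
    z_raw: dict[str, Optional[float]] = {}
    z_measurements = (assessment.weight, assessment.temperature)
    for it, raw in zip(catalog.z_items, z_measurements):
        z_raw[it.name] = raw

    per_item: dict[str, float] = {}
    for it in catalog.items:
        if it.mode is ItemMode.ORDINAL:
            score = assessment.ordinal_scores.get(it.name)
            if score is None:
                continue
            if score not in ORDINAL_SCORES:
                raise ValidationError(
                    f"mouse {assessment.mouse_id!r}, item {it.name!r}: "
                    f"score {score} not in {ORDINAL_SCORES}"
                )
            per_item[it.name] = float(score)
        else:
            raw = z_raw.get(it.name)
            if raw is None:
                continue
            per_item[it.name] = score_z_binned(
                raw, it.ref_mean, it.ref_sd, it.bin_edges, it.bin_scores
            )
    if not per_item:
        raise ValidationError(
            f"mouse {assessment.mouse_id!r}: all items missing, FI undefined"
        )
    n = len(per_item)
    fi = sum(per_item.values()) / n
    return FIResult(fi=fi, n_assessed=n, per_item_scores=per_item)


def stratify_fi(fi: float, cutoff: float = FI_CUTOFF) -> FrailtyStratum:
    """Stratify an FI score as low (< cutoff) or high (>= cutoff)."""
    if not 0 <= fi <= 1:
        raise ValidationError(f"FI must lie in [0, 1], got {fi}")
    return FrailtyStratum.HIGH if fi >= cutoff else FrailtyStratum.LOW
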