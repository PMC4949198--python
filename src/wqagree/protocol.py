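"""Data model and scoring for the Welfare Quality growing-pig protocol.

The protocol combines three groups of animal-based measures taken during a
farm visit:

* **QBA** (Qualitative Behaviour Assessment): 20 expressive adjectives, each
  rated on a 0-125 mm visual analogue scale at group level, combined into a
  single score by a weighted sum.
* **BO** (behaviour observations): instantaneous scan sampling; at fixed
  intervals every visible pig is assigned to one of six behaviour
  categories, and behaviour fractions are expressed relative to total
  active (non-resting) behaviour.  Coughs and sneezes are counted
  separately and expressed per pig.
* **IP** (individual parameters): per-animal clinical indicators (bursitis,
  wounds, tail biting, ...) scored on two-point (0/2) or three-point
  (0/1/2) ordinal scales, summarised as the farm-level prevalence of each
  score category.

Two observers assess the same animals at the same time but independently;
the scoring operations here turn each observer's raw records into
farm-level measure values, and :func:`build_measure_tables` pairs them into
complete two-way tables ready for the agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np

from .errors import (
    ConfigError,
    IntegrityError,
    PairingError,
    RangeError,
    SchemaError,
    UndefinedStatisticError,
)

#: Intercept of the published QBA weighted-sum formula (score units).
QBA_INTERCEPT = -4.5367

#: Number of QBA adjectives in the growing-pig protocol.
N_ADJECTIVES = 20

#: The 20 QBA adjectives in protocol order.
QBA_ADJECTIVES = (
    "active", "relaxed", "fearful", "agitated", "calm", "content", "tense",
    "enjoying", "frustrated", "bored", "playful", "positively occupied",
    "listless", "lively", "indifferent", "irritable", "aimless", "happy",
    "distressed", "sociable",
)

#: Scan-sampling behaviour categories.  ``resting`` is the only
#: non-active category; every fraction is expressed relative to the summed
#: count of the other five.
SCAN_CATEGORIES = (
    "positive social",
    "negative social",
    "pen investigation",
    "use of enrichment material",
    "other active",
    "resting",
)

ACTIVE_CATEGORIES = tuple(c for c in SCAN_CATEGORIES if c != "resting")

#: Behaviour fractions reported at farm level.  Positive and negative
#: social behaviour are pooled into "social behaviour"; negative social
#: behaviour is additionally reported on its own.
BO_MEASURES = (
    "social behaviour",
    "negative social behaviour",
    "pen investigation",
    "use of enrichment material",
)


@dataclass(frozen=True)
class QBAConfig:
    """Adjectives, weights and scale of the QBA weighted-sum score.

    The adjective weights are published in the Welfare Quality protocol
    document, not fixed here; they must be supplied by configuration.

    Parameters
    ----------
    adjectives
        Ordered tuple of exactly 20 adjective labels.
    weights
        Signed weight per adjective (dimensionless).
    intercept
        Additive constant of the weighted sum, in score units.
    scale_max
        Upper end of the visual analogue scale in millimetres.
    score_range
        Width of the theoretical score range implied by the weights and
        the 0..``scale_max`` scale; used to normalise QBA score
        differences to the fraction scale for SDC/LoA thresholding.
        Computed from the weights when not given.
    """

    adjectives: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float = QBA_INTERCEPT
    scale_max: float = 125.0
    score_range: float | None = None

    def __post_init__(self) -> None:
        if len(self.adjectives) != N_ADJECTIVES:
            raise ConfigError(
                f"QBA requires exactly {N_ADJECTIVES} adjectives, "
                f"got {len(self.adjectives)}"
            )
        if len(set(self.adjectives)) != len(self.adjectives):
            raise ConfigError("duplicate adjective labels")
        if len(self.weights) != len(self.adjectives):
            raise ConfigError("one weight per adjective required")
        if not all(math.isfinite(w) for w in self.weights):
            raise ConfigError("weights must be finite")
        if not self.scale_max > 0:
            raise ConfigError("scale_max must be positive")

    @property
    def theoretical_range(self) -> tuple[float, float]:
        """(min, max) attainable score given the weights and scale."""
        lo = self.intercept + self.scale_max * sum(w for w in self.weights if w < 0)
        hi = self.intercept + self.scale_max * sum(w for w in self.weights if w > 0)
        return lo, hi

    @property
    def effective_score_range(self) -> float:
        """Divisor for normalising score differences to the fraction scale."""
        if self.score_range is not None:
            return self.score_range
        lo, hi = self.theoretical_range
        return hi - lo


@dataclass(frozen=True)
class AdjectiveRatings:
    """One observer's QBA marks for one farm visit, in millimetres."""

    visit_id: str
    observer_id: str
    values: Mapping[str, float]


@dataclass(frozen=True)
class ParameterDefinition:
    """Scoring scale of one individual parameter.

    ``scale`` is ``"binary"`` (categories 0/2, absent/present),
    ``"ternary"`` (0/1/2, absent/light/strong) or ``"count"`` (nonnegative
    integer, used for coughing and sneezing).
    """

    id: str
    scale: str
    descriptions: Mapping[int, str] = field(default_factory=dict)

    _CATEGORIES = {"binary": (0, 2), "ternary": (0, 1, 2)}

    def __post_init__(self) -> None:
        if self.scale not in ("binary", "ternary", "count"):
            raise ConfigError(f"unknown scale {self.scale!r} for {self.id!r}")

    @property
    def categories(self) -> tuple[int, ...]:
        if self.scale == "count":
            raise ConfigError(f"{self.id!r} is a count, not a categorical scale")
        return self._CATEGORIES[self.scale]


@dataclass(frozen=True)
class AnimalScoreSheet:
    """One observer's per-animal category scores for one farm visit.

    ``scores`` maps animal id -> {parameter id -> category}.  Animals may
    be scored for different parameter subsets (pens differ), so the number
    assessed is derived per parameter.
    """

    visit_id: str
    observer_id: str
    scores: Mapping[str, Mapping[str, int]]

    def n_assessed(self, parameter_id: str) -> int:
        return sum(1 for animal in self.scores.values() if parameter_id in animal)


@dataclass(frozen=True)
class ScanRecord:
    """Counts of pigs per behaviour category for one scan at one viewpoint."""

    visit_id: str
    observer_id: str
    viewpoint: int
    scan: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for cat, n in self.counts.items():
            if cat not in SCAN_CATEGORIES:
                raise SchemaError(f"unknown scan category {cat!r}")
            if n < 0:
                raise RangeError(f"negative scan count for {cat!r}")
        if self.scan < 1:
            raise RangeError("scan index must be >= 1")


@dataclass(frozen=True)
class FarmVisitAssessment:
    """One observer's complete protocol record for one farm visit.

    Visits are keyed by (farm id, visit date): 29 paired visits on 24
    farms mean some farms recur, so the farm id alone is ambiguous.
    """

    farm_id: str
    visit_date: str
    observer_id: str
    qba: AdjectiveRatings
    scans: tuple[ScanRecord, ...]
    animals: AnimalScoreSheet
    cough_count: int
    sneeze_count: int
    n_pigs_respiration: int

    @property
    def visit_id(self) -> str:
        return f"{self.farm_id}:{self.visit_date}"


@dataclass
class MeasureTable:
    """Farm-level values of one measure paired across the two observers.

    ``kind`` is ``"fraction"`` (prevalences and behaviour fractions, in
    [0, 1]), ``"score"`` (the QBA score and raw adjective values) or
    ``"rate"`` (coughs/sneezes per pig).  The fraction-scale SDC/LoA
    acceptability thresholds are applied directly only to fractions;
    scores carry a ``scale_divisor`` that maps differences onto the
    fraction scale first.
    """

    measure_id: str
    visit_ids: list[str]
    value_a: np.ndarray
    value_bc: np.ndarray
    kind: str = "fraction"
    scale_divisor: float | None = None

    def __post_init__(self) -> None:
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_bc = np.asarray(self.value_bc, dtype=float)
        if not (len(self.visit_ids) == self.value_a.size == self.value_bc.size):
            raise SchemaError("visit ids and value columns must align")
        if np.isnan(self.value_a).any() or np.isnan(self.value_bc).any():
            raise SchemaError(f"missing cells in measure table {self.measure_id!r}")
        if self.kind == "fraction":
            allv = np.concatenate([self.value_a, self.value_bc])
            if ((allv < -1e-12) | (allv > 1 + 1e-12)).any():
                raise RangeError(
                    f"fraction measure {self.measure_id!r} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.visit_ids)


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------

def qba_score(ratings: AdjectiveRatings, config: QBAConfig) -> float:
    """Weighted-sum QBA score: ``intercept + sum_k w_k * N_k``.

    ``N_k`` is the millimetre mark for adjective *k*.  Raises
    :class:`SchemaError` for a missing adjective and :class:`RangeError`
    for a mark outside [0, scale_max].
    """
    total = config.intercept
    for adjective, weight in zip(config.adjectives, config.weights):
        try:
            value = float(ratings.values[adjective])
        except KeyError:
            raise SchemaError(
                f"visit {ratings.visit_id!r}: adjective {adjective!r} missing"
            ) from None
        if not 0.0 <= value <= config.scale_max:
            raise RangeError(
                f"visit {ratings.visit_id!r}: {adjective!r} = {value} mm "
                f"outside [0, {config.scale_max}]"
            )
        total += weight * value
    return total


def category_prevalences(
    sheet: AnimalScoreSheet, param: ParameterDefinition
) -> dict[int, float]:
    """Fraction of assessed animals in each score category of *param*.

    Ternary parameters yield three prevalences (treated downstream as
    independent measures); the fractions over a parameter's categories
    always sum to one.
    """
    categories = param.categories
    counts = dict.fromkeys(categories, 0)
    for animal_id, animal in sheet.scores.items():
        if param.id not in animal:
            continue
        cat = animal[param.id]
        if cat not in counts:
            raise RangeError(
                f"animal {animal_id!r}: category {cat} not on the "
                f"{param.scale} scale of {param.id!r}"
            )
        counts[cat] += 1
    total = sum(counts.values())
    if total == 0:
        raise UndefinedStatisticError(
            f"no animals scored for {param.id!r} in visit {sheet.visit_id!r}"
        )
    return {cat: counts[cat] / total for cat in categories}


def bo_fractions(scans: Sequence[ScanRecord]) -> dict[str, float]:
    """Behaviour fractions relative to total active behaviour.

    Counts are pooled over all scans and viewpoints before division.  The
    denominator is the total of every category except resting; positive
    and negative social behaviour are pooled into "social behaviour" and
    negative social behaviour is also reported individually.
    """
    totals = dict.fromkeys(SCAN_CATEGORIES, 0)
    for record in scans:
        for cat, n in record.counts.items():
            totals[cat] += n
    active = sum(totals[c] for c in ACTIVE_CATEGORIES)
    if active == 0:
        raise UndefinedStatisticError(
            "no active-behaviour observations: behaviour fractions undefined"
        )
    return {
        "social behaviour": (totals["positive social"] + totals["negative social"])
        / active,
        "negative social behaviour": totals["negative social"] / active,
        "pen investigation": totals["pen investigation"] / active,
        "use of enrichment material": totals["use of enrichment material"] / active,
    }


def respiration_rates(assessment: FarmVisitAssessment) -> tuple[float, float]:
    """(coughs per pig, sneezes per pig) for one visit."""
    n = assessment.n_pigs_respiration
    if n < 1:
        raise UndefinedStatisticError("no pigs observed for respiration counts")
    if assessment.cough_count < 0 or assessment.sneeze_count < 0:
        raise RangeError("negative respiration count")
    return assessment.cough_count / n, assessment.sneeze_count / n


def visit_measures(
    assessment: FarmVisitAssessment,
    qba_config: QBAConfig,
    parameters: Sequence[ParameterDefinition],
) -> dict[str, float]:
    """All farm-level measure values for a single observer's visit record."""
    out: dict[str, float] = {}
    for adjective in qba_config.adjectives:
        ratings = assessment.qba
        if adjective not in ratings.values:
            raise SchemaError(
                f"visit {assessment.visit_id!r}: adjective {adjective!r} missing"
            )
        out[f"qba:{adjective}"] = float(ratings.values[adjective])
    out["qba:score"] = qba_score(assessment.qba, qba_config)
    for measure, value in bo_fractions(assessment.scans).items():
        out[f"bo:{measure}"] = value
    for param in parameters:
        if param.scale == "count":
            continue
        prevalences = category_prevalences(assessment.animals, param)
        for cat, frac in prevalences.items():
            out[f"ip:{param.id}:{cat}"] = frac
    coughs, sneezes = respiration_rates(assessment)
    out["resp:coughs per pig"] = coughs
    out["resp:sneezes per pig"] = sneezes
    return out


def _measure_kind(measure_id: str) -> str:
    if measure_id.startswith(("bo:", "ip:")):
        return "fraction"
    if measure_id.startswith("resp:"):
        return "rate"
    return "score"


def build_measure_tables(
    assessments: Iterable[FarmVisitAssessment],
    pairs: Sequence[tuple[str, str]],
    qba_config: QBAConfig,
    parameters: Sequence[ParameterDefinition],
) -> list[MeasureTable]:
    """Pair observers visit by visit into one two-way table per measure.

    ``pairs`` lists the observer pairings, e.g. ``[("A", "B"), ("A", "C")]``.
    The first observer of every pair supplies ``value_a``; the partner
    columns are concatenated into the single ``value_bc`` column, so an
    A-B visit and an A-C visit each contribute one row to every measure's
    table (the A-vs-BC aggregation).

    Raises :class:`PairingError` when a visit lacks exactly one record per
    pair member, and :class:`IntegrityError` on conflicting duplicates.
    """
    by_key: dict[tuple[str, str], FarmVisitAssessment] = {}
    for a in assessments:
        key = (a.visit_id, a.observer_id)
        if key in by_key:
            if by_key[key] == a:
                continue
            raise IntegrityError(
                f"conflicting duplicate records for visit {a.visit_id!r}, "
                f"observer {a.observer_id!r}"
            )
        by_key[key] = a

    primary_ids = {p[0] for p in pairs}
    partner_of = {p[1]: p[0] for p in pairs}
    if len(primary_ids) != 1:
        raise ConfigError("all pairs must share the same primary observer")

    rows: list[tuple[str, dict[str, float], dict[str, float]]] = []
    visits = sorted({k[0] for k in by_key})
    for visit_id in visits:
        records = {obs: a for (v, obs), a in by_key.items() if v == visit_id}
        if len(records) != 2:
            raise PairingError(
                f"visit {visit_id!r} has {len(records)} records, expected 2"
            )
        partners = [o for o in records if o in partner_of]
        primaries = [o for o in records if o in primary_ids]
        if len(primaries) != 1 or len(partners) != 1:
            raise PairingError(
                f"visit {visit_id!r}: observers {sorted(records)} do not form "
                f"a configured pair"
            )
        row_a = visit_measures(records[primaries[0]], qba_config, parameters)
        row_bc = visit_measures(records[partners[0]], qba_config, parameters)
        if set(row_a) != set(row_bc):
            raise SchemaError(
                f"visit {visit_id!r}: observers report different measure sets"
            )
        rows.append((visit_id, row_a, row_bc))

    if not rows:
        return []
    measure_ids = list(rows[0][1])
    divisor = qba_config.effective_score_range
    tables = []
    for measure_id in measure_ids:
        kind = _measure_kind(measure_id)
        tables.append(
            MeasureTable(
                measure_id=measure_id,
                visit_ids=[r[0] for r in rows],
                value_a=np.array([r[1][measure_id] for r in rows]),
                value_bc=np.array([r[2][measure_id] for r in rows]),
                kind=kind,
                scale_divisor=(
                    divisor if measure_id == "qba:score"
                    else qba_config.scale_max if kind == "score"
                    else None
                ),
            )
        )
    return tables


def filter_rare_measures(
    tables: Sequence[MeasureTable], threshold: float = 0.005
) -> tuple[list[MeasureTable], list[tuple[MeasureTable, str]]]:
    """Drop prevalence measures too rare for a meaningful reliability estimate.

    A category prevalence whose mean over both observers and all visits is
    at or below *threshold* (default 0.5 %) is excluded; behaviour
    fractions, QBA measures and respiration rates are always kept.

    Returns ``(kept, excluded)`` where each excluded entry carries a
    human-readable reason.
    """
    if not 0 <= threshold < 1:
        raise ConfigError("rare-measure threshold must be in [0, 1)")
    kept: list[MeasureTable] = []
    excluded: list[tuple[MeasureTable, str]] = []
    for table in tables:
        if not table.measure_id.startswith("ip:"):
            kept.append(table)
            continue
        mean_prev = float(
            np.concatenate([table.value_a, table.value_bc]).mean()
        )
        if mean_prev <= threshold:
            excluded.append(
                (
                    table,
                    f"mean prevalence {mean_prev:.4%} <= "
                    f"exclusion threshold {threshold:.2%}",
                )
            )
        else:
            kept.append(table)
    return kept, excluded
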