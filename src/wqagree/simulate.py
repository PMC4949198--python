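"""Synthetic paired-observer farm-visit data with known ground truth.

The raw 29-visit field dataset behind the protocol's reliability study is
not public, so every statistic is validated by parameter recovery on
simulated data instead.  The generator mirrors the study design: 24 farms
visited in 29 paired assessments, observer A paired with observer B on 19
visits and with observer C on 10, both observers rating the same animals
at the same time but independently.

Continuous farm-level measures are drawn from the same two-way model the
ANOVA estimates, ``x_ij = mu + a_i + b_j + e_ij`` with visit (object)
effects ``a_i ~ N(0, sigma2_objects)``, fixed observer biases ``b_j`` and
residuals ``e_ij ~ N(0, sigma2_residual)``, so the implied true ICC is
known in closed form.  Animal-level categorical scores are drawn from
farm-level true prevalences and passed through a per-observer
misclassification matrix; QBA marks are truncated normal on the 0-125 mm
scale and scan counts multinomial over the six behaviour categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError
from .protocol import (
    QBA_ADJECTIVES,
    SCAN_CATEGORIES,
    AdjectiveRatings,
    AnimalScoreSheet,
    FarmVisitAssessment,
    MeasureTable,
    ParameterDefinition,
    ScanRecord,
)

#: Default base prevalence vectors (absent / light / strong or absent /
#: present), chosen to roughly match the spread of the published farm-level
#: mean prevalences; not calibrated claims.
DEFAULT_PREVALENCES: dict[str, tuple[float, ...]] = {
    "body condition": (0.98, 0.02),
    "bursitis": (0.55, 0.38, 0.07),
    "manure": (0.77, 0.16, 0.07),
    "huddling": (0.98, 0.02),
    "shivering": (0.999, 0.001),
    "panting": (0.995, 0.005),
    "wounds": (0.87, 0.11, 0.02),
    "tail biting": (0.965, 0.035),
    "lameness": (0.99, 0.007, 0.003),
    "pumping": (0.99, 0.01),
    "scouring": (0.95, 0.04, 0.01),
    "skin condition": (0.965, 0.02, 0.015),
    "hernia": (0.99, 0.008, 0.002),
    "twisted snout": (0.999, 0.001),
    "rectal prolapse": (0.998, 0.002),
}

#: Default multinomial scan probabilities over the six behaviour
#: categories (positive social, negative social, pen investigation,
#: enrichment use, other active, resting); roughly half the herd rests.
DEFAULT_SCAN_PROBS = (0.04, 0.012, 0.13, 0.025, 0.29, 0.503)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the paired-observer study design.

    Defaults reproduce the field design: 29 paired visits on 24 farms
    split 19 (A-B) / 10 (A-C).  Observer effects are fixed biases —
    ``observer_bias`` maps observer id to an additive shift on the
    continuous scale — matching the single observer contrast of the
    two-observer ANOVA; the implied observer variance component is
    derived, not drawn.

    The seed contract is strict: identical configs (including ``seed``)
    produce bit-identical datasets.
    """

    n_farms: int = 24
    visits_ab: int = 19
    visits_ac: int = 10
    seed: int = 0

    # continuous farm-level measure (fraction scale by default)
    mean: float = 0.30
    sigma2_objects: float = 0.01
    sigma2_residual: float = 0.001
    observer_bias: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.0, "C": 0.0}
    )
    value_range: tuple[float, float] | None = (0.0, 1.0)

    # animal-level categorical scores
    animals_per_visit: int = 60
    prevalence_concentration: float = 40.0
    base_prevalences: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    misclassification: Mapping[str, np.ndarray] | None = None
    observer_confusion: float = 0.08

    # QBA and scan sampling
    qba_mean: Mapping[str, float] = field(
        default_factory=lambda: {a: 40.0 for a in QBA_ADJECTIVES}
    )
    qba_farm_sd: float = 18.0
    qba_observer_sd: float = 9.0
    scans_per_viewpoint: int = 5
    n_viewpoints: int = 3
    pigs_per_scan: int = 50
    scan_probs: tuple[float, ...] = DEFAULT_SCAN_PROBS
    scan_farm_concentration: float = 150.0
    pigs_respiration: int = 50
    cough_rate: float = 0.2
    sneeze_rate: float = 0.06
    respiration_count_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma2_objects < 0 or self.sigma2_residual < 0:
            raise ConfigError("variances must be nonnegative")
        if self.visits_ab + self.visits_ac < 3:
            raise ConfigError("need at least 3 paired visits")
        if len(self.scan_probs) != len(SCAN_CATEGORIES):
            raise ConfigError("one scan probability per behaviour category")
        if abs(sum(self.scan_probs) - 1.0) > 1e-9:
            raise ConfigError("scan probabilities must sum to 1")
        for pid, p in self.base_prevalences.items():
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ConfigError(f"base prevalence for {pid!r} not a distribution")

    @property
    def n_visits(self) -> int:
        return self.visits_ab + self.visits_ac

    @property
    def sigma2_observers_true(self) -> float:
        """Observer variance component implied by the fixed A-vs-BC biases.

        For two observers with fixed biases the ANOVA observer component
        estimates ``(b_A - b_BC)**2 / 2``; the partner bias is the
        visit-weighted mean of the B and C biases.
        """
        b_a = self.observer_bias.get("A", 0.0)
        b_bc = (
            self.visits_ab * self.observer_bias.get("B", 0.0)
            + self.visits_ac * self.observer_bias.get("C", 0.0)
        ) / self.n_visits
        return (b_a - b_bc) ** 2 / 2.0


@dataclass(frozen=True)
class GroundTruth:
    """True generative quantities behind a simulated measure table."""

    true_values: np.ndarray
    sigma2_objects: float
    sigma2_observers: float
    sigma2_residual: float
    clip_fraction: float = 0.0

    @property
    def icc(self) -> float:
        total = self.sigma2_objects + self.sigma2_observers + self.sigma2_residual
        if total == 0:
            raise ConfigError("degenerate truth: all variance components zero")
        return self.sigma2_objects / total

    @property
    def sdc(self) -> float:
        return 1.96 * np.sqrt(2.0) * np.sqrt(
            self.sigma2_observers + self.sigma2_residual
        )


def _partner_ids(config: SimulationConfig) -> list[str]:
    return ["B"] * config.visits_ab + ["C"] * config.visits_ac


def _visit_keys(config: SimulationConfig) -> list[tuple[str, str]]:
    """(farm_id, visit_date) keys; farms recycle when visits exceed farms."""
    keys = []
    for i in range(config.n_visits):
        farm = f"farm{(i % config.n_farms) + 1:02d}"
        date = f"2026-{(i // config.n_farms) + 1:02d}-{(i % 28) + 1:02d}"
        keys.append((farm, date))
    return keys


def simulate_continuous_measure(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    measure_id: str = "sim:continuous",
) -> tuple[MeasureTable, GroundTruth]:
    """Draw one paired-observer table from the two-way generative model.

    Values falling outside ``config.value_range`` are clipped (not
    resampled) and the clipping fraction is reported in the ground truth;
    clipping above ~5 % invalidates normal-theory recovery checks, so
    heavy clipping should be treated as a misconfiguration by the caller.

    Raises :class:`ConfigError` for a fully degenerate configuration
    (all variances zero and all biases equal), which would make every
    reliability statistic undefined.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    biases = _partner_ids(config)
    if (
        config.sigma2_objects == 0
        and config.sigma2_residual == 0
        and config.sigma2_observers_true == 0
    ):
        raise ConfigError(
            "degenerate simulation: zero variances and equal biases leave "
            "nothing to estimate"
        )
    n = config.n_visits
    truth = config.mean + rng.normal(0.0, np.sqrt(config.sigma2_objects), size=n)
    res_sd = np.sqrt(config.sigma2_residual)
    value_a = truth + config.observer_bias.get("A", 0.0) + rng.normal(0, res_sd, n)
    value_bc = truth + np.array(
        [config.observer_bias.get(p, 0.0) for p in biases]
    ) + rng.normal(0, res_sd, n)

    clip_fraction = 0.0
    if config.value_range is not None:
        lo, hi = config.value_range
        stacked = np.concatenate([value_a, value_bc])
        clip_fraction = float(((stacked < lo) | (stacked > hi)).mean())
        value_a = np.clip(value_a, lo, hi)
        value_bc = np.clip(value_bc, lo, hi)

    keys = _visit_keys(config)
    table = MeasureTable(
        measure_id=measure_id,
        visit_ids=[f"{f}:{d}" for f, d in keys],
        value_a=value_a,
        value_bc=value_bc,
        kind="fraction" if config.value_range == (0.0, 1.0) else "score",
        scale_divisor=None,
    )
    return table, GroundTruth(
        true_values=truth,
        sigma2_objects=config.sigma2_objects,
        sigma2_observers=config.sigma2_observers_true,
        sigma2_residual=config.sigma2_residual,
        clip_fraction=clip_fraction,
    )


def _check_stochastic(matrix: np.ndarray, n_cat: int, pid: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (n_cat, n_cat):
        raise ConfigError(
            f"misclassification matrix for {pid!r} must be {n_cat}x{n_cat}"
        )
    if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
        raise ConfigError(f"misclassification rows for {pid!r} must sum to 1")
    return m


def adjacent_confusion_matrix(n_cat: int, rate: float) -> np.ndarray:
    """Row-stochastic matrix confusing adjacent score categories.

    *rate* is the total probability of recording a neighbouring category
    instead of the true one (split between two neighbours for a middle
    ternary category).  ``rate=0`` gives the identity — an error-free
    observer.
    """
    if not 0 <= rate <= 1:
        raise ConfigError("confusion rate must be in [0, 1]")
    m = np.eye(n_cat) * (1.0 - rate)
    for i in range(n_cat):
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < n_cat]
        for j in neighbours:
            m[i, j] += rate / len(neighbours)
    return m


def misclassified_prevalence(
    true_prevalence: Sequence[float], matrix: np.ndarray
) -> np.ndarray:
    """Expected observed category distribution: ``p_obs = p_true @ M``."""
    return np.asarray(true_prevalence, dtype=float) @ np.asarray(matrix, dtype=float)


def simulate_animal_scores(
    config: SimulationConfig,
    param: ParameterDefinition,
    rng: np.random.Generator | None = None,
) -> list[tuple[AnimalScoreSheet, AnimalScoreSheet]]:
    """Per-visit paired score sheets for one individual parameter.

    Farm-level true prevalences are drawn from a Dirichlet centred on the
    configured base prevalence (``prevalence_concentration`` controls
    between-farm spread); each animal's true category is drawn from the
    farm's prevalence, and each observer's recorded category from the
    parameter's misclassification matrix, independently given the truth.
    An identity matrix therefore reproduces the truth exactly and a
    uniform-row matrix makes the two observers' records independent.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    categories = np.array(param.categories)
    n_cat = len(categories)
    base = config.base_prevalences.get(param.id)
    if base is None:
        raise ConfigError(f"no base prevalence configured for {param.id!r}")
    if len(base) != n_cat:
        raise ConfigError(
            f"base prevalence for {param.id!r} has {len(base)} entries, "
            f"scale has {n_cat} categories"
        )
    if config.misclassification and param.id in config.misclassification:
        matrix = _check_stochastic(
            config.misclassification[param.id], n_cat, param.id
        )
    else:
        matrix = adjacent_confusion_matrix(n_cat, config.observer_confusion)

    partners = _partner_ids(config)
    out = []
    for (farm, date), partner in zip(_visit_keys(config), partners):
        visit_id = f"{farm}:{date}"
        alpha = np.maximum(np.asarray(base) * config.prevalence_concentration, 1e-6)
        farm_prev = rng.dirichlet(alpha)
        true_idx = rng.choice(n_cat, size=config.animals_per_visit, p=farm_prev)
        sheets = []
        for observer in ("A", partner):
            obs_idx = np.array(
                [rng.choice(n_cat, p=matrix[t]) for t in true_idx]
            )
            scores = {
                f"pig{j + 1:03d}": {param.id: int(categories[i])}
                for j, i in enumerate(obs_idx)
            }
            sheets.append(
                AnimalScoreSheet(visit_id=visit_id, observer_id=observer,
                                 scores=scores)
            )
        out.append((sheets[0], sheets[1]))
    return out


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float,
    size: int | None = None,
):
    if sd == 0:
        value = np.clip(mean, lo, hi)
        return value if size is None else np.full(size, value)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_qba_and_scans(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[
    list[tuple[AdjectiveRatings, AdjectiveRatings]],
    list[tuple[list[ScanRecord], list[ScanRecord]]],
]:
    """Paired QBA ratings and scan records for every visit.

    Each adjective has a farm-level latent intensity (truncated normal on
    the 0-125 mm scale); each observer's mark adds truncated-normal
    observer noise around it.  Scan counts are multinomial over the six
    behaviour categories with farm-level probabilities drawn from a
    Dirichlet around ``scan_probs``; both observers scan the same pens,
    so their counts share the farm's probabilities but are drawn
    independently, mimicking independent instantaneous classification.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    partners = _partner_ids(config)
    qba_pairs = []
    scan_pairs = []
    for (farm, date), partner in zip(_visit_keys(config), partners):
        visit_id = f"{farm}:{date}"
        latent = {
            adj: float(
                _truncnorm_draw(rng, config.qba_mean[adj], config.qba_farm_sd,
                                0.0, 125.0)
            )
            for adj in QBA_ADJECTIVES
        }
        ratings = []
        for observer in ("A", partner):
            values = {
                adj: float(
                    _truncnorm_draw(rng, latent[adj], config.qba_observer_sd,
                                    0.0, 125.0)
                )
                for adj in QBA_ADJECTIVES
            }
            ratings.append(
                AdjectiveRatings(visit_id=visit_id, observer_id=observer,
                                 values=values)
            )
        qba_pairs.append((ratings[0], ratings[1]))

        farm_probs = rng.dirichlet(
            np.maximum(
                np.asarray(config.scan_probs) * config.scan_farm_concentration,
                1e-6,
            )
        )
        per_observer = []
        for observer in ("A", partner):
            records = []
            for vp in range(1, config.n_viewpoints + 1):
                for scan in range(1, config.scans_per_viewpoint + 1):
                    counts = rng.multinomial(config.pigs_per_scan, farm_probs)
                    records.append(
                        ScanRecord(
                            visit_id=visit_id,
                            observer_id=observer,
                            viewpoint=vp,
                            scan=scan,
                            counts=dict(zip(SCAN_CATEGORIES, counts.tolist())),
                        )
                    )
            per_observer.append(records)
        scan_pairs.append((per_observer[0], per_observer[1]))
    return qba_pairs, scan_pairs


def simulate_dataset(
    config: SimulationConfig,
    parameters: Sequence[ParameterDefinition],
) -> tuple[list[FarmVisitAssessment], list[tuple[str, str]]]:
    """Complete paired :class:`FarmVisitAssessment` records for a study.

    Combines the QBA, scan, animal-score and respiration generators under
    a single seed so the whole dataset is reproducible from the config
    alone.  Returns the assessment records plus the observer pairing list
    ``[("A", "B"), ("A", "C")]`` expected by the pairing step.
    """
    rng = np.random.default_rng(config.seed)
    qba_pairs, scan_pairs = simulate_qba_and_scans(config, rng)
    categorical = [p for p in parameters if p.scale != "count"]
    sheets_by_param = {
        p.id: simulate_animal_scores(config, p, rng) for p in categorical
    }
    partners = _partner_ids(config)

    assessments = []
    for i, ((farm, date), partner) in enumerate(zip(_visit_keys(config), partners)):
        visit_id = f"{farm}:{date}"
        # merge per-parameter sheets into one sheet per observer
        merged: dict[str, dict[str, dict[str, int]]] = {
            "A": {}, partner: {}
        }
        for pid, visits in sheets_by_param.items():
            for sheet in visits[i]:
                for animal, scores in sheet.scores.items():
                    merged[sheet.observer_id].setdefault(animal, {}).update(scores)
        lam_c = config.cough_rate * config.pigs_respiration
        lam_s = config.sneeze_rate * config.pigs_respiration
        true_c = rng.gamma(1 / max(config.respiration_count_dispersion, 1e-9),
                           lam_c * config.respiration_count_dispersion)
        true_s = rng.gamma(1 / max(config.respiration_count_dispersion, 1e-9),
                           lam_s * config.respiration_count_dispersion)
        for observer, qba in zip(("A", partner), qba_pairs[i]):
            scans = scan_pairs[i][0 if observer == "A" else 1]
            assessments.append(
                FarmVisitAssessment(
                    farm_id=farm,
                    visit_date=date,
                    observer_id=observer,
                    qba=qba,
                    scans=tuple(scans),
                    animals=AnimalScoreSheet(
                        visit_id=visit_id,
                        observer_id=observer,
                        scores=merged[observer],
                    ),
                    cough_count=int(rng.poisson(true_c)),
                    sneeze_count=int(rng.poisson(true_s)),
                    n_pigs_respiration=config.pigs_respiration,
                )
            )
    return assessments, [("A", "B"), ("A", "C")]
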