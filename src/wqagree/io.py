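"""CSV interchange and protocol-definition files.

The on-disk layout is four UTF-8 comma-separated files with header rows:

``qba.csv``
    visit_id, observer_id, adjective, mm
``animals.csv``
    visit_id, observer_id, animal_id, parameter, category
``scans.csv``
    visit_id, observer_id, viewpoint, scan, category, count
``respiration.csv``
    visit_id, observer_id, coughs, sneezes, n_pigs

``visit_id`` is ``<farm_id>:<visit_date>`` — farm id alone is ambiguous
because farms can be visited more than once.

The protocol definition (adjectives, QBA weights and intercept, parameter
scales) comes from a YAML file; the weights are published only in the
protocol document itself and are therefore always configuration, never
constants in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .protocol import (
    N_ADJECTIVES,
    QBA_ADJECTIVES,
    QBA_INTERCEPT,
    SCAN_CATEGORIES,
    AdjectiveRatings,
    AnimalScoreSheet,
    FarmVisitAssessment,
    ParameterDefinition,
    QBAConfig,
    ScanRecord,
)

CSV_FILES = ("qba.csv", "animals.csv", "scans.csv", "respiration.csv")

#: Growing-pig individual parameters and their scoring scales.
PARAMETER_SCALES: dict[str, str] = {
    "body condition": "binary",
    "bursitis": "ternary",
    "manure": "ternary",
    "huddling": "binary",
    "shivering": "binary",
    "panting": "binary",
    "wounds": "ternary",
    "tail biting": "binary",
    "lameness": "ternary",
    "pumping": "binary",
    "scouring": "ternary",
    "skin condition": "ternary",
    "hernia": "ternary",
    "twisted snout": "binary",
    "rectal prolapse": "binary",
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Parsed protocol definition: QBA configuration plus parameter scales."""

    qba: QBAConfig
    parameters: tuple[ParameterDefinition, ...]

    def parameter(self, pid: str) -> ParameterDefinition:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(pid)


def synthetic_qba_weights(seed: int = 2026) -> tuple[float, ...]:
    """Synthetic stand-in weights for the QBA weighted sum.

    The published weights live only in the protocol document and are not
    reproduced here.  These are generated: positive-valence adjectives get
    positive weights and negative-valence ones negative weights, scaled so
    the theoretical score range has a realistic width of roughly 24 score
    units over the 0-125 mm scale.  Use only for simulation and testing;
    real analyses must load the published weights from configuration.
    """
    negative = {"fearful", "agitated", "tense", "frustrated", "bored",
                "listless", "indifferent", "irritable", "aimless", "distressed"}
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.02, 0.12, size=N_ADJECTIVES)
    signs = np.array([-1.0 if a in negative else 1.0 for a in QBA_ADJECTIVES])
    w = raw * signs
    w *= 24.2 / (125.0 * np.abs(w).sum())
    return tuple(float(v) for v in w)


def default_protocol(weights: Sequence[float] | None = None) -> ProtocolConfig:
    """Protocol definition with all parameter scales and QBA settings.

    When *weights* is omitted, synthetic weights are used (see
    :func:`synthetic_qba_weights`).
    """
    qba = QBAConfig(
        adjectives=QBA_ADJECTIVES,
        weights=tuple(weights) if weights is not None else synthetic_qba_weights(),
        intercept=QBA_INTERCEPT,
        scale_max=125.0,
    )
    params = tuple(
        ParameterDefinition(id=pid, scale=scale)
        for pid, scale in PARAMETER_SCALES.items()
    )
    return ProtocolConfig(qba=qba, parameters=params)


def load_protocol(path: str | Path) -> ProtocolConfig:
    """Load and validate a protocol definition from YAML (or JSON).

    Expected structure::

        qba:
          adjectives: [active, relaxed, ...]   # 20 labels
          weights: [0.01, -0.02, ...]          # 20 signed reals
          intercept: -4.5367
          scale_max: 125
          score_range: 24.21                    # optional
        parameters:
          bursitis: ternary
          tail biting: binary
          ...
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "qba" not in data or "parameters" not in data:
        raise ConfigError(f"{path}: protocol file needs 'qba' and 'parameters'")
    q = data["qba"]
    try:
        qba = QBAConfig(
            adjectives=tuple(q["adjectives"]),
            weights=tuple(float(w) for w in q["weights"]),
            intercept=float(q.get("intercept", QBA_INTERCEPT)),
            scale_max=float(q.get("scale_max", 125.0)),
            score_range=(
                float(q["score_range"]) if "score_range" in q else None
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid qba section: {exc}") from exc
    params = tuple(
        ParameterDefinition(id=pid, scale=scale)
        for pid, scale in data["parameters"].items()
    )
    if not params:
        raise ConfigError(f"{path}: no parameters defined")
    return ProtocolConfig(qba=qba, parameters=params)


def dump_protocol(protocol: ProtocolConfig, path: str | Path) -> None:
    data = {
        "qba": {
            "adjectives": list(protocol.qba.adjectives),
            "weights": [float(w) for w in protocol.qba.weights],
            "intercept": float(protocol.qba.intercept),
            "scale_max": float(protocol.qba.scale_max),
        },
        "parameters": {p.id: p.scale for p in protocol.parameters},
    }
    if protocol.qba.score_range is not None:
        data["qba"]["score_range"] = float(protocol.qba.score_range)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_assessments(
    assessments: Iterable[FarmVisitAssessment], outdir: str | Path
) -> dict[str, Path]:
    """Write assessment records as the four-file CSV interchange set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qba_rows, animal_rows, scan_rows, resp_rows = [], [], [], []
    for a in assessments:
        for adjective, mm in a.qba.values.items():
            qba_rows.append((a.visit_id, a.observer_id, adjective, mm))
        for animal_id, scores in a.animals.scores.items():
            for parameter, category in scores.items():
                animal_rows.append(
                    (a.visit_id, a.observer_id, animal_id, parameter, category)
                )
        for rec in a.scans:
            for category, count in rec.counts.items():
                scan_rows.append(
                    (a.visit_id, a.observer_id, rec.viewpoint, rec.scan,
                     category, count)
                )
        resp_rows.append(
            (a.visit_id, a.observer_id, a.cough_count, a.sneeze_count,
             a.n_pigs_respiration)
        )
    paths = {}
    frames = {
        "qba.csv": pd.DataFrame(
            qba_rows, columns=["visit_id", "observer_id", "adjective", "mm"]
        ),
        "animals.csv": pd.DataFrame(
            animal_rows,
            columns=["visit_id", "observer_id", "animal_id", "parameter",
                     "category"],
        ),
        "scans.csv": pd.DataFrame(
            scan_rows,
            columns=["visit_id", "observer_id", "viewpoint", "scan",
                     "category", "count"],
        ),
        "respiration.csv": pd.DataFrame(
            resp_rows,
            columns=["visit_id", "observer_id", "coughs", "sneezes", "n_pigs"],
        ),
    }
    for name, frame in frames.items():
        path = outdir / name
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def write_truth(truth: Mapping, path: str | Path) -> None:
    """Serialise a ground-truth mapping (scalars and arrays) to JSON."""
    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        return v

    Path(path).write_text(
        json.dumps({k: _clean(v) for k, v in truth.items()}, indent=2),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _split_visit(visit_id: str) -> tuple[str, str]:
    farm, _, date = str(visit_id).partition(":")
    return farm, date


def read_assessments(
    directory: str | Path, protocol: ProtocolConfig
) -> list[FarmVisitAssessment]:
    """Assemble :class:`FarmVisitAssessment` records from the CSV set.

    Structural problems (missing files or columns) raise
    :class:`SchemaError`; value-level problems are left to
    :func:`wqagree.pipeline.validate_inputs`, which reports them all
    instead of failing on the first.
    """
    directory = Path(directory)
    frames = {}
    for name in CSV_FILES:
        path = directory / name
        if not path.exists():
            raise SchemaError(f"missing interchange file {path}")
        frames[name] = pd.read_csv(path)

    qba = frames["qba.csv"]
    animals = frames["animals.csv"]
    scans = frames["scans.csv"]
    resp = frames["respiration.csv"]
    for name, frame, cols in (
        ("qba.csv", qba, {"visit_id", "observer_id", "adjective", "mm"}),
        ("animals.csv", animals,
         {"visit_id", "observer_id", "animal_id", "parameter", "category"}),
        ("scans.csv", scans,
         {"visit_id", "observer_id", "viewpoint", "scan", "category", "count"}),
        ("respiration.csv", resp,
         {"visit_id", "observer_id", "coughs", "sneezes", "n_pigs"}),
    ):
        missing = cols - set(frame.columns)
        if missing:
            raise SchemaError(f"{name}: missing columns {sorted(missing)}")

    assessments = []
    keys = resp[["visit_id", "observer_id"]].drop_duplicates()
    for visit_id, observer_id in keys.itertuples(index=False):
        farm, date = _split_visit(visit_id)
        q = qba[(qba.visit_id == visit_id) & (qba.observer_id == observer_id)]
        ratings = AdjectiveRatings(
            visit_id=visit_id,
            observer_id=observer_id,
            values={str(r.adjective): float(r.mm) for r in q.itertuples()},
        )
        an = animals[
            (animals.visit_id == visit_id) & (animals.observer_id == observer_id)
        ]
        scores: dict[str, dict[str, int]] = {}
        for r in an.itertuples():
            scores.setdefault(str(r.animal_id), {})[str(r.parameter)] = int(
                r.category
            )
        sc = scans[
            (scans.visit_id == visit_id) & (scans.observer_id == observer_id)
        ]
        records = []
        for (vp, scan), grp in sc.groupby(["viewpoint", "scan"]):
            records.append(
                ScanRecord(
                    visit_id=visit_id,
                    observer_id=observer_id,
                    viewpoint=int(vp),
                    scan=int(scan),
                    counts={str(r.category): int(r.count) for r in grp.itertuples()},
                )
            )
        rrow = resp[
            (resp.visit_id == visit_id) & (resp.observer_id == observer_id)
        ].iloc[0]
        assessments.append(
            FarmVisitAssessment(
                farm_id=farm,
                visit_date=date,
                observer_id=str(observer_id),
                qba=ratings,
                scans=tuple(records),
                animals=AnimalScoreSheet(
                    visit_id=visit_id, observer_id=str(observer_id), scores=scores
                ),
                cough_count=int(rrow.coughs),
                sneeze_count=int(rrow.sneezes),
                n_pigs_respiration=int(rrow.n_pigs),
            )
        )
    return assessments
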