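"""End-to-end orchestration: read -> score -> pair -> filter -> statistics.

The pipeline is deterministic: the same input files and configuration
produce byte-identical report files.  Data-file validation is fail-open
(every violation is collected and reported with its file and row);
configuration validation is fail-fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import AgreementResult, Thresholds, bland_altman_points, evaluate_measure
from .errors import WQAgreeError
from .io import CSV_FILES, ProtocolConfig, read_assessments
from .protocol import (
    SCAN_CATEGORIES,
    MeasureTable,
    build_measure_tables,
    filter_rare_measures,
)

log = logging.getLogger("wqagree")

REPORT_COLUMNS = [
    "measure", "n", "mean_A", "mean_BC", "RS", "ICC", "SDC",
    "LoA_lower", "LoA_upper",
    "label_RS", "label_ICC", "label_SDC", "label_LoA",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: Path
    protocol: ProtocolConfig
    out_dir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    rare_threshold: float = 0.005
    pairs: tuple[tuple[str, str], ...] = (("A", "B"), ("A", "C"))


@dataclass
class Violation:
    file: str
    row: int
    message: str

    def __str__(self) -> str:
        return f"{self.file}:{self.row}: {self.message}"


def validate_inputs(
    directory: str | Path, protocol: ProtocolConfig
) -> list[Violation]:
    """Check every record against the protocol scales; collect all violations.

    Checks: QBA adjectives known and marks within [0, scale_max];
    individual-parameter categories on the parameter's scale; scan
    categories from the six-category set with nonnegative counts;
    respiration counts nonnegative with at least one pig observed.
    """
    directory = Path(directory)
    violations: list[Violation] = []
    scales = {p.id: p for p in protocol.parameters}

    def _frame(name: str) -> pd.DataFrame | None:
        path = directory / name
        if not path.exists():
            violations.append(Violation(name, 0, "file missing"))
            return None
        return pd.read_csv(path)

    qba = _frame("qba.csv")
    if qba is not None:
        known = set(protocol.qba.adjectives)
        for i, r in enumerate(qba.itertuples(), start=2):
            if str(r.adjective) not in known:
                violations.append(
                    Violation("qba.csv", i, f"unknown adjective {r.adjective!r}")
                )
            mm = float(r.mm)
            if not 0 <= mm <= protocol.qba.scale_max:
                violations.append(
                    Violation(
                        "qba.csv", i,
                        f"{r.adjective!r} = {mm} mm outside "
                        f"[0, {protocol.qba.scale_max}]",
                    )
                )

    animals = _frame("animals.csv")
    if animals is not None:
        for i, r in enumerate(animals.itertuples(), start=2):
            pid = str(r.parameter)
            if pid not in scales:
                violations.append(
                    Violation("animals.csv", i, f"unknown parameter {pid!r}")
                )
                continue
            param = scales[pid]
            if param.scale == "count":
                continue
            if int(r.category) not in param.categories:
                violations.append(
                    Violation(
                        "animals.csv", i,
                        f"category {r.category} not on the {param.scale} "
                        f"scale of {pid!r}",
                    )
                )

    scans = _frame("scans.csv")
    if scans is not None:
        for i, r in enumerate(scans.itertuples(), start=2):
            if str(r.category) not in SCAN_CATEGORIES:
                violations.append(
                    Violation("scans.csv", i, f"unknown category {r.category!r}")
                )
            if int(r.count) < 0:
                violations.append(
                    Violation("scans.csv", i, f"negative count {r.count}")
                )

    resp = _frame("respiration.csv")
    if resp is not None:
        for i, r in enumerate(resp.itertuples(), start=2):
            if int(r.n_pigs) < 1:
                violations.append(
                    Violation("respiration.csv", i, "n_pigs must be >= 1")
                )
            if int(r.coughs) < 0 or int(r.sneezes) < 0:
                violations.append(
                    Violation("respiration.csv", i, "negative respiration count")
                )
    return violations


def results_frame(results: list[AgreementResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "measure": r.measure_id,
                "n": r.n,
                "mean_A": r.mean_a,
                "mean_BC": r.mean_bc,
                "RS": r.rs,
                "ICC": np.nan if r.icc is None else r.icc,
                "SDC": r.sdc,
                "LoA_lower": r.loa_lower,
                "LoA_upper": r.loa_upper,
                "label_RS": r.labels["rs"],
                "label_ICC": r.labels["icc"],
                "label_SDC": r.labels["sdc"],
                "label_LoA": r.labels["loa"],
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def analyse_tables(
    tables: list[MeasureTable],
    thresholds: Thresholds,
    rare_threshold: float,
) -> tuple[list[AgreementResult], list[tuple[MeasureTable, str]]]:
    """Filter rare measures and evaluate the agreement statistics per table."""
    kept, excluded = filter_rare_measures(tables, rare_threshold)
    results = [evaluate_measure(t, thresholds) for t in kept]
    return results, excluded


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Full analysis: read CSVs, score, pair, filter, compute, write reports.

    Writes to ``config.out_dir``:

    * ``report.csv`` — display report rounded to 2 decimals;
    * ``report_full.csv`` — same rows at full precision;
    * ``excluded.csv`` — rare measures dropped, with reasons;
    * ``bland_altman.csv`` — per-visit (average, difference) points per
      measure for Bland-Altman plotting.

    Returns the full-precision report frame.  Raises on validation
    failure; callers wanting the complete violation list should run
    :func:`validate_inputs` first.
    """
    violations = validate_inputs(config.input_dir, config.protocol)
    if violations:
        raise WQAgreeError(
            f"{len(violations)} validation violation(s); first: {violations[0]}"
        )
    assessments = read_assessments(config.input_dir, config.protocol)
    log.info("read %d assessment records", len(assessments))
    tables = build_measure_tables(
        assessments, list(config.pairs),
        config.protocol.qba, config.protocol.parameters,
    )
    n_visits = len(tables[0]) if tables else 0
    results, excluded = analyse_tables(
        tables, config.thresholds, config.rare_threshold
    )
    log.info(
        "visits=%d measures=%d kept=%d excluded=%d",
        n_visits, len(tables), len(results), len(excluded),
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    full = results_frame(results)
    full.to_csv(out / "report_full.csv", index=False)
    display = full.copy()
    for col in ("mean_A", "mean_BC", "RS", "ICC", "SDC", "LoA_lower", "LoA_upper"):
        display[col] = display[col].round(2)
    display.to_csv(out / "report.csv", index=False)

    pd.DataFrame(
        [(t.measure_id, reason) for t, reason in excluded],
        columns=["measure", "reason"],
    ).to_csv(out / "excluded.csv", index=False)

    ba_rows = []
    kept_ids = {r.measure_id for r in results}
    for table in tables:
        if table.measure_id not in kept_ids:
            continue
        for (avg, diff), visit in zip(bland_altman_points(table), table.visit_ids):
            ba_rows.append((table.measure_id, visit, avg, diff))
    pd.DataFrame(
        ba_rows, columns=["measure", "visit_id", "average", "difference"]
    ).to_csv(out / "bland_altman.csv", index=False)
    return full
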