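"""CSV/JSON I/O, case records, bundled fixtures and run configuration.

CSV is the interchange format for pathology score sheets: one row per
case (full-face mode, percentage profile columns) or one row per core
(TMA mode).  Reports are written as CSV or JSON with deterministic byte
output for fixed inputs, and every report embeds the scoring
configuration that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .concordance import CaseCoreSet
from .scoring import (
    CategoryThresholds,
    IntensityProfile,
    ProfileError,
    ScoreWeights,
)

__all__ = [
    "CaseRecord",
    "RunConfig",
    "read_cases",
    "write_report",
    "fixture_path",
    "load_fixture",
    "load_table2_cases",
    "FIXTURES",
]

log = logging.getLogger("hetrank")

#: Controlled vocabularies for covariates that have one.  Values outside a
#: vocabulary are rejected in strict mode and passed through with a
#: warning otherwise (real score sheets are messy).
COVARIATE_VOCAB: dict[str, frozenset[str]] = {
    "her2_status": frozenset({"positive", "negative", "unspecified"}),
    "sex": frozenset({"female", "male"}),
    "survival_status": frozenset({"living", "deceased"}),
    "lauren": frozenset({"intestinal", "diffuse", "mixed"}),
    "ki67_band": frozenset({"0-1%", "2-10%", "11-20%", "21-50%", ">50%"}),
}

#: Known optional covariate columns, in canonical output order.
COVARIATE_COLUMNS = (
    "her2_status",
    "t_stage",
    "n_stage",
    "m_stage",
    "differentiation",
    "lauren",
    "location",
    "ki67_band",
    "sex",
    "survival_status",
)

FULLFACE_REQUIRED = ("case_id", "pct_1plus", "pct_2plus", "pct_3plus")
TMA_REQUIRED = ("case_id", "core_id", "score")

#: Names of the bundled fixture tables.
FIXTURES = ("table2", "table1-location", "table1-her2", "table3-her2")
_FIXTURE_FILES = {
    "table2": "table2.csv",
    "table1-location": "table1_location.csv",
    "table1-her2": "table1_her2.csv",
    "table3-her2": "table3_her2.csv",
}


@dataclass(frozen=True)
class CaseRecord:
    """One patient case: a full-face profile or TMA core scores, plus covariates."""

    case_id: str
    profile: IntensityProfile | None = None
    cores: CaseCoreSet | None = None
    covariates: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class RunConfig:
    """Scoring configuration embedded in every report for provenance."""

    weights: ScoreWeights = field(default_factory=ScoreWeights)
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "weights": {"w1": self.weights.w1, "w2": self.weights.w2, "w3": self.weights.w3},
            "thresholds": {
                "low_cut": self.thresholds.low_cut,
                "high_cut": self.thresholds.high_cut,
            },
            "seed": self.seed,
        }


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture table."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    return Path(str(resources.files("hetrank").joinpath("data", _FIXTURE_FILES[name])))


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled fixture as a DataFrame."""
    return pd.read_csv(fixture_path(name))


def _parse_covariates(row: pd.Series, columns, strict: bool) -> dict:
    cov: dict[str, Any] = {}
    for col in columns:
        if col not in row.index:
            continue
        val = row[col]
        if pd.isna(val):
            cov[col] = None
            continue
        val = str(val).strip()
        vocab = COVARIATE_VOCAB.get(col)
        if vocab is not None and val.lower() not in vocab:
            msg = f"covariate {col}={val!r} is not in the declared vocabulary"
            if strict:
                raise ValueError(msg)
            log.warning("%s (kept as-is)", msg)
            cov[col] = val
        else:
            cov[col] = val.lower() if vocab is not None else val
    return cov


def read_cases(
    path: str | Path,
    mode: str = "fullface",
    strict: bool = False,
) -> tuple[list[CaseRecord], list[tuple[int, str]]]:
    """Read and validate a case sheet.

    ``mode='fullface'`` expects one row per case with percentage columns
    ``pct_1plus/pct_2plus/pct_3plus`` (optional ``pct_0``); ``mode='tma'``
    expects one row per core with ``case_id, core_id, score`` and groups
    cores by case.  Returns ``(records, rejected)`` where *rejected* holds
    ``(1-based data row number, reason)`` for every row that failed
    validation.  Raises on structural problems (missing file, missing
    required columns) rather than per-row ones.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty; expected a header with columns "
                         f"{FULLFACE_REQUIRED if mode == 'fullface' else TMA_REQUIRED}")
    required = FULLFACE_REQUIRED if mode == "fullface" else TMA_REQUIRED
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {', '.join(missing)}")

    records: list[CaseRecord] = []
    rejected: list[tuple[int, str]] = []
    if mode == "fullface":
        cov_cols = [c for c in COVARIATE_COLUMNS if c in frame.columns]
        seen: set[str] = set()
        for idx, row in frame.iterrows():
            rowno = int(idx) + 1
            case_id = str(row["case_id"])
            if case_id in seen:
                rejected.append((rowno, f"duplicate case_id {case_id!r}"))
                continue
            try:
                pcts = {
                    k: float(row[c])
                    for k, c in (("p1", "pct_1plus"), ("p2", "pct_2plus"), ("p3", "pct_3plus"))
                }
                if "pct_0" in frame.columns and not pd.isna(row["pct_0"]):
                    pcts["p0"] = float(row["pct_0"])
                profile = IntensityProfile(**pcts)
                cov = _parse_covariates(row, cov_cols, strict)
            except (ProfileError, ValueError, TypeError) as exc:
                rejected.append((rowno, str(exc)))
                continue
            seen.add(case_id)
            records.append(CaseRecord(case_id=case_id, profile=profile, covariates=cov))
    elif mode == "tma":
        by_case: dict[str, list[int]] = {}
        order: list[str] = []
        for idx, row in frame.iterrows():
            rowno = int(idx) + 1
            case_id = str(row["case_id"])
            try:
                score = float(row["score"])
                if score != int(score) or not (0 <= score <= 3):
                    raise ValueError(f"score {row['score']!r} is not an integer in 0..3")
            except (ValueError, TypeError) as exc:
                rejected.append((rowno, str(exc)))
                continue
            if case_id not in by_case:
                by_case[case_id] = []
                order.append(case_id)
            by_case[case_id].append(int(score))
        for case_id in order:
            records.append(
                CaseRecord(
                    case_id=case_id,
                    cores=CaseCoreSet(case_id=case_id, scores=tuple(by_case[case_id])),
                )
            )
    else:
        raise ValueError(f"mode must be 'fullface' or 'tma', got {mode!r}")

    log.info(
        "read %d case(s) from %s (%d row(s) rejected)", len(records), path, len(rejected)
    )
    return records, rejected


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, IntensityProfile):
        return {"p0": obj.p0, "p1": obj.p1, "p2": obj.p2, "p3": obj.p3}
    return obj


def write_report(
    results: pd.DataFrame | Mapping[str, Any],
    path: str | Path,
    format: str | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write a report with deterministic bytes for fixed inputs.

    CSV output (DataFrames) uses a fixed column order and pandas' float
    repr; JSON output keeps insertion order and 2-space indentation.
    When ``config`` is given, a JSON report embeds it under ``"config"``
    and a CSV report gains a comment-free sidecar-style header row is
    avoided: the config is written next to it as ``<path>.config.json``.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        if not isinstance(results, pd.DataFrame):
            raise TypeError("CSV reports require a DataFrame")
        results.to_csv(path, index=False)
        if config is not None:
            Path(str(path) + ".config.json").write_text(
                json.dumps(config.to_dict(), indent=2) + "\n"
            )
    elif format == "json":
        payload = _jsonable(results)
        if config is not None:
            if not isinstance(payload, dict):
                payload = {"results": payload}
            payload["config"] = config.to_dict()
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
    log.info("wrote %s report to %s", format, path)


def load_table2_cases() -> list[CaseRecord]:
    """The bundled 25-case full-face reference cohort as CaseRecords."""
    records, rejected = read_cases(fixture_path("table2"), mode="fullface")
    assert not rejected, "bundled fixture must validate cleanly"
    return records
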