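"""Readers, writers and run configuration.

All on-disk formats are plain text: CSV with a mandatory header row, comma
separators, '.' decimals and UTF-8; JSON reports with sorted keys and
default float repr (shortest round-trip), so identical inputs produce
byte-identical outputs. Microvolt columns carry a ``_uV`` suffix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .metrics import AQRGrid
from .signals import BeatEnsemble, BeatSignal
from .simulate import Cohort, CohortSpec

__all__ = [
    "RunConfig",
    "load_config",
    "parse_range",
    "read_signal_csv",
    "write_signal_csv",
    "read_ensemble_csv",
    "write_fit_report",
    "write_grid",
    "read_grid",
    "write_cohort",
    "read_feature_table",
    "write_feature_table",
    "write_json_report",
]


def _jsonify(obj):
    """Recursively convert numpy scalars/arrays for deterministic JSON."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json_report(path, payload: dict) -> None:
    """Write a JSON report with stable key order and float formatting."""
    text = json.dumps(_jsonify(payload), indent=2, sort_keys=True)
    Path(path).write_text(text + "\n", encoding="utf-8")


def parse_range(spec: str) -> list:
    """Expand a "lo:hi[:step]" range (inclusive) or comma list to numbers.

    ``"1:20"`` -> 1..20, ``"2:40:2"`` -> 2, 4, ..., 40 (the conventional
    grid notations), ``"5,10,12"`` -> [5, 10, 12], ``"7"`` -> [7]. Values
    come back as ints when exact, floats otherwise.
    """

    def _num(tok: str):
        v = float(tok)
        return int(v) if v == int(v) else v

    spec = spec.strip()
    if ":" in spec:
        parts = spec.split(":")
        if len(parts) not in (2, 3):
            raise InvalidInputError(f"malformed range {spec!r}; expected lo:hi[:step]")
        lo, hi = _num(parts[0]), _num(parts[1])
        step = _num(parts[2]) if len(parts) == 3 else 1
        if step <= 0 or hi < lo:
            raise InvalidInputError(f"malformed range {spec!r}")
        vals = list(np.arange(lo, hi + step / 2, step))
        return [_num(repr(float(v))) for v in vals]
    return [_num(tok) for tok in spec.split(",") if tok.strip()]


# -- signal CSV ------------------------------------------------------------

def read_signal_csv(path, fs: float = 2000.0) -> dict:
    """Read a ``sample_index,<lead>[,...]`` CSV into lead -> BeatSignal."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    if "sample_index" not in frame.columns:
        raise InvalidInputError(f"{path}: missing required 'sample_index' column")
    leads = [c for c in frame.columns if c != "sample_index"]
    if not leads:
        raise InvalidInputError(f"{path}: no lead columns found")
    frame[leads] = frame[leads].apply(pd.to_numeric, errors="coerce")
    if frame[leads].isna().any().any():
        first = int(frame[frame[leads].isna().any(axis=1)].index[0]) + 2  # header+1-based
        raise InvalidInputError(f"{path}: non-numeric or missing value near line {first}")
    return {
        lead: BeatSignal(frame[lead].to_numpy(dtype=float), fs=fs, lead=lead)
        for lead in leads
    }


def write_signal_csv(path, signals: dict) -> None:
    """Write lead -> BeatSignal (equal lengths) as one signal CSV."""
    leads = list(signals)
    p = signals[leads[0]].p
    data = {"sample_index": np.arange(1, p + 1)}
    for lead in leads:
        data[lead] = signals[lead].samples
    pd.DataFrame(data).to_csv(path, index=False)


def read_ensemble_csv(path, fs: float = 2000.0, lead: str = "X") -> BeatEnsemble:
    """Read a ``beat_id,sample_index,value_uV`` long-format beat ensemble."""
    frame = pd.read_csv(path)
    needed = {"beat_id", "sample_index", "value_uV"}
    if not needed.issubset(frame.columns):
        raise InvalidInputError(f"{path}: ensemble CSV needs columns {sorted(needed)}")
    beats = [
        g.sort_values("sample_index")["value_uV"].to_numpy(dtype=float)
        for _, g in frame.groupby("beat_id", sort=True)
    ]
    return BeatEnsemble(beats=beats, fs=fs, lead=lead)


# -- fit / grid reports ----------------------------------------------------

def write_fit_report(path, model, result, trace) -> None:
    """JSON fit report: centers, spread, weights, SSE, AIQP, AQR, err ratios."""
    write_json_report(
        path,
        {
            "M": model.M,
            "sigma": model.spread,
            "centers": model.centers,
            "weights": model.weights,
            "sse": result.sse,
            "aiqp_uV": result.aiqp,
            "aqr": result.aqr,
            "err_ratios": trace.err_ratios,
        },
    )


def write_grid(path_csv, grid: AQRGrid, path_json=None) -> None:
    """AQR grid as CSV (rows = M, columns = sigma) plus a JSON sidecar."""
    grid.to_dataframe().to_csv(path_csv)
    if path_json is not None:
        write_json_report(
            path_json,
            {
                "lead": grid.lead,
                "m_values": grid.m_values,
                "sigma_values": grid.sigma_values,
                "n_missing": int(np.isnan(grid.values).sum()),
            },
        )


def read_grid(path_csv, lead: str = "X") -> AQRGrid:
    frame = pd.read_csv(path_csv, index_col=0)
    return AQRGrid(
        lead=lead,
        m_values=frame.index.to_numpy(dtype=int),
        sigma_values=frame.columns.to_numpy(dtype=float),
        values=frame.to_numpy(dtype=float),
    )


# -- cohorts and feature tables -------------------------------------------

def write_cohort(out_dir, cohort: Cohort) -> Path:
    """One signal CSV per subject plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        fname = f"{subj.subject_id}.csv"
        write_signal_csv(out / fname, subj.leads)
        row = {"subject_id": subj.subject_id, "label": subj.label, "file": fname}
        for lead, v in subj.true_aiqp_rms.items():
            row[f"true_aiqp_rms_{lead.lower()}_uV"] = v
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_feature_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise InvalidInputError(f"{path}: feature table needs a 'label' column")
    return frame


def write_feature_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


# -- run configuration -----------------------------------------------------

@dataclass
class RunConfig:
    """Validated bundle of pipeline parameters (mirrors the CLI flags)."""

    sampling_rate: float = 2000.0
    filter_band: tuple = (40.0, 250.0)
    filter_order: int = 4
    m_values: list = field(default_factory=lambda: [20])
    sigma_values: list = field(default_factory=lambda: list(range(1, 21)))
    las_threshold_uV: float = 40.0
    seed: int | None = None
    output_dir: str = "."

    def __post_init__(self):
        low, high = self.filter_band
        if not (0 < low < high < self.sampling_rate / 2):
            raise InvalidInputError(f"filter band {self.filter_band} infeasible")
        if self.filter_order < 1:
            raise InvalidInputError("filter order must be >= 1")
        if not self.m_values or not self.sigma_values:
            raise InvalidInputError("m_values and sigma_values must be nonempty")
        if any(m < 1 for m in self.m_values):
            raise InvalidInputError("neuron counts must be >= 1")
        if any(s <= 0 for s in self.sigma_values):
            raise InvalidInputError("spreads must be positive")


def load_config(path) -> RunConfig:
    """Load a YAML or JSON RunConfig; unknown keys are rejected."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("m_values", "sigma_values"):
        if isinstance(data.get(key), str):
            data[key] = parse_range(data[key])
    if isinstance(data.get("filter_band"), list):
        data["filter_band"] = tuple(data["filter_band"])
    return RunConfig(**data)


def load_cohort_spec(path) -> CohortSpec:
    """Load a YAML or JSON CohortSpec."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: cohort spec must be a mapping")
    for key in ("aiqp_rms_normal", "aiqp_rms_vt", "qrs_rms_range", "leads"):
        if isinstance(data.get(key), list):
            data[key] = tuple(data[key])
    known = set(CohortSpec.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"{path}: unknown cohort spec keys {sorted(unknown)}")
    return CohortSpec(**data)
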