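"""Configuration loading, validation and report writing.

Configs are YAML (JSON is a YAML subset and therefore also accepted) with up
to four top-level sections: ``monitoring``, ``trial``, ``scenario`` and
run-level keys (``seed``, ``out_dir``, ``designs``, ``n_trials``).  Unknown
keys are rejected by name; every omitted field falls back to the package
default and the applied default is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .dose_finding import TrialConfig
from .monitoring import MonitoringConfig
from .simulator import DESIGNS, OCSummary, Scenario

__all__ = ["RunConfig", "load_and_validate", "write_oc_table", "read_oc_table"]

logger = logging.getLogger("backfill_qol")

_RUN_KEYS = {"monitoring", "trial", "scenario", "seed", "out_dir", "designs", "n_trials"}


@dataclass
class RunConfig:
    monitoring: MonitoringConfig
    trial: TrialConfig
    scenario: Optional[Scenario] = None
    seed: int = 0
    out_dir: Optional[Path] = None
    designs: list[str] = field(default_factory=lambda: ["backfill_qol"])
    n_trials: int = 1000


def _build_section(cls, raw: dict[str, Any], section: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{section}' section: {', '.join(sorted(unknown))}"
        )
    for name, fld in known.items():
        if name not in raw and fld.default is not dataclasses.MISSING:
            logger.info("config: %s.%s defaulted to %r", section, name, fld.default)
    return cls(**raw)


def _build_scenario(raw: dict[str, Any]) -> Scenario:
    known = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in 'scenario' section: {', '.join(sorted(unknown))}"
        )
    raw = dict(raw)
    for key in ("dlt_probs", "response_probs", "qol_means", "qol_sds"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    if raw.get("corr") is not None:
        raw["corr"] = np.asarray(raw["corr"], dtype=float)
    return Scenario(**raw)


def load_and_validate(source: str | Path | dict) -> RunConfig:
    """Parse and validate a run configuration.

    ``source`` may be a path to a YAML/JSON file, YAML text, or an
    already-parsed mapping.  Raises ``ValueError`` naming the offending field
    on schema or invariant violations.
    """
    if isinstance(source, dict):
        raw = source
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).is_file()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    monitoring = _build_section(MonitoringConfig, raw.get("monitoring", {}) or {}, "monitoring")
    trial = _build_section(TrialConfig, raw.get("trial", {}) or {}, "trial")
    scenario = None
    if raw.get("scenario") is not None:
        scen_raw = raw["scenario"]
        if isinstance(scen_raw, str):
            scen_path = Path(scen_raw)
            if not scen_path.is_file():
                raise ValueError(f"scenario file not found: {scen_raw}")
            scen_raw = yaml.safe_load(scen_path.read_text())
        scenario = _build_scenario(scen_raw)
        if scenario.n_doses != trial.n_doses:
            raise ValueError(
                f"scenario defines {scenario.n_doses} doses but trial.n_doses is "
                f"{trial.n_doses}"
            )
    seed = int(raw.get("seed", 0))
    if seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    designs = list(raw.get("designs", ["backfill_qol"]))
    for d in designs:
        if d not in DESIGNS:
            raise ValueError(f"unknown design {d!r}; expected one of {DESIGNS}")
    n_trials = int(raw.get("n_trials", 1000))
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if trial.n_escalation_max % trial.cohort_size != 0:
        logger.warning(
            "config: n_escalation_max (%d) is not a multiple of cohort_size (%d)",
            trial.n_escalation_max,
            trial.cohort_size,
        )
    out_dir = Path(raw["out_dir"]) if raw.get("out_dir") else None
    return RunConfig(
        monitoring=monitoring,
        trial=trial,
        scenario=scenario,
        seed=seed,
        out_dir=out_dir,
        designs=designs,
        n_trials=n_trials,
    )


_OC_COLUMNS = [
    "scenario",
    "design",
    "pcs_mtd",
    "pcs_rp2d",
    "expected_n",
    "avg_duration",
]


def write_oc_table(summaries: list[OCSummary], path: str | Path, fmt: str = "csv") -> None:
    """Write operating characteristics with a fixed column order.

    CSV round-trips exactly at 6-decimal precision; ``json`` dumps the full
    summaries including per-dose frequencies.
    """
    path = Path(path)
    if fmt == "json":
        payload = [dataclasses.asdict(s) for s in summaries]
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    rows = [
        {key: getattr(s, key) for key in _OC_COLUMNS}
        for s in summaries
    ]
    frame = pd.DataFrame(rows, columns=_OC_COLUMNS)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "text":
        path.write_text(frame.to_string(index=False, float_format="%.2f".__mod__) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected csv, json or text")


def read_oc_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
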