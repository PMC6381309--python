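"""Report assembly and serialisation for the command-line front end.

A per-bout analysis report is a JSON-serialisable dict with explicit
units on every numeric block, provenance (input path, config hash,
software version, pipeline stages) and a warnings list. The schema is
versioned so downstream consumers can detect changes.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from typing import Optional

import pandas as pd

SCHEMA_VERSION = "1.0"


def package_version() -> str:
    try:
        return _pkg_version("critspeed")
    except PackageNotFoundError:
        return "unknown"


def config_hash(options: dict) -> str:
    """Stable short hash of the analysis options; changes iff an option does."""
    blob = json.dumps(options, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_report(
    results,
    input_path: str,
    options: dict,
    warnings: Optional[list] = None,
) -> dict:
    """Assemble the versioned per-bout report from AllOutTestResults."""
    d = results.to_dict()
    stages = results.model.series.meta.get("stages")
    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "input": str(input_path),
            "software": {"name": "critspeed", "version": package_version()},
            "config_hash": config_hash(options),
            "options": options,
            "stages": stages,
        },
        "units": {
            "params": {"s0": "m/s", "a_d": "m/s", "a_g": "m/s", "t_c": "s", "tau_g": "s", "tau_d": "s"},
            "derived": {
                "s_max": "m/s", "fi_percent": "%", "s_prime": "m",
                "total_distance": "m", "anaerobic_fraction": "%", "t_star": "s",
            },
            "classic": {"cs": "m/s", "d_prime": "m", "mean_speed_150": "m/s"},
            "rmse": "m/s",
        },
        "fit": {
            "params": d["params"],
            "bse": d["bse"],
            "r": d["r"],
            "rmse": d["rmse"],
            "converged": d["converged"],
            "n_iter": d["n_iter"],
        },
        "derived": d["derived"],
        "classic": d["classic"],
        "warnings": list(warnings or []),
    }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV with columns path, subject, condition."""
    df = pd.read_csv(path)
    needed = {"path", "subject", "condition"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
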