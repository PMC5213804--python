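"""Report serialization and small file helpers."""

from __future__ import annotations

import json
from pathlib import Path

REPORT_SCHEMA_VERSION = 1


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, path) -> None:
    """Write an analysis report as JSON (schema-versioned, round-trippable)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **_jsonable(report)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {report.get('schema_version')!r}"
        )
    return report
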