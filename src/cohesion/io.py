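"""CSV readers, JSON report writers and run manifests.

Long-format CSV in, JSON out.  Continuous data: columns
``sample_id,value`` (one observation per row).  Categorical data:
``sample_id,category,count``.  Every JSON report embeds a manifest
(command, parameters, seed, version) so a run can be reproduced; the
timestamp is recorded but excluded from any byte-identity comparison.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .ensemble import Ensemble, Sample

__all__ = ["ParseError", "read_samples", "write_report", "read_report", "make_manifest"]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""


_SCHEMAS = {
    "continuous": ["sample_id", "value"],
    "categorical": ["sample_id", "category", "count"],
}


def read_samples(path: str | Path, kind: str, weighting: str = "equal") -> Ensemble:
    """Read a long-format CSV into a validated ensemble.

    ``kind`` must match the file's header (``continuous`` needs
    sample_id,value; ``categorical`` needs sample_id,category,count).
    Malformed rows are reported with their 1-based line numbers.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"kind must be one of {sorted(_SCHEMAS)}, got {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty")
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: header {list(df.columns)} lacks required column(s) {missing} "
            f"for kind={kind!r}"
        )
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")

    samples: list[Sample] = []
    labels = df["label"] if "label" in df.columns else None
    if kind == "continuous":
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: line {bad[0] + 2}: non-numeric value {df['value'][bad[0]]!r}"
            )
        for sid, grp in df.assign(_v=values).groupby("sample_id", sort=True):
            label = str(grp["label"].iloc[0]) if labels is not None else None
            samples.append(Sample(id=str(sid), observations=tuple(grp["_v"]), label=label))
    else:
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.index[counts.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: line {bad[0] + 2}: non-numeric count {df['count'][bad[0]]!r}"
            )
        for sid, grp in df.assign(_c=counts).groupby("sample_id", sort=True):
            cmap = dict(zip(grp["category"], grp["_c"]))
            samples.append(Sample(id=str(sid), counts=cmap))
    return Ensemble(tuple(samples), weighting=weighting)


def make_manifest(command: str, parameters: dict, seed: int | None) -> dict:
    return {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_report(report: dict, path: str | Path, manifest: dict | None = None) -> None:
    """Write a JSON report (full float precision) with an embedded manifest."""
    doc = dict(report)
    if manifest is not None:
        doc["manifest"] = manifest
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=False) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
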