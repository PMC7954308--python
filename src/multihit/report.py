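"""Versioned JSON result reports and summary-row derivation."""

from __future__ import annotations

import json
import os
import platform
import time
from typing import Optional

import pandas as pd

from .fit import FitResult
from .hypotheses import TestReport

SCHEMA_VERSION = "1.0"


def build_report(
    fits: dict[str, FitResult],
    tests: Optional[TestReport] = None,
    events: Optional[pd.DataFrame] = None,
    input_summary: Optional[dict] = None,
) -> dict:
    """Assemble the analysis result dictionary."""
    doc: dict = {
        "schema version": SCHEMA_VERSION,
        "input": input_summary or {},
        "fits": {name: fr.to_dict() for name, fr in fits.items()},
        "runtime": {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "python": platform.python_version(),
        },
    }
    if tests is not None:
        doc.update(tests.to_dict())
    if events is not None:
        doc["substitution census"] = events.to_dict(orient="records")
    return doc


def write_report(doc: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_report(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def summary_row(doc: dict) -> dict:
    """One benchmark-table-style row from a report.

    N (sequences), S (codons), T (tree length under 1H), the multiple-hit
    rate estimates under the 3H model (delta also under 2H), the five LRT
    p-values, and the counts of sites with ER > 5 for 2H:1H and 3H+:2H.
    """
    fits = doc["fits"]
    tests = doc.get("test results", {})
    ers = doc.get("evidence ratios", {})
    row: dict = {
        "N": doc.get("input", {}).get("n_taxa"),
        "S": doc.get("input", {}).get("n_sites"),
    }
    if "1H" in fits:
        bl = fits["1H"]["params"].get("branch_lengths") or []
        row["T"] = float(sum(bl))
    source = "3H" if "3H" in fits else "3H+"
    if source in fits:
        p = fits[source]["params"]
        row["delta"] = p["delta"]
        row["psi_s"] = p["psi_s"]
        row["psi"] = p["psi"]
    if "2H" in fits:
        row["delta_2H"] = fits["2H"]["params"]["delta"]
    for name in ("2H:1H", "3H+:1H", "3H+:2H", "3H+:3HSI", "3HSI:2H"):
        if name in tests:
            row[f"p {name}"] = tests[name]["p-value"]
    for name in ("2H:1H", "3H+:2H"):
        if name in ers:
            row[f"ER>5 {name}"] = int(sum(1 for e in ers[name] if e > 5))
    return row
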