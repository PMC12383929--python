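"""Reproducible synthetic fixtures for tests and demos.

These stand-ins exercise the I/O and metrics paths without any external
dataset: a SYNTHETIC observed concentration series, a dosing schedule for
the default suspension, and the benchmark timestep-policy table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .blink import STANDARD_POLICIES
from .metrics import synthetic_observed_series
from .transport import DrugProperties

__all__ = ["generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("observed_series", "dosing_schedule", "policy_table")


def generate_fixture(kind: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write the named fixture into ``outdir``; same seed, same bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "observed_series":
        path = outdir / f"observed_series_seed{seed}.csv"
        synthetic_observed_series(seed).to_csv(path)
        return [path]
    if kind == "dosing_schedule":
        drug = DrugProperties()
        path = outdir / "dosing_schedule.csv"
        pd.DataFrame(
            [
                {
                    "time_s": 0.0,
                    "volume_uL": drug.dose_volume_uL,
                    "drug_mass_ug": drug.dose_mass_ug,
                }
            ]
        ).to_csv(path, index=False)
        return [path]
    if kind == "policy_table":
        path = outdir / "policy_table.json"
        payload = {
            label: [list(w) for w in pol.windows]
            for label, pol in STANDARD_POLICIES.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return [path]
    raise ValueError(f"unknown fixture kind {kind!r}; pick from {FIXTURE_KINDS}")
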