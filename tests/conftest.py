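"""Shared fixtures: small hand-built assays and hypothesis configuration."""

import hypothesis
import numpy as np
import pandas as pd
import pytest

from platefeed import AssayConfig, join_layout
from platefeed.plates import ROWS, WELL_COLUMNS, well_name

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")


def build_wells(plate_values: dict) -> pd.DataFrame:
    """Well table from {plate_id: [v0, v1, ...]} filled row-major (role='empty')."""
    rows = []
    for pid, values in plate_values.items():
        for i, v in enumerate(values):
            rows.append(
                (pid, well_name(ROWS[i // 12], i % 12 + 1), ROWS[i // 12], i % 12 + 1,
                 float(v), "empty", None, None)
            )
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def build_assay(
    plates: dict,
    meta: dict | None = None,
    config: AssayConfig | None = None,
) -> pd.DataFrame:
    """Annotated well table from a compact description.

    ``plates`` maps plate_id -> dict with optional keys ``controls``,
    ``stressor_controls``, ``blanks`` (lists of RFU) and ``samples``
    (dict sample_id -> list of technical-replicate RFU).  ``meta`` maps
    sample_id -> dict overriding genotype/block/status/volume_mL/hours.
    """
    meta = meta or {}
    values, layout_rows = {}, []
    role_of = {"controls": "control", "stressor_controls": "stressor_control",
               "blanks": "blank"}
    for pid, contents in plates.items():
        vals = []

        def put(v, role, sid=None):
            i = len(vals)
            vals.append(float(v))
            layout_rows.append((pid, well_name(ROWS[i // 12], i % 12 + 1), role, sid))

        for key, role in role_of.items():
            for v in contents.get(key, []):
                put(v, role)
        for sid, reps in contents.get("samples", {}).items():
            for v in reps:
                put(v, "sample", sid)
        values[pid] = vals

    wells = build_wells(values)
    layout = pd.DataFrame(layout_rows, columns=["plate_id", "well", "role", "sample_id"])
    sids = sorted({sid for _, _, r, sid in layout_rows if r == "sample"})
    meta_df = pd.DataFrame(
        columns=["sample_id", "genotype", "block", "status", "volume_mL", "hours"],
        data=[
            {
                "sample_id": sid,
                "genotype": meta.get(sid, {}).get("genotype", "G1"),
                "block": meta.get(sid, {}).get("block", "B1"),
                "status": meta.get(sid, {}).get("status", "ok"),
                "volume_mL": meta.get(sid, {}).get("volume_mL", np.nan),
                "hours": meta.get(sid, {}).get("hours", np.nan),
            }
            for sid in sids
        ]
    )
    return join_layout(wells, layout, meta_df, config=config)


@pytest.fixture
def one_plate_assay() -> pd.DataFrame:
    """Single plate: 3 controls at 1000, one sample at {500, 500}."""
    return build_assay({"P1": {"controls": [1000, 1000, 1000],
                               "samples": {"S1": [500, 500]}}})


@pytest.fixture
def no_bootstrap_config() -> AssayConfig:
    return AssayConfig(bootstrap_B=0, rng_seed=0)
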