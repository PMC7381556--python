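"""Feeding under a fluorescent stressor, and exposure/dose conversion.

When the medium carries a fluorescent contaminant or infectious agent
(microplastics, fungal spores, ...), animal-free control tubes that
*include the stressor* replace the pure-algae controls, so the stressor's
background fluorescence enters F(0) and F(t) alike and the clearance-rate
ratio stays interpretable.  A clearance rate then converts directly to
encounter quantities for a particle suspended at concentration ``Z``
(particles mL^-1):

* exposure rate  E = f * Z            (particles hr^-1)
* cumulative dose, constant concentration   D = f * Z0 * t
* cumulative dose, depleting concentration  D = Z0 * V * (1 - exp(-f t / V))

The depleting model treats the particles like the algae — cleared from a
closed volume — and is the default; it is bounded by the ``Z0 * V``
particles present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import FeedingAssay, FeedingRateResults
from .errors import EstimationError
from .plates import AssayConfig

DOSE_MODELS = ("constant_Z", "depleting_Z")


@dataclass(frozen=True)
class ExposureEstimate:
    """Per-animal exposure summary at particle concentration Z."""

    sample_id: str
    f_value: float  # mL hr^-1
    particle_concentration_Z: float  # particles mL^-1
    exposure_rate: float  # particles hr^-1
    cumulative_dose: float  # particles over the assay
    dose_model: str


def estimate_with_stressor(
    wells: pd.DataFrame, config: AssayConfig | None = None
) -> FeedingRateResults:
    """Clearance rates with stressor-bearing controls defining F(0).

    Identical pipeline to :func:`platefeed.assay.estimate_all`, except each
    plate's F(0) is the mean of its ``stressor_control`` wells; pure-algae
    controls, if present, are ignored.  A plate carrying samples but no
    stressor controls is a hard error.
    """
    return FeedingAssay(wells, config=config, control_role="stressor_control").fit()


def exposure_rate(f, Z):
    """Particles encountered per hour: E = f * Z."""
    f = np.asarray(f, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if (f < 0).any() or (Z < 0).any():
        raise EstimationError("exposure_rate needs f >= 0 and Z >= 0")
    out = f * Z
    return float(out) if out.ndim == 0 else out


def cumulative_dose(f, Z0, V, t, model: str = "depleting_Z"):
    """Total particles ingested over the assay under the chosen dose model."""
    if model not in DOSE_MODELS:
        raise EstimationError(f"unknown dose model {model!r}; use one of {DOSE_MODELS}")
    f = np.asarray(f, dtype=float)
    if (f < 0).any():
        raise EstimationError("cumulative_dose needs f >= 0")
    if not (V > 0 and t > 0):
        raise EstimationError("V and t must be > 0")
    if Z0 < 0:
        raise EstimationError("Z0 must be >= 0")
    if model == "constant_Z":
        out = f * Z0 * t
    else:
        out = Z0 * V * (1.0 - np.exp(-f * t / V))
    return float(out) if out.ndim == 0 else out


def exposure_table(
    results: FeedingRateResults,
    Z: float,
    model: str = "depleting_Z",
) -> pd.DataFrame:
    """Per-animal exposure rates and doses from retained clearance estimates.

    Negative or excluded estimates never reach this table; V and t are the
    assay config defaults (per-sample overrides are reflected through f
    only insofar as the estimate used them, so the dose uses the config's
    V and t unless the retained table carries its own).
    """
    cfg = results.model.config
    kept = results.retained
    rows = []
    for r in kept.itertuples(index=False):
        f = float(r.f_mL_per_hr)
        rows.append(
            ExposureEstimate(
                sample_id=r.sample_id,
                f_value=f,
                particle_concentration_Z=float(Z),
                exposure_rate=exposure_rate(f, Z),
                cumulative_dose=cumulative_dose(
                    f, Z, cfg.default_volume_mL, cfg.default_hours, model
                ),
                dose_model=model,
            ).__dict__
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "f_value", "particle_concentration_Z",
            "exposure_rate", "cumulative_dose", "dose_model",
        ],
    )
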