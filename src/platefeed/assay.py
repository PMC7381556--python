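"""Clearance-rate estimation from annotated well tables.

The measurement model: an individual filtering a tube of volume ``V``
(mL) at clearance rate ``f`` (mL hr^-1) depletes algal fluorescence
exponentially, ``F(t) = F(0) exp(-f t / V)``.  Each plate carries its own
consumer-free control wells whose mean stands in for ``F(0)``, so the
estimate for a sample on that plate is

    f = (V / t) * ln( F0_mean / Ft_mean )

with ``Ft_mean`` the mean over the sample's technical-replicate wells.
Because the estimate depends only on the within-plate fluorescence ratio,
any multiplicative plate or gain effect cancels — the point of the
matched-pairs plate design.

:class:`FeedingAssay` is the model object (data + configuration); its
:meth:`~FeedingAssay.fit` returns a :class:`FeedingRateResults` carrying
per-animal estimates, bootstrap intervals, QC flags and the exclusion log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError
from .plates import AssayConfig

ML_PER_HR = "mL_per_hr"
L_PER_DAY = "L_per_day"
_ML_HR_TO_L_DAY = 24.0 / 1000.0

#: QC flags that force exclusion (vs. ``high_tech_cv`` which only warns).
EXCLUDING_FLAGS = ("negative_rate", "died", "male")


@dataclass(frozen=True)
class ControlSummary:
    """Per-plate consumer-free control fluorescence: the plate's F(0)."""

    plate_id: str
    F0_mean: float
    F0_sd: float
    n_controls: int


@dataclass(frozen=True)
class SampleSummary:
    """Technical-replicate aggregate for one sample: the sample's F(t)."""

    sample_id: str
    plate_id: str
    Ft_mean: float
    tech_rep_cv: float
    n_reps: int


def summarize_controls(
    wells: pd.DataFrame, plate_id: str, control_role: str = "control"
) -> ControlSummary:
    """Mean/sd/n of control fluorescence on one plate (never pooled across plates)."""
    sub = wells[(wells["plate_id"] == plate_id) & (wells["role"] == control_role)]
    if len(sub) == 0:
        raise EstimationError(
            f"plate {plate_id} has no wells with role={control_role!r}; "
            "feeding rates on this plate cannot be computed"
        )
    if len(sub) == 1:
        warnings.warn(f"plate {plate_id}: single control well", stacklevel=2)
    vals = sub["fluorescence"].to_numpy(dtype=float)
    return ControlSummary(
        plate_id=plate_id,
        F0_mean=float(vals.mean()),
        F0_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        n_controls=len(vals),
    )


def aggregate_technical_replicates(
    wells: pd.DataFrame, sample_id: str, cv_warn: float = 0.15
) -> SampleSummary:
    """Mean fluorescence across a sample's wells, with the replicate CV."""
    sub = wells[(wells["role"] == "sample") & (wells["sample_id"] == sample_id)]
    if len(sub) == 0:
        raise EstimationError(f"no sample wells for sample_id {sample_id!r}")
    plates = sub["plate_id"].unique()
    if len(plates) > 1:
        raise EstimationError(
            f"sample {sample_id} spans plates {sorted(plates)}; "
            "control pairing is undefined across plates"
        )
    vals = sub["fluorescence"].to_numpy(dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    cv = sd / mean if mean > 0 else 0.0
    if len(vals) == 1:
        warnings.warn(f"sample {sample_id}: single technical replicate", stacklevel=2)
    return SampleSummary(
        sample_id=sample_id,
        plate_id=str(plates[0]),
        Ft_mean=mean,
        tech_rep_cv=float(cv),
        n_reps=len(vals),
    )


def compute_feeding_rate(F0_mean: float, Ft_mean: float, V: float, t: float) -> float:
    """Closed-form clearance rate f = (V/t) ln(F0/Ft), in mL hr^-1 ind^-1.

    Negative when the sample reads brighter than its plate controls; such
    values are flagged downstream, never clamped here.
    """
    if not (F0_mean > 0 and Ft_mean > 0):
        raise EstimationError(
            f"fluorescence means must be > 0, got F0={F0_mean!r}, Ft={Ft_mean!r}"
        )
    if not (V > 0 and t > 0):
        raise EstimationError(f"V and t must be > 0, got V={V!r}, t={t!r}")
    return (V / t) * float(np.log(F0_mean / Ft_mean))


def convert_units(f, target: str, source: str = ML_PER_HR):
    """Convert clearance rates between mL hr^-1 and L day^-1 (exact round trip)."""
    for u in (target, source):
        if u not in (ML_PER_HR, L_PER_DAY):
            raise EstimationError(f"unknown unit token {u!r}")
    f = np.asarray(f, dtype=float)
    if source == target:
        out = f
    elif source == ML_PER_HR:  # -> L/day
        out = f * _ML_HR_TO_L_DAY
    else:  # L/day -> mL/hr
        out = f / _ML_HR_TO_L_DAY
    return float(out) if out.ndim == 0 else out


def pooled_well_cv(wells: pd.DataFrame, plate_id: str, control_role: str = "control") -> float:
    """Pooled within-replicate-group CV of all wells on a plate.

    Groups are the plate's control wells plus each sample's technical
    replicates; groups of size 1 contribute no degrees of freedom.  This is
    the plate-level noise scale the parametric bootstrap resamples from.
    """
    sub = wells[wells["plate_id"] == plate_id]
    groups = []
    ctrl = sub.loc[sub["role"] == control_role, "fluorescence"].to_numpy(dtype=float)
    if len(ctrl):
        groups.append(ctrl)
    for _, g in sub[sub["role"] == "sample"].groupby("sample_id"):
        groups.append(g["fluorescence"].to_numpy(dtype=float))
    num, dof = 0.0, 0
    for g in groups:
        if len(g) < 2:
            continue
        m = g.mean()
        if m <= 0:
            continue
        num += float(((g - m) ** 2).sum()) / m**2
        dof += len(g) - 1
    if dof == 0:
        return 0.0
    return float(np.sqrt(num / dof))


def bootstrap_ci(
    control_values,
    replicate_values,
    V: float,
    t: float,
    B: int,
    rng: np.random.Generator,
    method: str = "plate_pooled",
    plate_cv: float | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for one sample's clearance rate.

    ``method="plate_pooled"`` (default) resamples the two means
    parametrically with multiplicative Gaussian noise at the plate's pooled
    well CV (``plate_cv``), scaled by 1/sqrt(n) for each mean.  With only
    two technical replicates per sample, nonparametric well resampling
    cannot estimate tails, so pooling the noise scale across the plate's
    replicate groups is what makes the interval usable.

    ``method="wells"`` is the naive scheme: resample control wells and
    technical-replicate wells independently with replacement.
    """
    if B < 1:
        raise EstimationError("bootstrap_ci needs B >= 1; use B=0 upstream to skip CIs")
    ctrl = np.asarray(control_values, dtype=float)
    reps = np.asarray(replicate_values, dtype=float)
    if len(ctrl) == 0 or len(reps) == 0:
        raise EstimationError("bootstrap_ci needs >= 1 control and >= 1 sample well")

    if method == "wells":
        f0 = ctrl[rng.integers(0, len(ctrl), size=(B, len(ctrl)))].mean(axis=1)
        ft = reps[rng.integers(0, len(reps), size=(B, len(reps)))].mean(axis=1)
    elif method == "plate_pooled":
        cv = pooled_well_cv_from_groups([ctrl, reps]) if plate_cv is None else plate_cv
        f0 = ctrl.mean() * (1.0 + cv / np.sqrt(len(ctrl)) * rng.standard_normal(B))
        ft = reps.mean() * (1.0 + cv / np.sqrt(len(reps)) * rng.standard_normal(B))
    else:
        raise EstimationError(f"unknown bootstrap method {method!r}")

    ok = (f0 > 0) & (ft > 0)
    if not ok.any():
        raise EstimationError("all bootstrap resamples degenerate (non-positive means)")
    fb = (V / t) * np.log(f0[ok] / ft[ok])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(fb, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def pooled_well_cv_from_groups(groups) -> float:
    """Pooled CV from explicit replicate groups (fallback when no plate context)."""
    num, dof = 0.0, 0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            continue
        m = g.mean()
        if m <= 0:
            continue
        num += float(((g - m) ** 2).sum()) / m**2
        dof += len(g) - 1
    return float(np.sqrt(num / dof)) if dof else 0.0


def apply_qc(estimates: pd.DataFrame, include_excluded: bool = False):
    """Partition estimates into retained rows and a reasoned exclusion log.

    Exclusion reasons (negative rate = technical error; deaths; males) are
    those of the assay protocol; ``high_tech_cv`` warns but never excludes.
    ``include_excluded=True`` is the explicit override that retains
    everything while still producing the log.
    """
    logs = []
    for row in estimates.itertuples(index=False):
        flags = set(str(row.qc_flags).split(",")) if row.qc_flags else set()
        for reason in sorted(flags & set(EXCLUDING_FLAGS)):
            logs.append({"sample_id": row.sample_id, "reason": reason})
    log = pd.DataFrame(logs, columns=["sample_id", "reason"])
    if include_excluded:
        return estimates.copy(), log
    return estimates[~estimates["excluded"]].reset_index(drop=True), log


class FeedingAssay:
    """Model object: one annotated well table plus assay configuration.

    Parameters
    ----------
    wells
        Annotated well table from :func:`platefeed.plates.join_layout`.
    config
        :class:`~platefeed.plates.AssayConfig`; defaults follow the
        original protocol (10 mL, 7 h, two technical replicates expected).
    control_role
        Which wells define each plate's F(0): ``"control"`` for plain
        consumer-free tubes, ``"stressor_control"`` when a fluorescent
        stressor is present (see :mod:`platefeed.exposure`).
    """

    def __init__(
        self,
        wells: pd.DataFrame,
        config: AssayConfig | None = None,
        control_role: str = "control",
    ):
        self.wells = wells.reset_index(drop=True)
        self.config = config or AssayConfig()
        self.control_role = control_role

    @classmethod
    def from_csv(cls, reads_path, layout_path, meta_path, config=None, **kw):
        """Build directly from the three interchange CSVs (long-format reads)."""
        from . import plates

        wells = plates.parse_long_table(reads_path)
        layout = plates.read_layout(layout_path)
        meta = plates.read_metadata(meta_path)
        annotated = plates.join_layout(wells, layout, meta, config=config)
        return cls(annotated, config=config, **kw)

    def _blank_corrected(self) -> pd.DataFrame:
        wells = self.wells.copy()
        if not self.config.blank_subtract:
            return wells
        for pid, sub in wells.groupby("plate_id"):
            blanks = sub.loc[sub["role"] == "blank", "fluorescence"]
            if len(blanks):
                mask = wells["plate_id"] == pid
                wells.loc[mask, "fluorescence"] = (
                    wells.loc[mask, "fluorescence"] - blanks.mean()
                )
        return wells

    def fit(self) -> "FeedingRateResults":
        """Estimate one clearance rate per sample, with QC and bootstrap CIs."""
        cfg = self.config
        wells = self._blank_corrected()
        rng = np.random.default_rng(cfg.rng_seed)

        sample_wells = wells[wells["role"] == "sample"]
        cols = [
            "sample_id", "genotype", "block", "plate_id",
            "f_mL_per_hr", "ci_low_mL_per_hr", "ci_high_mL_per_hr",
            "tech_rep_cv", "n_reps", "qc_flags", "excluded",
        ]
        if len(sample_wells) == 0:
            est = pd.DataFrame(
                {c: pd.Series(dtype="float" if "f" in c or "ci" in c else "object")
                 for c in cols + ["f", "ci_low", "ci_high", "units"]}
            ).astype({"excluded": bool})
            return FeedingRateResults(self, est, {})

        # Plates that carry samples must carry controls; summarize each once.
        controls: dict[str, ControlSummary] = {}
        plate_cvs: dict[str, float] = {}
        for pid in sorted(sample_wells["plate_id"].unique()):
            controls[pid] = summarize_controls(wells, pid, self.control_role)
            plate_cvs[pid] = pooled_well_cv(wells, pid, self.control_role)

        split = sample_wells.groupby("sample_id")["plate_id"].nunique()
        if (split > 1).any():
            bad = sorted(split[split > 1].index)
            raise EstimationError(
                f"sample(s) {bad} span multiple plates; control pairing is undefined"
            )

        g = sample_wells.groupby("sample_id", sort=True)
        agg = g.agg(
            Ft_mean=("fluorescence", "mean"),
            Ft_sd=("fluorescence", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n_reps=("fluorescence", "size"),
            plate_id=("plate_id", "first"),
            genotype=("genotype", "first"),
            block=("block", "first"),
            status=("status", "first"),
            volume_mL=("volume_mL", "first"),
            hours=("hours", "first"),
        ).reset_index()
        if (agg["n_reps"] == 1).any():
            singles = agg.loc[agg["n_reps"] == 1, "sample_id"].tolist()
            warnings.warn(f"single technical replicate for sample(s) {singles}", stacklevel=2)

        F0 = agg["plate_id"].map({p: c.F0_mean for p, c in controls.items()}).to_numpy(float)
        Ft = agg["Ft_mean"].to_numpy(float)
        V = agg["volume_mL"].to_numpy(float)
        t = agg["hours"].to_numpy(float)
        if (Ft <= 0).any() or (F0 <= 0).any():
            bad = agg.loc[(Ft <= 0) | (F0 <= 0), "sample_id"].tolist()
            raise EstimationError(f"non-positive fluorescence mean for sample(s) {bad}")
        if (V <= 0).any() or (t <= 0).any():
            raise EstimationError("V and t must be > 0 for every sample")
        f_ml_hr = (V / t) * np.log(F0 / Ft)
        cv = np.where(Ft > 0, agg["Ft_sd"].to_numpy(float) / Ft, 0.0)

        status = agg["status"].fillna("ok").astype(str)
        died = status.str.contains(r"\bdied\b").to_numpy()
        male = status.str.contains(r"\bmale\b").to_numpy()
        flags_list = []
        for i in range(len(agg)):
            flags = set()
            if f_ml_hr[i] < 0:
                flags.add("negative_rate")
            if died[i]:
                flags.add("died")
            if male[i]:
                flags.add("male")
            if cv[i] > cfg.tech_rep_cv_warn:
                flags.add("high_tech_cv")
            flags_list.append(flags)

        ci_lo = np.full(len(agg), np.nan)
        ci_hi = np.full(len(agg), np.nan)
        if cfg.bootstrap_B > 0:
            ctrl_vals = {
                p: wells.loc[
                    (wells["plate_id"] == p) & (wells["role"] == self.control_role),
                    "fluorescence",
                ].to_numpy(float)
                for p in controls
            }
            rep_groups = {sid: grp["fluorescence"].to_numpy(float) for sid, grp in g}
            for i, row in enumerate(agg.itertuples(index=False)):
                ci_lo[i], ci_hi[i] = bootstrap_ci(
                    ctrl_vals[row.plate_id],
                    rep_groups[row.sample_id],
                    float(row.volume_mL),
                    float(row.hours),
                    cfg.bootstrap_B,
                    rng,
                    method=cfg.bootstrap_method,
                    plate_cv=plate_cvs[row.plate_id],
                )

        est = pd.DataFrame(
            {
                "sample_id": agg["sample_id"],
                "genotype": agg["genotype"],
                "block": agg["block"],
                "plate_id": agg["plate_id"],
                "f_mL_per_hr": f_ml_hr,
                "ci_low_mL_per_hr": ci_lo,
                "ci_high_mL_per_hr": ci_hi,
                "tech_rep_cv": cv,
                "n_reps": agg["n_reps"],
                "qc_flags": [",".join(sorted(fl)) for fl in flags_list],
                "excluded": [bool(fl & set(EXCLUDING_FLAGS)) for fl in flags_list],
            },
            columns=cols,
        )

        # report in the configured output units
        est["f"] = convert_units(est["f_mL_per_hr"].to_numpy(), cfg.output_units)
        est["ci_low"] = convert_units(est["ci_low_mL_per_hr"].to_numpy(), cfg.output_units)
        est["ci_high"] = convert_units(est["ci_high_mL_per_hr"].to_numpy(), cfg.output_units)
        est["units"] = cfg.output_units
        return FeedingRateResults(self, est, controls)


class FeedingRateResults:
    """Per-animal clearance-rate estimates with QC and uncertainty.

    Attributes
    ----------
    estimates
        One row per sample (all samples, including excluded ones); ``f``,
        ``ci_low``, ``ci_high`` are in ``units``.
    exclusion_log
        One row per (sample, reason) for every excluding QC flag.
    control_summaries
        Mapping plate_id -> :class:`ControlSummary`.
    """

    def __init__(self, model: FeedingAssay, estimates: pd.DataFrame, controls):
        self.model = model
        self.estimates = estimates
        self.control_summaries = controls
        self.retained, self.exclusion_log = apply_qc(estimates)

    @property
    def units(self) -> str:
        return self.model.config.output_units

    def summary(self) -> str:
        est = self.estimates
        lines = [
            "Feeding-rate assay results",
            "=" * 58,
            f"samples: {len(est)}   retained: {len(self.retained)}   "
            f"excluded: {int(est['excluded'].sum())}",
            f"plates: {len(self.control_summaries)}   units: {self.units}",
            "",
            "Per-genotype clearance rate (retained samples):",
        ]
        if len(self.retained):
            g = self.retained.groupby("genotype")["f"]
            tab = pd.DataFrame(
                {"n": g.size(), "mean": g.mean(), "se": g.sem(), "sd": g.std()}
            )
            lines.append(tab.to_string(float_format=lambda v: f"{v:.4f}"))
        else:
            lines.append("  (none retained)")
        if len(self.exclusion_log):
            counts = self.exclusion_log["reason"].value_counts()
            lines += ["", "Exclusions: " + ", ".join(f"{k}={v}" for k, v in counts.items())]
        return "\n".join(lines)

    def to_csv(self, estimates_path, exclusions_path=None) -> None:
        cols = [
            "sample_id", "genotype", "block", "plate_id", "f", "units",
            "ci_low", "ci_high", "qc_flags", "excluded",
        ]
        self.estimates[cols].to_csv(estimates_path, index=False)
        if exclusions_path is not None:
            self.exclusion_log.to_csv(exclusions_path, index=False)

    def plot(self, ax=None):
        """Genotype means ± SE of retained estimates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        g = self.retained.groupby("genotype")["f"]
        means, sems = g.mean(), g.sem()
        ax.errorbar(range(len(means)), means.values, yerr=sems.values, fmt="o", capsize=3)
        ax.set_xticks(range(len(means)))
        ax.set_xticklabels(means.index, rotation=45, ha="right")
        ax.set_ylabel(f"clearance rate ({self.units})")
        ax.set_xlabel("genotype")
        return ax


def estimate_all(
    wells: pd.DataFrame,
    config: AssayConfig | None = None,
    control_role: str = "control",
) -> FeedingRateResults:
    """Functional entry point: fit a :class:`FeedingAssay` in one call."""
    return FeedingAssay(wells, config=config, control_role=control_role).fit()
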