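"""Blocked genotype comparisons of clearance rates.

The inference layer mirrors the assay's matched-pairs design: clearance
rates are modelled as ``f ~ genotype + block + genotype:block`` by OLS with
sum-to-zero contrasts, and each term is tested with Type III (marginal)
sums of squares, which stay valid under the unbalanced group sizes QC
leaves behind.  Residual normality is checked with Shapiro-Wilk.  When the
interaction is negligible the model is refitted with main effects only and
all-pairs genotype differences are compared with Tukey-Kramer simultaneous
intervals built from the studentized range on estimated marginal means
(genotype means averaged over blocks).

:class:`GenotypeAnova` is the model object; :meth:`GenotypeAnova.fit`
returns :class:`GenotypeAnovaResults`.
"""

from __future__ import annotations

import functools
import itertools

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.anova import anova_lm

from .errors import ModelSpecError

_TERM_NAMES = {
    "C(genotype, Sum)": "genotype",
    "C(block, Sum)": "block",
    "C(genotype, Sum):C(block, Sum)": "genotype:block",
}


class GenotypeAnova:
    """Blocked ANOVA model for per-animal clearance rates.

    Parameters
    ----------
    estimates
        DataFrame with columns ``f``, ``genotype``, ``block`` — normally
        the retained table of a
        :class:`~platefeed.assay.FeedingRateResults`.
    include_interaction
        Fit ``genotype:block`` (default); automatically dropped when the
        data hold a single block, where it is inestimable.
    """

    def __init__(self, estimates: pd.DataFrame, include_interaction: bool = True):
        df = estimates.copy()
        missing = {"f", "genotype", "block"} - set(df.columns)
        if missing:
            raise ModelSpecError(f"estimates lack column(s) {sorted(missing)}")
        df = df.dropna(subset=["f", "genotype", "block"]).reset_index(drop=True)
        counts = df.groupby("genotype")["f"].size()
        if len(counts) < 2:
            raise ModelSpecError("need >= 2 genotypes with retained observations")
        self.data = df
        self.n_blocks = df["block"].nunique()
        self.include_interaction = include_interaction and self.n_blocks > 1
        self.single_block = self.n_blocks == 1

    @classmethod
    def from_results(cls, results, **kw) -> "GenotypeAnova":
        """Build from assay results, erroring on genotypes wiped out by QC."""
        all_g = set(results.estimates["genotype"].dropna())
        kept_g = set(results.retained["genotype"].dropna())
        gone = sorted(all_g - kept_g)
        if gone:
            raise ModelSpecError(
                f"genotype(s) with zero retained observations: {gone}"
            )
        return cls(results.retained, **kw)

    def _formula(self, interaction: bool) -> str:
        if self.single_block:
            return "f ~ C(genotype, Sum)"
        if interaction:
            return "f ~ C(genotype, Sum) * C(block, Sum)"
        return "f ~ C(genotype, Sum) + C(block, Sum)"

    def fit(self, interaction: bool | None = None) -> "GenotypeAnovaResults":
        """OLS fit with sum-to-zero contrasts and Type III marginal tests."""
        use_inter = self.include_interaction if interaction is None else interaction
        use_inter = use_inter and not self.single_block
        formula = self._formula(use_inter)
        ols = smf.ols(formula, data=self.data)
        if np.linalg.matrix_rank(ols.exog) < ols.exog.shape[1]:
            raise ModelSpecError(f"singular design for {formula!r}")
        fit = ols.fit()
        return GenotypeAnovaResults(self, fit, has_interaction=use_inter)


class GenotypeAnovaResults:
    """Fitted blocked ANOVA: effect tests, residuals, post hoc machinery."""

    def __init__(self, model: GenotypeAnova, fit, has_interaction: bool):
        self.model = model
        self.fit = fit
        self.has_interaction = has_interaction
        self.residuals = np.asarray(fit.resid, dtype=float)
        self.effects = self._type3_effects()
        self.notes: list[str] = []
        if model.single_block:
            self.notes.append("single block: block and interaction terms inestimable")

    def _type3_effects(self) -> pd.DataFrame:
        tab = anova_lm(self.fit, typ=3)
        rows = []
        for raw, name in _TERM_NAMES.items():
            if raw not in tab.index:
                continue
            F = float(tab.loc[raw, "F"])
            df_num = int(tab.loc[raw, "df"])
            df_den = int(tab.loc["Residual", "df"])
            p_F = float(tab.loc[raw, "PR(>F)"])
            chi2 = F * df_num  # Wald statistic on the same contrast
            rows.append(
                {
                    "term": name,
                    "F": F,
                    "df_num": df_num,
                    "df_den": df_den,
                    "p_F": p_F,
                    "chi_square": chi2,
                    "p_chi_square": float(sps.chi2.sf(chi2, df_num)),
                    "sum_sq": float(tab.loc[raw, "sum_sq"]),
                }
            )
        return pd.DataFrame(rows)

    def effect(self, term: str) -> pd.Series:
        sub = self.effects[self.effects["term"] == term]
        if sub.empty:
            raise ModelSpecError(f"term {term!r} not in fitted model")
        return sub.iloc[0]

    # ---- diagnostics ----------------------------------------------------

    def test_normality(self) -> tuple[float, float]:
        """Shapiro-Wilk W and p for the residuals."""
        return test_normality(self.residuals)

    # ---- interaction handling -------------------------------------------

    def drop_interaction(self, threshold: float = 0.05, force: bool = False):
        """Refit with main effects only when the interaction is negligible.

        Refuses (without ``force``) when the interaction p-value is below
        ``threshold`` — averaging over blocks would then misrepresent the
        genotype effects.  Single-block fits are returned as-is with a note.
        """
        if self.model.single_block or not self.has_interaction:
            out = self.model.fit(interaction=False)
            out.notes.append("interaction inestimable or absent; main-effects fit")
            return out
        p_int = float(self.effect("genotype:block")["p_F"])
        if p_int < threshold and not force:
            raise ModelSpecError(
                f"interaction p = {p_int:.4g} < {threshold}; refusing to average "
                "over blocks (pass force=True to override)"
            )
        out = self.model.fit(interaction=False)
        out.notes.append(
            f"interaction dropped (p = {p_int:.4g} >= {threshold}); "
            "genotype effects averaged across blocks"
        )
        return out

    # ---- post hoc --------------------------------------------------------

    def genotype_emmeans(self) -> pd.DataFrame:
        """Estimated marginal genotype means (averaged over blocks) and their covariance."""
        if self.has_interaction:
            raise ModelSpecError(
                "post hoc comparisons require the main-effects fit; "
                "call drop_interaction() first"
            )
        info = self.fit.model.data.design_info
        genotypes = sorted(self.model.data["genotype"].unique())
        blocks = sorted(self.model.data["block"].unique())
        L = []
        for g in genotypes:
            grid = pd.DataFrame(
                {"genotype": [g] * len(blocks), "block": blocks}
            )
            (X,) = build_design_matrices([info], grid)
            L.append(np.asarray(X).mean(axis=0))
        L = np.vstack(L)
        means = L @ np.asarray(self.fit.params)
        cov = L @ np.asarray(self.fit.cov_params()) @ L.T
        out = pd.DataFrame({"genotype": genotypes, "emmean": means, "se": np.sqrt(np.diag(cov))})
        out.attrs["cov"] = cov
        return out

    def tukey(self, level: float = 0.95, adjusted_p: bool = True) -> pd.DataFrame:
        """All-pairs Tukey-Kramer comparisons of genotype marginal means."""
        return tukey_genotype(self, level=level, adjusted_p=adjusted_p)

    def compact_letters(self, alpha: float = 0.05) -> pd.Series:
        """Compact letter display derived from the Tukey adjusted p-values."""
        return compact_letter_display(self.tukey(), alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Blocked clearance-rate ANOVA (Type III, sum-to-zero contrasts)",
            "=" * 64,
            self.effects.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        try:
            W, p = self.test_normality()
            lines.append(f"\nShapiro-Wilk residual normality: W = {W:.4f}, p = {p:.4g}")
        except ModelSpecError as exc:
            lines.append(f"\nShapiro-Wilk: {exc}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def fit_blocked_anova(estimates: pd.DataFrame, include_interaction: bool = True):
    """Functional wrapper: fit the blocked genotype ANOVA in one call."""
    return GenotypeAnova(estimates, include_interaction=include_interaction).fit()


def test_normality(residuals) -> tuple[float, float]:
    """Shapiro-Wilk test of residual normality; errors on n < 3 or constant input."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 3:
        raise ModelSpecError(f"Shapiro-Wilk needs n >= 3, got n = {len(r)}")
    if np.ptp(r) == 0:
        raise ModelSpecError("residuals are constant; W undefined")
    W, p = sps.shapiro(r)
    return float(W), float(p)


def drop_interaction_and_refit(
    results: GenotypeAnovaResults, threshold: float = 0.05, force: bool = False
) -> GenotypeAnovaResults:
    """Functional wrapper around :meth:`GenotypeAnovaResults.drop_interaction`."""
    return results.drop_interaction(threshold=threshold, force=force)


@functools.lru_cache(maxsize=64)
def _q_crit(level: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(level, k, df))


def tukey_genotype(
    results: GenotypeAnovaResults, level: float = 0.95, adjusted_p: bool = True
) -> pd.DataFrame:
    """Tukey-Kramer all-pairs genotype comparisons with simultaneous CIs.

    Works on the main-effects fit: pairwise differences of genotype
    marginal means, standard errors from the fit's coefficient covariance
    (robust to unequal group sizes), critical values from the studentized
    range with the residual degrees of freedom.  Returns one row per
    unordered pair with the difference, simultaneous interval, adjusted
    p-value and the unadjusted t-test p-value for reference.

    ``adjusted_p=False`` skips the (relatively expensive) studentized-range
    p-values and returns NaN in those columns; the intervals are unchanged.
    """
    emm = results.genotype_emmeans()
    k = len(emm)
    if k < 2:
        raise ModelSpecError("post hoc comparisons need >= 2 genotypes")
    cov = emm.attrs["cov"]
    df_resid = int(results.fit.df_resid)
    q_crit = _q_crit(level, k, df_resid)

    pairs = list(itertools.combinations(range(k), 2))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    means = emm["emmean"].to_numpy(float)
    diff = means[ii] - means[jj]
    se = np.sqrt(np.maximum(cov[ii, ii] + cov[jj, jj] - 2 * cov[ii, jj], 0.0))
    margin = q_crit / np.sqrt(2.0) * se
    if adjusted_p:
        with np.errstate(divide="ignore", invalid="ignore"):
            # zero-variance contrasts: p = 1 for a zero difference, 0 otherwise
            q_obs = np.where(
                se > 0, np.sqrt(2.0) * np.abs(diff) / np.where(se > 0, se, 1.0),
                np.where(diff == 0, 0.0, np.inf),
            )
        adj_p = np.minimum(sps.studentized_range.sf(q_obs, k, df_resid), 1.0)
        adj_p = np.where(np.isfinite(q_obs), adj_p, 0.0)
        adj_p = np.where((se == 0) & (diff == 0), 1.0, adj_p)
        t_obs = np.where(se > 0, np.abs(diff) / np.where(se > 0, se, 1.0),
                         np.where(diff == 0, 0.0, np.inf))
        p_unadj = np.minimum(2 * sps.t.sf(t_obs, df_resid), 1.0)
        p_unadj = np.where((se == 0) & (diff == 0), 1.0, p_unadj)
    else:
        adj_p = np.full(len(pairs), np.nan)
        p_unadj = np.full(len(pairs), np.nan)
    return pd.DataFrame(
        {
            "genotype_a": emm["genotype"].to_numpy()[ii],
            "genotype_b": emm["genotype"].to_numpy()[jj],
            "difference": diff,
            "se": se,
            "ci_low": diff - margin,
            "ci_high": diff + margin,
            "adj_p": adj_p,
            "p_unadj": p_unadj,
        }
    )


def compact_letter_display(pairwise: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Assign letters so groups sharing a letter are not significantly different.

    Insert-and-absorb algorithm on the adjusted p-values; genotypes mapped
    to letter strings (e.g. ``"a"``, ``"ab"``).
    """
    genotypes = sorted(set(pairwise["genotype_a"]) | set(pairwise["genotype_b"]))
    sig = {
        frozenset((r.genotype_a, r.genotype_b))
        for r in pairwise.itertuples(index=False)
        if r.adj_p < alpha
    }
    # start from one group holding everything, split on significant pairs
    groups: list[set] = [set(genotypes)]
    for pair in sig:
        a, b = tuple(pair)
        new_groups = []
        for grp in groups:
            if a in grp and b in grp:
                new_groups.append(grp - {a})
                new_groups.append(grp - {b})
            else:
                new_groups.append(grp)
        # absorb subsets
        groups = []
        for grp in sorted(new_groups, key=len, reverse=True):
            if not any(grp <= other for other in groups):
                groups.append(grp)
    groups.sort(key=lambda grp: sorted(grp)[0])
    letters = {g: "" for g in genotypes}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for g in grp:
            letters[g] += letter
    return pd.Series(letters, name="letters")
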