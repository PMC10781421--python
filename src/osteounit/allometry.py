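"""Allometric power-law scaling and group-comparison statistics.

Allometry relates a trait y to body mass M through y = b * M**a.  Fits are
done as ordinary least squares of log10(y) on log10(M) — the standard in the
scaling literature — so the exponent a is the slope and the prefactor b is
10**intercept.  Group comparisons use one-way ANOVA with either
Bonferroni-corrected pairwise t-tests or Tukey's HSD, with Shapiro-Wilk and
Levene assumption checks reported alongside.

    model = AllometryModel.from_dataframe(df, "body_mass_kg", "thickness_mm")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class AllometryResults:
    """Fitted power law y = b * M**a with log-log regression diagnostics."""

    a: float                      # scaling exponent (log-log slope)
    b: float                      # prefactor: response at M = 1 kg
    r_squared: float
    n: int
    ci_a: tuple[float, float]     # 95 % CI on the exponent
    se_a: float
    group_label: str | None = None
    _sm_results: object | None = field(default=None, repr=False)

    def predict(self, mass_kg) -> np.ndarray:
        return self.b * np.asarray(mass_kg, dtype=float) ** self.a

    def summary(self) -> str:
        label = f" [{self.group_label}]" if self.group_label else ""
        lines = [
            f"Allometric power fit{label}: y = b * M^a",
            "=" * 46,
            f"{'n':<26}{self.n:>20d}",
            f"{'exponent a':<26}{self.a:>20.4f}",
            f"{'95% CI on a':<26}"
            f"{f'({self.ci_a[0]:.4f}, {self.ci_a[1]:.4f})':>20}",
            f"{'prefactor b (y at 1 kg)':<26}{self.b:>20.4g}",
            f"{'R-squared (log-log)':<26}{self.r_squared:>20.4f}",
        ]
        if self.ci_a[1] - self.ci_a[0] > 0.5:
            lines.append("note: wide exponent CI — weak mass leverage or noise")
        return "\n".join(lines)

    @property
    def wide_ci(self) -> bool:
        return self.ci_a[1] - self.ci_a[0] > 0.5


class AllometryModel:
    """Log-log OLS model of a positive trait against body mass."""

    def __init__(self, mass_kg, response, group_label: str | None = None):
        mass = np.asarray(mass_kg, dtype=float)
        resp = np.asarray(response, dtype=float)
        if mass.shape != resp.shape or mass.ndim != 1:
            raise ValueError("mass and response must be 1-D of equal length")
        if mass.size < 3:
            raise ValueError("need at least 3 observations (fit underdetermined)")
        if np.any(mass <= 0) or np.any(resp <= 0):
            raise ValueError("mass and response must be strictly positive")
        self.mass = mass
        self.response = resp
        self.group_label = group_label

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mass_col: str, response_col: str,
                       group_col: str | None = None, group: str | None = None):
        if group_col is not None and group is not None:
            df = df[df[group_col] == group]
        return cls(df[mass_col].to_numpy(), df[response_col].to_numpy(),
                   group_label=group)

    def fit(self) -> AllometryResults:
        x = sm.add_constant(np.log10(self.mass))
        res = sm.OLS(np.log10(self.response), x).fit()
        ci = res.conf_int(alpha=0.05)
        return AllometryResults(
            a=float(res.params[1]),
            b=float(10.0 ** res.params[0]),
            r_squared=float(res.rsquared),
            n=int(res.nobs),
            ci_a=(float(ci[1, 0]), float(ci[1, 1])),
            se_a=float(res.bse[1]),
            group_label=self.group_label,
            _sm_results=res,
        )


def power_fit(df: pd.DataFrame, mass_col: str = "body_mass_kg",
              response_col: str = "response", group_col: str | None = None,
              group: str | None = None) -> AllometryResults:
    """Functional wrapper: fit y = b * M**a on (a subset of) a table."""
    return AllometryModel.from_dataframe(
        df, mass_col, response_col, group_col=group_col, group=group
    ).fit()


@dataclass
class GroupComparison:
    """One-way ANOVA with post-hoc pairwise tests and assumption checks."""

    design: str                       # "bonferroni_t" or "tukey"
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame            # group1, group2, stat, p_raw, p_adj
    shapiro: dict[str, float]         # per-group Shapiro-Wilk p
    levene_p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.anova_p < self.alpha

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA ({self.design}): F = {self.anova_F:.4g}, "
            f"p = {self.anova_p:.4g}",
            f"Levene homogeneity p = {self.levene_p:.3g}; "
            "Shapiro-Wilk normality p: "
            + ", ".join(f"{g}={p:.3g}" for g, p in self.shapiro.items()),
            self.pairwise.to_string(index=False),
        ]
        return "\n".join(lines)


def group_compare(values, labels, design: str = "bonferroni_t") -> GroupComparison:
    """Compare ≥2 groups: ANOVA plus the chosen post-hoc family.

    ``design="bonferroni_t"`` runs all pairwise Welch-free t-tests with
    Bonferroni-adjusted p = min(1, m * p); ``design="tukey"`` uses Tukey's
    HSD.  Shapiro-Wilk (per group) and Levene (across groups) are always
    reported; a zero-variance group triggers an exact-tie warning rather than
    an error.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels)
    if vals.shape != labs.shape:
        raise ValueError("values and labels must align")
    groups = {g: vals[labs == g] for g in pd.unique(labs)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        if np.ptp(v) == 0:
            warnings.warn(f"group {g!r} has zero variance (exact ties)",
                          stacklevel=2)

    arrays = list(groups.values())
    names = list(groups.keys())
    if np.ptp(np.concatenate(arrays)) == 0:
        F, p_anova = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p_anova = stats.f_oneway(*arrays)
        if not np.isfinite(F):
            F, p_anova = 0.0, 1.0

    shapiro = {}
    for g, v in groups.items():
        if np.ptp(v) == 0 or v.size < 3:
            shapiro[g] = float("nan")
        else:
            shapiro[g] = float(stats.shapiro(v).pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        levene_p = float(stats.levene(*arrays).pvalue)
        if not np.isfinite(levene_p):
            levene_p = 1.0

    rows = []
    if design == "bonferroni_t":
        pairs = list(itertools.combinations(names, 2))
        m = len(pairs)
        for g1, g2 in pairs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = stats.ttest_ind(groups[g1], groups[g2])
            if not np.isfinite(p):
                t, p = 0.0, 1.0
            rows.append((g1, g2, float(t), float(p), float(min(1.0, m * p))))
    elif design == "tukey":
        res = pairwise_tukeyhsd(vals, labs, alpha=0.05)
        for (g1, g2), diff, p_adj in zip(
                itertools.combinations(res.groupsunique, 2),
                res.meandiffs, res.pvalues):
            p_adj = float(p_adj) if np.isfinite(p_adj) else 1.0
            rows.append((g1, g2, float(diff), p_adj, p_adj))
    else:
        raise ValueError(f"unknown design {design!r}")

    pairwise = pd.DataFrame(rows,
                            columns=["group1", "group2", "stat", "p_raw", "p_adj"])
    return GroupComparison(design=design, anova_F=float(F), anova_p=float(p_anova),
                           pairwise=pairwise, shapiro=shapiro, levene_p=levene_p)


def scaling_report(species_table: pd.DataFrame,
                   measurements: pd.DataFrame | None = None,
                   mass_col: str = "body_mass_kg",
                   group_col: str = "habitat") -> dict:
    """Per-habitat power fits for each measurement column.

    ``measurements`` (optional) must carry a ``species`` column joinable to
    the species table plus numeric measurement columns; when omitted, the
    table's own ``thickness_mm`` column is analysed.  Species that fail to
    join are listed under ``"unjoined"``, never silently dropped.
    """
    unjoined: list[str] = []
    if measurements is None:
        data = species_table.copy()
        value_cols = ["thickness_mm"]
    else:
        known = set(species_table["species"])
        unjoined = sorted(set(measurements["species"]) - known)
        data = measurements.merge(
            species_table[["species", mass_col, group_col]], on="species",
            how="inner")
        value_cols = [c for c in measurements.columns
                      if c != "species" and np.issubdtype(
                          measurements[c].dtype, np.number)]

    report: dict = {"fits": {}, "unjoined": unjoined}
    for col in value_cols:
        report["fits"][col] = {}
        for grp in pd.unique(data[group_col]):
            sub = data[(data[group_col] == grp) & data[col].notna()]
            entry: dict = {"n": int(len(sub))}
            if len(sub) >= 3 and (sub[col] > 0).all() and sub[col].nunique() > 1:
                fit = AllometryModel(sub[mass_col], sub[col],
                                     group_label=str(grp)).fit()
                entry.update(a=round(fit.a, 2), b=fit.b,
                             r_squared=round(fit.r_squared, 2),
                             slope_sign="positive" if fit.a > 0 else
                             ("negative" if fit.a < 0 else "zero"),
                             ci_a=fit.ci_a, wide_ci=fit.wide_ci)
            else:
                entry.update(error="fit refused: need at least 3 positive, "
                                   "non-constant values")
            report["fits"][col][str(grp)] = entry
    return report


def scaling_report_markdown(report: dict) -> str:
    lines = ["# Allometric scaling report", ""]
    for col, groups in report["fits"].items():
        lines.append(f"## {col}")
        for grp, entry in groups.items():
            if "error" in entry:
                lines.append(f"- {grp}: {entry['error']} (n={entry['n']})")
            else:
                lines.append(
                    f"- {grp}: a = {entry['a']:.2f}, R² = "
                    f"{entry['r_squared']:.2f}, n = {entry['n']} "
                    f"({entry['slope_sign']} slope)")
        lines.append("")
    if report["unjoined"]:
        lines.append("Unjoined species: " + ", ".join(report["unjoined"]))
    return "\n".join(lines)
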