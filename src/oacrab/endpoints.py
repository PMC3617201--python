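"""Terminal endpoints: condition index, calcification, per-molt size tests.

The condition index is dry mass (g) divided by the cube of a linear size
measure (mm): carapace length for red king crab, carapace width for Tanner
crab. Endpoints are compared across treatments with a Levene-gated test: a
one-way ANOVA (plus Fisher LSD when the omnibus is significant) when
variances are homogeneous, otherwise a Kruskal-Wallis test with pairwise
rank-sum post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import fisher_lsd, kruskal_wallis, levene, one_way_anova

__all__ = ["condition_index", "endpoint_comparison", "EndpointReport"]


def condition_index(dry_mass_g, length_mm):
    """Condition (body-mass) index: dry mass / length^3, in g mm^-3."""
    dry_mass_g = np.asarray(dry_mass_g, dtype=float)
    length_mm = np.asarray(length_mm, dtype=float)
    if (dry_mass_g <= 0).any() or (length_mm <= 0).any():
        raise ValueError("dry mass and length must be positive")
    out = dry_mass_g / length_mm**3
    return float(out) if out.ndim == 0 else out


@dataclass
class EndpointReport:
    variable: str
    test_used: str  # "anova" | "kruskal_wallis"
    statistic: float
    p: float
    levene_W: float
    levene_p: float
    group_means: pd.Series
    percent_differences: pd.DataFrame
    posthoc: pd.DataFrame | None

    def to_frame(self) -> pd.DataFrame:
        row = {
            "variable": self.variable,
            "test": self.test_used,
            "statistic": self.statistic,
            "p": self.p,
            "levene_W": self.levene_W,
            "levene_p": self.levene_p,
        }
        for g, m in self.group_means.items():
            row[f"mean[{g}]"] = m
        return pd.DataFrame([row])


def _pairwise_ranksum(sample, alpha: float) -> pd.DataFrame:
    values, groups = sample
    parts = {g: values[groups == g] for g in np.unique(groups)}
    rows = []
    for (ga, va), (gb, vb) in combinations(parts.items(), 2):
        stat, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append(
            {"group_a": ga, "group_b": gb, "U": float(stat), "p": float(p),
             "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def endpoint_comparison(
    table: pd.DataFrame,
    variable: str,
    *,
    group_col: str = "treatment",
    alpha: float = 0.05,
    levene_alpha: float = 0.05,
) -> EndpointReport:
    """Levene-gated treatment comparison of one endpoint variable.

    Percent differences between treatments are reported as
    100 (mean_A / mean_B - 1) of the group arithmetic means for every
    ordered pair, alongside the omnibus test. Post-hoc comparisons (Fisher
    LSD under ANOVA, pairwise rank-sum under Kruskal-Wallis) are included
    only when the omnibus test is significant at ``alpha``.
    """
    df = table.dropna(subset=[variable, group_col])
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 treatments")
    values = df[variable].to_numpy(dtype=float)
    groups = df[group_col].to_numpy()
    sample = (values, groups)
    lev = levene(sample)
    if lev["p"] < levene_alpha:
        kw = kruskal_wallis(sample)
        test_used, stat, p = "kruskal_wallis", kw["H"], kw["p"]
    else:
        an = one_way_anova(sample)
        test_used, stat, p = "anova", an["F"], an["p"]
    means = df.groupby(group_col)[variable].mean()
    rows = []
    for ga, gb in combinations(means.index, 2):
        if means[gb] != 0:
            rows.append(
                {"group_a": ga, "group_b": gb,
                 "percent_difference": 100.0 * (means[ga] / means[gb] - 1.0)}
            )
    posthoc = None
    if p < alpha:
        if test_used == "anova":
            posthoc = fisher_lsd(sample, {"p": p}, alpha=alpha)
        else:
            posthoc = _pairwise_ranksum(sample, alpha)
    return EndpointReport(
        variable=variable,
        test_used=test_used,
        statistic=float(stat),
        p=float(p),
        levene_W=lev["W"],
        levene_p=lev["p"],
        group_means=means,
        percent_differences=pd.DataFrame(rows),
        posthoc=posthoc,
    )
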