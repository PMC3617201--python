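"""Shared statistical primitives.

Small-sample-corrected AIC (AICc) with Akaike-weight model ranking, and the
classical univariate tests used throughout the pipeline: one-way ANOVA,
Levene's test for homogeneity of variance, the Kruskal-Wallis rank test, and
Fisher's least-significant-difference (LSD) post-hoc comparisons.

The omnibus tests delegate to :mod:`scipy.stats`; AICc, model ranking and
Fisher's LSD are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelScore",
    "ModelRanking",
    "GroupedSample",
    "aicc",
    "rank_models",
    "one_way_anova",
    "levene",
    "kruskal_wallis",
    "fisher_lsd",
]


@dataclass(frozen=True)
class ModelScore:
    """Maximized log-likelihood of one candidate model.

    Parameters
    ----------
    label : str
        Model name as it should appear in the ranking table.
    k : int
        Number of free parameters (including any fitted residual scale).
    loglik : float
        Log-likelihood at the maximum-likelihood estimates.
    n : int
        Effective sample size used in the small-sample correction. For the
        cohort analyses this is the number of crabs (independent subjects)
        by default; see the ``aicc_n`` options on the fitting entry points.
    """

    label: str
    k: int
    loglik: float
    n: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"model {self.label!r}: K must be >= 1, got {self.k}")
        if self.n <= self.k + 1:
            raise ValueError(
                f"model {self.label!r}: AICc requires n > K + 1 "
                f"(n={self.n}, K={self.k})"
            )


@dataclass
class ModelRanking:
    """AICc ranking of a set of candidate models fit to the same data."""

    table: pd.DataFrame
    tie_delta: float = 2.0

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    @property
    def co_best(self) -> list[str]:
        """All models within ``tie_delta`` AICc of the best (treated as ties)."""
        mask = self.table["delta_aicc"] < self.tie_delta
        return [str(m) for m in self.table.loc[mask, "model"]]

    def to_csv(self, path) -> None:
        out = self.table.rename(
            columns={
                "model": "Model",
                "k": "K",
                "aicc": "AICc",
                "delta_aicc": "dAICc",
                "rel_likelihood": "Likelihood",
                "weight": "AICc Weights",
            }
        )
        out.to_csv(path, index=False)


@dataclass
class GroupedSample:
    """Values partitioned into >= 2 named groups."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape:
            raise ValueError("values and groups must have the same length")
        labels, counts = np.unique(self.groups, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need at least 2 groups")
        if (counts == 0).any():
            raise ValueError("every group must be non-empty")

    def split(self) -> dict:
        return {
            g: self.values[self.groups == g] for g in np.unique(self.groups)
        }


def aicc(score: ModelScore) -> float:
    """Akaike's information criterion with the small-sample correction.

    AICc = -2 lnL + 2K + 2K(K+1)/(n - K - 1).
    """
    k, n = score.k, score.n
    return -2.0 * score.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(
    scores: Sequence[ModelScore],
    *,
    tie_delta: float = 2.0,
    precomputed_aicc: Sequence[float] | None = None,
) -> ModelRanking:
    """Rank candidate models by AICc with Akaike weights.

    Models whose AICc lies within ``tie_delta`` of the minimum are reported
    as co-best rather than forcing a single winner. ``precomputed_aicc``
    bypasses the AICc computation, e.g. to re-rank published criterion
    values whose underlying log-likelihoods are unknown.
    """
    if len(scores) == 0:
        raise ValueError("rank_models needs at least one ModelScore")
    if precomputed_aicc is not None:
        vals = np.asarray(precomputed_aicc, dtype=float)
        if len(vals) != len(scores):
            raise ValueError("precomputed_aicc length mismatch")
    else:
        vals = np.array([aicc(s) for s in scores])
    delta = vals - vals.min()
    rel = np.exp(-delta / 2.0)
    weights = rel / rel.sum()
    table = pd.DataFrame(
        {
            "model": [s.label for s in scores],
            "k": [s.k for s in scores],
            "loglik": [s.loglik for s in scores],
            "aicc": vals,
            "delta_aicc": delta,
            "rel_likelihood": rel,
            "weight": weights,
            "co_best": delta < tie_delta,
        }
    ).sort_values("aicc", kind="stable", ignore_index=True)
    return ModelRanking(table=table, tie_delta=tie_delta)


def _as_grouped(sample) -> GroupedSample:
    if isinstance(sample, GroupedSample):
        return sample
    values, groups = sample
    return GroupedSample(np.asarray(values), np.asarray(groups))


def one_way_anova(sample) -> dict:
    """Classical one-way fixed-effects ANOVA.

    Returns ``{"F", "df", "p"}`` with df = (between, within). Raises if both
    the between- and within-group variances are zero (F undefined).
    """
    gs = _as_grouped(sample)
    parts = list(gs.split().values())
    n = len(gs.values)
    k = len(parts)
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = gs.values.mean()
    ssb = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    if ssw == 0.0 and ssb == 0.0:
        raise ZeroDivisionError("F undefined: no variance between or within groups")
    f, p = sps.f_oneway(*parts)
    return {"F": float(f), "df": (k - 1, n - k), "p": float(p)}


def levene(sample, *, center: str = "mean") -> dict:
    """Levene's test for homogeneity of variance.

    W is the one-way ANOVA F statistic applied to absolute deviations from
    the group center (classical mean-centered form by default; ``center``
    may be ``"median"`` for the Brown-Forsythe variant).
    """
    gs = _as_grouped(sample)
    parts = list(gs.split().values())
    w, p = sps.levene(*parts, center=center)
    return {"W": float(w), "p": float(p)}


def kruskal_wallis(sample, *, exact: bool = False, n_resamples: int = 500_000) -> dict:
    """Kruskal-Wallis rank test with midrank tie correction.

    The default p-value uses the chi-square approximation with
    (groups - 1) df. That approximation is poor for very small samples
    (fewer than ~5 values per group); ``exact=True`` computes the p-value
    from the permutation distribution of H instead (exhaustive whenever the
    number of distinct group assignments is below ``n_resamples``).
    """
    gs = _as_grouped(sample)
    parts = list(gs.split().values())
    if np.ptp(gs.values) == 0:
        # all values tied: H = 0 by convention, p = 1
        return {"H": 0.0, "p": 1.0, "df": len(parts) - 1}
    h, p = sps.kruskal(*parts)
    if exact:
        res = sps.permutation_test(
            parts,
            lambda *samples: sps.kruskal(*samples).statistic,
            permutation_type="independent",
            alternative="greater",
            n_resamples=n_resamples,
            rng=0,
        )
        p = float(res.pvalue)
    return {"H": float(h), "p": float(p), "df": len(parts) - 1}


def fisher_lsd(sample, anova_fit: dict | None = None, *, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher's least-significant-difference pairwise comparisons.

    Pairwise t statistics use the pooled within-group mean square (MSW) and
    its degrees of freedom from the omnibus ANOVA:

        t = (mean_i - mean_j) / sqrt(MSW * (1/n_i + 1/n_j))

    By convention LSD is applied only after a significant omnibus F; pass
    the ANOVA result to enforce the gate (a non-significant omnibus raises).
    """
    gs = _as_grouped(sample)
    if anova_fit is not None and anova_fit["p"] > alpha:
        raise ValueError(
            "Fisher's LSD is only applied after a significant omnibus F "
            f"(omnibus p = {anova_fit['p']:.4g} > alpha = {alpha})"
        )
    parts = gs.split()
    k = len(parts)
    n = len(gs.values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in parts.values())
    df_w = n - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom for the pooled variance")
    msw = ssw / df_w
    rows = []
    for (ga, va), (gb, vb) in combinations(parts.items(), 2):
        se = np.sqrt(msw * (1.0 / len(va) + 1.0 / len(vb)))
        if se == 0.0:
            raise ZeroDivisionError(
                f"zero pooled variance: cannot compare {ga!r} vs {gb!r}"
            )
        t = (va.mean() - vb.mean()) / se
        p = 2.0 * sps.t.sf(abs(t), df_w)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_a": va.mean(),
                "mean_b": vb.mean(),
                "t": t,
                "df": df_w,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
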