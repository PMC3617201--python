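"""Morphometric PCA for multi-landmark carapace measurements.

Landmark measurements (five for red king crab, eight for Tanner crab) are
standardized column-wise and decomposed by PCA on the correlation matrix.
Juvenile crab landmarks are dominated by a single size axis, so PC1
typically carries ~90% of the variance with same-signed loadings; the sign
convention here flips each component so the majority of loadings are
negative, making larger crabs score lower on PC1. Treatment and molt
effects on the scores are tested with a fixed-effects model of Treatment
crossed with Molt number plus crab-within-treatment intercepts, followed by
Fisher LSD contrasts of treatments within each molt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import _crab_within_treatment, _dummies, type2_anova
from .stats_core import fisher_lsd, one_way_anova

__all__ = [
    "LANDMARKS",
    "normalize",
    "pca",
    "pc_anova",
    "filter_molts",
    "PcaResult",
]

LANDMARKS = {
    "red_king_crab": [
        "carapace_width",
        "carapace_length",
        "rostrum_base_width",
        "orbital_spine_width",
        "first_spine_length",
    ],
    "tanner": [
        "carapace_width",
        "carapace_length",
        "cl_to_rostrum",
        "cl_to_orbit",
        "rostrum_base_width",
        "rostrum_length",
        "orbital_spine_width",
        "orbital_spine_length",
    ],
}


def normalize(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Standardize each measurement column to mean 0, sd 1 (n-1 denominator)."""
    df = table[columns] if columns is not None else table
    if len(df) < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = df.std(ddof=1)
    zero = sd[sd == 0.0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    return (df - df.mean()) / sd


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame  # columns PC1.., rows = variables
    scores: pd.DataFrame  # columns PC1.., one row per input row
    rank: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "PC": np.arange(1, len(self.eigenvalues) + 1),
                "Eigenvalues": self.eigenvalues,
                "%Variation": self.percent_variance,
                "Cum.%Variation": self.cumulative_percent,
            }
        )


def pca(standardized: pd.DataFrame) -> PcaResult:
    """PCA as an eigendecomposition of the correlation matrix.

    Input should already be standardized (see :func:`normalize`); scores are
    projections of the standardized rows onto unit-norm eigenvectors. Each
    component's sign is fixed deterministically: flipped so that the
    majority of its loadings are negative, with ties broken by making the
    first loading non-positive.
    """
    X = np.asarray(standardized, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    corr = (X.T @ X) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int((evals > 1e-10 * max(evals.max(), 1.0)).sum())
    if rank < p:
        warnings.warn(f"correlation matrix is rank-deficient (rank {rank} < {p})")
    for j in range(p):
        v = evecs[:, j]
        neg = (v < 0).sum()
        pos = (v > 0).sum()
        if neg < pos or (neg == pos and v[0] > 0):
            evecs[:, j] = -v
    pct = 100.0 * evals / evals.sum()
    names = [f"PC{i + 1}" for i in range(p)]
    cols = list(standardized.columns) if hasattr(standardized, "columns") else list(range(p))
    return PcaResult(
        eigenvalues=evals,
        percent_variance=pct,
        cumulative_percent=np.cumsum(pct),
        loadings=pd.DataFrame(evecs, index=cols, columns=names),
        scores=pd.DataFrame(
            X @ evecs,
            columns=names,
            index=standardized.index if hasattr(standardized, "index") else None,
        ),
        rank=rank,
    )


def filter_molts(
    table: pd.DataFrame, *, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Drop molt stages reached by too few crabs in any treatment.

    A molt number is kept only if, in every treatment, at least
    ``min_fraction`` of that treatment's crabs have a measurement at that
    molt — mirroring the exclusion of sparsely-reached late molts from the
    score ANOVA.
    """
    crabs_per_tr = table.groupby("treatment")["crab_id"].nunique()
    keep = []
    for m, g in table.groupby("molt_number"):
        frac = g.groupby("treatment")["crab_id"].nunique().reindex(crabs_per_tr.index).fillna(0) / crabs_per_tr
        if (frac >= min_fraction).all():
            keep.append(m)
        else:
            warnings.warn(f"excluding molt {m}: reached by < {min_fraction:.0%} of crabs in some treatment")
    return table[table["molt_number"].isin(keep)].reset_index(drop=True)


def pc_anova(
    scores: pd.DataFrame,
    *,
    response: str = "PC1",
    alpha: float = 0.05,
) -> dict:
    """Treatment x Molt fixed-effects model on PC scores with nested crabs.

    ``scores`` must carry ``treatment``, ``molt_number``, ``crab_id`` and the
    response column. Returns the F table plus, for each molt, Fisher LSD
    contrasts of treatments within that molt (the lettering of per-molt
    comparisons); contrasts are reported only where the within-molt omnibus
    F is significant at ``alpha``.
    """
    df = scores.dropna(subset=[response]).copy()
    cells = df.groupby(["treatment", "molt_number"]).size().unstack()
    if cells.isna().any().any() or (cells == 0).any().any():
        empty = int(cells.isna().sum().sum() + (cells == 0).sum().sum())
        warnings.warn(
            f"{empty} empty treatment x molt cell(s); consider filter_molts first"
        )
    y = df[response].to_numpy(dtype=float)
    T = _dummies(df["treatment"])
    M = _dummies(df["molt_number"].astype(str))
    TM = np.column_stack([T[:, i] * M[:, j] for i in range(T.shape[1]) for j in range(M.shape[1])]) \
        if T.shape[1] and M.shape[1] else np.empty((len(df), 0))
    terms = {
        "Treatment": T,
        "Molt": M,
        "Treatment:Molt": TM,
        "Crab(Treatment)": _crab_within_treatment(df),
    }
    contains = {
        "Treatment": {"T"},
        "Molt": {"M"},
        "Treatment:Molt": {"T", "M"},
        "Crab(Treatment)": {"crab"},
    }
    anova = type2_anova(y, terms, contains)
    within = {}
    for m, g in df.groupby("molt_number"):
        if g["treatment"].nunique() < 2:
            continue
        sample = (g[response].to_numpy(dtype=float), g["treatment"].to_numpy())
        try:
            omnibus = one_way_anova(sample)
        except (ValueError, ZeroDivisionError):
            continue
        entry = {"omnibus": omnibus, "lsd": None}
        if omnibus["p"] < alpha:
            entry["lsd"] = fisher_lsd(sample, omnibus, alpha=alpha)
        within[m] = entry
    return {"anova": anova, "within_molt": within}
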