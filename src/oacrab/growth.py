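"""Degree-day growth models for juvenile crabs.

Time is measured on a thermal clock: degree-days accumulated as the sum of
daily mean temperatures above a base (default 0 °C). Carapace length (CL)
grows linearly on that clock and is analyzed with an ANCOVA in which
Treatment is fully crossed with Time and crabs are nested within Treatment;
a significant Treatment x Time interaction means the growth rates differ and
each treatment is then regressed separately. Wet mass (WM) grows
exponentially, WM = a_crab * exp(b t), fit by maximum likelihood with
additive Gaussian errors on the mass scale; four variants letting the
intercept a and/or the growth coefficient b vary with treatment are ranked
by AICc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .stats_core import ModelRanking, ModelScore, rank_models

__all__ = [
    "cumulative_degree_days",
    "degree_day_clock",
    "fit_cl_linear",
    "fit_wm_exponential",
    "rank_wm_models",
    "predict_percent_difference",
    "intermolt_degree_days",
    "WM_VARIANTS",
    "CLFit",
    "GrowthFit",
]

WM_VARIANTS = ("a,b", "a(T),b", "a,b(T)", "a(T),b(T)")


# ---------------------------------------------------------------- degree days

def degree_day_clock(temperature: pd.DataFrame, *, base: float = 0.0) -> np.ndarray:
    """Cumulative degree-days at the end of each day of a temperature series.

    ``temperature`` has contiguous integer ``day`` (1..N) and ``temp_c``
    columns; entry ``i`` of the result is the degree-days accumulated through
    day ``i+1``.
    """
    df = temperature.sort_values("day")
    days = df["day"].to_numpy()
    if len(days) == 0:
        raise ValueError("empty temperature series")
    if not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
        raise ValueError("temperature series days must be contiguous")
    temps = df["temp_c"].to_numpy(dtype=float)
    if (temps < -2).any() or (temps > 30).any():
        warnings.warn("temperatures outside the plausible range -2..30 degC")
    return np.cumsum(np.maximum(temps - base, 0.0))


def cumulative_degree_days(
    temperature: pd.DataFrame, start_day: int, end_day: int, *, base: float = 0.0
) -> float:
    """Degree-days accumulated over the half-open day interval (start, end]."""
    if start_day > end_day:
        raise ValueError("start_day must be <= end_day")
    df = temperature.sort_values("day")
    first = int(df["day"].iloc[0])
    last = int(df["day"].iloc[-1])
    if start_day < first - 1 or end_day > last:
        raise ValueError(
            f"requested interval ({start_day}, {end_day}] outside series days "
            f"{first}..{last}"
        )
    clock = degree_day_clock(temperature, base=base)
    upto = lambda d: 0.0 if d < first else float(clock[d - first])
    return upto(end_day) - upto(start_day)


# ------------------------------------------------- fixed-effects SS machinery

def _rss_rank(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _crab_within_treatment(df: pd.DataFrame) -> np.ndarray:
    """Sum-to-zero crab dummies within each treatment (m-1 columns per
    treatment), orthogonal to the treatment main effect."""
    cols = []
    for tr in sorted(df["treatment"].unique()):
        in_tr = (df["treatment"] == tr).to_numpy()
        crabs = sorted(df.loc[in_tr, "crab_id"].unique())
        for crab in crabs[:-1]:
            c = np.zeros(len(df))
            c[(df["crab_id"] == crab).to_numpy() & in_tr] = 1.0
            c[(df["crab_id"] == crabs[-1]).to_numpy() & in_tr] = -1.0
            cols.append(c)
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _dummies(labels: pd.Series) -> np.ndarray:
    levels = sorted(labels.unique())
    return np.column_stack(
        [(labels == lev).to_numpy(dtype=float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def type2_anova(
    y: np.ndarray, terms: dict, contains: dict
) -> pd.DataFrame:
    """Type-II F tests for a fixed-effects linear model.

    ``terms`` maps term name -> design columns; ``contains`` maps term name
    -> set of factor names appearing in it. The test for a term compares a
    model with all terms not containing that term's factors against the same
    model plus the term, with the error mean square taken from the full
    model. Equivalent to classical Type-I/III on balanced designs.
    """
    n = len(y)
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [terms[t] for t in terms])
    rss_full, rank_full = _rss_rank(y, X_full)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom in the full model")
    mse = rss_full / df_resid
    rows = []
    from scipy import stats as sps

    for term in terms:
        base = [
            terms[t]
            for t in terms
            if t != term and not (contains[term] <= contains[t])
        ]
        X0 = np.hstack([intercept] + base) if base else intercept
        X1 = np.hstack([X0, terms[term]])
        rss0, rank0 = _rss_rank(y, X0)
        rss1, rank1 = _rss_rank(y, X1)
        df_term = rank1 - rank0
        if df_term == 0:
            rows.append({"term": term, "ss": 0.0, "df": 0, "F": np.nan, "p": np.nan})
            continue
        ss = rss0 - rss1
        F = (ss / df_term) / mse
        p = float(sps.f.sf(F, df_term, df_resid))
        rows.append({"term": term, "ss": ss, "df": df_term, "F": F, "p": p})
    rows.append({"term": "Residual", "ss": rss_full, "df": df_resid, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ CL linear model

@dataclass
class CLFit:
    """ANCOVA of carapace length on the degree-day clock."""

    anova: pd.DataFrame
    interaction_F: float
    interaction_p: float
    per_treatment: pd.DataFrame | None  # slope/intercept per treatment when fit
    n_crabs: int
    dropped_crabs: list


def fit_cl_linear(
    obs: pd.DataFrame,
    *,
    min_points: int = 3,
    alpha: float = 0.05,
    time_col: str = "degree_days",
    response: str = "cl_mm",
) -> CLFit:
    """Linear carapace growth with treatment-by-time interaction testing.

    Crabs with fewer than ``min_points`` measurements are excluded. The
    model regresses CL on Time crossed with Treatment plus crab-within-
    treatment intercepts. When the Treatment x Time interaction is
    significant at ``alpha``, each treatment is refit separately (Time plus
    crab intercepts) and per-treatment slopes and mean intercepts reported.
    """
    df = obs.dropna(subset=[response, time_col]).copy()
    counts = df.groupby("crab_id")[response].count()
    keep = counts[counts >= min_points].index
    dropped = sorted(set(df["crab_id"]) - set(keep))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} crabs with < {min_points} data points")
    df = df[df["crab_id"].isin(keep)].reset_index(drop=True)
    # a crab needs >= 2 distinct times to inform a slope
    bad = [
        c for c, g in df.groupby("crab_id") if g[time_col].nunique() < 2
    ]
    if bad:
        warnings.warn(f"dropping {len(bad)} crabs with < 2 distinct times")
        df = df[~df["crab_id"].isin(bad)].reset_index(drop=True)
        dropped += bad
    if df["treatment"].nunique() < 2:
        raise ValueError("need >= 2 treatments with usable crabs for the ANCOVA")
    y = df[response].to_numpy(dtype=float)
    t = df[time_col].to_numpy(dtype=float)[:, None]
    T = _dummies(df["treatment"])
    terms = {
        "Treatment": T,
        "Time": t,
        "Treatment:Time": T * t,
        "Crab(Treatment)": _crab_within_treatment(df),
    }
    contains = {
        "Treatment": {"T"},
        "Time": {"t"},
        "Treatment:Time": {"T", "t"},
        "Crab(Treatment)": {"crab"},
    }
    anova = type2_anova(y, terms, contains)
    inter = anova.set_index("term").loc["Treatment:Time"]
    per_treatment = None
    if inter["p"] < alpha:
        rows = []
        for tr, g in df.groupby("treatment"):
            crabs = sorted(g["crab_id"].unique())
            D = np.column_stack(
                [(g["crab_id"] == c).to_numpy(dtype=float) for c in crabs]
            )
            X = np.hstack([D, g[time_col].to_numpy(dtype=float)[:, None]])
            beta, *_ = np.linalg.lstsq(X, g[response].to_numpy(dtype=float), rcond=None)
            rows.append(
                {
                    "treatment": tr,
                    "slope": beta[-1],
                    "intercept": float(np.mean(beta[:-1])),
                    "n_crabs": len(crabs),
                    "n_obs": len(g),
                }
            )
        per_treatment = pd.DataFrame(rows)
    return CLFit(
        anova=anova,
        interaction_F=float(inter["F"]),
        interaction_p=float(inter["p"]),
        per_treatment=per_treatment,
        n_crabs=df["crab_id"].nunique(),
        dropped_crabs=dropped,
    )


# ------------------------------------------------------- WM exponential model

@dataclass
class GrowthFit:
    """One exponential wet-mass model variant at its maximum likelihood."""

    variant: str
    a_by_crab: dict
    b_by_treatment: dict
    sigma: float
    loglik: float
    k: int
    n_obs: int
    n_crabs: int
    confounded: bool = False
    converged: bool = True
    message: str = ""

    def predict(self, crab_id, t):
        tr = self._crab_treatment[crab_id]
        return self.a_by_crab[crab_id] * np.exp(self.b_by_treatment[tr] * np.asarray(t))

    _crab_treatment: dict = field(default_factory=dict, repr=False)


def _profile_rss(b: float, groups: list) -> float:
    """Residual sum of squares with per-crab intercepts profiled out.

    For fixed b the model is linear in each crab's a; the optimum is
    a_i = (y.g)/(g.g) with g = exp(b t), giving rss_i = y.y - (y.g)^2/(g.g).
    """
    rss = 0.0
    for t, y in groups:
        g = np.exp(b * t)
        gg = float(g @ g)
        yg = float(y @ g)
        rss += float(y @ y) - yg * yg / gg
    return rss


def _optimize_b(groups: list, bounds=(-0.005, 0.02)) -> tuple[float, float, bool, str]:
    res = minimize_scalar(
        _profile_rss,
        args=(groups,),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-13},
    )
    ok = bool(res.success)
    msg = "" if ok else str(res.message)
    b = float(res.x)
    if ok and (abs(b - bounds[0]) < 1e-10 or abs(b - bounds[1]) < 1e-10):
        ok = False
        msg = f"b estimate {b:.3g} at the search boundary {bounds}"
    return b, float(res.fun), ok, msg


def fit_wm_exponential(
    obs: pd.DataFrame,
    variant: str = "a,b",
    *,
    time_col: str = "degree_days",
    response: str = "wm_g",
    b_bounds: tuple = (-0.005, 0.02),
) -> GrowthFit:
    """Maximum-likelihood fit of WM = a_crab exp(b t) + Normal(0, sigma).

    Per-crab intercepts ``a`` are always free (differences among crabs
    within a treatment are part of every variant) and are profiled out in
    closed form, leaving a one-dimensional search per b parameter. The
    residual standard deviation is a fitted parameter. Variants labelled
    a(T) are structurally confounded with their a counterparts because the
    crab intercepts absorb any treatment-level intercept; they refit
    identically and are flagged ``confounded``, with
    K = n_crabs + n_b_parameters + 1 either way.
    """
    if variant not in WM_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {WM_VARIANTS}")
    df = obs.dropna(subset=[response, time_col]).copy()
    counts = df.groupby("crab_id")[response].count()
    keep = counts[counts >= 2].index
    df = df[df["crab_id"].isin(keep)]
    if df.empty:
        raise ValueError("no crabs with >= 2 wet-mass observations")
    crab_tr = df.groupby("crab_id")["treatment"].first().to_dict()
    b_per_treatment = variant.endswith("b(T)")
    groups_by_tr: dict[str, list] = {}
    crab_groups: dict[str, tuple] = {}
    for crab, g in df.groupby("crab_id"):
        t = g[time_col].to_numpy(dtype=float)
        y = g[response].to_numpy(dtype=float)
        crab_groups[crab] = (t, y)
        groups_by_tr.setdefault(crab_tr[crab], []).append((t, y))

    b_by_treatment: dict[str, float] = {}
    total_rss = 0.0
    converged, messages = True, []
    if b_per_treatment:
        for tr, groups in groups_by_tr.items():
            b, rss, ok, msg = _optimize_b(groups, b_bounds)
            b_by_treatment[tr] = b
            total_rss += rss
            converged &= ok
            if msg:
                messages.append(f"{tr}: {msg}")
        n_b = len(groups_by_tr)
    else:
        all_groups = [g for gs in groups_by_tr.values() for g in gs]
        b, total_rss, ok, msg = _optimize_b(all_groups, b_bounds)
        for tr in groups_by_tr:
            b_by_treatment[tr] = b
        converged &= ok
        if msg:
            messages.append(msg)
        n_b = 1

    a_by_crab = {}
    for crab, (t, y) in crab_groups.items():
        g = np.exp(b_by_treatment[crab_tr[crab]] * t)
        a_by_crab[crab] = float((y @ g) / (g @ g))

    n = len(df)
    sigma2 = max(total_rss / n, 1e-300)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = len(a_by_crab) + n_b + 1
    fit = GrowthFit(
        variant=variant,
        a_by_crab=a_by_crab,
        b_by_treatment=b_by_treatment,
        sigma=math.sqrt(sigma2),
        loglik=loglik,
        k=k,
        n_obs=n,
        n_crabs=len(a_by_crab),
        confounded=variant.startswith("a(T)"),
        converged=converged,
        message="; ".join(messages),
    )
    fit._crab_treatment = crab_tr
    return fit


def rank_wm_models(
    obs: pd.DataFrame,
    *,
    aicc_n: str = "observations",
    tie_delta: float = 2.0,
    **fit_kwargs,
) -> tuple[ModelRanking, dict]:
    """Fit all four wet-mass variants and rank them by AICc.

    The AICc sample size defaults to the number of observations because the
    parameter count (one intercept per crab) exceeds the number of crabs,
    which would leave the small-sample correction undefined.
    """
    fits = {v: fit_wm_exponential(obs, v, **fit_kwargs) for v in WM_VARIANTS}
    any_fit = next(iter(fits.values()))
    if aicc_n == "observations":
        n_eff = any_fit.n_obs
    elif aicc_n == "crabs":
        n_eff = any_fit.n_crabs
    else:
        raise ValueError("aicc_n must be 'observations' or 'crabs'")
    scores = [
        ModelScore(label=v, k=f.k, loglik=f.loglik, n=n_eff) for v, f in fits.items()
    ]
    return rank_models(scores, tie_delta=tie_delta), fits


# ----------------------------------------------------------- worked contrasts

def predict_percent_difference(
    params_a, params_b, t: float, *, model: str
) -> float:
    """Percent difference 100 (pred_A/pred_B - 1) at degree-days ``t``.

    ``model="linear"`` takes (slope, intercept) pairs for carapace length;
    ``model="exponential"`` takes (a, b) pairs for wet mass, where with a
    shared intercept the ratio reduces to exp((b_A - b_B) t).
    """
    if model == "linear":
        sa, ia = params_a
        sb, ib = params_b
        pa, pb = sa * t + ia, sb * t + ib
    elif model == "exponential":
        aa, ba = params_a
        ab, bb = params_b
        pa, pb = aa * math.exp(ba * t), ab * math.exp(bb * t)
    else:
        raise ValueError("model must be 'linear' or 'exponential'")
    if pb <= 0:
        raise ValueError("reference prediction must be positive")
    return 100.0 * (pa / pb - 1.0)


def intermolt_degree_days(molts: pd.DataFrame) -> pd.DataFrame:
    """Intermolt periods on the degree-day clock.

    For each crab, the degree-days elapsed between successive molts (the
    first period runs from experiment start to the first molt). Requires a
    ``degree_days`` column giving the clock reading at each molt.
    """
    rows = []
    for crab, g in molts.sort_values("molt_number").groupby("crab_id"):
        dd = g["degree_days"].to_numpy(dtype=float)
        nums = g["molt_number"].to_numpy()
        prev = 0.0
        for m, d in zip(nums, dd):
            rows.append(
                {
                    "crab_id": crab,
                    "treatment": g["treatment"].iloc[0],
                    "molt_pair": f"{m - 1}->{m}",
                    "intermolt_dd": d - prev,
                }
            )
            prev = d
    return pd.DataFrame(rows)
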