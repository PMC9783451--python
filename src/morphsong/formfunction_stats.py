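"""Within-morph form-function correlations and the supporting test suite.

The decoupling analysis asks whether the mapping from wing structure
(form) to song characteristics (function) is the same in every morph. Its
operational signature: a wing-song trait pair is "decoupled" when the set
of morphs showing a significant correlation — or the sign of that
correlation — differs among morphs. Cells where within-morph variation is
insufficient (a structure fixed or absent in a morph, or too few
individuals) are reported as NA with a reason rather than silently
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationEntry",
    "TestResult",
    "ManovaResult",
    "pearson_with_p",
    "welch_t_test",
    "levene_test",
    "manova_pillai",
    "formfunction_report",
    "DEFAULT_TRAIT_PAIRS",
]

#: wing-structure x calling-song pairs examined by default
DEFAULT_TRAIT_PAIRS = tuple(
    (x, y)
    for x in ("mirror_size", "harp_width", "scraper_present")
    for y in (
        "calling_dominant_frequency",
        "calling_amplitude_db",
        "calling_frequency_evenness",
    )
)

MIN_N_FOR_P = 4  # below this, correlations are reported without a p-value


@dataclass(frozen=True)
class CorrelationEntry:
    trait_x: str
    trait_y: str
    r: float | None
    n: int
    t_stat: float | None
    df: int | None
    p_two_sided: float | None
    flagged_small_n: bool = False
    na_reason: str | None = None

    @property
    def is_na(self) -> bool:
        return self.r is None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_sided is not None and self.p_two_sided < alpha


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_two_sided: float
    test_name: str
    group_ns: tuple[int, ...]


@dataclass(frozen=True)
class ManovaResult:
    statistic_name: str
    statistic_value: float
    approx_f: float
    df1: float
    df2: float
    p: float


def _na_entry(tx: str, ty: str, n: int, reason: str) -> CorrelationEntry:
    return CorrelationEntry(
        trait_x=tx, trait_y=ty, r=None, n=n, t_stat=None, df=None,
        p_two_sided=None, flagged_small_n=n < MIN_N_FOR_P, na_reason=reason,
    )


def pearson_with_p(
    x, y, trait_x: str = "x", trait_y: str = "y"
) -> CorrelationEntry:
    """Pearson product-moment correlation with the asymptotic t p-value.

    Pairwise-complete observations only. t = r sqrt((n-2)/(1-r^2)) against
    Student t with n-2 df; |r| = 1 gives p = 0. Degenerate input (constant
    vector, too few pairs) yields an NA entry with a reason — Fig-style NA
    semantics, not an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return _na_entry(trait_x, trait_y, n, "fewer than 3 complete pairs")
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if denom == 0:
        return _na_entry(trait_x, trait_y, n, "insufficient variation")
    r = float(np.clip(np.sum(sx * sy) / denom, -1.0, 1.0))
    if n < MIN_N_FOR_P:
        return CorrelationEntry(
            trait_x=trait_x, trait_y=trait_y, r=r, n=n, t_stat=None, df=None,
            p_two_sided=None, flagged_small_n=True,
            na_reason="too few pairs for a p-value",
        )
    df = n - 2
    if abs(r) == 1.0:
        t_inf = float("inf") if r > 0 else float("-inf")
        return CorrelationEntry(trait_x, trait_y, r, n, t_inf, df, 0.0)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationEntry(trait_x, trait_y, r, n, float(t), df, p)


def welch_t_test(x, y) -> TestResult:
    """Welch's two-sample t-test (unequal variances, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("degenerate groups: both variances are zero")
    res = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / len(x), vy / len(y)
    df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_two_sided=float(res.pvalue),
        test_name="welch_t",
        group_ns=(len(x), len(y)),
    )


def levene_test(groups, center: str = "median") -> TestResult:
    """Levene's variance-homogeneity test (Brown-Forsythe by default).

    One-way ANOVA F on absolute deviations from each group's center
    (median by default; mean available).
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has n < 2")
    stat, p = stats.levene(*groups, center=center)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    return TestResult(
        statistic=float(stat),
        df=(float(k - 1), float(n_total - k)),
        p_two_sided=float(p),
        test_name=f"levene_{center}",
        group_ns=tuple(len(g) for g in groups),
    )


def manova_pillai(Y, groups, statistic: str = "pillai") -> ManovaResult:
    """One-way MANOVA on a response matrix (e.g., PC1-2) by group.

    Between- and within-group SSCP matrices give Pillai's trace
    V = tr(H (H + E)^-1) with its standard approximate F; Wilks' lambda is
    available via ``statistic="wilks"``.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    levels, counts = np.unique(groups, return_counts=True)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs n >= 2")
    if n < g + p:
        raise ValueError("too few rows for the number of groups and responses")

    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lev in levels:
        sub = Y[groups == lev]
        mean = sub.mean(axis=0)
        diff = (mean - grand)[:, None]
        H += len(sub) * diff @ diff.T
        E += (sub - mean).T @ (sub - mean)
    s = min(p, g - 1)
    m = (abs(g - 1 - p) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    if statistic == "pillai":
        try:
            V = float(np.trace(H @ np.linalg.inv(H + E)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular total SSCP; reduce the number of responses"
            ) from exc
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        f = (df2 / df1) * (V / (s - V))
        p_val = float(stats.f.sf(f, df1, df2))
        return ManovaResult("pillai", V, float(f), df1, df2, p_val)
    if statistic == "wilks":
        try:
            lam = float(np.linalg.det(E) / np.linalg.det(H + E))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular within-group SSCP; reduce the number of responses"
            ) from exc
        q = g - 1
        t_exp = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
        df1 = p * q
        df2 = (n - 1 - (p + q + 1) / 2.0) * t_exp - (p * q - 2) / 2.0
        lam_t = lam ** (1.0 / t_exp)
        f = (1 - lam_t) / lam_t * df2 / df1
        p_val = float(stats.f.sf(f, df1, df2))
        return ManovaResult("wilks", lam, float(f), df1, df2, p_val)
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# Form-function report


def formfunction_report(
    features: pd.DataFrame,
    morphs: pd.Series | dict,
    trait_pairs: tuple[tuple[str, str], ...] = DEFAULT_TRAIT_PAIRS,
    alpha: float = 0.05,
    holm: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-morph wing-song correlation grid plus a decoupling summary.

    Returns a tidy grid (one row per morph x trait pair) and a summary dict
    flagging pairs whose significant correlations differ among morphs in
    identity or sign. Raw p-values by default; optional Holm adjustment
    applied within the grid.
    """
    morphs = pd.Series(morphs)
    rows = []
    entries: dict[tuple[str, str, str], CorrelationEntry] = {}
    for morph in morphs.unique():
        ids = morphs.index[morphs == morph]
        sub = features.loc[features.index.intersection(ids)]
        if len(sub) < MIN_N_FOR_P:
            warnings.warn(
                f"morph {morph!r} has n = {len(sub)} < {MIN_N_FOR_P}; "
                f"its correlation cells are NA",
                stacklevel=2,
            )
        for tx, ty in trait_pairs:
            if tx not in sub.columns or ty not in sub.columns:
                entry = _na_entry(tx, ty, len(sub), "trait not measured")
            else:
                entry = pearson_with_p(sub[tx], sub[ty], trait_x=tx, trait_y=ty)
            entries[(str(morph), tx, ty)] = entry
            rows.append(
                {
                    "morph": morph,
                    "trait_x": tx,
                    "trait_y": ty,
                    "n": entry.n,
                    "r": np.nan if entry.r is None else entry.r,
                    "t_stat": np.nan if entry.t_stat is None else entry.t_stat,
                    "p": np.nan if entry.p_two_sided is None else entry.p_two_sided,
                    "na_reason": entry.na_reason or "",
                }
            )
    grid = pd.DataFrame(rows)
    if holm and len(grid):
        grid["p"] = _holm(grid["p"].to_numpy())

    morph_list = [str(m) for m in morphs.unique()]
    flags = []
    for tx, ty in trait_pairs:
        status = {}
        for morph in morph_list:
            e = entries[(morph, tx, ty)]
            if e.is_na:
                status[morph] = "NA"
            elif e.p_two_sided is not None and (
                grid.query("morph == @morph and trait_x == @tx and trait_y == @ty")[
                    "p"
                ].iloc[0]
                < alpha
            ):
                status[morph] = "+" if e.r > 0 else "-"
            else:
                status[morph] = "ns"
        defined = [v for v in status.values() if v != "NA"]
        sig = [v for v in defined if v in ("+", "-")]
        decoupled = bool(sig) and len(set(defined)) > 1
        flags.append(
            {
                "trait_x": tx,
                "trait_y": ty,
                "per_morph": status,
                "decoupled": decoupled,
            }
        )
    summary = {
        "alpha": alpha,
        "holm": holm,
        "morphs": morph_list,
        "pairs": flags,
        "n_decoupled_pairs": int(sum(f["decoupled"] for f in flags)),
    }
    return grid, summary


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, NaN-aware."""
    adj = np.full_like(p, np.nan, dtype=float)
    idx = np.where(np.isfinite(p))[0]
    m = len(idx)
    order = idx[np.argsort(p[idx])]
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
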