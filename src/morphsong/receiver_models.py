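"""Receiver-side analyses: detectability thresholds and phonotaxis models.

Female crickets respond to tones only above a frequency-dependent amplitude
threshold (a behavioral audiogram). A song's detectability margin is its
sound pressure level minus the threshold at its dominant frequency; a shift
in dominant frequency therefore changes detectability even at constant
amplitude, which is the receiver-side consequence of the scraper-dependent
frequency shift in purring males.

Phonotaxis outcomes (response / speaker contact per stimulus) are binary
and can be completely separated (e.g., no female ever contacts the speaker
for white noise), so the logistic models use Firth's Jeffreys-prior
penalty, which keeps every coefficient finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "ThresholdCurve",
    "FirthFit",
    "required_amplitude",
    "detectability_margin",
    "threshold_difference",
    "firth_logistic",
    "fit_phonotaxis",
    "pairwise_contrasts",
    "synthetic_threshold_curve",
]


@dataclass(frozen=True)
class ThresholdCurve:
    """Frequency -> required amplitude (dB SPL), linear in log-frequency.

    Queries outside the node range raise: an audiogram says nothing about
    frequencies it was never measured at.
    """

    frequencies_hz: np.ndarray
    amplitudes_db: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        a = np.asarray(self.amplitudes_db, dtype=float)
        if f.ndim != 1 or f.shape != a.shape or len(f) < 2:
            raise ValueError("curve needs >= 2 (frequency, amplitude) nodes")
        if np.any(np.diff(f) <= 0):
            raise ValueError("node frequencies must be strictly increasing")
        if f[0] <= 0:
            raise ValueError("frequencies must be positive for log interpolation")
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "amplitudes_db", a)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.frequencies_hz[0]), float(self.frequencies_hz[-1])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThresholdCurve":
        df = pd.read_csv(path)
        if not {"hz", "db_spl"} <= set(df.columns):
            raise ValueError(f"{path}: need columns 'hz' and 'db_spl'")
        df = df.sort_values("hz")
        return cls(df["hz"].to_numpy(), df["db_spl"].to_numpy())


def synthetic_threshold_curve() -> ThresholdCurve:
    """Synthetic stand-in for a female behavioral response-threshold curve.

    Shaped like published cricket audiograms — most sensitive near the
    ancestral calling-song frequency (~4-5 kHz) and progressively less
    sensitive at higher frequencies — but the node values are invented.
    Use a digitized curve (CSV of hz, db_spl) for any quantitative claim
    about real receivers.
    """
    return ThresholdCurve(
        frequencies_hz=np.array([2000.0, 4000.0, 5000.0, 8000.0, 12000.0, 16000.0, 20000.0]),
        amplitudes_db=np.array([72.0, 52.0, 50.0, 58.0, 68.0, 76.0, 82.0]),
    )


def required_amplitude(frequency_hz: float, curve: ThresholdCurve) -> float:
    """Threshold amplitude at a frequency, interpolated linearly in log f."""
    lo, hi = curve.domain
    if not lo <= frequency_hz <= hi:
        raise ValueError(
            f"frequency {frequency_hz:g} Hz outside the curve's domain "
            f"[{lo:g}, {hi:g}] Hz"
        )
    return float(
        np.interp(
            np.log2(frequency_hz),
            np.log2(curve.frequencies_hz),
            curve.amplitudes_db,
        )
    )


def detectability_margin(
    dominant_frequency_hz: float, song_spl_db: float, curve: ThresholdCurve
) -> float:
    """Song SPL minus the threshold at its dominant frequency (dB).

    Positive margins predict a detectable song.
    """
    return song_spl_db - required_amplitude(dominant_frequency_hz, curve)


def threshold_difference(
    frequency_a_hz: float, frequency_b_hz: float, curve: ThresholdCurve
) -> float:
    """How much louder a song at frequency A must be than one at B (dB).

    Positive values mean frequency A sits in a less sensitive region, i.e.
    a song there needs that many more dB to be equally detectable.
    """
    return required_amplitude(frequency_a_hz, curve) - required_amplitude(
        frequency_b_hz, curve
    )


# ---------------------------------------------------------------------------
# Firth penalized logistic regression


@dataclass(frozen=True)
class FirthFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    cov: np.ndarray
    penalized_loglik: float
    iterations: int
    converged: bool
    term_names: tuple[str, ...] = ()


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    p = expit(eta)
    # guard exact 0/1 probabilities
    eps = np.finfo(float).tiny
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    w = p * (1 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(
    X, y, max_iter: int = 100, tol: float = 1e-6, term_names: tuple[str, ...] = ()
) -> FirthFit:
    """Logistic regression maximizing the Jeffreys-penalized likelihood.

    Newton iteration on the hat-value-adjusted score
    U*(b) = X' (y - p + h (1/2 - p)); estimates remain finite under
    complete separation. Step-halving keeps the penalized log-likelihood
    non-decreasing. Non-convergence is flagged, never silent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per outcome")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1 - p)
        info = X.T @ (X * w[:, None])
        info_inv = np.linalg.inv(info)
        # leverages of the weighted design
        sqw = np.sqrt(w)
        h = np.einsum("ij,jk,ik->i", X * sqw[:, None], info_inv, X * sqw[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        # step-halving on the penalized objective
        for _ in range(20):
            candidate = beta + step
            ll_new = _penalized_loglik(X, y, candidate)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll = _penalized_loglik(X, y, beta)

    p = expit(X @ beta)
    w = p * (1 - p)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    return FirthFit(
        coefficients=beta,
        standard_errors=np.sqrt(np.diag(cov)),
        cov=cov,
        penalized_loglik=ll,
        iterations=it,
        converged=converged,
        term_names=tuple(term_names) or tuple(f"b{i}" for i in range(k)),
    )


def _design_from_stimulus(stimuli: pd.Series) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(stimuli.unique())
    X = np.ones((len(stimuli), len(levels)))
    names = ["intercept"]
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (stimuli == lev).to_numpy(dtype=float)
        names.append(f"stimulus[{lev}]")
    return X, names, levels


def fit_phonotaxis(
    trials: pd.DataFrame, outcome: str = "responded"
) -> tuple[FirthFit, list[str]]:
    """Firth logistic fit of a binary phonotaxis outcome on stimulus.

    Treatment coding with the alphabetically first stimulus as reference.
    Returns the fit and the stimulus level order.
    """
    if outcome not in trials.columns:
        raise ValueError(f"trials table has no column {outcome!r}")
    X, names, levels = _design_from_stimulus(trials["stimulus"])
    y = trials[outcome].astype(float).to_numpy()
    fit = firth_logistic(X, y, term_names=tuple(names))
    return fit, levels


def pairwise_contrasts(
    fit: FirthFit, levels: list[str], holm: bool = False
) -> pd.DataFrame:
    """All pairwise log-odds differences between stimulus levels.

    Wald tests on the penalized fit; the first level is the reference of
    the treatment coding used by :func:`fit_phonotaxis`.
    """
    k = len(levels)
    if len(fit.coefficients) != k:
        raise ValueError(
            f"fit has {len(fit.coefficients)} terms but {k} levels were given"
        )
    rows = []
    for a, b in combinations(range(k), 2):
        c = np.zeros(k)
        # log-odds(level j) = intercept + beta_j (beta_0 = 0 for reference)
        if a > 0:
            c[a] += 1.0
        if b > 0:
            c[b] -= 1.0
        est = float(c @ fit.coefficients)
        se = float(np.sqrt(c @ fit.cov @ c))
        z = est / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "level_a": levels[a],
                "level_b": levels[b],
                "log_odds_diff": est,
                "se": se,
                "z": z,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if holm and len(df):
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[i])
            adj[i] = min(1.0, running)
        df["p_holm"] = adj
    return df
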