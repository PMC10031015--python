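"""Signal processing and statistics for gait-curve comparison.

Covers the whole measured-vs-predicted comparison chain: zero-phase
Butterworth filtering of kinetic signals, gait-event detection from
vertical-force thresholds, time normalization to the 0-100% gait cycle,
RMSD / Pearson correlation (with the conventional category bands) /
cross-correlation metrics, representative-trial selection, alignment of
wrenches with the walking direction, and one-dimensional statistical
parametric mapping (SPM) with nonparametric sign-flip permutation
inference for paired comparisons of whole curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .dynamics import Wrench

__all__ = [
    "GaitEvents",
    "ComparisonMetrics",
    "SPMResult",
    "butterworth_filter",
    "detect_events",
    "time_normalize",
    "rmsd",
    "pcc_and_category",
    "pcc_category",
    "xcorr_lag",
    "spm_paired_ttest",
    "representative_trial",
    "align_to_gait_frame",
]

GC_SAMPLES = 101  # 0..100% gait cycle


def butterworth_filter(series: np.ndarray, rate: float, cutoff: float = 12.0,
                       order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    Defaults follow the conventional treatment of ground reaction signals:
    second order, 12 Hz cut-off.  Constant signals pass unchanged (DC gain 1).
    """
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate / 2} Hz)")
    b, a = butter(order, cutoff / (rate / 2.0))
    return filtfilt(b, a, np.asarray(series, float), axis=0)


@dataclass
class GaitEvents:
    """Initial-contact and toe-off times (s) for one foot."""

    ic_times: np.ndarray
    to_times: np.ndarray

    def stance_windows(self) -> list[tuple[float, float]]:
        """(IC, next TO) pairs; alternation is enforced at detection."""
        out = []
        for ic in self.ic_times:
            later = self.to_times[self.to_times > ic]
            if len(later):
                out.append((float(ic), float(later[0])))
        return out

    def cycles(self) -> list[tuple[float, float]]:
        """(IC, next ipsilateral IC) windows."""
        return [(float(a), float(b)) for a, b in zip(self.ic_times[:-1], self.ic_times[1:])]


def detect_events(vertical_force: np.ndarray, rate: float,
                  threshold: float = 20.0, min_gap: float = 0.05) -> GaitEvents:
    """Detect IC/TO from a vertical-force series via threshold crossings.

    Initial contact at upward crossings of ``threshold`` (in N, not
    mass-normalized), toe-off at downward crossings.  Pairs of opposite
    crossings closer than ``min_gap`` seconds are treated as chatter and
    removed.  Warns and returns empty events if the series never exceeds
    the threshold.
    """
    f = np.asarray(vertical_force, float)
    t = np.arange(len(f)) / rate
    if not np.any(f > threshold):
        warnings.warn("vertical force never exceeds the event threshold", stacklevel=2)
        return GaitEvents(np.array([]), np.array([]))
    up = np.flatnonzero((f[:-1] < threshold) & (f[1:] >= threshold))
    dn = np.flatnonzero((f[:-1] >= threshold) & (f[1:] < threshold))
    events = sorted([(t[i + 1], "ic") for i in up] + [(t[i + 1], "to") for i in dn])
    kept: list[tuple[float, str]] = []
    for ev in events:
        if kept and ev[0] - kept[-1][0] < min_gap and ev[1] != kept[-1][1]:
            kept.pop()  # chatter: cancel the previous opposite crossing
        else:
            kept.append(ev)
    return GaitEvents(np.array([e[0] for e in kept if e[1] == "ic"]),
                      np.array([e[0] for e in kept if e[1] == "to"]))


def time_normalize(series: np.ndarray, time: np.ndarray, ic_time: float,
                   next_ic_time: float, n_samples: int = GC_SAMPLES) -> np.ndarray:
    """Resample one gait cycle (foot-strike to foot-strike) to 101 points."""
    if not next_ic_time > ic_time:
        raise ValueError("next_ic_time must be after ic_time")
    if ic_time < time[0] - 1e-12 or next_ic_time > time[-1] + 1e-12:
        raise ValueError("cycle window lies outside the series")
    grid = np.linspace(ic_time, next_ic_time, n_samples)
    series = np.asarray(series, float)
    if series.ndim == 1:
        return np.interp(grid, time, series)
    return np.stack([np.interp(grid, time, series[:, k])
                     for k in range(series.shape[1])], axis=1)


@dataclass
class ComparisonMetrics:
    """Curve-pair agreement metrics on a normalized gait cycle."""

    rmsd_abs: float
    rmsd_pct_max: float           # % of the reference curve's max |value|
    pcc: float
    pcc_category: str
    xcorr_max: float
    xcorr_lag_pct: float          # % gait cycle
    flags: tuple[str, ...] = ()


def rmsd(reference: np.ndarray, other: np.ndarray) -> tuple[float, float]:
    """Root-mean-square deviation, absolute and as % of the reference maximum.

    The first argument is the reference (measured) curve; its maximum
    absolute value is the denominator of the percentage.  A zero reference
    maximum leaves the percentage undefined (NaN) with a warning.
    """
    a = np.asarray(reference, float)
    b = np.asarray(other, float)
    if a.shape != b.shape:
        raise ValueError("curves must have identical shape")
    abs_val = float(np.sqrt(np.mean((a - b) ** 2)))
    denom = float(np.max(np.abs(a)))
    if denom == 0.0:
        warnings.warn("reference curve is identically zero; %max undefined",
                      stacklevel=2)
        return abs_val, float("nan")
    return abs_val, 100.0 * abs_val / denom


#: Pearson correlation category bands (upper bound inclusive).
PCC_CATEGORIES = (("weak", 0.35), ("moderate", 0.67), ("strong", 0.90),
                  ("excellent", 1.0))


def pcc_category(r: float) -> str:
    """Qualitative band for a Pearson correlation.

    weak <= 0.35 < moderate <= 0.67 < strong <= 0.90 < excellent; boundary
    values belong to the lower band.
    """
    for name, hi in PCC_CATEGORIES:
        if r <= hi:
            return name
    return "excellent"


def pcc_and_category(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Pearson correlation and its conventional qualitative category.

    weak <= 0.35 < moderate <= 0.67 < strong <= 0.90 < excellent.
    Negative correlations fall in the lowest band.  Zero-variance input is
    flagged as undefined.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero-variance input; correlation undefined", stacklevel=2)
        return float("nan"), "undefined"
    r = float(np.corrcoef(a, b)[0, 1])
    return r, pcc_category(r)


def xcorr_lag(a: np.ndarray, b: np.ndarray, max_lag_pct: float = 25.0
              ) -> tuple[float, float]:
    """Maximum normalized circular cross-correlation and its lag in % GC.

    Positive lag means ``b`` is delayed relative to ``a`` (b ~ a shifted
    right).  Ties are broken toward the smallest absolute lag.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("curves must be 1-D with identical length")
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero-variance input; cross-correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    n = len(a)
    pct_per_sample = 100.0 / (n - 1)
    max_lag = int(round(max_lag_pct / pct_per_sample))
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.array([np.mean(np.roll(az, lag) * bz) for lag in lags])
    best = np.flatnonzero(vals == vals.max())
    lag = lags[best[np.argmin(np.abs(lags[best]))]]
    return float(vals.max()), float(lag * pct_per_sample)


def compare_curves(reference: np.ndarray, other: np.ndarray) -> ComparisonMetrics:
    """All pairwise metrics for one normalized curve pair."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        abs_val, pct = rmsd(reference, other)
        r, cat = pcc_and_category(reference, other)
        xmax, xlag = xcorr_lag(reference, other)
    flags = tuple(str(w.message) for w in caught)
    return ComparisonMetrics(abs_val, pct, r, cat, xmax, xlag, flags)


# --- statistical parametric mapping -------------------------------------------

@dataclass
class SPMResult:
    """Paired SPM{t} over the gait cycle with permutation inference."""

    t_curve: np.ndarray                       # (101,)
    critical_threshold: float
    clusters: list[tuple[float, float, float]]  # (start %, end %, p-value)
    alpha: float
    n_permutations: int


def spm_paired_ttest(group_a: np.ndarray, group_b: np.ndarray,
                     alpha: float = 0.05, n_perm: int = 10000,
                     seed: int | None = 0) -> SPMResult:
    """Paired t-test over whole 1-D curves with sign-flip permutation inference.

    ``group_a``/``group_b`` are (n_pairs, n_nodes) arrays of paired curves.
    The pointwise paired t statistic is computed at every node; family-wise
    inference uses the permutation distribution of the maximum |t| over the
    curve, from all 2^n sign flips when feasible, otherwise ``n_perm``
    random flips.  Supra-threshold clusters are maximal runs where
    |t| exceeds the (1 - alpha) quantile of that distribution; each cluster
    p-value is the permutation probability of a maximum |t| at least as
    large as the cluster's peak.
    """
    A = np.asarray(group_a, float)
    B = np.asarray(group_b, float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("groups must be paired (n_pairs, n_nodes) arrays")
    n, q = A.shape
    if n < 5:
        raise ValueError("need at least 5 pairs")
    D = A - B
    mean_sq = np.mean(D ** 2, axis=0)

    def t_from_mean(mu):
        var = (mean_sq - mu ** 2) * n / (n - 1)
        var = np.maximum(var, 1e-300)
        return mu / np.sqrt(var / n)

    t_obs = t_from_mean(D.mean(axis=0))
    if 2 ** n <= n_perm:
        bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]
        flips = np.where(bits & 1, -1.0, 1.0)
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
        flips[0] = 1.0  # include the identity
    mu_perm = (flips @ D) / n
    t_perm = t_from_mean(mu_perm)
    max_stat = np.max(np.abs(t_perm), axis=1)
    thresh = float(np.quantile(max_stat, 1.0 - alpha))

    clusters = []
    over = np.abs(t_obs) > thresh
    idx = np.flatnonzero(np.diff(np.concatenate([[0], over.astype(int), [0]])))
    pct = 100.0 / (q - 1)
    for k in range(0, len(idx), 2):
        i0, i1 = idx[k], idx[k + 1]
        peak = np.max(np.abs(t_obs[i0:i1]))
        p = float(np.mean(max_stat >= peak))
        clusters.append((i0 * pct, (i1 - 1) * pct, max(p, 1.0 / len(max_stat))))
    return SPMResult(t_obs, thresh, clusters, alpha, len(flips))


# --- trial-level helpers -------------------------------------------------------

def representative_trial(trials: list[dict[str, np.ndarray]]) -> int:
    """Index of the trial closest to the across-trial mean curves.

    Each trial is a mapping from plane/curve name to a normalized curve.
    Per plane, the across-trial mean curve is computed; each trial's RMSDs
    to those means are averaged over planes and the argmin index returned
    (ties resolve to the lowest index).
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    keys = set(trials[0])
    if any(set(tr) != keys for tr in trials):
        raise ValueError("trials must contain identical curve sets")
    means = {k: np.mean([tr[k] for tr in trials], axis=0) for k in keys}
    scores = [np.mean([rmsd(means[k], tr[k])[0] for k in sorted(keys)])
              for tr in trials]
    return int(np.argmin(scores))


def align_to_gait_frame(wrench: Wrench, pelvis_xy_displacement) -> Wrench:
    """Rotate a wrench series about the vertical axis into the gait frame.

    The walking direction is the net horizontal pelvis displacement over
    the trial; after alignment, X is the direction of progression and the
    vertical component is unchanged.
    """
    d = np.asarray(pelvis_xy_displacement, float)
    norm = np.hypot(d[0], d[1])
    if norm < 1e-9:
        raise ValueError("no net horizontal displacement; walking direction undefined")
    c, s = d[0] / norm, d[1] / norm
    R = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    return Wrench(wrench.force @ R.T, wrench.moment @ R.T, wrench.point @ R.T,
                  wrench.frame)
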