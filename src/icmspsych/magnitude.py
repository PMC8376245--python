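"""Magnitude-estimation analysis pipeline.

Preprocessing (first-block exclusion), per-electrode frequency-intensity
profiles, Friedman screening for a frequency effect with Benjamini-
Hochberg correction, amplitude/duration response fits, and the
shape-invariance and group-median tests.

Functions operate on the canonical long DataFrame produced by
:func:`icmspsych.core_io.trials_to_frame` (columns: electrode, day, block,
frequency_Hz, amplitude_uA, duration_s, response).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import ValidationError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def exclude_first_block(df: pd.DataFrame) -> pd.DataFrame:
    """Drop the first presentation block of every (electrode, day) set.

    The participant uses the first block of a session to settle on a
    rating scale, so those ratings carry a calibration bias.  The rule
    keys on the *minimum* block index within each set rather than the
    literal value 1, so it is robust to block-numbering conventions.
    A set consisting of a single block becomes empty (warning, not error).
    """
    if df.empty:
        return df.copy()
    min_block = df.groupby(["electrode", "day"])["block"].transform("min")
    n_blocks = df.groupby(["electrode", "day"])["block"].transform("nunique")
    single = df.loc[n_blocks == 1, ["electrode", "day"]].drop_duplicates()
    for row in single.itertuples(index=False):
        warnings.warn(
            f"set (electrode={row.electrode}, day={row.day}) has a single "
            "block; all its trials are excluded",
            stacklevel=2)
    return df.loc[df["block"] != min_block].copy()


def compute_profiles(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM intensity per (electrode, frequency), pooling sessions.

    Frequencies never tested on an electrode are simply absent from its
    profile (no imputation).  SEM is 0 when all responses are equal
    (including n = 1).
    """
    def sem(x: pd.Series) -> float:
        if len(x) < 2 or x.nunique() == 1:
            return 0.0
        return float(x.std(ddof=1) / math.sqrt(len(x)))

    prof = (
        df.groupby(["electrode", "frequency_Hz"])["response"]
        .agg(mean="mean", sem=sem, n="count")
        .reset_index()
    )
    return prof


# --------------------------------------------------------------------------
# Friedman test (own implementation; scipy cross-checks it in the tests)
# --------------------------------------------------------------------------

def friedman_statistic(data: np.ndarray) -> float:
    """Friedman rank statistic for an (n_blocks, k_treatments) table.

    Q = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1), with average ranks for
    ties (no tie correction applied; the screening data are continuous
    ratings where exact ties are rare).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1))


def friedman_test(data: np.ndarray, method: str = "chisq") -> tuple[float, float]:
    """Friedman test on an (n_blocks, k_treatments) table.

    ``method='chisq'`` uses the chi-square approximation with k-1 degrees
    of freedom (valid for moderate n or k).  ``method='exact'`` enumerates
    all (k!)^n equally likely within-block rank permutations and returns
    the exact tail probability P(Q >= observed); it requires
    (k!)^n <= 10^6.

    Returns ``(statistic, p_value)``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("Friedman input must be a 2-D block x treatment table")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError(
            f"Friedman test needs >= 2 blocks and >= 2 treatments, got {data.shape}")
    q = friedman_statistic(data)
    if method == "chisq":
        p = float(stats.chi2.sf(q, k - 1))
    elif method == "exact":
        n_arrangements = math.factorial(k) ** n
        if n_arrangements > 10 ** 6:
            raise ValidationError(
                f"(k!)^n = {n_arrangements} too large for exact enumeration")
        perms = list(itertools.permutations(range(1, k + 1)))
        count = 0
        scale = 12.0 / (n * k * (k + 1))
        const = 3.0 * n * (k + 1)
        for combo in itertools.product(perms, repeat=n):
            rank_sums = np.sum(combo, axis=0)
            stat = scale * float(np.sum(rank_sums ** 2)) - const
            if stat >= q - 1e-9:
                count += 1
        p = count / n_arrangements
    else:
        raise ValueError(f"unknown method {method!r}")
    return q, p


@dataclass
class ScreenResult:
    """Per-electrode Friedman screening summary (one row per electrode)."""

    table: pd.DataFrame  # electrode, statistic, p_value, n_blocks, n_dropped, significant
    critical_p: float
    alpha: float


def friedman_screen(df: pd.DataFrame, alpha: float = 0.05) -> ScreenResult:
    """Screen each electrode for a frequency effect on rated intensity.

    Blocks (pooled across days, day excluded as a cofactor) are the
    replicates and pulse frequencies the treatments.  Blocks missing any
    frequency are dropped (count logged).  Electrodes with fewer than two
    complete blocks or two frequencies are flagged (``statistic`` NaN) and
    excluded from the multiple-comparison correction and from significance
    counts.  The Benjamini-Hochberg critical p-value is applied across the
    testable electrodes.
    """
    rows = []
    for electrode, sub in df.groupby("electrode"):
        pivot = sub.pivot_table(index=["day", "block"], columns="frequency_Hz",
                                values="response", aggfunc="mean")
        complete = pivot.dropna()
        n_dropped = len(pivot) - len(complete)
        if n_dropped:
            logger.info("electrode %s: dropped %d incomplete block(s)",
                        electrode, n_dropped)
        if len(complete) < 2 or complete.shape[1] < 2:
            rows.append((electrode, np.nan, np.nan, len(complete), n_dropped))
            continue
        q, p = friedman_test(complete.to_numpy())
        rows.append((electrode, q, p, len(complete), n_dropped))
    table = pd.DataFrame(
        rows, columns=["electrode", "statistic", "p_value", "n_blocks", "n_dropped"])

    testable = table["p_value"].notna()
    mask = np.zeros(len(table), dtype=bool)
    critical = 0.0
    if testable.any():
        sub_mask, critical = bh_adjust(table.loc[testable, "p_value"].to_numpy(), alpha)
        mask[np.flatnonzero(testable)] = sub_mask
    table["significant"] = mask
    return ScreenResult(table=table, critical_p=critical, alpha=alpha)


# --------------------------------------------------------------------------
# Benjamini-Hochberg with the critical-p convention
# --------------------------------------------------------------------------

def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up returning (significance mask, critical p).

    The critical p-value is the largest sorted p(i) satisfying
    p(i) <= (i/m) * alpha; every p at or below it is significant.  When no
    p passes its threshold the critical p-value is 0 and nothing is
    significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) / m) * alpha
    passing = sorted_p <= thresholds
    if not passing.any():
        return np.zeros(m, dtype=bool), 0.0
    critical = float(sorted_p[np.flatnonzero(passing)[-1]])
    return p <= critical, critical


# --------------------------------------------------------------------------
# Amplitude / duration response fits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n: int


def _normalize_per_set(df: pd.DataFrame) -> pd.Series:
    """Divide responses by their (electrode, day) set median."""
    med = df.groupby(["electrode", "day"])["response"].transform("median")
    if (med == 0).any():
        raise ValidationError("a set has zero median response; cannot normalize")
    return df["response"] / med


def fit_amplitude_linear(df: pd.DataFrame, normalize: bool | None = None) -> LinearFit:
    """Least-squares line of rated intensity vs current amplitude.

    Used for the fixed-frequency (100 Hz, 1 s) amplitude series.  When the
    data span several (electrode, day) sets — or when ``normalize=True`` —
    responses are first divided by their set median so sets rated on
    different self-selected scales are commensurate.
    """
    if df["amplitude_uA"].nunique() < 2:
        raise ValidationError("need >= 2 distinct amplitudes for a linear fit")
    n_sets = df.groupby(["electrode", "day"]).ngroups
    if normalize is None:
        normalize = n_sets > 1
    y = _normalize_per_set(df) if normalize else df["response"]
    res = stats.linregress(df["amplitude_uA"], y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2), stderr=float(res.stderr),
                     n=len(df))


@dataclass(frozen=True)
class LogisticFit:
    asymptote: float
    midpoint: float
    rate: float
    sse: float
    n: int


class LogisticFitError(RuntimeError):
    """Raised when the duration-logistic fit fails to converge."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def _logistic3(t, asymptote, midpoint, rate):
    return asymptote / (1.0 + np.exp(-rate * (t - midpoint)))


def fit_duration_logistic(df: pd.DataFrame, n_restarts: int = 5) -> LogisticFit:
    """Fit rated intensity vs train duration with a 3-parameter logistic.

    Initialisation rule: asymptote = max response, midpoint = median
    duration, rate = 1; up to ``n_restarts`` deterministic perturbed
    restarts guard against bad starting points.  Requires >= 4 distinct
    durations.
    """
    if df["duration_s"].nunique() < 4:
        raise ValidationError("need >= 4 distinct durations for a logistic fit")
    n_sets = df.groupby(["electrode", "day"]).ngroups if {
        "electrode", "day"}.issubset(df.columns) else 1
    y = (_normalize_per_set(df) if n_sets > 1 else df["response"]).to_numpy(float)
    t = df["duration_s"].to_numpy(float)

    p0_base = np.array([max(y.max(), 1e-6), float(np.median(t)), 1.0])
    # deterministic perturbation ladder, no RNG involved
    factors = [1.0, 0.5, 2.0, 0.25, 4.0][: n_restarts + 1]
    best = None
    failures = []
    for fac in factors:
        p0 = p0_base * np.array([1.0, 1.0, fac])
        try:
            popt, _ = optimize.curve_fit(
                _logistic3, t, y, p0=p0,
                bounds=([1e-9, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10000)
            sse = float(np.sum((_logistic3(t, *popt) - y) ** 2))
            if best is None or sse < best[1]:
                best = (popt, sse)
        except RuntimeError as exc:
            failures.append(str(exc))
    if best is None:
        raise LogisticFitError(
            "logistic fit failed to converge from all starting points",
            diagnostics={"failures": failures, "p0": p0_base.tolist()})
    popt, sse = best
    return LogisticFit(asymptote=float(popt[0]), midpoint=float(popt[1]),
                       rate=float(popt[2]), sse=sse, n=len(df))


# --------------------------------------------------------------------------
# Shape invariance across amplitudes
# --------------------------------------------------------------------------

def shape_invariance_test(df: pd.DataFrame) -> tuple[float, float]:
    """Test whether the frequency-intensity *shape* changes with amplitude.

    Each amplitude condition's responses are divided by that condition's
    median, which removes a pure gain change.  What remains of a shape
    difference is an amplitude x frequency interaction, tested with a
    Friedman test on the within-replicate condition differences: for each
    (frequency, replicate) pair the normalized response at the higher
    amplitude is subtracted from that at the lower (replicates are matched
    by presentation order within each frequency x amplitude cell), and the
    differences enter a Friedman test with replicates as blocks and
    frequencies as treatments.  A shape-invariant (pure gain) change makes
    the differences exchangeable across frequencies (high p); a peak that
    moves with amplitude makes them frequency-dependent (low p).  Exactly
    two amplitude conditions are compared, matching the pairwise use of
    the analysis; compare several amplitudes pairwise.

    Returns ``(statistic, p_value)``.
    """
    amps = sorted(df["amplitude_uA"].unique())
    if len(amps) != 2:
        raise ValidationError(
            f"exactly 2 amplitude conditions required, got {len(amps)}; "
            "compare multiple amplitudes pairwise")
    norm = df.copy()
    for amp in amps:
        sel = norm["amplitude_uA"] == amp
        med = norm.loc[sel, "response"].median()
        if med == 0:
            raise ValidationError(f"zero median response at {amp} µA")
        norm.loc[sel, "response"] = norm.loc[sel, "response"] / med
    norm["replicate"] = norm.groupby(["frequency_Hz", "amplitude_uA"]).cumcount()
    pivot = norm.pivot_table(index=["frequency_Hz", "replicate"],
                             columns="amplitude_uA", values="response").dropna()
    diffs = (pivot[amps[0]] - pivot[amps[1]]).unstack("frequency_Hz").dropna()
    if diffs.shape[0] < 2 or diffs.shape[1] < 2:
        raise ValidationError(
            "need >= 2 replicates and >= 2 shared frequencies across amplitudes")
    return friedman_test(diffs.to_numpy())


# --------------------------------------------------------------------------
# Group median comparison
# --------------------------------------------------------------------------

@dataclass
class GroupMedianResult:
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None  # pairwise Tukey HSD on ranks, if significant


def group_median_test(df: pd.DataFrame, labels: dict[int, str],
                      alpha: float = 0.05) -> GroupMedianResult:
    """Kruskal-Wallis across category groups on per-trial intensities.

    When the omnibus test is significant, a Tukey HSD post-hoc is run on
    the rank-transformed responses (rank transform keeps the post-hoc
    consistent with the non-parametric omnibus test).
    """
    df = df.copy()
    df["category"] = df["electrode"].map(labels)
    groups = {cat: sub["response"].to_numpy()
              for cat, sub in df.groupby("category")}
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for cat, vals in groups.items():
        if len(vals) == 0:
            raise ValidationError(f"group {cat} has no trials")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # identical constant data: H statistic is 0 by definition
        return GroupMedianResult(statistic=0.0, p_value=1.0, posthoc=None)
    stat, p = stats.kruskal(*arrays)

    posthoc = None
    if p < alpha:
        all_ranks = stats.rankdata(np.concatenate(arrays))
        split = np.split(all_ranks, np.cumsum([len(a) for a in arrays])[:-1])
        res = stats.tukey_hsd(*split)
        names = list(groups.keys())
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append((names[i], names[j], float(res.pvalue[i, j])))
        posthoc = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value"])
    return GroupMedianResult(statistic=float(stat), p_value=float(p), posthoc=posthoc)


# --------------------------------------------------------------------------
# Normality gate
# --------------------------------------------------------------------------

def is_normal_anderson(x, alpha: float = 0.05) -> bool:
    """Anderson-Darling normality gate deciding parametric vs rank tests.

    Returns True when normality is *not* rejected at the given level.
    The gate outcome is logged so analysis reports can state which branch
    was taken.
    """
    x = np.asarray(x, dtype=float)
    with warnings.catch_warnings():
        # critical-value tables are the classical decision rule used here
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float)
    idx = int(np.argmin(np.abs(levels - alpha * 100)))
    normal = bool(res.statistic < res.critical_values[idx])
    logger.info("Anderson-Darling gate: statistic=%.4f critical=%.4f -> %s",
                res.statistic, res.critical_values[idx],
                "parametric" if normal else "non-parametric")
    return normal
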