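"""Synthetic participants for the ICMS psychophysics pipeline.

Generates datasets with the statistical structure the analysis assumes:

* per-category frequency-intensity archetypes with block/session structure,
  multiplicative log-normal rating noise and a first-block calibration
  bias (an additive offset on the first block of every session, emulating
  the participant settling on a rating scale);
* spatially clustered category labels on two 6 x 10 arrays with a 32-site
  wired mask (Potts-style label-swap Gibbs sampling with clustering
  strength ``theta``);
* multinomial percept-quality reports conditioned on category x frequency;
* psychometric 2AFC observers whose detection thresholds depend on pulse
  frequency (higher pulse frequencies are detectable at lower amplitudes).

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    CATEGORIES,
    GRID_COLS,
    GRID_ROWS,
    ArrayGridMap,
    MagnitudeTrial,
    QualityCountTable,
    StimulusTrain,
    ValidationError,
)

import pandas as pd

#: The nine pulse frequencies of the standard frequency series (Hz).
STANDARD_FREQUENCIES = (20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0, 250.0, 300.0)

#: The three frequencies used for clustering features and surveys (Hz).
FEATURE_FREQUENCIES = (20.0, 100.0, 300.0)


# --------------------------------------------------------------------------
# Category archetypes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryArchetype:
    """Frequency-intensity response archetype for one electrode category.

    ``knots`` gives the mean intensity rating (self-selected scale, 60 µA,
    1 s train) at each tested frequency; intensities at other frequencies
    are piecewise-linear interpolations.  Amplitude scales the response
    linearly (gain per µA relative to the 60 µA reference); train duration
    scales it through a saturating logistic normalised to 1 at a 1 s train.
    """

    category: str
    knots: Mapping[float, float]
    amplitude_gain_per_uA: float = 0.01
    duration_midpoint_s: float = 0.4
    duration_rate: float = 4.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if any(v < 0 for v in self.knots.values()):
            raise ValidationError("archetype intensities must be non-negative")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array(sorted(self.knots), dtype=float)

    def mean_intensity(self, frequency_Hz) -> np.ndarray | float:
        """Piecewise-linear mean intensity at the reference condition."""
        freqs = self.frequencies
        vals = np.array([self.knots[f] for f in freqs])
        return np.interp(frequency_Hz, freqs, vals)

    def amplitude_scale(self, amplitude_uA: float) -> float:
        """Linear amplitude scaling, = 1 at the 60 µA reference."""
        return max(0.0, 1.0 + self.amplitude_gain_per_uA * (amplitude_uA - 60.0))

    def duration_scale(self, duration_s: float) -> float:
        """Saturating logistic duration scaling, = 1 at a 1 s train."""
        def raw(d):
            return 1.0 / (1.0 + math.exp(-self.duration_rate * (d - self.duration_midpoint_s)))
        return raw(duration_s) / raw(1.0)

    def expected_response(self, frequency_Hz: float, amplitude_uA: float = 60.0,
                          duration_s: float = 1.0) -> float:
        return (float(self.mean_intensity(frequency_Hz))
                * self.amplitude_scale(amplitude_uA)
                * self.duration_scale(duration_s))

    @property
    def overall_median(self) -> float:
        return float(np.median([self.knots[f] for f in sorted(self.knots)]))

    @property
    def peak_frequency(self) -> float:
        freqs = self.frequencies
        vals = np.array([self.knots[f] for f in freqs])
        return float(freqs[int(np.argmax(vals))])


def default_archetypes() -> dict[str, CategoryArchetype]:
    """Default archetypes on the 0-4 self-selected rating scale.

    LFP peaks at low frequency (<= 100 Hz) and declines with frequency;
    IFP peaks between 40 and 100 Hz and has the highest overall median;
    HFP rises monotonically to a 300 Hz peak and has the lowest overall
    median (HFP percepts are faintest overall).
    """
    f = STANDARD_FREQUENCIES
    return {
        "LFP": CategoryArchetype(
            "LFP", dict(zip(f, (3.0, 2.8, 2.5, 2.2, 2.0, 1.5, 1.2, 1.0, 0.8)))),
        "IFP": CategoryArchetype(
            "IFP", dict(zip(f, (2.0, 3.0, 3.4, 3.5, 3.3, 2.6, 2.2, 2.0, 1.8)))),
        "HFP": CategoryArchetype(
            "HFP", dict(zip(f, (0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.3, 1.6, 2.0)))),
    }


def validate_archetypes(archetypes: Mapping[str, CategoryArchetype]) -> None:
    """Check the qualitative constraints the categories are defined by.

    LFP peak <= 100 Hz; IFP peak in [40, 100] Hz with the highest overall
    median; HFP peak at the top frequency with the lowest overall median.
    """
    lfp, ifp, hfp = archetypes["LFP"], archetypes["IFP"], archetypes["HFP"]
    if lfp.peak_frequency > 100.0:
        raise ValidationError("LFP archetype must peak at <= 100 Hz")
    if not (40.0 <= ifp.peak_frequency <= 100.0):
        raise ValidationError("IFP archetype must peak in [40, 100] Hz")
    if hfp.peak_frequency != max(hfp.frequencies):
        raise ValidationError("HFP archetype must peak at the highest frequency")
    medians = {c: a.overall_median for c, a in archetypes.items()}
    if not (medians["IFP"] > medians["LFP"] > medians["HFP"]):
        raise ValidationError(
            f"median ordering must be IFP > LFP > HFP, got {medians}")


# --------------------------------------------------------------------------
# Psychometric 2AFC observer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricObserver:
    """Stationary 2AFC observer with a logistic psychometric function in dB.

    ``threshold_uA`` is anchored so that P(correct) at the threshold equals
    0.5^(1/3) ~ 0.794, the convergence point of a 1-up-3-down staircase.
    ``slope`` is the logistic rate per dB of amplitude.
    """

    threshold_uA: float
    slope: float = 1.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.0

    CONVERGENCE_P = 0.5 ** (1.0 / 3.0)  # ~0.7937

    def __post_init__(self) -> None:
        if self.threshold_uA <= 0:
            raise ValidationError("threshold must be positive")
        if self.slope <= 0:
            raise ValidationError("slope must be positive")
        if not (0 <= self.lapse_rate < 0.1):
            raise ValidationError("lapse rate must be in [0, 0.1)")
        p_max = 1.0 - self.lapse_rate
        if self.CONVERGENCE_P >= p_max:
            raise ValidationError("lapse rate too high to reach 79.4% correct")

    def p_correct(self, amplitude_uA: float) -> float:
        """Probability of a correct 2AFC response at a given amplitude."""
        if amplitude_uA <= 0:
            return self.guess_rate
        span = 1.0 - self.guess_rate - self.lapse_rate
        # inner-function value needed at threshold for P = 0.794 overall
        f_star = (self.CONVERGENCE_P - self.guess_rate) / span
        offset = math.log(f_star / (1.0 - f_star)) / self.slope
        x_db = 20.0 * math.log10(amplitude_uA / self.threshold_uA)
        f = 1.0 / (1.0 + math.exp(-self.slope * (x_db + offset)))
        return self.guess_rate + span * f


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def default_quality_probabilities() -> dict[tuple[str, float, str], float]:
    """Per-(category, frequency, quality) report probabilities.

    Encodes the qualitative survey patterns: at 20 Hz the low- and
    intermediate-preferring electrodes evoke pressure / tapping / touch /
    sparkle percepts, which the high-preferring electrodes never do at any
    frequency; at 100-300 Hz the intermediate group reports buzzing,
    vibration and sharp, while the high group reports electrical / prick
    percepts; pressure reports fade at 300 Hz.
    """
    p: dict[tuple[str, float, str], float] = {}
    table = {
        ("LFP", 20.0): {"pressure": 0.50, "touch": 0.40, "tapping": 0.30, "sparkle": 0.10},
        ("LFP", 100.0): {"pressure": 0.40, "touch": 0.30, "tapping": 0.15, "warm": 0.10},
        ("LFP", 300.0): {"pressure": 0.10, "touch": 0.25, "electrical": 0.15},
        ("IFP", 20.0): {"pressure": 0.50, "touch": 0.40, "tapping": 0.25, "sparkle": 0.15},
        ("IFP", 100.0): {"buzzing": 0.40, "vibration": 0.45, "sharp": 0.20, "pressure": 0.30},
        ("IFP", 300.0): {"buzzing": 0.30, "vibration": 0.40, "sharp": 0.20, "pressure": 0.08},
        # HFP percepts are faint at 20 Hz (mostly undetectable) and carry
        # electrical/prick qualities at higher frequencies; pressure and
        # tapping stay at zero across all frequencies.
        ("HFP", 20.0): {"electrical": 0.05},
        ("HFP", 100.0): {"electrical": 0.30, "prick": 0.20, "touch": 0.25},
        ("HFP", 300.0): {"electrical": 0.35, "prick": 0.20, "touch": 0.25, "vibration": 0.10},
    }
    for (cat, freq), quals in table.items():
        for q, prob in quals.items():
            p[(cat, freq, q)] = prob
    return p


def default_frequency_thresholds() -> dict[float, float]:
    """Default detection thresholds (µA) per pulse frequency.

    Decreasing with frequency: higher pulse frequencies evoke detectable
    percepts at lower current amplitudes.  At the standard test amplitude
    (1.2 x the 100 Hz threshold) the 20 Hz condition sits far below its
    own threshold (near chance) while 300 Hz sits well above.
    """
    return {20.0: 60.0, 100.0: 15.0, 300.0: 11.0}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic participant.

    ``noise_sd`` is the standard deviation of the multiplicative log-normal
    rating noise (free magnitude estimation is a ratio scale, so noise is
    multiplicative and ratings stay non-negative).  ``first_block_bias`` is
    an additive offset on every rating in the first block of a session,
    which the first-block exclusion rule must neutralise.
    """

    n_electrodes_per_category: int = 10
    noise_sd: float = 0.2
    first_block_bias: float = 0.5
    clustering_strength: float = 2.0
    archetypes: dict[str, CategoryArchetype] = field(default_factory=default_archetypes)
    quality_probabilities: dict[tuple[str, float, str], float] = field(
        default_factory=default_quality_probabilities)
    frequency_thresholds: dict[float, float] = field(
        default_factory=default_frequency_thresholds)
    observer_slope: float = 1.0
    observer_lapse: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        for key, prob in self.quality_probabilities.items():
            if not (0.0 <= prob <= 1.0):
                raise ValidationError(f"probability {prob} at {key} outside [0, 1]")
        if self.clustering_strength < 0:
            raise ValidationError("clustering strength must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MagnitudeDesign:
    """One magnitude-estimation session design.

    Every block presents each frequency once (order randomised per block);
    each electrode runs ``n_blocks`` blocks per session over ``n_sessions``
    sessions.
    """

    frequencies: tuple[float, ...] = STANDARD_FREQUENCIES
    amplitude_uA: float = 60.0
    duration_s: float = 1.0
    n_blocks: int = 6
    n_sessions: int = 1

    def __post_init__(self) -> None:
        for f in self.frequencies:
            if not (20.0 <= f <= 300.0):
                raise ValidationError(f"design frequency {f} Hz outside [20, 300]")


# --------------------------------------------------------------------------
# Grid / category-map generation
# --------------------------------------------------------------------------

def make_standard_grid(n_arrays: int = 2) -> ArrayGridMap:
    """The default two-array layout: 32 wired, all tested, per 6 x 10 array.

    The wired mask is a fixed contiguous 4 x 8 block per array (real array
    wiring is hardware-determined; a connected block keeps the adjacency
    graph non-trivial).
    """
    wired = np.zeros((n_arrays, GRID_ROWS, GRID_COLS), dtype=bool)
    wired[:, 0:4, 0:8] = True
    category = np.full(wired.shape, None, dtype=object)
    return ArrayGridMap(wired=wired, category=category)


def _site_neighbors(sites: list[tuple[int, int, int]]) -> list[list[int]]:
    """Rook-adjacency neighbour indices among the given sites."""
    index = {s: i for i, s in enumerate(sites)}
    neighbors: list[list[int]] = [[] for _ in sites]
    for (a, r, c), i in index.items():
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            j = index.get((a, r + dr, c + dc))
            if j is not None:
                neighbors[i].append(j)
    return neighbors


def gen_category_map(
    grid: ArrayGridMap,
    counts: Mapping[str, int],
    theta: float = 0.0,
    seed: int | np.random.Generator | None = None,
    n_sweeps: int = 60,
) -> ArrayGridMap:
    """Place category labels on the tested sites with tunable clustering.

    ``theta = 0`` places the label multiset as a uniform random
    permutation.  For ``theta > 0`` the permutation is annealed by
    Metropolis label-swap sweeps with acceptance
    ``min(1, exp(theta * delta_same_edges))`` (a fixed-composition Potts
    model), so larger ``theta`` yields more same-category adjacency while
    category counts stay exactly as requested.
    """
    rng = np.random.default_rng(seed)
    sites = grid.tested_sites()
    total = sum(counts.values())
    if total != len(sites):
        raise ValidationError(
            f"label counts sum to {total} but grid has {len(sites)} tested sites")
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown categories in counts: {sorted(unknown)}")

    labels = np.array(
        [cat for cat, n in sorted(counts.items()) for _ in range(n)], dtype=object)
    rng.shuffle(labels)

    if theta > 0 and len(sites) > 1:
        neighbors = _site_neighbors(sites)

        def local_same(i: int, lab: np.ndarray) -> int:
            return sum(1 for j in neighbors[i] if lab[j] == lab[i])

        n = len(sites)
        for _ in range(n_sweeps):
            pairs = rng.integers(0, n, size=(n, 2))
            for i, j in pairs:
                if labels[i] == labels[j]:
                    continue
                before = local_same(i, labels) + local_same(j, labels)
                labels[i], labels[j] = labels[j], labels[i]
                after = local_same(i, labels) + local_same(j, labels)
                delta = after - before
                if delta < 0 and rng.random() >= math.exp(theta * delta):
                    labels[i], labels[j] = labels[j], labels[i]  # reject

    out = grid.copy()
    for site, lab in zip(sites, labels):
        out.category[site] = lab
    return out


# --------------------------------------------------------------------------
# Magnitude-estimation dataset generation
# --------------------------------------------------------------------------

def gen_magnitude_dataset(
    cfg: SyntheticConfig,
    design: MagnitudeDesign | None = None,
    seed: int | np.random.Generator | None = None,
    labels: Mapping[int, str] | None = None,
) -> tuple[list[MagnitudeTrial], dict[int, str]]:
    """Generate magnitude-estimation trials plus ground-truth labels.

    Each electrode's rating is
    ``archetype_mean(f) * amplitude_scale * duration_scale * exp(noise)``
    with ``noise ~ N(0, noise_sd)``, plus ``first_block_bias`` on every
    trial of a session's first block.  Frequency order is randomised
    within each block.

    Returns the trial list and a ``{electrode_id: category}`` dict.
    """
    design = design or MagnitudeDesign()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)

    if labels is None:
        labels = {}
        eid = 0
        for cat in CATEGORIES:
            for _ in range(cfg.n_electrodes_per_category):
                labels[eid] = cat
                eid += 1
    unknown = set(labels.values()) - set(CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown categories in ground truth: {sorted(unknown)}")

    trials: list[MagnitudeTrial] = []
    for electrode, cat in labels.items():
        arch = cfg.archetypes[cat]
        for session in range(design.n_sessions):
            day = 100 + 7 * session
            for block in range(1, design.n_blocks + 1):
                order = rng.permutation(len(design.frequencies))
                for k in order:
                    f = design.frequencies[k]
                    mean = arch.expected_response(
                        f, design.amplitude_uA, design.duration_s)
                    noise = math.exp(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 1.0
                    response = mean * noise
                    if block == 1:
                        response += cfg.first_block_bias
                    trials.append(MagnitudeTrial(
                        electrode_id=electrode, day=day, block=block,
                        stimulus=StimulusTrain(design.amplitude_uA, f, design.duration_s),
                        response=response))
    return trials, dict(labels)


# --------------------------------------------------------------------------
# Quality-report generation
# --------------------------------------------------------------------------

def gen_quality_dataset(
    cfg: SyntheticConfig,
    n_stimulations: Mapping[tuple[str, float], int],
    seed: int | np.random.Generator | None = None,
) -> QualityCountTable:
    """Binomial quality counts per (category, frequency) cell.

    Each quality's report count is Binomial(n_stimulations, p) with p from
    the configured probability table (qualities absent from the table have
    p = 0 and are stored as zero counts).
    """
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    qualities = sorted({q for (_, _, q) in cfg.quality_probabilities})
    reports: dict[tuple[str, float, str], int] = {}
    stims: dict[tuple[str, float], int] = {}
    for (cat, freq), n in n_stimulations.items():
        if n < 0:
            raise ValidationError("stimulation count must be >= 0")
        stims[(cat, float(freq))] = int(n)
        for q in qualities:
            p = cfg.quality_probabilities.get((cat, float(freq), q), 0.0)
            count = int(rng.binomial(n, p)) if n > 0 else 0
            reports[(cat, float(freq), q)] = count
    rep = pd.Series(reports)
    rep.index = pd.MultiIndex.from_tuples(rep.index)
    st = pd.Series(stims)
    st.index = pd.MultiIndex.from_tuples(st.index)
    return QualityCountTable(rep, st)


def gen_electrode_quality_counts(
    cfg: SyntheticConfig,
    labels: Mapping[int, str],
    n_per_frequency: int = 20,
    frequencies: Sequence[float] = FEATURE_FREQUENCIES,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-electrode quality report counts (rows = electrodes, cols = qualities).

    Each electrode receives ``n_per_frequency`` stimulations at each survey
    frequency; counts are summed over frequencies.  This is the input to
    quality-based electrode clustering.
    """
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    qualities = sorted({q for (_, _, q) in cfg.quality_probabilities})
    rows = {}
    for electrode, cat in labels.items():
        counts = np.zeros(len(qualities), dtype=int)
        for f in frequencies:
            for qi, q in enumerate(qualities):
                p = cfg.quality_probabilities.get((cat, float(f), q), 0.0)
                counts[qi] += rng.binomial(n_per_frequency, p)
        rows[electrode] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=qualities)
    df.index.name = "electrode"
    return df.sort_index()


# --------------------------------------------------------------------------
# Observer factory
# --------------------------------------------------------------------------

def gen_observer(frequency_Hz: float, cfg: SyntheticConfig) -> PsychometricObserver:
    """Observer for one pulse frequency, from the configured threshold map."""
    thr = cfg.frequency_thresholds.get(float(frequency_Hz))
    if thr is None:
        raise ValidationError(
            f"no threshold configured for {frequency_Hz} Hz "
            f"(mapped: {sorted(cfg.frequency_thresholds)})")
    return PsychometricObserver(
        threshold_uA=thr, slope=cfg.observer_slope, lapse_rate=cfg.observer_lapse)
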