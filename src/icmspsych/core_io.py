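"""Domain types and tabular I/O for ICMS psychophysics datasets.

The data model follows a human somatosensory neural-interface study in
which charge-balanced biphasic pulse trains are delivered through
penetrating microelectrodes on two 6 x 10 arrays (32 wired sites each).
Three kinds of behavioural records are handled:

* magnitude-estimation trials — free numeric intensity ratings of single
  stimulus trains, organised in randomised presentation blocks;
* percept-quality count tables — how often each quality descriptor
  (pressure, vibration, ...) was reported per electrode category and
  pulse frequency, together with the number of stimulations delivered;
* 2AFC detection trials — which of two intervals contained the stimulus.

All tabular formats are plain CSV (comma-separated, UTF-8, header row
mandatory for long tables).  Grid maps are headerless CSV with one 6 x 10
block of cells per array, stacked vertically; empty/'NaN' cells mark
unwired sites.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Vocabulary and constants
# --------------------------------------------------------------------------

#: Frequency-preference category labels: low / intermediate / high preferring.
CATEGORIES = ("LFP", "IFP", "HFP")

#: Marker for a wired electrode that was never tested behaviourally.
UNTESTED = "untested"

#: Marker (in memory: ``None`` on a wired site) for a tested site whose
#: category has not been assigned yet.  Used by the grid-map CSV format.
UNASSIGNED = "unassigned"

#: Full percept-quality descriptor vocabulary, including the four
#: participant-coined descriptors (tapping, buzzing, prick, sparkle).
QUALITY_VOCABULARY = (
    "touch", "pressure", "sharp",
    "vibration", "movement-across-skin",
    "warm", "cool",
    "electrical", "tickle", "itch",
    "tapping", "buzzing", "prick", "sparkle",
)

GRID_ROWS = 6
GRID_COLS = 10
WIRED_PER_ARRAY = 32

#: Stimulator hard limits (µA) and tested pulse-frequency range (Hz).
AMPLITUDE_RANGE_UA = (2.0, 100.0)
FREQUENCY_RANGE_HZ = (20.0, 300.0)

#: Row label used for the stimulation-count row in quality-count files.
STIMULATION_ROW = "stimulations"


class SchemaError(ValueError):
    """A required column or structural element is missing from a file."""


class ValidationError(ValueError):
    """A value violates a domain invariant (with cell/row context)."""


class ShapeError(ValueError):
    """A grid block does not have the expected 6 x 10 shape."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusTrain:
    """One biphasic, cathodal-first, charge-balanced pulse train.

    The pulse shape is fixed by the stimulator protocol: 200 µs cathodal
    phase, 100 µs interphase gap, 400 µs anodal phase at half the cathodal
    amplitude, so that cathodal and anodal phases carry equal charge.
    """

    amplitude_uA: float
    frequency_Hz: float
    duration_s: float = 1.0

    CATHODAL_WIDTH_US = 200.0
    INTERPHASE_US = 100.0
    ANODAL_WIDTH_US = 400.0

    def __post_init__(self) -> None:
        lo, hi = AMPLITUDE_RANGE_UA
        if not (lo <= self.amplitude_uA <= hi):
            raise ValidationError(
                f"amplitude {self.amplitude_uA} µA outside [{lo}, {hi}] µA"
            )
        flo, fhi = FREQUENCY_RANGE_HZ
        if not (flo <= self.frequency_Hz <= fhi):
            raise ValidationError(
                f"frequency {self.frequency_Hz} Hz outside [{flo}, {fhi}] Hz"
            )
        if not self.duration_s > 0:
            raise ValidationError(f"duration {self.duration_s} s must be > 0")

    @property
    def anodal_amplitude_uA(self) -> float:
        """Anodal amplitude is half the cathodal amplitude (charge balance)."""
        return self.amplitude_uA / 2.0

    @property
    def charge_balanced(self) -> bool:
        cathodal = self.CATHODAL_WIDTH_US * self.amplitude_uA
        anodal = self.ANODAL_WIDTH_US * self.anodal_amplitude_uA
        return np.isclose(cathodal, anodal)


@dataclass(frozen=True)
class MagnitudeTrial:
    """A single free-magnitude-estimation rating of one stimulus train."""

    electrode_id: int
    day: int
    block: int
    stimulus: StimulusTrain
    response: float

    def __post_init__(self) -> None:
        if self.response < 0:
            raise ValidationError(
                f"response {self.response} must be non-negative"
            )
        if self.block < 1:
            raise ValidationError(f"block {self.block} must be >= 1")


@dataclass(frozen=True)
class QualityReport:
    """One verbal percept-quality report for a stimulus on one electrode."""

    electrode_id: int
    frequency_Hz: float
    qualities: tuple[str, ...]
    naturalness: int | None = None
    pain: int | None = None
    depth: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.qualities) - set(QUALITY_VOCABULARY)
        if unknown:
            raise ValidationError(f"unknown quality descriptors: {sorted(unknown)}")
        if self.naturalness is not None and not (1 <= self.naturalness <= 5):
            raise ValidationError("naturalness must be in 1..5")
        if self.pain is not None and not (0 <= self.pain <= 10):
            raise ValidationError("pain must be in 0..10")
        if self.depth is not None and self.depth not in ("on-skin", "below-skin"):
            raise ValidationError(f"depth {self.depth!r} invalid")


@dataclass(frozen=True)
class DetectionTrial:
    """One 2AFC detection trial: stimulus in one of two intervals."""

    electrode_id: int
    stimulus: StimulusTrain
    stimulus_interval: int
    response_interval: int

    def __post_init__(self) -> None:
        if self.stimulus_interval not in (1, 2):
            raise ValidationError("stimulus_interval must be 1 or 2")
        if self.response_interval not in (1, 2):
            raise ValidationError("response_interval must be 1 or 2")

    @property
    def correct(self) -> bool:
        return self.stimulus_interval == self.response_interval


class QualityCountTable:
    """Report counts per (category, frequency, quality) plus stimulation counts.

    Mirrors the deposited per-frequency sheets: for every pulse frequency
    there is one table whose rows are quality descriptors plus a
    stimulation-count row, and whose columns are electrode categories.

    Parameters
    ----------
    reports
        Series indexed by (category, frequency_Hz, quality) -> report count.
    stimulations
        Series indexed by (category, frequency_Hz) -> number of stimulations.
    """

    def __init__(self, reports: pd.Series, stimulations: pd.Series):
        reports = reports.astype(int)
        stimulations = stimulations.astype(int)
        reports.index = reports.index.set_names(
            ["category", "frequency_Hz", "quality"])
        stimulations.index = stimulations.index.set_names(
            ["category", "frequency_Hz"])
        for (cat, freq, quality), count in reports.items():
            if quality not in QUALITY_VOCABULARY:
                raise ValidationError(f"unknown quality {quality!r}")
            if cat not in CATEGORIES:
                raise ValidationError(f"unknown category {cat!r}")
            if count < 0:
                raise ValidationError(
                    f"negative report count at ({cat}, {freq}, {quality})")
            stim = stimulations.get((cat, freq))
            if stim is None:
                raise ValidationError(
                    f"no stimulation count for ({cat}, {freq} Hz)")
            if count > stim:
                raise ValidationError(
                    f"report count {count} exceeds stimulation count {stim} "
                    f"at ({cat}, {freq} Hz, {quality})")
        if (stimulations < 0).any():
            raise ValidationError("negative stimulation count")
        self.reports = reports.sort_index()
        self.stimulations = stimulations.sort_index()

    # -- accessors ---------------------------------------------------------

    def report_count(self, category: str, frequency_Hz: float, quality: str) -> int:
        return int(self.reports.get((category, frequency_Hz, quality), 0))

    def stimulation_count(self, category: str, frequency_Hz: float) -> int:
        return int(self.stimulations[(category, frequency_Hz)])

    @property
    def frequencies(self) -> list[float]:
        return sorted(self.stimulations.index.get_level_values("frequency_Hz").unique())

    @property
    def categories(self) -> list[str]:
        cats = self.stimulations.index.get_level_values("category").unique()
        return [c for c in CATEGORIES if c in set(cats)]

    def category_total(self, category: str, frequency_Hz: float) -> int:
        """Total reports summed over qualities for one (category, frequency)."""
        sub = self.reports.loc[
            (self.reports.index.get_level_values("category") == category)
            & (self.reports.index.get_level_values("frequency_Hz") == frequency_Hz)
        ]
        return int(sub.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, QualityCountTable):
            return NotImplemented
        return (self.reports.equals(other.reports)
                and self.stimulations.equals(other.stimulations))


@dataclass
class ArrayGridMap:
    """Electrode positions and category labels on one or more 6 x 10 arrays.

    ``wired`` is a boolean mask of shape ``(n_arrays, 6, 10)``.  ``category``
    is an object array of the same shape holding, per site, one of:

    * ``None`` — unwired site (if not wired) or tested-but-unassigned site
      (if wired);
    * ``"untested"`` — wired but never tested behaviourally;
    * a category label in :data:`CATEGORIES`.

    Site coordinates are ``(array, row, col)``, 0-based, row-major within
    each array.  Arrays are physically disjoint: no adjacency relations
    cross array boundaries.
    """

    wired: np.ndarray
    category: np.ndarray
    hand_segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wired = np.asarray(self.wired, dtype=bool)
        self.category = np.asarray(self.category, dtype=object)
        if self.wired.ndim != 3 or self.wired.shape[1:] != (GRID_ROWS, GRID_COLS):
            raise ShapeError(
                f"wired mask shape {self.wired.shape} != (n, {GRID_ROWS}, {GRID_COLS})")
        if self.category.shape != self.wired.shape:
            raise ShapeError("category array shape differs from wired mask")
        valid = set(CATEGORIES) | {UNTESTED}
        for idx in np.ndindex(self.wired.shape):
            cat = self.category[idx]
            if cat is not None and cat not in valid:
                raise ValidationError(f"invalid category {cat!r} at site {idx}")
            if cat is not None and not self.wired[idx]:
                raise ValidationError(f"category on unwired site {idx}")
        if int(self.wired.sum()) == 0:
            logger.warning("grid map has zero wired sites")

    @property
    def n_arrays(self) -> int:
        return self.wired.shape[0]

    def tested_mask(self) -> np.ndarray:
        """Wired sites that were behaviourally tested (labelled or pending)."""
        untested = np.frompyfunc(lambda c: c == UNTESTED, 1, 1)(self.category)
        return self.wired & ~untested.astype(bool)

    def labeled_mask(self) -> np.ndarray:
        """Tested sites carrying an actual category label."""
        has_label = np.frompyfunc(
            lambda c: c in CATEGORIES, 1, 1)(self.category).astype(bool)
        return self.wired & has_label

    def tested_sites(self) -> list[tuple[int, int, int]]:
        return [tuple(map(int, idx)) for idx in np.argwhere(self.tested_mask())]

    def labeled_sites(self) -> list[tuple[int, int, int]]:
        return [tuple(map(int, idx)) for idx in np.argwhere(self.labeled_mask())]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for idx in np.argwhere(self.labeled_mask()):
            cat = self.category[tuple(idx)]
            counts[cat] = counts.get(cat, 0) + 1
        return counts

    def copy(self) -> "ArrayGridMap":
        return ArrayGridMap(
            wired=self.wired.copy(),
            category=self.category.copy(),
            hand_segment=None if self.hand_segment is None else self.hand_segment.copy(),
        )


# --------------------------------------------------------------------------
# Magnitude-trial table I/O
# --------------------------------------------------------------------------

#: Canonical column names of the long magnitude-trial CSV layout.
MAGNITUDE_COLUMNS = (
    "electrode", "day", "block", "frequency_Hz",
    "amplitude_uA", "duration_s", "response",
)
_MANDATORY_MAGNITUDE = ("electrode", "day", "block", "frequency_Hz", "response")

DEFAULT_AMPLITUDE_UA = 60.0
DEFAULT_DURATION_S = 1.0


def read_magnitude_table(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    default_amplitude_uA: float = DEFAULT_AMPLITUDE_UA,
    default_duration_s: float = DEFAULT_DURATION_S,
) -> list[MagnitudeTrial]:
    """Read a long-format magnitude-estimation CSV into trials.

    Parameters
    ----------
    path
        CSV file with header columns for electrode, day, block, frequency
        and response; amplitude and duration columns are optional and
        default to 60 µA / 1 s (the standard frequency-series condition).
    column_map
        Optional mapping from canonical column names
        (:data:`MAGNITUDE_COLUMNS`) to the names actually used in the file,
        for files exported with different spellings.

    Returns
    -------
    list of :class:`MagnitudeTrial`, in file row order.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY_MAGNITUDE if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if "amplitude_uA" not in df.columns:
        df["amplitude_uA"] = default_amplitude_uA
    if "duration_s" not in df.columns:
        df["duration_s"] = default_duration_s

    trials: list[MagnitudeTrial] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based file line, after the header
        try:
            stim = StimulusTrain(
                amplitude_uA=float(row.amplitude_uA),
                frequency_Hz=float(row.frequency_Hz),
                duration_s=float(row.duration_s),
            )
            trial = MagnitudeTrial(
                electrode_id=int(row.electrode),
                day=int(row.day),
                block=int(row.block),
                stimulus=stim,
                response=float(row.response),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {rownum}: {exc}") from exc
        trials.append(trial)
    return trials


def trials_to_frame(trials: list[MagnitudeTrial]) -> pd.DataFrame:
    """Convert magnitude trials to the canonical analysis DataFrame."""
    return pd.DataFrame(
        {
            "electrode": [t.electrode_id for t in trials],
            "day": [t.day for t in trials],
            "block": [t.block for t in trials],
            "frequency_Hz": [t.stimulus.frequency_Hz for t in trials],
            "amplitude_uA": [t.stimulus.amplitude_uA for t in trials],
            "duration_s": [t.stimulus.duration_s for t in trials],
            "response": [t.response for t in trials],
        }
    )


def frame_to_trials(df: pd.DataFrame) -> list[MagnitudeTrial]:
    """Inverse of :func:`trials_to_frame`."""
    return [
        MagnitudeTrial(
            electrode_id=int(r.electrode),
            day=int(r.day),
            block=int(r.block),
            stimulus=StimulusTrain(float(r.amplitude_uA), float(r.frequency_Hz),
                                   float(r.duration_s)),
            response=float(r.response),
        )
        for r in df.itertuples(index=False)
    ]


def write_magnitude_table(trials: list[MagnitudeTrial], path: str | os.PathLike) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Quality-count table I/O (one wide file per pulse frequency)
# --------------------------------------------------------------------------

_QUALITY_FILE_TEMPLATE = "quality_counts_{freq:g}Hz.csv"


def write_quality_counts(table: QualityCountTable, directory: str | os.PathLike) -> None:
    """Write one wide CSV per frequency: rows = qualities + stimulation row."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for freq in table.frequencies:
        cats = table.categories
        qualities = sorted(
            {q for (c, f, q) in table.reports.index if f == freq})
        data = {
            cat: [table.report_count(cat, freq, q) for q in qualities]
            + [table.stimulation_count(cat, freq)]
            for cat in cats
        }
        wide = pd.DataFrame(data, index=qualities + [STIMULATION_ROW])
        wide.index.name = "quality"
        wide.to_csv(directory / _QUALITY_FILE_TEMPLATE.format(freq=freq))


def read_quality_counts(
    source: str | os.PathLike | Mapping[float, str | os.PathLike],
) -> QualityCountTable:
    """Read per-frequency quality-count CSVs into a :class:`QualityCountTable`.

    ``source`` is either a directory containing files written by
    :func:`write_quality_counts` (``quality_counts_<freq>Hz.csv``) or an
    explicit mapping ``{frequency_Hz: path}``.
    """
    if isinstance(source, Mapping):
        paths = {float(f): Path(p) for f, p in source.items()}
    else:
        directory = Path(source)
        paths = {}
        for p in sorted(directory.glob("quality_counts_*Hz.csv")):
            freq = float(p.stem.replace("quality_counts_", "").replace("Hz", ""))
            paths[freq] = p
        if not paths:
            raise SchemaError(f"no quality_counts_*Hz.csv files in {directory}")

    reports: dict[tuple[str, float, str], int] = {}
    stimulations: dict[tuple[str, float], int] = {}
    for freq, path in paths.items():
        wide = pd.read_csv(path, index_col=0)
        if STIMULATION_ROW not in wide.index:
            raise SchemaError(
                f"{path}: missing {STIMULATION_ROW!r} row")
        for cat in wide.columns:
            if cat not in CATEGORIES:
                raise ValidationError(f"{path}: unknown category column {cat!r}")
            stimulations[(cat, freq)] = int(wide.loc[STIMULATION_ROW, cat])
        for quality in wide.index:
            if quality == STIMULATION_ROW:
                continue
            if quality not in QUALITY_VOCABULARY:
                raise ValidationError(f"{path}: unknown quality {quality!r}")
            for cat in wide.columns:
                reports[(cat, freq, quality)] = int(wide.loc[quality, cat])

    rep = pd.Series(reports)
    rep.index = pd.MultiIndex.from_tuples(rep.index)
    stim = pd.Series(stimulations)
    stim.index = pd.MultiIndex.from_tuples(stim.index)
    return QualityCountTable(rep, stim)


# --------------------------------------------------------------------------
# Grid-map I/O (headerless CSV, one stacked 6 x 10 block per array)
# --------------------------------------------------------------------------

_UNWIRED_TOKENS = {"", "nan", "na"}


def read_grid_map(path: str | os.PathLike) -> ArrayGridMap:
    """Read a grid-map CSV with one stacked 6 x 10 block per array.

    Cell values: empty / ``NaN`` = unwired; ``untested``; ``unassigned``
    (tested, no label yet); or a category label (``LFP``/``IFP``/``HFP``).
    """
    raw = pd.read_csv(path, header=None, dtype=str)
    n_rows, n_cols = raw.shape
    if n_cols != GRID_COLS:
        raise ShapeError(f"grid map has {n_cols} columns, expected {GRID_COLS}")
    if n_rows % GRID_ROWS != 0:
        raise ShapeError(
            f"grid map has {n_rows} rows, not a multiple of {GRID_ROWS}")
    n_arrays = n_rows // GRID_ROWS

    wired = np.zeros((n_arrays, GRID_ROWS, GRID_COLS), dtype=bool)
    category = np.full((n_arrays, GRID_ROWS, GRID_COLS), None, dtype=object)
    for a in range(n_arrays):
        block = raw.iloc[a * GRID_ROWS:(a + 1) * GRID_ROWS, :]
        for r in range(GRID_ROWS):
            for c in range(GRID_COLS):
                cell = block.iat[r, c]
                token = "" if pd.isna(cell) else str(cell).strip()
                if token.lower() in _UNWIRED_TOKENS:
                    continue
                wired[a, r, c] = True
                if token == UNASSIGNED:
                    category[a, r, c] = None
                elif token in CATEGORIES or token == UNTESTED:
                    category[a, r, c] = token
                else:
                    raise ValidationError(
                        f"site ({a}, {r}, {c}): invalid label {token!r}")
    return ArrayGridMap(wired=wired, category=category)


def write_grid_map(grid: ArrayGridMap, path: str | os.PathLike) -> None:
    rows = []
    for a in range(grid.n_arrays):
        for r in range(GRID_ROWS):
            row = []
            for c in range(GRID_COLS):
                if not grid.wired[a, r, c]:
                    row.append("NaN")
                elif grid.category[a, r, c] is None:
                    row.append(UNASSIGNED)
                else:
                    row.append(str(grid.category[a, r, c]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, header=False, index=False)
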