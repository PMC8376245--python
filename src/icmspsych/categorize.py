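"""Electrode categorization by frequency preference and percept quality.

Electrodes are clustered with k-means on their mean rated intensity at
20, 100 and 300 Hz, clusters are named LFP/IFP/HFP by the frequency at
which each centroid peaks, and k is validated with silhouette and elbow
curves.  An independent clustering on normalized quality-report vectors
allows the two partitions to be compared (adjusted Rand index), and
pairwise Fisher exact tests relate quality reports to categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .core_io import CATEGORIES, QualityCountTable, ValidationError
from .magnitude import bh_adjust

logger = logging.getLogger(__name__)

#: Feature frequencies used for intensity-based clustering (Hz).
FEATURE_FREQUENCIES = (20.0, 100.0, 300.0)

#: The ten quality descriptors used for quality-based clustering.  The
#: participant-coined descriptors are folded onto this list through
#: :data:`DEFAULT_QUALITY_ALIASES` before feature building.
DEFAULT_CLUSTER_QUALITIES = (
    "touch", "pressure", "sharp", "vibration", "movement-across-skin",
    "warm", "cool", "electrical", "tickle", "itch",
)

#: Mapping of coined descriptors onto the clustered ten.  The coined
#: percepts were described as combinations of standard ones; each is
#: folded onto its closest standard descriptor.
DEFAULT_QUALITY_ALIASES = {
    "tapping": "pressure",
    "buzzing": "vibration",
    "prick": "sharp",
    "sparkle": "tickle",
}


class NamingConflictError(ValueError):
    """Two k-means centroids peak at the same feature frequency."""


class DegenerateDataError(ValueError):
    """All feature rows identical; silhouette analysis is undefined."""


# --------------------------------------------------------------------------
# Feature construction
# --------------------------------------------------------------------------

def build_intensity_features(
    profiles: pd.DataFrame,
    frequencies=FEATURE_FREQUENCIES,
) -> pd.DataFrame:
    """Electrode x frequency feature matrix of raw mean intensities.

    ``profiles`` is the output of
    :func:`icmspsych.magnitude.compute_profiles`.  Electrodes missing any
    of the feature frequencies are excluded (logged), since k-means cannot
    handle missing entries.  Features stay raw (not per-electrode
    normalized): categories genuinely differ in overall rating level, and
    normalization would erase that separation.
    """
    wide = profiles.pivot(index="electrode", columns="frequency_Hz", values="mean")
    missing = [f for f in frequencies if f not in wide.columns]
    if missing:
        raise ValidationError(f"profiles lack feature frequencies {missing}")
    feats = wide[list(frequencies)]
    incomplete = feats.index[feats.isna().any(axis=1)]
    if len(incomplete):
        logger.info("excluding %d electrode(s) lacking a feature frequency: %s",
                    len(incomplete), list(incomplete))
        feats = feats.drop(index=incomplete)
    return feats


def build_quality_features(
    counts: pd.DataFrame | QualityCountTable,
    qualities=DEFAULT_CLUSTER_QUALITIES,
    aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Normalize per-electrode quality counts to a [0, 1] feature matrix.

    Each quality column is divided by the maximum report count any
    electrode attained for that quality, so every column with any reports
    peaks at exactly 1; all-zero columns stay zero.  Coined descriptors
    are first folded onto the ten clustered qualities through ``aliases``.
    No dimensionality reduction is applied.
    """
    if isinstance(counts, QualityCountTable):
        raise TypeError(
            "per-electrode counts required: pass a DataFrame with electrodes "
            "as rows and quality descriptors as columns")
    if aliases is None:
        aliases = DEFAULT_QUALITY_ALIASES
    if (counts.to_numpy() < 0).any():
        raise ValidationError("quality counts must be non-negative")

    folded = pd.DataFrame(0.0, index=counts.index, columns=list(qualities))
    for col in counts.columns:
        target = aliases.get(col, col)
        if target in folded.columns:
            folded[target] += counts[col]
        else:
            logger.info("quality %r not in the clustered list; ignored", col)
    col_max = folded.max(axis=0)
    scale = col_max.replace(0, 1.0)
    return folded / scale


# --------------------------------------------------------------------------
# k-means clustering and naming
# --------------------------------------------------------------------------

def _name_clusters(centroids: pd.DataFrame, k: int) -> dict[int, str]:
    """Map cluster indices to LFP/IFP/HFP by the centroid's peak frequency."""
    argmax_freq = centroids.idxmax(axis=1)
    if argmax_freq.duplicated().any():
        raise NamingConflictError(
            f"centroids share a peak frequency; cannot name clusters:\n{centroids}")
    if k == 3:
        by_freq = {20.0: "LFP", 100.0: "IFP", 300.0: "HFP"}
        return {ci: by_freq[float(f)] for ci, f in argmax_freq.items()}
    if k == 2:
        ordered = argmax_freq.sort_values()
        return {ordered.index[0]: "LFP", ordered.index[1]: "HFP"}
    raise ValueError(f"category naming defined for k in {{2, 3}}, got k={k}")


def cluster_frequency_preference(
    features: pd.DataFrame,
    k: int = 3,
    n_init: int = 50,
    seed: int | None = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """k-means categorization of electrodes from intensity features.

    Runs k-means (k-means++ initialisation, ``n_init`` restarts, best
    inertia kept) and names the clusters by the frequency at which each
    centroid attains its maximum: 20 Hz -> LFP, 100 Hz -> IFP,
    300 Hz -> HFP (for k = 2: the lower-peaking cluster is LFP, the
    higher-peaking HFP).

    Returns ``(labels, centroids)`` where labels is a Series of category
    names indexed by electrode and centroids a k x len(features.columns)
    DataFrame.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(features) < k:
        raise ValidationError(f"{len(features)} rows < k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(features.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=features.columns)
    names = _name_clusters(centroids, k)
    labels = pd.Series([names[a] for a in assignments],
                       index=features.index, name="category")
    centroids.index = [names[i] for i in range(k)]
    return labels, centroids


@dataclass
class KSelection:
    best_k: int
    silhouettes: dict[int, float]
    inertias: dict[int, float]


def select_k(
    features: pd.DataFrame,
    k_range=range(2, 7),
    n_init: int = 50,
    seed: int | None = 0,
) -> KSelection:
    """Choose k by mean silhouette, with the inertia (elbow) curve attached.

    ``best_k`` is the argmax of the mean silhouette over ``k_range``; the
    inertia curve is returned alongside for elbow inspection in reports.
    Identical feature rows make the silhouette undefined (error suggesting
    k = 1).
    """
    X = features.to_numpy()
    if np.allclose(X, X[0]):
        raise DegenerateDataError(
            "all feature rows are identical; silhouette is undefined (use k=1)")
    if len(features) <= max(k_range):
        raise ValidationError(
            f"need more rows than max(k_range)={max(k_range)}, got {len(features)}")
    silhouettes: dict[int, float] = {}
    inertias: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        inertias[k] = float(km.inertia_)
        silhouettes[k] = float(silhouette_score(X, km.labels_))
    best_k = max(silhouettes, key=silhouettes.get)
    return KSelection(best_k=best_k, silhouettes=silhouettes, inertias=inertias)


# --------------------------------------------------------------------------
# Partition agreement
# --------------------------------------------------------------------------

def cluster_agreement(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Adjusted Rand index between two electrode partitions.

    ARI is 1 for identical partitions and has expectation 0 under the
    permutation model; degenerate single-cluster partitions score 0
    against anything.
    """
    if set(labels_a.index) != set(labels_b.index):
        raise ValidationError("labelings cover different electrode sets")
    b = labels_b.reindex(labels_a.index)
    return float(adjusted_rand_score(labels_a.to_numpy(), b.to_numpy()))


# --------------------------------------------------------------------------
# Quality-category association (pairwise Fisher exact + BH)
# --------------------------------------------------------------------------

def quality_association(
    table: QualityCountTable,
    frequency_Hz: float,
    qualities=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise category association tests for each quality at one frequency.

    For every quality and every category pair (a, b) a 2x2 contingency
    table ``[[reports_a, stims_a - reports_a], [reports_b, stims_b -
    reports_b]]`` is tested with a two-sided Fisher exact test (sample
    sizes are small, so the exact hypergeometric tail is used rather than
    a chi-squared approximation).  Benjamini-Hochberg correction is
    applied across all pairs x qualities at the frequency.

    Returns a DataFrame with columns quality, category_a, category_b,
    p_value, significant; the BH critical p is in ``.attrs['critical_p']``.
    """
    cats = table.categories
    if qualities is None:
        qualities = sorted({q for (c, f, q) in table.reports.index
                            if f == frequency_Hz})
    rows = []
    for quality in qualities:
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                a, b = cats[i], cats[j]
                sa = table.stimulation_count(a, frequency_Hz)
                sb = table.stimulation_count(b, frequency_Hz)
                if sa == 0 or sb == 0:
                    raise ValidationError(
                        f"zero stimulation count for {a if sa == 0 else b} "
                        f"at {frequency_Hz} Hz")
                ra = table.report_count(a, frequency_Hz, quality)
                rb = table.report_count(b, frequency_Hz, quality)
                p = fisher_exact_2x2(ra, sa - ra, rb, sb - rb)
                rows.append((quality, a, b, p))
    out = pd.DataFrame(rows, columns=["quality", "category_a", "category_b",
                                      "p_value"])
    mask, critical = bh_adjust(out["p_value"].to_numpy(), alpha)
    out["significant"] = mask
    out.attrs["critical_p"] = critical
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError("contingency cells must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
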