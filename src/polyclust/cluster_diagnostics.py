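"""Per-cluster statistics used to recognize meta-stable and transition states.

For each cluster the diagnostics collect: its size, the distribution of
intra-cluster pairwise distances, the distribution of member scaling
parameters sigma, the median member frame time, and (when coordinates are
available) the distribution of member radii of gyration.  Distributions are
summarized as notched boxplots; the notch half-width ``1.58 * R_IQ / sqrt(n)``
approximates a 95% confidence interval on the median, so non-overlapping
notches between temporally adjacent clusters indicate a credible median
difference.

A cluster whose median sigma is a strict local minimum along the temporal
ordering of clusters, with notches that do not overlap either neighbor's, is
classified *meta-stable* (a densely populated basin); a strict local maximum
with the same non-overlap condition is a *transition* (a sparsely populated
region between basins); anything else is *intermediate*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import InvalidInputError, InvalidParameterError, StructureEnsemble
from .spectral_clustering import ClusterResult
from .structure_metrics import radius_of_gyration_series

__all__ = [
    "BoxplotSummary",
    "ClusterDiagnostics",
    "boxplot_summary",
    "compute_diagnostics",
    "representative_structure",
    "classify_states",
]

META_STABLE = "meta-stable"
TRANSITION = "transition"
INTERMEDIATE = "intermediate"


class InsufficientDataError(InvalidInputError):
    """Too few values to summarize a distribution."""


@dataclass(frozen=True)
class BoxplotSummary:
    """Notched boxplot summary of a sample.

    Whiskers extend beyond each quartile by 1.5 times the distance from the
    median to that quartile, then are truncated to the most extreme data
    points within those limits; values beyond the limits are outliers.
    The alternative conventional rule (1.5 times the interquartile range)
    is available via ``style="tukey"`` in :func:`boxplot_summary`.
    """

    q1: float
    median: float
    q3: float
    notch_halfwidth: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def notch_low(self) -> float:
        return self.median - self.notch_halfwidth

    @property
    def notch_high(self) -> float:
        return self.median + self.notch_halfwidth


@dataclass
class ClusterDiagnostics:
    """Statistics of one cluster (ids are 1-based, temporally ordered)."""

    cluster_id: int
    size: int
    median_time: float
    intra_rmsd: BoxplotSummary | None
    intra_sigma: BoxplotSummary | None
    rg: BoxplotSummary | None = None
    state: str = INTERMEDIATE


def boxplot_summary(values, style: str = "median-quartile") -> BoxplotSummary:
    """Summarize a sample as a notched boxplot.

    Quartiles use linear interpolation between order statistics; the notch
    half-width is ``1.58 * (q3 - q1) / sqrt(n)``.

    Parameters
    ----------
    values : array-like
        At least two numbers.
    style : {"median-quartile", "tukey"}
        Whisker rule: limits at 1.5x the median-to-quartile distance beyond
        each quartile (default), or the conventional 1.5x IQR beyond each
        quartile.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise InsufficientDataError(
            f"need at least 2 values to summarize, got {values.size}"
        )
    q1, median, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    notch = 1.58 * (q3 - q1) / np.sqrt(values.size)
    if style == "median-quartile":
        lo_limit = q1 - 1.5 * (median - q1)
        hi_limit = q3 + 1.5 * (q3 - median)
    elif style == "tukey":
        iqr = q3 - q1
        lo_limit = q1 - 1.5 * iqr
        hi_limit = q3 + 1.5 * iqr
    else:
        raise InvalidParameterError(f"unknown whisker style: {style!r}")
    inside = (values >= lo_limit) & (values <= hi_limit)
    outliers = np.sort(values[~inside])
    whisker_low = float(values[inside].min())
    whisker_high = float(values[inside].max())
    return BoxplotSummary(q1=float(q1), median=float(median), q3=float(q3),
                          notch_halfwidth=float(notch),
                          whisker_low=whisker_low, whisker_high=whisker_high,
                          outliers=outliers, n=int(values.size))


def compute_diagnostics(X, result: ClusterResult,
                        ensemble: StructureEnsemble | None = None,
                        frame_times: np.ndarray | None = None,
                        classify: bool = True,
                        whisker_style: str = "median-quartile"
                        ) -> list[ClusterDiagnostics]:
    """Per-cluster diagnostics, clusters in temporal order.

    ``X`` is the dissimilarity matrix used for clustering; ``ensemble`` is
    optional (the analytic models have no 3D coordinates, so no radius of
    gyration there).  Singleton clusters have no intra-cluster distance
    distribution; their summaries are flagged ``None``.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if result.labels.shape[0] != n:
        raise InvalidInputError(
            f"label count {result.labels.shape[0]} does not match matrix size {n}"
        )
    if frame_times is None:
        frame_times = np.arange(1, n + 1)
    sigma = result.sigma.sigma if result.sigma is not None else None
    rg_series = radius_of_gyration_series(ensemble) if ensemble is not None else None
    if rg_series is not None and len(rg_series) != n:
        raise InvalidInputError("ensemble frame count does not match matrix size")

    records = []
    for cid in range(1, result.k + 1):
        members = result.members(cid)
        size = members.size
        if size == 0:
            raise InvalidInputError(f"cluster {cid} is empty")
        if size >= 3:  # at least 3 pairwise distances
            sub = X[np.ix_(members, members)]
            intra = boxplot_summary(sub[np.triu_indices(size, 1)],
                                    style=whisker_style)
        else:
            intra = None  # singleton/pair: too few pairwise distances
        intra_sigma = (boxplot_summary(sigma[members], style=whisker_style)
                       if sigma is not None and size >= 2 else None)
        rg = (boxplot_summary(rg_series[members], style=whisker_style)
              if rg_series is not None and size >= 2 else None)
        records.append(ClusterDiagnostics(
            cluster_id=cid, size=size,
            median_time=float(np.median(frame_times[members])),
            intra_rmsd=intra, intra_sigma=intra_sigma, rg=rg))
    if classify:
        classify_states(records)
    return records


def representative_structure(X, result: ClusterResult, cluster_id: int) -> int:
    """Most central member of a cluster (1-based frame index).

    The representative minimizes the sum of intra-cluster distances to all
    other members; ties are broken by the smallest frame index.
    """
    X = np.asarray(X, dtype=np.float64)
    if not 1 <= cluster_id <= result.k:
        raise InvalidParameterError(f"unknown cluster id {cluster_id}")
    members = result.members(cluster_id)
    if members.size == 0:
        raise InvalidParameterError(f"cluster {cluster_id} is empty")
    sums = X[np.ix_(members, members)].sum(axis=1)
    return int(members[np.argmin(sums)]) + 1


def _notches_disjoint(a: BoxplotSummary, b: BoxplotSummary) -> bool:
    return a.notch_high < b.notch_low or b.notch_high < a.notch_low


def classify_states(diagnostics: list[ClusterDiagnostics]
                    ) -> list[ClusterDiagnostics]:
    """Label clusters meta-stable / transition / intermediate, in place.

    Works on the temporal ordering of clusters (they are already sorted by
    median frame time).  A cluster is *meta-stable* when its median sigma is
    a strict local minimum and its notch interval is disjoint from both
    temporal neighbors' (endpoints: the single neighbor); *transition* when
    a strict local maximum under the same condition; *intermediate*
    otherwise.  Clusters lacking a sigma summary stay intermediate.
    """
    k = len(diagnostics)
    if k < 3:
        warnings.warn("fewer than 3 clusters: no local extrema, all intermediate")
        for d in diagnostics:
            d.state = INTERMEDIATE
        return diagnostics
    for i, d in enumerate(diagnostics):
        d.state = INTERMEDIATE
        s = d.intra_sigma
        if s is None:
            continue
        neighbors = [diagnostics[j].intra_sigma
                     for j in (i - 1, i + 1) if 0 <= j < k]
        if any(nb is None for nb in neighbors):
            continue
        if (all(s.median < nb.median for nb in neighbors)
                and all(_notches_disjoint(s, nb) for nb in neighbors)):
            d.state = META_STABLE
        elif (all(s.median > nb.median for nb in neighbors)
                and all(_notches_disjoint(s, nb) for nb in neighbors)):
            d.state = TRANSITION
    return diagnostics
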