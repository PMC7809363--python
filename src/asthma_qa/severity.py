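"""Medication-based asthma severity: daily rank-sums, monthly trajectories,
K-means severity clusters I-IV, and the yearly total medication rank.

Each controller prescription contributes its stepwise-treatment rank (1-4)
to every day it covers; ranks of overlapping prescriptions add.  Averaging
the daily rank-sum within each calendar month of the July-June window yields
a 12-point trajectory per patient-period, which is clustered with K-means
(Euclidean distance) into severity groups ordered I (mildest) to IV by the
annual mean of their centroids.  Reliever and exacerbation drugs carry rank
0 and never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .catalog import DrugCatalog
from .periods import MONTH_LABELS, AssessmentPeriod

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def build_daily_rank_series(
    prescriptions: pd.DataFrame,
    catalog: DrugCatalog,
    period: AssessmentPeriod,
    patient_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-patient daily rank-sum over window A.

    Returns a frame indexed by patient_id with one column per day offset
    (0 = July 1).  A prescription starting at ``date`` with ``days_supplied``
    d covers ``[date, date + d)``; only the overlap with A contributes.
    """
    rx = prescriptions
    if (rx["days_supplied"] < 0).any():
        raise ValueError("negative days_supplied in prescriptions")
    n_days = period.n_days_a

    if patient_ids is None:
        index = pd.Index(sorted(rx["patient_id"].unique()), name="patient_id")
    else:
        index = pd.Index(patient_ids, name="patient_id")
    out = np.zeros((len(index), n_days + 1))
    if len(rx):
        ranks = np.array(
            [
                catalog.rank_for(c, d)
                for c, d in zip(rx["drug_code"], rx["days_supplied"])
            ],
            dtype=float,
        )
        start = (pd.to_datetime(rx["date"]) - pd.Timestamp(period.a_start)).dt.days
        start = start.to_numpy()
        end = start + rx["days_supplied"].to_numpy()
        s = np.clip(start, 0, n_days)
        e = np.clip(end, 0, n_days)
        keep = (ranks > 0) & (e > s)
        pos = index.get_indexer(rx["patient_id"])
        keep &= pos >= 0
        pos, s, e, ranks = pos[keep], s[keep], e[keep], ranks[keep]
        # difference-array accumulation, then prefix sum along days
        np.add.at(out, (pos, s), ranks)
        np.add.at(out, (pos, e), -ranks)
        out = np.cumsum(out, axis=1)
    return pd.DataFrame(out[:, :n_days], index=index)


def monthly_means(daily: pd.DataFrame, period: AssessmentPeriod) -> pd.DataFrame:
    """12-month mean-rank trajectory (columns Jul..Jun) from a daily series.

    Month value = (sum of daily rank-sums in the month) / (days in month),
    so months without any ranked exposure are 0.
    """
    month = period.month_of_day()
    if daily.shape[1] != len(month):
        raise ValueError("daily series not aligned to window A")
    sums = np.zeros((len(daily), 12))
    vals = daily.to_numpy()
    for m in range(12):
        sums[:, m] = vals[:, month == m].sum(axis=1)
    traj = sums / period.days_in_month()
    return pd.DataFrame(traj, index=daily.index, columns=list(MONTH_LABELS))


def total_rank(daily: pd.DataFrame) -> pd.Series:
    """Yearly total medication rank: sum of the daily rank-sums over A."""
    s = daily.sum(axis=1)
    s.name = "total_rank"
    return s


def overall_r_square(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster sum of squares as a fraction of the total."""
    total = ((X - X.mean(axis=0)) ** 2).sum()
    if total == 0:
        return float("nan")
    within = 0.0
    for lab in np.unique(labels):
        grp = X[labels == lab]
        within += ((grp - grp.mean(axis=0)) ** 2).sum()
    return float(1.0 - within / total)


class SeverityTrajectoryClusterer(ClusterMixin, BaseEstimator):
    """K-means clustering of 12-month mean-rank trajectories.

    Parameters
    ----------
    n_clusters : int or "elbow"
        Number of severity groups.  The default 4 mirrors the national
        assessment analysis; ``"elbow"`` picks the k in `k_candidates` with
        the largest gain in overall R-square over k-1 (R-square itself is
        non-decreasing in k, so the raw maximum is not informative).
    k_candidates : sequence of int
        Candidate k values scanned for the R-square profile.
    n_init, random_state
        Passed to :class:`sklearn.cluster.KMeans` (k-means++ restarts).

    Attributes
    ----------
    labels_ : ndarray of int
        Severity group per trajectory, 0-based in severity order
        (0 = group I, mildest).
    label_names_ : list of str
        Roman-numeral name per ordered cluster id.
    cluster_centers_ : ndarray (k, 12)
        Centroids reordered by ascending annual mean.
    overall_r2_ : float
        Between/total sum-of-squares ratio at the selected k.
    r2_by_k_ : dict
        R-square per candidate k (only the selected k when k is fixed).
    degenerate_ : bool
        True when the input has zero total variance (single effective
        cluster; R-square undefined).
    """

    def __init__(
        self,
        n_clusters=4,
        k_candidates: Sequence[int] = tuple(range(2, 9)),
        n_init: int = 20,
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        self.degenerate_ = bool(np.all(X == X[0]))
        if self.degenerate_:
            warnings.warn(
                "zero-variance trajectories: single effective cluster, "
                "overall R-square undefined"
            )
            self.selected_k_ = 1
            self.labels_ = np.zeros(len(X), dtype=int)
            self.label_names_ = [ROMAN[0]]
            self.cluster_centers_ = X[:1].copy()
            self.overall_r2_ = float("nan")
            self.r2_by_k_ = {1: float("nan")}
            return self

        if self.n_clusters == "elbow":
            ks = sorted(set(int(k) for k in self.k_candidates))
        else:
            ks = [int(self.n_clusters)]
        if len(X) < max(ks):
            raise ValueError(
                f"need at least {max(ks)} trajectories, got {len(X)}"
            )
        fits, r2 = {}, {}
        for k in ks:
            km = KMeans(
                n_clusters=k,
                n_init=self.n_init,
                random_state=self.random_state,
            ).fit(X)
            fits[k] = km
            r2[k] = overall_r_square(X, km.labels_)
        if self.n_clusters == "elbow":
            best = self._elbow(ks, r2)
        else:
            best = ks[0]
        km = fits[best]
        order = np.argsort(km.cluster_centers_.mean(axis=1), kind="stable")
        relabel = np.empty(best, dtype=int)
        relabel[order] = np.arange(best)
        self.selected_k_ = best
        self.labels_ = relabel[km.labels_]
        self.cluster_centers_ = km.cluster_centers_[order]
        self.label_names_ = [ROMAN[i] for i in range(best)]
        self.overall_r2_ = r2[best]
        self.r2_by_k_ = r2
        return self

    @staticmethod
    def _elbow(ks, r2) -> int:
        """k after which the marginal R-square gain collapses.

        R-square is non-decreasing in k, so the raw maximum is
        uninformative; the elbow is the k whose gain over k-1 most
        dominates the following gain (largest gain ratio).
        """
        if len(ks) < 3:
            return max(ks, key=lambda k: r2[k])
        gains = {k: r2[k] - r2[km1] for km1, k in zip(ks, ks[1:])}
        inner = ks[1:-1]
        return max(
            inner,
            key=lambda k: gains[k] / max(gains[ks[ks.index(k) + 1]], 1e-12),
        )

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def label_name(self, label: int) -> str:
        return self.label_names_[label]


@dataclass
class SeverityModel:
    """Fitted severity clustering plus per-observation assignments."""

    clusterer: SeverityTrajectoryClusterer
    assignments: pd.Series  # index = trajectory index, values "I".."IV"
    centroids: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.centroids = pd.DataFrame(
            self.clusterer.cluster_centers_,
            index=self.clusterer.label_names_,
            columns=list(MONTH_LABELS),
        )

    @property
    def overall_r2(self) -> float:
        return self.clusterer.overall_r2_


def fit_severity_clusters(
    trajectories: pd.DataFrame,
    n_clusters=4,
    k_candidates: Sequence[int] = tuple(range(2, 9)),
    seed: Optional[int] = None,
    n_init: int = 20,
) -> SeverityModel:
    """Cluster trajectories into ordered severity groups.

    The input is sorted by its index before fitting so that assignments do
    not depend on row order.
    """
    traj = trajectories.sort_index()
    clf = SeverityTrajectoryClusterer(
        n_clusters=n_clusters,
        k_candidates=k_candidates,
        n_init=n_init,
        random_state=seed,
    ).fit(traj.to_numpy())
    names = np.array(clf.label_names_)
    assignments = pd.Series(
        names[clf.labels_], index=traj.index, name="severity"
    )
    return SeverityModel(clusterer=clf, assignments=assignments)
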