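"""Surface preprocessing: statistical outlier removal and ROI cropping.

Both steps are exposed as sklearn-style transformers so they compose into
pipelines, plus plain functions for one-off use.  They are applied
identically to the reference and current surfaces before registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import RigidTransform, as_cloud

__all__ = [
    "ROIBox",
    "remove_outliers",
    "crop_roi",
    "StatisticalOutlierFilter",
    "ROICrop",
]

#: Default region of interest, mm: a rectangular patch over the abdomen.
DEFAULT_ROI_EXTENTS = (600.0, 380.0, 160.0)


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned rectangular region of interest (closed box, mm)."""

    center: np.ndarray
    extents: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(3)
        e = np.asarray(self.extents, dtype=float).reshape(3)
        if not np.all(e > 0):
            raise ValueError(f"ROI extents must be positive, got {e}")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "extents", e)

    def contains(self, points) -> np.ndarray:
        """Boolean mask of points inside the closed box."""
        pts = as_cloud(points)
        return np.all(np.abs(pts - self.center) <= self.extents / 2.0, axis=1)

    def transformed(self, pose: RigidTransform) -> "ROIBox":
        """The box whose centre follows ``pose`` (extents unchanged).

        Only exact for poses without rotation; used to co-move the ROI with
        a couch shift.
        """
        return ROIBox(pose.apply(self.center[None])[0], self.extents)


def remove_outliers(cloud, k: int = 20, m: float = 2.0) -> np.ndarray:
    """Drop points whose mean k-nearest-neighbour distance is anomalous.

    For each point the mean distance to its ``k`` nearest neighbours is
    computed; points above ``global mean + m * global std`` are removed.
    Order is preserved.  A cloud with ``k`` or fewer points is returned
    unchanged with a warning.
    """
    pts = as_cloud(cloud)
    if k < 1 or m <= 0:
        raise ValueError("need k >= 1 and m > 0")
    if len(pts) <= k:
        warnings.warn(
            f"cloud of {len(pts)} points is too small for k={k} neighbours; "
            "returned unchanged", stacklevel=2)
        return pts.copy()
    tree = cKDTree(pts)
    # k+1 because each point is its own nearest neighbour at distance 0
    dists, _ = tree.query(pts, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + m * mean_d.std()
    return pts[mean_d <= cutoff]


def crop_roi(cloud, box: ROIBox) -> np.ndarray:
    """Retain the points inside the closed ROI box, order preserved."""
    pts = as_cloud(cloud)
    out = pts[box.contains(pts)]
    if len(pts) and not len(out):
        warnings.warn("ROI crop removed every point; registration requires "
                      "a non-empty cloud", stacklevel=2)
    return out


class StatisticalOutlierFilter(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`remove_outliers`.

    Parameters
    ----------
    k : int, default 20
        Neighbour count for the mean-distance statistic.
    m : float, default 2.0
        Standard-deviation multiplier of the rejection threshold.
    """

    def __init__(self, k: int = 20, m: float = 2.0):
        self.k = k
        self.m = m

    def fit(self, X, y=None):
        as_cloud(X)
        self.n_features_in_ = 3
        return self

    def transform(self, X):
        return remove_outliers(X, k=self.k, m=self.m)


class ROICrop(TransformerMixin, BaseEstimator):
    """Transformer that crops a cloud to a rectangular region of interest.

    Parameters
    ----------
    center : array-like of 3 floats or None
        Box centre in mm.  ``None`` (default) uses the centroid of the cloud
        passed to :meth:`fit` — typically the reference surface — so the
        same fitted box is applied to both surfaces.
    extents : array-like of 3 floats, default (600, 380, 160)
        Box edge lengths in mm (lateral, longitudinal, vertical).
    """

    def __init__(self, center=None, extents=DEFAULT_ROI_EXTENTS):
        self.center = center
        self.extents = extents

    def fit(self, X, y=None):
        pts = as_cloud(X)
        if self.center is None:
            if not len(pts):
                raise ValueError("cannot infer ROI centre from an empty cloud")
            center = pts.mean(axis=0)
        else:
            center = self.center
        self.box_ = ROIBox(center, self.extents)
        self.n_features_in_ = 3
        return self

    def transform(self, X):
        if not hasattr(self, "box_"):
            raise AttributeError("ROICrop must be fitted before transform")
        return crop_roi(X, self.box_)
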