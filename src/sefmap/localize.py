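"""Delineation of the activated cortical area from a distributed estimate.

The pipeline that turns a standardized source estimate into a bounded
cortical region:

1. anatomical spatial filtering — each source's time course is replaced by
   the mean over its neighbours within 5 mm that share its parcellation
   label (self included);
2. windowed SVD — economy SVD of the source x time matrix restricted to the
   closed [15, 60] ms post-stimulus window, ``X = U S V^T``;
3. the dominant spatial mode u1 (first left singular vector) is thresholded
   at 80 % of its maximum absolute loading to give the activation region,
   and the dominant temporal mode v1 gives the peak activation time.

Everything is deterministic; SVD signs are fixed by making the
largest-magnitude entry of each temporal mode positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .evoked import Evoked
from .geometry import CortexModel, Parcellation, SourceSpace
from .inverse import InverseOperator, SourceEstimate, apply_sloreta

__all__ = [
    "SvdDecomposition",
    "ActivationRegion",
    "ANALYSIS_WINDOW_MS",
    "spatial_filter",
    "svd_window",
    "dominant_modes",
    "threshold_region",
    "peak_activation_time",
    "localize_patient",
]

ANALYSIS_WINDOW_MS = (15.0, 60.0)  # closed on both ends
FILTER_RADIUS_MM = 5.0
REGION_THRESHOLD = 0.80


@dataclass
class SvdDecomposition:
    """Economy SVD of the windowed source x time matrix."""

    U: np.ndarray  # (l, t) left singular vectors (spatial modes)
    S: np.ndarray  # (t,) singular values, descending
    V: np.ndarray  # (t, t) right singular vectors as columns (temporal modes)
    window_ms: tuple[float, float]
    times: np.ndarray  # (t,) ms, the samples inside the window

    def variance_fractions(self) -> np.ndarray:
        s2 = self.S**2
        return s2 / s2.sum()


@dataclass
class ActivationRegion:
    """Thresholded dominant spatial mode: the delineated cortical area."""

    members: np.ndarray  # sorted global source indices
    loadings: np.ndarray  # |u1| at the members
    centroid: np.ndarray  # (3,) mm
    centroid_vertex: int
    centroid_label: str
    peak_time: float  # ms
    threshold: float

    @property
    def size(self) -> int:
        return len(self.members)


def _neighbor_averaging_matrix(
    source_space: SourceSpace,
    parcellation: Parcellation,
    radius: float,
    label_respecting: bool = True,
) -> sp.csr_matrix:
    """Row-stochastic matrix averaging each source over its (same-label) 5 mm ball."""
    pos = source_space.positions
    tree = cKDTree(pos)
    pairs = tree.query_ball_point(pos, r=radius)
    rows, cols = [], []
    labels = parcellation.labels
    for i, neigh in enumerate(pairs):
        neigh = np.asarray(neigh)
        if label_respecting:
            neigh = neigh[labels[neigh] == labels[i]]
        rows.append(np.full(len(neigh), i))
        cols.append(neigh)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    counts = np.bincount(r, minlength=len(pos)).astype(float)
    w = 1.0 / counts[r]
    return sp.csr_matrix((w, (r, c)), shape=(len(pos), len(pos)))


def spatial_filter(
    stc: SourceEstimate,
    source_space: SourceSpace,
    parcellation: Parcellation,
    radius: float = FILTER_RADIUS_MM,
    label_respecting: bool = True,
) -> SourceEstimate:
    """Anatomical smoothing: mean over same-label neighbours within ``radius`` mm.

    The neighbourhood is the Euclidean ball (self included) intersected with
    the source's own parcellation label; ``radius=0`` is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return SourceEstimate(stc.values.copy(), stc.times.copy())
    A = _neighbor_averaging_matrix(source_space, parcellation, radius, label_respecting)
    return SourceEstimate(A @ stc.values, stc.times.copy())


def svd_window(stc: SourceEstimate, window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS) -> SvdDecomposition:
    """Economy SVD of the estimate restricted to the closed analysis window.

    Requires at least as many sources as window samples (l >= t).  Each
    mode's sign is fixed so that the largest-|entry| of its temporal vector
    is positive.
    """
    t = stc.times
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    n_t = int(mask.sum())
    if n_t == 0:
        raise ValueError(f"window {window_ms} ms contains no samples")
    X = stc.values[:, mask]
    if X.shape[0] < n_t:
        raise ValueError("windowed matrix needs at least as many sources as samples")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    for k in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, k])))
        if V[i, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return SvdDecomposition(U=U, S=S, V=V, window_ms=window_ms, times=t[mask].copy())


def dominant_modes(svd: SvdDecomposition) -> tuple[np.ndarray, np.ndarray, float]:
    """First spatial mode, first temporal mode, and its variance fraction."""
    if svd.S.size == 0:
        raise ValueError("empty decomposition")
    return svd.U[:, 0], svd.V[:, 0], float(svd.variance_fractions()[0])


def threshold_region(
    u1: np.ndarray,
    parcellation: Parcellation,
    source_space: SourceSpace,
    threshold: float = REGION_THRESHOLD,
    semantics: str = "fraction_of_max",
) -> ActivationRegion:
    """Threshold the dominant spatial mode into a bounded region.

    With the default ``fraction_of_max`` semantics the members are the
    sources whose |loading| is at least ``threshold`` times the maximum
    |loading|; ``quantile`` instead keeps sources above the ``threshold``
    quantile of |loadings|.  The centroid is the arithmetic mean of member
    positions; its label is that of the nearest source vertex.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    a = np.abs(np.asarray(u1, dtype=float))
    if a.max() == 0:
        raise ValueError("all-zero spatial mode")
    if semantics == "fraction_of_max":
        members = np.flatnonzero(a >= threshold * a.max())
    elif semantics == "quantile":
        members = np.flatnonzero(a >= np.quantile(a, threshold))
    else:
        raise ValueError(f"unknown threshold semantics: {semantics!r}")
    centroid = source_space.positions[members].mean(axis=0)
    d = np.linalg.norm(source_space.positions - centroid, axis=1)
    cv = int(np.argmin(d))
    return ActivationRegion(
        members=members,
        loadings=a[members],
        centroid=centroid,
        centroid_vertex=cv,
        centroid_label=parcellation.name_of(parcellation.labels[cv]),
        peak_time=float("nan"),
        threshold=threshold,
    )


def peak_activation_time(v1: np.ndarray, window_times: np.ndarray) -> float:
    """Time (ms) of the maximum |v1|; earliest sample wins ties."""
    v1 = np.asarray(v1)
    if len(v1) != len(window_times):
        raise ValueError("temporal mode length does not match window samples")
    return float(window_times[int(np.argmax(np.abs(v1)))])


def localize_patient(
    evoked: Evoked,
    inverse_operator: InverseOperator,
    model: CortexModel,
    filter_radius: float = FILTER_RADIUS_MM,
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
    threshold: float = REGION_THRESHOLD,
    semantics: str = "fraction_of_max",
    label_respecting: bool = True,
) -> ActivationRegion:
    """Full delineation: sLORETA -> spatial filter -> SVD -> threshold.

    Deterministic, and invariant to positive rescaling or sign flips of the
    evoked data (the threshold is relative to the maximum loading).
    """
    stc = apply_sloreta(inverse_operator, evoked)
    stc = spatial_filter(
        stc, model.source_space, model.parcellation, radius=filter_radius,
        label_respecting=label_respecting,
    )
    svd = svd_window(stc, window_ms)
    u1, v1, _ = dominant_modes(svd)
    region = threshold_region(u1, model.parcellation, model.source_space, threshold, semantics)
    region.peak_time = peak_activation_time(v1, svd.times)
    return region
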