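"""Distributed (sLORETA) and discrete (dipole) source estimation.

sLORETA standardizes the regularized minimum-norm estimate by the diagonal
of its resolution matrix.  With whitened gain ``G = L / sigma`` the
minimum-norm kernel is ``W = G^T (G G^T + lam2 * tr(G G^T)/n_chan * I)^-1``
and the standardized estimate at source j is
``(W b)_j / sqrt((W L)_jj)``.  For noiseless point sources and vanishing
regularization the argmax of the standardized map is the true source
(zero localization error), which is why the method anchors the pipeline.

The clinical comparator is an equivalent current dipole (ECD): a grid
search over candidate positions solving the free-orientation least-squares
moment at each sample of a latency window, keeping the fit with the highest
goodness of fit, GOF = 100 * (1 - |b - b_hat|^2 / |b|^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evoked import Evoked, pmax_time
from .forward import LeadField
from .geometry import Parcellation, SourceSpace

__all__ = [
    "InverseOperator",
    "SourceEstimate",
    "DipoleFit",
    "make_inverse",
    "apply_sloreta",
    "fit_dipole",
    "fit_named_dipoles",
    "reject_dipole",
    "DIPOLE_WINDOWS",
    "REJECT_DISTANCE_MM",
]

#: latency windows for the named dipole fits: center +/- half-width, ms
DIPOLE_WINDOWS = {"P20m": (20.0, 5.0), "P40m": (40.0, 5.0)}

#: dipoles farther than this from the contralateral sensorimotor labels are rejected
REJECT_DISTANCE_MM = 9.0


@dataclass
class InverseOperator:
    """sLORETA kernel with its standardization diagonal."""

    kernel: np.ndarray  # (n_sources, n_channels), unwhitened data -> MNE amplitudes
    resolution_diag: np.ndarray  # (n_sources,) positive
    lam2: float
    sigma: float


@dataclass
class SourceEstimate:
    """Standardized current-density values: (n_sources, n_samples)."""

    values: np.ndarray
    times: np.ndarray  # ms


@dataclass
class DipoleFit:
    """An equivalent current dipole with its fit quality."""

    time: float  # ms
    position: np.ndarray  # (3,) mm, surface RAS
    moment: np.ndarray  # (3,) nA*m
    gof: float  # percent, in [0, 100]
    kind: str  # "P20m" | "P40m" | "PMaxm" | other
    accepted: bool | None = None

    @property
    def moment_magnitude(self) -> float:
        return float(np.linalg.norm(self.moment))


def make_inverse(leadfield: LeadField, noise_scale: float = 1.0, lam2: float = 1.0 / 9.0) -> InverseOperator:
    """Build the sLORETA operator for a fixed-orientation lead field.

    ``noise_scale`` is sigma of the assumed white noise covariance
    ``sigma^2 I``; ``lam2`` the relative regularization (default 1/9,
    nominal amplitude SNR of 3).
    """
    if lam2 < 0:
        raise ValueError("lam2 must be non-negative")
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    L = leadfield.gain
    n_chan = L.shape[0]
    G = L / noise_scale
    gram = G @ G.T
    reg = lam2 * np.trace(gram) / n_chan
    kernel_w = G.T @ np.linalg.inv(gram + reg * np.eye(n_chan))  # whitened-data kernel
    # resolution matrix diagonal: (W L)_jj with W acting on whitened data
    res_diag = np.einsum("sc,cs->s", kernel_w, G)
    bad = np.flatnonzero(res_diag <= 1e-14 * res_diag.max())
    if bad.size:
        raise ValueError(f"non-positive resolution diagonal (silent sources?): {bad.tolist()}")
    kernel = kernel_w / noise_scale  # absorb whitening of the data
    return InverseOperator(kernel=kernel, resolution_diag=res_diag, lam2=lam2, sigma=noise_scale)


def apply_sloreta(inverse_operator: InverseOperator, evoked: Evoked) -> SourceEstimate:
    """Standardized source estimate of the evoked data."""
    if evoked.data.shape[0] != inverse_operator.kernel.shape[1]:
        raise ValueError("channel count mismatch between evoked and inverse operator")
    mne_vals = inverse_operator.kernel @ evoked.data
    values = mne_vals / np.sqrt(inverse_operator.resolution_diag)[:, None]
    return SourceEstimate(values=values, times=evoked.times.copy())


def fit_dipole(
    evoked: Evoked,
    free_gain: np.ndarray,
    grid_positions: np.ndarray,
    window_center: float,
    half_width: float,
    kind: str = "dipole",
) -> DipoleFit:
    """Grid-search ECD over a latency window.

    ``free_gain`` is (n_channels, n_grid, 3): the field of unit dipoles
    along x/y/z at each candidate position.  For every sample in the closed
    window ``[center - half_width, center + half_width]`` and every grid
    node the least-squares 3-vector moment is solved; the (sample, node)
    pair with maximal GOF wins (first occurrence on exact ties).
    """
    t = evoked.times
    mask = (t >= window_center - half_width) & (t <= window_center + half_width)
    if not mask.any():
        raise ValueError("dipole window lies outside the evoked time axis")
    B = evoked.data[:, mask]  # (C, T)
    bnorm2 = np.einsum("ct,ct->t", B, B)
    if not (bnorm2 > 0).any():
        raise ValueError("all-zero data in the dipole window: fit undefined")

    G = free_gain  # (C, P, 3)
    M = np.einsum("cpi,cpj->pij", G, G)  # (P, 3, 3)
    # the radial moment component is magnetically silent in a spherical
    # conductor, so M is rank-deficient; the pseudo-inverse solves the
    # least-squares moment in the observable (tangential) subspace
    Minv = np.linalg.pinv(M, rcond=1e-10, hermitian=True)
    A = np.einsum("cpi,ct->pit", G, B)  # (P, 3, T)
    # |b_hat|^2 = a^T M^-1 a  (projection onto the 3-dim column space)
    quad = np.einsum("pit,pij,pjt->pt", A, Minv, A)
    with np.errstate(invalid="ignore", divide="ignore"):
        gof = 100.0 * quad / bnorm2[None, :]
    gof[:, bnorm2 == 0] = -np.inf
    p, s = np.unravel_index(int(np.argmax(gof)), gof.shape)
    moment = Minv[p] @ A[p, :, s]  # nA*m
    return DipoleFit(
        time=float(t[mask][s]),
        position=np.asarray(grid_positions[p], dtype=float).copy(),
        moment=moment,
        gof=float(np.clip(gof[p, s], 0.0, 100.0)),
        kind=kind,
    )


def fit_named_dipoles(
    evoked: Evoked,
    free_gain: np.ndarray,
    grid_positions: np.ndarray,
) -> dict[str, DipoleFit]:
    """The three clinical fits: P20m, P40m (20/40 +/- 5 ms) and PMaxm.

    PMaxm is fit at the single sample of maximum gradiometer RMS in the
    closed [15, 60] ms window.
    """
    out = {}
    for kind, (center, hw) in DIPOLE_WINDOWS.items():
        out[kind] = fit_dipole(evoked, free_gain, grid_positions, center, hw, kind=kind)
    t_max = pmax_time(evoked)
    out["PMaxm"] = fit_dipole(evoked, free_gain, grid_positions, t_max, 0.0, kind="PMaxm")
    return out


def reject_dipole(
    dipole: DipoleFit,
    parcellation: Parcellation,
    source_space: SourceSpace,
    side: str,
    max_distance: float = REJECT_DISTANCE_MM,
) -> bool:
    """Accept a dipole iff it lies within ``max_distance`` mm (inclusive) of
    any sensorimotor-labelled source contralateral to the stimulated side."""
    if side not in ("UL", "UR"):
        raise ValueError("side must be 'UL' or 'UR'")
    hemi = "right" if side == "UL" else "left"
    roi = parcellation.roi_mask(hemi)
    if not roi.any():
        raise ValueError(f"parcellation has no {hemi}-hemisphere sensorimotor labels")
    d = np.linalg.norm(source_space.positions[roi] - dipole.position, axis=1)
    accepted = bool(d.min() <= max_distance)
    dipole.accepted = accepted
    return accepted
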