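"""Baseline correction, epoch averaging, gradiometer RMS and peak timing.

The evoked response (SEF) is the arithmetic mean over all epochs after
per-channel baseline correction over the pre-stimulus interval [-50, 0) ms.
The RMS time course over the planar gradiometers,
``sqrt((x_1^2 + ... + x_n^2) / n)``, defines the PMaxm latency: the time of
its maximum within the closed window [15, 60] ms post-stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import EpochsArray

__all__ = [
    "Evoked",
    "baseline_correct",
    "average_epochs",
    "rms_time_course",
    "pmax_time",
    "estimate_noise_scale",
]

BASELINE_MS = (-50.0, 0.0)  # half-open [start, stop)
PMAX_WINDOW_MS = (15.0, 60.0)  # closed on both ends


@dataclass
class Evoked:
    """Averaged evoked response: (n_channels, n_samples)."""

    data: np.ndarray
    times: np.ndarray  # ms, stimulus at 0
    n_ave: int
    ch_kinds: np.ndarray | None = None

    def grad_mask(self) -> np.ndarray:
        if self.ch_kinds is None:
            raise ValueError("evoked carries no channel-kind information")
        return np.asarray(self.ch_kinds) == "grad"


def _baseline_mask(times: np.ndarray) -> np.ndarray:
    mask = (times >= BASELINE_MS[0]) & (times < BASELINE_MS[1])
    if not mask.any():
        raise ValueError("time axis does not cover the baseline interval [-50, 0) ms")
    return mask


def baseline_correct(epochs: EpochsArray) -> EpochsArray:
    """Subtract each channel's pre-stimulus mean, per epoch.

    The baseline is the half-open interval [-50, 0) ms, excluding the
    stimulus sample.  Idempotent.
    """
    mask = _baseline_mask(epochs.times)
    means = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    return EpochsArray(
        data=epochs.data - means,
        sfreq=epochs.sfreq,
        t0_ms=epochs.t0_ms,
        ch_kinds=epochs.ch_kinds,
    )


def average_epochs(epochs: EpochsArray) -> Evoked:
    """Arithmetic mean over epochs (no epoch rejection)."""
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    return Evoked(
        data=epochs.data.mean(axis=0),
        times=epochs.times,
        n_ave=epochs.n_epochs,
        ch_kinds=epochs.ch_kinds,
    )


def rms_time_course(evoked: Evoked, channel_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-sample RMS over the masked channels (default: gradiometers)."""
    mask = evoked.grad_mask() if channel_mask is None else np.asarray(channel_mask)
    if mask.dtype == bool:
        if not mask.any():
            raise ValueError("channel mask selects no channels")
        sel = evoked.data[mask]
    else:
        if len(mask) == 0:
            raise ValueError("channel mask selects no channels")
        sel = evoked.data[mask]
    return np.sqrt(np.mean(sel**2, axis=0))


def pmax_time(evoked: Evoked, window_ms: tuple[float, float] = PMAX_WINDOW_MS) -> float:
    """Latency (ms) of maximum gradiometer RMS within the closed window.

    Ties resolve to the earliest sample.
    """
    t = evoked.times
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} ms outside the time axis")
    rms = rms_time_course(evoked)[mask]
    return float(t[mask][int(np.argmax(rms))])


def estimate_noise_scale(evoked: Evoked) -> float:
    """Median per-channel standard deviation over the evoked baseline.

    Used as the scalar noise scale (sigma, covariance sigma^2 I) of the
    inverse operator.
    """
    mask = _baseline_mask(evoked.times)
    stds = evoked.data[:, mask].std(axis=1, ddof=1)
    sigma = float(np.median(stds))
    if sigma <= 0:
        # noiseless simulation: fall back to a scale tied to the data so the
        # whitening stays well-conditioned
        sigma = float(np.abs(evoked.data).max()) or 1.0
    return sigma
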