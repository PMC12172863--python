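"""Ground-truthed synthetic somatosensory-evoked MEG epochs.

Emulates the acquisition used for clinical median-nerve mapping: a
306-channel whole-head array sampled at 1 kHz, epochs from 50 ms before to
250 ms after the stimulus, and roughly 160-230 stimulation events per
patient.  The evoked response is a contiguous cortical patch in the
postcentral gyrus / central sulcus contralateral to the stimulated side,
driven by a causal waveform with deflections near 20 and 35 ms.  Sensor
noise is white Gaussian, scaled to a prescribed evoked-response SNR defined
on the planar gradiometers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .forward import LeadField, SensorArray, build_leadfield, build_sensor_array, regularize_orientations
from .geometry import CortexModel, build_cortex_model, grow_patch

__all__ = [
    "GroundTruth",
    "EpochsArray",
    "Workbench",
    "DEFAULT_COMPONENTS",
    "sef_waveform",
    "build_workbench",
    "simulate_patient",
    "cohort_seeds",
    "iter_cohort",
    "simulate_cohort",
]

#: (latency ms, width ms, amplitude): deflections near 20 and 35 ms
DEFAULT_COMPONENTS: tuple[tuple[float, float, float], ...] = (
    (20.0, 3.0, 1.0),
    (35.0, 6.0, 0.9),
)

#: stimulation-event count distribution: mean, sd, truncation bounds
EVENT_COUNT = dict(mean=197.0, sd=31.0, low=160, high=230)


@dataclass
class GroundTruth:
    """The simulated cortical activation behind one patient's epochs."""

    patch: np.ndarray  # global source indices, sorted
    taper: np.ndarray  # per-patch-source amplitude factor in (0, 1]
    waveform: np.ndarray  # unit-peak time course over the epoch
    peak_latencies: tuple[float, ...]  # ms
    side: str  # "UL" | "UR"
    seed_vertex: int
    moment_total: float  # summed peak moment, nA*m


@dataclass
class EpochsArray:
    """Epoched multichannel data: (n_epochs, n_channels, n_samples)."""

    data: np.ndarray
    sfreq: float = 1000.0
    t0_ms: float = -50.0
    ch_kinds: np.ndarray | None = None  # (n_channels,) "mag" | "grad"

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, stimulus at t = 0."""
        n = self.data.shape[-1]
        return self.t0_ms + np.arange(n) * 1000.0 / self.sfreq

    @property
    def stim_sample(self) -> int:
        return int(round(-self.t0_ms * self.sfreq / 1000.0))


@dataclass
class Workbench:
    """Cortical model + sensor array + lead field: the fixed study apparatus."""

    model: CortexModel
    sensors: SensorArray
    leadfield: LeadField
    head_radius: float


def sef_waveform(
    times_ms: np.ndarray,
    components: Sequence[tuple[float, float, float]] = DEFAULT_COMPONENTS,
) -> np.ndarray:
    """Causal sum of Gaussian deflections.

    Each component is ``(latency, width, amplitude)`` in ms/ms/unitless; the
    result is ``sum_k A_k exp(-(t - l_k)^2 / (2 w_k^2))`` multiplied by the
    indicator ``t >= 0``.
    """
    t = np.asarray(times_ms, dtype=float)
    out = np.zeros_like(t)
    for latency, width, amplitude in components:
        if width <= 0:
            raise ValueError("component widths must be positive")
        out += amplitude * np.exp(-((t - latency) ** 2) / (2 * width**2))
    return out * (t >= 0)


def build_workbench(
    subdivisions: int = 4,
    radius: float = 35.0,
    fold_amplitude: float = 5.0,
    hemisphere_gap: float = 8.0,
    head_radius: float = 85.0,
    helmet_radius: float = 110.0,
    band_width: float = 0.19,
    seed: int = 0,
) -> Workbench:
    """Assemble the synthetic cortex, the 306-channel array and the lead field.

    Source orientations are tilted at least 5 degrees off head-centre radial
    before the lead field is built, so no source is magnetically silent.
    """
    model = build_cortex_model(
        subdivisions=subdivisions,
        fold_amplitude=fold_amplitude,
        hemisphere_gap=hemisphere_gap,
        radius=radius,
        band_width=band_width,
        seed=seed,
    )
    model.source_space = regularize_orientations(model.source_space)
    sensors = build_sensor_array(helmet_radius=helmet_radius, seed=seed)
    lf = build_leadfield(model.source_space, sensors, head_radius=head_radius)
    return Workbench(model, sensors, lf, head_radius)


def _epoch_times(sfreq: float = 1000.0, t0_ms: float = -50.0, t1_ms: float = 250.0) -> np.ndarray:
    # half-open [t0, t1): 300 samples at 1 kHz, stimulus at sample 50
    n = int(round((t1_ms - t0_ms) * sfreq / 1000.0))
    return t0_ms + np.arange(n) * 1000.0 / sfreq


def _draw_epoch_count(rng: np.random.Generator) -> int:
    while True:
        n = rng.normal(EVENT_COUNT["mean"], EVENT_COUNT["sd"])
        if EVENT_COUNT["low"] <= n <= EVENT_COUNT["high"]:
            return int(round(n))


def simulate_patient(
    workbench: Workbench,
    side: str,
    snr: float = 5.0,
    n_epochs: int | None = None,
    patch_size: int = 50,
    moment_total: float = 50.0,
    components: Sequence[tuple[float, float, float]] = DEFAULT_COMPONENTS,
    seed: int = 0,
) -> tuple[EpochsArray, GroundTruth]:
    """Simulate one patient's somatosensory epochs with known ground truth.

    The activated patch is seeded uniformly within the postcentral gyrus or
    central sulcus contralateral to ``side`` ("UL" = left median nerve, so
    the right hemisphere, and vice versa) and grown to ``patch_size``
    contiguous sources.  Per-source peak moments taper smoothly from the
    patch seed and sum to ``moment_total`` nA*m.  White sensor noise is
    scaled so that the noiseless gradiometer peak RMS divided by the
    expected residual noise RMS in the average (per-epoch sigma / sqrt(n))
    equals ``snr``; ``snr=inf`` yields noiseless epochs.
    """
    if side not in ("UL", "UR"):
        raise ValueError("side must be 'UL' or 'UR'")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    model, lf = workbench.model, workbench.leadfield
    rng = np.random.default_rng(seed)
    hemi = "right" if side == "UL" else "left"

    parc = model.parcellation
    seed_ids = {
        lid
        for lid, (name, h) in parc.label_table.items()
        if h == hemi and name in ("postcentral_gyrus", "central_sulcus")
    }
    candidates = np.flatnonzero(np.isin(parc.labels, sorted(seed_ids)))
    if candidates.size == 0:
        raise ValueError(f"no {hemi}-hemisphere seed region in the parcellation")
    seed_vertex = int(rng.choice(candidates))
    # the activation is somatosensory cortex: the patch stays entirely inside
    # the contralateral sensorimotor labels (growth restricted to that subgraph)
    allowed = parc.roi_mask(hemi)
    sel = sp.diags(allowed.astype(float))
    roi_adjacency = (sel @ model.adjacency @ sel).tocsr()
    try:
        patch = grow_patch(model.source_space, roi_adjacency, seed_vertex, patch_size)
    except ValueError as exc:
        raise ValueError(
            f"patch_size={patch_size} exceeds the contralateral sensorimotor "
            f"region ({int(allowed.sum())} sources)"
        ) from exc

    seed_pos = model.source_space.positions[seed_vertex]
    d = np.linalg.norm(model.source_space.positions[patch] - seed_pos, axis=1)
    dmax = d.max() if d.max() > 0 else 1.0
    taper = 0.3 + 0.7 * np.cos(0.5 * np.pi * d / dmax)  # in (0, 1]
    amplitudes = taper / taper.sum() * moment_total  # nA*m at waveform peak

    times = _epoch_times()
    wave = sef_waveform(times, components)
    activation = amplitudes[:, None] * wave[None, :]  # (patch, samples)
    noiseless = lf.gain[:, patch] @ activation  # (channels, samples)

    if n_epochs is None:
        n_epochs = _draw_epoch_count(rng)

    grad = lf.sensors.kind_mask("grad")
    peak_rms = np.sqrt(np.mean(noiseless[grad] ** 2, axis=0)).max()
    sigma = 0.0 if np.isinf(snr) else float(peak_rms * np.sqrt(n_epochs) / snr)
    data = np.tile(noiseless, (n_epochs, 1, 1))
    if sigma > 0:
        data += rng.normal(0.0, sigma, size=data.shape)

    epochs = EpochsArray(data=data, ch_kinds=np.asarray(lf.sensors.kinds).copy())
    latencies = tuple(c[0] for c in components)
    truth = GroundTruth(
        patch=patch,
        taper=taper,
        waveform=wave,
        peak_latencies=latencies,
        side=side,
        seed_vertex=seed_vertex,
        moment_total=moment_total,
    )
    return epochs, truth


def cohort_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-patient sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2**31)).astype(np.int64)


def iter_cohort(
    workbench: Workbench,
    n_patients: int,
    sides: str | Sequence[str] = "UL",
    snr: float = 5.0,
    n_epochs: int | None = None,
    patch_size: int = 50,
    moment_total: float = 50.0,
    seed: int = 0,
):
    """Yield ``(patient_id, EpochsArray, GroundTruth)`` one patient at a time.

    ``sides`` is either one side for the whole cohort or a per-patient
    sequence.  Patients get pairwise distinct sub-seeds derived from the
    master seed.  Streaming keeps only one patient's epochs in memory.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if isinstance(sides, str):
        sides = [sides] * n_patients
    if len(sides) != n_patients:
        raise ValueError("sides must match n_patients")
    seeds = cohort_seeds(seed, n_patients)
    for i in range(n_patients):
        ep, gt = simulate_patient(
            workbench,
            side=sides[i],
            snr=snr,
            n_epochs=n_epochs,
            patch_size=patch_size,
            moment_total=moment_total,
            seed=int(seeds[i]),
        )
        yield f"p{i:03d}", ep, gt


def simulate_cohort(
    workbench: Workbench,
    n_patients: int,
    sides: str | Sequence[str] = "UL",
    snr: float = 5.0,
    n_epochs: int | None = None,
    patch_size: int = 50,
    moment_total: float = 50.0,
    seed: int = 0,
) -> tuple[list[tuple[EpochsArray, GroundTruth]], pd.DataFrame]:
    """Materialized cohort (small cohorts only) plus a manifest table."""
    seeds = cohort_seeds(seed, n_patients)
    patients = []
    rows = []
    it = iter_cohort(
        workbench, n_patients, sides, snr=snr, n_epochs=n_epochs,
        patch_size=patch_size, moment_total=moment_total, seed=seed,
    )
    for i, (pid, ep, gt) in enumerate(it):
        patients.append((ep, gt))
        rows.append(
            dict(
                patient_id=pid,
                side=gt.side,
                seed=int(seeds[i]),
                n_epochs=ep.n_epochs,
                patch_size=len(gt.patch),
                seed_vertex=gt.seed_vertex,
            )
        )
    return patients, pd.DataFrame(rows)
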