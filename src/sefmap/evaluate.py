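"""Accuracy metrics and statistics for the delineated regions.

Comparisons implemented:

* atlas overlap — percentage of region members carrying one of the four
  sensorimotor labels (either hemisphere, since ipsilateral responses are
  anatomically plausible);
* sphere overlap — percentage of region members inside a 3 cm^3 sphere
  centred on a fitted dipole;
* centroid distance — Euclidean distance between a dipole and the region
  centroid, with nearest-vertex projection onto the atlas;
* random-patch permutation null — size-matched contiguous patches grown
  from uniformly drawn seed vertices, 10,000 draws by default, summarized
  by their median ("chance level");
* cohort statistics — binomial significance of beating chance, Wilcoxon
  signed-rank between tasks, and a chi-squared test on the 5-category
  anatomical location table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .geometry import CortexModel, Parcellation, SourceSpace, grow_patch
from .localize import ActivationRegion

__all__ = [
    "NullDistribution",
    "CohortResult",
    "SPHERE_VOLUME_CM3",
    "sphere_radius_mm",
    "atlas_overlap",
    "sphere_overlap",
    "centroid_distance",
    "project_to_atlas",
    "permutation_null",
    "beats_chance",
    "cohort_binomial",
    "wilcoxon_signed_rank",
    "chi2_location_test",
    "location_counts",
    "summarize_cohort",
    "LOCATION_CATEGORIES",
]

SPHERE_VOLUME_CM3 = 3.0
N_PERMUTATIONS = 10_000

#: the 5 anatomical location categories of the contingency table
LOCATION_CATEGORIES = (
    "precentral_gyrus",
    "central_sulcus",
    "postcentral_gyrus",
    "postcentral_sulcus",
    "other",
)


@dataclass
class NullDistribution:
    """Metric values of size-matched random patches."""

    values: np.ndarray
    seed: int
    region_size: int

    @property
    def n_permutations(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass
class CohortResult:
    """Cohort-level summary statistics."""

    n_patients: int
    n_success: int
    binomial_p_all_success_mass: float
    binomial_p_tail: float
    wilcoxon_p: float | None = None
    chi2_statistic: float | None = None
    chi2_p: float | None = None
    location_table: Mapping[str, Sequence[int]] = field(default_factory=dict)


def _member_indices(region: ActivationRegion | np.ndarray) -> np.ndarray:
    if isinstance(region, ActivationRegion):
        return region.members
    return np.asarray(region, dtype=np.int64)


def atlas_overlap(region: ActivationRegion | np.ndarray, parcellation: Parcellation) -> float:
    """Percentage of region members with a sensorimotor label (either hemisphere)."""
    members = _member_indices(region)
    if members.size == 0:
        raise ValueError("empty region")
    roi = parcellation.roi_mask(None)
    return 100.0 * float(roi[members].mean())


def sphere_radius_mm(volume_cm3: float = SPHERE_VOLUME_CM3) -> float:
    """Radius of a sphere of the given volume: r = (3 V / 4 pi)^(1/3), in mm."""
    if volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def sphere_overlap(
    region: ActivationRegion | np.ndarray,
    source_space: SourceSpace,
    dipole_position: np.ndarray,
    volume_cm3: float = SPHERE_VOLUME_CM3,
) -> float:
    """Percentage of region members inside the dipole-centred sphere (inclusive)."""
    members = _member_indices(region)
    if members.size == 0:
        raise ValueError("empty region")
    r = sphere_radius_mm(volume_cm3)
    d = np.linalg.norm(source_space.positions[members] - np.asarray(dipole_position), axis=1)
    return 100.0 * float((d <= r).mean())


def centroid_distance(region: ActivationRegion, dipole_position: np.ndarray) -> float:
    """Euclidean distance (mm) between the dipole and the region centroid."""
    return float(np.linalg.norm(region.centroid - np.asarray(dipole_position)))


def project_to_atlas(
    point: np.ndarray,
    source_space: SourceSpace,
    parcellation: Parcellation,
) -> tuple[int, str]:
    """Nearest source vertex (lowest index on exact ties) and its label name."""
    d = np.linalg.norm(source_space.positions - np.asarray(point), axis=1)
    v = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return v, parcellation.name_of(parcellation.labels[v])


def permutation_null(
    region_size: int,
    metric_fn: Callable[[np.ndarray], float],
    model: CortexModel,
    n: int = N_PERMUTATIONS,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of ``metric_fn`` over random size-matched patches.

    Each draw grows a contiguous patch of exactly ``region_size`` sources
    from a seed vertex drawn uniformly over the whole cortical surface.
    Bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_src = model.source_space.n_sources
    seeds = rng.integers(0, n_src, size=n)
    values = np.empty(n)
    for i, sv in enumerate(seeds):
        patch = grow_patch(model.source_space, model.adjacency, int(sv), region_size)
        values[i] = metric_fn(patch)
    return NullDistribution(values=values, seed=seed, region_size=region_size)


def beats_chance(observed_metric: float, null: NullDistribution) -> bool:
    """True iff the observed metric strictly exceeds the null median."""
    return bool(observed_metric > null.median)


def cohort_binomial(n_success: int, n_patients: int, p0: float = 0.05, mode: str = "tail") -> float:
    """Binomial significance of the per-patient success count.

    ``mode="tail"``: one-sided P(X >= n_success) under Binomial(n, p0),
    computed in log space.  ``mode="all_success_mass"``: the probability
    mass p0**n of every patient succeeding by chance, the quantity matching
    the values printed in clinical reports of this analysis.
    """
    if not 0 <= n_success <= n_patients:
        raise ValueError("need 0 <= n_success <= n_patients")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if mode == "all_success_mass":
        return float(np.exp(n_patients * np.log(p0)))
    if mode != "tail":
        raise ValueError(f"unknown mode: {mode!r}")
    k = np.arange(n_success, n_patients + 1)
    logpmf = (
        gammaln(n_patients + 1)
        - gammaln(k + 1)
        - gammaln(n_patients - k + 1)
        + k * np.log(p0)
        + (n_patients - k) * np.log1p(-p0)
    )
    m = logpmf.max()
    return float(min(1.0, np.exp(m) * np.exp(logpmf - m).sum()))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped.  For up to 25 nonzero differences the
    exact sign-flip null of the rank sum is computed (midranks for ties,
    doubled to stay integral); larger samples use the normal approximation
    with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    if n <= 25:
        # exact distribution of W+ over the 2^n sign assignments, via a
        # subset-sum table on 2*ranks (integers even with midranks)
        r2 = np.round(2 * ranks).astype(np.int64)
        t_max = int(r2.sum())
        counts = np.zeros(t_max + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: t_max + 1 - r]
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        lo_tail = counts[: w2 + 1].sum()  # P(W+ <= w_plus)
        hi_tail = counts[w2:].sum()  # P(W+ >= w_plus)
        return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def chi2_location_test(contingency: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared test on a methods x location-categories table.

    All-zero columns are dropped (with a log note) before testing; no
    continuity correction.
    """
    table = np.asarray(contingency, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    nonzero_cols = table.sum(axis=0) > 0
    if not nonzero_cols.all():
        import logging

        logging.getLogger(__name__).info(
            "dropping %d all-zero location categories", int((~nonzero_cols).sum())
        )
        table = table[:, nonzero_cols]
    if table.shape[0] < 2 or table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def location_counts(labels: Sequence[str]) -> list[int]:
    """Counts of each of the five location categories in a label sequence."""
    return [sum(1 for x in labels if x == cat) for cat in LOCATION_CATEGORIES]


def summarize_cohort(
    successes: Sequence[bool],
    p0: float = 0.05,
    ul_metric: Sequence[float] | None = None,
    ur_metric: Sequence[float] | None = None,
    location_table: np.ndarray | None = None,
    location_rows: Sequence[str] | None = None,
) -> CohortResult:
    """Assemble the cohort-level statistics from per-patient results.

    The Wilcoxon comparison pairs the two tasks' metric sequences truncated
    to their common length (the synthetic cohorts are independent, so this
    mirrors the clinical between-task comparison only in form).
    """
    successes = list(successes)
    n = len(successes)
    k = int(sum(successes))
    res = CohortResult(
        n_patients=n,
        n_success=k,
        binomial_p_all_success_mass=cohort_binomial(k, n, p0, mode="all_success_mass"),
        binomial_p_tail=cohort_binomial(k, n, p0, mode="tail"),
    )
    if ul_metric is not None and ur_metric is not None and len(ul_metric) and len(ur_metric):
        m = min(len(ul_metric), len(ur_metric))
        diffs = np.asarray(ul_metric[:m]) - np.asarray(ur_metric[:m])
        if (diffs != 0).any():
            res.wilcoxon_p = wilcoxon_signed_rank(ul_metric[:m], ur_metric[:m])
    if location_table is not None:
        stat, p = chi2_location_test(location_table)
        res.chi2_statistic = stat
        res.chi2_p = p
        rows = location_rows or [f"row{i}" for i in range(len(location_table))]
        res.location_table = {r: [int(x) for x in row] for r, row in zip(rows, np.asarray(location_table))}
    return res
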