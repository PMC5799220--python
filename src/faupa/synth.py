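"""Synthetic 4D volumes with planted unitary-activity clusters.

The generator follows the separable generative model of a FAUPA: the
voxel course inside a planted cluster k is

    S_i(t) = C_i * G_k(t) + delta_i(t)

with a common cluster course G_k(t), per-voxel amplitude coefficients
C_i, and additive noise delta_i(t). Background voxels carry noise alone.
Both the cluster courses and the noise are band-limited to the
detection band (0.009-0.08 Hz at TR 2.5 s), because detection operates
on bandpassed data; courses are normalised to unit standard deviation,
so ``noise_sd`` is directly the noise-to-signal ratio for a unit
coefficient.

Cluster shapes start from a compact five-voxel kernel (a voxel plus
four of its 26-neighbours) and then accrete random 26-connected
neighbours up to the target size. The kernel guarantees that every
planted cluster contains at least one fully surrounded anchor voxel,
i.e. the minimal configuration the seeding rule can respond to; planted
areas below five voxels would be undetectable by construction.

Data are emitted in percent-change-like units (mean 0); a raw-intensity
view on a constant baseline is available so the preprocessing chain can
be exercised end to end. Everything is reproducible from ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .detect import Faupa
from .errors import CalibrationError, ParameterError, PlacementError
from .task import HrfParams, TaskParadigm, default_paradigm, ideal_response
from .volume_io import STRUCT26, BoldVolume, GridGeometry, Voxel

DEFAULT_GEOMETRY = GridGeometry(dims=(32, 32, 16), voxel_size=(3.5, 3.5, 3.5),
                                tr=2.5, n_timepoints=288)

#: smallest plantable cluster: anchor voxel plus four neighbours
MIN_CLUSTER_SIZE = 5

RAW_BASELINE = 1000.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated volume."""

    geometry: GridGeometry = DEFAULT_GEOMETRY
    n_clusters: int = 10
    size_range: tuple[int, int] = (5, 12)
    amplitude_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.33
    course_model: str = "bandlimited"          # or "task"
    band: tuple[float, float] = (0.009, 0.08)
    min_gap: int = 2
    rng_seed: int = 0
    task_condition: str = "FT"

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ParameterError("n_clusters must be >= 0")
        lo, hi = self.size_range
        if not MIN_CLUSTER_SIZE <= lo <= hi <= 29:
            raise ParameterError(
                f"size_range must lie within [{MIN_CLUSTER_SIZE}, 29]")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[0] > self.amplitude_range[1]:
            raise ParameterError("amplitude_range must be positive and ordered")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.course_model not in ("bandlimited", "task"):
            raise ParameterError("course_model must be 'bandlimited' or 'task'")
        if self.min_gap < 1:
            raise ParameterError("min_gap must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: the recovery oracle."""

    cluster_members: list[frozenset[Voxel]]
    cluster_courses: list[np.ndarray]
    coefficients: list[np.ndarray]          # aligned with sorted member order
    noise_sd: float


@dataclass(frozen=True)
class ClusterRecovery:
    cluster_index: int
    best_faupa_id: Optional[int]
    dice: float
    hit: bool


@dataclass
class RecoveryReport:
    per_cluster: list[ClusterRecovery]
    n_false_positives: int

    @property
    def sensitivity(self) -> float:
        if not self.per_cluster:
            return float("nan")
        return sum(c.hit for c in self.per_cluster) / len(self.per_cluster)

    @property
    def dice_values(self) -> np.ndarray:
        return np.asarray([c.dice for c in self.per_cluster])


def _band_mask(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    return (freqs >= band[0]) & (freqs <= band[1])


def _bandlimit(x: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~_band_mask(x.shape[-1], tr, band)] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1], axis=-1)


def _grow_cluster(rng: np.random.Generator, dims: tuple[int, int, int],
                  size: int, allowed: np.ndarray) -> Optional[frozenset[Voxel]]:
    """One placement attempt: compact 5-voxel kernel, then random accretion."""
    free = np.argwhere(allowed)
    if free.shape[0] == 0:
        return None
    origin = tuple(int(c) for c in free[rng.integers(free.shape[0])])
    neigh = [n for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
             if (dx, dy, dz) != (0, 0, 0)
             and 0 <= (n := (origin[0] + dx, origin[1] + dy, origin[2] + dz))[0] < dims[0]
             and 0 <= n[1] < dims[1] and 0 <= n[2] < dims[2] and allowed[n]]
    if len(neigh) < MIN_CLUSTER_SIZE - 1:
        return None
    picks = rng.choice(len(neigh), size=MIN_CLUSTER_SIZE - 1, replace=False)
    members = {origin} | {neigh[i] for i in picks}
    while len(members) < size:
        frontier = sorted({n for v in members
                           for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                           if (dx, dy, dz) != (0, 0, 0)
                           and 0 <= (n := (v[0] + dx, v[1] + dy, v[2] + dz))[0] < dims[0]
                           and 0 <= n[1] < dims[1] and 0 <= n[2] < dims[2]
                           and allowed[n] and n not in members})
        if not frontier:
            return None
        members.add(frontier[rng.integers(len(frontier))])
    return frozenset(members)


def simulate(spec: SyntheticSpec,
             paradigm: Optional[TaskParadigm] = None) -> tuple[BoldVolume, SyntheticTruth]:
    """Generate one volume with planted clusters plus its ground truth.

    Background and cluster noise are band-limited white noise rescaled so
    the realised global standard deviation equals ``noise_sd``; cluster
    courses are unit-sd. The returned volume is in percent-change-like
    units with a full (all-True) brain mask.
    """
    rng = np.random.default_rng(spec.rng_seed)
    geo = spec.geometry
    dims = geo.dims
    T = geo.n_timepoints

    # --- place clusters ---------------------------------------------------
    occupied = np.zeros(dims, dtype=bool)
    clusters: list[frozenset[Voxel]] = []
    for k in range(spec.n_clusters):
        size = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
        allowed = ~ndimage.binary_dilation(occupied, structure=STRUCT26,
                                           iterations=spec.min_gap)
        placed = None
        for _ in range(200):
            placed = _grow_cluster(rng, dims, size, allowed)
            if placed is not None:
                break
        if placed is None:
            raise PlacementError(
                f"could not place cluster {k + 1}/{spec.n_clusters} "
                f"(size {size}, min_gap {spec.min_gap}) in grid {dims}")
        clusters.append(placed)
        arr = np.asarray(sorted(placed), dtype=int)
        occupied[arr[:, 0], arr[:, 1], arr[:, 2]] = True

    # --- cluster courses ---------------------------------------------------
    courses: list[np.ndarray] = []
    if spec.course_model == "task":
        paradigm = paradigm or default_paradigm(tr=geo.tr, n_timepoints=T)
        base = ideal_response(paradigm, spec.task_condition).relative_course
        sd = base.std()
        if sd == 0:
            raise ParameterError("task ideal response is flat")
        base = base / sd
        courses = [base.copy() for _ in clusters]
    else:
        for _ in clusters:
            g = _bandlimit(rng.standard_normal(T), geo.tr, spec.band)
            courses.append(g / g.std())

    # --- noise field and assembly -------------------------------------------
    data = np.zeros((*dims, T))
    if spec.noise_sd > 0:
        noise = _bandlimit(rng.standard_normal((*dims, T)), geo.tr, spec.band)
        noise *= spec.noise_sd / noise.std()
        data += noise
    coeffs: list[np.ndarray] = []
    for members, g in zip(clusters, courses):
        arr = np.asarray(sorted(members), dtype=int)
        c = rng.uniform(*spec.amplitude_range, size=arr.shape[0])
        coeffs.append(c)
        data[arr[:, 0], arr[:, 1], arr[:, 2], :] += c[:, np.newaxis] * g

    volume = BoldVolume(geometry=geo, data=data, mask=np.ones(dims, dtype=bool))
    truth = SyntheticTruth(cluster_members=clusters, cluster_courses=courses,
                           coefficients=coeffs, noise_sd=spec.noise_sd)
    return volume, truth


def to_raw_intensity(volume: BoldVolume, baseline: float = RAW_BASELINE) -> BoldVolume:
    """Percent-change data on a constant raw-intensity baseline."""
    raw = baseline * (1.0 + volume.data / 100.0)
    return BoldVolume(geometry=volume.geometry, data=raw, mask=volume.mask)


def dice(a: frozenset[Voxel] | set[Voxel], b: frozenset[Voxel] | set[Voxel]) -> float:
    """Dice overlap 2|A & B| / (|A| + |B|); 0 when both sets are empty."""
    if not a and not b:
        return 0.0
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def recovery_metrics(detected: Sequence[Faupa], truth: SyntheticTruth) -> RecoveryReport:
    """Match detections to planted clusters by Dice overlap.

    A cluster counts as hit when its best-matching detection reaches
    Dice >= 0.5; a detection whose best overlap with any cluster stays
    below 0.1 counts as a false positive.
    """
    per_cluster: list[ClusterRecovery] = []
    for i, members in enumerate(truth.cluster_members):
        best_id, best = None, 0.0
        for f in detected:
            d = dice(members, set(f.voxels))
            if d > best:
                best, best_id = d, f.id
        per_cluster.append(ClusterRecovery(cluster_index=i, best_faupa_id=best_id,
                                           dice=best, hit=best >= 0.5))
    n_fp = 0
    for f in detected:
        best = max((dice(m, set(f.voxels)) for m in truth.cluster_members),
                   default=0.0)
        if best < 0.1:
            n_fp += 1
    return RecoveryReport(per_cluster=per_cluster, n_false_positives=n_fp)


def measure_r_bar(volume: BoldVolume, truth: SyntheticTruth) -> float:
    """Mean, over planted clusters, of the within-cluster R-bar.

    R-bar of a cluster is the mean correlation of each member course
    with the cluster's mean course -- the quantity the detection model
    summarises per region.
    """
    from .detect import _CourseCache   # local import to avoid cycle at import time
    cache = _CourseCache(volume)
    vals = []
    for members in truth.cluster_members:
        arr = np.asarray(sorted(members), dtype=int)
        mean_course = cache.data[arr[:, 0], arr[:, 1], arr[:, 2], :].mean(axis=0)
        r = cache.corr_voxels_with_course(arr, mean_course)
        vals.append(float(np.nanmean(r)))
    if not vals:
        raise ParameterError("truth contains no clusters")
    return float(np.mean(vals))


def calibrate_noise(target_r_bar: float, spec: SyntheticSpec,
                    *, n_reps: int = 3, tol: float = 0.01,
                    max_iter: int = 40) -> float:
    """Bisect ``noise_sd`` until the planted within-cluster R-bar hits a target.

    The objective at a given sd is the mean R-bar over ``n_reps``
    simulations with seeds derived from ``spec.rng_seed`` (so the
    objective is deterministic and monotone in sd). Returns the
    calibrated sd; raises :class:`CalibrationError` if the target cannot
    be bracketed.
    """
    if not 0.0 < target_r_bar <= 1.0:
        raise ParameterError("target_r_bar must lie in (0, 1]")
    if target_r_bar == 1.0:
        return 0.0

    def objective(sd: float) -> float:
        vals = [measure_r_bar(*simulate(replace(spec, noise_sd=sd,
                                                rng_seed=spec.rng_seed + 7919 * i)))
                for i in range(n_reps)]
        return float(np.mean(vals))

    lo, hi = 0.0, 0.5
    f_hi = objective(hi)
    doublings = 0
    while f_hi > target_r_bar:
        lo, hi = hi, hi * 2.0
        f_hi = objective(hi)
        doublings += 1
        if doublings > 8:
            raise CalibrationError(
                f"target R-bar {target_r_bar} not bracketed by sd <= {hi}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = objective(mid)
        if abs(f_mid - target_r_bar) <= tol * 0.5 or (hi - lo) < 1e-4:
            return mid
        if f_mid > target_r_bar:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
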