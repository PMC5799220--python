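"""FAUPA detection: seeded, iterative correlation-threshold region growing.

A FAUPA (functional area of unitary pooled activity) is a contiguous set
of voxels whose BOLD time courses are, up to amplitude and noise, the
same course. Detection scans every candidate centre voxel and runs three
stages:

1. **Seeding.** The centre's course is correlated with each of its 26
   neighbours. If at least ``seed_size`` (default 4) neighbours exceed
   ``r_seed`` (default 0.9), the ``seed_size`` best-correlated
   neighbours form the seed.
2. **Growth.** From the seed's mean course, the member correlations R_i
   give mu and sigma, hence a membership threshold TH1 = mu - 1.645*sigma.
   All voxels of an 11x11x11 box around the centre are correlated with
   the current mean course and thresholded at TH1; the largest
   26-connected supra-threshold cluster becomes the new region, whose
   own mean course and moments give the next TH1. Iteration stops at an
   exactly repeating voxel set (stable), or fails if the region exceeds
   ``max_voxels`` (29) or ``max_iter`` (20) iterations.
3. **Acceptance.** With TH2 = mu - 2.327*sigma, a voxel whose R_i follows
   the region's own correlation model has a ~4% chance of falling in
   (TH2, TH1). The one-voxel border layer (K voxels) is therefore allowed
   at most K_c = 4% x K members of that band; the region is accepted as a
   FAUPA iff the observed band count L satisfies L <= K_c.

Voxels of accepted FAUPAs are removed from further candidacy and
membership, so the output parcels are pairwise disjoint. Scan order is
lexicographic and all ties are broken deterministically, so identical
input and configuration produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage

from . import core_stats
from .core_stats import Thresholds, corr_with_course
from .errors import ParameterError
from .volume_io import (STRUCT26, BoldVolume, LabelMap, Voxel, border_layer,
                        connected_components)


@dataclass(frozen=True)
class DetectionConfig:
    """Every constant of the detection algorithm, with the published defaults."""

    r_seed: float = 0.9
    seed_size: int = 4
    box_halfwidth: int = 5
    z1: float = core_stats.Z_TH1
    z2: float = core_stats.Z_TH2
    max_voxels: int = 29
    max_iter: int = 20
    border_frac: float = 0.04
    min_voxels: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.r_seed < 1.0:
            raise ParameterError("r_seed must lie in (0, 1)")
        if self.seed_size < 2:
            raise ParameterError("seed_size must be >= 2")
        if self.box_halfwidth < 1:
            raise ParameterError("box_halfwidth must be >= 1")
        if not self.z2 > self.z1 > 0:
            raise ParameterError("need z2 > z1 > 0")
        if not self.max_voxels >= self.min_voxels >= 2:
            raise ParameterError("need max_voxels >= min_voxels >= 2")
        if not 0.0 < self.border_frac < 1.0:
            raise ParameterError("border_frac must lie in (0, 1)")


@dataclass(frozen=True)
class BorderCheck:
    """Outcome of the 4%-band acceptance criterion on the border layer."""

    k_total: int
    k_crit: float
    l_count: int
    accepted: bool


@dataclass
class Faupa:
    """A detected region with its full acceptance record."""

    voxels: tuple[Voxel, ...]
    seed_voxel: Voxel
    mean_course: np.ndarray
    r_values: np.ndarray
    mu: float
    sigma: float
    r_bar: float
    th1: float
    th2: float
    n_iterations: int
    border: BorderCheck
    id: int = 0

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class _GrowResult:
    voxels: frozenset[Voxel]
    thresholds: Thresholds
    mean_course: np.ndarray
    r_values: np.ndarray
    mu: float
    sigma: float
    n_iterations: int


class _CourseCache:
    """Centred, unit-norm time courses plus a validity mask.

    Correlation between voxels then reduces to a dot product. Voxels
    outside the brain mask or with zero temporal variance are invalid
    and transparent to every stage.
    """

    def __init__(self, volume: BoldVolume):
        d = volume.data - volume.data.mean(axis=3, keepdims=True)
        norm = np.sqrt((d * d).sum(axis=3))
        self.valid = volume.mask & (norm > 0)
        safe = np.where(norm > 0, norm, 1.0)
        self.z = d / safe[..., np.newaxis]
        self.data = volume.data
        self.dims = volume.geometry.dims

    def corr_voxels_with_course(self, idx: np.ndarray, course: np.ndarray) -> np.ndarray:
        """R_i of the voxels at integer index array (N, 3) vs an arbitrary course."""
        dc = course - course.mean()
        nc = np.linalg.norm(dc)
        zc = dc / nc
        r = self.z[idx[:, 0], idx[:, 1], idx[:, 2], :] @ zc
        return core_stats._snap(r)


def _candidate_prefilter(cache: _CourseCache, config: DetectionConfig) -> np.ndarray:
    """Count, per voxel, valid 26-neighbours correlated above ``r_seed``.

    Used as a cheap superset filter for seed centres: claiming voxels
    later can only remove neighbours, so a voxel failing this count can
    never seed.
    """
    z, valid = cache.z, cache.valid
    count = np.zeros(cache.dims, dtype=np.int16)
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) > (0, 0, 0)]  # half set; each pair counted both ways
    for dx, dy, dz in offsets:
        sa = tuple(slice(max(d, 0), None if d >= 0 else d) for d in (dx, dy, dz))
        sb = tuple(slice(max(-d, 0), None if d <= 0 else -d) for d in (dx, dy, dz))
        r = (z[sb] * z[sa]).sum(axis=3)
        hit = (r > config.r_seed) & valid[sa] & valid[sb]
        count[sb] += hit
        count[sa] += hit
    return count


def make_seed(voxel: Voxel, volume: BoldVolume, config: DetectionConfig,
              *, cache: Optional[_CourseCache] = None,
              exclude: Optional[np.ndarray] = None) -> Optional[set[Voxel]]:
    """Seed rule at one centre voxel.

    Returns the ``seed_size`` neighbours with the largest correlation
    against the centre's course if at least ``seed_size`` valid
    neighbours exceed ``r_seed``; ties broken by lexicographic index.
    Returns None otherwise (including for a degenerate centre).
    """
    cache = cache or _CourseCache(volume)
    x, y, z = voxel
    if not cache.valid[x, y, z] or (exclude is not None and exclude[x, y, z]):
        return None
    dims = cache.dims
    neigh = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                n = (x + dx, y + dy, z + dz)
                if (0 <= n[0] < dims[0] and 0 <= n[1] < dims[1]
                        and 0 <= n[2] < dims[2] and cache.valid[n]
                        and (exclude is None or not exclude[n])):
                    neigh.append(n)
    if len(neigh) < config.seed_size:
        return None
    idx = np.asarray(neigh, dtype=int)
    zc = cache.z[x, y, z, :]
    r = core_stats._snap(cache.z[idx[:, 0], idx[:, 1], idx[:, 2], :] @ zc)
    above = [(float(ri), n) for ri, n in zip(r, neigh) if ri > config.r_seed]
    if len(above) < config.seed_size:
        return None
    above.sort(key=lambda t: (-t[0], t[1]))
    return {n for _, n in above[:config.seed_size]}


def grow_roi(seed: Iterable[Voxel], center: Voxel, volume: BoldVolume,
             config: DetectionConfig, *, cache: Optional[_CourseCache] = None,
             exclude: Optional[np.ndarray] = None) -> Optional[_GrowResult]:
    """Iterate the threshold-and-recluster loop to a stable region.

    Starting from the seed, each pass correlates every valid voxel of the
    (2*box_halfwidth+1)^3 box around ``center`` with the current region's
    mean course, thresholds at the region's own TH1 (R_i >= TH1) and keeps
    the largest 26-connected cluster. Returns None on failure (region
    exceeds ``max_voxels``, iteration cap reached, or an empty cluster).
    """
    cache = cache or _CourseCache(volume)
    hw = config.box_halfwidth
    dims = cache.dims
    lo = [max(c - hw, 0) for c in center]
    hi = [min(c + hw, d - 1) for c, d in zip(center, dims)]
    box_valid = cache.valid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1].copy()
    if exclude is not None:
        box_valid &= ~exclude[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    box_idx = np.argwhere(box_valid) + lo   # lexicographic (N, 3), global coords
    if box_idx.size == 0:
        return None
    members = frozenset(tuple(v) for v in seed)
    if not members:
        return None

    def stats_of(mem: frozenset[Voxel]):
        arr = np.asarray(sorted(mem), dtype=int)
        mean_course = cache.data[arr[:, 0], arr[:, 1], arr[:, 2], :].mean(axis=0)
        r_mem = cache.corr_voxels_with_course(arr, mean_course)
        mu = float(r_mem.mean())
        sigma = float(r_mem.std(ddof=1)) if r_mem.size > 1 else 0.0
        return mean_course, r_mem, mu, sigma

    mean_course, r_mem, mu, sigma = stats_of(members)
    for iteration in range(1, config.max_iter + 1):
        th = core_stats.thresholds_from_moments(mu, sigma, config.z1, config.z2)
        r_box = cache.corr_voxels_with_course(box_idx, mean_course)
        above = box_idx[r_box >= th.th1]
        if above.shape[0] == 0:
            return None
        comps = connected_components(map(tuple, above))
        new = frozenset(comps[0])
        if len(new) > config.max_voxels:
            return None
        if new == members:
            return _GrowResult(voxels=members, thresholds=th,
                               mean_course=mean_course,
                               r_values=r_mem, mu=mu, sigma=sigma,
                               n_iterations=iteration)
        members = new
        mean_course, r_mem, mu, sigma = stats_of(members)
    return None


def border_check(roi: Iterable[Voxel], thresholds: Thresholds,
                 volume: BoldVolume, config: DetectionConfig,
                 *, cache: Optional[_CourseCache] = None,
                 mean_course: Optional[np.ndarray] = None) -> BorderCheck:
    """Apply the 4%-band criterion to the region's one-voxel border layer.

    K counts the valid (in-mask, non-degenerate) border voxels, and L
    those whose correlation with the region's mean course lies strictly
    between TH2 and TH1. The bound K_c = border_frac * K is kept
    real-valued; acceptance is L <= K_c.
    """
    cache = cache or _CourseCache(volume)
    roi = set(roi)
    if mean_course is None:
        arr = np.asarray(sorted(roi), dtype=int)
        mean_course = cache.data[arr[:, 0], arr[:, 1], arr[:, 2], :].mean(axis=0)
    border = border_layer(roi, cache.valid)
    k_total = len(border)
    k_crit = config.border_frac * k_total
    if k_total == 0:
        return BorderCheck(k_total=0, k_crit=0.0, l_count=0, accepted=True)
    idx = np.asarray(sorted(border), dtype=int)
    r = cache.corr_voxels_with_course(idx, mean_course)
    l_count = int(np.sum((r > thresholds.th2) & (r < thresholds.th1)))
    return BorderCheck(k_total=k_total, k_crit=k_crit, l_count=l_count,
                       accepted=l_count <= k_crit)


def detect_faupas(volume: BoldVolume,
                  config: DetectionConfig = DetectionConfig()
                  ) -> tuple[list[Faupa], LabelMap]:
    """Whole-volume scan: seed, grow and accept at every candidate centre.

    Centres are visited in lexicographic order. Voxels of accepted FAUPAs
    are removed from later seeding and membership, so accepted regions
    are pairwise disjoint; ids follow discovery order (1-based in the
    returned label map).
    """
    cache = _CourseCache(volume)
    counts = _candidate_prefilter(cache, config)
    candidates = np.argwhere((counts >= config.seed_size) & cache.valid)
    claimed = np.zeros(cache.dims, dtype=bool)
    faupas: list[Faupa] = []
    for cand in candidates:
        center = tuple(int(c) for c in cand)
        if claimed[center]:
            continue
        seed = make_seed(center, volume, config, cache=cache, exclude=claimed)
        if seed is None:
            continue
        grown = grow_roi(seed, center, volume, config, cache=cache, exclude=claimed)
        if grown is None or len(grown.voxels) < config.min_voxels:
            continue
        check = border_check(grown.voxels, grown.thresholds, volume, config,
                             cache=cache, mean_course=grown.mean_course)
        if not check.accepted:
            continue
        ordered = tuple(sorted(grown.voxels))
        faupa = Faupa(voxels=ordered, seed_voxel=center,
                      mean_course=grown.mean_course,
                      r_values=grown.r_values, mu=grown.mu, sigma=grown.sigma,
                      r_bar=float(grown.r_values.mean()),
                      th1=grown.thresholds.th1, th2=grown.thresholds.th2,
                      n_iterations=grown.n_iterations, border=check,
                      id=len(faupas) + 1)
        faupas.append(faupa)
        arr = np.asarray(ordered, dtype=int)
        claimed[arr[:, 0], arr[:, 1], arr[:, 2]] = True
    labels = np.zeros(cache.dims, dtype=np.int32)
    for f in faupas:
        arr = np.asarray(f.voxels, dtype=int)
        labels[arr[:, 0], arr[:, 1], arr[:, 2]] = f.id
    return faupas, LabelMap(geometry=volume.geometry, labels=labels)


def verify_faupa(faupa: Faupa, volume: BoldVolume,
                 config: DetectionConfig = DetectionConfig()) -> bool:
    """Recompute a FAUPA's full acceptance record from its stored voxel set.

    Checks that the mean course, member correlations, moments, thresholds
    and the border criterion all reproduce the stored record with
    ``accepted=True`` -- the self-consistency property of the detection
    model.
    """
    cache = _CourseCache(volume)
    arr = np.asarray(sorted(faupa.voxels), dtype=int)
    mean_course = cache.data[arr[:, 0], arr[:, 1], arr[:, 2], :].mean(axis=0)
    if not np.allclose(mean_course, faupa.mean_course, atol=1e-10):
        return False
    r = cache.corr_voxels_with_course(arr, mean_course)
    mu = float(r.mean())
    sigma = float(r.std(ddof=1)) if r.size > 1 else 0.0
    th = core_stats.thresholds_from_moments(mu, sigma, config.z1, config.z2)
    if not (np.allclose(r, faupa.r_values, atol=1e-10)
            and abs(mu - faupa.mu) < 1e-10 and abs(sigma - faupa.sigma) < 1e-10
            and abs(th.th1 - faupa.th1) < 1e-10 and abs(th.th2 - faupa.th2) < 1e-10):
        return False
    if np.any(r < th.th1):
        return False
    check = border_check(faupa.voxels, th, volume, config,
                         cache=cache, mean_course=mean_course)
    return (check.k_total == faupa.border.k_total
            and check.l_count == faupa.border.l_count
            and check.accepted)
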