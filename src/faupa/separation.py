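"""Separation of a detected region from its one-voxel adjacent layer.

For each FAUPA, every member and every border voxel is correlated with
the FAUPA's mean course S-bar(t); a one-tailed two-sample t-test
(member R_i > border R_i, pooled variance by default) yields the
separation p-value. A FAUPA counts as separated when p < 0.05
(uncorrected -- each region is its own question).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_stats import one_tail_two_sample_t
from .detect import Faupa, _CourseCache
from .errors import DegenerateSeriesError, ParameterError
from .volume_io import BoldVolume, border_layer

SEPARATION_ALPHA = 0.05


@dataclass(frozen=True)
class SeparationResult:
    faupa_id: int
    p_value: float
    n_border: int
    n_members: int
    separated: bool
    testable: bool = True


def separation_test(faupa: Faupa, volume: BoldVolume,
                    *, cache: Optional[_CourseCache] = None,
                    exclude_other_faupas: Optional[np.ndarray] = None,
                    equal_var: bool = True) -> SeparationResult:
    """Test one FAUPA against its border layer.

    Border voxels belonging to other detected FAUPAs are included by
    default; pass a boolean exclusion mask via ``exclude_other_faupas``
    to drop them. A border with fewer than 2 usable voxels makes the
    test impossible; the result is then flagged ``testable=False`` and
    excluded from histograms.
    """
    cache = cache or _CourseCache(volume)
    members = np.asarray(sorted(faupa.voxels), dtype=int)
    if members.shape[0] < 2:
        raise ParameterError("need at least 2 member voxels")
    mean_course = cache.data[members[:, 0], members[:, 1], members[:, 2], :].mean(axis=0)
    r_members = cache.corr_voxels_with_course(members, mean_course)
    usable = cache.valid.copy()
    if exclude_other_faupas is not None:
        usable &= ~exclude_other_faupas
    border = sorted(border_layer(faupa.voxels, usable))
    if len(border) < 2:
        return SeparationResult(faupa_id=faupa.id, p_value=float("nan"),
                                n_border=len(border), n_members=members.shape[0],
                                separated=False, testable=False)
    bidx = np.asarray(border, dtype=int)
    r_border = cache.corr_voxels_with_course(bidx, mean_course)
    try:
        p = one_tail_two_sample_t(r_members, r_border, equal_var=equal_var)
    except DegenerateSeriesError:
        return SeparationResult(faupa_id=faupa.id, p_value=float("nan"),
                                n_border=len(border), n_members=members.shape[0],
                                separated=False, testable=False)
    return SeparationResult(faupa_id=faupa.id, p_value=p,
                            n_border=len(border), n_members=members.shape[0],
                            separated=p < SEPARATION_ALPHA)


def separation_tests(faupas: Sequence[Faupa], volume: BoldVolume,
                     **kwargs) -> list[SeparationResult]:
    """Run :func:`separation_test` for every FAUPA, sharing one course cache."""
    cache = _CourseCache(volume)
    return [separation_test(f, volume, cache=cache, **kwargs) for f in faupas]


def pvalue_histogram(results: Iterable[SeparationResult],
                     bin_edges: Sequence[float]) -> np.ndarray:
    """Counts of testable separation p-values per bin.

    Bins are half-open [lo, hi) except the last, which is closed -- the
    numpy histogram convention.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("bin_edges must be strictly increasing, length >= 2")
    p = np.asarray([r.p_value for r in results if r.testable], dtype=float)
    counts, _ = np.histogram(p, bins=edges)
    return counts
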