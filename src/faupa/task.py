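"""Task paradigms, hemodynamic ideal responses and FAUPA-task association.

The expected BOLD course for a task condition is built the standard way:
a boxcar (1 during task periods, 0 otherwise) on a fine time grid is
convolved with a canonical double-gamma hemodynamic response function
(peak ~6 s, undershoot ~16 s, undershoot ratio 1/6), sampled at the TR,
and placed on a unit baseline. The relative-change conversion
(subtract the mean, divide by the mean) makes the course dimensionless
and invariant to any overall scaling of the response, so only the shape
matters for the Pearson correlation used to quantify association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core_stats import pearson_p, pearson_r
from .errors import ParameterError

Trial = tuple[float, float, str]

#: support of the sampled HRF kernel, seconds
HRF_SUPPORT_S = 32.0


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (seconds, except the dimensionless ratio)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_disp, self.undershoot_disp) <= 0:
            raise ParameterError("delays and dispersions must be positive")
        if not 0.0 < self.undershoot_ratio < 1.0:
            raise ParameterError("undershoot_ratio must lie in (0, 1)")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")


@dataclass(frozen=True)
class TaskParadigm:
    """Trial timing: (onset s, duration s, condition label) per trial."""

    trials: tuple[Trial, ...]
    tr: float
    n_timepoints: int
    conditions: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.n_timepoints < 3:
            raise ParameterError("need tr > 0 and n_timepoints >= 3")
        total = self.tr * self.n_timepoints
        last = -1.0
        for onset, duration, _ in self.trials:
            if onset < 0 or duration < 0:
                raise ParameterError("onsets and durations must be non-negative")
            if onset <= last:
                raise ParameterError("onsets must be strictly increasing")
            if onset + duration > total + 1e-9:
                raise ParameterError(
                    f"trial at {onset}s exceeds scan length {total}s")
            last = onset
        labels = frozenset(t[2] for t in self.trials)
        object.__setattr__(self, "conditions", self.conditions | labels)

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float, n_timepoints: int) -> "TaskParadigm":
        df = pd.read_csv(path, sep="\t")
        need = {"onset_s", "duration_s", "condition"}
        if not need.issubset(df.columns):
            raise ParameterError(f"paradigm TSV must have columns {sorted(need)}")
        trials = tuple((float(r.onset_s), float(r.duration_s), str(r.condition))
                       for r in df.itertuples())
        return cls(trials=trials, tr=tr, n_timepoints=n_timepoints)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.trials, columns=["onset_s", "duration_s", "condition"]
                     ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class IdealResponse:
    """Expected BOLD course at the TR and its relative-change version."""

    course: np.ndarray
    relative_course: np.ndarray


def default_paradigm(tr: float = 2.5, n_timepoints: int = 288) -> TaskParadigm:
    """The bundled three-task paradigm used throughout the simulations.

    24 trials, each a 6-s task period followed by a 24-s rest period;
    the three conditions (word reading WR, pattern viewing PV, finger
    tapping FT) are interleaved, 8 trials each, filling a 720-s scan.
    """
    labels = ("WR", "PV", "FT")
    trials = tuple((30.0 * k, 6.0, labels[k % 3]) for k in range(24))
    return TaskParadigm(trials=trials, tr=tr, n_timepoints=n_timepoints)


def load_bundled_paradigm(tr: float = 2.5, n_timepoints: int = 288) -> TaskParadigm:
    """Load the packaged copy of the default paradigm TSV."""
    with resources.as_file(resources.files("faupa").joinpath(
            "data/ft_paradigm.tsv")) as p:
        return TaskParadigm.from_tsv(p, tr=tr, n_timepoints=n_timepoints)


def hrf(params: HrfParams = HrfParams()) -> np.ndarray:
    """Double-gamma HRF sampled on the dt grid over [0, 32 s], peak = 1."""
    t = np.arange(0.0, HRF_SUPPORT_S + params.dt / 2, params.dt)
    peak = sstats.gamma.pdf(t, params.peak_delay / params.peak_disp,
                            scale=params.peak_disp)
    under = sstats.gamma.pdf(t, params.undershoot_delay / params.undershoot_disp,
                             scale=params.undershoot_disp)
    h = peak - params.undershoot_ratio * under
    return h / h.max()


def ideal_response(paradigm: TaskParadigm, condition: str,
                   hrf_params: HrfParams = HrfParams()) -> IdealResponse:
    """Expected course for one condition: boxcar * HRF on a unit baseline.

    A condition with no trials yields a flat course whose relative
    version is the zero series. An unknown condition label is an error.
    """
    if condition not in paradigm.conditions:
        raise ParameterError(f"condition {condition!r} not in paradigm "
                             f"{sorted(paradigm.conditions)}")
    dt = hrf_params.dt
    total = paradigm.tr * paradigm.n_timepoints
    n_fine = int(round(total / dt))
    box = np.zeros(n_fine)
    tgrid = np.arange(n_fine) * dt
    for onset, duration, label in paradigm.trials:
        if label == condition:
            box[(tgrid >= onset) & (tgrid < onset + duration)] = 1.0
    kernel = hrf(hrf_params)
    resp = np.convolve(box, kernel)[:n_fine] * dt
    sample = np.minimum(np.round(np.arange(paradigm.n_timepoints)
                                 * paradigm.tr / dt).astype(int), n_fine - 1)
    course = 1.0 + resp[sample]
    m = course.mean()
    relative = (course - m) / m
    return IdealResponse(course=course, relative_course=relative)


def associate(faupa_course: Sequence[float], ideal: IdealResponse) -> tuple[float, float]:
    """Pearson r and two-tailed p of a FAUPA course vs the ideal response."""
    course = np.asarray(faupa_course, dtype=float)
    r = pearson_r(course, ideal.relative_course)
    return r, pearson_p(r, course.size)


def group_mean_course(courses: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sd (n-1; zeros for a single course) of a course stack."""
    if len(courses) < 1:
        raise ParameterError("need at least one course")
    stack = np.asarray(courses, dtype=float)
    if stack.ndim != 2:
        raise ParameterError("courses must share one length")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    return mean, sd


def association_table(courses: dict[int, np.ndarray], paradigm: TaskParadigm,
                      condition: str,
                      hrf_params: HrfParams = HrfParams()) -> pd.DataFrame:
    """Rank FAUPA mean courses by correlation with a condition's ideal response."""
    ideal = ideal_response(paradigm, condition, hrf_params)
    rows = []
    for fid, course in courses.items():
        r, p = associate(course, ideal)
        rows.append({"faupa_id": fid, "condition": condition, "r": r, "p": p})
    df = pd.DataFrame(rows, columns=["faupa_id", "condition", "r", "p"])
    return df.sort_values("r", ascending=False, ignore_index=True)
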