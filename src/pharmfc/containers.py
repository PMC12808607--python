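"""Core in-memory containers shared across the pipeline.

The central currency is :class:`RoiTimeSeriesSet`: one ROI x time BOLD
matrix per animal, together with the acquisition timing (TR, injection
onsets) and genotype labels. Condition bookkeeping lives in
:class:`ConditionSegmentation`, an ordered list of equal-length,
half-open sample intervals labelled baseline / vehicle / drug.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

CONDITIONS = ("baseline", "vehicle", "drug")


@dataclass
class RoiTimeSeriesSet:
    """Per-animal ROI x time signal matrices plus shared experiment timing.

    Parameters
    ----------
    data:
        Array of shape ``(n_animals, n_roi, n_t)`` in arbitrary BOLD units.
    animal_ids, genotypes:
        One entry per animal; genotype is ``"WT"`` or ``"KO"``.
    roi_labels:
        Region labels, one per row of each signal matrix.
    tr_s:
        Sampling interval (repetition time) in seconds.
    vehicle_onset_s, drug_onset_s:
        Injection times relative to run start, in seconds.
    nuisance:
        Optional per-animal nuisance regressors ``(n_animals, n_reg, n_t)``
        (e.g. pseudo white-matter / CSF signals, motion parameters).
    """

    data: np.ndarray
    animal_ids: list[str]
    genotypes: list[str]
    roi_labels: list[str]
    tr_s: float
    vehicle_onset_s: float
    drug_onset_s: float
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_animals, n_roi, n_t)")
        n_animals, n_roi, _ = self.data.shape
        if len(self.animal_ids) != n_animals or len(self.genotypes) != n_animals:
            raise ValueError("animal_ids/genotypes length mismatch with data")
        if len(self.roi_labels) != n_roi:
            raise ValueError("roi_labels length mismatch with data")
        if not (0 < self.vehicle_onset_s < self.drug_onset_s < self.duration_s):
            raise ValueError("onsets must satisfy 0 < vehicle < drug < duration")

    # -- shape helpers -------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    @property
    def n_t(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_t * self.tr_s

    def roi_index(self, label: str | int) -> int:
        if isinstance(label, (int, np.integer)):
            return int(label)
        try:
            return self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label: {label!r}") from None

    def subset(self, genotype: str) -> "RoiTimeSeriesSet":
        """Return the animals of one genotype as a new set."""
        mask = [g == genotype for g in self.genotypes]
        if not any(mask):
            raise ValueError(f"no animals with genotype {genotype!r}")
        idx = np.flatnonzero(mask)
        return replace(
            self,
            data=self.data[idx],
            animal_ids=[self.animal_ids[i] for i in idx],
            genotypes=[self.genotypes[i] for i in idx],
            nuisance=None if self.nuisance is None else self.nuisance[idx],
        )

    def with_data(self, data: np.ndarray) -> "RoiTimeSeriesSet":
        return replace(self, data=data)


@dataclass(frozen=True)
class Interval:
    """Half-open sample interval ``[start, stop)`` within one condition."""

    condition: str
    index: int  # 0-based index within its condition
    start: int  # inclusive sample
    stop: int   # exclusive sample

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class ConditionSegmentation:
    """Ordered, contiguous, equal-length condition intervals covering a run."""

    intervals: list[Interval]
    interval_length_s: float
    tr_s: float

    def __post_init__(self) -> None:
        pos = 0
        for iv in self.intervals:
            if iv.start != pos:
                raise ValueError("intervals must be contiguous and ordered")
            if iv.stop - iv.start != self.interval_samples:
                raise ValueError("all intervals must share interval_length_s")
            pos = iv.stop

    @property
    def interval_samples(self) -> int:
        return int(round(self.interval_length_s / self.tr_s))

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def condition(self, name: str) -> list[Interval]:
        if name not in CONDITIONS:
            raise ValueError(f"unknown condition {name!r}")
        return [iv for iv in self.intervals if iv.condition == name]

    def condition_slice(self, name: str) -> slice:
        """Full half-open sample span of one condition."""
        ivs = self.condition(name)
        if not ivs:
            raise ValueError(f"condition {name!r} has no intervals")
        return slice(ivs[0].start, ivs[-1].stop)

    def counts(self) -> dict[str, int]:
        return {c: len(self.condition(c)) for c in CONDITIONS}


def group_mean_sem(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error across animals (ddof=1, sqrt(n) scaling)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    mean = np.nanmean(values, axis=axis)
    if n < 2:
        return mean, np.full_like(mean, np.nan)
    sem = np.nanstd(values, axis=axis, ddof=1) / np.sqrt(n)
    return mean, sem
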