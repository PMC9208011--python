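"""Domain containers shared across the pipeline.

The study unit is a *dish*: a culture imaged at up to three timepoints under
one of four treatment arms (MEM/MPEP x Sham/Injury). ROIs are either whole
neurons or astrocyte segments (microdomains); segments of one astrocyte carry
a common ``parent_cell_id`` and are analyzed as independent network nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

def as_seedseq(seed) -> np.random.SeedSequence:
    """Coerce an int (or an existing SeedSequence) into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


NEURON = "neuron"
ASTRO = "astrocyte_segment"
CELL_TYPES = (NEURON, ASTRO)

DRUGS = ("MEM", "MPEP")
INJURIES = ("Sham", "Injury")
TIMEPOINTS = ("baseline", "post_drug", "post_injury")


@dataclass(frozen=True)
class Roi:
    """A region of interest: one neuron or one astrocyte segment."""

    roi_id: str
    cell_type: str
    x: float
    y: float
    parent_cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.cell_type == ASTRO and self.parent_cell_id is None:
            raise ValueError(f"astrocyte segment {self.roi_id} lacks parent_cell_id")
        if self.cell_type == NEURON and self.parent_cell_id is not None:
            raise ValueError(f"neuron {self.roi_id} must not have parent_cell_id")


@dataclass
class Population:
    """All ROIs of one dish, with the imaging field-of-view geometry."""

    rois: list[Roi]
    fov_width: float
    fov_height: float
    dish_id: str = "dish"

    def __post_init__(self) -> None:
        if self.fov_width <= 0 or self.fov_height <= 0:
            raise ValueError("FOV dimensions must be positive")
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValueError("ROI ids must be unique")
        for r in self.rois:
            if not (0 <= r.x <= self.fov_width and 0 <= r.y <= self.fov_height):
                raise ValueError(f"ROI {r.roi_id} centroid outside FOV")

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def roi_ids(self) -> list[str]:
        return [r.roi_id for r in self.rois]

    @property
    def cell_types(self) -> np.ndarray:
        return np.array([r.cell_type for r in self.rois])

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) centroid array in FOV units."""
        return np.array([[r.x, r.y] for r in self.rois], dtype=float)

    @property
    def fov_diagonal(self) -> float:
        return float(np.hypot(self.fov_width, self.fov_height))

    def indices_of(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(self.cell_types == cell_type)

    def subset(self, roi_ids: Sequence[str]) -> "Population":
        """Sub-population keeping ``roi_ids`` in the original order."""
        keep = set(roi_ids)
        return replace(self, rois=[r for r in self.rois if r.roi_id in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "dish_id": self.dish_id,
                "cell_type": self.cell_types,
                "parent_cell_id": [r.parent_cell_id for r in self.rois],
                "x": [r.x for r in self.rois],
                "y": [r.y for r in self.rois],
            }
        )


@dataclass(frozen=True)
class ConditionSpec:
    """Treatment arm, timepoint, and the effect knobs active at that timepoint.

    Knobs are multiplicative and type-targeted: ``neuron_rate_multiplier``
    scales neuronal event rates, ``neuron_coupling_multiplier`` scales
    neuron-neuron ground-truth coupling, ``spatial_multiplier`` scales the
    spatial-dependence mixing fraction of the coupling model. Baseline
    recordings are untouched by construction (all knobs identity).
    """

    drug: str = "MEM"
    injury: str = "Sham"
    timepoint: str = "baseline"
    neuron_rate_multiplier: float = 1.0
    neuron_coupling_multiplier: float = 1.0
    spatial_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.injury not in INJURIES:
            raise ValueError(f"unknown injury {self.injury!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        knobs = (
            self.neuron_rate_multiplier,
            self.neuron_coupling_multiplier,
            self.spatial_multiplier,
        )
        if any(k < 0 for k in knobs):
            raise ValueError("effect multipliers must be >= 0")
        if self.timepoint == "baseline" and any(k != 1.0 for k in knobs):
            raise ValueError("baseline knobs must be identity (1.0)")

    @property
    def group(self) -> str:
        return f"{self.drug}-{self.injury}"


@dataclass
class TraceSet:
    """Fluorescence matrix (frames x ROIs) for one dish at one timepoint."""

    traces: np.ndarray
    sampling_rate: float
    population: Population
    condition: ConditionSpec = field(default_factory=ConditionSpec)
    event_times: Optional[list[np.ndarray]] = None  # ground truth, seconds

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (frames x ROIs) array")
        if self.traces.shape[1] != len(self.population):
            raise ValueError(
                f"trace columns ({self.traces.shape[1]}) != ROIs "
                f"({len(self.population)})"
            )
        if self.sampling_rate <= 10:
            raise ValueError("sampling_rate must exceed 10 Hz")
        if self.event_times is not None and len(self.event_times) != len(self.population):
            raise ValueError("event_times must have one entry per ROI")

    @property
    def dish_id(self) -> str:
        return self.population.dish_id

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate

    @property
    def roi_ids(self) -> list[str]:
        return self.population.roi_ids

    def subset(self, roi_ids: Sequence[str]) -> "TraceSet":
        keep = set(roi_ids)
        cols = [i for i, rid in enumerate(self.population.roi_ids) if rid in keep]
        return TraceSet(
            traces=self.traces[:, cols],
            sampling_rate=self.sampling_rate,
            population=self.population.subset(roi_ids),
            condition=self.condition,
            event_times=None
            if self.event_times is None
            else [self.event_times[i] for i in cols],
        )


def validate_coupling(matrix: np.ndarray, n: int) -> np.ndarray:
    """Check a ground-truth coupling matrix: symmetric, zero diagonal, [0, 1]."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"coupling shape {m.shape} does not match {n} ROIs")
    if not np.allclose(m, m.T):
        raise ValueError("coupling must be symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError("coupling diagonal must be zero")
    if m.min() < 0 or m.max() > 1:
        raise ValueError("coupling strengths must lie in [0, 1]")
    return m
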