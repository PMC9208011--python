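"""Trace preprocessing, template-matching event detection, and ROI pruning.

Detection mirrors the study pipeline: a sliding-window Pearson correlation of
the processed trace against a library of canonical transient waveforms; local
correlation maxima above a strict threshold become events (the threshold
stands in for the original manual confirmation step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .types import ASTRO, NEURON, Population, TraceSet
from .waveforms import TemplateLibrary

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_CUTOFF_HZ = 2.0


def preprocess_trace(
    raw: np.ndarray,
    sampling_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = 4,
) -> np.ndarray:
    """Linear detrend, zero-phase low-pass, then z-score.

    Constant traces come back as all zeros. The filter is a 4th-order
    Butterworth applied forward-backward (``filtfilt``) so event timing is
    preserved.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D trace")
    if len(x) < 10:
        raise ValueError("trace too short (< 10 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if np.ptp(x) == 0:
        return np.zeros_like(x)
    x = signal.detrend(x, type="linear")
    nyq = sampling_rate / 2.0
    if 0 < cutoff < nyq:
        sos = signal.butter(order, cutoff / nyq, btype="low", output="sos")
        x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def preprocess_traceset(ts: TraceSet, cutoff: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Column-wise :func:`preprocess_trace` on a TraceSet -> (frames x ROIs).

    Vectorized over columns (detrend/filter/z-score act identically per
    column); constant columns come back all-zero.
    """
    X = np.asarray(ts.traces, dtype=float)
    if X.shape[1] == 0:
        return X.copy()
    if not np.all(np.isfinite(X)):
        raise ValueError("traces contain non-finite samples")
    const = np.ptp(X, axis=0) == 0
    Y = signal.detrend(X, axis=0, type="linear")
    nyq = ts.sampling_rate / 2.0
    if 0 < cutoff < nyq:
        sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
        Y = signal.sosfiltfilt(sos, Y, axis=0)
    sd = Y.std(axis=0)
    ok = (sd > 0) & ~const
    out = np.zeros_like(Y)
    out[:, ok] = (Y[:, ok] - Y[:, ok].mean(axis=0)) / sd[ok]
    return out


@dataclass
class EventTrain:
    """Detected events of one ROI: onset times and matched correlations."""

    roi_id: str
    times: np.ndarray  # seconds, strictly increasing
    correlations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if len(self.times) != len(self.correlations):
            raise ValueError("times and correlations must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if len(self.correlations) and (
            self.correlations.min() < -1 - 1e-9 or self.correlations.max() > 1 + 1e-9
        ):
            raise ValueError("correlations must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.times)


def _sliding_correlation(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pearson r between ``w`` and every length-``len(w)`` window of ``x``."""
    n, L = len(x), len(w)
    if n < L:
        return np.empty(0)
    wc = w - w.mean()
    sw = np.sqrt((wc**2).sum())
    cross = signal.fftconvolve(x, wc[::-1], mode="valid")  # sum x[t+k] * wc[k]
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x**2)))
    s1 = csum[L:] - csum[:-L]
    s2 = csum2[L:] - csum2[:-L]
    var = s2 - s1**2 / L
    var[var < 0] = 0.0
    denom = np.sqrt(var) * sw
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cross / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def detect_events(
    trace: np.ndarray,
    library: TemplateLibrary,
    sampling_rate: float,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    cell_type: str | None = None,
    roi_id: str = "",
) -> EventTrain:
    """Template-matching event detection on a processed trace.

    For every template, the sliding-window correlation is computed at each
    candidate onset; the per-onset maximum over templates is kept. Local
    maxima above ``r_threshold`` become events, and overlapping candidates
    within one template length are resolved greedily to the
    highest-correlation onset.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    templates = library.for_type(cell_type) if cell_type else library.all_templates()
    if not templates:
        raise ValueError(f"no templates available (cell_type={cell_type!r})")
    x = np.asarray(trace, dtype=float)
    n = len(x)
    max_len = max(len(w) for w in templates)
    best_r = np.full(n, -np.inf)
    for w in templates:
        r = _sliding_correlation(x, w)
        if len(r):
            best_r[: len(r)] = np.maximum(best_r[: len(r)], r)
    best_r[~np.isfinite(best_r)] = -1.0

    above = best_r >= r_threshold
    # local maxima (plateau-tolerant on the left, strict right)
    left = np.empty(n, dtype=bool)
    right = np.empty(n, dtype=bool)
    left[0], right[-1] = True, True
    left[1:] = best_r[1:] >= best_r[:-1]
    right[:-1] = best_r[:-1] > best_r[1:]
    candidates = np.flatnonzero(above & left & right)

    # greedy non-maximum suppression within one template length
    order = candidates[np.argsort(best_r[candidates])[::-1]]
    accepted: list[int] = []
    for t in order:
        if all(abs(t - a) >= max_len for a in accepted):
            accepted.append(int(t))
    accepted.sort()
    times = np.asarray(accepted, dtype=float) / sampling_rate
    return EventTrain(roi_id=roi_id, times=times,
                      correlations=best_r[accepted] if accepted else np.empty(0))


def detect_events_traceset(
    ts: TraceSet,
    library: TemplateLibrary,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    cutoff: float = DEFAULT_CUTOFF_HZ,
) -> list[EventTrain]:
    """Preprocess and detect per ROI, using that ROI's cell-type templates."""
    processed = preprocess_traceset(ts, cutoff=cutoff)
    return [
        detect_events(
            processed[:, i],
            library,
            ts.sampling_rate,
            r_threshold=r_threshold,
            cell_type=roi.cell_type,
            roi_id=roi.roi_id,
        )
        for i, roi in enumerate(ts.population.rois)
    ]


@dataclass
class PruneReport:
    """Per-dish outcome of inactive-ROI pruning."""

    kept_roi_ids: dict[str, list[str]] = field(default_factory=dict)
    n_active_astro: dict[str, int] = field(default_factory=dict)
    astro_excluded: dict[str, bool] = field(default_factory=dict)

    def astro_dishes(self) -> list[str]:
        """Dishes eligible for astrocyte-layer analyses (>= 2 active segments)."""
        return [d for d, excl in self.astro_excluded.items() if not excl]


def prune_inactive(
    tracesets: list[TraceSet],
    trains: list[list[EventTrain]],
) -> tuple[list[TraceSet], list[list[EventTrain]], PruneReport]:
    """Drop ROIs with zero events across *all* of a dish's recordings.

    An ROI active in any one timepoint is retained at every timepoint of that
    dish. Dishes left with fewer than 2 active astrocyte segments are flagged
    as excluded from astrocyte-layer analyses (they remain in the output).
    """
    if len(tracesets) != len(trains):
        raise ValueError("one train list per traceset required")
    for ts, tr in zip(tracesets, trains):
        ids = {e.roi_id for e in tr}
        if ids != set(ts.roi_ids):
            raise ValueError(f"trains do not cover ROIs of dish {ts.dish_id}")

    active: dict[str, set[str]] = {}
    for ts, tr in zip(tracesets, trains):
        active.setdefault(ts.dish_id, set()).update(
            e.roi_id for e in tr if len(e) > 0
        )

    report = PruneReport()
    out_ts: list[TraceSet] = []
    out_tr: list[list[EventTrain]] = []
    for ts, tr in zip(tracesets, trains):
        keep = [rid for rid in ts.roi_ids if rid in active[ts.dish_id]]
        report.kept_roi_ids[ts.dish_id] = keep
        sub = ts.subset(keep)
        out_ts.append(sub)
        by_id = {e.roi_id: e for e in tr}
        out_tr.append([by_id[rid] for rid in keep])
        n_astro = int(np.sum(sub.population.cell_types == ASTRO))
        report.n_active_astro[ts.dish_id] = n_astro
        report.astro_excluded[ts.dish_id] = n_astro < 2
    return out_ts, out_tr, report


def event_rate_summary(
    tracesets: list[TraceSet],
    trains: list[list[EventTrain]],
) -> pd.DataFrame:
    """Mean event frequency (Hz) per dish / timepoint / cell type.

    Per-ROI rate is event count over recording duration; the summary averages
    over the ROIs present (post-pruning these are the ROIs active at any
    timepoint). Cell types with no ROIs yield no row rather than a zero.
    """
    rows = []
    for ts, tr in zip(tracesets, trains):
        if ts.duration <= 0:
            raise ValueError("recording duration must be positive")
        types = ts.population.cell_types
        rates = np.array([len(e) for e in tr], dtype=float) / ts.duration
        for ct in (NEURON, ASTRO):
            mask = types == ct
            if mask.sum() == 0:
                continue
            rows.append(
                {
                    "dish_id": ts.dish_id,
                    "timepoint": ts.condition.timepoint,
                    "group": ts.condition.group,
                    "cell_type": ct,
                    "mean_rate_hz": float(rates[mask].mean()),
                    "n_rois": int(mask.sum()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["dish_id", "timepoint", "group", "cell_type", "mean_rate_hz", "n_rois"],
    )
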