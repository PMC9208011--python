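"""Calcium transient template waveforms.

Templates are double-exponential (fast rise, slow decay) kernels normalized
to unit peak, emulating GCaMP6f-like kinetics: neuronal transients rise and
decay faster than astrocytic microdomain transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ASTRO, CELL_TYPES, NEURON

# (rise tau, decay tau) in seconds
DEFAULT_KINETICS = {NEURON: (0.1, 0.6), ASTRO: (0.5, 2.0)}


def calcium_template(
    rise_tau: float, decay_tau: float, sampling_rate: float, n_decay: float = 5.0
) -> np.ndarray:
    """Unit-peak double-exponential kernel sampled at ``sampling_rate``.

    The kernel spans ``rise_tau + n_decay * decay_tau`` seconds, long enough
    for the tail to fall below ~1% of the peak.
    """
    if rise_tau <= 0 or decay_tau <= rise_tau:
        raise ValueError("need 0 < rise_tau < decay_tau")
    duration = rise_tau + n_decay * decay_tau
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    h = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate template (sampling rate too low?)")
    return h / peak


@dataclass
class TemplateLibrary:
    """Per-cell-type sets of unit-peak waveforms at a common sampling rate."""

    templates: dict[str, list[np.ndarray]]
    sampling_rate: float

    def __post_init__(self) -> None:
        if not self.templates or all(len(v) == 0 for v in self.templates.values()):
            raise ValueError("template library is empty")
        for ct, tmpls in self.templates.items():
            if ct not in CELL_TYPES:
                raise ValueError(f"unknown cell type {ct!r}")
            for w in tmpls:
                if len(w) < 3:
                    raise ValueError("templates must have >= 3 samples")
                if not np.isclose(np.max(w), 1.0):
                    raise ValueError("templates must be peak-normalized to 1")

    def for_type(self, cell_type: str) -> list[np.ndarray]:
        return self.templates.get(cell_type, [])

    def all_templates(self) -> list[np.ndarray]:
        return [w for tmpls in self.templates.values() for w in tmpls]

    @classmethod
    def default(cls, sampling_rate: float = 20.0) -> "TemplateLibrary":
        return cls(
            templates={
                ct: [calcium_template(rt, dt, sampling_rate)]
                for ct, (rt, dt) in DEFAULT_KINETICS.items()
            },
            sampling_rate=sampling_rate,
        )

    def to_frame(self):
        """Wide table, one template per column, padded with NaN."""
        import pandas as pd

        cols = {}
        for ct, tmpls in self.templates.items():
            for k, w in enumerate(tmpls):
                cols[f"{ct}_{k}"] = pd.Series(w)
        return pd.DataFrame(cols)
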