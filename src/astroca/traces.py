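"""Multi-trial time-series container shared by both simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TraceSet:
    """Seeded multi-trial simulation output.

    ``data`` maps a species/variable name (e.g. ``"ca"``, ``"ip3"``,
    ``"n_open"``, ``"v_post"``) to an array of shape
    ``(n_trials, n_samples, n_columns)`` whose columns are named by
    ``columns[name]`` (compartment ids, or a single variable label).
    ``time`` is in seconds and starts at 0; ``meta['burn_in']`` marks the
    part of the record that analysis discards.
    """

    time: np.ndarray
    data: dict[str, np.ndarray]
    columns: dict[str, list[str]]
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def burn_in(self) -> float:
        return float(self.meta.get("burn_in", 0.0))

    def get(self, species: str, column: str) -> np.ndarray:
        """Trace of one column, shape (n_trials, n_samples)."""
        j = self.columns[species].index(column)
        return self.data[species][:, :, j]

    def window(self, t_min: float | None = None) -> "TraceSet":
        """Restrict to t >= t_min (default: the burn-in time)."""
        if t_min is None:
            t_min = self.burn_in
        keep = self.time >= t_min
        return TraceSet(
            time=self.time[keep],
            data={k: v[:, keep, :] for k, v in self.data.items()},
            columns=dict(self.columns),
            meta={**self.meta, "burn_in": 0.0, "window_start": float(t_min)},
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraceSet):
            return NotImplemented
        return (
            np.array_equal(self.time, other.time)
            and self.columns == other.columns
            and set(self.data) == set(other.data)
            and all(np.array_equal(self.data[k], other.data[k]) for k in self.data)
        )
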