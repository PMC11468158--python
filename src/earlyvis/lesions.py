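"""In-silico lesion analyses: channel knockouts and consistent-weight subsets.

Two families of lesion, each followed by retraining the readout from scratch
on the surviving units:

* *spatial-frequency channel lesions* — drop (or keep only) one or more of
  the four frequency channels F0..F3 and refit;
* *consistency lesions* — across the runs of the full model, count for every
  unit how often its trained readout weight was positive and how often
  negative; keep only (or remove) the units whose dominant sign recurs in at
  least a threshold number of runs (e.g. 90/95/99/100 out of 100).

A unit's consistency score is max(positive count, negative count) over the
full-model runs' final weights. Weights exactly at zero count toward
neither sign. Keep-only and remove at the same threshold partition the
full unit set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import models as md
from .protocol import RunResult

__all__ = ["LesionSpec", "ConsistencyTable", "drop_channels", "keep_channels",
           "weight_sign_consistency", "apply_consistency_subset"]

N_CHANNELS = 4


@dataclass(frozen=True)
class LesionSpec:
    """Declarative lesion description (as embedded in experiment configs)."""

    mode: str  # {"drop_channels", "keep_channels", "consistency"}
    channels: tuple[int, ...] = ()
    consistency_threshold: int = 0
    action: str = "keep_only"  # or "remove"

    def __post_init__(self) -> None:
        if self.mode not in ("drop_channels", "keep_channels", "consistency"):
            raise ValueError(f"unknown lesion mode: {self.mode!r}")
        if self.action not in ("keep_only", "remove"):
            raise ValueError(f"unknown lesion action: {self.action!r}")
        if any(not 0 <= c < N_CHANNELS for c in self.channels):
            raise ValueError("channel indices must be in 0..3 (F0..F3)")


def _channel_mask(m: md.ModelSpec, channels) -> np.ndarray:
    keep = np.ones(m.n_units_full, dtype=bool)
    unit_ch = m.unit_channels()
    for c in channels:
        keep &= unit_ch != c
    return keep


def drop_channels(m: md.ModelSpec, channels) -> md.ModelSpec:
    """Model with the named frequency channels removed (readout must be retrained)."""
    channels = tuple(sorted(set(int(c) for c in channels)))
    if any(not 0 <= c < N_CHANNELS for c in channels):
        raise ValueError("channel indices must be in 0..3 (F0..F3)")
    if m.unit_mask is not None:
        raise ValueError("channel lesions apply to the full model")
    mask = _channel_mask(m, channels)
    if not mask.any():
        raise ValueError("lesion would remove every unit (all four channels dropped)")
    return replace(m, unit_mask=mask)


def keep_channels(m: md.ModelSpec, channels) -> md.ModelSpec:
    """Model restricted to the named frequency channels."""
    channels = tuple(sorted(set(int(c) for c in channels)))
    drop = tuple(c for c in range(N_CHANNELS) if c not in channels)
    return drop_channels(m, drop)


@dataclass
class ConsistencyTable:
    """Per-unit weight-sign counts across the full model's runs."""

    pos_count: np.ndarray
    neg_count: np.ndarray
    n_runs: int

    @property
    def score(self) -> np.ndarray:
        """max(pos, neg) occurrences: how reliably a unit's sign recurs."""
        return np.maximum(self.pos_count, self.neg_count)

    def zeros(self) -> np.ndarray:
        return self.n_runs - self.pos_count - self.neg_count


def weight_sign_consistency(runs: list[RunResult]) -> ConsistencyTable:
    """Count positive/negative trained-weight signs per unit across runs.

    All runs must come from the same (full) architecture; final weights
    only. Exact zeros count toward neither sign.
    """
    if not runs:
        raise ValueError("no runs given")
    signs = np.stack([r.weight_signs for r in runs])
    if signs.ndim != 2:
        raise ValueError("mismatched weight lengths across runs")
    return ConsistencyTable(pos_count=(signs > 0).sum(axis=0),
                            neg_count=(signs < 0).sum(axis=0),
                            n_runs=len(runs))


def apply_consistency_subset(m: md.ModelSpec, table: ConsistencyTable,
                             threshold: int, action: str = "keep_only") -> md.ModelSpec:
    """Lesion by weight-sign consistency; the readout must be retrained.

    ``keep_only`` retains units with score >= threshold; ``remove`` deletes
    them. The two actions at one threshold partition the unit set.
    """
    if action not in ("keep_only", "remove"):
        raise ValueError(f"unknown lesion action: {action!r}")
    if len(table.score) != m.n_units_full:
        raise ValueError("consistency table does not match the model")
    consistent = table.score >= threshold
    mask = consistent if action == "keep_only" else ~consistent
    if not mask.any():
        raise ValueError("lesion would leave no surviving unit")
    base = m.unit_mask if m.unit_mask is not None else np.ones(m.n_units_full, bool)
    return replace(m, unit_mask=base & mask)
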