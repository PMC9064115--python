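"""Degradation of relative-abundance profiles into presence/absence profiles.

A taxon is called present when its relative abundance is strictly positive
and at least the detection threshold. At threshold 0 this is the plain
support indicator: 1 marks presence regardless of abundance. Values equal
to a positive threshold count as present (only values *below* the threshold
are forced to zero).
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles_io import ProfileError, ProfileTable

#: Detection thresholds (percent) used throughout the benchmark.
DEFAULT_THRESHOLDS_PERCENT: tuple[float, ...] = (0.0, 0.0001, 0.001, 0.01, 0.1)


@dataclass(frozen=True)
class ThresholdSpec:
    """An ordered sweep of detection thresholds, expressed in percent."""

    values_percent: tuple[float, ...] = DEFAULT_THRESHOLDS_PERCENT

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values_percent)
        object.__setattr__(self, "values_percent", vals)
        if not vals:
            raise ValueError("threshold sweep must contain at least one value")
        if any(v < 0 for v in vals):
            raise ValueError("thresholds must be nonnegative")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly increasing")


def binarize(table: ProfileTable, threshold_percent: float) -> ProfileTable:
    """Convert a profile table to presence/absence at a detection threshold.

    An entry becomes 1 iff the abundance is > 0 and >= threshold (as a
    fraction). Binarizing an already-binary table at threshold 0 is the
    identity.
    """
    if threshold_percent < 0:
        raise ProfileError(f"negative threshold: {threshold_percent}")
    t = threshold_percent / 100.0  # percent at the interface, fraction internally
    present = (table.values > 0) & (table.values >= t)
    return ProfileTable(
        sample_ids=list(table.sample_ids),
        taxa=list(table.taxa),
        values=present.astype(float),
        rank=table.rank,
        is_binary=True,
    )


def threshold_sweep(
    table: ProfileTable, spec: ThresholdSpec = ThresholdSpec()
) -> list[tuple[float, ProfileTable]]:
    """Binarize at every threshold in the sweep, coarsest detection last.

    Per-sample presence counts are non-increasing along the sweep.
    """
    return [(t, binarize(table, t)) for t in spec.values_percent]
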