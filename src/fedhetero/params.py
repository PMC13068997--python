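"""Flat, segment-mapped model parameter vectors.

A :class:`ParamVector` is the unit of broadcast and aggregation in the
federation: a single ordered 1-D float array plus a named segment map
(``backbone`` / ``norm`` / ``head``).  All clients of one federation share
an identical length and segment map, so element-wise weighted averages and
segment surgery (FedBN-style exclusion of normalization parameters) are
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParamVector"]


@dataclass(frozen=True)
class ParamVector:
    """Ordered parameter vector with named, contiguous, disjoint segments.

    Parameters
    ----------
    values
        1-D float array of parameters.
    segments
        Mapping segment name -> ``(start, stop)`` half-open index range.
        Ranges must be disjoint and cover ``[0, len(values))``.
    """

    values: np.ndarray
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        object.__setattr__(self, "values", vals)
        covered = 0
        last_stop = None
        for name, (start, stop) in self.segments.items():
            if not (0 <= start <= stop <= vals.size):
                raise ValueError(f"segment {name!r} range {(start, stop)} out of bounds")
            if last_stop is not None and start != last_stop:
                raise ValueError("segments must be contiguous and ordered")
            last_stop = stop
            covered += stop - start
        if self.segments:
            first = next(iter(self.segments.values()))[0]
            if first != 0 or covered != vals.size:
                raise ValueError("segments must cover the whole vector")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def segment_map(self) -> dict[str, tuple[int, int]]:
        return dict(self.segments)

    def has_segment(self, name: str) -> bool:
        return name in self.segments

    def segment(self, name: str) -> np.ndarray:
        """Return a copy of one named segment."""
        start, stop = self.segments[name]
        return self.values[start:stop].copy()

    def replace_segment(self, name: str, new: np.ndarray) -> "ParamVector":
        """Return a new vector with one segment replaced."""
        start, stop = self.segments[name]
        new = np.asarray(new, dtype=np.float64).ravel()
        if new.size != stop - start:
            raise ValueError(
                f"segment {name!r} expects length {stop - start}, got {new.size}"
            )
        values = self.values.copy()
        values[start:stop] = new
        return ParamVector(values, self.segments)

    def same_structure(self, other: "ParamVector") -> bool:
        return len(self) == len(other) and self.segments == other.segments

    def copy(self) -> "ParamVector":
        return ParamVector(self.values.copy(), self.segments)
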