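"""Periodontitis extent and CAL quartile assignment.

Extent of periodontitis is the proportion of probed interproximal sites
with clinical attachment loss (CAL) at or above a threshold, by default
3 mm. Participants are ranked by extent and split into four equal-count
quartiles: quartile 1 = least severe, quartile 4 = most severe.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError


def cal_extent(sites_mm: Sequence[float], threshold_mm: float = 3.0) -> float:
    """Proportion of sites with CAL >= ``threshold_mm`` (inclusive).

    ``sites_mm`` holds per-site clinical attachment loss in millimetres
    (up to 6 interproximal sites per tooth, third molars excluded).
    Raises :class:`ValidationError` on an empty site list — edentulous
    participants are excluded upstream, so no sites is a data error.
    """
    sites = np.asarray(sites_mm, dtype=float)
    if sites.size == 0:
        raise ValidationError("cannot compute CAL extent from an empty site list")
    if (sites < 0).any():
        raise ValidationError("CAL site values must be non-negative")
    return float((sites >= threshold_mm).sum() / sites.size)


@dataclass(frozen=True)
class QuartileAssignment:
    """Participant -> CAL quartile (1..4) plus the interior cut points used."""

    labels: dict[str, int]
    cut_points: tuple[float, float, float]

    def group(self, quartile: int) -> list[str]:
        """Participant ids in a given quartile, in assignment order."""
        return [pid for pid, q in self.labels.items() if q == quartile]

    def sizes(self) -> tuple[int, int, int, int]:
        counts = [0, 0, 0, 0]
        for q in self.labels.values():
            counts[q - 1] += 1
        return tuple(counts)  # type: ignore[return-value]


def assign_quartiles(extents: Mapping[str, float]) -> QuartileAssignment:
    """Rank-based split of participants into 4 equal-count CAL quartiles.

    Participants are sorted by (extent, participant_id) — the id is the
    deterministic tie-break — and cut into four contiguous groups whose
    sizes differ by at most one (remainders go to the lower quartiles).
    Quartile 1 holds the lowest extents, quartile 4 the highest.
    """
    n = len(extents)
    if n < 4:
        raise ValidationError(f"need at least 4 participants to form quartiles, got {n}")
    for pid, e in extents.items():
        if not (0.0 <= e <= 1.0):
            raise ValidationError(f"extent for {pid!r} outside [0, 1]: {e}")

    order = sorted(extents, key=lambda pid: (extents[pid], pid))
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    labels: dict[str, int] = {}
    bounds: list[float] = []
    start = 0
    for q, size in enumerate(sizes, start=1):
        chunk = order[start:start + size]
        for pid in chunk:
            labels[pid] = q
        if q < 4:
            bounds.append(extents[chunk[-1]])
        start += size
    return QuartileAssignment(labels=labels, cut_points=tuple(bounds))  # type: ignore[arg-type]
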