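"""1:1 age- and sex-matched cohort construction across CAL quartiles.

Multimorbidity is strongly patterned by age and sex, so quartile
comparisons are made on a cohort in which all four CAL quartile groups
have identical size and identical (sex, age-cell) composition. Matching
is exact-cell: participants are stratified by sex and an age cell of
width ``caliper + 1`` years, and within every cell each quartile
contributes the same number of participants (the minimum count across
quartiles), selected uniformly at random under a fixed seed. At caliper
0 the age cells are single years, so post-match age and sex marginals
are exactly equal across quartiles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable
from .errors import MatchingError
from .perio import QuartileAssignment


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters.

    age_caliper_years
        Maximum allowed age difference within a matched quadruple;
        0 (default) means exact age match.
    seed
        Seed for the random choice among interchangeable candidates in
        oversupplied cells.
    """

    age_caliper_years: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_caliper_years < 0:
            raise ValueError("age caliper must be non-negative")


def match_across_quartiles(table: CohortTable, quartiles: QuartileAssignment,
                           config: MatchConfig = MatchConfig()) -> CohortTable:
    """Return the matched sub-cohort with equal quartile group sizes.

    Deterministic given ``config.seed``; idempotent (matching an already
    matched cohort returns it unchanged); output row order follows input.
    Raises :class:`MatchingError` if any quartile group is empty.
    """
    frame = table.frame
    ids = frame["participant_id"].astype(str).to_numpy()
    missing = [pid for pid in ids if pid not in quartiles.labels]
    if missing:
        raise MatchingError(f"{len(missing)} participant(s) lack a quartile label, e.g. {missing[0]!r}")

    q = np.array([quartiles.labels[pid] for pid in ids])
    if set(np.unique(q)) != {1, 2, 3, 4}:
        empty = sorted({1, 2, 3, 4} - set(np.unique(q)))
        raise MatchingError(f"quartile group(s) {empty} are empty in this cohort")

    width = config.age_caliper_years + 1
    age_cell = frame["age"].to_numpy(dtype=int) // width
    sex = frame["sex"].to_numpy()

    rng = np.random.default_rng(config.seed)
    keep = np.zeros(len(frame), dtype=bool)
    cells = sorted(set(zip(sex, age_cell)))
    for cell_sex, cell_age in cells:
        in_cell = (sex == cell_sex) & (age_cell == cell_age)
        groups = [np.flatnonzero(in_cell & (q == k)) for k in (1, 2, 3, 4)]
        m = min(len(g) for g in groups)
        if m == 0:
            continue
        for g in groups:
            if len(g) == m:
                chosen = g
            else:
                chosen = rng.choice(g, size=m, replace=False)
            keep[np.sort(chosen)] = True
    return table.subset(keep)
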