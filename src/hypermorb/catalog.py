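"""The disease catalog: an ordered list of disease labels.

The catalog order is load-bearing — it indexes every matrix produced
downstream (incidence, adjacency, co-occurrence) and breaks centrality
ties deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: Default catalog: the systemic conditions surveyed in NHANES-style health
#: interviews, plus obesity derived from measured BMI (>= 30 kg/m^2).
DEFAULT_DISEASES: tuple[str, ...] = (
    "diabetes",
    "cancer",
    "heart_attack",
    "coronary_heart_disease",
    "congestive_heart_failure",
    "angina",
    "stroke",
    "hypertension",
    "arthritis",
    "liver_disease",
    "osteoporosis",
    "thyroid_disorder",
    "emphysema",
    "bronchitis",
    "obesity",
)


@dataclass(frozen=True)
class DiseaseCatalog:
    """Ordered, distinct disease labels.

    Parameters
    ----------
    names
        Disease labels in their canonical order. Defaults to the 15-condition
        systemic-disease catalog used throughout the package.
    """

    names: tuple[str, ...] = field(default=DEFAULT_DISEASES)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("disease catalog must not be empty")
        if any(not n for n in names):
            raise ValueError("disease labels must be non-empty strings")
        if len(set(names)) != len(names):
            raise ValueError("disease labels must be distinct")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self._index  # type: ignore[attr-defined]

    def index(self, name: str) -> int:
        """Position of ``name`` in catalog order."""
        try:
            return self._index[name]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"disease {name!r} is not in the catalog") from None
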