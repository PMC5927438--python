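"""Area schemes: the universe of reachable (sextant, surface) areas.

The dentition is divided into six sextants (1-3 upper right to upper left,
4-6 lower left to lower right; sextants 2 and 5 are the anterior segments).
Each sextant exposes a vestibular (lip/cheek-facing) and an oral
(tongue/palate-facing) surface; the four posterior sextants additionally
expose an occlusal (chewing) surface, and the two anterior sextants an
incisal edge.  An *area* is one (sextant, surface) pair and is the unit
over which brushing time and brush changes are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "VESTIBULAR",
    "ORAL",
    "OCCLUSAL",
    "INCISAL",
    "SURFACES",
    "SURFACE_CODES",
    "Area",
    "AreaScheme",
    "SchemeError",
]

VESTIBULAR = "vestibular"
ORAL = "oral"
OCCLUSAL = "occlusal"
INCISAL = "incisal"

SURFACES = (VESTIBULAR, ORAL, OCCLUSAL, INCISAL)

#: Short codes used in event-log files.
SURFACE_CODES = {
    "V": VESTIBULAR,
    "O": ORAL,
    "OCC": OCCLUSAL,
    "INC": INCISAL,
}

SEXTANTS = (1, 2, 3, 4, 5, 6)
POSTERIOR_SEXTANTS = (1, 3, 4, 6)
ANTERIOR_SEXTANTS = (2, 5)

#: An area is a (sextant, surface) pair, e.g. ``(1, "vestibular")``.
Area = tuple[int, str]


class SchemeError(ValueError):
    """Invalid area scheme (duplicates, unknown surface, empty)."""


def _validate_area(area: Area) -> Area:
    sextant, surface = area
    if sextant not in SEXTANTS:
        raise SchemeError(f"sextant must be 1-6, got {sextant!r}")
    if surface not in SURFACES:
        raise SchemeError(
            f"surface must be one of {SURFACES}, got {surface!r}"
        )
    return (int(sextant), surface)


@dataclass(frozen=True)
class AreaScheme:
    """An ordered set of reachable areas.

    Parameters
    ----------
    areas
        The reachable (sextant, surface) pairs, in a stable order.
        Duplicates are rejected.
    name
        Optional label used in result tables (e.g. ``"all"``, ``"vo"``).

    The count of reachable areas is the index denominator ``n``.
    """

    areas: tuple[Area, ...]
    name: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        areas = tuple(_validate_area(a) for a in self.areas)
        if not areas:
            raise SchemeError("scheme must contain at least one area")
        if len(set(areas)) != len(areas):
            seen: set[Area] = set()
            dup = next(a for a in areas if a in seen or seen.add(a))
            raise SchemeError(f"duplicate area {dup} in scheme")
        object.__setattr__(self, "areas", areas)

    @property
    def n(self) -> int:
        """Number of reachable areas (the denominator of C and I)."""
        return len(self.areas)

    def __contains__(self, area: Area) -> bool:
        return tuple(area) in self.areas

    def __iter__(self):
        return iter(self.areas)

    def restrict(self, surfaces: Iterable[str]) -> "AreaScheme":
        """Return the sub-scheme containing only the given surfaces."""
        keep = set(surfaces)
        unknown = keep - set(SURFACES)
        if unknown:
            raise SchemeError(f"unknown surface(s): {sorted(unknown)}")
        retained = tuple(a for a in self.areas if a[1] in keep)
        if not retained:
            raise SchemeError("surface restriction leaves an empty scheme")
        label = self.name + "|" + "+".join(sorted(keep))
        return AreaScheme(retained, name=label)

    # -- standard schemes ---------------------------------------------------

    @classmethod
    def all_areas(cls, include_incisal: bool = False) -> "AreaScheme":
        """The default 16-area scheme: vestibular and oral surfaces of all
        six sextants plus the occlusal surfaces of the four posterior
        sextants.  With ``include_incisal=True`` the two incisal-edge areas
        of the anterior sextants are added (n = 18)."""
        areas: list[Area] = []
        for s in SEXTANTS:
            areas.append((s, VESTIBULAR))
            areas.append((s, ORAL))
        for s in POSTERIOR_SEXTANTS:
            areas.append((s, OCCLUSAL))
        name = "all"
        if include_incisal:
            for s in ANTERIOR_SEXTANTS:
                areas.append((s, INCISAL))
            name = "all_incisal"
        return cls(tuple(areas), name=name)

    @classmethod
    def vestibular_oral(cls) -> "AreaScheme":
        """The 12-area scheme restricted to vestibular and oral surfaces."""
        scheme = cls.all_areas().restrict({VESTIBULAR, ORAL})
        return cls(scheme.areas, name="vo")

    @classmethod
    def from_name(cls, name: str) -> "AreaScheme":
        """Resolve a named scheme: ``all`` (n=16), ``vo`` (n=12) or
        ``all_incisal`` (n=18)."""
        table = {
            "all": lambda: cls.all_areas(),
            "vo": cls.vestibular_oral,
            "all_incisal": lambda: cls.all_areas(include_incisal=True),
        }
        try:
            return table[name]()
        except KeyError:
            raise SchemeError(
                f"unknown scheme {name!r}; expected one of {sorted(table)}"
            ) from None
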