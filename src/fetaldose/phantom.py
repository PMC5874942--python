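"""Axial slab geometry of the pregnant mathematical phantom.

The phantom is a stylized adult female divided from the crown of the head to
mid-thigh into 208 axial slabs of 5 mm (1040 mm total).  Every dose quantity
in the pipeline is accounted on this grid: an organ is the half-open set of
slabs it occupies, and a scan irradiates half-open slab intervals.

Coordinates are 0-based half-open slab indices; the public helpers accept
millimetres and convert, so off-by-one ambiguity never leaks into callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import BoundsError, FormatError, GridError

SLAB_THICKNESS_MM = 5
N_SLABS = 208
PHANTOM_EXTENT_MM = SLAB_THICKNESS_MM * N_SLABS  # 1040 mm, head to mid-thigh


def mm_to_slab_interval(start_mm: float, end_mm: float) -> tuple[int, int]:
    """Convert a 5-mm-aligned axial interval in mm to a half-open slab interval.

    Parameters
    ----------
    start_mm, end_mm : float
        Axial positions measured from the crown of the head, both multiples
        of 5 with ``0 <= start_mm < end_mm <= 1040``.

    Returns
    -------
    (start_slab, end_slab) : tuple of int
        0-based half-open slab interval ``[start_mm/5, end_mm/5)``.

    Raises
    ------
    GridError
        If either position is not a multiple of 5 mm.
    BoundsError
        If the interval is empty, reversed, or outside the phantom.
    """
    for x in (start_mm, end_mm):
        if x % SLAB_THICKNESS_MM != 0:
            raise GridError(
                f"position {x} mm is not on the {SLAB_THICKNESS_MM}-mm slab grid"
            )
    if not (0 <= start_mm < end_mm <= PHANTOM_EXTENT_MM):
        raise BoundsError(
            f"interval [{start_mm}, {end_mm}) mm outside phantom "
            f"[0, {PHANTOM_EXTENT_MM}] mm or empty"
        )
    return int(start_mm) // SLAB_THICKNESS_MM, int(end_mm) // SLAB_THICKNESS_MM


def slab_interval_to_mm(start_slab: int, end_slab: int) -> tuple[float, float]:
    """Inverse of :func:`mm_to_slab_interval` (exact for any valid interval)."""
    if not (0 <= start_slab < end_slab <= N_SLABS):
        raise BoundsError(f"slab interval [{start_slab}, {end_slab}) out of range")
    return start_slab * SLAB_THICKNESS_MM, end_slab * SLAB_THICKNESS_MM


@dataclass(frozen=True)
class OrganRegion:
    """An organ's contiguous axial extent, as a half-open slab interval."""

    name: str
    slab_start: int
    slab_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.slab_start < self.slab_end <= N_SLABS):
            raise BoundsError(
                f"organ {self.name!r}: slab interval "
                f"[{self.slab_start}, {self.slab_end}) outside [0, {N_SLABS}]"
            )

    @property
    def slabs(self) -> range:
        return range(self.slab_start, self.slab_end)

    def distance(self, slab: int) -> int:
        """Axial distance (in slabs) from ``slab`` to the organ; 0 inside."""
        if slab < self.slab_start:
            return self.slab_start - slab
        if slab >= self.slab_end:
            return slab - self.slab_end + 1
        return 0


@dataclass(frozen=True)
class Phantom:
    """The 208-slab phantom with its organ roster.

    Attributes
    ----------
    organs : list of OrganRegion
        Organ extents; names are unique.
    remainder_organs : tuple of str
        The subset entering the ICRP remainder tissue as their mean dose.
    """

    organs: tuple[OrganRegion, ...]
    remainder_organs: tuple[str, ...] = ()
    slab_thickness_mm: int = SLAB_THICKNESS_MM
    n_slabs: int = N_SLABS
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise FormatError("duplicate organ names in phantom roster")
        missing = set(self.remainder_organs) - set(names)
        if missing:
            raise FormatError(f"remainder organs not in roster: {sorted(missing)}")
        object.__setattr__(self, "_by_name", {o.name: o for o in self.organs})

    @property
    def organ_names(self) -> list[str]:
        return [o.name for o in self.organs]

    def organ(self, name: str) -> OrganRegion:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"organ {name!r} not in phantom roster") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organ": [o.name for o in self.organs],
                "slab_start": [o.slab_start for o in self.organs],
                "slab_end": [o.slab_end for o in self.organs],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, remainder_organs: tuple[str, ...] = ()) -> "Phantom":
        df = pd.read_csv(path)
        required = {"organ", "slab_start", "slab_end"}
        if not required.issubset(df.columns):
            raise FormatError(f"phantom CSV needs columns {sorted(required)}")
        organs = tuple(
            OrganRegion(str(r.organ), int(r.slab_start), int(r.slab_end))
            for r in df.itertuples()
        )
        return cls(organs=organs, remainder_organs=remainder_organs)


def _mm(start_mm: int, end_mm: int) -> tuple[int, int]:
    return mm_to_slab_interval(start_mm, end_mm)


# Fixed fixture roster.  Positions are plausible for a near-term pregnant
# adult (enlarged uterus displacing the bowel) but are a documented modeling
# convention, not anatomical ground truth: the reference Monte Carlo phantom
# geometry is not published at slab resolution.  The abdominal/pelvic scan
# ranges used by the shipped protocols (starting at 560 mm from the crown)
# fully cover the uterus and partially cover stomach and liver.
_DEFAULT_ROSTER_MM: tuple[tuple[str, int, int], ...] = (
    ("brain", 30, 180),
    ("salivary_glands", 185, 225),
    ("thyroid", 255, 280),
    ("oesophagus", 300, 560),
    ("lungs", 330, 560),
    ("thymus", 330, 380),
    ("breast", 380, 520),
    ("heart", 430, 530),
    ("liver", 530, 640),
    ("stomach", 540, 610),
    ("spleen", 545, 600),
    ("adrenals", 550, 575),
    ("pancreas", 560, 605),
    ("kidneys", 570, 650),
    ("gall_bladder", 590, 620),
    ("small_intestine", 560, 760),
    ("colon", 570, 790),
    ("uterus_fetus", 580, 730),
    ("ovaries", 590, 615),
    ("bladder", 740, 790),
    # distributed tissues span the whole phantom
    ("red_bone_marrow", 0, 1040),
    ("bone_surface", 0, 1040),
    ("skin", 0, 1040),
)

#: Organs pooled into the ICRP remainder tissue (female subset of the
#: remainder list restricted to organs this slab model can localize).
REMAINDER_ORGANS: tuple[str, ...] = (
    "adrenals",
    "gall_bladder",
    "heart",
    "kidneys",
    "pancreas",
    "small_intestine",
    "spleen",
    "thymus",
    "uterus_fetus",
)


def default_pregnant_phantom() -> Phantom:
    """Return the fixed pregnant-phantom roster (deterministic fixture).

    The roster places ``uterus_fetus`` strictly inside the small-intestine to
    bladder span; repeated calls return identical phantoms.
    """
    organs = tuple(
        OrganRegion(name, *_mm(a, b)) for name, a, b in _DEFAULT_ROSTER_MM
    )
    return Phantom(organs=organs, remainder_organs=REMAINDER_ORGANS)
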