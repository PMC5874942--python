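"""Acquisition modeling: CTDIvol/DLP accounting and rotation planning.

Two acquisition geometries are modeled:

* **wide-volume** — a long range is covered by N contiguous axial cone-beam
  rotations of nominal beam width BW with overlapping junctions; the total
  irradiated length is N x BW and the overlap N x BW - L is the mechanism of
  the extra dose this mode deposits;
* **helical** — a single continuous acquisition at pitch > 1, with no
  overlap; the irradiated length equals the scan length (over-ranging is not
  modeled).

Scan lengths are snapped to the phantom's 5-mm slab grid before slab-level
planning; the scanner-console DLP accounting uses the nominal lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .coefficients import BEAM_WIDTH_CLASSES
from .errors import ConfigurationError, CoverageError, DoseDomainError
from .phantom import SLAB_THICKNESS_MM

#: Default cranial edge of the shipped abdominal/pelvic scan ranges
#: (mm from the crown of the head); places the uterus inside every range.
DEFAULT_SCAN_START_MM = 560

#: Scan length -> value entered on the calculator's 5-mm grid in the study
#: protocols.  Most follow nearest-5 rounding, but 232 -> 235, 264 -> 270 and
#: 306 -> 310 do not; no single rule explains all entries, so they are
#: reproduced by lookup.
STUDY_ENTERED_LENGTHS: dict[int, int] = {
    176: 175,
    184: 185,
    204: 205,
    232: 235,
    264: 270,
    276: 275,
    306: 310,
    348: 350,
    352: 350,
}

#: Scan length -> (beam width mm, number of rotations) as the 320-row
#: scanner's firmware assigns them.  The assignment rule is unpublished;
#: only these nine combinations are known.
WIDE_VOLUME_COMBOS: dict[int, tuple[int, int]] = {
    176: (120, 2),
    184: (128, 2),
    204: (140, 2),
    232: (160, 2),
    264: (120, 3),
    276: (128, 3),
    306: (140, 3),
    348: (160, 3),
    352: (120, 4),
}

HELICAL_SCAN_LENGTHS: tuple[int, ...] = (176, 184, 204, 232, 264, 276, 306, 348)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places (console convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def snap_length(length_mm: float, use_study_overrides: bool = False) -> int:
    """Snap a scan length to the 5-mm grid (nearest multiple, ties up).

    With ``use_study_overrides`` the exact entered values of the study
    protocols (:data:`STUDY_ENTERED_LENGTHS`) take precedence.
    """
    if length_mm <= 0:
        raise DoseDomainError(f"scan length must be > 0, got {length_mm}")
    if use_study_overrides and length_mm in STUDY_ENTERED_LENGTHS:
        return STUDY_ENTERED_LENGTHS[int(length_mm)]
    return int(
        round_half_up(length_mm / SLAB_THICKNESS_MM) * SLAB_THICKNESS_MM
    )


@dataclass(frozen=True)
class ScannerModel:
    """A CT scanner: acquisition mode, beam widths, and nCTDIw table.

    ``nctdiw`` maps (kV, beam-width class) to the weighted CTDI in mGy per
    100 mAs measured in the 32-cm phantom.
    """

    name: str
    mode: str  # "wide_volume" | "helical"
    beam_widths_mm: tuple[int, ...]
    nctdiw: dict[tuple[int, str], float]

    def __post_init__(self) -> None:
        if self.mode not in ("wide_volume", "helical"):
            raise ConfigurationError(f"unknown scanner mode {self.mode!r}")
        if self.mode == "wide_volume" and len(self.beam_widths_mm) < 1:
            raise ConfigurationError("wide-volume scanner needs >= 1 beam width")
        if self.mode == "helical" and len(self.beam_widths_mm) != 1:
            raise ConfigurationError("helical scanner needs exactly one collimation")

    def nctdiw_for(self, kv: int, beam_width_mm: int) -> float:
        try:
            bw_class = BEAM_WIDTH_CLASSES[beam_width_mm]
        except KeyError:
            raise ConfigurationError(
                f"no beam-width class for {beam_width_mm} mm"
            ) from None
        try:
            return self.nctdiw[(kv, bw_class)]
        except KeyError:
            raise ConfigurationError(
                f"scanner {self.name!r}: no nCTDIw for kV={kv}, class={bw_class!r}"
            ) from None


@dataclass(frozen=True)
class ScanProtocol:
    """One acquisition's parameters.

    ``entered_length_mm`` optionally records the value keyed into the
    dose calculator's 5-mm grid when it differs from plain nearest-5
    snapping of ``scan_length_mm``.
    """

    kv: int
    ma: float
    rotation_time_s: float
    pitch: float
    beam_width_mm: int
    n_rotations: int
    scan_length_mm: float
    scan_start_mm: float = DEFAULT_SCAN_START_MM
    entered_length_mm: int | None = None

    def __post_init__(self) -> None:
        if self.ma < 0 or self.rotation_time_s <= 0 or self.pitch <= 0:
            raise ConfigurationError("mA >= 0, rotation time > 0, pitch > 0 required")
        if self.scan_length_mm <= 0:
            raise ConfigurationError("scan length must be > 0")
        if self.n_rotations < 1:
            raise ConfigurationError("need >= 1 rotation")

    @property
    def mas_per_rotation(self) -> float:
        return self.ma * self.rotation_time_s

    @property
    def planned_length_mm(self) -> int:
        """Length on the 5-mm grid used for slab planning."""
        if self.entered_length_mm is not None:
            return self.entered_length_mm
        return snap_length(self.scan_length_mm)


@dataclass(frozen=True)
class RotationPlan:
    """Concrete irradiated slab intervals of one acquisition."""

    mode: str
    intervals_slabs: tuple[tuple[int, int], ...]  # half-open [start, end)
    scan_range_slabs: tuple[int, int]
    total_irradiated_mm: float
    total_overlap_mm: float
    overlap_ratio_unrounded: float
    overlap_ratio_pct: int
    intervals_mm: tuple[tuple[float, float], ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "intervals_mm",
            tuple(
                (a * SLAB_THICKNESS_MM, b * SLAB_THICKNESS_MM)
                for a, b in self.intervals_slabs
            ),
        )

    @property
    def n_rotations(self) -> int:
        return len(self.intervals_slabs)

    def covered_slabs(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.intervals_slabs:
            out.update(range(a, b))
        return out


def compute_ctdivol(protocol: ScanProtocol, scanner: ScannerModel) -> float:
    """CTDIvol (mGy, 32-cm phantom) = nCTDIw x mAs / 100 / pitch."""
    n = scanner.nctdiw_for(protocol.kv, protocol.beam_width_mm)
    return n * protocol.mas_per_rotation / 100.0 / protocol.pitch


def compute_dlp(ctdivol_mgy: float, irradiated_length_mm: float) -> float:
    """DLP (mGy cm) = CTDIvol x irradiated length; unrounded.

    Use :func:`console_dlp` for the integer value a scanner console displays.
    """
    if ctdivol_mgy < 0 or irradiated_length_mm < 0:
        raise DoseDomainError("CTDIvol and irradiated length must be >= 0")
    return ctdivol_mgy * irradiated_length_mm / 10.0


def console_dlp(ctdivol_mgy: float, irradiated_length_mm: float) -> int:
    """Console-style displayed DLP: round half-up to an integer."""
    return int(round_half_up(compute_dlp(ctdivol_mgy, irradiated_length_mm)))


def overlap_ratio(
    scan_length_mm: float, beam_width_mm: float, n_rotations: int
) -> tuple[float, int]:
    """Overlap of a wide-volume acquisition relative to its scan length.

    Returns ``(unrounded_percent, rounded_percent)`` where the overlap is
    N x BW - L and the ratio is taken against L.
    """
    total = n_rotations * beam_width_mm
    if total < scan_length_mm:
        raise CoverageError(
            f"{n_rotations} x {beam_width_mm} mm = {total} mm cannot cover "
            f"{scan_length_mm} mm"
        )
    pct = 100.0 * (total - scan_length_mm) / scan_length_mm
    return pct, int(round_half_up(pct))


def _snap_to_grid(x: float, tie_down: bool = True) -> int:
    """Nearest multiple of 5; exact midpoints resolve toward the scan start."""
    lo = math.floor(x / SLAB_THICKNESS_MM) * SLAB_THICKNESS_MM
    hi = lo + SLAB_THICKNESS_MM
    if x - lo < hi - x:
        return int(lo)
    if x - lo > hi - x:
        return int(hi)
    return int(lo if tie_down else hi)


def plan_wide_volume(
    scan_length_mm: float,
    beam_width_mm: int,
    n_rotations: int,
    scan_start_mm: float = DEFAULT_SCAN_START_MM,
    entered_length_mm: int | None = None,
) -> RotationPlan:
    """Place N overlapping rotations of width BW over the scan range.

    Junction overlaps are equalized before snapping each rotation start to
    the 5-mm grid (nearest, ties toward the scan start); the union of the
    snapped intervals covers the whole snapped scan range.  The reported
    ``total_overlap_mm`` is the nominal N x BW - L.
    """
    L = scan_length_mm
    N, BW = n_rotations, beam_width_mm
    if N * BW < L:
        raise CoverageError(
            f"{N} x {BW} mm = {N * BW} mm cannot cover {L} mm"
        )
    planned = (
        entered_length_mm if entered_length_mm is not None else snap_length(L)
    )
    start = _snap_to_grid(scan_start_mm)
    range_slabs = (
        start // SLAB_THICKNESS_MM,
        (start + planned) // SLAB_THICKNESS_MM,
    )
    if N == 1:
        starts = [float(start)]
    else:
        stride = (planned - BW) / (N - 1)  # BW - equalized junction overlap
        starts = [start + k * stride for k in range(N)]
    snapped = [_snap_to_grid(s) for s in starts]
    snapped[0] = start
    if N > 1:
        # anchor the last rotation so its interval reaches the range end
        snapped[-1] = (
            math.floor((start + planned - BW) / SLAB_THICKNESS_MM)
            * SLAB_THICKNESS_MM
        )
    intervals: list[tuple[int, int]] = []
    for s in snapped:
        a = s // SLAB_THICKNESS_MM
        b = math.ceil((s + BW) / SLAB_THICKNESS_MM)
        if intervals and a > intervals[-1][1]:  # close any snapping gap
            width = b - a
            a = intervals[-1][1]
            b = a + width
        intervals.append((a, b))
    pct, pct_rounded = overlap_ratio(L, BW, N)
    return RotationPlan(
        mode="wide_volume",
        intervals_slabs=tuple(intervals),
        scan_range_slabs=range_slabs,
        total_irradiated_mm=float(N * BW),
        total_overlap_mm=float(N * BW - L),
        overlap_ratio_unrounded=pct,
        overlap_ratio_pct=pct_rounded,
    )


def plan_helical(
    scan_length_mm: float,
    scan_start_mm: float = DEFAULT_SCAN_START_MM,
    entered_length_mm: int | None = None,
) -> RotationPlan:
    """Single-interval helical plan: no overlap, irradiated length = L."""
    if scan_length_mm <= 0:
        raise DoseDomainError(f"scan length must be > 0, got {scan_length_mm}")
    planned = (
        entered_length_mm
        if entered_length_mm is not None
        else snap_length(scan_length_mm)
    )
    start = _snap_to_grid(scan_start_mm)
    a = start // SLAB_THICKNESS_MM
    b = (start + planned) // SLAB_THICKNESS_MM
    return RotationPlan(
        mode="helical",
        intervals_slabs=((a, b),),
        scan_range_slabs=(a, b),
        total_irradiated_mm=float(scan_length_mm),
        total_overlap_mm=0.0,
        overlap_ratio_unrounded=0.0,
        overlap_ratio_pct=0,
    )


def plan_from_protocol(protocol: ScanProtocol, scanner: ScannerModel) -> RotationPlan:
    """Build the rotation plan a scanner produces for a protocol."""
    if scanner.mode == "wide_volume":
        return plan_wide_volume(
            protocol.scan_length_mm,
            protocol.beam_width_mm,
            protocol.n_rotations,
            protocol.scan_start_mm,
            protocol.entered_length_mm,
        )
    if protocol.n_rotations != 1:
        raise ConfigurationError("helical protocols use n_rotations = 1")
    return plan_helical(
        protocol.scan_length_mm, protocol.scan_start_mm, protocol.entered_length_mm
    )
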