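"""Shipped study configuration: the two scanners and their protocols.

The package's default acquisition set is a fetal-CT protocol family at
100 kV: nine wide-volume scan lengths on a 320-row scanner (beam width and
rotation count assigned by scan length) and eight helical lengths on an
80-row scanner at pitch 1.39.  Published per-acquisition fetal doses and
DLPs for these protocols are included as reproduction-mode inputs so the
conversion-factor analysis can be run on them without any organ-dose data.
"""

from __future__ import annotations

import pandas as pd

from .coefficients import DEFAULT_NCTDIW
from .protocol import (
    HELICAL_SCAN_LENGTHS,
    STUDY_ENTERED_LENGTHS,
    WIDE_VOLUME_COMBOS,
    ScannerModel,
    ScanProtocol,
)

STUDY_KV = 100

#: 320-row wide-volume scanner (160-mm detector; 120/128/140/160-mm beams).
SCANNER_320_ROW = ScannerModel(
    name="320-row wide-volume",
    mode="wide_volume",
    beam_widths_mm=(120, 128, 140, 160),
    nctdiw={
        (STUDY_KV, "A"): DEFAULT_NCTDIW["A"],
        (STUDY_KV, "B"): DEFAULT_NCTDIW["B"],
    },
)

#: 80-row helical scanner (40-mm collimation, pitch 1.39).
SCANNER_80_ROW = ScannerModel(
    name="80-row helical",
    mode="helical",
    beam_widths_mm=(40,),
    nctdiw={(STUDY_KV, "H"): DEFAULT_NCTDIW["H"]},
)


def wide_volume_protocols() -> list[ScanProtocol]:
    """The nine wide-volume acquisitions (103 mA, 0.5 s, pitch 1)."""
    return [
        ScanProtocol(
            kv=STUDY_KV,
            ma=103,
            rotation_time_s=0.5,
            pitch=1.0,
            beam_width_mm=bw,
            n_rotations=n,
            scan_length_mm=length,
            entered_length_mm=STUDY_ENTERED_LENGTHS[length],
        )
        for length, (bw, n) in sorted(WIDE_VOLUME_COMBOS.items())
    ]


def helical_protocols() -> list[ScanProtocol]:
    """The eight helical acquisitions (160 mA, 0.5 s, pitch 1.39)."""
    return [
        ScanProtocol(
            kv=STUDY_KV,
            ma=160,
            rotation_time_s=0.5,
            pitch=1.39,
            beam_width_mm=40,
            n_rotations=1,
            scan_length_mm=length,
            entered_length_mm=STUDY_ENTERED_LENGTHS[length],
        )
        for length in HELICAL_SCAN_LENGTHS
    ]


# Published per-acquisition results for the shipped protocols:
# (scan length mm, beam width mm, rotations, CTDIvol mGy, DLP mGy cm,
#  fetal dose mGy, maternal effective dose mSv)
_PUBLISHED_WIDE = (
    (176, 120, 2, 2.6, 62, 3.51, 1.05),
    (184, 128, 2, 2.6, 68, 3.82, 1.15),
    (204, 140, 2, 2.7, 74, 3.96, 1.29),
    (232, 160, 2, 2.7, 88, 4.40, 1.54),
    (264, 120, 3, 2.6, 93, 4.55, 1.65),
    (276, 128, 3, 2.6, 102, 5.32, 1.81),
    (306, 140, 3, 2.7, 111, 5.50, 2.01),
    (348, 160, 3, 2.7, 132, 6.52, 2.35),
    (352, 120, 4, 2.6, 124, 5.99, 2.17),
)

_PUBLISHED_HELICAL = (
    (176, 40, 1, 2.9, 52, 2.50, 0.83),
    (184, 40, 1, 2.9, 54, 2.60, 0.85),
    (204, 40, 1, 2.9, 58, 2.70, 0.99),
    (232, 40, 1, 2.9, 67, 2.90, 1.14),
    (264, 40, 1, 2.9, 78, 3.10, 1.33),
    (276, 40, 1, 2.9, 80, 3.10, 1.34),
    (306, 40, 1, 2.9, 90, 3.20, 1.51),
    (348, 40, 1, 2.9, 101, 3.30, 1.68),
)

_PUBLISHED_COLUMNS = [
    "scan_length_mm",
    "beam_width_mm",
    "n_rotations",
    "ctdivol_mgy",
    "dlp_mgycm",
    "fetal_dose_mgy",
    "effective_dose_msv",
]


def published_rows(mode: str) -> pd.DataFrame:
    """Published dose/DLP rows for ``mode`` ('wide_volume' or 'helical')."""
    data = {"wide_volume": _PUBLISHED_WIDE, "helical": _PUBLISHED_HELICAL}[mode]
    return pd.DataFrame(data, columns=_PUBLISHED_COLUMNS)
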