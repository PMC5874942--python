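"""Fetal-dose / DLP conversion factors.

The headline analysis: for each acquisition, form the ratio of the fetal
dose (mGy) to the displayed DLP (mGy cm), round it half-up to two decimals
as a dose report would print it, and recommend the *maximum* rounded ratio
per scanner mode as the conversion factor — the conservative choice, since
multiplying any displayed DLP by the maximum ratio never underestimates a
tabulated fetal dose by more than the 2-decimal rounding slack.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .engine import DoseReport
from .errors import DoseDomainError
from .protocol import round_half_up


def ratio(fetal_dose_mgy: float, dlp_mgycm: float) -> tuple[float, float]:
    """Fetal dose per unit DLP (cm^-1): (unrounded, rounded half-up 2 dp)."""
    if dlp_mgycm <= 0:
        raise DoseDomainError(f"DLP must be > 0, got {dlp_mgycm}")
    if fetal_dose_mgy < 0:
        raise DoseDomainError(f"fetal dose must be >= 0, got {fetal_dose_mgy}")
    r = fetal_dose_mgy / dlp_mgycm
    return r, round_half_up(r, 2)


_TABLE_COLUMNS = [
    "scan_length_mm",
    "beam_width_mm",
    "n_rotations",
    "dlp_mgycm",
    "fetal_dose_mgy",
    "ratio",
    "ratio_unrounded",
]


@dataclass(frozen=True)
class ConversionTable:
    """Per-acquisition fetal-dose/DLP ratios for one scanner mode."""

    rows: pd.DataFrame  # columns _TABLE_COLUMNS, sorted by scan length
    mode: str

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self, path: str | Path) -> None:
        out = self.rows[_TABLE_COLUMNS[:-1]].copy()
        out["ratio"] = out["ratio"].map(lambda r: f"{r:.2f}")
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class ConversionFactor:
    """Recommended DLP -> fetal dose factor (cm^-1) for one mode."""

    value: float
    mode: str
    provenance: str = "max over table rows"


def build_conversion_table(
    rows: Sequence[DoseReport] | Sequence[Mapping] | Iterable,
    mode: str | None = None,
) -> ConversionTable:
    """Assemble a conversion table from engine reports or printed rows.

    ``rows`` may be :class:`~fetaldose.engine.DoseReport` objects (engine
    mode) or mappings with keys ``scan_length_mm, beam_width_mm,
    n_rotations, dlp_mgycm, fetal_dose_mgy`` (reproduction mode, for
    externally published dose/DLP pairs).
    """
    rows = list(rows)
    if not rows:
        raise DoseDomainError("cannot build a conversion table from no rows")
    records = []
    modes = set()
    for row in rows:
        if isinstance(row, DoseReport):
            rec = {
                "scan_length_mm": row.protocol.scan_length_mm,
                "beam_width_mm": row.protocol.beam_width_mm,
                "n_rotations": row.protocol.n_rotations,
                "dlp_mgycm": float(row.dlp_displayed),
                "fetal_dose_mgy": row.fetal_dose,
            }
            modes.add(row.plan.mode)
        else:
            rec = {k: row[k] for k in _TABLE_COLUMNS[:5]}
        records.append(rec)
    if mode is None:
        if len(modes) != 1:
            raise DoseDomainError(
                f"rows span modes {sorted(modes)}; pass mode= explicitly"
            )
        mode = modes.pop()
    df = pd.DataFrame.from_records(records)
    rr = [ratio(f, d) for f, d in zip(df["fetal_dose_mgy"], df["dlp_mgycm"])]
    df["ratio_unrounded"] = [r[0] for r in rr]
    df["ratio"] = [r[1] for r in rr]
    df = df[_TABLE_COLUMNS].sort_values("scan_length_mm", ignore_index=True)
    return ConversionTable(rows=df, mode=mode)


def recommend_conversion_factor(table: ConversionTable) -> ConversionFactor:
    """The conservative recommendation: the maximum rounded ratio."""
    if len(table) == 0:
        raise DoseDomainError("empty conversion table")
    return ConversionFactor(value=float(table.rows["ratio"].max()), mode=table.mode)


def estimate_fetal_dose(displayed_dlp_mgycm: float, cf: ConversionFactor) -> float:
    """Fetal dose estimate (mGy) = displayed DLP x conversion factor."""
    if displayed_dlp_mgycm < 0:
        raise DoseDomainError(f"DLP must be >= 0, got {displayed_dlp_mgycm}")
    return displayed_dlp_mgycm * cf.value
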