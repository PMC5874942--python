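"""Organ-dose integration and effective dose for one acquisition.

An acquisition deposits dose slab by slab: every rotation interval
contributes ``n[T, i] * mAs / pitch`` to organ T for each slab i it covers,
and overlap zones are counted once per covering rotation — that repeated
irradiation is precisely the dose penalty of overlapping wide-volume
junctions.  The uterus dose is reported as the fetal dose: in a fetal scan
the whole fetus lies within the scanned uterus, so the uterus average is the
natural whole-body fetal estimate.

The maternal effective dose is the ICRP risk-weighted sum E = sum_T w_T D_T
restricted to female organs, with the remainder tissue entering as the mean
dose over the remainder organ set.  It is an approximation — effective dose
is defined for a sex-averaged reference person — and the weight table is a
documented, swappable constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coefficients import BEAM_WIDTH_CLASSES, DoseCoefficientTable
from .errors import BoundsError, ConfigurationError
from .phantom import N_SLABS, Phantom
from .protocol import (
    RotationPlan,
    ScannerModel,
    ScanProtocol,
    compute_ctdivol,
    compute_dlp,
    plan_from_protocol,
    round_half_up,
)


@dataclass(frozen=True)
class TissueWeights:
    """ICRP tissue weighting factors w_T restricted to female organs.

    ``remainder_weight`` applies to the arithmetic mean dose over
    ``remainder_organs``.  The female-only table sums to <= 1.
    """

    weights: Mapping[str, float]
    remainder_weight: float
    remainder_organs: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()) or self.remainder_weight < 0:
            raise ConfigurationError("tissue weights must be >= 0")
        total = sum(self.weights.values()) + self.remainder_weight
        if total > 1 + 1e-9:
            raise ConfigurationError(f"tissue weights sum to {total} > 1")

    @property
    def total_weight(self) -> float:
        return sum(self.weights.values()) + self.remainder_weight


#: ICRP Publication 103 weighting factors, female organs only; the gonad
#: weight is carried by the ovaries.  Sums to exactly 1.00 because every
#: ICRP target tissue has a female counterpart in the roster.
ICRP103_FEMALE_WEIGHTS = TissueWeights(
    weights={
        "red_bone_marrow": 0.12,
        "colon": 0.12,
        "lungs": 0.12,
        "stomach": 0.12,
        "breast": 0.12,
        "ovaries": 0.08,
        "bladder": 0.04,
        "liver": 0.04,
        "oesophagus": 0.04,
        "thyroid": 0.04,
        "bone_surface": 0.01,
        "brain": 0.01,
        "salivary_glands": 0.01,
        "skin": 0.01,
    },
    remainder_weight=0.12,
    remainder_organs=(
        "adrenals",
        "gall_bladder",
        "heart",
        "kidneys",
        "pancreas",
        "small_intestine",
        "spleen",
        "thymus",
        "uterus_fetus",
    ),
)

FETAL_ORGAN = "uterus_fetus"


def integrate_organ_dose(
    coeffs: DoseCoefficientTable,
    plan: RotationPlan,
    mas_per_rotation: float,
    pitch: float = 1.0,
    *,
    kv: int = 100,
    bw_class: str = "A",
    phantom: Phantom | None = None,
) -> dict[str, float]:
    """Sum per-slab dose contributions over all rotations of a plan.

    D_T = sum over rotations, sum over covered slabs of
    ``n[T, i] * mas_per_rotation / pitch``.  Slabs covered by several
    rotations contribute once per rotation.

    Raises
    ------
    BoundsError
        If any rotation interval leaves the phantom.
    ConfigurationError
        If the coefficient table lacks a roster organ (when ``phantom`` is
        given) or the (kV, class) matrix.
    """
    matrix = coeffs.matrix(kv, bw_class)
    if phantom is not None:
        missing = set(phantom.organ_names) - set(matrix.index)
        if missing:
            raise ConfigurationError(
                f"coefficient table lacks organs {sorted(missing)}"
            )
    multiplicity = np.zeros(N_SLABS)
    for a, b in plan.intervals_slabs:
        if not (0 <= a < b <= N_SLABS):
            raise BoundsError(f"rotation interval [{a}, {b}) outside phantom")
        multiplicity[a:b] += 1.0
    values = matrix.to_numpy() @ multiplicity * (mas_per_rotation / pitch)
    return dict(zip(matrix.index, values.astype(float)))


def effective_dose(
    organ_dose: Mapping[str, float], weights: TissueWeights = ICRP103_FEMALE_WEIGHTS
) -> float:
    """E (mSv) = sum_T w_T D_T + w_rem * mean(D over remainder organs)."""
    missing = (set(weights.weights) | set(weights.remainder_organs)) - set(organ_dose)
    if missing:
        raise ConfigurationError(f"dose map lacks weighted organs {sorted(missing)}")
    e = sum(w * organ_dose[t] for t, w in weights.weights.items())
    if weights.remainder_organs:
        remainder_mean = float(
            np.mean([organ_dose[t] for t in weights.remainder_organs])
        )
        e += weights.remainder_weight * remainder_mean
    return float(e)


@dataclass(frozen=True)
class DoseReport:
    """All dose quantities of one acquisition."""

    organ_dose: Mapping[str, float]  # mGy
    fetal_dose: float  # mGy, = organ_dose[uterus_fetus]
    effective_dose_msv: float
    ctdivol_mgy: float
    dlp_mgycm: float  # unrounded
    dlp_displayed: int  # console-style round-half-up
    protocol: ScanProtocol
    scanner_name: str
    plan: RotationPlan

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.organ_dose.values()):
            raise ConfigurationError("negative organ dose")
        if self.fetal_dose != self.organ_dose[FETAL_ORGAN]:
            raise ConfigurationError("fetal dose must equal the uterus_fetus dose")

    def organ_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"organ": list(self.organ_dose), "dose_mGy": list(self.organ_dose.values())}
        )

    def to_dict(self) -> dict:
        p = self.protocol
        return {
            "scanner": self.scanner_name,
            "mode": self.plan.mode,
            "kv": p.kv,
            "ma": p.ma,
            "rotation_time_s": p.rotation_time_s,
            "pitch": p.pitch,
            "beam_width_mm": p.beam_width_mm,
            "n_rotations": p.n_rotations,
            "scan_length_mm": p.scan_length_mm,
            "entered_length_mm": p.planned_length_mm,
            "ctdivol_mgy": self.ctdivol_mgy,
            "dlp_mgycm": self.dlp_mgycm,
            "dlp_displayed": self.dlp_displayed,
            "fetal_dose_mgy": self.fetal_dose,
            "effective_dose_msv": self.effective_dose_msv,
            "organ_dose_mgy": dict(self.organ_dose),
        }

    def write_organ_csv(self, path: str | Path) -> None:
        self.organ_frame().to_csv(path, index=False)


def run_acquisition(
    protocol: ScanProtocol,
    scanner: ScannerModel,
    phantom: Phantom,
    coeffs: DoseCoefficientTable,
    weights: TissueWeights = ICRP103_FEMALE_WEIGHTS,
) -> DoseReport:
    """Plan, integrate and account one acquisition end to end.

    Wide-volume DLP uses the total irradiated length N x BW; helical DLP
    uses the scan length (no over-ranging).  The helical pitch divides the
    effective mAs uniformly across the interval.
    """
    plan = plan_from_protocol(protocol, scanner)
    ctdivol = compute_ctdivol(protocol, scanner)
    dlp = compute_dlp(ctdivol, plan.total_irradiated_mm)
    bw_class = BEAM_WIDTH_CLASSES[protocol.beam_width_mm]
    organ_dose = integrate_organ_dose(
        coeffs,
        plan,
        protocol.mas_per_rotation,
        protocol.pitch,
        kv=protocol.kv,
        bw_class=bw_class,
        phantom=phantom,
    )
    return DoseReport(
        organ_dose=organ_dose,
        fetal_dose=organ_dose[FETAL_ORGAN],
        effective_dose_msv=effective_dose(organ_dose, weights),
        ctdivol_mgy=ctdivol,
        dlp_mgycm=dlp,
        dlp_displayed=int(round_half_up(dlp)),
        protocol=protocol,
        scanner_name=scanner.name,
        plan=plan,
    )
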