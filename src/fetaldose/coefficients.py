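"""Synthetic normalized organ-dose coefficient tables.

The dosimetry engine consumes tables of n[T, i]: the dose (mGy) delivered to
organ T per mAs spent irradiating slab i, for a given tube voltage and beam
width class.  The reference Monte Carlo datasets that scanner dose
calculators embed are proprietary, so this module generates a synthetic
stand-in with the same structure: an in-field plateau over the organ's slab
extent and an exponentially decaying scatter tail with axial distance, scaled
per beam-width class by an output factor proportional to the scanner's
weighted CTDI per 100 mAs (nCTDIw).

    n[T, i] = output_factor(class) * alpha_T * exp(-d(i, T) / lambda_T) * (1 + jitter_i)

where d(i, T) is the slab distance from slab i to organ T's extent (0 inside)
and output_factor(class) = nCTDIw(class) / nCTDIw(reference class).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import FormatError, ParameterError
from .phantom import Phantom

#: Beam-width (mm) to beam-width-class label for the scanners modeled here.
BEAM_WIDTH_CLASSES: dict[int, str] = {120: "A", 128: "A", 140: "B", 160: "B", 40: "H"}

# nCTDIw (mGy per 100 mAs, 32-cm phantom) back-solved from the scanners'
# displayed CTDIvol at 100 kV: CTDIvol = nCTDIw * mAs / 100 / pitch.
#   class A: 2.6 mGy at 103 mA * 0.5 s, pitch 1      -> 5.049
#   class B: 2.7 mGy at 103 mA * 0.5 s, pitch 1      -> 5.243
#   class H: 2.9 mGy at 160 mA * 0.5 s, pitch 1.39   -> 5.039
DEFAULT_NCTDIW: dict[str, float] = {
    "A": 2.6 * 100 / (103 * 0.5),
    "B": 2.7 * 100 / (103 * 0.5),
    "H": 2.9 * 100 * 1.39 / (160 * 0.5),
}

#: Default in-organ peak amplitudes alpha_T (mGy per mAs, reference class).
#: Fixture values chosen so that the shipped abdominal protocols produce
#: organ doses in the low-mGy range with the uterus/fetus highest and the
#: small intestine highest among maternal organs.
DEFAULT_ALPHA: dict[str, float] = {
    "uterus_fetus": 2.0e-3,
    "small_intestine": 1.5e-3,
    "colon": 1.4e-3,
    "ovaries": 1.4e-3,
    "bladder": 1.2e-3,
    "pancreas": 1.2e-3,
    "kidneys": 1.1e-3,
    "gall_bladder": 1.1e-3,
    "stomach": 1.0e-3,
    "spleen": 1.0e-3,
    "liver": 1.0e-3,
    "adrenals": 1.0e-3,
    "heart": 6.0e-4,
    "thymus": 5.0e-4,
    "lungs": 4.0e-4,
    "breast": 4.0e-4,
    "oesophagus": 4.0e-4,
    "thyroid": 2.0e-4,
    "salivary_glands": 1.0e-4,
    "brain": 8.0e-5,
    "red_bone_marrow": 6.0e-4,
    "bone_surface": 6.0e-4,
    "skin": 4.0e-4,
}

DEFAULT_DECAY_SLABS = 6.0  # scatter e-folding length, 30 mm
DEFAULT_KV = 100


class SynthCoeffParams(BaseModel):
    """Parameters of the synthetic coefficient generator.

    Attributes
    ----------
    alpha : mapping organ -> mGy/mAs
        In-organ peak amplitude; organs missing from the mapping fall back
        to ``default_alpha``.
    decay_slabs : float
        Scatter e-folding length lambda in slabs (5 mm each).
    nctdiw : mapping class -> mGy per 100 mAs
        Weighted CTDI per beam-width class; sets the output factors.
    reference_class : str
        Class whose output factor is 1.
    jitter : float
        Fractional uniform jitter in [0, 0.2]; 0 gives exact closed forms.
    seed : int
        Seed for the jitter noise (ignored when jitter is 0).
    """

    alpha: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ALPHA))
    default_alpha: float = 5.0e-4
    decay_slabs: float = DEFAULT_DECAY_SLABS
    nctdiw: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_NCTDIW))
    reference_class: str = "A"
    kv: int = DEFAULT_KV
    jitter: float = 0.0
    seed: int = 0

    @field_validator("alpha", "nctdiw")
    @classmethod
    def _positive_entries(cls, v: dict[str, float]) -> dict[str, float]:
        bad = {k: x for k, x in v.items() if not x > 0}
        if bad:
            raise ValueError(f"entries must be > 0: {bad}")
        return v

    @field_validator("decay_slabs", "default_alpha")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("jitter")
    @classmethod
    def _jitter_range(cls, v: float) -> float:
        if not 0 <= v <= 0.2:
            raise ValueError("jitter fraction must lie in [0, 0.2]")
        return v


@dataclass(frozen=True)
class DoseCoefficientTable:
    """Normalized organ-dose coefficients per (kV, beam-width class).

    ``matrices[(kv, bw_class)]`` is an organs x slabs DataFrame of n[T, i]
    in mGy/mAs; ``output_factors[bw_class]`` is the dimensionless per-class
    scale (nCTDIw ratio to the reference class).
    """

    matrices: Mapping[tuple[int, str], pd.DataFrame]
    output_factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for key, m in self.matrices.items():
            if (m.to_numpy() < 0).any():
                raise FormatError(f"negative coefficient in matrix {key}")

    def matrix(self, kv: int, bw_class: str) -> pd.DataFrame:
        try:
            return self.matrices[(kv, bw_class)]
        except KeyError:
            raise FormatError(
                f"no coefficient matrix for kV={kv}, class={bw_class!r}"
            ) from None

    def coefficient(self, kv: int, bw_class: str, organ: str, slab: int) -> float:
        return float(self.matrix(kv, bw_class).at[organ, slab])

    def organs(self) -> list[str]:
        first = next(iter(self.matrices.values()))
        return list(first.index)

    def equals(self, other: "DoseCoefficientTable") -> bool:
        if set(self.matrices) != set(other.matrices):
            return False
        if set(self.output_factors) != set(other.output_factors):
            return False
        for c, f in self.output_factors.items():
            if not np.isclose(f, other.output_factors[c], rtol=0, atol=1e-12):
                return False
        for k, m in self.matrices.items():
            a, b = m.sort_index(), other.matrices[k].sort_index()
            if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
                return False
            if not np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12, atol=1e-18):
                return False
        return True


def generate_coefficients(
    phantom: Phantom, params: SynthCoeffParams | None = None
) -> DoseCoefficientTable:
    """Generate a synthetic coefficient table for ``phantom``.

    Deterministic for a fixed seed; with ``jitter=0`` every coefficient has
    the closed form ``output_factor * alpha * exp(-d / lambda)``.
    """
    params = params or SynthCoeffParams()
    if params.reference_class not in params.nctdiw:
        raise ParameterError(
            f"reference class {params.reference_class!r} has no nCTDIw entry"
        )
    ref = params.nctdiw[params.reference_class]
    slabs = np.arange(phantom.n_slabs)
    # distance of each slab from each organ extent (0 inside)
    dist = np.empty((len(phantom.organs), phantom.n_slabs))
    for r, organ in enumerate(phantom.organs):
        below = organ.slab_start - slabs
        above = slabs - (organ.slab_end - 1)
        dist[r] = np.maximum(0, np.maximum(below, above))
    alpha = np.array(
        [params.alpha.get(o.name, params.default_alpha) for o in phantom.organs]
    )
    base = alpha[:, None] * np.exp(-dist / params.decay_slabs)

    rng = np.random.default_rng(params.seed)
    matrices: dict[tuple[int, str], pd.DataFrame] = {}
    factors: dict[str, float] = {}
    for bw_class in sorted(params.nctdiw):
        factor = params.nctdiw[bw_class] / ref
        factors[bw_class] = factor
        values = factor * base
        if params.jitter > 0:
            noise = rng.uniform(-params.jitter, params.jitter, size=base.shape)
            values = values * (1.0 + noise)
        matrices[(params.kv, bw_class)] = pd.DataFrame(
            values, index=phantom.organ_names, columns=slabs
        )
    return DoseCoefficientTable(matrices=matrices, output_factors=factors)


_CSV_COLUMNS = ["kv", "beam_width_class", "organ", "slab", "coefficient"]


def write_coefficients(table: DoseCoefficientTable, path: str | Path) -> None:
    """Write a coefficient table as long-format CSV.

    Output factors are preserved in ``# output_factor,<class>,<value>``
    comment lines so that write/read round-trips losslessly.
    """
    path = Path(path)
    rows = []
    for (kv, bw_class), m in sorted(table.matrices.items()):
        long = m.stack()
        rows.append(
            pd.DataFrame(
                {
                    "kv": kv,
                    "beam_width_class": bw_class,
                    "organ": long.index.get_level_values(0),
                    "slab": long.index.get_level_values(1),
                    "coefficient": long.to_numpy(),
                }
            )
        )
    with path.open("w") as fh:
        for bw_class, factor in sorted(table.output_factors.items()):
            fh.write(f"# output_factor,{bw_class},{factor!r}\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False)


def read_coefficients(
    path: str | Path, phantom: Phantom | None = None
) -> DoseCoefficientTable:
    """Read a coefficient CSV written by :func:`write_coefficients`.

    Raises :class:`FormatError` on missing columns, negative coefficients,
    duplicate (kv, class, organ, slab) keys, empty files, or organs absent
    from ``phantom``'s roster when a phantom is supplied.
    """
    path = Path(path)
    factors: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("# output_factor,"):
            _, bw_class, value = line.strip().split(",")
            factors[bw_class] = float(value)
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path}: empty coefficient file")
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("".join(body)))
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: unparseable CSV ({exc})") from exc
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: no coefficient rows")
    if (df["coefficient"] < 0).any():
        raise FormatError(f"{path}: negative coefficients")
    if df.duplicated(subset=["kv", "beam_width_class", "organ", "slab"]).any():
        raise FormatError(f"{path}: duplicate (kv, class, organ, slab) keys")
    if phantom is not None:
        unknown = set(df["organ"]) - set(phantom.organ_names)
        if unknown:
            raise FormatError(f"{path}: organs not in roster: {sorted(unknown)}")
    matrices: dict[tuple[int, str], pd.DataFrame] = {}
    for (kv, bw_class), grp in df.groupby(["kv", "beam_width_class"], sort=True):
        m = grp.pivot(index="organ", columns="slab", values="coefficient")
        m.columns = m.columns.astype(int)
        m = m.sort_index(axis=1)
        m.index.name = None
        m.columns.name = None
        matrices[(int(kv), str(bw_class))] = m
    if not factors:
        factors = {c: 1.0 for _, c in matrices}
    return DoseCoefficientTable(matrices=matrices, output_factors=factors)
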