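# fetaldose

Slab-phantom CT dosimetry for fetal scans: organ and fetal doses, CTDIvol/DLP
accounting, wide-volume overlap geometry, and DLP → fetal-dose conversion
factors.

## The problem

Fetal CT (most commonly for suspected skeletal dysplasia) irradiates the most
radiosensitive patient there is, and the only dose numbers a clinician sees on
the console are CTDIvol (mGy) and the dose–length product DLP (mGy·cm).
`fetaldose` is for medical physicists and radiology researchers who want to

* estimate per-organ and fetal doses for abdominal/pelvic scan protocols on a
  stylized pregnant phantom,
* understand the dose penalty of **wide-volume** scanning — covering a long
  range with N overlapping axial cone-beam rotations of nominal beam width BW,
  where the overlap N·BW − L is re-irradiated once per covering rotation — and
* convert a displayed DLP into an approximate fetal dose with a single
  conservative factor.

## The model

The phantom is divided head to mid-thigh into 208 axial slabs of 5 mm
(1040 mm). A dose-coefficient table gives n[T, i], the dose to organ T per
mAs spent irradiating slab i, for each tube voltage and beam-width class.
For a rotation plan with per-rotation slab intervals, the organ dose is

    D_T = Σ_rotations Σ_{i ∈ interval} n[T, i] · (mAs / pitch)

so slabs inside overlap zones count once per covering rotation. The fetal
dose is the uterus dose (in a fetal scan the fetus fills the scanned uterus).
The maternal effective dose is the ICRP-103 weighted sum E = Σ w_T D_T over
female organs, with the remainder tissue entering as the mean over the
remainder organ set. Console quantities follow scanner convention:

    CTDIvol = nCTDIw · mAs / 100 / pitch          DLP = CTDIvol · scan length (cm)

with the irradiated length N·BW for wide-volume mode and the scan length for
helical mode. The conversion factor of a scanner mode is the **maximum** of
the per-protocol rounded ratios fetal dose / DLP (cm⁻¹) — the conservative
choice.

The reference Monte Carlo organ-dose datasets embedded in commercial CT dose
calculators are proprietary, so the package ships a synthetic coefficient
generator with the same structure (in-organ plateau, exponential scatter
tail, per-beam-width-class output factor); see `docs/methods.md`. Published
per-protocol fetal doses and DLPs for the two shipped scanners are included
as "reproduction-mode" inputs, so the conversion-factor analysis is exact
without any proprietary data.

## Worked example

Plan a 348-mm wide-volume acquisition (160-mm beam, 3 rotations):

```
$ fetaldose plan 348 160 3
rotation 0: 560-720 mm (slabs 112-144)
rotation 1: 655-815 mm (slabs 131-163)
rotation 2: 750-910 mm (slabs 150-182)
total irradiated: 480 mm
total overlap: 132 mm
overlap ratio: 38% (37.93%)
```

Three 160-mm rotations irradiate 480 mm to cover 348 mm: 132 mm (38 % of the
scan length) is inside overlap zones and is irradiated twice. The competing
352-mm plan (120 mm × 4) overlaps only 128 mm (36 %) — the *larger* nominal
beam width produces the larger overlap fraction, which is why its fetal dose
is higher despite the shorter scan.

Derive the conversion factors from the published per-protocol doses and
estimate a fetal dose from a console DLP:

```
$ fetaldose run-study --reproduction --out-dir out
wrote out/conversion_factors.json: {'wide_volume': 0.06, 'helical': 0.05}
$ fetaldose estimate --dlp 132 --mode wide
fetal dose ~ 7.92 mGy (DLP 132 mGy cm x CF 0.06 cm^-1)
```

0.06 cm⁻¹ (wide-volume) and 0.05 cm⁻¹ (helical) are the maxima of the rounded
fetal-dose/DLP columns; multiplying the displayed 132 mGy·cm by 0.06 gives a
deliberately conservative 7.92 mGy for an acquisition whose tabulated fetal
dose is 6.52 mGy. `fetaldose run-study` (without `--reproduction`) runs the
full synthetic-coefficient engine over all seventeen shipped protocols and
writes per-protocol dose reports, organ-dose tables and conversion tables.

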