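# Methods

## Geometry and coordinates

All dose accounting happens on a fixed axial grid: 208 slabs of 5 mm,
origin at the crown of the head, increasing toward mid-thigh (1040 mm).
Intervals are 0-based and half-open in slab units; every public interface
also accepts millimetres and converts exactly (positions must be multiples
of 5 mm). Scan lengths that are not on the grid are snapped to the nearest
multiple of 5 with ties rounded up. The shipped study protocols carry an
explicit entered-length override (e.g. 232 → 235, 264 → 270, 306 → 310)
because the values actually keyed into the original dose calculator do not
all follow nearest-5 rounding; no single rule explains them, so they are
reproduced by lookup, keyed by scan length.

## The phantom roster

The organ extents in `default_pregnant_phantom()` are a **documented fixture**,
not anatomical ground truth: the reference Monte Carlo phantom geometry is
not published at slab resolution. Positions are plausible for a near-term
pregnant adult — the uterus (580–730 mm from the crown) lies strictly inside
the small-intestine-to-bladder span, and the default scan ranges (cranial
edge 560 mm) cover the uterus fully and the stomach/liver partially. The
roster is deterministic and serializes to CSV (`organ,slab_start,slab_end`).
Distributed tissues (red bone marrow, bone surface, skin) span the whole
phantom; their per-slab coefficients are correspondingly small.

## Synthetic dose coefficients

The engine consumes n[T, i] — dose to organ T per mAs delivered while
irradiating slab i — per (tube voltage, beam-width class). Real tables of
this kind come from Monte Carlo transport in proprietary datasets; the
generator emulates their structure:

    n[T, i] = output_factor(class) · α_T · exp(−d(i, T)/λ) · (1 + jitter_i)

* **α_T** (mGy/mAs): in-organ plateau amplitude. Defaults are fixture
  values chosen once so the shipped abdominal protocols give organ doses in
  the low-mGy range, with the uterus/fetus highest and the small intestine
  highest among maternal organs; organs without an entry fall back to
  5·10⁻⁴. They are not fitted to any published organ dose — absolute doses
  from the synthetic tables are illustrative, not predictive.
* **λ** (slabs): scatter e-folding length, default 6 slabs (30 mm), a
  typical axial scatter scale in an adult trunk.
* **output_factor**: nCTDIw(class)/nCTDIw(reference class A). nCTDIw values
  (mGy per 100 mAs, 32-cm phantom) are back-solved from the scanners'
  displayed CTDIvol via CTDIvol = nCTDIw·mAs/100/pitch: ≈5.05 (class A,
  120/128-mm beams, from 2.6 mGy), ≈5.24 (class B, 140/160-mm beams, from
  2.7 mGy), ≈5.04 (class H, 40-mm helical collimation, from 2.9 mGy at
  pitch 1.39). Coefficients are per mAs internally; nCTDIw stays per
  100 mAs to match console convention — that is the single unit boundary.
* **jitter**: uniform multiplicative noise in [0, 0.2], seeded and
  deterministic; default 0 so the closed forms (and monotone scatter decay)
  are exact. It exists to exercise robustness, not to model physics.

What the synthetic tables do *not* emulate: tube-spectrum and bow-tie filter
detail, heel effect, voxel-level anatomy, body-size scaling. Tests passing
on them demonstrate the accounting machinery (summation, overlap handling,
class scaling, rounding), not agreement with measured organ doses.

## Rotation planning

**Wide-volume**: N rotations of nominal width BW cover a scan length L
(N·BW ≥ L). Junction overlaps are equalized at (N·BW − L)/(N − 1) and each
rotation start is snapped to the 5-mm grid (nearest, ties toward the scan
start); the first and last rotations are anchored so the union always covers
the snapped scan range (a repair pass closes any snapping gap). Equalized
placement is the only parameter-free choice; the scanners' true placement is
unpublished. Reported overlap quantities use the nominal arithmetic
(total = N·BW − L, ratio over L, percent rounded half-up) so they are exact
regardless of snapping. The beam-width/rotation combination for a scan
length is not invertible from L (firmware rule unpublished); the nine known
combinations ship as a lookup and anything else must state BW and N
explicitly.

**Helical**: a single interval; pitch 1.39 > 1 means no overlap, and
over-ranging is not modeled. The effective mAs per slab is mAs/pitch, a
flat profile. DLP accounting uses the *raw* scan length (the snapped length
is only used for slab planning) — this reproduces the published console DLPs,
e.g. 2.9 mGy × 34.8 cm = 100.92 → 101 mGy·cm for the 348-mm scan.

## Dose integration and effective dose

D_T sums n[T, i]·mAs/pitch over every (rotation, slab) incidence, so overlap
slabs contribute once per covering rotation — the mechanism of the
wide-volume dose penalty. The implementation is a matrix–vector product
against the slab multiplicity vector; tests verify it against an independent
brute-force loop at 10⁻¹² relative tolerance.

Effective dose uses the ICRP-103 weights restricted to female organs
(gonad weight on the ovaries), with the remainder tissue as 0.12 × the mean
dose over a 9-organ remainder subset (adrenals, gall bladder, heart,
kidneys, pancreas, small intestine, spleen, thymus, uterus; the four
non-localizable remainder tissues are omitted). The shipped table sums to
exactly 1.00 and is a swappable constant — female-only effective dose is an
approximation by construction, since effective dose is defined for a
sex-averaged reference person.

## Conversion factors

For each acquisition, ratio = fetal dose / displayed DLP, rounded half-up at
two decimals as dose reports print it; the recommended factor per scanner
mode is the **maximum** rounded ratio. Rounding before the maximum is the
convention consistent with the published tables. The conservatism guarantee
is: DLP × factor ≥ fetal dose − 0.005·DLP for every table row (the slack is
the 2-decimal rounding quantum). Reproduction mode (published dose/DLP rows
shipped in `fetaldose.study`) is a first-class input path, distinct from the
synthetic-coefficient engine, so the factor analysis is exact without any
proprietary coefficient data.

## Numerical conventions and degenerate inputs

Round-half-up (not banker's rounding) everywhere a console-style value is
printed: integer DLP, integer overlap percent, 2-decimal ratios. Zero mA is
valid (all doses 0); zero or negative DLP is rejected in ratio computation;
empty conversion tables, coefficient files, and off-grid positions raise
typed errors that the CLI maps to distinct exit codes (3 configuration,
4 coverage, 5 format, 6 other domain errors).

## Problem sizes

The full study is small by construction — 17 protocols, 23 organs × 208
slabs, ≤ 4 rotations — so every pipeline stage runs in well under a second.
Randomized property checks (oracle equivalence) use 100–120 plans of up to
4 intervals, enough to cover overlap multiplicities 1–4 on every organ class.

## Known limitations

* Absolute organ/fetal doses from the synthetic coefficients are
  order-of-magnitude realistic but not predictive; only the published-row
  reproduction path yields the published conversion factors.
* No tube-current modulation, partial rotations, over-ranging, heel effect,
  or patient-size (abdominal-circumference) scaling.
* One tube voltage class is exercised by the shipped scanners (100 kV);
  the table structure supports others but no defaults are provided.
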