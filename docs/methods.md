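# Methods

## The measurement being modelled

STR genotyping by fragment length analysis rests on a linear size model per
locus: an amplicon of a tetranucleotide STR locus has length

    size_bp = flank_offset_bp + 4 · repeats

where `flank_offset_bp` is the total non-repeat sequence amplified by the
primer pair. Loci co-amplified in one multiplex well are designed with
pairwise-disjoint predicted size windows, so an estimated fragment size
identifies its locus by containment alone, and the repeat number follows by
nearest-integer inversion of the size model. The default panel carries nine
murine loci and the human sentinel D8S1106 in four multiplex sets (at most
three markers per well), with predicted amplicon sizes spanning 130–515 bp —
inside the 25–1000 bp sizing range of a DNA-1000-class chip.

The exact window bounds, flank offsets and the membership of sets 1 and 4
are panel design parameters of this package rather than published constants:
windows were chosen once to be disjoint within each set, to sit on the
allele-size grid, to span exactly 130–515 bp overall, and to contain every
allele of the six packaged reference profiles. Set 2 pairs 9-2 with D8S1106
and set 3 pairs 15-3 with 6-4, following the published per-set
electropherograms; everything is overridable through a YAML panel config.

## Simulator

A well's trace is fluorescence sampled on a uniform time grid. Fragments
follow a log-mobility law `t(size) = t0 + slope·log10(size)` — monotone and
concave in size, qualitatively matching chip electropherograms — and each
contributes a Gaussian peak of height proportional to its relative amount.
Homozygous (single-allele) loci contribute one fragment at double amount;
heterozygous loci two fragments at single amount. Every well carries the two
internal alignment markers; i.i.d. Gaussian baseline noise is added; an
optional stutter artifact places a shadow peak one repeat unit below each
fragment at a configurable height fraction (off by default — reference
electropherograms show no stutter handling, so it is kept purely as a
stressor).

Defaults (all in `MigrationModel`, all overridable): `t0 = 10 s`,
`slope = 40 s/decade`, `peak_sigma_s = 0.08 s`, `noise_sd_fu = 1 FU`,
sampling step `dt_s = 0.01 s`, 60 FU per unit fragment amount, 150 FU
markers. These were fixed once as a realistic chip-like regime with one
deliberate property: the closest allele pair that must be resolved (adjacent
4 bp alleles at ~248 bp, e.g. 5-5 = 16,17) sits ~3.5 peak-sigmas apart in
time, so genuine heterozygotes produce two distinct maxima while peak
shapes remain realistic. Signal-to-noise (60:1 at the apex) corresponds to a
clean PCR at recommended loading, not a limiting-dilution experiment.

What the simulator deliberately does not model: dye chemistry and
quantitation, intensity imbalance between loci (amplification efficiency is
uniform), allele dropout, off-ladder artifacts other than stutter, and
non-affine migration drift. Passing tests therefore demonstrate the
correctness of the sizing/calling chain under the stated physics, not
robustness to every instrument pathology; the affine-drift invariance test
covers the dominant real-world well-to-well effect.

## Sizing chain

1. **Peak detection.** Baseline is a rolling median (2 s window, far wider
   than a peak's ~0.2 s FWHM); noise is the scaled median absolute deviation
   of the detrended trace; peaks are local maxima above
   `max(min_snr·noise, min_height_fu)` with prominence at least half that
   threshold and apex-to-apex separation ≥ 0.1 s (closer maxima are noise
   wiggles on one peak). Apexes are refined to sub-sample precision by a
   least-squares parabola over ±3 samples. Defaults `min_snr = 5`,
   `min_height_fu = 0`.
2. **Marker identification** is positional — first and last qualifying
   peaks — restricted to peaks reaching 25% of the trace's tallest peak.
   The markers are the tallest features of every well, so the height
   qualification only excludes rare near-threshold noise blips in the dead
   time before/after the markers, which would otherwise corrupt the affine
   alignment; ordinary sample peaks are never height-qualified.
3. **Calibration** pairs the ladder's between-marker peaks to the declared
   rung sizes in order (a count mismatch is an error) and interpolates
   log10(size) piecewise-linearly in time, extrapolating the end segments
   towards the markers. The map reproduces every anchor exactly and is
   asserted strictly monotone.
4. **Alignment** solves the two-point affine transform taking a sample
   well's marker times onto the ladder's, making sizing invariant to affine
   time distortion of the well.
5. **Sizing** maps each non-marker peak's aligned time through the
   calibration; estimates outside 25–1000 bp are flagged rather than
   dropped.

Under the defaults the end-to-end maximum absolute sizing error over 500
uniform fragments is ~0.6 bp — an order below the 5 bp chip resolution the
pipeline is held to — because the piecewise-linear log-size interpolation is
exact for the log-linear migration law and the residual error is apex jitter.

## Allele calling

Within a locus, the tallest peak is always an allele. A second peak becomes
the other allele if its height reaches `het_ratio = 0.4` of the tallest,
unless it lies one repeat unit (±1.5 bp) below a taller peak at under
`stutter_ratio = 0.3` of that peak's height, in which case it is filtered as
stutter. More than two qualifying peaks truncate to the top two and set the
`extra_allele` flag. Sizes convert to repeats by nearest-allele binning with
half-unit tolerance (±2 bp); larger residuals are no-calls, and no emitted
call ever carries a residual above half a unit. The ratio defaults are
calling-chemistry conventions chosen so equal-amount heterozygotes call
robustly at default noise while a 0.25-amount minority genome does not leak
into single-source calls; both are exposed as arguments. A per-locus
systematic size offset (for calibrating against a known reference sample) is
supported and defaults to zero; it exists because a 4 bp allele grid sits
close to the chip's 5 bp resolution, so a fixed per-locus bias is the
realistic failure mode on hardware.

Calls are invariant under peak-order permutation and uniform height scaling
(only height ratios enter the rules).

## Matching and contamination

Match scores are computed over murine loci called in both profiles, counting
distinct alleles (a single printed value counts once — reference tables do
not distinguish homozygosity from single detectable alleles, e.g. hemizygous
X-1, and the multiset model stays agnostic): Tanabe
`2·shared/(n_q + n_r)` (symmetric) and the two Masters variants
`shared/n_q`, `shared/n_r`. Verdict bands default to match ≥ 0.8 and
related ≥ 0.55, the thresholds conventional in human-line authentication;
their transfer to a 9-locus murine panel is a configuration choice and both
thresholds are echoed in every result. The human sentinel never contributes
to identity scores.

Interspecies contamination raises when the sentinel locus and at least one
murine locus show signal in the same sample; a pure human sample is reported
as human, not contaminated. Intraspecies contamination counts supporting
loci from two sources: loci whose calls carry `extra_allele` (more than two
surviving peaks — unambiguous for mixtures involving heterozygous lines),
and, when a reference database is available, loci where the profile holds
alleles beyond those of the reference line that best covers it (highest
`shared/n_ref`). The second route exists because a 1:1 mixture of two lines
that are single-allele at every locus produces at most two alleles per locus
— indistinguishable per-locus from a heterozygote — yet is flagrant against
the database (two references fully covered at once). It presumes the
contaminated line itself is in the database; a genuinely novel heterozygous
line checked against a database lacking it can accumulate spurious
supporting loci, which is the standard limitation of reference-based
checking. The flag requires `min_extra_loci = 2` supporting loci by default,
so a single stutter or noise artifact never raises it. The minority
contribution must also clear the het-ratio calling threshold, which makes
flagging monotone in the mixing fraction: at 20% a minority allele
(0.25 height ratio) is below threshold, from ~30% upwards it calls and the
mixture flags.

## Problem sizes and numerical choices

The sizing-accuracy study uses 500 single-fragment wells (the acceptance
script's default); profile-recovery checks run all six reference lines ×
four wells × three seeds. Ties in nearest-allele binning (residual exactly
half a unit) round up; size-window boundaries are closed intervals, so a
boundary size belongs to the locus. All simulator and study randomness flows
from explicit integer seeds through `numpy.random.default_rng`; derived
per-well seeds stay below 2^31.

## Known limitations

- Panel geometry (windows, offsets, sets 1/4) is package-designed, not
  transcribed from a published primer appendix; real primers would slot in
  via the panel config, with the per-locus size offset absorbing systematic
  bias.
- The packaged MM.1S profile is a synthetic stand-in (its D8S1106 genotype
  is invented; see `data/synthetic_human_mm1s.yaml`).
- Mixture deconvolution into full contributor genotypes, likelihood-ratio
  mixture statistics, and population-genetic allele frequencies are out of
  scope; the contamination report names supporting loci and a best-covering
  secondary candidate only.
- The intraspecies database route requires the primary line to be present in
  the reference database (see above).
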