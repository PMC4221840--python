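# Methods

## Chemical model

All masses are nominal integer masses (C = 12, H = 1, O = 16), matching
unit-resolution quadrupole EI data scanned over m/z 50–920. A saturated
CnH2nO2 fatty acid weighs 14n + 32, a saturated fatty alcohol 14m + 18, an
alkane 14n + 2; each double bond subtracts 2 and each hydroxyl adds 16.
Sterol-related species use a cholesterol-type backbone CnH2n−8O (14n + 8;
C27 → 386). Esters condense with loss of one water, triglycerides with
loss of three.

The diagnostic acid-side fragment series used throughout is acid MW + 1
(14n + 33 for saturated acids: 257 for C16:0 through 481 for C32:0).
Although this series is conventionally written [RCOO]⁺, its m/z equals
the protonated acid, so the ion type is named `acid_acylium_plus_H` to
avoid implying a radical formula. The remaining ester ions are modeled as
acylium [R¹CO]⁺ = MW − 17, acid alkyl [R¹]⁺ = MW − 45, alcohol alkenyl
[R²]⁺ = 14m − 1 − 2d, and [R²OCO]⁺ = 14m + 43 − 2d, plus the molecular
ion. Whether the observed [R¹]⁺/[R²]⁺ ions are alkyl or alkenyl cations
is not established experimentally; the formulas here are fixed model
conventions, and nothing downstream depends on the alcohol-side values.
Triglycerides contribute their molecular ion (tripalmitin PPP = 806,
1,2-dipalmitoyl-3-oleoylglycerol PPO = 832), the acyloxy-loss ions
[M − R¹COO]⁺ and acylium ions. Branched and hydroxy chains are
representable (they occur among calibration standards) but their
fragmentation is deliberately not modeled.

## Retention-time calibration

A single global OLS line RT = a·C + b maps total carbon number to
retention time; per-structural-class offsets (branched, hydroxy,
unsaturated) are not modeled, since a single correlation is adequate for
carbon-number assignment at even-integer resolution. The package default
is RT(C) = C − 29 min, which places the C50–C56 esters at 21–27 min and
the C29–C44 standards inside a 19-minute window; any fitted line can be
substituted. Inversion rounds to the nearest even carbon (gum-base esters
are even-carbon); ties round up, for determinism. `parity="any"` exists
for odd-carbon standards. Peak-area quantitation uses the same
`LinearModel` on (concentration, area) pairs over the 0.1–0.5 mg/mL
working range; estimates below the fitted range are returned as-is with a
`below_range` flag rather than clipped.

## Forward simulation

Each profile species elutes as a Gaussian of width sigma = 0.05 min
(apex at the RT model's prediction for its total carbon count, scans
every 0.01 min over a 1–34 min window, truncated at ±5 sigma). Every scan
under the peak carries the species' full fragment set with fixed
within-spectrum intensity ratios — for esters,
molecular : acid+1 : acylium : acid-alkyl : alcohol ions =
10 : 100 : 40 : 20 : 30 (the alcohol share split evenly over its two
ions). These ratios are invented: no relative intensities are asserted
anywhere downstream; only the set of m/z present and the proportionality
of integrated current to abundance matter. Detector response is assumed
equal across species and acid chains, so EIC areas are proportional to
molar composition. Noise is additive Gaussian on every centroid with
standard deviation `noise_sd` × (maximum centroid intensity), truncated
at zero; a run is a pure function of (profile, config, seed). Runs keep
only scans holding at least one centroid, so the CSV scan-table round
trip reproduces scan structure exactly (`%.17g` on write,
`float_precision="round_trip"` on read keeps doubles bit-exact); with a
positive `baseline` every grid scan carries a baseline centroid at
m/z 50. mzML output is minimal PSI-MS 1.1.0 (centroided MS1, uncompressed
base64 doubles) written and read by the package's own serializer, which
also accepts 32-bit and zlib-compressed arrays and second-valued scan
times.

## Packaged reference profiles

The ten profiles encode each gum base's documented character: lanolin,
C48–C52 esters (C16:0–C20:0 acids) plus a sterol-related interferent;
beeswax, palmitate-dominated C40–C48 esters plus long-chain alkanes;
jojoba, monounsaturated C38–C44 esters (C18:1–C22:1); candelilla, alkanes
only (C31 major); shellac, C44–C50 esters plus minor alkanes; carnauba,
rice-bran and montan, C50–C56 esters whose C54/C56 acid splits embed the
reported compositions exactly; urushi and Japan wax, PPO/PPP
triglycerides at 50:50 and 12:88. Three stand-in choices deserve note.
(1) Relative abundances across an ester carbon range are uniform except
where a reported acid split fixes them — within-profile weights are not
measured data. (2) The rice-bran C56 column embeds the reported 29:70
C22:0/C24:0 split; its trace C20:0 entry (printed as 0, i.e. below 0.5%)
is omitted because a zero print fixes no embeddable value. (3) Under the
global linear RT model a C27 alkane or free cholesterol would elute below
the scan window, so the alkane interferents use the heavier genuine
homologues C31/C33 and lanolin's sterol block is represented by a
C43 cholesteryl-ester-like species whose EI signature is the cholesterol
backbone ion set (353/368/386), as in real cholesteryl-ester spectra.

## Peak detection and integration

The TIC is smoothed with a 5-point moving average (edge-corrected);
local maxima above 1% of the global maximum become apexes, and apex pairs
whose separating valley stays above half the lower apex are merged (such
doublets are noise jitter on one peak top, not valley-resolved peaks).
Boundaries extend downhill to the nearest flanking local minimum or to
where the smoothed trace falls below 0.5% of the apex; genuinely
overlapping peaks are therefore split at the valley, with no
deconvolution — co-eluting isomers are resolved downstream through EICs.
Areas are trapezoidal after subtracting a local linear baseline drawn
between the window endpoints, floored at zero. EIC extraction uses a
±0.5 Th tolerance (unit resolution). All settings are exposed.

## Composition estimation

For each TIC peak, the ester carbon number comes from the inverted RT
line (even parity); each panel acid's share is its acid-series EIC area
integrated over the peak's own window, normalized across the panel.
Because every co-eluting isomeric ester shares the same Gaussian envelope
and the baseline correction is linear in the signal, the envelope cancels
exactly in the ratios: on noiseless runs recovered fractions equal the
generating weights to ≤ 1e−6 (verified by test). Acids below
`min_fraction` = 0.005 are dropped and the remainder renormalized, so
table columns sum to 100 (absent cells print as "-"); rounding to integer
percent happens only at presentation. Alcohol chains are inferred by
subtraction (alcohol C = ester C − acid C), never from alcohol-side ions.
The default panel is saturated even-carbon C16:0–C32:0; an
`extended=True` panel adds even-carbon monounsaturated C16:1–C24:1 for
unsaturated waxes. Peak classes are assigned in order: wax ester when the
summed acid-series EIC area reaches 20% of the TIC peak area;
triglyceride when the TAG diagnostic ions (molecular + acyloxy-loss from
a small packaged TAG table) reach 20%, the label taken from the strongest
molecular ion (832 vs 806 resolves PPO from PPP); hydrocarbon when the
apex spectrum is ≥ 50% alkyl ladder (57/71/85); sterol-related when the
backbone triplet reaches 20%; otherwise unknown. The PPO/PPP ratio is
the TIC-area ratio of the PPO- and PPP-assigned peaks; a missing PPP
raises an undefined-ratio error, a missing PPO yields 0. The ratio is
invariant to uniform intensity rescaling.

## Fingerprint classification

A fingerprint holds four blocks: the ester-carbon-number TIC-area
distribution, the flattened acid-composition matrix (fractions keyed by
acid × ester carbon), class-presence area fractions
(hydrocarbon / sterol-related / triglyceride), and the PPO/PPP ratio when
defined. Similarity is a weighted mean of per-block scores — cosine for
the vector blocks, min/max agreement for the ratio — with default weights
0.40 / 0.40 / 0.15 / 0.05. Blocks absent from both fingerprints are
dropped and the remaining weights renormalized; a block present on only
one side scores 0. This rule is what makes the two boundary cases
consistent: identical fingerprints always score 1, and two fingerprints
that differ only in orthogonal ester distributions score 0. References
are fingerprinted from noiseless fixed-seed runs generated on demand and
passed through the identical annotation pipeline, so query and reference
cannot drift apart in feature construction; the classifier's default
configuration uses the extended acid panel so monounsaturated waxes
produce a populated acid block. Carnauba, rice-bran and montan share the
C50–C56 carbon range and are separated almost entirely by the acid
matrix; zeroing its weight collapses their pairwise margins to run-to-run
noise level (asserted by test), which is exactly why the fragment-ion
chromatograms are needed on top of the TIC.

## Problem sizes and numerical choices

Simulated runs span 1–34 min at 0.01 min per scan with only non-empty
scans retained (200–350 scans, a few thousand centroids per run), so the
full test suite — including a 10-profile × 5-seed self-classification
matrix — and the acceptance script each finish in seconds. Determinism:
one `numpy` Generator seeded from the config drives all noise; centroids
are perturbed in (scan, m/z) order; classification ties break
alphabetically. Degenerate inputs raise typed errors (all-identical
calibration x, non-positive slope inversion, empty runs, windows outside
a chromatogram, unknown catalog names, malformed CSV rows with line
numbers).

## What the synthetic data does and does not show

The generator reproduces the features the method actually relies on —
RT/carbon linearity, co-elution of isomeric esters, acid-series EIC
proportionality, characteristic interferent classes, TAG molecular-ion
resolution — under exactly known ground truth, which is what the
round-trip and classification tests exercise. It omits chromatographic
tailing and skew, column bleed, isotope clusters, response-factor
differences between chains, spectral-library interferences and
between-sample biological variability. Passing tests therefore
demonstrate correctness of the inference arithmetic and pipeline
plumbing, not instrument-level validation: on real data, detector
response factors and peak-shape asymmetry would add systematic error to
the composition estimates that the equal-response assumption hides, and
the classifier's margins would shrink accordingly.

## Known limitations

Positional isomers of triglycerides beyond the PPO/PPP labels are not
resolved; the TAG table is small and palmitate/oleate/stearate-centric.
Hydroxy and branched esters are representable but not fragment-modeled.
Mixtures of gum bases are not deconvolved — classification assumes a
single dominant source. The quantitation model is a rough single-line
fit, adequate for concentration estimates, not for certified assays.
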