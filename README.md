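# waxgc

Direct high-temperature EI-GC/MS analysis of ester-type gum bases, as a
reusable Python pipeline.

Natural ester-type gum bases — beeswax, carnauba wax, lanolin, jojoba,
candelilla, shellac, rice bran, montan, urushi and Japan wax — are food
additives whose major constituents are wax esters: condensation products
of a long-chain fatty acid (R¹COOH) and a long-chain fatty alcohol
(R²OH), labeled by total carbon number (C40–C56). Quality control needs a
way to tell these materials apart without hydrolysis and derivatization.
On a short high-temperature column, ester retention time is nearly linear
in carbon number, and under electron ionization each ester emits
diagnostic product ions from its acid moiety ([R¹COO]⁺-type at acid
MW + 1, [R¹CO]⁺, [R¹]⁺) and alcohol moiety ([R²]⁺, [R²OCO]⁺). `waxgc`
implements the whole workflow around those two facts:

- **`waxgc.chem`** — nominal-mass and fragment-ion arithmetic. For a
  saturated Cₙ acid the diagnostic series is m/z = 14n + 33 (C16:0 → 257,
  …, C32:0 → 481); behenyl stearate (C22:0 alcohol × C18:0 acid) has
  nominal mass 592.
- **`waxgc.calibration`** — OLS retention-time ↔ carbon-number calibration
  (RT = aC + b) and linear peak-area quantitation.
- **`waxgc.simulate`** — a seeded forward model that turns a packaged
  gum-base reference profile into a centroided EI-GC/MS run (Gaussian
  peaks, fixed within-spectrum fragment ratios, additive noise).
- **`waxgc.peaks`** — TIC/EIC construction, peak detection, trapezoidal
  integration with a local linear baseline.
- **`waxgc.annotate`** — the core inference: carbon number from the RT
  line, per-ester fatty-acid fractions from acid-series EIC areas
  integrated over the shared peak window, peak classification
  (wax ester / triglyceride / hydrocarbon / sterol-related), and the
  PPO/PPP triglyceride ratio that separates urushi wax from Japan wax.
- **`waxgc.classify`** — gum-base identification by weighted cosine
  similarity over fingerprint blocks (ester-carbon distribution, acid
  matrix, class flags, PPO/PPP).

## Worked example

```
$ waxgc simulate --profile carnauba --seed 7 --out run.csv
wrote 250 scans to run.csv
$ waxgc annotate --run run.csv --out composition.csv
5 peaks, 4 wax esters; table -> composition.csv
$ cat composition.csv
constitutive_fatty_acid,C50,C52,C54,C56
C18:0,11,-,-,-
C20:0,34,24,16,-
C22:0,45,55,62,12
C24:0,10,21,22,84
C26:0,-,-,-,4
$ waxgc classify --run run.csv --out result.json
call: carnauba (margin 0.2695)
```

The simulated carnauba run contains four ester TIC peaks (C50–C56, eluting
at 21–27 min under the default RT model RT = C − 29) plus the
characteristic free C32 alcohol. The table gives, for each ester, the
percentage of each constitutive fatty acid estimated from its
fragment-ion mass chromatograms: the C54 ester is mostly C22:0 (62%) with
C20:0/C24:0, the C56 ester mostly C24:0 (84%) — the signature that
distinguishes carnauba from rice-bran wax (C22:0/C24:0 only, regardless of
ester size) and montan wax (C24:0–C32:0). The classifier then ranks all
ten packaged reference profiles by fingerprint similarity; `margin` is
the similarity gap between the top two calls.

The same workflow runs as a library (`generate_run`, `annotate_run`,
`composition_table`, `classify`) and accepts measured data as CSV scan
tables (`rt_min, mz, intensity`) or centroided MS1 mzML.

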