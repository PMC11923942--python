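# Methods

This note documents the models, conventions and numerical choices behind
`hocscreen`, and what the synthetic bench does and does not establish
about behaviour on real instrument data.

## Ions and masses

GC-APCI produces singly charged (quasi-)molecular ions by charge transfer
(M⁺˙) or proton transfer ([M+H]⁺; [M−H]⁻ in negative mode). Adduct m/z is
computed from the neutral monoisotopic mass with the electron mass handled
explicitly:

- M⁺˙ = M − mₑ
- [M+H]⁺ = M + (1.00782503 − mₑ) = M + 1.00727647
- [M−H]⁻ = M − 1.00727647

At the 2 mDa mass gate applied below 200 Da, the ~0.549 mDa electron term
is a quarter of the tolerance, so it cannot be neglected. Isotope masses
and natural abundances come from the NIST table embedded in `pyteomics`, a
fixed snapshot that keeps results reproducible offline.

A deliberate convention runs through the package: the m/z of record for
both theoretical and measured ions is the **most abundant isotopologue**
(the envelope base peak). For lightly halogenated compounds this is the
all-principal-isotope ion; for Br₂₊ or Cl₅₊ compounds the base peak moves
to M+2 or beyond, and the mass gate compares base peak against base peak.
Deconvolution software reports feature m/z the same way.

## Isotope patterns

Theoretical envelopes are computed by exact abundance convolution: each
element's multinomial isotope distribution is built by repeated
convolution of the single-atom distribution and combined across elements,
tracking per-bin probability and probability-weighted mass. Isotopologues
are aggregated into nominal-mass (mass-number) bins with intensity-weighted
centroid m/z, mirroring how fine structure (e.g. ¹³C₂ vs ³⁷Cl) merges in
centroided spectra. Terms below 10⁻¹² probability are pruned; the test
suite verifies agreement with brute-force enumeration over all C/H/Cl/Br
compositions of ≤ 8 atoms to 10⁻⁶ relative intensity. Patterns are pruned
to peaks ≥ 1 % of base and at most 8 peaks by default — the regime an
instrument actually observes. The ionising proton of [M+H]⁺ is treated as
pure ¹H (deuterium contributes 0.0115 %, far below the 5 % intensity
gate), so envelope shape is adduct-independent up to the m/z shift.

## Gates

**Mass gate.** |error| < 5 ppm for theoretical m/z ≥ 200 Da, < 2 mDa
below. The boundary case uses the ppm rule: at exactly 200 Da the rules
give 1 mDa vs 2 mDa, so ppm is the stricter, conservative choice. Both
inequalities are strict.

**Isotope gate.** Every non-base theoretical peak is paired with the
nearest measured envelope peak within the active mass tolerance. At least
one non-base isotopologue must be matched (configurable), and the
geometric mean of relative intensity deviations,
|measured − theoretical| / theoretical × 100, over matched isotopologues
must be strictly below 5 %. Unmatched theoretical peaks beyond the first
do not fail the gate — weak isotopologues fall below detection limits
routinely. Compounds of single-isotope elements have a one-peak pattern;
the gate then passes vacuously and flags the bypass, rather than
penalising compounds for their elemental composition. A deviation of
exactly zero is floored at 10⁻¹² % before the geometric mean so the mean
stays finite.

## Continuous scoring

Deviations are signed: ΔRT = RT_measured − RT_reference (minutes),
ΔCCS = (CCS_measured − CCS_reference)/CCS_reference × 100 (%). Each
dimension has a high-confidence threshold CT_high (score 1 inside) and a
low-confidence threshold CT_low (score 0 at or beyond; candidate
excluded). Between them the score decays linearly toward the low boundary
on the same side as the deviation; the decay shape is a pluggable hook
(`ScoringConfig.score_shape`) with linear decay as the default — the
simplest function consistent with the two endpoints. The score is
continuous at the high boundary and right-continuous in the limit at the
low boundary.

CCS thresholds are symmetric percentage bands per reference source:
±2 % / ±3 % for literature values (interlaboratory CCS reproducibility is
about ±2 %, and observed isomer CCS differences stay within 5 %, so the
bands also guard against isomeric misassignment) and ±5 % / ±7 % for
model-predicted values, which carry a systematic overprediction for
halogenated compounds and a wider spread.

RT thresholds are *intervals*, mean ± SD (high) and mean ± 2 SD (low) of
the measured-minus-reference residual distribution for each source:
0.15 ± 0.69 min for RTs converted from literature retention indices
(n = 36) and 0.086 ± 1.13 min for model-predicted RTs (n = 102). The
mean ± SD rule is literally asymmetric about zero, and that asymmetry is
preserved rather than symmetrised: a biased reference source shifts both
boundaries. In-house-measured reference RTs have no published residual
summary; they are assigned the literature-converted intervals — the
tighter calibrated pair — as this package's own default, adjustable via
`ThresholdSet`. `calibrate_rt_thresholds` recalibrates the intervals from
any user-supplied residual set (≥ 3 values; zero spread triggers a
degenerate-calibration warning).

## Fusion and retention

S = 0.2·S_RT + 0.4·S_CCS + 0.4·S_MS². RT carries less weight because it
depends on chromatographic conditions; CCS and MS² are
instrument-independent(ish) evidence. The MS² similarity score is produced
by an external fragmentation scorer operating on exported per-candidate
files; it is attached only when the feature has at least two monoisotopic
fragment ions (below that the score is considered not estimable). A
missing MS² score contributes 0 **without renormalising the weights**:
with the 60 % cutoff this forces perfect RT and CCS agreement whenever
fragmentation evidence is absent, which is the designed behaviour of the
operating point, not an accident of implementation. Candidates with fused
score ≥ cutoff are retained; per suspect only the highest-scoring retained
candidate survives. Ranking ties break by smaller |ΔCCS|, then smaller
|ppm error|, then suspect id — fully deterministic.

A feature may match several suspects and a suspect several features;
many-to-many pairings are kept until best-per-suspect resolution. Per
(feature, suspect) pair only the best-matching adduct (smallest |ppm|
among gate-passing adducts) is kept. The CCS comparison uses a single
reference value per compound regardless of adduct, assuming CCS
differences among M⁺˙/[M+H]⁺/[M−H]⁻ fall within measurement uncertainty
(reported differences are under 2 %).

Stage counts tally candidates at four stages — full-scan (mass + isotope)
with RT inside CT_low; plus CCS inside CT_low; fused score above cutoff;
best per suspect — and are non-increasing by construction.

## Retention-index machinery

Because alkanes evade APCI ionisation, libraries use the Fiehn retention
index (fatty acid methyl ester references). Kovats indices from
n-alkane-referenced libraries are mapped to the Fiehn scale by a single
least-squares line fitted over compounds indexed on both scales — both
scales are near-affine in elution temperature over the relevant range, so
a global linear map is standard practice; it is exposed as a configurable
object should a segmented fit be needed. Fiehn index → RT conversion is
piecewise-linear interpolation over a user-supplied anchor table (anchor
tables are instrument-specific), with linear extrapolation from the
terminal segment outside the anchor range, flagged to the caller.

## Synthetic bench

`simulate_dataset` emulates the validation experiment entirely in silico:

- a library of unique aromatic, halogen-rich compositions (C₆–C₂₄, up to
  6 Cl / 4 Br, ~35 % unhalogenated PAH-like) with RT and CCS references
  loosely correlated with mass (RT ≈ 2 + 0.07·m/z min, CCS ≈
  110 + 0.33·m/z Å²), matching the ranges typical of GC-amenable HOCs;
- planted features for a configurable fraction of suspects, observed as
  M⁺˙ or [M+H]⁺ with Gaussian noise: absolute RT noise (default σ
  0.69 min, the literature-converted residual spread), relative CCS noise
  (default 2 %, interlaboratory reproducibility), relative m/z noise
  (default 2 ppm, a well-calibrated ToF) and per-peak isotope intensity
  noise (default 2 %);
- isomeric decoy library entries (same formula, CCS shifted ±3–5 %, RT
  shifted ±0.5–2 min) at a configurable rate (default 0.3), probing the
  workflow's hardest failure mode;
- MS² similarity simulated directly as a [0, 1]-truncated Gaussian score
  (true candidates 0.724 ± 0.180, matching scorer performance on known
  HOC standards; decoys 0.30 ± 0.20 as this package's choice of a clearly
  non-matching population), with 38 % of features lacking enough fragments
  for a score (63 of 102 reference standards yielded scorable spectra).

All randomness derives from a single seed; identical configurations yield
byte-identical written datasets. `evaluate` computes the true positive
rate over retained best candidates and classifies false positives as
isomer-level (the matched suspect is the planted compound's same-formula
decoy) or other.

What the bench does *not* emulate: matrix interferences and coelution,
deconvolution artefacts, in-source fragmentation, detector saturation,
correlated (non-Gaussian) RT drift, and real MS² spectra. Passing the
bench therefore demonstrates the correctness and statistical behaviour of
the gating/scoring logic under controlled noise — not instrument-level
performance on sediment extracts, whose published true positive rates
(~70 %) reflect those additional effects.

Problem sizes used in the test suite (200 suspects × 20 replicates for
parameter recovery and the isomer-false-positive property) were chosen to
give stable statistics at interactive runtimes.

## Numerical and interface choices

- Thresholds accept either symmetric ± bounds (scalars) or explicit
  asymmetric intervals; degenerate configurations (high boundary touching
  low) raise a configuration error rather than producing 0/0.
- Floating-point: 0.2 + 0.4 = 0.6000000000000001 ≥ 0.6, so the
  perfect-RT/CCS-no-MS² candidate is retained at the cutoff boundary as
  intended; tests assert the equality within 10⁻¹².
- Scoring configuration round-trips through YAML; the CLI archives the
  effective configuration and input digests in a per-run `manifest.json`.
  Data outputs are byte-identical for identical inputs and seed; the
  manifest additionally records a wall-clock timestamp and is excluded
  from that byte-identity contract.
- Library rows carrying both a literature and a predicted CCS keep the
  literature value (tighter calibrated thresholds). Duplicate InChIKeys
  keep the first occurrence and are logged.
- Out-of-range MS² scores are rejected row-wise on import, never clamped;
  invalid feature/library rows are skipped with a logged row number, so
  one bad row cannot abort a batch.

## Known limitations

- Charge states > 1 and fine isotopic structure are out of scope; the
  nominal-mass aggregation is inappropriate for resolving powers that
  separate ¹³C₂ from ³⁷Cl.
- The Kovats→Fiehn map is global-linear; strongly curved index
  relationships would need a segmented calibration.
- The external fragmentation scorer is neither invoked nor reimplemented;
  MS² evidence is only as good as the imported scores.
- Isomer-level misassignment is detectable only insofar as CCS/RT
  references separate the isomers — exactly as with real libraries.
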