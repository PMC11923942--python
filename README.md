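# hocscreen

Multidimensional-constrained suspect screening of hydrophobic organic
contaminants (HOCs — PAHs, PCBs, PBDEs, organophosphate esters and other
organohalogens) for **GC-APCI-IM-HRMS** data: gas chromatography with
atmospheric-pressure chemical ionization, ion mobility and high-resolution
mass spectrometry.

Conventional GC-MS suspect screening matches electron-ionization spectra
and retention indices, and is limited by library coverage and the frequent
loss of the molecular ion. Soft APCI ionization preserves (quasi-)molecular
ions — M⁺˙ by charge transfer or [M+H]⁺ by proton transfer — and ion
mobility adds the collision cross section (CCS, Å²), an
instrument-independent descriptor of ion size and shape. `hocscreen`
implements a screening workflow that exploits all four dimensions
(full-scan MS¹, retention time, CCS, fragmentation MS²) with a continuous
scoring system, for analysts matching deconvoluted feature tables against
curated suspect lists.

## The scoring system

A candidate (feature, suspect) pairing must pass two mandatory full-scan
gates:

- **exact mass** — |error| < 5 ppm for ions with *m/z* ≥ 200 Da, < 2 mDa
  below (measured *m/z* and theoretical *m/z* both refer to the most
  abundant isotopologue);
- **isotope pattern** — at least one non-base isotopologue observed, and
  the geometric mean of relative intensity deviations of matched
  isotopologues < 5%. Theoretical envelopes are computed by exact abundance
  convolution over the elements.

Retention time and CCS are then scored continuously. Each dimension has a
high-confidence threshold *CT*<sub>high</sub> and a low-confidence
threshold *CT*<sub>low</sub>:

- deviation inside *CT*<sub>high</sub> → score 1;
- deviation beyond *CT*<sub>low</sub> → score 0, candidate excluded;
- in between → linear decay from 1 to 0.

Default thresholds are calibrated per reference source: CCS ±2 % / ±3 %
(literature values) and ±5 % / ±7 % (model predictions); RT intervals are
mean ± SD / mean ± 2 SD of the per-source residual distributions
(0.15 ± 0.69 min for literature-converted retention indices,
0.086 ± 1.13 min for predicted retention times) — deliberately asymmetric
so reference bias is preserved.

The dimension scores fuse into a weighted multidimensional score

&nbsp;&nbsp;&nbsp;&nbsp;*S* = *W*<sub>RT</sub>·*S*<sub>RT</sub> + *W*<sub>CCS</sub>·*S*<sub>CCS</sub> + *W*<sub>MS²</sub>·*S*<sub>MS²</sub>,&nbsp;&nbsp;&nbsp;*W* = (0.2, 0.4, 0.4)

where the MS² similarity score is imported from an external fragmentation
scorer and contributes 0 when unavailable (weights are not renormalized).
Candidates scoring ≥ 60 % are retained; per suspect only the
highest-scoring candidate survives. Since 0.2 + 0.4 = 0.6, a candidate
without fragmentation evidence is retained exactly when both RT and CCS
agree perfectly — a deliberate property of the operating point.

## Worked example

```bash
python examples/03_simulate_screen_evaluate.py
```

generates a 200-compound suspect library with isomeric decoys, plants half
the suspects as noise-perturbed features, screens and evaluates:

```
library: 252 entries (52 isomeric decoys)
features planted: 107; MS2 scores available: 74

hits per workflow stage:
  full-scan + RT match        : 111
  + CCS match                 : 88
  multidimensional score >60% : 61
  best candidate per suspect  : 61

true positive rate: 0.984
false positives: 1 isomer-level, 0 other
```

The stage counts show the CCS dimension pruning candidates that mass,
isotope pattern and RT alone would keep (111 → 88), and the only
misidentification is isomer-level: a same-formula decoy whose shifted
RT/CCS still fell within the thresholds. The other examples demonstrate
isotope-envelope computation (`01`), the continuous scoring and fusion
arithmetic (`02`) and retention-index calibration (`04`).

The same workflow is scriptable from the shell:

```bash
hocscreen simulate --seed 7 --output sim/
hocscreen screen --library sim/library.csv --features sim/features.csv \
    --ms2-scores sim/ms2_scores.csv --output run/
hocscreen evaluate --results run/candidates.csv --truth sim/truth.csv
```

## Layout

- `src/hocscreen/chem.py` — formulas, adduct masses, isotope patterns
- `src/hocscreen/library.py` — suspect entries, retention-index
  calibration, threshold sets, library I/O
- `src/hocscreen/features.py` — feature tables, NIST MSP, fragmentation
  scorer export, MS² score import
- `src/hocscreen/screening.py` — gates, continuous scores, fusion,
  retention, ranking
- `src/hocscreen/bench.py` — synthetic datasets and evaluation
- `src/hocscreen/cli.py` — `hocscreen` command group

See `docs/methods.md` for the model, assumptions and numerical choices.
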