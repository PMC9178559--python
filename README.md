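# xlstub

Fragmentation analysis for crosslinking mass spectrometry with MS-cleavable
crosslinkers.

Crosslinking MS identifies residue–residue proximities by covalently joining
two peptides and fragmenting them together, which means two peptides must be
inferred from one spectrum out of a search space of (n² + n)/2 pairs.
MS-cleavable reagents such as DSSO and DSBU break apart inside the mass
spectrometer, leaving complementary "stub" masses on each peptide — DSSO
cleaves asymmetrically into an alkene (A, 54.01056 Da) and a sulfenic acid
(S, 103.99320 Da) stub, with S commonly losing water to the unsaturated thiol
(T, 85.98264 Da). The intact-peptide A/T peaks form a signature doublet with
a fixed Δm ≈ 31.972 Da from which the individual peptide masses can be read,
and on which MS3 acquisition can be triggered.

`xlstub` is a tested, reusable pipeline for asking quantitative questions
about this chemistry:

- **Theoretical fragments** for crosslinked peptide pairs: b/y ions, cleaved
  stub variants (A/S/T for DSSO, A/B for DSBU), intact-partner (+P)
  fragments, and intact-peptide P ions, for cleavable (DSSO, DSBU) and
  non-cleavable (BS3) reagents.
- **Spectrum annotation**: deisotoping with charge assignment, deisotoped
  intensity ranks, ppm-tolerant fragment matching.
- **Signature doublets**: per-peptide doublet calls (both stub P ions at one
  charge; doublet rank = rank of its more intense peak), prevalence and
  cumulative rank-cutoff curves.
- **Sequence coverage**, computed conservatively as the fraction of the
  2(L−1) possible N-/C-terminal cleavage fragments matched at least once,
  split by fragment category (linear / link-site / stub-only / +P).
- **MS3 evaluation**: classify each MS3 precursor as a correctly-triggered
  stub fragment (20 ppm), a linear or crosslinker-modified linear peptide, or
  unmatched; merge correctly-triggered MS3 fragments into combined coverage.
- **Grouped target–decoy FDR** on unique CSMs, FDR = max(0, TD−DD)/TT,
  separately for self and heteromeric matches, with pre-FDR quality filters
  (≥3 matched fragments per peptide, delta score > 15% of score, length ≥ 6,
  unambiguous protein assignment, no noncovalent flag) and the
  doublet-prefilter and cleavable-vs-noncleavable comparisons.
- **Synthetic data**: a seeded generator of protein databases, reversed
  decoys, crosslinked pairs and MS2/MS3 spectra emulating stepped-HCD and
  low-energy-CID acquisition, with full ground truth for every peak —
  so every stage is testable without instrument data.

## Worked example

```
xlstub pipeline --seed 2 --n-csms 500 --acquisition sHCD --out runs/shcd
```

simulates 500 DSSO-crosslinked spectra (doublet emission probability 0.9 per
peptide, 30 noise peaks per spectrum), annotates them, and runs grouped 5%
FDR. The same stages are available as library calls:

```python
from xlstub import SimulationConfig, run_simulated_pipeline
from xlstub.doublets import doublet_prevalence_summary

run = run_simulated_pipeline(SimulationConfig(seed=2, n_csms=500))
print(doublet_prevalence_summary([r.doublet_class for r in run["passing"]]))
print(run["fdr_results"]["heteromeric"])
```

prints (seed 2):

```
{'at_least_one': 0.99, 'both': 0.828, 'n': 500}
FdrGroupResult(group='heteromeric', threshold_score=1.272..., counts=(500, 0, 0),
               achieved_fdr=0.0, degenerate=False)
```

At a per-peptide doublet emission probability of 0.9, 99% of CSMs contain at
least one signature doublet and ~83% contain both (≈ 0.9² plus sampling
noise) — the doublet statistic the pipeline recovers from raw peaks. All 500
spectra carry their true pair as the best-scoring candidate, so every CSM
passes the 5% heteromeric FDR with zero decoys above threshold.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch at the given seed: the closed-loop
simulation (zero noise, unit emission probabilities → exact recovery of
doublet classes, coverage and FDR), a default-noise stepped-HCD run with
doublet prevalence, a CID-MS2-MS3 run with trigger-correctness proportions,
and the stub-aware vs stub-blind (noncleavable) annotation comparison. It
prints stage summaries and writes the machine-readable result JSON to
`--out`.

## Layout

- `xlstub.chem` — digestion, masses, crosslinker specs, theoretical fragments
- `xlstub.io` — MGF (with MS3 parent linkage in TITLE tokens), FASTA, CSM TSV
- `xlstub.annotate` — deisotoping, ranks, ppm matching
- `xlstub.doublets` — doublet calls, rank curves, sequence coverage
- `xlstub.ms3` — MS3 trigger classification, combined coverage
- `xlstub.fdr` — scoring, prefilters, grouped FDR, QC comparisons
- `xlstub.simulate` — ground-truthed synthetic data
- `xlstub.pipeline`, `xlstub.report`, `xlstub.cli` — orchestration and tables

See `docs/methods.md` for the model, parameter defaults, and limitations.
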