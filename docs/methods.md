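# Methods

## Chemistry model

A crosslinker is described by its intact spacer (linker) mass, its dead-end
modification masses (hydrolyzed −OH and amidated −NH₂, applicable to Lys and
the protein N-terminus), its reactive residues (Lys, Ser, Thr, Tyr plus the
protein N-terminus), and — for MS-cleavable reagents — a table of stub
masses and a designated doublet pair.

Built-in specifications (masses in Da):

| reagent | stubs | doublet pair (Δm) | hydrolyzed | amidated |
|---|---|---|---|---|
| DSSO | A 54.01056, S 103.99320, T 85.98264 | A/T (31.97208) | 176.01433 | 175.03031 |
| DSBU | A 85.05276, B 111.032028 | A/B (25.979268) | 214.095357 | 213.11134 |
| BS3 | — (non-cleavable) | — | 156.07864 | 155.09463 |

Internal consistency of these independently printed values is enforced by
tests: hydrolyzed = linker + H₂O and amidated = linker + NH₃ within 1e-4 Da
for both cleavable reagents; S − T = H₂O (the sulfenic-acid stub dehydrates
to the thiol); the BS3 linker mass is derived from its hydrolyzed mass.

Monoisotopic constants: proton 1.00727646677, H₂O 18.0105646863,
NH₃ 17.0265491015, isotope spacing 1.0033548378.

## Theoretical fragments

For a crosslinked pair, each peptide contributes b₁..b_{L−1} and
y₁..y_{L−1}. A fragment that does not span the link site gets its plain
mass. A fragment spanning the link site is emitted once per stub label
(cleavable reagents) and once as +P — plain mass + linker mass + the intact
partner peptide including its modifications. Intact-peptide P ions are
emitted once per stub label; the doublet-pair P ions are the signature
doublet species. An N-terminal link (site 0) behaves like a link on residue
1 for span computations.

Charges default to 1..min(3, precursor charge − 1). Neutral losses
(−H₂O, −NH₃ generally; −CH₃SOH only on S/T-stub fragments) are optional and
off by default in the pipeline — the generator does not emit them, and
enabling them only enlarges the ambiguous-match space. a/c/z ions are not
generated.

Stub-blind ("noncleavable") annotation mode generates the same set minus all
stub-state fragments and stub P ions, i.e. only plain and +P fragments —
the information a search engine has when it treats the reagent as
non-cleavable.

## Annotation

Deisotoping is greedy: seeds are visited by decreasing intensity; for each
seed the charge (1..4) giving the longest chain of peaks at
seed + k·1.0033548378/z with non-increasing intensity wins, and the seed is
reported as the monoisotopic peak with the summed cluster intensity.
Two deliberate choices: (1) each chain step takes the candidate **nearest
the exact isotope position** (tie: higher intensity) — spacing is the most
precise envelope signal and this prevents a co-isolated isobaric
monoisotopic peak from being swallowed as an isotope; (2) the
isotope-position window defaults to min(match tolerance, 5 ppm), tighter
than the fragment-match tolerance, because systematic calibration error
cancels in within-scan peak differences. Intensity is conserved exactly;
ranks (1 = most intense, ties broken toward lower m/z) are assigned on
deisotoped peaks, and all doublet rank statistics use these deisotoped
ranks.

Matching assigns each theoretical fragment to the nearest compatible peak
within the ppm tolerance (default 15 ppm); a peak is compatible if its
charge equals the fragment charge or is undetermined (0). One peak may
satisfy several isobaric fragments (flagged ambiguous). Recalibration is a
global multiplicative ppm correction applied before annotation.

## Doublets and coverage

A doublet is called for a peptide when **both** doublet-pair stub variants
of its intact-peptide P ion are matched at the same charge; its rank is the
rank of the more intense peak. Doublets are defined on P ions only, not on
backbone stub pairs, and require equal charge for both partners — a mass
difference signature is only meaningful at one charge. A CSM's doublet
class (0/1/2) is the number of peptides with at least one call.

Sequence coverage is conservative: the denominator is 2(L−1) — one
N-terminal and one C-terminal fragment between every adjacent residue
pair — and a slot counts once no matter how many stub/charge/loss variants
matched. Category fractions (linear, link-site, stub-only, +P) share the
denominator and restrict the numerator by fragment category, so
stub-only and +P are sub-fractions of link-site coverage.

## MS3 evaluation

The MS3 precursor m/z (carried in the MGF TITLE as `selected_mz`, with
`parent=` linking to the MS2 scan — standard MGF has no MS3 linkage field,
so this TITLE-token dialect is our convention) is compared against the
**matched** intact-peptide stub fragments of the parent CSM at 20 ppm; a
hit is a correct trigger for that peptide. Backbone stub fragments do not
count as correct triggers. Misses are attributed to linear or
crosslinker-modified (−OH/−NH₂) linear peptide masses at the same
tolerance, else unmatched. Correctly-triggered MS3 scans are annotated
against the released stub-bearing linear peptide (stub mass as a fixed
modification at the link site) and their matched cleavage slots are
unioned into the parent peptide's coverage; the combined coverage can
therefore never be below the MS2-only coverage.

## Scoring and FDR

The CSM score is deliberately simple and declared (search-engine scoring
functions are out of scope): explained fraction of total deisotoped
intensity plus the mean total coverage of the two peptides, range [0, 2].
The delta score is the gap to the second-best candidate pair for the same
spectrum. Pre-FDR filters: ≥3 matched fragments for both peptides, delta
score strictly greater than 15% of the score, both peptides ≥6 residues,
no peptide shared by two or more proteins, no noncovalent
(gas-phase-association) flag.

FDR is estimated on unique CSMs — key (peptide sequences + modifications,
link sites, precursor charge), best score kept — with
FDR(t) = max(0, TD − DD)/TT over records scoring ≥ t, the standard
estimator for crosslink searches against an equal-size decoy database
(random matches are TT:TD:DD ≈ 1:2:1, so TD − DD estimates false TT).
Groups (self when the peptides share a protein accession, with decoys
inheriting their target's accession; heteromeric otherwise) are thresholded
independently: the estimate is monotonized by a running minimum from the
high-score end and the threshold is the lowest score whose monotonized
estimate is at or below the requested level. Exactly two groups are used.
Score normalization divides each score by its group's threshold at a given
level (default 10%), mapping the cutoff to 1.0.

## Synthetic data

The generator states a world; its defaults are not tuned to test outcomes.

- Protein database: 20 random 300-residue proteins with Lys/Arg frequencies
  (8%/5%) chosen so tryptic peptides fall mostly in the 6–30 residue band;
  decoys are reversed sequences with a `REV_` accession prefix.
- Per CSM: two target peptides from distinct proteins, random reactive link
  sites, precursor charge 3–4.
- Doublets: each peptide emits both doublet-pair P ions with probability
  0.9 (per peptide), at intensity boosted by the acquisition-dependent stub
  scale.
- Backbone: each b/y slot emits independently with the
  acquisition-dependent probability; link-site slots emit a random stub
  variant (cleavable) or +P (non-cleavable), plus an extra +P variant with
  probability 0.2.
- Acquisition presets: sHCD — backbone probability 0.7, stub intensity
  scale 3 (mixed collision energies fragment the backbone well; stubs
  moderately dominant); CID — backbone probability 0.35, stub scale 10
  (low-energy CID cleaves the crosslinker preferentially). These contrasts
  are qualitative statements of the known acquisition behavior, not fits.
- Peaks: 3-isotope envelopes with fixed ratios (1, 0.45, 0.15); intensities
  log-normal (μ=2, σ=0.6); 30 uniform-m/z noise peaks per spectrum with
  log-normal intensities (μ=0.5, σ=0.8).
- MS3: the instrument model scans the **deisotoped** MS2 peak list for peak
  pairs separated by the doublet Δm at charge 1–2 (10 ppm), selects up to 4
  doublets by intensity, and fragments the more intense peak of each;
  correct triggers yield backbone fragments of the stub-bearing linear
  peptide (per-slot probability 0.9), false triggers yield noise-only MS3
  scans. Scanning raw peaks instead would re-trigger on isotope satellites,
  which real instruments suppress.
- Candidates: each scan carries its true pair plus 3 random pairs drawn
  from the combined target+decoy peptide pool, standing in for a search
  engine's candidate list; precursor-mass filtering of candidates is not
  emulated. Noncovalent spectra (two co-isolated linear peptides) carry a
  pre-flagged candidate, emulating the zero-mass-crosslinker flag of the
  search step.
- A score-level generator (`simulate_fdr_records`) supplies CSM records
  with known true/false composition and overlapping score distributions
  (true N(1.2, 0.25), false N(0.4, 0.2), false classes 1:2:1) for testing
  FDR calibration where a threshold must fall inside the data.

What a green test does and does not establish: the generator emits peaks at
exact theoretical m/z with idealized 3-peak envelopes, no peak-shape,
retention-time, charge-state or co-elution structure, and no
collision-energy physics. Closed-loop recovery therefore validates the
bookkeeping of the pipeline (fragment arithmetic, matching, doublet logic,
coverage sets, FDR thresholds), not instrument realism. Published
per-dataset percentages depend on real raw data and a full search engine
and are out of scope; the simulations reproduce the qualitative structure
(doublet prevalence near p², CID stub dominance, stub-blind yield ≤
stub-aware yield).

## Numerical choices and degenerate inputs

- Nearest-peak matching ties break toward smaller |ppm error|, then higher
  peak intensity.
- Rank ties break toward lower m/z.
- FDR groups without targets are flagged degenerate rather than thresholded;
  score normalization refuses a zero/absent threshold.
- Coverage is undefined (error) for peptides shorter than 2 residues; MS3
  classification refuses MS2 scans and dangling parent links.
- Mass-identity tests use 1e-4 Da tolerances, matching the precision of the
  printed modification masses.

## Known limitations

- The deisotoper is a greedy stand-in validated against the generator's
  ground truth, not against an averagine-fitting reference.
- Whether a doublet search should also accept the S stub as a doublet
  partner is configurable via the crosslinker's `doublet_pair`; the default
  uses A/T for DSSO.
- The candidate-generation step is not a search engine: random candidates
  are not precursor-mass matched, so absolute decoy rates in
  spectrum-level simulations are lower than in real searches (the
  score-level generator covers FDR calibration instead).
- MS3 triggers matching a backbone stub fragment (not a P ion) are counted
  as not correct; the alternative convention would require only a config
  change in `classify_ms3_trigger`.
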