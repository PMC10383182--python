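# Methods

## Scope and data model

The pipeline quantifies phosphopeptides from a 4-plex iTRAQ experiment with
three subject groups (NC, DM, DN) and one reference channel. Its unit of
inference is the **unique phosphopeptide**, the pair *(peptide sequence,
number of phosphates)*: the same sequence phosphorylated on different
residues is one peptide (site placement is a separate, downstream question),
while the same sequence with a different phosphate count is a different
analyte. PSM tables, spectra (MGF), the protein database (FASTA), and the
reporter purity matrix (CSV) are inputs; search-engine scoring itself is out
of scope — scores arrive in the PSM table.

## Identification filtering

Mass bookkeeping uses monoisotopic residue masses (pyteomics' standard
table), water 18.010565 Da, proton 1.007276 Da, and accurate modification
deltas: carbamidomethyl +57.02146, deamidation +0.98402, oxidation
+15.99491, phospho +79.96633, 4-plex iTRAQ +144.10207 Da. Methods sections
often quote the nominal integers (57, 1, 16, 80, 145); those are accepted
through a config override, and at the 0.6 Da precursor tolerance the
validation outcome is the same either way. A PSM passes validation when
`|(precursor_mz − proton)·z − computed mass| ≤ 0.6 Da` and `z ∈ [2, 4]` (the
acquisition charge window).

The FDR filter considers rank-1 PSMs only and uses the simple target-decoy
ratio `#decoys(≥c)/#targets(≥c)`. Candidate cutoffs are the observed scores;
the chosen cutoff is the lowest one whose estimate stays at or below the
bound, which maximizes the retained set. At tied scores, decoys at the
cutoff count against it (conservative). Decoys are never retained. If no
cutoff qualifies, the retained set is empty with cutoff +∞ — a defined
outcome, not an error. The implementation is a vectorized cumulative scan;
the test suite checks it against an exhaustive brute-force scan over every
candidate cutoff, which serves as the independent oracle.

Collapsing excludes non-phospho PSMs (counted and logged). The identity key
deliberately ignores variable non-phospho modifications (oxidation,
deamidation): the unit of inference keys on sequence and phosphorylation
state only.

## Site localization

The MD score of a peptide is the score difference between its best and
second-best candidate with the same sequence and phosphate count but a
different site arrangement. Calls: `confident` at MD ≥ 10 (the cutoff is
configurable), `ambiguous` below, `single_candidate` — treated as localized
— when no competing arrangement exists, including peptides whose sequence
admits only one placement. Competitor hits are matched per spectrum; the
peptide-level call uses the best-scoring member spectrum. Ambiguous peptides
keep their rank-1 positions for reporting, are excluded from site-level
tallies, and still contribute to quantification (which does not depend on
the site). Probabilistic localization (Ascore-style posteriors) is a
non-goal. Note that MD-score cutoffs and fold-change thresholds are distinct
quantities even when numerically similar in a methods description; here 10
is the localization cutoff and 1.5 the fold threshold.

## Reporter quantification

Reporter masses default to the 4-plex monoisotopic values 114.1112,
115.1083, 116.1116, 117.1150 m/z (configurable). Extraction takes the most
intense peak within ±0.1 Da of each reporter mass (the fragment tolerance),
zero when absent. The purity matrix P has entry (i, j) = fraction of channel
j's reagent observed in channel i; columns may sum below 1 (bleed outside
the detected window). Correction solves `P·x = raw` exactly and clamps
negative components to zero (logged); on noise-free mixed data the round
trip recovers truth to machine precision.

Normalization factors are `f_c = mean(T)/T_c` from the channel totals `T`
of a designated reference run (emulating an unbound-fraction analysis whose
channel totals reflect only the loaded protein amounts); with no reference
configured, the factors fall back to the phosphopeptide data's own channel
totals — documented, weaker, since real group differences then leak into
the factors. Order of operations: impurity-correct each scan, normalize each
scan, then sum over a peptide's scans, then take group ratios on the sums.
Summing before the ratio weights scans by signal; the per-scan noise of weak
scans does not propagate into the ratio the way averaging per-scan ratios
would. Whether normalization precedes summation is an open choice; per-scan
normalization was chosen because the factors are per-channel constants, so
the two orders give identical sums, and per-scan tables remain directly
comparable.

## Error model and differential calls

Per comparison (default DN/DM, DN/NC, DM/NC), the null for log2 ratios is a
single robust normal fitted on all quantified peptides: location = median,
spread = 1.4826 × median absolute deviation, so the (assumed sparse)
regulated fraction does not inflate the null. The spread is floored at 1e-6
with a warning for degenerate inputs (e.g. noise-free simulations). Each
peptide's p-value is the two-sided normal tail of its standardized log2
ratio. Calls require both fold ≥ 1.5 (or ≤ 1/1.5, symmetric on the linear
scale) and p < 0.05; no multiple-testing correction by default, mirroring
common practice for this design, with Benjamini–Hochberg behind a config
flag. An optional per-peptide one-sample t-test over ≥ 3 member scans is
available for designs with enough replicate scans.

A global null assumes a common ratio variance across peptides. When scan
counts differ per peptide (1–3 in the simulator), ratio variances are
heterogeneous and the global null is an approximation: peptides quantified
from a single scan are slightly anti-conservative, multi-scan peptides
slightly conservative. Calibration of the fit itself (type-I error 0.05 ±
0.01 on 5,000 null ratios) is checked on draws from the model family.

## The synthetic experiment

The generator emulates the target study's design, not its raw data:

- **Proteins**: 400 uniform-random 360-residue sequences (a FASTA can be
  supplied instead); tryptic digestion cleaves after K/R except before P
  (the in-silico rule; up to 2 missed cleavages supported, the generator
  uses fully cleaved peptides), lengths 6–40.
- **Phosphopeptides**: 2,000 by default, 15% doubly phosphorylated where a
  second acceptor exists; base abundance log-normal (median 1e5, log-sd 0.5).
- **Regulation**: 50 peptides at 2-fold in the DN channel, half up, half
  down. These defaults define the benchmark condition for recovery tests.
- **Reporter signal**: truth × per-channel loading bias (default 1.0, 1.08,
  0.95, 1.02 — the "minor variations in source protein concentration" that
  normalization exists to remove) × purity mixing (2% neighbour bleed) ×
  multiplicative log-normal noise with CV 0.1, split over 1–3 scans per
  peptide. The reference run's totals carry the same bias, so normalization
  can cancel it exactly.
- **Scores**: targets ~ Normal(40, 8), decoys ~ Normal(20, 6), clipped at
  zero — overlapping enough to give a realistic, non-trivial 1% FDR cutoff
  (≈7% of true PSMs are sacrificed).
- **Decoys**: reversed unused peptides, count set to make decoys ≈10% of
  rank-1 PSMs exactly (deterministic rounding).
- **Isomer competitors**: half of eligible peptides get a rank-2 hit with an
  alternative site arrangement whose score trails rank 1 by a gap drawn once
  per peptide from Uniform(1, 30), giving controlled MD scores on both sides
  of the cutoff.

All randomness flows from one mandatory seed through named substreams;
repeated runs are byte-identical. What the simulator does **not** model:
fragment-ion ladders and peak shapes, chromatographic behaviour, co-isolation
interference, missing reporter channels, peptide-level abundance vs
detectability correlation, and real proteome sequence composition. Passing
recovery tests therefore demonstrate the correctness of the pipeline's
bookkeeping and statistics under the stated noise model, not performance on
real spectra.

## Numerical and design choices

- Decoy accessions use the `REV_` prefix (configurable).
- MGF dialect: PEPMASS carries m/z (optional intensity), CHARGE written
  `2+`; unknown headers round-trip via metadata. A structural pre-scan
  reports unterminated blocks and non-numeric peak lines with line numbers,
  since the underlying parser is lenient.
- Modification strings are `pos:residue:name`, semicolon-separated, with
  position 0 = peptide N-terminus.
- Summary percentages round at the conventional printed precision: one
  decimal for pS/pT, two for pY and for the all-groups overlap percentage
  (both configurable).
- Problem sizes in the test and acceptance suites (2,000-peptide benchmark,
  1,000 FDR instances with five at 10,000 PSMs, 5,000 null ratios) were
  chosen as the smallest sizes at which the measured rates are stable to
  well within their acceptance bands.

## Known limitations

- Protein inference is a provided peptide→accession map (first accession
  wins); no parsimony inference.
- Only the 4-plex channel set is wired up, though the structures permit
  more channels.
- The global error model ignores per-peptide scan-count heterogeneity (see
  above); the per-peptide t-test option trades that for low power at 1–3
  scans.
- Site-level tallies count unique (protein, peptide, position) triples;
  without protein coordinates, the same protein site seen in two
  overlapping peptides counts twice.
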