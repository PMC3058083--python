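# Methods

## Problem setting

Peptide mass fingerprinting identifies a gel spot's protein by comparing
the observed masses of its tryptic peptides against an in-silico digest
of a protein database. When no reliable proteome exists, the database
can be built straight from raw whole-genome shotgun reads: each trace is
translated in all six frames and every sufficiently long stop-free run
becomes a candidate protein. The price is an enormous, highly redundant
search space in which random mass coincidences are common, so the score
threshold must be calibrated empirically — here with a reversed-sequence
decoy database.

## ORF and URF construction

An ORF is a **maximal stop-free run** in one of the six frame
translations of a trace, including runs that touch the trace ends; no
initiator methionine is required because reads truncate genes
arbitrarily. The default length cut is 50 amino acids (inclusive),
configurable via `min_len`. Translation uses the standard genetic code
(table 1); ambiguous IUPAC codons translate to the unique residue they
imply when one exists, otherwise to `X`. `X` is not a stop and does not
break an ORF, but peptides containing `X` have no defined mass and are
dropped at digestion time.

Coordinates are 0-based half-open **on the forward strand for both
strands**, with the frame's sign carrying the strand; this single
convention makes it trivial to slice the original nucleotide sequence
back out of a trace (e.g. for probe design) regardless of strand.

URFs deduplicate ORFs by amino-acid sequence. The identifier is the
SHA-1 hex digest of the uppercase sequence — a deterministic function of
the sequence alone, so identical ORFs found on different traces collapse
to one entry whose provenance list records every (trace, frame, start,
end). Digest collisions are checked by direct sequence comparison within
each digest bucket and are fatal (none is expected at any realistic
scale). The algorithm name is recorded in the run metadata.

Databases may be partitioned into chunks of at most `max_entries`
entries, preserving order. Because each entry is scored independently,
searching partitions and merging rankings is exactly equivalent to
searching the concatenated database; a property test asserts this.

## Decoy model

The decoy database reverses every URF: same length, same residue
multiset (hence identical total mass, asserted bit-exactly with `fsum`),
but displaced trypsin cleavage targets, so decoy digests provide an
honest null for random mass matching. Decoy ids are the forward id with
a `DECOY_` prefix, keeping the forward/decoy pairing recoverable. No
shuffling or Markov decoys are offered; plain reversal is the procedure
being modelled. Note that reversal does not *always* change the
cleavage-site multiset — symmetric K/R layouts (e.g. `AKCGKA`) survive
reversal without being palindromes — so displacement is a statistical
property, not a universal one; the test suite checks it as such.

## Digestion and masses

Trypsin cleavage follows the plain Keil rule (after K or R, suppressed
before P). Peptides are enumerated for 0..`max_missed` missed cleavages
(default 1). Masses are monoisotopic by default (average-mass mode via
`monoisotopic=False`), with residue masses taken from the pyteomics
tables; MH⁺ = Σ residues + H₂O + proton. Fixed modifications are
additive per residue; none is applied by default, with
carbamidomethyl-C available as a preset. The search layer drops peptides
shorter than 4 residues (`min_pep_len`): below that length,
within-tolerance mass collisions carry essentially no information.

## Scoring

Matching is greedy one-to-one nearest-mass within a tolerance (default
0.2 Da absolute; ppm mode available): candidate (peak, peptide) pairs
are sorted by absolute error, ties broken by lower peptide start offset,
and each peak and peptide is used at most once — preventing score
inflation from mass-degenerate peptides.

The hit score is a binomial tail. For an entry with `m` theoretical
peptides inside the query mass range `[min peak − tol, max peak + tol]`,
the chance that one random peak lands within the full window `w = 2·tol`
of some entry peptide is approximated as `p = min(1, m·w/R)` where `R`
is the span of the observed peaks. With `k` of `n` peaks matched, the
p-value is `P(X ≥ k)` for `X ~ Binomial(n, p)` and the reported score is
`−10·log10(P)` — the scale of MOWSE-family PMF scorers. This scorer is
a deliberate, fully specified stand-in for the commercial engine used in
the original workflow; its absolute score values (and hence any
particular published threshold value) are not comparable, but the
thresholding *procedure* downstream is scorer-agnostic. Degenerate
cases: `k = 0` or `p ≥ 1` give `P = 1`, score 0; p-values are floored at
1e−300 to keep the log finite. Forward and decoy entries go through the
identical code path; on pure-noise input the two score populations are
statistically indistinguishable (tested).

Per spot, every entry of every partition is scored (entries with no
candidate peak provably score 0 and are materialized lazily), rankings
are merged, and the top 50 per database label are retained — 100 hits
per spot across forward + decoy. Ordering is deterministic: score
descending, matched count descending, entry id ascending.

Peptide assignments collapse hit-level results: one record per distinct
(peptide, database label), keeping the best score over every hit that
matched the peptide and listing all carrier entries. The per-peptide
score is defined as the score of the best hit containing it.

## Threshold selection and URF flagging

Given the decoy unique-peptide scores, the false-negative rate `fn_rate`
(default 0.05) fixes `k = ⌊fn_rate·n⌋`; the threshold is the k-th
highest decoy score, and "passing" means score ≥ threshold, so with
distinct scores exactly `k` decoy peptides pass. Ties at the threshold
all pass with a logged warning about the excess. `k = 0` (e.g.
`fn_rate = 0`) sets the threshold to +∞ so that nothing passes on either
database — the one coherent reading of "admit nothing" once forward
scores can exceed every decoy score. Thresholding always operates on
**unique** peptide scores, after the max-collapse.

A URF is flagged *reliable* iff at least one passing forward peptide
maps onto it (set semantics; a URF with three passing peptides is
flagged once, with the count reported). Direct peptide-to-URF mapping
only; no URF-to-URF alignment step is performed.

The composition bias of a peptide is
`Σ_a f_a · log2(f_a / (1/20))` bits — the KL divergence of its residue
composition from the uniform background, equal to `log2(20) − H(f)`.
It is 0 for a peptide using all 20 residues equally and `log2 20 ≈ 4.32`
for a homopolymer; high values mean low complexity. The flag threshold
(default 2.5 bits, strict `>`) is an annotation, not an exclusion,
since low-complexity peptides are plotted for inspection rather than
removed.

## Reporting conventions

All derived percentages are `100·num/den` rounded **half-up** to two
decimals (via `decimal`), the convention that reproduces published
proportions exactly from their printed counts. Overlap tables consume
externally computed homology pairs (candidate id, study label) as TSV;
sequence alignment itself is out of scope.

## Synthetic data generator

`make_traces` draws background nucleotides i.i.d. at a configurable GC
fraction (default 0.32 — the AT-rich regime typical of the planarian
genome) with trace lengths ~ Normal(800, 80) nt, and plants each given
protein by back-translating it with uniform synonymous-codon choice,
flanking it with stop codons, and splicing the cassette into a random
strand and position of its trace. The flanking stops guarantee that ORF
extraction recovers the planted protein exactly (the truth JSON records
protein, trace, frame and start for independent verification). Uniform
codon usage is the simplest model preserving that guarantee; no
sequencing-error or quality model is included.

`make_fingerprint` includes each tryptic MH⁺ mass independently with
probability `detect_prob` (default 0.7), perturbs it with Gaussian error
(sd 0.05 Da), and appends `n_noise_peaks` (default 5) masses uniform on
700–3000 Da. Uniform noise matches the scorer's random-match model,
which is what makes the decoy FDR calibration interpretable. One true
peak is always forced in when every Bernoulli draw fails, so a non-noise
spot never degenerates to pure noise (a negligible-probability event at
the defaults, but the truth invariant is absolute).

The default benchmark — 2,000 traces, 20 planted proteins of 60–120
residues, 20 matching spectra plus 20 pure-noise spectra of 15 peaks,
database capped at 2,500 entries per partition so the split/merge path
is exercised — runs the full pipeline in a few seconds on one CPU and
measures (a) the fraction of planted proteins whose source URF is the
rank-1 forward hit for its spectrum, and (b) the false-pass fraction
among forward unique peptides that are not planted-protein peptides,
compared with the decoy-estimated pass fraction by a two-sided binomial
test. These problem sizes were chosen as the smallest at which the
decoy set yields a stable threshold (≈ 2,000 decoy unique peptides, so
the 5% quantile rests on ≈ 100 scores) while the per-spot signal (≈ 6–9
true peaks against ≈ 4,000 background URFs) still separates cleanly.

## What passing the synthetic benchmark does and does not show

The generator emulates the statistical structure the pipeline relies on
— coding ORFs hidden in non-coding background, partial peptide
detection, mass error, uniform chemical noise — but not base-calling
error, codon bias, repeats, polymorphism, correlated contaminant peaks
(keratin, autolysis), or intensity information. Perfect rank-1 recovery
here therefore validates the machinery (translation, digestion,
matching, scoring, merging, calibration), not field performance on real
traces and spectra, where scores are lower and thresholds higher.

## Numerical choices

- Mass tolerance 0.2 Da absolute by default (PMF-era calibration); ppm
  mode available.
- Binomial p-values floored at 1e−300; score 0 reserved for `P = 1`.
- Tie-breaks are total and deterministic everywhere (matching: error
  then start offset; ranking: score, matched, entry id; collapse:
  lexicographic output order), so all outputs are pure functions of
  (inputs, config, seed).
- `floor(fn_rate · n)` uses plain float multiplication; at every integer
  boundary of interest (e.g. 5% of 26,741) the product is exact well
  beyond rounding distance.

## Known limitations

- The binomial scorer ignores peak intensities and the non-uniform mass
  distribution of real tryptic peptides (MOWSE's frequency matrices);
  scores are comparable within a run, not across engines.
- PMF only: no MS/MS fragment evidence, so mass-degenerate peptides are
  distinguishable only through their parent context.
- The decoy estimate calibrates the *peptide*-level pass fraction; the
  URF-level reliability flag inherits no formal FDR.
- Proteins shorter than the ORF length cut (small ORFs) are invisible to
  the database by construction.
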