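# Methods

This note records the models, algorithms and numerical choices behind
`glycofirst`, and what the synthetic benchmarks do and do not demonstrate.

## Glycan model

Monosaccharides are identified by short symbols (H = Hex, N = HexNAc,
F = Fuc/dHex, A = NeuAc, G = NeuGc) with residue masses computed from
elemental compositions under standard monoisotopic atomic masses
(Hex 162.05282, HexNAc 203.07937, Fuc 146.05791, NeuAc 291.09542,
NeuGc 307.09033 Da). Modified units are base unit + adduct elements:
aH = Hex + NH₃ (17.02655) and pH = Hex + HPO₃ (79.96633). A composition is
a count vector over the fixed symbol order (H, N, F, A, G, aH, pH),
compared componentwise; the fixed order makes subcomposition enumeration —
sorted by (total units, counts) — reproducible, which the localization
ScoreTable requires.

Structures are rooted labeled trees (root = reducing end), serialized to a
canonical string by sorting each node's child substrings, so sibling order
never matters. Databases are plain text, one `id<TAB>entry` per line, where
an entry is either a canonical string or a composition like `H(5)N(2)`;
glycan ids must fit in 31 bits because the search index packs id + core
flag into one 32-bit word.

Modified-unit expansion substitutes 1..k base units per glycan. On
structures this is node-subset substitution deduplicated by canonical
string, so chemically distinct positions (branching vs terminal Hex) yield
distinct entries while symmetric positions collapse; on compositions it is
plain count replacement. The default cap for aH is two per glycan,
matching how extensively ammonia adducts are observed on yeast glycans.

**Core Y ions.** The N-glycan core set is the reducing-end ladder
{Y0, N1, N2, N2H1, N2H2, N2H3} (chitobiose + trimannosyl steps); the
O-glycan core set is {Y0}. Y0 is always core. Partial ladder members count
individually toward the core-count gate. These sets are configurable on
`GlycanDB`; the defaults encode the trimannosyl-core convention for
N-glycans and the absence of a conserved O-glycan core.

## Spectrum preprocessing

MGF I/O goes through pyteomics. HCD-pd-ETxxD pairs are linked by a
`pair=<scan>` TITLE token, or by identical precursor m/z (within 1e-4) on
adjacent scan numbers.

Deisotoping is greedy, strongest peak first: for each unclaimed seed peak
and each charge z from 1 to the precursor charge, walk +1.00335/z steps
(within the fragment tolerance) while each next isotope is at most 1.25×
the previous peak's intensity; the longest chain wins, is collapsed to the
monoisotopic neutral mass (m/z − proton)·z with summed intensity, and its
peaks are claimed. Unclustered peaks are taken as singly charged. Peaks
within tolerance of the precursor (any charge state, ±3 isotopes) are
removed first. The procedure is idempotent by construction (a preprocessed
spectrum passes through). The intensity-compatibility factor 1.25 is a
pragmatic bound: it accepts the rising isotope envelopes of heavy
fragments while rejecting unrelated adjacent peaks.

Merging a preprocessed HCD/ETxxD pair collapses peaks within ±20 ppm to
their intensity-weighted mean with summed intensity; every merged peak
keeps a provenance bitmask (HCD/ETxxD/both) so b/y matching can use HCD
evidence and c/z matching ETxxD evidence.

Defaults: fragment tolerance ±20 ppm, precursor tolerance ±10 ppm,
diagnostic-ion prefilter at 204.087 m/z (HexNAc oxonium; 163.060 for
O-Man-style Hex-only searches). The summed relative intensity of the
Hex-diagnostic ions (163.060 + 366.139) is exposed as a report column
(`hex_diag_frac`, threshold of interest 10% of base peak), not a hard
filter.

## Glycan-first search

The Y-complement index stores, for every (glycan, Y composition) pair, the
mass `glycan mass − Y glycan mass`, sorted and bucketed by integer mass for
O(1) range lookup. Scoring a spectrum queries `P − m` per peak and
increments the matched glycans' ion and core counts; the tolerance is
±20 ppm of the observed peak mass, and the brute-force reference matcher
uses the identical rule, so the two are exactly interchangeable. The
complement-0 entry (the full-glycan Y, i.e. the precursor itself) is indexed
but never scores, since precursor peaks are removed during preprocessing.

Candidate selection: core-count gate (≥2 N-mode / ≥1 O-mode), then the
monosaccharide-diagnostic veto (a glycan containing A/G/F needs its oxonium
evidence in the raw spectrum; table configurable), then rank by
ion + core count keeping the top 100 (ties broken toward smaller glycan id,
for determinism), then unconditional re-admission of glycans with ≤3 units,
which have too few Y ions to rank. Candidates heavier than the precursor
are excluded throughout.

Glycan fine score: over matched theoretical Y ions,
Σ w·(1 + log₁₀ rel), with the relative intensity clamped to [0.1, 1]
(keeping each term nonnegative, hence the score monotone in the matched
set), w = 2 for core ions and 1 otherwise, normalized by the theoretical Y
count.

**Glycan decoys.** Every target glycan spawns one decoy whose complement
masses are shifted by a per-glycan offset drawn uniformly from [1, 30] Da
(seeded); decoys ride in the same index and compete in scoring, candidate
selection and peptide search, giving the glycan-level null.

## Peptide search and FDR

Sequon Asn (N-X-S/T/C, X ≠ P) is rewritten to 'J' on the protein *before*
digestion, so sequon context crossing a cleavage site is preserved; J keeps
Asn's mass. Digestion is rule-based (default trypsin: after K/R, not
before P; ≤2 missed cleavages; length 6–40), fixed mods are applied
everywhere (default carbamidomethyl-C), variable mods expand up to 3 per
peptide (default oxidation-M), and entries are mass-sorted for window
queries. Decoy peptides come from whole-protein reversal, re-marked and
re-digested.

For each candidate glycan and each precursor isotope hypothesis
k ∈ {0, ±1, ±2} (substituting for vendor mono-peak correction), peptides
within ±10 ppm of `P − k·1.00335 − glycan mass` are scored. Matched series:
b/y and b/y+HexNAc on HCD peaks; in merged mode additionally c, c+1 and
z•, z•+1 (one-hydrogen rearrangements) on ETxxD peaks, each (series,
position) counting once. The peptide score is Σ(1 + log₁₀ clamped rel
intensity) normalized by 2(L−1). The total score is glycan fine score +
peptide score; the top glycopeptide per (scan, isotope hypothesis) is
retained. This scoring function is this package's own documented choice —
no equivalence with any other engine's tuned scores is claimed.

The chimera filter removes, within one MS2 scan, the lower-scoring of two
GPSMs whose corrected precursor masses differ by 1 or 2 isotope spacings
within ±0.02 Da — a window wide enough to catch the NeuAc(1) vs Fuc(2)
near-isobar (Δ = 1.0204 Da ≈ 1 isotope).

FDR: peptide-level q-values from reversed-protein decoys on the peptide
score (#decoy/#target above threshold, monotonized); glycan-level q-values
from the mass-shifted glycan decoys on the glycan score; combined
glycopeptide FDR = F_g + F_p − F_g·F_p. Glycans with ≤3 units skip glycan
FDR (reported 0): their Y ladders are too short for the decoy competition
to be meaningful, so the combined level falls back to the peptide FDR.

## Site localization

ScoreTable: rows are the F subcompositions of G in the fixed order, columns
0..L; cells are scored for 1 ≤ p ≤ L−1 as (c matched) + (z matched) ∈
{0, 1, 2}, where c_p carries g and z_{L−p} carries G−g, each accepting its
+1 Da rearrangement variant (variants collapse into the same point — the
cell maximum of 2 is what makes 2(L−1) the maximum attainable path score,
as the regularizer requires). Theoretical Y ions (the full subcomposition
ladder on the peptide) and b/y ± HexNAc masses are deleted from the peak
list first so HCD fragments cannot masquerade as c/z evidence.

The DP starts at [g₀, 0] only; other column-0 cells are invalid. A
transition [g_s, p−1] → [g, p] is valid iff g_s ≤ g and (g = g_s or residue
p is a candidate site). Attachments are single events: the increment at a
site may be any nonzero subcomposition. With this initialization the DP
optimum provably equals the maximum over exhaustively enumerated glycoforms
(tested on 500 randomized instances per run), which would not hold if every
[g, 0] were a legal start.

Backtracking marks every cell lying on *some* optimal path (forward +
backward DP sums equal to the optimum). Columns where the optimal cell is
unique are "settled"; a maximal run of unsettled columns between two
settled ones, across which the cumulative glycan increases, becomes one
localized unit — a single site when the run is one column, otherwise a
site-group whose span is trimmed to the candidate sites it contains
(rendered `{S3:T5}`). Site positions are 1-based from the peptide
N-terminus. Increments over all units always sum to G.

**Probabilities.** Per unit, 1000 random valid paths are sampled that do
not contain the unit's determining sub-path (visiting both its start and
end cells); sampling is uniform over valid successors per column, with
dead ends excluded by precomputed feasibility tables, so no rejection loop
is needed. A Poisson with λ = the sample mean (floored at 0.01) gives
pv(s) = P(X ≥ s), clamped to [1e−16, 1];
Prob_Poisson = log pv(Best) / (log pv(Best) + log pv(RandomBest)) with
RandomBest the best sampled score, and
Prob = Prob_Poisson · (Best / 2(L−1))^α, α = 0.05. Degenerate cases: a unit
contained in every valid path gets Prob_Poisson = 1 (so Prob = r); Best = 0
gives Prob_Poisson = 0.5 and Prob = 0 via r; a single-residue peptide is
trivially localized with Prob = 1. Per-unit sampling seeds derive from one
master seed, so results are reproducible. Because Best ≥ RandomBest always,
Prob_Poisson ≥ 0.5; probabilities below threshold are still reported so the
FDR estimator sees the full distribution.

The estimated SSGL-FDR at threshold x is Σ(1−Prob_i | Prob_i ≥ x) / #(≥ x),
returning an explicit "undefined" (None) when nothing passes. Two
orthogonal empirical estimators are provided: entrapment (localize N-mode
GPSMs with candidate sites widened to J/S/T; a GPSM is true iff every
selected unit can only sit on J) and an O-glycoprotease scheme (peptides
starting with S/T are true iff a selected unit covers position 1).

## Synthetic data

The generator emits HCD/ETxxD pairs for ground-truth glycopeptides: Y ions
from the glycan topology, b/y and b/y+HexNAc, c/z carrying the cumulative
site glycans, oxonium/diagnostic ions, isotope clusters (+1/+2 at
envelope-like ratios, charge 2 above 1800 Da) and uniform background peaks;
intensities are log-normal; every series is thinned independently at
1 − coverage; everything is a deterministic function of the seed. Default
coverages are 0.9 for Y/b/y/c/z. Diagnostic oxonium ions are emitted with
probability 1: the simulator emulates confirmed glycopeptide scans, where
they are the dominant peaks, and the diagnostic prefilter's false-negative
rate is deliberately not under test.

What the generator does **not** emulate: correlated chemical noise,
internal/satellite fragments, co-isolation chimeras, charge-reduced ETD
species, mass-error drift, retention time. Passing closed-loop tests
therefore demonstrates algorithmic correctness and calibrated error
estimation under the stated noise model, not instrument-grade performance
on real data.

## Benchmarks (problem sizes are the package's own choices)

* **Index equivalence** — 200 spectra × 50 glycans: indexed scoring equals
  per-glycan brute force exactly, spectrum by spectrum.
* **DP equivalence** — 500 instances (L ≤ 10, |G| ≤ 5, ≤ 4 sites, variable
  c/z coverage and noise): DP score and site/site-group structure equal the
  enumeration oracle; c and z hypothesis counts respect F·(L−1).
* **Calibration** — 500 O-glycopeptide spectra with 2–5 S/T sites, c/z
  coverage uniform on [0, 0.6] and 300 background peaks per scan. The hard
  regime is deliberate: a benchmark whose localizations are essentially
  always correct cannot probe FDR calibration — there the estimate is just
  an upper bound (its conservatism on clean spectra is a known property of
  the Poisson construction, since RandomBest's p-value is ~1/n_samples by
  definition of a sample maximum). Under genuine ambiguity the estimated
  and empirical FDR at thresholds 0.75/0.8 agree to a few percent.
* **Closed loop** — 200 N-glycopeptide spectra at 80% coverage, 30 noise
  peaks: ≥95% of spectra correctly identified (peptide + glycan
  composition) at 1% reported glycopeptide FDR.
* **Entrapment** — high-mannose truth searched against doubled space
  (shuffled proteins + 8 NeuAc compositions): the fraction of
  NeuAc/entrapment identifications at 1% glycan/peptide FDR stays within
  the reported level.

## Known limitations

* Localization uses c/z evidence only; HCD-only spectra are identified but
  not localized, and topology (linkage) is never resolved — site-specific
  results are composition-level.
* The Poisson null treats cell scores as exchangeable along a path;
  correlated matches (e.g. isotope leftovers) violate this mildly, which is
  part of why the estimator is conservative on clean spectra.
* The deisotoper is a greedy heuristic without an averagine intensity
  model; heavily overlapping clusters at equal intensity can deconvolute to
  the wrong charge.
* Protein inference, quantification, mzML/vendor-RAW input and
  released-glycan analysis are out of scope.
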