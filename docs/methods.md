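# Methods

## Model and scope

The package treats a 16S rRNA amplification primer as a degenerate
IUPAC oligonucleotide with an intended footprint in *E. coli*
numbering (1–1542), and a template collection as plus-strand gene
sequences with optional ~50-nt flanks and two-level taxonomy labels
(phylum, class). Three questions are answered computationally: where a
primer sits on each template and how well it matches; whether its
footprint overlaps variable sites that are base-paired in the central
pseudoknot (helix h2: 17–918, 18–917, 19–916) or the lone variable
site 1527; and what base-pair state an amplicon will carry after the
primer's bases overwrite the template's at footprint positions.

The 19–916 functionality classification is an *experimental* rule
table, not a thermodynamic model: A–U and C–G (native) and A–G
(non-native) are functional, C–U is defective, and every combination
that was never assayed — including G·U wobbles — is `unknown` by
design. Temperature-dependent severity of the C–U defect is outside
computational scope. The h2 companion pairs 17–918 and 18–917 are
reported with Watson-Crick/wobble/mispair geometry but never
functionality-classified.

## Coordinate anchoring

Multiple alignment is unnecessary for the quantities computed here;
each template is aligned pairwise to a single 1,542-nt reference with
Biopython's `PairwiseAligner` in semi-global mode (end gaps free on
both sequences, so flanks and truncations are unpenalized). Scoring is
match +2 / mismatch −3 / gap open −5 / gap extend −2 over an
IUPAC-aware substitution matrix (two codes score as a match when their
expansions intersect); all four values are configurable
(`AlignParams`). A map is flagged unanchorable — queries then return
absent states, never exceptions — when the template is shorter than
200 nt, the aligned reference span is below 200 columns (this rejects
the spurious short high-identity overlaps any free-end-gap aligner
finds in unrelated sequence), or identity over aligned columns
(matches / (matches + mismatches + internal gap columns)) is below
0.60.

Primer placement is deliberately gap-free: primers anneal contiguously
and footprints are fixed-length windows. The placement scan minimizes
IUPAC mismatch count over the terminal window (default 100 nt; 5' end
for forward primers, 3' for reverse, matched as the reverse complement
against the plus strand). Ties break first toward the primer's
intended footprint, then toward the terminus, making output
deterministic. Mismatch positions are reported in *E. coli*
coordinates; a position the map cannot carry over (gapped/unspanned)
is reported as absent rather than invented.

## Composition, coverage and variable sites

A composition profile counts A/C/G/T/gap per *E. coli* position over
all anchorable templates; a template gapped at or not spanning a
position contributes gap, and ambiguous template codes are tallied
under gap ("unresolved") so per-position counts always sum to the
anchorable depth. Coverage of a primer is the fraction of anchorable
templates whose best placement has at most `max_mismatch`
IUPAC-incompatible positions (default 0, the strictest reading);
unanchorable templates are excluded from the denominator but reported,
with a strict mode that counts them as uncovered. An N in the template
counts as a match under intersection semantics. Variable-site calls
use a minor-allele frequency threshold over called bases, default
0.05 — the documented polymorphisms at 19 and 1527 are major
(tens of percent), so the default is conservative and configurable.

## Artifact prediction

The predicted amplicon is the template span between the two footprints
with each footprint position overwritten by the primer-imposed base.
A degenerate primer position compatible with the template imposes
nothing (the template base is copied); an incompatible degenerate
position imposes the lexicographically smallest member of its
expansion and is flagged ambiguous, keeping output deterministic. Pair
states are re-read from the mutated sequence through the same
coordinate map (valid because substitutions are gap-free); the risk
flag compares the focus-pair class before and after: unchanged →
`none`, changed to the non-native functional pair →
`artifact_functional`, to the defective pair → `artifact_defective`,
to an untested combination → `unknown_pair`. Prediction is idempotent:
re-amplifying a predicted amplicon yields no further substitutions.

## Synthetic data

The generator emulates the features of real 16S collections that the
analysis depends on: a hypervariable 5' heptamer (per-position
substitution probability 0.5), a conserved 8–27 block, class-linked
19/916 covariation (gamma-like 19A–916U, beta-like 19C–916G, an
"other" class at 50% 19A; `pair_consistency` dials in shuffled
partners), an even C/U split at 1527, 2% background substitutions
outside conserved blocks, optional deletions in designated
variable-helix windows, 50-nt random flanks, and occasional severe
truncation (a retained 80–150-nt fragment, deliberately below the
anchoring floor so the anchorable fraction estimates 1 − truncation
rate). One seeded NumPy generator drives a corpus; identical config
and seed give byte-identical output, and every planted state is
returned in a ground-truth table.

What it does **not** emulate: phylogenetic correlation between
sequences (templates are i.i.d. perturbations of one reference),
realistic substitution models, chimeras, or sequencing error. Passing
tests therefore demonstrate correctness of the pipeline's accounting
and classification on data with the assumed structure, not robustness
to real-database heterogeneity — on real collections the anchoring
identity floor and the coverage denominators do more work.

The packaged reference is a constructed E. coli-like sequence: the
published primer sites and landmark bases (19A, 916U, 1527C, the h2
partner strand 916–918 = UGA) are placed at their design coordinates
and the remainder is fixed-seed random fill. It is drop-in replaceable
by a real 16S reference FASTA.

Clone-set generation plants requested 19/916 pattern counts and origin
labels directly into reference-derived sequences, with background
substitutions (rate 0.005) kept away from footprints and pseudoknot
sites so that sequence-level round trips recover the planted vectors
exactly.

## Tabulation

Clone summaries count origins and 19–916 patterns per library;
percentages are always recomputed from counts with half-up integer
rounding, which reproduces the conventional printed values (52/61 →
85%, 39/45 → 87%, 29/44 → 66%, 32/38 → 84%, 25/45 → 56%, 35/48 →
73%). When a record carries both a sequence and explicit states, the
sequence-derived states win and discrepancies are logged. A label is
counted proteobacterial if it names Proteobacteria or one of its
classes.

## Problem sizes and numerical choices

All analyses are desk-scale. The default synthetic corpus is 100
templates (50 gamma-like / 30 beta-like / 20 other), chosen to match
the scale of the clone libraries being emulated while keeping any
example under a minute; parameter-recovery tests use 150–400 templates
and 99% binomial envelopes. Alignment of one template costs ~40 ms, so
the full test suite (including property tests) runs in well under five
minutes on one CPU. Degenerate inputs are contracts, not crashes:
empty collections and undefined rates raise `ValidationError`, while
absent positions and unanchorable templates flow through as reported
absent states.

## Known limitations

* Mismatch counting is position-uniform; 3'-proximal mismatches are
  not weighted more heavily, although positions are reported so a
  caller can weight them. No melting-temperature or ΔG model.
* The identity floor and span floor are heuristics tuned for 16S-scale
  inputs; very short amplicons (<200 nt) require loosening
  `AlignParams`.
* Reverse primers templating position 916 are handled generically but
  no shipped primer covers that site, so the path is exercised only
  synthetically.
* The pair rule table is binary (functional/defective) and silent on
  growth-rate gradations between functional pairs.
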