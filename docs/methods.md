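# Methods

## Problem and model

Dicer cleaves both arms of a pre-miRNA stem-loop, leaving a 2-nt 3'
overhang on the resulting miRNA:miRNA\* duplex. `dicerscan` casts cut-site
recognition as binary classification of fixed-width windows of the stem:
the *cleavage* class has the scissile bond at the window centre (between
tokens w/2 and w/2+1), the *non-cleavage* class is drawn from the interior
of the mature miRNA, where cutting essentially never happens. An RBF-kernel
support vector machine separates the two classes in the encoded feature
space; at scan time, every overlapping stem window is scored and candidate
bonds are ranked by decision value.

The model assumes: (i) the hairpin is a single stem-loop (structures with
more than one hairpin loop are rejected, or skipped with a warning during
scanning); (ii) the supplied dot-bracket structure is trusted as-is —
pairing state comes from the folding tool, so G:U wobble pairs are treated
as paired and no complement table is consulted; (iii) the discriminative
context is local to ±7 nt around the bond.

## Coordinates and the duplex alignment

Positions are 1-based; a cut is the bond *after* `cut_after`. The stem is
represented as an antiparallel two-row alignment anchored on one arm. In
the default **arm-anchored** mode there is exactly one column per
anchoring-arm stem nucleotide (outermost to innermost paired position,
bulged arm nucleotides included with a gap partner), which fixes the window
geometry: a 14-column window always contributes 14 arm tokens, hence the
56/112/140-dimensional encodings. The **full-alignment** mode additionally
inserts gap-on-anchor columns for opposite-arm bulges, reproducing the
information content of aligned structure renderings; window extraction is
column-indexed so both modes share one code path. Two text dialects render
a missing base as `-` or `0`; internally both are a single GAP token.

## Arm mapping

For a 5p cut after *i*, the 5' nucleotide of the 3p product is
`partner(i−2)` (the 2-nt overhang consumed from the 5p product's 3' end),
so the 3p cut falls after `partner(i−2) − 1`; the inverse direction uses
`partner(j+1) + 2`. The round trip is the identity whenever the probed
positions are paired. The behaviour when the probed position is bulged is
genuinely underdetermined, so both policies are exposed: strict mode raises
`UnpairedOverhangError`, lenient mode substitutes the nearest paired
neighbour and warns.

## Encodings

Composition features are relative frequencies by default (windows with
gaps have fewer valid k-mers, and frequencies keep them comparable); raw
counts sit behind a flag since the choice is not canonical. Any k-mer
containing a gap is excluded from numerator and denominator; an all-gap
window yields a zero vector with a `degenerate` flag rather than NaNs.
K-mer order is fixed lexicographic over (A, C, G, U). One-hot encodings
use A=[1,0,0,0] … U=[0,0,0,1] with gap as the zero block; the extended
5-state encoding gives the loop/bulge its own class `[0,0,0,0,1]`, so
exactly one bit fires per token. No further feature scaling is applied —
binary features are already 0/1 and compositions lie in [0,1].

## Training and selection

The SVM^light-style cost factor j is realised as the class-weight
multiplier on the positive class. The declared grid is g ∈ {0.001, 0.01,
0.1} × C ∈ 1..10 × j ∈ 1..10 (300 configurations); callers may restrict it
to any subset. Cross-validation is family-grouped: families are shuffled
(seeded), stably sorted largest-first and packed greedily onto the
currently smallest fold, so no family ever spans folds and fold sizes are
as balanced as family sizes allow. Selection is by mean per-fold CV
accuracy, tie-broken by higher mean MCC, then smaller C, then smaller j,
then smaller g (the last tie-break added purely for determinism). The CV
table additionally reports pooled-over-folds Sn/Sp/Ac/MCC and the AUC of
the pooled held-out decision scores. The winner is refit on all data; the
decision threshold defaults to 0 and can be raised for higher specificity.
Metrics with zero denominators are reported as undefined, never silently
zeroed. Model archives store the config, fitted estimator, scheme tag, CV
table and a SHA-256 digest of the training matrix.

## Scanning, PSE and SNP effects

Scanning emits only full (unpadded) windows, one per stem column, and
ranks bonds by score with ties broken by ascending position (a convention;
ranking needs to be deterministic). PSE is predicted − actual (negative =
upstream), summarised per rank as the mean of absolute values. The
SNP-effect rule — `loss_of_site` if the annotated cut leaves the variant
top-k, `remain_same` if the top prediction is unchanged and the annotated
cut keeps its rank, `altered` otherwise — is the simplest rule consistent
with the reference ranked-list behaviours it is tested against, and is
deliberately a pluggable convention, not a claim about mechanism. Variant
hairpins keep the reference structure unless the caller supplies a variant
structure (refolding is out of scope; an optional shell-out to an installed
RNAfold-compatible folder exists for convenience).

## Synthetic benchmark

The generator emulates the statistical core of the problem: discriminable
sequence and structure context at true cuts, homology structure that makes
grouped CV necessary, and a proper null. Defaults (the study conditions of
the recovery experiment): 500 hairpins in 50 families, stems of 22–32 bp,
loops of 4–8 nt, background bulge probability 0.05 (half arm bulges, half
opposite-arm insertions), 10% wobble pairs, signal strength 1.

The planted signal has two components scaled by `signal_strength` s ∈
[0, 1]: a base-identity tilt (each of the 14 window columns prefers a fixed
base with mixing weight 0.45·s on top of the uniform background) and a
structural component (arm-bulge probability raised towards 0.90·s at fixed
offsets −5, +2, +5 from the cut). The base tilt is visible to sequence-only
encodings; the bulge pattern only to structure-aware ones — so structure
encodings demonstrably outperform sequence encodings at full signal, the
qualitative behaviour the classifier design banks on. At s = 0 both
components equal the background exactly, making positive and negative
windows identically distributed up to negligible stem-boundary effects.
Families are mutated copies (1–3 positions re-drawn from the same
position-specific distribution) of an ancestral hairpin, so homologs stay
similar without eroding the signal. The cut is placed so that the positive
window and its offset-7 negative both fit unpadded in the stem, which is
why stems must span ≥ 21 bp. The generator makes no attempt at
thermodynamic realism or real miRBase base statistics; passing tests show
the pipeline recovers a planted signal of this kind, not that real Dicer
sites are equally separable.

## Evaluation sizes and numerical choices

The planted-signal recovery experiment runs at 500 hairpins (1 000
patterns) with the grid restricted to g ∈ {0.001, 0.01, 0.1} × C ∈ {1, 10}
× j = 1 — the declared-set corners that matter for this well-separated
benchmark. The null check uses a *single* fixed configuration (g = 0.01,
C = 1, j = 1): selecting the best of several grid points by CV accuracy
would bias the winner's held-out AUC above 0.5 (winner's curse), so the
null must be estimated without selection. Because family clustering leaves
few effective units per dataset, the null AUC is averaged over 10
independently generated datasets of 300 hairpins in 150 families. Negative
windows default to offset 7 from the cut (the 6 omitted nucleotides plus
one); the offset is a parameter since only the omission count, not the
exact centre, is canonical.

## Known limitations

* Trained models transfer only to hairpins folded with comparable structure
  conventions; the package never folds sequences itself on the main path.
* Pseudoknots and multi-loop precursors are out of scope by design.
* The SNP-effect labels describe ranking changes, not processing
  efficiency; they say nothing about expression-level consequences.
* Synthetic benchmarks bound what the tests can certify: performance
  numbers here characterise the pipeline, not biological Dicer accuracy.
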