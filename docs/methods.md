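# Methods

## Model

The classifier is a nearest-neighbour annotation transfer in alignment
space.  Proteins are represented by per-residue embeddings
`e ∈ ℝ^(l×D)` from a protein language model; the package is agnostic to
`D` (production models emit thousands of dimensions, the test suite
uses 16–32).  For a query/bait pair the pairwise Euclidean distance
matrix between residue vectors provides position-specific substitution
scores; because a maximising dynamic program needs similarities, each
distance is normalised against the background of all residue pairs of
the two proteins ("signal enhancement"):

```
S(i,j) = (rowmean_i(D) + colmean_j(D)) / 2 − D(i,j)
```

This is the single distance→similarity transform used throughout; a
plain-negation mode (`−D`, no enhancement) is kept behind a flag for
ablation.  Two useful identities, both asserted in the test suite: a
constant distance matrix maps to the zero matrix, and the global mean
of the enhanced matrix is exactly zero for any input.  The transform
commutes with transposition, so alignment scores are symmetric in the
pair.

The alignment is true global (Needleman–Wunsch) with affine gap
penalties and **penalised terminal gaps**: the downstream length
normalisation is only meaningful if unaligned overhangs cost score.
The reported `s_align` is the full dynamic-programming optimum, gap
penalties included.  Normalised scores are
`EBAmin = s_align / max(l₁,l₂)` and `EBAmax = s_align / min(l₁,l₂)`;
EBAmin is used for classification because a high EBAmax can merely mean
the short protein is contained in the long one.  Note the naming
assumes non-negative optima: for a (rare) negative total score the
min/max ordering inverts, which is why the score-contract tests
restrict to positive scores.

Class transfer is structurally safe only where the fold is conserved,
and fold conservation constrains length.  Each class therefore carries
a reference length range (RLR) — the closed interval `[min, max]` over
its bait lengths — and every call is triaged `within`/`below`/`above`
the RLR of its **predicted** class (in labeled runs the expected label
coincides with the prediction for every agreeing call, so the
region-by-class tables reconcile with expectation-side counts).

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `gap_open` | −1.0 | enhanced-score units | enhanced scores are O(1) per pair; one opened gap should cost about one good match |
| `gap_extend` | −0.1 | enhanced-score units | long gaps tolerated at ~10% of an opening |
| redundancy threshold | 95% | identity | strict `>`: a query at exactly 95.0% is retained |
| identity scoring | BLOSUM62, open −11 / extend −1 | — | the standard protein-database convention; configurable |

Gap penalties are a genuinely open design point — no canonical values
exist for enhanced-embedding score scales — so they are prominent,
configurable arguments; comparisons against other EBA implementations
may require matching their defaults.  DP tie-breaks prefer diagonal >
up > left, making paths deterministic; across baits, ties in EBAmin are
broken by higher path identity, then lexicographically smaller bait id.
Scores accumulate in float64 regardless of embedding storage precision
(stores are float32).

## Synthetic data generator

The generator emulates the geometry that makes embedding-based
classification work, not protein evolution.  Each of `K` classes gets a
centroid in `ℝ^D`; centroids are a randomly rotated orthogonal frame
scaled so every pairwise distance is exactly the separation `Δ`
(default 6.0).  A protein of class `k` and length `l` has residue
vectors

```
e_i = c_k + a · sin(2π f i/l + φ) · u + ε_i ,   ε_i ~ N(0, σ² I)
```

with a per-protein random direction `u`, frequency `f ∈ [0.5, 3]` and
phase `φ`: the sinusoidal drift (amplitude `a`, default = `σ`) makes
residues within a protein correlated, mimicking contextual embeddings.
Sequences are drawn from class-specific residue-frequency profiles
(Dirichlet(1) over the 20 amino acids), so sequence identity within a
class is above background but uninformative — classification signal
lives in the embeddings, as intended.

Default calibration, fixed once: `K = 5`, `D = 32`, `σ = Δ/8 = 0.75`,
20 baits + 20 queries per class, overlapping GST-like length ranges
(class `k`: `[170+6k, 230+6k]`), query region mix 60% within / 20%
below / 20% above, below/above lengths 1–40 residues outside the range.
The first two bait lengths are pinned to the range endpoints so the
realised RLR equals the configured one.  These sizes keep the full
benchmark (10,000 pairwise alignments) around fifteen seconds on one
CPU while leaving the ≥95% recovery bar a real constraint at higher
noise levels.

**Degenerate limit worth knowing:** with `σ = 0` *and* zero drift,
every residue of a protein is its class centroid, every distance matrix
is constant, and signal enhancement maps it to the zero matrix — all
baits tie and classification collapses to tie-breaking.  "Noise-free"
runs therefore keep the drift term (the tests pass
`drift_amplitude = 0.75` explicitly with `σ = 0`).

What passing the synthetic benchmarks does **not** show: real pLM
embedding geometry (anisotropy, length- and composition-dependent
shifts), realistic indel structure, or class-imbalanced reference sets.
The synthetic results validate the machinery — distances, enhancement,
DP, normalisation, triage, reporting — not the biological performance
of any particular language model.

## Packaged GST data

Three plain-TSV tables summarise the GST superfamily study the package
is built around: the curated 284-protein reference set (20 classes,
per-taxon counts, per-class length ranges — e.g. Mu 211–225, MAPEG
146–155), the per-class expected/agreeing counts of a 15,061-protein
labeled benchmark split by length region, and the per-taxon counts of a
64,207-protein unlabeled survey.  The reporting module reproduces the
headline figures from these counts: 99.3% agreement with the rule-based
annotation, 46% of the labeled set outside the RLR, 41% of the
unlabeled set within and 58% outside.

The reference set itself is shipped as metadata only.
`eba.gst.synthetic_gst_refset()` builds a synthetic stand-in — real
class labels, taxon assignments and length ranges; synthetic sequences
and embeddings — spreading bait lengths across each class range with
both endpoints included so the derived RLRs reproduce the published
ones exactly.  Users with the curated sequences and real embeddings
load them through `eba.refset.load_reference_set`.

## Numerical and edge-case choices

- Agreement percentages round to one decimal; region fractions round to
  integer percent, half away from zero.  `within% + outside%` may be 99
  or 101 when some queries are unclassified or by rounding; the
  reconciliation tests allow ±1.
- Empty substitution matrices, empty sequences, non-finite embeddings,
  mixed embedding dimensions within a store or reference set, and
  classes with zero baits are all hard errors.
- An alignment path with no aligned pairs (all gaps) yields identity 0
  with a warning.
- Self-exclusion during classification triggers on exact id equality
  only; sequence-identical baits under different ids are legitimate
  neighbours.
- No score threshold rejects low-confidence calls by default; the
  pipeline classifies everything (margins are reported so users can
  filter downstream).
- The affine DP is JIT-compiled (numba) with a semantically identical
  pure-Python fallback; equivalence to exhaustive alignment enumeration
  is asserted over a seeded grid of all shapes up to 5×5.

## Limitations

- The exact enhancement formula of other EBA implementations is not
  guaranteed to match this one; results should be compared only with
  the transform versioned here.
- The redundancy filter is O(queries × baits) full global alignments —
  fine for reference-set scale, not for database scale.
- Letter-based identity of co-optimal alignments depends on which
  optimum the aligner reports; identities near a filtering threshold
  should be treated as approximate to ~0.1%.
- Embedding generation is out of scope: the optional ESM2 adapter is
  provided untested against a live model and requires GPU-scale
  resources for large inputs.
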