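# Methods

`itsphylo` asks a single scientific question of ITS1/ITS2 ribosomal spacer
data: does carrying the RNA secondary structure through alignment and tree
inference change the number and strength of supported clades?  The package
implements every stage needed to answer it — folding, structure validation,
sequence+structure coding and alignment, the compensatory-change census,
four inference methods run with and without the structure, and the paired
comparison — plus a simulator that generates data with known truth so each
stage is testable without external sequences.

## Secondary-structure prediction

Structures are nested (pseudoknot-free) base-pair sets over the canonical
pairs AU, UA, GC, CG and the GU/UG wobble.  `folding.energy` scores a
structure by full loop decomposition: stacking energies for adjacent pairs,
tabulated hairpin/bulge/internal-loop initiation penalties with
Jacobson–Stockmayer logarithmic extrapolation beyond the tabulated lengths,
and an affine multiloop term `a + b·(branches+1) + c·unpaired`
(a = 3.4, b = 0.4, c = 0.1 kcal/mol).  Exterior bases are free.

The parameter set is deliberately reduced: a 6×6 stacking table for the
canonical pairs (GC/CG stacks strongest near −3.4 kcal/mol, wobble stacks
weakest, filled out by the opposite-strand reciprocity identity
E(p→q) = E(reverse q→reverse p)), no dangling ends, no coaxial stacking,
temperature fixed at 37 °C.  A full published nearest-neighbour set would
add many parameters that this pipeline's downstream statistics are
insensitive to; a compact self-contained table keeps every prediction
deterministic and lets the test suite verify exact optimality.  Hairpins of
1–2 nt get steep but finite penalties so that `energy` can score any
structure a parser accepts, while folding itself never proposes them
(minimum hairpin loop 3 nt).

`fold_mfe` is a Zuker-style dynamic programme whose recursions mirror the
`energy` decomposition exactly, so the reported ΔG always equals
`energy(seq, structure)`.  Interior loops are capped at 30 unpaired bases
(binding only for sequences longer than the cap); traceback case order and
(i, j) enumeration are fixed, so output is reproducible.  Constraints are
implemented by barring forbidden pairs from the DP and attaching a large
bonus to forced pairs, verified present afterwards.  Suboptimal structures
within an energy band (default 5 % of |MFE|) are enumerated by refolding
with each MFE pair forbidden in turn — a deterministic neighbourhood
enumeration, not an exhaustive suboptimal census.  Ambiguity codes are
treated as unpairable rather than expanded, a conservative choice matching
the information loss the 12-letter coding imposes anyway.
`nussinov_maxpairs` (pair-count maximisation, documented tie-breaks) is
kept as an independent combinatorial baseline; the suite checks
`fold_mfe` against exhaustive enumeration of all nested structures for
sequences up to length 12.

## Structure annotation

`decompose_helices` partitions the pairs of a structure into helices: a
pair continues its parent's helix iff the parent encloses exactly one pair
directly, so bulges and internal loops of any size never split a helix and
multiloop branching always does.  Top-level helices are labelled H1…H4
positionally (5′→3′); when more are present the four largest keep the main
labels and the remainder are flagged as additional low-stability helices
(Ha, …), matching the architecture of ITS1 in these taxa — four main
helices radiating from a central loop plus an occasional extra helix.

ITS2 correctness checks mirror the hallmarks used to validate predicted
spacer structures: a conserved motif (default `UGGU`, window 10 nt) on the
5′ arm of helix III near its apex, a 1×1 U·U internal loop in helix II, and
the proximal hybrid stem — at least 6 consecutive canonical pairs between
the 3′ end of the 5.8S flank and the 5′ end of the 28S flank.  Motif, window
and pair threshold are configurable; checks without inputs are skipped
rather than failed.  `select_structure` returns the lowest-ΔG candidate
passing all enabled checks and falls back to the MFE structure flagged
`unverified` when none passes.

Helix variants are classified by exact identity of the helix's gap-stripped
dot-bracket substring — structure only; sequence differences are handled by
the phylogenetics downstream.  Variant ids A, B, C… are assigned by
decreasing membership with ties broken by first occurrence.  The consensus
structure keeps a column pair when the fraction of rows mutually paired
there reaches the threshold (default 0.5), with rows gapped at either
column excluded from the denominator; crossing candidates are resolved by
frequency, then span, so the consensus is always nested.  Majority rather
than union is the default because the union of row structures generally
breaks nestedness; the union is recoverable by lowering the threshold.
Columns gapped in any row are marked indels and rendered lowercase.

## 12-letter coding and alignment

Each position is recoded as nucleotide × structural state (open, unpaired,
close): A→{A,B,C}, C→{D,E,F}, G→{G,H,I}, U→{J,K,L}.  Any fixed bijection is
equivalent up to relabelling; this one is documented so outputs are
comparable across runs.  Ambiguity codes map to `?`, which scores 0 against
everything and never opens or closes a helix.  Decoding recovers pairing by
bracket matching, so encode∘decode is the identity on unambiguous input
(property-tested).

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh),
default scores +3 identity, +1 same nucleotide or same structural state,
−1 otherwise, gap open −5, extend −1 — rewarding simultaneous sequence and
structure agreement.  A gap of length L costs `open + extend·(L−1)`.
Tie-breaking prefers substitution over a gap in the first sequence over a
gap in the second.  Multiple alignment is progressive profile–profile
extension along a guide tree built from 12-letter 3-mer distances by
neighbour joining, with merges applied in deterministic order, making the
result invariant to input order up to row order.  Manual curation of
alignments is out of scope; column anchoring is the supported substitute.

## CBC/hCBC census

At each consensus pair, every unordered pair of rows is classified from the
two residue doublets alone: identical; CBC (both partners differ, both
doublets canonical pairs); hCBC (one partner differs, pairing retained —
G-C↔G-U being the classic wobble exchange); pairing_lost (valid on one
side only); other (gap or ambiguity, excluded from numerator and
denominator).  G·U counts as a valid pair — without it hCBC would not be
definable as a pairing-preserving single change.  Counting is site-level: a
consensus pair is one hCBC site regardless of how many row pairs show the
change, with event-level counts reported alongside.  Changes are evaluated
between extant rows, not against a reconstructed ancestor, because the
pipeline performs no ancestral-state reconstruction.

## Tree inference

All four methods operate on the same alignment, with and without structure.

**Distances and NJ.**  Pairwise distances are maximum-likelihood under the
selected model (numeric optimisation of the two-sequence likelihood,
polished with the analytic gradient; equal-rates models reproduce the
Jukes–Cantor closed form to machine precision).  Saturated pairs are capped
at 5.0 substitutions/site with a warning.  `nj_tree` is Saitou–Nei with
deterministic tie-breaking by sorted leaf-label keys; negative branch
lengths are clamped to zero with the deficit moved to the sister branch.
It recovers additive matrices exactly (tested on 100 seeded cases).  The
default GTR rate matrix is estimated from the input alignment by counting
(frequencies plus pair-mismatch exchangeabilities) since no fixed published
matrix is assumed.

**Parsimony.**  Fitch parsimony (unweighted, unordered states) on the
4-letter or 12-letter alphabet, `-`/`?` treated as missing.  The search is
random stepwise addition followed by NNI hill climbing from `n_starts`
starts, returning all tied-best topologies; deterministic per seed.

**Likelihood.**  Felsenstein pruning over site patterns with reversible
models normalised to one expected substitution per site.  +I is a
two-category mixture (rate 0 with probability p, variable categories
rescaled by 1/(1−p)); +G uses four discrete categories with
mean-of-quantile rates.  A `PartitionedAlignment` splits columns by the
consensus mask: paired columns become 16-state doublet sites under a model
whose only nonzero transitions change one nucleotide of the doublet
(rate = exchangeability × π of the target), so a full compensatory change
requires two events; unpaired columns follow 4×4 GTR+I.  With an empty
paired partition the partitioned likelihood reduces exactly to the plain
one (tested to 1e-9).  `ml_search` starts from the NJ tree and alternates
NNI moves with Brent branch-length optimisation until the improvement
drops below 1e-6.

**Bootstrap.**  Columns are resampled with replacement; when a structure
mask is active, a doublet site's two columns travel as one resampling
unit.  Supports are split frequencies on the majority-rule consensus
(greedy by frequency, compatibility-checked), clades below the cutoff
(default 50 %) collapsed.  The with- and without-structure arms share the
same resampling seed so the comparison isolates the structure effect.

**Bayesian MCMC.**  A deliberately minimal Metropolis–Hastings sampler:
proposals are NNI on a random internal edge, a multiplier move on a random
branch length (Hastings-corrected), and a sliding window on the
invariant-site proportion; priors are exponential(10) branch lengths,
uniform topology, uniform p_inv.  Two independent single-chain runs are
compared by the average standard deviation of split frequencies (splits at
pooled frequency ≥ 0.1), with convergence declared below 0.01; there is no
Metropolis coupling.  The consensus is the 50 %-majority tree of pooled
post-burn-in samples (default burn-in 10 %) with clade posterior
probabilities as supports; clades above 0.95 posterior count as supported.

## Clade-support comparison

Clades are identified by unrooted split identity on leaf-label sets — the
reproducible formalisation of comparing drawn trees side by side.
`count_supported_clades` counts non-trivial splits at or above the cutoff;
`match_clades` reports shared and unique supported splits with support
deltas; `compare_runs` executes one method on both arms and emits the full
table.  Support cutoffs default to 0.5 (bootstrap) and 0.95 (posterior).

## Synthetic data

The simulator mirrors the inference models so every recovery test has
exact ground truth.  Trees are Yule (pure birth) with exponential waiting
times; one extra waiting time is appended after the last birth so terminal
branches are strictly positive.  The root sequence follows a fixed helix
layout — by default four helices of 12/14/16/10 stacked pairs with 4–6 nt
terminal loops and 8 nt spacers, ≈250 nt in total, a desk-scale rendering
of the ITS architecture — with paired positions drawn from a stationary
distribution restricted to the six canonical doublets and unpaired
positions uniform.

Evolution is simulated by the jump chain (Gillespie) of the same CTMCs the
likelihood uses: paired sites under the 16-state single-change doublet
kernel, whose stationary mass on valid doublets only makes every event
pairing-preserving — an hCBC arises in one event and a CBC only via two
successive events on the same pair — and unpaired sites under GTR with an
invariant fraction (default 0.2).  Every event is logged and replaying the
log from the root reproduces the leaves exactly.  A test verifies the
simulator's CBC frequency on long branches against the exact
matrix-exponential calculation.  Indels are off by default; when enabled,
only deletions of unpaired columns are generated (insertions are not
modelled), so the true alignment remains the root coordinate system.

What the simulator does not emulate: real indel processes and alignment
ambiguity, base-composition heterogeneity across lineages, rate variation
between helices, pseudoknots, and the manual curation a practitioner would
apply to real spacer alignments.  Passing recovery tests therefore
demonstrates internal correctness of the algorithms, not robustness to
those real-data complications.

## Problem sizes and numerical choices

The packaged verification runs use desk-scale sizes chosen to make each
property sharp: folding exactness on 500–1000 random sequences of length
≤ 12 (exhaustive enumeration stays trivial there); likelihood/parsimony
enumeration on ≤ 5 leaves × 3 sites; NJ recovery on 100 additive matrices
of 6–10 leaves; ML topology recovery on 6 taxa × ≈2000 simulated columns;
Bayesian convergence on a 4-taxon strong-signal simulation at 100k–200k
iterations sampled every 100.  Seeds are explicit everywhere; per-stage
seeds derive from the global seed by hashing the stage name, so stages are
independently reproducible.  Branch lengths are bounded to [1e-8, 10],
distances to [0, 5]; ties in every search and traceback are broken by
documented fixed orders.

## Known limitations

- The energy model is reduced; predicted ΔG values are internally
  consistent but not comparable to full nearest-neighbour servers.
- Suboptimal enumeration is a one-pair-forbidden neighbourhood, which can
  miss structurally distant low-energy alternatives.
- The MCMC sampler has no Metropolis coupling or model-parameter moves
  beyond p_inv; mixing on large trees is untested and out of scope.
- The empirical GTR estimator is a counting moment estimator, not a joint
  ML fit.
- Progressive alignment does no iterative refinement; badly misaligned
  helices will propagate into the consensus mask.
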