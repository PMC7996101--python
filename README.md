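# itsphylo

Structure-aware phylogenetic analysis of the nuclear ribosomal internal
transcribed spacers (ITS1/ITS2).

ITS sequences are the workhorse marker for species-level phylogenetics in
plants and fungi, but in groups with weak reproductive barriers and
frequent hybridisation the sequences alone often fail to resolve closely
related taxa.  The spacers are transcribed RNAs with conserved secondary
structure — for ITS1 in birches, four main helices (H1–H4) plus an
occasional extra helix (Ha); for ITS2, the canonical four-helix model with
a UGGU motif on helix III, a U·U mismatch in helix II and the 5.8S–28S
hybrid stem.  Carrying that structure through the analysis adds
information: paired sites evolve under compensating constraints, so
hemi-compensatory (hCBC, e.g. G-C → G-U) and compensatory (CBC,
e.g. G-C → A-U) changes are phylogenetically meaningful events, and a
structure-aware alignment and substitution model can sharpen clade support.

`itsphylo` is for molecular systematists who want that workflow as one
reproducible, scriptable pipeline:

1. **Folding** — minimum-free-energy nested structures by a Zuker-style
   dynamic programme over a packaged nearest-neighbour table
   (ΔG = Σ stacks + loop penalties + affine multiloop term).
2. **Annotation** — helix decomposition, ITS2 hallmark checks, structural
   variant catalogues, genus-level consensus structure models.
3. **Coding & alignment** — the 12-letter nucleotide × structural-state
   alphabet (A…L), progressive profile alignment with affine gaps.
4. **CBC census** — site-level hCBC/CBC counts over consensus pairs, with
   per-taxon-pair matrices.
5. **Trees** — NJ (ML distances, Saitou–Nei), maximum parsimony (Fitch),
   maximum likelihood (Felsenstein pruning, GTR+I+G), and Bayesian MCMC
   with the 16-state doublet model for paired sites
   (rate(d→d′) = s·π(d′) for single-nucleotide changes) and 4×4 GTR+I for
   unpaired sites — each runnable with and without structure, with shared
   bootstrap resampling seeds.
6. **Comparison** — supported-clade counts at a cutoff (bootstrap ≥ 50 %,
   posterior > 0.95), shared clades and support deltas between the
   with-structure and without-structure trees.

A first-class simulator generates ITS-like sequences evolving on Yule
trees under the same paired/unpaired models, with a complete event log, so
every stage is testable against known ground truth.  See
`docs/methods.md` for models, parameters, defaults and limitations.

## Worked example

```python
from itsphylo import (SimulationConfig, simulate_evolution,
                      build_consensus_structure, scan_alignment,
                      compare_runs, fold_mfe)

cfg = SimulationConfig(n_taxa=8, seed=4, tree_scale=0.2)
records, aln, truth = simulate_evolution(cfg)
print(f"{len(aln.rows)} sequences, alignment width {aln.width}")

res = fold_mfe(records[0])
print(f"{records[0].id}: dG = {res.delta_g:.2f} kcal/mol, "
      f"{res.structure.n_pairs()} pairs")

cons = build_consensus_structure(aln)
report = scan_alignment(aln, cons)
print(f"hCBC sites: {report.n_hcbc_sites}, CBC sites: {report.n_cbc_sites}")

comp = compare_runs(aln, cons, method="nj", n_reps=100, cutoff=0.5, seed=1)
print(f"supported clades with structure:    {comp.n_supported_a}")
print(f"supported clades without structure: {comp.n_supported_b}")
for split, sa, sb, delta in comp.shared_supported:
    print(f"  {{{','.join(sorted(split))}}}: {sa:.0f}% vs {sb:.0f}% "
          f"(delta {delta:+.0f})")
```

Output:

```
8 sequences, alignment width 163
T1: dG = -64.70 kcal/mol, 61 pairs
hCBC sites: 36, CBC sites: 4
supported clades with structure:    3
supported clades without structure: 3
  {T3,T4,T5,T6,T7,T8}: 95% vs 95% (delta +0)
  {T5,T6}: 100% vs 100% (delta +0)
  {T7,T8}: 98% vs 95% (delta +3)
```

Reading it: the eight simulated spacers fold to a stable four-helix
structure (−64.7 kcal/mol); 36 of the 52 consensus pairs show at least one
hemi-compensatory change between some pair of taxa while only 4 show a full
compensatory change (CBCs need two hits on the same pair, so they are much
rarer); both NJ bootstrap trees support the same three clades, and one of
them ({T7,T8}) gains 3 bootstrap points when the 12-letter structure
coding is used.

The same study runs from the shell:

```bash
itsphylo simulate --n-taxa 8 --seed 4 --out simdir/
itsphylo pipeline --in simdir/leaves.fasta --out run/ --seed 1 --boot 100
```

which writes folds, the structural alignment (Stockholm with `SS_cons`),
the CBC site table, eight supported trees (4 methods × with/without
structure), per-method comparison TSVs and a run manifest.

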