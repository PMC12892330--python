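# abforge

Diversity-guided, iterative antibody optimization at desk scale.

`abforge` is for protein engineers and computational immunologists who
want to prototype and test antibody affinity-maturation strategies
without a GPU modeling stack. Starting from an antibody Fv sequence and
an antibody–antigen complex, it optimizes the antibody through
Metropolis-style modification cycles that mirror B-cell maturation:

1. **CDR-H3 grafting** from a naive CDR pool (similar-length by default);
2. a **canonical-conformation sweep** grafting registry representatives
   of the non-H3 CDRs (cografting the DE loop for H2/L1) until no
   further improvement;
3. **constrained naive CDR grafting** with ±1-residue indels, same-
   germline and same-conformation constraints;
4. **diversity-weighted point mutagenesis**, sampling positions by
   α diversity and residues from observed mutation spectra;
5. **framework hybridization** against memory-antibody frameworks,
   keeping the optimized CDRs and returning the best hybrid only if it
   beats the pre-graft antibody.

Where a modification is proposed is driven by repertoire diversity.
For an abundance vector *p* over distinct sequences, the Hill number of
order *q*

&nbsp;&nbsp;&nbsp;&nbsp;*D(q)* = (Σᵢ pᵢ^q)^{1/(1−q)},&nbsp;&nbsp;
*D(1)* = exp(−Σᵢ pᵢ ln pᵢ)

is the "effective number of sequences". γ diversity per CDR (each CDR
type pooled as one population) sets the probability that a CDR is
selected for modification (p ∝ D^w); α diversity per CDR position
steers mutagenesis. A Murphy 10-group reduced alphabet identifies
framework positions tolerant of class-changing mutations (e.g. S→E).

Each cycle runs propose → model → superpose → minimize → score →
accept. Acceptance uses the Metropolis criterion (accept a worsening
ΔE with probability exp(−ΔE/T)), or stricter improve-only / minimum-
threshold rules. External tools (structure predictors, MD minimizers,
physics scoring functions) sit behind four adapter contracts — modeler,
superposer, minimizer, scorer — each shipped with a deterministic toy
implementation, so the full pipeline runs reproducibly in seconds on
one CPU.

The package also builds the optimization datasets from annotated
repertoire tables (filtering, greedy identity clustering at 95%/40%,
the ≥4-framework-mutation "mutated framework" subset anchored at
Vernier/interface positions) and includes a generic harness for
benchmarking scoring protocols on mutation panels with known
directional effects (per-class accuracy, F1, consensus rules, threshold
sweeps, ΔΔH correlation).

## Worked example

Generate a synthetic input bundle (repertoire table, canonical-conformation
registry, antibody FASTA and a docked toy complex) and optimize:

```bash
abforge fixtures --outdir bundle --seed 3
abforge run --fasta bundle/antibody.fasta --complex bundle/complex.pdb \
            --out runout --seed 3
```

which prints

```
initial score 0.000 -> final -14.500 (410 cycles)
```

The score is the toy contact "energy": a symmetric residue-pair weight
table summed over antibody–antigen residue pairs within 8 Å Cα
distance, lower = better. Here the optimizer grafted CDR sequences
whose interface residues form favorable (hydrophobic / charge-
complementary, negative-weight) contacts, improving the predicted
interaction energy from 0 to −14.5 over 410 modification cycles.
`runout/` contains the final Fv FASTA, the final complex PDB, a
JSON-lines trajectory (one record per cycle: proposal, ΔE, acceptance,
RNG draw) and a summary TSV. Rerunning with the same seed reproduces
the trajectory byte for byte.

Diversity analytics on the same bundle:

```bash
abforge diversity --repertoire bundle/repertoire.tsv --group memory --out div.tsv
```

```
CDR1: gamma=10.794 p_select=0.136
CDR2: gamma=7.203 p_select=0.091
CDR3: gamma=61.569 p_select=0.774
```

CDR3 carries most of the effective diversity, so it receives most of
the modification attempts — the behavior the diversity weighting is
designed to produce (a power exponent and per-CDR caps are
configurable).

## Library use

```python
from abforge import fixtures, RunConfig, PipelineResources, AdapterSet, run_pipeline

fv = fixtures.make_fv(seed=0)
cx = fixtures.make_docked_complex(fv, seed=0)
records, truth = fixtures.make_repertoire(fixtures.RepertoireSpec(seed=0))
...
```

Every spec'd operation is a plain function (`hill_diversity`,
`greedy_identity_cluster`, `propose_h3`, `canonical_sweep`,
`framework_swap`, `accept`, `report`, ...); the CLI is a thin wrapper.

## Layout

```
src/abforge/
  regions.py        numbered chains, region tables, grafting substrate
  diversity.py      Hill numbers, site-selection probabilities, mutation spectra
  datasets.py       filters, greedy identity clustering, pools, registries
  modifications.py  the five modification operators
  engine.py         acceptance criteria, cycle loop, trajectories, config
  adapters.py       modeler/superposer/minimizer/scorer contracts + toys
  evalharness.py    mutation-effect classification harness
  fixtures.py       synthetic generators with closed-form ground truth
  data/             region tables, Murphy10 groups, special positions, weights
docs/methods.md     models, assumptions, parameter choices, limitations
```
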