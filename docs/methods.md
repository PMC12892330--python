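# Methods

This note documents the models and procedures implemented in `abforge`,
the assumptions behind them, the parameters that matter, and what the
synthetic fixtures do and do not emulate.

## Numbering and regions

Antibody variable domains are represented as ordered, scheme-labeled
positions (integer number plus optional insertion code; blank code
sorts before A, B, …). Numbering is **consumed, not computed**: chains
arrive pre-numbered (TSV: chain_tag, number, insertion_code, residue)
or through a pluggable numberer. Re-deriving scheme numbers from raw
sequence requires profile alignment against germline HMMs and is out of
scope; the shipped fallback numberer spreads residues evenly over the
scheme's label range, which preserves every region's occupancy and is
adequate for synthetic chains but is *not* a substitute for real
numbering on natural sequences.

Region boundaries (FR1, CDR1, FR2, CDR2, FR3, DE, CDR3, FR4 per chain,
Martin-style) ship as an editable TSV (`data/martin_regions.tsv`) with
a `default` and an `expanded` variant; the expanded CDR windows contain
the default ones and are used when grafting sequences curated under a
different CDR definition. Boundary disputes are config edits, not code
changes. The DE loop ("CDR4") is carved out of FR3 as its own region
because its conformation couples to CDR-H2/L1.

**Length-changing grafts.** When a replacement sequence is longer or
shorter than the region, labels change only at the region's insertion
anchor (the region midpoint): insertions take insertion-coded labels at
the anchor (placed after the last label sharing the anchor's number, so
ordering is preserved); deletions remove the labels nearest the anchor
first. Flanking labels never move, which keeps superposition and
region bookkeeping stable across indels. The anchored-edit convention
is a design choice; alternatives (e.g. C-terminal-biased insertion)
would be config-level changes.

## Diversity

Diversity is quantified with Hill numbers, `D(q) = (Σ p_i^q)^(1/(1−q))`
with `D(1) = exp(Shannon entropy)` as the limit. Defaults: `q = 1`.
The plug-in (maximum-likelihood) estimator is used; a bias-corrected
estimator could be slotted in behind the same interface but is not
implemented.

* **γ per CDR**: each CDR type is one pooled population over its
  observed sequences. Site-selection probabilities are
  `p_CDR ∝ D_CDR^w` with weight exponent `w = 1` by default. Because
  CDR3's γ can dominate by orders of magnitude, `w` and optional
  per-CDR probability caps are configurable (capped mass is
  redistributed proportionally), and fully custom probabilities
  override the derivation.
* **α per position**: residue-level counts per column of CDRs restricted
  to one type and length (mixing lengths is an error — columns are not
  homologous across lengths).
* **Mutation spectra**: per-germline-position frequencies of
  non-germline residues from gapped sequence/germline alignments;
  identity columns contribute no mutated mass. Under the Murphy
  10-group reduced alphabet (LVIM, C, A, G, ST, P, FYW, EDNQ, KR, H;
  shipped as `data/murphy10.tsv`) within-group substitutions are
  discarded, leaving only class-changing mutations, with a per-position
  flag.

## Dataset construction

Filters: records must be from healthy donors and carry all three CDRs;
group selection keeps the requested cell origin, and the memory group
additionally drops IgM (low-affinity, low-specificity isotype). The
filters commute.

Clustering replaces an external heuristic tool with a **deterministic
greedy centroid algorithm**: sequences processed longest-first (ties
broken lexicographically), each joining the first representative with
identity ≥ threshold (inclusive), else founding a cluster. Identity =
matches / max(len_a, len_b) × 100; equal lengths compare ungapped,
unequal lengths count matches under a free-gap global alignment. The
longer-sequence denominator is deliberately conservative (an exact
substring does not reach 100%). Clustering is idempotent on its own
representatives and the representative count is monotone in the
threshold.

Datasets: the naive CDR pool clusters each CDR multiset at **40%**
identity (a small but chemically diverse pool, mimicking V(D)J
recombination); the memory framework dataset is all filtered memory
records; its mutated subset keeps records with **≥ 4 framework
mutation events** against the germline framework *and* at least one
substitution at a "special" position — Vernier-zone or chain-interface
residues whose mutation can shift CDR conformation or the VH–VL angle.
The shipped special-position list (`data/special_positions.tsv`) is
transcribed from the Vernier/interface literature and is replaceable.
Gap handling: one contiguous indel = one mutation event, matching the
biology of somatic-hypermutation indels; per-residue gap counting would
be a one-line change.

The canonical-conformation registry (53 non-H3 CDR representatives,
with DE-loop sequences mandatory for H2/L1 entries) is upstream curated
data consumed as a validated TSV; the synthetic registry generator used
in tests is a placeholder with the same schema, not a structural
database.

## Modification operators

* **H3 grafting**: similar-length mode (default, tolerance 0 — exact
  length, configurable) or any-length, uniform or weighted by the
  pool's empirical length distribution.
* **Canonical sweep**: every registry entry is grafted and evaluated;
  an accepted graft becomes the new reference and the remaining entries
  are retested; terminates when a full pass accepts nothing. Acceptance
  combines the engine's criterion with a strict-decrease requirement,
  which guarantees termination under any criterion (including
  Metropolis).
* **Naive CDR grafting**: site drawn from the (diversity-derived or
  custom) probabilities over non-H3 CDRs; target length = current ±
  {0, +1, −1} with default probabilities (0.8, 0.1, 0.1) — a config
  default in the absence of a measured indel spectrum; candidates
  filtered by germline when `same_germline` is set. H2/L1 grafts carry
  the DE loop from the same source entry when available, otherwise the
  current DE loop is retained (flag-controlled).
* **Mutagenesis**: diversity mode samples the position ∝ α diversity
  (restricted to positions whose mutation spectrum offers a residue
  different from the current one) and the residue from that spectrum;
  random mode is uniform with the current residue excluded.
* **Framework hybridization**: per chain, the `match_k` (default 1)
  most similar dataset frameworks under global alignment with BLOSUM62
  (gap open −10, extend −0.5) donate their framework regions; single-
  mature and mature-mature hybrids preserve all CDRs; the best variant
  is returned only if it scores strictly below the input. The DE loop
  is treated as framework and swapped by default (flag-controlled).
  Exact alignment replaces a heuristic database search: deterministic
  and exact at desk scale.

**Conformation guard.** Loop conformations are compared by the
dihedral distance `d = sqrt(Σ_r 2(1−cos Δφ_r) + 2(1−cos Δψ_r))`
(degrees, symmetric, zero iff equal mod 360°). A guarded proposal is
remodeled and rejected before scoring if its loop's distance to the
reference exceeds the threshold. With a deterministic modeler an
unchanged sequence reproduces its torsions exactly, so the default
threshold is 10⁻⁶ — effectively "no torsion change"; real modelers
carry stochastic noise and need a calibrated, larger threshold.
A length change always fails the guard (the metric is undefined across
lengths).

## Engine

Acceptance rules: Metropolis (accept ΔE ≤ 0 always, else with
probability `exp(−ΔE/T)`; default `T = 1` scorer unit — scores are
unitless "energies" and only differences matter), improve-only
(strict `ΔE < 0`), and threshold (`ΔE ≤ −τ`, inclusive — a move
exactly meeting the required improvement is accepted; zero improvement
at τ = 0 under improve-only is rejected).

One seeded RNG stream drives all stochastic choices; each cycle's
uniform draw is logged in its trajectory record, and trajectories
serialize to JSON-lines byte-identically across reruns (wall-clock
timing is kept in memory but excluded from serialization).
Operator and adapter failures (no candidate, conformation rejection,
adapter error) become rejected cycles tagged with the error, and the
run continues — long runs should not die on a single bad proposal.

Step budgets: per-cycle steps (H3, naive CDR, mutagenesis) run exactly
their budget; the canonical sweep treats its budget as a pass cap
(0 = run to convergence); the framework step runs a single enumeration
(budget 0 skips it). The default order — H3 → canonical → naive CDR →
mutagenesis → framework — follows the biological progression from
V(D)J recombination to somatic hypermutation. The default per-step
budgets (50 / conv. / 100 / 100 / 1) keep a full default run in the
hundreds of cycles; they are starting points, not recommendations.

## Adapters and toy implementations

Four contracts isolate external tools: modeler (Fv → backbone +
torsions), superposer, minimizer, scorer. The bundled implementations
are deliberately simple and fully deterministic:

* **toy_model** assigns each residue a fixed (φ, ψ) from a shipped
  table (values spread over the plausible Ramachandran range, distinct
  per letter) and builds N/CA/C backbones by NeRF chain extension with
  ideal bond geometry. It is a modeling *convention*, not a predictor:
  its purpose is that sequence changes deterministically change
  torsions and coordinates so conformation checks and superposition are
  exercised honestly.
* **superpose** is an exact Kabsch fit on backbone atoms of residues
  with shared labels; the antigen is coordinate-identical before and
  after.
* **toy_minimize** pushes inter-chain atom pairs closer than 2 Å apart
  to 2 Å in one pass (half the deficit each); identity on clash-free
  structures and idempotent absent cascades.
* **contact_scorer** sums a shipped symmetric 20×20 residue-pair weight
  table over Ab–Ag pairs within 8 Å Cα (hydrophobic pairs −1,
  charge-complementary −1.5, like-charge +1, polar-polar −0.5, else 0).
  Rigid-motion invariant; lower is better.
* **surrogate_scorer** is a sequence-level oracle: minus the summed
  per-CDR similarity (target length − edit distance) to a hidden target
  paratope, minimized exactly at the target with unit cost per
  mismatch. It bypasses structure entirely and exists for
  planted-solution recovery tests and fast optimization experiments.

Because the toys are not physical, absolute scores are meaningless;
everything the engine consumes is a score *difference* plus a
direction flag, so swapping in a real scorer changes no engine logic.

## Synthetic data

`make_repertoire` draws per-CDR abundances from a symmetric Dirichlet
over a declared number of distinct sequences (concentration parameter
controls evenness) and returns the exact abundance vectors with the
records, so expected Hill numbers are available in closed form to any
test. Framework mutations are injected uniformly at random into
germline templates (Poisson-distributed count per record, mean 0 for
naive and 3 for memory records — a realistic order of magnitude for
memory-derived substitution loads at this scale), with optional forced
special-position hits. Default group sizes (150 records per
chain × origin) and pool sizes keep every desk-scale analysis under a
second while leaving per-CDR abundance estimation well-conditioned;
the calibration checks use 4 000–5 000 records so the plug-in estimate
sits within a few percent of the closed form.

What the generator does **not** emulate: V(D)J junctional structure,
CDR length distributions of real repertoires, hypermutation hotspots,
clonal lineage structure, isotype biology beyond a label, or any
covariance between CDRs. Passing tests therefore demonstrate the
correctness of the statistics and the optimization machinery on
distributions with known ground truth — not performance on real
repertoires or structures.

`make_complex` constructs geometry where declared interface pairs are
the *only* Ab–Ag Cα pairs within the 8 Å scoring cutoff (contact sum
exactly computable); `make_docked_complex` instead wraps the antigen
around the modeled antibody's CDR-H3, accepting incidental contacts as
a real interface would. `make_planted_pool` plants one optimal CDR
among decoys at edit distance ≥ 2.

## Evaluation harness

Directional classification of mutation effects: a score change is an
"approval" if it clears the threshold in the scorer's improving
direction (inclusive at τ > 0; at τ = 0 a zero change is *not* an
improvement). The affinity-increasing class is the positive class for
precision/recall/F1 throughout. Replicated protocol runs are
aggregated by mean score change before classification. Consensus of
two scorers approves only when both approve, which provably never
increases false approvals over either input. For lower-is-better
scorers the approved set shrinks monotonically in τ, so
rejection accuracy is non-decreasing along a threshold sweep.

## Known limitations

* The fallback numberer is length-proportional, not alignment-based;
  region boundaries on natural sequences will differ from a real
  numbering tool's.
* The plug-in diversity estimator is downward-biased for undersampled
  populations; no small-sample correction is applied.
* The greedy clusterer is O(n·k) in pairwise comparisons and intended
  for desk-scale inputs (≤ ~10⁴ sequences), not repertoire-scale
  redundancy removal.
* Toy adapters carry no physics; optimization results demonstrate the
  machinery, not binding predictions. Real-tool adapters must supply
  their own conformation-guard thresholds and score scales.
* Framework donors must provide per-region framework segments;
  un-segmented framework strings cannot be grafted safely across
  scheme boundaries and are rejected.
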