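"""The five antibody modification operators.

1. CDR-H3 grafting from the naive pool (similar-length by default, or
   any length, random or weighted by the pool's length distribution).
2. Canonical-conformation sweep over registry representatives of the
   non-H3 CDRs (DE loop cografted for H2/L1), iterated to convergence.
3. Constrained naive CDR grafting with ±1-residue indels, optional
   same-germline and same-conformation constraints.
4. Point mutagenesis, diversity-weighted (position ∝ alpha diversity,
   residue from the observed mutation spectrum) or uniform-random.
5. Framework hybridization against a memory framework dataset, keeping
   the optimized CDRs and returning the best of the single-mature and
   mature-mature hybrids only if it beats the input.

Proposal operators are pure: they return a ``ModificationProposal``
carrying the resulting Fv; acceptance is the engine's job.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import Align

from .adapters import ModelResult, loop_torsions, toy_model
from .datasets import CanonicalEntry, PoolEntry, RepertoireRecord
from .diversity import PositionProfile
from .errors import ConfigurationError, ConformationRejected, NoCandidateError
from .regions import AntibodyFv, RegionTable, assign_regions, graft_fv

logger = logging.getLogger(__name__)

NON_H3_SITES = ("H1", "H2", "L1", "L2", "L3")
DE_COGRAFT_SITES = ("H2", "L1")


def _site_to_region(site: str) -> tuple[str, str]:
    """Pool site key (e.g. ``H2``) -> (chain_tag, region_id)."""
    return site[0], f"CDR{site[1]}"


@dataclass(frozen=True)
class ModificationProposal:
    kind: str                 # h3_graft | canonical_graft | naive_graft | point_mutation | framework_swap
    site: str                 # region id or position label
    payload: str              # grafted sequence or new residue
    source: str               # pool id / registry cluster / dataset record
    fv: AntibodyFv
    de_loop: str = ""         # cografted DE loop, when applicable


@dataclass(frozen=True)
class IndelPolicy:
    """Probabilities of proposing same-length / +1 / -1 CDR grafts."""

    p_same: float = 0.8
    p_plus1: float = 0.1
    p_minus1: float = 0.1

    def __post_init__(self) -> None:
        probs = (self.p_same, self.p_plus1, self.p_minus1)
        if any(p < 0 for p in probs):
            raise ConfigurationError("indel probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"indel probabilities sum to {sum(probs)}, not 1")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice([0, 1, -1], p=[self.p_same, self.p_plus1, self.p_minus1]))


def conformation_distance(
    loop_a: Sequence[tuple[float, float]],
    loop_b: Sequence[tuple[float, float]],
) -> float:
    """Dihedral distance between two loop backbones (degrees).

    ``d = sqrt( sum_r [ 2(1-cos dphi_r) + 2(1-cos dpsi_r) ] )`` —
    symmetric, zero iff torsions agree modulo 360°.
    """
    if len(loop_a) != len(loop_b):
        raise ConfigurationError(f"loop length mismatch: {len(loop_a)} vs {len(loop_b)}")
    total = 0.0
    for (pa, sa), (pb, sb) in zip(loop_a, loop_b):
        total += 2.0 * (1.0 - math.cos(math.radians(pa - pb)))
        total += 2.0 * (1.0 - math.cos(math.radians(sa - sb)))
    return math.sqrt(total)


@dataclass
class ConformationCheck:
    """Guard comparing a loop's modeled torsions to a reference.

    The default threshold is small but nonzero: remodeling an identical
    sequence with a deterministic modeler reproduces its torsions
    exactly, so identity always passes; any real torsion change at a
    residue exceeds it.
    """

    reference: Sequence[tuple[float, float]]
    threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("conformation threshold must be positive")

    def passes(self, torsions: Sequence[tuple[float, float]]) -> bool:
        if len(torsions) != len(self.reference):
            return False  # length change is a conformation change
        return conformation_distance(torsions, self.reference) <= self.threshold


# ---------------------------------------------------------------------------
# 1. CDR-H3 grafting

def propose_h3(
    fv: AntibodyFv,
    pool: Sequence[PoolEntry],
    mode: str = "similar_length",
    rng: np.random.Generator | None = None,
    tolerance: int = 0,
    table: RegionTable | None = None,
) -> ModificationProposal:
    """Propose a naive H3 graft.

    ``similar_length`` draws uniformly among entries within the length
    tolerance of the current H3 (default exact length);
    ``any_random`` draws uniformly over the whole pool; ``any_weighted``
    draws a length from the pool's empirical length distribution and
    then uniformly within that length.
    """
    if not pool:
        raise NoCandidateError("H3 pool is empty")
    rng = rng if rng is not None else np.random.default_rng()
    table = table or RegionTable.default()
    cur_len = len(assign_regions(fv.heavy, table)["CDR3"])
    if mode == "similar_length":
        candidates = [e for e in pool if abs(e.length - cur_len) <= tolerance]
        if not candidates:
            raise NoCandidateError(f"no H3 candidate within length tolerance {tolerance} of {cur_len}")
        entry = candidates[int(rng.integers(len(candidates)))]
    elif mode == "any_random":
        entry = pool[int(rng.integers(len(pool)))]
    elif mode == "any_weighted":
        lengths = np.array([e.length for e in pool])
        uniq, counts = np.unique(lengths, return_counts=True)
        target_len = int(rng.choice(uniq, p=counts / counts.sum()))
        candidates = [e for e in pool if e.length == target_len]
        entry = candidates[int(rng.integers(len(candidates)))]
    else:
        raise ConfigurationError(f"unknown H3 grafting mode {mode!r}")
    new_fv = graft_fv(fv, "H", "CDR3", entry.sequence, table)
    return ModificationProposal(
        kind="h3_graft", site="H3", payload=entry.sequence,
        source=entry.source_id or "pool:H3", fv=new_fv,
    )


# ---------------------------------------------------------------------------
# 2. Canonical-conformation sweep

def _graft_canonical(fv: AntibodyFv, entry: CanonicalEntry, table: RegionTable) -> AntibodyFv:
    chain_tag, region_id = _site_to_region(entry.cdr_type)
    out = graft_fv(fv, chain_tag, region_id, entry.sequence, table)
    if entry.cdr_type in DE_COGRAFT_SITES and entry.de_loop:
        out = graft_fv(out, chain_tag, "DE", entry.de_loop, table)
    return out


def canonical_sweep(
    fv: AntibodyFv,
    registry: Sequence[CanonicalEntry],
    evaluate: Callable[[AntibodyFv], float],
    rng: np.random.Generator | None = None,
    criterion=None,
    table: RegionTable | None = None,
    max_passes: int | None = None,
    on_proposal: Callable[[ModificationProposal, float, float, bool], None] | None = None,
) -> AntibodyFv:
    """Iterative best-found sweep over canonical-conformation representatives.

    Each non-H3 registry entry is grafted (with DE-loop cograft for
    H2/L1) and evaluated; an accepted graft becomes the new reference
    and the remaining alternatives are retested against it.  Terminates
    when a full pass yields no acceptance (or at the pass cap).
    Acceptance combines the configured criterion with a strict-decrease
    requirement; the accepted-score sequence is therefore strictly
    decreasing and termination is guaranteed under any criterion.
    """
    from .engine import AcceptanceCriterion, accept

    table = table or RegionTable.default()
    criterion = criterion or AcceptanceCriterion(mode="improve_only")
    rng = rng if rng is not None else np.random.default_rng()
    current = fv
    current_score = evaluate(current)
    passes = 0
    while True:
        improved = False
        for entry in registry:
            candidate = _graft_canonical(current, entry, table)
            score = evaluate(candidate)
            de = score - current_score
            u = float(rng.random())
            ok = accept(de, criterion, u) and de < 0
            if on_proposal is not None:
                prop = ModificationProposal(
                    kind="canonical_graft", site=entry.cdr_type, payload=entry.sequence,
                    source=entry.cluster_id, fv=candidate, de_loop=entry.de_loop,
                )
                on_proposal(prop, current_score, score, ok)
            if ok:
                current, current_score = candidate, score
                improved = True
        passes += 1
        if not improved or (max_passes is not None and passes >= max_passes):
            return current


# ---------------------------------------------------------------------------
# 3. Constrained naive CDR grafting

def propose_naive_cdr(
    fv: AntibodyFv,
    pools: Mapping[str, Sequence[PoolEntry]],
    constraints: Mapping[str, bool] | None = None,
    indel: IndelPolicy | None = None,
    site_probs: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    table: RegionTable | None = None,
) -> ModificationProposal:
    """Propose a naive non-H3 CDR graft with controlled indels.

    The site is drawn from ``site_probs`` over non-H3 CDRs; the target
    length is the current length plus an indel sampled from the policy;
    candidates are restricted to pool entries of that length (and to the
    chain's germline when ``same_germline`` is set).  H2/L1 proposals
    cograft the DE loop from the source entry when it carries one.  The
    conformation constraint is enforced by the engine at evaluation
    time.  Raises ``NoCandidateError`` (skip-cycle) when no entry fits.
    """
    from .engine import select_site

    constraints = dict(constraints or {"same_germline": True, "same_conformation": True})
    indel = indel or IndelPolicy()
    rng = rng if rng is not None else np.random.default_rng()
    table = table or RegionTable.default()
    if site_probs is None:
        site_probs = {s: 1.0 / len(NON_H3_SITES) for s in NON_H3_SITES}
    site = select_site(site_probs, rng)
    chain_tag, region_id = _site_to_region(site)
    pool = pools.get(site)
    if not pool:
        raise NoCandidateError(f"no pool for site {site}")
    cur_len = len(assign_regions(fv.chain(chain_tag), table)[region_id])
    target_len = cur_len + indel.sample(rng)
    candidates = [e for e in pool if e.length == target_len]
    if constraints.get("same_germline"):
        germ = fv.chain(chain_tag).germline_id
        candidates = [e for e in candidates if e.germline_id == germ]
    if not candidates:
        raise NoCandidateError(f"no candidate for site {site} at length {target_len}")
    entry = candidates[int(rng.integers(len(candidates)))]
    new_fv = graft_fv(fv, chain_tag, region_id, entry.sequence, table)
    de_loop = ""
    if site in DE_COGRAFT_SITES and entry.de_loop:
        new_fv = graft_fv(new_fv, chain_tag, "DE", entry.de_loop, table)
        de_loop = entry.de_loop
    return ModificationProposal(
        kind="naive_graft", site=site, payload=entry.sequence,
        source=entry.source_id or f"pool:{site}", fv=new_fv, de_loop=de_loop,
    )


# ---------------------------------------------------------------------------
# 4. Mutagenesis

_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


def propose_mutation(
    fv: AntibodyFv,
    position_profiles: Mapping[str, PositionProfile] | None = None,
    mode: str = "diversity",
    guard: ConformationCheck | None = None,
    rng: np.random.Generator | None = None,
    table: RegionTable | None = None,
    modeler: Callable[[AntibodyFv], ModelResult] = toy_model,
    sites: Sequence[str] = ("H1", "H2", "H3", "L1", "L2", "L3"),
) -> ModificationProposal:
    """Propose a single CDR point mutation.

    Diversity mode samples the position proportionally to its alpha
    diversity and the residue from that position's observed mutation
    spectrum (excluding the current residue); random mode is uniform
    over positions and over the 19 alternative residues.  When a guard
    is supplied, the mutated loop is remodeled and proposals that change
    its conformation raise ``ConformationRejected`` before scoring.
    """
    rng = rng if rng is not None else np.random.default_rng()
    table = table or RegionTable.default()
    positions: list[tuple[str, int, float, dict[str, float]]] = []  # (site, pos_idx, weight, residue freqs)
    for site in sites:
        chain_tag, region_id = _site_to_region(site)
        cur = assign_regions(fv.chain(chain_tag), table)[region_id]
        if mode == "diversity":
            if position_profiles is None or site not in position_profiles:
                continue
            prof = position_profiles[site]
            if prof.length != len(cur):
                raise ConfigurationError(
                    f"profile for {site} covers length {prof.length}, current CDR has {len(cur)}"
                )
            freqs = prof.mutation_freqs if prof.mutation_freqs else prof.residue_freqs
            for i in range(prof.length):
                positions.append((site, i, float(prof.alpha[i]), freqs[i]))
        else:
            for i in range(len(cur)):
                positions.append((site, i, 1.0, {}))
    if not positions:
        raise NoCandidateError("no mutable positions available")
    if mode == "diversity":
        # weight by the mass actually proposable (excluding the current residue)
        weights = []
        for site, i, w, freqs in positions:
            chain_tag, region_id = _site_to_region(site)
            cur = assign_regions(fv.chain(chain_tag), table)[region_id]
            mass = sum(f for aa, f in freqs.items() if aa != cur[i])
            weights.append(w if mass > 0 else 0.0)
        weights = np.asarray(weights)
        if weights.sum() <= 0:
            raise NoCandidateError("mutation spectra propose nothing new at any position")
        pick = int(rng.choice(len(positions), p=weights / weights.sum()))
    elif mode == "random":
        pick = int(rng.integers(len(positions)))
    else:
        raise ConfigurationError(f"unknown mutagenesis mode {mode!r}")
    site, pos_idx, _w, freqs = positions[pick]
    chain_tag, region_id = _site_to_region(site)
    cur = assign_regions(fv.chain(chain_tag), table)[region_id]
    current_aa = cur[pos_idx]
    if mode == "diversity":
        options = {aa: f for aa, f in freqs.items() if aa != current_aa and f > 0}
        aas = sorted(options)
        p = np.array([options[a] for a in aas])
        new_aa = str(rng.choice(aas, p=p / p.sum()))
    else:
        aas = [a for a in _ALL_AA if a != current_aa]
        new_aa = aas[int(rng.integers(len(aas)))]
    new_seq = cur[:pos_idx] + new_aa + cur[pos_idx + 1:]
    new_fv = graft_fv(fv, chain_tag, region_id, new_seq, table)
    if guard is not None:
        tors = loop_torsions(new_fv, chain_tag, region_id, table, modeler)
        if not guard.passes(tors):
            raise ConformationRejected(f"mutation {site}:{pos_idx + 1}{new_aa} alters loop conformation")
    return ModificationProposal(
        kind="point_mutation", site=f"{site}:{pos_idx + 1}", payload=new_aa,
        source=mode, fv=new_fv,
    )


# ---------------------------------------------------------------------------
# 5. Framework hybridization

_fw_aligner = Align.PairwiseAligner()
_fw_aligner.mode = "global"
_fw_aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
_fw_aligner.open_gap_score = -10.0
_fw_aligner.extend_gap_score = -0.5

_FW_REGIONS = ("FR1", "FR2", "FR3", "DE", "FR4")


def _swap_framework(fv: AntibodyFv, chain_tag: str, donor: RepertoireRecord,
                    table: RegionTable, swap_de: bool = True) -> AntibodyFv:
    if not donor.framework_regions:
        raise ConfigurationError(
            f"framework record {donor.record_id} lacks per-region framework segments"
        )
    out = fv
    for rid in _FW_REGIONS:
        if rid == "DE" and not swap_de:
            continue
        seg = donor.framework_regions.get(rid)
        if seg:
            out = graft_fv(out, chain_tag, rid, seg, table)
    return out


def framework_swap(
    fv: AntibodyFv,
    framework_dataset: Sequence[RepertoireRecord],
    evaluate: Callable[[AntibodyFv], float],
    match_k: int = 1,
    table: RegionTable | None = None,
    conformation_guards: Mapping[tuple[str, str], ConformationCheck] | None = None,
    modeler: Callable[[AntibodyFv], ModelResult] = toy_model,
    input_score: float | None = None,
    swap_de: bool = True,
) -> AntibodyFv:
    """Mature the frameworks by hybridization with memory records.

    For each chain the ``match_k`` dataset frameworks most similar to the
    current one (global-alignment score) donate their framework regions;
    single-mature hybrids (new H + old L, old H + new L) and mature-mature
    combinations are built with all CDRs preserved, evaluated, and the
    best variant is returned only if it scores below the input; otherwise
    the input is returned unchanged.  Variants failing the paratope
    conformation re-check are discarded before scoring.
    """
    table = table or RegionTable.default()
    by_chain: dict[str, list[RepertoireRecord]] = {"H": [], "L": []}
    for rec in framework_dataset:
        if rec.chain_tag in by_chain:
            by_chain[rec.chain_tag].append(rec)
    if not by_chain["H"] and not by_chain["L"]:
        logger.warning("framework dataset empty; returning input unchanged")
        return fv
    top: dict[str, list[RepertoireRecord]] = {}
    for tag in ("H", "L"):
        cur_fw = "".join(assign_regions(fv.chain(tag), table)[r] for r in _FW_REGIONS)
        scored = sorted(
            by_chain[tag],
            key=lambda rec: (-_fw_aligner.score(cur_fw, rec.framework), rec.record_id),
        )
        top[tag] = scored[:match_k]
    variants: list[tuple[str, AntibodyFv]] = []
    for hrec in top["H"]:
        variants.append((f"H:{hrec.record_id}", _swap_framework(fv, "H", hrec, table, swap_de)))
    for lrec in top["L"]:
        variants.append((f"L:{lrec.record_id}", _swap_framework(fv, "L", lrec, table, swap_de)))
    for hrec in top["H"]:
        for lrec in top["L"]:
            mature = _swap_framework(fv, "H", hrec, table, swap_de)
            mature = _swap_framework(mature, "L", lrec, table, swap_de)
            variants.append((f"H:{hrec.record_id}+L:{lrec.record_id}", mature))
    base = evaluate(fv) if input_score is None else input_score
    best_score, best_fv = base, fv
    for name, variant in variants:
        if conformation_guards:
            ok = True
            for (ct, rid), guard in conformation_guards.items():
                if not guard.passes(loop_torsions(variant, ct, rid, table, modeler)):
                    ok = False
                    break
            if not ok:
                logger.info("framework variant %s rejected by conformation guard", name)
                continue
        score = evaluate(variant)
        if score < best_score:
            best_score, best_fv = score, variant
    return best_fv
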