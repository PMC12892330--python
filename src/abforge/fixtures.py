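"""Synthetic input generators with closed-form ground truth.

The generators emulate the pipeline's real inputs at desk scale:

* ``make_repertoire`` draws annotated repertoire records whose per-CDR
  abundance vectors follow a symmetric Dirichlet over a declared number
  of distinct sequences — so the exact abundance vector is returned
  alongside the records and expected Hill diversities are computable in
  closed form by any test.
* ``make_complex`` builds a toy antibody-antigen complex whose declared
  interface pairs sit within Cα contact range (5 Å) while every other
  inter-molecular pair is far outside it, so the contact score is a
  known finite sum.
* ``make_planted_pool`` builds CDR pools containing one target sequence
  plus decoys at controlled edit distance, for planted-solution
  recovery tests.
* ``make_registry`` writes a placeholder canonical-conformation table
  (synthetic stand-in for a curated conformation registry).

Everything is deterministic under its seed.  These fixtures deliberately
ignore real immunogenetics (no V(D)J junction structure, no hypermutation
hotspots); they control only the statistics the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .adapters import ComplexStructure, Residue
from .datasets import PoolEntry, RepertoireRecord
from .errors import ConfigurationError
from .regions import AntibodyFv, NumberedChain, RegionTable, assign_regions

_AA = "ACDEFGHIKLMNPQRSTVWY"

# framework segment lengths used by synthetic germline templates
_FW_LENGTHS = {"FR1": 22, "FR2": 14, "FR3": 20, "DE": 6, "FR4": 10}
_CDR_DEFAULT_LENGTHS = {"CDR1": 8, "CDR2": 7, "CDR3": 12}


@dataclass
class RepertoireSpec:
    """Controls for the synthetic repertoire generator."""

    n_records: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {("H", "naive"): 150, ("H", "memory"): 150,
                                 ("L", "naive"): 150, ("L", "memory"): 150}
    )
    cdr_lengths: Mapping[str, int] = field(default_factory=lambda: dict(_CDR_DEFAULT_LENGTHS))
    n_distinct: Mapping[str, int] = field(
        default_factory=lambda: {"CDR1": 6, "CDR2": 4, "CDR3": 40}
    )
    concentration: float = 5.0            # symmetric Dirichlet evenness control
    n_germlines: int = 2
    mutation_rate: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 0.0, "memory": 3.0}
    )  # Poisson mean framework mutations per record
    p_igm_memory: float = 0.2
    p_unhealthy: float = 0.0
    seed: int = 0
    ensure_special_fraction: float = 0.0  # fraction of memory records given a forced special-position hit


@dataclass
class RepertoireTruth:
    """Exact generating distributions, for closed-form oracles."""

    abundances: dict[tuple[str, str, str], np.ndarray]     # (chain, origin, cdr) -> probability vector
    distinct: dict[tuple[str, str, str], list[str]]
    germline_frameworks: dict[str, str]                    # germline_id -> framework concatenation
    germline_framework_regions: dict[str, dict[str, str]]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _distinct_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n > 20 ** length:
        raise ConfigurationError(f"cannot draw {n} distinct sequences of length {length}")
    seen: set[str] = set()
    while len(seen) < n:
        seen.add(_random_seq(rng, length))
    return sorted(seen)


def make_repertoire(spec: RepertoireSpec) -> tuple[list[RepertoireRecord], RepertoireTruth]:
    """Draw annotated records plus the exact per-CDR abundance vectors."""
    rng = np.random.default_rng(spec.seed)
    germ_regions: dict[str, dict[str, str]] = {}
    germ_fw: dict[str, str] = {}
    for chain in ("H", "L"):
        for gi in range(spec.n_germlines):
            gid = f"IG{chain}V{gi + 1}-syn"
            regions = {rid: _random_seq(rng, L) for rid, L in _FW_LENGTHS.items()}
            germ_regions[gid] = regions
            germ_fw[gid] = "".join(regions[r] for r in ("FR1", "FR2", "FR3", "DE", "FR4"))
    abundances: dict[tuple[str, str, str], np.ndarray] = {}
    distinct: dict[tuple[str, str, str], list[str]] = {}
    records: list[RepertoireRecord] = []
    from .datasets import load_special_positions

    special = sorted(load_special_positions())
    for (chain, origin), n in sorted(spec.n_records.items()):
        pools: dict[str, tuple[list[str], np.ndarray]] = {}
        for cdr, L in spec.cdr_lengths.items():
            seqs = _distinct_seqs(rng, spec.n_distinct[cdr], L)
            p = rng.dirichlet(np.full(len(seqs), spec.concentration))
            pools[cdr] = (seqs, p)
            abundances[(chain, origin, cdr)] = p
            distinct[(chain, origin, cdr)] = seqs
        germ_ids = [g for g in germ_fw if g.startswith(f"IG{chain}")]
        for i in range(n):
            gid = germ_ids[int(rng.integers(len(germ_ids)))]
            cdrs = {cdr: seqs[int(rng.choice(len(seqs), p=p))] for cdr, (seqs, p) in pools.items()}
            fw_regions = dict(germ_regions[gid])
            n_mut = int(rng.poisson(spec.mutation_rate.get(origin, 0.0)))
            fw = list("".join(fw_regions[r] for r in ("FR1", "FR2", "FR3", "DE", "FR4")))
            mut_pos = rng.choice(len(fw), size=min(n_mut, len(fw)), replace=False)
            for pos in mut_pos:
                alt = [a for a in _AA if a != fw[pos]]
                fw[pos] = alt[int(rng.integers(len(alt)))]
            if origin == "memory" and rng.random() < spec.ensure_special_fraction:
                chain_special = [int(s[1:]) for s in special if s[0] == chain and int(s[1:]) <= len(fw)]
                if chain_special:
                    pos = chain_special[int(rng.integers(len(chain_special)))] - 1
                    alt = [a for a in _AA if a != fw[pos]]
                    fw[pos] = alt[int(rng.integers(len(alt)))]
            fw_str = "".join(fw)
            # rebuild per-region segments from the mutated concatenation
            segs: dict[str, str] = {}
            off = 0
            for rid in ("FR1", "FR2", "FR3", "DE", "FR4"):
                L = _FW_LENGTHS[rid]
                segs[rid] = fw_str[off:off + L]
                off += L
            full = (segs["FR1"] + cdrs["CDR1"] + segs["FR2"] + cdrs["CDR2"]
                    + segs["FR3"] + segs["DE"] + cdrs["CDR3"] + segs["FR4"])
            isotype = "IgM" if origin == "naive" or rng.random() < spec.p_igm_memory else "IgG"
            donor = "other" if rng.random() < spec.p_unhealthy else "healthy"
            records.append(RepertoireRecord(
                record_id=f"{chain}-{origin}-{i:05d}",
                chain_tag=chain, cell_origin=origin, isotype=isotype,
                donor_status=donor, germline_id=gid, sequence=full,
                cdrs=cdrs, framework=fw_str, framework_regions=segs,
            ))
    truth = RepertoireTruth(
        abundances=abundances, distinct=distinct,
        germline_frameworks=germ_fw, germline_framework_regions=germ_regions,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Toy complexes

@dataclass
class ComplexSpec:
    """Geometry controls for the toy antibody-antigen complex."""

    antibody_lengths: Mapping[str, int] = field(default_factory=lambda: {"H": 12, "L": 10})
    antigen_length: int = 10
    interface_pairs: Sequence[tuple[tuple[str, int], int]] = ()  # ((ab_chain, res_idx), ag_res_idx), 1-based
    antibody_seqs: Mapping[str, str] | None = None
    antigen_seq: str | None = None
    contact_distance: float = 5.0
    seed: int = 0


def make_complex(spec: ComplexSpec) -> ComplexStructure:
    """Deterministic toy complex honoring the declared contact map.

    Antibody chains lie on widely separated lines with 10 Å Cα spacing;
    the antigen line sits far away, except that each declared interface
    antigen residue is moved to ``contact_distance`` above its antibody
    partner.  All undeclared inter-molecular Cα pairs remain > 8 Å.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, str] = {}
    for cid, n in spec.antibody_lengths.items():
        given = (spec.antibody_seqs or {}).get(cid)
        seqs[cid] = given if given else _random_seq(rng, n)
        if len(seqs[cid]) != n:
            raise ConfigurationError(f"antibody chain {cid}: sequence length != declared length")
    ag_seq = spec.antigen_seq or _random_seq(rng, spec.antigen_length)
    if len(ag_seq) != spec.antigen_length:
        raise ConfigurationError("antigen sequence length != declared length")
    if spec.contact_distance > 8.0:
        raise ConfigurationError("contact distance must be within the 8 Å scoring cutoff")

    def residue(number: int, aa: str, ca: np.ndarray) -> Residue:
        atoms = {
            "N": ca + np.array([-0.8, 0.5, 0.0]),
            "CA": ca.copy(),
            "C": ca + np.array([0.8, 0.5, 0.0]),
        }
        return Residue(number, "", aa, atoms)

    chains: dict[str, list[Residue]] = {}
    offsets = {"H": 0.0, "L": 500.0}
    for cid, seq in seqs.items():
        z = offsets.get(cid, 900.0)
        chains[cid] = [
            residue(i + 1, aa, np.array([10.0 * i, 0.0, z])) for i, aa in enumerate(seq)
        ]
    # antigen far away by default
    ag = [residue(j + 1, aa, np.array([10.0 * j, 1000.0, 250.0])) for j, aa in enumerate(ag_seq)]
    used_ag: dict[int, tuple[str, int]] = {}
    for (ab_cid, ab_idx), ag_idx in spec.interface_pairs:
        if ab_cid not in chains or not (1 <= ab_idx <= len(chains[ab_cid])):
            raise ConfigurationError(f"interface pair references invalid antibody residue {ab_cid}{ab_idx}")
        if not (1 <= ag_idx <= len(ag)):
            raise ConfigurationError(f"interface pair references invalid antigen residue {ag_idx}")
        if ag_idx in used_ag and used_ag[ag_idx] != (ab_cid, ab_idx):
            raise ConfigurationError(
                f"antigen residue {ag_idx} cannot contact two different antibody residues"
            )
        used_ag[ag_idx] = (ab_cid, ab_idx)
        target = chains[ab_cid][ab_idx - 1].ca + np.array([0.0, spec.contact_distance, 0.0])
        shift = target - ag[ag_idx - 1].ca
        for name in ag[ag_idx - 1].atoms:
            ag[ag_idx - 1].atoms[name] = ag[ag_idx - 1].atoms[name] + shift
    chains["G"] = ag
    return ComplexStructure(chains, tuple(sorted(seqs)), ("G",))


def make_docked_complex(
    fv: AntibodyFv,
    antigen_length: int = 12,
    n_contacts: int = 4,
    seed: int = 0,
    table: RegionTable | None = None,
    contact_distance: float = 5.0,
) -> ComplexStructure:
    """A complex in which the antigen hugs the modeled antibody's CDR-H3.

    The antibody chains are the deterministic toy model of ``fv``;
    ``n_contacts`` antigen residues are placed ``contact_distance`` Å
    outward from evenly spaced CDR-H3 Cα atoms and the remaining antigen
    residues far away.  Unlike :func:`make_complex` the contact count is
    not exact — nearby framework residues may also fall within scoring
    range, as they would in a real interface.
    """
    from .adapters import toy_model
    from .regions import region_positions

    rng = np.random.default_rng(seed)
    table = table or RegionTable.default()
    model = toy_model(fv)
    chains = {tag: [r.copy() for r in model.chains[tag]] for tag in ("H", "L")}
    # keep the two antibody chains apart so inter-chain clash relief stays idle
    for res in chains["L"]:
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] + np.array([0.0, 0.0, 60.0])
    all_ca = np.array([r.ca for r in chains["H"]])
    centroid = all_ca.mean(axis=0)
    h3_idx = region_positions(fv.heavy, "CDR3", table)
    anchors = [h3_idx[int(k)] for k in np.linspace(0, len(h3_idx) - 1, n_contacts)]
    ag_seq = _random_seq(rng, antigen_length)
    ag: list[Residue] = []
    contact_slots = sorted(set(np.linspace(0, antigen_length - 1, n_contacts).astype(int)))
    slot_to_anchor = dict(zip(contact_slots, anchors))
    for j, aa in enumerate(ag_seq):
        if j in slot_to_anchor:
            anchor_ca = chains["H"][slot_to_anchor[j]].ca
            u = anchor_ca - centroid
            u = u / np.linalg.norm(u)
            ca = anchor_ca + contact_distance * u
        else:
            ca = np.array([10.0 * j, 1000.0, 0.0])
        ag.append(Residue(j + 1, "", aa, {
            "N": ca + np.array([-0.8, 0.5, 0.0]),
            "CA": ca.copy(),
            "C": ca + np.array([0.8, 0.5, 0.0]),
        }))
    chains["G"] = ag
    return ComplexStructure(chains, ("H", "L"), ("G",))


# ---------------------------------------------------------------------------
# Planted pools and Fv fixtures

def make_planted_pool(
    target_cdr: str,
    n_decoys: int,
    seed: int = 0,
    min_edit: int = 2,
    germline_id: str = "",
) -> list[PoolEntry]:
    """A pool containing the target plus same-length decoys at edit
    distance >= ``min_edit`` from it."""
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    pool = [PoolEntry(sequence=target_cdr, germline_id=germline_id, source_id="planted")]
    seen = {target_cdr}
    while len(pool) < n_decoys + 1:
        decoy = list(target_cdr)
        k = max(min_edit, int(rng.integers(min_edit, max(min_edit + 1, len(target_cdr) // 2))))
        idx = rng.choice(len(decoy), size=min(k, len(decoy)), replace=False)
        for i in idx:
            alt = [a for a in _AA if a != decoy[i]]
            decoy[i] = alt[int(rng.integers(len(alt)))]
        d = "".join(decoy)
        dist = edlib.align(d, target_cdr, task="distance")["editDistance"]
        if d not in seen and dist >= min_edit:
            seen.add(d)
            pool.append(PoolEntry(sequence=d, germline_id=germline_id,
                                  source_id=f"decoy-{len(pool)}"))
    return pool


def make_fv(seed: int = 0, table: RegionTable | None = None,
            germline_h: str = "IGHV1-syn", germline_l: str = "IGLV1-syn") -> AntibodyFv:
    """A random but valid numbered Fv covering every region of the table."""
    rng = np.random.default_rng(seed)
    table = table or RegionTable.default()
    heavy = NumberedChain.from_sequence(_random_seq(rng, 110), "H", table, germline_id=germline_h)
    light = NumberedChain.from_sequence(_random_seq(rng, 105), "L", table, germline_id=germline_l)
    return AntibodyFv(heavy, light)


def make_registry(path: str | Path | None, n_clusters: int = 53, seed: int = 0,
                  fv: AntibodyFv | None = None, table: RegionTable | None = None) -> pd.DataFrame:
    """A synthetic placeholder canonical-conformation registry.

    Entries cycle over the non-H3 CDRs with lengths matching the given
    Fv (so grafts are exercised at both equal and shifted lengths); H2
    and L1 rows carry DE-loop sequences.  Writes TSV when a path is
    given and returns the table.
    """
    rng = np.random.default_rng(seed)
    table = table or RegionTable.default()
    fv = fv or make_fv(seed=seed, table=table)
    cdr_types = ["H1", "H2", "L1", "L2", "L3"]
    rows = []
    for i in range(n_clusters):
        ct = cdr_types[i % len(cdr_types)]
        chain_tag, region_id = ct[0], f"CDR{ct[1]}"
        base_len = len(assign_regions(fv.chain(chain_tag), table)[region_id])
        length = base_len + int(rng.integers(-1, 2))
        length = max(3, length)
        de_len = len(assign_regions(fv.chain(chain_tag), table)["DE"])
        rows.append({
            "cluster_id": f"{ct}-syn-{i:02d}",
            "cdr_type": ct,
            "length": length,
            "sequence": _random_seq(rng, length),
            "de_loop": _random_seq(rng, de_len) if ct in ("H2", "L1") else "",
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
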