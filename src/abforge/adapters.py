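"""Adapter contracts isolating external structural-biology tools.

The optimization engine needs four capabilities: a modeler (sequence ->
backbone structure + loop torsions), a superposer (rigid placement of a
new antibody model onto the previous one inside the complex), a
minimizer, and a scorer.  In production these would be deep-learning
modelers, MD minimizers and physics scoring functions; here each
contract ships with a deterministic toy implementation good enough to
exercise every pipeline stage:

* ``toy_model`` builds a backbone by natural-extension (NeRF) chain
  growth from a fixed residue->(phi, psi) table, so any sequence change
  deterministically changes torsions and coordinates.
* ``superpose`` is an exact least-squares (Kabsch) rigid fit on shared
  backbone atoms; the antigen is never touched.
* ``toy_minimize`` relieves inter-chain clashes below 2 Å in a single
  deterministic pass.
* ``contact_scorer`` sums a shipped symmetric residue-pair weight table
  over antibody-antigen residue pairs within 8 Å (Cα); lower is better.
* ``surrogate_scorer`` scores sequence similarity to a hidden target
  paratope — a fast oracle for planted-solution recovery tests.

Real-tool adapters (subprocess or HTTP shims) can implement the same
contracts; they are intentionally not bundled.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import edlib
import gemmi
import numpy as np
import pandas as pd

from .errors import AdapterError, SequenceError
from .regions import AntibodyFv, RegionTable, assign_regions

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed per-residue backbone torsions (degrees).  Values are spread over
#: the Ramachandran-plausible range so every letter maps to a distinct
#: (phi, psi) pair; the table is a modeling convention, not a physical
#: prediction.
TORSION_TABLE: dict[str, tuple[float, float]] = {
    aa: (-160.0 + 13.0 * i, 170.0 - 16.0 * i) for i, aa in enumerate(AA_ORDER)
}

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


@dataclass
class Residue:
    number: int
    icode: str
    aa: str
    atoms: dict[str, np.ndarray]

    def copy(self) -> "Residue":
        return Residue(self.number, self.icode, self.aa, {k: v.copy() for k, v in self.atoms.items()})

    @property
    def ca(self) -> np.ndarray:
        try:
            return self.atoms["CA"]
        except KeyError:
            raise AdapterError(f"residue {self.number}{self.icode} lacks a CA atom") from None


@dataclass
class ComplexStructure:
    """A multi-chain backbone structure with declared Ab / Ag chain ids."""

    chains: dict[str, list[Residue]]
    antibody_ids: tuple[str, ...]
    antigen_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for cid in (*self.antibody_ids, *self.antigen_ids):
            if cid not in self.chains:
                raise AdapterError(f"declared chain {cid!r} absent from structure")
        for cid, residues in self.chains.items():
            for r in residues:
                for name, xyz in r.atoms.items():
                    if not np.all(np.isfinite(xyz)):
                        raise AdapterError(f"non-finite coordinates at {cid}/{r.number}/{name}")

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            {cid: [r.copy() for r in res] for cid, res in self.chains.items()},
            self.antibody_ids,
            self.antigen_ids,
        )


@dataclass
class ModelResult:
    """Modeler output: per-chain residues and per-chain (phi, psi) lists."""

    chains: dict[str, list[Residue]]
    torsions: dict[str, list[tuple[float, float]]]


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom D from internal coordinates (degrees)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor), bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(seq: str, phis: Sequence[float], psis: Sequence[float]) -> list[dict[str, np.ndarray]]:
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, len(seq)):
        prev = atoms[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, psis[i - 1])
        ca = _place_atom(prev["CA"], prev["C"], n, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        c = _place_atom(prev["C"], n, ca, _BOND_CA_C, _ANG_N_CA_C, phis[i])
        atoms.append({"N": n, "CA": ca, "C": c})
    return atoms


def toy_model(fv: AntibodyFv) -> ModelResult:
    """Deterministic pseudo-modeler: torsion-table lookup + NeRF backbone."""
    chains: dict[str, list[Residue]] = {}
    torsions: dict[str, list[tuple[float, float]]] = {}
    for chain in (fv.heavy, fv.light):
        seq = chain.sequence()
        bad = [aa for aa in seq if aa not in TORSION_TABLE]
        if bad:
            raise SequenceError(f"non-canonical residues {sorted(set(bad))}")
        tors = [TORSION_TABLE[aa] for aa in seq]
        phis = [t[0] for t in tors]
        psis = [t[1] for t in tors]
        backbone = _build_backbone(seq, phis, psis)
        chains[chain.chain_tag] = [
            Residue(p.number, p.insertion_code, p.residue, atoms)
            for p, atoms in zip(chain.positions, backbone)
        ]
        torsions[chain.chain_tag] = tors
    return ModelResult(chains=chains, torsions=torsions)


def loop_torsions(fv: AntibodyFv, chain_tag: str, region_id: str, table: RegionTable,
                  modeler: Callable[[AntibodyFv], ModelResult] = toy_model) -> list[tuple[float, float]]:
    """Torsions of one loop region under the given modeler."""
    from .regions import region_positions

    model = modeler(fv)
    idx = region_positions(fv.chain(chain_tag), region_id, table)
    return [model.torsions[chain_tag][i] for i in idx]


# ---------------------------------------------------------------------------
# Superposition

def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation R and translations so that R@(x-mc)+tc ≈ target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, mc, tc


def superpose(
    model: ModelResult,
    complex_structure: ComplexStructure,
    chain_map: Mapping[str, str],
) -> ComplexStructure:
    """Rigidly fit a new antibody model onto the previous antibody and
    swap it into the complex; antigen coordinates are untouched.

    ``chain_map`` maps model chain tags (H/L) to complex chain ids.  The
    fit uses backbone atoms of residues whose (number, insertion code)
    labels are shared between model and complex.
    """
    mob, tgt = [], []
    for tag, cid in chain_map.items():
        if cid not in complex_structure.chains:
            raise AdapterError(f"complex lacks declared antibody chain {cid!r}")
        old = {(r.number, r.icode): r for r in complex_structure.chains[cid]}
        for res in model.chains[tag]:
            prev = old.get((res.number, res.icode))
            if prev is None:
                continue
            for name in ("N", "CA", "C"):
                if name in res.atoms and name in prev.atoms:
                    mob.append(res.atoms[name])
                    tgt.append(prev.atoms[name])
    if not mob:
        raise AdapterError("no shared backbone atoms between model and complex antibody")
    r, mc, tc = _kabsch(np.array(mob), np.array(tgt))
    out = complex_structure.copy()
    for tag, cid in chain_map.items():
        placed = []
        for res in model.chains[tag]:
            atoms = {name: (r @ (xyz - mc)) + tc for name, xyz in res.atoms.items()}
            placed.append(Residue(res.number, res.icode, res.aa, atoms))
        out.chains[cid] = placed
    return out


def superpose_rmsd(a: Sequence[np.ndarray], b: Sequence[np.ndarray]) -> float:
    pa, pb = np.asarray(a), np.asarray(b)
    r, mc, tc = _kabsch(pa, pb)
    moved = (pa - mc) @ r.T + tc
    return float(np.sqrt(((moved - pb) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Minimization

_MIN_DIST = 2.0


def toy_minimize(complex_structure: ComplexStructure, min_dist: float = _MIN_DIST) -> ComplexStructure:
    """Single-pass clash relief: inter-chain atom pairs closer than
    ``min_dist`` are pushed apart along the pair vector to ``min_dist``
    (half the deficit each).  Identity on clash-free complexes."""
    from scipy.spatial import cKDTree

    out = complex_structure.copy()
    refs: list[np.ndarray] = []
    chain_idx: list[int] = []
    for k, cid in enumerate(sorted(out.chains)):
        for res in out.chains[cid]:
            for name in sorted(res.atoms):
                refs.append(res.atoms[name])
                chain_idx.append(k)
    coords = np.array(refs)
    cidx = np.array(chain_idx)
    shifts = np.zeros_like(coords)
    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(min_dist)):
        if cidx[i] == cidx[j]:
            continue
        v = coords[j] - coords[i]
        d = float(np.linalg.norm(v))
        if d == 0.0 or d >= min_dist:
            continue
        push = (min_dist - d) / 2.0
        u = v / d
        shifts[i] -= push * u
        shifts[j] += push * u
    for xyz, s in zip(refs, shifts):
        xyz += s
    return out


# ---------------------------------------------------------------------------
# Scoring

_weights_cache: pd.DataFrame | None = None


def contact_weights() -> pd.DataFrame:
    """Shipped symmetric 20x20 residue-pair weight table (negative =
    favorable: hydrophobic and charge-complementary pairs)."""
    global _weights_cache
    if _weights_cache is None:
        ref = importlib.resources.files("abforge.data") / "contact_weights.tsv"
        with importlib.resources.as_file(ref) as p:
            _weights_cache = pd.read_csv(p, sep="\t", index_col=0)
    return _weights_cache


def contact_scorer(complex_structure: ComplexStructure, cutoff: float = 8.0) -> float:
    """Sum pair weights over Ab-Ag residue pairs with Cα distance <= cutoff."""
    from scipy.spatial.distance import cdist

    w = contact_weights()
    wmat = w.to_numpy()
    aa_index = {aa: k for k, aa in enumerate(w.index)}
    total = 0.0
    for ab_id in complex_structure.antibody_ids:
        ab_res = complex_structure.chains[ab_id]
        ca_ab = np.array([r.ca for r in ab_res])
        ia = np.array([aa_index[r.aa] for r in ab_res])
        for ag_id in complex_structure.antigen_ids:
            ag_res = complex_structure.chains[ag_id]
            ca_ag = np.array([r.ca for r in ag_res])
            ig = np.array([aa_index[r.aa] for r in ag_res])
            close = cdist(ca_ab, ca_ag) <= cutoff
            ii, jj = np.nonzero(close)
            total += float(wmat[ia[ii], ig[jj]].sum())
    return total


@dataclass(frozen=True)
class ScorerContract:
    id: str
    fn: Callable[[ComplexStructure], float]
    lower_is_better: bool = True

    def __call__(self, complex_structure: ComplexStructure) -> float:
        return self.fn(complex_structure)


def make_surrogate_scorer(
    target: AntibodyFv,
    table: RegionTable | None = None,
    regions: Sequence[tuple[str, str]] | None = None,
) -> Callable[[AntibodyFv], float]:
    """Sequence-level scorer minimized exactly at a hidden target paratope.

    Score = -sum over configured (chain, region) pairs of
    ``len(target_region) - editdistance(current_region, target_region)``;
    the global minimum is minus the total target paratope length, and a
    single mismatch costs exactly +1.  By default only CDRs contribute,
    so framework edits leave the score unchanged.
    """
    table = table or RegionTable.default()
    if regions is None:
        regions = [(ct, f"CDR{i}") for ct in ("H", "L") for i in (1, 2, 3)]
    target_regions = {
        (ct, rid): assign_regions(target.chain(ct), table)[rid] for ct, rid in regions
    }

    def score(fv: AntibodyFv) -> float:
        total = 0.0
        for (ct, rid), tseq in target_regions.items():
            cur = assign_regions(fv.chain(ct), table)[rid]
            dist = edlib.align(cur, tseq, task="distance")["editDistance"]
            total -= len(tseq) - dist
        return total

    return score


def surrogate_optimum(target: AntibodyFv, table: RegionTable | None = None,
                      regions: Sequence[tuple[str, str]] | None = None) -> float:
    """The minimum value the matching surrogate scorer can reach."""
    table = table or RegionTable.default()
    if regions is None:
        regions = [(ct, f"CDR{i}") for ct in ("H", "L") for i in (1, 2, 3)]
    return -float(sum(len(assign_regions(target.chain(ct), table)[rid]) for ct, rid in regions))


# ---------------------------------------------------------------------------
# PDB I/O (standard columns, single model, no altlocs)

def write_pdb(path: str | Path, complex_structure: ComplexStructure) -> None:
    st = gemmi.Structure()
    st.name = "abforge"
    model = gemmi.Model("1")
    aa3 = gemmi.ResidueInfo
    for cid in sorted(complex_structure.chains):
        chain = gemmi.Chain(cid)
        for res in complex_structure.chains[cid]:
            r = gemmi.Residue()
            r.name = gemmi.expand_one_letter(res.aa, gemmi.ResidueKind.AA) or "UNK"
            r.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for name in ("N", "CA", "C"):
                if name not in res.atoms:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("C" if name != "N" else "N")
                x, y, z = (float(v) for v in res.atoms[name])
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = 0.0
                r.add_atom(atom)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path: str | Path, antibody_ids: Sequence[str], antigen_ids: Sequence[str]) -> ComplexStructure:
    st = gemmi.read_structure(str(path))
    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            one = gemmi.find_tabulated_residue(res.name)
            aa = one.one_letter_code.upper() if one else "X"
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            icode = res.seqid.icode.strip()
            residues.append(Residue(res.seqid.num, icode, aa, atoms))
        chains[chain.name] = residues
    return ComplexStructure(chains, tuple(antibody_ids), tuple(antigen_ids))
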