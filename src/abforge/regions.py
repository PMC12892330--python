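"""Antibody variable regions under a fixed numbering scheme.

Chains are represented as ordered lists of scheme-labeled positions
(Martin-style numbering: integer position plus optional insertion code).
Region boundaries (FR1..FR4, CDR1..3 and the DE loop) are shipped as an
editable data table rather than hard-coded, so boundary disputes are
configuration changes.  Numbering itself is consumed, not computed: chains
arrive pre-numbered, or the simplified length-proportional fallback
numberer is used for synthetic inputs.
"""

from __future__ import annotations

import importlib.resources
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import RegionError, SequenceError

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Region identifiers in N→C order along the variable domain.  FR3 is
#: split around the DE loop (a short framework-3 loop, sometimes called
#: CDR4, that modulates the conformations of CDR-H2 and CDR-L1).
REGION_IDS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "DE", "CDR3", "FR4")
CDR_IDS = ("CDR1", "CDR2", "CDR3")


@dataclass(frozen=True)
class NumberedPosition:
    """A single scheme-labeled residue position."""

    chain_tag: str
    number: int
    insertion_code: str
    residue: str

    def __post_init__(self) -> None:
        if self.chain_tag not in ("H", "L"):
            raise SequenceError(f"chain_tag must be H or L, got {self.chain_tag!r}")
        if self.number < 1:
            raise SequenceError(f"position number must be positive, got {self.number}")
        if self.insertion_code and (
            len(self.insertion_code) != 1 or self.insertion_code not in string.ascii_uppercase
        ):
            raise SequenceError(f"bad insertion code {self.insertion_code!r}")
        if self.residue not in CANONICAL_AA:
            raise SequenceError(f"non-canonical residue {self.residue!r} at {self.label}")

    @property
    def label(self) -> str:
        return f"{self.chain_tag}{self.number}{self.insertion_code}"

    @property
    def sort_key(self) -> tuple[int, str]:
        # blank insertion code sorts before A, B, ...
        return (self.number, self.insertion_code)


class RegionTable:
    """Scheme region boundaries: ``(chain_tag, region_id) -> intervals``.

    Intervals are inclusive 1-based ``(start, end)`` pairs on the integer
    part of the position label; insertion-coded positions inherit the
    region of their integer parent.  A table may carry several variants
    (``default`` and ``expanded``); ``variant()`` views one of them.
    """

    def __init__(
        self,
        scheme: str,
        intervals: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
        variant_name: str = "default",
    ) -> None:
        self.scheme = scheme
        self.variant_name = variant_name
        self._intervals = {k: tuple(v) for k, v in intervals.items()}
        self._validate()

    def _validate(self) -> None:
        for chain_tag in ("H", "L"):
            spans = []
            for rid in REGION_IDS:
                for (s, e) in self._intervals.get((chain_tag, rid), ()):
                    if s > e:
                        raise RegionError(f"inverted interval {s}-{e} for {chain_tag}/{rid}")
                    spans.append((s, e, rid))
            spans.sort()
            for (s1, e1, r1), (s2, e2, r2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise RegionError(
                        f"overlapping intervals on chain {chain_tag}: {r1} {s1}-{e1} vs {r2} {s2}-{e2}"
                    )

    def intervals(self, chain_tag: str, region_id: str) -> tuple[tuple[int, int], ...]:
        try:
            return self._intervals[(chain_tag, region_id)]
        except KeyError:
            raise RegionError(f"region {region_id!r} absent for chain {chain_tag}") from None

    def region_of(self, chain_tag: str, number: int) -> str | None:
        for rid in REGION_IDS:
            for (s, e) in self._intervals.get((chain_tag, rid), ()):
                if s <= number <= e:
                    return rid
        return None

    def max_number(self, chain_tag: str) -> int:
        return max(e for (ct, _), ivs in self._intervals.items() if ct == chain_tag for (_, e) in ivs)

    @classmethod
    def from_tsv(cls, path: str | Path, variant: str = "default", scheme: str = "martin") -> "RegionTable":
        df = pd.read_csv(path, sep="\t", dtype={"chain_tag": str, "variant": str, "region_id": str})
        required = {"chain_tag", "variant", "region_id", "start", "end"}
        if not required.issubset(df.columns):
            raise RegionError(f"region table missing columns {sorted(required - set(df.columns))}")
        sub = df[df["variant"] == variant]
        if sub.empty:
            raise RegionError(f"variant {variant!r} not present in {path}")
        intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for row in sub.itertuples():
            intervals.setdefault((row.chain_tag, row.region_id), []).append((int(row.start), int(row.end)))
        return cls(scheme, intervals, variant_name=variant)

    @classmethod
    def default(cls, variant: str = "default") -> "RegionTable":
        """The Martin-scheme table shipped with the package."""
        ref = importlib.resources.files("abforge.data") / "martin_regions.tsv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_tsv(p, variant=variant)


@dataclass(frozen=True)
class NumberedChain:
    """An antibody variable-domain chain as ordered numbered positions."""

    chain_tag: str
    positions: tuple[NumberedPosition, ...]
    germline_id: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise SequenceError("empty chain")
        keys = [p.sort_key for p in self.positions]
        if keys != sorted(keys):
            raise SequenceError(f"chain {self.chain_tag} positions out of order")
        if len(set(keys)) != len(keys):
            raise SequenceError(f"duplicate position labels in chain {self.chain_tag}")
        for p in self.positions:
            if p.chain_tag != self.chain_tag:
                raise SequenceError(f"position {p.label} does not belong to chain {self.chain_tag}")

    def sequence(self) -> str:
        return "".join(p.residue for p in self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_sequence(
        cls,
        seq: str,
        chain_tag: str,
        table: RegionTable | None = None,
        germline_id: str = "",
    ) -> "NumberedChain":
        """Length-proportional fallback numberer.

        Spreads the residues evenly over the scheme's label range so every
        region receives occupancy roughly proportional to its width.  A
        stand-in for alignment-based numbering, adequate for synthetic
        chains; real chains should arrive pre-numbered.
        """
        table = table or RegionTable.default()
        seq = seq.upper()
        bad = set(seq) - CANONICAL_AA
        if bad:
            raise SequenceError(f"non-canonical residues {sorted(bad)}")
        n_max = table.max_number(chain_tag)
        n = len(seq)
        if n > n_max:
            raise SequenceError(f"sequence length {n} exceeds scheme range {n_max}")
        if n < len(REGION_IDS):
            raise SequenceError(f"sequence length {n} too short to cover all regions")
        # evenly spaced distinct integer labels in [1, n_max]
        numbers = sorted({round(1 + i * (n_max - 1) / (n - 1)) for i in range(n)})
        # rounding collisions: fill from unused labels closest to the gaps
        free = [k for k in range(1, n_max + 1) if k not in set(numbers)]
        while len(numbers) < n:
            numbers.append(free.pop(0))
            numbers.sort()
        positions = tuple(
            NumberedPosition(chain_tag, num, "", aa) for num, aa in zip(numbers, seq)
        )
        return cls(chain_tag, positions, germline_id=germline_id)


@dataclass(frozen=True)
class AntibodyFv:
    """Paired heavy and light variable domains."""

    heavy: NumberedChain
    light: NumberedChain

    def __post_init__(self) -> None:
        if self.heavy.chain_tag != "H":
            raise SequenceError("heavy chain must carry tag H")
        if self.light.chain_tag != "L":
            raise SequenceError("light chain must carry tag L")

    def chain(self, tag: str) -> NumberedChain:
        if tag == "H":
            return self.heavy
        if tag == "L":
            return self.light
        raise SequenceError(f"unknown chain tag {tag!r}")

    def with_chain(self, chain: NumberedChain) -> "AntibodyFv":
        if chain.chain_tag == "H":
            return AntibodyFv(chain, self.light)
        return AntibodyFv(self.heavy, chain)


def assign_regions(chain: NumberedChain, table: RegionTable) -> dict[str, str]:
    """Partition a chain into its named region subsequences.

    Returns ``region_id -> subsequence``; concatenating the regions in
    chain order reproduces ``chain.sequence()``.  Every region of the
    table must be occupied — a chain lacking, e.g., DE-loop labels is an
    error naming the first missing label.
    """
    out: dict[str, list[str]] = {rid: [] for rid in REGION_IDS}
    for p in chain.positions:
        rid = table.region_of(chain.chain_tag, p.number)
        if rid is None:
            raise RegionError(f"position {p.label} falls outside every region interval")
        out[rid].append(p.residue)
    for rid in REGION_IDS:
        if not out[rid]:
            first = table.intervals(chain.chain_tag, rid)[0][0]
            raise RegionError(
                f"region {rid} has no positions on chain {chain.chain_tag}; "
                f"first missing label {chain.chain_tag}{first}"
            )
    return {rid: "".join(chars) for rid, chars in out.items()}


def region_positions(chain: NumberedChain, region_id: str, table: RegionTable) -> list[int]:
    """Indices (into chain.positions) belonging to a region, in order."""
    idx = [
        i
        for i, p in enumerate(chain.positions)
        if table.region_of(chain.chain_tag, p.number) == region_id
    ]
    if not idx:
        raise RegionError(f"region {region_id} empty on chain {chain.chain_tag}")
    return idx


def _next_insertion_codes(existing: set[str], k: int) -> list[str]:
    codes = []
    for letter in string.ascii_uppercase:
        if letter not in existing:
            codes.append(letter)
        if len(codes) == k:
            return codes
    raise SequenceError("insertion-code alphabet exhausted")


def replace_region(
    chain: NumberedChain,
    region_id: str,
    new_seq: str,
    table: RegionTable | None = None,
) -> NumberedChain:
    """Graft ``new_seq`` into a region, keeping all other labels fixed.

    Length-changing grafts edit labels at the region's insertion anchor
    (the region midpoint): insertions gain insertion-coded labels there,
    deletions remove the labels nearest the anchor first.  Flanking
    regions are never relabeled.
    """
    table = table or RegionTable.default()
    new_seq = new_seq.upper()
    if not new_seq:
        raise SequenceError("replacement sequence must be non-empty")
    bad = set(new_seq) - CANONICAL_AA
    if bad:
        raise SequenceError(f"non-canonical residues {sorted(bad)}")
    idx = region_positions(chain, region_id, table)
    labels = [(chain.positions[i].number, chain.positions[i].insertion_code) for i in idx]
    delta = len(new_seq) - len(labels)
    anchor = (len(labels) - 1) // 2
    if delta > 0:
        # anchor after the last label sharing the anchor's integer number,
        # so inserted codes stay sorted
        anum = labels[anchor][0]
        while anchor + 1 < len(labels) and labels[anchor + 1][0] == anum:
            anchor += 1
        used = {ic for (num, ic) in labels if num == anum and ic}
        codes = _next_insertion_codes(used, delta)
        for j, code in enumerate(codes):
            labels.insert(anchor + 1 + j, (anum, code))
    elif delta < 0:
        if len(new_seq) < 1:
            raise SequenceError("cannot delete entire region")
        drop = sorted(range(len(labels)), key=lambda i: (abs(i - anchor), i))[: -delta]
        labels = [lab for i, lab in enumerate(labels) if i not in set(drop)]
    region_pos = [
        NumberedPosition(chain.chain_tag, num, ic, aa) for (num, ic), aa in zip(labels, new_seq)
    ]
    before = [chain.positions[i] for i in range(idx[0])]
    after = [chain.positions[i] for i in range(idx[-1] + 1, len(chain.positions))]
    # region intervals may be split (FR3 around DE): interior non-region
    # positions must be preserved in place
    interior = [
        chain.positions[i]
        for i in range(idx[0], idx[-1] + 1)
        if i not in set(idx)
    ]
    merged = sorted(region_pos + interior, key=lambda p: p.sort_key)
    return NumberedChain(chain.chain_tag, tuple(before + merged + after), chain.germline_id)


def graft_fv(
    fv: AntibodyFv,
    chain_tag: str,
    region_id: str,
    new_seq: str,
    table: RegionTable | None = None,
) -> AntibodyFv:
    """Convenience: replace one region on one chain of an Fv."""
    return fv.with_chain(replace_region(fv.chain(chain_tag), region_id, new_seq, table))


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_numbered_chain_tsv(path: str | Path, germline_id: str = "") -> NumberedChain:
    """Read a pre-numbered chain (columns chain_tag, number, insertion_code, residue)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    required = {"chain_tag", "number", "insertion_code", "residue"}
    if not required.issubset(df.columns):
        raise SequenceError(f"numbered-chain TSV missing columns {sorted(required - set(df.columns))}")
    positions = tuple(
        NumberedPosition(r.chain_tag, int(r.number), r.insertion_code, r.residue)
        for r in df.itertuples()
    )
    return NumberedChain(positions[0].chain_tag, positions, germline_id=germline_id)


def write_numbered_chain_tsv(path: str | Path, chain: NumberedChain) -> None:
    rows = [
        {"chain_tag": p.chain_tag, "number": p.number, "insertion_code": p.insertion_code, "residue": p.residue}
        for p in chain.positions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
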