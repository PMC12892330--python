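"""Optimization dataset construction from annotated repertoire tables.

Implements the filtering and redundancy-reduction rules that build the
pipeline's sequence pools: a naive CDR pool clustered at 40% identity
(broad chemical-space exploration, mimicking V(D)J recombination), the
memory framework dataset (all filtered memory records), and its mutated
subset — records with at least four framework mutations relative to the
IMGT germline, at least one of which sits at a "special" position known
to influence CDR conformation or the VH–VL packing angle (Vernier zone
and chain-interface residues).

Clustering is a deterministic greedy centroid pass (longest-first,
lexicographic tie-break, inclusive identity threshold with the longer
sequence as denominator), so results are reproducible without any
external clustering tool.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .errors import ConfigurationError, DatasetError

CDR_KEYS = ("CDR1", "CDR2", "CDR3")
POOL_KEYS = ("H1", "H2", "H3", "L1", "L2", "L3")


@dataclass
class RepertoireRecord:
    """One observed antibody sequence with its annotations."""

    record_id: str
    chain_tag: str
    cell_origin: str           # naive | memory
    isotype: str               # IgM, IgG, ...
    donor_status: str          # healthy | other
    germline_id: str
    sequence: str
    cdrs: dict[str, str]       # CDR1..CDR3 subsequences
    framework: str             # concatenated framework (incl. DE loop)
    framework_regions: dict[str, str] = field(default_factory=dict)  # FR1,FR2,FR3,DE,FR4


@dataclass(frozen=True)
class ClusterResult:
    threshold: float
    representatives: tuple[str, ...]
    assignment: Mapping[str, str]  # member id -> representative id

    def __post_init__(self) -> None:
        reps = set(self.representatives)
        for member, rep in self.assignment.items():
            if rep not in reps:
                raise DatasetError(f"member {member} assigned to unknown representative {rep}")
        for rep in reps:
            if self.assignment.get(rep) != rep:
                raise DatasetError(f"representative {rep} does not map to itself")


@dataclass(frozen=True)
class PoolEntry:
    """A representative CDR sequence in an optimization pool."""

    sequence: str
    germline_id: str = ""
    de_loop: str = ""
    source_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CanonicalEntry:
    """A canonical-conformation representative for a non-H3 CDR."""

    cluster_id: str
    cdr_type: str  # H1, H2, L1, L2, L3
    length: int
    sequence: str
    de_loop: str = ""
    torsions: tuple[tuple[float, float], ...] = ()


# ---------------------------------------------------------------------------
# Filtering

_REQUIRED_FIELDS = ("cell_origin", "isotype", "donor_status", "chain_tag")


def filter_repertoire(records: Iterable[RepertoireRecord], group: str) -> list[RepertoireRecord]:
    """Select the naive or memory subgroup after quality filters.

    Keeps healthy-donor records of the requested cell origin with all
    three CDRs present; the memory group additionally excludes IgM
    isotypes (low-specificity, low-affinity antibodies).  The health,
    CDR-completeness and isotype filters commute.
    """
    if group not in ("naive", "memory"):
        raise ConfigurationError(f"group must be naive or memory, got {group!r}")
    out = []
    for rec in records:
        for f in _REQUIRED_FIELDS:
            if not getattr(rec, f, None):
                raise DatasetError(f"record {rec.record_id}: missing annotation {f!r}")
        if rec.donor_status != "healthy":
            continue
        if any(not rec.cdrs.get(k) for k in CDR_KEYS):
            continue
        if rec.cell_origin != group:
            continue
        if group == "memory" and rec.isotype == "IgM":
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Clustering

_match_aligner = Align.PairwiseAligner()
_match_aligner.mode = "global"
_match_aligner.match_score = 1.0
_match_aligner.mismatch_score = 0.0
_match_aligner.open_gap_score = 0.0
_match_aligner.extend_gap_score = 0.0


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity with the longer sequence as denominator.

    Equal lengths compare ungapped; unequal lengths count matches under
    a free-gap global alignment.
    """
    if not a or not b:
        raise DatasetError("cannot compare empty sequences")
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
    else:
        matches = _match_aligner.score(a, b)
    return 100.0 * matches / max(len(a), len(b))


def greedy_identity_cluster(
    seqs: Mapping[str, str] | Sequence[str],
    threshold_pct: float,
) -> ClusterResult:
    """Deterministic greedy centroid clustering at a percent-identity threshold.

    Sequences are processed longest-first (ties lexicographic by
    sequence, then id); each joins the first representative at identity
    >= threshold (inclusive), else founds a new cluster.  Idempotent on
    its own representatives.
    """
    if not 0 < threshold_pct <= 100:
        raise ConfigurationError(f"threshold must be in (0, 100], got {threshold_pct}")
    if isinstance(seqs, Mapping):
        items = list(seqs.items())
    else:
        items = [(str(i), s) for i, s in enumerate(seqs)]
    if not items:
        raise DatasetError("empty input to clustering")
    items.sort(key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    reps: list[tuple[str, str]] = []
    assignment: dict[str, str] = {}
    for sid, seq in items:
        for rid, rseq in reps:
            if pairwise_identity(seq, rseq) >= threshold_pct:
                assignment[sid] = rid
                break
        else:
            reps.append((sid, seq))
            assignment[sid] = sid
    return ClusterResult(
        threshold=threshold_pct,
        representatives=tuple(r for r, _ in reps),
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# Pools and framework datasets

def build_ncdr(
    naive_records: Sequence[RepertoireRecord],
    threshold_pct: float = 40.0,
) -> dict[str, list[PoolEntry]]:
    """Build the naive CDR pools, clustered per CDR at 40% identity.

    Returns pools keyed H1..H3, L1..L3; entries carry the representative
    sequence with the germline of its source record.
    """
    pools: dict[str, list[PoolEntry]] = {k: [] for k in POOL_KEYS}
    by_key: dict[str, dict[str, RepertoireRecord]] = {k: {} for k in POOL_KEYS}
    for rec in naive_records:
        for i, cdr_key in enumerate(CDR_KEYS, start=1):
            pool_key = f"{rec.chain_tag}{i}"
            seq = rec.cdrs.get(cdr_key)
            if seq:
                by_key[pool_key].setdefault(f"{rec.record_id}/{cdr_key}", rec)
    for pool_key in POOL_KEYS:
        members = by_key[pool_key]
        if not members:
            continue
        cdr_idx = int(pool_key[1])
        seqmap = {mid: rec.cdrs[f"CDR{cdr_idx}"] for mid, rec in members.items()}
        result = greedy_identity_cluster(seqmap, threshold_pct)
        for rid in result.representatives:
            rec = members[rid]
            pools[pool_key].append(
                PoolEntry(sequence=seqmap[rid], germline_id=rec.germline_id, source_id=rid)
            )
    return pools


_blosum_aligner = Align.PairwiseAligner()
_blosum_aligner.mode = "global"
_blosum_aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
_blosum_aligner.open_gap_score = -10.0
_blosum_aligner.extend_gap_score = -0.5


def align_to_germline(seq: str, germline: str) -> tuple[str, str]:
    """Global alignment of a sequence against its germline (gapped strings)."""
    aln = _blosum_aligner.align(seq, germline)[0]
    return str(aln[0]), str(aln[1])


def mutation_events(seq: str, germline: str) -> list[tuple[int, str, str]]:
    """Mutation events vs the germline, in germline coordinates (1-based).

    Substitutions are one event each; a contiguous gap run (on either
    side) is one indel event, reported at the last germline position
    before/within the run with residue symbol ``-``.
    """
    a, g = align_to_germline(seq, germline)
    events: list[tuple[int, str, str]] = []
    gi = 0
    in_gap = False
    for x, y in zip(a, g):
        if y != "-":
            gi += 1
        if x == "-" or y == "-":
            if not in_gap:
                events.append((max(gi, 1), y if y != "-" else "-", "-"))
                in_gap = True
            continue
        in_gap = False
        if x != y:
            events.append((gi, y, x))
    return events


def count_germline_mutations(
    record: RepertoireRecord | str,
    germline_seq: str,
    framework_only: bool = True,
) -> int:
    """Count mutation events relative to the germline.

    With ``framework_only`` the record's framework concatenation is
    compared against the germline framework (CDR columns are excluded by
    construction).  One contiguous gap counts as a single event.
    """
    if isinstance(record, RepertoireRecord):
        seq = record.framework if framework_only else record.sequence
    else:
        seq = record
    if not germline_seq:
        raise DatasetError("germline sequence not found")
    return len(mutation_events(seq, germline_seq))


@dataclass(frozen=True)
class FrameworkDatasets:
    """Memory framework dataset and its mutated subset (Mu ⊆ Me)."""

    me_fwk: tuple[RepertoireRecord, ...]
    mu_fwk: tuple[RepertoireRecord, ...]


def load_special_positions(path: str | Path | None = None) -> set[str]:
    """Position labels (e.g. ``H71``) whose mutation can shift CDR
    conformation or the VH–VL angle; default list transcribed from the
    Vernier-zone / chain-interface literature."""
    if path is None:
        ref = importlib.resources.files("abforge.data") / "special_positions.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return {f"{r.chain_tag}{r.position}" for r in df.itertuples()}


def build_mufwk(
    memory_records: Sequence[RepertoireRecord],
    germlines: Mapping[str, str],
    special_positions: set[str],
    min_mutations: int = 4,
) -> FrameworkDatasets:
    """Split filtered memory records into Me-FWK and its Mu-FWK subset.

    Me-FWK is every filtered memory record.  Mu-FWK retains records with
    at least ``min_mutations`` framework mutation events against their
    germline framework AND at least one substitution at a special
    position (germline framework coordinates, labeled ``<chain><pos>``).
    """
    if not special_positions:
        raise ConfigurationError("special-position set is empty")
    mu = []
    for rec in memory_records:
        try:
            germ = germlines[rec.germline_id]
        except KeyError:
            raise DatasetError(f"germline {rec.germline_id!r} not found for record {rec.record_id}") from None
        events = mutation_events(rec.framework, germ)
        if len(events) < min_mutations:
            continue
        labels = {f"{rec.chain_tag}{pos}" for pos, _old, new in events if new != "-"}
        if labels & special_positions:
            mu.append(rec)
    return FrameworkDatasets(me_fwk=tuple(memory_records), mu_fwk=tuple(mu))


# ---------------------------------------------------------------------------
# Canonical-conformation registry

_DE_REQUIRED = ("H2", "L1")


def load_canonical_registry(path: str | Path) -> list[CanonicalEntry]:
    """Load and validate a canonical-conformation registry TSV.

    Required columns: cluster_id, cdr_type, length, sequence; optional
    de_loop (mandatory for H2/L1 entries, whose conformation couples to
    the DE loop).  Rejects duplicate cluster ids and rows whose sequence
    length disagrees with the declared length.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"cluster_id", "cdr_type", "length", "sequence"}
    if not required.issubset(df.columns):
        raise DatasetError(f"registry missing columns {sorted(required - set(df.columns))}")
    entries: list[CanonicalEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        if row.cluster_id in seen:
            raise DatasetError(f"line {i}: duplicate cluster_id {row.cluster_id!r}")
        seen.add(row.cluster_id)
        if row.cdr_type not in ("H1", "H2", "L1", "L2", "L3"):
            raise DatasetError(f"line {i}: cdr_type {row.cdr_type!r} is not a non-H3 CDR")
        try:
            length = int(row.length)
        except ValueError:
            raise DatasetError(f"line {i}: length {row.length!r} is not an integer") from None
        if len(row.sequence) != length:
            raise DatasetError(
                f"line {i}: sequence length {len(row.sequence)} != declared length {length}"
            )
        de_loop = getattr(row, "de_loop", "")
        if row.cdr_type in _DE_REQUIRED and not de_loop:
            raise DatasetError(f"line {i}: {row.cdr_type} entry requires a DE-loop sequence")
        entries.append(
            CanonicalEntry(
                cluster_id=row.cluster_id,
                cdr_type=row.cdr_type,
                length=length,
                sequence=row.sequence,
                de_loop=de_loop,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Repertoire table I/O (AIRR-like TSV)

_AIRR_COLUMNS = {
    "record_id": "sequence_id",
    "chain_tag": "chain",
    "cell_origin": "cell_origin",
    "isotype": "isotype",
    "donor_status": "donor_status",
    "germline_id": "v_call",
    "sequence": "sequence_aa",
    "CDR1": "cdr1_aa",
    "CDR2": "cdr2_aa",
    "CDR3": "cdr3_aa",
    "framework": "framework_aa",
}


def read_repertoire_tsv(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[RepertoireRecord]:
    cmap = dict(_AIRR_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise DatasetError(f"repertoire TSV missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        records.append(
            RepertoireRecord(
                record_id=r[cmap["record_id"]],
                chain_tag=r[cmap["chain_tag"]],
                cell_origin=r[cmap["cell_origin"]],
                isotype=r[cmap["isotype"]],
                donor_status=r[cmap["donor_status"]],
                germline_id=r[cmap["germline_id"]],
                sequence=r[cmap["sequence"]],
                cdrs={k: r[cmap[k]] for k in CDR_KEYS},
                framework=r[cmap["framework"]],
            )
        )
    return records


def write_repertoire_tsv(path: str | Path, records: Sequence[RepertoireRecord]) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "sequence_id": rec.record_id,
                "chain": rec.chain_tag,
                "cell_origin": rec.cell_origin,
                "isotype": rec.isotype,
                "donor_status": rec.donor_status,
                "v_call": rec.germline_id,
                "sequence_aa": rec.sequence,
                "cdr1_aa": rec.cdrs.get("CDR1", ""),
                "cdr2_aa": rec.cdrs.get("CDR2", ""),
                "cdr3_aa": rec.cdrs.get("CDR3", ""),
                "framework_aa": rec.framework,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pool_fasta(path: str | Path, pool: Sequence[PoolEntry], pool_key: str) -> None:
    from .regions import write_fasta

    write_fasta(path, {f"{pool_key}_{i}|{e.germline_id}": e.sequence for i, e in enumerate(pool)})
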