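"""Repertoire diversity analytics.

Diversity is measured with Hill numbers — the "effective number of
species" ``D_q = (sum_i p_i^q)^(1/(1-q))``, with ``q=1`` taken as the
limit ``exp(H_Shannon)``.  Gamma diversity treats each CDR type as one
pooled population; alpha diversity is computed per position within CDRs
of fixed type and length.  Per-CDR gamma values are converted into
modification-site selection probabilities by a configurable power
weighting; germline mutation frequencies are computed from gapped
sequence/germline alignments, optionally under a reduced amino-acid
alphabet (Murphy 10-group) so that only class-changing substitutions
are counted.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .errors import ConfigurationError, DatasetError, SequenceError

SequenceCounts = Mapping[str, int]


def hill_diversity(counts: SequenceCounts, q: float = 1.0) -> float:
    """Hill number of order ``q`` of an abundance vector.

    ``q=0`` is richness, ``q=1`` the exponential of Shannon entropy,
    ``q=2`` the inverse Simpson concentration.  Always between 1 and the
    number of distinct sequences.
    """
    if q < 0:
        raise ConfigurationError(f"diversity order q must be non-negative, got {q}")
    if not counts:
        raise DatasetError("empty abundance vector")
    n = np.asarray(list(counts.values()), dtype=float)
    if (n < 1).any():
        raise DatasetError("abundance counts must be >= 1")
    p = n / n.sum()
    if q == 0:
        return float(len(p))
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(entropy(p)))
    return float(np.power(np.sum(p**q), 1.0 / (1.0 - q)))


@dataclass(frozen=True)
class DiversityProfile:
    """Per-CDR effective (gamma) diversities and site-selection probabilities."""

    d: dict[str, float]
    p: dict[str, float]
    q: float

    def __post_init__(self) -> None:
        total = sum(self.p.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"selection probabilities sum to {total}, not 1")


def selection_probabilities(
    d: Mapping[str, float],
    weight_exponent: float = 1.0,
    caps: Mapping[str, float] | None = None,
    custom: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Turn per-site diversities into selection probabilities.

    ``p_site ∝ D_site^w``; an optional per-site probability cap redistributes
    excess mass proportionally (CDR3's gamma diversity can otherwise
    monopolize site selection).  ``custom`` overrides everything.
    """
    if custom is not None:
        total = sum(custom.values())
        if total <= 0:
            raise ConfigurationError("custom probabilities must have positive mass")
        return {k: v / total for k, v in custom.items()}
    w = np.array([d[k] ** weight_exponent for k in d], dtype=float)
    if w.sum() <= 0:
        raise ConfigurationError("all diversities zero; cannot derive probabilities")
    p = dict(zip(d.keys(), w / w.sum()))
    if caps:
        for _ in range(50):
            over = {k: caps[k] for k in p if k in caps and p[k] > caps[k]}
            if not over:
                break
            excess = sum(p[k] - over[k] for k in over)
            for k in over:
                p[k] = over[k]
            free = [k for k in p if k not in over]
            mass = sum(p[k] for k in free)
            for k in free:
                p[k] += excess * p[k] / mass
    return p


def gamma_by_cdr(
    repertoire: Sequence,
    cdr_ids: Sequence[str],
    q: float = 1.0,
    weight_exponent: float = 1.0,
    caps: Mapping[str, float] | None = None,
    custom_probs: Mapping[str, float] | None = None,
) -> DiversityProfile:
    """Gamma diversity per CDR over the pooled multiset of its sequences.

    Each record must expose a ``cdrs`` mapping carrying every requested
    CDR id.
    """
    if not repertoire:
        raise DatasetError("empty repertoire")
    d: dict[str, float] = {}
    for cid in cdr_ids:
        counts: Counter[str] = Counter()
        for rec in repertoire:
            try:
                seq = rec.cdrs[cid]
            except (AttributeError, KeyError):
                raise DatasetError(f"record missing CDR column {cid!r}") from None
            if not seq:
                raise DatasetError(f"record has empty CDR {cid!r}")
            counts[seq] += 1
        d[cid] = hill_diversity(counts, q)
    p = selection_probabilities(d, weight_exponent, caps, custom_probs)
    return DiversityProfile(d=d, p=p, q=q)


@dataclass
class PositionProfile:
    """Per-position diversity for one CDR type at one fixed length."""

    cdr_id: str
    length: int
    alpha: np.ndarray                       # per-position Hill diversity
    residue_freqs: list[dict[str, float]]   # per-position residue frequency vectors
    mutation_freqs: list[dict[str, float]] = field(default_factory=list)
    germline: str = ""
    class_changing: list[bool] = field(default_factory=list)
    q: float = 1.0

    def __post_init__(self) -> None:
        if len(self.alpha) != self.length or len(self.residue_freqs) != self.length:
            raise ConfigurationError("profile arrays must have one entry per position")
        for f in self.residue_freqs:
            if f and abs(sum(f.values()) - 1.0) > 1e-9:
                raise ConfigurationError("residue frequency vector does not sum to 1")


def alpha_by_position(seqs: Sequence[str], cdr_id: str = "", q: float = 1.0) -> PositionProfile:
    """Per-position alpha diversity of equal-length CDR sequences.

    Uses residue-level counts at each column, so a column occupied by a
    single residue has alpha 1 and a uniformly occupied column has alpha
    equal to the number of residues observed.
    """
    if not seqs:
        raise DatasetError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise DatasetError(f"mixed sequence lengths {sorted(lengths)}; restrict to one length")
    L = lengths.pop()
    alpha = np.empty(L)
    freqs: list[dict[str, float]] = []
    for i in range(L):
        col = Counter(s[i] for s in seqs)
        alpha[i] = hill_diversity(col, q)
        total = sum(col.values())
        freqs.append({aa: c / total for aa, c in sorted(col.items())})
    return PositionProfile(cdr_id=cdr_id, length=L, alpha=alpha, residue_freqs=freqs, q=q)


@dataclass(frozen=True)
class ReducedAlphabet:
    """A total mapping of the 20 canonical letters onto group symbols."""

    name: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.mapping)
        if missing:
            raise ConfigurationError(f"alphabet {self.name!r} missing letters {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "ReducedAlphabet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"letter", "group"}.issubset(df.columns):
            raise ConfigurationError("reduced-alphabet TSV needs columns letter, group")
        return cls(name or Path(path).stem, dict(zip(df["letter"], df["group"])))

    @classmethod
    def murphy10(cls) -> "ReducedAlphabet":
        """The 10-group reduction: LVIM / C / A / G / ST / P / FYW / EDNQ / KR / H."""
        ref = importlib.resources.files("abforge.data") / "murphy10.tsv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_tsv(p, name="murphy10")


def reduce(seq: str, alphabet: ReducedAlphabet) -> str:
    """Map a sequence onto the reduced alphabet; idempotent for group symbols."""
    out = []
    for aa in seq:
        if aa in alphabet.mapping:
            out.append(alphabet.mapping[aa])
        elif aa in set(alphabet.mapping.values()):
            out.append(aa)  # already a group symbol
        else:
            raise SequenceError(f"letter {aa!r} not covered by alphabet {alphabet.name!r}")
    return "".join(out)


def mutation_frequencies(
    aligned_pairs: Sequence[tuple[str, str]],
    cdr_id: str = "",
    alphabet: ReducedAlphabet | None = None,
) -> PositionProfile:
    """Per-germline-position mutation frequencies from gapped alignments.

    Each pair is ``(observed, germline)`` of equal gapped length.
    Frequencies at position i are counts of each non-germline residue
    divided by the number of records; identity columns contribute no
    mutated mass.  Under a reduced alphabet, substitutions within a
    group are not counted (only class-changing mutations remain) and the
    per-position ``class_changing`` flag marks positions with any such
    mutation observed.
    """
    if not aligned_pairs:
        raise DatasetError("no alignments")
    germ0 = aligned_pairs[0][1].replace("-", "")
    L = len(germ0)
    counts: list[Counter[str]] = [Counter() for _ in range(L)]
    n = len(aligned_pairs)
    for obs, germ in aligned_pairs:
        if len(obs) != len(germ):
            raise DatasetError(f"misaligned pair: lengths {len(obs)} vs {len(germ)}")
        gi = -1
        for a, g in zip(obs, germ):
            if g == "-":
                continue
            gi += 1
            if a == "-" or a == g:
                continue
            if alphabet is not None and reduce(a, alphabet) == reduce(g, alphabet):
                continue  # same group: not class-changing
            counts[gi][a] += 1
    alpha = np.ones(L)
    mut = [{aa: c / n for aa, c in sorted(col.items())} for col in counts]
    res_freqs: list[dict[str, float]] = []
    for i, g in enumerate(germ0):
        mutated = sum(counts[i].values())
        col = Counter(counts[i])
        col[g] += n - mutated
        col = Counter({aa: c for aa, c in col.items() if c > 0})
        total = sum(col.values())
        res_freqs.append({aa: c / total for aa, c in sorted(col.items())})
        alpha[i] = hill_diversity(col)
    flags = [bool(col) for col in counts] if alphabet is not None else []
    return PositionProfile(
        cdr_id=cdr_id,
        length=L,
        alpha=alpha,
        residue_freqs=res_freqs,
        mutation_freqs=mut,
        germline=germ0,
        class_changing=flags,
    )


# ---------------------------------------------------------------------------
# I/O

def write_diversity_tsv(path: str | Path, profile: DiversityProfile) -> None:
    rows = [{"cdr": k, "gamma": profile.d[k], "p_select": profile.p[k], "q": profile.q} for k in profile.d]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_position_tsv(path: str | Path, profile: PositionProfile) -> None:
    rows = []
    for i in range(profile.length):
        rows.append(
            {
                "cdr": profile.cdr_id,
                "length": profile.length,
                "position": i + 1,
                "alpha": profile.alpha[i],
                "residue_freqs": ";".join(f"{a}:{f:.6g}" for a, f in profile.residue_freqs[i].items()),
                "mutation_freqs": ";".join(
                    f"{a}:{f:.6g}" for a, f in (profile.mutation_freqs[i] if profile.mutation_freqs else {}).items()
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
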