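"""Optimization engine: preparation, cycle loop, acceptance, trajectory.

Each modification cycle proposes an edit at a probabilistically selected
site, models the modified antibody, superposes it back onto the complex
(preserving the starting binding pose), relieves clashes, scores the
complex, and accepts or rejects the proposal.  The default acceptance
rule is the Metropolis criterion — accept improvements always, accept a
worsening ``dE > 0`` with probability ``exp(-dE/T)``; stricter
improve-only and minimum-threshold criteria are available per step.

The five modification steps run in a configurable order; the default
mirrors B-cell maturation: H3 grafting -> canonical-conformation sweep
-> naive non-H3 CDR grafting -> mutagenesis -> framework hybridization.
A single seeded RNG stream drives every stochastic choice, and each
cycle's uniform draw is logged so runs are bit-reproducible and
replayable.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from . import modifications as mods
from .adapters import (
    ComplexStructure,
    ModelResult,
    contact_scorer,
    superpose,
    toy_minimize,
    toy_model,
)
from .datasets import CanonicalEntry, PoolEntry, RepertoireRecord
from .errors import (
    AdapterError,
    ConfigurationError,
    ConformationRejected,
    NoCandidateError,
)
from .regions import AntibodyFv, RegionTable

logger = logging.getLogger(__name__)

STEP_IDS = ("h3", "canonical", "naive_cdr", "mutagenesis", "framework")
DEFAULT_STEP_ORDER = STEP_IDS


@dataclass(frozen=True)
class AcceptanceCriterion:
    """metropolis | improve_only | threshold acceptance rules."""

    mode: str = "metropolis"
    temperature: float = 1.0   # energy units of the active scorer
    tau: float = 0.0           # minimum improvement (threshold mode)

    def __post_init__(self) -> None:
        if self.mode not in ("metropolis", "improve_only", "threshold"):
            raise ConfigurationError(f"unknown acceptance mode {self.mode!r}")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.tau < 0:
            raise ConfigurationError("threshold tau must be non-negative")


def accept(delta_e: float, criterion: AcceptanceCriterion, u: float) -> bool:
    """Acceptance decision for a score change ``delta_e`` (lower = better).

    Metropolis: always accept non-worsening moves, else ``u < exp(-dE/T)``.
    Improve-only: strict decrease.  Threshold: decrease by at least tau
    (inclusive).
    """
    if criterion.mode == "metropolis":
        if delta_e <= 0:
            return True
        return u < math.exp(-delta_e / criterion.temperature)
    if criterion.mode == "improve_only":
        return delta_e < 0
    return delta_e <= -criterion.tau


def select_site(probs: Mapping[str, float], rng: np.random.Generator, tol: float = 1e-6) -> str:
    """Categorical draw of a modification site from normalized probabilities."""
    total = sum(probs.values())
    if abs(total - 1.0) > tol:
        raise ConfigurationError(f"site probabilities sum to {total}, not 1")
    sites = sorted(probs)
    p = np.array([probs[s] for s in sites])
    return sites[int(rng.choice(len(sites), p=p / p.sum()))]


# ---------------------------------------------------------------------------
# Adapters bundle

@dataclass
class AdapterSet:
    """The pluggable tool stack used by every cycle.

    ``scorer`` consumes the full complex; ``scorer_fv`` (when set)
    consumes the Fv directly and bypasses structure building — used by
    the sequence-level surrogate scorer in optimization tests.
    """

    modeler: Callable[[AntibodyFv], ModelResult] = toy_model
    superposer: Callable[..., ComplexStructure] = superpose
    minimizer: Callable[[ComplexStructure], ComplexStructure] = toy_minimize
    scorer: Callable[[ComplexStructure], float] = contact_scorer
    scorer_fv: Callable[[AntibodyFv], float] | None = None
    lower_is_better: bool = True

    def evaluate(self, fv: AntibodyFv, complex_structure: ComplexStructure | None,
                 chain_map: Mapping[str, str]) -> tuple[float, ComplexStructure | None]:
        """model -> superpose -> minimize -> score; returns (score, new complex)."""
        if self.scorer_fv is not None:
            return float(self.scorer_fv(fv)), complex_structure
        if complex_structure is None:
            raise AdapterError("structural scoring requires a complex")
        model = self.modeler(fv)
        placed = self.superposer(model, complex_structure, chain_map)
        minimized = self.minimizer(placed)
        score = float(self.scorer(minimized))
        if not self.lower_is_better:
            score = -score
        return score, minimized


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class StepConfig:
    step: str
    budget: int = 0
    criterion: AcceptanceCriterion = field(default_factory=AcceptanceCriterion)
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step not in STEP_IDS:
            raise ConfigurationError(f"unknown step {self.step!r}; valid: {STEP_IDS}")
        if self.budget < 0:
            raise ConfigurationError("budget must be >= 0")


@dataclass
class RunConfig:
    steps: list[StepConfig] = field(default_factory=lambda: [
        StepConfig("h3", budget=50),
        StepConfig("canonical", budget=0),      # 0 = run to convergence
        StepConfig("naive_cdr", budget=100),
        StepConfig("mutagenesis", budget=100),
        StepConfig("framework", budget=1),
    ])
    seed: int = 0
    scorer_id: str = "contact"
    site_probs: dict[str, float] | None = None   # override diversity-derived probs
    region_variant: str = "default"
    h3_mode: str = "similar_length"
    mutation_mode: str = "diversity"
    indel: mods.IndelPolicy = field(default_factory=mods.IndelPolicy)
    constraints: dict = field(default_factory=lambda: {"same_germline": True, "same_conformation": True})
    match_k: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        steps = [
            StepConfig(
                step=s["step"],
                budget=int(s.get("budget", 0)),
                criterion=AcceptanceCriterion(
                    mode=s.get("criterion", "metropolis"),
                    temperature=float(s.get("temperature", 1.0)),
                    tau=float(s.get("tau", 0.0)),
                ),
                options=s.get("options", {}),
            )
            for s in raw.get("steps", [])
        ] or None
        cfg = cls()
        if steps:
            cfg.steps = steps
        for key in ("seed", "scorer_id", "site_probs", "region_variant", "h3_mode",
                    "mutation_mode", "match_k"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "indel" in raw:
            cfg.indel = mods.IndelPolicy(**raw["indel"])
        if "constraints" in raw:
            cfg.constraints = raw["constraints"]
        return cfg


@dataclass
class PipelineResources:
    """Datasets and profiles consumed by the modification operators."""

    h3_pool: Sequence[PoolEntry] = ()
    cdr_pools: Mapping[str, Sequence[PoolEntry]] = field(default_factory=dict)
    registry: Sequence[CanonicalEntry] = ()
    position_profiles: Mapping[str, object] | None = None
    framework_dataset: Sequence[RepertoireRecord] = ()
    site_probs: Mapping[str, float] | None = None    # non-H3 CDR selection probs
    guards: Mapping[tuple[str, str], mods.ConformationCheck] | None = None


# ---------------------------------------------------------------------------
# State and trajectory

@dataclass
class PipelineState:
    fv: AntibodyFv
    complex: ComplexStructure | None
    score: float
    chain_map: Mapping[str, str]


@dataclass
class CycleRecord:
    cycle: int
    step: str
    kind: str
    site: str
    payload: str
    source: str
    score_before: float
    score_after: float
    delta_e: float
    accepted: bool
    rng_draw: float
    wall_clock: float
    error: str = ""

    def to_json(self) -> str:
        # wall-clock timing is diagnostic only; excluding it keeps
        # trajectories byte-identical across reruns with the same seed
        d = asdict(self)
        d.pop("wall_clock")
        return json.dumps(d, sort_keys=True)


@dataclass
class Trajectory:
    records: list[CycleRecord] = field(default_factory=list)
    initial_score: float = float("nan")
    final_score: float = float("nan")
    initial_sequences: dict[str, str] = field(default_factory=dict)
    final_sequences: dict[str, str] = field(default_factory=dict)

    def append(self, rec: CycleRecord) -> None:
        self.records.append(rec)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(rec.to_json() + "\n")

    def accepted_scores(self) -> list[float]:
        return [r.score_after for r in self.records if r.accepted]

    def summary_rows(self) -> list[dict]:
        return [asdict(r) for r in self.records]


# ---------------------------------------------------------------------------
# Preparation

def prepare(
    fv: AntibodyFv,
    complex_structure: ComplexStructure | None,
    adapters: AdapterSet,
    chain_map: Mapping[str, str] | None = None,
) -> PipelineState:
    """Model the input antibody, place it into the complex, score it.

    The modeled input replaces the antibody chains of the complex so all
    later score differences are computed against a structure produced by
    the same modeling protocol.
    """
    chain_map = dict(chain_map or {"H": "H", "L": "L"})
    if complex_structure is not None:
        for cid in chain_map.values():
            if cid not in complex_structure.chains:
                raise AdapterError(f"antibody chain {cid!r} not present in complex")
    score, new_complex = adapters.evaluate(fv, complex_structure, chain_map)
    return PipelineState(fv=fv, complex=new_complex, score=score, chain_map=chain_map)


# ---------------------------------------------------------------------------
# Cycle loop

def _propose(step: str, state: PipelineState, resources: PipelineResources,
             config: RunConfig, rng: np.random.Generator, table: RegionTable) -> mods.ModificationProposal:
    if step == "h3":
        return mods.propose_h3(state.fv, resources.h3_pool, mode=config.h3_mode, rng=rng, table=table)
    if step == "naive_cdr":
        return mods.propose_naive_cdr(
            state.fv, resources.cdr_pools, constraints=config.constraints,
            indel=config.indel, site_probs=resources.site_probs, rng=rng, table=table,
        )
    if step == "mutagenesis":
        return mods.propose_mutation(
            state.fv, resources.position_profiles, mode=config.mutation_mode,
            guard=None, rng=rng, table=table,
        )
    raise ConfigurationError(f"step {step!r} is not a per-cycle proposal step")


def _check_guards(proposal: mods.ModificationProposal, resources: PipelineResources,
                  config: RunConfig, adapters: AdapterSet, table: RegionTable) -> None:
    """Reject conformation-changing CDR edits before scoring, when guarded."""
    if not resources.guards or not config.constraints.get("same_conformation", True):
        return
    if proposal.kind not in ("point_mutation", "naive_graft"):
        return
    site = proposal.site.split(":")[0]
    chain_tag, region_id = site[0], f"CDR{site[1]}"
    guard = resources.guards.get((chain_tag, region_id))
    if guard is None:
        return
    from .adapters import loop_torsions

    tors = loop_torsions(proposal.fv, chain_tag, region_id, table, adapters.modeler)
    if not guard.passes(tors):
        raise ConformationRejected(f"{proposal.kind} at {proposal.site} alters loop conformation")


def run_cycle(
    state: PipelineState,
    step: str,
    adapters: AdapterSet,
    criterion: AcceptanceCriterion,
    rng: np.random.Generator,
    resources: PipelineResources,
    config: RunConfig,
    table: RegionTable,
    cycle_index: int = 0,
) -> tuple[PipelineState, CycleRecord]:
    """One propose -> model -> superpose -> minimize -> score -> accept cycle.

    Operator and adapter failures become rejected cycles carrying an
    error tag; the run continues.
    """
    t0 = time.perf_counter()
    try:
        proposal = _propose(step, state, resources, config, rng, table)
        _check_guards(proposal, resources, config, adapters, table)
        score_after, new_complex = adapters.evaluate(proposal.fv, state.complex, state.chain_map)
    except (NoCandidateError, ConformationRejected, AdapterError) as exc:
        rec = CycleRecord(
            cycle=cycle_index, step=step, kind="skip", site="", payload="", source="",
            score_before=state.score, score_after=state.score, delta_e=0.0,
            accepted=False, rng_draw=float("nan"),
            wall_clock=time.perf_counter() - t0, error=f"{type(exc).__name__}: {exc}",
        )
        return state, rec
    delta_e = score_after - state.score
    u = float(rng.random())
    ok = accept(delta_e, criterion, u)
    rec = CycleRecord(
        cycle=cycle_index, step=step, kind=proposal.kind, site=proposal.site,
        payload=proposal.payload, source=proposal.source,
        score_before=state.score, score_after=score_after, delta_e=delta_e,
        accepted=ok, rng_draw=u, wall_clock=time.perf_counter() - t0,
    )
    if ok:
        state = PipelineState(fv=proposal.fv, complex=new_complex, score=score_after,
                              chain_map=state.chain_map)
    return state, rec


def run_pipeline(
    config: RunConfig,
    fv: AntibodyFv,
    complex_structure: ComplexStructure | None,
    resources: PipelineResources,
    adapters: AdapterSet | None = None,
    chain_map: Mapping[str, str] | None = None,
) -> tuple[AntibodyFv, Trajectory]:
    """Run the configured steps in order and return the final Fv + trajectory.

    Per-cycle steps consume their cycle budgets; the canonical sweep and
    framework hybridization use their internal convergence/enumeration
    logic (budgets are pass caps, 0 meaning run-to-convergence for the
    sweep and a single pass for the framework step).
    """
    adapters = adapters or AdapterSet()
    table = RegionTable.default(variant=config.region_variant)
    rng = np.random.default_rng(config.seed)
    state = prepare(fv, complex_structure, adapters, chain_map)
    traj = Trajectory(
        initial_score=state.score,
        initial_sequences={"H": fv.heavy.sequence(), "L": fv.light.sequence()},
    )
    cycle = 0

    def evaluate_fv(candidate: AntibodyFv) -> float:
        score, _ = adapters.evaluate(candidate, state.complex, state.chain_map)
        return score

    for step_cfg in config.steps:
        step = step_cfg.step
        if step in ("h3", "naive_cdr", "mutagenesis"):
            for _ in range(step_cfg.budget):
                state, rec = run_cycle(
                    state, step, adapters, step_cfg.criterion, rng,
                    resources, config, table, cycle_index=cycle,
                )
                traj.append(rec)
                cycle += 1
        elif step == "canonical":
            if not resources.registry:
                continue

            def log_canonical(prop, before, after, ok, _step=step):
                nonlocal cycle
                traj.append(CycleRecord(
                    cycle=cycle, step=_step, kind=prop.kind, site=prop.site,
                    payload=prop.payload, source=prop.source,
                    score_before=before, score_after=after, delta_e=after - before,
                    accepted=ok, rng_draw=float("nan"), wall_clock=0.0,
                ))
                cycle += 1

            new_fv = mods.canonical_sweep(
                state.fv, resources.registry, evaluate_fv, rng=rng,
                criterion=step_cfg.criterion, table=table,
                max_passes=step_cfg.budget or None, on_proposal=log_canonical,
            )
            if new_fv is not state.fv:
                score, new_complex = adapters.evaluate(new_fv, state.complex, state.chain_map)
                state = PipelineState(new_fv, new_complex, score, state.chain_map)
        elif step == "framework":
            if step_cfg.budget == 0:
                continue
            before = state.score
            new_fv = mods.framework_swap(
                state.fv, resources.framework_dataset, evaluate_fv,
                match_k=config.match_k, table=table,
                conformation_guards=resources.guards if config.constraints.get("same_conformation") else None,
                input_score=state.score,
            )
            changed = new_fv is not state.fv
            if changed:
                score, new_complex = adapters.evaluate(new_fv, state.complex, state.chain_map)
                state = PipelineState(new_fv, new_complex, score, state.chain_map)
            traj.append(CycleRecord(
                cycle=cycle, step=step, kind="framework_swap", site="FR",
                payload="", source="framework_dataset",
                score_before=before, score_after=state.score,
                delta_e=state.score - before, accepted=changed,
                rng_draw=float("nan"), wall_clock=0.0,
            ))
            cycle += 1
    traj.final_score = state.score
    traj.final_sequences = {"H": state.fv.heavy.sequence(), "L": state.fv.light.sequence()}
    return state.fv, traj
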