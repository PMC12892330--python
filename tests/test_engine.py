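"""Acceptance criteria, site selection, cycle loop and full-pipeline runs."""

import math

import numpy as np
import pytest

from abforge import fixtures
from abforge.adapters import make_surrogate_scorer, surrogate_optimum, toy_model, superpose
from abforge.datasets import build_ncdr, filter_repertoire
from abforge.engine import (
    AcceptanceCriterion,
    AdapterSet,
    PipelineResources,
    RunConfig,
    StepConfig,
    accept,
    prepare,
    run_cycle,
    run_pipeline,
    select_site,
)
from abforge.errors import AdapterError, ConfigurationError
from abforge.regions import RegionTable, assign_regions, replace_region


class TestAccept:
    def test_improvement_always_accepted(self):
        for mode in ("metropolis", "improve_only"):
            assert accept(-1.0, AcceptanceCriterion(mode=mode), u=0.999)

    def test_metropolis_boundary_at_half_probability(self):
        crit = AcceptanceCriterion(mode="metropolis", temperature=2.0)
        de = 2.0 * math.log(2)  # exp(-dE/T) = 0.5
        assert accept(de, crit, u=0.49)
        assert not accept(de, crit, u=0.51)

    def test_threshold_inclusive(self):
        crit = AcceptanceCriterion(mode="threshold", tau=2.0)
        assert not accept(-1.5, crit, u=0.0)
        assert accept(-2.0, crit, u=0.0)

    def test_improve_only_strict(self):
        crit = AcceptanceCriterion(mode="improve_only")
        assert not accept(0.0, crit, u=0.0)

    def test_metropolis_frequency_matches_boltzmann(self):
        crit = AcceptanceCriterion(mode="metropolis", temperature=1.0)
        de = 1.0
        rng = np.random.default_rng(99)
        n = 100_000
        hits = sum(accept(de, crit, float(rng.random())) for _ in range(n))
        p = math.exp(-de)
        assert abs(hits / n - p) < 3 * math.sqrt(p * (1 - p) / n) + 1e-3

    def test_invalid_criteria(self):
        with pytest.raises(ConfigurationError):
            AcceptanceCriterion(mode="magic")
        with pytest.raises(ConfigurationError):
            AcceptanceCriterion(temperature=0.0)
        with pytest.raises(ConfigurationError):
            AcceptanceCriterion(mode="threshold", tau=-1.0)


class TestSelectSite:
    def test_degenerate_always_selected(self, rng):
        assert all(select_site({"H3": 1.0}, rng) == "H3" for _ in range(100))

    def test_frequencies_converge(self, rng):
        probs = {"H1": 0.2, "H2": 0.3, "L1": 0.5}
        counts = {k: 0 for k in probs}
        n = 10_000
        for _ in range(n):
            counts[select_site(probs, rng)] += 1
        for k, p in probs.items():
            assert abs(counts[k] / n - p) < 0.02

    def test_unnormalized_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            select_site({"a": 0.5, "b": 0.4}, rng)


def _surrogate_setup(seed=0):
    table = RegionTable.default()
    fv = fixtures.make_fv(seed=21, table=table)
    # target differs from fv only inside CDRs, same lengths
    rng = np.random.default_rng(seed)
    target = fv
    for tag in ("H", "L"):
        for i in (1, 2, 3):
            cur = assign_regions(target.chain(tag), table)[f"CDR{i}"]
            new = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=len(cur)))
            target = target.with_chain(replace_region(target.chain(tag), f"CDR{i}", new, table))
    return table, fv, target


class TestPrepare:
    def test_missing_antibody_chain_errors(self, fv):
        spec = fixtures.ComplexSpec(seed=2)
        cx = fixtures.make_complex(spec)
        with pytest.raises(AdapterError):
            prepare(fv, cx, AdapterSet(), chain_map={"H": "H", "L": "Z"})

    def test_prepare_deterministic(self, fv):
        spec = fixtures.ComplexSpec(
            antibody_lengths={"H": len(fv.heavy), "L": len(fv.light)},
            antibody_seqs={"H": fv.heavy.sequence(), "L": fv.light.sequence()},
            seed=2,
        )
        cx = fixtures.make_complex(spec)
        s1 = prepare(fv, cx, AdapterSet())
        s2 = prepare(fv, cx, AdapterSet())
        assert s1.score == s2.score
        for cid in s1.complex.chains:
            for r1, r2 in zip(s1.complex.chains[cid], s2.complex.chains[cid]):
                for name in r1.atoms:
                    assert np.array_equal(r1.atoms[name], r2.atoms[name])

    def test_surrogate_prepare_scores_input(self, fv):
        table = RegionTable.default()
        scorer = make_surrogate_scorer(fv, table)
        state = prepare(fv, None, AdapterSet(scorer_fv=scorer))
        assert state.score == surrogate_optimum(fv, table)


class TestRunCycle:
    def test_infinite_scorer_never_changes_state(self):
        table, fv, target = _surrogate_setup()
        pool = fixtures.make_planted_pool(
            assign_regions(target.heavy, table)["CDR3"], 5, seed=1,
            germline_id=fv.heavy.germline_id,
        )
        adapters = AdapterSet(scorer_fv=lambda f: float("inf"))
        resources = PipelineResources(h3_pool=pool)
        cfg = RunConfig()
        state = prepare(fv, None, adapters)
        rng = np.random.default_rng(0)
        crit = AcceptanceCriterion(mode="improve_only")
        for i in range(30):
            state, rec = run_cycle(state, "h3", adapters, crit, rng, resources, cfg, table, i)
            assert not rec.accepted
        assert state.fv is fv

    def test_record_count_matches_budget(self):
        table, fv, target = _surrogate_setup()
        scorer = make_surrogate_scorer(target, table)
        pool = fixtures.make_planted_pool(
            assign_regions(target.heavy, table)["CDR3"], 5, seed=1,
            germline_id=fv.heavy.germline_id,
        )
        cfg = RunConfig(seed=3)
        cfg.steps = [StepConfig("h3", budget=25, criterion=AcceptanceCriterion(mode="improve_only"))]
        res = PipelineResources(h3_pool=pool)
        _, traj = run_pipeline(cfg, fv, None, res, adapters=AdapterSet(scorer_fv=scorer))
        assert len(traj.records) == 25


class TestRunPipeline:
    def _resources(self, table, fv, target):
        pools = {}
        for site in ("H1", "H2", "L1", "L2", "L3"):
            tag, rid = site[0], f"CDR{site[1]}"
            pools[site] = fixtures.make_planted_pool(
                assign_regions(target.chain(tag), table)[rid], 4,
                seed=ord(site[0]) * 10 + int(site[1]), germline_id=fv.chain(tag).germline_id,
            )
        h3 = fixtures.make_planted_pool(
            assign_regions(target.heavy, table)["CDR3"], 4, seed=5,
            germline_id=fv.heavy.germline_id,
        )
        return PipelineResources(h3_pool=h3, cdr_pools=pools)

    def _config(self, seed):
        crit = AcceptanceCriterion(mode="improve_only")
        cfg = RunConfig(seed=seed)
        cfg.steps = [
            StepConfig("h3", budget=40, criterion=crit),
            StepConfig("naive_cdr", budget=200, criterion=crit),
        ]
        from abforge.modifications import IndelPolicy

        cfg.indel = IndelPolicy(1.0, 0.0, 0.0)
        return cfg

    def test_budget_zero_returns_prepared_input(self):
        table, fv, target = _surrogate_setup()
        scorer = make_surrogate_scorer(target, table)
        cfg = RunConfig(seed=1)
        cfg.steps = [StepConfig(s, budget=0) for s in ("h3", "naive_cdr", "mutagenesis", "framework")]
        res = self._resources(table, fv, target)
        final, traj = run_pipeline(cfg, fv, None, res, adapters=AdapterSet(scorer_fv=scorer))
        assert final is fv
        assert traj.records == []
        assert traj.final_score == traj.initial_score

    def test_trajectory_byte_identical_under_fixed_seed(self):
        table, fv, target = _surrogate_setup()
        scorer = make_surrogate_scorer(target, table)
        res = self._resources(table, fv, target)
        runs = []
        for _ in range(2):
            _, traj = run_pipeline(self._config(7), fv, None, res,
                                   adapters=AdapterSet(scorer_fv=scorer))
            runs.append("\n".join(r.to_json() for r in traj.records))
        assert runs[0] == runs[1]

    def test_improve_only_scores_strictly_decrease(self):
        table, fv, target = _surrogate_setup()
        scorer = make_surrogate_scorer(target, table)
        res = self._resources(table, fv, target)
        _, traj = run_pipeline(self._config(11), fv, None, res,
                               adapters=AdapterSet(scorer_fv=scorer))
        accepted = traj.accepted_scores()
        assert accepted, "expected at least one accepted modification"
        for a, b in zip(accepted, accepted[1:]):
            assert b < a
        assert traj.final_score <= traj.initial_score

    def test_planted_solution_recovered_within_budget(self):
        table, fv, target = _surrogate_setup()
        scorer = make_surrogate_scorer(target, table)
        res = self._resources(table, fv, target)
        optimum = surrogate_optimum(target, table)
        final, traj = run_pipeline(self._config(13), fv, None, res,
                                   adapters=AdapterSet(scorer_fv=scorer))
        assert traj.final_score == optimum
        for tag in ("H", "L"):
            for i in (1, 2, 3):
                assert (assign_regions(final.chain(tag), table)[f"CDR{i}"]
                        == assign_regions(target.chain(tag), table)[f"CDR{i}"])


def test_structural_cycle_runs_end_to_end(fv):
    """The full model->superpose->minimize->score chain executes on a toy complex."""
    spec = fixtures.ComplexSpec(
        antibody_lengths={"H": len(fv.heavy), "L": len(fv.light)},
        antigen_length=10,
        antibody_seqs={"H": fv.heavy.sequence(), "L": fv.light.sequence()},
        interface_pairs=((("H", 40), 3),),
        seed=4,
    )
    cx = fixtures.make_complex(spec)
    state = prepare(fv, cx, AdapterSet())
    assert np.isfinite(state.score)
    # antigen is carried through untouched by preparation
    for r0, r1 in zip(cx.chains["G"], state.complex.chains["G"]):
        assert np.array_equal(r0.ca, r1.ca)
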