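"""Modification operators: grafts, sweeps, mutagenesis, framework swaps."""

import math

import numpy as np
import pytest

from abforge import fixtures
from abforge.datasets import CanonicalEntry, PoolEntry
from abforge.diversity import PositionProfile
from abforge.errors import ConfigurationError, NoCandidateError
from abforge.modifications import (
    ConformationCheck,
    IndelPolicy,
    canonical_sweep,
    conformation_distance,
    framework_swap,
    propose_h3,
    propose_mutation,
    propose_naive_cdr,
)
from abforge.regions import assign_regions


def _diff_sites(fv_a, fv_b, table):
    """Regions whose sequences differ between two Fvs."""
    out = set()
    for tag in ("H", "L"):
        ra = assign_regions(fv_a.chain(tag), table)
        rb = assign_regions(fv_b.chain(tag), table)
        for rid in ra:
            if ra[rid] != rb[rid]:
                out.add((tag, rid))
    return out


class TestProposeH3:
    def _pool(self, len10, len12):
        return (
            [PoolEntry(sequence="A" * 10, source_id=f"p10-{i}") for i in range(len10)]
            + [PoolEntry(sequence="W" * 12, source_id=f"p12-{i}") for i in range(len12)]
        )

    def test_similar_length_only_draws_matching_length(self, fv, table, rng):
        cur_len = len(assign_regions(fv.heavy, table)["CDR3"])
        pool = (
            [PoolEntry(sequence="A" * cur_len, source_id=f"a{i}") for i in range(5)]
            + [PoolEntry(sequence="W" * (cur_len + 2), source_id=f"b{i}") for i in range(5)]
        )
        for _ in range(2000):
            prop = propose_h3(fv, pool, "similar_length", rng, table=table)
            assert len(prop.payload) == cur_len

    def test_any_weighted_reproduces_length_distribution(self, fv, table, rng):
        pool = self._pool(5, 5)
        n10 = sum(
            len(propose_h3(fv, pool, "any_weighted", rng, table=table).payload) == 10
            for _ in range(10_000)
        )
        assert abs(n10 / 10_000 - 0.5) < 0.02

    def test_empty_pool_errors(self, fv, table, rng):
        with pytest.raises(NoCandidateError):
            propose_h3(fv, [], rng=rng, table=table)

    def test_proposal_changes_only_h3(self, fv, table, rng):
        pool = [PoolEntry(sequence="WYWYWYWYWY")]
        prop = propose_h3(fv, pool, "any_random", rng, table=table)
        assert _diff_sites(fv, prop.fv, table) == {("H", "CDR3")}


class TestCanonicalSweep:
    def test_constant_scorer_one_pass_no_change(self, fv, registry, table, rng):
        calls = []
        sweep_out = canonical_sweep(
            fv, registry, lambda f: calls.append(1) or 0.0, rng=rng, table=table
        )
        assert sweep_out is fv
        # one reference evaluation plus exactly one full pass
        assert len(calls) == 1 + len(registry)

    def test_scorer_favoring_one_h1_entry(self, fv, registry, table, rng):
        target = next(e for e in registry if e.cdr_type == "H1")

        def evaluate(f):
            return -1.0 if assign_regions(f.heavy, table)["CDR1"] == target.sequence else 0.0

        out = canonical_sweep(fv, registry, evaluate, rng=rng, table=table)
        assert assign_regions(out.heavy, table)["CDR1"] == target.sequence

    def test_accepted_scores_strictly_decrease(self, fv, registry, table, rng):
        scores = []

        def evaluate(f):
            # deterministic pseudo-score from the paratope sequence
            s = sum(assign_regions(f.chain(t), table)[f"CDR{i}"].count("W")
                    for t in "HL" for i in (1, 2, 3))
            return -float(s)

        accepted = []

        def on_prop(prop, before, after, ok):
            if ok:
                accepted.append((before, after))

        canonical_sweep(fv, registry, evaluate, rng=rng, table=table, on_proposal=on_prop)
        for before, after in accepted:
            assert after < before

    def test_de_loop_cografted_for_h2(self, fv, table, rng):
        de_len = len(assign_regions(fv.heavy, table)["DE"])
        entry = CanonicalEntry("h2x", "H2", 8, "WWWWWWWW", de_loop="Y" * de_len)
        out = canonical_sweep(fv, [entry], lambda f: -1.0 if "WWWWWWWW" in f.heavy.sequence() else 0.0,
                              rng=rng, table=table)
        diff = _diff_sites(fv, out, table)
        assert diff == {("H", "CDR2"), ("H", "DE")}


class TestProposeNaiveCdr:
    def _pools(self, fv, table, lengths_delta=(0, 1, -1)):
        pools = {}
        for site in ("H1", "H2", "L1", "L2", "L3"):
            tag, rid = site[0], f"CDR{site[1]}"
            cur = len(assign_regions(fv.chain(tag), table)[rid])
            germ = fv.chain(tag).germline_id
            pools[site] = [
                PoolEntry(sequence="W" * (cur + d), germline_id=germ, source_id=f"{site}d{d}")
                for d in lengths_delta
            ]
        return pools

    def test_zero_indel_policy_preserves_length(self, fv, table, rng):
        pools = self._pools(fv, table)
        indel = IndelPolicy(1.0, 0.0, 0.0)
        for _ in range(500):
            prop = propose_naive_cdr(fv, pools, {"same_germline": True}, indel, None, rng, table)
            site = prop.site
            tag, rid = site[0], f"CDR{site[1]}"
            assert len(prop.payload) == len(assign_regions(fv.chain(tag), table)[rid])

    def test_indel_frequencies_match_policy(self, fv, table, rng):
        pools = self._pools(fv, table)
        indel = IndelPolicy(0.8, 0.1, 0.1)
        deltas = {0: 0, 1: 0, -1: 0}
        n = 10_000
        for _ in range(n):
            prop = propose_naive_cdr(fv, pools, {"same_germline": True}, indel, None, rng, table)
            tag, rid = prop.site[0], f"CDR{prop.site[1]}"
            cur = len(assign_regions(fv.chain(tag), table)[rid])
            deltas[len(prop.payload) - cur] += 1
        assert abs(deltas[0] / n - 0.8) < 0.01
        assert abs(deltas[1] / n - 0.1) < 0.01
        assert abs(deltas[-1] / n - 0.1) < 0.01

    def test_germline_mismatch_signals_skip(self, fv, table, rng):
        pools = self._pools(fv, table)
        pools = {k: [PoolEntry(sequence=e.sequence, germline_id="OTHER") for e in v]
                 for k, v in pools.items()}
        with pytest.raises(NoCandidateError):
            propose_naive_cdr(fv, pools, {"same_germline": True}, IndelPolicy(1, 0, 0), None, rng, table)

    def test_indel_policy_validation(self):
        with pytest.raises(ConfigurationError):
            IndelPolicy(0.8, 0.3, 0.1)
        with pytest.raises(ConfigurationError):
            IndelPolicy(1.2, -0.1, -0.1)


class TestProposeMutation:
    def _profile(self, length, hot_pos=None, hot_res="W"):
        alpha = np.ones(length)
        freqs = [dict() for _ in range(length)]
        if hot_pos is not None:
            alpha = np.full(length, 1e-12)
            alpha[hot_pos] = 1.0
            freqs[hot_pos] = {hot_res: 1.0}
        else:
            for i in range(length):
                freqs[i] = {"W": 0.5, "Y": 0.5}
        return PositionProfile(cdr_id="", length=length, alpha=alpha,
                               residue_freqs=[{"A": 1.0}] * length, mutation_freqs=freqs)

    def test_concentrated_profile_always_hits_hot_position(self, fv, table, rng):
        profiles = {}
        for site in ("H1",):
            tag, rid = site[0], f"CDR{site[1]}"
            L = len(assign_regions(fv.chain(tag), table)[rid])
            profiles[site] = self._profile(L, hot_pos=2)
        for _ in range(200):
            prop = propose_mutation(fv, profiles, "diversity", None, rng, table, sites=("H1",))
            assert prop.site == "H1:3"
            assert prop.payload == "W"

    def test_random_mode_never_proposes_current_residue(self, fv, table, rng):
        for _ in range(2000):
            prop = propose_mutation(fv, None, "random", None, rng, table)
            site, pos = prop.site.split(":")
            tag, rid = site[0], f"CDR{site[1]}"
            cur = assign_regions(fv.chain(tag), table)[rid]
            assert prop.payload != cur[int(pos) - 1]

    def test_guard_disabled_bypasses_conformation_check(self, fv, table, rng):
        # an impossible guard would reject everything if consulted
        impossible = ConformationCheck(reference=[(0.0, 0.0)], threshold=1e-9)
        prop = propose_mutation(fv, None, "random", None, rng, table)
        assert prop.fv is not fv  # proposal produced despite impossible guard existing

    def test_mutation_changes_single_position(self, fv, table, rng):
        prop = propose_mutation(fv, None, "random", None, rng, table)
        site = prop.site.split(":")[0]
        tag, rid = site[0], f"CDR{site[1]}"
        assert _diff_sites(fv, prop.fv, table) == {(tag, rid)}
        a = assign_regions(fv.chain(tag), table)[rid]
        b = assign_regions(prop.fv.chain(tag), table)[rid]
        assert sum(x != y for x, y in zip(a, b)) == 1


class TestConformationDistance:
    def test_identical_torsions_zero(self):
        tors = [(10.0, -20.0), (30.0, 40.0)]
        assert conformation_distance(tors, tors) == 0.0

    def test_single_residue_half_turn(self):
        assert conformation_distance([(180.0, 0.0)], [(0.0, 0.0)]) == pytest.approx(2.0)

    def test_matches_brute_force_formula(self, rng):
        a = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180))) for _ in range(12)]
        b = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180))) for _ in range(12)]
        expected = math.sqrt(sum(
            2 * (1 - math.cos(math.radians(pa - pb))) + 2 * (1 - math.cos(math.radians(sa - sb)))
            for (pa, sa), (pb, sb) in zip(a, b)
        ))
        assert conformation_distance(a, b) == pytest.approx(expected, rel=1e-12)
        assert conformation_distance(b, a) == pytest.approx(expected, rel=1e-12)

    def test_periodicity(self):
        assert conformation_distance([(370.0, -350.0)], [(10.0, 10.0)]) == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            conformation_distance([(0, 0)], [(0, 0), (0, 0)])


class TestFrameworkSwap:
    def test_constant_scorer_returns_input(self, fv, table, memory_records):
        out = framework_swap(fv, memory_records[:10], lambda f: 0.0, table=table)
        assert out is fv

    def test_empty_dataset_returns_input(self, fv, table):
        assert framework_swap(fv, [], lambda f: 0.0, table=table) is fv

    def test_three_variants_evaluated_at_match_k_one(self, fv, table, memory_records):
        both = ([r for r in memory_records if r.chain_tag == "H"][:10]
                + [r for r in memory_records if r.chain_tag == "L"][:10])
        calls = []
        framework_swap(fv, both, lambda f: calls.append(1) or 0.0,
                       match_k=1, table=table, input_score=0.0)
        assert len(calls) == 3  # H-hybrid, L-hybrid, mature-mature

    def test_best_hybrid_preserves_cdrs(self, fv, table, memory_records):
        donor = next(r for r in memory_records if r.chain_tag == "H")

        def evaluate(f):
            # reward the heavy FR1 of one specific donor
            return -1.0 if assign_regions(f.heavy, table)["FR1"] == donor.framework_regions["FR1"] else 0.0

        out = framework_swap(fv, [donor], evaluate, table=table, input_score=0.0)
        assert assign_regions(out.heavy, table)["FR1"] == donor.framework_regions["FR1"]
        for tag in ("H", "L"):
            for i in (1, 2, 3):
                assert (assign_regions(out.chain(tag), table)[f"CDR{i}"]
                        == assign_regions(fv.chain(tag), table)[f"CDR{i}"])

    def test_never_returns_worse_than_input(self, fv, table, memory_records, rng):
        def noisy(f):
            return float(len(f.heavy) % 7) - 3.0

        base = noisy(fv)
        out = framework_swap(fv, memory_records[:10], noisy, table=table)
        assert noisy(out) <= base
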