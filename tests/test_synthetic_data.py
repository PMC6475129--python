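"""Generator determinism, feasibility checks, self-check, and distributions."""

import dataclasses
from pathlib import Path

import numpy as np
import pytest
from scipy import stats as sps

from nanofix.synthetic_data import (
    ConfigError,
    SynthConfig,
    default_pathways,
    generate,
    satisfying_kos,
    self_check,
)


def file_bytes(directory):
    return {p.name: p.read_bytes() for p in sorted(Path(directory).iterdir())}


def small_config(seed, **overrides):
    base = dict(
        seed=seed,
        n_clusters=60,
        sites=(("001", "SRF"), ("002", "MES"), ("003", "DCM")),
        planted_completeness=(
            (("001", "CBB"), 0.8), (("001", "DH"), 0.4),
            (("002", "rTCA"), 0.5), (("003", "WL"), 1.0),
        ),
    )
    base.update(overrides)
    return SynthConfig(**base)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        for sub in ("a", "b"):
            bundle, truth = generate(SynthConfig(seed=1, n_clusters=120))
            bundle.write(tmp_path / sub)
            truth.to_json(tmp_path / sub / "truth.json")
        assert file_bytes(tmp_path / "a") == file_bytes(tmp_path / "b")

    def test_different_seeds_differ(self):
        b1, _ = generate(small_config(1))
        b2, _ = generate(small_config(2))
        assert b1.nr_hits != b2.nr_hits


class TestFeasibility:
    def test_infeasible_planted_completeness_names_pathway(self):
        cfg = small_config(0, planted_completeness=((("001", "HBC"), 0.5),
                                                    (("002", "CBB"), 0.3)))
        with pytest.raises(ConfigError, match="CBB"):
            generate(cfg)  # 0.3 of 5 modules = 1.5 modules

    def test_unknown_pathway_rejected(self):
        cfg = small_config(0, planted_completeness=((("001", "XXX"), 0.5),))
        with pytest.raises(ConfigError, match="XXX"):
            generate(cfg)

    def test_planting_requires_two_sites(self):
        cfg = small_config(
            0, sites=(("001", "SRF"),),
            planted_completeness=((("001", "WL"), 1.0),),
        )
        with pytest.raises(ConfigError, match="two sites"):
            generate(cfg)

    def test_mixture_must_sum_to_one(self):
        cfg = small_config(0, class_mixture=(("novel_ultrasmall", 0.5),))
        with pytest.raises(ConfigError, match="mixture"):
            generate(cfg)

    def test_planted_truth_matches_target(self):
        bundle, truth = generate(small_config(3))
        # 0.8 of CBB's 5 modules at site 001, in every dataset stringency
        for ds in ("UO", "WUO_dm", "PU"):
            assert truth.completeness[("001", "SRF", ds, "CBB")] == pytest.approx(80.0)
            assert truth.completeness[("002", "MES", ds, "rTCA")] == pytest.approx(50.0)


class TestSelfCheck:
    def test_default_bundle_is_internally_consistent(self, default_bundle):
        bundle, truth = default_bundle
        assert self_check(bundle, truth) == []

    def test_mutated_fraction_is_detected_and_named(self, default_bundle):
        bundle, truth = default_bundle
        # move one ultrasmall-only cluster member into the other fraction
        target = next(
            m for m in bundle.meta
            if truth.cluster_tiers[m.cluster_id] == frozenset({"PU", "UO"})
        )
        mutated = dataclasses.replace(bundle)
        mutated.meta = [
            dataclasses.replace(m, size_fraction="other")
            if m.seq_id == target.seq_id else m
            for m in bundle.meta
        ]
        mismatches = self_check(mutated, truth)
        assert any(target.cluster_id in m for m in mismatches)

    @pytest.mark.parametrize("seed", range(12))
    def test_fuzzed_configs_pass_self_check(self, seed):
        rng = np.random.default_rng(seed)
        sites = tuple(
            (f"{i:03d}", ("SRF", "DCM", "MES", "MIX")[i % 4])
            for i in range(int(rng.integers(2, 5)))
        )
        cfg = SynthConfig(
            seed=seed + 100,
            n_clusters=int(rng.integers(30, 120)),
            sites=sites,
            identity_noise=float(rng.choice([0.0, 0.1, 0.3])),
            p_no_hit_novel=float(rng.uniform(0.0, 0.5)),
            planted_completeness=((((sites[0][0]), "HB"), 0.75),),
        )
        bundle, truth = generate(cfg)
        assert self_check(bundle, truth) == []


class TestDistributions:
    def test_class_conditional_identity_recovered(self):
        """KS distance of realised identities vs the configured uniform laws."""
        bundle, truth = generate(SynthConfig(seed=17, n_clusters=2500,
                                             p_no_hit_novel=0.0, p_extra_hit=0.0))
        best = {}
        for h in bundle.nr_hits:
            cur = best.get(h.query_id)
            if cur is None or h.bitscore > cur.bitscore:
                best[h.query_id] = h
        meta_cluster = {m.seq_id: m.cluster_id for m in bundle.meta}
        for cls, (lo, hi) in (("novel_ultrasmall", (45.0, 68.0)),
                              ("known_regular", (92.0, 99.0))):
            ids = np.array([
                h.pct_identity for s, h in best.items()
                if truth.cluster_class[meta_cluster[s]] == cls
            ])
            assert len(ids) >= 1000
            stat = sps.kstest(ids, "uniform", args=(lo, hi - lo)).statistic
            assert stat < 0.05

    def test_generated_hits_respect_invariants_under_noise(self):
        # AlignmentHit validates its invariants on construction; generating
        # under heavy noise exercises that nothing out-of-contract is emitted
        bundle, _ = generate(small_config(5, identity_noise=0.5))
        for h in bundle.nr_hits + bundle.kegg_hits + bundle.virome_hits:
            assert 1 <= h.qstart <= h.qend <= h.qlen
            assert 1 <= min(h.sstart, h.send) and max(h.sstart, h.send) <= h.slen


class TestPathwayStandins:
    def test_six_pathways_with_disjoint_ko_blocks(self):
        pathways = default_pathways()
        assert [p.pathway_id for p in pathways] == [
            "CBB", "rTCA", "HBC", "WL", "DH", "HB"]
        all_sets = [p.all_kos() for p in pathways]
        for i, s in enumerate(all_sets):
            for t in all_sets[i + 1:]:
                assert not s & t

    def test_every_pathway_declares_a_key_enzyme(self):
        for p in default_pathways():
            assert p.key_kos
            assert p.key_modules

    def test_satisfying_set_satisfies(self):
        for p in default_pathways():
            for module in p.modules:
                assert module.expression.evaluate(satisfying_kos(module))
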