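import numpy as np
import pandas as pd
import pytest

from unigroup import group_builder as gb
from unigroup import profile_model as pm
from unigroup.cli import run_stages
from unigroup.group_builder import (
    Candidate,
    GeneGroup,
    PipelineConfig,
    assign_exclusive,
    finalize_universal,
    optimize_group,
    prune_sparse,
    rescue_from_unassigned,
    seed_groups,
)
from unigroup.pairwise import collapse_reference_clusters
from unigroup.seqio import OrthologTable, PeptideRecord, SpeciesPeptideSet
from unigroup.synthetic_data import evolve_sequence, random_peptide

from conftest import best_family, group_from_members, make_config, make_inputs


def rec(pep_id, species, seq, gene=None):
    return PeptideRecord(pep_id=pep_id, gene_id=gene or pep_id.rsplit(".", 1)[0],
                         species=species, sequence=seq)


def pepset(species, records):
    return SpeciesPeptideSet(species=species, records=records)


def table(ref, rows):
    return OrthologTable(
        reference_species=ref,
        rows=pd.DataFrame(rows, columns=["ref_gene", "target_species",
                                         "target_gene", "confidence"]),
    )


class TestConfig:
    def test_min_present_count(self):
        cfg = PipelineConfig(species_order=[f"s{i}" for i in range(16)])
        assert cfg.min_present_count == 12

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(species_order=["a"], min_present_fraction=0.0)

    def test_reference_must_be_listed(self):
        with pytest.raises(ValueError):
            PipelineConfig(species_order=["a", "b"], reference_species=("a", "z"))


def four_species_world(rng):
    """Two families across (r1, m1, s3, s4) plus one maize-only family."""
    fams = {f: random_peptide(80, rng) for f in ("A", "B", "C")}
    seqs = {
        (f, sp): evolve_sequence(fams[f], 0.03, rng)
        for f in fams
        for sp in ("r1", "m1", "s3", "s4")
    }
    peps = {
        "r1": pepset("r1", [rec("r1_gA.p1", "r1", seqs[("A", "r1")]),
                            rec("r1_gB.p1", "r1", seqs[("B", "r1")])]),
        "m1": pepset("m1", [rec("m1_gA.p1", "m1", seqs[("A", "m1")]),
                            rec("m1_gB.p1", "m1", seqs[("B", "m1")]),
                            rec("m1_gC.p1", "m1", seqs[("C", "m1")])]),
        "s3": pepset("s3", [rec("s3_gA.p1", "s3", seqs[("A", "s3")]),
                            rec("s3_gB.p1", "s3", seqs[("B", "s3")]),
                            rec("s3_gC.p1", "s3", seqs[("C", "s3")])]),
        "s4": pepset("s4", [rec("s4_gA.p1", "s4", seqs[("A", "s4")]),
                            rec("s4_gB.p1", "s4", seqs[("B", "s4")]),
                            rec("s4_gC.p1", "s4", seqs[("C", "s4")])]),
    }
    cfg = PipelineConfig(species_order=["r1", "m1", "s3", "s4"],
                         reference_species=("r1", "m1"),
                         min_present_fraction=0.75)
    return peps, cfg, seqs


def clusters_for(peps, cfg):
    c1 = collapse_reference_clusters(list(peps["r1"]), cfg.cluster_identity_pct, "r")
    c2 = collapse_reference_clusters(list(peps["m1"]), cfg.cluster_identity_pct, "m")
    return c1, c2


class TestSeedGroups:
    def test_ortholog_everywhere_makes_full_group(self, rng):
        peps, cfg, _ = four_species_world(rng)
        t1 = table("r1", [("r1_gA", "m1", "m1_gA", 1), ("r1_gA", "s3", "s3_gA", 1),
                          ("r1_gA", "s4", "s4_gA", 1),
                          ("r1_gB", "m1", "m1_gB", 1), ("r1_gB", "s3", "s3_gB", 1),
                          ("r1_gB", "s4", "s4_gB", 1)])
        t2 = table("m1", [("m1_gA", "r1", "r1_gA", 1), ("m1_gA", "s3", "s3_gA", 1),
                          ("m1_gA", "s4", "s4_gA", 1)])
        c1, c2 = clusters_for(peps, cfg)
        groups = seed_groups(t1, t2, c1, c2, peps, cfg)
        gA = next(g for g in groups if "r1_gA.p1" in g.pinned)
        assert set(gA.candidates) == {"r1", "m1", "s3", "s4"}
        assert "+" in gA.group_id  # merged with the maize cluster

    def test_best_hit_orthologous_to_other_rice_gene_not_merged(self, rng):
        peps, cfg, _ = four_species_world(rng)
        # gA has no maize ortholog row; best maize hit m1_gA is claimed by rice gB
        t1 = table("r1", [("r1_gA", "s3", "s3_gA", 1), ("r1_gA", "s4", "s4_gA", 1)])
        t2 = table("m1", [("m1_gA", "r1", "r1_gB", 1)])
        c1, c2 = clusters_for(peps, cfg)
        groups = seed_groups(t1, t2, c1, c2, peps, cfg)
        gA = next(g for g in groups if "r1_gA.p1" in g.pinned)
        assert "m1" not in gA.candidates
        assert "+" not in gA.group_id

    def test_maize_only_group_when_rice_has_nothing_similar(self, rng):
        peps, cfg, _ = four_species_world(rng)
        t1 = table("r1", [])
        t2 = table("m1", [("m1_gC", "s3", "s3_gC", 1), ("m1_gC", "s4", "s4_gC", 1)])
        c1, c2 = clusters_for(peps, cfg)
        groups = seed_groups(t1, t2, c1, c2, peps, cfg)
        gC = [g for g in groups if "m1_gC.p1" in g.pinned]
        assert len(gC) == 1
        assert set(gC[0].candidates) == {"m1", "s3", "s4"}
        assert gC[0].group_id.startswith("m")

    def test_reference_species_missing_rejected(self, rng):
        peps, cfg, _ = four_species_world(rng)
        del peps["m1"]
        with pytest.raises(ValueError, match="reference"):
            seed_groups(table("r1", []), table("m1", []), [], [], peps, cfg)


def bare_group(gid, ref, candidates):
    g = GeneGroup(group_id=gid, ref_record=ref)
    for sp, cands in candidates.items():
        g.candidates[sp] = list(cands)
    g.original_candidates = {
        sp: [Candidate(c.record, c.confidence, c.similarity) for c in lst]
        for sp, lst in g.candidates.items()
    }
    return g


class TestAssignExclusive:
    def setup_method(self):
        self.ref = rec("r1_g1.p1", "r1", "MKVLIMKVLI")
        self.shared = rec("s3_g9.p1", "s3", "MKVLIMKVLV")

    def _pair(self, conf_a, conf_b, sim_a=90.0, sim_b=90.0):
        ga = bare_group("g_a", self.ref,
                        {"s3": [Candidate(self.shared, conf_a, sim_a)]})
        gb_ = bare_group("g_b", self.ref,
                         {"s3": [Candidate(self.shared, conf_b, sim_b)]})
        return ga, gb_

    def test_confidence_wins(self):
        ga, gb_ = self._pair(0, 1)
        assign_exclusive([ga, gb_])
        assert "s3" not in ga.candidates
        assert len(gb_.candidates["s3"]) == 1

    def test_similarity_breaks_confidence_tie(self):
        ga, gb_ = self._pair(1, 1, sim_a=88.0, sim_b=92.0)
        assign_exclusive([ga, gb_])
        assert "s3" not in ga.candidates
        assert "s3" in gb_.candidates

    def test_full_tie_goes_to_smaller_group_id(self):
        ga, gb_ = self._pair(1, 1, sim_a=90.0, sim_b=90.0)
        assign_exclusive([ga, gb_])
        assert "s3" in ga.candidates
        assert "s3" not in gb_.candidates

    def test_pinned_peps_stay_home(self):
        pinned = rec("r1_g2.p1", "r1", "MKVLIMKVLI")
        ga = bare_group("g_a", self.ref, {"r1": [Candidate(pinned, 1, 100.0)]})
        ga.pinned.add(pinned.pep_id)
        gb_ = bare_group("g_b", self.ref, {"r1": [Candidate(pinned, 1, 100.0)]})
        assign_exclusive([ga, gb_])
        assert "r1" in ga.candidates
        assert "r1" not in gb_.candidates


class TestPruneSparse:
    def _group_with_coverage(self, gid, species, n_covered, shared=None):
        ref = rec(f"{gid}_ref", species[0], "MKVLIMKVLI")
        cands = {}
        for sp in species[:n_covered]:
            r = rec(f"{gid}_{sp}.p1", sp, "MKVLIMKVLI")
            cands[sp] = [Candidate(r, 1, 95.0)]
        if shared is not None:
            sp, cand = shared
            cands.setdefault(sp, []).append(cand)
        return bare_group(gid, ref, cands)

    def test_eleven_of_sixteen_deleted_twelve_kept(self):
        species = [f"s{i:02d}" for i in range(16)]
        cfg = PipelineConfig(species_order=species)
        g11 = self._group_with_coverage("g11", species, 11)
        g12 = self._group_with_coverage("g12", species, 12)
        prune_sparse([g11, g12], cfg)
        assert g11.status == "discarded"
        assert g11.reason == "sparse"
        assert g12.status != "discarded"

    def test_deleted_groups_candidates_reassigned(self):
        species = [f"s{i:02d}" for i in range(16)]
        cfg = PipelineConfig(species_order=species)
        shared_rec = rec("shared.p1", "s05", "MKVLIMKVLI")
        shared = Candidate(shared_rec, 1, 99.0)
        doomed = self._group_with_coverage("a_doomed", species, 11,
                                           shared=("s05", shared))
        survivor = self._group_with_coverage("b_live", species, 12,
                                             shared=("s05", Candidate(shared_rec, 0, 99.0)))
        # before pruning the doomed group outranks (confidence 1 beats 0)
        assign_exclusive([doomed, survivor])
        assert all(c.record.pep_id != "shared.p1"
                   for c in survivor.candidates.get("s05", []))
        prune_sparse([doomed, survivor], cfg)
        assert doomed.status == "discarded"
        assert any(c.record.pep_id == "shared.p1"
                   for c in survivor.candidates.get("s05", []))


def planted_family(rng, n_species=8, length=300, rate=0.04):
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    anc = random_peptide(length, rng)
    return species, {sp: evolve_sequence(anc, rate, rng) for sp in species}


def candidate_group(gid, species, members, extra=None):
    """Group whose candidates are exactly one member per species (+extras)."""
    recs = {sp: rec(f"{gid}_{sp}.p1", sp, seq) for sp, seq in members.items()}
    g = GeneGroup(group_id=gid, ref_record=recs.get(species[0], next(iter(recs.values()))))
    for sp in species:
        if sp in recs:
            g.candidates[sp] = [Candidate(recs[sp], 1, 100.0)]
    if extra:
        for sp, cand in extra:
            g.candidates[sp].append(cand)
    g.original_candidates = {sp: list(v) for sp, v in g.candidates.items()}
    return g


class TestOptimizeGroup:
    def test_single_candidates_fixpoint_no_substitutions(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        g = candidate_group("g1", species, members)
        optimize_group(g, cfg)
        assert g.status == "optimized"
        assert g.substitutions == []
        assert set(g.members) == set(species)

    def test_truncated_top_candidate_replaced_by_full_length(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        sp = species[3]
        full = rec("alt_full.p1", sp, members[sp])
        trunc = rec("top_trunc.p1", sp, members[sp][: len(members[sp]) // 2])
        g = candidate_group("g1", species, {s: q for s, q in members.items() if s != sp})
        # confidence makes the truncated variant the initial member
        g.candidates[sp] = [Candidate(trunc, 1, None), Candidate(full, 0, None)]
        g.original_candidates[sp] = list(g.candidates[sp])
        optimize_group(g, cfg)
        assert g.members[sp].pep_id == "alt_full.p1"
        subs = [s for s in g.substitutions if s["species"] == sp]
        assert len(subs) == 1
        assert subs[0]["delta_R"] > cfg.delta_improve

    def test_marginal_improvement_rejected(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        sp = species[3]
        better = members[sp]
        pos = 150
        worse = better[:pos] + ("W" if better[pos] != "W" else "Y") + better[pos + 1:]
        g = candidate_group("g1", species, {s: q for s, q in members.items() if s != sp})
        g.candidates[sp] = [Candidate(rec("cur.p1", sp, worse), 1, None),
                            Candidate(rec("alt.p1", sp, better), 0, None)]
        g.original_candidates[sp] = list(g.candidates[sp])
        optimize_group(g, cfg)
        # independent oracle: score both choices against the optimized profile
        delta = (pm.score(g.profile, better).R - pm.score(g.profile, worse).R)
        assert 0.0 < delta <= cfg.delta_improve
        assert g.members[sp].pep_id == "cur.p1"

    def test_substitution_log_deltas_positive(self, small_result):
        for g in small_result.groups:
            for s in g.substitutions:
                if s["stage"] == "optimize":
                    assert s["delta_R"] > small_result.config.delta_improve


class TestRescueFromUnassigned:
    def test_hole_filled_by_unassigned_hit(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        sp = species[5]
        held_out = members.pop(sp)
        g = candidate_group("g1", species, members)
        optimize_group(g, cfg)
        assert sp not in g.members
        peps = {s: pepset(s, []) for s in species}
        peps[sp].records.append(rec("late.p1", sp, held_out))
        rescue_from_unassigned([g], peps, cfg)
        assert g.members[sp].pep_id == "late.p1"
        assert g.member_R[sp] > 0.65

    def test_member_of_other_group_never_offered(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        sp = species[5]
        held_out = members.pop(sp)
        g = candidate_group("g1", species, members)
        optimize_group(g, cfg)
        owner = candidate_group("g0", species, {sp: held_out})
        owner.members = {sp: owner.candidates[sp][0].record}
        owner.status = "optimized"
        gb._build_profile(owner, cfg)
        peps = {s: pepset(s, []) for s in species}
        peps[sp].records.append(owner.members[sp])
        rescue_from_unassigned([owner, g], peps, cfg)
        assert sp not in g.members

    def test_sub_threshold_peps_not_offered(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        sp = species[5]
        members.pop(sp)
        g = candidate_group("g1", species, members)
        optimize_group(g, cfg)
        peps = {s: pepset(s, []) for s in species}
        peps[sp].records.append(rec("junk.p1", sp, "MWYWYWYWYWYWYWYWYWYWYWYWYWYWYW"))
        rescue_from_unassigned([g], peps, cfg)
        assert sp not in g.members


class TestFinalize:
    def test_full_coverage_above_threshold_universal(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        g = candidate_group("g1", species, members)
        optimize_group(g, cfg)
        finalize_universal([g], cfg)
        assert g.status == "universal"
        assert g.min_R >= cfg.r_min

    def test_threshold_boundary_inclusive(self, rng):
        species, members = planted_family(rng)
        g0 = candidate_group("g1", species,
                             members)
        cfg = PipelineConfig(species_order=species)
        optimize_group(g0, cfg)
        gb.finalize_universal([g0], cfg)
        min_R = g0.min_R
        at = PipelineConfig(species_order=species, r_min=min_R)
        g0.status = "optimized"
        finalize_universal([g0], at)
        assert g0.status == "universal"  # min_R >= r_min is inclusive
        above = PipelineConfig(species_order=species, r_min=min(1.0, min_R + 1e-6))
        g0.status = "optimized"
        finalize_universal([g0], above)
        assert (g0.status, g0.reason) == ("discarded", "low_R")

    def test_low_scoring_member_discarded(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        sp = species[-1]
        members[sp] = random_peptide(len(members[sp]), rng)  # unrelated member
        g = candidate_group("g1", species, members)
        optimize_group(g, cfg)
        finalize_universal([g], cfg)
        assert (g.status, g.reason) == ("discarded", "low_R")

    def test_missing_species_discarded(self, rng):
        species, members = planted_family(rng)
        cfg = PipelineConfig(species_order=species)
        members.pop(species[2])
        g = candidate_group("g1", species, members)
        optimize_group(g, cfg)
        finalize_universal([g], cfg)
        assert g.status == "discarded"
        assert g.reason.startswith("missing_species")
        assert species[2] in g.reason


class TestPipelineInvariants:
    def test_membership_exclusive(self, small_result):
        gb.assert_exclusive_membership(small_result.groups)

    def test_universal_groups_full_and_conserved(self, small_result):
        cfg = small_result.config
        for g in small_result.universal():
            assert set(g.members) == set(cfg.species_order)
            assert g.min_R >= cfg.r_min

    def test_synthetic_recovery_small(self, sim_small, small_result):
        truth = sim_small.truth
        uni = small_result.universal()
        planted = {fid for fid, f in truth.families.items() if f.kind == "universal"}
        recovered = {best_family(g, sim_small) for g in uni}
        # every group maps to a planted family; every family is found
        assert all(f is not None for f in recovered)
        mapped = {f for f in recovered
                  if truth.families[f].kind in ("universal", "duplicate")}
        covered = {truth.families[f].duplication_partner
                   if truth.families[f].kind == "duplicate" else f
                   for f in mapped}
        assert planted <= covered
        assert len(uni) >= len(planted)

    def test_determinism_in_memory(self, sim_small, small_config):
        r1 = run_stages(make_inputs(sim_small), make_config(sim_small))
        r2 = run_stages(make_inputs(sim_small), make_config(sim_small))
        m1 = [(g.group_id, g.status, sorted((sp, r.pep_id) for sp, r in g.members.items()))
              for g in r1.groups]
        m2 = [(g.group_id, g.status, sorted((sp, r.pep_id) for sp, r in g.members.items()))
              for g in r2.groups]
        assert m1 == m2
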