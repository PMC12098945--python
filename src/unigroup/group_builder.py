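"""Seed, refine and finalize universal gene groups.

Groups are seeded from the ortholog tables of two reference species,
candidates are made exclusive to one group, sparse groups are pruned,
membership is optimized (one peptide per species) against the group
profile, unassigned peptides are offered back, and groups are graded
universal when every species is covered and the lowest member R clears
the conservation threshold.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from . import profile_model
from .pairwise import RefCluster, global_identity
from .profile_model import MSA, ProfileModel, ProfileError
from .seqio import OrthologTable, PeptideRecord, SpeciesPeptideSet

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the pipeline, with their defaults."""

    species_order: list[str]
    reference_species: tuple[str, str] | None = None
    r_min: float = 0.65
    delta_improve: float = 0.01
    cluster_identity_pct: float = 90.0
    min_present_fraction: float = 0.75
    max_rescued: int = 4
    specificity_cutoff: float = 0.25
    min_raw_bits: float = 10.0
    delete_bits: float = 2.0
    insert_open_bits: float = 3.0
    insert_extend_bits: float = 1.0
    max_passes: int = 5
    seed_similarity_pct: float = 50.0
    rebuild_per_substitution: bool = True
    novelty_exact: bool = False
    supergroup_clique: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_present_fraction <= 1.0:
            raise ValueError("min_present_fraction out of range")
        if not 0.0 <= self.r_min <= 1.0:
            raise ValueError("r_min out of range")
        if self.delta_improve < 0:
            raise ValueError("delta_improve must be >= 0")
        if self.reference_species is not None:
            for sp in self.reference_species:
                if sp not in self.species_order:
                    raise ValueError(f"reference species {sp!r} not in species_order")

    @property
    def n_species(self) -> int:
        return len(self.species_order)

    @property
    def min_present_count(self) -> int:
        return math.ceil(self.min_present_fraction * self.n_species)

    @property
    def min_annotated_count(self) -> int:
        return math.ceil(self.min_present_fraction * self.n_species)

    def profile_kwargs(self) -> dict:
        return dict(
            delete_bits=self.delete_bits,
            insert_open_bits=self.insert_open_bits,
            insert_extend_bits=self.insert_extend_bits,
        )


@dataclass
class Candidate:
    record: PeptideRecord
    confidence: int
    similarity: float | None = None  # % identity to the group's reference pep


@dataclass
class GeneGroup:
    group_id: str
    ref_record: PeptideRecord
    candidates: dict[str, list[Candidate]] = field(default_factory=dict)
    members: dict[str, PeptideRecord] = field(default_factory=dict)
    member_R: dict[str, float] = field(default_factory=dict)
    status: str = "seeded"  # seeded | optimized | universal | discarded
    reason: str = ""
    msa: MSA | None = None
    profile: ProfileModel | None = None
    pinned: set[str] = field(default_factory=set)
    original_candidates: dict[str, list[Candidate]] = field(default_factory=dict)
    substitutions: list[dict] = field(default_factory=list)
    n_rescued: int = 0

    @property
    def min_R(self) -> float:
        return min(self.member_R.values()) if self.member_R else float("nan")

    def coverage(self, species_order: Sequence[str]) -> int:
        return sum(1 for sp in species_order if self.candidates.get(sp))

    def member_ids(self) -> set[str]:
        return {r.pep_id for r in self.members.values()}

    def add_candidate(self, species: str, record: PeptideRecord, confidence: int) -> None:
        lst = self.candidates.setdefault(species, [])
        for c in lst:
            if c.record.pep_id == record.pep_id:
                c.confidence = max(c.confidence, confidence)
                return
        lst.append(Candidate(record=record, confidence=confidence))


def _similarity(group: GeneGroup, cand: Candidate) -> float:
    if cand.similarity is None:
        if cand.record.pep_id == group.ref_record.pep_id:
            cand.similarity = 100.0
        else:
            ident = global_identity(cand.record.sequence, group.ref_record.sequence)
            cand.similarity = (ident.pct_ab + ident.pct_ba) / 2.0
    return cand.similarity


def rank_key(group: GeneGroup, cand: Candidate) -> tuple:
    """Candidate ranking: confidence desc, similarity desc, pep_id asc."""
    return (-cand.confidence, -_similarity(group, cand), cand.record.pep_id)


def default_best_hit(seq: str, pepset: SpeciesPeptideSet) -> tuple[PeptideRecord | None, float]:
    """Most similar peptide of a set by mean bidirectional global identity."""
    best: PeptideRecord | None = None
    best_sim = -1.0
    for rec in pepset:
        ident = global_identity(seq, rec.sequence)
        sim = (ident.pct_ab + ident.pct_ba) / 2.0
        if sim > best_sim:
            best, best_sim = rec, sim
    return best, best_sim


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def seed_groups(table1: OrthologTable, table2: OrthologTable,
                clusters1: Sequence[RefCluster], clusters2: Sequence[RefCluster],
                peps: Mapping[str, SpeciesPeptideSet], config: PipelineConfig,
                best_hit_fn: Callable | None = None) -> list[GeneGroup]:
    """One group per first-reference cluster, merged with the second reference.

    The second reference's entries are merged when orthologous, or via a
    best-hit search when not (provided the hit is not orthologous to a
    different first-reference gene); second-reference-only groups are
    created for clusters the first reference cannot seed.
    """
    ref1, ref2 = table1.reference_species, table2.reference_species
    if ref1 not in peps or ref2 not in peps:
        raise ValueError("reference species absent from peptide sets")
    if best_hit_fn is None:
        best_hit_fn = default_best_hit

    peps1 = peps[ref1].by_pep_id()
    peps2 = peps[ref2].by_pep_id()
    genes1 = peps[ref1].by_gene()
    genes2 = peps[ref2].by_gene()
    cluster_of_gene2 = {}
    cluster_by_id2 = {c.cluster_id: c for c in clusters2}
    for c in clusters2:
        for pid in c.pep_ids:
            cluster_of_gene2.setdefault(peps2[pid].gene_id, c.cluster_id)

    t1 = table1.rows
    t2 = table2.rows
    rows1_by_gene: dict[str, list] = {}
    for row in t1.itertuples(index=False):
        rows1_by_gene.setdefault(row.ref_gene, []).append(row)
    rows2_by_gene: dict[str, list] = {}
    for row in t2.itertuples(index=False):
        rows2_by_gene.setdefault(row.ref_gene, []).append(row)

    groups: list[GeneGroup] = []
    absorbed_clusters2: set[str] = set()

    def pep_records_of_gene(species: str, gene: str) -> list[PeptideRecord]:
        if species == ref1:
            return genes1.get(gene, [])
        if species == ref2:
            return genes2.get(gene, [])
        return peps[species].by_gene().get(gene, []) if species in peps else []

    gene_index: dict[str, dict[str, list[PeptideRecord]]] = {
        sp: peps[sp].by_gene() for sp in peps
    }

    def import_ref2_orthologs(group: GeneGroup, ref2_gene: str, conf: int) -> None:
        for rec in genes2.get(ref2_gene, []):
            group.add_candidate(ref2, rec, conf)
        for row in rows2_by_gene.get(ref2_gene, []):
            if row.target_species in (ref1, ref2) or row.target_species not in gene_index:
                continue
            for rec in gene_index[row.target_species].get(row.target_gene, []):
                group.add_candidate(row.target_species, rec, int(row.confidence))

    for c1 in clusters1:
        rep = peps1[c1.pep_ids[0]]
        group = GeneGroup(group_id=c1.cluster_id, ref_record=rep)
        cluster_genes1 = []
        for pid in c1.pep_ids:
            rec = peps1[pid]
            group.add_candidate(ref1, rec, 1)
            group.pinned.add(pid)
            if rec.gene_id not in cluster_genes1:
                cluster_genes1.append(rec.gene_id)

        ref2_links: list[tuple[str, int]] = []
        for gene in cluster_genes1:
            for row in rows1_by_gene.get(gene, []):
                if row.target_species == ref2:
                    ref2_links.append((row.target_gene, int(row.confidence)))
                elif row.target_species in gene_index and row.target_species != ref1:
                    for rec in gene_index[row.target_species].get(row.target_gene, []):
                        group.add_candidate(row.target_species, rec, int(row.confidence))

        if ref2_links:
            for g2, conf in ref2_links:
                import_ref2_orthologs(group, g2, conf)
                cid2 = cluster_of_gene2.get(g2)
                if cid2:
                    absorbed_clusters2.add(cid2)
            first_cid2 = cluster_of_gene2.get(ref2_links[0][0])
            if first_cid2:
                group.group_id = f"{c1.cluster_id}+{first_cid2}"
        else:
            # no orthologous second-reference gene: try the best similarity hit
            hit, sim = best_hit_fn(rep.sequence, peps[ref2])
            if hit is not None and sim >= config.seed_similarity_pct:
                other_rice = False
                for row in rows2_by_gene.get(hit.gene_id, []):
                    if row.target_species == ref1 and row.target_gene not in cluster_genes1:
                        other_rice = True
                        break
                if not other_rice:
                    import_ref2_orthologs(group, hit.gene_id, 0)
                    cid2 = cluster_of_gene2.get(hit.gene_id)
                    if cid2:
                        absorbed_clusters2.add(cid2)
                        group.group_id = f"{c1.cluster_id}+{cid2}"
        groups.append(group)

    # second-reference-only groups where the first reference has nothing similar
    for c2 in clusters2:
        if c2.cluster_id in absorbed_clusters2:
            continue
        rep2 = peps2[c2.pep_ids[0]]
        cluster_genes2 = {peps2[pid].gene_id for pid in c2.pep_ids}
        has_ref1_ortholog = any(
            row.target_species == ref1
            for g in cluster_genes2
            for row in rows2_by_gene.get(g, [])
        )
        if has_ref1_ortholog:
            continue
        hit, sim = best_hit_fn(rep2.sequence, peps[ref1])
        if hit is not None and sim >= config.seed_similarity_pct:
            continue
        group = GeneGroup(group_id=c2.cluster_id, ref_record=rep2)
        for pid in c2.pep_ids:
            group.add_candidate(ref2, peps2[pid], 1)
            group.pinned.add(pid)
        for g in sorted(cluster_genes2):
            import_ref2_orthologs(group, g, 1)
        groups.append(group)

    groups.sort(key=lambda g: g.group_id)
    for g in groups:
        g.original_candidates = {
            sp: [Candidate(c.record, c.confidence) for c in lst]
            for sp, lst in g.candidates.items()
        }
    return groups


# ---------------------------------------------------------------------------
# Exclusive assignment and pruning
# ---------------------------------------------------------------------------


def assign_exclusive(groups: Sequence[GeneGroup]) -> list[GeneGroup]:
    """Keep each candidate peptide in exactly one group.

    Rank: ortholog confidence desc, similarity to the group reference desc,
    then lexicographically smaller group id.  Peptides pinned to their seed
    cluster always stay with that group.
    """
    holders: dict[str, list[tuple[GeneGroup, str, Candidate]]] = {}
    pinned_home: dict[str, str] = {}
    for g in groups:
        for pid in g.pinned:
            pinned_home[pid] = g.group_id
        for sp, lst in g.candidates.items():
            for cand in lst:
                holders.setdefault(cand.record.pep_id, []).append((g, sp, cand))

    for pid in sorted(holders):
        entries = holders[pid]
        if len(entries) == 1:
            continue
        if pid in pinned_home:
            keep_id = pinned_home[pid]
        else:
            ranked = sorted(
                entries,
                key=lambda e: (-e[2].confidence, -_similarity(e[0], e[2]), e[0].group_id),
            )
            keep_id = ranked[0][0].group_id
        for g, sp, cand in entries:
            if g.group_id != keep_id:
                g.candidates[sp] = [c for c in g.candidates[sp] if c.record.pep_id != pid]
    for g in groups:
        g.candidates = {sp: lst for sp, lst in g.candidates.items() if lst}
    return list(groups)


def prune_sparse(groups: Sequence[GeneGroup], config: PipelineConfig) -> list[GeneGroup]:
    """Delete under-covered groups, reassigning their candidates, to fixpoint."""
    needed = config.min_present_count
    alive = [g for g in groups if g.status != "discarded"]
    while True:
        doomed = [g for g in alive if g.coverage(config.species_order) < needed]
        if not doomed:
            break
        for g in doomed:
            g.status = "discarded"
            g.reason = "sparse"
            g.candidates = {}
        alive = [g for g in alive if g.status != "discarded"]
        # re-offer every originally listed candidate to the surviving groups
        for g in alive:
            g.candidates = {
                sp: [Candidate(c.record, c.confidence) for c in lst]
                for sp, lst in g.original_candidates.items()
            }
        assign_exclusive(alive)
    return list(groups)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


def _build_profile(group: GeneGroup, config: PipelineConfig) -> None:
    order = [sp for sp in config.species_order if sp in group.members]
    seqs = [group.members[sp].sequence for sp in order]
    ids = [group.members[sp].pep_id for sp in order]
    group.msa = profile_model.build_msa(seqs, ids)
    group.profile = profile_model.build_profile(group.msa, **config.profile_kwargs())


def score_R(profile: ProfileModel, seq: str) -> float:
    return profile_model.score(profile, seq).R


def optimize_group(group: GeneGroup, config: PipelineConfig) -> GeneGroup:
    """One member per species, iteratively improved under the ΔR rule.

    Starts from the top-ranked candidate per species; an alternative
    replaces the member only when its R against the current profile beats
    the member's by more than ``delta_improve``; the profile is rebuilt
    after each accepted substitution (configurable to once per pass).
    """
    if group.status == "discarded":
        return group
    ranked: dict[str, list[Candidate]] = {}
    for sp in config.species_order:
        lst = group.candidates.get(sp, [])
        if lst:
            ranked[sp] = sorted(lst, key=lambda c: rank_key(group, c))
    if len(ranked) < config.min_present_count:
        group.status = "discarded"
        group.reason = "sparse"
        return group
    group.members = {sp: lst[0].record for sp, lst in ranked.items()}
    try:
        _build_profile(group, config)
    except ProfileError as exc:
        group.status = "discarded"
        group.reason = f"degenerate_profile: {exc}"
        return group

    for pass_no in range(1, config.max_passes + 1):
        changed = False
        for sp in config.species_order:
            lst = ranked.get(sp)
            if not lst or len(lst) < 2:
                continue
            current = group.members[sp]
            cur_R = score_R(group.profile, current.sequence)
            best_alt, best_R = None, cur_R
            for cand in lst:
                if cand.record.pep_id == current.pep_id:
                    continue
                alt_R = score_R(group.profile, cand.record.sequence)
                if alt_R > best_R:
                    best_alt, best_R = cand.record, alt_R
            if best_alt is not None and best_R > cur_R + config.delta_improve:
                group.substitutions.append(
                    {
                        "group_id": group.group_id,
                        "stage": "optimize",
                        "pass": pass_no,
                        "species": sp,
                        "old_pep": current.pep_id,
                        "new_pep": best_alt.pep_id,
                        "delta_R": best_R - cur_R,
                    }
                )
                group.members[sp] = best_alt
                changed = True
                if config.rebuild_per_substitution:
                    _build_profile(group, config)
        if not config.rebuild_per_substitution and changed:
            _build_profile(group, config)
        if not changed:
            break
    else:
        log.warning("group %s: optimization did not reach a fixpoint in %d passes",
                    group.group_id, config.max_passes)

    _recompute_member_R(group)
    group.status = "optimized"
    return group


def _recompute_member_R(group: GeneGroup) -> None:
    group.member_R = {
        sp: score_R(group.profile, rec.sequence) for sp, rec in group.members.items()
    }


# ---------------------------------------------------------------------------
# Rescue from unassigned annotated peptides
# ---------------------------------------------------------------------------


def rescue_from_unassigned(groups: Sequence[GeneGroup],
                           peps: Mapping[str, SpeciesPeptideSet],
                           config: PipelineConfig) -> list[GeneGroup]:
    """Offer peptides that are members of no group back to the groups.

    A hole (species with no member) is filled by the best-scoring unassigned
    hit; an existing member is replaced under the ΔR > delta_improve rule.
    Adopted peptides immediately become members (exclusive); displaced
    members return to the unassigned pool.
    """
    member_ids: set[str] = set()
    for g in groups:
        if g.status != "discarded":
            member_ids |= g.member_ids()
    pool: dict[str, list[PeptideRecord]] = {
        sp: [r for r in peps[sp] if r.pep_id not in member_ids]
        for sp in config.species_order
        if sp in peps
    }

    for group in sorted((g for g in groups if g.status == "optimized"),
                        key=lambda g: g.group_id):
        changed = False
        for sp in config.species_order:
            available = pool.get(sp, [])
            if not available:
                continue
            scored: list[tuple[float, PeptideRecord]] = []
            for rec in available:
                ps = profile_model.score(group.profile, rec.sequence)
                if profile_model.hit_filter(ps, config.min_raw_bits):
                    scored.append((ps.R, rec))
            if not scored:
                continue
            scored.sort(key=lambda t: (-t[0], t[1].pep_id))
            best_R, best = scored[0]
            if sp not in group.members:
                group.members[sp] = best
                group.substitutions.append(
                    {
                        "group_id": group.group_id,
                        "stage": "unassigned",
                        "pass": 0,
                        "species": sp,
                        "old_pep": "",
                        "new_pep": best.pep_id,
                        "delta_R": best_R,
                    }
                )
                pool[sp] = [r for r in pool[sp] if r.pep_id != best.pep_id]
                changed = True
                _build_profile(group, config)
            else:
                cur_R = score_R(group.profile, group.members[sp].sequence)
                if best_R > cur_R + config.delta_improve:
                    old = group.members[sp]
                    group.members[sp] = best
                    group.substitutions.append(
                        {
                            "group_id": group.group_id,
                            "stage": "unassigned",
                            "pass": 0,
                            "species": sp,
                            "old_pep": old.pep_id,
                            "new_pep": best.pep_id,
                            "delta_R": best_R - cur_R,
                        }
                    )
                    pool[sp] = [r for r in pool[sp] if r.pep_id != best.pep_id]
                    pool[sp].append(old)
                    changed = True
                    _build_profile(group, config)
        if changed:
            _recompute_member_R(group)
    return list(groups)


# ---------------------------------------------------------------------------
# Finalization
# ---------------------------------------------------------------------------


def finalize_universal(groups: Sequence[GeneGroup], config: PipelineConfig) -> list[GeneGroup]:
    """Grade groups: universal iff full coverage and min member R >= r_min."""
    for group in groups:
        if group.status == "discarded":
            continue
        if group.profile is None:
            group.status = "discarded"
            group.reason = "no_profile"
            continue
        _recompute_member_R(group)
        missing = [sp for sp in config.species_order if sp not in group.members]
        if missing:
            group.status = "discarded"
            group.reason = f"missing_species:{','.join(missing)}"
        elif group.min_R < config.r_min:
            group.status = "discarded"
            group.reason = "low_R"
        else:
            group.status = "universal"
    return list(groups)


def universal_groups(groups: Iterable[GeneGroup]) -> list[GeneGroup]:
    return sorted((g for g in groups if g.status == "universal"), key=lambda g: g.group_id)


def write_substitution_log(groups: Iterable[GeneGroup], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("group_id\tstage\tpass\tspecies\told_pep\tnew_pep\tdelta_R\n")
        for g in sorted(groups, key=lambda g: g.group_id):
            for s in g.substitutions:
                fh.write(
                    f"{s['group_id']}\t{s['stage']}\t{s['pass']}\t{s['species']}\t"
                    f"{s['old_pep']}\t{s['new_pep']}\t{s['delta_R']:.6f}\n"
                )


def write_discarded(groups: Iterable[GeneGroup], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("group_id\treason\n")
        for g in sorted(groups, key=lambda g: g.group_id):
            if g.status == "discarded":
                fh.write(f"{g.group_id}\t{g.reason}\n")


def assert_exclusive_membership(groups: Iterable[GeneGroup]) -> None:
    """Invariant: a peptide is a member of at most one group."""
    seen: dict[str, str] = {}
    for g in groups:
        if g.status == "discarded":
            continue
        for rec in g.members.values():
            if rec.pep_id in seen:
                raise AssertionError(
                    f"{rec.pep_id} is a member of both {seen[rec.pep_id]} and {g.group_id}"
                )
            seen[rec.pep_id] = g.group_id
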