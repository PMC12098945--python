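"""Post-pipeline scans: associates, supergroups, external validation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import profile_model
from .gene_rescue import GeneFinderAdapter, find_candidate_models
from .group_builder import GeneGroup, PipelineConfig
from .seqio import SpeciesPeptideSet


@dataclass(frozen=True)
class AssociateHit:
    pep_id: str
    species: str
    group_id: str
    R: float


@dataclass
class Supergroup:
    supergroup_id: str
    group_ids: list[str]


def assign_associates(groups: Sequence[GeneGroup],
                      peps: Mapping[str, SpeciesPeptideSet],
                      config: PipelineConfig) -> list[AssociateHit]:
    """Every (peptide, group) pair with R above threshold, members excluded.

    Many-to-many: a peptide may associate to several groups and a group may
    hold many associates.
    """
    live = sorted((g for g in groups if g.status == "universal"), key=lambda g: g.group_id)
    hits: list[AssociateHit] = []
    for group in live:
        member_ids = group.member_ids()
        for sp in config.species_order:
            if sp not in peps:
                continue
            for rec in peps[sp]:
                if rec.pep_id in member_ids:
                    continue
                ps = profile_model.score(group.profile, rec.sequence)
                if not profile_model.hit_filter(ps, config.min_raw_bits):
                    continue
                if ps.R > config.r_min:
                    hits.append(AssociateHit(rec.pep_id, sp, group.group_id, ps.R))
    hits.sort(key=lambda h: (h.group_id, h.species, h.pep_id))
    return hits


def _mutual_edge(a: GeneGroup, b: GeneGroup, config: PipelineConfig) -> bool:
    """True iff every member of each group clears r_min on the other's profile."""
    for rec in a.members.values():
        if profile_model.score(b.profile, rec.sequence).R <= config.r_min:
            return False
    for rec in b.members.values():
        if profile_model.score(a.profile, rec.sequence).R <= config.r_min:
            return False
    return True


def find_supergroups(groups: Sequence[GeneGroup], config: PipelineConfig) -> list[Supergroup]:
    """Groups linked by mutual all-member hits, merged into components.

    Default: connected components of the mutual-hit relation with >= 2
    nodes.  With ``config.supergroup_clique`` components are reported only
    where they form a clique, otherwise split into maximal cliques greedily.
    """
    live = sorted((g for g in groups if g.status == "universal"), key=lambda g: g.group_id)
    n = len(live)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if _mutual_edge(live[i], live[j], config):
                edges.add((i, j))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    clusters: list[list[int]] = []
    for root in sorted(comps):
        nodes = comps[root]
        if len(nodes) < 2:
            continue
        if not config.supergroup_clique:
            clusters.append(nodes)
            continue
        remaining = list(nodes)
        while len(remaining) >= 2:
            clique = [remaining[0]]
            for x in remaining[1:]:
                if all((min(x, y), max(x, y)) in edges for y in clique):
                    clique.append(x)
            if len(clique) >= 2:
                clusters.append(clique)
            remaining = [x for x in remaining if x not in clique]

    width = max(3, len(str(len(clusters))))
    return [
        Supergroup(
            supergroup_id=f"sg{idx:0{width}d}",
            group_ids=[live[i].group_id for i in sorted(nodes)],
        )
        for idx, nodes in enumerate(clusters, start=1)
    ]


def match_external_proteome(groups: Sequence[GeneGroup], external: SpeciesPeptideSet,
                            config: PipelineConfig) -> tuple[pd.DataFrame, float]:
    """Best R per group over an external proteome; matched iff R > r_min."""
    if len(external) == 0:
        raise ValueError("empty external peptide set")
    live = sorted((g for g in groups if g.status == "universal"), key=lambda g: g.group_id)
    rows = []
    for group in live:
        best = 0.0
        for rec in external:
            ps = profile_model.score(group.profile, rec.sequence)
            if profile_model.hit_filter(ps, config.min_raw_bits) and ps.R > best:
                best = ps.R
        rows.append(
            {"group_id": group.group_id, "best_R": best, "supported": best > config.r_min}
        )
    df = pd.DataFrame(rows, columns=["group_id", "best_R", "supported"])
    fraction = float(df["supported"].mean()) if len(df) else 0.0
    return df, fraction


def match_external_genome(groups: Sequence[GeneGroup], species: str,
                          adapter: GeneFinderAdapter,
                          config: PipelineConfig) -> tuple[pd.DataFrame, float]:
    """Rescue-style search of an unannotated genome with each group consensus."""
    live = sorted((g for g in groups if g.status == "universal"), key=lambda g: g.group_id)
    rows = []
    for group in live:
        models = find_candidate_models(
            adapter, species, group.profile.consensus, group.profile, config
        )
        best = 0.0
        for m in models:
            R = profile_model.score(group.profile, m.peptide.sequence).R
            if R > best:
                best = R
        rows.append(
            {"group_id": group.group_id, "best_R": best, "supported": best > config.r_min}
        )
    df = pd.DataFrame(rows, columns=["group_id", "best_R", "supported"])
    fraction = float(df["supported"].mean()) if len(df) else 0.0
    return df, fraction


def write_associates(hits: Sequence[AssociateHit], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("group_id\tspecies\tpep_id\tR\n")
        for h in hits:
            fh.write(f"{h.group_id}\t{h.species}\t{h.pep_id}\t{h.R:.6f}\n")


def write_supergroups(supergroups: Sequence[Supergroup], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("supergroup_id\tgroup_id\n")
        for sg in supergroups:
            for gid in sg.group_ids:
                fh.write(f"{sg.supergroup_id}\t{gid}\n")


def write_validation(df: pd.DataFrame, fraction: float, tsv_path) -> None:
    out = df.copy()
    out["best_R"] = out["best_R"].map(lambda v: f"{v:.6f}")
    out.to_csv(tsv_path, sep="\t", index=False)
    with open(tsv_path, "a") as fh:
        fh.write(f"# matched_fraction\t{fraction:.6f}\n")
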