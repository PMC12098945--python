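"""Taxon-specificity of universal groups: the S statistic at three depths.

S at a depth is the group's lowest member R minus the highest R of any
outgroup peptide at or below that depth.  S <= 0 means some outgroup
peptide matches the profile as well as a member, so the group is not
specific at that depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import profile_model
from .group_builder import GeneGroup, PipelineConfig
from .pairwise import global_alignment, global_identity
from .profile_model import ProfileModel
from .seqio import SpeciesPeptideSet

# shallowest -> deepest divergence from the focal clade
LEVELS = ("non_grass_commelinid", "non_commelinid_monocot", "non_monocot")

# peptides counted at each depth: the named level and everything deeper
DEPTH_QUERY: dict[str, tuple[str, ...]] = {
    "non_monocot": ("non_monocot",),
    "non_commelinid_monocot": ("non_commelinid_monocot", "non_monocot"),
    "non_grass_commelinid": LEVELS,
}

LABELS = ("non_specific", "monocot_specific", "commelinid_specific", "grass_specific")


@dataclass
class OutgroupPanel:
    """Outgroup peptide sets, each labelled with its taxonomic level."""

    entries: list[tuple[str, SpeciesPeptideSet, str]] = field(default_factory=list)

    def add(self, species: str, pepset: SpeciesPeptideSet, level: str) -> None:
        if level not in LEVELS:
            raise ValueError(f"unknown outgroup level {level!r}")
        self.entries.append((species, pepset, level))

    def at_depth(self, depth: str) -> list[tuple[str, SpeciesPeptideSet]]:
        wanted = DEPTH_QUERY[depth]
        return [(sp, ps) for sp, ps, lvl in self.entries if lvl in wanted]

    def species_counts(self) -> dict[str, int]:
        return {d: len(self.at_depth(d)) for d in DEPTH_QUERY}


@dataclass
class SpecificityResult:
    group_id: str
    min_member_R: float
    max_outgroup_R: dict[str, float]  # keyed by depth name
    S_monocot: float
    S_commelinid: float
    S_grass: float
    label: str = ""
    supporting_species: dict[str, int] = field(default_factory=dict)


def best_outgroup_scores(profile: ProfileModel, panel: OutgroupPanel,
                         config: PipelineConfig) -> dict[str, float]:
    """Max R per depth over every outgroup peptide at or below that depth.

    Peptides failing the significance filter contribute nothing; a depth
    with no passing hit reports max R = 0.
    """
    if not panel.entries:
        raise ValueError("empty outgroup panel")
    best_by_level: dict[str, float] = {lvl: 0.0 for lvl in LEVELS}
    for _sp, pepset, level in panel.entries:
        for rec in pepset:
            ps = profile_model.score(profile, rec.sequence)
            if not profile_model.hit_filter(ps, config.min_raw_bits):
                continue
            if ps.R > best_by_level[level]:
                best_by_level[level] = ps.R
    return {
        depth: max((best_by_level[lvl] for lvl in DEPTH_QUERY[depth]), default=0.0)
        for depth in DEPTH_QUERY
    }


def specificity_scores(group: GeneGroup, outgroup_maxima: Mapping[str, float],
                       supporting_species: Mapping[str, int] | None = None) -> SpecificityResult:
    """S at each depth = min member R minus the depth's max outgroup R."""
    min_R = group.min_R
    return SpecificityResult(
        group_id=group.group_id,
        min_member_R=min_R,
        max_outgroup_R=dict(outgroup_maxima),
        S_monocot=min_R - outgroup_maxima["non_monocot"],
        S_commelinid=min_R - outgroup_maxima["non_commelinid_monocot"],
        S_grass=min_R - outgroup_maxima["non_grass_commelinid"],
        supporting_species=dict(supporting_species or {}),
    )


def classify_specificity(result: SpecificityResult, config: PipelineConfig) -> str:
    """Deepest depth at which S clears the cutoff (strict >), else non-specific."""
    cutoff = config.specificity_cutoff
    if result.S_grass > cutoff:
        return "grass_specific"
    if result.S_commelinid > cutoff:
        return "commelinid_specific"
    if result.S_monocot > cutoff:
        return "monocot_specific"
    return "non_specific"


def evaluate_group(group: GeneGroup, panel: OutgroupPanel,
                   config: PipelineConfig) -> SpecificityResult:
    maxima = best_outgroup_scores(group.profile, panel, config)
    result = specificity_scores(group, maxima, panel.species_counts())
    result.label = classify_specificity(result, config)
    return result


def pairwise_identity_baseline(group: GeneGroup, panel: OutgroupPanel,
                               reference_species: str,
                               config: PipelineConfig) -> float | None:
    """Percent identity (over alignment length) of the reference member to
    its best deep-outgroup hit; None when no hit passes the filter."""
    member = group.members.get(reference_species)
    if member is None:
        raise ValueError(f"group {group.group_id} has no member for {reference_species}")
    best_rec, best_score = None, -np.inf
    for _sp, pepset in panel.at_depth("non_monocot"):
        for rec in pepset:
            ps = profile_model.score(group.profile, rec.sequence)
            if not profile_model.hit_filter(ps, config.min_raw_bits):
                continue
            _, _, aln_score = global_alignment(member.sequence, rec.sequence)
            if aln_score > best_score:
                best_rec, best_score = rec, aln_score
    if best_rec is None:
        return None
    return global_identity(member.sequence, best_rec.sequence).pct_alignment


def evaluate_cutoffs(metric_values: Sequence[float], labels: Sequence[bool],
                     cutoff_grid: Sequence[float]) -> pd.DataFrame:
    """Sweep cutoffs over two labelled sets (True = known specific).

    A value passes a cutoff when it is strictly greater.  FP rate is the
    fraction of the non-specific set passing; FN rate the fraction of the
    specific set failing.
    """
    values = np.asarray(metric_values, dtype=float)
    mask = np.asarray(labels, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both labelled sets must be non-empty")
    spec, nonspec = values[mask], values[~mask]
    rows = []
    for cutoff in cutoff_grid:
        rows.append(
            {
                "cutoff": float(cutoff),
                "false_positive_rate": float(np.mean(nonspec > cutoff)),
                "false_negative_rate": float(np.mean(spec <= cutoff)),
            }
        )
    return pd.DataFrame(rows)


def write_specificity_table(results: Sequence[SpecificityResult], tsv_path) -> None:
    rows = []
    for r in sorted(results, key=lambda r: r.group_id):
        rows.append(
            {
                "group_id": r.group_id,
                "min_member_R": f"{r.min_member_R:.6f}",
                "max_R_non_monocot": f"{r.max_outgroup_R['non_monocot']:.6f}",
                "max_R_non_commelinid": f"{r.max_outgroup_R['non_commelinid_monocot']:.6f}",
                "max_R_non_grass": f"{r.max_outgroup_R['non_grass_commelinid']:.6f}",
                "S_monocot": f"{r.S_monocot:.6f}",
                "S_commelinid": f"{r.S_commelinid:.6f}",
                "S_grass": f"{r.S_grass:.6f}",
                "label": r.label,
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
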