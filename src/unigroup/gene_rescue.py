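"""Recover missing group members from genome sequence.

A pluggable gene-finder adapter proposes scored gene models for a query
peptide; the built-in stub finder scans six-frame single-exon ORFs, which
matches the synthetic genome dialect.  Proposed models are checked for
novelty against existing annotation before adoption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

from Bio.Seq import Seq

from . import profile_model
from .group_builder import GeneGroup, PipelineConfig, _build_profile, _recompute_member_R, score_R
from .profile_model import ProfileModel
from .seqio import AnnotationIndex, PeptideRecord

log = logging.getLogger(__name__)

MIN_ORF_AA = 30


@dataclass
class RescuedModel:
    species: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, includes the stop codon
    peptide: PeptideRecord  # source == "rescued"
    adapter_score: float  # adapter-native units (stub: raw bits)


class GeneFinderAdapter(Protocol):
    """Contract for external or built-in gene finders."""

    def find(self, species: str, query: str, profile: ProfileModel,
             config: PipelineConfig) -> list[RescuedModel]: ...


@dataclass(frozen=True)
class _Orf:
    chromosome: str
    strand: str
    start: int  # 1-based inclusive, ATG..stop codon
    end: int
    peptide: str


def _scan_orfs(chromosome: str, seq: str, min_aa: int = MIN_ORF_AA) -> list[_Orf]:
    """All ATG-initiated, stop-terminated single-exon ORFs in six frames.

    Every ATG within a stop-to-stop segment starts its own (nested) ORF, so
    a gene is found even when an upstream in-frame ATG precedes it.
    """
    out: list[_Orf] = []
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            starts: list[int] = []
            for j in range(frame, n - 2, 3):
                codon = s[j : j + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    for i in starts:
                        if (j - i) // 3 >= min_aa:
                            pep = str(Seq(s[i:j]).translate())
                            if strand == "+":
                                start, end = i + 1, j + 3
                            else:
                                start, end = n - (j + 3) + 1, n - i
                            out.append(_Orf(chromosome, strand, start, end, pep))
                    starts = []
                elif codon == "ATG":
                    starts.append(j)
    out.sort(key=lambda o: (o.chromosome, o.start, o.end, o.strand))
    return out


class StubGeneFinder:
    """Built-in single-exon gene finder over in-memory genomes.

    ORFs are scanned once per genome and cached; per query they are scored
    against the group profile and gated by the significance filter.
    """

    def __init__(self, genomes: Mapping[str, Mapping[str, str]]):
        self._genomes = genomes
        self._orf_cache: dict[str, list[_Orf]] = {}

    def _orfs(self, species: str) -> list[_Orf]:
        if species not in self._orf_cache:
            genome = self._genomes.get(species, {})
            orfs: list[_Orf] = []
            for chrom in sorted(genome):
                orfs.extend(_scan_orfs(chrom, genome[chrom]))
            self._orf_cache[species] = orfs
        return self._orf_cache[species]

    def find(self, species: str, query: str, profile: ProfileModel,
             config: PipelineConfig) -> list[RescuedModel]:
        models: list[RescuedModel] = []
        for orf in self._orfs(species):
            ps = profile_model.score(profile, orf.peptide)
            if not profile_model.hit_filter(ps, config.min_raw_bits):
                continue
            pid = f"rescue_{species}_{orf.chromosome}_{orf.start}_{orf.strand.replace('-', 'm').replace('+', 'p')}"
            rec = PeptideRecord(
                pep_id=pid, gene_id=pid, species=species,
                sequence=orf.peptide, source="rescued",
            )
            models.append(
                RescuedModel(
                    species=species,
                    chromosome=orf.chromosome,
                    strand=orf.strand,
                    exons=[(orf.start, orf.end)],
                    peptide=rec,
                    adapter_score=ps.raw,
                )
            )
        models.sort(key=lambda m: (-m.adapter_score, m.chromosome, m.exons[0][0]))
        return models


def find_candidate_models(adapter: GeneFinderAdapter, species: str, consensus_query: str,
                          profile: ProfileModel, config: PipelineConfig) -> list[RescuedModel]:
    """Ask the adapter for scored models; adapter failures yield an empty list."""
    try:
        return adapter.find(species, consensus_query, profile, config)
    except Exception as exc:  # adapter failure is non-fatal per group
        log.warning("gene finder failed for %s: %s", species, exc)
        return []


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def is_novel(model: RescuedModel, annotations: AnnotationIndex,
             exact: bool = False) -> bool:
    """True iff the model does not collide with any annotated exon.

    Default: any same-strand exon overlap of >= 1 bp disqualifies; with
    ``exact`` only an identical same-strand exon set does.
    """
    if exact:
        for g in annotations.genes.values():
            if (g.chromosome == model.chromosome and g.strand == model.strand
                    and sorted(g.exons) == sorted(model.exons)):
                return False
        return True
    annotated = annotations.exons_on(model.chromosome, model.strand)
    for exon in model.exons:
        for known in annotated:
            if _intervals_overlap(exon, known):
                return False
    return True


def translate_model(model: RescuedModel, genome: Mapping[str, str]) -> str:
    """Translate the model's exons off the genome (consistency check)."""
    chrom = genome[model.chromosome]
    cds = "".join(chrom[s - 1 : e] for s, e in sorted(model.exons))
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    pep = str(Seq(cds).translate())
    return pep[:-1] if pep.endswith("*") else pep


def adopt_rescued(group: GeneGroup, models_by_species: Mapping[str, Sequence[RescuedModel]],
                  config: PipelineConfig) -> GeneGroup:
    """Adopt novel rescued models under the ΔR rule and the per-group caps.

    Holes (species with no member) are visited first, then members below
    r_min from lowest R upward; within a species models are tried best ΔR
    first.  At most ``max_rescued`` models per group, and the count of
    annotated members never drops below the floor.
    """
    if group.status == "discarded" or group.profile is None:
        return group
    holes = [sp for sp in config.species_order if sp not in group.members
             and sp in models_by_species]
    weak = sorted(
        (sp for sp, R in group.member_R.items()
         if R < config.r_min and sp in models_by_species),
        key=lambda sp: (group.member_R[sp], sp),
    )
    for sp in holes + weak:
        if group.n_rescued >= config.max_rescued:
            break
        models = models_by_species.get(sp, [])
        if not models:
            continue
        scored = sorted(
            ((score_R(group.profile, m.peptide.sequence), m) for m in models),
            key=lambda t: (-t[0], t[1].chromosome, t[1].exons[0][0]),
        )
        best_R, best = scored[0]
        if sp in group.members:
            cur_R = score_R(group.profile, group.members[sp].sequence)
            if best_R <= cur_R + config.delta_improve:
                continue
            annotated_after = sum(
                1 for s, rec in group.members.items()
                if rec.source == "annotated" and s != sp
            )
            if annotated_after < config.min_annotated_count:
                continue
            old_pep = group.members[sp].pep_id
            delta = best_R - cur_R
        else:
            old_pep = ""
            delta = best_R
        group.members[sp] = best.peptide
        group.n_rescued += 1
        group.substitutions.append(
            {
                "group_id": group.group_id,
                "stage": "rescue",
                "pass": 0,
                "species": sp,
                "old_pep": old_pep,
                "new_pep": best.peptide.pep_id,
                "delta_R": delta,
            }
        )
        _build_profile(group, config)
    _recompute_member_R(group)
    return group


def rescue_groups(groups: Sequence[GeneGroup], adapter: GeneFinderAdapter,
                  annotations: Mapping[str, AnnotationIndex],
                  config: PipelineConfig) -> list[RescuedModel]:
    """Run the rescue stage over all live groups; returns adopted models."""
    adopted: list[RescuedModel] = []
    for group in sorted((g for g in groups if g.status == "optimized"),
                        key=lambda g: g.group_id):
        need = [sp for sp in config.species_order if sp not in group.members]
        need += [sp for sp, R in group.member_R.items() if R < config.r_min]
        if not need:
            continue
        models_by_species: dict[str, list[RescuedModel]] = {}
        for sp in need:
            models = find_candidate_models(
                adapter, sp, group.profile.consensus, group.profile, config
            )
            ann = annotations.get(sp)
            if ann is not None:
                models = [m for m in models if is_novel(m, ann, config.novelty_exact)]
            if models:
                models_by_species[sp] = models
        if not models_by_species:
            continue
        before = dict(group.members)
        adopt_rescued(group, models_by_species, config)
        for sp, rec in group.members.items():
            if rec.source == "rescued" and before.get(sp) is not rec:
                for m in models_by_species.get(sp, []):
                    if m.peptide.pep_id == rec.pep_id:
                        adopted.append(m)
                        break
    return adopted


def write_rescued_gff3(models: Sequence[RescuedModel], gff3_path) -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.species, m.chromosome, m.exons[0][0])):
            gid = m.peptide.pep_id
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            fh.write(f"{m.chromosome}\trescue\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={gid}\n")
            fh.write(
                f"{m.chromosome}\trescue\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for i, (s, e) in enumerate(sorted(m.exons), start=1):
                fh.write(
                    f"{m.chromosome}\trescue\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={gid}.t1.exon{i};Parent={gid}.t1\n"
                )
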