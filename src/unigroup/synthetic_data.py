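"""Truth-labelled synthetic inputs for every pipeline stage.

Generates an ingroup clade of species over a balanced binary tree with
planted universal families, decoy (non-universal) families, duplicated
family pairs, splice variants, genomes + annotations with controllable
annotation dropout, and outgroup peptide panels at three taxonomic levels.
Everything is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import (
    AA20,
    AnnotationIndex,
    GeneAnnotation,
    OrthologTable,
    PeptideRecord,
    SpeciesPeptideSet,
)
from .specificity import LEVELS, OutgroupPanel

# fixed replacement distribution, roughly typical globular-protein frequencies
_REPLACEMENT_FREQ = {
    "A": 0.083, "C": 0.014, "D": 0.054, "E": 0.062, "F": 0.039,
    "G": 0.072, "H": 0.022, "I": 0.052, "K": 0.058, "L": 0.090,
    "M": 0.022, "N": 0.044, "P": 0.050, "Q": 0.037, "R": 0.051,
    "S": 0.069, "T": 0.058, "V": 0.066, "W": 0.013, "Y": 0.032,
}
_FREQ = np.array([_REPLACEMENT_FREQ[a] for a in AA20])
_FREQ = _FREQ / _FREQ.sum()

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "X": "GGG",
    "Y": "TAT",
}
_ALT_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTC", "W": "TGG", "X": "GGC",
    "Y": "TAC",
}
_STOP = "TAA"

LABEL_CHOICES = ("non_specific", "monocot_specific", "commelinid_specific", "grass_specific")


@dataclass
class SimConfig:
    seed: int = 0
    n_ingroup_species: int = 8
    n_universal_families: int = 30
    n_decoy_families: int = 10
    n_duplicated_families: int = 2
    substitution_rate: float = 0.02  # expected substitutions/site per tree branch
    indel_rate: float = 0.01  # indel events per site per unit distance
    indel_mean_len: int = 3
    splice_variant_prob: float = 0.15
    annotation_dropout_fraction: float = 0.1
    outgroup_depths: tuple[float, float, float] = (0.10, 0.35, 0.70)
    outgroup_species_per_level: int = 2
    mean_peptide_length: int = 300
    duplication_identity: float = 0.95
    confidence_downgrade_fraction: float = 0.05
    ortholog_row_drop_fraction: float = 0.02
    label_fractions: dict[str, float] = field(
        default_factory=lambda: {lbl: 0.25 for lbl in LABEL_CHOICES}
    )

    def __post_init__(self) -> None:
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        d = self.outgroup_depths
        if not (d[0] < d[1] < d[2]):
            raise ValueError("outgroup depths must be strictly increasing")
        if self.n_ingroup_species < 4:
            raise ValueError("need at least 4 ingroup species")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_ingroup_species)]

    @property
    def reference_species(self) -> tuple[str, str]:
        sp = self.species
        return sp[0], sp[len(sp) // 2]


@dataclass
class MemberTruth:
    family_id: str
    species: str
    gene_id: str
    pep_id: str
    sequence: str
    chromosome: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    dropped: bool = False


@dataclass
class FamilyTruth:
    family_id: str
    label: str
    kind: str  # universal | duplicate | decoy
    members: dict[str, MemberTruth] = field(default_factory=dict)
    duplication_partner: str | None = None


@dataclass
class SyntheticTruth:
    families: dict[str, FamilyTruth] = field(default_factory=dict)

    def universal_ids(self) -> list[str]:
        return sorted(
            fid for fid, f in self.families.items() if f.kind in ("universal", "duplicate")
        )

    def dropped_members(self) -> list[MemberTruth]:
        return [
            m
            for f in self.families.values()
            for m in f.members.values()
            if m.dropped
        ]


@dataclass
class SimulatedDataset:
    config: SimConfig
    pepsets: dict[str, SpeciesPeptideSet]
    ortholog_tables: tuple[OrthologTable, OrthologTable]
    genomes: dict[str, dict[str, str]]
    annotations: dict[str, AnnotationIndex]
    outgroup_panel: OutgroupPanel
    truth: SyntheticTruth
    ancestors: dict[str, str]  # family_id -> ancestral peptide


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def random_peptide(length: int, rng: np.random.Generator) -> str:
    body = rng.choice(list(AA20), size=length - 1, p=_FREQ)
    return "M" + "".join(body)


def evolve_sequence(ancestor: str, distance: float, rng: np.random.Generator,
                    indel_rate: float = 0.0, indel_mean_len: int = 3) -> str:
    """Per-site substitution with probability 1 - exp(-distance).

    A substituted site is redrawn from a fixed exchangeability-weighted
    distribution excluding the current residue, so expected identity is
    exp(-distance).  Indels (half insertions, half deletions, geometric
    lengths) are applied on top when configured.  The leading residue is
    pinned (synthetic genes keep their start codon).
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance == 0 and indel_rate == 0:
        return ancestor
    p_sub = 1.0 - math.exp(-distance)
    chars = list(ancestor)
    aa_idx = {a: i for i, a in enumerate(AA20)}
    for i in range(1, len(chars)):
        if rng.random() < p_sub:
            cur = aa_idx.get(chars[i])
            w = _FREQ.copy()
            if cur is not None:
                w[cur] = 0.0
            w = w / w.sum()
            chars[i] = AA20[rng.choice(20, p=w)]
    if indel_rate > 0:
        n_events = rng.poisson(indel_rate * distance * len(chars))
        for _ in range(n_events):
            length = 1 + rng.geometric(1.0 / indel_mean_len)
            if rng.random() < 0.5 and len(chars) > length + 10:
                pos = int(rng.integers(1, len(chars) - length))
                del chars[pos : pos + length]
            else:
                pos = int(rng.integers(1, len(chars)))
                ins = rng.choice(list(AA20), size=length, p=_FREQ)
                chars[pos:pos] = list(ins)
    return "".join(chars)


def _evolve_down_tree(ancestor: str, n_leaves: int, rng: np.random.Generator,
                      rate: float, indel_rate: float, indel_mean_len: int) -> list[str]:
    """Balanced binary descent; every branch has the same expected distance."""
    if n_leaves == 1:
        return [ancestor]
    left_n = (n_leaves + 1) // 2
    left_anc = evolve_sequence(ancestor, rate, rng, indel_rate, indel_mean_len)
    right_anc = evolve_sequence(ancestor, rate, rng, indel_rate, indel_mean_len)
    left = _evolve_down_tree(left_anc, left_n, rng, rate, indel_rate, indel_mean_len)
    right = _evolve_down_tree(right_anc, n_leaves - left_n, rng, rate, indel_rate, indel_mean_len)
    return left + right


def plant_duplication(members: Mapping[str, str], identity_target: float,
                      rng: np.random.Generator) -> dict[str, str]:
    """A duplicate family evolved to the target cross-family identity."""
    if not 0.8 < identity_target < 1.0:
        raise ValueError("identity_target must be in (0.8, 1.0)")
    distance = -math.log(identity_target)
    return {sp: evolve_sequence(seq, distance, rng) for sp, seq in members.items()}


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _back_translate(pep: str, rng: np.random.Generator) -> str:
    return "".join(
        (_CODON if rng.random() < 0.5 else _ALT_CODON)[aa] for aa in pep
    ) + _STOP


def _spacer(rng: np.random.Generator, lo: int = 80, hi: int = 140) -> str:
    n = int(rng.integers(lo, hi))
    return "".join(rng.choice(list("ACGT"), size=n))


def _assign_labels(config: SimConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_universal_families
    counts = {lbl: int(round(frac * n)) for lbl, frac in config.label_fractions.items()}
    pool: list[str] = []
    for lbl in LABEL_CHOICES:
        pool.extend([lbl] * counts.get(lbl, 0))
    while len(pool) < n:
        pool.append("grass_specific")
    pool = pool[:n]
    return [pool[i] for i in rng.permutation(n)]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full synthetic input set plus its truth table."""
    rng = np.random.default_rng(config.seed)
    species = config.species
    ref1, ref2 = config.reference_species
    n_sp = len(species)

    truth = SyntheticTruth()
    ancestors: dict[str, str] = {}
    family_members: dict[str, dict[str, str]] = {}  # family -> species -> sequence
    family_order: list[str] = []

    labels = _assign_labels(config, rng)
    for i in range(config.n_universal_families):
        fid = f"fam{i + 1:03d}"
        length = max(80, int(rng.normal(config.mean_peptide_length,
                                        config.mean_peptide_length / 10)))
        anc = random_peptide(length, rng)
        leaves = _evolve_down_tree(anc, n_sp, rng, config.substitution_rate,
                                   config.indel_rate, config.indel_mean_len)
        ancestors[fid] = anc
        family_members[fid] = dict(zip(species, leaves))
        family_order.append(fid)
        truth.families[fid] = FamilyTruth(family_id=fid, label=labels[i], kind="universal")

    for j in range(config.n_duplicated_families):
        src = family_order[j]
        fid = f"dup{j + 1:03d}"
        dup = plant_duplication(family_members[src], config.duplication_identity, rng)
        ancestors[fid] = ancestors[src]
        family_members[fid] = dup
        family_order.append(fid)
        truth.families[fid] = FamilyTruth(
            family_id=fid, label="grass_specific", kind="duplicate",
            duplication_partner=src,
        )
        truth.families[src].duplication_partner = fid

    decoy_present: dict[str, list[str]] = {}
    n_present = max(2, n_sp // 2 - 1)
    others = [sp for sp in species if sp not in (ref1, ref2)]
    for k in range(config.n_decoy_families):
        fid = f"dec{k + 1:03d}"
        anchor = ref1 if k % 2 == 0 else ref2
        rest = list(rng.choice(others, size=n_present - 1, replace=False))
        present = [sp for sp in species if sp == anchor or sp in rest]
        length = max(80, int(rng.normal(config.mean_peptide_length,
                                        config.mean_peptide_length / 10)))
        anc = random_peptide(length, rng)
        leaves = _evolve_down_tree(anc, n_sp, rng, config.substitution_rate,
                                   config.indel_rate, config.indel_mean_len)
        ancestors[fid] = anc
        family_members[fid] = {sp: seq for sp, seq in zip(species, leaves) if sp in present}
        decoy_present[fid] = present
        family_order.append(fid)
        truth.families[fid] = FamilyTruth(family_id=fid, label="decoy", kind="decoy")

    # gene/pep ids, splice variants
    gene_counter = {sp: 0 for sp in species}
    variants: dict[tuple[str, str], str] = {}  # (family, species) -> variant seq
    for fid in family_order:
        fam = truth.families[fid]
        for sp in species:
            if sp not in family_members[fid]:
                continue
            gene_counter[sp] += 1
            gene = f"{sp}_g{gene_counter[sp]:04d}"
            pep = f"{gene}.p1"
            seq = family_members[fid][sp]
            fam.members[sp] = MemberTruth(
                family_id=fid, species=sp, gene_id=gene, pep_id=pep, sequence=seq
            )
            if fam.kind != "decoy" and rng.random() < config.splice_variant_prob:
                frac = rng.uniform(0.5, 0.8)
                cut = max(30, int(len(seq) * frac))
                variants[(fid, sp)] = seq[:cut]

    # annotation dropout: universal families, non-reference species only
    n_entries = config.n_universal_families * n_sp
    n_drop = int(round(config.annotation_dropout_fraction * n_entries))
    droppable = [
        (fid, sp)
        for fid in family_order
        if truth.families[fid].kind == "universal"
        for sp in species
        if sp not in (ref1, ref2)
    ]
    if n_drop > len(droppable):
        raise ValueError("dropout fraction too high for the non-reference entries")
    drop_idx = rng.choice(len(droppable), size=n_drop, replace=False)
    dropped = {droppable[int(i)] for i in drop_idx}
    for fid, sp in dropped:
        truth.families[fid].members[sp].dropped = True

    # peptide sets (dropout removes the annotated peptide, variants follow it)
    pepsets = {sp: SpeciesPeptideSet(species=sp) for sp in species}
    for fid in family_order:
        fam = truth.families[fid]
        for sp, m in fam.members.items():
            if m.dropped:
                continue
            pepsets[sp].records.append(
                PeptideRecord(pep_id=m.pep_id, gene_id=m.gene_id, species=sp,
                              sequence=m.sequence)
            )
            var = variants.get((fid, sp))
            if var is not None:
                pepsets[sp].records.append(
                    PeptideRecord(pep_id=f"{m.gene_id}.p2", gene_id=m.gene_id,
                                  species=sp, sequence=var)
                )

    # ortholog tables for the two reference species
    import pandas as pd

    tables = []
    for ref in (ref1, ref2):
        rows = []
        for fid in family_order:
            fam = truth.families[fid]
            ref_m = fam.members.get(ref)
            if ref_m is None or ref_m.dropped:
                continue
            for sp, m in fam.members.items():
                if sp == ref or m.dropped:
                    continue
                conf = 0 if rng.random() < config.confidence_downgrade_fraction else 1
                if rng.random() < config.ortholog_row_drop_fraction:
                    continue
                rows.append(
                    {"ref_gene": ref_m.gene_id, "target_species": sp,
                     "target_gene": m.gene_id, "confidence": conf}
                )
        tables.append(
            OrthologTable(
                reference_species=ref,
                rows=pd.DataFrame(rows, columns=["ref_gene", "target_species",
                                                 "target_gene", "confidence"]),
            )
        )

    # genomes and annotations (the genome keeps dropped genes)
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, AnnotationIndex] = {}
    for sp in species:
        chrom = f"{sp}_chr1"
        parts = [_spacer(rng)]
        pos = len(parts[0])
        index = AnnotationIndex(species=sp)
        gene_i = 0
        for fid in family_order:
            m = truth.families[fid].members.get(sp)
            if m is None:
                continue
            cds = _back_translate(m.sequence, rng)
            strand = "+" if gene_i % 2 == 0 else "-"
            if strand == "-":
                from Bio.Seq import Seq

                cds_genomic = str(Seq(cds).reverse_complement())
            else:
                cds_genomic = cds
            start = pos + 1
            end = pos + len(cds)
            parts.append(cds_genomic)
            spacer = _spacer(rng)
            parts.append(spacer)
            pos = end + len(spacer)
            m.chromosome, m.start, m.end, m.strand = chrom, start, end, strand
            if not m.dropped:
                index.genes[m.gene_id] = GeneAnnotation(
                    gene_id=m.gene_id, chromosome=chrom, strand=strand,
                    exons=[(start, end)],
                )
            gene_i += 1
        genomes[sp] = {chrom: "".join(parts)}
        annotations[sp] = index

    # outgroup panel: conserved copies at the shallow depth where the family's
    # function is shared at that level, diverged homologs deeper
    panel = OutgroupPanel()
    d_sh, d_mid, d_deep = config.outgroup_depths
    plant_plan = {
        # label -> {level: distance or None}
        "non_specific": {lvl: d_sh for lvl in LEVELS},
        "monocot_specific": {
            "non_grass_commelinid": d_sh,
            "non_commelinid_monocot": d_sh,
            "non_monocot": d_mid,
        },
        "commelinid_specific": {
            "non_grass_commelinid": d_sh,
            "non_commelinid_monocot": d_mid,
            "non_monocot": d_deep,
        },
        "grass_specific": {
            "non_grass_commelinid": d_mid,
            "non_commelinid_monocot": d_deep,
            "non_monocot": d_deep,
        },
    }
    for level_i, level in enumerate(LEVELS):
        for s in range(config.outgroup_species_per_level):
            og = f"og_{level}_{s + 1}"
            pepset = SpeciesPeptideSet(species=og)
            gi = 0
            for fid in family_order:
                fam = truth.families[fid]
                if fam.kind != "universal":
                    continue
                dist = plant_plan[fam.label][level]
                gi += 1
                seq = evolve_sequence(ancestors[fid], dist, rng,
                                      config.indel_rate, config.indel_mean_len)
                pepset.records.append(
                    PeptideRecord(pep_id=f"{og}_g{gi:04d}.p1",
                                  gene_id=f"{og}_g{gi:04d}", species=og, sequence=seq)
                )
            for extra in range(5):  # unrelated background peptides
                gi += 1
                seq = random_peptide(
                    max(80, int(rng.normal(config.mean_peptide_length,
                                           config.mean_peptide_length / 10))), rng)
                pepset.records.append(
                    PeptideRecord(pep_id=f"{og}_g{gi:04d}.p1",
                                  gene_id=f"{og}_g{gi:04d}", species=og, sequence=seq)
                )
            panel.add(og, pepset, level)

    return SimulatedDataset(
        config=config,
        pepsets=pepsets,
        ortholog_tables=(tables[0], tables[1]),
        genomes=genomes,
        annotations=annotations,
        outgroup_panel=panel,
        truth=truth,
        ancestors=ancestors,
    )


def simulate_holdout(dataset: SimulatedDataset, distance: float = 0.10,
                     seed: int = 99) -> tuple[SpeciesPeptideSet, dict[str, str]]:
    """A species outside the pipeline carrying every planted family.

    Members are evolved from the family ancestors at the given distance;
    the genome encodes them with spacers, for unannotated-genome matching.
    """
    rng = np.random.default_rng(seed)
    sp = "holdout"
    pepset = SpeciesPeptideSet(species=sp)
    parts = [_spacer(rng)]
    for i, fid in enumerate(sorted(dataset.truth.universal_ids())):
        seq = evolve_sequence(dataset.ancestors[fid], distance, rng,
                              dataset.config.indel_rate, dataset.config.indel_mean_len)
        pepset.records.append(
            PeptideRecord(pep_id=f"{sp}_g{i + 1:04d}.p1", gene_id=f"{sp}_g{i + 1:04d}",
                          species=sp, sequence=seq)
        )
        parts.append(_back_translate(seq, rng))
        parts.append(_spacer(rng))
    return pepset, {f"{sp}_chr1": "".join(parts)}


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Write all inputs in pipeline formats plus truth.tsv and config.yaml.

    Returns the path of the pipeline-ready config file.
    """
    import yaml

    from . import seqio

    out = Path(out_dir)
    for sub in ("peps", "orthologs", "genomes", "annotations", "outgroups"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    cfg = dataset.config
    species = cfg.species
    ref1, ref2 = cfg.reference_species
    for sp in species:
        seqio.write_peptides(dataset.pepsets[sp], out / "peps" / f"{sp}.fasta")
        seqio.write_genome(dataset.genomes[sp], out / "genomes" / f"{sp}.fasta")
        seqio.write_annotations(dataset.annotations[sp], out / "annotations" / f"{sp}.gff3",
                                source="simulated")
    for table, ref in zip(dataset.ortholog_tables, (ref1, ref2)):
        seqio.write_ortholog_table(table, out / "orthologs" / f"{ref}.tsv")
    outgroup_cfg = {}
    for og, pepset, level in dataset.outgroup_panel.entries:
        seqio.write_peptides(pepset, out / "outgroups" / f"{og}.fasta")
        outgroup_cfg[og] = {"path": f"outgroups/{og}.fasta", "level": level}
    write_truth(dataset.truth, out / "truth.tsv")

    pipeline_cfg = {
        "out_dir": "results",
        "species": species,
        "reference_species": [ref1, ref2],
        "peptides": {sp: f"peps/{sp}.fasta" for sp in species},
        "orthologs": {ref1: f"orthologs/{ref1}.tsv", ref2: f"orthologs/{ref2}.tsv"},
        "genomes": {sp: f"genomes/{sp}.fasta" for sp in species},
        "annotations": {sp: f"annotations/{sp}.gff3" for sp in species},
        "outgroups": outgroup_cfg,
        "thresholds": {},
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    return cfg_path


TRUTH_COLUMNS = [
    "family_id", "kind", "label", "species", "gene_id", "pep_id", "dropped",
    "chromosome", "start", "end", "strand", "duplication_partner", "sequence",
]


def write_truth(truth: SyntheticTruth, tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for fid in sorted(truth.families):
            fam = truth.families[fid]
            for sp in sorted(fam.members):
                m = fam.members[sp]
                fh.write(
                    f"{fid}\t{fam.kind}\t{fam.label}\t{sp}\t{m.gene_id}\t{m.pep_id}\t"
                    f"{int(m.dropped)}\t{m.chromosome}\t{m.start}\t{m.end}\t{m.strand}\t"
                    f"{fam.duplication_partner or ''}\t{m.sequence}\n"
                )


def read_truth(tsv_path) -> SyntheticTruth:
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    truth = SyntheticTruth()
    for row in df.itertuples(index=False):
        fam = truth.families.setdefault(
            row.family_id,
            FamilyTruth(family_id=row.family_id, label=row.label, kind=row.kind,
                        duplication_partner=row.duplication_partner or None),
        )
        fam.members[row.species] = MemberTruth(
            family_id=row.family_id, species=row.species, gene_id=row.gene_id,
            pep_id=row.pep_id, sequence=row.sequence, chromosome=row.chromosome,
            start=int(row.start), end=int(row.end), strand=row.strand,
            dropped=bool(int(row.dropped)),
        )
    return truth
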