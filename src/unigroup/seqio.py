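"""Input/output for every format the pipeline touches.

Peptide FASTA (with the identical-sequence deduplication rule), ortholog
tables (TSV), gene annotations (GFF3), and the final group/specificity
tables.  All genomic coordinates are GFF3-style: 1-based, inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = frozenset(AA20 + "X")

MEMBERSHIP_COLUMNS = ["group_id", "species", "pep_id", "source", "R"]
SPECIFICITY_COLUMNS = [
    "group_id",
    "min_member_R",
    "max_R_non_monocot",
    "max_R_non_commelinid",
    "max_R_non_grass",
    "S_monocot",
    "S_commelinid",
    "S_grass",
    "label",
]


class SeqIOError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class PeptideRecord:
    """A single peptide with its gene, species and provenance."""

    pep_id: str
    gene_id: str
    species: str
    sequence: str
    source: str = "annotated"  # "annotated" | "rescued"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqIOError(f"empty sequence for peptide {self.pep_id!r}")
        if self.source not in ("annotated", "rescued"):
            raise SeqIOError(f"bad source {self.source!r} for {self.pep_id!r}")


@dataclass
class SpeciesPeptideSet:
    """Deduplicated peptides of one species, in first-seen order."""

    species: str
    records: list[PeptideRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_pep_id(self) -> dict[str, PeptideRecord]:
        return {r.pep_id: r for r in self.records}

    def by_gene(self) -> dict[str, list[PeptideRecord]]:
        out: dict[str, list[PeptideRecord]] = {}
        for r in self.records:
            out.setdefault(r.gene_id, []).append(r)
        return out


@dataclass
class OrthologTable:
    """Reference-species ortholog assignments.

    One row per (reference gene, target gene) link with a binary
    confidence flag.
    """

    reference_species: str
    rows: pd.DataFrame  # columns: ref_gene, target_species, target_gene, confidence

    def targets_of(self, ref_gene: str) -> pd.DataFrame:
        return self.rows[self.rows["ref_gene"] == ref_gene]


@dataclass
class GeneAnnotation:
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by start


@dataclass
class AnnotationIndex:
    """Per-species map of gene_id to exon structure."""

    species: str
    genes: dict[str, GeneAnnotation] = field(default_factory=dict)

    def exons_on(self, chromosome: str, strand: str) -> list[tuple[int, int]]:
        out = []
        for g in self.genes.values():
            if g.chromosome == chromosome and g.strand == strand:
                out.extend(g.exons)
        return sorted(out)


def _clean_sequence(raw: str, pep_id: str) -> str:
    seq = raw.strip().upper()
    if seq.endswith("*"):  # tolerate exporter-style trailing stop
        seq = seq[:-1]
    if not seq:
        raise SeqIOError(f"empty sequence record {pep_id!r}")
    for pos, ch in enumerate(seq, start=1):
        if ch == "*":
            raise SeqIOError(f"internal stop '*' at position {pos} in {pep_id!r}")
        if ch not in _VALID_AA:
            raise SeqIOError(
                f"non-amino-acid character {ch!r} at position {pos} in {pep_id!r}"
            )
    return seq


def _parse_header(header: str) -> tuple[str, str]:
    """Return (pep_id, gene_id) from a FASTA header line.

    The first token is the pep id; a ``gene=`` (or ``gene:``) tag names the
    gene, otherwise the gene id defaults to the pep id.
    """
    fields = header.split()
    pep_id = fields[0]
    gene_id = pep_id
    for tok in fields[1:]:
        if tok.startswith("gene="):
            gene_id = tok[len("gene="):]
            break
        if tok.startswith("gene:"):
            gene_id = tok[len("gene:"):]
            break
    return pep_id, gene_id


def read_peptides(fasta_path: str | os.PathLike, species: str) -> SpeciesPeptideSet:
    """Read one species' peptide FASTA, collapsing identical sequences.

    Identical sequences are collapsed to the first-seen record; non-identical
    splice variants of the same gene are all retained.  Order of first
    appearance is preserved.
    """
    path = Path(fasta_path)
    out = SpeciesPeptideSet(species=species)
    seen: set[str] = set()
    seen_ids: set[str] = set()
    with open(path) as fh:
        for header, raw in SimpleFastaParser(fh):
            pep_id, gene_id = _parse_header(header)
            seq = _clean_sequence(raw, pep_id)
            if seq in seen:
                continue
            if pep_id in seen_ids:
                raise SeqIOError(f"duplicate pep_id {pep_id!r} in {path}")
            seen.add(seq)
            seen_ids.add(pep_id)
            out.records.append(
                PeptideRecord(pep_id=pep_id, gene_id=gene_id, species=species, sequence=seq)
            )
    return out


def write_peptides(pepset: SpeciesPeptideSet, fasta_path: str | os.PathLike) -> None:
    with open(fasta_path, "w") as fh:
        for r in pepset:
            fh.write(f">{r.pep_id} gene={r.gene_id}\n{r.sequence}\n")


ORTHOLOG_COLUMNS = ["ref_gene", "target_species", "target_gene", "confidence"]


def read_ortholog_table(tsv_path: str | os.PathLike, reference_species: str) -> OrthologTable:
    """Load a 4-column ortholog TSV; confidence must be 0 or 1."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"ortholog table {tsv_path} missing columns {missing}")
    df = df[ORTHOLOG_COLUMNS].copy()
    bad = ~df["confidence"].isin(["0", "1"])
    if bad.any():
        i = int(df.index[bad][0])
        raise SeqIOError(
            f"ortholog table {tsv_path}: confidence {df.loc[i, 'confidence']!r} "
            f"outside {{0,1}} in row {i} ({df.loc[i, 'ref_gene']})"
        )
    df["confidence"] = df["confidence"].astype(int)
    return OrthologTable(reference_species=reference_species, rows=df.reset_index(drop=True))


def write_ortholog_table(table: OrthologTable, tsv_path: str | os.PathLike) -> None:
    table.rows.to_csv(tsv_path, sep="\t", index=False)


def _gff3_attributes(field9: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotations(gff3_path: str | os.PathLike, species: str) -> AnnotationIndex:
    """Index exon intervals per gene from a GFF3 file.

    Handles the common gene -> mRNA -> exon feature hierarchy; exons whose
    Parent chain does not resolve to a gene are an error.
    """
    genes: dict[str, GeneAnnotation] = {}
    parent_of: dict[str, str] = {}  # transcript id -> gene id
    exon_rows: list[tuple[str, str, str, int, int]] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise SeqIOError(f"{gff3_path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise SeqIOError(f"{gff3_path}:{lineno}: malformed coordinate") from exc
            if end < start:
                raise SeqIOError(f"{gff3_path}:{lineno}: end {end} < start {start}")
            attrs = _gff3_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise SeqIOError(f"{gff3_path}:{lineno}: gene without ID")
                genes[gid] = GeneAnnotation(gene_id=gid, chromosome=chrom, strand=strand, exons=[])
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise SeqIOError(f"{gff3_path}:{lineno}: exon without Parent")
                exon_rows.append((parent, chrom, strand, start, end))
    for parent, chrom, strand, start, end in exon_rows:
        gid = parent_of.get(parent, parent)
        if gid not in genes:
            raise SeqIOError(f"exon parent {parent!r} does not resolve to a gene")
        genes[gid].exons.append((start, end))
    for g in genes.values():
        g.exons.sort()
        # deduplicate identical exons contributed by sibling transcripts
        g.exons = sorted(set(g.exons))
    return AnnotationIndex(species=species, genes=genes)


def write_annotations(index: AnnotationIndex, gff3_path: str | os.PathLike,
                      source: str = "unigroup") -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(index.genes):
            g = index.genes[gid]
            lo = min(s for s, _ in g.exons)
            hi = max(e for _, e in g.exons)
            fh.write(f"{g.chromosome}\t{source}\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={gid}\n")
            fh.write(
                f"{g.chromosome}\t{source}\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={gid}.t1.exon{i};Parent={gid}.t1\n"
                )


def read_genome(fasta_path: str | os.PathLike) -> dict[str, str]:
    """Genome FASTA as {chromosome: sequence} (uppercased)."""
    out: dict[str, str] = {}
    with open(fasta_path) as fh:
        for header, seq in SimpleFastaParser(fh):
            out[header.split()[0]] = seq.upper()
    return out


def write_genome(genome: Mapping[str, str], fasta_path: str | os.PathLike,
                 width: int = 80) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_group_tables(groups: Sequence, specificity_results: Sequence,
                       out_dir: str | os.PathLike,
                       species_order: Sequence[str] | None = None) -> list[Path]:
    """Write membership/specificity TSVs plus per-group MSA and profile files.

    Row order is deterministic: group_id, then the fixed species order.
    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = []
    for g in sorted(groups, key=lambda g: g.group_id):
        order = species_order if species_order is not None else sorted(g.members)
        for sp in order:
            rec = g.members.get(sp)
            if rec is None:
                continue
            rows.append(
                {
                    "group_id": g.group_id,
                    "species": sp,
                    "pep_id": rec.pep_id,
                    "source": rec.source,
                    "R": f"{g.member_R.get(sp, float('nan')):.6f}",
                }
            )
    mem_path = out / "membership.tsv"
    pd.DataFrame(rows, columns=MEMBERSHIP_COLUMNS).to_csv(mem_path, sep="\t", index=False)
    written.append(mem_path)

    srows = []
    for r in sorted(specificity_results, key=lambda r: r.group_id):
        srows.append(
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
    spec_path = out / "specificity.tsv"
    pd.DataFrame(srows, columns=SPECIFICITY_COLUMNS).to_csv(spec_path, sep="\t", index=False)
    written.append(spec_path)

    msa_dir = out / "msa"
    prof_dir = out / "profiles"
    msa_dir.mkdir(exist_ok=True)
    prof_dir.mkdir(exist_ok=True)
    for g in sorted(groups, key=lambda g: g.group_id):
        if g.msa is not None:
            p = msa_dir / f"{_safe_name(g.group_id)}.msa.fasta"
            with open(p, "w") as fh:
                for pid, row in zip(g.msa.pep_ids, g.msa.rows):
                    fh.write(f">{pid}\n{row}\n")
            written.append(p)
        if g.profile is not None:
            p = prof_dir / f"{_safe_name(g.group_id)}.profile.tsv"
            with open(p, "w") as fh:
                fh.write(g.profile.to_text())
            written.append(p)
    return written


def _safe_name(group_id: str) -> str:
    return group_id.replace("/", "_").replace("+", "_")
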