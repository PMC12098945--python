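"""Pairwise global identity and near-identity clustering of reference peptides."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import PeptideRecord


@dataclass(frozen=True)
class IdentityPair:
    """Percent identity of a global alignment, from each sequence's viewpoint.

    ``pct_ab`` uses sequence a's ungapped length as denominator, ``pct_ba``
    sequence b's; the match count (numerator) is shared.
    """

    pct_ab: float
    pct_ba: float
    matches: int
    alignment_length: int

    @property
    def pct_alignment(self) -> float:
        """Identity over alignment columns (used by the specificity baseline)."""
        return 100.0 * self.matches / self.alignment_length


@dataclass
class RefCluster:
    cluster_id: str
    pep_ids: list[str]


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    return a


def global_alignment(a: str, b: str) -> tuple[str, str, float]:
    """Global affine-gap alignment (BLOSUM62, open 11 / extend 1).

    Returns the two gapped rows and the alignment score.  Deterministic:
    the first optimal alignment reported by the DP is used.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aln = _aligner().align(a, b)[0]
    return aln[0], aln[1], float(aln.score)


def global_identity(a: str, b: str) -> IdentityPair:
    """Percent identity in both directions of one global alignment."""
    row_a, row_b, _ = global_alignment(a, b)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return IdentityPair(
        pct_ab=100.0 * matches / len(a),
        pct_ba=100.0 * matches / len(b),
        matches=matches,
        alignment_length=len(row_a),
    )


def _kmers(seq: str, k: int = 4) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def identical_both_directions(a: str, b: str, threshold_pct: float,
                              kmer_prefilter: bool = True) -> bool:
    """True iff the pair clears ``threshold_pct`` identity in both directions.

    A 4-mer screen may skip the alignment for clearly unrelated pairs; at
    thresholds >= 50% and lengths >= 20 two sequences above threshold must
    share a 4-mer, so the screen is behaviour-neutral there.
    """
    if kmer_prefilter and min(len(a), len(b)) >= 20 and threshold_pct >= 50.0:
        if not (_kmers(a) & _kmers(b)):
            return False
    ident = global_identity(a, b)
    return ident.pct_ab > threshold_pct and ident.pct_ba > threshold_pct


def collapse_reference_clusters(peps: Sequence[PeptideRecord],
                                threshold_pct: float = 90.0,
                                cluster_prefix: str = "c") -> list[RefCluster]:
    """Greedy complete-linkage clustering at a bidirectional identity threshold.

    Peptides are visited in input order; a peptide joins the first existing
    cluster for which it clears the threshold against *every* member
    (complete linkage), otherwise it seeds a new cluster.  Deterministic
    given input order.
    """
    clusters: list[list[PeptideRecord]] = []
    for rec in peps:
        placed = False
        for members in clusters:
            if all(
                identical_both_directions(rec.sequence, m.sequence, threshold_pct)
                for m in members
            ):
                members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append([rec])
    width = max(4, len(str(len(clusters))))
    return [
        RefCluster(cluster_id=f"{cluster_prefix}{i:0{width}d}",
                   pep_ids=[m.pep_id for m in members])
        for i, members in enumerate(clusters, start=1)
    ]


def write_cluster_table(clusters: Iterable[RefCluster], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("pep_id\tcluster_id\n")
        for c in clusters:
            for pid in c.pep_ids:
                fh.write(f"{pid}\t{c.cluster_id}\n")
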