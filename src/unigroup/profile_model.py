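"""Profile models over multiple alignments and the relative score R.

A profile is a sequence of match states with log-odds emission scores in
bits.  A query is aligned to the whole profile (every state is either
matched or deleted; extra query residues are inserts) by Viterbi dynamic
programming; the raw bit score divided by the score of the profile's own
consensus gives the relative score R, with R(consensus) = 1 exactly and
R <= 1 for every query.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pairwise import global_alignment
from .seqio import AA20

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

DEFAULT_DELETE_BITS = 2.0
DEFAULT_INSERT_OPEN_BITS = 3.0
DEFAULT_INSERT_EXTEND_BITS = 1.0
DEFAULT_MIN_RAW_BITS = 10.0

_NEG = -1e30


class ProfileError(ValueError):
    pass


@dataclass
class MSA:
    """Equal-length gapped rows plus the ids of the source peptides."""

    pep_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ProfileError("empty MSA")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ProfileError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class ProfileModel:
    """Match-state emission scores (bits), consensus and path penalties."""

    match_scores: np.ndarray  # (n_states, 20) log-odds bits
    consensus: str
    column_map: list[int]  # MSA column index per match state
    delete_bits: float = DEFAULT_DELETE_BITS
    insert_open_bits: float = DEFAULT_INSERT_OPEN_BITS
    insert_extend_bits: float = DEFAULT_INSERT_EXTEND_BITS
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.max_score = float(self.match_scores.max(axis=1).sum())
        if self.max_score < 1.0:
            raise ProfileError(
                f"degenerate profile: max attainable score {self.max_score:.3f} < 1 bit"
            )
        if len(self.consensus) != self.n_states:
            raise ProfileError("consensus length != number of match states")

    @property
    def n_states(self) -> int:
        return int(self.match_scores.shape[0])

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# unigroup profile\tstates={self.n_states}\t")
        buf.write(f"penalties={self.delete_bits:g},{self.insert_open_bits:g},"
                  f"{self.insert_extend_bits:g}\n")
        buf.write(f"# consensus\t{self.consensus}\n")
        buf.write("state\tcolumn\tconsensus\t" + "\t".join(AA20) + "\n")
        for k in range(self.n_states):
            scores = "\t".join(f"{v:.17g}" for v in self.match_scores[k])
            buf.write(f"{k + 1}\t{self.column_map[k]}\t{self.consensus[k]}\t{scores}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ProfileModel":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        penalties = (DEFAULT_DELETE_BITS, DEFAULT_INSERT_OPEN_BITS, DEFAULT_INSERT_EXTEND_BITS)
        consensus = ""
        rows, cols = [], []
        for ln in lines:
            if ln.startswith("# unigroup profile"):
                for tok in ln.split("\t"):
                    if tok.startswith("penalties="):
                        penalties = tuple(float(x) for x in tok[10:].split(","))
            elif ln.startswith("# consensus"):
                consensus = ln.split("\t")[1]
            elif ln.startswith("#") or ln.startswith("state\t"):
                continue
            else:
                parts = ln.split("\t")
                cols.append(int(parts[1]))
                rows.append([float(x) for x in parts[3:23]])
        return cls(
            match_scores=np.asarray(rows, dtype=np.float64),
            consensus=consensus,
            column_map=cols,
            delete_bits=penalties[0],
            insert_open_bits=penalties[1],
            insert_extend_bits=penalties[2],
        )


@dataclass(frozen=True)
class ProfileScore:
    raw: float  # bits
    R: float  # raw / max_score


# ---------------------------------------------------------------------------
# Multiple alignment (deterministic center-star progressive aligner)
# ---------------------------------------------------------------------------


def _merge_alignment(master_center: list[str], master_rows: list[list[str]],
                     center_aln: str, new_aln: str) -> tuple[list[str], list[list[str]]]:
    """Merge a (center, new) pairwise alignment into the running MSA.

    ``master_center`` is the center row of the MSA built so far.  Gaps are
    reconciled column by column ("once a gap, always a gap").
    """
    out_center: list[str] = []
    out_rows: list[list[str]] = [[] for _ in master_rows]
    new_row: list[str] = []
    i = j = 0  # i over master columns, j over pairwise columns
    n_master, n_pair = len(master_center), len(center_aln)
    while i < n_master or j < n_pair:
        mc = master_center[i] if i < n_master else None
        pc = center_aln[j] if j < n_pair else None
        if mc == "-" and (pc != "-" or j >= n_pair):
            # master-only gap column: pad new row
            out_center.append("-")
            for r, row in zip(out_rows, master_rows):
                r.append(row[i])
            new_row.append("-")
            i += 1
        elif pc == "-" and (mc != "-" or i >= n_master):
            # pairwise-only gap column: pad all master rows
            out_center.append("-")
            for r in out_rows:
                r.append("-")
            new_row.append(new_aln[j])
            j += 1
        else:
            # both residue (or both gap) columns advance together
            out_center.append(master_center[i] if i < n_master else "-")
            for r, row in zip(out_rows, master_rows):
                r.append(row[i] if i < n_master else "-")
            new_row.append(new_aln[j] if j < n_pair else "-")
            i += 1
            j += 1
    out_rows.append(new_row)
    return out_center, out_rows


def build_msa(sequences: Sequence[str], pep_ids: Sequence[str] | None = None) -> MSA:
    """Deterministic center-star multiple alignment.

    The center is the sequence with the greatest total pairwise alignment
    score to the others (ties: first in input order); every other sequence
    is globally aligned to the center and the pairwise alignments merged
    column-wise.  For two sequences this reduces to the exact global
    pairwise alignment.
    """
    if not sequences:
        raise ProfileError("build_msa: empty input")
    ids = list(pep_ids) if pep_ids is not None else [f"seq{i + 1}" for i in range(len(sequences))]
    if len(ids) != len(sequences):
        raise ProfileError("pep_ids length mismatch")
    n = len(sequences)
    if n == 1:
        return MSA(pep_ids=ids, rows=[sequences[0]])

    pair_aln: dict[tuple[int, int], tuple[str, str, float]] = {}
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb, s = global_alignment(sequences[i], sequences[j])
            pair_aln[(i, j)] = (ra, rb, s)
            totals[i] += s
            totals[j] += s
    center = int(np.argmax(totals))

    master_center = list(sequences[center])
    master_rows: list[list[str]] = []
    order = [i for i in range(n) if i != center]
    for i in order:
        if (center, i) in pair_aln:
            c_aln, s_aln, _ = pair_aln[(center, i)]
        else:
            s_aln, c_aln, _ = pair_aln[(i, center)]
        master_center, master_rows = _merge_alignment(master_center, master_rows, c_aln, s_aln)
    rows_by_index: dict[int, str] = {center: "".join(master_center)}
    for pos, i in enumerate(order):
        rows_by_index[i] = "".join(master_rows[pos])
    msa = MSA(pep_ids=ids, rows=[rows_by_index[i] for i in range(n)])
    for i, seq in enumerate(sequences):
        assert msa.ungapped(i) == seq, "alignment lost residues"
    return msa


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------


def build_profile(msa: MSA,
                  occupancy_threshold: float = 0.5,
                  pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  delete_bits: float = DEFAULT_DELETE_BITS,
                  insert_open_bits: float = DEFAULT_INSERT_OPEN_BITS,
                  insert_extend_bits: float = DEFAULT_INSERT_EXTEND_BITS) -> ProfileModel:
    """Turn an MSA into a profile of match states.

    Columns whose non-gap occupancy is >= ``occupancy_threshold`` (inclusive)
    become match states.  Emission probabilities use a uniform-background
    pseudocount: e_k(a) = (c_k(a) + alpha*q_a) / (n_k + alpha) with alpha =
    ``pseudocount`` and q = 1/20 by default; match scores are
    log2(e_k(a)/q_a).  'X' residues count toward occupancy but not toward
    emission counts.
    """
    q = np.full(20, 1.0 / 20) if background is None else np.asarray(background, float)
    n_rows = len(msa.rows)
    scores: list[np.ndarray] = []
    column_map: list[int] = []
    consensus_chars: list[str] = []
    for col in range(msa.n_columns):
        column = [row[col] for row in msa.rows]
        non_gap = sum(1 for ch in column if ch != "-")
        if non_gap / n_rows < occupancy_threshold:
            continue
        counts = np.zeros(20)
        for ch in column:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        n_k = counts.sum()
        e = (counts + pseudocount * q) / (n_k + pseudocount)
        scores.append(np.log2(e / q))
        column_map.append(col)
        consensus_chars.append(AA20[int(np.argmax(e))])  # argmax ties -> alphabetical
    if not scores:
        raise ProfileError("MSA yields zero match states")
    return ProfileModel(
        match_scores=np.asarray(scores),
        consensus="".join(consensus_chars),
        column_map=column_map,
        delete_bits=delete_bits,
        insert_open_bits=insert_open_bits,
        insert_extend_bits=insert_extend_bits,
    )


def consensus(profile: ProfileModel) -> str:
    """The per-state maximum-emission residue (ties already alphabetical)."""
    return profile.consensus


def build_group_profile(sequences: Sequence[str], pep_ids: Sequence[str] | None = None,
                        **kwargs) -> tuple[MSA, ProfileModel]:
    msa = build_msa(sequences, pep_ids)
    return msa, build_profile(msa, **kwargs)


# ---------------------------------------------------------------------------
# Viterbi scoring (global in profile and query)
# ---------------------------------------------------------------------------


def _viterbi_impl(emit, x, d, go, ge):  # pragma: no cover - jitted
    n_states = emit.shape[0]
    n = x.shape[0]
    NEG = -1e30
    M = np.full((n + 1, n_states + 1), NEG)
    I = np.full((n + 1, n_states + 1), NEG)
    D = np.full((n + 1, n_states + 1), NEG)
    M[0, 0] = 0.0
    # deletions along the top row (query not yet started)
    for k in range(1, n_states + 1):
        best = M[0, k - 1]
        if D[0, k - 1] > best:
            best = D[0, k - 1]
        D[0, k] = best - d
    for i in range(1, n + 1):
        xi = x[i - 1]
        for k in range(n_states + 1):
            if k > 0:
                e = emit[k - 1, xi] if xi >= 0 else 0.0
                best = M[i - 1, k - 1]
                if I[i - 1, k - 1] > best:
                    best = I[i - 1, k - 1]
                if D[i - 1, k - 1] > best:
                    best = D[i - 1, k - 1]
                if best > NEG / 2:
                    M[i, k] = best + e
            # insert after state k
            a = M[i - 1, k] - go
            b = I[i - 1, k] - ge
            c = D[i - 1, k] - go
            best = a
            if b > best:
                best = b
            if c > best:
                best = c
            if best > NEG / 2:
                I[i, k] = best
        for k in range(1, n_states + 1):
            best = M[i, k - 1]
            if I[i, k - 1] > best:
                best = I[i, k - 1]
            if D[i, k - 1] > best:
                best = D[i, k - 1]
            if best > NEG / 2:
                D[i, k] = best - d
    res = M[n, n_states]
    if I[n, n_states] > res:
        res = I[n, n_states]
    if D[n, n_states] > res:
        res = D[n, n_states]
    return res


try:  # numba is optional; the pure-Python path is identical but slow
    from numba import njit

    _viterbi = njit(cache=False)(_viterbi_impl)
except ImportError:  # pragma: no cover
    _viterbi = _viterbi_impl


def encode_sequence(seq: str) -> np.ndarray:
    """Map residues to alphabet indices; 'X' becomes -1 (scores background 0)."""
    return np.asarray([_AA_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)


def score(profile: ProfileModel, seq: str) -> ProfileScore:
    """Viterbi raw bit score of ``seq`` against the whole profile, and R.

    Every match state is matched or deleted (``delete_bits`` each); query
    residues not matched are inserts with zero emission, penalized affinely
    (``insert_open_bits`` for the first residue of a run,
    ``insert_extend_bits`` for each further one).  R = raw / max_score.
    """
    if not seq:
        raise ProfileError("cannot score empty sequence")
    raw = float(
        _viterbi(
            profile.match_scores,
            encode_sequence(seq),
            profile.delete_bits,
            profile.insert_open_bits,
            profile.insert_extend_bits,
        )
    )
    return ProfileScore(raw=raw, R=raw / profile.max_score)


def hit_filter(profile_score: ProfileScore, min_raw_bits: float = DEFAULT_MIN_RAW_BITS) -> bool:
    """Significance gate: raw bit score at or above the threshold (inclusive)."""
    return profile_score.raw >= min_raw_bits
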