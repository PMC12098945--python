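"""Independent brute-force oracles shared by the test suite.

These deliberately re-implement the scoring semantics by exhaustive
enumeration (no dynamic programming) so that they stay independent of the
production code paths they check.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from unigroup.profile_model import ProfileModel, encode_sequence


def enumerate_alignment_score(profile: ProfileModel, seq: str) -> float:
    """Best alignment score by exhaustive path enumeration.

    Semantics mirrored independently: every state matched or deleted
    (flat delete cost), unmatched query residues are inserts with affine
    open/extend costs; insert runs are per-position (a delete or match
    resets the run).
    """
    x = encode_sequence(seq)
    L = profile.n_states
    d = profile.delete_bits
    go = profile.insert_open_bits
    ge = profile.insert_extend_bits
    scores = profile.match_scores

    @lru_cache(maxsize=None)
    def best(i: int, k: int, in_insert_run: bool) -> float:
        if i == len(x) and k == L:
            return 0.0
        out = -math.inf
        if i < len(x) and k < L:  # match
            e = float(scores[k][x[i]]) if x[i] >= 0 else 0.0
            out = max(out, e + best(i + 1, k + 1, False))
        if k < L:  # delete state k
            out = max(out, -d + best(i, k + 1, False))
        if i < len(x):  # insert residue i
            cost = ge if in_insert_run else go
            out = max(out, -cost + best(i + 1, k, True))
        return out

    result = best(0, 0, False)
    best.cache_clear()
    return result


def random_profile(rng: np.random.Generator, n_states: int, n_rows: int = 4) -> ProfileModel:
    """A profile built from random gap-free MSA rows (retry if degenerate)."""
    from unigroup.profile_model import MSA, ProfileError, build_profile
    from unigroup.seqio import AA20

    while True:
        rows = [
            "".join(rng.choice(list(AA20), size=n_states)) for _ in range(n_rows)
        ]
        try:
            return build_profile(MSA(pep_ids=[f"r{i}" for i in range(n_rows)], rows=rows))
        except ProfileError:
            continue


def random_query(rng: np.random.Generator, length: int) -> str:
    from unigroup.seqio import AA20

    return "".join(rng.choice(list(AA20), size=length))


def complete_linkage_valid(clusters, seqs_by_id, threshold_pct) -> bool:
    """Independent all-pairs check of the bidirectional identity rule."""
    from unigroup.pairwise import global_identity

    for c in clusters:
        for i, a in enumerate(c.pep_ids):
            for b in c.pep_ids[i + 1:]:
                ident = global_identity(seqs_by_id[a], seqs_by_id[b])
                if not (ident.pct_ab > threshold_pct and ident.pct_ba > threshold_pct):
                    return False
    return True


def supergroup_components_bruteforce(groups, config) -> set[frozenset[str]]:
    """Recompute supergroup components by direct all-member cross-scoring."""
    from unigroup import profile_model as pm

    live = [g for g in groups if g.status == "universal"]
    n = len(live)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            ok = all(
                pm.score(live[j].profile, r.sequence).R > config.r_min
                for r in live[i].members.values()
            ) and all(
                pm.score(live[i].profile, r.sequence).R > config.r_min
                for r in live[j].members.values()
            )
            if ok:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    comps: set[frozenset[str]] = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        if len(comp) >= 2:
            comps.add(frozenset(live[k].group_id for k in comp))
    return comps
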