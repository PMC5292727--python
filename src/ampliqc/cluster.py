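"""Back end of step 1: de-novo chimera removal, greedy abundance-seeded
clustering with end-free overlap identity, consensus calling, small-cluster
removal.

Clustering tolerates length differences (quality truncation shortens reads
from the 3' end), so a truncated copy of a sequence joins its full-length
cluster at 100% overlap identity instead of seeding a spurious new one.
Merged, read-1 and read-2 sequences are never co-clustered; the caller
runs this module once per specimen x marker x stream.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .align import align, overlap_identity, prefix_cost_profile
from .model import Cluster, PreparedSequence


# ------------------------------------------------------------- chimeras

def detect_chimeras(
    uniques: Sequence[PreparedSequence],
    min_parent_ratio: float = 2.0,
    min_score: int = 3,
) -> list[bool]:
    """De-novo two-parent chimera flags, one per unique (input order).

    Queries are examined from least to most abundant. Candidate parents
    are unflagged uniques with abundance >= min_parent_ratio x the query's.
    For every parent the query's cumulative mismatch profile is computed
    from a global alignment; for every ordered parent pair the best single
    crossover (left from A, right from B) is found on that common query
    coordinate. The query is chimeric when the two-parent model beats the
    best single parent by >= min_score differences and each parent
    explains at least one diagnostic site on its own segment.
    """
    n = len(uniques)
    flags = [False] * n
    if n < 3:
        return flags
    order = sorted(range(n), key=lambda i: (uniques[i].abundance, -i))
    for qi in order:
        q = uniques[qi]
        parents = [
            i
            for i in range(n)
            if i != qi
            and not flags[i]
            and uniques[i].abundance >= min_parent_ratio * q.abundance
        ]
        if len(parents) < 2:
            continue
        P = np.array(
            [prefix_cost_profile(q.bases, uniques[pi].bases) for pi in parents],
            dtype=np.int32,
        )  # parents x (L+1) cumulative left-segment costs
        best_single = int(P[:, -1].min())
        right = P[:, -1:] - P  # cost of the segment right of crossover k
        # two-parent cost tensor: C[a, b, k] = left(A up to k) + right(B from k)
        C = P[:, None, :] + right[None, :, :]
        a_idx = np.arange(len(parents))
        C[a_idx, a_idx, :] = np.iinfo(np.int32).max  # forbid A == B
        cmin = int(C.min())
        if best_single - cmin < min_score:
            continue
        # diagnostic support: among all minimal crossovers, require one where
        # A strictly beats B on the left and B strictly beats A on the right
        left_gain = P[None, :, :] - P[:, None, :]   # [a, b, k] = cb[k] - ca[k]
        right_gain = right[:, None, :] - right[None, :, :]
        ok = (C == cmin) & (left_gain >= 1) & (right_gain >= 1)
        if ok.any():
            flags[qi] = True
    return flags


def remove_chimeras(
    uniques: Sequence[PreparedSequence],
    min_parent_ratio: float = 2.0,
    min_score: int = 3,
) -> tuple[list[PreparedSequence], list[PreparedSequence]]:
    """Split uniques into (kept, flagged_chimeric)."""
    flags = detect_chimeras(uniques, min_parent_ratio, min_score)
    kept = [u for u, f in zip(uniques, flags) if not f]
    flagged = [u for u, f in zip(uniques, flags) if f]
    return kept, flagged


# ------------------------------------------------------------ consensus

class _Profile:
    """Incremental per-seed-column base weights for consensus calling.

    Column t keeps abundance weights over {A,C,G,T,N,'-'} plus, per base,
    the index of the first (most abundant) member carrying it — the tie
    breaker. Member insertions relative to the seed contribute no columns;
    bases of members not covering a seed column count as gaps, including
    end gaps, so a truncated majority shortens the consensus via the
    gap-majority rule.
    """

    def __init__(self, seed: str):
        self.seed = seed
        self.weights: list[dict] = [{} for _ in range(len(seed))]
        self.carriers: list[dict] = [{} for _ in range(len(seed))]
        self.total = 0

    def _bump(self, t: int, base: str, abundance: int, member_index: int) -> None:
        self.weights[t][base] = self.weights[t].get(base, 0) + abundance
        self.carriers[t].setdefault(base, member_index)

    def add(self, member: PreparedSequence, member_index: int) -> None:
        self.total += member.abundance
        if member.bases == self.seed:
            for t, b in enumerate(self.seed):
                self._bump(t, b, member.abundance, member_index)
            return
        covered = bytearray(len(self.seed))
        if len(member.bases) <= len(self.seed):
            # member sits inside the seed with free seed end gaps
            aln = align(member.bases, self.seed, mode="HW")
            for qpos, tpos in aln.columns():
                if tpos is None:
                    continue
                base = member.bases[qpos] if qpos is not None else "-"
                self._bump(tpos, base, member.abundance, member_index)
                covered[tpos] = 1
        else:
            # longer member: place the seed inside it and read the member's
            # base at every seed column (member overhangs are dropped —
            # consensus columns are the seed's)
            aln = align(self.seed, member.bases, mode="HW")
            for spos, mpos in aln.columns():
                if spos is None:
                    continue
                base = member.bases[mpos] if mpos is not None else "-"
                self._bump(spos, base, member.abundance, member_index)
                covered[spos] = 1
        for t, c in enumerate(covered):
            if not c:
                self._bump(t, "-", member.abundance, member_index)

    def consensus(self) -> str:
        out = []
        for w, carrier in zip(self.weights, self.carriers):
            gap_w = w.get("-", 0)
            if gap_w * 2 > self.total:
                continue
            best = None
            for base, weight in w.items():
                if base == "-":
                    continue
                key = (-weight, carrier[base])
                if best is None or key < best[0]:
                    best = (key, base)
            if best is not None:
                out.append(best[1])
        return "".join(out)


def call_consensus(cluster: Cluster) -> str:
    """Abundance-weighted per-column majority over members aligned to the
    seed; ties resolve toward the base carried by the most abundant
    (earliest) member; columns with a strict gap majority are omitted."""
    if not cluster.members:
        raise ValueError("empty cluster")
    prof = _Profile(cluster.seed.bases)
    for mi, m in enumerate(cluster.members):
        prof.add(m, mi)
    return prof.consensus()


# ------------------------------------------------------------ clustering

def cluster_sequences(
    uniques: Sequence[PreparedSequence],
    min_overlap: int = 100,
    min_identity: float = 0.97,
) -> list[Cluster]:
    """Greedy abundance-seeded agglomeration.

    Uniques are processed in the canonical order (abundance descending,
    lexicographic tiebreak). Each joins the first cluster whose current
    consensus it matches with overlap >= min_overlap columns and identity
    >= min_identity under the end-free overlap alignment; otherwise it
    seeds a new cluster. The cluster consensus is refreshed incrementally
    after every join; final clusters are ranked by total reads
    (descending), consensus string as tiebreak.
    """
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.bases))
    clusters: list[Cluster] = []
    profiles: list[_Profile] = []
    for u in ordered:
        placed = False
        for cl, prof in zip(clusters, profiles):
            ident, ov = overlap_identity(u.bases, cl.consensus)
            if ov >= min_overlap and ident >= min_identity:
                cl.members.append(u)
                prof.add(u, len(cl.members) - 1)
                cl.consensus = prof.consensus()
                placed = True
                break
        if not placed:
            prof = _Profile(u.bases)
            prof.add(u, 0)
            clusters.append(Cluster(members=[u], consensus=u.bases))
            profiles.append(prof)
    clusters.sort(key=lambda c: (-c.total_reads, c.consensus))
    for rank, cl in enumerate(clusters, start=1):
        cl.rank = rank
    return clusters


def filter_small_clusters(
    clusters: Sequence[Cluster], min_reads: int = 10
) -> list[Cluster]:
    """Keep clusters with total_reads >= min_reads (10 kept, 9 dropped)."""
    kept = [c for c in clusters if c.total_reads >= min_reads]
    for rank, cl in enumerate(kept, start=1):
        cl.rank = rank
    return kept
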