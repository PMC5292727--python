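"""Chimera detection, clustering, consensus calling — each checked against
an independent brute-force oracle where the operation is non-trivial."""

import numpy as np
import pytest

from ampliqc.align import overlap_identity
from ampliqc.cluster import (
    call_consensus,
    cluster_sequences,
    detect_chimeras,
    filter_small_clusters,
)
from ampliqc.model import Cluster

from conftest import mutate, prepared, random_seq


# --------------------------------------------------------------- oracles

def single_linkage_partition(seqs, min_overlap, min_identity):
    """Brute-force single-linkage: connect every pair meeting the overlap
    identity threshold, return connected components as frozensets of
    indices."""
    n = len(seqs)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            ident, ov = overlap_identity(seqs[i], seqs[j])
            if ov >= min_overlap and ident >= min_identity:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def chimera_scan_oracle(uniques, min_parent_ratio, min_score):
    """Exhaustive ungapped parent-pair x crossover scan for equal-length
    uniques (independent of the alignment machinery)."""
    n = len(uniques)
    flags = [False] * n
    for qi in sorted(range(n), key=lambda i: uniques[i].abundance):
        q = uniques[qi].bases
        parents = [
            i for i in range(n)
            if i != qi and not flags[i]
            and uniques[i].abundance >= min_parent_ratio * uniques[qi].abundance
        ]
        if len(parents) < 2:
            continue
        mism = {
            p: [a != b for a, b in zip(q, uniques[p].bases)] for p in parents
        }
        cum = {p: np.concatenate([[0], np.cumsum(mism[p])]) for p in parents}
        L = len(q)
        best_single = min(int(cum[p][L]) for p in parents)
        hit = False
        for a in parents:
            for b in parents:
                if a == b:
                    continue
                total = cum[a] + (cum[b][L] - cum[b])
                k = int(np.argmin(total))
                cost = int(total[k])
                left_gain = int(cum[b][k] - cum[a][k])
                right_gain = int(
                    (cum[a][L] - cum[a][k]) - (cum[b][L] - cum[b][k])
                )
                if (
                    best_single - cost >= min_score
                    and left_gain >= 1
                    and right_gain >= 1
                ):
                    hit = True
        flags[qi] = hit
    return flags


# --------------------------------------------------------------- chimeras

class TestDetectChimeras:
    def test_two_parent_splice_is_flagged(self, rng):
        a = random_seq(rng, 400)
        b = mutate(rng, a, 40)  # ~10% divergent
        query = a[:200] + b[200:]
        uniques = [prepared(a, 20), prepared(b, 20), prepared(query, 2)]
        assert detect_chimeras(uniques, 2.0, 3) == [False, False, True]

    def test_copy_of_parent_not_flagged(self, rng):
        a = random_seq(rng, 400)
        b = mutate(rng, a, 40)
        uniques = [prepared(a, 20), prepared(b, 20), prepared(a, 2)]
        assert detect_chimeras(uniques, 2.0, 3) == [False, False, False]

    def test_single_unique_nothing_flagged(self, rng):
        assert detect_chimeras([prepared(random_seq(rng, 200), 5)]) == [False]

    def test_agrees_with_exhaustive_scan(self, rng):
        # up to 50 equal-length uniques: a few abundant haplotypes, planted
        # chimeras, and error singletons
        for trial in range(5):
            haps = [random_seq(rng, 300)]
            for _ in range(2):
                haps.append(mutate(rng, haps[0], 30))
            uniques = [prepared(h, int(rng.integers(15, 40))) for h in haps]
            for _ in range(6):  # planted chimeras
                i, j = rng.choice(len(haps), size=2, replace=False)
                cut = int(rng.integers(80, 220))
                uniques.append(prepared(haps[i][:cut] + haps[j][cut:], 1))
            for _ in range(10):  # error singletons
                h = haps[int(rng.integers(len(haps)))]
                uniques.append(prepared(mutate(rng, h, 2), 1))
            uniques.sort(key=lambda u: (-u.abundance, u.bases))
            got = detect_chimeras(uniques, 2.0, 3)
            want = chimera_scan_oracle(uniques, 2.0, 3)
            assert got == want


# -------------------------------------------------------------- clustering

class TestClusterSequences:
    def test_two_divergent_haplotypes_two_clusters(self, rng):
        a = random_seq(rng, 400)
        b = mutate(rng, a, 40)
        uniques = [prepared(a, 30), prepared(b, 12)]
        clusters = cluster_sequences(uniques, min_overlap=100, min_identity=0.97)
        assert len(clusters) == 2
        assert clusters[0].total_reads == 30 and clusters[1].total_reads == 12

    def test_truncated_copy_joins_full_length_cluster(self, rng):
        a = random_seq(rng, 400)
        uniques = [prepared(a, 20), prepared(a[:-50], 5)]
        clusters = cluster_sequences(uniques, 100, 0.97)
        assert len(clusters) == 1

    def test_all_identical_single_cluster(self, rng):
        a = random_seq(rng, 300)
        clusters = cluster_sequences([prepared(a, 25)], 100, 0.97)
        assert len(clusters) == 1
        assert clusters[0].consensus == a

    def test_agrees_with_single_linkage_oracle(self, rng):
        # well-separated haplotype families with small within-family noise:
        # greedy abundance-seeded agglomeration must equal single linkage
        for trial in range(3):
            n_fam = int(rng.integers(2, 5))
            fams = [random_seq(rng, 350)]
            while len(fams) < n_fam:
                fams.append(mutate(rng, fams[0], int(rng.integers(40, 80))))
            uniques = []
            for f in fams:
                uniques.append(prepared(f, int(rng.integers(20, 60))))
                for _ in range(int(rng.integers(5, 20))):
                    variant = mutate(rng, f, int(rng.integers(1, 4)))
                    if int(rng.integers(2)):
                        variant = variant[: -int(rng.integers(1, 60))]
                    uniques.append(prepared(variant, 1))
            seen = set()
            uniques = [
                u for u in uniques
                if u.bases not in seen and not seen.add(u.bases)
            ][:200]
            uniques.sort(key=lambda u: (-u.abundance, u.bases))
            clusters = cluster_sequences(uniques, 100, 0.97)
            got = {
                frozenset(uniques.index(m) for m in c.members) for c in clusters
            }
            want = single_linkage_partition(
                [u.bases for u in uniques], 100, 0.97
            )
            assert got == want

    def test_partition_and_abundance_conservation(self, rng):
        seqs = [prepared(random_seq(rng, 200), int(rng.integers(1, 30)))
                for _ in range(30)]
        clusters = cluster_sequences(seqs, 100, 0.97)
        members = [m for c in clusters for m in c.members]
        assert len(members) == len(seqs)
        assert sum(c.total_reads for c in clusters) == sum(s.abundance for s in seqs)

    def test_deterministic_on_identical_input(self, rng):
        a = random_seq(rng, 300)
        uniques = [prepared(mutate(rng, a, k % 3), 10 - k) for k in range(5)]
        c1 = cluster_sequences(list(uniques), 100, 0.97)
        c2 = cluster_sequences(list(uniques), 100, 0.97)
        assert [c.consensus for c in c1] == [c.consensus for c in c2]
        assert [c.total_reads for c in c1] == [c.total_reads for c in c2]


class TestFilterSmallClusters:
    def test_boundary_at_ten_reads(self, rng):
        a, b = random_seq(rng, 200), random_seq(rng, 200)
        nine = Cluster(members=[prepared(a, 9)], consensus=a)
        ten = Cluster(members=[prepared(b, 10)], consensus=b)
        kept = filter_small_clusters([nine, ten], min_reads=10)
        assert [c.consensus for c in kept] == [b]

    def test_empty_list(self):
        assert filter_small_clusters([], 10) == []


# --------------------------------------------------------------- consensus

class TestCallConsensus:
    def test_identical_members(self, rng):
        a = random_seq(rng, 120)
        cl = Cluster(members=[prepared(a, 5), prepared(a, 3)])
        assert call_consensus(cl) == a

    def test_weighted_majority_column(self, rng):
        a = random_seq(rng, 120)
        b = a[:60] + ("G" if a[60] != "G" else "T") + a[61:]
        cl = Cluster(members=[prepared(a, 7), prepared(b, 3)])
        assert call_consensus(cl) == a

    def test_tie_goes_to_most_abundant_member(self, rng):
        a = random_seq(rng, 120)
        b = a[:60] + ("G" if a[60] != "G" else "T") + a[61:]
        cl = Cluster(members=[prepared(a, 5), prepared(b, 5)])
        assert call_consensus(cl) == a

    def test_consensus_matches_independent_weighted_count(self, rng):
        # ungapped members: per-column weighted majority is computable by
        # direct counting
        a = random_seq(rng, 150)
        members = [prepared(a, 10)]
        for k in range(4):
            members.append(prepared(mutate(rng, a, 3), int(rng.integers(1, 4))))
        cl = Cluster(members=members)
        got = call_consensus(cl)
        cols = []
        for t in range(len(a)):
            weights = {}
            order = {}
            for mi, m in enumerate(members):
                bb = m.bases[t]
                weights[bb] = weights.get(bb, 0) + m.abundance
                order.setdefault(bb, mi)
            cols.append(
                min(weights, key=lambda bb: (-weights[bb], order[bb]))
            )
        assert got == "".join(cols)
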