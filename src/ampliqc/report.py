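"""Final-level curation and reporting: p-distances, neighbor-joining
fallback trees, monophyly and divergent-group flagging, and the per-marker
stage-count tables with printed-style percentages.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .align import align
from .model import DistanceMatrix, ValidationError

_ACGT = frozenset("ACGT")


# ----------------------------------------------------------- p-distance

def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among sites where both sequences have
    an unambiguous base (pairwise deletion of gaps and Ns).

    Equal-length sequences are aligned globally; otherwise the shorter is
    placed within the longer with free end gaps, so the distance is taken
    over the shared extent. Raises if no site is comparable.
    """
    a, b = a.upper(), b.upper()
    # canonical argument order makes the distance symmetric even where the
    # optimal alignment path is tied
    if len(a) > len(b) or (len(a) == len(b) and a > b):
        a, b = b, a
    aln = align(a, b, mode="NW" if len(a) == len(b) else "HW")
    comparable = 0
    diffs = 0
    for qpos, tpos in aln.columns():
        if qpos is None or tpos is None:
            continue
        ba, bb = aln.query[qpos], aln.target[tpos]
        if ba in _ACGT and bb in _ACGT:
            comparable += 1
            if ba != bb:
                diffs += 1
    if comparable == 0:
        raise ValueError("p_distance undefined: zero comparable sites")
    return diffs / comparable


def distance_matrix(labels: Sequence[str], seqs: Sequence[str]) -> DistanceMatrix:
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(seqs[i], seqs[j])
    return DistanceMatrix(list(labels), m)


def group_divergence(groups: Sequence[Sequence[str]]) -> float:
    """Arithmetic mean of all between-group pairwise p-distances."""
    if any(len(g) == 0 for g in groups):
        raise ValueError("group_divergence: empty group")
    dists = []
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            for a in groups[gi]:
                for b in groups[gj]:
                    dists.append(p_distance(a, b))
    if not dists:
        raise ValueError("group_divergence needs at least two groups")
    return float(np.mean(dists))


# ------------------------------------------------------------------ trees

@dataclass
class PhyloTree:
    """An unrooted tree over sequence ids, newick-serializable."""

    tree: object  # skbio.TreeNode

    def __post_init__(self):
        tips = [t.name for t in self.tree.tips()]
        if len(tips) != len(set(tips)):
            raise ValidationError("duplicate leaf labels in tree")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        from skbio import TreeNode

        return cls(TreeNode.read(_io.StringIO(newick), format="newick"))


def build_nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining via scikit-bio; deterministic for a fixed label
    order. Used as the fallback when no externally inferred tree is
    supplied."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    if len(dm.labels) < 3:
        raise ValueError("build_nj_tree needs at least 3 labels")
    sk = SkbioDM(dm.matrix, ids=dm.labels)
    return PhyloTree(nj(sk))


def check_monophyly(tree: PhyloTree, species_map: dict[str, str]) -> dict[str, bool]:
    """Per-species monophyly under the unrooted convention: species S is
    monophyletic iff some edge bipartition isolates exactly S's leaves.
    Singleton species are monophyletic by definition."""
    tips = set(tree.tip_names)
    unmapped = tips - set(species_map)
    if unmapped:
        raise ValueError(f"leaves without species mapping: {sorted(unmapped)}")
    species_leaves: dict[str, frozenset] = {}
    for leaf, sp in species_map.items():
        if leaf in tips:
            species_leaves.setdefault(sp, set())
            species_leaves[sp] = species_leaves[sp] | {leaf}
    # every edge bipartition = tipset of a non-root node vs its complement
    splits = set()
    for node in tree.tree.postorder(include_self=False):
        clade = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        splits.add(clade)
        splits.add(frozenset(tips - clade))
    return {
        sp: (len(leaves) <= 1 or frozenset(leaves) in splits)
        for sp, leaves in species_leaves.items()
    }


# --------------------------------------------------------- problem species

@dataclass
class ProblemSpecies:
    species: str
    paraphyletic: bool
    n_groups: int
    groups: list[list[str]]
    between_group_divergence: Optional[float]


def divergent_groups(
    ids: Sequence[str], seqs: Sequence[str], threshold: float = 0.07
) -> list[list[str]]:
    """Single-linkage groups of a species' sequences cut strictly above
    ``threshold`` p-distance: members chain together while every link is
    <= threshold; a split requires all between-group distances > it."""
    if len(ids) == 1:
        return [list(ids)]
    dm = distance_matrix(ids, seqs)
    condensed = squareform(dm.matrix, checks=False)
    Z = linkage(condensed, method="single")
    assignment = fcluster(Z, t=threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for label, g in zip(ids, assignment):
        groups.setdefault(int(g), []).append(label)
    return [groups[k] for k in sorted(groups)]


def flag_problem_species(
    sequences: dict[str, str],
    species_map: dict[str, str],
    tree: Optional[PhyloTree],
    threshold: float = 0.07,
) -> list[ProblemSpecies]:
    """Flag species that are paraphyletic on the tree OR whose sequences
    split into >= 2 single-linkage groups at p-distance strictly above
    ``threshold``. ``sequences`` maps sequence id -> sequence and should
    contain the combined final + reference data set for one marker."""
    mono = (
        check_monophyly(tree, species_map)
        if tree is not None and len(sequences) >= 3
        else {}
    )
    by_species: dict[str, list[str]] = {}
    for sid in sequences:
        by_species.setdefault(species_map[sid], []).append(sid)
    problems = []
    for sp, ids in sorted(by_species.items()):
        para = not mono.get(sp, True)
        groups = divergent_groups(ids, [sequences[i] for i in ids], threshold)
        split = len(groups) > 1
        if para or split:
            div = None
            if split:
                div = group_divergence(
                    [[sequences[i] for i in g] for g in groups]
                )
            problems.append(
                ProblemSpecies(
                    species=sp,
                    paraphyletic=para,
                    n_groups=len(groups),
                    groups=groups,
                    between_group_divergence=div,
                )
            )
    return problems


# ------------------------------------------------------------ percentages

def percent(numerator: int, denominator: int) -> float:
    """Printed-table percentage: 100*n/d rounded half-up to 1 decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# -------------------------------------------------------------- summaries

@dataclass
class MarkerStageCounts:
    """Per marker(/stream) pipeline stage counts, Tables 2/3 style."""

    marker: str
    stream: str
    n_specimens: int
    pcr_positive: int = 0
    with_cluster: int = 0
    with_cluster_pcr_neg: int = 0
    pcr_pos_no_cluster: int = 0
    mean_clusters: float = 0.0
    max_clusters: int = 0
    passed_translation: int = 0
    major_failed_translation: int = 0
    major_off_target: int = 0
    major_contaminant: int = 0
    # mutually exclusive specimen-level funnel categories; they sum to
    # n_specimens so per-stage report counts stay additive
    no_cluster_specimens: int = 0
    removed_translation_specimens: int = 0
    removed_taxon_specimens: int = 0
    removed_contaminant_specimens: int = 0
    valid_specimens: int = 0

    def to_row(self) -> dict:
        d = {
            "marker": self.marker,
            "stream": self.stream,
            "n_specimens": self.n_specimens,
            "pcr_positive": self.pcr_positive,
            "pcr_positive_pct": percent(self.pcr_positive, self.n_specimens),
            "with_cluster": self.with_cluster,
            "with_cluster_pct": percent(self.with_cluster, self.n_specimens),
            "with_cluster_pcr_neg": self.with_cluster_pcr_neg,
            "pcr_pos_no_cluster": self.pcr_pos_no_cluster,
            "mean_clusters": self.mean_clusters,
            "max_clusters": self.max_clusters,
            "passed_translation": self.passed_translation,
            "passed_translation_pct": percent(
                self.passed_translation, self.with_cluster
            )
            if self.with_cluster
            else 0.0,
            "major_failed_translation": self.major_failed_translation,
            "major_off_target": self.major_off_target,
            "major_contaminant": self.major_contaminant,
            "no_cluster_specimens": self.no_cluster_specimens,
            "removed_translation_specimens": self.removed_translation_specimens,
            "removed_taxon_specimens": self.removed_taxon_specimens,
            "removed_contaminant_specimens": self.removed_contaminant_specimens,
            "valid_specimens": self.valid_specimens,
        }
        return d


@dataclass
class FinalMarkerCounts:
    """Per final (post-merge) marker counts, Table 4 style."""

    marker: str
    n_specimens: int
    n_species: int
    with_sequence: int = 0
    species_with_sequence: int = 0
    with_sequence_pcr_neg: int = 0
    pcr_pos_no_sequence: int = 0
    two_valid_sequences: int = 0
    problem_species: int = 0
    internal_gap_sequences: int = 0

    def to_row(self) -> dict:
        return {
            "marker": self.marker,
            "n_specimens": self.n_specimens,
            "n_species": self.n_species,
            "with_sequence": self.with_sequence,
            "with_sequence_pct": percent(self.with_sequence, self.n_specimens),
            "species_with_sequence": self.species_with_sequence,
            "species_with_sequence_pct": percent(
                self.species_with_sequence, self.n_species
            ),
            "with_sequence_pcr_neg": self.with_sequence_pcr_neg,
            "pcr_pos_no_sequence": self.pcr_pos_no_sequence,
            "two_valid_sequences": self.two_valid_sequences,
            "problem_species": self.problem_species,
            "internal_gap_sequences": self.internal_gap_sequences,
        }


@dataclass
class CurationReport:
    """The run's curation summary: stage tables, per-specimen flags, and
    the amplification-success-vs-storage-time series."""

    stage_counts: list[MarkerStageCounts] = field(default_factory=list)
    final_counts: list[FinalMarkerCounts] = field(default_factory=list)
    problem_species: dict[str, list[ProblemSpecies]] = field(default_factory=dict)
    contaminant_pairs: list = field(default_factory=list)
    success_by_year: Optional[pd.DataFrame] = None
    year_rank_correlation: Optional[float] = None

    def stage_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_row() for c in self.stage_counts])

    def final_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_row() for c in self.final_counts])

    def write(self, dir_path: str) -> None:
        import os

        os.makedirs(dir_path, exist_ok=True)
        self.stage_table().to_csv(
            os.path.join(dir_path, "stage_counts.tsv"), sep="\t", index=False
        )
        self.final_table().to_csv(
            os.path.join(dir_path, "final_counts.tsv"), sep="\t", index=False
        )
        if self.success_by_year is not None:
            self.success_by_year.to_csv(
                os.path.join(dir_path, "success_by_year.tsv"), sep="\t", index=False
            )
        rows = []
        for marker, probs in self.problem_species.items():
            for p in probs:
                rows.append(
                    {
                        "marker": marker,
                        "species": p.species,
                        "paraphyletic": p.paraphyletic,
                        "n_groups": p.n_groups,
                        "between_group_divergence": p.between_group_divergence,
                        "groups": ";".join(",".join(g) for g in p.groups),
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "marker",
                "species",
                "paraphyletic",
                "n_groups",
                "between_group_divergence",
                "groups",
            ],
        ).to_csv(os.path.join(dir_path, "problem_species.tsv"), sep="\t", index=False)


def success_by_year_series(
    years: Sequence[Optional[int]], successes: Sequence[bool]
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-collection-year amplification success fraction and the Spearman
    rank correlation between specimen age and success."""
    df = pd.DataFrame({"year": years, "success": successes}).dropna(subset=["year"])
    if df.empty:
        return pd.DataFrame(columns=["year", "n", "success_rate"]), None
    grouped = (
        df.groupby("year")["success"]
        .agg(n="count", success_rate="mean")
        .reset_index()
    )
    corr = None
    if len(grouped) >= 3 and grouped["success_rate"].nunique() > 1:
        rho, _ = spearmanr(grouped["year"], grouped["success_rate"])
        corr = float(rho) if not np.isnan(rho) else None
    return grouped, corr
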