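"""Screening genes for horizontal acquisition from non-fungal donors.

The screen mirrors the classic two-filter candidate call on per-gene
homolog hit tables: a gene is a candidate if (i) fewer than 15% of its
homolog hits are fungal (taxonomic skew) and/or (ii) the best fungal bit
score is below the best non-fungal one (bit-score dominance). Candidate
homolog sets are reduced with greedy centroid clustering at an identity
threshold adapted downward from 0.95 in 0.05 steps until at most 40
clusters remain (floor 0.50), a distance matrix of one-minus-identity is
built over cluster representatives, a neighbor-joining tree stands in for
the full alignment/ML stage, and the focal gene's smallest enclosing clade
decides whether the tree supports a non-fungal origin.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
from Bio import Phylo
from Bio.Align import PairwiseAligner

from .errors import EndosigError, FormatError


@dataclass(frozen=True)
class Hit:
    hit_id: str
    taxon_name: str
    kingdom: str  # "fungal" | "non_fungal"
    bit_score: float
    identity: float
    query_coverage: float
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kingdom not in ("fungal", "non_fungal"):
            raise FormatError(f"kingdom must be fungal/non_fungal, got {self.kingdom!r}")
        if self.bit_score <= 0:
            raise FormatError("bit_score must be positive")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise FormatError("identity and query_coverage must lie in [0, 1]")


@dataclass
class HitTable:
    gene_id: str
    hits: list[Hit]
    filtered: bool = False


@dataclass
class CandidateCall:
    gene_id: str
    fungal_fraction: float
    max_fungal_bit: float | None
    max_nonfungal_bit: float | None
    is_candidate: bool
    reasons: frozenset[str]
    evaluable: bool = True


def filter_hits(
    gene_id: str,
    raw_hits: list[Hit],
    min_coverage: float = 0.40,
    min_identity: float = 0.20,
    max_hits: int = 1000,
) -> HitTable:
    """Apply the load-time hit filter: coverage >= 40%, identity >= 20%, best 1,000.

    Survivors are sorted by bit score descending (ties: hit id ascending)
    and truncated; an empty result is returned as a flagged empty table.
    """
    survivors = [
        h for h in raw_hits
        if h.query_coverage >= min_coverage and h.identity >= min_identity
    ]
    survivors.sort(key=lambda h: (-h.bit_score, h.hit_id))
    return HitTable(gene_id=gene_id, hits=survivors[:max_hits], filtered=True)


def call_candidate(
    table: HitTable,
    fungal_frac_threshold: float = 0.15,
    score_mode: str = "max",
) -> CandidateCall:
    """Two-filter HGT candidate call on one gene's homolog hit table.

    ``score_mode`` selects how "fungal hits score lower" is judged:
    ``max`` compares the best hits (robust to hit-list truncation),
    ``mean`` the averages. A gene with no fungal hits at all triggers both
    reasons; a gene with no hits is returned not-evaluable.
    """
    if score_mode not in ("max", "mean"):
        raise FormatError(f"unknown score_mode {score_mode!r}")
    if not table.hits:
        return CandidateCall(table.gene_id, float("nan"), None, None,
                             False, frozenset(), evaluable=False)
    fungal = [h.bit_score for h in table.hits if h.kingdom == "fungal"]
    nonfungal = [h.bit_score for h in table.hits if h.kingdom == "non_fungal"]
    agg = max if score_mode == "max" else (lambda xs: sum(xs) / len(xs))
    fungal_frac = len(fungal) / len(table.hits)
    reasons = set()
    if not fungal:
        reasons.update({"taxonomic_skew", "bitscore_dominance"})
    else:
        if fungal_frac < fungal_frac_threshold:
            reasons.add("taxonomic_skew")
        if nonfungal and agg(fungal) < agg(nonfungal):
            reasons.add("bitscore_dominance")
    return CandidateCall(
        gene_id=table.gene_id,
        fungal_fraction=fungal_frac,
        max_fungal_bit=max(fungal) if fungal else None,
        max_nonfungal_bit=max(nonfungal) if nonfungal else None,
        is_candidate=bool(reasons),
        reasons=frozenset(reasons),
    )


# ---------------------------------------------------------------------------
# Pairwise identity and greedy clustering

_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str, return_aligned_columns: bool = False):
    """Global-alignment identity between two sequences.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1. Identity is
    the number of identical aligned positions divided by the alignment
    length (columns including gaps); symmetric in its arguments. With
    ``return_aligned_columns`` also returns the number of columns where
    both sequences are aligned (gap-free), used for coverage checks.
    """
    if not a or not b:
        raise EndosigError("pairwise_identity requires non-empty sequences")
    aln = _aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    identity = matches / len(ga)
    if return_aligned_columns:
        aligned_cols = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
        return identity, aligned_cols
    return identity


@dataclass
class ClusterSet:
    threshold_used: float
    clusters: list[tuple[str, list[str]]]  # (representative id, member ids incl. rep)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]


def greedy_cluster(seqs: dict[str, str], threshold: float) -> ClusterSet:
    """Greedy centroid clustering, longest-first (uclust-style).

    Sequences are visited by decreasing length (ties: id ascending); each
    joins the first existing centroid with identity >= ``threshold``, else
    founds a new cluster with itself as centroid.
    """
    if not (0.0 < threshold <= 1.0):
        raise FormatError("threshold must lie in (0, 1]")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[tuple[str, list[str]]] = []
    for sid in order:
        for idx, (rep, members) in enumerate(clusters):
            if pairwise_identity(seqs[sid], seqs[rep]) >= threshold:
                members.append(sid)
                break
        else:
            clusters.append((sid, [sid]))
    return ClusterSet(threshold_used=threshold, clusters=clusters)


def adaptive_cluster(
    seqs: dict[str, str],
    start: float = 0.95,
    step: float = 0.05,
    max_clusters: int = 40,
    floor: float = 0.50,
) -> ClusterSet:
    """Greedy clustering with the threshold stepped down until <= 40 clusters.

    Starts at 0.95; while the cluster count exceeds ``max_clusters`` and the
    threshold is above ``floor``, the threshold is reduced by 0.05 and the
    set re-clustered. The last result (with its threshold) is returned even
    if the floor is reached with more than ``max_clusters`` clusters.
    """
    if start <= floor:
        raise FormatError("start threshold must exceed floor")
    if step <= 0:
        raise FormatError("step must be positive")
    threshold = start
    result = greedy_cluster(seqs, threshold)
    while result.n_clusters > max_clusters and threshold - step >= floor - 1e-9:
        threshold = round(threshold - step, 10)
        result = greedy_cluster(seqs, threshold)
    return result


def rpb2_control_settings() -> MappingProxyType:
    """Clustering preset for conserved-control genes (e.g. RNA polymerase II).

    Highly conserved housekeeping genes are screened with a tighter preset:
    only hits with >75% identity enter the analysis and clustering runs at
    a 0.90 threshold. Returned as an immutable mapping.
    """
    return MappingProxyType({"identity_floor": 0.75, "cluster_threshold": 0.90})


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(distance_matrix: np.ndarray, labels: list[str]) -> str:
    """Neighbor-joining tree from a distance matrix, serialized as newick.

    Standard NJ agglomeration with deterministic tie-breaking (the
    lexicographically smallest index pair among minimal Q entries). The
    matrix must be symmetric, non-negative and zero on the diagonal, with
    at least three taxa. The returned tree is unrooted (trifurcating root).
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise EndosigError("neighbor joining requires at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise FormatError("distance matrix must be square, symmetric, non-negative, zero-diagonal")
    if len(labels) != n:
        raise FormatError("labels must match matrix dimension")

    nodes = [f"{label}" for label in labels]  # newick fragments
    d = d.copy()
    active = list(range(n))
    newick = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * d[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i][j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        # new node u replacing i and j
        u = d.shape[0]
        newrow = np.zeros((1, d.shape[1]))
        d = np.vstack([d, newrow])
        d = np.hstack([d, np.zeros((d.shape[0], 1))])
        for k in active:
            if k in (i, j):
                continue
            d[u][k] = d[k][u] = 0.5 * (d[i][k] + d[j][k] - d[i][j])
        newick[u] = f"({newick[i]}:{vi:.6f},{newick[j]}:{vj:.6f})"
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    vi = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    vj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    vk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    vi, vj, vk = (max(v, 0.0) for v in (vi, vj, vk))
    return f"({newick[i]}:{vi:.6f},{newick[j]}:{vj:.6f},{newick[k]}:{vk:.6f});"


# ---------------------------------------------------------------------------
# Sister-clade origin call

@dataclass
class SisterCladeCall:
    gene_id: str
    sister_members: list[str]
    origin: str  # "non_fungal" | "fungal" | "mixed"
    supported_hgt: bool


def sister_clade_call(
    tree_newick: str, focal_leaf: str, leaf_kingdoms: dict[str, str],
    gene_id: str | None = None,
) -> SisterCladeCall:
    """Decide the focal gene's origin from its placement in a gene tree.

    The unrooted tree is rooted at the leaf farthest from the focal leaf
    (path length; ties broken by leaf name). The smallest clade enclosing
    the focal leaf together with at least one other leaf defines the sister
    members; the origin is ``non_fungal`` if all of them are non-fungal,
    ``fungal`` if all are fungal, else ``mixed``. Only a uniformly
    non-fungal sister set supports horizontal transfer.
    """
    tree = Phylo.read(_io.StringIO(tree_newick), "newick")
    leaves = tree.get_terminals()
    names = [leaf.name for leaf in leaves]
    if focal_leaf not in names:
        raise EndosigError(f"focal leaf {focal_leaf!r} not in tree")
    for name in names:
        if name != focal_leaf and name not in leaf_kingdoms:
            raise EndosigError(f"leaf {name!r} has no fungal/non-fungal label")
    focal = next(l for l in leaves if l.name == focal_leaf)
    others = [l for l in leaves if l.name != focal_leaf]
    farthest = max(others, key=lambda l: (tree.distance(focal, l), l.name))
    tree.root_with_outgroup(farthest)

    path = tree.get_path(next(l for l in tree.get_terminals() if l.name == focal_leaf))
    sister: list[str] = []
    for clade in reversed(path[:-1]):  # path excludes root, ends at the leaf
        members = [l.name for l in clade.get_terminals() if l.name != focal_leaf]
        if members:
            sister = sorted(members)
            break
    if not sister:  # tree root is the smallest enclosing clade
        sister = sorted(l.name for l in tree.get_terminals() if l.name != focal_leaf)
    kingdoms = {leaf_kingdoms[name] for name in sister}
    if kingdoms == {"non_fungal"}:
        origin = "non_fungal"
    elif kingdoms == {"fungal"}:
        origin = "fungal"
    else:
        origin = "mixed"
    return SisterCladeCall(
        gene_id=gene_id or focal_leaf,
        sister_members=sister,
        origin=origin,
        supported_hgt=origin == "non_fungal",
    )


# ---------------------------------------------------------------------------
# End-to-end screen

@dataclass
class ScreenResult:
    call: CandidateCall
    clusters: ClusterSet | None = None
    tree: str | None = None
    sister: SisterCladeCall | None = None


def screen_gene(
    table: HitTable,
    focal_sequence: str | None = None,
    fungal_frac_threshold: float = 0.15,
    score_mode: str = "max",
    phylogeny: bool = True,
) -> ScreenResult:
    """Candidate call plus (optionally) clustering, NJ tree and origin call.

    The phylogenetic stage needs hit sequences: non-fungal hits are
    clustered adaptively, fungal hits at 0.95 with the same downward
    adjustment; a distance matrix of one-minus-identity over the focal
    sequence and cluster representatives feeds neighbor joining.
    """
    call = call_candidate(table, fungal_frac_threshold, score_mode)
    result = ScreenResult(call=call)
    if not (phylogeny and call.is_candidate and focal_sequence):
        return result
    seqs = {h.hit_id: h.sequence for h in table.hits if h.sequence}
    kingdom_of = {h.hit_id: h.kingdom for h in table.hits}
    nonfungal = {i: s for i, s in seqs.items() if kingdom_of[i] == "non_fungal"}
    fungal = {i: s for i, s in seqs.items() if kingdom_of[i] == "fungal"}
    if len(nonfungal) < 2:
        return result
    nf_clusters = adaptive_cluster(nonfungal)
    reps = list(nf_clusters.representatives())
    if fungal:
        f_clusters = adaptive_cluster(fungal)
        reps += f_clusters.representatives()
    labels = [table.gene_id] + reps
    all_seqs = {table.gene_id: focal_sequence, **{r: seqs[r] for r in reps}}
    if len(labels) < 3:
        return result
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = 1.0 - pairwise_identity(all_seqs[labels[i]], all_seqs[labels[j]])
            dist[i][j] = dist[j][i] = dij
    tree = nj_tree(dist, labels)
    leaf_kingdoms = {r: kingdom_of[r] for r in reps}
    sister = sister_clade_call(tree, table.gene_id, leaf_kingdoms, gene_id=table.gene_id)
    result.clusters = nf_clusters
    result.tree = tree
    result.sister = sister
    return result
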