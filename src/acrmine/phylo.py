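"""Grishin-distance, fast minimum-evolution phylogenetics for Acr families.

The distance model relates the fraction of identical residues q between two
proteins to an evolutionary distance d (substitutions/site) via

    q = ln(1 + 2d) / (2d),

a protein distance correction accounting for among-site rate variation.
q comes from optimal global pairwise alignment (BLOSUM62, affine gaps),
counted over residue–residue columns only. Trees are fast minimum-evolution:
neighbor joining (the standard greedy ME heuristic) gives the topology,
branch lengths are refit by ordinary least squares against the distance
matrix with negative lengths clamped to zero. An exhaustive-ME validation
mode fits every unrooted topology for small taxon sets.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .records import HomologyHit, validate_residues

logger = logging.getLogger(__name__)


@dataclass
class PhyloParams:
    """Homolog-filter and alignment settings.

    The filter defaults are the printed thresholds (E-value < 0.001, query
    coverage > 0.70, both strict; maximum sequence difference 1−q ≤ 0.85)."""

    evalue_max: float = 1e-3
    coverage_min: float = 0.70
    max_difference: float = 0.85
    d_cap: float = 10.0
    scoring: str = "blosum62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    n_identical: int
    n_aligned_pairs: int
    score: float

    @property
    def q(self) -> float:
        """Fraction identical over residue–residue columns."""
        if self.n_aligned_pairs == 0:
            return 0.0
        return self.n_identical / self.n_aligned_pairs


def _make_aligner(scoring: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring == "blosum62":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    elif scoring == "identity":
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
    else:
        raise ValueError(f"unknown scoring {scoring!r}")
    # a gap of length k costs gap_open + (k-1)*gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    scoring: str = "blosum62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    id_a: str = "A",
    id_b: str = "B",
) -> PairwiseAlignment:
    """Optimal global alignment; q counts residue–residue columns only."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    validate_residues(seq_a)
    validate_residues(seq_b)
    aligner = _make_aligner(scoring, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    n_pairs = n_ident = 0
    for x, y in zip(sa, sb):
        if x != "-" and y != "-":
            n_pairs += 1
            if x == y:
                n_ident += 1
    return PairwiseAlignment(id_a, id_b, sa, sb, n_ident, n_pairs, float(aln.score))


# ---------------------------------------------------------------------------
# Grishin distance
# ---------------------------------------------------------------------------

def grishin_identity(d: float) -> float:
    """Forward model: expected identity fraction q at distance d."""
    if d < 0:
        raise ValueError("d must be >= 0")
    if d == 0:
        return 1.0
    return float(np.log1p(2.0 * d) / (2.0 * d))


def grishin_distance_capped(q: float, d_cap: float = 10.0) -> tuple[float, bool]:
    """Invert q = ln(1+2d)/(2d) by bracketed root finding.

    Returns ``(d, capped)``; identities below q(d_cap) saturate at d_cap.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"q must be in (0, 1], got {q}")
    if q == 1.0:
        return 0.0, False
    q_floor = grishin_identity(d_cap)
    if q < q_floor:
        return d_cap, True
    lo, hi = 1e-12, d_cap
    if grishin_identity(lo) - q <= 0:
        return lo, False
    d = brentq(lambda x: grishin_identity(x) - q, lo, hi,
               xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(d), False


def grishin_distance(q: float, d_cap: float = 10.0) -> float:
    """Grishin distance for identity fraction q (see
    :func:`grishin_distance_capped` for the saturation flag)."""
    return grishin_distance_capped(q, d_cap)[0]


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances; taxa are kept in lexicographic
    order so downstream tree building is order-independent."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if np.isnan(self.matrix).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distances")
        order = np.argsort(self.ids)
        self.ids = [self.ids[i] for i in order]
        self.matrix = self.matrix[np.ix_(order, order)]

    def __len__(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])


def distance_matrix_from_sequences(
    sequences: dict[str, str],
    params: Optional[PhyloParams] = None,
) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """All-pairs alignment -> identity -> Grishin distances.

    Returns the matrix plus the list of saturated (capped) pairs."""
    params = params or PhyloParams()
    ids = sorted(sequences)
    n = len(ids)
    D = np.zeros((n, n))
    capped_pairs = []
    for i, j in itertools.combinations(range(n), 2):
        aln = align_pair(sequences[ids[i]], sequences[ids[j]],
                         params.scoring, params.gap_open, params.gap_extend,
                         id_a=ids[i], id_b=ids[j])
        q = aln.q
        if q <= 0.0:
            d, capped = params.d_cap, True
        else:
            d, capped = grishin_distance_capped(q, params.d_cap)
        D[i, j] = D[j, i] = d
        if capped:
            capped_pairs.append((ids[i], ids[j]))
    return DistanceMatrix(ids, D), capped_pairs


# ---------------------------------------------------------------------------
# Neighbor joining + OLS branch lengths (fast minimum evolution)
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree: adjacency map with branch lengths, plus the Newick
    serialization (rooted for display at the neighbor of the lexicographically
    first taxon, children ordered by smallest descendant leaf)."""

    taxa: list[str]
    adjacency: dict[str, dict[str, float]]
    newick: str
    tree_length: float

    def as_dendropy(self, taxon_namespace=None):
        import dendropy

        return dendropy.Tree.get(
            data=self.newick, schema="newick",
            taxon_namespace=taxon_namespace)

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, as frozensets of the smaller side."""
        out = set()
        for a, b in _edges(self.adjacency):
            side = _leaves_on_side(self.adjacency, a, b)
            if 1 < len(side) < len(self.taxa) - 1:
                other = frozenset(self.taxa) - side
                out.add(min(frozenset(side), other, key=lambda s: (len(s), sorted(s))))
        return out


def _edges(adj: dict[str, dict[str, float]]) -> list[tuple[str, str]]:
    return sorted({tuple(sorted((a, b))) for a in adj for b in adj[a]})


def _leaves_on_side(adj, a: str, b: str) -> frozenset:
    """Leaves reachable from ``b`` without crossing edge (a, b)."""
    seen, stack, leaves = {a, b}, [b], []
    while stack:
        u = stack.pop()
        nbrs = [v for v in adj[u] if v not in seen]
        if not nbrs and not u.startswith("_int"):
            pass
        for v in nbrs:
            seen.add(v)
            stack.append(v)
        if not u.startswith("_int"):
            leaves.append(u)
    return frozenset(leaves)


def nj_topology(D: DistanceMatrix) -> dict[str, dict[str, float]]:
    """Neighbor-joining topology (Saitou–Nei with the standard Q criterion),
    deterministic: taxa pre-sorted, ties broken by lexicographic node name."""
    n = len(D)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    names = list(D.ids)
    dist = {a: {} for a in names}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i != j:
                dist[a][b] = float(D.matrix[i, j])
    adj: dict[str, dict[str, float]] = {a: {} for a in names}
    active = sorted(names)
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            qv = (m - 2) * dist[a][b] - r[a] - r[b]
            key = (qv, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        counter += 1
        u = f"_int{counter:04d}"
        la = 0.5 * dist[a][b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist[a][b] - la
        adj.setdefault(u, {})
        adj[u][a] = adj.setdefault(a, {})[u] = la
        adj[u][b] = adj.setdefault(b, {})[u] = lb
        dist[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
            dist[u][c] = dist[c][u] = duc
        active = sorted([c for c in active if c not in (a, b)] + [u])
    # final star join
    counter += 1
    u = f"_int{counter:04d}"
    a, b, c = active
    adj.setdefault(u, {})
    la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    for node, ln in ((a, la), (b, lb), (c, lc)):
        adj[u][node] = adj.setdefault(node, {})[u] = ln
    return adj


def ols_branch_lengths(
    adj: dict[str, dict[str, float]],
    D: DistanceMatrix,
) -> tuple[dict[str, dict[str, float]], float]:
    """Refit all branch lengths by OLS against the distance matrix; negative
    estimates are clamped to zero and the tree length recomputed post-clamp."""
    taxa = D.ids
    edges = _edges(adj)
    edge_idx = {e: k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in _path_edges(adj, taxa[i], taxa[j]):
            A[row, edge_idx[e]] = 1.0
        y[row] = D.matrix[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    x = np.maximum(x, 0.0)
    fitted = {a: {} for a in adj}
    for e, k in edge_idx.items():
        a, b = e
        fitted[a][b] = fitted[b][a] = float(x[k])
    return fitted, float(x.sum())


def _path_edges(adj, a: str, b: str) -> list[tuple[str, str]]:
    parent = {a: None}
    stack = [a]
    while stack:
        u = stack.pop()
        if u == b:
            break
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    path = []
    u = b
    while parent[u] is not None:
        path.append(tuple(sorted((u, parent[u]))))
        u = parent[u]
    return path


def _to_newick(adj: dict[str, dict[str, float]], taxa: Sequence[str]) -> str:
    root_leaf = min(taxa)
    root = next(iter(adj[root_leaf]))

    def min_leaf(node: str, parent: str) -> str:
        if not node.startswith("_int"):
            return node
        return min(min_leaf(v, node) for v in adj[node] if v != parent)

    def render(node: str, parent: str) -> str:
        length = adj[node][parent]
        if not node.startswith("_int"):
            return f"{node}:{length!r}"
        children = sorted((v for v in adj[node] if v != parent),
                          key=lambda v: min_leaf(v, node))
        inner = ",".join(render(v, node) for v in children)
        return f"({inner}):{length!r}"

    children = sorted(adj[root], key=lambda v: min_leaf(v, root))
    inner = ",".join(render(v, root) for v in children)
    return f"({inner});"


def build_me_tree(D: DistanceMatrix) -> PhyloTree:
    """Fast minimum-evolution tree: NJ topology, OLS branch lengths (clamped
    at zero). Deterministic given the taxon set; input order is irrelevant."""
    if len(D) < 3:
        raise ValueError("need >= 3 taxa to build a tree")
    adj = nj_topology(D)
    fitted, total = ols_branch_lengths(adj, D)
    return PhyloTree(
        taxa=list(D.ids),
        adjacency=fitted,
        newick=_to_newick(fitted, D.ids),
        tree_length=total,
    )


# ---------------------------------------------------------------------------
# Exhaustive minimum-evolution validation mode
# ---------------------------------------------------------------------------

def enumerate_topologies(taxa: Sequence[str]):
    """Yield every unrooted binary topology over the taxa (n <= 8) as an
    adjacency map with unit branch lengths, by recursive edge insertion."""
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    if len(taxa) > 8:
        raise ValueError("exhaustive enumeration limited to n <= 8")

    base = {"_int0001": {t: 1.0 for t in taxa[:3]}}
    for t in taxa[:3]:
        base[t] = {"_int0001": 1.0}

    def insert(adj, leaf, counter):
        for a, b in _edges(adj):
            new = {k: dict(v) for k, v in adj.items()}
            u = f"_int{counter:04d}"
            del new[a][b]
            del new[b][a]
            new[u] = {a: 1.0, b: 1.0, leaf: 1.0}
            new[a][u] = new[b][u] = 1.0
            new[leaf] = {u: 1.0}
            yield new

    trees = [base]
    counter = 2
    for leaf in taxa[3:]:
        trees = [t2 for t in trees for t2 in insert(t, leaf, counter)]
        counter += 1
    yield from trees


def exhaustive_me_tree(D: DistanceMatrix) -> PhyloTree:
    """Fit OLS branch lengths on every topology and return the minimum
    total-length tree (ties broken by Newick string)."""
    best: Optional[PhyloTree] = None
    for adj in enumerate_topologies(D.ids):
        fitted, total = ols_branch_lengths(adj, D)
        tree = PhyloTree(list(D.ids), fitted, _to_newick(fitted, D.ids), total)
        if best is None or (tree.tree_length, tree.newick) < (best.tree_length,
                                                              best.newick):
            best = tree
    return best


# ---------------------------------------------------------------------------
# Homolog filtering and the family pipeline
# ---------------------------------------------------------------------------

def filter_homologs(
    hits: Sequence[HomologyHit],
    sequences: dict[str, str],
    seed_id: str,
    params: Optional[PhyloParams] = None,
) -> tuple[list[str], dict]:
    """Apply the homolog filters: E-value < evalue_max and coverage >
    coverage_min (strict), then sequence difference 1−q <= max_difference
    against the family seed. The seed itself is always retained."""
    params = params or PhyloParams()
    if seed_id not in sequences:
        raise KeyError(f"seed {seed_id!r} not among sequences")
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.subject_gene_id not in sequences:
            continue
        prev = best.get(h.subject_gene_id)
        if prev is None or h.evalue < prev.evalue:
            best[h.subject_gene_id] = h
    retained = [seed_id]
    audit_rows = []
    for sid in sorted(best):
        if sid == seed_id:
            continue
        h = best[sid]
        pass_hit = h.evalue < params.evalue_max and h.query_coverage > params.coverage_min
        difference = None
        keep = False
        if pass_hit:
            q = align_pair(sequences[seed_id], sequences[sid], params.scoring,
                           params.gap_open, params.gap_extend).q
            difference = 1.0 - q
            keep = difference <= params.max_difference
        if keep:
            retained.append(sid)
        audit_rows.append({"id": sid, "evalue": h.evalue,
                           "coverage": h.query_coverage,
                           "difference": difference, "retained": keep})
    audit = {"seed": seed_id, "n_hits": len(best), "n_retained": len(retained),
             "rows": audit_rows}
    return retained, audit


@dataclass
class FamilyTreeResult:
    distance_matrix: DistanceMatrix
    tree: PhyloTree
    newick: str
    capped_pairs: list = field(default_factory=list)
    audit: dict = field(default_factory=dict)


def family_tree_pipeline(
    sequences: dict[str, str],
    params: Optional[PhyloParams] = None,
    hits: Optional[Sequence[HomologyHit]] = None,
    seed_id: Optional[str] = None,
) -> FamilyTreeResult:
    """Homolog filter -> all-pairs alignment -> Grishin distances -> fast
    minimum-evolution tree -> Newick, with per-stage audit counts."""
    params = params or PhyloParams()
    seed_id = seed_id or sorted(sequences)[0]
    audit: dict = {"n_input": len(sequences)}
    if hits is not None:
        retained, filter_audit = filter_homologs(hits, sequences, seed_id, params)
        audit["filter"] = filter_audit
    else:
        retained = []
        for sid in sorted(sequences):
            if sid == seed_id:
                retained.append(sid)
                continue
            q = align_pair(sequences[seed_id], sequences[sid], params.scoring,
                           params.gap_open, params.gap_extend).q
            if 1.0 - q <= params.max_difference:
                retained.append(sid)
    audit["n_retained"] = len(retained)
    if len(retained) < 3:
        raise ValueError(
            f"only {len(retained)} sequences survive filtering; "
            ">= 3 required for a tree")
    subset = {sid: sequences[sid] for sid in retained}
    D, capped = distance_matrix_from_sequences(subset, params)
    if capped:
        logger.warning("%d saturated pairs capped at d=%s", len(capped), params.d_cap)
    tree = build_me_tree(D)
    audit["n_capped_pairs"] = len(capped)
    audit["tree_length"] = tree.tree_length
    return FamilyTreeResult(D, tree, tree.newick, capped, audit)
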