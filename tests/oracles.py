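"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain loops over the raw inputs,
sharing no code path with the package internals it checks.
"""
from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Candidate criteria, re-derived row by row
# ---------------------------------------------------------------------------

def brute_labels(hits, evalue_max=1e-3, coverage_min=0.70):
    lab = {}
    for h in hits:
        if h.evalue < evalue_max and h.query_coverage > coverage_min:
            lab.setdefault(h.subject_gene_id, set()).add(h.query_family)
    return lab


def brute_candidates(genomes, hits, domains, acr_families, aca_families, params):
    """Apply the six printed criteria to every gene with flat scans.

    Returns the set of (gene_id, candidate_class) pairs.
    """
    acr_fams = set(acr_families)
    aca_fams = set(aca_families)
    marker_fams = acr_fams | aca_fams
    lab = brute_labels(hits, params.evalue_max, params.coverage_min)
    dom_ok = {
        d.gene_id for d in domains
        if d.domain_label in ("HTH", "AP2") and d.probability >= params.domain_prob_min
    }

    def neighbors(genes, i):
        out = []
        for j in range(len(genes)):
            if j == i or abs(j - i) > params.window_genes:
                continue
            a, b = genes[i], genes[j]
            if b.start > a.end:
                gap = b.start - a.end - 1
            elif a.start > b.end:
                gap = a.start - b.end - 1
            else:
                gap = 0
            if gap <= params.max_intergenic_bp:
                out.append(genes[j])
        return out

    # association: family -> set of distinct acr marker families seen adjacent
    assoc: dict[str, set] = {}
    for genome in genomes:
        genes = sorted(genome.genes, key=lambda g: g.start)
        for i, g in enumerate(genes):
            own = lab.get(g.gene_id, set()) - acr_fams
            if not own:
                continue
            for nb in neighbors(genes, i):
                if nb.strand != g.strand:
                    continue
                for af in lab.get(nb.gene_id, set()) & acr_fams:
                    for fam in own:
                        assoc.setdefault(fam, set()).add(af)

    found = set()
    for genome in genomes:
        genes = sorted(genome.genes, key=lambda g: g.start)
        for i, g in enumerate(genes):
            nbs = neighbors(genes, i)
            acr_nb = any(nb.strand == g.strand
                         and lab.get(nb.gene_id, set()) & acr_fams
                         for nb in nbs)
            any_nb = any(nb.strand == g.strand
                         and lab.get(nb.gene_id, set()) & marker_fams
                         for nb in nbs)
            own = lab.get(g.gene_id, set()) - acr_fams
            a_count = max((len(assoc.get(f, set())) for f in own), default=0)
            if acr_nb and g.gene_id in dom_ok \
                    and a_count > params.association_threshold:
                found.add((g.gene_id, "aca_candidate"))
            if g.protein_length < params.max_protein_aa and any_nb:
                found.add((g.gene_id, "acr_candidate"))
    return found


# ---------------------------------------------------------------------------
# Homolog-filter row oracle
# ---------------------------------------------------------------------------

def brute_filter_rows(rows, evalue_max=1e-3, coverage_min=0.70, max_difference=0.85):
    """rows: (id, evalue, coverage, difference). Returns retained ids."""
    return [
        rid for rid, ev, cov, diff in rows
        if ev < evalue_max and cov > coverage_min and diff <= max_difference
    ]


# ---------------------------------------------------------------------------
# Affine-gap global alignment score (Gotoh), matching the convention that a
# gap of length k costs open + (k-1)*extend, terminal gaps penalized.
# ---------------------------------------------------------------------------

def gotoh_score(a, b, score_fn, gap_open=11.0, gap_extend=1.0):
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - gap_open)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def blosum62_fn():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(mat[x, y])


# ---------------------------------------------------------------------------
# Random additive distance matrices from random trees
# ---------------------------------------------------------------------------

def random_additive_matrix(n_taxa, rng):
    """Build a random unrooted binary tree with U(0.1, 1) branch lengths and
    return (taxa, matrix, splits) where matrix holds exact path distances and
    splits the set of nontrivial bipartitions (smaller side, ties by sorted
    content)."""
    taxa = [f"t{i}" for i in range(1, n_taxa + 1)]
    adj = {"x1": {}}
    for t in taxa[:3]:
        ln = rng.uniform(0.1, 1.0)
        adj["x1"][t] = ln
        adj[t] = {"x1": ln}
    counter = 1
    for t in taxa[3:]:
        edges = sorted({tuple(sorted(e)) for u in adj for e in
                        ((u, v) for v in adj[u])})
        a, b = edges[rng.integers(len(edges))]
        counter += 1
        u = f"x{counter}"
        old = adj[a].pop(b)
        adj[b].pop(a)
        split_at = rng.uniform(0.25, 0.75) * old
        adj[u] = {a: split_at, b: old - split_at, t: rng.uniform(0.1, 1.0)}
        adj[a][u] = split_at
        adj[b][u] = old - split_at
        adj[t] = {u: adj[u][t]}

    def path_len(s, t):
        import heapq

        dist = {s: 0.0}
        heap = [(0.0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if u == t:
                return d
            if d > dist.get(u, 1e18):
                continue
            for v, w in adj[u].items():
                nd = d + w
                if nd < dist.get(v, 1e18):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        raise RuntimeError("disconnected")

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = path_len(taxa[i], taxa[j])

    splits = set()
    full = frozenset(taxa)
    for u in adj:
        for v in adj[u]:
            if u < v:
                side = _leaves_beyond(adj, u, v)
                if 1 < len(side) < n_taxa - 1:
                    other = full - side
                    splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return taxa, D, splits, adj


def _leaves_beyond(adj, a, b):
    seen = {a, b}
    stack = [b]
    leaves = []
    while stack:
        u = stack.pop()
        if not u.startswith("x"):
            leaves.append(u)
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return frozenset(leaves)
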