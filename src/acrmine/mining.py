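"""Guilt-by-association mining of anti-CRISPR (Acr) and Acr-associated (Aca)
candidate genes.

Acr proteins are small mobile-genetic-element proteins that inhibit CRISPR–Cas
effectors; Aca proteins are DNA-binding (HTH/AP2) regulators that co-occur
with them in small same-strand cassettes. New candidates are found by their
genomic adjacency to known marker families ("guilt by association"):

Aca candidate — all three of
  (i)   directly upstream or downstream of an Acr homolog on the same strand;
  (ii)  carries a predicted DNA-binding domain (HTH or AP2);
  (iii) its family associates with more than two distinct Acr families
        corpus-wide.

Acr candidate —
  (i)   small protein (< 300 aa, strict);
  (ii)  directly upstream or downstream of an Acr or Aca marker on the same
        strand;
  (iii) an Acr–Aca fusion architecture, when present, upgrades confidence
        (a booster, not a requirement).

Validated candidates become markers for the next search round — the
iterative "search–validation" loop implemented by
:func:`search_validation_loop`, with the wet-lab validation step replaced by
a pluggable validator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .records import (
    DomainAnnotation,
    GeneRecord,
    GenomeAnnotation,
    HomologyHit,
    genes_by_id,
)

logger = logging.getLogger(__name__)

ACR = "acr"
ACA = "aca"


@dataclass
class MinerParams:
    """Thresholds of the candidate criteria.

    Defaults are the printed values where the source analysis prints one
    (300 aa size cap, E-value 0.001, coverage 0.70, association > 2 distinct
    families); all comparisons are strict, so boundary values fail.
    """

    evalue_max: float = 1e-3
    coverage_min: float = 0.70
    max_protein_aa: int = 300
    window_genes: int = 1           # "directly upstream or downstream"
    max_intergenic_bp: int = 1000
    association_threshold: int = 2  # candidate needs > this many distinct Acr families
    domain_prob_min: float = 0.5
    terminal_fraction: float = 0.4  # fusion: Aca evidence confined to this terminal slice
    min_remainder_aa: int = 40      # fusion: minimum Acr-like remainder
    max_iterations: int = 25
    audit_window_genes: int = 5     # wider window used only for audit listings

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class Neighbor:
    gene: GeneRecord
    side: str               # "upstream" | "downstream" (left/right on the replicon)
    rank: int               # 1 = immediately adjacent
    same_strand: bool
    intergenic_bp: int
    labels: frozenset = frozenset()


@dataclass
class NeighborhoodContext:
    focal: GeneRecord
    upstream: list[Neighbor] = field(default_factory=list)
    downstream: list[Neighbor] = field(default_factory=list)

    @property
    def neighbors(self) -> list[Neighbor]:
        return self.upstream + self.downstream


@dataclass(frozen=True)
class FusionCall:
    """An Acr–Aca fusion ORF: Aca-matching evidence confined to one terminal
    portion of the protein, with an Acr-sized remainder."""

    gene_id: str
    aca_start: int
    aca_end: int
    terminal_side: str  # "N" | "C"
    acr_remainder_length: int


@dataclass
class CandidateLocus:
    """A classified candidate with its per-criterion evidence trail."""

    gene_id: str
    replicon_id: str
    candidate_class: str  # acr_candidate | aca_candidate
    size_ok: bool
    adjacent_marker: Optional[str]   # marker family of the supporting neighbor
    adjacent_side: Optional[str]
    orientation_ok: bool
    has_dna_binding_domain: bool
    association_count: int
    fusion: Optional[FusionCall] = None
    confidence_tier: str = "standard"


class AssociationGraph:
    """Per-family counts of distinct Acr families observed adjacent (same
    strand, within window) to genes of that family, across all loci."""

    def __init__(self) -> None:
        self._edges: dict[str, dict[str, set]] = {}

    def add(self, family: str, acr_family: str, locus: str) -> None:
        self._edges.setdefault(family, {}).setdefault(acr_family, set()).add(locus)

    def distinct_acr_families(self, family: str) -> int:
        return len(self._edges.get(family, {}))

    def partners(self, family: str) -> dict[str, int]:
        return {a: len(loci) for a, loci in sorted(self._edges.get(family, {}).items())}

    def families(self) -> list[str]:
        return sorted(self._edges)

    def to_dict(self) -> dict:
        return {fam: self.partners(fam) for fam in self.families()}


class MarkerSet:
    """Marker families labeled acr or aca, with the loop iteration at which
    each was adopted. A family appears under exactly one label."""

    def __init__(self) -> None:
        self._families: dict[str, tuple[str, int]] = {}

    @classmethod
    def from_families(cls, acr: Iterable[str] = (), aca: Iterable[str] = (),
                      iteration: int = 0) -> "MarkerSet":
        ms = cls()
        for fam in acr:
            ms.add(fam, ACR, iteration)
        for fam in aca:
            ms.add(fam, ACA, iteration)
        return ms

    def add(self, family: str, label: str, iteration: int) -> bool:
        if label not in (ACR, ACA):
            raise ValueError(f"label must be acr or aca, got {label!r}")
        if family in self._families:
            return False
        self._families[family] = (label, iteration)
        return True

    def __contains__(self, family: str) -> bool:
        return family in self._families

    def __len__(self) -> int:
        return len(self._families)

    @property
    def acr_families(self) -> frozenset:
        return frozenset(f for f, (l, _) in self._families.items() if l == ACR)

    @property
    def aca_families(self) -> frozenset:
        return frozenset(f for f, (l, _) in self._families.items() if l == ACA)

    @property
    def families(self) -> frozenset:
        return frozenset(self._families)

    def iteration_of(self, family: str) -> int:
        return self._families[family][1]

    def copy(self) -> "MarkerSet":
        ms = MarkerSet()
        ms._families = dict(self._families)
        return ms

    def to_dict(self) -> dict:
        return {f: {"label": l, "iteration": i}
                for f, (l, i) in sorted(self._families.items())}


# ---------------------------------------------------------------------------
# Evidence mapping
# ---------------------------------------------------------------------------

def map_hits_to_genes(
    hits: Sequence[HomologyHit],
    genomes: Sequence[GenomeAnnotation],
    evalue_max: float = 1e-3,
    coverage_min: float = 0.70,
    families: Optional[Iterable[str]] = None,
) -> dict[str, dict[str, list[HomologyHit]]]:
    """Map passing homology hits onto genes.

    A gene carries family label F iff it has at least one hit to F with
    ``evalue < evalue_max`` and ``coverage > coverage_min`` (both strict).
    Returns ``{gene_id: {family: [passing hits]}}``; multiple labels per gene
    are allowed (fusion ORFs). Hits to unknown gene ids are skipped with a
    logged count. ``families``, when given, restricts to those query families.
    """
    gene_index = genes_by_id(genomes)
    fam_filter = set(families) if families is not None else None
    labels: dict[str, dict[str, list[HomologyHit]]] = {}
    unknown = 0
    for hit in hits:
        if fam_filter is not None and hit.query_family not in fam_filter:
            continue
        if not (hit.evalue < evalue_max and hit.query_coverage > coverage_min):
            continue
        if hit.subject_gene_id not in gene_index:
            unknown += 1
            continue
        labels.setdefault(hit.subject_gene_id, {}).setdefault(
            hit.query_family, []).append(hit)
    if unknown:
        logger.warning("skipped %d hits to unknown gene ids", unknown)
    return labels


def _intergenic_bp(a: GeneRecord, b: GeneRecord) -> int:
    """Gap in bp between two gene intervals (0 if they touch or overlap)."""
    if b.start > a.end:
        return b.start - a.end - 1
    if a.start > b.end:
        return a.start - b.end - 1
    return 0


def build_context(
    gene: GeneRecord,
    genome: GenomeAnnotation,
    window_genes: int = 1,
    max_intergenic_bp: int = 1000,
    labels: Optional[dict[str, dict]] = None,
) -> NeighborhoodContext:
    """Collect up to ``window_genes`` neighbors per side, ordered by genomic
    distance, dropping neighbors whose gap to the focal gene exceeds
    ``max_intergenic_bp``. Replicon edges yield truncated sides."""
    idx = genome.index_of(gene.gene_id)
    ctx = NeighborhoodContext(focal=gene)
    for side, step in (("upstream", -1), ("downstream", +1)):
        out = []
        for rank in range(1, window_genes + 1):
            j = idx + step * rank
            if j < 0 or j >= len(genome.genes):
                break
            nb = genome.genes[j]
            gap = _intergenic_bp(gene, nb)
            if gap > max_intergenic_bp:
                break
            fams = frozenset((labels or {}).get(nb.gene_id, {}))
            out.append(Neighbor(
                gene=nb, side=side, rank=rank,
                same_strand=nb.strand == gene.strand,
                intergenic_bp=gap, labels=fams))
        if side == "upstream":
            ctx.upstream = out
        else:
            ctx.downstream = out
    return ctx


def build_association_graph(
    genomes: Sequence[GenomeAnnotation],
    gene_labels: dict[str, dict],
    acr_marker_families: Iterable[str],
    params: MinerParams,
) -> AssociationGraph:
    """For every labeled gene, record the distinct Acr marker families found
    among its same-strand neighbors within the window, aggregated per family
    across all loci."""
    acr_set = frozenset(acr_marker_families)
    graph = AssociationGraph()
    for genome in genomes:
        for gene in genome:
            fams = [f for f in gene_labels.get(gene.gene_id, {}) if f not in acr_set]
            if not fams:
                continue
            ctx = build_context(gene, genome, params.window_genes,
                                params.max_intergenic_bp, gene_labels)
            for nb in ctx.neighbors:
                if not nb.same_strand:
                    continue
                for acr_fam in nb.labels & acr_set:
                    for fam in fams:
                        graph.add(fam, acr_fam, gene.gene_id)
    return graph


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _marker_neighbor(ctx: NeighborhoodContext, marker_families: frozenset):
    """Evidence for criterion (i): any neighbor carrying a marker label, and
    whether some such neighbor is on the same strand.

    Returns (adjacent_any, same_strand_ok, family, side) with the supporting
    neighbor chosen deterministically (same-strand first, then rank, side,
    lexicographic family)."""
    best = None
    adjacent_any = False
    for nb in sorted(ctx.neighbors, key=lambda n: (not n.same_strand, n.rank, n.side)):
        marker_fams = sorted(nb.labels & marker_families)
        if not marker_fams:
            continue
        adjacent_any = True
        if nb.same_strand:
            best = (marker_fams[0], nb.side)
            break
        if best is None:
            best = (marker_fams[0], nb.side)
    if best is None:
        return False, False, None, None
    fam, side = best
    same_ok = adjacent_any and any(
        nb.same_strand and (nb.labels & marker_families) for nb in ctx.neighbors)
    return adjacent_any, same_ok, fam, side


def detect_fusion(
    gene: GeneRecord,
    aca_intervals: Sequence[tuple[int, int]],
    params: MinerParams,
) -> Optional[FusionCall]:
    """Call an Acr–Aca fusion when one Aca-evidence interval lies entirely
    within the terminal ``terminal_fraction`` of the protein (N or C side)
    and the remainder is at least ``min_remainder_aa``."""
    L = gene.protein_length
    limit = int(params.terminal_fraction * L)
    calls = []
    for (s, e) in aca_intervals:
        if not (1 <= s <= e <= L):
            continue
        if e <= limit:  # N-terminal
            remainder = L - e
            if remainder >= params.min_remainder_aa:
                calls.append(FusionCall(gene.gene_id, s, e, "N", remainder))
        if s >= L - limit + 1:  # C-terminal
            remainder = s - 1
            if remainder >= params.min_remainder_aa:
                calls.append(FusionCall(gene.gene_id, s, e, "C", remainder))
    if not calls:
        return None
    # deterministic: largest Acr remainder, then leftmost interval
    calls.sort(key=lambda c: (-c.acr_remainder_length, c.aca_start, c.terminal_side))
    return calls[0]


def classify_aca(
    gene: GeneRecord,
    context: NeighborhoodContext,
    domains: Sequence[DomainAnnotation],
    assoc: AssociationGraph,
    acr_marker_families: frozenset,
    gene_families: Iterable[str],
    params: MinerParams,
) -> Optional[CandidateLocus]:
    """Apply the three Aca criteria; returns a candidate only if all hold."""
    adjacent_any, orientation_ok, fam, side = _marker_neighbor(
        context, acr_marker_families)
    has_domain = any(
        d.is_dna_binding and d.probability >= params.domain_prob_min
        for d in domains)
    own_families = [f for f in gene_families if f not in acr_marker_families]
    association = max(
        (assoc.distinct_acr_families(f) for f in own_families), default=0)
    if adjacent_any and orientation_ok and has_domain \
            and association > params.association_threshold:
        return CandidateLocus(
            gene_id=gene.gene_id,
            replicon_id=gene.replicon_id,
            candidate_class="aca_candidate",
            size_ok=gene.protein_length < params.max_protein_aa,
            adjacent_marker=fam,
            adjacent_side=side,
            orientation_ok=True,
            has_dna_binding_domain=True,
            association_count=association,
        )
    return None


def classify_acr_candidate(
    gene: GeneRecord,
    context: NeighborhoodContext,
    fusion: Optional[FusionCall],
    marker_families: frozenset,
    params: MinerParams,
) -> Optional[CandidateLocus]:
    """Apply the Acr-candidate criteria: strict size cap plus a same-strand
    adjacent Acr or Aca marker; a fusion call upgrades the confidence tier."""
    size_ok = gene.protein_length < params.max_protein_aa
    adjacent_any, orientation_ok, fam, side = _marker_neighbor(
        context, marker_families)
    if size_ok and adjacent_any and orientation_ok:
        return CandidateLocus(
            gene_id=gene.gene_id,
            replicon_id=gene.replicon_id,
            candidate_class="acr_candidate",
            size_ok=True,
            adjacent_marker=fam,
            adjacent_side=side,
            orientation_ok=True,
            has_dna_binding_domain=False,
            association_count=0,
            fusion=fusion,
            confidence_tier="fusion_boosted" if fusion else "standard",
        )
    return None


def audit_gene(
    gene: GeneRecord,
    genome: GenomeAnnotation,
    gene_labels: dict[str, dict],
    domains_by_gene: dict[str, list[DomainAnnotation]],
    assoc: AssociationGraph,
    markers: MarkerSet,
    params: MinerParams,
) -> dict:
    """Full per-criterion evidence for one gene, regardless of outcome.

    Used for audit listings (with the wider enumeration window) and for the
    decoy post-mortem: which criterion failed."""
    ctx = build_context(gene, genome, params.window_genes,
                        params.max_intergenic_bp, gene_labels)
    acr_fams = markers.acr_families
    all_fams = markers.families
    adj_acr, orient_acr, *_ = _marker_neighbor(ctx, acr_fams)
    adj_any, orient_any, *_ = _marker_neighbor(ctx, frozenset(all_fams))
    doms = domains_by_gene.get(gene.gene_id, [])
    own = [f for f in gene_labels.get(gene.gene_id, {}) if f not in acr_fams]
    return {
        "gene_id": gene.gene_id,
        "protein_length": gene.protein_length,
        "size_ok": gene.protein_length < params.max_protein_aa,
        "adjacent_acr_marker": adj_acr,
        "orientation_ok_acr": orient_acr,
        "adjacent_any_marker": adj_any,
        "orientation_ok_any": orient_any,
        "has_dna_binding_domain": any(
            d.is_dna_binding and d.probability >= params.domain_prob_min
            for d in doms),
        "association_count": max(
            (assoc.distinct_acr_families(f) for f in own), default=0),
    }


def audit_all(
    genomes: Sequence[GenomeAnnotation],
    hits: Sequence[HomologyHit],
    domains: Sequence[DomainAnnotation],
    markers: "MarkerSet",
    params: Optional[MinerParams] = None,
) -> dict[str, dict]:
    """Per-criterion evidence for every gene (audit mode)."""
    params = params or MinerParams()
    gene_labels = map_hits_to_genes(hits, genomes, params.evalue_max,
                                    params.coverage_min)
    domains_by_gene: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        domains_by_gene.setdefault(d.gene_id, []).append(d)
    assoc = build_association_graph(genomes, gene_labels,
                                    markers.acr_families, params)
    out = {}
    for genome in genomes:
        for gene in genome:
            out[gene.gene_id] = audit_gene(
                gene, genome, gene_labels, domains_by_gene, assoc, markers,
                params)
    return out


# ---------------------------------------------------------------------------
# One-shot mining pass
# ---------------------------------------------------------------------------

def _aca_intervals_for(gene_id: str, labels: dict[str, dict],
                       aca_families: frozenset,
                       domains_by_gene: dict) -> list[tuple[int, int]]:
    intervals = [
        (h.subject_start, h.subject_end)
        for fam in sorted(labels.get(gene_id, {}))
        if fam in aca_families
        for h in labels[gene_id][fam]
    ]
    intervals += [
        (d.region_start, d.region_end)
        for d in domains_by_gene.get(gene_id, [])
        if d.is_dna_binding
    ]
    return intervals


def mine_candidates(
    genomes: Sequence[GenomeAnnotation],
    hits: Sequence[HomologyHit],
    domains: Sequence[DomainAnnotation],
    markers: MarkerSet,
    params: Optional[MinerParams] = None,
) -> tuple[list[CandidateLocus], dict]:
    """Single classification pass against a fixed marker set.

    Labels genes from passing hits, builds the corpus-wide association graph,
    then applies the Aca criteria followed by the Acr-candidate criteria to
    every gene. A gene may be reported under both classes (a small
    DNA-binding gene adjacent to an Acr satisfies both criteria lists; the
    original screen likewise forwarded such neighbors to validation).
    """
    params = params or MinerParams()
    gene_labels = map_hits_to_genes(hits, genomes, params.evalue_max,
                                    params.coverage_min)
    domains_by_gene: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        domains_by_gene.setdefault(d.gene_id, []).append(d)

    acr_fams = markers.acr_families
    aca_fams = markers.aca_families
    assoc = build_association_graph(genomes, gene_labels, acr_fams, params)

    candidates: list[CandidateLocus] = []
    for genome in genomes:
        for gene in genome:
            ctx = build_context(gene, genome, params.window_genes,
                                params.max_intergenic_bp, gene_labels)
            aca_cand = classify_aca(
                gene, ctx, domains_by_gene.get(gene.gene_id, []), assoc,
                acr_fams, gene_labels.get(gene.gene_id, {}), params)
            if aca_cand is not None:
                candidates.append(aca_cand)
            fusion = detect_fusion(
                gene,
                _aca_intervals_for(gene.gene_id, gene_labels, aca_fams,
                                   domains_by_gene),
                params)
            acr_cand = classify_acr_candidate(
                gene, ctx, fusion, frozenset(acr_fams | aca_fams), params)
            if acr_cand is not None:
                candidates.append(acr_cand)

    audit = {
        "n_genes": sum(len(g) for g in genomes),
        "n_labeled_genes": len(gene_labels),
        "n_candidates": len(candidates),
        "association_graph": assoc.to_dict(),
        "params": params.to_dict(),
    }
    return candidates, audit


# ---------------------------------------------------------------------------
# Search–validation loop
# ---------------------------------------------------------------------------

Validator = Callable[[Sequence[CandidateLocus]], Sequence[CandidateLocus]]


def accept_all_validator(candidates: Sequence[CandidateLocus]):
    return list(candidates)


def reject_all_validator(candidates: Sequence[CandidateLocus]):
    return []


def truth_ledger_validator(ledger) -> Validator:
    """Validator standing in for the wet-lab screen: accept a candidate iff
    the ground-truth ledger marks its gene as a planted acr, aca or fusion."""
    def _validate(candidates):
        keep = []
        for c in candidates:
            entry = ledger.get(c.gene_id)
            if entry is not None and entry.true_class in ("acr", "aca", "fusion"):
                keep.append(c)
        return keep
    return _validate


def list_validator(accepted_gene_ids: Iterable[str]) -> Validator:
    ids = set(accepted_gene_ids)
    def _validate(candidates):
        return [c for c in candidates if c.gene_id in ids]
    return _validate


def search_validation_loop(
    seed_markers: MarkerSet,
    genomes: Sequence[GenomeAnnotation],
    hits: Sequence[HomologyHit],
    domains: Sequence[DomainAnnotation],
    validator: Validator,
    params: Optional[MinerParams] = None,
) -> tuple[MarkerSet, list[CandidateLocus], list[dict]]:
    """Iterative marker expansion.

    Each round classifies every gene against the marker set as of the start
    of the round (so adoptions take effect in the next round), passes new
    candidates to the validator, and adopts the accepted candidates' hit
    families as new markers — aca families from aca candidates, acr families
    from acr candidates (an accepted fusion contributes its terminal-matching
    family as aca and the remainder family as acr). Stops at a fixed point
    (no new family) or after ``max_iterations``.
    """
    if len(seed_markers) == 0:
        raise ValueError("seed_markers must be nonempty")
    params = params or MinerParams()
    markers = seed_markers.copy()
    all_labels = map_hits_to_genes(hits, genomes, params.evalue_max,
                                   params.coverage_min)
    ledger: list[CandidateLocus] = []
    seen_candidates: set[tuple[str, str]] = set()
    audit: list[dict] = []

    for iteration in range(1, params.max_iterations + 1):
        marker_labels = {
            gid: {f: hs for f, hs in fams.items() if f in markers.families}
            for gid, fams in all_labels.items()
        }
        marker_labels = {g: f for g, f in marker_labels.items() if f}
        domains_by_gene: dict[str, list[DomainAnnotation]] = {}
        for d in domains:
            domains_by_gene.setdefault(d.gene_id, []).append(d)
        acr_fams = markers.acr_families
        aca_fams = markers.aca_families
        assoc = build_association_graph(genomes, all_labels, acr_fams, params)

        new_candidates: list[CandidateLocus] = []
        for genome in genomes:
            for gene in genome:
                ctx = build_context(gene, genome, params.window_genes,
                                    params.max_intergenic_bp, marker_labels)
                own_fams = all_labels.get(gene.gene_id, {})
                aca_cand = classify_aca(
                    gene, ctx, domains_by_gene.get(gene.gene_id, []), assoc,
                    acr_fams, own_fams, params)
                if aca_cand and (gene.gene_id, "aca_candidate") not in seen_candidates:
                    new_candidates.append(aca_cand)
                fusion = detect_fusion(
                    gene,
                    _aca_intervals_for(gene.gene_id, all_labels, aca_fams,
                                       domains_by_gene),
                    params)
                acr_cand = classify_acr_candidate(
                    gene, ctx, fusion, frozenset(acr_fams | aca_fams), params)
                if acr_cand and (gene.gene_id, "acr_candidate") not in seen_candidates:
                    new_candidates.append(acr_cand)

        accepted = list(validator(new_candidates))
        adopted: list[tuple[str, str]] = []
        # aca adoptions first so a family proposed under both labels lands as aca
        for cand in sorted(accepted, key=lambda c: (c.candidate_class != "aca_candidate",
                                                    c.gene_id)):
            fams = sorted(all_labels.get(cand.gene_id, {}))
            for fam in fams:
                if fam in markers.families:
                    continue
                if cand.candidate_class == "aca_candidate":
                    label = ACA
                elif cand.fusion is not None and _family_in_terminal(
                        all_labels[cand.gene_id][fam], cand.fusion):
                    label = ACA
                else:
                    label = ACR
                if markers.add(fam, label, iteration):
                    adopted.append((fam, label))
        for c in new_candidates:
            seen_candidates.add((c.gene_id, c.candidate_class))
        ledger.extend(new_candidates)
        audit.append({
            "iteration": iteration,
            "n_new_candidates": len(new_candidates),
            "n_accepted": len(accepted),
            "adopted_families": [{"family": f, "label": l} for f, l in adopted],
            "marker_count": len(markers),
        })
        logger.info("iteration %d: %d new candidates, %d accepted, %d adopted",
                    iteration, len(new_candidates), len(accepted), len(adopted))
        if not adopted:
            break
    else:
        logger.warning(
            "search-validation loop hit max_iterations=%d without a fixed "
            "point; markers=%s", params.max_iterations, markers.to_dict())

    return markers, ledger, audit


def _family_in_terminal(hits: Sequence[HomologyHit], fusion: FusionCall) -> bool:
    """True if all of the family's hit intervals fall inside the fusion's
    Aca-matching terminal interval."""
    return all(
        fusion.aca_start <= h.subject_start and h.subject_end <= fusion.aca_end
        for h in hits)
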