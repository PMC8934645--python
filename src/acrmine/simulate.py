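"""Synthetic Streptococcus-like replicons with planted acr–aca operons.

Generates every input the mining pipeline consumes — annotated replicons,
protein sequences, homology-hit tables, domain tables, assay count tables —
with a ground-truth ledger recording what was planted where. Planted elements:

* acr–aca operons: same-strand adjacent gene pairs (small Acr gene + small
  DNA-binding Aca gene), with aca families reused across operons so that each
  associates with at least three distinct Acr families corpus-wide;
* Acr–Aca fusion ORFs whose Aca-matching evidence is confined to one terminal
  portion of the protein;
* decoy genes, each violating exactly one classifier criterion while
  satisfying the others (oversize, wrong strand, non-adjacent, Aca without a
  DNA-binding domain, Aca with too few distinct Acr partners);
* background genes.

Sequence residues are iid uniform amino acids: homology evidence lives in the
generated hit/domain tables, not in the residues (the family simulator
:func:`simulate_family` is the sequence-level tool for phylogenetics).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, GeneRecord, GenomeAnnotation, HomologyHit, DomainAnnotation

DECOY_CLASSES = ("oversize", "wrong_strand", "non_adjacent",
                 "no_domain_aca", "low_association_aca")


class ConfigurationError(ValueError):
    """The simulation configuration cannot host the planted elements."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    The defaults define the standard test corpus: 20 linear replicons, 12
    planted acr–aca operons drawn from 9 Acr and 3 Aca families (so every Aca
    family pairs with ≥3 distinct Acr families), 2 fusion ORFs, and one decoy
    cohort per violated criterion.
    """

    seed: int = 0
    n_replicons: int = 20
    genes_per_replicon: tuple[int, int] = (12, 20)
    n_planted_operons: int = 12
    acr_length_range: tuple[int, int] = (50, 250)
    aca_length_range: tuple[int, int] = (60, 120)
    decoy_spec: dict = field(default_factory=lambda: {
        "oversize": 2,
        "wrong_strand": 2,
        "non_adjacent": 2,
        "no_domain_aca": 3,
        "low_association_aca": 2,
    })
    n_fusions: int = 2
    fusion_terminal_side: str = "random"  # N | C | random
    acr_families: tuple = tuple(f"acrF{i:02d}" for i in range(1, 10))
    aca_families: tuple = ("acaF01", "acaF02", "acaF03")
    intergenic_range: tuple[int, int] = (20, 200)
    background_length_range: tuple[int, int] = (80, 400)

    def __post_init__(self) -> None:
        if self.acr_length_range[1] >= 300:
            raise ConfigurationError("acr_length_range upper bound must be < 300")
        if self.fusion_terminal_side not in ("N", "C", "random"):
            raise ConfigurationError("fusion_terminal_side must be N, C or random")
        unknown = set(self.decoy_spec) - set(DECOY_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown decoy classes {sorted(unknown)}")
        nd = self.decoy_spec.get("no_domain_aca", 0)
        if 0 < nd < 3:
            raise ConfigurationError(
                "no_domain_aca decoys need >= 3 loci (their family must reach "
                "association > 2 so that only the domain criterion fails)")
        if nd > max(0, len(self.acr_families) - 2):
            raise ConfigurationError(
                "no_domain_aca decoys need distinct Acr-family anchors; "
                f"at most {len(self.acr_families) - 2} supported")
        n_aca_side = nd + self.decoy_spec.get("low_association_aca", 0)
        n_acr_side = (self.decoy_spec.get("oversize", 0)
                      + self.decoy_spec.get("wrong_strand", 0))
        if max(n_aca_side, n_acr_side) > self.n_planted_operons:
            raise ConfigurationError(
                "not enough planted operons to anchor the requested decoys")
        if self.decoy_spec.get("low_association_aca", 0) > 2:
            raise ConfigurationError(
                "low_association_aca decoys are anchored to two fixed Acr "
                "families; at most 2 supported")
        if self.n_planted_operons > 0 and len(self.acr_families) < 3:
            raise ConfigurationError("need >= 3 acr families for association counts")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["acr_families"] = list(self.acr_families)
        d["aca_families"] = list(self.aca_families)
        return d


@dataclass
class TruthEntry:
    gene_id: str
    true_class: str  # acr | aca | fusion | decoy:<criterion> | background
    family: Optional[str]
    replicon_id: str
    start: int
    end: int
    strand: str
    protein_length: int
    acr_family: Optional[str] = None      # fusion only
    aca_family: Optional[str] = None      # fusion only
    aca_interval: Optional[tuple[int, int]] = None  # fusion only
    terminal_side: Optional[str] = None   # fusion only


class TruthLedger:
    """One entry per generated gene; decoys name the criterion they violate."""

    def __init__(self, entries: Sequence[TruthEntry] = ()) -> None:
        self.entries: list[TruthEntry] = list(entries)
        self._by_id = {e.gene_id: e for e in self.entries}

    def add(self, entry: TruthEntry) -> None:
        if entry.gene_id in self._by_id:
            raise ValueError(f"duplicate ledger entry {entry.gene_id}")
        self.entries.append(entry)
        self._by_id[entry.gene_id] = entry

    def get(self, gene_id: str) -> Optional[TruthEntry]:
        return self._by_id.get(gene_id)

    def by_class(self, true_class: str) -> list[TruthEntry]:
        return [e for e in self.entries if e.true_class == true_class]

    def decoys(self) -> list[TruthEntry]:
        return [e for e in self.entries if e.true_class.startswith("decoy:")]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump([dataclasses.asdict(e) for e in self.entries], fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "TruthLedger":
        with open(path) as fh:
            raw = json.load(fh)
        entries = []
        for r in raw:
            if r.get("aca_interval") is not None:
                r["aca_interval"] = tuple(r["aca_interval"])
            entries.append(TruthEntry(**r))
        return cls(entries)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@dataclass
class _GeneSpec:
    true_class: str
    family: Optional[str]
    length_aa: int
    strand_relative: int = +1  # relative to block strand; -1 for wrong-strand decoys
    acr_family: Optional[str] = None
    aca_family: Optional[str] = None
    aca_interval: Optional[tuple[int, int]] = None
    terminal_side: Optional[str] = None


def _make_fusion_spec(cfg: SimConfig, rng: np.random.Generator,
                      acr_family: str, aca_family: str) -> _GeneSpec:
    length = int(rng.integers(170, 251))
    side = cfg.fusion_terminal_side
    if side == "random":
        side = "N" if rng.random() < 0.5 else "C"
    # Aca segment inside the terminal 40%, remainder >= 40 aa by construction
    seg = int(0.30 * length)
    if side == "N":
        interval = (3, 3 + seg - 1)
    else:
        interval = (length - seg - 1, length - 2)
    return _GeneSpec(
        true_class="fusion", family=f"{acr_family}+{aca_family}",
        length_aa=length, acr_family=acr_family, aca_family=aca_family,
        aca_interval=interval, terminal_side=side)


def _plan_blocks(cfg: SimConfig, rng: np.random.Generator) -> list[list[_GeneSpec]]:
    """Assemble planted gene blocks (contiguous same-strand cassettes)."""
    n_acr = len(cfg.acr_families)
    n_aca = len(cfg.aca_families)
    blocks: list[list[_GeneSpec]] = []

    operons: list[list[_GeneSpec]] = []
    for i in range(cfg.n_planted_operons):
        acr_fam = cfg.acr_families[i % n_acr]
        aca_fam = cfg.aca_families[i % n_aca]
        acr = _GeneSpec("acr", acr_fam,
                        int(rng.integers(cfg.acr_length_range[0],
                                         cfg.acr_length_range[1] + 1)))
        aca = _GeneSpec("aca", aca_fam,
                        int(rng.integers(cfg.aca_length_range[0],
                                         cfg.aca_length_range[1] + 1)))
        operons.append([acr, aca])  # acr end is index 0

    # aca-type decoys attach on the acr end (criterion i needs an Acr neighbor);
    # they are oversized so the Acr size criterion keeps them out of that class.
    spec = cfg.decoy_spec
    low_fams = (3 % n_acr, 4 % n_acr)
    low_anchor_operons = [k for k in range(cfg.n_planted_operons)
                          if k % n_acr in low_fams]
    nd_anchor_operons = [k for k in range(cfg.n_planted_operons)
                         if k not in low_anchor_operons]
    for j in range(spec.get("no_domain_aca", 0)):
        decoy = _GeneSpec(
            "decoy:no_domain", "acaND01", int(rng.integers(300, 401)))
        operons[nd_anchor_operons[j % len(nd_anchor_operons)]].insert(0, decoy)
    for j in range(spec.get("low_association_aca", 0)):
        k = low_anchor_operons[j % len(low_anchor_operons)]
        decoy = _GeneSpec(
            "decoy:low_association", "acaLOW01", int(rng.integers(300, 401)))
        operons[k].insert(0, decoy)

    # acr-type decoys attach on the aca end (any Acr/Aca marker neighbor works)
    aca_end_slot = 0
    for j in range(spec.get("oversize", 0)):
        operons[aca_end_slot].append(
            _GeneSpec("decoy:size", None, int(rng.integers(300, 401))))
        aca_end_slot += 1
    for j in range(spec.get("wrong_strand", 0)):
        operons[aca_end_slot].append(_GeneSpec(
            "decoy:strand", None,
            int(rng.integers(cfg.acr_length_range[0], cfg.acr_length_range[1] + 1)),
            strand_relative=-1))
        aca_end_slot += 1

    blocks.extend(operons)

    for j in range(cfg.n_fusions):
        helper_fam = cfg.acr_families[j % n_acr]
        fusion_acr_fam = cfg.acr_families[(j + 5) % n_acr]
        fusion_aca_fam = cfg.aca_families[j % n_aca]
        helper = _GeneSpec("acr", helper_fam,
                           int(rng.integers(cfg.acr_length_range[0],
                                            cfg.acr_length_range[1] + 1)))
        fusion = _make_fusion_spec(cfg, rng, fusion_acr_fam, fusion_aca_fam)
        blocks.append([helper, fusion])

    for j in range(spec.get("non_adjacent", 0)):
        blocks.append([_GeneSpec(
            "decoy:adjacency", None,
            int(rng.integers(cfg.acr_length_range[0], cfg.acr_length_range[1] + 1)))])

    return blocks


def generate_genomes(
    config: SimConfig,
) -> tuple[list[GenomeAnnotation], dict[str, str], TruthLedger]:
    """Generate annotated replicons, protein sequences and the truth ledger.

    All randomness derives from ``config.seed``; identical configs yield
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    blocks = _plan_blocks(config, rng)

    # Non-adjacent decoy blocks go to replicons without markers when possible.
    marker_blocks: list[list[_GeneSpec]] = []
    lone_blocks: list[list[_GeneSpec]] = []
    for b in blocks:
        if len(b) == 1 and b[0].true_class == "decoy:adjacency":
            lone_blocks.append(b)
        else:
            marker_blocks.append(b)
    per_replicon: list[list[list[_GeneSpec]]] = [[] for _ in range(config.n_replicons)]
    for i, b in enumerate(marker_blocks):
        per_replicon[i % config.n_replicons].append(b)
    free = [r for r in range(config.n_replicons) if not per_replicon[r]]
    for i, b in enumerate(lone_blocks):
        target = free[i % len(free)] if free else (len(marker_blocks) + i) % config.n_replicons
        per_replicon[target].append(b)

    genomes: list[GenomeAnnotation] = []
    proteins: dict[str, str] = {}
    ledger = TruthLedger()
    lo_n, hi_n = config.genes_per_replicon
    buffer = 2  # background genes isolating blocks from one another

    for r in range(config.n_replicons):
        rid = f"replicon{r:02d}"
        rep_blocks = per_replicon[r]
        n_planted = sum(len(b) for b in rep_blocks)
        required = n_planted + buffer * (len(rep_blocks) + 1)
        n_genes = int(rng.integers(lo_n, hi_n + 1))
        if n_genes < required:
            if hi_n < required:
                raise ConfigurationError(
                    f"genes_per_replicon={config.genes_per_replicon} too small "
                    f"to host {n_planted} planted genes in {rid} "
                    f"(need >= {required})")
            n_genes = required

        # slot plan: buffer bg, block, buffer bg, block, ..., remaining bg
        slots: list[tuple[Optional[_GeneSpec], Optional[int]]] = []
        n_background = n_genes - n_planted
        bg_left = n_background
        for b in rep_blocks:
            take = buffer if bg_left >= buffer else bg_left
            for _ in range(take):
                slots.append((None, None))
                bg_left -= 1
            block_strand = "+" if rng.random() < 0.5 else "-"
            for s in b:
                slots.append((s, +1 if block_strand == "+" else -1))
        for _ in range(bg_left):
            slots.append((None, None))

        genes: list[GeneRecord] = []
        pos = int(rng.integers(*config.intergenic_range))
        for gi, (spec, block_dir) in enumerate(slots):
            gene_id = f"{rid}_g{gi:03d}"
            if spec is None:
                length_aa = int(rng.integers(config.background_length_range[0],
                                             config.background_length_range[1] + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                true_class, family = "background", None
                extra = {}
            else:
                length_aa = spec.length_aa
                direction = block_dir * spec.strand_relative
                strand = "+" if direction > 0 else "-"
                true_class, family = spec.true_class, spec.family
                extra = dict(acr_family=spec.acr_family,
                             aca_family=spec.aca_family,
                             aca_interval=spec.aca_interval,
                             terminal_side=spec.terminal_side)
            start = pos + 1
            end = start + 3 * (length_aa + 1) - 1
            pos = end + int(rng.integers(*config.intergenic_range))
            seq = _random_protein(rng, length_aa)
            genes.append(GeneRecord(
                replicon_id=rid, gene_id=gene_id, start=start, end=end,
                strand=strand, protein_length=length_aa,
                product=true_class if true_class != "background"
                else "hypothetical protein",
                protein_seq=seq))
            proteins[gene_id] = seq
            ledger.add(TruthEntry(
                gene_id=gene_id, true_class=true_class, family=family,
                replicon_id=rid, start=start, end=end, strand=strand,
                protein_length=length_aa, **extra))
        genomes.append(GenomeAnnotation(rid, genes, source_label="synthetic MGE",
                                        length_bp=pos + 50))

    return genomes, proteins, ledger


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------

@dataclass
class HitNoiseParams:
    """Sampling parameters of the emulated homology-search table.

    Planted hits draw E-values log-uniform in [1e-50, 1e-5] (safely inside the
    0.001 cutoff); spurious hits in [1e-3, 10] (straddling/above it, so they
    never pass the strict filter)."""

    spurious_rate: float = 0.1
    coverage_range: tuple[float, float] = (0.75, 1.0)
    identity_range: tuple[float, float] = (40.0, 95.0)
    evalue_range: tuple[float, float] = (1e-50, 1e-5)
    spurious_evalue_range: tuple[float, float] = (1e-3, 10.0)

    @classmethod
    def zero_noise(cls) -> "HitNoiseParams":
        return cls(spurious_rate=0.0, coverage_range=(1.0, 1.0),
                   identity_range=(90.0, 90.0), evalue_range=(1e-30, 1e-30))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_hit_table(
    truth: TruthLedger,
    noise: Optional[HitNoiseParams] = None,
    seed: Optional[int] = None,
) -> list[HomologyHit]:
    """Emulated homology evidence: every planted family member receives a hit
    to its family marker; fusion ORFs receive one Acr-family hit on the
    non-terminal segment and one Aca-family hit confined to the planted
    terminal portion; background genes receive spurious hits at
    ``noise.spurious_rate``."""
    if len(truth) == 0:
        raise ValueError("truth ledger is empty")
    noise = noise or HitNoiseParams()
    rng = np.random.default_rng(seed)
    families = sorted({e.family for e in truth if e.family and "+" not in e.family})
    hits: list[HomologyHit] = []

    def planted_hit(family: str, gene_id: str, L: int,
                    interval: Optional[tuple[int, int]] = None,
                    coverage: Optional[float] = None) -> HomologyHit:
        cov = coverage if coverage is not None else float(
            rng.uniform(*noise.coverage_range))
        if interval is None:
            span = max(1, round(cov * L))
            interval = (1, min(L, span))
        return HomologyHit(
            query_family=family, subject_gene_id=gene_id,
            percent_identity=float(rng.uniform(*noise.identity_range)),
            evalue=_log_uniform(rng, *noise.evalue_range),
            query_coverage=cov,
            subject_start=interval[0], subject_end=interval[1])

    for e in truth:
        L = e.protein_length
        if e.true_class == "fusion":
            s, t = e.aca_interval
            if e.terminal_side == "N":
                acr_iv = (t + 1, L)
            else:
                acr_iv = (1, s - 1)
            hits.append(planted_hit(e.acr_family, e.gene_id, L, interval=acr_iv))
            hits.append(planted_hit(e.aca_family, e.gene_id, L, interval=(s, t)))
        elif e.family is not None:
            hits.append(planted_hit(e.family, e.gene_id, L))
        elif e.true_class == "background" and noise.spurious_rate > 0 \
                and rng.random() < noise.spurious_rate and families:
            fam = families[int(rng.integers(len(families)))]
            s = int(rng.integers(1, max(2, L // 2)))
            t = int(rng.integers(s, L + 1))
            hits.append(HomologyHit(
                query_family=fam, subject_gene_id=e.gene_id,
                percent_identity=float(rng.uniform(20.0, 40.0)),
                evalue=_log_uniform(rng, *noise.spurious_evalue_range),
                query_coverage=float(rng.uniform(0.2, 1.0)),
                subject_start=s, subject_end=t))
    return hits


def generate_domain_table(
    truth: TruthLedger,
    false_positive_rate: float = 0.0,
    seed: Optional[int] = None,
) -> list[DomainAnnotation]:
    """Emulated DNA-binding-domain calls: every planted aca (and
    low-association decoy, and fusion ORF — inside its Aca segment) gets an
    HTH or AP2 record; no-domain decoys get none; other genes get a record at
    ``false_positive_rate``."""
    rng = np.random.default_rng(seed)
    out: list[DomainAnnotation] = []
    for e in truth:
        L = e.protein_length
        if e.true_class in ("aca", "decoy:low_association"):
            label = "HTH" if rng.random() < 0.8 else "AP2"
            end = min(L, 5 + 50)
            out.append(DomainAnnotation(e.gene_id, label,
                                        float(rng.uniform(0.9, 1.0)), 5, end))
        elif e.true_class == "fusion":
            s, t = e.aca_interval
            out.append(DomainAnnotation(e.gene_id, "HTH",
                                        float(rng.uniform(0.9, 1.0)), s, t))
        elif false_positive_rate > 0 and rng.random() < false_positive_rate:
            label = "HTH" if rng.random() < 0.5 else "other"
            out.append(DomainAnnotation(e.gene_id, label,
                                        float(rng.uniform(0.5, 1.0)),
                                        1, min(L, 60)))
    return out


# ---------------------------------------------------------------------------
# Sequence-level family simulator (for phylogenetics)
# ---------------------------------------------------------------------------

def simulate_family(
    tree,
    root_protein: str,
    rate: float = 1.0,
    seed: Optional[int] = None,
) -> dict[str, str]:
    """Evolve a root protein down a tree under a Poisson, uniform-replacement
    model: along a branch of length t, each site receives Poisson(rate*t)
    substitution events, each replacing the residue with one of the other 19
    amino acids uniformly. Returns ``{leaf label: sequence}``."""
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    idx = {c: i for i, c in enumerate(AMINO_ACIDS)}

    def mutate(seq_arr: np.ndarray, t: float) -> np.ndarray:
        out = seq_arr.copy()
        if t <= 0:
            return out
        n_events = rng.poisson(rate * t, size=out.size)
        for site in np.nonzero(n_events)[0]:
            cur = out[site]
            for _ in range(n_events[site]):
                step = int(rng.integers(19))
                cur = (cur + 1 + step) % 20
            out[site] = cur
        return out

    root_arr = np.array([idx[c] for c in root_protein], dtype=np.int64)
    leaves: dict[str, str] = {}

    def walk(node, seq_arr):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_arr = mutate(seq_arr, float(t))
            if child.is_leaf():
                label = child.taxon.label if child.taxon else str(child)
                leaves[label] = "".join(AMINO_ACIDS[i] for i in child_arr)
            else:
                walk(child, child_arr)

    seed_node = tree.seed_node
    if seed_node.is_leaf() and seed_node.taxon:
        leaves[seed_node.taxon.label] = root_protein
    walk(seed_node, root_arr)
    return leaves


def expected_identity(path_length: float, rate: float = 1.0) -> float:
    """Closed-form expected per-site identity between two sequences separated
    by total path length ``path_length`` under the Poisson uniform-replacement
    model (20 states, jumps to one of the other 19 uniformly)."""
    lam = rate * path_length
    return 1.0 / 20.0 + (19.0 / 20.0) * float(np.exp(-(20.0 / 19.0) * lam))


# ---------------------------------------------------------------------------
# Assay readouts
# ---------------------------------------------------------------------------

def simulate_assay_counts(
    true_activity: float,
    n_replicates: int = 3,
    mean_cfu: float = 200.0,
    seed: Optional[int] = None,
    acr_label: str = "Acr",
    cas9_label: str = "Cas9",
    assay: str = "bacterial",
) -> pd.DataFrame:
    """Poisson-count colony readouts of a plasmid-interference assay with
    known inhibitory activity: mismatching-spacer cfu ~ Poisson(mean_cfu),
    matching-spacer cfu ~ Poisson(mean_cfu * true_activity / 100)."""
    if not (0.0 <= true_activity <= 100.0):
        raise ValueError("true_activity must be in [0, 100]")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append({
            "acr_label": acr_label,
            "cas9_label": cas9_label,
            "assay": assay,
            "replicate_id": rep,
            "cfu_matching": int(rng.poisson(mean_cfu * true_activity / 100.0)),
            "cfu_mismatching": int(rng.poisson(mean_cfu)),
        })
    return pd.DataFrame(rows)
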