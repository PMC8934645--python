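import pytest

from acrmine import (
    MarkerSet,
    SimConfig,
    generate_domain_table,
    generate_genomes,
    generate_hit_table,
)


@pytest.fixture(scope="session")
def default_corpus():
    """The standard synthetic corpus: 20 replicons, 12 operons, fusions and
    one decoy cohort per violated criterion."""
    cfg = SimConfig(seed=11)
    genomes, proteins, ledger = generate_genomes(cfg)
    hits = generate_hit_table(ledger, seed=cfg.seed + 1)
    domains = generate_domain_table(ledger, seed=cfg.seed + 2)
    markers = MarkerSet.from_families(acr=cfg.acr_families, aca=cfg.aca_families)
    return cfg, genomes, proteins, ledger, hits, domains, markers


def small_corpus(seed):
    """A small randomized corpus (<= 50 genes) with noise, for oracle
    cross-checks."""
    cfg = SimConfig(
        seed=seed,
        n_replicons=3,
        genes_per_replicon=(10, 16),
        n_planted_operons=5,
        decoy_spec={
            "oversize": seed % 2,
            "wrong_strand": (seed + 1) % 2,
            "non_adjacent": int(seed % 3 == 0),
            "no_domain_aca": 3 if seed % 3 == 1 else 0,
            "low_association_aca": seed % 2,
        },
        n_fusions=seed % 2,
    )
    genomes, proteins, ledger = generate_genomes(cfg)
    from acrmine import HitNoiseParams

    hits = generate_hit_table(
        ledger, noise=HitNoiseParams(spurious_rate=0.3), seed=seed + 1)
    domains = generate_domain_table(ledger, false_positive_rate=0.15,
                                    seed=seed + 2)
    markers = MarkerSet.from_families(acr=cfg.acr_families,
                                      aca=cfg.aca_families)
    return cfg, genomes, ledger, hits, domains, markers


@pytest.fixture
def chain_fixture():
    """Hand-built 2-hop discovery chain: three seed Acr families anchor one
    Aca family at three loci; a fourth Acr family sits next to one Aca gene
    and is only reachable once the Aca family has been adopted."""
    from acrmine import DomainAnnotation, HomologyHit
    from acrmine.records import GeneRecord, GenomeAnnotation

    def gene(rid, gid, i, strand="+", aa=100):
        s = 1000 * i + 1
        return GeneRecord(rid, gid, s, s + 3 * (aa + 1) - 1, strand, aa)

    def hit(fam, gid):
        return HomologyHit(fam, gid, 80.0, 1e-20, 0.95, 1, 90)

    genomes = [
        GenomeAnnotation("r1", [gene("r1", "r1_a1", 0), gene("r1", "r1_b1", 1)]),
        GenomeAnnotation("r2", [gene("r2", "r2_a2", 0), gene("r2", "r2_b2", 1)]),
        GenomeAnnotation("r3", [gene("r3", "r3_a3", 0), gene("r3", "r3_b3", 1),
                                gene("r3", "r3_a4", 2)]),
    ]
    hits = [
        hit("A1", "r1_a1"), hit("B", "r1_b1"),
        hit("A2", "r2_a2"), hit("B", "r2_b2"),
        hit("A3", "r3_a3"), hit("B", "r3_b3"), hit("A4", "r3_a4"),
    ]
    domains = [DomainAnnotation(g, "HTH", 0.97, 5, 55)
               for g in ("r1_b1", "r2_b2", "r3_b3")]
    seeds = MarkerSet.from_families(acr=["A1", "A2", "A3"])
    return genomes, hits, domains, seeds
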