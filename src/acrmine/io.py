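"""Readers and writers for the standard formats the pipeline consumes.

GenBank and GFF3+FASTA for annotated replicons, FASTA for proteins, TSV for
homology-hit / domain / assay tables, TSV+JSON for candidate reports and
Newick for trees. All genomic coordinates are 1-based inclusive in memory;
conversions to biopython's 0-based half-open convention happen only here.
"""
from __future__ import annotations

import json
import logging
import os
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, Field

from .records import (
    AnnotationError,
    DomainAnnotation,
    GeneRecord,
    GenomeAnnotation,
    HomologyHit,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path: str) -> list[GenomeAnnotation]:
    """Parse GenBank file(s) into one :class:`GenomeAnnotation` per record.

    One :class:`GeneRecord` is produced per CDS feature; the ``translation``
    qualifier is captured when present.
    """
    genomes = []
    for rec in SeqIO.parse(path, "genbank"):
        genes = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            try:
                quals = feat.qualifiers
                gene_id = quals.get("locus_tag", quals.get("protein_id", [None]))[0]
                if gene_id is None:
                    raise AnnotationError("CDS without locus_tag/protein_id")
                translation = quals.get("translation", [None])[0]
                start = int(feat.location.start) + 1
                end = int(feat.location.end)
                strand = "+" if feat.location.strand >= 0 else "-"
                if translation:
                    plen = len(translation)
                else:
                    plen = max(1, (end - start + 1) // 3 - 1)
                genes.append(GeneRecord(
                    replicon_id=rec.id,
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein_length=plen,
                    product=quals.get("product", [""])[0],
                    protein_seq=translation,
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise AnnotationError(
                    f"malformed CDS in record {rec.id!r}: {exc}") from exc
        genomes.append(GenomeAnnotation(
            replicon_id=rec.id,
            genes=genes,
            source_label=rec.annotations.get("source", ""),
            length_bp=len(rec.seq) or None,
        ))
    return genomes


def write_genbank(genomes: Iterable[GenomeAnnotation], path: str) -> None:
    """Write annotations as GenBank; the nucleotide sequence is emitted as N
    runs (the pipeline is protein-level and carries no nucleotide residues)."""
    records = []
    for genome in genomes:
        length = genome.length_bp or (genome.genes[-1].end if genome.genes else 1)
        rec = SeqRecord(
            Seq("N" * length),
            id=genome.replicon_id,
            name=genome.replicon_id[:16],
            description=genome.source_label or "synthetic replicon",
            annotations={"molecule_type": "DNA", "source": genome.source_label},
        )
        for g in genome:
            quals = {
                "locus_tag": [g.gene_id],
                "product": [g.product or "hypothetical protein"],
            }
            if g.protein_seq:
                quals["translation"] = [g.protein_seq]
            rec.features.append(SeqFeature(
                FeatureLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            ))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------

def read_gff_fasta(gff_path: str, fasta_path: str) -> list[GenomeAnnotation]:
    """Read CDS features from GFF3 plus matching protein FASTA.

    Feature ``ID`` attributes must match FASTA headers; unmatched ids on
    either side raise an error listing the orphans.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique")
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}

    by_replicon: dict[str, list[GeneRecord]] = {}
    region_lengths: dict[str, int] = {}
    seen_ids = set()
    for feat in db.all_features():
        if feat.featuretype == "region":
            region_lengths[feat.seqid] = feat.end
        if feat.featuretype != "CDS":
            continue
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            raise AnnotationError(f"CDS at {feat.seqid}:{feat.start} lacks ID")
        seen_ids.add(gene_id)
        seq = proteins.get(gene_id)
        plen = len(seq) if seq else max(1, (feat.end - feat.start + 1) // 3 - 1)
        by_replicon.setdefault(feat.seqid, []).append(GeneRecord(
            replicon_id=feat.seqid,
            gene_id=gene_id,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            protein_length=plen,
            product=feat.attributes.get("product", [""])[0],
            protein_seq=seq,
        ))

    orphan_fasta = sorted(set(proteins) - seen_ids)
    orphan_gff = sorted(seen_ids - set(proteins))
    if orphan_fasta or orphan_gff:
        raise AnnotationError(
            "GFF/FASTA id mismatch; "
            f"FASTA-only: {orphan_fasta}; GFF-only: {orphan_gff}")

    return [
        GenomeAnnotation(rid, genes, length_bp=region_lengths.get(rid))
        for rid, genes in sorted(by_replicon.items())
    ]


def write_gff_fasta(genomes: Iterable[GenomeAnnotation],
                    gff_path: str, fasta_path: str) -> None:
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        records = []
        for genome in genomes:
            length = genome.length_bp or (genome.genes[-1].end if genome.genes else 1)
            gff.write(f"##sequence-region {genome.replicon_id} 1 {length}\n")
            gff.write("\t".join([
                genome.replicon_id, "acrmine", "region", "1", str(length),
                ".", "+", ".", f"ID={genome.replicon_id}",
            ]) + "\n")
            for g in genome:
                attrs = f"ID={g.gene_id}"
                if g.product:
                    attrs += f";product={g.product}"
                gff.write("\t".join([
                    g.replicon_id, "acrmine", "CDS", str(g.start), str(g.end),
                    ".", g.strand, "0", attrs,
                ]) + "\n")
                if g.protein_seq:
                    records.append(SeqRecord(
                        Seq(g.protein_seq), id=g.gene_id, description=""))
    SeqIO.write(records, fasta_path, "fasta")


def read_protein_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_protein_fasta(proteins: dict[str, str], path: str) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=gid, description="") for gid, s in proteins.items()],
        path, "fasta")


# ---------------------------------------------------------------------------
# Tabular evidence layers
# ---------------------------------------------------------------------------

_HIT_ALIASES = {
    "query_family": ("query_family", "qseqid"),
    "subject_gene_id": ("subject_gene_id", "sseqid"),
    "percent_identity": ("percent_identity", "pident"),
    "evalue": ("evalue",),
    "query_coverage": ("query_coverage", "qcovs", "qcovhsp"),
    "subject_start": ("subject_start", "sstart"),
    "subject_end": ("subject_end", "send"),
}


def _resolve_columns(df: pd.DataFrame, aliases: dict, what: str) -> dict[str, str]:
    mapping = {}
    missing = []
    for canonical, names in aliases.items():
        found = next((n for n in names if n in df.columns), None)
        if found is None:
            missing.append(canonical)
        else:
            mapping[canonical] = found
    if missing:
        raise SchemaError(
            f"{what}: missing required column(s) {missing}; "
            f"accepted names: { {k: list(v) for k, v in aliases.items()} }")
    return mapping


def _normalize_fraction(x: float) -> float:
    """Coverage/probability given as a percentage is normalized to a fraction."""
    return x / 100.0 if x > 1.0 else x


def read_hit_table(path: str) -> list[HomologyHit]:
    """Read a BLAST-outfmt-6-like homology table.

    Required columns (by name; outfmt-6 aliases such as ``qseqid``/``pident``
    accepted, extra columns ignored): query family, subject gene id, percent
    identity, E-value, query coverage (percent or fraction), subject start/end.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.empty:
        logger.warning("hit table %s is empty", path)
        return []
    cols = _resolve_columns(df, _HIT_ALIASES, "hit table")
    hits = []
    for _, row in df.iterrows():
        hits.append(HomologyHit(
            query_family=str(row[cols["query_family"]]),
            subject_gene_id=str(row[cols["subject_gene_id"]]),
            percent_identity=float(row[cols["percent_identity"]]),
            evalue=float(row[cols["evalue"]]),
            query_coverage=_normalize_fraction(float(row[cols["query_coverage"]])),
            subject_start=int(row[cols["subject_start"]]),
            subject_end=int(row[cols["subject_end"]]),
        ))
    return hits


def write_hit_table(hits: Sequence[HomologyHit], path: str) -> None:
    pd.DataFrame([{
        "query_family": h.query_family,
        "subject_gene_id": h.subject_gene_id,
        "percent_identity": h.percent_identity,
        "evalue": h.evalue,
        "query_coverage": h.query_coverage,
        "subject_start": h.subject_start,
        "subject_end": h.subject_end,
    } for h in hits]).to_csv(path, sep="\t", index=False, float_format="%.17g")


_DOMAIN_ALIASES = {
    "gene_id": ("gene_id",),
    "domain_label": ("domain_label", "domain"),
    "probability": ("probability", "prob"),
    "region_start": ("region_start",),
    "region_end": ("region_end",),
}


def read_domain_table(path: str) -> list[DomainAnnotation]:
    """Read a TSV of predicted protein domains (HTH/AP2/other)."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.empty:
        logger.warning("domain table %s is empty", path)
        return []
    cols = _resolve_columns(df, _DOMAIN_ALIASES, "domain table")
    return [
        DomainAnnotation(
            gene_id=str(row[cols["gene_id"]]),
            domain_label=str(row[cols["domain_label"]]),
            probability=_normalize_fraction(float(row[cols["probability"]])),
            region_start=int(row[cols["region_start"]]),
            region_end=int(row[cols["region_end"]]),
        )
        for _, row in df.iterrows()
    ]


def write_domain_table(domains: Sequence[DomainAnnotation], path: str) -> None:
    pd.DataFrame([{
        "gene_id": d.gene_id,
        "domain_label": d.domain_label,
        "probability": d.probability,
        "region_start": d.region_start,
        "region_end": d.region_end,
    } for d in domains]).to_csv(path, sep="\t", index=False, float_format="%.17g")


_ASSAY_KEY_COLUMNS = ("acr_label", "cas9_label", "assay", "replicate_id")
_ASSAY_MEASURES = ("cfu_matching", "cfu_mismatching", "cleaved_fraction",
                   "efficiency_no4ht", "efficiency_4ht")


def read_assay_table(path: str) -> pd.DataFrame:
    """Read an assay count/efficiency table into a typed DataFrame.

    Requires the key columns acr_label / cas9_label / assay / replicate_id and
    at least one measure column among cfu_matching+cfu_mismatching,
    cleaved_fraction, or efficiency_no4ht+efficiency_4ht.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.empty:
        logger.warning("assay table %s is empty", path)
        return df
    missing = [c for c in _ASSAY_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assay table: missing required column(s) {missing}")
    if not any(c in df.columns for c in _ASSAY_MEASURES):
        raise SchemaError(
            f"assay table: needs at least one measure column of {_ASSAY_MEASURES}")
    return df


def write_assay_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Candidate report (TSV + JSON, validated by a pydantic schema)
# ---------------------------------------------------------------------------

class FusionCallModel(BaseModel):
    gene_id: str
    aca_start: int = Field(ge=1)
    aca_end: int = Field(ge=1)
    terminal_side: str = Field(pattern="^[NC]$")
    acr_remainder_length: int = Field(ge=0)


class CandidateModel(BaseModel):
    gene_id: str
    replicon_id: str
    candidate_class: str = Field(pattern="^(acr_candidate|aca_candidate)$")
    size_ok: bool
    adjacent_marker: Optional[str] = None
    adjacent_side: Optional[str] = None
    orientation_ok: bool
    has_dna_binding_domain: bool
    association_count: int = Field(ge=0)
    fusion: Optional[FusionCallModel] = None
    confidence_tier: str = Field(pattern="^(standard|fusion_boosted)$")


class CandidateReport(BaseModel):
    candidates: list[CandidateModel]


_CANDIDATE_COLUMNS = [
    "gene_id", "replicon_id", "candidate_class", "size_ok", "adjacent_marker",
    "adjacent_side", "orientation_ok", "has_dna_binding_domain",
    "association_count", "fusion_side", "confidence_tier",
]


def candidates_to_models(candidates) -> CandidateReport:
    models = []
    for c in candidates:
        fusion = None
        if c.fusion is not None:
            fusion = FusionCallModel(
                gene_id=c.fusion.gene_id,
                aca_start=c.fusion.aca_start,
                aca_end=c.fusion.aca_end,
                terminal_side=c.fusion.terminal_side,
                acr_remainder_length=c.fusion.acr_remainder_length,
            )
        models.append(CandidateModel(
            gene_id=c.gene_id,
            replicon_id=c.replicon_id,
            candidate_class=c.candidate_class,
            size_ok=c.size_ok,
            adjacent_marker=c.adjacent_marker,
            adjacent_side=c.adjacent_side,
            orientation_ok=c.orientation_ok,
            has_dna_binding_domain=c.has_dna_binding_domain,
            association_count=c.association_count,
            fusion=fusion,
            confidence_tier=c.confidence_tier,
        ))
    return CandidateReport(candidates=models)


def write_candidates(candidates, tsv_path: str, json_path: Optional[str] = None) -> None:
    """Write the candidate report as TSV (one row per candidate, per-criterion
    evidence columns) and optionally JSON validated against the shipped
    pydantic schema."""
    report = candidates_to_models(candidates)
    rows = []
    for m in report.candidates:
        row = m.model_dump()
        fusion = row.pop("fusion")
        row["fusion_side"] = fusion["terminal_side"] if fusion else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        with open(json_path, "w") as fh:
            fh.write(report.model_dump_json(indent=2))


def read_candidates_json(path: str) -> CandidateReport:
    """Load and validate a candidate JSON report."""
    with open(path) as fh:
        return CandidateReport.model_validate_json(fh.read())


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str) -> None:
    """Write a tree (PhyloTree or newick string) with full-precision lengths."""
    newick = tree if isinstance(tree, str) else tree.newick
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def read_newick(path: str):
    """Parse a Newick file into a dendropy Tree."""
    import dendropy

    return dendropy.Tree.get(path=path, schema="newick")


def write_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
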