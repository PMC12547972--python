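"""Readers and writers for the external formats the pipeline touches.

Alignments arrive in the extended 14-column tabular format (the standard
12 columns plus query and subject lengths, which are the denominators for
every coverage computation downstream).  Genome features come from GFF3;
per-contig feature ranks — the adjacency coordinate used for split-homolog
detection — are assigned here by sorting CDS features by start coordinate.
Cluster maps, taxonomy tables, annotation tables and reaction tables are
plain TSV.

All coordinates are 1-based inclusive; interval length is end - start + 1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd

logger = logging.getLogger("splithom")

ALIGNMENT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]

#: GTDB lineage rank prefixes in order.
_LINEAGE_RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]
_LINEAGE_PREFIXES = ["d__", "p__", "c__", "o__", "f__", "g__", "s__"]


class CatalogError(ValueError):
    """Fatal input validation error (malformed or inconsistent input)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHSP:
    """One aligned segment pair: microbial family (query) vs host protein
    (subject)."""

    query_id: str
    subject_id: str
    pident: float
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise CatalogError(
                f"HSP {self.query_id}/{self.subject_id}: query coordinates "
                f"{self.qstart}-{self.qend} violate 1 <= qstart <= qend <= qlen={self.qlen}"
            )
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise CatalogError(
                f"HSP {self.query_id}/{self.subject_id}: subject coordinates "
                f"{self.sstart}-{self.send} violate 1 <= sstart <= send <= slen={self.slen}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise CatalogError(
                f"HSP {self.query_id}/{self.subject_id}: pident {self.pident} outside [0, 100]"
            )


@dataclass(frozen=True)
class GenomeFeature:
    """One protein-coding feature with its ordinal rank along the contig."""

    genome_id: str
    contig_id: str
    feature_rank: int
    strand: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CatalogError(f"feature {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise CatalogError(f"feature {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class TaxonomyRecord:
    genome_id: str
    species_id: str
    lineage: dict[str, str] = field(hash=False)

    @property
    def phylum(self) -> str:
        return self.lineage.get("phylum", "")

    @property
    def family(self) -> str:
        return self.lineage.get("family", "")


ClusterMap = dict  # gene_id -> family_id (many-to-one)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> list[AlignmentHSP]:
    """Read an extended 14-column tabular alignment file.

    The two extra columns (qlen, slen) are mandatory: they are the coverage
    denominators. Row order is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("alignment file %s is empty", path)
        return []
    if df.shape[1] != len(ALIGNMENT_COLUMNS):
        raise CatalogError(
            f"{path}: extended tabular required "
            f"(expected {len(ALIGNMENT_COLUMNS)} columns qseqid..slen, got {df.shape[1]})"
        )
    df.columns = ALIGNMENT_COLUMNS
    hsps = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            hsps.append(
                AlignmentHSP(
                    query_id=row.qseqid,
                    subject_id=row.sseqid,
                    pident=float(row.pident),
                    qstart=int(row.qstart),
                    qend=int(row.qend),
                    sstart=int(row.sstart),
                    send=int(row.send),
                    evalue=float(row.evalue),
                    bitscore=float(row.bitscore),
                    qlen=int(row.qlen),
                    slen=int(row.slen),
                )
            )
        except CatalogError as exc:
            raise CatalogError(f"{path}: row {i}: {exc}") from exc
    return hsps


def write_alignments(hsps: Iterable[AlignmentHSP], path: str | Path) -> None:
    rows = []
    for h in hsps:
        aln_len = max(h.qend - h.qstart + 1, h.send - h.sstart + 1)
        rows.append(
            (h.query_id, h.subject_id, h.pident, aln_len, 0, 0,
             h.qstart, h.qend, h.sstart, h.send, h.evalue, h.bitscore,
             h.qlen, h.slen)
        )
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Genome features (GFF3)
# ---------------------------------------------------------------------------

def read_features(gff_path: str | Path, genome_id: str) -> list[GenomeFeature]:
    """Read CDS features from a GFF3 file and assign per-contig ranks.

    Ranks are 1..n within each contig, ordered by start coordinate
    (strand-independent). Features with strand "." are skipped with a
    warning; a CDS without an ID attribute is fatal.
    """
    gff_path = Path(gff_path)
    text = gff_path.read_text()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return []
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[tuple[str, int, int, str, str]] = []
    for f in db.features_of_type("CDS"):
        if "ID" not in f.attributes:
            raise CatalogError(f"{gff_path}: CDS without ID attribute at {f.seqid}:{f.start}")
        gene_id = f.attributes["ID"][0]
        if f.strand not in ("+", "-"):
            logger.warning("%s: CDS %s has unknown strand %r, skipped", gff_path, gene_id, f.strand)
            continue
        raw.append((f.seqid, f.start, f.end, f.strand, gene_id))

    features: list[GenomeFeature] = []
    by_contig: dict[str, list[tuple[str, int, int, str, str]]] = {}
    for rec in raw:
        by_contig.setdefault(rec[0], []).append(rec)
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda r: (r[1], r[2], r[4]))
        for rank, (seqid, start, end, strand, gene_id) in enumerate(ordered, start=1):
            features.append(
                GenomeFeature(
                    genome_id=genome_id, contig_id=seqid, feature_rank=rank,
                    strand=strand, start=start, end=end, gene_id=gene_id,
                )
            )
    return features


def write_gff3(features: Iterable[GenomeFeature], path: str | Path) -> None:
    """Write features back out as minimal GFF3 (CDS rows with ID attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig_id}\tsplithom\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0"
                f"\tID={f.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Cluster map and taxonomy
# ---------------------------------------------------------------------------

def read_cluster_map(path: str | Path) -> ClusterMap:
    """Read the two-column gene_id -> family_id TSV.

    A gene mapped to two different families is fatal; an exact duplicate
    row is tolerated.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "family_id"], dtype=str)
    mapping: dict[str, str] = {}
    for gene, fam in zip(df["gene_id"], df["family_id"]):
        prev = mapping.get(gene)
        if prev is not None and prev != fam:
            raise CatalogError(f"{path}: gene {gene} mapped to both {prev} and {fam}")
        mapping[gene] = fam
    return mapping


def write_cluster_map(mapping: ClusterMap, path: str | Path) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=["gene_id", "family_id"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a GTDB-style lineage string into named ranks.

    "d__Bacteria;p__Firmicutes_A;...;f__Lachnospiraceae;...;s__X"
    -> {"phylum": "Firmicutes_A", "family": "Lachnospiraceae", ...}.
    Empty rank fields yield empty strings.
    """
    out = {rank: "" for rank in _LINEAGE_RANKS}
    for part in lineage.split(";"):
        part = part.strip()
        for rank, prefix in zip(_LINEAGE_RANKS, _LINEAGE_PREFIXES):
            if part.startswith(prefix):
                out[rank] = part[len(prefix):]
                break
    return out


def read_taxonomy(path: str | Path) -> list[TaxonomyRecord]:
    """Read the genome taxonomy TSV: genome_id, species_id, lineage string."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "species_id", "lineage"}
    if not required.issubset(df.columns):
        raise CatalogError(f"{path}: taxonomy requires columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        lineage = parse_lineage(row.lineage)
        if not lineage["phylum"] or not lineage["family"]:
            raise CatalogError(
                f"{path}: genome {row.genome_id}: lineage must name phylum and family"
            )
        records.append(
            TaxonomyRecord(genome_id=row.genome_id, species_id=row.species_id, lineage=lineage)
        )
    return records


def write_taxonomy(records: Iterable[TaxonomyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        lineage = ";".join(
            prefix + r.lineage.get(rank, "")
            for rank, prefix in zip(_LINEAGE_RANKS, _LINEAGE_PREFIXES)
        )
        rows.append((r.genome_id, r.species_id, lineage))
    pd.DataFrame(rows, columns=["genome_id", "species_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Host annotation tables
# ---------------------------------------------------------------------------

def read_go_annotations(path: str | Path) -> pd.DataFrame:
    """protein / term / evidence / namespace TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "term", "evidence", "namespace"}
    if not required.issubset(df.columns):
        raise CatalogError(f"{path}: GO annotation table requires columns {sorted(required)}")
    return df


def read_protein_info(path: str | Path) -> pd.DataFrame:
    """protein / description (family description string) / cc (cellular
    component strings, ';'-separated, may be empty) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein", "description", "cc"}
    if not required.issubset(df.columns):
        raise CatalogError(f"{path}: protein info table requires columns {sorted(required)}")
    return df
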