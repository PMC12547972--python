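"""Shared filtering steps and the full-length homolog pipeline.

The search orientation is fixed: the microbial protein family is the query,
the host protein the subject.  Two filters are shared between the
full-length and split tracks:

1. *Best human hit* — for each microbial family keep only the host protein
   of its highest-bitscore alignment (ties: lower e-value, then
   lexicographically smaller host accession).
2. *Microbe coverage* — keep alignments covering >= 67% of the microbial
   family sequence, and only families >= 80 residues long.

The full-length track then requires each alignment to cover >= 70% of the
host protein (F3), and drops alignments whose percent identity is more
than 3 sample standard deviations above the mean of the F3 survivors (F4)
— the contamination filter, which guards against human reads assembled
into metagenome-assembled genomes.  The fitted contamination model is
reused verbatim by the split track.

Families are then expanded to their member genes/genomes and the single
best alignment per (host protein, genome) is kept.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, replace

from .io import AlignmentHSP, ClusterMap, GenomeFeature

logger = logging.getLogger("splithom")


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds of the homolog-detection pipeline.

    Defaults are the study conditions: microbial coverage 0.67, host
    coverage 0.70, minimum microbial protein length 80 aa, contamination
    cutoff at mean + 3 SD, neighborhood distance 3 features.
    """

    microbe_cov_min: float = 0.67
    human_cov_min: float = 0.70
    min_microbe_len: int = 80
    contamination_sd_mult: float = 3.0
    max_feature_distance: int = 3

    def __post_init__(self) -> None:
        for name in ("microbe_cov_min", "human_cov_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_microbe_len < 1:
            raise ValueError("min_microbe_len must be >= 1")
        if self.contamination_sd_mult <= 0:
            raise ValueError("contamination_sd_mult must be > 0")
        if self.max_feature_distance < 1:
            raise ValueError("max_feature_distance must be >= 1")

    def with_coverages(self, microbe: float, human: float) -> "PipelineParams":
        return replace(self, microbe_cov_min=microbe, human_cov_min=human)


@dataclass(frozen=True)
class ContaminationModel:
    """Percent-identity contamination filter: mean + k*SD over the
    alignments surviving the host-coverage step."""

    mean_pident: float
    sd_pident: float
    cutoff: float
    n_alignments: int

    def passes(self, pident: float) -> bool:
        """True if the alignment is retained (pident not above the cutoff)."""
        return pident <= self.cutoff


@dataclass(frozen=True)
class FullLengthCall:
    human_id: str
    genome_id: str
    family_id: str
    gene_id: str
    human_coverage: float
    microbe_coverage: float
    pident: float
    bitscore: float


def coverage(hsp: AlignmentHSP, side: str) -> float:
    """Fraction of the query ("query") or subject ("subject") sequence
    spanned by the alignment; in (0, 1]."""
    if side == "query":
        return (hsp.qend - hsp.qstart + 1) / hsp.qlen
    if side == "subject":
        return (hsp.send - hsp.sstart + 1) / hsp.slen
    raise ValueError(f"side must be 'query' or 'subject', got {side!r}")


def _hit_rank_key(hsp: AlignmentHSP) -> tuple:
    # bitscore desc, e-value asc, accession lexicographic
    return (-hsp.bitscore, hsp.evalue, hsp.subject_id)


def best_human_hit(hsps: list[AlignmentHSP]) -> list[AlignmentHSP]:
    """Step 1: per microbial family, keep only alignments to the host
    protein of its best alignment.

    All HSPs pairing the family with that host protein are retained, so a
    family aligning to its best hit in several segments keeps them all.
    """
    best_subject: dict[str, AlignmentHSP] = {}
    for h in hsps:
        cur = best_subject.get(h.query_id)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            best_subject[h.query_id] = h
    return [h for h in hsps if best_subject[h.query_id].subject_id == h.subject_id]


def filter_microbe_side(hsps: list[AlignmentHSP], params: PipelineParams) -> list[AlignmentHSP]:
    """Step 2: query coverage >= microbe_cov_min and qlen >= min_microbe_len."""
    return [
        h for h in hsps
        if h.qlen >= params.min_microbe_len
        and coverage(h, "query") >= params.microbe_cov_min
    ]


def filter_human_side(hsps: list[AlignmentHSP], params: PipelineParams) -> list[AlignmentHSP]:
    """F3: subject coverage >= human_cov_min, per alignment row."""
    return [h for h in hsps if coverage(h, "subject") >= params.human_cov_min]


def fit_contamination(hsps: list[AlignmentHSP], params: PipelineParams) -> ContaminationModel:
    """F4 model: mean and sample SD (n-1) of percent identity over the
    F3-surviving alignments; cutoff = mean + sd_mult * SD."""
    if len(hsps) < 2:
        raise ValueError("insufficient alignments for contamination model (need >= 2)")
    pidents = [h.pident for h in hsps]
    mean = statistics.fmean(pidents)
    sd = statistics.stdev(pidents)
    if sd == 0.0:
        logger.warning(
            "contamination model degenerate: all %d pidents equal %.3f; "
            "cutoff collapses to the mean", len(pidents), mean,
        )
    cutoff = mean + params.contamination_sd_mult * sd
    return ContaminationModel(
        mean_pident=mean, sd_pident=sd, cutoff=cutoff, n_alignments=len(pidents)
    )


def family_members(
    cluster_map: ClusterMap, features: list[GenomeFeature]
) -> dict[str, list[GenomeFeature]]:
    """family_id -> member gene features (only genes with a feature record)."""
    by_gene = {f.gene_id: f for f in features}
    out: dict[str, list[GenomeFeature]] = {}
    for gene_id, family_id in cluster_map.items():
        feat = by_gene.get(gene_id)
        if feat is None:
            continue
        out.setdefault(family_id, []).append(feat)
    return out


def call_full_length(
    hsps: list[AlignmentHSP],
    cluster_map: ClusterMap,
    features: list[GenomeFeature],
    params: PipelineParams,
    contamination: ContaminationModel | None = None,
) -> tuple[list[FullLengthCall], ContaminationModel]:
    """F3-F4 plus genome expansion and best-per-genome reduction.

    `hsps` must already have passed steps 1-2. The contamination model is
    fitted on the F3 survivors unless one is supplied. Returns the calls
    and the model (the split track reuses it).
    """
    f3 = filter_human_side(hsps, params)
    model = contamination if contamination is not None else fit_contamination(f3, params)
    f4 = [h for h in f3 if model.passes(h.pident)]

    members = family_members(cluster_map, features)
    best: dict[tuple[str, str], tuple[tuple, FullLengthCall]] = {}
    seen_families = set()
    for h in f4:
        feats = members.get(h.query_id)
        if not feats:
            if h.query_id not in seen_families:
                logger.warning("family %s has no genome members; excluded", h.query_id)
                seen_families.add(h.query_id)
            continue
        for feat in feats:
            key = (h.subject_id, feat.genome_id)
            # bitscore desc, evalue asc, family then gene accession for determinism
            rank = (-h.bitscore, h.evalue, h.query_id, feat.gene_id)
            call = FullLengthCall(
                human_id=h.subject_id,
                genome_id=feat.genome_id,
                family_id=h.query_id,
                gene_id=feat.gene_id,
                human_coverage=coverage(h, "subject"),
                microbe_coverage=coverage(h, "query"),
                pident=h.pident,
                bitscore=h.bitscore,
            )
            cur = best.get(key)
            if cur is None or rank < cur[0]:
                best[key] = (rank, call)
    calls = [ranked_call[1] for _, ranked_call in sorted(best.items())]
    return calls, model
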