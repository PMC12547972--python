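"""Split-homolog detection: neighborhoods of microbial genes jointly
homologous to one host protein.

A split homolog is a set of >= 2 distinct microbial protein families,
encoded <= 3 feature ranks apart on the same contig and strand of one
genome, whose alignments jointly — but not individually — cover >= 70% of
a host protein.  The stages are:

S3  expand family-level alignments to member genes/genomes; keep only
    (host protein, genome) pairs where >= 2 distinct families align;
S4  joint-but-not-individual host coverage;
S5  adjacency: connected components under pairwise rank gap <= 3 within
    one (contig, strand); joint coverage re-tested per component;
S6  contamination filter using the model fitted on full-length homologs;
    joint coverage re-tested once more.

Each re-test is a single pass: removals only shrink coverage, so the
stated re-run order needs no fixed point iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .homology import ContaminationModel, PipelineParams, family_members
from .io import AlignmentHSP, ClusterMap, GenomeFeature

logger = logging.getLogger("splithom")


@dataclass(frozen=True)
class GenomeAlignmentInstance:
    """One family-level alignment instantiated at one genomic locus."""

    human_id: str
    genome_id: str
    contig_id: str
    strand: str
    feature_rank: int
    gene_id: str
    family_id: str
    sstart: int
    send: int
    slen: int
    pident: float
    bitscore: float

    @property
    def subject_coverage(self) -> float:
        return (self.send - self.sstart + 1) / self.slen


@dataclass(frozen=True)
class Neighborhood:
    """A candidate or final split-homolog call."""

    human_id: str
    genome_id: str
    contig_id: str
    strand: str
    members: tuple[GenomeAlignmentInstance, ...]
    joint_coverage: float

    @property
    def n_families(self) -> int:
        return len({m.family_id for m in self.members})

    @property
    def max_rank_gap(self) -> int:
        ranks = sorted({m.feature_rank for m in self.members})
        if len(ranks) < 2:
            return 0
        return max(b - a for a, b in zip(ranks, ranks[1:]))


def union_coverage(intervals: list[tuple[int, int]], length: int) -> float:
    """Fraction of [1, length] covered by the union of 1-based inclusive
    intervals."""
    if not intervals:
        return 0.0
    covered = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end > last_end:
            covered += end - start + 1
            last_end = end
    return covered / length


def expand_to_genomes(
    hsps: list[AlignmentHSP],
    cluster_map: ClusterMap,
    features: list[GenomeFeature],
) -> list[GenomeAlignmentInstance]:
    """S3: one instance per (alignment, member gene); genomes encoding < 2
    distinct aligning families for a host protein are dropped."""
    members = family_members(cluster_map, features)
    mapped_genes = set(cluster_map)
    for gene_id in sorted(mapped_genes - {f.gene_id for f in features}):
        logger.warning("gene %s has no feature record; instances skipped", gene_id)

    instances: list[GenomeAlignmentInstance] = []
    for h in hsps:
        for feat in members.get(h.query_id, ()):
            instances.append(
                GenomeAlignmentInstance(
                    human_id=h.subject_id,
                    genome_id=feat.genome_id,
                    contig_id=feat.contig_id,
                    strand=feat.strand,
                    feature_rank=feat.feature_rank,
                    gene_id=feat.gene_id,
                    family_id=h.query_id,
                    sstart=h.sstart,
                    send=h.send,
                    slen=h.slen,
                    pident=h.pident,
                    bitscore=h.bitscore,
                )
            )

    by_pair: dict[tuple[str, str], set[str]] = {}
    for inst in instances:
        by_pair.setdefault((inst.human_id, inst.genome_id), set()).add(inst.family_id)
    return [
        inst for inst in instances
        if len(by_pair[(inst.human_id, inst.genome_id)]) >= 2
    ]


def _group_joint_coverage(members: list[GenomeAlignmentInstance]) -> float:
    if not members:
        return 0.0
    return union_coverage([(m.sstart, m.send) for m in members], members[0].slen)


def joint_candidates(
    instances: list[GenomeAlignmentInstance], params: PipelineParams
) -> dict[tuple[str, str], list[GenomeAlignmentInstance]]:
    """S4: per (host protein, genome), keep groups whose union coverage
    reaches the host threshold while no single member reaches it alone.

    A group with an individually-qualifying member is excluded entirely —
    that pair belongs to the full-length track.
    """
    groups: dict[tuple[str, str], list[GenomeAlignmentInstance]] = {}
    for inst in instances:
        groups.setdefault((inst.human_id, inst.genome_id), []).append(inst)
    kept = {}
    for key in sorted(groups):
        members = groups[key]
        if any(m.subject_coverage >= params.human_cov_min for m in members):
            continue
        if _group_joint_coverage(members) >= params.human_cov_min:
            kept[key] = members
    return kept


def _components_by_rank(
    members: list[GenomeAlignmentInstance], max_gap: int
) -> list[list[GenomeAlignmentInstance]]:
    """Connected components under |rank_i - rank_j| <= max_gap (chained)."""
    ordered = sorted(members, key=lambda m: (m.feature_rank, m.gene_id, m.family_id))
    comps: list[list[GenomeAlignmentInstance]] = []
    current: list[GenomeAlignmentInstance] = []
    for m in ordered:
        if current and m.feature_rank - current[-1].feature_rank > max_gap:
            comps.append(current)
            current = []
        current.append(m)
    if current:
        comps.append(current)
    return comps


def _validate_components(
    comps: list[list[GenomeAlignmentInstance]], params: PipelineParams
) -> list[Neighborhood]:
    """Keep components with >= 2 distinct families and re-test joint
    coverage (the host-coverage step re-run)."""
    out = []
    for comp in comps:
        if len({m.family_id for m in comp}) < 2:
            continue
        cov = _group_joint_coverage(comp)
        if cov < params.human_cov_min:
            continue
        first = comp[0]
        out.append(
            Neighborhood(
                human_id=first.human_id,
                genome_id=first.genome_id,
                contig_id=first.contig_id,
                strand=first.strand,
                members=tuple(comp),
                joint_coverage=cov,
            )
        )
    return out


def neighborhood_filter(
    group: list[GenomeAlignmentInstance], params: PipelineParams
) -> list[Neighborhood]:
    """S5: partition a candidate group by (contig, strand), form rank-gap
    connected components, keep components with >= 2 distinct families and
    re-test joint coverage."""
    partitions: dict[tuple[str, str], list[GenomeAlignmentInstance]] = {}
    for m in group:
        partitions.setdefault((m.contig_id, m.strand), []).append(m)
    comps: list[list[GenomeAlignmentInstance]] = []
    for key in sorted(partitions):
        comps.extend(_components_by_rank(partitions[key], params.max_feature_distance))
    return _validate_components(comps, params)


def finalize_split_calls(
    neighborhoods: list[Neighborhood],
    contamination: ContaminationModel,
    params: PipelineParams,
) -> list[Neighborhood]:
    """S6: drop members above the contamination cutoff, then re-test each
    neighborhood (>= 2 distinct families, adjacency, joint coverage)."""
    out: list[Neighborhood] = []
    for nb in neighborhoods:
        survivors = [m for m in nb.members if contamination.passes(m.pident)]
        if not survivors:
            continue
        # removals can break the rank chain, so components are re-derived
        comps = _components_by_rank(survivors, params.max_feature_distance)
        out.extend(_validate_components(comps, params))
    return out


def detect_split_homologs(
    hsps: list[AlignmentHSP],
    cluster_map: ClusterMap,
    features: list[GenomeFeature],
    contamination: ContaminationModel,
    params: PipelineParams,
) -> list[Neighborhood]:
    """Run S3-S6 end to end on step-1/2-filtered alignments."""
    instances = expand_to_genomes(hsps, cluster_map, features)
    candidates = joint_candidates(instances, params)
    neighborhoods: list[Neighborhood] = []
    for key in sorted(candidates):
        neighborhoods.extend(neighborhood_filter(candidates[key], params))
    return finalize_split_calls(neighborhoods, contamination, params)
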