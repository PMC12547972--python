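"""End-to-end orchestration of the homolog-detection pipeline.

`run_pipeline` executes every stage on loaded inputs and keeps the
intermediate alignment sets, so the step ledger (how many alignments or
groups survive each filter) can be reported and individual rejections
traced.  `PipelineRun.ledger` mirrors the filter chain: counts are
non-increasing along the full-length chain and along the split chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import homology, split
from .homology import ContaminationModel, FullLengthCall, PipelineParams
from .tally import HomologTally, SensitivityResult
from .io import (AlignmentHSP, ClusterMap, GenomeFeature, TaxonomyRecord,
                 read_alignments, read_cluster_map, read_features, read_taxonomy)
from .split import GenomeAlignmentInstance, Neighborhood

logger = logging.getLogger("splithom")


@dataclass
class PipelineInputs:
    hsps: list[AlignmentHSP]
    cluster_map: ClusterMap
    features: list[GenomeFeature]
    taxonomy: list[TaxonomyRecord] | None = None

    @classmethod
    def load(
        cls,
        alignments: str | Path,
        cluster_map: str | Path,
        gff3_paths: dict[str, str | Path],
        taxonomy: str | Path | None = None,
    ) -> "PipelineInputs":
        features: list[GenomeFeature] = []
        for genome_id in sorted(gff3_paths):
            features.extend(read_features(gff3_paths[genome_id], genome_id))
        return cls(
            hsps=read_alignments(alignments),
            cluster_map=read_cluster_map(cluster_map),
            features=features,
            taxonomy=read_taxonomy(taxonomy) if taxonomy else None,
        )


@dataclass
class PipelineRun:
    """All stage outputs of one pipeline execution."""

    params: PipelineParams
    hsps_raw: list[AlignmentHSP]
    hsps_best: list[AlignmentHSP]
    hsps_step2: list[AlignmentHSP]
    hsps_f3: list[AlignmentHSP]
    contamination: ContaminationModel
    full_calls: list[FullLengthCall]
    instances: list[GenomeAlignmentInstance]
    candidates: dict[tuple[str, str], list[GenomeAlignmentInstance]]
    neighborhoods_s5: list[Neighborhood]
    split_calls: list[Neighborhood]
    ledger: dict[str, int] = field(default_factory=dict)


def run_pipeline(inputs: PipelineInputs, params: PipelineParams = PipelineParams()) -> PipelineRun:
    hsps_best = homology.best_human_hit(inputs.hsps)
    hsps_step2 = homology.filter_microbe_side(hsps_best, params)
    hsps_f3 = homology.filter_human_side(hsps_step2, params)
    model = homology.fit_contamination(hsps_f3, params)
    full_calls, _ = homology.call_full_length(
        hsps_step2, inputs.cluster_map, inputs.features, params, contamination=model
    )
    instances = split.expand_to_genomes(hsps_step2, inputs.cluster_map, inputs.features)
    candidates = split.joint_candidates(instances, params)
    neighborhoods_s5: list[Neighborhood] = []
    for key in sorted(candidates):
        neighborhoods_s5.extend(split.neighborhood_filter(candidates[key], params))
    split_calls = split.finalize_split_calls(neighborhoods_s5, model, params)

    hsps_f4 = [h for h in hsps_f3 if model.passes(h.pident)]
    ledger = {
        "alignments_raw": len(inputs.hsps),
        "after_best_human_hit": len(hsps_best),
        "after_microbe_coverage": len(hsps_step2),
        "full_after_human_coverage": len(hsps_f3),
        "full_after_contamination": len(hsps_f4),
        "full_calls": len(full_calls),
        "split_instances": len(instances),
        "split_candidate_groups": len(candidates),
        "split_neighborhoods_after_distance": len(neighborhoods_s5),
        "split_calls_final": len(split_calls),
    }
    return PipelineRun(
        params=params, hsps_raw=inputs.hsps, hsps_best=hsps_best,
        hsps_step2=hsps_step2, hsps_f3=hsps_f3, contamination=model,
        full_calls=full_calls, instances=instances, candidates=candidates,
        neighborhoods_s5=neighborhoods_s5, split_calls=split_calls, ledger=ledger,
    )


# ---------------------------------------------------------------------------
# Output writers (all TSV with headers)
# ---------------------------------------------------------------------------

def full_calls_frame(calls: list[FullLengthCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.human_id, c.genome_id, c.family_id, c.gene_id,
          round(c.human_coverage, 6), round(c.microbe_coverage, 6),
          c.pident, c.bitscore) for c in calls],
        columns=["human_id", "genome_id", "family_id", "gene_id",
                 "human_coverage", "microbe_coverage", "pident", "bitscore"],
    )


def split_calls_frame(split_calls: list[Neighborhood]) -> pd.DataFrame:
    rows = []
    for i, nb in enumerate(split_calls, start=1):
        for m in nb.members:
            rows.append(
                (f"NB{i:05d}", nb.human_id, nb.genome_id, nb.contig_id, nb.strand,
                 m.feature_rank, m.gene_id, m.family_id, m.sstart, m.send,
                 m.pident, round(nb.joint_coverage, 6))
            )
    return pd.DataFrame(
        rows,
        columns=["neighborhood_id", "human_id", "genome_id", "contig", "strand",
                 "rank", "gene_id", "family_id", "sstart", "send", "pident",
                 "joint_coverage"],
    )


def tallies_frame(tallies: list[HomologTally]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.human_id, t.n_full, t.n_split, t.category) for t in tallies],
        columns=["human_id", "n_full", "n_split", "category"],
    )


def sensitivity_frame(result: SensitivityResult) -> pd.DataFrame:
    rows = []
    for (m, h), tallies in sorted(result.tallies.items()):
        for t in tallies:
            rows.append((m, h, t.human_id, t.n_full, t.n_split, t.category))
    return pd.DataFrame(
        rows, columns=["microbe_cov", "human_cov", "human_id", "n_full", "n_split", "category"]
    )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    input_paths: dict[str, str],
    ledger: dict[str, int],
    extras: dict | None = None,
) -> None:
    """Machine-readable provenance: config echo, input checksums, per-step
    survivor counts, and any extra result summaries."""
    manifest = {
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(input_paths.items())
            if Path(p).is_file()
        },
        "step_ledger": ledger,
    }
    if extras:
        manifest.update(extras)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
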