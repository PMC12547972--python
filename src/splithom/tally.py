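"""Per-host-protein homolog tallies, sensitivity analysis and xenobiotic
class partitioning.

For each host protein the pipeline counts full-length homologs (distinct
genomes with a call, by default) and split homologs (distinct
neighborhoods).  A protein is *split-dominant* when it has strictly more
split than full-length homologs — the set of proteins a conventional
one-to-one search is most likely to miss.

The sensitivity grid re-runs the entire pipeline (contamination model
included) over a grid of microbe x host coverage thresholds; the defaults
are microbe 50/67/75% x host 60/70/80%, nine combinations.

Host xenobiotic-enzyme classes (short-chain reductases, aldo-keto
reductases, cytochrome P450s, ...) are assigned from UniProt family
description strings by ordered regular-expression match.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from . import homology, split
from .homology import FullLengthCall, PipelineParams
from .io import AlignmentHSP, ClusterMap, GenomeFeature, TaxonomyRecord
from .split import Neighborhood

logger = logging.getLogger("splithom")

DEFAULT_MICROBE_LEVELS = (0.50, 0.67, 0.75)
DEFAULT_HUMAN_LEVELS = (0.60, 0.70, 0.80)

#: (class key, regex) in declared order; first match wins.  Patterns with
#: regex metacharacters in the family name are escaped so the literal
#: UniProt description strings match.
DEFAULT_CLASS_TABLE: tuple[tuple[str, str], ...] = (
    ("akr", r"Aldo/keto reductase family"),
    ("udp", r"UDP-glycosyltransferase family"),
    ("gst", r"GST superfamily"),
    ("aryl", r"Arylamine N-acetyltransferase family"),
    ("gdxg", r"'GDXG' lipolytic enzyme family"),
    ("cyto", r"Cytochrome P450 family"),
    ("ester", r"Type-B carboxylesterase/lipase family"),
    ("flavin", r"Flavin monoamine oxidase family|FMO family"),
    ("sdr", r"Short-chain dehydrogenases/reductases \(SDR\)"),
    ("quin", r"Quinone oxidoreductase subfamily"),
)

CATEGORIES = ("full_dominant", "split_dominant", "none")


@dataclass(frozen=True)
class HomologTally:
    human_id: str
    n_full: int
    n_split: int
    category: str


@dataclass
class SensitivityResult:
    microbe_levels: tuple[float, ...]
    human_levels: tuple[float, ...]
    tallies: dict[tuple[float, float], list[HomologTally]] = field(default_factory=dict)
    consensus: pd.DataFrame | None = None

    @property
    def n_combinations(self) -> int:
        return len(self.microbe_levels) * len(self.human_levels)


def _category(n_full: int, n_split: int) -> str:
    if n_full == 0 and n_split == 0:
        return "none"
    return "split_dominant" if n_split > n_full else "full_dominant"


def tally(
    full_calls: list[FullLengthCall],
    split_calls: list[Neighborhood],
    counting_unit: str = "genome",
    taxonomy: list[TaxonomyRecord] | None = None,
) -> list[HomologTally]:
    """Count homologs per host protein and classify.

    `counting_unit` selects the unit for the full-length count: distinct
    genomes (default), distinct microbial protein families, or distinct
    species (requires taxonomy).  Split homologs are always counted as
    distinct neighborhoods, which are intrinsically per-genome.
    """
    if counting_unit not in ("genome", "family", "species"):
        raise ValueError(f"unknown counting unit {counting_unit!r}")
    species_of: dict[str, str] = {}
    if counting_unit == "species":
        if taxonomy is None:
            raise ValueError("species counting unit requires a taxonomy")
        species_of = {t.genome_id: t.species_id for t in taxonomy}

    full_units: dict[str, set] = {}
    for c in full_calls:
        if counting_unit == "genome":
            unit = c.genome_id
        elif counting_unit == "family":
            unit = c.family_id
        else:
            unit = species_of.get(c.genome_id)
            if unit is None:
                logger.warning("genome %s missing from taxonomy; call excluded", c.genome_id)
                continue
        full_units.setdefault(c.human_id, set()).add(unit)

    split_counts: dict[str, int] = {}
    for nb in split_calls:
        split_counts[nb.human_id] = split_counts.get(nb.human_id, 0) + 1

    out = []
    for human_id in sorted(set(full_units) | set(split_counts)):
        n_full = len(full_units.get(human_id, ()))
        n_split = split_counts.get(human_id, 0)
        out.append(HomologTally(human_id, n_full, n_split, _category(n_full, n_split)))
    return out


def run_calls(
    hsps_best: list[AlignmentHSP],
    cluster_map: ClusterMap,
    features: list[GenomeFeature],
    params: PipelineParams,
) -> tuple[list[FullLengthCall], list[Neighborhood]]:
    """Run steps 2..S6 on alignments that already passed the best-human-hit
    step, returning full-length and split calls."""
    step2 = homology.filter_microbe_side(hsps_best, params)
    full_calls, model = homology.call_full_length(step2, cluster_map, features, params)
    split_calls = split.detect_split_homologs(step2, cluster_map, features, model, params)
    return full_calls, split_calls


def sensitivity_grid(
    hsps: list[AlignmentHSP],
    cluster_map: ClusterMap,
    features: list[GenomeFeature],
    params: PipelineParams = PipelineParams(),
    microbe_levels: tuple[float, ...] = DEFAULT_MICROBE_LEVELS,
    human_levels: tuple[float, ...] = DEFAULT_HUMAN_LEVELS,
    counting_unit: str = "genome",
) -> SensitivityResult:
    """Re-run the full pipeline for every coverage-threshold combination.

    The contamination model is refitted for each combination.  The
    consensus table reports, per host protein, in how many combinations it
    was detected at all and in how many its category matched the default
    (or, if the default thresholds are not on the grid, the first
    combination).
    """
    if not microbe_levels or not human_levels:
        raise ValueError("coverage level lists must be nonempty")
    hsps_best = homology.best_human_hit(hsps)
    result = SensitivityResult(tuple(microbe_levels), tuple(human_levels))
    for m in microbe_levels:
        for h in human_levels:
            p = params.with_coverages(m, h)
            full_calls, split_calls = run_calls(hsps_best, cluster_map, features, p)
            result.tallies[(m, h)] = tally(full_calls, split_calls, counting_unit)

    ref_combo = (params.microbe_cov_min, params.human_cov_min)
    if ref_combo not in result.tallies:
        ref_combo = (microbe_levels[0], human_levels[0])
    ref_cat = {t.human_id: t.category for t in result.tallies[ref_combo]}
    proteins = sorted({t.human_id for ts in result.tallies.values() for t in ts})
    rows = []
    for prot in proteins:
        n_detected = 0
        n_same = 0
        for combo, tallies in result.tallies.items():
            cat = next((t.category for t in tallies if t.human_id == prot), "none")
            if cat != "none":
                n_detected += 1
            if cat == ref_cat.get(prot, "none"):
                n_same += 1
        rows.append((prot, n_detected, n_same, ref_cat.get(prot, "none")))
    result.consensus = pd.DataFrame(
        rows, columns=["human_id", "n_detected", "n_same_as_default", "default_category"]
    )
    return result


def assign_xenobiotic_class(
    family_description: str,
    class_table: tuple[tuple[str, str], ...] = DEFAULT_CLASS_TABLE,
) -> str | None:
    """First class whose regex matches the description string; None if no
    match."""
    for key, pattern in class_table:
        if re.search(pattern, family_description):
            return key
    return None


def presence_matrix(
    full_calls: list[FullLengthCall],
    taxonomy: list[TaxonomyRecord],
    class_of_protein: dict[str, str | None],
    class_table: tuple[tuple[str, str], ...] = DEFAULT_CLASS_TABLE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clade presence matrices for full-length calls.

    Returns (species_matrix, family_matrix), both indexed by bacterial
    family (rows, with the phylum as a separate column prepended) with one
    column per xenobiotic class: (a) distinct species with >= 1 full-length
    call in the class; (b) distinct microbial protein families.
    """
    tax_by_genome = {t.genome_id: t for t in taxonomy}
    class_keys = [key for key, _ in class_table]
    species_sets: dict[tuple[str, str], set[str]] = {}
    family_sets: dict[tuple[str, str], set[str]] = {}
    bact_families: dict[str, str] = {}
    missing: set[str] = set()
    for c in full_calls:
        tax = tax_by_genome.get(c.genome_id)
        if tax is None:
            if c.genome_id not in missing:
                logger.warning("genome %s missing taxonomy; excluded from presence matrix", c.genome_id)
                missing.add(c.genome_id)
            continue
        cls = class_of_protein.get(c.human_id)
        if cls is None:
            continue
        bact_families[tax.family] = tax.phylum
        species_sets.setdefault((tax.family, cls), set()).add(tax.species_id)
        family_sets.setdefault((tax.family, cls), set()).add(c.family_id)

    rows_s, rows_f = [], []
    for fam in sorted(bact_families):
        rows_s.append(
            [bact_families[fam], fam]
            + [len(species_sets.get((fam, k), ())) for k in class_keys]
        )
        rows_f.append(
            [bact_families[fam], fam]
            + [len(family_sets.get((fam, k), ())) for k in class_keys]
        )
    cols = ["phylum", "bacterial_family"] + class_keys
    return pd.DataFrame(rows_s, columns=cols), pd.DataFrame(rows_f, columns=cols)
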