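"""Deterministic synthetic input bundle with planted ground truth.

The generator emulates the structure of a host-proteome vs gut-microbial
catalog search at toy scale: host proteins (FASTA), microbial genomes with
ranked CDS features (GFF3), a gene-to-family cluster map, genome taxonomy,
a species tree, a toy ontology with annotations, and a drug-reaction
table.  Alignments are synthesized analytically from planted domain
correspondences, so coverage fractions are exact by construction and no
aligner is needed.

Planted cases:

* full-length homologs — one microbial family covering >= 72% of the host
  protein and >= 80% of itself, in 1-3 genomes;
* split homologs — two adjacent microbial families covering ~40-48% of
  the host protein each (union >= 79%), 1-3 feature ranks apart on one
  contig and strand;
* a decoy panel in which each decoy violates exactly one predicate of the
  pipeline: pair 4 ranks apart, pair on opposite strands, pair on
  different contigs, pair with 65% joint coverage, single gene with 66%
  microbe-side coverage, microbial protein of length 79, contaminant at
  90% identity, and a pair with one individually-covering member (which
  must surface as a full-length call, not a split call).

True-homolog identities are drawn uniformly from 25-45%; the contaminant
sits at 90%, far above the contamination cutoff the pipeline fits
(guaranteed: a single 90% outlier among <= 45% values keeps the
mean + 3 SD cutoff between ~58% and ~85%).

All randomness comes from one numpy Generator keyed by the seed; the same
config and seed produce a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .homology import FullLengthCall
from .split import Neighborhood

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DECOY_TYPES = (
    "gap4",
    "opposite_strand",
    "different_contig",
    "low_joint_coverage",
    "low_microbe_coverage",
    "short_microbe",
    "contaminant",
    "individual_member",
)

_TAXA = [
    ("Firmicutes_A", "Lachnospiraceae"),
    ("Proteobacteria", "Enterobacteriaceae"),
    ("Bacteroidota", "Bacteroidaceae"),
]

#: xenobiotic family description strings cycled over planted full targets
_DESCRIPTIONS = [
    "Short-chain dehydrogenases/reductases (SDR) family",
    "Aldo/keto reductase family",
    "Cytochrome P450 family",
    "GST superfamily",
    "Type-B carboxylesterase/lipase family",
    "'GDXG' lipolytic enzyme family",
    "UDP-glycosyltransferase family",
    "Arylamine N-acetyltransferase family",
    "Flavin monoamine oxidase family",
    "Quinone oxidoreductase subfamily",
]

_OBO_TEXT = """format-version: 1.2
ontology: toy-go

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0006805
name: xenobiotic metabolic process
namespace: biological_process
is_a: GO:0008152 ! metabolic process

[Term]
id: GO:0006139
name: nucleobase-containing compound metabolic process
namespace: biological_process
is_a: GO:0008152 ! metabolic process

[Term]
id: GO:0009117
name: nucleotide metabolic process
namespace: biological_process
is_a: GO:0006139 ! nucleobase-containing compound metabolic process

[Term]
id: GO:0006637
name: acyl-CoA metabolic process
namespace: biological_process
is_a: GO:0006139 ! nucleobase-containing compound metabolic process

[Term]
id: GO:0015936
name: coenzyme A metabolic process
namespace: biological_process
is_a: GO:0006637 ! acyl-CoA metabolic process

[Term]
id: GO:0046444
name: FMN metabolic process
namespace: biological_process
is_a: GO:0006139 ! nucleobase-containing compound metabolic process

[Term]
id: GO:0046443
name: FAD metabolic process
namespace: biological_process
is_a: GO:0006139 ! nucleobase-containing compound metabolic process

[Term]
id: GO:0019362
name: pyridine nucleotide metabolic process
namespace: biological_process
is_a: GO:0006139 ! nucleobase-containing compound metabolic process

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0016491
name: oxidoreductase activity
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0016616
name: oxidoreductase activity, acting on the CH-OH group of donors
namespace: molecular_function
is_a: GO:0016491 ! oxidoreductase activity
"""


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 42
    n_planted_full: int = 20
    n_planted_split: int = 20
    n_genomes: int = 6
    n_background_hosts: int = 10
    n_decoys_per_type: int = 1
    pident_range: tuple[float, float] = (25.0, 45.0)
    contaminant_pident: float = 90.0

    def __post_init__(self) -> None:
        for name in ("n_planted_full", "n_planted_split", "n_background_hosts",
                     "n_decoys_per_type"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genomes < 2:
            raise ValueError("need >= 2 genomes")
        if self.contaminant_pident <= self.pident_range[1]:
            raise ValueError("contaminant pident must exceed the planted-truth maximum")


@dataclass
class FixtureBundle:
    """Paths of the generated bundle plus the planted-truth table."""

    root: Path
    alignments: Path
    gff3: dict[str, Path]
    cluster_map: Path
    taxonomy: Path
    host_fasta: Path
    tree: Path
    obo: Path
    go_annotations: Path
    protein_info: Path
    reactions: Path
    chemicals: Path
    controller_map: Path
    truth: Path
    truth_df: pd.DataFrame = field(repr=False)


class _Builder:
    """Accumulates genes, alignments and truth rows during generation."""

    def __init__(self, config: FixtureConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.genomes = [f"G{i+1:03d}" for i in range(config.n_genomes)]
        # per (genome, contig): ordered list of (gene_id, cds_len)
        self.layout: dict[tuple[str, str], list[tuple[str, int]]] = {}
        self.cluster: dict[str, str] = {}
        self.hsps: list[tuple] = []
        self.truth_rows: list[tuple[str, str, str, str]] = []
        self.host_lengths: dict[str, int] = {}
        self.opposite_strand_genes: set[str] = set()
        self._gene_n = 0
        self._filler_n = 0

    def next_gene(self, genome: str) -> str:
        self._gene_n += 1
        return f"{genome}_{self._gene_n:05d}"

    def add_gene(self, genome: str, family: str, qlen: int, contig: str = "c1") -> str:
        gene = self.next_gene(genome)
        self.cluster[gene] = family
        self.layout.setdefault((genome, contig), []).append((gene, qlen * 3))
        return gene

    def add_fillers(self, genome: str, n: int, contig: str = "c1") -> None:
        for _ in range(n):
            gene = self.next_gene(genome)
            self._filler_n += 1
            self.cluster[gene] = f"FILLER{self._filler_n:05d}"
            self.layout.setdefault((genome, contig), []).append((gene, 300))

    def add_hsp(self, family: str, human: str, qstart: int, qend: int,
                sstart: int, send: int, pident: float, qlen: int, slen: int) -> None:
        bitscore = round(float(self.rng.uniform(100.0, 400.0)), 1)
        evalue = 10.0 ** -float(self.rng.integers(20, 80))
        aln_len = max(qend - qstart + 1, send - sstart + 1)
        mismatch = int(aln_len * (1 - pident / 100.0))
        self.hsps.append(
            (family, human, round(pident, 1), aln_len, mismatch, 0,
             qstart, qend, sstart, send, evalue, bitscore, qlen, slen)
        )

    def pident(self) -> float:
        lo, hi = self.config.pident_range
        return float(self.rng.uniform(lo, hi))

    def host(self, name: str, length: int) -> str:
        self.host_lengths[name] = length
        return name


def _plant_full(b: _Builder) -> None:
    rng = b.rng
    for i in range(b.config.n_planted_full):
        human = b.host(f"HF{i+1:03d}", int(rng.integers(300, 601)))
        slen = b.host_lengths[human]
        family = f"FF{i+1:03d}"
        hcov = float(rng.uniform(0.75, 0.95))
        send = int(hcov * slen)
        alen = send
        qc = float(rng.uniform(0.80, 0.95))
        qlen = max(80, int(alen / qc))
        n_members = 1 + i % 3
        member_genomes = sorted(
            rng.choice(b.genomes, size=min(n_members, len(b.genomes)), replace=False)
        )
        for genome in member_genomes:
            b.add_gene(genome, family, qlen)
            b.truth_rows.append((human, genome, "full", "planted:full"))
        b.add_hsp(family, human, 1, alen, 1, send, b.pident(), qlen, slen)


def _split_pair_geometry(b: _Builder, slen: int) -> tuple[tuple[int, int], tuple[int, int]]:
    f1 = float(b.rng.uniform(0.40, 0.48))
    f2 = float(b.rng.uniform(0.40, 0.48))
    a = (1, max(80, int(f1 * slen)))
    blen = max(80, int(f2 * slen))
    bint = (slen - blen + 1, slen)
    return a, bint


def _pair_qlen(b: _Builder, alen: int) -> int:
    qc = float(b.rng.uniform(0.80, 0.95))
    return max(80, int(alen / qc))


def _plant_split(b: _Builder) -> None:
    rng = b.rng
    for j in range(b.config.n_planted_split):
        human = b.host(f"HS{j+1:03d}", int(rng.integers(400, 601)))
        slen = b.host_lengths[human]
        fam_a, fam_b = f"SA{j+1:03d}", f"SB{j+1:03d}"
        ia, ib = _split_pair_geometry(b, slen)
        genome = b.genomes[int(rng.integers(len(b.genomes)))]
        gap = 1 + j % 3
        qlen_a = _pair_qlen(b, ia[1] - ia[0] + 1)
        qlen_b = _pair_qlen(b, ib[1] - ib[0] + 1)
        b.add_gene(genome, fam_a, qlen_a)
        b.add_fillers(genome, gap - 1)
        b.add_gene(genome, fam_b, qlen_b)
        b.add_hsp(fam_a, human, 1, ia[1] - ia[0] + 1, ia[0], ia[1], b.pident(), qlen_a, slen)
        b.add_hsp(fam_b, human, 1, ib[1] - ib[0] + 1, ib[0], ib[1], b.pident(), qlen_b, slen)
        b.truth_rows.append((human, genome, "split", "planted:split"))


def _plant_decoys(b: _Builder) -> None:
    rng = b.rng
    idx = 0
    for rep in range(b.config.n_decoys_per_type):
        for kind in DECOY_TYPES:
            idx += 1
            human = b.host(f"HD{idx:03d}", int(rng.integers(400, 601)))
            slen = b.host_lengths[human]
            genome = b.genomes[idx % len(b.genomes)]
            tag = f"decoy:{kind}"

            if kind in ("gap4", "opposite_strand", "different_contig"):
                fam_a, fam_b = f"DA{idx:03d}", f"DB{idx:03d}"
                ia, ib = _split_pair_geometry(b, slen)
                qa, qb = _pair_qlen(b, ia[1] - ia[0] + 1), _pair_qlen(b, ib[1] - ib[0] + 1)
                if kind == "gap4":
                    b.add_gene(genome, fam_a, qa)
                    b.add_fillers(genome, 3)
                    b.add_gene(genome, fam_b, qb)
                elif kind == "different_contig":
                    b.add_gene(genome, fam_a, qa, contig="c1")
                    b.add_gene(genome, fam_b, qb, contig="c2")
                else:  # opposite_strand: flag resolved at layout time
                    b.add_gene(genome, fam_a, qa)
                    gene_b = b.add_gene(genome, fam_b, qb)
                    b.opposite_strand_genes.add(gene_b)
                b.add_hsp(fam_a, human, 1, ia[1] - ia[0] + 1, ia[0], ia[1], b.pident(), qa, slen)
                b.add_hsp(fam_b, human, 1, ib[1] - ib[0] + 1, ib[0], ib[1], b.pident(), qb, slen)
                b.truth_rows.append((human, genome, "none", tag))

            elif kind == "low_joint_coverage":
                fam_a, fam_b = f"DA{idx:03d}", f"DB{idx:03d}"
                ia = (1, int(0.30 * slen))
                ib = (slen - int(0.35 * slen) + 1, slen)
                qa, qb = _pair_qlen(b, ia[1]), _pair_qlen(b, ib[1] - ib[0] + 1)
                b.add_gene(genome, fam_a, qa)
                b.add_gene(genome, fam_b, qb)
                b.add_hsp(fam_a, human, 1, ia[1], ia[0], ia[1], b.pident(), qa, slen)
                b.add_hsp(fam_b, human, 1, ib[1] - ib[0] + 1, ib[0], ib[1], b.pident(), qb, slen)
                b.truth_rows.append((human, genome, "none", tag))

            elif kind == "low_microbe_coverage":
                fam = f"DA{idx:03d}"
                send = int(0.75 * slen)
                qlen = 300
                qend = 198  # 198/300 = 0.66 < 0.67
                b.add_gene(genome, fam, qlen)
                b.add_hsp(fam, human, 1, qend, 1, send, b.pident(), qlen, slen)
                b.truth_rows.append((human, genome, "none", tag))

            elif kind == "short_microbe":
                fam = f"DA{idx:03d}"
                qlen = 79
                send = int(0.75 * slen)
                b.add_gene(genome, fam, qlen)
                b.add_hsp(fam, human, 1, qlen, 1, send, b.pident(), qlen, slen)
                b.truth_rows.append((human, genome, "none", tag))

            elif kind == "contaminant":
                fam = f"DA{idx:03d}"
                send = int(0.80 * slen)
                qlen = max(80, int(send / 0.90))
                b.add_gene(genome, fam, qlen)
                b.add_hsp(fam, human, 1, send, 1, send,
                          b.config.contaminant_pident, qlen, slen)
                b.truth_rows.append((human, genome, "none", tag))

            else:  # individual_member
                fam_a, fam_b = f"DA{idx:03d}", f"DB{idx:03d}"
                start_a = int(0.25 * slen) + 1
                ia = (start_a, slen)                  # covers ~75% -> full call
                ib = (1, int(0.30 * slen))            # covers 30%
                qa = _pair_qlen(b, ia[1] - ia[0] + 1)
                qb = _pair_qlen(b, ib[1])
                b.add_gene(genome, fam_a, qa)
                b.add_gene(genome, fam_b, qb)
                b.add_hsp(fam_a, human, 1, ia[1] - ia[0] + 1, ia[0], ia[1], b.pident(), qa, slen)
                b.add_hsp(fam_b, human, 1, ib[1], ib[0], ib[1], b.pident(), qb, slen)
                b.truth_rows.append((human, genome, "full", tag))


def _write_fasta(b: _Builder, path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(b.host_lengths):
            seq = "".join(b.rng.choice(AMINO_ACIDS, size=b.host_lengths[name]))
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")


def _write_gff3(b: _Builder, outdir: Path) -> dict[str, Path]:
    opposite = getattr(b, "opposite_strand_genes", set())
    paths = {}
    for genome in b.genomes:
        feats = []
        for contig in ("c1", "c2"):
            entries = b.layout.get((genome, contig), [])
            pos = 1
            for rank, (gene, cds_len) in enumerate(entries, start=1):
                gap = int(b.rng.integers(50, 500))
                start = pos + gap
                end = start + cds_len - 1
                strand = "-" if gene in opposite else "+"
                feats.append(cio.GenomeFeature(
                    genome_id=genome, contig_id=f"{genome}_{contig}",
                    feature_rank=rank, strand=strand, start=start, end=end,
                    gene_id=gene,
                ))
                pos = end
        path = outdir / f"{genome}.gff3"
        cio.write_gff3(feats, path)
        paths[genome] = path
    return paths


def _write_tree(b: _Builder, species: list[str], path: Path) -> None:
    # caterpillar topology with random branch lengths
    def bl() -> str:
        return f"{float(b.rng.uniform(0.1, 1.0)):.4f}"

    newick = f"{species[0]}:{bl()}"
    for sp in species[1:]:
        newick = f"({newick},{sp}:{bl()}):{bl()}"
    path.write_text(newick + ";\n")


def _write_annotations(b: _Builder, outdir: Path) -> tuple[Path, Path]:
    """Toy GO annotations and protein info table.

    Full-planted hosts: xenobiotic BP term; every third one IEA-only; some
    oxidoreductase MF; half mitochondrial CC.  Split-planted hosts:
    nucleotide metabolism, with one excluded-subtree case.
    """
    go_rows = []
    info_rows = []
    fulls = sorted(h for h in b.host_lengths if h.startswith("HF"))
    splits = sorted(h for h in b.host_lengths if h.startswith("HS"))
    others = sorted(h for h in b.host_lengths if not (h.startswith("HF") or h.startswith("HS")))

    for k, h in enumerate(fulls):
        ev = "IEA" if k % 3 == 0 else "IDA"
        go_rows.append((h, "GO:0006805", ev, "biological_process"))
        if k % 2 == 0:
            go_rows.append((h, "GO:0016616", "IDA", "molecular_function"))
        cc = "Mitochondrion inner membrane" if k % 2 == 0 else "Cytoplasm"
        info_rows.append((h, _DESCRIPTIONS[k % len(_DESCRIPTIONS)], cc))
    for k, h in enumerate(splits):
        go_rows.append((h, "GO:0009117", "IMP", "biological_process"))
        if k == 0:
            # annotated inside an excluded subtree as well
            go_rows.append((h, "GO:0015936", "IDA", "biological_process"))
        info_rows.append((h, "Multifunctional biosynthetic protein family", "Cytoplasm"))
    for h in others:
        go_rows.append((h, "GO:0008152", "IEA", "biological_process"))
        info_rows.append((h, "Uncharacterized protein family", ""))

    go_path = outdir / "go_annotations.tsv"
    pd.DataFrame(go_rows, columns=["protein", "term", "evidence", "namespace"]).to_csv(
        go_path, sep="\t", index=False
    )
    info_path = outdir / "protein_info.tsv"
    pd.DataFrame(info_rows, columns=["protein", "description", "cc"]).to_csv(
        info_path, sep="\t", index=False
    )
    return go_path, info_path


def _write_pharm(b: _Builder, outdir: Path) -> tuple[Path, Path, Path]:
    splits = sorted(h for h in b.host_lengths if h.startswith("HS"))
    fulls = sorted(h for h in b.host_lengths if h.startswith("HF"))
    controllers = []
    reactions = []
    chems = [
        ("fluorouracil", "Drug"), ("mercaptopurine", "Drug"),
        ("allopurinol", "Drug"), ("capecitabine", "Prodrug"),
        ("5-FUMP", "Metabolite"), ("homocysteine", "Biological Intermediate"),
        ("methionine", "Biological Intermediate"),
    ]
    # split-dominant controllers metabolizing drugs
    if splits:
        controllers.append(("CTRL_DPD", splits[0]))
        reactions += [
            ("pw1", "fluorouracil", "dihydrofluorouracil", "CTRL_DPD", "Biochemical"),
            ("pw1", "capecitabine", "fluorouracil", "CTRL_DPD", "Biochemical"),
        ]
    if len(splits) > 1:
        controllers.append(("CTRL_XDH", splits[1]))
        reactions += [
            ("pw2", "mercaptopurine", "thiouric acid", "CTRL_XDH", "Biochemical"),
            ("pw2", "allopurinol", "oxypurinol", "CTRL_XDH", "Biochemical"),
            # duplicate drug via a second reaction: listed once downstream
            ("pw3", "allopurinol", "allopurinol riboside", "CTRL_XDH", "Biochemical"),
        ]
    if fulls:
        controllers.append(("CTRL_FULL", fulls[0]))
        reactions.append(("pw4", "5-FUMP", "FdUMP", "CTRL_FULL", "Biochemical"))
    # rows the filter must drop
    reactions += [
        ("pw5", "fluorouracil", "fluorouracil", "CTRL_DPD", "Biochemical"),   # reactant == product
        ("pw5", "mercaptopurine", "mercaptopurine cell", "CTRL_XDH", "Transport"),
        ("pw5", "homocysteine", "methionine", "CTRL_FULL", "Biochemical"),    # intermediates only
        ("pw5", "fluorouracil", "dihydrofluorouracil", "", "Biochemical"),    # unknown controller
    ]
    rx_path = outdir / "reactions.tsv"
    pd.DataFrame(reactions, columns=["pathway_id", "reactant", "product",
                                     "controller", "reaction_type"]).to_csv(
        rx_path, sep="\t", index=False
    )
    chem_path = outdir / "chemicals.tsv"
    pd.DataFrame(chems, columns=["chemical", "chem_class"]).to_csv(
        chem_path, sep="\t", index=False
    )
    ctrl_path = outdir / "controller_map.tsv"
    pd.DataFrame(controllers, columns=["controller", "protein"]).to_csv(
        ctrl_path, sep="\t", index=False
    )
    return rx_path, chem_path, ctrl_path


def generate_fixture(config: FixtureConfig, outdir: str | Path) -> FixtureBundle:
    """Write the complete input bundle under `outdir` and return its paths
    plus the planted-truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gff_dir = outdir / "genomes"
    gff_dir.mkdir(exist_ok=True)

    b = _Builder(config)
    _plant_full(b)
    _plant_split(b)
    _plant_decoys(b)
    for k in range(config.n_background_hosts):
        b.host(f"HB{k+1:03d}", int(b.rng.integers(200, 500)))

    aln_path = outdir / "alignments.tsv"
    pd.DataFrame(b.hsps, columns=cio.ALIGNMENT_COLUMNS).to_csv(
        aln_path, sep="\t", header=False, index=False
    )
    cluster_path = outdir / "cluster_map.tsv"
    cio.write_cluster_map(b.cluster, cluster_path)

    species = [f"SP{i+1:03d}" for i in range(config.n_genomes)]
    tax_records = []
    for i, genome in enumerate(b.genomes):
        phylum, family = _TAXA[i % len(_TAXA)]
        lineage = (f"d__Bacteria;p__{phylum};c__C{i};o__O{i};f__{family};"
                   f"g__Genus{i};s__Species {i}")
        tax_records.append(cio.TaxonomyRecord(
            genome_id=genome, species_id=species[i], lineage=cio.parse_lineage(lineage)
        ))
    tax_path = outdir / "taxonomy.tsv"
    cio.write_taxonomy(tax_records, tax_path)

    gff_paths = _write_gff3(b, gff_dir)
    fasta_path = outdir / "host_proteome.fasta"
    _write_fasta(b, fasta_path)
    tree_path = outdir / "species_tree.nwk"
    _write_tree(b, species, tree_path)
    obo_path = outdir / "ontology.obo"
    obo_path.write_text(_OBO_TEXT)
    go_path, info_path = _write_annotations(b, outdir)
    rx_path, chem_path, ctrl_path = _write_pharm(b, outdir)

    truth_df = pd.DataFrame(
        b.truth_rows, columns=["human_id", "genome_id", "expected_call", "reason"]
    ).sort_values(["human_id", "genome_id"], kind="mergesort").reset_index(drop=True)
    truth_path = outdir / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)

    return FixtureBundle(
        root=outdir, alignments=aln_path, gff3=gff_paths, cluster_map=cluster_path,
        taxonomy=tax_path, host_fasta=fasta_path, tree=tree_path, obo=obo_path,
        go_annotations=go_path, protein_info=info_path, reactions=rx_path,
        chemicals=chem_path, controller_map=ctrl_path, truth=truth_path,
        truth_df=truth_df,
    )


def score_recovery(
    full_calls: list[FullLengthCall],
    split_calls: list[Neighborhood],
    truth: pd.DataFrame,
) -> dict[str, dict[str, float | None]]:
    """Exact set comparison of calls against planted truth at
    (human_id, genome_id, type) granularity.

    Returns {"full": {...}, "split": {...}} with precision (None when no
    calls were made), recall, and the set sizes.
    """
    predicted = {
        "full": {(c.human_id, c.genome_id) for c in full_calls},
        "split": {(nb.human_id, nb.genome_id) for nb in split_calls},
    }
    out: dict[str, dict[str, float | None]] = {}
    for call_type in ("full", "split"):
        expected = {
            (r.human_id, r.genome_id)
            for r in truth.itertuples(index=False)
            if r.expected_call == call_type
        }
        pred = predicted[call_type]
        tp = len(pred & expected)
        out[call_type] = {
            "precision": tp / len(pred) if pred else None,
            "recall": tp / len(expected) if expected else None,
            "n_predicted": len(pred),
            "n_expected": len(expected),
        }
    return out
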