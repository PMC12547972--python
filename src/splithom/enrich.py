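"""GO-based enrichment of host proteins with homologs.

Enrichment compares the proteins carrying (full-length or split) gut
microbial homologs against the whole host proteome using Fisher's exact
test per biological-process term, with Benjamini-Hochberg correction.
Annotations are first propagated up the is_a/part_of closure of the
ontology.  Evidence-code subsets ("noIEA" drops electronically inferred
annotations; "expOnly" keeps direct experimental codes) let the analysis
be repeated on progressively more trusted annotation sets.  Mitochondrial
localization is tested separately from cellular-component strings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("splithom")

EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
EVIDENCE_MODES = ("all", "noIEA", "expOnly")
MITO_REGEX = re.compile(r"[Mm]itochondr")

#: Annotation map: protein -> set of (GO term, evidence code).
Annotations = dict[str, set[tuple[str, str]]]


@dataclass
class OntologyDAG:
    """Ontology graph with edges child -> parent (is_a / part_of only)."""

    graph: nx.DiGraph
    namespace: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_obo(cls, path, relations: tuple[str, ...] = ("is_a", "part_of")) -> "OntologyDAG":
        multigraph = obonet.read_obo(path)
        g = nx.DiGraph()
        g.add_nodes_from(multigraph.nodes)
        for child, parent, key in multigraph.edges(keys=True):
            if key in relations:
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"ontology {path} contains a cycle")
        ns = {
            term: data.get("namespace", "")
            for term, data in multigraph.nodes(data=True)
        }
        return cls(graph=g, namespace=ns)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from `term` (excluding itself)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All terms below `term` (excluding itself)."""
        return nx.ancestors(self.graph, term)


def annotations_from_table(df: pd.DataFrame) -> Annotations:
    """Convert a protein/term/evidence/namespace table to the in-memory
    annotation map."""
    out: Annotations = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein, set()).add((row.term, row.evidence))
    return out


def propagate_annotations(dag: OntologyDAG, annotations: Annotations) -> Annotations:
    """Close each protein's annotation set over the DAG: a protein
    annotated to a term is annotated to every ancestor, carrying the same
    evidence code.  Terms absent from the DAG are kept unpropagated with a
    warning.  Idempotent."""
    missing_warned: set[str] = set()
    out: Annotations = {}
    for protein, terms in annotations.items():
        closed = set(terms)
        for term, evidence in terms:
            if term not in dag:
                if term not in missing_warned:
                    logger.warning("term %s absent from ontology; kept unpropagated", term)
                    missing_warned.add(term)
                continue
            closed.update((anc, evidence) for anc in dag.ancestors(term))
        out[protein] = closed
    return out


def filter_evidence(annotations: Annotations, mode: str) -> Annotations:
    """Restrict annotations by evidence code: "all" (identity), "noIEA"
    (drop electronic annotations), or "expOnly" (experimental codes
    only)."""
    if mode not in EVIDENCE_MODES:
        raise ValueError(f"unknown evidence mode {mode!r}; expected one of {EVIDENCE_MODES}")
    if mode == "all":
        return {p: set(terms) for p, terms in annotations.items()}
    if mode == "noIEA":
        keep = lambda ev: ev != "IEA"
    else:
        keep = lambda ev: ev in EXPERIMENTAL_CODES
    return {
        p: {(t, ev) for t, ev in terms if keep(ev)}
        for p, terms in annotations.items()
    }


def _terms_of(annotations: Annotations, protein: str) -> set[str]:
    return {t for t, _ in annotations.get(protein, ())}


def fisher_term_enrichment(
    study_set: set[str],
    background_set: set[str],
    closed_annotations: Annotations,
    dag: OntologyDAG | None = None,
    namespace: str = "biological_process",
) -> pd.DataFrame:
    """Per-term Fisher's exact test of study membership vs term
    annotation.

    Terms tested are all terms (of the requested namespace, when a DAG is
    supplied) with at least one study annotation; BH correction is applied
    across that tested family.  The odds ratio is the conditional MLE.
    """
    if not study_set:
        raise ValueError("study set is empty")
    if not study_set <= background_set:
        raise ValueError("study set must be a subset of the background set")

    term_proteins: dict[str, set[str]] = {}
    for protein in background_set:
        for term in _terms_of(closed_annotations, protein):
            if dag is not None and dag.namespace.get(term, "") != namespace:
                continue
            term_proteins.setdefault(term, set()).add(protein)

    n_study = len(study_set)
    n_rest = len(background_set) - n_study
    rows = []
    for term in sorted(term_proteins):
        with_term = term_proteins[term]
        a = len(with_term & study_set)
        if a == 0:
            continue
        c = len(with_term) - a
        table = [[a, n_study - a], [c, n_rest - c]]
        p = fisher_exact(table, alternative="two-sided").pvalue
        orr = _odds_ratio(table).statistic
        rows.append((term, a, len(with_term), orr, p))
    df = pd.DataFrame(rows, columns=["term", "study_count", "background_count", "odds_ratio", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def mito_odds_ratio(
    study_set: set[str],
    background_set: set[str],
    cc_strings: dict[str, str],
) -> tuple[float, tuple[float, float], float]:
    """Association between study membership and mitochondrial
    localization (any cellular-component string matching the
    mitochondrial regex).  Returns (conditional-MLE odds ratio, exact 95%
    CI, two-sided Fisher p)."""
    flagged = {p for p in background_set if MITO_REGEX.search(cc_strings.get(p, ""))}
    a = len(study_set & flagged)
    b = len(study_set) - a
    c = len(flagged - study_set)
    d = len(background_set) - len(study_set) - c
    table = [[a, b], [c, d]]
    p = fisher_exact(table, alternative="two-sided").pvalue
    res = _odds_ratio(table)
    ci = res.confidence_interval(0.95)
    return res.statistic, (ci.low, ci.high), p


def build_go_gene_set(
    dag: OntologyDAG,
    annotations: Annotations,
    root_term: str,
    excluded_subtrees: tuple[str, ...] = (),
) -> set[str]:
    """Proteins annotated to `root_term` or any term below it, minus
    proteins annotated to any excluded term or its descendants.

    Direct (unpropagated) annotations suffice: annotation anywhere in the
    subtree implies membership.
    """
    if root_term not in dag:
        raise KeyError(f"root term {root_term} not in ontology")
    include = {root_term} | dag.descendants(root_term)
    exclude: set[str] = set()
    for term in excluded_subtrees:
        if term not in dag:
            logger.warning("excluded term %s not in ontology; ignored", term)
            continue
        exclude |= {term} | dag.descendants(term)
    out = set()
    for protein, terms in annotations.items():
        direct = {t for t, _ in terms}
        if direct & include and not direct & exclude:
            out.add(protein)
    return out
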