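"""Cross-reference of homolog tallies with a drug-reaction table.

A PharmGKB-style pathway reaction table is filtered to reactions plausibly
relevant to drug metabolism — reactant and product differ, the reaction is
not transport, the controlling enzyme is known, and at least one side is a
chemical of interest (Drug / Drug Class / Prodrug / Metabolite; endogenous
"Biological Intermediate" chemicals are excluded).  Controllers are then
mapped to host proteins and joined with the homolog tallies to report,
per drug-metabolizing enzyme in the requested category (e.g. the
split-dominant proteins), the distinct drugs it touches.
"""

from __future__ import annotations

import logging

import pandas as pd

from .tally import HomologTally

logger = logging.getLogger("splithom")

DEFAULT_INTEREST_CLASSES = frozenset({"Drug", "Drug Class", "Prodrug", "Metabolite"})

REACTION_COLUMNS = ["pathway_id", "reactant", "product", "controller", "reaction_type"]


def read_reactions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reaction table missing columns {sorted(missing)}")
    return df


def read_chemical_classes(path) -> dict[str, set[str]]:
    """chemical -> set of chemical classes (one class per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, names=["chemical", "chem_class"], header=0)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.chemical, set()).add(row.chem_class)
    return out


def read_controller_map(path) -> dict[str, str]:
    """controller id -> host protein accession."""
    df = pd.read_csv(path, sep="\t", dtype=str, names=["controller", "protein"], header=0)
    return dict(zip(df["controller"], df["protein"]))


def chemicals_of_interest(
    chemical_classes: dict[str, set[str]],
    interest_classes: frozenset[str] = DEFAULT_INTEREST_CLASSES,
) -> set[str]:
    return {
        chem for chem, classes in chemical_classes.items()
        if classes & interest_classes
    }


def filter_reactions(
    reactions: pd.DataFrame,
    chemical_classes: dict[str, set[str]],
    interest_classes: frozenset[str] = DEFAULT_INTEREST_CLASSES,
) -> pd.DataFrame:
    """Apply the four reaction predicates conjunctively (order
    independent): reactant != product; type != Transport; controller
    known; reactant or product is a chemical of interest."""
    interest = chemicals_of_interest(chemical_classes, interest_classes)
    known = reactions["controller"].str.len().gt(0) & ~reactions["controller"].isin(["unknown", "Unknown"])
    mask = (
        (reactions["reactant"] != reactions["product"])
        & (reactions["reaction_type"] != "Transport")
        & known
        & (reactions["reactant"].isin(interest) | reactions["product"].isin(interest))
    )
    return reactions[mask].reset_index(drop=True)


def xref_drug_enzymes(
    reactions: pd.DataFrame,
    tallies: list[HomologTally],
    controller_map: dict[str, str],
    chemical_classes: dict[str, set[str]],
    category_filter: str = "split_dominant",
    interest_classes: frozenset[str] = DEFAULT_INTEREST_CLASSES,
) -> pd.DataFrame:
    """Join filtered reactions with homolog tallies.

    Returns one row per controller whose mapped host protein falls in
    `category_filter`, with its homolog counts and the sorted distinct
    chemicals of interest it touches.
    """
    interest = chemicals_of_interest(chemical_classes, interest_classes)
    tally_by_protein = {t.human_id: t for t in tallies}
    drugs: dict[str, set[str]] = {}
    for row in reactions.itertuples(index=False):
        touched = {c for c in (row.reactant, row.product) if c in interest}
        drugs.setdefault(row.controller, set()).update(touched)

    rows = []
    for controller in sorted(drugs):
        protein = controller_map.get(controller)
        if protein is None:
            logger.warning("controller %s has no protein mapping; excluded", controller)
            continue
        t = tally_by_protein.get(protein)
        if t is None:
            logger.warning("controller %s (protein %s) absent from tallies; excluded",
                           controller, protein)
            continue
        if category_filter and t.category != category_filter:
            continue
        rows.append((controller, protein, t.n_full, t.n_split, t.category,
                     ";".join(sorted(drugs[controller]))))
    return pd.DataFrame(
        rows,
        columns=["controller", "protein", "n_full", "n_split", "category", "drugs"],
    )
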