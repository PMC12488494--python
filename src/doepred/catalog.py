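"""Drug catalog unification and direction-of-effect (DOE) labelling.

Drug records arrive from several sources (ChEMBL-like, DrugBank-like, ...)
under different identifier namespaces.  Records are unified into drug
entities with a disjoint-set union over shared (namespace, value) pairs,
mechanism-of-action terms are classed into {activator, inhibitor, other},
per-pair discrepancies are resolved by source priority, and gene-level /
gene-disease-level DOE labels are derived as unions over a gene's drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

DOE_CLASSES = ("activator", "inhibitor", "other")

#: Sources whose mechanism annotations take priority in discrepancy
#: resolution (tier 1); everything else is tier 2.
TIER1_SOURCES = frozenset({"chembl", "drugbank"})

__all__ = [
    "DOE_CLASSES",
    "TIER1_SOURCES",
    "LinkParseError",
    "load_term_map",
    "unify_drugs",
    "classify_mechanism",
    "resolve_discrepancies",
    "build_labels",
]


class LinkParseError(ValueError):
    """A malformed identifier-link row; carries the offending line number."""


def load_term_map(path: str | None = None) -> pd.DataFrame:
    """Load the raw mechanism term -> DOE class map.

    The shipped default map is a reconstruction covering the common
    agonist/antagonist/activator/inhibitor/blocker/PAM/NAM/binding-agent
    term families; pass ``path`` to use a custom TSV with columns
    ``raw_term`` and ``doe``.
    """
    if path is None:
        ref = resources.files("doepred") / "data" / "mechanism_terms.tsv"
        with resources.as_file(ref) as p:
            tm = pd.read_csv(p, sep="\t")
    else:
        tm = pd.read_csv(path, sep="\t")
    if not set(tm.columns) >= {"raw_term", "doe"}:
        raise ValueError("term map needs columns raw_term, doe")
    bad = set(tm["doe"]) - set(DOE_CLASSES)
    if bad:
        raise ValueError(f"unknown DOE classes in term map: {sorted(bad)}")
    tm["raw_term"] = tm["raw_term"].str.strip().str.lower()
    return tm


class _DisjointSet:
    """Union-find with path compression and union by size."""

    def __init__(self) -> None:
        self.parent: dict = {}
        self.size: dict = {}

    def find(self, x):
        parent = self.parent
        if x not in parent:
            parent[x] = x
            self.size[x] = 1
            return x
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def unify_drugs(links: pd.DataFrame) -> pd.Series:
    """Unify drug records into entities via shared identifiers.

    Parameters
    ----------
    links : DataFrame with columns ``record_id``, ``namespace``, ``value``.
        One row per (record, identifier).  Identifier values are
        case-normalized before matching.

    Returns
    -------
    Series mapping record_id -> unified drug_id, where the drug_id is the
    lexicographically smallest record_id of the connected component (two
    records share a drug_id iff they are connected through shared
    (namespace, value) pairs).
    """
    required = {"record_id", "namespace", "value"}
    if not required <= set(links.columns):
        raise LinkParseError(f"link table needs columns {sorted(required)}")
    for i, row in enumerate(links.itertuples(index=False)):
        if (
            pd.isna(row.record_id)
            or pd.isna(row.namespace)
            or pd.isna(row.value)
            or str(row.record_id) == ""
            or str(row.value) == ""
        ):
            raise LinkParseError(f"malformed identifier link at line {i + 2}")

    dsu = _DisjointSet()
    records = links["record_id"].astype(str)
    keys = links["namespace"].astype(str).str.lower() + "\x00" + links["value"].astype(str).str.lower()
    for rec, key in zip(records, keys):
        dsu.union(("r", rec), ("k", key))
    # drug_id = smallest member record_id, for run-to-run reproducibility
    roots = pd.Series({rec: dsu.find(("r", rec)) for rec in records.unique()})
    smallest = roots.index.to_series().groupby(roots.values).min()
    return roots.map(smallest).rename("drug_id")


def classify_mechanism(raw_term: str, term_map: pd.DataFrame | None = None) -> str:
    """Map a raw mechanism-of-action term to a DOE class.

    Unmapped terms fall back to ``"other"`` (and are logged): binding
    agents, mixed agonist/antagonists, replacement therapies and the like
    carry no single direction of effect.
    """
    if term_map is None:
        term_map = load_term_map()
    lut = dict(zip(term_map["raw_term"], term_map["doe"]))
    term = str(raw_term).strip().lower()
    doe = lut.get(term)
    if doe is None:
        logger.info("unmapped mechanism term %r -> other", raw_term)
        return "other"
    return doe


def classify_mechanisms(terms: pd.Series, term_map: pd.DataFrame | None = None) -> pd.Series:
    """Vectorized :func:`classify_mechanism`."""
    if term_map is None:
        term_map = load_term_map()
    lut = dict(zip(term_map["raw_term"], term_map["doe"]))
    out = terms.astype(str).str.strip().str.lower().map(lut)
    n_unmapped = int(out.isna().sum())
    if n_unmapped:
        logger.info("%d unmapped mechanism terms -> other", n_unmapped)
    return out.fillna("other")


def _priority(source: str, doe: str) -> tuple:
    tier = 0 if str(source).lower() in TIER1_SOURCES else 1
    directional = 0 if doe in ("activator", "inhibitor") else 1
    return (tier, directional)


def resolve_discrepancies(assignments: pd.DataFrame) -> pd.Series | None:
    """Resolve multiple mechanism annotations for one drug-gene pair.

    Priority is lexicographic: tier-1 sources (ChEMBL/DrugBank families)
    beat tier-2, then directional classes (activator/inhibitor) beat
    ``other``.  If the surviving annotations still disagree between
    activator and inhibitor, the pair is unresolvable: ``None`` is
    returned and the caller should exclude (and log) it.

    Parameters
    ----------
    assignments : DataFrame with columns ``source``, ``doe`` (plus any
        passthrough columns); one row per annotation of a single pair.
    """
    if len(assignments) == 0:
        raise ValueError("resolve_discrepancies requires at least one assignment")
    ranks = [_priority(s, d) for s, d in zip(assignments["source"], assignments["doe"])]
    best = min(ranks)
    top = assignments.iloc[[i for i, r in enumerate(ranks) if r == best]]
    classes = set(top["doe"])
    if classes >= {"activator", "inhibitor"}:
        return None
    # deterministic representative: order rows by (doe, source) text
    top = top.sort_values(list(top.columns), kind="mergesort")
    return top.iloc[0]


def resolve_all(assignments: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve every (drug_id, gene_id) pair; return (resolved, unresolved).

    ``assignments`` needs columns drug_id, gene_id, source, doe.  Pairs
    whose top-priority annotations conflict between activator and
    inhibitor are excluded and reported in the second frame.
    """
    resolved_rows, unresolved_rows = [], []
    for (drug, gene), grp in assignments.groupby(["drug_id", "gene_id"], sort=True):
        dedup = grp.drop_duplicates(subset=["source", "doe"])
        if dedup["doe"].nunique() == 1:
            row = dedup.sort_values(list(dedup.columns), kind="mergesort").iloc[0]
        else:
            row = resolve_discrepancies(dedup)
        if row is None:
            unresolved_rows.append({"drug_id": drug, "gene_id": gene, "classes": ",".join(sorted(set(dedup["doe"])))})
        else:
            resolved_rows.append(row)
    resolved = pd.DataFrame(resolved_rows).reset_index(drop=True)
    unresolved = pd.DataFrame(unresolved_rows, columns=["drug_id", "gene_id", "classes"])
    if len(unresolved):
        logger.warning("%d drug-gene pairs with unresolvable activator/inhibitor conflicts excluded", len(unresolved))
    return resolved, unresolved


@dataclass
class DOELabels:
    """Gene-level and gene-disease-level multi-label DOE tables."""

    gene: pd.DataFrame  # index gene_id; bool columns is_activator/is_inhibitor/is_other
    gene_disease: pd.DataFrame  # index (gene_id, disease_code); same columns


LABEL_COLUMNS = ["is_activator", "is_inhibitor", "is_other"]


def build_labels(resolved: pd.DataFrame, indications: pd.DataFrame) -> DOELabels:
    """Derive DOE labels from resolved mechanisms and drug indications.

    Gene flags are the union over all drugs targeting the gene; gene-disease
    flags the union over drugs indicated for that disease targeting the
    gene.  Indications referencing unknown drugs are skipped with a warning.
    """
    mech = resolved[["drug_id", "gene_id", "doe"]].drop_duplicates()
    onehot = pd.get_dummies(mech["doe"]).reindex(columns=list(DOE_CLASSES), fill_value=False).astype(bool)
    onehot.columns = LABEL_COLUMNS
    mech = pd.concat([mech[["drug_id", "gene_id"]], onehot], axis=1)

    gene = mech.groupby("gene_id")[LABEL_COLUMNS].any().sort_index()

    known = set(mech["drug_id"])
    ind = indications[["drug_id", "disease_code"]].drop_duplicates()
    unknown = ~ind["drug_id"].isin(known)
    if unknown.any():
        logger.warning("%d indications reference unknown drugs; skipped", int(unknown.sum()))
        ind = ind[~unknown]
    pair = ind.merge(mech, on="drug_id")
    if len(pair):
        gene_disease = pair.groupby(["gene_id", "disease_code"])[LABEL_COLUMNS].any().sort_index()
    else:
        gene_disease = pd.DataFrame(columns=LABEL_COLUMNS, index=pd.MultiIndex.from_arrays([[], []], names=["gene_id", "disease_code"]))
    return DOELabels(gene=gene, gene_disease=gene_disease)
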