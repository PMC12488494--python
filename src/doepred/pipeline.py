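"""End-to-end synthetic-study pipelines.

These glue the generators, feature builders, nested-CV models, and the
evaluation suite into the two studies the package is organized around:

* the **gene-level** study: DOE-specific druggability from tabular
  features plus embeddings, one-vs-rest per DOE class;
* the **gene-disease** study: DOE for gene-disease pairs from the 31
  signed genetic-evidence features, plus the allele-frequency-bin
  support enrichment analysis.

Both are deterministic given the :class:`~doepred.simulate.SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._streams import stream
from .evaluate import macro_micro
from .features import ProteinEmbeddingPCA, assemble_matrix
from .genetics import bin_support_counts, build_feature_matrix
from .models import train_nested
from .simulate import (GENE_LABEL_COLUMNS, SimConfig, generate_gene_disease_labels,
                       generate_gene_universe, generate_genetic_associations)
from .validate import _or_from_table

__all__ = ["GeneLevelResult", "GeneDiseaseResult", "run_gene_level", "run_gene_disease",
           "bin_support_enrichment"]


@dataclass
class GeneLevelResult:
    predictions: pd.DataFrame  # tidy: item, doe, probability, outer_fold
    labels: pd.DataFrame
    per_class: dict
    macro_auroc: float
    micro_auroc: float
    manifest: dict
    design: pd.DataFrame
    models: dict


def run_gene_level(cfg: SimConfig, permute_labels: bool = False,
                   n_estimators: int = 100) -> GeneLevelResult:
    """Generate a gene universe, assemble the design, train, evaluate.

    With ``permute_labels`` the label rows are shuffled jointly before
    training (the multi-label structure is preserved but decoupled from
    the features), giving the null-model reference.
    """
    universe = generate_gene_universe(cfg)
    proj = ProteinEmbeddingPCA(n_components=cfg.embed_dim_protein).fit(universe.protein_embedding)
    design, manifest = assemble_matrix(universe.tabular, universe.gene_embedding,
                                       universe.protein_embedding, proj,
                                       d_gene=cfg.embed_dim_gene, schema=universe.schema)
    labels = universe.labels.loc[design.index, GENE_LABEL_COLUMNS]
    if permute_labels:
        rng = stream(cfg.seed, "label-permutation")
        labels = labels.iloc[rng.permutation(len(labels))].set_axis(design.index)
    preds, models = train_nested(design, labels, seed=cfg.seed, n_estimators=n_estimators)
    per_class = {}
    for cls in GENE_LABEL_COLUMNS:
        sub = preds[preds["doe"] == cls].set_index("item")
        y = labels.loc[sub.index, cls].astype(int).to_numpy()
        per_class[cls] = (sub["probability"].to_numpy(), y)
    macro, micro = macro_micro(per_class)
    return GeneLevelResult(predictions=preds, labels=labels, per_class=per_class,
                           macro_auroc=macro, micro_auroc=micro, manifest=manifest,
                           design=design, models=models)


@dataclass
class GeneDiseaseResult:
    predictions: pd.DataFrame
    labels: pd.DataFrame
    features: pd.DataFrame
    per_class: dict
    macro_auroc: float
    micro_auroc: float
    support_enrichment: pd.DataFrame
    models: dict


def bin_support_enrichment(features: pd.DataFrame, labels: pd.DataFrame,
                           mechanism: str) -> pd.DataFrame:
    """Odds ratio of carrying a mechanism label per bin-support count.

    For each support count k in 1..3 the 2x2 table compares pairs with
    exactly k supporting allele-frequency bins against pairs with 0
    supporting bins; the outcome is the mechanism label.
    """
    counts = bin_support_counts(features, mechanism)
    label_col = f"is_{mechanism}"
    y = labels[label_col].astype(bool).to_numpy()
    c = np.asarray(counts)
    rows = []
    for k in (1, 2, 3):
        sel = (c == k) | (c == 0)
        exposed = c[sel] == k
        yy = y[sel]
        a = int((exposed & yy).sum()); b = int((exposed & ~yy).sum())
        cc = int((~exposed & yy).sum()); d = int((~exposed & ~yy).sum())
        if (a + b) == 0:
            rows.append({"mechanism": mechanism, "support_bins": k, "odds_ratio": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan, "n_exposed": 0})
            continue
        or_, lo, hi, _ = _or_from_table(a, b, cc, d)
        rows.append({"mechanism": mechanism, "support_bins": k, "odds_ratio": or_,
                     "ci_lower": lo, "ci_upper": hi, "n_exposed": a + b})
    return pd.DataFrame(rows)


def run_gene_disease(cfg: SimConfig, n_pairs: int,
                     n_estimators: int = 100) -> GeneDiseaseResult:
    """Generate genetic evidence for labelled pairs, build features, train.

    Mirrors the gene-disease-specific DOE study: 31 signed features with
    tri-state semantics feed one-vs-rest nested-CV models; the support
    enrichment table replicates the bins-supporting-mechanism analysis.
    """
    pair_labels = generate_gene_disease_labels(cfg, n_pairs)
    data = generate_genetic_associations(cfg, pair_labels)
    features = build_feature_matrix(pair_labels, data.associations, data.eqtl_links,
                                    data.burden, data.l2g, data.complementary)
    labels = pair_labels[GENE_LABEL_COLUMNS].astype(bool)
    X = features.reset_index(drop=True)
    preds, models = train_nested(X, labels, seed=cfg.seed, n_estimators=n_estimators)
    per_class = {}
    for cls in GENE_LABEL_COLUMNS:
        sub = preds[preds["doe"] == cls].set_index("item").sort_index()
        y = labels[cls].astype(int).to_numpy()[sub.index.to_numpy().astype(int)]
        per_class[cls] = (sub["probability"].to_numpy(), y)
    macro, micro = macro_micro(per_class)
    enrich = pd.concat([bin_support_enrichment(features, pair_labels, m)
                        for m in ("inhibitor", "activator")], ignore_index=True)
    return GeneDiseaseResult(predictions=preds, labels=pair_labels, features=features,
                             per_class=per_class, macro_auroc=macro, micro_auroc=micro,
                             support_enrichment=enrich, models=models)
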