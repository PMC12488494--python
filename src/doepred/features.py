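"""Gene-level design matrix: tabular features plus embeddings.

The design matrix concatenates, per gene: the tabular features (schema
order, missing values preserved as NaN — the tree learner consumes them
natively), the gene embedding truncated to its leading dimensions (the
embedding is Matryoshka-style, so leading dimensions carry the most
information), and the protein embedding reduced by PCA.
"""

from __future__ import annotations

import json
import logging
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "load_gene_feature_schema",
    "truncate_gene_embedding",
    "ProteinEmbeddingPCA",
    "fit_protein_projection",
    "assemble_matrix",
]


def load_gene_feature_schema(path: str | None = None) -> pd.DataFrame:
    """Load the tabular gene-feature schema (columns: name, kind).

    The shipped default lists 41 features (constraint, dosage sensitivity,
    tractability, localization/function classes, ...); real-data users can
    point ``path`` at their own schema.
    """
    if path is None:
        ref = resources.files("doepred") / "data" / "gene_feature_schema.tsv"
        with resources.as_file(ref) as p:
            schema = pd.read_csv(p, sep="\t")
    else:
        schema = pd.read_csv(path, sep="\t")
    bad = set(schema["kind"]) - {"binary", "continuous"}
    if bad:
        raise ValueError(f"unknown feature kinds: {sorted(bad)}")
    return schema


def truncate_gene_embedding(vec, d: int = 256):
    """Keep the first ``d`` embedding dimensions, order preserved.

    Works on a single vector or a 2-D matrix / DataFrame (columns are
    dimensions).  Raises if fewer than ``d`` dimensions are available.
    """
    if d < 1:
        raise ValueError(f"d must be a positive count, got {d}")
    arr = vec.to_numpy() if isinstance(vec, (pd.DataFrame, pd.Series)) else np.asarray(vec)
    width = arr.shape[-1]
    if width < d:
        raise ValueError(f"embedding has {width} dimensions, cannot truncate to {d}")
    if isinstance(vec, pd.DataFrame):
        return vec.iloc[:, :d]
    if isinstance(vec, pd.Series):
        return vec.iloc[:d]
    return arr[..., :d]


class ProteinEmbeddingPCA(TransformerMixin, BaseEstimator):
    """Orthogonal PCA reduction of raw protein embeddings.

    Components are ordered by decreasing explained variance, with a fixed
    sign convention (the largest-magnitude loading of each component is
    positive) so the projection is reproducible across runs and platforms.
    The projection is fit unsupervised on all genes; labels are never
    seen, so a single shared fit is leakage-free.

    Parameters
    ----------
    n_components : target dimensionality (128 by default).
    """

    def __init__(self, n_components: int = 128):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = self._validate(X)
        d = self.n_components
        if X.shape[0] < d + 1:
            raise ValueError(f"need at least {d + 1} complete rows to fit {d} components, got {X.shape[0]}")
        pca = PCA(n_components=d, svd_solver="full")
        pca.fit(X)
        sv = pca.singular_values_
        tol = max(X.shape) * np.finfo(float).eps * (sv[0] if len(sv) else 0.0)
        rank = int(np.sum(sv > tol))
        if rank < d:
            raise ValueError(f"requested {d} components but data rank is {rank}")
        components = pca.components_.copy()
        # sign convention: largest-|loading| coordinate of each component positive
        flip = np.sign(components[np.arange(d), np.abs(components).argmax(axis=1)])
        components *= flip[:, None]
        self.mean_ = pca.mean_
        self.components_ = components
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = self._validate(X)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Z):
        check_is_fitted(self, "components_")
        return np.asarray(Z) @ self.components_ + self.mean_

    @staticmethod
    def _validate(X) -> np.ndarray:
        arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if np.isnan(arr).any():
            raise ValueError("protein embeddings must not contain missing values")
        return arr


def fit_protein_projection(matrix, d: int = 128) -> ProteinEmbeddingPCA:
    """Fit the protein-embedding PCA projection (thin wrapper)."""
    return ProteinEmbeddingPCA(n_components=d).fit(matrix)


def assemble_matrix(
    tabular: pd.DataFrame,
    gene_embedding: pd.DataFrame,
    protein_embedding: pd.DataFrame,
    projection: ProteinEmbeddingPCA,
    d_gene: int = 256,
    schema: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the gene-level design matrix and its column manifest.

    Column order is: tabular features (schema order), truncated gene
    embedding dimensions, projected protein dimensions.  Tabular missing
    values propagate as NaN; genes lacking either embedding are dropped
    (the count is logged and recorded in the manifest) because a zero
    vector would be an out-of-distribution imputation for a dense
    representation.
    """
    if schema is None:
        schema = load_gene_feature_schema()
        if not set(schema["name"]) <= set(tabular.columns):
            schema = pd.DataFrame({"name": tabular.columns, "kind": "continuous"})
    for df, what in ((tabular, "tabular"), (gene_embedding, "gene embedding"), (protein_embedding, "protein embedding")):
        if df.index.duplicated().any():
            raise ValueError(f"duplicate gene_id in {what} table")

    genes = tabular.index
    have_embeddings = genes.isin(gene_embedding.index) & genes.isin(protein_embedding.index)
    n_dropped = int((~have_embeddings).sum())
    if n_dropped:
        logger.warning("%d genes lack an embedding and were dropped", n_dropped)
    genes = genes[have_embeddings]

    tab = tabular.loc[genes, schema["name"].tolist()]
    gene_part = truncate_gene_embedding(gene_embedding.loc[genes], d_gene)
    gene_part.columns = [f"gene_emb_{i}" for i in range(d_gene)]
    prot = projection.transform(protein_embedding.loc[genes])
    prot_part = pd.DataFrame(prot, index=genes, columns=[f"protein_pc_{i}" for i in range(prot.shape[1])])

    design = pd.concat([tab, gene_part, prot_part], axis=1)
    manifest = {
        "columns": design.columns.tolist(),
        "n_tabular": int(len(schema)),
        "d_gene": int(d_gene),
        "d_protein": int(prot.shape[1]),
        "n_genes": int(len(genes)),
        "n_dropped_missing_embedding": n_dropped,
    }
    return design, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
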