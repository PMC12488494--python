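"""Gene-disease-specific DOE features from genetic evidence.

Builds the 31 signed features for each gene-disease pair from variant
association, eQTL, gene-burden, Locus2gene, and complementary clinical
evidence tables, with strict tri-state semantics throughout:

* **missing** — the pair was never tested in the contributing dataset;
* **0** — tested, but no association reached p < 0.05 (strict);
* **signed value** — ``sign(beta) * -log10(p)`` of the most significant
  qualifying association.

Sign conventions follow the allelic-series framework: a gain-of-function
or expression-raising signal that increases disease risk supports an
inhibitor mechanism, and the mirrored patterns support activation.

The exact composition of the 31 features (and of the 14 rare-variant
categories) is a documented reconstruction: 4 common-variant features
(eQTL concordance x2, Locus2gene x2), 14 rare-variant categories (7
functional strata x 2 dataset families), 9 burden features (3 datasets x
3 variant masks), and 4 complementary features.  The schema is a TSV
shipped with the package and can be replaced for real-data runs.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "load_feature_schema",
    "encode_association",
    "missense_score",
    "eqtl_direction_features",
    "l2g_harmonic_features",
    "rare_variant_features",
    "burden_features",
    "complementary_features",
    "build_feature_matrix",
    "bin_support_counts",
]

P_THRESHOLD = 0.05
MIN_MISSENSE_PREDICTIONS = 8
RANK_SCORE_THRESHOLD = 0.9
_QUALITATIVE_DELETERIOUS = {"D", "H", "R"}

RARE_FAMILIES = ("finngen", "genebass")
BURDEN_DATASETS = ("finngen", "genebass", "jurgens")
BURDEN_MASKS = ("plof", "missense", "plof_missense")
_RARE_CATEGORIES = ("gof", "lof_hc", "lof_lc", "missense_del", "missense_ben", "other", "unknown")


def load_feature_schema(path: str | None = None) -> pd.DataFrame:
    """Load the 31-feature schema (name, group, af_bin, direction)."""
    if path is None:
        ref = resources.files("doepred") / "data" / "gene_disease_feature_schema.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def encode_association(p_value: float, beta_sign: int) -> float:
    """Encode one association as ``sign(beta) * -log10(p)``, or 0.

    Associations with p >= 0.05 encode to 0 (tested, no signal); the
    threshold is strict, so p = 0.05 exactly is excluded.
    """
    p = float(p_value)
    if not (0.0 < p <= 1.0) or np.isnan(p):
        raise ValueError(f"p_value must be in (0, 1], got {p_value!r}")
    if p >= P_THRESHOLD:
        return 0.0
    return float(np.sign(beta_sign)) * (-np.log10(p))


def _encode_series(p: pd.Series, sign: pd.Series) -> pd.Series:
    p = p.astype(float)
    if ((p <= 0) | (p > 1) | p.isna()).any():
        raise ValueError("p values must be in (0, 1]")
    out = np.where(p < P_THRESHOLD, np.sign(sign.astype(float)) * (-np.log10(p)), 0.0)
    return pd.Series(out, index=p.index)


def missense_score(calls: Iterable[tuple[str, object]]) -> float | None:
    """Proportion of deleteriousness predictors calling a variant deleterious.

    ``calls`` holds (tool_kind, call) tuples: qualitative tools report a
    categorical call (deleterious = D/H/R or truthy boolean), quantitative
    tools a rank score (deleterious iff strictly > 0.9).  Returns None
    (missing) when fewer than 8 tools returned a prediction.
    """
    n_pred = 0
    n_del = 0
    for kind, call in calls:
        if call is None or (isinstance(call, float) and np.isnan(call)):
            continue
        n_pred += 1
        if kind == "quantitative":
            if float(call) > RANK_SCORE_THRESHOLD:
                n_del += 1
        else:
            if (isinstance(call, str) and call.upper() in _QUALITATIVE_DELETERIOUS) or call is True:
                n_del += 1
    if n_pred < MIN_MISSENSE_PREDICTIONS:
        return None
    return n_del / n_pred


def _pair_index(df: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(df[["gene_id", "disease_code"]])


def _best_per_group(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Most significant row per group; ties by larger |beta|, then variant_id."""
    d = df.copy()
    d["_beta_mag"] = -d["beta"].abs() if "beta" in d.columns else 0.0
    vid = d["variant_id"] if "variant_id" in d.columns else ""
    d = d.assign(_vid=vid).sort_values(["p_value", "_beta_mag", "_vid"], kind="mergesort")
    return d.groupby(keys, sort=True).first().reset_index()


def eqtl_direction_features(associations: pd.DataFrame, eqtl_links: pd.DataFrame) -> pd.DataFrame:
    """Per-pair eQTL sign-concordance features.

    Variants are joined to their closest significant eQTL gene (one gene
    per variant; distance ties break to the lexicographically smaller
    gene_id), then grouped by whether the association beta and the eQTL
    beta share a sign (inhibitor mechanism) or not (activator mechanism).
    Each direction's feature is the encoded most significant variant;
    pairs with no eQTL-intersected variant are missing both features.
    """
    cols = ["eqtl_inhibitor", "eqtl_activator"]
    if len(associations) == 0 or len(eqtl_links) == 0:
        return pd.DataFrame(columns=cols)
    eq = eqtl_links[eqtl_links["significant"].astype(bool)].copy()
    eq = eq.sort_values(["distance_to_gene", "gene_id"], kind="mergesort").groupby("variant_id").first().reset_index()
    merged = associations.drop(columns=["gene_id"], errors="ignore").merge(
        eq[["variant_id", "gene_id", "eqtl_sign"]], on="variant_id")
    if len(merged) == 0:
        return pd.DataFrame(columns=cols)
    concordant = np.sign(merged["beta_sign"].astype(float)) == np.sign(merged["eqtl_sign"].astype(float))
    merged["_direction"] = np.where(concordant, "eqtl_inhibitor", "eqtl_activator")
    best = _best_per_group(merged, ["gene_id", "disease_code", "_direction"])
    best["_value"] = _encode_series(best["p_value"], best["beta_sign"])
    wide = best.pivot_table(index=["gene_id", "disease_code"], columns="_direction",
                            values="_value", aggfunc="first")
    # a pair with any intersected variant was tested in both directions
    return wide.reindex(columns=cols).fillna(0.0)


def l2g_harmonic_features(l2g: pd.DataFrame) -> pd.DataFrame:
    """Normalized harmonic sums of Locus2gene scores per mechanism.

    For each (pair, mechanism) the scores are sorted descending and
    combined as H = sum(s_i / i^2) / sum(1 / i^2) over the observed count;
    only the mechanism with the larger H keeps its value (ties break to
    activator for determinism), the other direction is 0.  Pairs with no
    Locus2gene rows are missing both features.
    """
    cols = ["l2g_inhibitor", "l2g_activator"]
    if len(l2g) == 0:
        return pd.DataFrame(columns=cols)

    def _hsum(scores: np.ndarray) -> float:
        s = np.sort(np.asarray(scores, dtype=float))[::-1]
        w = 1.0 / np.arange(1, len(s) + 1) ** 2
        return float(np.sum(s * w) / np.sum(w))

    h = (l2g.groupby(["gene_id", "disease_code", "mechanism"])["score"]
         .apply(lambda s: _hsum(s.to_numpy())).rename("H").reset_index())
    wide = h.pivot_table(index=["gene_id", "disease_code"], columns="mechanism",
                         values="H", aggfunc="first")
    for mech in ("activator", "inhibitor"):
        if mech not in wide.columns:
            wide[mech] = np.nan
    a = wide["activator"].fillna(-np.inf)
    i = wide["inhibitor"].fillna(-np.inf)
    out = pd.DataFrame(index=wide.index, columns=cols, dtype=float)
    out["l2g_activator"] = np.where(a >= i, np.where(np.isfinite(a), a, 0.0), 0.0)
    out["l2g_inhibitor"] = np.where(i > a, np.where(np.isfinite(i), i, 0.0), 0.0)
    return out


def _rare_category(functional_class: pd.Series, missense: pd.Series) -> pd.Series:
    fc = functional_class.astype(str)
    cat = pd.Series("other", index=fc.index)
    cat[fc == "GOF"] = "gof"
    cat[fc == "LOF_hc"] = "lof_hc"
    cat[fc == "LOF_lc"] = "lof_lc"
    cat[fc == "unknown"] = "unknown"
    mis = fc == "missense_other"
    cat[mis & (missense > 0.5)] = "missense_del"
    cat[mis & (missense <= 0.5)] = "missense_ben"
    cat[mis & missense.isna()] = "other"
    return cat


def rare_variant_features(associations: pd.DataFrame) -> pd.DataFrame:
    """The 14 rare-variant category features per gene-disease pair.

    Categories are 7 functional strata (GOF, high-/low-confidence LOF,
    deleterious missense (score > 0.5), benign missense, other, unknown)
    crossed with the 2 rare-coding dataset families.  Each feature is the
    encoded most significant variant in its category; a pair tested in a
    family (any row present, significant or not) gets 0 for that family's
    categories lacking qualifying variants, and a pair absent from a
    family leaves that family's categories missing.
    """
    cols = [f"rare_{fam}_{cat}" for fam in RARE_FAMILIES for cat in _RARE_CATEGORIES]
    rare = associations[associations["dataset"].isin(RARE_FAMILIES)].copy()
    if len(rare) == 0:
        return pd.DataFrame(columns=cols)
    mis = rare["missense_score"] if "missense_score" in rare.columns else pd.Series(np.nan, index=rare.index)
    rare["_cat"] = _rare_category(rare["functional_class"], mis)
    best = _best_per_group(rare, ["gene_id", "disease_code", "dataset", "_cat"])
    best["_value"] = _encode_series(best["p_value"], best["beta_sign"])
    best["_feature"] = "rare_" + best["dataset"].astype(str) + "_" + best["_cat"]
    wide = best.pivot_table(index=["gene_id", "disease_code"], columns="_feature",
                            values="_value", aggfunc="first")
    wide = wide.reindex(columns=cols)
    # tested-ness is tracked per (pair, family): any row marks all 7
    tested = rare.groupby(["gene_id", "disease_code", "dataset"]).size().reset_index()
    for fam in RARE_FAMILIES:
        fam_pairs = pd.MultiIndex.from_frame(
            tested.loc[tested["dataset"] == fam, ["gene_id", "disease_code"]])
        fam_cols = [c for c in cols if c.startswith(f"rare_{fam}_")]
        mask = wide.index.isin(fam_pairs)
        wide.loc[mask, fam_cols] = wide.loc[mask, fam_cols].fillna(0.0)
    return wide


def burden_features(burden: pd.DataFrame) -> pd.DataFrame:
    """The 9 gene-burden features (3 datasets x 3 variant masks) per pair.

    One burden result per gene per mask per dataset; tested masks with
    p >= 0.05 encode to 0, untested masks stay missing.
    """
    cols = [f"burden_{ds}_{mask}" for ds in BURDEN_DATASETS for mask in BURDEN_MASKS]
    if len(burden) == 0:
        return pd.DataFrame(columns=cols)
    b = burden[burden["dataset"].isin(BURDEN_DATASETS) & burden["mask"].isin(BURDEN_MASKS)].copy()
    if len(b) == 0:
        return pd.DataFrame(columns=cols)
    best = _best_per_group(b, ["gene_id", "disease_code", "dataset", "mask"])
    best["_value"] = _encode_series(best["p_value"], best["beta_sign"])
    best["_feature"] = "burden_" + best["dataset"].astype(str) + "_" + best["mask"].astype(str)
    wide = best.pivot_table(index=["gene_id", "disease_code"], columns="_feature",
                            values="_value", aggfunc="first")
    return wide.reindex(columns=cols)


def complementary_features(complementary: pd.DataFrame) -> pd.DataFrame:
    """Pass-through of the 4 complementary signed evidence columns."""
    cols = ["clinical_gof", "clinical_lof", "mouse_ko_direction", "expression_direction"]
    if len(complementary) == 0:
        return pd.DataFrame(columns=cols)
    out = complementary.set_index(["gene_id", "disease_code"])
    return out.reindex(columns=cols)


def build_feature_matrix(
    pairs: pd.DataFrame,
    associations: pd.DataFrame,
    eqtl_links: pd.DataFrame,
    burden: pd.DataFrame,
    l2g: pd.DataFrame,
    complementary: pd.DataFrame,
    schema: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the 31-feature matrix for the given gene-disease pairs.

    Rows follow ``pairs`` (columns gene_id, disease_code); columns follow
    the feature schema order.  NaN = missing (channel never tested for the
    pair), 0 = tested without signal.
    """
    if schema is None:
        schema = load_feature_schema()
    idx = _pair_index(pairs)
    common = associations[~associations["dataset"].isin(RARE_FAMILIES)] if len(associations) else associations
    blocks = [
        eqtl_direction_features(common, eqtl_links),
        l2g_harmonic_features(l2g),
        rare_variant_features(associations),
        burden_features(burden),
        complementary_features(complementary),
    ]
    out = pd.concat([b.reindex(idx) for b in blocks], axis=1)
    missing_cols = [c for c in schema["feature_name"] if c not in out.columns]
    for c in missing_cols:
        out[c] = np.nan
    out = out[schema["feature_name"].tolist()]
    out.index = idx
    return out


def bin_support_counts(features: pd.DataFrame, mechanism: str,
                       schema: pd.DataFrame | None = None) -> pd.Series:
    """Count allele-frequency bins (common/rare/ultrarare) supporting a mechanism.

    A bin supports *inhibitor* when any of its features shows a
    GOF-with-risk (gof-like > 0) or LOF-with-protection (lof-like < 0)
    pattern, or a nonzero inhibitor-concordance feature; *activator*
    support is mirrored.  Features outside the three bins (complementary
    evidence) do not contribute.
    """
    if mechanism not in ("activator", "inhibitor"):
        raise ValueError(f"mechanism must be activator or inhibitor, got {mechanism!r}")
    if schema is None:
        schema = load_feature_schema()
    single = isinstance(features, pd.Series)
    f = features.to_frame().T if single else features
    counts = pd.Series(0, index=f.index, dtype=int)
    for bin_name in ("common", "rare", "ultrarare"):
        sub = schema[schema["af_bin"] == bin_name]
        support = pd.Series(False, index=f.index)
        for name, direction in zip(sub["feature_name"], sub["direction"]):
            if name not in f.columns or direction == "none":
                continue
            v = f[name]
            if direction == "gof_like":
                hit = v > 0 if mechanism == "inhibitor" else v < 0
            elif direction == "lof_like":
                hit = v < 0 if mechanism == "inhibitor" else v > 0
            elif direction == f"concordance_{mechanism}":
                hit = v.notna() & (v != 0)
            else:
                continue
            support |= hit.fillna(False)
        counts += support.astype(int)
    return counts.iloc[0] if single else counts
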