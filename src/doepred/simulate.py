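"""Synthetic inputs with the statistical structure the DOE analysis assumes.

The study's real inputs (drug databases, biobank association tests, eQTL
catalogs) are licensed and large; this module generates stand-ins that
reproduce the structure the pipeline depends on:

* multi-label gene DOE flags with a configurable activator/inhibitor/other
  imbalance (defaults follow the observed 23.2% / 75.9% / 42.9% split among
  druggable genes),
* a gene-level design with tabular features and Matryoshka-style embeddings
  whose class separation is controlled by one ``signal_strength`` knob,
* a multi-source drug catalog with overlapping identifier aliases (known
  connected components) and plantable mechanism discrepancies,
* sparse gene-disease genetic evidence whose sign conventions follow the
  GOF/LOF-to-mechanism mapping: a gain-of-function or expression-raising
  signal that increases disease risk supports inhibition, and mirrored
  patterns support activation.

Everything is deterministic given ``SimConfig.seed``: each generator draws
from a named stream split from the root seed, so module order never
changes results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._streams import stream
from .catalog import DOE_CLASSES, TIER1_SOURCES, load_term_map

__all__ = [
    "SimConfig",
    "SimConfigError",
    "GeneUniverse",
    "DrugCatalogSim",
    "GeneticDataSim",
    "generate_gene_universe",
    "generate_drug_catalog",
    "generate_gene_disease_labels",
    "generate_genetic_associations",
]

GENE_LABEL_COLUMNS = ["is_activator", "is_inhibitor", "is_other"]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration for all synthetic generators.

    Class-fraction defaults are the observed proportions among druggable
    genes (0.232 activator, 0.759 inhibitor, 0.429 other; multi-label) and
    among gene-disease pairs with indicated drugs (0.236 / 0.670 / 0.182).
    ``signal_strength`` scales the separation between classes everywhere:
    0 means no planted signal at all.
    """

    n_genes: int = 2000
    n_drugs: int = 5000
    n_diseases: int = 200
    n_sources: int = 5
    frac_activator: float = 0.232
    frac_inhibitor: float = 0.759
    frac_other: float = 0.429
    frac_druggable: float = 0.131
    frac_pair_activator: float = 0.236
    frac_pair_inhibitor: float = 0.670
    frac_pair_other: float = 0.182
    signal_strength: float = 1.0
    missing_rate: float = 0.071
    n_tabular: int = 41
    embed_dim_gene: int = 256
    embed_dim_protein: int = 128
    embed_dim_protein_raw: int = 512
    matryoshka_decay: float = 0.985
    discrepancy_fraction: float = 0.025
    alias_overlap: float = 1.0
    # availability of each genetic-evidence channel per gene-disease pair
    avail_common: float = 0.60
    avail_rare: float = 0.25
    avail_burden: float = 0.12
    avail_l2g: float = 0.05
    avail_complementary: float = 0.04
    noise_variant_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_genes=self.n_genes, n_drugs=self.n_drugs, n_diseases=self.n_diseases,
                      n_sources=self.n_sources, n_tabular=self.n_tabular,
                      embed_dim_gene=self.embed_dim_gene, embed_dim_protein=self.embed_dim_protein,
                      embed_dim_protein_raw=self.embed_dim_protein_raw)
        for name, v in counts.items():
            if int(v) != v or v < 0 or (name.startswith(("n_sources", "embed")) and v <= 0):
                raise SimConfigError(f"{name} must be a non-negative count, got {v!r}")
        props = dict(frac_activator=self.frac_activator, frac_inhibitor=self.frac_inhibitor,
                     frac_other=self.frac_other, frac_druggable=self.frac_druggable,
                     frac_pair_activator=self.frac_pair_activator,
                     frac_pair_inhibitor=self.frac_pair_inhibitor,
                     frac_pair_other=self.frac_pair_other,
                     missing_rate=self.missing_rate, discrepancy_fraction=self.discrepancy_fraction,
                     alias_overlap=self.alias_overlap, avail_common=self.avail_common,
                     avail_rare=self.avail_rare, avail_burden=self.avail_burden,
                     avail_l2g=self.avail_l2g, avail_complementary=self.avail_complementary)
        for name, v in props.items():
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.signal_strength < 0:
            raise SimConfigError(f"signal_strength must be non-negative, got {self.signal_strength!r}")
        if self.embed_dim_protein_raw < self.embed_dim_protein:
            raise SimConfigError("embed_dim_protein_raw must be >= embed_dim_protein")
        if not (0 < self.matryoshka_decay <= 1):
            raise SimConfigError("matryoshka_decay must be in (0, 1]")


def _adjusted_multilabel_probs(fracs: np.ndarray) -> np.ndarray:
    """Bernoulli probabilities whose conditional-on-any marginals hit `fracs`.

    With independent flags and rejection of all-false rows, the marginal of
    flag k given >=1 flag is p_k / P(>=1).  The fixed point
    p_k = frac_k * P(>=1 | p) makes those conditionals equal the requested
    fractions exactly.
    """
    fracs = np.asarray(fracs, dtype=float)
    if fracs.sum() == 0:
        return fracs
    p = fracs.copy()
    for _ in range(500):
        z = 1.0 - np.prod(1.0 - p)
        new = np.clip(fracs * z, 0.0, 1.0)
        if np.allclose(new, p, atol=1e-14):
            p = new
            break
        p = new
    return p


def _sample_multilabel(rng: np.random.Generator, n: int, fracs: tuple[float, float, float]) -> np.ndarray:
    """Sample n multi-label flag triples with >=1 flag each, matching fracs."""
    fr = np.asarray(fracs, dtype=float)
    if n == 0:
        return np.zeros((0, 3), dtype=bool)
    if fr.sum() == 0:
        raise SimConfigError("cannot sample multi-label flags when all class fractions are 0")
    p = _adjusted_multilabel_probs(fr)
    flags = rng.random((n, 3)) < p
    for _ in range(10_000):
        bad = ~flags.any(axis=1)
        if not bad.any():
            break
        flags[bad] = rng.random((int(bad.sum()), 3)) < p
    else:  # pragma: no cover - pathological fractions
        raise SimConfigError("rejection sampling of multi-label flags did not converge")
    return flags


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------


@dataclass
class GeneUniverse:
    """Gene feature tables plus latent DOE labels (the ground truth)."""

    tabular: pd.DataFrame  # index gene_id; n_tabular columns, NaN = missing
    schema: pd.DataFrame  # columns name, kind
    gene_embedding: pd.DataFrame  # index gene_id
    protein_embedding: pd.DataFrame  # index gene_id; raw (pre-PCA) dims
    labels: pd.DataFrame  # index gene_id; bool is_activator/is_inhibitor/is_other + druggable

    def write(self, outdir: str | Path, config: SimConfig | None = None) -> None:
        """Write tables as TSV (empty field = missing) plus a JSON manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("tabular", "schema", "gene_embedding", "protein_embedding", "labels"):
            df = getattr(self, name)
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=name != "schema")
            paths[name] = p.name
        manifest = {"tables": paths, "ground_truth": "labels.tsv"}
        if config is not None:
            manifest["config"] = asdict(config)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _default_schema(n_tabular: int) -> pd.DataFrame:
    from .features import load_gene_feature_schema

    shipped = load_gene_feature_schema()
    if n_tabular == len(shipped):
        return shipped
    names = [f"feat_{i:02d}" for i in range(n_tabular)]
    kinds = ["continuous" if i % 2 == 0 else "binary" for i in range(n_tabular)]
    return pd.DataFrame({"name": names, "kind": kinds})


def generate_gene_universe(cfg: SimConfig) -> GeneUniverse:
    """Generate the gene-level design inputs and latent DOE labels.

    Continuous features are Gaussian with class-shifted means and binary
    features Bernoulli with class-shifted log-odds, the shift scaling with
    ``signal_strength``; embeddings are isotropic Gaussians around per-class
    centroids whose separation decays geometrically with dimension index
    (leading dimensions carry more signal, so truncation stays meaningful).
    Missingness is completely at random and affects tabular columns only.
    """
    n = cfg.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    schema = _default_schema(cfg.n_tabular)

    rng_lab = stream(cfg.seed, "gene-labels")
    n_druggable = int(round(cfg.frac_druggable * n))
    flags = np.zeros((n, 3), dtype=bool)
    if n_druggable > 0:
        druggable_idx = rng_lab.choice(n, size=n_druggable, replace=False)
        flags[np.sort(druggable_idx)] = _sample_multilabel(
            rng_lab, n_druggable, (cfg.frac_activator, cfg.frac_inhibitor, cfg.frac_other)
        )
    labels = pd.DataFrame(flags, index=gene_ids, columns=GENE_LABEL_COLUMNS)
    labels["druggable"] = flags.any(axis=1)

    s = cfg.signal_strength
    F = flags.astype(float)

    rng_w = stream(cfg.seed, "gene-weights")
    W = rng_w.normal(size=(3, cfg.n_tabular)) * rng_w.uniform(0.2, 1.0, size=cfg.n_tabular)
    shift = s * (F @ W)

    rng_t = stream(cfg.seed, "gene-tabular")
    tab = np.empty((n, cfg.n_tabular))
    kinds = schema["kind"].to_numpy()
    base_logit = rng_w.uniform(-2.0, 0.0, size=cfg.n_tabular)
    for j in range(cfg.n_tabular):
        if kinds[j] == "continuous":
            tab[:, j] = rng_t.normal(size=n) + shift[:, j]
        else:
            p = 1.0 / (1.0 + np.exp(-(base_logit[j] + shift[:, j])))
            tab[:, j] = (rng_t.random(n) < p).astype(float)
    if cfg.missing_rate > 0 and n > 0:
        rng_m = stream(cfg.seed, "gene-missing")
        tab[rng_m.random((n, cfg.n_tabular)) < cfg.missing_rate] = np.nan
    tabular = pd.DataFrame(tab, index=gene_ids, columns=schema["name"].tolist())

    def _embed(name: str, dim: int) -> pd.DataFrame:
        rng_e = stream(cfg.seed, name)
        decay = cfg.matryoshka_decay ** np.arange(dim)
        centroids = rng_e.normal(size=(3, dim)) * decay
        E = s * (F @ centroids) + rng_e.normal(size=(n, dim))
        cols = [f"{name.split('-')[0]}_dim_{d}" for d in range(dim)]
        return pd.DataFrame(E, index=gene_ids, columns=cols)

    gene_embedding = _embed("gene-embedding", cfg.embed_dim_gene)
    protein_embedding = _embed("protein-embedding", cfg.embed_dim_protein_raw)
    return GeneUniverse(tabular=tabular, schema=schema, gene_embedding=gene_embedding,
                        protein_embedding=protein_embedding, labels=labels)


# ---------------------------------------------------------------------------
# drug catalog
# ---------------------------------------------------------------------------

SOURCES = ("chembl", "drugbank", "otp", "gtp", "curated")


@dataclass
class DrugCatalogSim:
    """Synthetic multi-source drug catalog with planted ground truth."""

    links: pd.DataFrame  # record_id, namespace, value
    mechanisms: pd.DataFrame  # record_id, source, gene_id, raw_term
    indications: pd.DataFrame  # record_id, disease_code
    truth_components: pd.Series  # record_id -> planted component id
    truth_pair_doe: pd.DataFrame  # drug_key, gene_id, doe (planted mechanisms)
    truth_gene_labels: pd.DataFrame  # index gene_id; is_activator/is_inhibitor/is_other
    truth_pair_labels: pd.DataFrame  # index (gene_id, disease_code); same columns


def _union_flags(pairs: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    onehot = pd.get_dummies(pairs["doe"]).reindex(columns=list(DOE_CLASSES), fill_value=False).astype(bool)
    onehot.columns = GENE_LABEL_COLUMNS
    return pd.concat([pairs[keys], onehot], axis=1).groupby(keys)[GENE_LABEL_COLUMNS].any().sort_index()


def generate_drug_catalog(cfg: SimConfig, labels: pd.DataFrame) -> DrugCatalogSim:
    """Generate identifier links, mechanism annotations, and indications.

    Each drug appears in 1..n_sources sources; alias links between a drug's
    records form a chain whose links are present with probability
    ``alias_overlap`` (1.0 plants each drug as one connected component,
    0.0 leaves every record a singleton).  A ``discrepancy_fraction`` of
    drug-gene pairs receives an extra tier-2 annotation of a wrong class;
    a tier-1 annotation of the true class is always present for those
    pairs, so priority resolution recovers the planted mechanism.
    """
    rng = stream(cfg.seed, "drug-catalog")
    term_map = load_term_map()
    terms_by_doe = {d: term_map.loc[term_map["doe"] == d, "raw_term"].tolist() for d in DOE_CLASSES}
    sources = SOURCES[: cfg.n_sources]
    tier1 = [src for src in sources if src in TIER1_SOURCES]

    flagged = labels[labels[GENE_LABEL_COLUMNS].any(axis=1)]
    coverage = [(g, d) for g, row in flagged[GENE_LABEL_COLUMNS].iterrows()
                for d, on in zip(DOE_CLASSES, row) if on]
    disease_codes = [f"{chr(65 + i // 100)}{i % 100:02d}" for i in range(cfg.n_diseases)]

    link_rows, mech_rows, ind_rows = [], [], []
    comp_of: dict[str, str] = {}
    pair_rows = []

    n_discrepant_target = int(np.floor(cfg.discrepancy_fraction * cfg.n_drugs))
    for i in range(cfg.n_drugs):
        drug = f"D{i:05d}"
        make_discrepant = i < n_discrepant_target and len(tier1) > 0 and len(sources) > len(tier1)
        n_src = 1 + int(rng.binomial(cfg.n_sources - 1, 0.35))
        chosen = list(rng.choice(cfg.n_sources, size=n_src, replace=False))
        if make_discrepant:
            # ensure one tier-1 and one tier-2 source are present
            if not any(sources[k] in TIER1_SOURCES for k in chosen):
                chosen[0] = sources.index(tier1[0])
            if all(sources[k] in TIER1_SOURCES for k in chosen):
                extra = next(k for k, s_ in enumerate(sources) if s_ not in TIER1_SOURCES)
                chosen.append(extra)
        chosen = sorted(set(chosen))
        recs = [f"{sources[k]}:{drug}" for k in chosen]

        # identifier aliases: chain with per-link presence = alias_overlap
        seg = 0
        comp_members = [[recs[0]]]
        for j, rec in enumerate(recs):
            link_rows.append((rec, "srcid", rec))
            if j < len(recs) - 1:
                if rng.random() < cfg.alias_overlap:
                    alias_ns = ("pubchem", "name", "inchikey")[j % 3]
                    alias_val = f"{drug}-a{j}"
                    link_rows.append((recs[j], alias_ns, alias_val))
                    link_rows.append((recs[j + 1], alias_ns, alias_val))
                    comp_members[seg].append(recs[j + 1])
                else:
                    seg += 1
                    comp_members.append([recs[j + 1]])
        for members in comp_members:
            cid = min(members)
            for m in members:
                comp_of[m] = cid

        # mechanism annotations (only if any druggable gene exists)
        if coverage:
            targets = [coverage[i % len(coverage)]] if i < len(coverage) else \
                [coverage[int(rng.integers(len(coverage)))]]
            if rng.random() < 0.45:  # multi-target drugs
                targets.append(coverage[int(rng.integers(len(coverage)))])
            seen = set()
            for gene, doe in targets:
                if gene in seen:
                    continue
                seen.add(gene)
                pair_rows.append((drug, gene, doe))
                for rec in recs:
                    term = terms_by_doe[doe][int(rng.integers(len(terms_by_doe[doe])))]
                    mech_rows.append((rec, rec.split(":")[0], gene, term))
                if make_discrepant:
                    t2 = next(r for r in recs if r.split(":")[0] not in TIER1_SOURCES)
                    wrong = [d for d in DOE_CLASSES if d != doe][int(rng.integers(2))]
                    wrong_term = terms_by_doe[wrong][int(rng.integers(len(terms_by_doe[wrong])))]
                    mech_rows = [(r, s_, g, (wrong_term if r == t2 and g == gene else t))
                                 for (r, s_, g, t) in mech_rows]
                    make_discrepant = False  # one discrepant pair per drug

        if cfg.n_diseases > 0:
            n_ind = 1 + int(rng.poisson(1.5))
            for k in rng.choice(cfg.n_diseases, size=min(n_ind, cfg.n_diseases), replace=False):
                ind_rows.append((recs[0], disease_codes[int(k)]))

    links = pd.DataFrame(link_rows, columns=["record_id", "namespace", "value"])
    mechanisms = pd.DataFrame(mech_rows, columns=["record_id", "source", "gene_id", "raw_term"])
    indications = pd.DataFrame(ind_rows, columns=["record_id", "disease_code"])
    truth_components = pd.Series(comp_of, name="component").sort_index()
    truth_pair = pd.DataFrame(pair_rows, columns=["drug_key", "gene_id", "doe"]).drop_duplicates()

    if len(truth_pair):
        truth_gene = _union_flags(truth_pair.rename(columns={"drug_key": "k"}), ["gene_id"])
        ind_by_drug = indications.assign(drug_key=indications["record_id"].str.split(":").str[1])
        merged = ind_by_drug.merge(truth_pair, on="drug_key")[["gene_id", "disease_code", "doe"]]
        truth_pair_labels = _union_flags(merged, ["gene_id", "disease_code"]) if len(merged) else \
            pd.DataFrame(columns=GENE_LABEL_COLUMNS)
    else:
        truth_gene = pd.DataFrame(columns=GENE_LABEL_COLUMNS)
        truth_pair_labels = pd.DataFrame(columns=GENE_LABEL_COLUMNS)
    return DrugCatalogSim(links=links, mechanisms=mechanisms, indications=indications,
                          truth_components=truth_components, truth_pair_doe=truth_pair,
                          truth_gene_labels=truth_gene, truth_pair_labels=truth_pair_labels)


# ---------------------------------------------------------------------------
# genetic evidence
# ---------------------------------------------------------------------------

RARE_FAMILIES = ("finngen", "genebass")
BURDEN_DATASETS = ("finngen", "genebass", "jurgens")
BURDEN_MASKS = ("plof", "missense", "plof_missense")
FUNCTIONAL_CLASSES = ("GOF", "LOF_hc", "LOF_lc", "missense_other", "other", "unknown")
_FC_PROBS = (0.22, 0.22, 0.08, 0.28, 0.12, 0.08)


@dataclass
class GeneticDataSim:
    """Synthetic association / eQTL / burden / complementary evidence."""

    pairs: pd.DataFrame  # gene_id, disease_code, is_activator/is_inhibitor/is_other
    associations: pd.DataFrame  # variant-level rows (common + rare)
    eqtl_links: pd.DataFrame
    burden: pd.DataFrame
    l2g: pd.DataFrame
    complementary: pd.DataFrame

    def write(self, outdir: str | Path, config: SimConfig | None = None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("pairs", "associations", "eqtl_links", "burden", "l2g", "complementary"):
            p = out / f"{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", index=False)
            paths[name] = p.name
        manifest = {"tables": paths, "ground_truth": "pairs.tsv"}
        if config is not None:
            manifest["config"] = asdict(config)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_gene_disease_labels(cfg: SimConfig, n_pairs: int) -> pd.DataFrame:
    """Sample gene-disease pairs with multi-label DOE flags.

    Fractions default to the observed split among pairs with indicated
    drugs (23.6% activator / 67.0% inhibitor / 18.2% other; >=1 flag each).
    """
    rng = stream(cfg.seed, "pair-labels")
    genes = [f"G{i:05d}" for i in range(max(cfg.n_genes, 1))]
    diseases = [f"{chr(65 + i // 100)}{i % 100:02d}" for i in range(max(cfg.n_diseases, 1))]
    gi = rng.integers(len(genes), size=n_pairs)
    di = rng.integers(len(diseases), size=n_pairs)
    df = pd.DataFrame({"gene_id": [genes[i] for i in gi], "disease_code": [diseases[i] for i in di]})
    df = df.drop_duplicates().reset_index(drop=True)
    while len(df) < n_pairs:  # top up collisions
        gi = rng.integers(len(genes), size=n_pairs)
        di = rng.integers(len(diseases), size=n_pairs)
        extra = pd.DataFrame({"gene_id": [genes[i] for i in gi], "disease_code": [diseases[i] for i in di]})
        df = pd.concat([df, extra]).drop_duplicates().reset_index(drop=True)
        if len(genes) * len(diseases) <= len(df):
            break
    df = df.iloc[:n_pairs].reset_index(drop=True)
    flags = _sample_multilabel(rng, len(df),
                               (cfg.frac_pair_activator, cfg.frac_pair_inhibitor, cfg.frac_pair_other))
    for k, col in enumerate(GENE_LABEL_COLUMNS):
        df[col] = flags[:, k]
    return df


def _p_match(signal_strength: float) -> float:
    """Probability a planted evidence row supports the pair's true mechanism.

    0.5 (uninformative) at signal 0, saturating toward 1; 0.75 at the
    default signal_strength of 1.
    """
    s = float(signal_strength)
    return 0.5 + 0.5 * s / (1.0 + s)


def _neglog_p(rng: np.random.Generator, n: int) -> np.ndarray:
    """-log10 p for significant rows: just past 0.05, exponential tail."""
    return -np.log10(0.05) + rng.exponential(scale=1.2, size=n)


def _target_direction(rng: np.random.Generator, act: np.ndarray, inh: np.ndarray) -> np.ndarray:
    """Per-row supported mechanism: +1 = inhibitor, -1 = activator.

    Pairs flagged for exactly one direction get that direction; both or
    neither -> coin flip (no consistent signal to plant).
    """
    coin = np.where(rng.random(len(act)) < 0.5, 1.0, -1.0)
    out = np.where(inh & ~act, 1.0, np.where(act & ~inh, -1.0, coin))
    return out


def generate_genetic_associations(cfg: SimConfig, pair_labels: pd.DataFrame) -> GeneticDataSim:
    """Generate variant association, eQTL, burden, and complementary tables.

    Sign conventions for planted (non-noise) rows follow the genetic
    framework exactly: for an inhibitor-labelled pair, risk-increasing GOF
    variants, risk-concordant expression-raising eQTL alleles, and
    protective LOF/burden signals are enriched; activator-labelled pairs
    get the mirrored pattern.  With ``signal_strength=0`` every sign is a
    coin flip and no feature carries label information.
    """
    pairs = pair_labels.reset_index(drop=True).copy()
    n = len(pairs)
    pm = _p_match(cfg.signal_strength)
    act = pairs["is_activator"].to_numpy(bool)
    inh = pairs["is_inhibitor"].to_numpy(bool)
    gene = pairs["gene_id"].to_numpy()
    dis = pairs["disease_code"].to_numpy()

    assoc_parts, eqtl_parts = [], []

    # --- common variants with eQTL intersection -------------------------
    rng = stream(cfg.seed, "assoc-common")
    tested = rng.random(n) < cfg.avail_common
    direction = _target_direction(rng, act, inh)
    k_sig = rng.poisson(1.0, size=n) * tested
    k_noise = rng.poisson(cfg.noise_variant_rate, size=n) * tested
    idx = np.repeat(np.arange(n), k_sig)
    if len(idx):
        m = len(idx)
        match = rng.random(m) < pm
        supported = np.where(match, direction[idx], -direction[idx])
        eqtl_sign = np.where(rng.random(m) < 0.5, 1, -1)
        # same-sign (beta x eqtl > 0) predicts inhibitor
        beta_sign = np.where(supported > 0, eqtl_sign, -eqtl_sign)
        vid = np.array([f"cv{j:07d}" for j in range(m)])
        assoc_parts.append(pd.DataFrame({
            "variant_id": vid, "gene_id": gene[idx], "disease_code": dis[idx],
            "dataset": "gwas", "af_bin": "common", "beta_sign": beta_sign,
            "p_value": 10.0 ** (-_neglog_p(rng, m)), "functional_class": "unknown",
        }))
        eqtl_parts.append(pd.DataFrame({
            "variant_id": vid, "gene_id": gene[idx], "eqtl_sign": eqtl_sign,
            "significant": True, "distance_to_gene": rng.integers(500, 50_000, size=m),
        }))
        # occasional decoy eQTL to a farther gene (closest-gene rule is live)
        decoy = rng.random(m) < 0.2
        if decoy.any():
            eqtl_parts.append(pd.DataFrame({
                "variant_id": vid[decoy],
                "gene_id": np.char.add(gene[idx][decoy].astype(str), "_far"),
                "eqtl_sign": np.where(rng.random(int(decoy.sum())) < 0.5, 1, -1),
                "significant": True,
                "distance_to_gene": rng.integers(100_000, 900_000, size=int(decoy.sum())),
            }))
    idx = np.repeat(np.arange(n), k_noise)
    if len(idx):
        m = len(idx)
        vid = np.array([f"cn{j:07d}" for j in range(m)])
        eqtl_sign = np.where(rng.random(m) < 0.5, 1, -1)
        assoc_parts.append(pd.DataFrame({
            "variant_id": vid, "gene_id": gene[idx], "disease_code": dis[idx],
            "dataset": "gwas", "af_bin": "common",
            "beta_sign": np.where(rng.random(m) < 0.5, 1, -1),
            "p_value": 10.0 ** (-_neglog_p(rng, m)), "functional_class": "unknown",
        }))
        eqtl_parts.append(pd.DataFrame({
            "variant_id": vid, "gene_id": gene[idx], "eqtl_sign": eqtl_sign,
            "significant": True, "distance_to_gene": rng.integers(500, 50_000, size=m),
        }))
    # tested-but-nonsignificant marker rows (p >= 0.05 -> encoded 0)
    idx = np.flatnonzero(tested)
    if len(idx):
        assoc_parts.append(pd.DataFrame({
            "variant_id": [f"cz{j:07d}" for j in range(len(idx))],
            "gene_id": gene[idx], "disease_code": dis[idx], "dataset": "gwas",
            "af_bin": "common", "beta_sign": np.where(rng.random(len(idx)) < 0.5, 1, -1),
            "p_value": rng.uniform(0.05, 1.0, size=len(idx)), "functional_class": "unknown",
        }))

    # --- rare coding variants ------------------------------------------
    fc = np.array(FUNCTIONAL_CLASSES)
    for fam in RARE_FAMILIES:
        rng = stream(cfg.seed, f"assoc-rare-{fam}")
        tested = rng.random(n) < cfg.avail_rare
        direction = _target_direction(rng, act, inh)
        k_sig = rng.poisson(0.9, size=n) * tested
        idx = np.repeat(np.arange(n), k_sig)
        m = len(idx)
        if m:
            classes = fc[rng.choice(len(fc), size=m, p=_FC_PROBS)]
            mis_score = np.where(classes == "missense_other", rng.random(m), np.nan)
            # directional strata: GOF is gof-like; LOF_hc/lc and deleterious
            # missense (score > 0.5) are lof-like; the rest carry no direction
            gof_like = classes == "GOF"
            lof_like = np.isin(classes, ("LOF_hc", "LOF_lc")) | (
                (classes == "missense_other") & (mis_score > 0.5))
            match = rng.random(m) < pm
            supported = np.where(match, direction[idx], -direction[idx])
            coin = np.where(rng.random(m) < 0.5, 1, -1)
            # inhibitor support: GOF risk-increasing (+) or LOF protective (-)
            beta_sign = np.where(gof_like, np.where(supported > 0, 1, -1),
                                 np.where(lof_like, np.where(supported > 0, -1, 1), coin))
            assoc_parts.append(pd.DataFrame({
                "variant_id": [f"r{fam[0]}{j:07d}" for j in range(m)],
                "gene_id": gene[idx], "disease_code": dis[idx], "dataset": fam,
                "af_bin": np.where(rng.random(m) < 0.6, "rare", "ultrarare"),
                "beta_sign": beta_sign, "p_value": 10.0 ** (-_neglog_p(rng, m)),
                "functional_class": classes, "missense_score": mis_score,
            }))
        idx = np.flatnonzero(tested)
        if len(idx):
            assoc_parts.append(pd.DataFrame({
                "variant_id": [f"z{fam[0]}{j:07d}" for j in range(len(idx))],
                "gene_id": gene[idx], "disease_code": dis[idx], "dataset": fam,
                "af_bin": "rare", "beta_sign": np.where(rng.random(len(idx)) < 0.5, 1, -1),
                "p_value": rng.uniform(0.05, 1.0, size=len(idx)),
                "functional_class": fc[rng.choice(len(fc), size=len(idx), p=_FC_PROBS)],
            }))

    # --- gene burden ----------------------------------------------------
    burden_parts = []
    for ds in BURDEN_DATASETS:
        rng = stream(cfg.seed, f"burden-{ds}")
        tested = rng.random(n) < cfg.avail_burden
        direction = _target_direction(rng, act, inh)
        idx = np.flatnonzero(tested)
        for mask in BURDEN_MASKS:
            m = len(idx)
            if m == 0:
                continue
            sig = rng.random(m) < 0.5
            match = rng.random(m) < pm
            supported = np.where(match, direction[idx], -direction[idx])
            # burden aggregates LOF-ish variants: inhibitor support = protective (-)
            beta_sign = np.where(supported > 0, -1, 1)
            p = np.where(sig, 10.0 ** (-_neglog_p(rng, m)), rng.uniform(0.05, 1.0, size=m))
            burden_parts.append(pd.DataFrame({
                "gene_id": gene[idx], "disease_code": dis[idx], "dataset": ds,
                "mask": mask, "beta_sign": beta_sign, "p_value": p,
            }))
    burden = pd.concat(burden_parts, ignore_index=True) if burden_parts else pd.DataFrame(
        columns=["gene_id", "disease_code", "dataset", "mask", "beta_sign", "p_value"])

    # --- Locus2gene scores ----------------------------------------------
    rng = stream(cfg.seed, "l2g")
    tested = rng.random(n) < cfg.avail_l2g
    direction = _target_direction(rng, act, inh)
    k = (1 + rng.poisson(1.0, size=n)) * tested
    idx = np.repeat(np.arange(n), k)
    if len(idx):
        m = len(idx)
        match = rng.random(m) < pm
        supported = np.where(match, direction[idx], -direction[idx])
        l2g = pd.DataFrame({
            "gene_id": gene[idx], "disease_code": dis[idx],
            "mechanism": np.where(supported > 0, "inhibitor", "activator"),
            "score": rng.uniform(0.2, 1.0, size=m),
        })
    else:
        l2g = pd.DataFrame(columns=["gene_id", "disease_code", "mechanism", "score"])

    # --- complementary clinical / model-organism evidence ----------------
    rng = stream(cfg.seed, "complementary")
    comp_cols = {"clinical_gof": 1.0, "clinical_lof": -1.0,
                 "mouse_ko_direction": -1.0, "expression_direction": 1.0}
    comp = pd.DataFrame({"gene_id": gene, "disease_code": dis})
    direction = _target_direction(rng, act, inh)
    keep = np.zeros(n, dtype=bool)
    for col, inhibitor_sign in comp_cols.items():
        avail = rng.random(n) < cfg.avail_complementary
        keep |= avail
        match = rng.random(n) < pm
        supported = np.where(match, direction, -direction)
        val = inhibitor_sign * np.where(supported > 0, 1.0, -1.0) * _neglog_p(rng, n)
        comp[col] = np.where(avail, val, np.nan)
    complementary = comp.loc[keep].reset_index(drop=True)

    associations = pd.concat(assoc_parts, ignore_index=True) if assoc_parts else pd.DataFrame(
        columns=["variant_id", "gene_id", "disease_code", "dataset", "af_bin",
                 "beta_sign", "p_value", "functional_class", "missense_score"])
    if "missense_score" not in associations.columns:
        associations["missense_score"] = np.nan
    eqtl_links = pd.concat(eqtl_parts, ignore_index=True) if eqtl_parts else pd.DataFrame(
        columns=["variant_id", "gene_id", "eqtl_sign", "significant", "distance_to_gene"])
    return GeneticDataSim(pairs=pairs, associations=associations, eqtl_links=eqtl_links,
                          burden=burden, l2g=l2g, complementary=complementary)
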