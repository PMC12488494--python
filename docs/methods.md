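# Methods

## The prediction problem

A drug modulates a gene product in a direction: *activators* increase
its activity, *inhibitors* decrease it, and a heterogeneous *other*
class (binding agents, mixed agonist/antagonists, gene/protein
replacement) carries no single direction. Direction of effect (DOE) is
modelled as a multi-label property — one gene can be targeted by drugs
of several classes — so every model in the package is a one-vs-rest
binary classifier per class, and per-class probabilities are reported
alongside macro/micro aggregates.

Two levels are modelled. The **gene level** asks which genes are
tractable and useful to modulate in a given direction, using only
disease-agnostic gene features. The **gene-disease level** asks which
direction is correct for a specific disease, using human-genetics
evidence: genetic variants mimic drug effects, so a gain-of-function
(GOF) variant or an expression-raising allele that increases disease
risk argues for inhibition, and the mirrored patterns argue for
activation. Variants across the allele frequency spectrum (common,
rare, ultrarare) form an allelic series whose graded effects model a
dose-response.

## Drug catalog

Drug records from multiple sources are unified with a disjoint-set
union over shared `(identifier namespace, value)` pairs
(case-normalized); the unified drug id is the lexicographically
smallest member record id, which makes the partition reproducible
across runs and platforms. Mechanism terms are mapped to DOE classes
through an editable TSV (`data/mechanism_terms.tsv`); the shipped map is
a reconstruction covering the common agonist / antagonist / activator /
inhibitor / blocker / PAM / NAM / binding-agent families, and unmapped
terms fall back to *other*. When sources disagree about a drug-gene
pair, resolution is lexicographic: tier-1 sources (the ChEMBL and
DrugBank families) beat tier-2, then directional classes beat *other*.
Pairs whose surviving annotations still conflict between activator and
inhibitor are excluded and logged rather than guessed — the stated
priority rules need not resolve arbitrary inputs. Gene labels are the
union of classes over a gene's drugs; gene-disease labels the union
over drugs indicated for the disease.

## Gene-level design matrix

425 columns: 41 tabular features (schema in
`data/gene_feature_schema.tsv`; binary and continuous; the shipped
names — constraint, dosage-sensitivity, tractability, localization and
function classes — are a plausible reconstruction and user-replaceable),
256 gene-embedding dimensions, and 128 protein-embedding principal
components. The gene embedding is truncated, not projected: it is
assumed Matryoshka-style, with leading dimensions carrying the most
information. The protein embedding is reduced by PCA fit on all genes;
this is label-free, so a single shared fit leaks nothing into
cross-validation. Component signs are fixed (largest-magnitude loading
positive) for reproducibility, and requesting more components than the
data rank is an error. Tabular missingness is passed through to the
tree learner natively — no imputation, no normalization. Genes lacking
an embedding are dropped with a logged count rather than zero-imputed,
since a zero vector is out-of-distribution for a dense representation.

## Gene-disease features (31)

Encoding: `sign(β) · (−log₁₀ p)` of the most significant qualifying
association; inclusion is strictly `p < 0.05` (the boundary encodes to
0). Tri-state semantics are preserved end-to-end: missing = the pair
was never tested in the contributing dataset, 0 = tested with no
qualifying association, signed value = evidence. TSV round-trips keep
the distinction (empty field vs literal `0`).

The composition is a documented reconstruction of the stated subtotals
(4 common + 14 rare + 9 burden + 4 complementary), bound by the schema
file `data/gene_disease_feature_schema.tsv`:

* **Common (4).** Two eQTL-concordance features: GWAS variants are
  joined to their closest significant eQTL gene (distance ties break to
  the smaller gene id), grouped by whether the association β and eQTL β
  share a sign (inhibitor mechanism) or not (activator), and each
  direction keeps its minimum-p encoding. Two Locus2gene features: per
  mechanism, scores are combined by a normalized harmonic sum
  `H = Σ s₍ᵢ₎/i² / Σ 1/i²` over the observed count (the normalization
  divisor is this package's explicit choice), and only the larger H is
  retained (ties break to activator).
* **Rare (14).** Seven functional strata — GOF, high-/low-confidence
  LOF, deleterious missense (missense score > 0.5), benign missense,
  other, unknown — crossed with two rare-coding dataset families. The
  missense score is the proportion of deleteriousness predictors
  calling a variant deleterious (quantitative tools: rank score
  strictly > 0.9), missing when fewer than 8 tools returned a
  prediction. Tested-ness is tracked per (pair × family): any row in a
  family's table baselines all seven of that family's categories at 0,
  because a tested-but-empty category emits no variant rows and is not
  otherwise reconstructible.
* **Burden (9).** Three datasets × three variant masks (pLOF, missense,
  pLOF+missense), one result per gene per mask per dataset.
* **Complementary (4).** Signed clinical-GOF, clinical-LOF,
  mouse-knockout-direction, and expression-direction evidence, passed
  through.

Ties at equal minimum p break by larger |β| (when a magnitude column is
present), then variant id — output is deterministic.

**Bin support.** A bin (common / rare / ultrarare; complementary
features sit outside the bins) supports *inhibitor* when any of its
features shows GOF-with-risk (gof-like > 0), LOF-with-protection
(lof-like < 0), or nonzero inhibitor-concordance; *activator* support is
mirrored. Flipping every β sign in the raw tables negates all signed
features, swaps the concordance-derived column pairs, and swaps the
support counts — this antisymmetry is enforced by tests both end-to-end
and at the feature-vector level.

## Models

XGBoost binary classifiers under nested 8×8 cross-validation: the outer
loop holds out one fold; the inner loop trains eight models per outer
round, each early-stopped on its inner validation fold (validation
log-loss, patience 10); all eight predict the outer holdout, and their
*probabilities* are averaged. Every item gets exactly one holdout
prediction per class from models that never saw its row, and folds are
shared across the three class models so predictions are comparable.
Splits are unstratified (random), but the trainer aborts with a
stratification hint when a class is absent from an inner fold.

Hyperparameters are library defaults except `min_child_weight = 10`
(guards against overly complex splits) and the histogram settings
`tree_method="hist", max_bin=64`, a numerical choice that cuts training
time ~8× with negligible effect on holdout AUROC; the boosting cap is
100 rounds. Feature attribution uses TreeSHAP as implemented inside
XGBoost (`pred_contribs`), which satisfies exact local additivity:
base value + Σ contributions = model margin; tests enforce the
additivity contract rather than a specific algorithm. A
generalization-to-novel-targets check trains on the low-novelty portion
of genes (ranked by a novelty score, ties by id) with an inner 8-fold
CV and predicts the held-out high-novelty fraction (1/8 by default, 1/2
supported).

## Evaluation

AUROC is the rank statistic (ties ½), cross-checked in tests against an
O(n²) pair-counting oracle. Confidence intervals use the reverse
percentile bootstrap, `[2θ̂ − q₀.₉₇₅, 2θ̂ − q₀.₀₂₅]`, resampling
(score, label) rows; degenerate resamples are redrawn (cap 100) so the
bootstrap count stays fixed. Macro averaging is the unweighted mean of
per-class metrics; micro averaging pools one-vs-rest rows (each item
contributes once per class). Calibration uses 10 equal-width bins and a
count-weighted least-squares fit of observed rate on mean prediction;
with fewer than two occupied bins the fit is undefined and flagged.
Decision cutoffs scan every distinct prediction value (positive when
prediction ≥ threshold) for the F_β maximum — F₁ for gene-level models,
F₀.₂ (heavily precision-weighted) for gene-disease models, where
performance is modest and precision matters more; ties break to the
smallest threshold, which maximizes recall at equal F.

Phase-transition outcomes: a unit (target, target-DOE, or
target-DOE-disease) succeeds for X→Y if any drug reached phase ≥ Y,
fails if some drug reached ≥ X but none reached Y and none is still in
active development (statuses: recruiting; active, not recruiting; not
yet recruiting; enrolling by invitation — the latest status per drug is
consulted; unknown statuses count as inactive and are logged), and is
excluded otherwise. Enrichment odds ratios come from the 2×2 table at a
nearest-rank percentile or explicit cutoff, with Wald 95% CIs and
Haldane 0.5 correction on zero cells; tests verify equality with the
logistic-regression estimate.

## Synthetic data: what it emulates and what it does not

All generators draw from named streams split from one root seed
(CRC-32 spawn keys), so identical configurations give byte-identical
outputs regardless of call order.

**Labels.** Gene flags are multi-label with configurable fractions
among druggable genes (defaults 0.232 activator / 0.759 inhibitor /
0.429 other, ~13.1% of genes druggable; pair labels 0.236 / 0.670 /
0.182). Flags are independent Bernoullis with fixed-point-adjusted
probabilities `p'ₖ = fₖ · P(≥1 flag)` plus rejection of all-false rows,
which makes the conditional marginals equal the configured fractions
exactly.

**Gene features.** Continuous features are Gaussian with class-shifted
means, binary features Bernoulli with class-shifted log-odds;
embeddings are isotropic Gaussians around per-class centroids whose
separation decays geometrically with dimension (decay 0.985 per
dimension), emulating the Matryoshka property. One knob,
`signal_strength`, scales every shift. Missingness is completely at
random (default rate 0.071, the observed median) and affects tabular
columns only — real missingness is unlikely to be MCAR, but its
mechanism is uncharacterized.

**Drug catalog.** Each drug appears in 1–5 sources; identifier aliases
chain its records into known connected components (per-link presence =
`alias_overlap`). A configurable fraction of drug-gene pairs (default
0.025) receives a wrong-class tier-2 annotation alongside a true-class
tier-1 annotation, so priority resolution recovers the planted truth.

**Genetic evidence.** For each labelled pair, each evidence channel is
available with its own probability (common 0.60, rare 0.25 per family,
burden 0.12 per dataset, Locus2gene 0.05, complementary 0.04 per
feature — chosen to mirror the steep availability gradient of real
evidence, where complementary clinical features cover only a few
percent of pairs). Planted rows support the pair's labelled mechanism
with probability `p_match = ½ + ½·s/(1+s)` (s = `signal_strength`;
0.75 at the default s = 1, exactly ½ — no information — at s = 0), with
sign patterns following the GOF/LOF framework exactly for matching
rows; noise rows and tested-but-nonsignificant marker rows are emitted
irrespective of labels.

**What passing tests do not show.** The generator has no linkage
disequilibrium, genome coordinates, population structure, confounding
between druggability and constraint, or correlated missingness; the
*other* class receives no directional genetic signal (its real-data
predictability arises from correlations between mechanism classes that
are not modelled), so gene-disease AUROC for *other* is ~0.5 here by
construction. Recovery results therefore demonstrate that the pipeline
is correct and leakage-free, not that real-data performance will match.

## Study conditions and problem sizes

The packaged studies use: gene-level runs at n = 4 000 genes with 40
tabular features, 64 gene-embedding and 32 protein-embedding dimensions
and `signal_strength = 0.3` — the documented gene-level condition,
chosen because the dense 136-column design is far more informative per
unit class shift than the sparse genetic features and 0.3 lands
holdout macro-AUROC near 0.9, the realistic regime (1.0 saturates);
gene-disease runs at 20 000 pairs with the default
`signal_strength = 1.0`; bootstrap-coverage simulation at 500
replicates of n = 500 with 200 bootstrap iterations (the reported CIs
elsewhere use 1 000); calibration checks at n = 10 000. The full
425-column assembly (41 + 256 + 128) is exercised at a smaller gene
count. These sizes are the package's own desk-scale choices; all scale
up by configuration.

## Known limitations

* The 41-feature and 31-feature schemas, the 14 rare-variant
  categories, and the mechanism term map are reconstructions; all are
  schema-file-driven so real-data users can rebind them.
* Predictions are deterministic given seed *and* library versions;
  XGBoost does not guarantee bit-identical models across versions.
* The gene-disease model's *other* class is structurally at chance on
  synthetic data (see above).
* `bootstrap_ci` can return intervals not containing the point estimate
  in principle — a property of the reverse percentile method, not a
  bug.
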