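"""Downstream validation: trial-phase outcomes and enrichment odds ratios.

Checks whether DOE predictions are associated with real-world signals:
clinical-trial phase progression (success = any drug of the unit reached
the target phase; failure = reached the source phase but stalled with no
active development), and enrichment of outcomes above prediction
percentiles via 2x2 odds ratios with Wald confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ACTIVE_STATUSES",
    "phase_outcomes",
    "enrichment_or",
    "two_score_logistic",
    "intersect_predictions",
    "EnrichmentResult",
]

#: Trial statuses counted as active development; anything else (or an
#: unknown status) is treated as inactive.
ACTIVE_STATUSES = frozenset({
    "recruiting",
    "active, not recruiting",
    "not yet recruiting",
    "enrolling by invitation",
})

_PHASE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4, "1": 1, "2": 2, "3": 3, "4": 4}

_UNIT_KEYS = {
    "target": ["gene_id"],
    "target-doe": ["gene_id", "doe"],
    "target-doe-disease": ["gene_id", "doe", "disease_code"],
}


def _phase_num(phase) -> int:
    key = str(phase).strip().upper()
    if key not in _PHASE_ORDER:
        raise ValueError(f"unknown trial phase {phase!r}")
    return _PHASE_ORDER[key]


def phase_outcomes(records: pd.DataFrame, from_phase, to_phase,
                   unit: str = "target") -> pd.DataFrame:
    """Label analysis units as phase-transition successes or failures.

    A unit succeeds for X -> Y when any of its drugs reached phase >= Y;
    it fails when some drug reached >= X, none reached Y, and none of the
    drugs that reached >= X is still in active development (latest status
    per drug; unknown statuses count as inactive and are logged).  Units
    with an active not-yet-successful drug are excluded (still running).

    ``unit`` is one of target, target-doe, target-doe-disease.
    """
    if unit not in _UNIT_KEYS:
        raise ValueError(f"unit must be one of {sorted(_UNIT_KEYS)}")
    x, y_phase = _phase_num(from_phase), _phase_num(to_phase)
    if x >= y_phase:
        raise ValueError("from_phase must precede to_phase")
    keys = _UNIT_KEYS[unit]
    rec = records.copy()
    rec["_phase"] = rec["max_phase"].map(_phase_num)
    status = rec["status"].astype(str).str.strip().str.lower()
    known = status.isin(ACTIVE_STATUSES) | status.isin(
        {"completed", "terminated", "withdrawn", "suspended", "unknown", "approved", "nan", ""})
    if (~known).any():
        logger.warning("%d records with unrecognized status treated as inactive", int((~known).sum()))
    rec["_active"] = status.isin(ACTIVE_STATUSES)

    # latest status per drug within unit: keep the last record per drug
    per_drug = rec.groupby(keys + ["drug_id"], sort=True).agg(
        _phase=("_phase", "max"), _active=("_active", "last")).reset_index()

    rows = []
    for unit_key, grp in per_drug.groupby(keys, sort=True):
        if not isinstance(unit_key, tuple):
            unit_key = (unit_key,)
        reached_y = (grp["_phase"] >= y_phase).any()
        eligible = grp[grp["_phase"] >= x]
        if reached_y:
            outcome = "success"
        elif len(eligible) == 0:
            continue  # never entered the transition
        elif eligible["_active"].any():
            outcome = "excluded"  # still in active development
        else:
            outcome = "failure"
        rows.append(dict(zip(keys, unit_key)) | {"outcome": outcome})
    return pd.DataFrame(rows, columns=keys + ["outcome"])


@dataclass
class EnrichmentResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    table: np.ndarray  # [[exposed&pos, exposed&neg], [rest&pos, rest&neg]]
    threshold: float
    corrected: bool  # Haldane 0.5 correction applied to a zero cell


def _or_from_table(a: float, b: float, c: float, d: float) -> tuple[float, float, float, bool]:
    corrected = False
    if min(a, b, c, d) == 0:
        logger.warning("zero cell in 2x2 table; applying Haldane 0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return or_, float(np.exp(np.log(or_) - z * se)), float(np.exp(np.log(or_) + z * se)), corrected


def enrichment_or(scores, outcomes, percentile: float | None = None,
                  cutoff: float | None = None) -> EnrichmentResult:
    """Odds ratio of a binary outcome above vs below a score threshold.

    Dichotomize at the given percentile (nearest-rank over the analyzed
    population) or explicit cutoff; the OR comes from the 2x2 table
    (identical to a single-covariate logistic regression estimate) with a
    Wald 95% CI on the log OR; zero cells get the Haldane 0.5 correction
    with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome levels must be present")
    if (percentile is None) == (cutoff is None):
        raise ValueError("give exactly one of percentile or cutoff")
    if percentile is not None:
        thr = float(np.quantile(s, percentile / 100.0, method="inverted_cdf"))
        exposed = s > thr
    else:
        thr = float(cutoff)
        exposed = s >= thr
    a = int((exposed & (y == 1)).sum())
    b = int((exposed & (y == 0)).sum())
    c = int((~exposed & (y == 1)).sum())
    d = int((~exposed & (y == 0)).sum())
    or_, lo, hi, corrected = _or_from_table(a, b, c, d)
    return EnrichmentResult(odds_ratio=float(or_), ci_lower=lo, ci_upper=hi,
                            table=np.array([[a, b], [c, d]]), threshold=thr, corrected=corrected)


def two_score_logistic(score1, score2, outcomes) -> pd.DataFrame:
    """Multivariable logistic fit of an outcome on two prediction scores.

    Thin extension of the enrichment analysis for the case where both the
    gene-level and gene-disease-level scores enter one model; returns per
    -covariate odds ratios with Wald CIs.
    """
    import statsmodels.api as sm

    X = sm.add_constant(pd.DataFrame({"score1": np.asarray(score1, float),
                                      "score2": np.asarray(score2, float)}))
    fit = sm.Logit(np.asarray(outcomes).astype(int), X).fit(disp=0)
    ci = fit.conf_int()
    out = pd.DataFrame({
        "odds_ratio": np.exp(fit.params), "ci_lower": np.exp(ci[0]), "ci_upper": np.exp(ci[1]),
        "p_value": fit.pvalues,
    })
    return out.drop(index="const")


def intersect_predictions(gene_preds: pd.DataFrame, pair_preds: pd.DataFrame,
                          thresholds: dict[str, tuple[float, float]],
                          labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine gene-level and gene-disease-level predictions per class.

    ``gene_preds`` is indexed by gene_id with one probability column per
    class; ``pair_preds`` and ``labels`` are indexed by (gene_id,
    disease_code) with per-class probability / boolean columns.
    ``thresholds`` maps class -> (gene threshold, pair threshold).
    Returns the per-pair flag table and an enrichment summary per class
    and flag type; pairs missing a gene-level prediction are skipped and
    counted.
    """
    flags_rows = []
    enrich_rows = []
    for cls, (thr_gene, thr_pair) in thresholds.items():
        pp = pair_preds[cls]
        genes = pp.index.get_level_values("gene_id")
        has_gene = genes.isin(gene_preds.index)
        n_skipped = int((~has_gene).sum())
        if n_skipped:
            logger.warning("%d pairs lack a gene-level prediction for %s; skipped", n_skipped, cls)
        pp = pp[has_gene]
        gp = gene_preds.loc[pp.index.get_level_values("gene_id"), cls].to_numpy()
        flag_gene = gp >= thr_gene
        flag_pair = pp.to_numpy() >= thr_pair
        flag_both = flag_gene & flag_pair
        y = labels.reindex(pp.index)[cls].astype(bool).to_numpy()
        df = pd.DataFrame({"doe": cls, "gene_flag": flag_gene, "pair_flag": flag_pair,
                           "both_flag": flag_both, "label": y}, index=pp.index)
        df["n_skipped_missing_gene_pred"] = n_skipped
        flags_rows.append(df)
        for name, flag in (("gene", flag_gene), ("pair", flag_pair), ("both", flag_both)):
            if flag.all() or not flag.any():
                enrich_rows.append({"doe": cls, "flag": name, "odds_ratio": np.nan,
                                    "ci_lower": np.nan, "ci_upper": np.nan, "degenerate": True})
                continue
            a = int((flag & y).sum()); b = int((flag & ~y).sum())
            c = int((~flag & y).sum()); d = int((~flag & ~y).sum())
            or_, lo, hi, _ = _or_from_table(a, b, c, d)
            enrich_rows.append({"doe": cls, "flag": name, "odds_ratio": or_,
                                "ci_lower": lo, "ci_upper": hi, "degenerate": False})
    return pd.concat(flags_rows), pd.DataFrame(enrich_rows)
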