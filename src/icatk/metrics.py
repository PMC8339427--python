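"""Diagnostic-evaluation statistics.

ROC AUC (Mann-Whitney convention, ties at 1/2), sensitivity/specificity with
Wald binomial confidence intervals, paper-and-pencil comparator cutoffs
(MoCA >= 26 healthy, ACE >= 90 healthy), positive/negative/overall percent
agreement between two binary tests, Cohen's d with pooled sd, Pearson
correlation, a one-way ANOVA over session index for practice-effect analysis,
and per-image group performance matrices.

AUC confidence intervals use DeLong's method.  Proportion intervals use the
Wald normal approximation clipped to [0, 100], which is the convention the
published tables follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "BinaryMetrics",
    "AgreementResult",
    "EffectSizeResult",
    "ImagePerformanceMatrix",
    "roc_auc",
    "roc_points",
    "auc_delong_ci",
    "sensitivity_specificity",
    "wald_ci",
    "comparator_prediction",
    "COMPARATOR_CUTOFFS",
    "percent_agreement",
    "cohens_d",
    "pearson_correlation",
    "practice_effect_anova",
    "image_performance_matrix",
    "bonferroni",
]

Z_95 = 1.959964

COMPARATOR_CUTOFFS = {"moca": (26, 30), "ace": (90, 100)}  # (healthy cutoff, scale max)


@dataclass(frozen=True)
class BinaryMetrics:
    """Sensitivity/specificity (percent, with 95% CIs) and optional AUC."""

    sensitivity_pct: float
    sensitivity_ci: tuple[float, float]
    specificity_pct: float
    specificity_ci: tuple[float, float]
    n_positive: int
    n_negative: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class AgreementResult:
    """Percent agreement between two binary tests, with 95% Wald CIs."""

    ppa_pct: float
    ppa_ci: tuple[float, float]
    npa_pct: float
    npa_ci: tuple[float, float]
    opa_pct: float
    opa_ci: tuple[float, float]
    reference: str


@dataclass(frozen=True)
class EffectSizeResult:
    cohens_d: float
    p_value: float


@dataclass(frozen=True)
class ImagePerformanceMatrix:
    """Per-(group, item) mean accuracy and reaction time, animal items first."""

    accuracy: pd.DataFrame  # groups x items, values in [0, 1] (NaN = no data)
    rt_ms: pd.DataFrame


def _binary_arrays(scores, labels, positive_label=None):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have the same length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[1]
    y = (labels == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return scores, y


def roc_auc(scores, labels, positive_label=None) -> float:
    """Area under the ROC curve on a continuous score.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, with ties counted 1/2.
    """
    scores, y = _binary_arrays(scores, labels, positive_label)
    return float(roc_auc_score(y, scores))


def roc_points(scores, labels, positive_label=None) -> pd.DataFrame:
    """ROC curve points (false positive rate, true positive rate, threshold)."""
    scores, y = _binary_arrays(scores, labels, positive_label)
    fpr, tpr, thr = roc_curve(y, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def auc_delong_ci(scores, labels, positive_label=None, level: float = 0.95):
    """AUC with a DeLong confidence interval, clipped to [0, 1]."""
    scores, y = _binary_arrays(scores, labels, positive_label)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_scores)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    # placement values (DeLong structural components)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(auc), (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))


def wald_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald binomial CI for a proportion, in percent, clipped to [0, 100]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    p = successes / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return (
        float(np.clip(100 * (p - half), 0, 100)),
        float(np.clip(100 * (p + half), 0, 100)),
    )


def sensitivity_specificity(
    predictions,
    labels,
    positive_label="impaired",
    scores=None,
) -> BinaryMetrics:
    """Sensitivity and specificity of predicted labels against true labels.

    Sensitivity is the percent of true positives (impaired) predicted
    positive; specificity the percent of true negatives predicted negative.
    CIs are Wald intervals.  If a continuous ``scores`` vector is supplied,
    AUC with a DeLong CI is included.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels must have the same length")
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the true labels")
    tp = int(((predictions == positive_label) & pos).sum())
    tn = int(((predictions != positive_label) & ~pos).sum())
    sens = 100.0 * tp / n_pos
    spec = 100.0 * tn / n_neg
    auc = auc_ci = None
    if scores is not None:
        auc, auc_ci = auc_delong_ci(scores, labels, positive_label)
    return BinaryMetrics(
        sensitivity_pct=sens,
        sensitivity_ci=wald_ci(tp, n_pos),
        specificity_pct=spec,
        specificity_ci=wald_ci(tn, n_neg),
        n_positive=n_pos,
        n_negative=n_neg,
        auc=auc,
        auc_ci=auc_ci,
    )


def comparator_prediction(score: float, test: str) -> str:
    """Healthy/impaired label from a paper-and-pencil test's single cutoff."""
    test = test.lower()
    if test not in COMPARATOR_CUTOFFS:
        raise ValueError(f"test must be one of {sorted(COMPARATOR_CUTOFFS)}, got {test!r}")
    cutoff, scale_max = COMPARATOR_CUTOFFS[test]
    if not 0 <= score <= scale_max:
        raise ValueError(f"{test} score must be in [0, {scale_max}], got {score}")
    return "healthy" if score >= cutoff else "impaired"


def percent_agreement(pred_a, pred_b, reference: str = "comparator") -> AgreementResult:
    """Positive/negative/overall percent agreement between two binary tests.

    ``pred_b`` is the reference: PPA is agreement among reference-impaired
    participants, NPA among reference-healthy.  OPA is symmetric in the two
    tests.  Labels must be "healthy"/"impaired".
    """
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("prediction sequences must have the same length")
    if a.shape[0] == 0:
        raise ValueError("empty predictions")
    ref_pos = b == "impaired"
    n_pos, n_neg = int(ref_pos.sum()), int((~ref_pos).sum())
    both_pos = int(((a == "impaired") & ref_pos).sum())
    both_neg = int(((a == "healthy") & ~ref_pos).sum())
    agree = int((a == b).sum())
    n = a.shape[0]
    return AgreementResult(
        ppa_pct=100.0 * both_pos / n_pos if n_pos else float("nan"),
        ppa_ci=wald_ci(both_pos, n_pos) if n_pos else (float("nan"), float("nan")),
        npa_pct=100.0 * both_neg / n_neg if n_neg else float("nan"),
        npa_ci=wald_ci(both_neg, n_neg) if n_neg else (float("nan"), float("nan")),
        opa_pct=100.0 * agree / n,
        opa_ci=wald_ci(agree, n),
        reference=reference,
    )


def cohens_d(group_x, group_y) -> EffectSizeResult:
    """Standardized mean difference (pooled sd, n-1 weights) with t-test p."""
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = ((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2)
    if pooled <= 0:
        raise ValueError("pooled variance is zero; effect size undefined")
    d = (x.mean() - y.mean()) / np.sqrt(pooled)
    t = stats.ttest_ind(x, y)
    return EffectSizeResult(cohens_d=float(d), p_value=float(t.pvalue))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant sequence")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def practice_effect_anova(session_table: pd.DataFrame, value: str = "ica_index"):
    """One-way ANOVA of a session score grouped by session number.

    Tests whether the mean score drifts across repeated test administrations;
    a flat profile (no practice effect) should not reject.  Returns (F, p).

    When the table carries a ``participant_id`` column, stable participant
    effects are removed first (each participant's scores are centred on their
    own mean).  With the same participants re-tested in every session, a raw
    one-way ANOVA is severely conservative — between-participant spread
    inflates the within-group variance while the session means, sharing the
    same participants, barely move — so the centred version is required for
    the test to hold its nominal size.
    """
    if "session_index" not in session_table.columns:
        raise ValueError("session table must have a 'session_index' column")
    table = session_table
    if "participant_id" in table.columns:
        centred = table[value] - table.groupby("participant_id")[value].transform("mean")
        table = table.assign(**{value: centred})
    groups = [
        g[value].to_numpy()
        for _, g in table.groupby("session_index")
        if len(g) >= 2
    ]
    if len(groups) < 2:
        raise ValueError("need at least two session groups with >= 2 observations")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance; ANOVA undefined")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def image_performance_matrix(
    session_logs: Mapping[str, Sequence],
    diagnoses: Mapping[str, str],
    bank: Sequence | None = None,
    groups: Sequence[str] = ("healthy", "mci", "mild_ad"),
) -> ImagePerformanceMatrix:
    """Mean accuracy and RT per (diagnosis group, item) over main-phase trials.

    ``session_logs`` maps participant id to trial records; ``diagnoses`` maps
    participant id to group.  Items are ordered with the animal block first.
    Groups without any sessions yield NaN rows (missing, not zero).
    """
    rows = []
    for pid, records in session_logs.items():
        if pid not in diagnoses:
            raise ValueError(f"no diagnosis for participant {pid!r}")
        for r in records:
            if r.phase != "main":
                continue
            rows.append(
                {
                    "group": diagnoses[pid],
                    "item_id": r.item_id,
                    "category": r.category,
                    "correct": float(r.correct),
                    "rt_ms": r.rt_ms if r.rt_ms is not None else np.nan,
                }
            )
    if not rows:
        raise ValueError("no main-phase records in the session logs")
    df = pd.DataFrame(rows)

    if bank is not None:
        known = {it.item_id for it in bank}
        unknown = sorted(set(df["item_id"]) - known)
        if unknown:
            raise ValueError(f"records reference items not in the bank: {unknown[:5]}")
        order = [it.item_id for it in sorted(bank, key=lambda it: it.category != "animal")]
    else:
        cats = df.drop_duplicates("item_id").set_index("item_id")["category"]
        order = sorted(cats.index, key=lambda i: (cats[i] != "animal", i))

    acc = (
        df.pivot_table(index="group", columns="item_id", values="correct", aggfunc="mean")
        .reindex(index=list(groups), columns=order)
    )
    rt = (
        df.pivot_table(index="group", columns="item_id", values="rt_ms", aggfunc="mean")
        .reindex(index=list(groups), columns=order)
    )
    return ImagePerformanceMatrix(accuracy=acc, rt_ms=rt)


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni-adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    adj = np.minimum(p * p.size, 1.0)
    return adj, adj < alpha
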