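"""Evaluation statistics for classifier and site-level analyses.

ROC/AUC with midrank tie handling, Youden's J operating cutoffs, exact
binomial (Clopper-Pearson) confidence intervals, Cohen's kappa, chi-square
goodness of fit, and Wilcoxon rank-sum testing with Benjamini-Hochberg FDR
correction. Confidence intervals and accuracies are reported in percent; one
decimal is a formatting convention only, full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class BinomialCI:
    successes: int
    trials: int
    alpha: float
    lower: float  # percent
    upper: float  # percent

    @property
    def estimate(self) -> float:
        return 100.0 * self.successes / self.trials

    def formatted(self) -> str:
        """Report string in percent to one decimal, e.g. '95.8% (78.9% - 99.9%)'."""
        return (f"{self.estimate:.1f}% ({self.lower:.1f}% - {self.upper:.1f}%)")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC curve and AUC for a binary contrast.

    AUC uses the midrank convention for ties and equals the normalized
    Mann-Whitney U statistic; orientation is AUC > 0.5 when positive-class
    scores tend higher.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(y, s)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auc=float(roc_auc_score(y, s)))


def youden_cutoff(r: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (the more conservative cutoff).
    Returns (threshold, sensitivity, specificity) at the chosen point.
    """
    j = r.sensitivity + r.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    i = best[np.argmax(r.specificity[best])]
    return float(r.thresholds[i]), float(r.sensitivity[i]), float(r.specificity[i])


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> BinomialCI:
    """Exact two-sided binomial confidence interval, in percent.

    Lower bound is 0 when successes = 0 and upper bound 100 when
    successes = trials (the usual one-sided conventions at the boundary).
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    x, n = successes, trials
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialCI(successes=x, trials=n, alpha=alpha,
                      lower=100.0 * lower, upper=100.0 * upper)


def format_accuracy(successes: int, trials: int) -> str:
    """Accuracy as percent to one decimal, e.g. 28/30 -> '93.3%'."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    return f"{100.0 * successes / trials:.1f}%"


def cohen_kappa(confusion: pd.DataFrame | np.ndarray) -> float:
    """Cohen's kappa from a square label-count table.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    marginal products. Raises on p_e = 1 (degenerate marginals).
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion table must be square")
    if np.any(c < 0):
        raise ValueError("confusion counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion table must contain counts")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) / total) @ (c.sum(axis=0) / total))
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_table(predicted: Sequence[str], truth: Sequence[str],
                    labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Square count table with truth on rows and predictions on columns."""
    pred = pd.Series(list(predicted), name="predicted")
    true = pd.Series(list(truth), name="truth")
    if len(pred) != len(true):
        raise ValueError("predicted and truth must have equal length")
    if labels is None:
        labels = sorted(set(pred) | set(true))
    tab = pd.crosstab(true, pred).reindex(index=labels, columns=labels, fill_value=0)
    return tab


def chisq_gof(observed: Sequence[float],
              expected_proportions: Sequence[float]) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit against expected proportions.

    Returns (statistic, df, p) with df = k - 1 and an upper-tail p-value.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("observed counts must sum to a positive total")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = props * obs.sum()
    if np.any(expected <= 0):
        raise ValueError("expected counts must all be positive")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), len(obs) - 1, float(p)


def wilcoxon_fdr(groups: Mapping[str, Sequence[float]],
                 pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment.

    ``pairs`` defines the family over which the FDR correction is applied
    (e.g. the comparisons shown together in one figure panel). Returns a
    DataFrame with columns group_a, group_b, statistic, p, q.
    """
    rows = []
    for a, b in pairs:
        va = np.asarray(groups[a], dtype=float)
        vb = np.asarray(groups[b], dtype=float)
        if va.size == 0 or vb.size == 0:
            raise ValueError(f"empty group in pair ({a}, {b})")
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def evaluate_predictions(predicted: Sequence[str], truth: Sequence[str],
                         alpha: float = 0.05,
                         ignore: tuple[str, ...] = ("equivocal",)) -> dict:
    """Accuracy with exact CI, kappa, and per-class sensitivity/specificity.

    Samples whose prediction is in ``ignore`` (equivocal abstentions by
    default) are excluded from accuracy/kappa, and their count is reported.
    """
    pred = pd.Series(list(predicted))
    true = pd.Series(list(truth))
    if len(pred) != len(true):
        raise ValueError("predicted and truth must have equal length")
    keep = ~pred.isin(ignore)
    n_excluded = int((~keep).sum())
    pred_k, true_k = pred[keep], true[keep]
    n = len(pred_k)
    if n == 0:
        raise ValueError("no classified samples to evaluate")
    correct = int((pred_k.to_numpy() == true_k.to_numpy()).sum())
    ci = clopper_pearson(correct, n, alpha=alpha)
    tab = confusion_table(pred_k, true_k)
    per_class = {}
    arr = tab.to_numpy(dtype=float)
    for i, lab in enumerate(tab.index):
        tp = arr[i, i]
        fn = arr[i].sum() - tp
        fp = arr[:, i].sum() - tp
        tn = arr.sum() - tp - fn - fp
        per_class[lab] = {
            "sensitivity": tp / (tp + fn) if tp + fn > 0 else np.nan,
            "specificity": tn / (tn + fp) if tn + fp > 0 else np.nan,
        }
    return {
        "n": n,
        "n_excluded": n_excluded,
        "correct": correct,
        "accuracy": correct / n,
        "accuracy_formatted": format_accuracy(correct, n),
        "ci": ci,
        "kappa": cohen_kappa(tab),
        "confusion": tab,
        "per_class": per_class,
    }
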