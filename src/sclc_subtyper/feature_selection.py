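"""One-vs-rest AUROC association of features with subtypes, site selection
under per-subtype AUC / effect-size criteria, top-k gene selection, and
gene-ratio feature construction.

The association statistic per feature is the one-vs-rest AUC, computed as the
normalized Mann-Whitney U with midrank tie handling, oriented so that
AUC > 0.5 when in-class values tend higher. ``delta`` is the mean in-class
value minus the mean out-of-class value (percentage points for methylation).
Missing values are excluded pairwise per feature.

Site selection follows the published per-subtype criteria: a site is selected
for a subtype when its association AUC passes the subtype's threshold in
either direction (hyper- or hypomethylated markers both count, i.e.
max(AUC, 1-AUC) is compared against the threshold, matching ROC analysis
with automatic direction) and |delta| passes the subtype's minimum
methylation difference. Default thresholds: SCLC-A (0.70, 25 points),
SCLC-N (0.70, 30), SCLC-P (0.80, 35), SCLC-I (0.70, 30). An optional
secondary association table (e.g. from cell lines) restricts the selection
to sites that are also associated in the second dataset (AUC > 0.7 by
default), the guard used to keep tumor-intrinsic signals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .methylome_io import SUBTYPES, CpGSite, ExpressionMatrix

DEFAULT_SITE_CRITERIA: dict[str, tuple[float, float]] = {
    "SCLC-A": (0.70, 25.0),
    "SCLC-N": (0.70, 30.0),
    "SCLC-P": (0.80, 35.0),
    "SCLC-I": (0.70, 30.0),
}
DEFAULT_SECONDARY_MIN_AUC = 0.70


@dataclass
class SiteCriteria:
    """Per-subtype (min AUC, min |mean beta difference| in points) thresholds."""

    thresholds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SITE_CRITERIA))

    def __post_init__(self) -> None:
        for subtype, (min_auc, min_delta) in self.thresholds.items():
            if not 0.5 <= min_auc <= 1.0:
                raise ValueError(f"{subtype}: min_auc must lie in [0.5, 1]")
            if min_delta < 0:
                raise ValueError(f"{subtype}: min_abs_delta must be >= 0")


def _ovr_auc_delta(values: np.ndarray, in_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-vs-rest AUC and mean difference per feature (row).

    NaNs are excluded pairwise. Features where either class has no observed
    value, or with zero variance, get AUC 0.5 by convention; delta is NaN when
    a class mean is undefined.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    ranks = rankdata(values, axis=1, nan_policy="omit")
    in_obs = obs & in_mask
    out_obs = obs & ~in_mask
    n1 = in_obs.sum(axis=1).astype(float)
    n0 = out_obs.sum(axis=1).astype(float)
    r1 = np.where(in_obs, np.nan_to_num(ranks), 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        mean_in = np.where(in_obs, np.nan_to_num(values), 0.0).sum(axis=1) / n1
        mean_out = np.where(out_obs, np.nan_to_num(values), 0.0).sum(axis=1) / n0
    auc = np.where((n1 == 0) | (n0 == 0), 0.5, auc)
    delta = mean_in - mean_out
    return auc, delta


def associate_features(matrix: pd.DataFrame, labels: Sequence[str] | pd.Series,
                       subtype: str) -> pd.DataFrame:
    """One-vs-rest association of every feature (row) with one subtype.

    ``matrix`` is features x samples; ``labels`` gives the subtype per sample
    in column order (or indexed by sample id). Returns a DataFrame indexed by
    feature id with columns ``auc`` and ``delta``.
    """
    if isinstance(labels, pd.Series):
        labels = labels.loc[list(matrix.columns)]
    labels = np.asarray(labels)
    if len(labels) != matrix.shape[1]:
        raise ValueError("labels length must match number of samples")
    in_mask = labels == subtype
    if not in_mask.any() or in_mask.all():
        raise ValueError(f"need samples both in and out of class {subtype!r}")
    auc, delta = _ovr_auc_delta(matrix.to_numpy(dtype=float), in_mask)
    return pd.DataFrame({"auc": auc, "delta": delta}, index=matrix.index)


def associate_all_subtypes(matrix: pd.DataFrame,
                           labels: Sequence[str] | pd.Series,
                           subtypes: Sequence[str] = SUBTYPES
                           ) -> dict[str, pd.DataFrame]:
    """Per-subtype one-vs-rest association tables for every feature."""
    return {s: associate_features(matrix, labels, s) for s in subtypes}


def select_sites(assoc: Mapping[str, pd.DataFrame],
                 criteria: SiteCriteria | None = None,
                 secondary_assoc: Mapping[str, pd.DataFrame] | None = None,
                 secondary_min_auc: float = DEFAULT_SECONDARY_MIN_AUC,
                 ) -> dict[str, list[str]]:
    """Per-subtype site sets passing the AUC and |delta| criteria.

    Association is two-sided on the AUC (max(auc, 1-auc) against the
    threshold), so markers methylated either above or below the other
    subtypes qualify. When ``secondary_assoc`` is given (a second dataset,
    e.g. cell lines), a site must additionally pass ``secondary_min_auc``
    there (two-sided as well). Within each subtype, selected sites are
    ordered by descending two-sided AUC, then larger |delta|, then id.
    """
    criteria = criteria or SiteCriteria()
    out: dict[str, list[str]] = {}
    for subtype, (min_auc, min_delta) in criteria.thresholds.items():
        table = assoc[subtype]
        auc2 = np.maximum(table["auc"], 1.0 - table["auc"])
        keep = (auc2 >= min_auc) & (table["delta"].abs() >= min_delta)
        if secondary_assoc is not None:
            sec = secondary_assoc[subtype]
            sec_auc2 = np.maximum(sec["auc"], 1.0 - sec["auc"])
            sec_pass = sec_auc2.reindex(table.index) >= secondary_min_auc
            keep &= sec_pass.fillna(False)
        selected = table[keep].copy()
        selected["auc2"] = auc2[keep]
        selected["abs_delta"] = selected["delta"].abs()
        selected["_id"] = selected.index
        selected = selected.sort_values(
            by=["auc2", "abs_delta", "_id"], ascending=[False, False, True],
            kind="mergesort")
        out[subtype] = list(selected.index)
    return out


def selection_report(assoc: Mapping[str, pd.DataFrame],
                     selected: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Tidy export of selected features: feature, subtype, auc, delta."""
    rows = []
    for subtype, feats in selected.items():
        sub = assoc[subtype].loc[list(feats)]
        for feat, row in sub.iterrows():
            rows.append((feat, subtype, row["auc"], row["delta"]))
    return pd.DataFrame(rows, columns=["feature", "subtype", "auc", "delta"])


def sites_to_bed(site_ids: Sequence[str], path) -> None:
    """Write CpG site ids as a BED file (0-based half-open single bases)."""
    sites = [CpGSite.parse(s) for s in site_ids]
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: x.sort_key()):
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.id}\n")


def select_top_genes(assoc: Mapping[str, pd.DataFrame], k: int = 50) -> list[str]:
    """Union of the k genes with highest one-vs-rest AUC per subtype.

    Ties are broken by larger |delta|, then lexicographic gene id. The union
    may be smaller than 4k when subtypes share top genes (e.g. the published
    gene-ratio classifier kept 181 of a possible 200).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    union: set[str] = set()
    for subtype, table in assoc.items():
        if len(table) < k:
            raise ValueError(
                f"only {len(table)} genes available for {subtype}, need {k}")
        ranked = table.assign(abs_delta=table["delta"].abs(), _id=table.index)
        ranked = ranked.sort_values(by=["auc", "abs_delta", "_id"],
                                    ascending=[False, False, True],
                                    kind="mergesort")
        union.update(ranked.index[:k])
    return sorted(union)


def make_ratio_features(expr: ExpressionMatrix, genes: Sequence[str],
                        epsilon: float = 1.0, log2: bool = True) -> pd.DataFrame:
    """All pairwise gene-ratio features over a gene set.

    One feature per unordered pair {a, b} (g(g-1)/2 features), canonically
    oriented with the lexicographically smaller gene as numerator, valued
    log2((a + eps) / (b + eps)) per sample. ``log2=False`` gives the raw
    pseudocounted ratio instead.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in ratio feature request")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0 to keep ratios finite")
    genes = sorted(genes)
    vals = expr.values.loc[genes].to_numpy(dtype=float) + epsilon
    pairs = list(itertools.combinations(range(len(genes)), 2))
    num = np.array([i for i, _ in pairs])
    den = np.array([j for _, j in pairs])
    ratio = vals[num] / vals[den]
    if log2:
        ratio = np.log2(ratio)
    index = [f"{genes[i]}/{genes[j]}" for i, j in pairs]
    return pd.DataFrame(ratio, index=index, columns=expr.values.columns)
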