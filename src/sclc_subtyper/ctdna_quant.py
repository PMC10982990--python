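"""cfDNA tumor-fraction estimation from methylation reporter sites.

Sites whose methylation level tracks the tumor fraction linearly are found by
regressing each site's beta value (percent) on an external per-sample tumor
fraction truth (percent, e.g. from ultra-low-pass WGS copy-number profiling).
Sites pass calibration when the fit has R^2 > 0.65, slope within 0.9–1.1 and
intercept within -10..10 — i.e. the site reads out the fraction near the
identity on the percent scale. The estimator itself is the arithmetic mean of
the observed reporter-site betas; the package ships the seven published
reporter sites as the default so the estimator runs without calibration data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome_io import MethylationMatrix

#: Published cfDNA tumor-fraction reporter CpGs (GRCh38).
SEVEN_SITE_PANEL: tuple[str, ...] = (
    "chr12:27974490",
    "chr1:7236563",
    "chr17:29139387",
    "chr19:128737209",
    "chr2:10401557",
    "chr21:34669078",
    "chr21:45590104",
)


@dataclass
class CalibrationCriteria:
    """Thresholds a site must meet to qualify as a tumor-fraction reporter."""

    min_r2: float = 0.65
    slope_range: tuple[float, float] = (0.9, 1.1)
    intercept_range: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_r2 <= 1.0:
            raise ValueError("min_r2 must lie in [0, 1]")
        for name, (lo, hi) in (("slope_range", self.slope_range),
                               ("intercept_range", self.intercept_range)):
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high")


@dataclass
class FractionEstimator:
    """Mean-methylation tumor-fraction estimator over a reporter-site panel."""

    sites: tuple[str, ...] = field(default_factory=lambda: SEVEN_SITE_PANEL)

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("estimator needs at least one site")
        self.sites = tuple(self.sites)


def calibrate_sites(m: MethylationMatrix,
                    truth_fractions: pd.Series | Mapping[str, float],
                    criteria: CalibrationCriteria | None = None,
                    min_pairs: int = 3,
                    return_all: bool = False) -> pd.DataFrame:
    """Per-site OLS of beta (percent) on tumor-fraction truth (percent).

    Uses pairwise-complete samples per site. Sites with fewer than
    ``min_pairs`` complete pairs, or with an undefined fit (constant truth or
    constant beta), are skipped with a warning. Returns the sites passing all
    criteria sorted by R^2 descending, with columns r2/slope/intercept/n;
    ``return_all=True`` instead returns every evaluated site with a
    ``selected`` flag.
    """
    criteria = criteria or CalibrationCriteria()
    if isinstance(truth_fractions, Mapping):
        truth_fractions = pd.Series(truth_fractions, dtype=float)
    common = [s for s in m.samples if s in truth_fractions.index
              and np.isfinite(truth_fractions[s])]
    if len(common) < min_pairs:
        raise ValueError(
            f"need at least {min_pairs} samples with tumor-fraction truth")
    x_all = truth_fractions.loc[common].to_numpy(dtype=float)
    beta = m.beta[common].to_numpy(dtype=float)

    rows = []
    skipped = 0
    for i, site in enumerate(m.site_ids):
        y = beta[i]
        obs = np.isfinite(y)
        n = int(obs.sum())
        if n < min_pairs:
            skipped += 1
            continue
        x, yy = x_all[obs], y[obs]
        sxx = np.var(x)
        syy = np.var(yy)
        if sxx == 0 or syy == 0:
            skipped += 1
            continue
        sxy = np.mean((x - x.mean()) * (yy - yy.mean()))
        slope = sxy / sxx
        intercept = yy.mean() - slope * x.mean()
        r2 = (sxy * sxy) / (sxx * syy)
        rows.append((site, r2, slope, intercept, n))
    if skipped:
        warnings.warn(f"{skipped} site(s) skipped in calibration "
                      "(too few pairs or degenerate values)")
    report = pd.DataFrame(rows, columns=["site", "r2", "slope", "intercept", "n"])
    lo_s, hi_s = criteria.slope_range
    lo_i, hi_i = criteria.intercept_range
    report["selected"] = ((report["r2"] > criteria.min_r2)
                          & report["slope"].between(lo_s, hi_s)
                          & report["intercept"].between(lo_i, hi_i))
    report = report.sort_values(["r2", "site"], ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
    if return_all:
        return report
    return report[report["selected"]].drop(columns="selected").reset_index(drop=True)


def estimate_fraction(estimator: FractionEstimator,
                      sample_betas: pd.Series | Mapping[str, float]
                      ) -> tuple[float, int]:
    """Tumor fraction (percent) for one sample: mean of observed reporter betas.

    Returns (fraction, number of contributing sites); raises when none of the
    panel's sites is observed.
    """
    if isinstance(sample_betas, Mapping):
        sample_betas = pd.Series(sample_betas, dtype=float)
    vals = sample_betas.reindex(list(estimator.sites)).to_numpy(dtype=float)
    obs = np.isfinite(vals)
    if not obs.any():
        raise ValueError("no reporter sites observed in sample")
    return float(vals[obs].mean()), int(obs.sum())


def estimate_fractions(estimator: FractionEstimator,
                       m: MethylationMatrix) -> pd.DataFrame:
    """Per-sample tumor-fraction estimates over a methylation matrix."""
    rows = []
    for sample in m.samples:
        frac, n_used = estimate_fraction(estimator, m.beta[sample])
        rows.append((sample, frac, n_used))
    return pd.DataFrame(rows, columns=["sample", "fraction", "n_sites_used"])
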