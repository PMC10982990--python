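"""Seeded generator of methylation and expression cohorts with the
statistical structure the subtype classifiers assume.

The tissue generator emulates, per sample:

* a trimodal per-site baseline beta (modes near 5 / 50 / 95 percent,
  mimicking the bimodality of CpG methylation with a minor intermediate
  component);
* subtype-specific differential CpG sites, shifted by a planted effect size
  (``delta_beta`` percentage points) in that subtype's samples. The planted
  direction follows each subtype's global methylation phenotype:
  hypomethylated markers for SCLC-P, hypermethylated for the others;
* a genome-wide per-subtype offset (``global_shift``; default SCLC-P -8,
  SCLC-N +6 points, SCLC-A/I 0) reproducing the hypo-/hypermethylated
  phenotypes seen in tiled whole-genome profiles;
* ctDNA-reporter sites that are near-fully methylated in tumor of every
  subtype and unmethylated in the non-tumor background, so that a cfDNA
  mixture reads out the tumor fraction directly in percent;
* Gaussian within-class noise clipped to [0, 100] (transparent effect-size
  control; a Beta-noise option exists for realism), and uniform missingness
  emulating FFPE/cfDNA dropout.

Expression is generated analogously: log-normal null genes plus
subtype-specific marker programs with a multiplicative fold change.

cfDNA samples are linear tumor/leukocyte mixtures at a known tumor fraction:
``cfdna = f * tissue + (1 - f) * background + noise``, clipped to [0, 100].
The background is a constant non-tumor methylation level except at the
ctDNA-reporter sites, where it is 0.

Planted truth (differential site ids per subtype, marker genes, ctDNA sites,
labels, chromosome lengths) is returned alongside the data; recovery tests
read truth only from this channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome_io import (SUBTYPES, CpGSite, ExpressionMatrix,
                           MethylationMatrix, SampleSheet)

DEFAULT_GLOBAL_SHIFT = {"SCLC-A": 0.0, "SCLC-N": 6.0, "SCLC-P": -8.0, "SCLC-I": 0.0}
# planted direction of differential sites, aligned with the subtype's
# global methylation phenotype
DEFAULT_DIFF_SIGN = {"SCLC-A": +1.0, "SCLC-N": +1.0, "SCLC-P": -1.0, "SCLC-I": +1.0}
DEFAULT_CHROM_LENGTHS = {f"chr{i}": 10_000_000 for i in range(1, 23)}


@dataclass
class CohortSpec:
    """Study conditions for a synthetic tissue cohort."""

    n_per_subtype: int = 40
    n_sites_null: int = 2000
    n_sites_differential_per_subtype: int = 60
    delta_beta: float = 35.0              # planted in-class shift, points
    noise_sd: float = 8.0                 # within-class beta sd, points
    global_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLOBAL_SHIFT))
    diff_sign: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIFF_SIGN))
    missing_frac: float = 0.10
    n_sites_ctdna: int = 7
    ctdna_site_noise_sd: float = 1.0   # reporter sites are near-invariant in tumor
    n_genes_null: int = 400
    n_marker_genes_per_subtype: int = 25
    expression_fold_change: float = 8.0
    expression_sigma: float = 0.5         # log-normal within-class sd (ln scale)
    baseline_modes: tuple[float, float, float] = (5.0, 50.0, 95.0)
    baseline_weights: tuple[float, float, float] = (0.40, 0.20, 0.40)
    beta_noise: str = "gaussian"          # or "beta" for Beta-distributed noise
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_subtype, self.n_sites_null,
               self.n_sites_differential_per_subtype, self.n_sites_ctdna,
               self.n_genes_null, self.n_marker_genes_per_subtype) < 0:
            raise ValueError("counts must be >= 0")
        if self.delta_beta < 0 or self.noise_sd < 0:
            raise ValueError("delta_beta and noise_sd must be >= 0")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.beta_noise not in ("gaussian", "beta"):
            raise ValueError("beta_noise must be 'gaussian' or 'beta'")


@dataclass
class CfdnaSpec:
    """Mixture model for plasma samples derived from tissue profiles."""

    tumor_fraction: Mapping[str, float]   # per tissue sample id, in [0, 1]
    background_beta_mean: float = 50.0
    background_noise_sd: float = 3.0
    site_dropout_frac: float = 0.0        # extra cfDNA site thinning
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for sid, f in self.tumor_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"tumor fraction for {sid} outside [0, 1]: {f}")
        if not 0.0 <= self.site_dropout_frac < 1.0:
            raise ValueError("site_dropout_frac must lie in [0, 1)")


@dataclass
class CohortTruth:
    """Planted ground truth emitted with every synthetic cohort."""

    labels: dict[str, str]
    differential_sites: dict[str, list[str]]
    marker_genes: dict[str, list[str]]
    ctdna_sites: list[str]
    baseline_beta: dict[str, float]
    chrom_lengths: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_sites(rng: np.random.Generator, n: int,
                  chrom_lengths: Mapping[str, int]) -> list[str]:
    chroms = list(chrom_lengths)
    ids = set()
    out = []
    while len(out) < n:
        need = n - len(out)
        picks = rng.integers(0, len(chroms), size=need)
        for ci in picks:
            chrom = chroms[ci]
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            sid = CpGSite(chrom, pos).id
            if sid not in ids:
                ids.add(sid)
                out.append(sid)
    return out


def _add_noise(rng: np.random.Generator, means: np.ndarray, sd: float,
               kind: str) -> np.ndarray:
    if sd == 0:
        return means.copy()
    if kind == "gaussian":
        return means + rng.normal(0.0, sd, size=means.shape)
    # Beta-distributed noise with matched mean and (approximate) sd
    mu = np.clip(means / 100.0, 1e-4, 1 - 1e-4)
    var = (sd / 100.0) ** 2
    cap = mu * (1 - mu) * 0.99
    var = np.minimum(var, cap)
    conc = mu * (1 - mu) / var - 1.0
    return 100.0 * rng.beta(mu * conc, (1 - mu) * conc)


def simulate_tissue(spec: CohortSpec) -> tuple[MethylationMatrix, ExpressionMatrix,
                                               SampleSheet, CohortTruth]:
    """Generate a labeled tissue cohort with planted methylation and
    expression structure. Deterministic under ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    subtypes = SUBTYPES
    samples = [f"{s.split('-')[1]}{i:03d}" for s in subtypes
               for i in range(spec.n_per_subtype)]
    labels = {sid: s for s in subtypes for sid in
              [f"{s.split('-')[1]}{i:03d}" for i in range(spec.n_per_subtype)]}
    label_arr = np.array([labels[sid] for sid in samples])
    n_samples = len(samples)

    n_diff = spec.n_sites_differential_per_subtype
    n_total = (spec.n_sites_null + len(subtypes) * n_diff + spec.n_sites_ctdna)
    site_ids = _random_sites(rng, n_total, spec.chrom_lengths)
    site_ids = sorted(site_ids, key=lambda s: CpGSite.parse(s).sort_key())
    # role assignment is a seeded permutation over the sorted site list
    perm = rng.permutation(n_total)
    null_idx = perm[: spec.n_sites_null]
    diff_idx = {s: perm[spec.n_sites_null + k * n_diff:
                        spec.n_sites_null + (k + 1) * n_diff]
                for k, s in enumerate(subtypes)}
    ctdna_idx = perm[spec.n_sites_null + len(subtypes) * n_diff:]

    # per-site baseline: trimodal mixture; differential sites get a baseline
    # that keeps both classes away from the clip boundaries
    baseline = np.empty(n_total)
    modes = rng.choice(spec.baseline_modes, size=n_total, p=spec.baseline_weights)
    baseline[:] = modes + rng.normal(0, 2.0, size=n_total)
    margin = 2.5 * spec.noise_sd + 12.0
    lo = margin
    hi = 100.0 - margin - spec.delta_beta
    if hi <= lo:  # very large effects: center the band
        lo, hi = 20.0, max(21.0, 100.0 - spec.delta_beta - 20.0)
    for s in subtypes:
        idx = diff_idx[s]
        base = rng.uniform(lo, max(hi, lo + 1.0), size=idx.size)
        if spec.diff_sign.get(s, 1.0) < 0:
            base = base + spec.delta_beta  # shifting down: start high
        baseline[idx] = base
    baseline[ctdna_idx] = 99.0
    baseline = np.clip(baseline, 0.5, 99.5)

    means = np.tile(baseline[:, None], (1, n_samples))
    # genome-wide per-subtype offset
    for s in subtypes:
        shift = float(spec.global_shift.get(s, 0.0))
        if shift:
            means[:, label_arr == s] += shift
    # planted subtype-specific differential shifts
    for s in subtypes:
        sign = float(spec.diff_sign.get(s, 1.0))
        rows = diff_idx[s][:, None]
        cols = np.flatnonzero(label_arr == s)[None, :]
        means[rows, cols] += sign * spec.delta_beta
    # ctDNA reporter sites stay uniformly high in tumor of every subtype
    means[ctdna_idx, :] = 99.0

    beta = _add_noise(rng, means, spec.noise_sd, spec.beta_noise)
    # ctDNA reporters emulate sites chosen for invariant, near-complete tumor
    # methylation: they carry their own (small) noise scale
    beta[ctdna_idx, :] = _add_noise(rng, means[ctdna_idx, :],
                                    spec.ctdna_site_noise_sd, spec.beta_noise)
    beta = np.clip(beta, 0.0, 100.0)
    if spec.missing_frac > 0:
        mask = rng.random(beta.shape) < spec.missing_frac
        beta[mask] = np.nan

    meth = MethylationMatrix(pd.DataFrame(beta, index=site_ids, columns=samples))

    # ---- expression ----
    n_marker = spec.n_marker_genes_per_subtype
    genes = ([f"GENE{i:04d}" for i in range(spec.n_genes_null)]
             + [f"MRK_{s.split('-')[1]}_{i:02d}" for s in subtypes
                for i in range(n_marker)])
    base_expr = rng.lognormal(mean=3.0, sigma=1.0, size=len(genes))
    expr_means = np.tile(base_expr[:, None], (1, n_samples))
    marker_genes: dict[str, list[str]] = {}
    offset = spec.n_genes_null
    for k, s in enumerate(subtypes):
        rows = np.arange(offset + k * n_marker, offset + (k + 1) * n_marker)
        marker_genes[s] = [genes[r] for r in rows]
        cols = np.flatnonzero(label_arr == s)
        expr_means[np.ix_(rows, cols)] *= spec.expression_fold_change
    expr = expr_means * rng.lognormal(mean=0.0, sigma=spec.expression_sigma,
                                      size=expr_means.shape)
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": samples,
        "specimen_type": "tissue",
        "subtype_label": [labels[s] for s in samples],
        "timepoint": "baseline",
        "tumor_fraction_truth": np.nan,
    }))

    truth = CohortTruth(
        labels=labels,
        differential_sites={s: [site_ids[i] for i in np.sort(diff_idx[s])]
                            for s in subtypes},
        marker_genes=marker_genes,
        ctdna_sites=[site_ids[i] for i in np.sort(ctdna_idx)],
        baseline_beta={site_ids[i]: float(baseline[i]) for i in range(n_total)},
        chrom_lengths=dict(spec.chrom_lengths),
    )
    return meth, expression, sheet, truth


def simulate_cfdna(tissue: MethylationMatrix, spec: CfdnaSpec,
                   ctdna_sites: Sequence[str] = ()) -> MethylationMatrix:
    """Mix tissue methylation with a non-tumor background at known fractions.

    ``cfdna = f * tissue + (1 - f) * background + noise``, clipped to
    [0, 100]. The background is ``background_beta_mean`` everywhere except at
    ``ctdna_sites`` where it is 0 (tumor-specific fully methylated reporters).
    Missing tissue values stay missing; optional uniform site dropout thins
    the cfDNA site set to emulate lower plasma coverage.
    """
    missing = [s for s in spec.tumor_fraction if s not in tissue.samples]
    if missing:
        raise ValueError(f"tumor fractions given for unknown samples: {missing[:5]}")
    absent = [s for s in tissue.samples if s not in spec.tumor_fraction]
    if absent:
        raise ValueError(f"tumor fraction missing for samples: {absent[:5]}")
    rng = np.random.default_rng(spec.rng_seed)
    f = np.array([spec.tumor_fraction[s] for s in tissue.samples])
    background = np.full(tissue.n_sites, spec.background_beta_mean)
    if len(ctdna_sites):
        pos = tissue.beta.index.get_indexer(list(ctdna_sites))
        if (pos < 0).any():
            raise ValueError("ctdna_sites not all present in tissue matrix")
        background[pos] = 0.0
    beta = tissue.beta.to_numpy(dtype=float)
    mixed = f[None, :] * beta + (1.0 - f)[None, :] * background[:, None]
    if spec.background_noise_sd > 0:
        mixed = mixed + rng.normal(0.0, spec.background_noise_sd, size=mixed.shape)
    mixed = np.clip(mixed, 0.0, 100.0)
    mixed[np.isnan(beta)] = np.nan
    out = pd.DataFrame(mixed, index=tissue.beta.index, columns=tissue.samples)
    if spec.site_dropout_frac > 0:
        keep = rng.random(len(out)) >= spec.site_dropout_frac
        out = out[keep]
    return MethylationMatrix(out)
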