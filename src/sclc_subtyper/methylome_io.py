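"""Data model and readers/writers for methylation matrices, expression matrices
and sample sheets.

Beta values are kept on the 0–100 percent scale throughout (percent of
methylated cytosines at a CpG). Coordinates are 1-based, matching site
identifiers of the form ``chr12:27974490``; bedGraph-style 0-based inputs are
converted on read via the ``zero_based`` flag. Strand is ignored: CpGs on
opposite strands are distinct sites.

Two tabular dialects are read for per-sample methylation calls:

* Bismark-coverage style, six columns, no header:
  ``chrom  start  end  beta%  count_methylated  count_unmethylated``
* a three-column dialect: ``chrom  pos  beta%`` (no read counts, so
  coverage-based filtering does not apply).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBTYPES: tuple[str, ...] = ("SCLC-A", "SCLC-N", "SCLC-P", "SCLC-I")
SUBTYPE_LABELS: tuple[str, ...] = SUBTYPES + ("unknown",)
SPECIMEN_TYPES: tuple[str, ...] = ("tissue", "cfDNA", "cell_line")
TIMEPOINTS: tuple[str, ...] = ("baseline", "progression", "NA")

DEFAULT_MIN_COVERAGE = 10
DEFAULT_MAX_MISSING_FRAC = 0.10

_CHROM_NUM = re.compile(r"^chr(\d+)$")


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Natural chromosome ordering: chr1..chr22, then chrX, chrY, then others."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)))
    if chrom == "chrX":
        return (1, 0)
    if chrom == "chrY":
        return (1, 1)
    return (2, chrom)


@dataclass(frozen=True, order=False)
class CpGSite:
    """A single CpG position, 1-based, on a "chr"-prefixed chromosome."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"CpG position must be >= 1, got {self.pos}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @classmethod
    def parse(cls, site_id: str) -> "CpGSite":
        chrom, _, pos = site_id.rpartition(":")
        if not chrom or not pos:
            raise ValueError(f"malformed site id {site_id!r}")
        return cls(chrom=chrom, pos=int(pos))

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos)


def _site_order(site_ids: Iterable[str]) -> list[str]:
    return sorted(site_ids, key=lambda s: CpGSite.parse(s).sort_key())


class MethylationMatrix:
    """Sites x samples matrix of beta values (percent) with optional coverage.

    ``beta`` is a DataFrame indexed by site id ("chrom:pos") with sample-id
    columns; missing observations are NaN. ``coverage`` (optional) has the
    same shape with non-negative read counts.
    """

    def __init__(self, beta: pd.DataFrame, coverage: pd.DataFrame | None = None):
        if beta.index.has_duplicates:
            raise ValueError("duplicate site ids in methylation matrix")
        if beta.columns.has_duplicates:
            raise ValueError("duplicate sample ids in methylation matrix")
        vals = beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 100:
                raise ValueError("beta values must lie in [0, 100]")
        if coverage is not None:
            if coverage.shape != beta.shape:
                raise ValueError("coverage shape does not match beta shape")
            coverage = coverage.set_axis(beta.index).set_axis(beta.columns, axis=1)
        self.beta = beta.astype(float)
        self.coverage = coverage

    # -- basic introspection -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sites(self) -> list[CpGSite]:
        return [CpGSite.parse(s) for s in self.beta.index]

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-site fraction of samples with a missing beta value."""
        return self.beta.isna().mean(axis=1)

    # -- manipulation --------------------------------------------------------
    def sort_sites(self) -> "MethylationMatrix":
        order = _site_order(self.beta.index)
        cov = self.coverage.loc[order] if self.coverage is not None else None
        return MethylationMatrix(self.beta.loc[order], cov)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        cov = self.coverage[list(sample_ids)] if self.coverage is not None else None
        return MethylationMatrix(self.beta[list(sample_ids)], cov)

    def subset_sites(self, site_ids: Sequence[str]) -> "MethylationMatrix":
        cov = self.coverage.loc[list(site_ids)] if self.coverage is not None else None
        return MethylationMatrix(self.beta.loc[list(site_ids)], cov)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MethylationMatrix({self.n_sites} sites x {self.n_samples} samples)"


class ExpressionMatrix:
    """Genes x samples non-negative abundance table."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(np.isnan(arr)):
            raise ValueError("expression values must be non-negative and complete")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({len(self.genes)} genes x {len(self.samples)} samples)"


class SampleSheet:
    """Per-sample metadata: specimen type, subtype label, timepoint, optional
    tumor-fraction truth (fraction in [0, 1])."""

    COLUMNS = ("sample_id", "specimen_type", "subtype_label", "timepoint",
               "tumor_fraction_truth")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "tumor_fraction_truth" not in table.columns:
            table["tumor_fraction_truth"] = np.nan
        if "timepoint" not in table.columns:
            table["timepoint"] = "NA"
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"sample sheet is missing columns: {missing}")
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in sample sheet: {dups}")
        bad = set(table["subtype_label"]) - set(SUBTYPE_LABELS)
        if bad:
            raise ValueError(
                f"unknown subtype labels {sorted(bad)}; allowed: {SUBTYPE_LABELS}")
        bad = set(table["specimen_type"]) - set(SPECIMEN_TYPES)
        if bad:
            raise ValueError(f"unknown specimen types {sorted(bad)}")
        table["timepoint"] = table["timepoint"].fillna("NA")
        bad = set(table["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise ValueError(f"unknown timepoints {sorted(bad)}")
        tf = table["tumor_fraction_truth"].astype(float)
        if ((tf < 0) | (tf > 1)).any():
            raise ValueError("tumor_fraction_truth must lie in [0, 1]")
        self.table = table[list(self.COLUMNS)].reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def labels(self, samples: Sequence[str] | None = None) -> pd.Series:
        s = self.table.set_index("sample_id")["subtype_label"]
        return s.loc[list(samples)] if samples is not None else s

    def labeled_ids(self) -> list[str]:
        mask = self.table["subtype_label"] != "unknown"
        return list(self.table.loc[mask, "sample_id"])

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleSheet({len(self.table)} samples)"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_methylation_file(path: Path, zero_based: bool) -> pd.DataFrame:
    """Parse one per-sample methylation call file into (site_id, beta, coverage).

    Raises ValueError naming the file and line on any malformed row.
    """
    rows: list[tuple[str, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 6:
                    chrom, start, _end, _beta, m, u = fields
                    pos = int(start) + (1 if zero_based else 0)
                    m_i, u_i = int(m), int(u)
                    if m_i < 0 or u_i < 0:
                        raise ValueError("negative read count")
                    total = m_i + u_i
                    if total == 0:
                        raise ValueError("zero total reads")
                    beta = 100.0 * m_i / total
                    cov = float(total)
                elif len(fields) == 3:
                    chrom, p, b = fields
                    pos = int(p) + (1 if zero_based else 0)
                    beta = float(b)
                    cov = np.nan
                else:
                    raise ValueError(f"expected 3 or 6 columns, got {len(fields)}")
                if not 0.0 <= beta <= 100.0:
                    raise ValueError(f"beta {beta} outside [0, 100]")
                site = CpGSite(chrom=chrom, pos=pos)
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
            rows.append((site.id, beta, cov))
    df = pd.DataFrame(rows, columns=["site", "beta", "coverage"])
    if df["site"].duplicated().any():
        dup = df.loc[df["site"].duplicated(), "site"].iloc[0]
        raise ValueError(f"{path}: duplicate site {dup}")
    return df.set_index("site")


def read_methylation(
    paths: Sequence[str | Path],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    sample_ids: Sequence[str] | None = None,
    zero_based: bool = False,
) -> MethylationMatrix:
    """Read per-sample methylation call files into a union matrix.

    Sites with coverage below ``min_coverage`` in a sample are set missing for
    that sample (high-confidence filter; default 10 reads). The site set is
    the union across samples, ordered by chromosome (natural order) then
    position. Sample ids default to file stems.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    paths = [Path(p) for p in paths]
    if sample_ids is None:
        sample_ids = [p.stem.removesuffix(".cov") for p in paths]
    if len(sample_ids) != len(paths):
        raise ValueError("sample_ids length does not match number of files")
    betas, covs = {}, {}
    for sid, path in zip(sample_ids, paths):
        df = _parse_methylation_file(path, zero_based=zero_based)
        beta = df["beta"]
        low = df["coverage"] < min_coverage  # NaN coverage (3-col dialect) passes
        beta = beta.mask(low)
        betas[sid] = beta
        covs[sid] = df["coverage"]
    beta_df = pd.DataFrame(betas)
    cov_df = pd.DataFrame(covs)
    order = _site_order(beta_df.index)
    return MethylationMatrix(beta_df.loc[order], cov_df.loc[order])


def write_methylation(m: MethylationMatrix, directory: str | Path,
                      suffix: str = ".cov") -> list[Path]:
    """Write one Bismark-coverage-style file per sample (1-based positions).

    Read counts are synthesized from coverage when available, otherwise a
    3-column (chrom, pos, beta) dialect is written. Missing sites are omitted
    per sample. Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    sites = m.sites
    for sid in m.samples:
        path = directory / f"{sid}{suffix}"
        beta = m.beta[sid]
        cov = m.coverage[sid] if m.coverage is not None else None
        with open(path, "w") as fh:
            for site, b in zip(sites, beta):
                if np.isnan(b):
                    continue
                c = cov.loc[site.id] if cov is not None else np.nan
                if c is not None and np.isfinite(c):
                    meth = int(round(b / 100.0 * c))
                    unmeth = int(c) - meth
                    fh.write(f"{site.chrom}\t{site.pos}\t{site.pos}\t{b:.6g}"
                             f"\t{meth}\t{unmeth}\n")
                else:
                    fh.write(f"{site.chrom}\t{site.pos}\t{b:.10g}\n")
        written.append(path)
    return written


def filter_missingness(
    m: MethylationMatrix, max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC
) -> MethylationMatrix:
    """Keep only sites whose missing fraction across samples is <= threshold.

    The default 0.10 reflects the modeling rule that only sites with at most
    10% missing data enter classifier training.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    keep = m.missing_fraction() <= max_missing_frac
    site_ids = [s for s, k in zip(m.site_ids, keep) if k]
    return m.subset_sites(site_ids)


class MedianImputer:
    """Per-site median imputation with parameters learned on training samples.

    Observed values are never altered; only missing cells are filled. Use
    ``fit`` on the training matrix and ``transform`` on training and test
    matrices alike so no test-sample information leaks into the fill values.
    """

    def __init__(self) -> None:
        self.medians_: pd.Series | None = None

    def fit(self, m: MethylationMatrix) -> "MedianImputer":
        medians = m.beta.median(axis=1, skipna=True)
        if medians.isna().any():
            bad = medians.index[medians.isna()][:5].tolist()
            raise ValueError(
                f"sites with no observed values cannot be imputed: {bad} ...")
        self.medians_ = medians
        return self

    def transform(self, m: MethylationMatrix) -> MethylationMatrix:
        if self.medians_ is None:
            raise RuntimeError("MedianImputer must be fit before transform")
        common = m.beta.index.intersection(self.medians_.index)
        if len(common) < len(m.beta.index):
            missing_sites = m.beta.index.difference(self.medians_.index)
            raise ValueError(
                f"no imputation parameters for sites {list(missing_sites[:5])} ...")
        filled = m.beta.apply(lambda col: col.fillna(self.medians_), axis=0)
        return MethylationMatrix(filled, m.coverage)

    def fit_transform(self, m: MethylationMatrix) -> MethylationMatrix:
        return self.fit(m).transform(m)


def impute_missing(
    m: MethylationMatrix,
    strategy: str = "median_per_site",
    fill_value: float = 50.0,
) -> MethylationMatrix:
    """Fill missing betas so downstream learners see complete feature vectors.

    ``median_per_site`` learns medians from this matrix itself (convenience
    form; use :class:`MedianImputer` directly for a train/test discipline).
    ``constant`` fills with ``fill_value``.
    """
    if strategy == "median_per_site":
        return MedianImputer().fit_transform(m)
    if strategy == "constant":
        if not 0.0 <= fill_value <= 100.0:
            raise ValueError("fill_value must lie in [0, 100]")
        return MethylationMatrix(m.beta.fillna(fill_value), m.coverage)
    raise ValueError(f"unknown imputation strategy {strategy!r}")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-as-rows TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene symbols {dups[:5]}")
    return ExpressionMatrix(df)


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    e.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
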