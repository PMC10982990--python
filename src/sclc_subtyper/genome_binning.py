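"""Genome tiling of beta values and global-methylation profiles.

The genome is partitioned into fixed-width tiles (100 bp for site-level
association, 100 kbp for global profiles; the last tile of each chromosome is
cut short). Per tile and sample, the beta values of the CpGs falling in the
tile are averaged, excluding missing data. Global methylation profiles are
the per-subtype tile means smoothed by a centered rolling average (500 tiles
of 100 kbp = 50 Mbp by convention). Tiles strongly associated with a subtype
(one-vs-rest AUC above a threshold, 0.8 by default) are reported with their
genomic position.

Internally tiles are half-open [start, end) with 0-based starts; exports
render 1-based starts where noted. A CpG belongs to exactly one tile, chosen
by its position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_selection import associate_features
from .methylome_io import (SUBTYPES, MethylationMatrix, SampleSheet,
                           chrom_sort_key)

DEFAULT_ASSOCIATION_AUC = 0.8
FINE_TILE_WIDTH = 100
COARSE_TILE_WIDTH = 100_000
DEFAULT_ROLLING_WINDOW = 500


@dataclass
class GenomeTiling:
    """Fixed-width partition of each chromosome into tiles."""

    tile_width: int
    tiles: pd.DataFrame  # columns chrom, start (0-based), end (half-open)
    chrom_lengths: dict[str, int]

    def tile_ids(self) -> pd.Index:
        return pd.Index(self.tiles["chrom"] + ":"
                        + self.tiles["start"].astype(str) + "-"
                        + self.tiles["end"].astype(str))

    def to_bed(self, path: str | Path) -> None:
        self.tiles.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class BinnedMatrix:
    """Tiles x samples mean beta values, with per-cell contributing-site counts."""

    tiling: GenomeTiling
    values: pd.DataFrame       # tile id x sample, mean beta or NaN
    site_counts: pd.DataFrame  # tile id x sample, number of observed sites

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def export_bedgraph(self, path: str | Path, column: str) -> None:
        """bedGraph-like TSV (chrom, start, end, value) for one sample/profile."""
        out = self.tiling.tiles.copy()
        out["value"] = self.values[column].to_numpy()
        out.dropna(subset=["value"]).to_csv(path, sep="\t", header=False,
                                            index=False, float_format="%.6g")


def make_tiling(chrom_lengths: Mapping[str, int], tile_width: int) -> GenomeTiling:
    """Tile each chromosome with ceil(length / width) tiles.

    Only the last tile per chromosome may be shorter than ``tile_width``;
    tiles are sorted by (chrom natural order, start).
    """
    if tile_width < 1:
        raise ValueError("tile_width must be >= 1")
    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    rows = []
    for chrom in chroms:
        length = int(chrom_lengths[chrom])
        if length < 1:
            raise ValueError(f"chromosome length must be >= 1 for {chrom}")
        starts = np.arange(0, length, tile_width)
        ends = np.minimum(starts + tile_width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    tiles = pd.concat(rows, ignore_index=True)
    return GenomeTiling(tile_width=tile_width, tiles=tiles,
                        chrom_lengths={c: int(chrom_lengths[c]) for c in chroms})


def bin_methylation(m: MethylationMatrix, tiling: GenomeTiling) -> BinnedMatrix:
    """Average beta per tile and sample, excluding missing data.

    A tile with no CpG sites, or all-missing values for a sample, is missing
    for that sample. Sites on chromosomes absent from the tiling raise.
    """
    sites = m.sites
    chroms = np.array([s.chrom for s in sites])
    pos = np.array([s.pos for s in sites])
    unknown = set(chroms) - set(tiling.chrom_lengths)
    if unknown:
        raise ValueError(f"sites on chromosomes absent from tiling: {sorted(unknown)}")
    for s in sites:
        if s.pos > tiling.chrom_lengths[s.chrom]:
            raise ValueError(f"site {s.id} beyond chromosome length")

    # global tile index: offset per chromosome + local tile number
    tiles = tiling.tiles
    n_tiles = len(tiles)
    tile_offsets: dict[str, int] = {}
    counts_per_chrom = tiles.groupby("chrom", sort=False).size()
    running = 0
    for chrom, cnt in counts_per_chrom.items():
        tile_offsets[chrom] = running
        running += int(cnt)
    local = (pos - 1) // tiling.tile_width
    tile_idx = np.array([tile_offsets[c] for c in chroms]) + local

    beta = m.beta.to_numpy(dtype=float)
    obs = ~np.isnan(beta)
    n_samples = beta.shape[1]
    sums = np.zeros((n_tiles, n_samples))
    counts = np.zeros((n_tiles, n_samples))
    np.add.at(sums, tile_idx, np.nan_to_num(beta))
    np.add.at(counts, tile_idx, obs.astype(float))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ids = tiling.tile_ids()
    return BinnedMatrix(
        tiling=tiling,
        values=pd.DataFrame(means, index=ids, columns=m.samples),
        site_counts=pd.DataFrame(counts.astype(int), index=ids, columns=m.samples),
    )


def subtype_profile(b: BinnedMatrix, sheet: SampleSheet,
                    subtypes: Sequence[str] = SUBTYPES) -> pd.DataFrame:
    """Mean tile value over each subtype's samples (non-missing only)."""
    labels = sheet.labels()
    cols = {}
    for subtype in subtypes:
        ids = [s for s in b.samples if labels.get(s) == subtype]
        if not ids:
            raise ValueError(f"no samples labeled {subtype} in binned matrix")
        cols[subtype] = b.values[ids].mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def rolling_mean(series: pd.Series | Sequence[float], window: int,
                 min_count: int = 1, center: bool = True,
                 shrink_at_edges: bool = False) -> pd.Series:
    """Centered moving average over non-missing values.

    Positions with fewer than ``min_count`` observed values in the window are
    missing. By default positions where the full window does not fit inside
    the series (the edges) are also missing; ``shrink_at_edges=True`` relaxes
    this and averages over whatever part of the window is in bounds.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    s = pd.Series(series, dtype=float) if not isinstance(series, pd.Series) \
        else series.astype(float)
    out = s.rolling(window=window, center=center, min_periods=min_count).mean()
    if not shrink_at_edges and window > 1:
        n = len(s)
        if center:
            left = (window - 1) // 2
            right = window - 1 - left
        else:
            left, right = window - 1, 0
        mask = np.zeros(n, dtype=bool)
        mask[:left] = True
        if right:
            mask[n - right:] = True
        out = out.mask(pd.Series(mask, index=out.index))
    return out


def global_methylation_profile(b: BinnedMatrix, sheet: SampleSheet,
                               window: int = DEFAULT_ROLLING_WINDOW,
                               subtypes: Sequence[str] = SUBTYPES,
                               min_count: int = 1) -> pd.DataFrame:
    """Per-subtype genome-wide methylation profile.

    Tile means are first averaged per subtype, then smoothed with a centered
    rolling average per chromosome (windows never span a chromosome break).
    """
    prof = subtype_profile(b, sheet, subtypes)
    chrom = b.tiling.tiles["chrom"].to_numpy()
    smoothed = {}
    for subtype in prof.columns:
        parts = []
        col = prof[subtype]
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            parts.append(rolling_mean(col.iloc[idx], window=window,
                                      min_count=min_count))
        smoothed[subtype] = pd.concat(parts)
    return pd.DataFrame(smoothed)


def bin_subtype_association(b: BinnedMatrix, sheet: SampleSheet,
                            auc_threshold: float = DEFAULT_ASSOCIATION_AUC,
                            min_per_class: int = 2,
                            subtypes: Sequence[str] = SUBTYPES
                            ) -> dict[str, pd.DataFrame]:
    """Tiles highly associated with each subtype (two-sided one-vs-rest AUC).

    Tiles must have non-missing values in at least ``min_per_class`` samples
    both in and out of the subtype. Returns, per subtype, a DataFrame with
    chrom/start/end and the (oriented) auc, filtered on
    max(auc, 1-auc) >= auc_threshold and sorted by genomic position.
    """
    labels = sheet.labels(b.samples)
    out = {}
    tiles = b.tiling.tiles.set_index(b.tiling.tile_ids())
    for subtype in subtypes:
        in_mask = (labels == subtype).to_numpy()
        obs = b.values.notna().to_numpy()
        enough = ((obs[:, in_mask].sum(axis=1) >= min_per_class)
                  & (obs[:, ~in_mask].sum(axis=1) >= min_per_class))
        sub = b.values[enough]
        assoc = associate_features(sub, labels, subtype)
        auc2 = np.maximum(assoc["auc"], 1.0 - assoc["auc"])
        hits = assoc[auc2 >= auc_threshold]
        report = tiles.loc[hits.index, ["chrom", "start", "end"]].copy()
        report["auc"] = hits["auc"]
        report["delta"] = hits["delta"]
        out[subtype] = report
    return out
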