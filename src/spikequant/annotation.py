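"""Interval logic for CGI/TSS feature definitions.

All coordinates are 0-based half-open.  A TSS is a point (a single base);
distances between a TSS and an interval are measured in bases between the
TSS base and the nearest base of the interval (0 when the TSS lies inside
it), and threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "associate_tss_to_islands",
    "peaks_overlapping_tss",
    "isolated_tss_filter",
    "make_quant_regions",
    "expression_deciles",
]

ROLES = {
    "tss", "gene", "island", "peak", "enhancer",
    "antisense_window", "enhancer_window",
}


@dataclass
class RegionSet:
    """A named set of genomic intervals (chrom, start, end, strand, id)."""

    df: pd.DataFrame
    role: str = "gene"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        df = self.df.reset_index(drop=True)
        required = ["chrom", "start", "end", "strand", "id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"region table lacks columns {missing}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"region {df.loc[bad, 'id']!r} has start >= end")
        if df["id"].duplicated().any():
            raise ValueError("region ids must be unique within a set")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, keep: np.ndarray) -> "RegionSet":
        return RegionSet(self.df[keep].reset_index(drop=True), role=self.role)


def _tss_points(tss: RegionSet) -> pd.DataFrame:
    """TSS regions are single-base intervals; use the start as the point."""
    df = tss.df
    return pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"], "strand": df["strand"],
         "id": df["id"]}
    )


def associate_tss_to_islands(
    tss: RegionSet, islands: RegionSet, window: int = 1500
) -> tuple[pd.Series, pd.Series]:
    """Flag TSSs within ``window`` bp of a non-methylated island, and islands
    within ``window`` bp of a TSS.

    Distance from the TSS base to an island [a, b) is 0 inside the island,
    else bases to its nearest end base; comparison is inclusive (<= window).
    Returns (per-TSS boolean indexed by TSS id, per-island boolean indexed
    by island id).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pts = _tss_points(tss)
    tss_flag = pd.Series(False, index=pts["id"])
    isl_flag = pd.Series(False, index=islands.df["id"])
    for chrom, sub in pts.groupby("chrom", sort=False):
        isl = islands.df[islands.df["chrom"] == chrom]
        if isl.empty:
            continue
        t = sub["pos"].to_numpy()[:, None]
        a = isl["start"].to_numpy()[None, :]
        b = isl["end"].to_numpy()[None, :]
        dist = np.maximum.reduce([a - t, t - (b - 1), np.zeros_like(a - t)])
        hit = dist <= window
        tss_flag.loc[sub["id"]] = hit.any(axis=1)
        isl_flag.loc[isl["id"]] = isl_flag.loc[isl["id"]].to_numpy() | hit.any(axis=0)
    return tss_flag, isl_flag


def peaks_overlapping_tss(peaks: RegionSet, tss: RegionSet) -> RegionSet:
    """Retain peaks that overlap a TSS directly: some TSS base lies in
    the half-open peak interval [start, end)."""
    pts = _tss_points(tss)
    keep = np.zeros(len(peaks.df), dtype=bool)
    for chrom, sub in pts.groupby("chrom", sort=False):
        sel = (peaks.df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        a = peaks.df.loc[sel, "start"].to_numpy()[:, None]
        b = peaks.df.loc[sel, "end"].to_numpy()[:, None]
        t = sub["pos"].to_numpy()[None, :]
        keep[sel] |= ((t >= a) & (t < b)).any(axis=1)
    return peaks.subset(keep)


def isolated_tss_filter(tss: RegionSet, window: int = 1000) -> RegionSet:
    """Drop TSSs with a divergent (opposite-strand) TSS within ``window`` bp.

    Both members of a divergent pair are removed; same-strand neighbours
    do not count as divergent.  Idempotent.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pts = _tss_points(tss)
    keep = np.ones(len(pts), dtype=bool)
    for chrom, sub in pts.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        strand = sub["strand"].to_numpy()
        idx = sub.index.to_numpy()
        d = np.abs(pos[:, None] - pos[None, :])
        opposite = strand[:, None] != strand[None, :]
        near = (d <= window) & opposite
        keep[idx] &= ~near.any(axis=1)
    return tss.subset(keep)


def make_quant_regions(
    genes: RegionSet,
    enhancers: RegionSet | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    antisense_window: int = 5000,
    enhancer_half: int = 5000,
) -> dict[str, RegionSet]:
    """Quantification windows: gene bodies, 5 kb upstream-antisense windows
    (strand-flipped), and 10 kb windows centred on enhancer midpoints.

    A plus-strand gene with TSS t gets antisense window [t-5000, t) on the
    minus strand; a minus-strand gene (whose TSS is its half-open end
    coordinate e, i.e. first transcribed base e-1) gets [e, e+5000) on
    the plus strand — the exact coordinate mirror.  Windows are clipped
    to chromosome bounds.
    """
    chrom_lengths = chrom_lengths or {}

    def clip(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["start"] = df["start"].clip(lower=0)
        if chrom_lengths:
            limits = df["chrom"].map(lambda c: chrom_lengths.get(c, np.inf))
            df["end"] = np.minimum(df["end"], limits)
        return df[df["start"] < df["end"]].reset_index(drop=True)

    gdf = genes.df
    fwd = gdf["strand"] != "-"
    tss = np.where(fwd, gdf["start"], gdf["end"])
    anti = pd.DataFrame(
        {
            "chrom": gdf["chrom"],
            "start": np.where(fwd, tss - antisense_window, tss),
            "end": np.where(fwd, tss, tss + antisense_window),
            "strand": np.where(fwd, "-", "+"),
            "id": "as:" + gdf["id"].astype(str),
        }
    )
    out = {
        "gene": RegionSet(gdf.copy(), role="gene"),
        "antisense_window": RegionSet(clip(anti), role="antisense_window"),
    }
    if enhancers is not None:
        edf = enhancers.df
        mid = (edf["start"] + edf["end"]) // 2
        win = pd.DataFrame(
            {
                "chrom": edf["chrom"],
                "start": mid - enhancer_half,
                "end": mid + enhancer_half,
                "strand": ".",
                "id": "win:" + edf["id"].astype(str),
            }
        )
        out["enhancer_window"] = RegionSet(clip(win), role="enhancer_window")
    return out


def expression_deciles(values: pd.Series) -> pd.Series:
    """Decile labels 1 (lowest expression) .. 10 (highest).

    Decile sizes differ by at most one; ties are broken by the stable
    feature order of the input.
    """
    values = pd.Series(values)
    n = len(values)
    if n < 10:
        raise ValueError("deciles require at least 10 genes")
    order = np.argsort(values.to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    labels = (ranks * 10) // n + 1
    return pd.Series(labels, index=values.index, name="decile")
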