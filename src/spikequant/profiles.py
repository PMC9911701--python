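"""Strand-aware coverage matrices, metaprofiles and attenuation summaries.

Coverage is held as fixed-width binned tracks, one per strand.  Profile
matrices anchor a window on each region's TSS (or rescale the region to a
fixed number of bins), orient every row so that transcription runs left to
right, and mask bins that fall outside the chromosome.  Metaprofiles are
per-bin means across regions; fold-change profiles compare a treated and
an untreated signal with pseudocount regularisation; the attenuation
summary locates the minimum of a log2 fold-change profile downstream of
the TSS and asks whether it falls inside the gene's CpG-island zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "ProfileMatrix",
    "coverage_matrix",
    "metaprofile",
    "foldchange_profile",
    "promoter_body_signal",
    "attenuation_summary",
]


@dataclass
class CoverageTrack:
    """Per-bin signal along each chromosome for one sample and strand."""

    data: dict[str, np.ndarray]
    bin_width: int
    strand: str = "."
    sample_id: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        for c, v in self.data.items():
            if (v < 0).any():
                raise ValueError(f"negative coverage on {c}")

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) * self.bin_width for c, v in self.data.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


@dataclass
class ProfileMatrix:
    """Regions x bins signal matrix, rows oriented 5' -> 3'.

    ``mask`` is True where a bin lies inside its chromosome; out-of-range
    bins carry value 0 and mask False.
    """

    values: np.ndarray
    mask: np.ndarray
    region_ids: list[str]
    offsets: np.ndarray  # bin start offsets relative to the anchor (bp)
    bin_width: int
    anchor: str = "TSS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[0] != len(self.region_ids):
            raise ValueError("row count does not match region ids")

    @property
    def bin_mids(self) -> np.ndarray:
        return self.offsets + self.bin_width / 2.0


def _region_frame(regions) -> pd.DataFrame:
    """Accept a RegionSet or a plain DataFrame with BED-like columns."""
    df = getattr(regions, "df", regions)
    required = {"chrom", "start", "end", "strand", "id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table lacks columns {sorted(missing)}")
    return df


def _pick_track(
    plus: CoverageTrack, minus: CoverageTrack | None, strand: str, mode: str
) -> dict[str, np.ndarray]:
    if mode == "unstranded":
        if minus is None:
            return plus.data
        return {
            c: plus.data[c] + minus.data.get(c, 0.0) for c in plus.data
        }
    if minus is None:
        raise ValueError("stranded mode requires both strand tracks")
    sense_is_plus = strand == "+"
    if mode == "antisense":
        sense_is_plus = not sense_is_plus
    return plus.data if sense_is_plus else minus.data


def coverage_matrix(
    plus: CoverageTrack,
    minus: CoverageTrack | None,
    regions,
    anchor: str = "TSS",
    upstream: int = 5000,
    downstream: int = 5000,
    strand_mode: str = "sense",
    n_body_bins: int = 100,
) -> ProfileMatrix:
    """Build a regions x bins matrix from per-strand coverage tracks.

    With ``anchor='TSS'`` the window spans [TSS - upstream, TSS + downstream)
    in transcription orientation; minus-strand rows are reversed and their
    sense signal is read from the minus track (antisense from plus).  With
    ``anchor='region-scaled'`` the region body is resampled to
    ``n_body_bins`` bins between flanks of ``upstream``/``downstream`` bp.

    Extents must be multiples of the track bin width; bins beyond
    chromosome ends are masked with value 0.
    """
    if minus is not None and minus.bin_width != plus.bin_width:
        raise ValueError("bin width mismatch between strand tracks")
    bw = plus.bin_width
    if anchor not in {"TSS", "region-scaled"}:
        raise ValueError(f"unknown anchor {anchor!r}")
    if upstream % bw or downstream % bw:
        raise ValueError("extents must be multiples of the bin width")
    if strand_mode not in {"sense", "antisense", "unstranded"}:
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    df = _region_frame(regions)
    n_up, n_down = upstream // bw, downstream // bw
    n_bins = n_up + n_down if anchor == "TSS" else n_up + n_body_bins + n_down
    values = np.zeros((len(df), n_bins))
    mask = np.zeros((len(df), n_bins), dtype=bool)

    for i, row in enumerate(df.itertuples(index=False)):
        track = _pick_track(plus, minus, row.strand, strand_mode)
        arr = track.get(row.chrom)
        if arr is None:
            continue
        nchrom = len(arr)
        fwd = row.strand != "-"
        tss = row.start if fwd else row.end
        if anchor == "TSS":
            if fwd:
                idx = tss // bw - n_up + np.arange(n_bins)
            else:
                idx = tss // bw + n_up - 1 - np.arange(n_bins)
        else:
            body_pos = row.start + (np.arange(n_body_bins) + 0.5) / n_body_bins * (
                row.end - row.start
            )
            if fwd:
                up_idx = row.start // bw - n_up + np.arange(n_up)
                down_idx = row.end // bw + np.arange(n_down)
                idx = np.concatenate(
                    [up_idx, (body_pos // bw).astype(int), down_idx]
                )
            else:
                up_idx = row.end // bw + n_up - 1 - np.arange(n_up)
                down_idx = row.start // bw - 1 - np.arange(n_down)
                idx = np.concatenate(
                    [up_idx, (body_pos[::-1] // bw).astype(int), down_idx]
                )
        ok = (idx >= 0) & (idx < nchrom)
        values[i, ok] = arr[idx[ok]]
        mask[i, :] = ok

    if anchor == "TSS":
        offsets = (np.arange(n_bins) - n_up) * bw
    else:
        offsets = np.arange(n_bins, dtype=float) * bw - upstream
    return ProfileMatrix(
        values=values,
        mask=mask,
        region_ids=list(df["id"]),
        offsets=np.asarray(offsets, dtype=float),
        bin_width=bw,
        anchor=anchor,
    )


def metaprofile(matrix: ProfileMatrix) -> pd.DataFrame:
    """Per-bin mean over unmasked rows, with contributing-region counts.

    Bins where no region contributes get mean NaN (flagged undefined).
    """
    if matrix.values.shape[0] < 1:
        raise ValueError("metaprofile requires at least one region")
    n = matrix.mask.sum(axis=0)
    total = np.where(matrix.mask, matrix.values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {"bin_mid": matrix.bin_mids, "mean": mean, "n": n.astype(int)}
    )


def foldchange_profile(treated, untreated, pseudocount: float):
    """Per-bin ratio (and log2 ratio) of two matching profiles.

    ``ratio = (treated + pc) / (untreated + pc)``; the pseudocount
    regularises empty bins (0/0 -> 1).  Accepts arrays or ProfileMatrix
    pairs of identical shape; returns ``(ratio, log2_ratio)`` of the same
    shape (for matrices, plain arrays are returned).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    t = treated.values if isinstance(treated, ProfileMatrix) else np.asarray(treated, float)
    u = untreated.values if isinstance(untreated, ProfileMatrix) else np.asarray(untreated, float)
    if t.shape != u.shape:
        raise ValueError("profile bin shapes do not match")
    ratio = (t + pseudocount) / (u + pseudocount)
    return ratio, np.log2(ratio)


def default_pseudocount(track: CoverageTrack) -> float:
    """1% of the genome-wide mean per-bin signal (scale-free default)."""
    vals = np.concatenate([v for v in track.data.values()])
    m = float(vals.mean())
    return 0.01 * m if m > 0 else 1e-6


def promoter_body_signal(
    track: CoverageTrack,
    genes,
    promoter_half: int = 250,
    body_offset: int = 500,
) -> pd.DataFrame:
    """Mean promoter ([TSS-250, TSS+250]) and gene-body ([TSS+500, TES])
    signal per gene, strand-oriented, from an (unstranded) Pol II track.

    Genes whose body window is empty after clipping are flagged missing.
    """
    bw = track.bin_width
    df = _region_frame(genes)
    rows = []
    for row in df.itertuples(index=False):
        arr = track.data.get(row.chrom)
        fwd = row.strand != "-"
        tss = row.start if fwd else row.end
        tes = row.end if fwd else row.start
        if abs(tes - tss) <= body_offset:
            raise ValueError(
                f"gene {row.id!r} shorter than the promoter/body offset"
            )
        prom_lo, prom_hi = tss - promoter_half, tss + promoter_half
        if fwd:
            body_lo, body_hi = tss + body_offset, tes
        else:
            body_lo, body_hi = tes, tss - body_offset
        prom = _interval_mean(arr, prom_lo, prom_hi, bw)
        body = _interval_mean(arr, body_lo, body_hi, bw)
        rows.append(
            {
                "id": row.id,
                "promoter": prom,
                "body": body,
                "missing": bool(np.isnan(body)),
            }
        )
    out = pd.DataFrame(rows).set_index("id")
    return out


def _interval_mean(arr: np.ndarray | None, lo: int, hi: int, bw: int) -> float:
    if arr is None:
        return float("nan")
    i0, i1 = max(lo, 0) // bw, -(-min(hi, len(arr) * bw) // bw)
    if i1 <= i0:
        return float("nan")
    return float(arr[i0:i1].mean())


def attenuation_summary(
    log2_matrix: ProfileMatrix,
    cgi_zones: Mapping[str, tuple[float, float] | None],
    max_downstream: int = 3000,
) -> pd.DataFrame:
    """Locate per-gene attenuation in a TSS-anchored log2 fold-change matrix.

    For each gene, over TSS..TSS+``max_downstream``: depth is the minimum
    log2 ratio, position the midpoint of the first (most TSS-proximal)
    bin attaining it, and ``in_cgi`` whether that position lies inside the
    gene's CpG-island attenuation zone (given as a TSS-relative interval;
    genes without a zone get False).
    """
    sel = (log2_matrix.offsets >= 0) & (log2_matrix.offsets < max_downstream)
    if not sel.any():
        raise ValueError("matrix has no bins in TSS..TSS+max_downstream")
    sub = log2_matrix.values[:, sel]
    mids = log2_matrix.bin_mids[sel]
    rows = []
    for i, gid in enumerate(log2_matrix.region_ids):
        j = int(np.argmin(sub[i]))  # argmin returns the first minimum: ties
        depth = float(sub[i, j])    # resolve to the TSS-proximal bin
        pos = float(mids[j])
        zone = cgi_zones.get(gid)
        in_cgi = bool(zone is not None and zone[0] <= pos < zone[1])
        rows.append(
            {"id": gid, "depth": depth, "position": pos, "in_cgi": in_cgi}
        )
    return pd.DataFrame(rows).set_index("id")
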