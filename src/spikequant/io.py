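"""Plain-text formats: BED6, bedGraph, count TSV, condition sheets, JSON.

Coordinates are 0-based half-open throughout; tabular files are
tab-separated with a header row and '#' comment lines; JSON sidecars hold
scalar provenance (factors, seeds, references) so runs are diffable and
bit-exact on re-execution.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import RegionSet
from .calibration import CalibrationResult, SampleCounts, SizeFactors
from .profiles import CoverageTrack

__all__ = [
    "ParseError",
    "read_regions",
    "write_regions",
    "read_track",
    "write_track",
    "read_counts",
    "write_counts",
    "read_conditions",
    "write_json",
]

BED_COLS = ["chrom", "start", "end", "id", "score", "strand"]


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def read_regions(path: str | Path, role: str = "gene") -> RegionSet:
    """Read a BED6 file into a RegionSet (0-based half-open, as BED is)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 0 or start_i >= end_i:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start_i}, {end_i})"
                )
            rows.append(
                {"chrom": chrom, "start": start_i, "end": end_i,
                 "id": name, "score": float(score), "strand": strand}
            )
    return RegionSet(pd.DataFrame(rows, columns=BED_COLS), role=role)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    df = regions.df.copy()
    if "score" not in df.columns:
        df["score"] = 0
    df[BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_track(track: CoverageTrack, path: str | Path) -> None:
    """Write a binned track as bedGraph, merging adjacent equal-value bins.

    Zero-value intervals are written too so that read(write(x)) == x over
    the declared chromosome extents.
    """
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{arr[s]:.6g}\n")


def read_track(
    path: str | Path,
    bin_width: int,
    chrom_lengths: Mapping[str, int] | None = None,
    strand: str = ".",
    sample_id: str = "",
) -> CoverageTrack:
    """Read a bedGraph into a fixed-bin track.

    Interval boundaries must align to the bin width; values fill every
    covered bin (intervals spanning several bins are expanded).
    """
    path = Path(path)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[:4]
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad field types") from exc
            if s < 0 or s >= e:
                raise ParseError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            if s % bin_width or e % bin_width:
                raise ParseError(
                    f"{path}:{lineno}: interval not aligned to bin width {bin_width}"
                )
            per_chrom.setdefault(chrom, []).append((s, e, v))
    data = {}
    for chrom, ivals in per_chrom.items():
        extent = max(e for _, e, _ in ivals)
        if chrom_lengths and chrom in chrom_lengths:
            extent = max(extent, chrom_lengths[chrom])
        arr = np.zeros(extent // bin_width)
        for s, e, v in ivals:
            arr[s // bin_width : e // bin_width] = v
        data[chrom] = arr
    if chrom_lengths:
        for chrom, L in chrom_lengths.items():
            data.setdefault(chrom, np.zeros(-(-L // bin_width)))
    return CoverageTrack(
        data=data, bin_width=bin_width, strand=strand, sample_id=sample_id
    )


def write_counts(samples: list[SampleCounts], path: str | Path) -> None:
    """Write the dual-genome count table: feature_id, genome, one column
    per sample."""
    target = pd.DataFrame({sc.sample_id: sc.target for sc in samples})
    spike = pd.DataFrame({sc.sample_id: sc.spike for sc in samples})
    target.insert(0, "genome", "target")
    spike.insert(0, "genome", "spike")
    out = pd.concat([target, spike])
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a dual-genome count table; returns (target, spike) matrices."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "genome" not in df.columns:
        raise ParseError(f"{path}: missing 'genome' column")
    target = df[df["genome"] == "target"].drop(columns="genome")
    spike = df[df["genome"] == "spike"].drop(columns="genome")
    return target.astype(np.int64), spike.astype(np.int64)


def counts_to_samples(
    target: pd.DataFrame,
    spike: pd.DataFrame,
    inputs: Mapping[str, str] | None = None,
) -> list[SampleCounts]:
    inputs = inputs or {}
    return [
        SampleCounts(
            sample_id=col,
            target=target[col],
            spike=spike[col],
            input_sample_id=inputs.get(col),
        )
        for col in target.columns
    ]


def read_conditions(path: str | Path) -> pd.DataFrame:
    """Read the condition sheet (sample_id, condition, s, z, assay, ...)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: condition sheet lacks 'sample_id'")
    return df.set_index("sample_id")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, (CalibrationResult,)):
            return {
                "retention": o.retention,
                "input_adjustment": o.input_adjustment,
                "reference": o.reference,
                "method": o.method,
            }
        if isinstance(o, SizeFactors):
            return {"factors": o.factors.to_dict(), "provenance": o.provenance}
        raise TypeError(f"not JSON serialisable: {type(o)!r}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
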