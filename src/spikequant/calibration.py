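"""Spike-in (exogenous genome) calibration of sequencing counts.

Samples are sequenced from a mixture of target cells and a fixed aliquot of
spike-in cells from another species.  Because the spike-in material is
biologically invariant, the number of spike-in reads recovered in each
library measures that library's effective sequencing yield per cell, and
target-genome counts can be placed on a common per-cell scale by
downsampling each library so that spike-in totals match.

Two calibration modes are provided:

``rna`` (cRNA-seq / cTT-seq)
    Each sample's raw factor is the reciprocal of its spike-in read total;
    target reads are randomly downsampled so every library reflects the
    same number of spike-in reads.

``chip`` (cChIP-seq)
    As above, but additionally corrected for sample-to-sample variation in
    the cell-mixing ratio using the matched input (non-enriched) library:
    the raw factor is multiplied by the input's spike/target read ratio,
    which is proportional to the actual spike-cells-per-target-cell ratio
    of that particular mixture.

For count-based differential testing, spike-in features alone are used to
derive median-of-ratios size factors which are then applied to the target
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleCounts",
    "CalibrationResult",
    "SizeFactors",
    "CalibrationError",
    "chip_calibration_factors",
    "rna_calibration_factors",
    "downsample",
    "spike_size_factors",
    "total_count_size_factors",
]


class CalibrationError(ValueError):
    """Raised when a sample cannot be calibrated (missing input, zero spike)."""


@dataclass
class SampleCounts:
    """Per-feature integer counts for one library, split into target and
    spike-in partitions, with an optional link to a matched input library."""

    sample_id: str
    target: pd.Series
    spike: pd.Series
    input_sample_id: str | None = None

    def __post_init__(self) -> None:
        self.target = pd.Series(self.target, dtype=np.int64)
        self.spike = pd.Series(self.spike, dtype=np.int64)
        if (self.target < 0).any() or (self.spike < 0).any():
            raise ValueError(f"negative counts in sample {self.sample_id!r}")

    @property
    def total_target(self) -> int:
        return int(self.target.sum())

    @property
    def total_spike(self) -> int:
        return int(self.spike.sum())


@dataclass
class CalibrationResult:
    """Per-sample retention probabilities for downsampling.

    ``retention[s]`` is in (0, 1]; the reference sample (largest raw
    factor) has retention exactly 1, so calibration only ever discards
    reads, never invents them.
    """

    retention: dict[str, float]
    input_adjustment: dict[str, float]
    reference: str
    method: str

    def __post_init__(self) -> None:
        rmax = max(self.retention.values())
        if not np.isclose(rmax, 1.0):
            raise ValueError("retention must be normalized to max 1")
        if any(r <= 0 for r in self.retention.values()):
            raise ValueError("retention probabilities must be positive")


@dataclass
class SizeFactors:
    """Per-sample scaling divisors, rescaled to geometric mean 1."""

    factors: pd.Series
    provenance: str = "spike_median_of_ratios"

    def __post_init__(self) -> None:
        self.factors = pd.Series(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")
        gm = np.exp(np.log(self.factors.to_numpy()).mean())
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"size factors must have geometric mean 1 (got {gm})")


def _normalize_raw_factors(
    raw: dict[str, float], adjust: dict[str, float], method: str
) -> CalibrationResult:
    reference = max(raw, key=lambda s: raw[s])
    gmax = raw[reference]
    retention = {s: g / gmax for s, g in raw.items()}
    return CalibrationResult(
        retention=retention,
        input_adjustment=adjust,
        reference=reference,
        method=method,
    )


def chip_calibration_factors(
    samples: Sequence[SampleCounts],
    inputs: Mapping[str, SampleCounts],
) -> CalibrationResult:
    """Downsampling factors for cChIP-seq with input-based mixing correction.

    The raw factor for sample *s* is

        g_s = (1 / spike_s) * (input_spike_s / input_target_s)

    i.e. the reciprocal spike total of the ChIP library, adjusted by the
    spike/target ratio of its matched input, which tracks the realised
    cell-mixing ratio.  Retention probabilities are g_s / max_s g_s.

    Parameters
    ----------
    samples
        ChIP libraries; each must carry ``input_sample_id``.
    inputs
        Mapping from input sample id to its :class:`SampleCounts`.
    """
    raw: dict[str, float] = {}
    adjust: dict[str, float] = {}
    for sc in samples:
        if sc.input_sample_id is None or sc.input_sample_id not in inputs:
            raise CalibrationError(
                f"sample {sc.sample_id!r} has no matched input sample"
            )
        if sc.total_spike <= 0:
            raise CalibrationError(
                f"sample {sc.sample_id!r} has zero spike-in reads"
            )
        inp = inputs[sc.input_sample_id]
        if inp.total_target <= 0 or inp.total_spike <= 0:
            raise CalibrationError(
                f"input {inp.sample_id!r} for sample {sc.sample_id!r} has "
                "a zero partition total"
            )
        a_s = inp.total_spike / inp.total_target
        adjust[sc.sample_id] = a_s
        raw[sc.sample_id] = a_s / sc.total_spike
    return _normalize_raw_factors(raw, adjust, "chip_input_adjusted")


def rna_calibration_factors(samples: Sequence[SampleCounts]) -> CalibrationResult:
    """Downsampling factors for cRNA-seq / cTT-seq: g_s = 1 / spike total."""
    raw: dict[str, float] = {}
    for sc in samples:
        if sc.total_spike <= 0:
            raise CalibrationError(
                f"sample {sc.sample_id!r} has zero spike-in reads"
            )
        raw[sc.sample_id] = 1.0 / sc.total_spike
    return _normalize_raw_factors(raw, {}, "rna_spike_only")


def downsample(obj, retention: float, seed: int):
    """Binomially thin counts (or a binned track) with probability ``retention``.

    Each count unit is retained independently with probability ``retention``,
    which is equivalent in distribution to random read-level downsampling.
    ``retention == 1`` returns the input unchanged.  Accepts a
    :class:`SampleCounts` (both partitions thinned), a pandas Series, a
    numpy array, or any object with a ``data`` dict of bin arrays
    (a coverage track); returns the same type.
    """
    if not (0.0 < retention <= 1.0):
        raise ValueError(f"retention must be in (0, 1], got {retention}")
    if retention == 1.0:
        return obj
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD5]))
    if isinstance(obj, SampleCounts):
        return SampleCounts(
            sample_id=obj.sample_id,
            target=pd.Series(
                rng.binomial(obj.target.to_numpy(), retention), index=obj.target.index
            ),
            spike=pd.Series(
                rng.binomial(obj.spike.to_numpy(), retention), index=obj.spike.index
            ),
            input_sample_id=obj.input_sample_id,
        )
    if isinstance(obj, pd.Series):
        return pd.Series(
            rng.binomial(obj.to_numpy().astype(np.int64), retention), index=obj.index
        )
    if isinstance(obj, np.ndarray):
        return rng.binomial(obj.astype(np.int64), retention)
    if hasattr(obj, "data") and isinstance(obj.data, dict):
        import copy

        out = copy.copy(obj)
        out.data = {
            chrom: rng.binomial(arr.astype(np.int64), retention).astype(float)
            for chrom, arr in obj.data.items()
        }
        out.calibrated = True
        return out
    raise TypeError(f"cannot downsample object of type {type(obj)!r}")


def spike_size_factors(
    spike_matrix: pd.DataFrame,
    input_ratios: pd.Series | None = None,
) -> SizeFactors:
    """Median-of-ratios size factors from spike-in features only.

    For each feature the reference is its geometric mean across samples;
    each sample's factor is the median of count/reference over features
    with a positive reference, rescaled so factors have geometric mean 1.
    Factors are applied to target counts as count / factor.

    Parameters
    ----------
    spike_matrix
        Spike features x samples count matrix.
    input_ratios
        Optional per-sample spike/target read ratio from matched inputs;
        when given, spike counts are pre-normalized (divided) by it to
        remove cell-mixing variation before computing factors (the
        H3K4me3-style variant).
    """
    if spike_matrix.shape[1] < 2:
        raise CalibrationError("size factors require at least 2 samples")
    mat = spike_matrix.astype(float)
    if input_ratios is not None:
        input_ratios = pd.Series(input_ratios, dtype=float)
        mat = mat.div(input_ratios.reindex(mat.columns), axis=1)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise CalibrationError(
            "no spike feature has positive counts in every sample"
        )
    logmat = np.log(mat.loc[positive])
    logref = logmat.mean(axis=1)
    logfac = (logmat.sub(logref, axis=0)).median(axis=0)
    logfac = logfac - logfac.mean()  # geometric mean 1
    return SizeFactors(
        factors=np.exp(logfac), provenance="spike_median_of_ratios"
    )


def total_count_size_factors(matrix: pd.DataFrame) -> SizeFactors:
    """Naive library-size factors (total target counts, geometric mean 1).

    Provided as the contrast to spike-derived factors: a uniform global
    change in target abundance is invisible to total-count normalization.
    """
    totals = matrix.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise CalibrationError("sample with zero total counts")
    logfac = np.log(totals)
    logfac = logfac - logfac.mean()
    return SizeFactors(factors=np.exp(logfac), provenance="total_count")
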