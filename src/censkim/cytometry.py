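"""Quantification of 1-D fluorescence intensity profiles.

Implements the image-measurement procedures downstream of line-profile
extraction: automatic (isodata) or fixed thresholding of a channel,
detection of discrete signal domains along the axis, centromere extent as
the outer-edge to outer-edge span of the outermost centromere-protein
domains relative to the chromosome (DNA stain) span, and two-channel
signal co-localization on extended chromatin fibers.

The isodata iterative-intermeans algorithm is what ImageJ applies as its
"Default" auto-threshold; presence after thresholding means intensity
strictly above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_isodata


@dataclass
class IntensityProfile:
    """Per-position multi-channel intensities along a polyline axis."""

    positions: np.ndarray  # strictly increasing physical coordinates
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        for name, values in self.channels.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.positions.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = values

    @property
    def pitch(self) -> float:
        """Median sampling interval (pixel size along the line)."""
        if len(self.positions) < 2:
            return 1.0
        return float(np.median(np.diff(self.positions)))


@dataclass(frozen=True)
class ChromosomeMeasurement:
    chromosome_length: float
    centromere_length: float
    ratio: float
    n_domains: int
    label: str | None = None

    @property
    def failed(self) -> bool:
        return self.n_domains == 0


@dataclass(frozen=True)
class OverlapResult:
    fiber_length_measured: float
    fraction_a: float
    fraction_b: float
    overlap_fraction: float


@dataclass(frozen=True)
class MeasureParams:
    """Thresholding and domain-calling parameters.

    ``min_gap_fraction`` and ``min_domain_fraction`` are expressed relative
    to the chromosome span: signal gaps shorter than the former are merged
    and domains shorter than the latter discarded when calling discrete
    centromere-protein domains.
    """

    threshold_method: str = "isodata"  # or "fixed"
    fixed_threshold: float = 0.0
    min_gap_fraction: float = 0.02
    min_domain_fraction: float = 0.01


class UndefinedOverlapError(ValueError):
    """No position carries signal in either channel."""


def threshold_profile(
    p: IntensityProfile,
    channel: str,
    method: str = "isodata",
    fixed_threshold: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Binarize one channel; returns (presence vector, threshold used)."""
    if channel not in p.channels:
        raise KeyError(f"unknown channel {channel!r}")
    values = p.channels[channel]
    if method == "fixed":
        thr = fixed_threshold
    elif method == "isodata":
        if np.allclose(values, values[0]):
            # flat channel: no contrast to split, so presence falls back to
            # strict positivity (all present if positive, none if zero)
            thr = 0.0
        else:
            thr = float(threshold_isodata(values, nbins=256))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return values > thr, thr


def detect_domains(
    presence: np.ndarray,
    positions: np.ndarray,
    min_gap: float = 0.0,
    min_domain: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal runs of present positions as (start, end) coordinate pairs.

    Runs separated by gaps of extent shorter than ``min_gap`` are merged;
    runs whose extent is below ``min_domain`` are discarded.  Extents are
    edge-inclusive: a run covering positions i..j measures
    positions[j] - positions[i] + pixel pitch (a one-pixel domain measures
    one pixel, not zero), and a gap's extent is likewise the span of its
    absent positions.
    """
    presence = np.asarray(presence, dtype=bool)
    positions = np.asarray(positions, dtype=float)
    if presence.shape != positions.shape:
        raise ValueError("presence and positions must be aligned")
    if not presence.any():
        return []
    pitch = float(np.median(np.diff(positions))) if len(positions) > 1 else 1.0
    padded = np.concatenate([[False], presence, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = [(int(edges[i]), int(edges[i + 1]) - 1) for i in range(0, len(edges), 2)]
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if positions[s] - positions[pe] - pitch < min_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        if positions[e] - positions[s] + pitch >= min_domain:
            out.append((float(positions[s]), float(positions[e])))
    return out


def centromere_measurement(
    p: IntensityProfile,
    dna_channel: str = "dna",
    cen_channel: str = "cen",
    params: MeasureParams = MeasureParams(),
    label: str | None = None,
) -> ChromosomeMeasurement:
    """Centromere extent relative to chromosome length from one profile.

    The chromosome is the span of the DNA-stain presence; the centromere is
    the distance between the outer edges of the first and last
    centromere-protein domains (inclusive of both outermost domains, so a
    single dot-like domain has the extent of that domain).  A profile with
    no detectable domain yields a failed measurement (NaN ratio,
    n_domains 0) rather than an error.
    """
    pitch = p.pitch
    dna_presence, _ = threshold_profile(
        p, dna_channel, params.threshold_method, params.fixed_threshold
    )
    if not dna_presence.any():
        return ChromosomeMeasurement(float("nan"), float("nan"), float("nan"), 0, label)
    idx = np.flatnonzero(dna_presence)
    chrom_len = float(p.positions[idx[-1]] - p.positions[idx[0]] + pitch)
    cen_presence, _ = threshold_profile(
        p, cen_channel, params.threshold_method, params.fixed_threshold
    )
    domains = detect_domains(
        cen_presence,
        p.positions,
        min_gap=params.min_gap_fraction * chrom_len,
        min_domain=params.min_domain_fraction * chrom_len,
    )
    if not domains:
        return ChromosomeMeasurement(chrom_len, float("nan"), float("nan"), 0, label)
    cen_len = float(domains[-1][1] - domains[0][0] + pitch)
    return ChromosomeMeasurement(chrom_len, cen_len, cen_len / chrom_len, len(domains), label)


def overlap_fraction(
    p: IntensityProfile,
    channel_a: str,
    channel_b: str,
    params: MeasureParams = MeasureParams(threshold_method="fixed"),
) -> OverlapResult:
    """Two-channel co-localization over the signal-bearing span.

    After per-channel thresholding, the overlap fraction is the number of
    co-positive positions divided by the number of positions where at least
    one channel is positive; per-channel fractions use the same
    denominator, so overlap <= min(fraction_a, fraction_b) by construction
    and the measure is symmetric in its channels.
    """
    pa, _ = threshold_profile(p, channel_a, params.threshold_method, params.fixed_threshold)
    pb, _ = threshold_profile(p, channel_b, params.threshold_method, params.fixed_threshold)
    union = pa | pb
    n_union = int(union.sum())
    if n_union == 0:
        raise UndefinedOverlapError("no position carries signal in either channel")
    idx = np.flatnonzero(union)
    length = float(p.positions[idx[-1]] - p.positions[idx[0]] + p.pitch)
    return OverlapResult(
        fiber_length_measured=length,
        fraction_a=float(pa.sum() / n_union),
        fraction_b=float(pb.sum() / n_union),
        overlap_fraction=float((pa & pb).sum() / n_union),
    )


def summarize_measurements(
    measurements: list[ChromosomeMeasurement],
) -> tuple[float, float, pd.DataFrame]:
    """Mean and sample SD of centromere/chromosome ratios.

    Failed measurements (NaN ratio) are excluded; groups are formed from
    the measurement labels.  A single valid measurement reports SD 0 with
    a warning (sample SD is undefined at n = 1).
    """
    if not measurements:
        raise ValueError("no measurements to summarize")
    rows = [
        {"label": m.label or "all", "ratio": m.ratio}
        for m in measurements
        if not m.failed
    ]
    if not rows:
        raise ValueError("all measurements failed")
    df = pd.DataFrame(rows)
    ratios = df["ratio"].to_numpy()
    if len(ratios) == 1:
        warnings.warn("sample SD undefined for a single measurement; reporting 0")
        mean, sd = float(ratios[0]), 0.0
    else:
        mean, sd = float(ratios.mean()), float(ratios.std(ddof=1))
    grouped = (
        df.groupby("label")["ratio"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    return mean, sd, grouped
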