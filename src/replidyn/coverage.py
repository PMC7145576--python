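"""Binned coverage profiles, replicate averaging and GC skew.

The quantitative substrate of the analysis: per-replicon read counts in
fixed-width genomic bins (0-based, half-open; the last bin may be short),
normalized to percent of total mapped reads, averaged over replicate
infections, plus (G-C)/(G+C) sliding-window skew tracks of the reference
sequences. Normalization precedes averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BinnedCoverage",
    "AveragedProfile",
    "SkewTrack",
    "CumulativeSkew",
    "bin_edges",
    "bin_coverage",
    "normalize_percent",
    "average_replicates",
    "gc_skew",
    "cumulative_skew",
    "plot_profile",
]

log = logging.getLogger(__name__)


def bin_edges(length: int, bin_size: int) -> np.ndarray:
    """Edges of 0-based half-open bins covering [0, length); ragged last bin."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    edges = np.arange(0, length + bin_size, bin_size, dtype=float)
    edges[-1] = min(edges[-1], length)
    if edges[-1] != length:  # length is an exact multiple of bin_size
        edges = np.append(edges, length)
    return edges[: math.ceil(length / bin_size) + 1]


@dataclass
class BinnedCoverage:
    """Per-bin read counts for one replicon in one sample."""

    replicon: str
    length: int
    bin_size: int
    counts: np.ndarray
    sample_id: str | None = None
    timepoint: float | None = None
    percent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected = math.ceil(self.length / self.bin_size)
        if self.counts.size != expected:
            raise ValueError(
                f"{self.replicon}: expected {expected} bins for length "
                f"{self.length} at bin_size {self.bin_size}, got {self.counts.size}"
            )
        if self.percent is not None:
            self.percent = np.asarray(self.percent, dtype=float)
            if self.percent.shape != self.counts.shape:
                raise ValueError("percent must match counts shape")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def edges(self) -> np.ndarray:
        return bin_edges(self.length, self.bin_size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AveragedProfile:
    """Replicate-averaged percent-coverage profile (mean and sample SD)."""

    replicon: str
    length: int
    bin_size: int
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    timepoint: float | None = None
    mean_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same shape")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.mean.size

    @property
    def edges(self) -> np.ndarray:
        return bin_edges(self.length, self.bin_size)


def bin_coverage(
    positions: Sequence[int] | np.ndarray,
    length: int,
    bin_size: int,
    replicon: str = "replicon",
    sample_id: str | None = None,
    timepoint: float | None = None,
) -> BinnedCoverage:
    """Bin per-read positions (0-based) into fixed-width bins.

    Total counts are conserved exactly; positions outside ``[0, length)``
    are rejected with the offender count.
    """
    pos = np.asarray(positions, dtype=np.int64)
    bad = int(np.count_nonzero((pos < 0) | (pos >= length)))
    if bad:
        raise ValueError(f"{bad} position(s) outside [0, {length})")
    n_bins = math.ceil(length / bin_size)
    counts = np.bincount(pos // bin_size, minlength=n_bins)
    return BinnedCoverage(
        replicon=replicon,
        length=length,
        bin_size=bin_size,
        counts=counts,
        sample_id=sample_id,
        timepoint=timepoint,
    )


def normalize_percent(binned: BinnedCoverage, total_mapped: int) -> BinnedCoverage:
    """Attach percent-of-total-mapped-reads per bin.

    ``total_mapped`` is the total read count of the whole sample (all
    replicons), so percent values sum to 100 across a sample. Scale
    equivariant: doubling counts and total leaves percent unchanged.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if total_mapped < binned.total:
        raise ValueError(
            f"total_mapped={total_mapped} < replicon total {binned.total}"
        )
    pct = 100.0 * binned.counts / float(total_mapped)
    return replace(binned, counts=binned.counts.copy(), percent=pct)


def average_replicates(profiles: Sequence[BinnedCoverage]) -> AveragedProfile:
    """Average normalized replicate profiles bin-wise (mean, sample SD).

    All profiles must carry percent values and share replicon, binning and
    timepoint. SD uses the n-1 denominator and is zero for one replicate.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if (
            p.replicon != first.replicon
            or p.bin_size != first.bin_size
            or p.length != first.length
            or p.timepoint != first.timepoint
        ):
            raise ValueError("profiles disagree on replicon, binning or timepoint")
    if any(p.percent is None for p in profiles):
        raise ValueError("profiles must be normalized before averaging")
    stack = np.vstack([p.percent for p in profiles])
    n = stack.shape[0]
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(stack.shape[1])
    counts = np.vstack([p.counts for p in profiles]).mean(axis=0)
    return AveragedProfile(
        replicon=first.replicon,
        length=first.length,
        bin_size=first.bin_size,
        mean=stack.mean(axis=0),
        sd=sd,
        n_replicates=n,
        timepoint=first.timepoint,
        mean_counts=counts,
    )


# ---------------------------------------------------------------------------
# GC skew
# ---------------------------------------------------------------------------

@dataclass
class SkewTrack:
    """(G-C)/(G+C) per sliding window; windows with G+C=0 are NaN-masked."""

    replicon: str
    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray
    circular: bool = True

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


def gc_skew(
    sequence: str,
    window: int = 1000,
    step: int | None = None,
    circular: bool = True,
    replicon: str = "replicon",
) -> SkewTrack:
    """Sliding-window GC skew (G-C)/(G+C) on the given (plus) strand.

    ``step`` defaults to ``window // 10`` (minimum 1). For circular
    sequences windows wrap around the end; for linear sequences only fully
    contained windows are evaluated, and a window longer than the sequence
    is rejected. ``N`` (or any non-G/C symbol) contributes to neither
    count; windows with no G or C at all are NaN and flagged missing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = sequence.upper()
    L = len(seq)
    if not circular and window > L:
        raise ValueError("window longer than a linear sequence")
    if step is None:
        step = max(window // 10, 1)
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    g = (arr == b"G").astype(np.int64)
    c = (arr == b"C").astype(np.int64)
    if circular:
        starts = np.arange(0, L, step)
        g2 = np.concatenate([g, g])
        c2 = np.concatenate([c, c])
        gcum = np.concatenate([[0], np.cumsum(g2)])
        ccum = np.concatenate([[0], np.cumsum(c2)])
        win = min(window, L)
        gw = gcum[starts + win] - gcum[starts]
        cw = ccum[starts + win] - ccum[starts]
    else:
        starts = np.arange(0, L - window + 1, step)
        gcum = np.concatenate([[0], np.cumsum(g)])
        ccum = np.concatenate([[0], np.cumsum(c)])
        gw = gcum[starts + window] - gcum[starts]
        cw = ccum[starts + window] - ccum[starts]
    denom = (gw + cw).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, (gw - cw) / denom, np.nan)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        log.warning("%s: %d skew window(s) with no G/C content", replicon, n_missing)
    return SkewTrack(
        replicon=replicon,
        window=window,
        step=step,
        starts=starts,
        values=values,
        circular=circular,
    )


@dataclass
class CumulativeSkew:
    """Cumulative skew curve with candidate ori (minimum) / ter (maximum)."""

    cumulative: np.ndarray
    starts: np.ndarray
    min_pos: int | None
    max_pos: int | None
    flat: bool


def cumulative_skew(track: SkewTrack, skip_missing: bool = False) -> CumulativeSkew:
    """Cumulative sum of the skew track.

    The global minimum of the cumulative curve is the candidate origin and
    the maximum the candidate terminus (skew is typically positive on the
    ori->ter replichore). An all-zero track is flagged flat with undefined
    extrema. Missing windows are rejected unless ``skip_missing``.
    """
    vals = track.values
    if np.isnan(vals).any():
        if not skip_missing:
            raise ValueError("track has missing windows; pass skip_missing=True")
        vals = np.nan_to_num(vals)
    cum = np.cumsum(vals)
    if np.allclose(vals, 0.0):
        return CumulativeSkew(cum, track.starts, None, None, flat=True)
    return CumulativeSkew(
        cumulative=cum,
        starts=track.starts,
        min_pos=int(track.starts[int(np.argmin(cum))]),
        max_pos=int(track.starts[int(np.argmax(cum))]),
        flat=False,
    )


def plot_profile(
    profile: AveragedProfile,
    skew: SkewTrack | None = None,
    path: str | None = None,
    title: str | None = None,
):
    """Percent-coverage profile (mean line, SD shading) with optional GC
    skew overlay on a secondary axis. Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    x = profile.edges[:-1] / 1000.0
    ax.plot(x, profile.mean, color="black", lw=1)
    ax.fill_between(
        x,
        profile.mean - profile.sd,
        profile.mean + profile.sd,
        color="0.4",
        alpha=0.5,
        lw=0,
    )
    ax.set_xlabel("position (kb)")
    ax.set_ylabel("percent reads coverage")
    if skew is not None:
        ax2 = ax.twinx()
        ax2.fill_between(
            skew.starts / 1000.0, 0, np.nan_to_num(skew.values), color="0.8", zorder=0
        )
        ax2.set_ylabel("GC skew")
    ax.set_title(title or f"{profile.replicon} t={profile.timepoint}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
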