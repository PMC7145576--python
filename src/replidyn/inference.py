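"""Replication-origin, replication-mode, terminus-spike and pac-site calls.

Marker-frequency logic: in a replicating population, sequencing coverage
peaks at the replication origin and declines toward the terminus, so the
shape of a binned coverage profile encodes both where replication starts
and how it proceeds.

* theta (bidirectional) replication — coverage declines symmetrically on
  both flanks of the origin;
* rolling circle — coverage declines gradually on the flank behind the
  replication fork and falls off a cliff immediately past the peak;
* static — flat profile, no origin call.

The classifier fits log2-coverage declines over a window on each flank of
the called origin. Asymmetry is the ratio of the smaller to the larger
*decline rate* (a flank that rises away from the peak — the wrapped tail
of a rolling-circle exponential — contributes a decline of zero), and the
drop ratio compares mean coverage of the gradual flank against the flank
immediately across the peak. Thresholds were calibrated by simulation ROC
at the generator's default noise and live in :data:`CLASSIFY_DEFAULTS`.

Pac sites appear as strand-specific spikes in read-start pileups; the
packaging terminus of injected particles shows as a coverage spike that
is present at the earliest timepoint and gone once genomes circularize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import AveragedProfile, BinnedCoverage

__all__ = [
    "CLASSIFY_DEFAULTS",
    "OriginCall",
    "ReplicationCall",
    "PacCall",
    "SpikeCall",
    "circular_moving_average",
    "detect_origin",
    "peak_trough_ratio",
    "classify_mode",
    "detect_terminus_spike",
    "locate_pac",
    "compare_conditions",
]

log = logging.getLogger(__name__)

#: Classifier defaults, simulation-ROC calibrated at the generator's
#: default noise (peak-to-trough 2, depth 1e5, ~126 bins):
#:   tau_sym  — minimum flank-decline symmetry to call theta;
#:   tau_drop — minimum across-peak drop ratio to call rolling circle;
#:   w        — flank window (bins) for slope fits and drop means;
#:   smooth_bins — circular moving-average width;
#:   pseudocount — added before log2 to avoid -inf on empty bins;
#:   flat_ptr — smoothed max/min below which a profile is called static.
CLASSIFY_DEFAULTS: dict[str, float] = {
    "tau_sym": 0.4,
    "tau_drop": 3.0,
    "w": 10,
    "smooth_bins": 5,
    "pseudocount": 0.5,
    "flat_ptr": 1.1,
    "flat_snr": 1.5,
}


def _values(profile) -> np.ndarray:
    """Bin values of a profile-like object, preferring count scale."""
    if isinstance(profile, AveragedProfile):
        if profile.mean_counts is not None:
            return np.asarray(profile.mean_counts, dtype=float)
        return np.asarray(profile.mean, dtype=float)
    if isinstance(profile, BinnedCoverage):
        return profile.counts.astype(float)
    return np.asarray(profile, dtype=float)


def _bin_size(profile, default: int = 1) -> int:
    return getattr(profile, "bin_size", default)


def circular_moving_average(y: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with circular wrap; ``w`` forced odd."""
    y = np.asarray(y, dtype=float)
    if w <= 1:
        return y.copy()
    if w % 2 == 0:
        w += 1
    h = w // 2
    ext = np.concatenate([y[-h:], y, y[:h]])
    return np.convolve(ext, np.ones(w) / w, mode="valid")


def _circ_dist(i: np.ndarray | int, j: int, n: int) -> np.ndarray | int:
    d = np.abs(np.asarray(i) - j) % n
    return np.minimum(d, n - d)


def _interpolate_masked(y: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Replace masked bins by circular linear interpolation of neighbors,
    so excluded spikes do not leak into moving-average smoothing."""
    if mask is None or not mask.any():
        return y
    good = np.flatnonzero(~mask)
    bad = np.flatnonzero(mask)
    out = y.copy()
    out[bad] = np.interp(bad, good, y[good], period=y.size)
    return out


def _signal_to_noise(profile) -> float | None:
    """Between-bin variance of the replicate mean over its sampling noise.

    The replicate SD estimates per-bin measurement noise; a profile whose
    between-bin variance matches noise/n is flat regardless of its
    max/min ratio. Returns None when no replicate SDs are available.
    """
    if not isinstance(profile, AveragedProfile) or profile.n_replicates < 2:
        return None
    mean = np.asarray(profile.mean, dtype=float)
    noise = float(np.mean(np.asarray(profile.sd, dtype=float) ** 2)) / profile.n_replicates
    signal = float(np.var(mean))
    if noise == 0:
        return float("inf") if signal > 0 else 0.0
    return signal / noise


# ---------------------------------------------------------------------------
# origin detection
# ---------------------------------------------------------------------------

@dataclass
class OriginCall:
    """Origin estimate: bin index, bp midpoint, optional bootstrap CI."""

    replicon: str
    ori_bin: int | None
    ori_bp: int | None
    flat: bool
    ptr_hat: float
    n_bins: int
    bin_size: int
    ci_bins: tuple[int, int] | None = None


def _template_sse(ly: np.ndarray, o: int, mode: str, keep: np.ndarray) -> float:
    """SSE of log2 coverage regressed on a distance-from-origin template.

    ``theta``: circular min-distance; ``rc``: anti-replication distance.
    The slope is constrained to be non-positive (coverage cannot rise away
    from the origin), which breaks the exact ori/ter degeneracy of the
    theta template.
    """
    n = ly.size
    x = np.arange(n)
    if mode == "theta":
        d = _circ_dist(x, o, n).astype(float)
    else:
        d = ((o - x) % n).astype(float)
    d, v = d[keep], ly[keep]
    dc = d - d.mean()
    denom = float(dc @ dc)
    slope = min(float(dc @ (v - v.mean())) / denom, 0.0) if denom > 0 else 0.0
    resid = (v - v.mean()) - slope * dc
    return float(resid @ resid)


def detect_origin(
    profile,
    smooth_bins: int | None = None,
    exclude_mask: np.ndarray | None = None,
    replicate_profiles: Sequence[np.ndarray] | None = None,
    refine: bool = True,
    n_boot: int = 200,
    seed: int = 0,
) -> OriginCall:
    """Locate the replication origin of a circular coverage profile.

    The coarse locator is the argmax of the circularly smoothed profile
    (ties to the lowest coordinate) outside ``exclude_mask``. Because
    moving-average smoothing displaces the peak of one-sided (rolling
    circle) shapes and the argmax of a noisy near-flat peak wanders,
    the estimate is refined by a local template fit: every candidate bin
    within two smoothing widths of the argmax is scored by the residual
    of a log2-coverage regression on distance-from-candidate (theta and
    rolling-circle distance templates; best of the two), and the lowest
    residual wins. The refinement is exact on noiseless shapes of either
    mode and uses the whole profile rather than the peak bins alone.

    A profile is called static (no position) when its smoothed max/min
    ratio is below the flatness threshold, or — when replicate SDs are
    available — when its between-bin variance is consistent with the
    replicate sampling noise (variance test). Excluded bins are bridged
    by circular interpolation before smoothing so masked spikes do not
    leak into neighboring bins. With replicate-level profiles a
    percentile bootstrap CI (bin arc) is attached.
    """
    y = _values(profile)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 bins to call an origin")
    cfg = CLASSIFY_DEFAULTS
    sw = int(cfg["smooth_bins"] if smooth_bins is None else smooth_bins)
    keep = np.ones(n, dtype=bool)
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.shape != (n,):
            raise ValueError("exclude_mask must have one flag per bin")
        keep = ~exclude_mask
        if not keep.any():
            raise ValueError("exclude_mask removes every bin")
    name = getattr(profile, "replicon", "replicon")
    bsz = _bin_size(profile)

    def locate(vals: np.ndarray) -> tuple[int, float]:
        vals = _interpolate_masked(vals, exclude_mask)
        sm = circular_moving_average(vals, sw)
        smk = sm[keep]
        trough = max(smk.min(), 1e-300)
        ptr_hat = float(smk.max() / trough)
        cand0 = int(np.flatnonzero(keep)[int(np.argmax(smk))])
        if not refine:
            return cand0, ptr_hat
        ly = np.log2(vals + cfg["pseudocount"])
        radius = max(2 * sw, 2)
        cands = [
            c
            for c in (np.arange(cand0 - radius, cand0 + radius + 1) % n)
            if keep[c]
        ]
        sses = [
            min(_template_sse(ly, c, "theta", keep), _template_sse(ly, c, "rc", keep))
            for c in cands
        ]
        return int(cands[int(np.argmin(sses))]), ptr_hat

    sm = circular_moving_average(_interpolate_masked(y, exclude_mask), sw)
    smk = sm[keep]
    ptr_hat = float(smk.max() / max(smk.min(), 1e-300))
    snr = _signal_to_noise(profile)
    if ptr_hat < cfg["flat_ptr"] or (snr is not None and snr < cfg["flat_snr"]):
        return OriginCall(
            replicon=name, ori_bin=None, ori_bp=None, flat=True,
            ptr_hat=ptr_hat, n_bins=n, bin_size=bsz,
        )
    est, ptr_hat = locate(y)
    ci = None
    if replicate_profiles is not None and len(replicate_profiles) > 1:
        reps = [np.asarray(r, dtype=float) for r in replicate_profiles]
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
        devs = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(reps), size=len(reps))
            bm = np.mean([reps[i] for i in idx], axis=0)
            b_est, _ = locate(bm)
            d = (b_est - est) % n
            devs.append(d - n if d > n // 2 else d)
        lo, hi = np.percentile(devs, [2.5, 97.5])
        ci = (int((est + int(np.floor(lo))) % n), int((est + int(np.ceil(hi))) % n))
    mid = int(est * bsz + bsz // 2) if bsz > 1 else est
    return OriginCall(
        replicon=name, ori_bin=est, ori_bp=mid, flat=False,
        ptr_hat=ptr_hat, n_bins=n, bin_size=bsz, ci_bins=ci,
    )


def peak_trough_ratio(
    profile,
    smooth_bins: int | None = None,
    exclude_mask: np.ndarray | None = None,
) -> float:
    """Smoothed coverage maximum over minimum (>= 1 by construction).

    A zero trough gets the configured pseudocount and a logged warning;
    the ratio is invariant to uniform depth scaling up to that floor.
    """
    y = _values(profile)
    cfg = CLASSIFY_DEFAULTS
    sw = int(cfg["smooth_bins"] if smooth_bins is None else smooth_bins)
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
    sm = circular_moving_average(_interpolate_masked(y, exclude_mask), sw)
    if exclude_mask is not None:
        sm = sm[~exclude_mask]
    trough = float(sm.min())
    if trough <= 0:
        log.debug("zero trough; applying pseudocount %.2f", cfg["pseudocount"])
        trough = float(cfg["pseudocount"])
    return max(float(sm.max()) / trough, 1.0)


# ---------------------------------------------------------------------------
# mode classification
# ---------------------------------------------------------------------------

@dataclass
class ReplicationCall:
    """Origin position, shape statistics and replication-mode label."""

    replicon: str
    timepoint: float | None
    ori_bin: int | None
    ori_bp: int | None
    ptr_hat: float
    slope_left: float  # log2 coverage per kb, left (lower-coordinate) flank
    slope_right: float
    asymmetry: float
    drop_ratio: float
    mode_label: str


def classify_mode(
    profile,
    origin: OriginCall | None = None,
    w: int | None = None,
    tau_sym: float | None = None,
    tau_drop: float | None = None,
    smooth_bins: int | None = None,
    exclude_mask: np.ndarray | None = None,
) -> ReplicationCall:
    """Label a coverage profile theta / rolling_circle / static /
    indeterminate from its shape around the called origin.

    Least-squares lines are fit to log2(smoothed coverage + pseudocount)
    over ``w`` bins on each flank of the origin in circular coordinates.
    theta requires symmetric declines (asymmetry >= tau_sym) without an
    across-peak discontinuity (drop_ratio < tau_drop); rolling circle
    requires the converse; a near-flat profile is static; anything else —
    including genuine theta/rolling-circle mixtures — is indeterminate.
    """
    cfg = CLASSIFY_DEFAULTS
    w = int(cfg["w"] if w is None else w)
    tau_sym = float(cfg["tau_sym"] if tau_sym is None else tau_sym)
    tau_drop = float(cfg["tau_drop"] if tau_drop is None else tau_drop)
    sw = int(cfg["smooth_bins"] if smooth_bins is None else smooth_bins)
    pc = float(cfg["pseudocount"])
    y = _values(profile)
    n = y.size
    if 2 * w + 1 > n:
        raise ValueError(f"flank window w={w} too wide for {n} bins")
    if origin is None:
        origin = detect_origin(profile, smooth_bins=sw, exclude_mask=exclude_mask)
    tp = getattr(profile, "timepoint", None)
    name = getattr(profile, "replicon", "replicon")
    if origin.flat or origin.ori_bin is None:
        return ReplicationCall(
            replicon=name, timepoint=tp, ori_bin=None, ori_bp=None,
            ptr_hat=origin.ptr_hat, slope_left=0.0, slope_right=0.0,
            asymmetry=1.0, drop_ratio=1.0, mode_label="static",
        )
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
    o = origin.ori_bin
    sm = circular_moving_average(_interpolate_masked(y, exclude_mask), sw)
    dist = np.arange(1, w + 1)
    left = sm[(o - dist) % n]
    right = sm[(o + dist) % n]
    bsz = _bin_size(profile)
    per_kb = 1000.0 / bsz if bsz > 1 else 1.0
    # slopes of log2 coverage vs distance-from-origin, one per flank
    slope_l = float(np.polyfit(dist, np.log2(left + pc), 1)[0])
    slope_r = float(np.polyfit(dist, np.log2(right + pc), 1)[0])
    decline_l, decline_r = max(-slope_l, 0.0), max(-slope_r, 0.0)
    big = max(decline_l, decline_r)
    asymmetry = 1.0 if big < 1e-9 else min(decline_l, decline_r) / big
    ml, mr = float(left.mean()), float(right.mean())
    drop_ratio = max(ml, mr) / max(min(ml, mr), pc)
    ptr_hat = peak_trough_ratio(profile, smooth_bins=sw, exclude_mask=exclude_mask)
    if ptr_hat < cfg["flat_ptr"]:
        label = "static"
    elif asymmetry >= tau_sym and drop_ratio < tau_drop:
        label = "theta"
    elif asymmetry < tau_sym and drop_ratio >= tau_drop:
        label = "rolling_circle"
    else:
        label = "indeterminate"
    return ReplicationCall(
        replicon=name, timepoint=tp, ori_bin=o, ori_bp=origin.ori_bp,
        ptr_hat=ptr_hat, slope_left=slope_l * per_kb, slope_right=slope_r * per_kb,
        asymmetry=asymmetry, drop_ratio=drop_ratio, mode_label=label,
    )


# ---------------------------------------------------------------------------
# transient terminus spike
# ---------------------------------------------------------------------------

@dataclass
class SpikeCall:
    """Bins enriched early and gone late (transient packaging terminus)."""

    transient_bins: list[int] = field(default_factory=list)
    transient_runs: list[tuple[int, int]] = field(default_factory=list)
    persistent_bins: list[int] = field(default_factory=list)
    transient: bool = False

    def exclude_mask(self, n_bins: int) -> np.ndarray:
        mask = np.zeros(n_bins, dtype=bool)
        mask[self.transient_bins] = True
        return mask


def _circular_local_median(y: np.ndarray, half: int) -> np.ndarray:
    n = y.size
    win = 2 * half + 1
    ext = np.concatenate([y[-half:], y, y[:half]])
    return np.median(
        np.lib.stride_tricks.sliding_window_view(ext, win), axis=1
    )[:n]


def _merge_runs(bins: np.ndarray, n: int) -> list[tuple[int, int]]:
    """Merge sorted bin indices into half-open circular runs."""
    if bins.size == 0:
        return []
    runs: list[list[int]] = []
    for b in (int(b) for b in bins):
        if runs and b == runs[-1][1]:
            runs[-1][1] = b + 1
        else:
            runs.append([b, b + 1])
    # circular join of last and first run
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n:
        first = runs.pop(0)
        runs[-1][1] = first[1]
    return [(a, b) for a, b in runs]


def detect_terminus_spike(
    early,
    late,
    k: float = 3.0,
    w: int = 3,
) -> SpikeCall:
    """Find transient coverage spikes: enriched early, resolved late.

    A bin is a transient-spike candidate when its early coverage exceeds
    ``k`` times the circular local median (window ``2*w+1``) and its late
    coverage is at most ``k/2`` times the late local median. Contiguous
    candidates are merged into runs. Bins enriched at both timepoints are
    reported separately as persistent (candidate origins, not termini).
    The transient bins are suitable as an ``exclude_mask`` for
    :func:`detect_origin` at the early timepoint.
    """
    ye, yl = _values(early), _values(late)
    if ye.shape != yl.shape:
        raise ValueError("early and late profiles must share binning")
    me = _circular_local_median(ye, w)
    ml = _circular_local_median(yl, w)
    hot_early = ye > k * me
    calm_late = yl <= (k / 2.0) * ml
    transient = hot_early & calm_late
    persistent = hot_early & ~calm_late & (yl > k * ml)
    tbins = np.flatnonzero(transient)
    return SpikeCall(
        transient_bins=[int(b) for b in tbins],
        transient_runs=_merge_runs(tbins, ye.size),
        persistent_bins=[int(b) for b in np.flatnonzero(persistent)],
        transient=bool(tbins.size),
    )


# ---------------------------------------------------------------------------
# pac-site localization
# ---------------------------------------------------------------------------

@dataclass
class PacCall:
    """Per-strand packaging-site calls from read-start pileups."""

    plus_pos: int | None
    minus_pos: int | None
    enrichment: dict[str, float]
    tie: dict[str, bool]
    transient: bool | None = None


def locate_pac(
    read_starts: Mapping[str, np.ndarray],
    z: float = 10.0,
    late_read_starts: Mapping[str, np.ndarray] | None = None,
) -> PacCall:
    """Call per-strand pac positions as read-start spike maxima.

    Per strand, the candidate is the argmax of the read-start histogram
    (ties broken to the lowest coordinate and flagged); it is called only
    if its count exceeds ``z`` times the genome-wide mean and carries at
    least ``z`` reads of absolute support. Strands are
    independent. With a late histogram set, ``transient`` records whether
    a site called early is absent late (headful-packaging signature of
    injected, not-yet-circularized genomes).
    """
    calls: dict[str, int | None] = {"+": None, "-": None}
    enrich: dict[str, float] = {}
    tie: dict[str, bool] = {}
    for strand in ("+", "-"):
        if strand not in read_starts:
            raise ValueError(f"missing {strand} strand histogram")
        h = np.asarray(read_starts[strand], dtype=float)
        if h.size == 0:
            raise ValueError("empty read-start histogram")
        mean = h.mean()
        cand = int(np.argmax(h))  # first (lowest-coordinate) maximum
        tie[strand] = int(np.count_nonzero(h == h[cand])) > 1
        if tie[strand]:
            log.warning("%s strand: tied read-start maxima; lowest kept", strand)
        enrich[strand] = float(h[cand] / mean) if mean > 0 else float("inf")
        # z doubles as minimum absolute read support: on sparse uniform
        # backgrounds (mean << 1 read/position) the Poisson maximum alone
        # can exceed z times the mean without being a real site
        if h[cand] > z * mean and h[cand] >= z:
            calls[strand] = cand
    transient = None
    if late_read_starts is not None:
        late = locate_pac(late_read_starts, z=z)
        early_called = calls["+"] is not None or calls["-"] is not None
        late_called = late.plus_pos is not None or late.minus_pos is not None
        transient = early_called and not late_called
    return PacCall(
        plus_pos=calls["+"], minus_pos=calls["-"],
        enrichment=enrich, tie=tie, transient=transient,
    )


# ---------------------------------------------------------------------------
# cross-condition comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Per-condition replication calls plus pairwise profile distances."""

    calls: pd.DataFrame
    distances: pd.DataFrame
    rotated: bool


def compare_conditions(
    profiles: Mapping[str, object],
    align: bool = True,
    **classify_kwargs,
) -> ComparisonReport:
    """Compare replication behavior of one replicon across conditions.

    ``profiles`` maps condition name to a coverage profile with matched
    binning. Each profile is classified; the report carries (condition,
    timepoint, ori, mode, ptr, asymmetry, drop_ratio) and an L1 distance
    matrix of sum-normalized profiles. With ``align=True`` each profile is
    circularly rotated so its called peak sits at the center bin before
    distances are computed, so conditions sharing a shape but not a peak
    position compare as similar.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two conditions")
    values = {c: _values(p) for c, p in profiles.items()}
    sizes = {v.size for v in values.values()}
    if len(sizes) > 1:
        raise ValueError("conditions must share binning")
    n = sizes.pop()
    rows = []
    rotated: dict[str, np.ndarray] = {}
    for cond, prof in profiles.items():
        call = classify_mode(prof, **classify_kwargs)
        rows.append(
            {
                "condition": cond,
                "timepoint": call.timepoint,
                "ori_bin": call.ori_bin,
                "ori_bp": call.ori_bp,
                "mode_label": call.mode_label,
                "ptr_hat": call.ptr_hat,
                "asymmetry": call.asymmetry,
                "drop_ratio": call.drop_ratio,
            }
        )
        v = values[cond] / values[cond].sum()
        if align and call.ori_bin is not None:
            rotated[cond] = np.roll(v, n // 2 - call.ori_bin)
        else:
            rotated[cond] = v
    conds = list(profiles)
    dist = pd.DataFrame(0.0, index=conds, columns=conds)
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            d = float(np.abs(rotated[a] - rotated[b]).sum())
            dist.loc[a, b] = dist.loc[b, a] = d
    return ComparisonReport(calls=pd.DataFrame(rows), distances=dist, rotated=align)
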