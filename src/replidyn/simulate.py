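"""Synthetic infection time-course generator.

Emulates the DNA content of a phage-infected cell carrying a replicating
satellite: a small set of replicons (host chromosomes, helper phage,
satellite element) whose per-cell copy numbers grow over an infection time
course, sequenced to a fixed read depth per sample. Reads are allocated to
(replicon, bin) cells in proportion to copy number, bin length and a
replication-shape density, so the downstream coverage, abundance and
inference stages can be exercised — and their estimates checked against
injected truth — without any external data.

Coverage shapes
---------------
``theta_bidirectional``
    Bidirectional replication from a single origin on a circular genome:
    log2 density declines linearly with circular distance from the origin
    on both flanks; the total peak-to-trough log2 range equals
    ``log2(ptr)``.
``rolling_circle``
    Unidirectional replication: density ∝ exp(-rc_decay * d(x)) where
    d(x) is the distance from the origin measured once around the circle
    against the direction of replication (replication runs toward
    increasing coordinate). This yields a gradual decline upstream of the
    peak and a sharp discontinuity immediately downstream of it.
``mixed``
    Convex combination of the two, weighted per timepoint.
``static``
    Uniform (non-replicating element, e.g. a host chromosome at these
    short time scales).

These functional forms are this package's formalization of the standard
verbal description of marker-frequency profiles; the literature the
profiles come from states the expected shapes without explicit formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage import BinnedCoverage, bin_edges

__all__ = [
    "RepliconSpec",
    "CopyTrajectory",
    "TerminusSpike",
    "InfectionScenario",
    "SimulatedSample",
    "copy_at",
    "shape_density",
    "sample_reads",
    "sample_read_starts",
    "synthesize_skewed_sequence",
    "simulate_qpcr",
    "default_scenario",
]

MODES = ("static", "theta_bidirectional", "rolling_circle", "mixed")

DEFAULT_TIMEPOINTS = (4.0, 8.0, 12.0, 16.0)  # minutes post-infection


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminusSpike:
    """Transient packaging-terminus enrichment on a rectangular window.

    The spike multiplies the weights of the bins overlapping
    ``[position, position + width)`` (circular) by ``amplitude[t]``.
    Amplitudes must be non-increasing over time: the terminus bias of
    injected particles fades once genomes circularize.
    """

    position: int
    width: int
    amplitude: Mapping[float, float]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("spike width must be positive")
        amps = dict(self.amplitude)
        if any(a < 0 for a in amps.values()):
            raise ValueError("spike amplitude must be >= 0")
        ts = sorted(amps)
        vals = [amps[t] for t in ts]
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("spike amplitude must be non-increasing in time")

    def amplitude_at(self, t: float) -> float:
        return float(dict(self.amplitude).get(t, 1.0))


@dataclass(frozen=True)
class RepliconSpec:
    """One genetic element: geometry, replication mode and shape parameters."""

    name: str
    length: int
    topology: str = "circular"
    mode: str = "static"
    ori_pos: int | None = None
    pac_pos_plus: int | None = None
    pac_pos_minus: int | None = None
    ptr: float = 1.0
    rc_decay: float = 1e-4
    mix_weight: float | Mapping[float, float] = 0.0
    bin_size: int = 1000
    terminus_spike: TerminusSpike | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"{self.name}: unknown topology {self.topology!r}")
        if self.mode not in MODES:
            raise ValueError(f"{self.name}: unknown mode {self.mode!r}")
        if self.mode != "static" and self.ori_pos is None:
            raise ValueError(f"{self.name}: ori_pos required for mode {self.mode}")
        for attr in ("ori_pos", "pac_pos_plus", "pac_pos_minus"):
            v = getattr(self, attr)
            if v is not None and not 0 <= v < self.length:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, {self.length})")
        if self.ptr < 1:
            raise ValueError(f"{self.name}: ptr must be >= 1")
        if self.rc_decay <= 0:
            raise ValueError(f"{self.name}: rc_decay must be > 0")
        if self.mode == "static" and self.ptr != 1.0:
            warnings.warn(
                f"{self.name}: ptr={self.ptr} ignored for a static replicon",
                stacklevel=2,
            )
        if self.bin_size < 1:
            raise ValueError(f"{self.name}: bin_size must be >= 1")

    def mix_weight_at(self, t: float) -> float:
        if isinstance(self.mix_weight, Mapping):
            try:
                w = float(self.mix_weight[t])
            except KeyError:
                raise KeyError(
                    f"{self.name}: mix_weight has no entry for timepoint {t}"
                ) from None
        else:
            w = float(self.mix_weight)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"{self.name}: mix_weight {w} outside [0, 1]")
        return w


@dataclass(frozen=True)
class CopyTrajectory:
    """Per-cell copy number over the infection: flat until onset, then
    exponential doubling, truncated at ``n0 * cap``.

    ``doubling_time=None`` means the element never replicates (host
    chromosomes on infection time scales).
    """

    replicon: str
    n0: float = 1.0
    onset: float = 0.0
    doubling_time: float | None = None
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError(f"{self.replicon}: n0 must be > 0")
        if self.onset < 0:
            raise ValueError(f"{self.replicon}: onset must be >= 0")
        if self.doubling_time is not None and self.doubling_time <= 0:
            raise ValueError(f"{self.replicon}: doubling_time must be > 0")
        if self.cap is not None and self.cap < 1:
            raise ValueError(f"{self.replicon}: cap must be >= 1")


def copy_at(trajectory: CopyTrajectory, t: float) -> float:
    """Copies per cell at time ``t`` (minutes post-infection)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    tr = trajectory
    if tr.doubling_time is None or t < tr.onset:
        return tr.n0
    n = tr.n0 * 2.0 ** ((t - tr.onset) / tr.doubling_time)
    if tr.cap is not None:
        n = min(n, tr.n0 * tr.cap)
    return float(n)


@dataclass(frozen=True)
class InfectionScenario:
    """Simulator contract: replicon set, copy trajectories, sampling design."""

    replicons: Sequence[RepliconSpec]
    trajectories: Sequence[CopyTrajectory]
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    reads_per_sample: int = 1_000_000
    replicates: int = 3
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicons", tuple(self.replicons))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            raise ValueError("replicon names must be unique")
        traj_names = [t.replicon for t in self.trajectories]
        if sorted(traj_names) != sorted(names):
            raise ValueError("every replicon needs exactly one trajectory")
        by_name = {t.replicon: t for t in self.trajectories}
        object.__setattr__(
            self, "trajectories", tuple(by_name[n] for n in names)
        )  # stored in replicon order
        tps = list(self.timepoints)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def trajectory(self, name: str) -> CopyTrajectory:
        for tr in self.trajectories:
            if tr.replicon == name:
                return tr
        raise KeyError(name)


@dataclass
class SimulatedSample:
    """One sequenced sample: per-replicon binned read counts."""

    sample_id: str
    timepoint: float
    replicate: int
    coverage: dict[str, BinnedCoverage] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return int(sum(int(c.counts.sum()) for c in self.coverage.values()))


# ---------------------------------------------------------------------------
# coverage shapes
# ---------------------------------------------------------------------------

def _density_per_bp(spec: RepliconSpec, t: float, x: np.ndarray) -> np.ndarray:
    """Unnormalized per-bp density of the replication shape at positions x."""
    L = spec.length
    if spec.mode == "static":
        return np.ones_like(x, dtype=float)

    def theta() -> np.ndarray:
        d = np.minimum((x - spec.ori_pos) % L, (spec.ori_pos - x) % L)
        dens = spec.ptr ** (-d / (L / 2.0))
        return dens / dens.mean()

    def rolling() -> np.ndarray:
        d = (spec.ori_pos - x) % L  # anti-replication distance
        dens = np.exp(-spec.rc_decay * d)
        return dens / dens.mean()

    if spec.mode == "theta_bidirectional":
        return theta()
    if spec.mode == "rolling_circle":
        return rolling()
    w = spec.mix_weight_at(t)
    return w * rolling() + (1.0 - w) * theta()


def _bin_weights(spec: RepliconSpec, t: float, edges: np.ndarray) -> np.ndarray:
    """Relative bin weights: midpoint density times bin width."""
    mid = (edges[:-1] + edges[1:]) / 2.0
    widths = np.diff(edges).astype(float)
    return _density_per_bp(spec, t, mid) * widths


def shape_density(spec: RepliconSpec, t: float, n_bins: int) -> np.ndarray:
    """Per-bin relative density over ``n_bins`` equal bins; sums to 1."""
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    edges = np.linspace(0.0, spec.length, n_bins + 1)
    w = _bin_weights(spec, t, edges)
    return w / w.sum()


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _sample_rng(seed: int, replicate: int, timepoint_index: int) -> np.random.Generator:
    # one master seed; fixed per-(replicate, timepoint) substreams
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate, timepoint_index))
    return np.random.default_rng(ss)


def _spike_mask(spec: RepliconSpec, edges: np.ndarray) -> np.ndarray:
    """Boolean mask of bins overlapping the spike window (circular)."""
    spike = spec.terminus_spike
    assert spike is not None
    L = spec.length
    start = spike.position % L
    stop = start + spike.width
    starts, ends = edges[:-1], edges[1:]
    if stop <= L:
        return (ends > start) & (starts < stop)
    # window wraps past the end of the genome
    return (ends > start) | (starts < stop - L)


def sample_reads(scenario: InfectionScenario) -> list[SimulatedSample]:
    """Allocate reads to (replicon, bin) cells for every sample.

    For each (replicate, timepoint) sample, ``reads_per_sample`` reads are
    drawn in a single multinomial with cell probabilities proportional to
    ``N_replicon(t) * bin_length * shape_density``, optionally multiplied
    by gamma weights (mean 1, variance ``dispersion``) for between-sample
    overdispersion, and by the terminus-spike amplitude on affected bins.
    Per-sample totals are exactly ``reads_per_sample``; identical seeds
    give identical output.
    """
    samples: list[SimulatedSample] = []
    per_rep_edges = {r.name: bin_edges(r.length, r.bin_size) for r in scenario.replicons}
    for ti, t in enumerate(scenario.timepoints):
        for rep in range(scenario.replicates):
            rng = _sample_rng(scenario.seed, rep, ti)
            weights: list[np.ndarray] = []
            for spec in scenario.replicons:
                edges = per_rep_edges[spec.name]
                n_copies = copy_at(scenario.trajectory(spec.name), t)
                w = n_copies * _bin_weights(spec, t, edges)
                if spec.terminus_spike is not None:
                    amp = spec.terminus_spike.amplitude_at(t)
                    if amp != 1.0:
                        w = np.where(_spike_mask(spec, edges), w * amp, w)
                weights.append(w)
            flat = np.concatenate(weights)
            if scenario.dispersion > 0:
                shape = 1.0 / scenario.dispersion
                flat = flat * rng.gamma(shape, scale=1.0 / shape, size=flat.size)
            total = flat.sum()
            if not total > 0:
                raise ValueError("all-zero sampling weights")
            counts = rng.multinomial(scenario.reads_per_sample, flat / total)
            sample = SimulatedSample(
                sample_id=f"t{t:g}_rep{rep + 1}", timepoint=float(t), replicate=rep + 1
            )
            offset = 0
            for spec, w in zip(scenario.replicons, weights):
                n = w.size
                sample.coverage[spec.name] = BinnedCoverage(
                    replicon=spec.name,
                    length=spec.length,
                    bin_size=spec.bin_size,
                    counts=counts[offset : offset + n].copy(),
                    sample_id=sample.sample_id,
                    timepoint=float(t),
                )
                offset += n
            samples.append(sample)
    return samples


def sample_read_starts(
    spec: RepliconSpec,
    n_reads: int,
    enrichment: float,
    seed: int,
) -> dict[str, np.ndarray]:
    """Per-strand read-start histograms with a pac-site spike.

    Read starts are uniform along each strand except at the pac position,
    whose per-position rate is ``enrichment`` times background. Returns
    ``{"+": counts, "-": counts}`` with one integer per genome position.
    """
    if spec.pac_pos_plus is None or spec.pac_pos_minus is None:
        raise ValueError("pac positions must be set to simulate read starts")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    out: dict[str, np.ndarray] = {}
    n_plus = n_reads // 2 + n_reads % 2
    for strand, pac, n in (
        ("+", spec.pac_pos_plus, n_plus),
        ("-", spec.pac_pos_minus, n_reads // 2),
    ):
        w = np.ones(spec.length)
        w[pac] = enrichment
        out[strand] = rng.multinomial(n, w / w.sum())
    return out


# ---------------------------------------------------------------------------
# sequences and qPCR
# ---------------------------------------------------------------------------

def synthesize_skewed_sequence(
    length: int,
    ori_pos: int,
    ter_pos: int,
    bias: float,
    seed: int,
) -> str:
    """Random sequence with replichore-structured GC skew.

    On the replichore running from ``ori_pos`` to ``ter_pos`` (increasing
    coordinate, circular) G is favored over C by ``bias``; on the other
    replichore C is favored; A/T are unbiased. The expected windowed skew
    (G-C)/(G+C) is ``+2*bias`` on the first replichore and ``-2*bias`` on
    the second, flipping sign at the origin and terminus.
    """
    if not 0 < bias < 0.5:
        raise ValueError("bias must be in (0, 0.5)")
    if ori_pos == ter_pos:
        raise ValueError("ori and ter must differ")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    x = np.arange(length)
    if ori_pos < ter_pos:
        first = (x >= ori_pos) & (x < ter_pos)
    else:
        first = (x >= ori_pos) | (x < ter_pos)
    # per-position categorical over A, C, G, T
    p_hi = np.array([0.25, 0.25 - bias / 2, 0.25 + bias / 2, 0.25])  # G-rich
    p_lo = np.array([0.25, 0.25 + bias / 2, 0.25 - bias / 2, 0.25])  # C-rich
    u = rng.random(length)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    idx_hi = np.searchsorted(np.cumsum(p_hi), u, side="right")
    idx_lo = np.searchsorted(np.cumsum(p_lo), u, side="right")
    idx = np.where(first, idx_hi, idx_lo).clip(0, 3)
    return alphabet[idx].tobytes().decode("ascii")


def simulate_qpcr(
    true_fold_target: float,
    true_fold_reference: float,
    noise_sd: float,
    replicates: int,
    seed: int,
) -> np.ndarray:
    """qPCR-style fold-copy measurements at the copy-number level.

    Each measurement is ``(true_fold_target / true_fold_reference) *
    exp(eps)`` with ``eps ~ Normal(0, noise_sd**2)`` — multiplicative
    (lognormal) noise, the natural error model for ratio quantities.
    """
    if true_fold_target <= 0 or true_fold_reference <= 0:
        raise ValueError("true folds must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    ratio = true_fold_target / true_fold_reference
    return ratio * np.exp(rng.normal(0.0, noise_sd, size=replicates))


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------

def default_scenario(
    seed: int = 0,
    reads_per_sample: int = 1_000_000,
    replicates: int = 3,
    dispersion: float = 0.02,
) -> InfectionScenario:
    """The canonical four-replicon infected-cell scenario.

    Large (~2.9 Mb) and small (~1.07 Mb) host chromosomes are static over
    the 16-minute course, with a pre-infection large:small copy skew of
    1.3 (the small chromosome initiates later, so fewer cells carry two
    copies of it). The 126 kb helper phage replicates by theta from an
    origin at 60 kb early and transitions to rolling circle by 16 min,
    reaching 125-fold; its packaging terminus produces a 1.3 kb transient
    spike at 4 min and strand-specific pac positions at 431 (+) and
    891 (-). The 18 kb satellite replicates by theta from an origin in
    its noncoding region, up to 1000-fold — so the 16-minute
    satellite:phage copy ratio is 8.
    """
    icp1 = RepliconSpec(
        name="phage",
        length=126_000,
        mode="mixed",
        ori_pos=60_000,
        ptr=2.0,
        rc_decay=1e-4,
        mix_weight={4.0: 0.0, 8.0: 0.0, 12.0: 0.5, 16.0: 1.0},
        pac_pos_plus=431,
        pac_pos_minus=891,
        bin_size=1000,
        terminus_spike=TerminusSpike(
            position=124_500,
            width=1300,
            amplitude={4.0: 10.0, 8.0: 1.0, 12.0: 1.0, 16.0: 1.0},
        ),
    )
    ple = RepliconSpec(
        name="satellite",
        length=18_000,
        mode="theta_bidirectional",
        ori_pos=5_000,
        ptr=2.0,
        bin_size=150,
    )
    chr1 = RepliconSpec(name="chr_large", length=2_900_000, mode="static", bin_size=1000)
    chr2 = RepliconSpec(name="chr_small", length=1_070_000, mode="static", bin_size=1000)
    trajectories = [
        CopyTrajectory("phage", n0=1.0, onset=6.0, doubling_time=1.4, cap=125.0),
        CopyTrajectory("satellite", n0=1.0, onset=4.0, doubling_time=1.2, cap=1000.0),
        CopyTrajectory("chr_large", n0=1.3),
        CopyTrajectory("chr_small", n0=1.0),
    ]
    return InfectionScenario(
        replicons=[chr1, chr2, icp1, ple],
        trajectories=trajectories,
        timepoints=DEFAULT_TIMEPOINTS,
        reads_per_sample=reads_per_sample,
        replicates=replicates,
        dispersion=dispersion,
        seed=seed,
    )
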