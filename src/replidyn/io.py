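"""Readers, writers and run configuration.

On-disk conventions: coverage tables are bedGraph-style 4-column TSV
(replicon, bin_start, bin_end, count) with 0-based half-open coordinates;
profiles, skew tracks and calls are tidy TSV; configuration and the
simulator truth manifest are YAML/JSON. All writers are deterministic —
identical inputs give byte-identical files — and every reader round-trips
its writer's output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import AveragedProfile, BinnedCoverage, SkewTrack, bin_edges
from .inference import ReplicationCall
from .simulate import (
    CopyTrajectory,
    InfectionScenario,
    RepliconSpec,
    TerminusSpike,
)

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_coverage_table",
    "write_coverage_table",
    "write_profile_table",
    "read_profile_table",
    "write_skew_table",
    "write_calls_table",
    "read_read_starts",
    "write_read_starts",
    "load_scenario",
    "dump_scenario",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences from a FASTA file, order preserved, uppercased.

    Duplicate names and empty records are rejected with the record index.
    """
    path = Path(path)
    out: dict[str, str] = {}
    n = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        n += 1
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record name {rec.id!r} (record {i})")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r} (record {i})")
        out[rec.id] = seq
    if n == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# coverage tables (bedGraph-style TSV)
# ---------------------------------------------------------------------------

_COV_COLUMNS = ["replicon", "bin_start", "bin_end", "count"]


def write_coverage_table(
    coverages: Mapping[str, BinnedCoverage] | Sequence[BinnedCoverage],
    path: str | Path,
) -> None:
    """Write binned coverage as 4-column TSV (0-based half-open bins)."""
    if isinstance(coverages, Mapping):
        coverages = list(coverages.values())
    frames = []
    for cov in coverages:
        edges = cov.edges
        frames.append(
            pd.DataFrame(
                {
                    "replicon": cov.replicon,
                    "bin_start": edges[:-1].astype(int),
                    "bin_end": edges[1:].astype(int),
                    "count": cov.counts.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coverage_table(
    path: str | Path,
    lengths: Mapping[str, int],
    dialect: str = "tsv",
    one_based: bool = False,
    sample_id: str | None = None,
    timepoint: float | None = None,
) -> dict[str, BinnedCoverage]:
    """Read a 4-column coverage table into per-replicon binned coverage.

    ``dialect="tsv"`` expects a header row with the writer's column names;
    ``dialect="bedgraph"`` expects headerless chrom/start/end/value lines.
    Coordinates are 0-based half-open unless ``one_based`` is set (then
    1-based inclusive starts are shifted down). Intervals are validated
    against the declared replicon lengths: overlaps, negative counts and
    intervals past the replicon end are rejected naming the row; interior
    gaps are zero-filled with a logged warning. Bin size is inferred from
    the interval widths (the last bin may be ragged).
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _COV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
    elif dialect == "bedgraph":
        df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS, comment="#")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if one_based:
        df["bin_start"] = df["bin_start"] - 1
    out: dict[str, BinnedCoverage] = {}
    for name, sub in df.groupby("replicon", sort=False):
        if name not in lengths:
            raise ValueError(f"{path}: unknown replicon {name!r}")
        L = int(lengths[name])
        sub = sub.sort_values("bin_start")
        starts = sub["bin_start"].to_numpy(dtype=np.int64)
        ends = sub["bin_end"].to_numpy(dtype=np.int64)
        counts = sub["count"].to_numpy()
        rows = sub.index.to_numpy()
        if np.any(counts < 0):
            row = int(rows[np.argmax(counts < 0)])
            raise ValueError(f"{path} row {row}: negative count")
        bad = (starts < 0) | (ends <= starts) | (ends > L)
        if np.any(bad):
            row = int(rows[np.argmax(bad)])
            raise ValueError(
                f"{path} row {row}: interval outside [0, {L}) for {name!r}"
            )
        if np.any(starts[1:] < ends[:-1]):
            row = int(rows[1:][np.argmax(starts[1:] < ends[:-1])])
            raise ValueError(f"{path} row {row}: overlapping intervals for {name!r}")
        widths = ends - starts
        bin_size = int(np.bincount(widths).argmax())
        edges = bin_edges(L, bin_size)
        full = np.zeros(len(edges) - 1, dtype=counts.dtype)
        idx = starts // bin_size
        if np.any(starts % bin_size != 0):
            row = int(rows[np.argmax(starts % bin_size != 0)])
            raise ValueError(
                f"{path} row {row}: interval start not on the {bin_size} bp grid"
            )
        full[idx] = counts
        if len(starts) < len(full):
            log.warning(
                "%s: %s has %d missing bin(s); zero-filled",
                path, name, len(full) - len(starts),
            )
        out[name] = BinnedCoverage(
            replicon=str(name), length=L, bin_size=bin_size, counts=full,
            sample_id=sample_id, timepoint=timepoint,
        )
    return out


# ---------------------------------------------------------------------------
# profiles, skew, calls, read starts
# ---------------------------------------------------------------------------

def write_profile_table(
    profiles: Sequence[AveragedProfile], path: str | Path
) -> None:
    frames = []
    for p in profiles:
        edges = p.edges
        frames.append(
            pd.DataFrame(
                {
                    "replicon": p.replicon,
                    "timepoint": p.timepoint,
                    "bin_start": edges[:-1].astype(int),
                    "bin_end": edges[1:].astype(int),
                    "mean": p.mean,
                    "sd": p.sd,
                    "mean_counts": (
                        p.mean_counts if p.mean_counts is not None else np.nan
                    ),
                    "n_replicates": p.n_replicates,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profile_table(path: str | Path) -> list[AveragedProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (name, tp), sub in df.groupby(["replicon", "timepoint"], sort=False):
        sub = sub.sort_values("bin_start")
        widths = (sub["bin_end"] - sub["bin_start"]).to_numpy()
        mc = sub["mean_counts"].to_numpy(dtype=float)
        out.append(
            AveragedProfile(
                replicon=str(name),
                length=int(sub["bin_end"].max()),
                bin_size=int(np.bincount(widths).argmax()),
                mean=sub["mean"].to_numpy(dtype=float),
                sd=sub["sd"].to_numpy(dtype=float),
                n_replicates=int(sub["n_replicates"].iloc[0]),
                timepoint=float(tp),
                mean_counts=None if np.isnan(mc).all() else mc,
            )
        )
    return out


def write_skew_table(tracks: Sequence[SkewTrack], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "replicon": t.replicon,
                "window": t.window,
                "step": t.step,
                "start": t.starts,
                "skew": t.values,
            }
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def write_calls_table(calls: Sequence[ReplicationCall], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def write_read_starts(
    read_starts: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Sparse per-strand read-start histogram (positions with count > 0)."""
    frames = []
    for strand in ("+", "-"):
        h = np.asarray(read_starts[strand])
        pos = np.flatnonzero(h)
        frames.append(
            pd.DataFrame({"strand": strand, "position": pos, "count": h[pos]})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_read_starts(path: str | Path, length: int) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for strand in ("+", "-"):
        h = np.zeros(length, dtype=np.int64)
        sub = df[df["strand"] == strand]
        h[sub["position"].to_numpy(dtype=np.int64)] = sub["count"].to_numpy()
        out[strand] = h
    return out


# ---------------------------------------------------------------------------
# run configuration and scenario serialization
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline thresholds and defaults; round-trips through YAML."""

    bin_size_phage: int = 1000
    bin_size_satellite: int = 150
    skew_window: int = 1000
    skew_step: int | None = None  # None -> window // 10
    smooth_bins: int = 5
    tau_sym: float = 0.4
    tau_drop: float = 3.0
    spike_k: float = 3.0
    pac_z: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_size_phage", "bin_size_satellite", "skew_window",
                     "smooth_bins", "tau_sym", "tau_drop", "spike_k", "pac_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _replicon_to_dict(spec: RepliconSpec, traj: CopyTrajectory) -> dict:
    d: dict = {
        "name": spec.name,
        "length": spec.length,
        "topology": spec.topology,
        "mode": spec.mode,
        "bin_size": spec.bin_size,
        "trajectory": {
            "n0": traj.n0,
            "onset": traj.onset,
            "doubling_time": traj.doubling_time,
            "cap": traj.cap,
        },
    }
    for k in ("ori_pos", "pac_pos_plus", "pac_pos_minus"):
        v = getattr(spec, k)
        if v is not None:
            d[k] = v
    if spec.mode != "static":
        d["ptr"] = spec.ptr
        d["rc_decay"] = spec.rc_decay
    if spec.mode == "mixed":
        mw = spec.mix_weight
        d["mix_weight"] = dict(mw) if isinstance(mw, Mapping) else mw
    if spec.terminus_spike is not None:
        sp = spec.terminus_spike
        d["terminus_spike"] = {
            "position": sp.position,
            "width": sp.width,
            "amplitude": dict(sp.amplitude),
        }
    return d


def dump_scenario(scenario: InfectionScenario, path: str | Path) -> None:
    d = {
        "seed": scenario.seed,
        "reads_per_sample": scenario.reads_per_sample,
        "replicates": scenario.replicates,
        "dispersion": scenario.dispersion,
        "timepoints": [float(t) for t in scenario.timepoints],
        "replicons": [
            _replicon_to_dict(spec, scenario.trajectory(spec.name))
            for spec in scenario.replicons
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_scenario(path: str | Path) -> InfectionScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    replicons, trajectories = [], []
    for rd in d["replicons"]:
        rd = dict(rd)
        td = rd.pop("trajectory", {})
        name = rd["name"]
        spike = rd.pop("terminus_spike", None)
        if spike is not None:
            spike = TerminusSpike(
                position=int(spike["position"]),
                width=int(spike["width"]),
                amplitude={float(k): float(v) for k, v in spike["amplitude"].items()},
            )
        mw = rd.pop("mix_weight", 0.0)
        if isinstance(mw, Mapping):
            mw = {float(k): float(v) for k, v in mw.items()}
        replicons.append(RepliconSpec(terminus_spike=spike, mix_weight=mw, **rd))
        trajectories.append(CopyTrajectory(replicon=name, **td))
    return InfectionScenario(
        replicons=replicons,
        trajectories=trajectories,
        timepoints=[float(t) for t in d.get("timepoints", (4.0, 8.0, 12.0, 16.0))],
        reads_per_sample=int(d.get("reads_per_sample", 1_000_000)),
        replicates=int(d.get("replicates", 3)),
        dispersion=float(d.get("dispersion", 0.0)),
        seed=int(d.get("seed", 0)),
    )
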