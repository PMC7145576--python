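"""Synthetic-data generator: copy trajectories, coverage shapes, read
sampling, read-start pileups, skewed sequences and qPCR measurements."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replidyn import (
    CopyTrajectory,
    InfectionScenario,
    RepliconSpec,
    TerminusSpike,
    copy_at,
    default_scenario,
    sample_read_starts,
    sample_reads,
    shape_density,
    simulate_qpcr,
    synthesize_skewed_sequence,
)
from replidyn.coverage import gc_skew


# ---------------------------------------------------------------------------
# copy trajectories
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs, t, expected",
    [
        (dict(n0=1, onset=8, doubling_time=4), 4, 1.0),  # pre-onset
        (dict(n0=1, onset=4, doubling_time=4), 16, 8.0),  # three doublings
        (dict(n0=1, onset=0, doubling_time=2, cap=1000), 40, 1000.0),  # cap binds
        (dict(n0=2.5), 100, 2.5),  # non-replicating element
    ],
)
def test_copy_at_follows_growth_law(kwargs, t, expected):
    traj = CopyTrajectory("x", **kwargs)
    assert copy_at(traj, t) == pytest.approx(expected)


def test_copy_at_rejects_negative_time():
    with pytest.raises(ValueError):
        copy_at(CopyTrajectory("x", n0=1), -1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n0=st.floats(0.1, 10),
    onset=st.floats(0, 20),
    doubling=st.floats(0.5, 10),
    cap=st.one_of(st.none(), st.floats(1, 2000)),
    t1=st.floats(0, 40),
    dt=st.floats(0, 40),
)
def test_copy_at_is_nondecreasing(n0, onset, doubling, cap, t1, dt):
    traj = CopyTrajectory("x", n0=n0, onset=onset, doubling_time=doubling, cap=cap)
    assert copy_at(traj, t1 + dt) >= copy_at(traj, t1) - 1e-12


# ---------------------------------------------------------------------------
# coverage shapes
# ---------------------------------------------------------------------------

def _spec(mode, **kw):
    base = dict(name="r", length=8000, ori_pos=500, bin_size=1000)
    base.update(kw)
    return RepliconSpec(mode=mode, **base)


def test_theta_with_unit_ptr_is_uniform():
    d = shape_density(_spec("theta_bidirectional", ptr=1.0), 0.0, 8)
    assert np.allclose(d, 1 / 8)


def test_theta_density_symmetric_about_origin():
    # ori at the center of bin 0: equidistant bins must match exactly
    d = shape_density(_spec("theta_bidirectional", ptr=2.0), 0.0, 8)
    assert d.argmax() == 0
    for k in (1, 2, 3):
        assert d[k] == pytest.approx(d[8 - k], rel=1e-12)


def test_theta_peak_to_trough_range_matches_ptr():
    ptr = 3.7
    d = shape_density(_spec("theta_bidirectional", ptr=ptr), 0.0, 8)
    assert d.max() / d.min() == pytest.approx(ptr, rel=1e-9)


def test_rolling_circle_flank_ratio_closed_form():
    # density(one bin upstream of ori) / density(one bin downstream)
    # equals exp(rc_decay * (L - 2 * bin_size)) for a mid-bin origin
    decay, L, bs = 3e-5, 8000, 1000
    d = shape_density(_spec("rolling_circle", rc_decay=decay), 0.0, 8)
    ratio = d[-1] / d[1]  # bins flanking bin 0
    assert ratio == pytest.approx(np.exp(decay * (L - 2 * bs)), rel=1e-9)


def test_rolling_circle_breaks_flank_symmetry_theta_keeps_it():
    # across-peak flank ratio: ~1 for theta (symmetry), large for rolling
    # circle even when the theta profile has the same overall peak/trough
    rc = shape_density(_spec("rolling_circle", rc_decay=3e-4), 0.0, 8)
    th = shape_density(
        _spec("theta_bidirectional", ptr=float(rc.max() / rc.min())), 0.0, 8
    )
    assert th[-1] / th[1] == pytest.approx(1.0, rel=1e-9)
    assert rc[-1] / rc[1] > 5 * th[-1] / th[1]


def test_static_is_uniform_and_warns_on_ptr():
    with pytest.warns(UserWarning):
        spec = _spec("static", ptr=2.0, ori_pos=None)
    assert np.allclose(shape_density(spec, 0.0, 8), 1 / 8)


def test_shape_density_rejects_tiny_binning():
    with pytest.raises(ValueError):
        shape_density(_spec("theta_bidirectional", ptr=2.0), 0.0, 3)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    mode=st.sampled_from(["static", "theta_bidirectional", "rolling_circle", "mixed"]),
    ptr=st.floats(1.0, 20.0),
    decay=st.floats(1e-6, 1e-3),
    mix=st.floats(0.0, 1.0),
    n_bins=st.integers(4, 60),
)
def test_shape_density_normalized_and_positive(mode, ptr, decay, mix, n_bins):
    spec = RepliconSpec(
        name="r", length=50_000, mode=mode, ori_pos=17_000,
        ptr=ptr if mode != "static" else 1.0, rc_decay=decay, mix_weight=mix,
    )
    d = shape_density(spec, 4.0, n_bins)
    assert d.sum() == pytest.approx(1.0, abs=1e-9)
    assert (d > 0).all()


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _two_static(reads=100_000, seed=0, lengths=(50_000, 50_000), copies=(1.0, 1.0)):
    reps = [
        RepliconSpec(name=f"r{i}", length=L, mode="static", bin_size=1000)
        for i, L in enumerate(lengths)
    ]
    trajs = [CopyTrajectory(f"r{i}", n0=c) for i, c in enumerate(copies)]
    return InfectionScenario(
        replicons=reps, trajectories=trajs, timepoints=[4.0],
        reads_per_sample=reads, replicates=1, dispersion=0.0, seed=seed,
    )


def test_sample_reads_conserves_total_and_is_deterministic():
    sc = default_scenario(seed=11, reads_per_sample=50_000)
    a = sample_reads(sc)
    b = sample_reads(sc)
    assert len(a) == len(sc.timepoints) * sc.replicates
    for sa, sb in zip(a, b):
        assert sa.total_reads == sc.reads_per_sample
        for name in sa.coverage:
            np.testing.assert_array_equal(sa.coverage[name].counts, sb.coverage[name].counts)


def test_equal_static_replicons_split_reads_evenly():
    sc = _two_static(reads=400_000, seed=3)
    (sample,) = sample_reads(sc)
    n0 = sample.coverage["r0"].total
    p = n0 / sc.reads_per_sample
    se = np.sqrt(0.25 / sc.reads_per_sample)
    assert abs(p - 0.5) < 4 * se


def test_copy_ratio_reflected_in_read_ratio_within_3_se():
    # 18 kb satellite at 8x the copies of a 126 kb phage
    sat = RepliconSpec(name="sat", length=18_000, mode="static", bin_size=150)
    ph = RepliconSpec(name="ph", length=126_000, mode="static", bin_size=1000)
    sc = InfectionScenario(
        replicons=[sat, ph],
        trajectories=[CopyTrajectory("sat", n0=8.0), CopyTrajectory("ph", n0=1.0)],
        timepoints=[16.0], reads_per_sample=10**6, replicates=1,
        dispersion=0.0, seed=21,
    )
    (sample,) = sample_reads(sc)
    p_expected = 8 * 18_000 / (8 * 18_000 + 126_000)
    p_obs = sample.coverage["sat"].total / sc.reads_per_sample
    se = np.sqrt(p_expected * (1 - p_expected) / sc.reads_per_sample)
    assert abs(p_obs - p_expected) < 3 * se


def test_terminus_spike_enriches_window_only_early():
    spike = TerminusSpike(position=40_000, width=2000, amplitude={4.0: 10.0, 8.0: 1.0})
    rep = RepliconSpec(
        name="r0", length=50_000, mode="static", bin_size=1000, terminus_spike=spike
    )
    sc = InfectionScenario(
        replicons=[rep], trajectories=[CopyTrajectory("r0")],
        timepoints=[4.0, 8.0], reads_per_sample=200_000, replicates=1,
        dispersion=0.0, seed=5,
    )
    early, late = sample_reads(sc)
    e = early.coverage["r0"].counts
    l = late.coverage["r0"].counts
    assert e[40] > 5 * np.median(e)
    assert l[40] < 2 * np.median(l)


def test_sample_reads_rejects_zero_weights():
    # an amplitude-0 spike over the whole genome kills every bin weight
    rep = RepliconSpec(
        name="r0", length=10_000, mode="static", bin_size=1000,
        terminus_spike=TerminusSpike(position=0, width=10_000, amplitude={4.0: 0.0}),
    )
    bad = InfectionScenario(
        replicons=[rep], trajectories=[CopyTrajectory("r0")],
        timepoints=[4.0], reads_per_sample=100, replicates=1, seed=0,
    )
    with pytest.raises(ValueError):
        sample_reads(bad)


# ---------------------------------------------------------------------------
# read starts
# ---------------------------------------------------------------------------

def _pac_spec(length=126_000):
    return RepliconSpec(
        name="ph", length=length, mode="static",
        pac_pos_plus=431, pac_pos_minus=891,
    )


def test_read_start_spikes_are_the_argmax_per_strand():
    starts = sample_read_starts(_pac_spec(), 10**5, enrichment=50.0, seed=2)
    assert int(np.argmax(starts["+"])) == 431
    assert int(np.argmax(starts["-"])) == 891


def test_read_starts_without_enrichment_have_no_outlier():
    starts = sample_read_starts(_pac_spec(length=10_000), 10**6, enrichment=1.0, seed=2)
    for strand in "+-":
        h = starts[strand]
        assert h[431 if strand == "+" else 891] < h.mean() + 6 * np.sqrt(h.mean())


def test_strand_spikes_are_independent():
    starts = sample_read_starts(_pac_spec(), 10**5, enrichment=50.0, seed=7)
    # the minus-strand spike does not bleed into the plus strand
    assert starts["+"][891] < 10
    assert starts["-"][431] < 10


def test_read_starts_require_pac_positions():
    spec = RepliconSpec(name="ph", length=1000, mode="static")
    with pytest.raises(ValueError):
        sample_read_starts(spec, 1000, 10.0, seed=0)


# ---------------------------------------------------------------------------
# skewed sequences
# ---------------------------------------------------------------------------

def test_skewed_sequence_mean_skew_positive_on_first_replichore():
    seq = synthesize_skewed_sequence(40_000, ori_pos=0, ter_pos=20_000, bias=0.2, seed=4)
    track = gc_skew(seq, window=2000, step=2000, circular=False)
    first = track.values[track.starts + 2000 <= 20_000]
    second = track.values[track.starts >= 20_000]
    assert first.mean() > 0.3  # expected skew 2*bias = 0.4
    assert second.mean() < -0.3


def test_skew_sign_flips_at_ori_and_ter():
    seq = synthesize_skewed_sequence(40_000, ori_pos=10_000, ter_pos=30_000, bias=0.49, seed=9)
    track = gc_skew(seq, window=1000, step=1000, circular=False)
    signs = np.sign(track.values)
    flips = np.flatnonzero(np.diff(signs) != 0)
    flip_pos = track.starts[flips + 1]
    assert any(abs(p - 10_000) <= 1000 for p in flip_pos)
    assert any(abs(p - 30_000) <= 1000 for p in flip_pos)


def test_reverse_complement_negates_skew():
    from Bio.Seq import Seq

    seq = synthesize_skewed_sequence(10_000, ori_pos=0, ter_pos=5_000, bias=0.3, seed=1)
    rc = str(Seq(seq).reverse_complement())
    fwd = gc_skew(seq, window=1000, step=1000, circular=False).values
    rev = gc_skew(rc, window=1000, step=1000, circular=False).values
    np.testing.assert_allclose(rev, -fwd[::-1], atol=1e-12)


def test_skewed_sequence_is_deterministic():
    a = synthesize_skewed_sequence(5000, 0, 2500, 0.2, seed=3)
    b = synthesize_skewed_sequence(5000, 0, 2500, 0.2, seed=3)
    assert a == b


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def test_qpcr_noiseless_returns_exact_fold():
    vals = simulate_qpcr(1000.0, 1.0, noise_sd=0.0, replicates=5, seed=0)
    np.testing.assert_allclose(vals, 1000.0)


def test_qpcr_equal_folds_center_on_one():
    vals = simulate_qpcr(7.0, 7.0, noise_sd=0.1, replicates=2000, seed=1)
    assert np.median(vals) == pytest.approx(1.0, rel=0.02)


def test_qpcr_median_recovers_true_ratio():
    vals = simulate_qpcr(50.0, 1.0, noise_sd=0.1, replicates=1000, seed=6)
    assert np.median(vals) == pytest.approx(50.0, rel=0.05)


def test_qpcr_rejects_nonpositive_folds():
    with pytest.raises(ValueError):
        simulate_qpcr(0.0, 1.0, 0.1, 3, seed=0)
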