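"""Palladium barcode deconvolution."""

import numpy as np
import pytest

from ddrcyto.debarcode import (BarcodeScheme, PD_CHANNELS, UNASSIGNED,
                               all_keys, debarcode, full_scheme,
                               load_code_book, save_code_book, split_by_sample)
from ddrcyto.errors import ConfigError, ManifestError, ValidationError
from ddrcyto.fcs_io import AcquisitionMetadata, ChannelDescriptor, EventFrame
from ddrcyto.preprocess import arcsinh_transform


def _pd_frame(rows):
    """A transformed frame whose Pd channels rescale to the identity.

    100 calibration events at 0 and 100 at 1 pin the robust 1st/99th
    percentiles of every channel to (0, 1), so the listed rescaled
    intensities pass through unchanged.
    """
    chans = [ChannelDescriptor(c, role="barcode") for c in PD_CHANNELS]
    calib = np.vstack([np.zeros((100, 6)), np.ones((100, 6))])
    values = np.vstack([calib, np.asarray(rows, dtype=float)])
    return EventFrame(values, chans, transformed=True)


def test_key_space_has_twenty_distinct_patterns():
    keys = all_keys()
    assert len(keys) == 20
    assert len(set(keys)) == 20
    assert all(len(k) == 3 for k in keys)
    assert len(full_scheme().keys) == 20


def test_top3_assignment_and_separation():
    scheme = BarcodeScheme(keys={"s1": (0, 1, 2)})
    f = _pd_frame([[0.9, 0.85, 0.95, 0.02, 0.05, 0.01]])
    res = debarcode(f, scheme)
    assert res.assignment[-1] == "s1"
    assert res.separation[-1] == pytest.approx(0.80, abs=1e-9)


def test_four_high_channels_have_zero_separation():
    scheme = BarcodeScheme(keys={"s1": (0, 1, 2)})
    f = _pd_frame([[0.9, 0.9, 0.9, 0.9, 0.02, 0.02]])
    res = debarcode(f, scheme)
    assert res.separation[-1] == pytest.approx(0.0, abs=1e-9)
    assert res.assignment[-1] == UNASSIGNED


def test_unregistered_pattern_is_unassigned():
    scheme = BarcodeScheme(keys={"s1": (0, 1, 2)})
    f = _pd_frame([[0.02, 0.01, 0.03, 0.9, 0.95, 0.85]])  # pattern {3,4,5}
    res = debarcode(f, scheme)
    assert res.assignment[-1] == UNASSIGNED


def test_yield_table_counts_sum_to_total(small_donors):
    d = small_donors[0]
    res = debarcode(arcsinh_transform(d.frame), d.scheme)
    assert res.yield_table["n_events"].sum() == d.frame.n_events


def test_singlet_assignment_accuracy(small_donors):
    d = small_donors[0]
    res = debarcode(arcsinh_transform(d.frame), d.scheme)
    singlet = ~d.truth["doublet"].to_numpy()
    correct = res.assignment[singlet] == d.truth["sample_label"].to_numpy()[singlet]
    assert correct.mean() >= 0.995


def test_cross_sample_doublets_rejected(small_donors):
    d = small_donors[0]
    res = debarcode(arcsinh_transform(d.frame), d.scheme)
    cross = (d.truth["doublet"] & (d.truth["sample_label"] == "DOUBLET")).to_numpy()
    assert cross.sum() > 50
    assert (res.assignment[cross] == UNASSIGNED).mean() >= 0.95


def test_channel_permutation_invariance(small_donors):
    d = small_donors[0]
    t = arcsinh_transform(d.frame)
    base = debarcode(t, d.scheme)
    perm = np.arange(t.n_channels)[::-1]
    permuted = EventFrame(t.values[:, perm], [t.channels[i] for i in perm],
                          transformed=True)
    res = debarcode(permuted, d.scheme)
    assert np.array_equal(res.assignment, base.assignment)


def test_raising_cutoff_never_assigns_more(small_donors):
    d = small_donors[0]
    t = arcsinh_transform(d.frame)
    counts = []
    for cutoff in (0.1, 0.3, 0.5, 0.8):
        scheme = BarcodeScheme(keys=dict(d.scheme.keys), separation_cutoff=cutoff)
        res = debarcode(t, scheme)
        counts.append(int((res.assignment != UNASSIGNED).sum()))
    assert counts == sorted(counts, reverse=True)


def test_constant_barcode_channel_is_config_error():
    chans = [ChannelDescriptor(c, role="barcode") for c in PD_CHANNELS]
    vals = np.ones((50, 6))
    vals[:, 1:] = np.random.default_rng(0).random((50, 5))
    f = EventFrame(vals, chans, transformed=True)
    with pytest.raises(ConfigError, match="Pd102"):
        debarcode(f, BarcodeScheme(keys={"s1": (0, 1, 2)}))


def test_scheme_validation():
    with pytest.raises(ValidationError):
        BarcodeScheme(keys={"a": (0, 1)})  # popcount 2
    with pytest.raises(ValidationError):
        BarcodeScheme(keys={"a": (0, 1, 2), "b": (0, 1, 2)})  # duplicate


def test_split_by_sample_conserves_counts(small_donors):
    d = small_donors[0]
    t = arcsinh_transform(d.frame)
    res = debarcode(t, d.scheme)
    frames = split_by_sample(t, res, d.manifest)
    n_assigned = sum(f.n_events for f in frames.values())
    n_unassigned = int((res.assignment == UNASSIGNED).sum())
    assert n_assigned + n_unassigned == t.n_events
    for label, f in frames.items():
        assert f.meta.timepoint_h == d.manifest[label].timepoint_h


def test_split_missing_manifest_label_raises(small_donors):
    d = small_donors[0]
    t = arcsinh_transform(d.frame)
    res = debarcode(t, d.scheme)
    partial = {k: v for k, v in list(d.manifest.items())[:2]}
    with pytest.raises(ManifestError):
        split_by_sample(t, res, partial)


def test_code_book_roundtrip(tmp_path):
    scheme = full_scheme()
    save_code_book(scheme, tmp_path / "cb.csv")
    loaded = load_code_book(tmp_path / "cb.csv")
    assert loaded.keys == scheme.keys


def test_even_split_into_three_frames():
    scheme = BarcodeScheme(keys={"a": (0, 1, 2), "b": (1, 2, 3), "c": (3, 4, 5)},
                           separation_cutoff=0.1)
    patterns = {"a": (0, 1, 2), "b": (1, 2, 3), "c": (3, 4, 5)}
    rows = []
    for label in ("a", "b", "c"):
        row = [0.02] * 6
        for b in patterns[label]:
            row[b] = 0.9
        rows += [row] * 100
    f = _pd_frame(rows)
    res = debarcode(f, scheme)
    manifest = {
        "a": AcquisitionMetadata("d", "untreated", 0.0),
        "b": AcquisitionMetadata("d", "IR_2Gy", 1.0),
        "c": AcquisitionMetadata("d", "IR_2Gy", 4.0),
    }
    frames = split_by_sample(f, res, manifest)
    assert {k: v.n_events for k, v in frames.items()} == {"a": 100, "b": 100, "c": 100}
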