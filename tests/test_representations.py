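"""Sample construction, count identities and volume bijectivity."""

import numpy as np
import pytest

import mirepr as m
from mirepr.montage import ChannelSelection
from mirepr.spectral import SpectrogramParams


def test_count_identities(tiny_corpus, tiny_epochs):
    n_epochs = len(tiny_epochs)
    expectations = {
        "spec-single": 64, "raw1d": 64,
        "spec-stack-64": 1, "raw2d-64": 1, "raw2d-21": 1, "vol-21": 1,
        "raw2d-9": 3, "raw2d-5": 3, "vol-9": 3, "vol-5": 3,
    }
    for rid, mult in expectations.items():
        assert m.samples_per_epoch(rid) == mult
        manifest = m.build_manifest(tiny_corpus, rid)
        assert manifest.total == mult * n_epochs
        # class distribution preserved: every class scales by mult
        epoch_counts = m.corpus_class_counts(tiny_epochs)
        assert manifest.counts == {k: mult * v
                                   for k, v in epoch_counts.items()}


def test_build_dataset_matches_manifest(tiny_corpus):
    samples, manifest = m.build_dataset(tiny_corpus, "raw2d-9")
    assert len(samples) == manifest.total
    tallies = {"T0": 0, "T1": 0, "T2": 0}
    for s in samples:
        tallies[s.label] += 1
    assert tallies == manifest.counts
    assert manifest.sample_shape == (9, 640)
    lazy = m.build_manifest(tiny_corpus, "raw2d-9")
    assert lazy.counts == manifest.counts


def test_empty_corpus():
    samples, manifest = m.build_dataset([], "vol-9")
    assert samples == [] and manifest.total == 0


def test_unknown_representation_rejected(tiny_corpus):
    with pytest.raises(ValueError):
        m.build_dataset(tiny_corpus, "vol-64")


def test_single_channel_image_deterministic(tiny_epochs):
    ep = tiny_epochs[0]
    a = m.single_channel_image(ep, "C3")
    b = m.single_channel_image(ep, "C3")
    assert a.pixels.shape == (32, 32, 3)
    assert np.array_equal(a.pixels, b.pixels)
    assert a.label == ep.label
    with pytest.raises(KeyError):
        m.single_channel_image(ep, "QQ7")


def test_stacked_image_native_extent(tiny_epochs):
    img = m.stacked_image(tiny_epochs[0], m.selection("motor21"))
    assert img.pixels.shape == (21 * 81, 31, 3)   # 1701 rows pre-resize
    img64 = m.stacked_image(tiny_epochs[0], m.selection("full64"),
                            size=(64, 64))
    assert img64.pixels.shape == (64, 64, 3)


def test_one_channel_stack_equals_single_channel_path(tiny_epochs):
    """A 1-channel stack reduces to the single-channel spectrogram render."""
    ep = tiny_epochs[1]
    sel = ChannelSelection("only-C3", ("C3",))
    stack = m.stacked_image(ep, sel)
    _, _, power = m.stft_power(ep.channel("C3"))
    direct = m.render_power_image(power)
    assert np.array_equal(stack.pixels, direct)


def test_epoch_matrix_row_order(tiny_epochs):
    ep = tiny_epochs[0]
    m21 = m.epoch_matrix(ep, m.selection("motor21"))
    assert m21.values.shape == (21, 640)
    assert np.array_equal(m21.values[4], ep.channel("C3"))   # 5th row is C3
    m13 = m.epoch_matrix(ep, m.selection("cross13"))
    assert m13.values.shape == (13, 640)
    m64 = m.epoch_matrix(ep, m.selection("full64"))
    assert np.array_equal(m64.values, ep.data)               # identity order


def test_volume_layout_and_bijection(tiny_epochs):
    ep = tiny_epochs[0]
    sel = m.selection("motor21")
    mat = m.epoch_matrix(ep, sel)
    vol = m.to_volume(mat, m.volume_spec(sel))
    assert vol.values.shape == (7, 3, 640)
    assert np.array_equal(vol.values[0],
                          mat.values[:3])      # layer 0 = FC5, C5, CP5
    assert not vol.zero_mask.any()
    back = m.volume_to_matrix(vol)
    assert np.array_equal(back.values, mat.values)

    cross = m.selection("cross13")
    vol13 = m.to_volume(m.epoch_matrix(ep, cross), m.volume_spec(cross))
    flat = vol13.values.reshape(21, 640)
    zero_rows = int((~flat.any(axis=1)).sum())
    assert zero_rows == 8
    assert np.all(flat[vol13.zero_mask.reshape(-1)] == 0)
    assert np.array_equal(m.volume_to_matrix(vol13).values,
                          m.epoch_matrix(ep, cross).values)


def test_volume_shape_mismatch_rejected(tiny_epochs):
    mat = m.epoch_matrix(tiny_epochs[0], m.selection("cross13"))
    with pytest.raises(ValueError):
        m.to_volume(mat, m.volume_spec(m.selection("motor21")))


def test_subgrid_split_shares_columns(tiny_epochs):
    ep = tiny_epochs[0]
    grids9 = m.split_subgrids(ep, 9)
    assert len(grids9) == 3
    assert all(g.values.shape == (9, 640) for g in grids9)
    assert all(g.label == ep.label for g in grids9)
    # C3-grid rows FC1,C1,CP1 == Cz-grid rows FC1,C1,CP1
    assert np.array_equal(grids9[0].values[6:9], grids9[1].values[0:3])
    grids5 = m.split_subgrids(ep, 5)
    assert all(g.values.shape == (5, 640) for g in grids5)
    assert np.array_equal(grids5[0].values[4], grids5[1].values[0])  # C1


def test_vectors_project_channels(tiny_epochs):
    ep = tiny_epochs[2]
    vectors = m.to_vectors(ep)
    assert len(vectors) == 64
    assert all(v.label == ep.label for v in vectors)
    c3 = next(v for v in vectors if v.channel == "C3")
    assert np.array_equal(c3.values, ep.channel("C3"))


def test_spec_single_dataset_count(tiny_corpus, tiny_epochs):
    samples, manifest = m.build_dataset(tiny_corpus, "spec-single")
    assert manifest.total == 64 * len(tiny_epochs)
    assert all(s.pixels.shape == (32, 32, 3) for s in samples[:8])


def test_export_layout(tiny_corpus, tmp_path):
    recs = tiny_corpus[:1]
    samples, manifest = m.build_dataset(recs, "raw2d-9")
    paths = m.export_samples(samples, manifest, tmp_path)
    assert len(paths) == manifest.total
    first = tmp_path / "raw2d-9" / recs[0].subject_id / recs[0].run_id / \
        "0000_C3.npz"
    assert first.exists()
    with np.load(first, allow_pickle=False) as z:
        assert z["values"].shape == (9, 640)
    assert (tmp_path / "raw2d-9" / "manifest.json").exists()

    imgs, man_img = m.build_dataset(recs, "spec-single")
    img_paths = m.export_samples(imgs[:4], man_img, tmp_path)
    assert img_paths[0].endswith(".png")
    import json as _json
    meta = _json.loads(
        (tmp_path / "spec-single" / recs[0].subject_id / recs[0].run_id /
         "0000_FC5.json").read_text())
    assert meta["label"] in ("T0", "T1", "T2")


def test_sample_shapes():
    params = SpectrogramParams()
    assert m.sample_shape("spec-stack-21", params) == (1701, 31, 3)
    assert m.sample_shape("vol-13", params) == (7, 3, 640)
    assert m.sample_shape("vol-5", params) == (3, 3, 640)
    assert m.sample_shape("raw1d", params) == (640,)
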