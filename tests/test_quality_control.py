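"""The QC ledger: S/N screen, length/brightness thresholds, colour splitting."""

import numpy as np
import pytest

from qdyefinder.colour_space import colour_distance, vector_normalize
from qdyefinder.quality_control import (
    QCConfig,
    channel_snr,
    compute_colour_vectors,
    determine_min_brightness,
    determine_min_length,
    run_qc,
    split_colour_changes,
)
from qdyefinder.synthesis import PhantomConfig, generate_phantom, make_hybrid_fragment
from qdyefinder.traces import Fragment


class TestChannelSnr:
    def _means(self, rng, n=50, n_ch=3, bright=(100.0, 200.0, 1.0)):
        return rng.uniform(0.8, 1.2, size=(n, n_ch)) * np.asarray(bright)

    def test_silent_channel_dropped(self, rng):
        means = self._means(rng)
        snr, keep = channel_snr(means, np.array([1.0, 1.0, 1.0]))
        assert keep.tolist() == [True, True, False]
        assert snr[2] < 2.5 <= snr[0]

    def test_zero_background_gives_inf_with_warning(self, rng):
        means = self._means(rng, n_ch=2, bright=(100.0, 50.0))
        with pytest.warns(UserWarning, match="inf"):
            snr, keep = channel_snr(means, np.array([0.0, 1.0]))
        assert np.isinf(snr[0])
        assert keep.all()

    def test_all_channels_failing_is_hard_error(self, rng):
        means = self._means(rng, n_ch=2, bright=(1.0, 1.0))
        with pytest.raises(ValueError, match="all channels"):
            channel_snr(means, np.array([1.0, 1.0]))

    def test_too_few_fragments_rejected(self):
        with pytest.raises(ValueError, match=">=10"):
            channel_snr(np.ones((5, 3)), np.ones(3))


class TestComputeColourVectors:
    def _frag(self, fid, means):
        f = Fragment(fid, [[0, 0, 0], [5, 0, 0]], [1, 1])
        f.raw_channel_means = np.asarray(means, dtype=float)
        return f

    def test_hand_computed_two_fragment_dataset(self):
        frags = [self._frag("a", (10.0, 0.0)), self._frag("b", (0.0, 20.0))]
        vectors = compute_colour_vectors(frags, np.zeros(2))
        np.testing.assert_allclose(vectors[0].values, [1, 0])
        np.testing.assert_allclose(vectors[1].values, [0, 1])

    def test_single_fragment_max_scaling(self):
        vectors = compute_colour_vectors(
            [self._frag("a", (10.0, 5.0))], np.zeros(2)
        )
        # every nonzero channel scales to 1 before unit normalization
        np.testing.assert_allclose(
            vectors[0].values, [1 / np.sqrt(2), 1 / np.sqrt(2)]
        )
        assert vectors[0].magnitude == pytest.approx(np.sqrt(2))

    def test_below_background_channel_contributes_zero(self):
        frags = [self._frag("a", (3.0, 10.0)), self._frag("b", (20.0, 10.0))]
        vectors = compute_colour_vectors(frags, np.array([5.0, 0.0]))
        assert vectors[0].values[0] == 0.0

    def test_scale_invariance(self, rng):
        """Multiplying all means and backgrounds by k leaves vectors unchanged."""
        means = rng.uniform(5, 50, size=(20, 4))
        bg = rng.uniform(0, 3, size=4)
        frags_1 = [self._frag(i, m) for i, m in enumerate(means)]
        frags_k = [self._frag(i, 7.3 * m) for i, m in enumerate(means)]
        v1 = compute_colour_vectors(frags_1, bg)
        vk = compute_colour_vectors(frags_k, 7.3 * bg)
        for a, b in zip(v1, vk):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)
            assert a.magnitude == pytest.approx(b.magnitude)

    def test_dead_channel_is_error(self):
        frags = [self._frag("a", (10.0, 0.0)), self._frag("b", (5.0, 0.0))]
        with pytest.raises(ValueError, match="S/N"):
            compute_colour_vectors(frags, np.zeros(2))


@pytest.fixture(scope="module")
def noiseless_phantom():
    """Sparse enough that fibres never cross: colours are exact everywhere."""
    cfg = PhantomConfig(
        n_neurons=2, n_channels=5, shape=(16, 96, 96), seed=11,
        branch_probability=0.0,
    )
    return generate_phantom(cfg)


class TestThresholdDetermination:
    def test_noiseless_phantom_picks_smallest_length(self, noiseless_phantom):
        ph = noiseless_phantom
        cfg = QCConfig(length_grid_um=(2.5, 5.0, 10.0))
        min_len, curve = determine_min_length(ph.fragments, ph.image, cfg)
        assert min_len == 2.5
        # the whole curve sits near zero without noise
        assert all(d < cfg.sub_accuracy_d for _, d in curve)

    def test_curve_is_reported_for_every_grid_value(self, noiseless_phantom):
        ph = noiseless_phantom
        cfg = QCConfig(length_grid_um=(2.5, 5.0, 10.0))
        _, curve = determine_min_length(ph.fragments, ph.image, cfg)
        assert [l for l, _ in curve] == [2.5, 5.0, 10.0]

    def test_all_accurate_pieces_give_zero_cutoff(self, noiseless_phantom):
        ph = noiseless_phantom
        cutoff = determine_min_brightness(
            ph.fragments, ph.image, min_length_um=5.0
        )
        assert cutoff == 0.0

    def test_brightness_cutoff_satisfies_its_contract(self):
        """On a noisy phantom the returned cutoff leaves <5% inaccurate pieces."""
        from qdyefinder.quality_control import _fragment_colour, _image_background
        from qdyefinder.traces import subdivide_fragment

        cfg = PhantomConfig(
            n_neurons=6, n_channels=5, shape=(16, 64, 64), seed=21,
            noise_scale=4.0, peak_brightness=(60.0, 900.0),
        )
        ph = generate_phantom(cfg)
        cutoff = determine_min_brightness(ph.fragments, ph.image, 5.0)
        # recheck the guarantee through the public sampling primitives
        bg = _image_background(ph.image)
        mags, bad = [], []
        for frag in ph.fragments:
            parent = _fragment_colour(frag, ph.image, background=bg)
            if parent.magnitude == 0:
                continue
            for piece in subdivide_fragment(frag, 5.0):
                cv = _fragment_colour(piece, ph.image, background=bg)
                mags.append(cv.magnitude)
                bad.append(colour_distance(cv, parent) > 0.2)
        mags = np.asarray(mags) / max(mags)
        bad = np.asarray(bad)
        survivors = mags >= cutoff
        assert survivors.any()
        assert bad[survivors].mean() < 0.05


class TestSplitColourChanges:
    def test_uniform_fragment_unchanged(self, noiseless_phantom):
        ph = noiseless_phantom
        frag = max(ph.fragments, key=lambda f: f.length)
        out = split_colour_changes(frag, ph.image, min_length_um=5.0)
        assert out == [frag]

    def test_hybrid_fragment_split_at_colour_boundary(self):
        a = np.array([1.0, 0, 0, 0, 0])
        b = np.array([0, 0, 0, 0, 1.0])
        assert colour_distance(a, b) > 0.9
        frag, img, boundary = make_hybrid_fragment(a, b, lengths=(15.0, 15.0))
        pieces = split_colour_changes(frag, img, min_length_um=5.0)
        assert len(pieces) == 2
        cut = pieces[0].length
        assert abs(cut - boundary) <= 5.0  # within one sub-fragment
        assert sum(p.length for p in pieces) == pytest.approx(
            frag.length, abs=1e-6
        )

    def test_identical_halves_not_split(self):
        a = np.array([0.6, 0.8, 0.0])
        frag, img, _ = make_hybrid_fragment(a, a, lengths=(12.0, 12.0))
        assert split_colour_changes(frag, img, min_length_um=5.0) == [frag]

    def test_short_fragment_passes_through(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        frag, img, _ = make_hybrid_fragment(a, b, lengths=(4.0, 4.0))
        assert split_colour_changes(frag, img, min_length_um=5.0) == [frag]


class TestRunQc:
    def test_noiseless_bright_phantom_drops_nothing_long(self, phantom_qc,
                                                         small_phantom):
        vectors, frags, report = phantom_qc
        long_inputs = [
            f for f in small_phantom.fragments if f.length >= 5.0
        ]
        assert report.n_after_length == len(long_inputs)
        assert len(vectors) == len(frags)
        assert report.channels_dropped == []

    def test_short_fragments_are_dropped(self, small_phantom):
        vectors, frags, report = run_qc(
            small_phantom.fragments, small_phantom.image,
            QCConfig(min_length_um=5.0, min_magnitude=0.1),
        )
        assert all(f.length >= 5.0 for f in frags)
        assert all(v.magnitude >= 0.0 for v in vectors)

    def test_output_respects_thresholds(self, phantom_qc):
        vectors, frags, report = phantom_qc
        for v, f in zip(vectors, frags):
            assert f.length >= report.min_length_um - 1e-9

    def test_empty_input_is_not_an_error(self, small_phantom):
        vectors, frags, report = run_qc([], small_phantom.image, QCConfig())
        assert vectors == [] and frags == []
        assert report.n_input == 0

    def test_same_neuron_vectors_cohere_across_neurons(self, phantom_qc,
                                                       small_phantom):
        """Colour vectors separate by neuron: within-neuron distances stay
        well below between-neuron distances (the property clustering needs;
        the per-channel max scaling makes absolute hues dataset-relative)."""
        vectors, frags, _ = phantom_qc
        labels = small_phantom.labels
        groups = {}
        for v, f in zip(vectors, frags):
            neuron = labels[f.parent_fragment or f.fragment_id]
            groups.setdefault(neuron, []).append(v.values)
        within, between = [], []
        neurons = list(groups)
        for i, n1 in enumerate(neurons):
            g = groups[n1]
            within += [
                colour_distance(a, b)
                for k, a in enumerate(g) for b in g[k + 1:]
            ]
            for n2 in neurons[i + 1:]:
                between += [
                    colour_distance(a, b) for a in g for b in groups[n2]
                ]
        assert np.median(within) < 0.1
        assert np.median(between) > 3 * np.median(within)
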