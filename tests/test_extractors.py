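"""Embedding streams: statistics oracle, chunking, contracts, dimensions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ehrfusion import (
    CHART_SIGNALS,
    LAB_SIGNALS,
    PROCEDURE_SIGNALS,
    NoteDocument,
    chunk_text,
    embed_image_multi,
    embed_image_single,
    embed_tabular,
    embed_text_source,
    embed_timeseries_signal,
    embed_timeseries_source,
    preprocess_image,
)
from ehrfusion.extractors import ContractError
from ehrfusion.patient_record import ImageStudy

from conftest import make_event_table


def reference_signal_stats(series):
    """Brute-force statistics oracle, independent of the implementation."""
    import statistics

    if not series:
        return [0.0] * 11
    t = [p[0] for p in series]
    v = [p[1] for p in series]
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    peaks = sum(
        1 for i in range(1, n - 1) if v[i - 1] < v[i] > v[i + 1]
    )
    slopes = [
        (v[i + 1] - v[i]) / (t[i + 1] - t[i])
        for i in range(n - 1)
        if t[i + 1] > t[i]
    ]
    mean_slope = sum(slopes) / len(slopes) if slopes else 0.0
    mean_abs = sum(abs(s) for s in slopes) / len(slopes) if slopes else 0.0
    trend = (v[-1] - v[0]) / (t[-1] - t[0]) if t[-1] > t[0] else 0.0
    return [
        float(n), max(v), min(v), mean, statistics.median(v),
        var ** 0.5, var, float(peaks), mean_slope, mean_abs, trend,
    ]


class TestTimeseriesSignal:
    def test_frozen_hand_example(self):
        out = embed_timeseries_signal([(0, 1), (1, 3), (2, 2)])
        expected = [3, 3, 1, 2, 2, np.sqrt(2 / 3), 2 / 3, 1, 0.5, 1.5, 0.5]
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_constant_series_has_no_spread_or_motion(self):
        out = embed_timeseries_signal([(t, 5.0) for t in range(7)])
        np.testing.assert_array_equal(out[5:], np.zeros(6))
        assert out[0] == 7 and out[1] == out[2] == out[3] == out[4] == 5.0

    def test_empty_series_is_zero_vector(self):
        np.testing.assert_array_equal(embed_timeseries_signal([]), np.zeros(11))

    def test_single_point(self):
        np.testing.assert_allclose(
            embed_timeseries_signal([(2.0, 7.0)]),
            [1, 7, 7, 7, 7, 0, 0, 0, 0, 0, 0],
        )

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            embed_timeseries_signal([(1, 0.0), (0, 1.0)])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            embed_timeseries_signal([(0, np.nan)])

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(0, 51))
            t = np.sort(rng.uniform(0, 48, n))
            v = rng.normal(50, 10, n)
            series = list(zip(t.tolist(), v.tolist()))
            np.testing.assert_allclose(
                embed_timeseries_signal(series),
                reference_signal_stats(series),
                atol=1e-9,
            )


class TestTimeseriesSource:
    @pytest.mark.parametrize(
        "signals,expected_dim",
        [(CHART_SIGNALS, 99), (PROCEDURE_SIGNALS, 110), (LAB_SIGNALS, 242)],
    )
    def test_source_dimensions(self, signals, expected_dim):
        table = make_event_table([(signals[0], 1.0, 10.0)])
        assert embed_timeseries_source(table, signals).shape == (expected_dim,)

    def test_lab_signal_list_is_deduplicated(self):
        assert len(LAB_SIGNALS) == len(set(LAB_SIGNALS)) == 22

    def test_signal_locality(self):
        table = make_event_table([("heart_rate", 1.0, 80.0), ("heart_rate", 2.0, 90.0)])
        out = embed_timeseries_source(table, CHART_SIGNALS)
        hr = CHART_SIGNALS.index("heart_rate")
        assert np.any(out[hr * 11 : (hr + 1) * 11] != 0)
        mask = np.ones(99, bool)
        mask[hr * 11 : (hr + 1) * 11] = False
        np.testing.assert_array_equal(out[mask], 0)

    def test_absent_table_gives_zero_vector(self):
        np.testing.assert_array_equal(
            embed_timeseries_source(None, CHART_SIGNALS), np.zeros(99)
        )


class TestTabular:
    def test_range_minima_give_zero_vector(self):
        demo = {"age": 0.0, "sex_code": 0.0, "ethnicity_code": 0.0,
                "marital_status_code": 0.0, "language_code": 0.0,
                "insurance_code": 0.0}
        np.testing.assert_array_equal(embed_tabular(demo), np.zeros(6))

    def test_midpoint_maps_to_half(self):
        assert embed_tabular({"age": 50.0})[0] == pytest.approx(0.5)

    def test_output_length_is_six(self):
        assert embed_tabular({}).shape == (6,)

    def test_out_of_range_clipped(self):
        assert embed_tabular({"age": 250.0})[0] == 1.0


class TestChunking:
    @pytest.mark.parametrize("n,expected", [(512, 1), (513, 2), (1100, 3), (0, 0)])
    def test_chunk_counts(self, n, expected):
        chunks = chunk_text([str(i) for i in range(n)])
        assert len(chunks) == expected
        if n == 1100:
            assert [len(c) for c in chunks] == [512, 512, 76]

    @given(n=st.integers(0, 5000))
    def test_chunking_is_minimal_and_lossless(self, n):
        tokens = [str(i) for i in range(n)]
        chunks = chunk_text(tokens)
        assert len(chunks) == -(-n // 512)
        assert [t for c in chunks for t in c] == tokens
        assert all(len(c) <= 512 for c in chunks)


class _FixedEncoder:
    max_tokens = 512
    output_dim = 768

    def __init__(self, fn):
        self._fn = fn

    def encode(self, tokens):
        return self._fn(tokens)


class TestTextSource:
    def test_single_short_note_equals_encoder_output(self, text_encoder):
        note = NoteDocument(1.0, "brief stable course")
        out = embed_text_source([note], text_encoder)
        np.testing.assert_array_equal(
            out, text_encoder.encode("brief stable course".split())
        )

    def test_symmetric_chunks_average_to_zero(self):
        v = np.arange(768.0)
        enc = _FixedEncoder(lambda toks: v if toks[0] == "a" else -v)
        notes = [NoteDocument(0.0, " ".join(["a"] * 512 + ["b"] * 512))]
        np.testing.assert_array_equal(embed_text_source(notes, enc), np.zeros(768))

    def test_no_notes_give_zero_vector(self, text_encoder):
        np.testing.assert_array_equal(
            embed_text_source([], text_encoder), np.zeros(768)
        )

    def test_constant_encoder_invariant_to_chunking(self):
        const = np.full(768, 3.25)
        enc = _FixedEncoder(lambda toks: const)
        for n_tokens in (10, 512, 513, 2000):
            notes = [NoteDocument(0.0, " ".join(["w"] * n_tokens))]
            np.testing.assert_array_equal(embed_text_source(notes, enc), const)

    def test_wrong_encoder_dim_is_contract_error(self):
        enc = _FixedEncoder(lambda toks: np.zeros(10))
        with pytest.raises(ContractError):
            embed_text_source([NoteDocument(0.0, "x")], enc)


class TestImagePreprocessing:
    def test_identity_at_target_size(self):
        img = np.random.default_rng(0).uniform(0, 255, (224, 224))
        np.testing.assert_array_equal(preprocess_image(img), img)

    def test_constant_image_stays_constant(self):
        out = preprocess_image(np.full((448, 448), 37.0))
        assert out.shape == (224, 224)
        np.testing.assert_allclose(out, 37.0, atol=1e-5)

    def test_checkerboard_area_conservation(self):
        img = np.indices((448, 448)).sum(axis=0)
        img = ((img // 2) % 2).astype(float)  # 2x2 block checkerboard of {0,1}
        out = preprocess_image(img)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert abs(out.mean() - img.mean()) < 1e-6

    def test_range_never_exceeds_input(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 20, (300, 500))
        out = preprocess_image(img)
        assert out.min() >= img.min() - 1e-6 and out.max() <= img.max() + 1e-6

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((0, 5)))


class _FixedImageModel:
    input_size = (224, 224)
    prob_dim = 18
    dense_dim = 1024

    def __init__(self, probs, dense):
        self._probs, self._dense = probs, dense

    def forward(self, image):
        return self._probs, self._dense


class TestImageEmbedding:
    def test_stub_passthrough(self):
        probs = np.linspace(0, 1, 18)
        dense = np.arange(1024.0)
        study = ImageStudy(1.0, (np.zeros((16, 16), dtype=np.uint8),))
        vp, vd = embed_image_single(study, _FixedImageModel(probs, dense))
        np.testing.assert_array_equal(vp, probs)
        np.testing.assert_array_equal(vd, dense)

    def test_probability_outside_unit_interval_is_contract_error(self):
        bad = _FixedImageModel(np.full(18, 1.5), np.zeros(1024))
        study = ImageStudy(1.0, (np.zeros((16, 16), dtype=np.uint8),))
        with pytest.raises(ContractError):
            embed_image_single(study, bad)

    def test_distinct_images_give_distinct_dense_vectors(self, image_model):
        rng = np.random.default_rng(7)
        s1 = ImageStudy(1.0, (rng.integers(0, 255, (32, 32)).astype(np.uint8),))
        s2 = ImageStudy(2.0, (rng.integers(0, 255, (32, 32)).astype(np.uint8),))
        _, d1 = embed_image_single(s1, image_model)
        _, d2 = embed_image_single(s2, image_model)
        assert not np.allclose(d1, d2)

    def test_multi_image_mean_of_one_equals_single(self, image_model):
        study = ImageStudy(
            1.0, (np.full((16, 16), 100, dtype=np.uint8),)
        )
        vp, vd = embed_image_single(study, image_model)
        vmp, vmd = embed_image_multi([study], image_model)
        np.testing.assert_array_equal(vmp, vp)
        np.testing.assert_array_equal(vmd, vd)

    def test_multi_image_arithmetic_mean(self):
        m1 = _FixedImageModel(np.full(18, 0.2), np.zeros(1024))

        class Switcher:
            input_size = (224, 224)
            prob_dim = 18
            dense_dim = 1024

            def forward(self, image):
                p = 0.2 if image.mean() < 50 else 0.6
                return np.full(18, p), np.full(1024, p)

        studies = [
            ImageStudy(1.0, (np.zeros((16, 16), dtype=np.uint8),)),
            ImageStudy(2.0, (np.full((16, 16), 200, dtype=np.uint8),)),
        ]
        vmp, vmd = embed_image_multi(studies, Switcher())
        assert vmp[0] == pytest.approx(0.4)
        assert vmd[0] == pytest.approx(0.4)

    def test_multi_image_permutation_invariant(self, image_model):
        rng = np.random.default_rng(3)
        studies = [
            ImageStudy(float(t), (rng.integers(0, 255, (24, 24)).astype(np.uint8),))
            for t in range(4)
        ]
        a = embed_image_multi(studies, image_model)
        b = embed_image_multi(studies[::-1], image_model)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)
        np.testing.assert_allclose(a[1], b[1], atol=1e-12)

    def test_duplicated_image_mean_idempotent(self, image_model):
        img = np.full((16, 16), 90, dtype=np.uint8)
        one = embed_image_multi([ImageStudy(1.0, (img,))], image_model)
        k = embed_image_multi(
            [ImageStudy(float(t), (img,)) for t in range(3)], image_model
        )
        np.testing.assert_allclose(one[0], k[0])
        np.testing.assert_allclose(one[1], k[1])
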