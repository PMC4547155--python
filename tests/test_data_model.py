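"""Session container, log-dialect and JSON serialization behaviour."""

import json

import numpy as np
import pytest

import harkit as hk
from harkit.data_model import ChannelLookupError, ParseError


class TestLogRoundtrip:
    def test_timestamps_synthesized_from_row_index(self, toy_session, tmp_path):
        path = tmp_path / "toy.log"
        hk.write_mhealth_log(toy_session, path)
        session = hk.read_mhealth_log(path, sampling_rate=50.0, subject_id="s1")
        assert len(session) == 3
        assert [s.timestamp for s in session.samples] == [0.0, 0.02, 0.04]

    def test_roundtrip_is_lossless(self, toy_session, tmp_path):
        path = tmp_path / "toy.log"
        hk.write_mhealth_log(toy_session, path)
        back = hk.read_mhealth_log(path, sampling_rate=50.0, subject_id="s1")
        assert np.array_equal(back.values, toy_session.values)
        assert np.array_equal(back.labels, toy_session.labels)

    def test_roundtrip_survives_awkward_floats(self, default_layout, tmp_path):
        rng = np.random.default_rng(7)
        n_ch = sum(len(s.axes) for d in default_layout for s in d.sensors)
        meta = hk.Metadata("x", "s", 0.0, 1 / 50, 50.0, default_layout)
        values = rng.normal(scale=1e3, size=(2, n_ch))
        samples = tuple(
            hk.Sample(i / 50.0, tuple(values[i]), 0) for i in range(2)
        )
        path = tmp_path / "x.log"
        hk.write_mhealth_log(hk.Session(meta, samples), path)
        back = hk.read_mhealth_log(path, sampling_rate=50.0)
        assert np.array_equal(back.values, values)  # bit-exact via repr rendering

    def test_one_line_per_sample_label_last(self, toy_session, tmp_path):
        path = tmp_path / "toy.log"
        hk.write_mhealth_log(toy_session, path)
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        assert len(lines) == 3
        assert [l.split()[-1] for l in lines] == ["1", "1", "2"]

    @pytest.mark.parametrize(
        "row, message_part",
        [
            ("1.0 " * 23, "line 1"),  # 23 columns under the 24-column layout
            ("1.0 " * 23 + "oops", "non-numeric"),
        ],
    )
    def test_malformed_row_cites_line(self, tmp_path, row, message_part):
        path = tmp_path / "bad.log"
        path.write_text(row.strip() + "\n")
        with pytest.raises(ParseError, match=message_part):
            hk.read_mhealth_log(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.log"
        path.write_text("")
        with pytest.raises(ParseError, match="empty"):
            hk.read_mhealth_log(path)


class TestJsonDocument:
    def test_metadata_appears_exactly_once(self, toy_session):
        doc = hk.session_to_json(toy_session)
        assert doc.count('"devices"') == 1
        parsed = json.loads(doc)
        assert len(parsed["samples"]) == 3
        assert "metadata" in parsed and "sampling_rate" in parsed["metadata"]

    def test_roundtrip_and_byte_stability(self, toy_session):
        doc = hk.session_to_json(toy_session)
        back = hk.session_from_json(doc)
        assert back == toy_session
        assert hk.session_to_json(back) == doc  # canonical rendering is idempotent

    def test_empty_sample_session(self, default_layout):
        meta = hk.Metadata("e", "s", 0.0, 0.0, 50.0, default_layout)
        doc = hk.session_to_json(hk.Session(meta, ()))
        parsed = json.loads(doc)
        assert parsed["samples"] == []
        assert hk.session_from_json(doc).metadata == meta

    def test_metadata_overhead_is_constant(self, default_layout):
        """Serialized size grows linearly in samples: the metadata block is
        not repeated per sample."""
        def doc_size(n):
            meta = hk.Metadata("e", "s", 0.0, (n - 1) / 50 if n else 0.0, 50.0,
                               default_layout)
            n_ch = meta.n_channels
            samples = tuple(
                hk.Sample(i / 50.0, (0.0,) * n_ch, 1) for i in range(n)
            )
            return len(hk.session_to_json(hk.Session(meta, samples)))

        per_sample = doc_size(20) - doc_size(10)
        assert doc_size(30) - doc_size(20) == per_sample

    def test_garbage_is_a_parse_error(self):
        with pytest.raises(ParseError):
            hk.session_from_json("{not json")
        with pytest.raises(ParseError):
            hk.session_from_json('{"metadata": {}}')


class TestSelectChannels:
    def test_nine_acceleration_channels(self, toy_session):
        names = hk.acceleration_channels(toy_session.metadata)
        assert len(names) == 9
        matrix = hk.select_channels(toy_session, names)
        assert matrix.values.shape == (3, 9)
        assert matrix.sampling_rate == 50.0
        assert np.array_equal(matrix.labels, toy_session.labels)

    def test_values_pass_through_untouched(self, toy_session):
        declared = toy_session.metadata.channel_names()
        matrix = hk.select_channels(toy_session, ["left-ankle/gyro/y"])
        col = declared.index("left-ankle/gyro/y")
        assert np.array_equal(matrix.values[:, 0], toy_session.values[:, col])

    def test_requested_order_is_respected(self, toy_session):
        names = ["right-wrist/acc/z", "chest/acc/x"]
        matrix = hk.select_channels(toy_session, names)
        assert matrix.channel_names == tuple(names)
        declared = toy_session.metadata.channel_names()
        for j, name in enumerate(names):
            assert np.array_equal(
                matrix.values[:, j], toy_session.values[:, declared.index(name)]
            )

    def test_unknown_channel_is_named_in_the_error(self, toy_session):
        with pytest.raises(ChannelLookupError, match="chest/acc/w"):
            hk.select_channels(toy_session, ["chest/acc/w"])


class TestSessionInvariants:
    def test_irregular_clock_rejected(self, default_layout):
        meta = hk.Metadata("x", "s", 0.0, 1.0, 50.0, default_layout)
        n_ch = meta.n_channels
        samples = (
            hk.Sample(0.0, (0.0,) * n_ch, 1),
            hk.Sample(0.05, (0.0,) * n_ch, 1),  # gap 0.05 != 0.02
        )
        with pytest.raises(ValueError, match="irregular"):
            hk.Session(meta, samples)

    def test_wrong_value_count_rejected(self, default_layout):
        meta = hk.Metadata("x", "s", 0.0, 0.0, 50.0, default_layout)
        with pytest.raises(ValueError, match="channels"):
            hk.Session(meta, (hk.Sample(0.0, (1.0, 2.0), 1),))

    def test_label_range_enforced(self):
        with pytest.raises(ValueError):
            hk.Sample(0.0, (1.0,), 13)
        with pytest.raises(ValueError):
            hk.Sample(0.0, (1.0,), -1)

    def test_duplicate_device_names_rejected(self, default_layout):
        with pytest.raises(ValueError, match="unique"):
            hk.Metadata("x", "s", 0.0, 0.0, 50.0, (default_layout[0], default_layout[0]))
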