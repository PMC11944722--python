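"""Series container, physiological-range cleaning, and file round-trips."""

import struct

import numpy as np
import pandas as pd
import pytest

from oxiscale import DomainError, SpO2Series, clean_spo2
from oxiscale.io import (
    ChannelNotFoundError,
    FormatError,
    IntegrityError,
    read_labels,
    read_spo2,
    write_spo2_csv,
)


class TestCleanSpo2:
    def test_masks_out_of_range_values(self, series_factory):
        out = clean_spo2(series_factory([98.0, 55.0, 97.0]))
        assert out.valid_mask.tolist() == [True, False, True]

    def test_in_range_series_untouched(self, series_factory):
        s = series_factory([96.0, 96.0, 96.0])
        out = clean_spo2(s)
        assert out.valid_mask.all()
        np.testing.assert_array_equal(out.values, s.values)

    def test_boundaries_are_strict(self, series_factory):
        out = clean_spo2(series_factory([101.0, 59.9, 60.0, 100.0]))
        assert out.valid_mask.tolist() == [False, False, True, True]

    def test_idempotent_and_values_preserved(self, series_factory, rng):
        vals = rng.uniform(40, 110, 500)
        once = clean_spo2(series_factory(vals))
        twice = clean_spo2(once)
        np.testing.assert_array_equal(once.valid_mask, twice.valid_mask)
        np.testing.assert_array_equal(once.values, vals)

    def test_masked_fraction_matches_count(self, series_factory, rng):
        vals = rng.uniform(40, 110, 1000)
        out = clean_spo2(series_factory(vals))
        expected = np.sum((vals < 60) | (vals > 100))
        assert (~out.valid_mask).sum() == expected

    def test_empty_series_rejected(self):
        with pytest.raises(DomainError):
            clean_spo2(SpO2Series(subject_id="x", values=np.array([])))


class TestSeriesInvariants:
    def test_duration_recoverable(self, series_factory):
        s = series_factory(np.zeros(120) + 96, dt=2.0)
        assert s.duration_s == 240.0

    def test_mask_length_must_match(self):
        with pytest.raises(DomainError):
            SpO2Series(subject_id="x", values=np.ones(3) * 96,
                       valid_mask=np.ones(4, dtype=bool))

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(DomainError):
            SpO2Series(subject_id="x", values=np.ones(3) * 96, dt_s=0.0)


class TestCsvIo:
    def test_read_simple(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("time_s,spo2_percent\n0,96\n1,97\n2,95\n")
        s = read_spo2(p)
        assert len(s) == 3 and s.dt_s == 1.0
        np.testing.assert_array_equal(s.values, [96, 97, 95])
        assert s.valid_mask.all()

    def test_gap_in_time_axis_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("time_s,spo2_percent\n0,96\n1,97\n3,95\n")
        with pytest.raises(FormatError):
            read_spo2(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_spo2(tmp_path / "nope.csv")

    def test_round_trip_bit_exact(self, tmp_path, series_factory, rng):
        vals = rng.uniform(60, 100, 50)
        mask = rng.random(50) > 0.1
        s = series_factory(vals, mask=mask)
        p = tmp_path / "rt.csv"
        write_spo2_csv(s, p)
        back = read_spo2(p)
        np.testing.assert_array_equal(back.values, vals)
        np.testing.assert_array_equal(back.valid_mask, mask)


class TestLabels:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("subject_id,nsrr_ahi_hp3r_aasm15\ns1,4.2\ns2,31.0\n")
        t = read_labels(p)
        assert len(t) == 2
        assert t.loc[t.subject_id == "s2", "ahi"].item() == 31.0

    def test_duplicate_subject_rejected(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("subject_id,nsrr_ahi_hp3r_aasm15\ns1,4.2\ns1,5.0\n")
        with pytest.raises(IntegrityError):
            read_labels(p)

    def test_missing_ahi_dropped(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("subject_id,nsrr_ahi_hp3r_aasm15\ns1,\ns2,12\n")
        t = read_labels(p)
        assert t.subject_id.tolist() == ["s2"]

    def test_negative_ahi_rejected(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("subject_id,nsrr_ahi_hp3r_aasm15\ns1,-1\n")
        with pytest.raises(IntegrityError):
            read_labels(p)

    def test_custom_column_name(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("subject_id,my_ahi\ns1,7\n")
        t = read_labels(p, ahi_column="my_ahi")
        assert t.ahi.item() == 7.0


def _write_minimal_edf(path, signal, label="SaO2", fs=1):
    """Byte-level EDF writer (independent of any reader library): one data
    record holding the whole integer-valued signal at `fs` Hz."""
    n = len(signal)
    header = (
        f"{'0':<8}{'X':<80}{'X':<80}01.01.2501.01.25"
        f"{256 + 256:<8}{'':44}{1:<8}{n // fs:<8}{1:<4}"
    ).encode()
    assert len(header) == 256
    phys_min, phys_max = 0, 200
    dig_min, dig_max = -32768, 32767
    ch = (
        f"{label:<16}{'':80}{'percent':<8}{phys_min:<8}{phys_max:<8}"
        f"{dig_min:<8}{dig_max:<8}{'':80}{n:<8}{'':32}"
    ).encode()
    assert len(ch) == 256
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = [int(round((v - phys_min) * gain + dig_min)) for v in signal]
    data = struct.pack(f"<{n}h", *digital)
    path.write_bytes(header + ch + data)


class TestEdf:
    def test_edf_round_trip(self, tmp_path):
        pytest.importorskip("mne")
        signal = [96, 97, 95, 94, 96] * 20
        p = tmp_path / "t.edf"
        _write_minimal_edf(p, signal)
        s = read_spo2(p)
        assert len(s) == 100
        assert s.dt_s == pytest.approx(1.0)
        np.testing.assert_allclose(s.values, signal, atol=0.01)

    def test_missing_channel_lists_available(self, tmp_path):
        pytest.importorskip("mne")
        p = tmp_path / "t.edf"
        _write_minimal_edf(p, [96] * 50, label="EEG1")
        with pytest.raises(ChannelNotFoundError, match="EEG1"):
            read_spo2(p)
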