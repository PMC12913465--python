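"""CSV dialects, round trips, replicate averaging, and id alignment."""

import io

import numpy as np
import pandas as pd
import pytest

from heatspec import spectra_io as sio
from heatspec.errors import AlignmentError, FormatError, ValidationError
from heatspec.spectra_io import Spectrum


def _random_spectra(rng, n=4, bands=7):
    wl = np.sort(rng.choice(np.arange(400, 900), size=bands, replace=False)).astype(float)
    out = []
    for i in range(n):
        # values representable at the emitted 6-significant-digit precision
        vals = np.round(rng.uniform(0.01, 0.9, bands), 5)
        md = {"sample_id": f"s{i}", "group": "CK" if i % 2 else "T",
              "stage": "budding", "replicate": str(i % 3 + 1)}
        out.append(Spectrum(wl, vals, metadata=md))
    return out


class TestSpectrumInvariants:
    def test_non_increasing_wavelengths_rejected(self):
        with pytest.raises(ValidationError):
            Spectrum([500.0, 500.0], [0.1, 0.2])

    def test_reflectance_range_enforced(self):
        with pytest.raises(ValidationError):
            Spectrum([500.0, 501.0], [0.1, 2.0])
        # derivative values may be negative
        Spectrum([500.0, 501.0], [-0.5, 0.5], kind="first_derivative")


class TestSpectraRoundTrip:
    @pytest.mark.parametrize("dialect", ["wide", "long"])
    def test_random_table_round_trips_exactly(self, rng, dialect):
        spectra = _random_spectra(rng)
        text = sio.write_spectra_table(spectra, dialect)
        back = sio.read_spectra_table(text, dialect)
        assert len(back) == len(spectra)
        for a, b in zip(spectra, back):
            np.testing.assert_array_equal(a.wavelengths, b.wavelengths)
            np.testing.assert_array_equal(a.values, b.values)
            assert a.sample_id == b.sample_id
            assert b.metadata.get("group") == a.metadata["group"]

    def test_wide_parse_shape(self):
        text = "# kind=reflectance\nwavelength,a,b\n500,0.1,0.2\n501,0.15,0.25\n502,0.2,0.3\n"
        spectra = sio.read_spectra_table(text, "wide")
        assert len(spectra) == 2 and all(len(s) == 3 for s in spectra)

    def test_duplicate_wavelength_row_is_format_error(self):
        text = "# kind=reflectance\nwavelength,a\n500,0.1\n500,0.2\n"
        with pytest.raises(FormatError):
            sio.read_spectra_table(text, "wide")

    def test_empty_list_writes_header_only(self):
        text = sio.write_spectra_table([], "wide")
        assert text.splitlines()[1] == "wavelength"

    def test_single_spectrum_single_column(self):
        s = Spectrum([500.0, 501.0], [0.1, 0.2], metadata={"sample_id": "x"})
        lines = sio.write_spectra_table([s], "wide").splitlines()
        assert lines[1] == "wavelength,x"
        assert lines[-1].count(",") == 1

    def test_mixed_kinds_rejected_on_write(self):
        a = Spectrum([500.0, 501.0], [0.1, 0.2])
        b = Spectrum([500.0, 501.0], [0.1, 0.2], kind="first_derivative")
        with pytest.raises(FormatError):
            sio.write_spectra_table([a, b], "wide")

    def test_percent_scale_rescaled_on_read(self):
        text = "# kind=reflectance\nwavelength,a\n500,45\n501,50\n"
        (s,) = sio.read_spectra_table(text, "wide", reflectance_scale="percent")
        np.testing.assert_allclose(s.values, [0.45, 0.50])


class TestPhysiologyTable:
    def test_toy_table_and_missing_indicator_flag(self):
        text = "sample_id,SPAD,A\ns1,30,10\ns2,35,12\ns3,40,15\n"
        df = sio.read_physiology_table(io.StringIO(text))
        assert len(df) == 3
        assert "qN" in df.attrs["missing"]

    def test_negative_spad_rejected(self):
        text = "sample_id,SPAD\ns1,-3\n"
        with pytest.raises(ValidationError):
            sio.read_physiology_table(io.StringIO(text))

    def test_round_trip(self, rng):
        df = pd.DataFrame(
            {"SPAD": np.round(rng.uniform(20, 50, 3), 3),
             "qP": np.round(rng.uniform(0.2, 0.9, 3), 4)},
            index=pd.Index(["a", "b", "c"], name="sample_id"),
        )
        back = sio.read_physiology_table(io.StringIO(sio.write_physiology_table(df)))
        pd.testing.assert_frame_equal(df, back[df.columns], check_names=False)


class TestAverageReplicates:
    def test_identical_replicates_idempotent(self):
        s = Spectrum([500.0, 501.0], [0.2, 0.4],
                     metadata={"sample_id": "a", "pot": "1", "replicate": "1"})
        s2 = Spectrum([500.0, 501.0], [0.2, 0.4],
                      metadata={"sample_id": "a", "pot": "1", "replicate": "2"})
        (avg,) = sio.average_replicates([s, s2], by=("pot",))
        np.testing.assert_array_equal(avg.values, s.values)
        assert "replicate" not in avg.metadata

    def test_two_values_average_to_midpoint(self):
        a = Spectrum([500.0], [0.2], metadata={"pot": "1"})
        b = Spectrum([500.0], [0.4], metadata={"pot": "1"})
        (avg,) = sio.average_replicates([a, b], by=("pot",))
        assert avg.values[0] == pytest.approx(0.3)

    def test_matches_naive_per_band_mean(self, rng):
        spectra = [
            Spectrum(np.arange(500.0, 510.0), rng.uniform(0.1, 0.5, 10),
                     metadata={"pot": "1"})
            for _ in range(5)
        ]
        (avg,) = sio.average_replicates(spectra, by=("pot",))
        naive = np.array([
            sum(s.values[i] for s in spectra) / 5 for i in range(10)
        ])
        np.testing.assert_allclose(avg.values, naive, atol=1e-12)

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            sio.average_replicates([])

    def test_group_count_preserved(self, rng):
        spectra = []
        for pot in ("1", "2", "3"):
            for rep in ("1", "2"):
                spectra.append(Spectrum(
                    [500.0, 501.0], rng.uniform(0.1, 0.5, 2),
                    metadata={"pot": pot, "replicate": rep}))
        assert len(sio.average_replicates(spectra, by=("pot",))) == 3


class TestValidateAlignment:
    def _spectra(self, ids):
        return [Spectrum([500.0, 501.0], [0.1, 0.2],
                         metadata={"sample_id": i}) for i in ids]

    def _phys(self, ids):
        return pd.DataFrame({"SPAD": np.arange(len(ids), dtype=float) + 30},
                            index=pd.Index(ids, name="sample_id"))

    def test_disjoint_ids_error(self):
        with pytest.raises(AlignmentError):
            sio.validate_alignment(self._spectra(["a", "b"]), self._phys(["c"]))

    def test_identical_ids_all_kept(self):
        table = sio.validate_alignment(self._spectra(["a", "b"]),
                                       self._phys(["a", "b"]))
        assert table.sample_ids == ["a", "b"] and table.dropped_ids == ()

    def test_partial_overlap_reports_dropped(self):
        table = sio.validate_alignment(
            self._spectra(["a", "b", "c", "d", "e"]),
            self._phys(["a", "b", "c"]))
        assert table.sample_ids == ["a", "b", "c"]
        assert table.dropped_ids == ("d", "e")
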