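"""Force-curve containers, calibration and text I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioafm import (Cantilever, ForceCurve, calibrate_deflection,
                       read_force_curve, tip_sample_separation,
                       write_force_curve)
from cardioafm.curves import (DataError, FormatError, Segment, StateError,
                              infer_segments)


def _simple_curve(n=100, calibrated=False):
    t = np.linspace(0, 1, n)
    z = np.linspace(0, 1e-6, n)
    d = np.linspace(0, 5e-9, n)
    kwargs = dict(force=0.2 * d, calibrated=True) if calibrated else dict(deflection=d)
    return ForceCurve(time=t, piezo_position=z,
                      segment=np.full(n, "approach", dtype=object), **kwargs)


class TestContainer:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(DataError):
            ForceCurve(time=[0.0, 1.0, 1.0], piezo_position=[0, 1, 2],
                       segment=np.array(["approach"] * 3, object),
                       deflection=[0.0, 0.0, 0.0])

    def test_non_contiguous_segment_rejected(self):
        with pytest.raises(DataError):
            ForceCurve(time=[0, 1, 2], piezo_position=[0, 1, 2],
                       segment=np.array(["approach", "retract", "approach"], object),
                       deflection=[0.0, 0.0, 0.0])

    def test_segment_extraction(self):
        n = 30
        seg = np.array(["approach"] * 10 + ["dwell"] * 10 + ["retract"] * 10, object)
        c = ForceCurve(time=np.arange(n, dtype=float),
                       piezo_position=np.r_[np.linspace(0, 1, 10), np.ones(10),
                                            np.linspace(1, 0, 10)],
                       segment=seg, deflection=np.zeros(n))
        assert len(c.extract(Segment.DWELL)) == 10
        assert c.has_segment("retract")


class TestIO:
    def test_row_count_preserved(self, tmp_path):
        # 3-column TSV with 1000 rows reads back as a 1000-sample curve
        n = 1000
        path = tmp_path / "curve.tsv"
        t = np.linspace(0, 1, n)
        z = np.linspace(0, 1e-6, n)
        d = np.zeros(n)
        lines = ["time\tpiezo_position\tdeflection"] + [
            f"{a}\t{b}\t{c}" for a, b, c in zip(t, z, d)]
        path.write_text("\n".join(lines))
        curve = read_force_curve(path)
        assert len(curve) == n

    def test_repeated_time_is_data_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time\tpiezo_position\tdeflection\n0\t0\t0\n0\t1e-9\t0\n1\t2e-9\t0\n")
        with pytest.raises(DataError):
            read_force_curve(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time\tz\n0\t0\n1\t1\n")
        with pytest.raises(FormatError):
            read_force_curve(path, columns={"piezo_position": "piezo_position"})

    def test_round_trip_preserves_arrays(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 300
        c = ForceCurve(time=np.sort(rng.random(n)) + np.arange(n) * 1e-9,
                       piezo_position=np.linspace(0, 2e-6, n),
                       segment=np.array(["approach"] * 150 + ["retract"] * 150, object),
                       deflection=rng.normal(0, 1e-9, n))
        path = tmp_path / "rt.tsv"
        write_force_curve(c, path)
        back = read_force_curve(path)
        for field in ("time", "piezo_position", "deflection"):
            a, b = getattr(c, field), getattr(back, field)
            assert np.allclose(a, b, rtol=1e-12, atol=0)
        assert list(back.segment) == list(c.segment)

    def test_comma_decimal_dialect(self, tmp_path):
        path = tmp_path / "eu.csv"
        path.write_text("time;piezo_position;deflection\n0,0;0,0;0,0\n1,5;2,5;0,5\n")
        curve = read_force_curve(path, sep=";", decimal=",")
        assert curve.time[1] == pytest.approx(1.5)
        assert curve.piezo_position[1] == pytest.approx(2.5)


class TestSegmentInference:
    def test_three_phase_motion_labelled(self):
        z = np.r_[np.linspace(0, 1e-6, 50), np.full(50, 1e-6), np.linspace(1e-6, 0, 50)]
        seg = infer_segments(z)
        assert seg[10] == "approach"
        assert seg[75] == "dwell"
        assert seg[130] == "retract"


class TestCalibration:
    def test_hookes_law(self):
        c = _simple_curve()
        cant = Cantilever(spring_constant=0.2, tip_geometry="sphere", tip_radius=1e-6)
        out = calibrate_deflection(c, cant)
        # k = 0.2 N/m at 5 nm deflection -> 1 nN
        assert out.force[-1] == pytest.approx(1e-9)
        assert out.calibrated

    def test_zero_deflection_zero_force_at_qpbioac_lower_bound(self):
        n = 50
        c = ForceCurve(time=np.arange(n, dtype=float), piezo_position=np.linspace(0, 1e-6, n),
                       segment=np.full(n, "approach", dtype=object), deflection=np.zeros(n))
        cant = Cantilever(spring_constant=0.15, tip_geometry="tipless")
        assert np.all(calibrate_deflection(c, cant).force == 0.0)

    def test_double_calibration_rejected(self):
        c = _simple_curve(calibrated=True)
        cant = Cantilever(spring_constant=1.0, tip_geometry="tipless")
        with pytest.raises(StateError):
            calibrate_deflection(c, cant)

    @settings(derandomize=True, max_examples=25)
    @given(alpha=st.floats(0.01, 100), seed=st.integers(0, 2**16))
    def test_calibration_is_linear(self, alpha, seed):
        rng = np.random.default_rng(seed)
        n = 40
        d = rng.normal(0, 1e-9, n)
        cant = Cantilever(spring_constant=0.3, tip_geometry="tipless")

        def force_of(defl):
            c = ForceCurve(time=np.arange(n, dtype=float),
                           piezo_position=np.linspace(0, 1e-6, n),
                           segment=np.full(n, "approach", dtype=object),
                           deflection=defl)
            return calibrate_deflection(c, cant).force

        np.testing.assert_allclose(force_of(alpha * d), alpha * force_of(d), rtol=1e-12)


class TestSeparation:
    def test_zero_deflection_gives_piezo(self):
        c = _simple_curve()
        c.deflection = np.zeros(len(c))
        np.testing.assert_array_equal(tip_sample_separation(c), c.piezo_position)

    def test_constant_deflection_uniform_offset(self):
        c = _simple_curve()
        c.deflection = np.full(len(c), 10e-9)
        np.testing.assert_allclose(tip_sample_separation(c),
                                   c.piezo_position - 10e-9)

    def test_samplewise_subtraction_oracle(self):
        rng = np.random.default_rng(3)
        c = _simple_curve()
        c.deflection = rng.normal(0, 1e-9, len(c))
        expected = np.array([z - d for z, d in zip(c.piezo_position, c.deflection)])
        np.testing.assert_allclose(tip_sample_separation(c), expected, rtol=0, atol=0)

    def test_contact_region_separation_below_piezo_travel(self, sphere_cantilever):
        from cardioafm.synthetic import gen_indentation_curve
        curve, _ = gen_indentation_curve(5e3, sphere_cantilever, seed=0)
        sep = tip_sample_separation(curve)
        contact = curve.force > 1e-10
        assert np.all(sep[contact] < curve.piezo_position[contact])
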