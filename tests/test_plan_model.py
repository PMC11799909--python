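"""Plan/dose/structure model, DICOM round trips, and the segment-time model."""

import numpy as np
import pydicom
import pytest

from planscope import (
    Beam,
    ControlPoint,
    DicomFormatError,
    DoseGrid,
    MachineLimits,
    Plan,
    StructureSet,
    Contour,
    ValidationError,
    read_rtdose,
    read_rtplan,
    read_rtstruct,
    segment_times,
    write_rtdose,
    write_rtplan,
    write_rtstruct,
)
from planscope.synthetic_data import SynthPlanParams, synth_plan

from conftest import make_random_beam, make_uniform_beam
from _oracles import oracle_segment_times


class TestModelInvariants:
    def test_negative_gap_rejected(self):
        with pytest.raises(ValidationError, match="gap"):
            ControlPoint(index=0, cumulative_meterset_weight=0, gantry_angle=0,
                         bank_a_positions=[0.0], bank_b_positions=[-1.0],
                         jaw_x=(-10, 10), jaw_y=(-10, 10))

    def test_non_monotonic_weights_rejected(self, uniform_beam):
        cps = uniform_beam.control_points
        cps[1].cumulative_meterset_weight = 2.0
        with pytest.raises(ValidationError):
            Beam(beam_mu=100, control_points=cps,
                 leaf_boundaries=uniform_beam.leaf_boundaries)

    def test_beam_needs_positive_mu_and_two_cps(self, uniform_beam):
        with pytest.raises(ValidationError):
            Beam(beam_mu=0, control_points=uniform_beam.control_points,
                 leaf_boundaries=uniform_beam.leaf_boundaries)
        with pytest.raises(ValidationError):
            Beam(beam_mu=10, control_points=uniform_beam.control_points[:1],
                 leaf_boundaries=uniform_beam.leaf_boundaries)

    def test_delta_mu_sums_to_beam_mu(self, small_beam):
        assert np.isclose(small_beam.delta_mu().sum(), small_beam.beam_mu,
                          rtol=1e-6)


class TestSegmentTimes:
    def test_hand_arithmetic_gantry_limited(self):
        # dgantry 2 deg, dMU 0.5, max travel 5 mm with TrueBeam limits:
        # t = max(2/4.8, 0.5/10, 5/25) = 0.41667 s.
        beam = make_uniform_beam(n_cp=2, gap=20.0, beam_mu=1.0, gantry_step=2.0)
        beam.control_points[1].bank_a_positions += 5.0
        beam.control_points[1].bank_b_positions += 5.0
        beam.beam_mu = 0.5
        t = segment_times(beam)
        assert t[0] == pytest.approx(2.0 / 4.8, abs=1e-9)

    def test_leaf_limited_segment(self):
        # travel 20 mm, gantry 1 deg, dMU 0.1 -> leaf-limited 0.8 s.
        beam = make_uniform_beam(n_cp=2, gap=25.0, beam_mu=0.1, gantry_step=1.0)
        beam.control_points[1].bank_a_positions += 20.0
        beam.control_points[1].bank_b_positions += 20.0
        assert segment_times(beam)[0] == pytest.approx(0.8)

    def test_static_segment_is_mu_limited(self):
        beam = make_uniform_beam(n_cp=2, gantry_step=0.0, beam_mu=5.0)
        assert segment_times(beam)[0] == pytest.approx(5.0 / 10.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            beam = make_random_beam(rng, n_cp=6, n_pairs=5)
            np.testing.assert_allclose(segment_times(beam),
                                       oracle_segment_times(beam), atol=1e-12)

    def test_invariant_to_arc_reversal(self, small_beam):
        t = segment_times(small_beam)
        rev = Beam(
            beam_mu=small_beam.beam_mu,
            control_points=[
                ControlPoint(
                    index=i,
                    cumulative_meterset_weight=1.0
                    - small_beam.control_points[-1 - i].cumulative_meterset_weight,
                    gantry_angle=small_beam.control_points[-1 - i].gantry_angle,
                    bank_a_positions=small_beam.control_points[-1 - i].bank_a_positions,
                    bank_b_positions=small_beam.control_points[-1 - i].bank_b_positions,
                    jaw_x=small_beam.control_points[-1 - i].jaw_x,
                    jaw_y=small_beam.control_points[-1 - i].jaw_y,
                )
                for i in range(small_beam.n_control_points)
            ],
            leaf_boundaries=small_beam.leaf_boundaries,
        )
        np.testing.assert_allclose(segment_times(rev), t[::-1], atol=1e-9)


class TestPlanRoundTrip:
    def test_two_arc_round_trip_field_equality(self, tmp_path):
        plan, _ = synth_plan(SynthPlanParams(seed=5, n_arcs=2, n_cp_per_arc=20,
                                             n_leaf_pairs=10))
        f = tmp_path / "plan.dcm"
        write_rtplan(plan, f)
        back = read_rtplan(f)
        assert len(back.beams) == 2
        assert back.prescription_dose == plan.prescription_dose
        for b0, b1 in zip(plan.beams, back.beams):
            assert b1.beam_mu == b0.beam_mu
            assert b1.arc_direction == b0.arc_direction
            np.testing.assert_array_equal(b1.leaf_boundaries, b0.leaf_boundaries)
            for c0, c1 in zip(b0.control_points, b1.control_points):
                assert c1.cumulative_meterset_weight == c0.cumulative_meterset_weight
                assert c1.gantry_angle == c0.gantry_angle
                np.testing.assert_array_equal(c1.bank_a_positions, c0.bank_a_positions)
                np.testing.assert_array_equal(c1.bank_b_positions, c0.bank_b_positions)
                assert c1.jaw_x == c0.jaw_x and c1.jaw_y == c0.jaw_y

    def test_setup_field_skipped_with_warning(self, tmp_path, caplog):
        plan, _ = synth_plan(SynthPlanParams(seed=2, n_arcs=3, n_cp_per_arc=10,
                                             n_leaf_pairs=6))
        f = tmp_path / "plan.dcm"
        write_rtplan(plan, f)
        ds = pydicom.dcmread(f)
        setup = pydicom.dataset.Dataset()   # static field without any MLC
        setup.BeamNumber = 99
        setup.BeamName = "SETUP"
        setup.ControlPointSequence = ds.BeamSequence[0].ControlPointSequence[:1]
        ds.BeamSequence.append(setup)
        f2 = tmp_path / "plan2.dcm"
        ds.save_as(f2)
        with caplog.at_level("WARNING"):
            back = read_rtplan(f2)
        assert len(back.beams) == 3
        assert any("skipping beam" in rec.message for rec in caplog.records)

    def test_decreasing_meterset_weight_rejected(self, tmp_path):
        plan, _ = synth_plan(SynthPlanParams(seed=2, n_arcs=1, n_cp_per_arc=10,
                                             n_leaf_pairs=6))
        f = tmp_path / "plan.dcm"
        write_rtplan(plan, f)
        ds = pydicom.dcmread(f)
        ds.BeamSequence[0].ControlPointSequence[5].CumulativeMetersetWeight = 0.01
        f2 = tmp_path / "bad.dcm"
        ds.save_as(f2)
        with pytest.raises(ValidationError, match="meterset"):
            read_rtplan(f2)

    def test_missing_beam_sequence_is_format_error(self, tmp_path):
        grid = DoseGrid(values=np.ones((1, 2, 2)), origin=(0, 0, 0),
                        spacing=(1, 1, 1))
        f = tmp_path / "dose.dcm"
        write_rtdose(grid, f)
        with pytest.raises(DicomFormatError, match="BeamSequence"):
            read_rtplan(f)


class TestDoseRoundTrip:
    def test_quantized_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 75, (4, 5, 6))
        values = np.round(raw / 1e-5) * 1e-5
        grid = DoseGrid(values=values, origin=(-10.0, -5.0, 0.0),
                        spacing=(2.0, 2.5, 3.0))
        f = tmp_path / "dose.dcm"
        write_rtdose(grid, f)
        back = read_rtdose(f)
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.origin == grid.origin and back.spacing == grid.spacing

    def test_uniform_grid_value_preserved(self, tmp_path):
        grid = DoseGrid(values=np.full((2, 3, 3), 2.0), origin=(0, 0, 0),
                        spacing=(1, 1, 1))
        f = tmp_path / "dose.dcm"
        write_rtdose(grid, f)
        assert np.all(read_rtdose(f).values == 2.0)

    def test_single_voxel_grid(self, tmp_path):
        grid = DoseGrid(values=np.array([[[1.5]]]), origin=(0, 0, 0),
                        spacing=(1, 1, 1))
        f = tmp_path / "dose.dcm"
        write_rtdose(grid, f)
        # Unquantized input: preserved to within the scaling quantum.
        assert abs(read_rtdose(f).values[0, 0, 0] - 1.5) <= 1e-5

    def test_irregular_frame_offsets_rejected(self, tmp_path):
        grid = DoseGrid(values=np.ones((3, 2, 2)), origin=(0, 0, 0),
                        spacing=(1, 1, 1))
        f = tmp_path / "dose.dcm"
        write_rtdose(grid, f)
        ds = pydicom.dcmread(f)
        ds.GridFrameOffsetVector = [0.0, 1.0, 3.0]
        f2 = tmp_path / "bad.dcm"
        ds.save_as(f2)
        with pytest.raises(DicomFormatError, match="GridFrameOffsetVector"):
            read_rtdose(f2)

    def test_missing_scaling_is_format_error(self, tmp_path):
        grid = DoseGrid(values=np.ones((1, 2, 2)), origin=(0, 0, 0),
                        spacing=(1, 1, 1))
        f = tmp_path / "dose.dcm"
        write_rtdose(grid, f)
        ds = pydicom.dcmread(f)
        del ds.DoseGridScaling
        f2 = tmp_path / "bad.dcm"
        ds.save_as(f2)
        with pytest.raises(DicomFormatError, match="DoseGridScaling"):
            read_rtdose(f2)


class TestStructRoundTrip:
    @staticmethod
    def _square(z, side=20.0):
        s = side / 2
        return Contour(z=z, vertices=[(-s, -s), (s, -s), (s, s), (-s, s)])

    def test_round_trip_and_z_sorting(self, tmp_path):
        ss = StructureSet(structures={
            "PTV": [self._square(4.0), self._square(0.0), self._square(2.0)]})
        f = tmp_path / "rs.dcm"
        write_rtstruct(ss, f)
        back = read_rtstruct(f)
        zs = [c.z for c in back.structures["PTV"]]
        assert zs == sorted(zs) and len(zs) == 3
        np.testing.assert_array_equal(back.structures["PTV"][0].vertices,
                                      ss.structures["PTV"][0].vertices)

    def test_empty_structure_flagged(self, tmp_path):
        ss = StructureSet(structures={"PTV": [self._square(0.0)], "Chiasm": []})
        f = tmp_path / "rs.dcm"
        write_rtstruct(ss, f)
        back = read_rtstruct(f)
        assert back.empty_structures == ["Chiasm"]

    def test_duplicate_names_deduplicated(self, tmp_path, caplog):
        ss = StructureSet(structures={"PTV": [self._square(0.0)]})
        f = tmp_path / "rs.dcm"
        write_rtstruct(ss, f)
        ds = pydicom.dcmread(f)
        import copy
        roi = copy.deepcopy(ds.StructureSetROISequence[0])
        roi.ROINumber = 2
        ds.StructureSetROISequence.append(roi)
        rc = copy.deepcopy(ds.ROIContourSequence[0])
        rc.ReferencedROINumber = 2
        ds.ROIContourSequence.append(rc)
        f2 = tmp_path / "dup.dcm"
        ds.save_as(f2)
        with caplog.at_level("WARNING"):
            back = read_rtstruct(f2)
        assert set(back.names()) == {"PTV", "PTV_2"}

    def test_explicit_closure_normalized(self):
        c = Contour(z=0.0, vertices=[(0, 0), (1, 0), (1, 1), (0, 0)])
        assert len(c.vertices) == 3
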