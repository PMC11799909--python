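"""In-memory model of DICOM-RT treatment plans, dose grids and structure sets.

The model keeps only what downstream analysis consumes: the per-control-point
mechanical state of each VMAT arc (MLC bank positions, jaws, gantry angle,
cumulative meterset weight), the 3D dose array with its grid geometry, and the
planar contours of each delineated structure.  Readers accept DICOM RT Plan /
RT Dose / RT Structure Set files (MLCX-type linacs, one fraction group);
writers emit files the readers round-trip losslessly, which is how synthetic
fixtures exercise the I/O path and the maths through the same objects.

Coordinates follow IEC 61217: leaf tips travel on the IEC-X axis, leaf-pair
boundaries live on IEC-Y, and the pair gap is ``bank_b - bank_a >= 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

logger = logging.getLogger(__name__)

#: Tolerated float noise on the gap non-negativity check, mm.
INTERDIGITATION_TOLERANCE = 0.01

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


class PlanscopeError(Exception):
    """Base class for all package errors."""


class DicomFormatError(PlanscopeError):
    """Input file lacks a required DICOM attribute or uses an unsupported dialect."""


class ValidationError(PlanscopeError):
    """An object violates a model invariant."""


class ParameterError(PlanscopeError):
    """Infeasible or inconsistent user parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MachineLimits:
    """Linac delivery limits bounding segment duration.

    Defaults are typical for a Varian TrueBeam: 4.8 deg/s gantry, 600 MU/min
    maximum dose rate, 25 mm/s leaf speed.
    """

    max_gantry_speed: float = 4.8   # deg/s
    max_dose_rate: float = 600.0    # MU/min
    max_leaf_speed: float = 25.0    # mm/s

    def __post_init__(self) -> None:
        if min(self.max_gantry_speed, self.max_dose_rate, self.max_leaf_speed) <= 0:
            raise ValidationError("machine limits must all be positive")


@dataclass
class ControlPoint:
    """One sampled machine state of an arc."""

    index: int
    cumulative_meterset_weight: float      # fraction of beam MU in [0, 1]
    gantry_angle: float                    # deg, [0, 360)
    bank_a_positions: np.ndarray           # mm, IEC-X, one tip per leaf pair
    bank_b_positions: np.ndarray           # mm, IEC-X
    jaw_x: tuple[float, float]             # (x1, x2) mm
    jaw_y: tuple[float, float]             # (y1, y2) mm

    def __post_init__(self) -> None:
        self.bank_a_positions = np.asarray(self.bank_a_positions, dtype=float)
        self.bank_b_positions = np.asarray(self.bank_b_positions, dtype=float)
        if self.bank_a_positions.shape != self.bank_b_positions.shape:
            raise ValidationError("leaf banks must have equal length")
        gap = self.bank_b_positions - self.bank_a_positions
        if np.any(gap < -INTERDIGITATION_TOLERANCE):
            raise ValidationError(
                f"negative leaf gap at control point {self.index}: min {gap.min():.3f} mm"
            )

    @property
    def n_leaf_pairs(self) -> int:
        return self.bank_a_positions.size

    @property
    def gaps(self) -> np.ndarray:
        return self.bank_b_positions - self.bank_a_positions


@dataclass
class Beam:
    """One VMAT arc: monitor units plus the ordered control-point sequence."""

    beam_mu: float
    control_points: list[ControlPoint]
    leaf_boundaries: np.ndarray            # n_leaf_pairs + 1 edges, mm, IEC-Y
    arc_direction: str = "CW"              # CW | CCW
    machine_limits: MachineLimits = field(default_factory=MachineLimits)
    name: str = ""

    def __post_init__(self) -> None:
        self.leaf_boundaries = np.asarray(self.leaf_boundaries, dtype=float)
        if self.beam_mu <= 0:
            raise ValidationError("beam_mu must be > 0")
        if len(self.control_points) < 2:
            raise ValidationError("a beam needs at least 2 control points")
        if np.any(np.diff(self.leaf_boundaries) <= 0):
            raise ValidationError("leaf widths must all be positive")
        n_pairs = self.leaf_boundaries.size - 1
        weights = [cp.cumulative_meterset_weight for cp in self.control_points]
        if np.any(np.diff(weights) < 0):
            raise ValidationError("cumulative meterset weight must be non-decreasing")
        if abs(weights[0]) > 1e-6 or abs(weights[-1] - 1.0) > 1e-6:
            raise ValidationError("cumulative meterset weight must run from 0 to 1")
        for cp in self.control_points:
            if cp.n_leaf_pairs != n_pairs:
                raise ValidationError("control point leaf count does not match boundaries")

    @property
    def n_leaf_pairs(self) -> int:
        return self.leaf_boundaries.size - 1

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    @property
    def leaf_widths(self) -> np.ndarray:
        return np.diff(self.leaf_boundaries)

    def delta_mu(self) -> np.ndarray:
        """Monitor units delivered in each of the n_cp - 1 segments."""
        w = np.array([cp.cumulative_meterset_weight for cp in self.control_points])
        return np.diff(w) * self.beam_mu


@dataclass
class Plan:
    """A treatment plan: one or more arcs plus the prescription."""

    plan_id: str
    beams: list[Beam]
    prescription_dose: float               # Gy, total over all fractions
    n_fractions: int = 33

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValidationError("a plan needs at least one beam")
        if self.prescription_dose <= 0:
            raise ValidationError("prescription_dose must be > 0")


@dataclass
class DoseGrid:
    """3D dose array in Gy on a regular grid; axes ordered (z, y, x)."""

    values: np.ndarray
    origin: tuple[float, float, float]     # (x0, y0, z0) mm of voxel (0,0,0) center
    spacing: tuple[float, float, float]    # (dx, dy, dz) mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("dose values must be a 3D array ordered (z, y, x)")
        if min(self.spacing) <= 0:
            raise ValidationError("grid spacing must be positive")
        if np.any(self.values < 0):
            raise ValidationError("dose values must be non-negative")

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def z_coords(self) -> np.ndarray:
        return self.origin[2] + self.spacing[2] * np.arange(self.values.shape[0])

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[1])

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[2])


@dataclass
class Contour:
    """One closed planar polygon at a fixed slice z (vertices in mm, not repeated)."""

    z: float
    vertices: np.ndarray                   # (n, 2) array of (x, y) mm

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        # Normalize explicit closure: drop a repeated last vertex.
        if len(self.vertices) > 1 and np.array_equal(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise ValidationError("a contour needs at least 3 vertices")


@dataclass
class StructureSet:
    """Named structures, each a list of planar contours sorted by z."""

    structures: dict[str, list[Contour]]
    empty_structures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for contours in self.structures.values():
            contours.sort(key=lambda c: c.z)

    def names(self) -> list[str]:
        return list(self.structures)


# ---------------------------------------------------------------------------
# Segment-time model
# ---------------------------------------------------------------------------


def gantry_deltas(angles: np.ndarray) -> np.ndarray:
    """Absolute shortest-arc gantry rotation between successive control points, deg."""
    d = np.diff(np.asarray(angles, dtype=float))
    d = (d + 180.0) % 360.0 - 180.0
    return np.abs(d)


def segment_times(beam: Beam, machine_limits: MachineLimits | None = None) -> np.ndarray:
    """Per-segment delivery duration in seconds (length n_cp - 1).

    DICOM VMAT plans carry no timestamps, so each segment's duration is the
    longest of its three mechanical bottlenecks::

        t_i = max( |dgantry_i| / v_gantry,
                   dMU_i / (max_dose_rate / 60),
                   max_leaf |dx| / v_leaf )

    A fully static segment (no gantry, leaf or MU change) has t_i = dMU_i
    divided by the maximum dose rate, i.e. zero.
    """
    limits = machine_limits or beam.machine_limits
    angles = np.array([cp.gantry_angle for cp in beam.control_points])
    t_gantry = gantry_deltas(angles) / limits.max_gantry_speed
    t_mu = beam.delta_mu() / (limits.max_dose_rate / 60.0)
    a = np.stack([cp.bank_a_positions for cp in beam.control_points])
    b = np.stack([cp.bank_b_positions for cp in beam.control_points])
    travel = np.maximum(np.abs(np.diff(a, axis=0)), np.abs(np.diff(b, axis=0)))
    max_travel = travel.max(axis=1)
    t = np.maximum(np.maximum(t_gantry, t_mu), max_travel / limits.max_leaf_speed)
    if np.any((t <= 0) & (max_travel > 0)):
        raise ValidationError("zero-duration segment with nonzero leaf travel")
    return t


# ---------------------------------------------------------------------------
# DICOM helpers
# ---------------------------------------------------------------------------


def _file_dataset(sop_class: str, modality: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "SYNTHETIC^PLANSCOPE"
    ds.PatientID = "SYNTH000"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    return ds


def _require(ds: Dataset, attr: str) -> object:
    if attr not in ds:
        raise DicomFormatError(f"missing required DICOM attribute {attr}")
    return getattr(ds, attr)


# ---------------------------------------------------------------------------
# RT Plan I/O
# ---------------------------------------------------------------------------


def read_rtplan(path) -> Plan:
    """Read a DICOM RT Plan into a :class:`Plan`.

    Setup or static beams that carry no MLC position sequence are skipped with
    a warning.  Cumulative meterset weights are normalized so the final value
    of each retained beam is exactly 1.
    """
    ds = pydicom.dcmread(path, force=True)
    beam_seq = _require(ds, "BeamSequence")
    mu_by_number: dict[int, float] = {}
    if "FractionGroupSequence" in ds:
        for fg in ds.FractionGroupSequence:
            for rb in getattr(fg, "ReferencedBeamSequence", []):
                if "BeamMeterset" in rb:
                    mu_by_number[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams: list[Beam] = []
    for beam_ds in beam_seq:
        if "ControlPointSequence" not in beam_ds:
            raise DicomFormatError("missing required DICOM attribute ControlPointSequence")
        boundaries = None
        for dev in getattr(beam_ds, "BeamLimitingDeviceSequence", []):
            if dev.RTBeamLimitingDeviceType == "MLCX":
                boundaries = np.array([float(v) for v in dev.LeafPositionBoundaries])
        has_mlc = any(
            getattr(d, "RTBeamLimitingDeviceType", "") == "MLCX"
            for cp in beam_ds.ControlPointSequence
            for d in getattr(cp, "BeamLimitingDevicePositionSequence", [])
        )
        if boundaries is None or not has_mlc:
            logger.warning(
                "skipping beam %s: no MLCX sequence (setup/static field?)",
                getattr(beam_ds, "BeamName", getattr(beam_ds, "BeamNumber", "?")),
            )
            continue
        n_pairs = boundaries.size - 1

        cps: list[ControlPoint] = []
        jaw_x = (-200.0, 200.0)
        jaw_y = (-200.0, 200.0)
        gantry = 0.0
        direction = "CW"
        for i, cp_ds in enumerate(beam_ds.ControlPointSequence):
            if "GantryAngle" in cp_ds:
                gantry = float(cp_ds.GantryAngle)
            if getattr(cp_ds, "GantryRotationDirection", "NONE") in ("CW", "CC"):
                direction = "CW" if cp_ds.GantryRotationDirection == "CW" else "CCW"
            bank_a = bank_b = None
            for dev in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
                pos = [float(v) for v in dev.LeafJawPositions]
                kind = dev.RTBeamLimitingDeviceType
                if kind == "MLCX":
                    bank_a = np.array(pos[:n_pairs])
                    bank_b = np.array(pos[n_pairs:])
                elif kind in ("X", "ASYMX"):
                    jaw_x = (pos[0], pos[1])
                elif kind in ("Y", "ASYMY"):
                    jaw_y = (pos[0], pos[1])
            if bank_a is None:
                if not cps:
                    raise DicomFormatError("first control point lacks MLCX positions")
                bank_a = cps[-1].bank_a_positions.copy()
                bank_b = cps[-1].bank_b_positions.copy()
            cps.append(
                ControlPoint(
                    index=i,
                    cumulative_meterset_weight=float(cp_ds.CumulativeMetersetWeight),
                    gantry_angle=gantry,
                    bank_a_positions=bank_a,
                    bank_b_positions=bank_b,
                    jaw_x=jaw_x,
                    jaw_y=jaw_y,
                )
            )

        weights = np.array([cp.cumulative_meterset_weight for cp in cps])
        if np.any(np.diff(weights) < 0):
            raise ValidationError(
                f"non-monotonic cumulative meterset weight in beam "
                f"{getattr(beam_ds, 'BeamNumber', '?')}"
            )
        final = weights[-1]
        if final <= 0:
            raise ValidationError("final cumulative meterset weight must be positive")
        for cp in cps:
            cp.cumulative_meterset_weight = cp.cumulative_meterset_weight / final

        mu = mu_by_number.get(int(getattr(beam_ds, "BeamNumber", -1)), 0.0)
        if mu <= 0:
            mu = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", 0)) or 100.0
        beams.append(
            Beam(
                beam_mu=mu,
                control_points=cps,
                leaf_boundaries=boundaries,
                arc_direction=direction,
                name=str(getattr(beam_ds, "BeamName", "")),
            )
        )

    if not beams:
        raise DicomFormatError("no arc beam with an MLCX sequence found")

    rx = 70.0
    n_fx = 33
    if "DoseReferenceSequence" in ds:
        for dr in ds.DoseReferenceSequence:
            if "TargetPrescriptionDose" in dr:
                rx = float(dr.TargetPrescriptionDose)
    if "FractionGroupSequence" in ds and "NumberOfFractionsPlanned" in ds.FractionGroupSequence[0]:
        n_fx = int(ds.FractionGroupSequence[0].NumberOfFractionsPlanned)
    return Plan(
        plan_id=str(getattr(ds, "RTPlanLabel", "plan")),
        beams=beams,
        prescription_dose=rx,
        n_fractions=n_fx,
    )


def write_rtplan(plan: Plan, path) -> None:
    """Write a :class:`Plan` as a DICOM RT Plan re-readable by :func:`read_rtplan`."""
    ds = _file_dataset(RTPLAN_SOP_CLASS, "RTPLAN")
    ds.RTPlanLabel = plan.plan_id
    ds.RTPlanGeometry = "PATIENT"

    dr = Dataset()
    dr.DoseReferenceNumber = 1
    dr.DoseReferenceStructureType = "SITE"
    dr.DoseReferenceType = "TARGET"
    dr.TargetPrescriptionDose = plan.prescription_dose
    ds.DoseReferenceSequence = [dr]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = plan.n_fractions
    fg.NumberOfBeams = len(plan.beams)
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for num, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = num
        rb.BeamMeterset = beam.beam_mu
        fg.ReferencedBeamSequence.append(rb)

        b = Dataset()
        b.BeamNumber = num
        b.BeamName = beam.name or f"Arc{num}"
        b.BeamType = "DYNAMIC"
        b.RadiationType = "PHOTON"
        b.TreatmentDeliveryType = "TREATMENT"
        b.NumberOfControlPoints = beam.n_control_points
        b.FinalCumulativeMetersetWeight = 1.0

        dev = Dataset()
        dev.RTBeamLimitingDeviceType = "MLCX"
        dev.NumberOfLeafJawPairs = beam.n_leaf_pairs
        dev.LeafPositionBoundaries = [float(v) for v in beam.leaf_boundaries]
        b.BeamLimitingDeviceSequence = [dev]

        b.ControlPointSequence = []
        for cp in beam.control_points:
            c = Dataset()
            c.ControlPointIndex = cp.index
            c.CumulativeMetersetWeight = cp.cumulative_meterset_weight
            c.GantryAngle = cp.gantry_angle
            c.GantryRotationDirection = "CW" if beam.arc_direction == "CW" else "CC"
            positions = []
            jx = Dataset()
            jx.RTBeamLimitingDeviceType = "ASYMX"
            jx.LeafJawPositions = [float(cp.jaw_x[0]), float(cp.jaw_x[1])]
            jy = Dataset()
            jy.RTBeamLimitingDeviceType = "ASYMY"
            jy.LeafJawPositions = [float(cp.jaw_y[0]), float(cp.jaw_y[1])]
            mlc = Dataset()
            mlc.RTBeamLimitingDeviceType = "MLCX"
            mlc.LeafJawPositions = [float(v) for v in cp.bank_a_positions] + [
                float(v) for v in cp.bank_b_positions
            ]
            positions = [jx, jy, mlc] if cp.index == 0 else [mlc]
            c.BeamLimitingDevicePositionSequence = positions
            b.ControlPointSequence.append(c)
        ds.BeamSequence.append(b)

    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# RT Dose I/O
# ---------------------------------------------------------------------------


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose into a :class:`DoseGrid` (values in Gy)."""
    ds = pydicom.dcmread(path, force=True)
    scaling = float(_require(ds, "DoseGridScaling"))
    raw = ds.pixel_array.astype(np.float64)
    if raw.ndim == 2:
        raw = raw[np.newaxis, :, :]
    ipp = [float(v) for v in _require(ds, "ImagePositionPatient")]
    dy, dx = (float(v) for v in _require(ds, "PixelSpacing"))
    offsets = np.atleast_1d(np.asarray(_require(ds, "GridFrameOffsetVector"),
                                       dtype=float))
    if offsets.size > 1:
        dzs = np.diff(offsets)
        if np.any(dzs <= 0) or np.ptp(dzs) > 1e-6:
            raise DicomFormatError(
                "non-uniform GridFrameOffsetVector spacing is not supported"
            )
        dz = float(dzs[0])
    else:
        dz = 1.0
    return DoseGrid(
        values=raw * scaling,
        origin=(ipp[0], ipp[1], ipp[2] + offsets[0]),
        spacing=(dx, dy, dz),
    )


def write_rtdose(grid: DoseGrid, path, scaling: float = 1e-5) -> None:
    """Write a :class:`DoseGrid` as DICOM RT Dose (uint32 pixels x ``scaling`` Gy)."""
    ints = np.round(grid.values / scaling)
    if np.any(ints >= 2**32):
        raise ValidationError("dose exceeds the uint32 range at this scaling")
    ds = _file_dataset(RTDOSE_SOP_CLASS, "RTDOSE")
    nz, ny, nx = grid.values.shape
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], grid.origin[2]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [grid.spacing[2] * k for k in range(nz)]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.PixelData = ints.astype("<u4").tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# RT Structure Set I/O
# ---------------------------------------------------------------------------


def read_rtstruct(path) -> StructureSet:
    """Read a DICOM RT Structure Set; names kept verbatim, contours sorted by z.

    Structures with no contour data are retained and listed in
    ``empty_structures``; duplicated ROI names are deduplicated with a numeric
    suffix (a warning is logged).
    """
    ds = pydicom.dcmread(path, force=True)
    roi_names: dict[int, str] = {}
    seen: dict[str, int] = {}
    for roi in _require(ds, "StructureSetROISequence"):
        name = str(roi.ROIName)
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            logger.warning("duplicated ROI name %r renamed to %r", name, new)
            name = new
        else:
            seen[name] = 1
        roi_names[int(roi.ROINumber)] = name

    structures: dict[str, list[Contour]] = {}
    empty: list[str] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        name = roi_names.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        contours: list[Contour] = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours.append(Contour(z=float(data[0, 2]), vertices=data[:, :2]))
        structures[name] = contours
        if not contours:
            empty.append(name)
    for num, name in roi_names.items():
        if name not in structures:
            structures[name] = []
            empty.append(name)
    return StructureSet(structures=structures, empty_structures=empty)


def write_rtstruct(ss: StructureSet, path) -> None:
    """Write a :class:`StructureSet` as DICOM RT Structure Set."""
    ds = _file_dataset(RTSTRUCT_SOP_CLASS, "RTSTRUCT")
    ds.StructureSetLabel = "synthetic"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    frame_uid = generate_uid()
    ds.ReferencedFrameOfReferenceSequence = []
    for num, (name, contours) in enumerate(ss.structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for contour in contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(contour.vertices)
            data: list[float] = []
            for x, y in contour.vertices:
                data.extend([float(x), float(y), float(contour.z)])
            c.ContourData = data
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)
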