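"""2D gamma-index comparison of dose images.

The gamma index combines a dose-difference criterion (percent of the global
maximum of the reference image) with a distance-to-agreement criterion (mm):
a reference point passes when some nearby point of the evaluated image agrees
within the combined ellipsoid, gamma <= 1.  Typical portal-dosimetry criteria
are 3%/2 mm, 2%/2 mm and 1%/1 mm, each with a 10% low-dose threshold below
which reference pixels are excluded from the analysis.

Conventions: global normalization to the reference maximum; the threshold
applies to reference pixels only; the evaluated image is sampled by bilinear
interpolation on a search disc of radius 3 x DTA at a step of DTA/10 (both
configurable).  Images are compared in millimetre coordinates anchored at
pixel (0, 0), so differing pixel spacings are handled by the interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .plan_model import ParameterError, ValidationError


@dataclass(frozen=True)
class GammaCriterion:
    """One gamma criterion: dose difference %, DTA mm, low-dose threshold %."""

    dose_diff: float            # % of max reference dose
    dta: float                  # mm
    threshold: float = 10.0     # % of max reference dose
    normalization: str = "global"

    def __post_init__(self) -> None:
        if min(self.dose_diff, self.dta, self.threshold) <= 0:
            raise ValidationError("gamma criterion components must be positive")
        if self.normalization != "global":
            raise ParameterError("only global normalization is supported")

    def label(self) -> str:
        return f"{self.dose_diff:g}%/{self.dta:g}mm"


#: The three standard portal-dosimetry criteria, all at a 10% threshold.
STANDARD_CRITERIA = [
    GammaCriterion(3.0, 2.0),
    GammaCriterion(2.0, 2.0),
    GammaCriterion(1.0, 1.0),
]


@dataclass
class DoseImage:
    """2D dose image with pixel spacing (dy, dx) in mm; row 0 / col 0 at origin."""

    values: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("a dose image must be 2D")
        if min(self.spacing) <= 0:
            raise ValidationError("pixel spacing must be positive")
        if np.any(self.values < 0):
            raise ValidationError("dose values must be non-negative")


@dataclass
class GammaResult:
    gamma: np.ndarray           # per-pixel gamma, NaN below threshold
    passing_rate: float         # % of evaluated pixels with gamma <= 1
    n_evaluated: int
    criterion: GammaCriterion


def gamma_map(
    reference: DoseImage,
    evaluated: DoseImage,
    criterion: GammaCriterion,
    search_radius_factor: float = 3.0,
    step_fraction: float = 0.1,
) -> GammaResult:
    """Gamma map and passing rate for one (reference, evaluated) pair.

    For each reference pixel at or above the threshold,
    ``gamma = min over the search disc of sqrt((dD/DD)^2 + (r/DTA)^2)``,
    with dD the dose difference to the bilinearly interpolated evaluated
    image and DD the dose-difference criterion as an absolute dose.
    Offsets are visited by increasing radius so the search stops as soon as
    the spatial term alone exceeds every pixel's current minimum.
    """
    ref = reference.values
    max_ref = ref.max()
    if max_ref <= 0:
        raise ParameterError("reference image is empty (max dose is zero)")
    if evaluated.values.max() <= 0:
        raise ParameterError("evaluated image is empty (max dose is zero)")

    dd_abs = criterion.dose_diff / 100.0 * max_ref
    dta = criterion.dta
    eval_mask = ref >= criterion.threshold / 100.0 * max_ref
    n_eval = int(eval_mask.sum())
    if n_eval == 0:
        raise ParameterError("no reference pixel above the dose threshold")

    # Reference pixel positions in mm.
    ny, nx = ref.shape
    yy, xx = np.nonzero(eval_mask)
    ref_y_mm = yy * reference.spacing[0]
    ref_x_mm = xx * reference.spacing[1]
    ref_dose = ref[eval_mask]

    # Search offsets, sorted by radius.
    step = dta * step_fraction
    radius = dta * search_radius_factor
    n_off = int(np.floor(radius / step))
    axis = np.arange(-n_off, n_off + 1) * step
    oy, ox = np.meshgrid(axis, axis, indexing="ij")
    r2 = oy**2 + ox**2
    keep = r2 <= radius**2 + 1e-12
    offsets = np.column_stack([oy[keep], ox[keep], r2[keep]])
    offsets = offsets[np.argsort(offsets[:, 2], kind="stable")]

    gamma2 = np.full(n_eval, np.inf)
    ey_sp, ex_sp = evaluated.spacing
    for off_y, off_x, off_r2 in offsets:
        spatial = off_r2 / dta**2
        if spatial >= gamma2.max():
            break
        coords = np.vstack([(ref_y_mm + off_y) / ey_sp, (ref_x_mm + off_x) / ex_sp])
        sampled = map_coordinates(evaluated.values, coords, order=1, mode="nearest")
        cand = ((sampled - ref_dose) / dd_abs) ** 2 + spatial
        np.minimum(gamma2, cand, out=gamma2)

    gamma_flat = np.sqrt(gamma2)
    gmap = np.full(ref.shape, np.nan)
    gmap[eval_mask] = gamma_flat
    rate = 100.0 * float(np.count_nonzero(gamma_flat <= 1.0)) / n_eval
    return GammaResult(gamma=gmap, passing_rate=rate, n_evaluated=n_eval,
                       criterion=criterion)


def passing_rate_table(
    pairs: list[tuple[DoseImage, DoseImage]],
    criteria: list[GammaCriterion] | None = None,
) -> dict:
    """Per-criterion passing rates for a list of image pairs plus summaries.

    Returns ``{label: {"rates": [...], "max", "min", "mean", "sd", "n"}}``;
    the sample SD is reported as 0 for a single pair (flagged ``n: 1``).
    """
    if not pairs:
        raise ParameterError("at least one image pair is required")
    criteria = criteria or STANDARD_CRITERIA
    table: dict = {}
    for crit in criteria:
        rates = [gamma_map(ref, ev, crit).passing_rate for ref, ev in pairs]
        arr = np.array(rates)
        table[crit.label()] = {
            "rates": rates,
            "max": float(arr.max()),
            "min": float(arr.min()),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size),
        }
    return table


# ---------------------------------------------------------------------------
# Plain-text grid I/O (2-line header: "nx ny" then "dx dy", then rows)
# ---------------------------------------------------------------------------


def read_dose_image(path) -> DoseImage:
    """Read a dose image from the plain-text grid format or DICOM RT Dose."""
    path = str(path)
    if path.lower().endswith(".dcm"):
        from .plan_model import read_rtdose

        grid = read_rtdose(path)
        if grid.values.shape[0] != 1:
            raise ParameterError("expected a single-frame 2D RT Dose")
        return DoseImage(values=grid.values[0],
                         spacing=(grid.spacing[1], grid.spacing[0]))
    with open(path) as fh:
        nx, ny = (int(v) for v in fh.readline().split())
        dx, dy = (float(v) for v in fh.readline().split())
        values = np.loadtxt(fh)
    values = values.reshape(ny, nx)
    return DoseImage(values=values, spacing=(dy, dx))


def write_dose_image(image: DoseImage, path) -> None:
    ny, nx = image.values.shape
    with open(path, "w") as fh:
        fh.write(f"{nx} {ny}\n")
        fh.write(f"{image.spacing[1]:g} {image.spacing[0]:g}\n")
        np.savetxt(fh, image.values, fmt="%.8g")
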