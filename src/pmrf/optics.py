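"""Paraxial ABCD ray tracing of the folded, polarization-split detection path.

The detection arm of the microscope relays the water-immersion detection
objective (obj1) through a tube lens (L4) and a pupil lens (L5) onto a remote
air objective (obj2).  A polarizing beam splitter (PBS) splits the fluorescence
into S and P components that are launched at a small angle ``theta`` toward
obj2; a small mirror near obj2's focal plane reflects them back so that a
single voice-coil actuator scans the focal plane (pupil-matched remote
focusing).  For paraxial purposes the mirror fold is unfolded: the remote
module appears twice in the element sequence (forward and backward pass) and
the mirror travel becomes a variable gap between the two copies of obj2.

Rays are represented by the reduced-angle state ``[n*alpha, y]`` (radians
weighted by the local refractive index, and transverse position in mm) and
propagate by left-multiplication with 2x2 unimodular matrices.  The medium is
water (n = 1.33) up to and including the detection objective and air
afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ParaxialRay",
    "ABCDElement",
    "DetectionPathModel",
    "RayTraceResult",
    "effective_focal_length",
    "make_translation",
    "make_thin_lens",
    "make_fold",
    "propagate_ray",
    "transfer_matrix",
    "build_detection_model",
    "trace_field",
    "magnification_vs_scan",
    "collection_efficiency",
    "select_theta",
    "fit_gap_to_measurements",
    "fit_s1_to_magnification",
]


# --------------------------------------------------------------------------
# elementary types and matrices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParaxialRay:
    """Paraxial ray state: reduced angle ``n*alpha`` (rad) and height y (mm)."""

    reduced_angle: float
    height: float

    def __post_init__(self):
        if not (math.isfinite(self.reduced_angle) and math.isfinite(self.height)):
            raise ValueError("ray state must be finite")

    def as_vector(self) -> np.ndarray:
        return np.array([self.reduced_angle, self.height], dtype=float)


@dataclass(frozen=True)
class ABCDElement:
    """One element of the optical train.

    ``matrix`` acts on ``[n*alpha, y]`` by left multiplication.  ``kind`` is
    one of ``"translation"``, ``"thin_lens"`` or ``"fold"``; a fold is a
    bookkeeping rotation of the working coordinate frame (identity on the
    reduced ray state), carried so exported ray polylines can be mapped back
    to laboratory coordinates.
    """

    matrix: np.ndarray
    kind: str
    d: float = 0.0
    f: float | None = None
    n: float = 1.0
    fold_angle: float | None = None
    label: str = ""


def effective_focal_length(f_tube: float, m_obj: float, n: float) -> float:
    """Effective focal length of an infinity-corrected immersion objective.

    ``f_obj = f_tube * n / M_obj`` with the designed tube-lens focal length
    ``f_tube`` (mm), the objective magnification ``M_obj`` and the immersion
    index ``n``.  For the 40x/0.8 water objective used with a 200 mm design
    tube lens this gives 6.65 mm.
    """
    if f_tube <= 0 or m_obj <= 0 or n <= 0:
        raise ValueError("f_tube, M_obj and n must all be positive")
    return f_tube * n / m_obj


def make_translation(d: float, n: float = 1.0, label: str = "") -> ABCDElement:
    """Free-space translation over distance d (mm) in a medium of index n."""
    if n <= 0:
        raise ValueError("refractive index must be positive")
    m = np.array([[1.0, 0.0], [d / n, 1.0]])
    return ABCDElement(matrix=m, kind="translation", d=d, n=n, label=label)


def make_thin_lens(f: float, n: float = 1.0, label: str = "") -> ABCDElement:
    """Thin lens of focal length f (mm) in a medium of index n."""
    if f == 0:
        raise ValueError("focal length must be nonzero")
    m = np.array([[1.0, -n / f], [0.0, 1.0]])
    return ABCDElement(matrix=m, kind="thin_lens", f=f, n=n, label=label)


def make_fold(angle_deg: float, label: str = "") -> ABCDElement:
    """Fold of the optical axis by ``angle_deg``.

    Paraxial ABCD propagation is invariant under unfolding, so the ray state
    is unchanged; the rotation is recorded for coordinate bookkeeping only.
    """
    return ABCDElement(matrix=np.eye(2), kind="fold", fold_angle=angle_deg,
                       label=label)


def transfer_matrix(elements) -> np.ndarray:
    """Composed system matrix (left-multiplication in element order)."""
    m = np.eye(2)
    for el in elements:
        m = el.matrix @ m
    return m


def propagate_ray(ray: ParaxialRay, elements) -> ParaxialRay:
    """Propagate a ray through an ordered element sequence."""
    u, y = transfer_matrix(elements) @ ray.as_vector()
    return ParaxialRay(reduced_angle=float(u), height=float(y))


# --------------------------------------------------------------------------
# detection-path model
# --------------------------------------------------------------------------

#: Catalogue design values of the detection path.
DESIGN_PRESET = dict(
    f_tube_design=200.0,   # design tube-lens focal length of obj1 (mm)
    m_obj=40.0,            # obj1 magnification
    n_water=1.33,
    f_l4=200.0,            # tube lens (mm)
    f_l5=300.0,            # pupil relay lens (mm)
    f_obj2=10.0,           # remote objective effective focal length (mm)
    f_l6=300.0,            # camera tube lens (mm, not traced to by default)
    na_obj=0.8,
    na_obj2=0.75,
    theta_deg=8.0,         # S/P launch angle at obj2
)

#: Gaps of the as-built (non-4f) system.  Only d1 (~100 mm obj1-to-L4) and the
#: PBS-to-obj2 distance (~500 mm) are known design values; the L5-to-PBS
#: distance is an
#: estimate.  S1 = 6.695 mm is the calibrated object distance.
AS_BUILT_GAPS = dict(
    s1=6.695,
    d1=100.0,              # obj1 -> L4, ~100 mm on the instrument
    l4_l5=500.0,           # 4f-nominal
    l5_pbs=150.0,          # estimated
    pbs_obj2=500.0,        # ~500 mm on the instrument
    s3=20.0,               # de-scanned image distance, estimated
)


@dataclass
class DetectionPathModel:
    """Folded pmRF detection-path geometry, unfolded for ABCD algebra.

    The element sequence runs object -> obj1 -> L4 -> L5 -> PBS fold -> obj2
    -> (mirror gap, twice the mirror-to-obj2 focus distance) -> obj2 -> image
    plane at distance ``s3``.  The remote module appears twice to model the
    forward and backward pass.
    """

    f_tube_design: float
    m_obj: float
    n_water: float
    f_obj: float
    f_l4: float
    f_l5: float
    f_obj2: float
    f_l6: float
    na_obj: float
    na_obj2: float
    theta_deg: float
    s1: float
    d1: float
    gap_l4_l5: float
    gap_l5_pbs: float
    gap_pbs_obj2: float
    mirror_gap: float
    delta_l: float
    s3: float = math.inf
    all_4f: bool = False

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta_deg)

    @property
    def f_obj_air(self) -> float:
        """Back focal distance of obj1 in air (mm)."""
        return self.f_obj / self.n_water

    @property
    def pupil_radius(self) -> float:
        """Paraxial back-pupil radius of obj1 (mm)."""
        return self.f_obj_air * self.na_obj

    def elements(self, s1: float | None = None,
                 mirror_gap: float | None = None) -> list[ABCDElement]:
        """Element sequence from the object plane to just after the second
        obj2 pass (the remote image space where S3 is measured)."""
        s1 = self.s1 if s1 is None else s1
        g = self.mirror_gap if mirror_gap is None else mirror_gap
        return [
            make_translation(s1, self.n_water, "object->obj1"),
            make_thin_lens(self.f_obj, self.n_water, "obj1"),
            make_translation(self.d1, 1.0, "obj1->L4"),
            make_thin_lens(self.f_l4, 1.0, "L4"),
            make_translation(self.gap_l4_l5, 1.0, "L4->L5"),
            make_thin_lens(self.f_l5, 1.0, "L5"),
            make_translation(self.gap_l5_pbs, 1.0, "L5->PBS"),
            make_fold(45.0, "PBS"),
            make_translation(self.gap_pbs_obj2, 1.0, "PBS->obj2"),
            make_thin_lens(self.f_obj2, 1.0, "obj2 (forward)"),
            make_translation(g, 1.0, "obj2->mirror->obj2"),
            make_thin_lens(self.f_obj2, 1.0, "obj2 (backward)"),
        ]


def build_detection_model(config: dict | None = None, *,
                          all_4f: bool = False) -> DetectionPathModel:
    """Build a :class:`DetectionPathModel` from a configuration mapping.

    ``config`` may override any of the preset focal lengths, indices, NA
    values, ``theta_deg``, ``s1``, ``mirror_defocus`` (mm) and the gaps
    ``d1``, ``l4_l5``, ``l5_pbs``, ``pbs_obj2``.  Missing gaps default to the
    4f-nominal value (sum of the adjacent focal lengths); ``all_4f=True``
    forces every gap to its 4f-nominal value and puts the object at the front
    focal plane.
    """
    cfg = dict(DESIGN_PRESET)
    if config:
        unknown = set(config) - set(DESIGN_PRESET) - {
            "s1", "d1", "l4_l5", "l5_pbs", "pbs_obj2", "mirror_defocus",
            "s3"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)

    f_obj = effective_focal_length(cfg["f_tube_design"], cfg["m_obj"],
                                   cfg["n_water"])
    # 4f-nominal gaps: sum of adjacent focal lengths
    nominal = dict(
        d1=f_obj + cfg["f_l4"],
        l4_l5=cfg["f_l4"] + cfg["f_l5"],
        l5_pbs=0.5 * (cfg["f_l5"] + cfg["f_obj2"]),
        pbs_obj2=0.5 * (cfg["f_l5"] + cfg["f_obj2"]),
    )
    if all_4f:
        gaps = dict(nominal)
        s1 = cfg.get("s1", f_obj) if config else f_obj
    else:
        gaps = {k: cfg.get(k, v) for k, v in nominal.items()}
        s1 = cfg.get("s1", f_obj)
    # the L5->obj2 path is split by the PBS fold; the two pieces must sum
    # consistently with whatever the caller supplied
    mirror_defocus = cfg.get("mirror_defocus", 0.0)
    mirror_gap = 2.0 * (cfg["f_obj2"] - mirror_defocus)

    model = DetectionPathModel(
        f_tube_design=cfg["f_tube_design"], m_obj=cfg["m_obj"],
        n_water=cfg["n_water"], f_obj=f_obj,
        f_l4=cfg["f_l4"], f_l5=cfg["f_l5"], f_obj2=cfg["f_obj2"],
        f_l6=cfg["f_l6"], na_obj=cfg["na_obj"], na_obj2=cfg["na_obj2"],
        theta_deg=cfg["theta_deg"], s1=s1, d1=gaps["d1"],
        gap_l4_l5=gaps["l4_l5"], gap_l5_pbs=gaps["l5_pbs"],
        gap_pbs_obj2=gaps["pbs_obj2"], mirror_gap=mirror_gap,
        delta_l=cfg["f_obj2"] * math.radians(cfg["theta_deg"]),
        all_4f=all_4f,
    )
    # a requested S3 (the de-scanned image distance after the second obj2
    # pass) is realized by solving for the mirror gap, as on the instrument,
    # where the mirror is positioned to focus the image onto the camera
    s3_req = cfg.get("s3") if config else None
    if s3_req is not None and not all_4f:
        model.mirror_gap = _solve_mirror_gap(model, model.s1, float(s3_req))
        model.s3 = float(s3_req)
    else:
        model.s3 = _image_distance(model.elements())
    return model


def as_built_model() -> DetectionPathModel:
    """The instrument's non-4f detection path; the unmeasured gaps carry
    estimated values (see :data:`AS_BUILT_GAPS`)."""
    return build_detection_model(dict(AS_BUILT_GAPS))


def _image_distance(elements) -> float:
    """Distance from the last element to the image plane (may be +/-inf).

    Imaging condition: the object-to-image transfer matrix T satisfies
    T[1, 0] = 0 (height independent of launch angle).  Appending a
    translation of length s in air gives T' = M_d(s) @ M, so
    T'[1, 0] = s * M[0, 0] + M[1, 0] = 0.
    """
    m = transfer_matrix(elements)
    if abs(m[0, 0]) < 1e-14:
        return math.inf
    return -m[1, 0] / m[0, 0]


def _magnification_at_image(elements) -> float:
    """Lateral magnification at the image plane after the last element.

    At an image plane the transfer matrix has B' (= T[1,0]) = 0 and the
    magnification is T[1, 1].  If the system is afocal after the last element
    (no finite crossing), fall back to the last interior crossing: scan the
    translation segments from the end and image inside the segment where the
    marginal rays cross.
    """
    s = _image_distance(elements)
    if math.isfinite(s):
        t = transfer_matrix(elements + [make_translation(s, 1.0)])
        return float(t[1, 1])
    # afocal tail: find the last interior gap in which rays from one field
    # point cross, i.e. where the partial system images the object
    for i in range(len(elements) - 1, -1, -1):
        el = elements[i]
        if el.kind != "translation":
            continue
        head = elements[:i]
        s_img = _image_distance(head)
        if math.isfinite(s_img) and -1e-9 <= s_img <= el.d + 1e-9:
            t = transfer_matrix(head + [make_translation(s_img, el.n)])
            return float(t[1, 1])
    raise ValueError("no image plane found along the traced path")


@dataclass
class RayTraceResult:
    """Sampled ray polylines plus the derived image-plane quantities."""

    polylines: list            # per ray: list of (z_mm, height_mm)
    field_point_labels: list   # per ray: field-point label
    image_plane_position: float  # mm from the object plane (unfolded axis)
    lateral_magnification: float
    converged: bool = True


def trace_field(model: DetectionPathModel,
                field_half_width: float = 50.0) -> RayTraceResult:
    """Trace 3 field points x 3 pupil rays through the full detection path.

    ``field_half_width`` is the object-space field half-width in um.  Field
    points are the two FOV edges and the axis; pupil rays hit the edge and the
    center of obj1's back pupil.  Returns the remote image plane (the last
    plane where rays from one field point intersect, measured along the
    unfolded axis from the object) and the lateral magnification there.
    """
    h = field_half_width * 1e-3  # um -> mm
    elements = model.elements()

    # transfer matrix object plane -> back pupil plane of obj1
    to_pupil = [elements[0], elements[1],
                make_translation(model.f_obj_air, 1.0)]
    mp = transfer_matrix(to_pupil)
    if abs(mp[1, 0]) < 1e-14:
        raise ValueError("degenerate pupil mapping")
    r_pupil = model.pupil_radius

    rays, labels = [], []
    for y0, flabel in ((-h, "field -"), (0.0, "axis"), (h, "field +")):
        for p in (-r_pupil, 0.0, r_pupil):
            # launch angle that maps (u, y0) to pupil height p
            u = (p - mp[1, 1] * y0) / mp[1, 0]
            rays.append(ParaxialRay(u, y0))
            labels.append(flabel)

    # sample each ray at every element boundary along the unfolded axis
    polylines = []
    for ray in rays:
        z = 0.0
        pts = [(z, ray.height)]
        state = ray
        for el in elements:
            state = propagate_ray(state, [el])
            if el.kind == "translation":
                z += el.d
            pts.append((z, state.height))
        polylines.append(pts)

    mag = _magnification_at_image(elements)
    s_img = _image_distance(elements)
    z_total = sum(el.d for el in elements if el.kind == "translation")
    converged = math.isfinite(s_img)
    if converged:
        z_image = z_total + s_img
    else:
        # image sits inside an interior gap; locate it for reporting
        z_image = _interior_image_position(elements)
    return RayTraceResult(polylines=polylines, field_point_labels=labels,
                          image_plane_position=z_image,
                          lateral_magnification=mag, converged=converged)


def _interior_image_position(elements) -> float:
    z = 0.0
    z_image = math.nan
    for i, el in enumerate(elements):
        if el.kind == "translation":
            s_img = _image_distance(elements[:i])
            if math.isfinite(s_img) and -1e-9 <= s_img <= el.d + 1e-9:
                z_image = z + s_img
            z += el.d
    return z_image


def magnification_vs_scan(model: DetectionPathModel, object_offsets,
                          max_offset: float = 60.0):
    """Lateral magnification vs axial object offset (the LFA surrogate).

    For each object offset (um; positive = farther from obj1) the gap between
    the two obj2 passes is re-solved so the image distance S3 after the second
    pass stays at its reference value, mimicking the voice-coil mirror travel
    during a scan.  Returns a list of ``(offset_um, magnification)``.
    """
    offsets = np.atleast_1d(np.asarray(object_offsets, dtype=float))
    if np.any(np.abs(offsets) > max_offset):
        raise ValueError(f"object offset outside modeled range "
                         f"(+/-{max_offset} um)")

    afocal = math.isinf(model.s3)
    curve = []
    for off in offsets:
        s1 = model.s1 + off * 1e-3
        if afocal:
            # exact-4f reference: the mirror travel restores afocality
            # (collimated output per field point) and the de-scanned image
            # is the stationary intermediate image at the mirror plane
            gap = _solve_afocal_gap(model, s1)
            els = model.elements(s1=s1, mirror_gap=gap)
            curve.append((float(off), _magnification_at_image(els)))
        else:
            gap = _solve_mirror_gap(model, s1, model.s3)
            els = model.elements(s1=s1, mirror_gap=gap)
            t = transfer_matrix(els + [make_translation(model.s3, 1.0)])
            curve.append((float(off), float(t[1, 1])))
    return curve


def _solve_afocal_gap(model: DetectionPathModel, s1: float) -> float:
    """Mirror gap restoring collimated output (T[0,0] = 0), linear in g."""
    def residual(g):
        return transfer_matrix(model.elements(s1=s1, mirror_gap=g))[0, 0]

    g0, g1 = model.mirror_gap, model.mirror_gap + 1.0
    r0, r1 = residual(g0), residual(g1)
    if r1 == r0:
        if abs(r0) < 1e-12:
            return g0  # already afocal for any gap
        raise ValueError("mirror gap does not control the output vergence")
    return g0 - r0 * (g1 - g0) / (r1 - r0)


def _solve_mirror_gap(model: DetectionPathModel, s1: float,
                      s3: float) -> float:
    """Mirror gap that images the (offset) object at fixed S3.

    The imaging condition T[1, 0] = 0 is linear in the gap length g because g
    enters exactly one translation matrix, so the root is solved exactly from
    two evaluations.
    """
    def residual(g):
        els = model.elements(s1=s1, mirror_gap=g)
        t = transfer_matrix(els + [make_translation(s3, 1.0)])
        return t[1, 0]

    g0, g1 = model.mirror_gap, model.mirror_gap + 1.0
    r0, r1 = residual(g0), residual(g1)
    if r1 == r0:
        raise ValueError("mirror gap does not control the image position")
    return g0 - r0 * (g1 - g0) / (r1 - r0)


# --------------------------------------------------------------------------
# collection efficiency (qualitative clipping model)
# --------------------------------------------------------------------------

def _disk_overlap(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two disks with center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = 0.5 * math.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2)
                            * (d - r1 + r2) * (d + r1 + r2)))
    return a1 + a2 - k


def collection_efficiency(model: DetectionPathModel, defocus: float,
                          field_offset: float,
                          aperture_radius: float | None = None) -> float:
    """Fraction of the returning ray fan accepted by the remote objective.

    Qualitative geometric model of why defocusing the remote mirror loses
    light: a point imaged at axial defocus (um) and lateral field offset (um)
    in remote space sends back a cone whose footprint at obj2's aperture is a
    disk of radius ``R * (f_obj2 + |defocus|) / f_obj2`` centered at the field
    offset.  The efficiency is the fraction of that footprint inside the
    aperture disk (radius ``R = f_obj2 * NA_obj2`` by default), computed from
    the closed-form two-circle intersection.
    """
    if aperture_radius is None:
        aperture_radius = model.f_obj2 * model.na_obj2
    if aperture_radius < 0:
        raise ValueError("aperture radius must be non-negative")
    if aperture_radius == 0:
        return 0.0
    x = abs(field_offset) * 1e-3          # um -> mm
    d = abs(defocus) * 1e-3
    r_beam = aperture_radius * (model.f_obj2 + d) / model.f_obj2
    a = _disk_overlap(x, r_beam, aperture_radius)
    return a / (math.pi * r_beam * r_beam)


# --------------------------------------------------------------------------
# calibration helpers
# --------------------------------------------------------------------------

def select_theta(model: DetectionPathModel, theta_min: float = 1.0,
                 theta_max: float = 20.0, step: float = 0.1,
                 beam_radius: float | None = None,
                 clearance: float = 0.1) -> float:
    """Launch angle (deg) minimizing the traced beam footprint at obj2.

    The S and P beams are displaced at obj2 by ``delta_L/2 = f_obj2*theta/2``
    each, so the footprint grows linearly with theta; shrinking theta forces
    the PBS-to-obj2 distance to grow (the mirrors must still clear each
    other), adding a divergence term ``clearance / theta``.  A 0.1-degree grid
    search over the resulting trade-off reproduces the criterion of minimal
    input/output beam diameters at the remote objective.
    """
    if beam_radius is None:
        beam_radius = model.pupil_radius * model.f_obj2 / model.f_l5
    thetas = np.arange(theta_min, theta_max + step / 2, step)
    footprints = [beam_radius + model.f_obj2 * math.radians(t) / 2
                  + clearance / math.radians(t) for t in thetas]
    return float(thetas[int(np.argmin(footprints))])


def fit_gap_to_measurements(model: DetectionPathModel, gap_name: str,
                            measured_curve, bounds=(10.0, 1000.0)) -> float:
    """Least-squares scalar fit of one gap length to a measured
    magnification-vs-offset curve (the d1 calibration procedure).

    ``measured_curve`` is a sequence of (offset_um, magnification) pairs.
    """
    offsets = [o for o, _ in measured_curve]
    meas = np.array([m for _, m in measured_curve])

    def sse(value):
        trial = replace(model, **{gap_name: value})
        trial.s3 = _image_distance(trial.elements())
        try:
            curve = magnification_vs_scan(trial, offsets)
        except ValueError:
            return 1e9
        sim = np.array([m for _, m in curve])
        return float(np.sum((sim - meas) ** 2))

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def fit_s1_to_magnification(model: DetectionPathModel,
                            measured_magnification: float,
                            bounds=(6.0, 7.5)) -> float:
    """Scalar fit of the object distance S1 so the traced on-axis absolute
    magnification matches a measured value (the S1 calibration procedure)."""
    def sse(s1):
        els = model.elements(s1=s1)
        try:
            mag = _magnification_at_image(els)
        except ValueError:
            return 1e9
        return (mag - measured_magnification) ** 2

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-9})
    return float(res.x)
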