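"""Face-like phantom volumes and simulated rater measurements.

The phantom is a stylized head — an ellipsoid cut by four planar facial
"panels" — decorated with six flat-topped protrusions ("bumps") whose apices
are the six protrusion landmarks, each oriented along its catalogued
anatomical normal.  Every apex is known analytically, so the whole landmark
pipeline can be validated without any patient data.

Geometry
--------
Each panel is a half-space cut along the voxel lattice, perpendicular to the
normal of the landmarks it carries: a flat anterior plate (the facial plane,
normal -y) for pronasale and the two lip points, a 45-degree subnasal notch
for the columella, and two 45-degree lateral chamfers for the cheeks.  Each
bump is a flat-topped frustum protruding five lattice steps out of its
panel.

Two exact lattice facts make this the regime in which the tabletop-averaging
landmark algorithm is *exact*:

* binary marching-cube vertices sit at cut-edge midpoints, so a lattice cut
  perpendicular to an axis, and equally a perfect 45-degree staircase cut,
  meshes into a surface whose vertices all lie on one plane;
* a bump facet five steps in front of its panel puts the panel (and, because
  the panels are planes, everything beyond them) far outside the 1-px
  tabletop band, so the band patch is exactly the bump facet plus its first
  flank ring — an absolute vertex set, independent of which facet vertex
  seeds the search.

Defaults emulate the acquisition geometry of a 0.3 mm isotropic CBCT scan;
the 160-voxel test grid is a desk-scale crop (4.8 cm), and ``shape=533``
reproduces the full 16 cm field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmarks import get_landmark, landmark_catalog
from .volume_io import Volume

__all__ = [
    "BumpSpec",
    "PanelCut",
    "PhantomSpec",
    "SimulatedRaterSpec",
    "face_phantom_spec",
    "generate_phantom",
    "generate_cohort",
    "generate_rater_series",
]


@dataclass(frozen=True)
class BumpSpec:
    """One landmark protrusion: a flat-topped frustum along the normal.

    The facet (halfwidth ``facet_halfwidth``) is cut along the voxel lattice
    perpendicular to the landmark normal; below it the radius widens by half
    a voxel per lattice step (capped), and after ``depth`` steps the head
    panel takes over.
    """

    landmark: str
    apex: tuple[float, float, float]
    facet_halfwidth: float = 8.0
    depth: int = 9


@dataclass(frozen=True)
class PanelCut:
    """A lattice half-space carve of the head: keep ``g . v <= level``.

    ``z_range`` restricts the carve to a slab of slices (used for the
    subnasal notch so it does not truncate the chin); ``None`` applies it
    globally.
    """

    g: tuple[float, float, float]
    level: float
    z_range: tuple[float, float] | None = None


@dataclass
class PhantomSpec:
    """Parameters of one synthetic face phantom."""

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: float = 0.3
    head_center: tuple[float, float, float] = (80.0, 94.4, 80.0)
    head_axes: tuple[float, float, float] = (55.0, 50.0, 72.0)
    panels: tuple[PanelCut, ...] = ()
    bumps: tuple[BumpSpec, ...] = ()
    tissue_intensity: float = 180.0
    air_intensity: float = 5.0
    noise_sd: float = 10.0
    seed: int = 0


@dataclass
class SimulatedRaterSpec:
    """Simulated digitization: truth + per-rater bias + per-click jitter."""

    truth: pd.DataFrame                      # columns: subject, landmark, x, y, z (mm)
    rater_bias_mm: dict = field(default_factory=dict)  # rater id -> 3-vector
    jitter_sd_mm: float = 0.0
    sessions: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter SD must be >= 0")


def _lattice_gradient(normal_raw) -> np.ndarray:
    """Sign pattern of the landmark normal, entries in {-1, 0, +1}."""
    g = np.sign(np.asarray(normal_raw, dtype=float))
    if not g.any():
        raise ValueError("landmark normal must be nonzero")
    return g


def _snap_apex(apex, normal_raw) -> tuple[np.ndarray, int]:
    """Move ``apex`` along the normal onto the nearest facet-vertex plane.

    Facet mesh vertices live where the lattice functional ``L(v) = g . v``
    (``g`` the sign pattern of the normal) equals ``f + 0.5`` for the integer
    facet level ``f``.  Returns the snapped apex and ``f``.
    """
    g = _lattice_gradient(normal_raw)
    apex = np.asarray(apex, dtype=float)
    level = float(g @ apex)
    f = int(np.round(level - 0.5))
    snapped = apex + ((f + 0.5) - level) * g / float(g @ g)
    return snapped, f


#: lattice steps a bump facet stands in front of its mounting panel
_PANEL_STANDOFF = 5.5

# base apex offsets from the head center (in 160-grid units) and the integer
# in-plane lattice vectors used for per-subject jitter (each preserves the
# facet-plane level g . apex)
_APEX_OFFSETS = {
    "Pn":   (0.0, -45.9, 32.0),
    "Co":   (0.0, -47.15, 9.25),
    "ULP":  (0.0, -45.9, -16.0),
    "LLP":  (0.0, -45.9, -40.0),
    "Ch_r": (-36.25, -35.65, 15.0),
    "Ch_l": (36.25, -35.65, 15.0),
}
_INPLANE_JITTER = {
    "Pn":   ((1, 0, 0), (0, 0, 1)),
    "Co":   ((1, 0, 0), (0, 1, -1)),
    "ULP":  ((1, 0, 0), (0, 0, 1)),
    "LLP":  ((1, 0, 0), (0, 0, 1)),
    "Ch_r": ((1, -1, 0), (0, 0, 1)),
    "Ch_l": ((1, 1, 0), (0, 0, 1)),
}
_MIDLINE = ("Pn", "ULP", "LLP")


def face_phantom_spec(shape: int | tuple[int, int, int] = 160,
                      rng: np.random.Generator | None = None) -> PhantomSpec:
    """The canonical six-bump face phantom (optionally subject-randomized).

    With ``rng`` given, head semi-axes are jittered continuously and each
    apex is shifted by an integer lattice offset within its facet plane (the
    three midline landmarks share one vertical offset so their facets stay
    on a common facial plane), producing a cohort with non-constant true
    landmark positions while every facet stays a clean lattice cut.
    """
    if isinstance(shape, int):
        shape = (shape, shape, shape)
    if min(shape) < 160:
        raise ValueError(
            "the six-bump face phantom needs a grid of at least 160 voxels per "
            "axis: facet sizes and the 1-px band are fixed lattice quantities, "
            "so landmark spacing cannot be scaled below the 160^3 crop")
    scale = shape[0] / 160.0
    center = np.array([shape[0] / 2.0, shape[1] * 0.59, shape[2] / 2.0])
    axes = np.array([55.0, 50.0, 72.0]) * scale
    if rng is not None:
        axes = axes + rng.uniform(-3.0, 1.0, size=3) * scale
        center = center + np.round(rng.uniform(-2, 2, size=3))

    midline_shift = rng.integers(-1, 2) if rng is not None else 0

    apexes = {}
    for lm in landmark_catalog():
        ab = lm.abbreviation
        apex = center + np.asarray(_APEX_OFFSETS[ab]) * scale
        if rng is not None:
            u1, u2 = (np.asarray(u) for u in _INPLANE_JITTER[ab])
            apex = apex + rng.integers(-2, 3) * u1 + rng.integers(-2, 3) * u2
        if ab in _MIDLINE:
            apex[1] = center[1] + _APEX_OFFSETS[ab][1] * scale + midline_shift
        apex, _ = _snap_apex(apex, lm.normal_raw)
        apexes[ab] = apex

    # the midline facets must be coplanar: snap leaves y identical because
    # they share the same (jittered) y by construction
    bumps = tuple(BumpSpec(ab, tuple(apexes[ab])) for ab in apexes)

    # panels: one cut per distinct mounting plane, derived from the apexes
    def cut(ab, z_window=None):
        lm = get_landmark(ab)
        g = _lattice_gradient(lm.normal_raw)
        level = float(g @ apexes[ab]) - _PANEL_STANDOFF
        return PanelCut(tuple(g), level, z_window)

    co_z = apexes["Co"][2]
    panels = (
        cut("ULP"),                                   # anterior facial plate
        cut("Co", (co_z - 10.0, co_z + 12.0)),        # subnasal notch
        cut("Ch_r"),                                  # right cheek chamfer
        cut("Ch_l"),                                  # left cheek chamfer
    )
    return PhantomSpec(shape=shape, head_center=tuple(center),
                       head_axes=tuple(axes), panels=panels, bumps=bumps)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, pd.DataFrame]:
    """Voxelize a phantom spec into a noisy two-level intensity volume.

    Returns the volume and the ground-truth table (one row per bump with the
    exact apex coordinates in continuous voxel space and the unit normal).
    Deterministic for a fixed ``spec.seed``.
    """
    shape = tuple(spec.shape)
    cx = np.arange(shape[0], dtype=float)[:, None, None]
    cy = np.arange(shape[1], dtype=float)[None, :, None]
    cz = np.arange(shape[2], dtype=float)[None, None, :]

    hc, ha = np.asarray(spec.head_center), np.asarray(spec.head_axes)
    head = (((cx - hc[0]) / ha[0]) ** 2 + ((cy - hc[1]) / ha[1]) ** 2
            + ((cz - hc[2]) / ha[2]) ** 2) <= 1.0

    for panel in spec.panels:
        g = np.asarray(panel.g)
        keep = (g[0] * cx + g[1] * cy + g[2] * cz) <= panel.level
        if panel.z_range is not None:
            lo, hi = panel.z_range
            keep |= (cz < lo) | (cz > hi)
        head &= keep

    solid = head
    truth_rows = []
    for bump in spec.bumps:
        lm = get_landmark(bump.landmark)
        g = _lattice_gradient(lm.normal_raw)
        n_hat = lm.normal_unit
        apex, f = _snap_apex(bump.apex, lm.normal_raw)
        if not np.allclose(apex, bump.apex, atol=1e-9):
            raise ValueError(
                f"bump apex for {bump.landmark} is not on a facet-vertex plane; "
                "snap it with the face_phantom_spec helper first")
        # integer lattice depth below the facet, per voxel
        lam = float(f) - (g[0] * cx + g[1] * cy + g[2] * cz)
        rel2 = (cx - apex[0]) ** 2 + (cy - apex[1]) ** 2 + (cz - apex[2]) ** 2
        proj = ((cx - apex[0]) * n_hat[0] + (cy - apex[1]) * n_hat[1]
                + (cz - apex[2]) * n_hat[2])
        rho2 = rel2 - proj ** 2
        radius = bump.facet_halfwidth + 0.5 * np.minimum(lam, 7.0)
        in_bump = (lam >= 0) & (lam <= bump.depth) & (rho2 <= radius ** 2)
        solid = solid | in_bump
        truth_rows.append({"landmark": bump.landmark,
                           "x": apex[0], "y": apex[1], "z": apex[2],
                           "nx": n_hat[0], "ny": n_hat[1], "nz": n_hat[2]})

    border = np.zeros(shape, dtype=bool)
    border[[0, 1, -2, -1]] = True
    border[:, [0, 1, -2, -1]] = True
    border[:, :, [0, 1, -2, -1]] = True
    if (solid & border).any():
        raise ValueError("phantom solid extends into the two outermost voxel layers")

    rng = np.random.default_rng(spec.seed)
    data = np.where(solid, spec.tissue_intensity, spec.air_intensity)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)
    vol = Volume(data, (spec.spacing,) * 3, metadata={"phantom_seed": spec.seed})
    return vol, pd.DataFrame(truth_rows)


def generate_cohort(n_subjects: int, seed: int = 0,
                    shape: int | tuple[int, int, int] = 160):
    """Yield ``(subject_id, spec, volume, truth)`` for a randomized cohort."""
    rng = np.random.default_rng(seed)
    for subject in range(n_subjects):
        spec = face_phantom_spec(shape, rng=rng)
        spec = replace(spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        vol, truth = generate_phantom(spec)
        yield subject, spec, vol, truth


def cohort_cc_series(n_subjects: int, seed: int = 0,
                     shape: int | tuple[int, int, int] = 160) -> pd.DataFrame:
    """Digitize a random phantom cohort from two independent starting points.

    Runs the full pipeline per subject (phantom -> Otsu binarization ->
    marching-cube surface) and computes each landmark's CC point twice,
    seeding the tabletop search from two different off-apex starting points
    (emulating two examiners' clicks: 3 px "up" and 2.5 px "right" of the
    apex in the landmark's tangent plane).  Returns a long table with
    columns ``subject, landmark, series (CC1/CC2), x_vox..z_vox,
    x/y/z/d`` (mm) suitable for the agreement statistics.
    """
    from . import landmarks as lmk
    from .marching import extract_isosurface
    from .volume_io import binarize_soft_tissue

    rows = []
    for subject, spec, vol, truth in generate_cohort(n_subjects, seed, shape):
        mesh = extract_isosurface(binarize_soft_tissue(vol))
        for _, rec in truth.iterrows():
            lm = lmk.get_landmark(rec["landmark"])
            apex = np.array([rec["x"], rec["y"], rec["z"]])
            tdir = lmk.tangent_directions(lm.normal_unit)
            starts = {"CC1": apex + 3.0 * tdir["up"],
                      "CC2": apex + 2.5 * tdir["right"]}
            for series, start in starts.items():
                region = lmk.find_tabletop(mesh, start, lm)
                cc = lmk.compute_cc_point(region, mesh)
                rows.append({"subject": subject, "landmark": lm.abbreviation,
                             "series": series,
                             "x_vox": cc.voxel_coords[0], "y_vox": cc.voxel_coords[1],
                             "z_vox": cc.voxel_coords[2],
                             "x": cc.mm_coords[0], "y": cc.mm_coords[1],
                             "z": cc.mm_coords[2], "d": cc.d,
                             "n_members": cc.n_members})
    return pd.DataFrame(rows)


def generate_rater_series(spec: SimulatedRaterSpec) -> pd.DataFrame:
    """Simulate repeated digitizations of known landmark positions.

    Each click is ``truth + rater_bias + N(0, jitter_sd)`` per axis.  Returns
    a long-format table ``{rater, session, subject, landmark, x, y, z, d}``
    in mm, reproducible for a fixed seed.
    """
    required = {"subject", "landmark", "x", "y", "z"}
    if missing := required - set(spec.truth.columns):
        raise ValueError(f"truth table lacks columns {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    raters = list(spec.rater_bias_mm) or ["Ob1"]
    rows = []
    for rater in raters:
        bias = np.asarray(spec.rater_bias_mm.get(rater, (0.0, 0.0, 0.0)), dtype=float)
        for session in range(1, spec.sessions + 1):
            for _, rec in spec.truth.iterrows():
                xyz = np.array([rec["x"], rec["y"], rec["z"]], dtype=float) + bias
                if spec.jitter_sd_mm > 0:
                    xyz = xyz + rng.normal(0.0, spec.jitter_sd_mm, size=3)
                rows.append({"rater": rater, "session": session,
                             "subject": rec["subject"], "landmark": rec["landmark"],
                             "x": xyz[0], "y": xyz[1], "z": xyz[2],
                             "d": float(np.linalg.norm(xyz))})
    return pd.DataFrame(rows)
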