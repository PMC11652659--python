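"""Digital phantoms and noise: vial grid, short-axis annulus, field maps.

Two synthetic inputs are provided:

* a nine-vial gel-phantom look-alike (3x3 disc layout) whose default T1 and
  T2 values span the ranges measured on a commercial T1/T2 calibration
  phantom (T1 297.8-1421.6 ms, T2 40.1-194.4 ms).  The per-vial TRAFF2
  ground truths are synthetic fixture values spanning 101.7-550.8 ms; they
  exercise the pipeline and are not claims about the physical vials.
* a short-axis left-ventricular annulus with configurable myocardial TRAFF2
  (default 79.1 ms, a typical healthy-myocardium value at 3 T) and an
  optional focal wedge lesion with elevated TRAFF2 emulating an infarct.

B0 maps default to a smooth linear ramp plus a Gaussian bump scaled to a
configurable peak (default +/-50 Hz); B1 maps default to a constant 1.05.
The pixel grid is unitless with 0-based row-major coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .blochsim import TissueParams
from .mapping import WeightedSeries

#: default per-vial parameters: T1/T2 span the calibration-phantom ranges,
#: TRAFF2 values are synthetic fixtures spanning the phantom-study range.
DEFAULT_VIAL_T1_MS = np.linspace(297.8, 1421.6, 9)
DEFAULT_VIAL_T2_MS = np.linspace(40.1, 194.4, 9)
DEFAULT_VIAL_TRAFF2_MS = np.linspace(101.7, 550.8, 9)


def default_vial_params() -> list:
    """Nine default vials (T1 and T2 spanning the printed phantom ranges)."""
    return [
        TissueParams(m0=1.0, t1=float(t1), t2=float(t2), traff2_true=float(tr))
        for t1, t2, tr in zip(DEFAULT_VIAL_T1_MS, DEFAULT_VIAL_T2_MS,
                              DEFAULT_VIAL_TRAFF2_MS)
    ]


@dataclass
class TissueMaps:
    """Per-voxel tissue parameters plus B0/B1 field maps.

    All maps share one 2-D shape; ``label_map`` assigns integer region
    labels with 0 = background.  Times are ms, ``b0_map`` is Hz and
    ``b1_map`` the dimensionless transmit scaling.
    """

    m0_map: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    traff2_map: np.ndarray
    b0_map: np.ndarray
    b1_map: np.ndarray
    label_map: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.m0_map, self.t1_map, self.t2_map, self.traff2_map,
                  self.b0_map, self.b1_map]
        self.m0_map, self.t1_map, self.t2_map, self.traff2_map, self.b0_map, \
            self.b1_map = [np.asarray(a, dtype=float) for a in arrays]
        self.label_map = np.asarray(self.label_map, dtype=int)
        shape = self.label_map.shape
        for a in (self.m0_map, self.t1_map, self.t2_map, self.traff2_map,
                  self.b0_map, self.b1_map):
            if a.shape != shape:
                raise ValueError("all maps must share one shape")
        sel = self.label_map > 0
        for name, a in (("t1_map", self.t1_map), ("t2_map", self.t2_map),
                        ("m0_map", self.m0_map)):
            vals = a[sel]
            if vals.size and (np.any(~np.isfinite(vals)) or np.any(vals <= 0)):
                raise ValueError(f"labeled voxels must have positive finite {name}")

    @property
    def shape(self) -> tuple:
        return self.label_map.shape


def _default_b0_map(shape, peak_hz: float) -> np.ndarray:
    """Smooth linear ramp + Gaussian bump, scaled so max |B0| = peak_hz."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    u = (xx - (nx - 1) / 2.0) / max(nx - 1, 1)
    v = (yy - (ny - 1) / 2.0) / max(ny - 1, 1)
    ramp = 0.6 * u + 0.2 * v
    bump = 0.8 * np.exp(-((u - 0.15) ** 2 + (v + 0.1) ** 2) / (2 * 0.18**2))
    field = ramp + bump
    m = np.max(np.abs(field))
    return peak_hz * field / m if m > 0 else field


def make_vial_phantom(grid_size: int = 128, vial_params: list | None = None,
                      vial_radius: float | None = None, b0_peak_hz: float = 50.0,
                      b1_value: float = 1.05, seed: int | None = None) -> TissueMaps:
    """Nine-vial (or fewer) disc phantom on a 3x3 layout.

    Raises if the requested radius would overlap neighbouring vials.  The
    ``seed`` is accepted for interface symmetry; construction itself is
    deterministic.
    """
    if grid_size < 64:
        raise ValueError("grid must be at least 64x64")
    params = vial_params if vial_params is not None else default_vial_params()
    if not 1 <= len(params) <= 9:
        raise ValueError("between 1 and 9 vials supported")
    radius = vial_radius if vial_radius is not None else grid_size / 10.0
    spacing = grid_size / 3.0
    if 2 * radius >= spacing:
        raise ValueError(
            f"vial radius {radius} overlaps neighbours at spacing {spacing:.1f}"
        )
    shape = (grid_size, grid_size)
    label = np.zeros(shape, dtype=int)
    m0 = np.zeros(shape)
    t1 = np.full(shape, np.nan)
    t2 = np.full(shape, np.nan)
    traff2 = np.full(shape, np.nan)
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    centers = [((i + 0.5) * spacing, (j + 0.5) * spacing)
               for i in range(3) for j in range(3)]
    for k, p in enumerate(params):
        cy, cx = centers[k]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        label[disc] = k + 1
        m0[disc] = p.m0
        t1[disc] = p.t1
        t2[disc] = p.t2
        traff2[disc] = p.traff2_true if p.traff2_true is not None else np.nan
    return TissueMaps(
        m0_map=m0, t1_map=t1, t2_map=t2, traff2_map=traff2,
        b0_map=_default_b0_map(shape, b0_peak_hz),
        b1_map=np.full(shape, float(b1_value)),
        label_map=label,
    )


@dataclass
class LesionSpec:
    """A focal wedge lesion inside the myocardial annulus.

    ``center_angle_deg`` / ``width_deg`` define the angular wedge (measured
    in the same convention as the segment labelling); ``traff2`` is the
    lesion's decay time in ms.
    """

    center_angle_deg: float = 200.0
    width_deg: float = 60.0
    traff2: float = 87.4
    t1: float = 1400.0
    t2: float = 55.0


@dataclass
class SaxPhantom:
    """Short-axis annulus phantom: tissue maps plus anatomy landmarks."""

    maps: TissueMaps
    lv_center: tuple
    rv_insertion: tuple
    myocardium_mask: np.ndarray
    blood_mask: np.ndarray
    lesion_mask: np.ndarray


def make_sax_phantom(grid_size: int = 128, radii: tuple = (18.0, 30.0),
                     traff2_myocardium: float = 79.1,
                     lesion_spec: LesionSpec | None = None,
                     b0_peak_hz: float = 25.0, b1_value: float = 1.0,
                     rv_angle_deg: float = 120.0,
                     seed: int | None = None) -> SaxPhantom:
    """Annular left-ventricular myocardium with blood pool and optional lesion.

    Angles are measured counterclockwise from "east" in the displayed image
    (x = column, y = upward); the RV insertion point is placed on the outer
    annulus boundary at ``rv_angle_deg``.
    """
    r_in, r_out = radii
    if not 0 < r_in < r_out:
        raise ValueError("need 0 < inner radius < outer radius")
    if 2 * r_out >= grid_size:
        raise ValueError("annulus does not fit in the grid")
    shape = (grid_size, grid_size)
    c = (grid_size - 1) / 2.0
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    rr = np.hypot(yy - c, xx - c)
    myo = (rr >= r_in) & (rr <= r_out)
    blood = rr < r_in

    theta = np.arctan2(-(yy - c), xx - c)  # CCW, y up

    lesion = np.zeros(shape, dtype=bool)
    if lesion_spec is not None:
        half = math.radians(lesion_spec.width_deg) / 2.0
        ctr = math.radians(lesion_spec.center_angle_deg)
        dang = np.angle(np.exp(1j * (theta - ctr)))
        lesion = myo & (np.abs(dang) <= half)
        if not np.any(lesion):
            raise ValueError("lesion wedge does not intersect the annulus")

    m0 = np.zeros(shape)
    t1 = np.full(shape, np.nan)
    t2 = np.full(shape, np.nan)
    traff2 = np.full(shape, np.nan)
    label = np.zeros(shape, dtype=int)

    # myocardium = 1, blood = 2, lesion = 3
    m0[myo | blood] = 1.0
    t1[myo], t2[myo], traff2[myo] = 1200.0, 45.0, traff2_myocardium
    t1[blood], t2[blood], traff2[blood] = 1900.0, 250.0, 200.0
    label[myo] = 1
    label[blood] = 2
    if lesion_spec is not None:
        t1[lesion], t2[lesion] = lesion_spec.t1, lesion_spec.t2
        traff2[lesion] = lesion_spec.traff2
        label[lesion] = 3

    ang = math.radians(rv_angle_deg)
    rv = (int(round(c - r_out * math.sin(ang))), int(round(c + r_out * math.cos(ang))))

    maps = TissueMaps(m0_map=m0, t1_map=t1, t2_map=t2, traff2_map=traff2,
                      b0_map=_default_b0_map(shape, b0_peak_hz),
                      b1_map=np.full(shape, float(b1_value)), label_map=label)
    return SaxPhantom(maps=maps, lv_center=(c, c), rv_insertion=rv,
                      myocardium_mask=myo, blood_mask=blood, lesion_mask=lesion)


def add_noise(series: WeightedSeries, sigma: float, model: str = "gaussian",
              seed: int | None = None) -> WeightedSeries:
    """Add seeded noise to a weighted series.

    ``gaussian`` adds N(0, sigma^2); ``rician`` returns
    ``|S + n1 + i*n2|`` with independent N(0, sigma^2) quadrature
    components, the magnitude-image noise model.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}")
    images = series.images.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        if model == "gaussian":
            images = images + rng.normal(0.0, sigma, size=images.shape)
        else:
            n1 = rng.normal(0.0, sigma, size=images.shape)
            n2 = rng.normal(0.0, sigma, size=images.shape)
            images = np.hypot(images + n1, n2)
    return WeightedSeries(images=images, prep_ms=series.prep_ms.copy(),
                          mask=None if series.mask is None else series.mask.copy())
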