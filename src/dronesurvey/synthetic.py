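"""Synthetic survey inputs with known ground truth.

Every input the pipeline consumes can be generated here under the study's
statistical assumptions, keeping the generating truth so that recovery can
be tested:

* repeated-count tables: ``N_j ~ Poisson(lambda)`` thinned by
  ``Binomial(N_j, psi)`` detection over T occasions (closed population);
* known-age growth tables: ages on a jittered uniform grid, lengths on the
  von Bertalanffy curve times multiplicative Gamma noise with unit mean
  (variance grows with the mean, matching the Gamma-GAM error assumption);
* body outlines: capsule shapes bent along a circular arc with thin limb
  protrusions, whose true head-to-tail curved length is known exactly;
* calibration panels: squares of stated side length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon as _ShapelyPolygon, box

from .abundance import CountData
from .growth import VBParams, vb_length
from .morphometry import BodyPolygon

__all__ = [
    "SyntheticTruth",
    "generate_counts",
    "generate_growth",
    "generate_body_polygon",
    "generate_panels",
    "DEFAULT_VB_TRUTH",
    "DEFAULT_NOISE_CV",
]

# study-condition defaults: expected site abundance ~19, detection 0.55,
# 8 sites x 4 occasions; growth truth around the fitted asymptote 512 cm
DEFAULT_VB_TRUTH = VBParams(l_inf=512.0, l_0=150.0, k=0.1)
DEFAULT_NOISE_CV = 0.08
LIMB_FRACTIONS = (0.25, 0.4, 0.6, 0.75)


@dataclass
class SyntheticTruth:
    """Generating parameters and latent states kept for recovery tests."""

    lambda_true: float
    psi_true: float
    N_true: np.ndarray
    vb_true: VBParams | None
    noise_cv: float
    seed: int | None

    def __post_init__(self) -> None:
        if self.lambda_true <= 0:
            raise ValueError("lambda_true must be positive")
        if not 0 <= self.psi_true <= 1:
            raise ValueError("psi_true must lie in [0, 1]")


def generate_counts(
    lam: float,
    psi: float,
    R: int = 8,
    T: int = 4,
    seed: int | None = None,
) -> tuple[CountData, SyntheticTruth]:
    """Simulate a closed-population repeated-count survey.

    Latent ``N_j ~ Poisson(lam)`` per site; each occasion's count is an
    independent ``Binomial(N_j, psi)`` thinning.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 <= psi <= 1:
        raise ValueError("psi must lie in [0, 1]")
    if R < 1 or T < 1:
        raise ValueError("need at least one site and one occasion")
    rng = np.random.default_rng(seed)
    N = rng.poisson(lam, size=R)
    counts = rng.binomial(N[:, None], psi, size=(R, T))
    truth = SyntheticTruth(
        lambda_true=float(lam),
        psi_true=float(psi),
        N_true=N,
        vb_true=None,
        noise_cv=0.0,
        seed=seed,
    )
    return CountData(counts), truth


def generate_growth(
    params: VBParams = DEFAULT_VB_TRUTH,
    n: int = 23,
    age_range: tuple[float, float] = (1.0, 40.0),
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a known-age growth table (columns id, age_years, length_cm).

    Ages sit on a jittered uniform grid over ``age_range`` so that even a
    small sample spans the curve; lengths are the growth curve times
    multiplicative Gamma noise with unit mean and the stated coefficient of
    variation (``noise_cv = 0`` gives the curve exactly).
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    lo, hi = age_range
    if not (0 < lo < hi):
        raise ValueError("age_range must be an increasing interval in (0, inf)")
    rng = np.random.default_rng(seed)
    grid = np.linspace(lo, hi, n)
    half_step = (hi - lo) / (2 * max(n - 1, 1))
    ages = np.clip(grid + rng.uniform(-half_step, half_step, n), lo, hi)
    lengths = vb_length(ages, params)
    if noise_cv > 0:
        shape = 1.0 / noise_cv**2
        lengths = lengths * rng.gamma(shape, 1.0 / shape, n)
    return pd.DataFrame(
        {"id": np.arange(1, n + 1), "age_years": ages, "length_cm": lengths}
    )


# ---------------------------------------------------------------------------
# body outlines


def _arc_centerline(length: float, bend_angle: float, n: int = 400) -> np.ndarray:
    """Polyline of given arc length turning ``bend_angle`` radians in total."""
    s = np.linspace(0.0, length, n)
    if abs(bend_angle) < 1e-12:
        return np.column_stack([s, np.zeros_like(s)])
    radius = length / bend_angle
    theta = s / radius
    # arc through the origin, initial heading along +x
    return np.column_stack([radius * np.sin(theta), radius * (1 - np.cos(theta))])


def _resample_ring(ring: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed ring (first==last) to n points at uniform arc length."""
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n + 1)[:-1]
    x = np.interp(t, s, ring[:, 0])
    y = np.interp(t, s, ring[:, 1])
    return np.column_stack([x, y])


def generate_body_polygon(
    centerline_length: float = 250.0,
    width: float = 60.0,
    bend_angle: float = 0.0,
    n_limbs: int = 4,
    limb_length: float = 40.0,
    limb_width: float = 15.0,
    vertex_count: int = 256,
    seed: int | None = None,
) -> tuple[BodyPolygon, float]:
    """Capsule-shaped outline with a known curved head-to-tail length (cm).

    The body is a round-capped buffer of a circular arc; ``centerline_length``
    is the full head-to-tail length along the body's curvature, i.e. the arc
    plus the two end-cap radii — exactly what the midline measurement targets.
    Thin rectangular limbs protrude perpendicular to the body at fixed
    fractions of its length, alternating sides.  Returns the outline (metres,
    GeoJSON-ready) and the ground-truth curved length in cm.
    """
    if not centerline_length > width > 0:
        raise ValueError("need centerline_length > width > 0")
    if vertex_count < 32:
        raise ValueError("vertex_count must be at least 32")
    if n_limbs < 0 or (n_limbs > 0 and (limb_length <= 0 or limb_width <= 0)):
        raise ValueError("invalid limb configuration")
    arc_len = centerline_length - width  # caps contribute width/2 at each end
    if arc_len <= 0:
        raise ValueError("centerline_length must exceed the body width")
    if abs(bend_angle) > 1e-12 and arc_len / abs(bend_angle) <= width / 2:
        raise ValueError(
            "bend too tight: arc radius must exceed half the body width"
        )
    center = _arc_centerline(arc_len, bend_angle)
    body = LineString(center).buffer(width / 2.0, quad_segs=64)

    if n_limbs > 0:
        seg = np.linalg.norm(np.diff(center, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        tangents = np.gradient(center, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        fractions = [LIMB_FRACTIONS[i % len(LIMB_FRACTIONS)] for i in range(n_limbs)]
        parts = [body]
        for i, frac in enumerate(fractions):
            idx = int(np.searchsorted(s, frac * arc_len))
            idx = min(idx, len(center) - 1)
            p = center[idx]
            tan = tangents[idx]
            nrm = np.array([-tan[1], tan[0]]) * (1 if i % 2 == 0 else -1)
            tip = p + nrm * (width / 2.0 + limb_length)
            limb = LineString([p, tip]).buffer(
                limb_width / 2.0, quad_segs=16, cap_style="flat"
            )
            parts.append(limb)
        body = shapely.union_all(parts)
    if body.geom_type != "Polygon" or not body.is_valid:
        raise ValueError("generated configuration self-intersects or is detached")

    ring = np.asarray(body.exterior.coords)
    verts = _resample_ring(ring, vertex_count)
    # counter-clockwise orientation by convention
    if _ShapelyPolygon(verts).exterior.is_ccw is False:
        verts = verts[::-1]
    if seed is not None:
        # digitisation jitter: sub-vertex-spacing noise on the outline
        rng = np.random.default_rng(seed)
        spacing = _ShapelyPolygon(verts).exterior.length / vertex_count
        verts = verts + rng.normal(0.0, 0.02 * spacing, verts.shape)
    poly = BodyPolygon(
        verts / 100.0,  # cm -> metres for the GeoJSON frame
        unit="m",
        properties={"truth_length_cm": float(centerline_length)},
    )
    return poly, float(centerline_length)


def generate_panels(
    sizes=None,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> list[BodyPolygon]:
    """Square calibration panels of known side length (metres).

    Defaults to ten panels spanning 1.2 to 7.5 m.  ``noise_sd`` perturbs the
    realised side length (measurement noise) while the nominal size stays in
    the feature properties.
    """
    if sizes is None:
        sizes = np.linspace(1.2, 7.5, 10)
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("panel sizes must be positive")
    rng = np.random.default_rng(seed)
    panels = []
    for i, s in enumerate(sizes):
        side = s + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        if side <= 0:
            raise ValueError("noise produced a non-positive panel side")
        origin = np.array([i * (sizes.max() + 2.0), 0.0])
        square = box(origin[0], origin[1], origin[0] + side, origin[1] + side)
        coords = np.asarray(square.exterior.coords)[:-1]
        panels.append(
            BodyPolygon(
                coords,
                unit="m",
                properties={"nominal_side_m": float(s), "side_m": float(side)},
            )
        )
    return panels
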