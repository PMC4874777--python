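"""Normalized single-cell coordinate systems for localization microscopy.

Rod-shaped bacteria vary in length, width and curvature, so localizations
from many cells are compared in a normalized frame.  From a sub-pixel cell
boundary, the two regions of largest curvature define the poles; each
boundary side between the poles is divided into equal arc-length regions
whose corresponding points are joined into "ribs"; the polyline through the
rib midpoints (pole to pole) is the centerline.  Every cell then maps onto
a common cylinder:

* X — fractional arc position along the centerline, in [0, 1];
* Y — signed in-plane distance from the centerline divided by the local
  rib half-length;
* Z — axial (optical-axis) distance divided by the same local half-length
  (circular cross-section assumption).

Membrane-localized molecules sit near |Y|, sqrt(Y^2+Z^2) ~ 1; cytoplasmic
molecules fill |Y| < 1.  Density profiles histogram Y over a central slab
(middle 50% of Z, middle 80% of X, which drops the poles), and a
membrane-enrichment index summarises peripheral vs central density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

__all__ = [
    "CellBoundary",
    "CellCoordinateSystem",
    "DensityProfile",
    "extract_boundary",
    "build_coordinate_system",
    "coordinate_system_from_ground_truth",
    "qc_filter_cell",
    "normalize_localizations",
    "density_profile",
    "average_cross_section",
    "membrane_enrichment_index",
]

N_REGIONS = 100  # boundary regions of equal arc length per cell side


@dataclass(frozen=True)
class CellBoundary:
    """Closed, simple boundary polygon (µm, sub-pixel vertices)."""

    vertices: np.ndarray
    source: str = "supplied"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 4:
            raise ValueError("boundary must be an (N,2) array, N >= 4")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("boundary polygon must be simple and non-degenerate")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class CellCoordinateSystem:
    """Poles, sides, ribs and centerline of one cell.

    ``side1``/``side2`` run pole-to-pole in the same direction, sampled at
    101 equal-arc points (100 regions per side).  Rib i joins
    ``side1[i]`` to ``side2[i]``; ribs 0 and 100 are degenerate at the
    poles.  The centerline is the 101 rib midpoints.
    """

    side1: np.ndarray          # (101, 2) µm
    side2: np.ndarray          # (101, 2) µm
    centerline: np.ndarray     # (101, 2) µm
    half_widths: np.ndarray    # (101,) µm, rib half-lengths
    L1: float                  # side arc lengths, µm
    L2: float
    area: float                # µm^2

    @property
    def poles(self) -> np.ndarray:
        return np.vstack([self.centerline[0], self.centerline[-1]])

    @property
    def n_ribs(self) -> int:
        return N_REGIONS

    @property
    def centerline_arc(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length(self) -> float:
        return float(self.centerline_arc[-1])


@dataclass
class DensityProfile:
    """Histogram of localizations along normalized Y."""

    edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray        # normalized to unit area over Y
    n_selected: int
    z_halfwidth: float
    x_window: tuple[float, float]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


# ---------------------------------------------------------------------------
# boundary extraction from a phase-contrast-like image


def extract_boundary(
    image: np.ndarray,
    pixel_um: float = 1.0,
    *,
    invert: bool = False,
    n_levels: int = 40,
) -> CellBoundary:
    """Extract a sub-pixel cell boundary from a single-cell image crop.

    The boundary is the iso-intensity contour lying on the steepest part of
    the edge: candidate levels spanning the image range are scanned and the
    closed contour with the largest mean gradient magnitude along it wins.
    ``invert`` flips contrast first (the result is contrast-symmetric).
    """
    from skimage import measure

    img = np.asarray(image, dtype=float)
    if invert:
        img = -img
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 1e-12:
        raise ValueError("image has no contrast; no closed contour found")
    gy, gx = np.gradient(img)
    gmag = np.hypot(gx, gy)

    def best_at(levels):
        contour, score, lev = None, -np.inf, None
        for level in levels:
            for cand in measure.find_contours(img, level):
                if len(cand) < 40 or not np.allclose(cand[0], cand[-1]):
                    continue
                vals = ndimage.map_coordinates(gmag, cand.T, order=1)
                s = float(vals.mean())
                if s > score:
                    contour, score, lev = cand, s, level
        return contour, lev

    coarse = np.linspace(lo, hi, n_levels + 2)[1:-1]
    best, lev = best_at(coarse)
    if best is None:
        raise ValueError("no closed contour found")
    step = coarse[1] - coarse[0]
    fine, _ = best_at(np.linspace(lev - step, lev + step, n_levels))
    if fine is not None:
        best = fine
    # contour is (row, col); map to (x, y) in µm
    xy = np.column_stack([best[:, 1], best[:, 0]]) * pixel_um
    return CellBoundary(xy, source="image iso-contour")


# ---------------------------------------------------------------------------
# coordinate-system construction


def _resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points of equal arc length."""
    v = np.vstack([vertices, vertices[0]])
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, v[:, 0])
    y = np.interp(target, s, v[:, 1])
    return np.column_stack([x, y])


def _resample_open(pts: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    return np.column_stack([x, y])


def _curvature_closed(pts: np.ndarray) -> np.ndarray:
    """Signed curvature of a closed equal-arc-sampled polyline."""
    x, y = pts[:, 0], pts[:, 1]
    dx = (np.roll(x, -1) - np.roll(x, 1)) / 2.0
    dy = (np.roll(y, -1) - np.roll(y, 1)) / 2.0
    ddx = np.roll(x, -1) - 2 * x + np.roll(x, 1)
    ddy = np.roll(y, -1) - 2 * y + np.roll(y, 1)
    denom = (dx * dx + dy * dy) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (dx * ddy - dy * ddx) / np.where(denom > 0, denom, np.inf)
    return k


def _plateau_center(kappa: np.ndarray, i: int, frac: float = 0.8) -> int:
    """Midpoint of the contiguous high-curvature run containing i.

    A spherocylinder cap has constant curvature, so the raw argmax lands
    anywhere on the cap; the run midpoint is the geometric pole tip.
    """
    n = len(kappa)
    thresh = frac * kappa[i]
    left = i
    while kappa[(left - 1) % n] >= thresh and (i - left) < n // 2:
        left -= 1
    right = i
    while kappa[(right + 1) % n] >= thresh and (right - i) < n // 2:
        right += 1
    return ((left + right) // 2) % n


def build_coordinate_system(
    boundary: CellBoundary,
    *,
    n_samples: int = 400,
    smooth_sigma: float = 2.0,
    min_pole_separation: float = 0.25,
    degeneracy_ratio: float = 1.5,
) -> CellCoordinateSystem:
    """Build poles, sides, ribs and centerline from a boundary.

    The boundary is resampled to equal arc length and Gaussian-smoothed
    (sigma in vertices) before curvature estimation; the poles are the two
    curvature maxima separated by at least ``min_pole_separation`` of the
    perimeter.  A near-circular boundary, whose curvature maxima do not
    stand out from the median by ``degeneracy_ratio``, raises a
    degenerate-geometry error.
    """
    if len(boundary.vertices) < 40:
        raise ValueError("need >= 40 boundary vertices for curvature estimation")
    pts = _resample_closed(boundary.vertices, n_samples)
    sm = np.column_stack(
        [
            ndimage.gaussian_filter1d(pts[:, 0], smooth_sigma, mode="wrap"),
            ndimage.gaussian_filter1d(pts[:, 1], smooth_sigma, mode="wrap"),
        ]
    )
    kappa = np.abs(_curvature_closed(sm))
    med = float(np.median(kappa))
    i1 = _plateau_center(kappa, int(np.argmax(kappa)))
    min_sep = int(min_pole_separation * n_samples)
    idx = np.arange(n_samples)
    sep = np.minimum((idx - i1) % n_samples, (i1 - idx) % n_samples)
    far = sep >= min_sep
    if not far.any():
        raise ValueError("degenerate geometry: poles indistinguishable")
    i2 = _plateau_center(kappa, int(idx[far][np.argmax(kappa[far])]))
    if med <= 0 or kappa[i1] / med < degeneracy_ratio or kappa[i2] / med < degeneracy_ratio:
        raise ValueError("degenerate geometry: near-circular boundary")
    a, b = sorted((i1, i2))
    side1_pts = sm[a : b + 1]
    side2_pts = np.vstack([sm[b:], sm[: a + 1]])[::-1]  # reversed: pole a -> pole b
    s1 = _resample_open(side1_pts, N_REGIONS + 1)
    s2 = _resample_open(side2_pts, N_REGIONS + 1)
    L1 = float(np.linalg.norm(np.diff(side1_pts, axis=0), axis=1).sum())
    L2 = float(np.linalg.norm(np.diff(side2_pts, axis=0), axis=1).sum())
    centerline = 0.5 * (s1 + s2)
    half_widths = 0.5 * np.linalg.norm(s1 - s2, axis=1)
    return CellCoordinateSystem(
        side1=s1, side2=s2, centerline=centerline, half_widths=half_widths,
        L1=L1, L2=L2, area=boundary.area,
    )


def coordinate_system_from_ground_truth(
    centerline: np.ndarray,
    half_widths: np.ndarray,
    area: float | None = None,
) -> CellCoordinateSystem:
    """Build an exact coordinate system from a known centerline and local
    half-width profile (synthetic cells).  Sides are offset along the local
    normal; by construction L1 = L2 up to curvature effects."""
    cl = _resample_open(np.asarray(centerline, dtype=float), N_REGIONS + 1)
    src = np.asarray(centerline, dtype=float)
    seg = np.linalg.norm(np.diff(src, axis=0), axis=1)
    s_src = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.linspace(0.0, s_src[-1], N_REGIONS + 1)
    hw = np.interp(s_new, s_src, np.asarray(half_widths, dtype=float))
    tan = np.gradient(cl, axis=0)
    tan /= np.maximum(np.linalg.norm(tan, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tan[:, 1], tan[:, 0]])
    s1 = cl + normal * hw[:, None]
    s2 = cl - normal * hw[:, None]
    L1 = float(np.linalg.norm(np.diff(s1, axis=0), axis=1).sum())
    L2 = float(np.linalg.norm(np.diff(s2, axis=0), axis=1).sum())
    if area is None:
        area = Polygon(np.vstack([s1, s2[::-1]])).area
    return CellCoordinateSystem(
        side1=s1, side2=s2, centerline=cl, half_widths=hw,
        L1=L1, L2=L2, area=float(area),
    )


def qc_filter_cell(
    cs: CellCoordinateSystem,
    *,
    max_side_ratio: float = 1.2,
    max_area_um2: float = 3.0,
) -> tuple[bool, str]:
    """Reject spurious or filamentous cells.

    Pass requires the two side lengths within 20% of each other
    (max/min <= 1.2, boundary equality passes) and total area <= 3 µm².
    """
    ratio = max(cs.L1, cs.L2) / min(cs.L1, cs.L2)
    if ratio > max_side_ratio:
        return False, "asymmetry: side lengths differ by more than 20%"
    if cs.area > max_area_um2:
        return False, "area exceeds 3 um^2"
    return True, "ok"


# ---------------------------------------------------------------------------
# localization normalization


def normalize_localizations(
    cs: CellCoordinateSystem,
    localizations_nm: np.ndarray | pd.DataFrame,
    *,
    outlier_y: float = 1.2,
) -> pd.DataFrame:
    """Map (x, y, z) localizations (nm) into normalized (X, Y, Z).

    Each localization is projected onto the centerline polyline; X is the
    arc fraction of the projection, Y the signed in-plane offset divided by
    the local rib half-length (linearly interpolated along the centerline),
    and Z the axial offset divided by the same half-length.  |Y| beyond
    ``outlier_y`` is flagged (localization error straddles the membrane, so
    slightly-outside points are kept, not dropped).
    """
    if isinstance(localizations_nm, pd.DataFrame):
        pts = localizations_nm[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(localizations_nm, dtype=float).reshape(-1, 3)
    cl = cs.centerline
    if len(cl) < 2:
        raise ValueError("empty centerline")
    arc = cs.centerline_arc
    total = arc[-1]
    p_um = pts[:, :2] / 1000.0
    z_um = pts[:, 2] / 1000.0

    a = cl[:-1]                      # (S,2) segment starts
    d = cl[1:] - cl[:-1]             # (S,2)
    seg_len2 = np.maximum((d * d).sum(axis=1), 1e-18)
    seg_len = np.sqrt(seg_len2)
    X = np.empty(len(pts))
    Y = np.empty(len(pts))
    Z = np.empty(len(pts))
    chunk = 4096
    for start in range(0, len(pts), chunk):
        p = p_um[start : start + chunk]                      # (B,2)
        diff = p[:, None, :] - a[None, :, :]                 # (B,S,2)
        t = np.clip((diff * d[None]).sum(-1) / seg_len2, 0.0, 1.0)
        proj = a[None] + t[..., None] * d[None]
        dist2 = ((p[:, None, :] - proj) ** 2).sum(-1)
        j = np.argmin(dist2, axis=1)
        rows = np.arange(len(p))
        tj = t[rows, j]
        s = arc[j] + tj * seg_len[j]
        tangent = d[j] / seg_len[j, None]
        off = p - proj[rows, j]
        signed = tangent[:, 0] * off[:, 1] - tangent[:, 1] * off[:, 0]
        hw = np.maximum(np.interp(s, arc, cs.half_widths), 1e-9)
        sl = slice(start, start + len(p))
        X[sl] = s / total
        Y[sl] = signed / hw
        Z[sl] = z_um[sl] / hw
    out = pd.DataFrame({"X": X, "Y": Y, "Z": Z})
    out["outlier"] = out["Y"].abs() > outlier_y
    return out


def density_profile(
    normalized: pd.DataFrame,
    *,
    z_halfwidth: float = 0.5,
    x_window: tuple[float, float] = (0.1, 0.9),
    n_bins: int = 40,
    y_range: tuple[float, float] = (-1.0, 1.0),
    normalize: bool = True,
) -> DensityProfile:
    """Histogram normalized Y over the central slab.

    Selects |Z| <= ``z_halfwidth`` (middle 50% of the Z range by default)
    and X in ``x_window`` (middle 80%, removing molecules at the poles).
    ``density`` integrates to one over the Y range when normalized.
    """
    sel = normalized[
        (normalized["Z"].abs() <= z_halfwidth)
        & (normalized["X"] >= x_window[0])
        & (normalized["X"] <= x_window[1])
    ]
    edges = np.linspace(y_range[0], y_range[1], n_bins + 1)
    counts, _ = np.histogram(sel["Y"].to_numpy(), bins=edges)
    n = int(counts.sum())
    if n == 0:
        warnings.warn("no localizations selected; empty profile")
        density = np.zeros(n_bins)
    else:
        width = edges[1] - edges[0]
        density = counts / (n * width) if normalize else counts.astype(float)
    return DensityProfile(
        edges=edges, counts=counts, density=density, n_selected=n,
        z_halfwidth=z_halfwidth, x_window=x_window,
    )


def average_cross_section(
    normalized: pd.DataFrame,
    axis: str = "short",
    *,
    x_window: tuple[float, float] = (0.1, 0.9),
    slice_halfwidth: float | None = None,
    slice_coord: str | None = None,
    n_bins: int = 50,
    extent: float = 1.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render an average cross-section 2-D histogram over many cells.

    ``axis="short"`` images (Y, Z) — the view down the cell's long axis;
    ``axis="long"`` images (X, Y) with X restricted to ``x_window`` to drop
    the poles.  An optional slab selection keeps |slice_coord| <=
    ``slice_halfwidth`` in normalized units (the physical 150-nm slice is
    converted per cell by its mean rib half-length upstream).  Returns
    (histogram, edges_axis1, edges_axis2); the histogram total equals the
    number of selected localizations.
    """
    df = normalized
    if slice_halfwidth is not None:
        coord = slice_coord or ("Y" if axis == "short" else "Z")
        df = df[df[coord].abs() <= slice_halfwidth]
    if axis == "short":
        u, v = df["Y"].to_numpy(), df["Z"].to_numpy()
        e1 = np.linspace(-extent, extent, n_bins + 1)
        e2 = np.linspace(-extent, extent, n_bins + 1)
    elif axis == "long":
        df = df[(df["X"] >= x_window[0]) & (df["X"] <= x_window[1])]
        u, v = df["X"].to_numpy(), df["Y"].to_numpy()
        e1 = np.linspace(x_window[0], x_window[1], n_bins + 1)
        e2 = np.linspace(-extent, extent, n_bins + 1)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    H, e1, e2 = np.histogram2d(u, v, bins=(e1, e2))
    return H, e1, e2


def membrane_enrichment_index(
    profile: DensityProfile,
    *,
    peripheral: tuple[float, float] = (0.75, 1.0),
    central: float = 0.5,
) -> float:
    """Peripheral / central mean density ratio.

    MEI = mean density over 0.75 <= |Y| <= 1 divided by mean density over
    |Y| <= 0.5; values above 1 indicate membrane enrichment.  Returns
    ``inf`` when the central density is zero (pure membrane shell).
    """
    y = profile.centers
    dens = profile.density
    per = dens[(np.abs(y) >= peripheral[0]) & (np.abs(y) <= peripheral[1])]
    cen = dens[np.abs(y) <= central]
    per_mean = per.mean() if len(per) else 0.0
    cen_mean = cen.mean() if len(cen) else 0.0
    if cen_mean == 0.0:
        return math.inf
    return float(per_mean / cen_mean)
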