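"""Synthetic data generators with the statistical structure of each assay.

Three families of generators make the whole pipeline testable without any
external data:

* decay time courses — per-species trajectories drawn from the delayed
  exponential-plus-baseline model with Poisson counting noise, per-sample
  depth factors, and constant spike-ins;
* cells and localizations — spherocylindrical (optionally bent) cell
  outlines with ground-truth centerline/half-width profiles, plus
  membrane-shell, uniform-volume or nucleoid-depleted 3-D point patterns;
* a toy proteome — protein/CDS records with transmembrane spans, signal
  flags, location labels, genome coordinates and abundances, for
  exercising library design, probe partitioning and group statistics.

All generators are deterministic for a fixed spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import ECOLI_CODON_USAGE, sample_codon
from .decay import evaluate_decay_model
from .fusion import ProteinRecord
from .groupstats import LOCATIONS

__all__ = [
    "DEFAULT_TIME_POINTS",
    "DecaySimSpec",
    "CellSimSpec",
    "LocalizationPattern",
    "SimulatedCell",
    "simulate_decay_counts",
    "simulate_cells",
    "simulate_localizations",
    "simulate_proteome",
    "phase_image",
]

#: default rifampicin time grid: 8 points, 0 through 20 minutes
DEFAULT_TIME_POINTS = (0.0, 1.0, 2.0, 4.0, 6.0, 9.0, 14.0, 20.0)

#: default per-parameter (low, high) sampling ranges: t=0 counts of a few
#: hundred to a few thousand, small stable baselines, half-lives ~1-15 min,
#: transcription-completion delays up to 5 min
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "N0": (500.0, 5000.0),
    "Nf": (5.0, 50.0),
    "k": (math.log(2) / 15.0, math.log(2) / 1.0),
    "alpha": (0.0, 5.0),
}

#: four spike-in species at fixed copies per cell
DEFAULT_SPIKEINS: dict[str, float] = {
    "spike1": 100.0,
    "spike2": 300.0,
    "spike3": 1000.0,
    "spike4": 3000.0,
}


@dataclass(frozen=True)
class DecaySimSpec:
    """Configuration of a synthetic decay-count experiment."""

    n_species: int = 100
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    param_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_RANGES)
    )
    spikein_copies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPIKEINS)
    )
    depth_factors: tuple[float, ...] | None = None
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.time_points, dtype=float)
        if len(t) < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_points must start at 0 and strictly increase")
        for name in ("N0", "Nf", "k", "alpha"):
            if name not in self.param_ranges:
                raise ValueError(f"param_ranges missing {name!r}")
            lo, hi = self.param_ranges[name]
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.param_ranges["N0"][0] <= 0 or self.param_ranges["k"][0] <= 0:
            raise ValueError("N0 and k ranges must be positive")
        # the rate range must allow half-lives inside the sampled window
        if math.log(2) / self.param_ranges["k"][1] > t[-1]:
            raise ValueError("k range yields no half-life within the time window")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.depth_factors is not None:
            d = np.asarray(self.depth_factors, dtype=float)
            if len(d) != len(t) or np.any(d <= 0):
                raise ValueError("depth_factors must be positive, one per time point")


def simulate_decay_counts(spec: DecaySimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-species decay trajectories and spike-in rows.

    Returns ``(counts, truth)``: counts is a (genes + spike-ins) × time
    table whose expected values follow the decay model times the per-sample
    depth factor (spike-ins are constant across time before depth); truth
    records the sampled (N0, Nf, k, alpha, tau) per species.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.time_points, dtype=float)
    depth = (
        np.ones(len(t))
        if spec.depth_factors is None
        else np.asarray(spec.depth_factors, dtype=float)
    )
    names = [f"gene{i:04d}" for i in range(spec.n_species)]
    truth_rows, expected = [], []
    for name in names:
        p = {
            key: rng.uniform(*spec.param_ranges[key])
            for key in ("N0", "Nf", "k", "alpha")
        }
        truth_rows.append({"species_id": name, **p, "tau": math.log(2) / p["k"]})
        expected.append(evaluate_decay_model(p["N0"], p["Nf"], p["k"], p["alpha"], t))
    for sname, copies in spec.spikein_copies.items():
        names.append(sname)
        expected.append(np.full(len(t), float(copies)))
    exp = np.asarray(expected) * depth[None, :]
    if spec.noise == "poisson":
        data = rng.poisson(exp).astype(float)
    else:
        data = exp
    counts = pd.DataFrame(data, index=names, columns=[f"{v:g}" for v in t])
    truth = pd.DataFrame(truth_rows).set_index("species_id")
    return counts, truth


# ---------------------------------------------------------------------------
# cells and localizations


@dataclass(frozen=True)
class CellSimSpec:
    """Spherocylindrical cell population parameters (µm)."""

    length_um: tuple[float, float] = (3.0, 0.3)   # mean, sd
    width_um: tuple[float, float] = (1.0, 0.05)
    bend_curvature: float = 0.0                   # 1/µm
    n_cells: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.length_um[0] <= 0 or self.width_um[0] <= 0 or self.n_cells < 0:
            raise ValueError("lengths, widths and counts must be positive")
        if self.width_um[0] >= self.length_um[0]:
            raise ValueError("mean width must be smaller than mean length")


@dataclass(frozen=True)
class LocalizationPattern:
    """A 3-D point pattern inside/on a cell."""

    kind: str = "membrane_shell"   # membrane_shell | uniform_volume | nucleoid_depleted
    n_points: int = 1000
    position_noise_nm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("membrane_shell", "uniform_volume", "nucleoid_depleted"):
            raise ValueError(f"unknown localization pattern {self.kind!r}")
        if self.n_points < 0 or self.position_noise_nm < 0:
            raise ValueError("n_points and noise must be non-negative")


@dataclass(frozen=True)
class SimulatedCell:
    """A synthetic cell outline with its ground truth geometry.

    The straight-frame axis runs from -length/2 to +length/2; bent cells
    are the straight cell mapped through a constant-curvature arc.
    ``centerline``/``half_widths`` are the mapped ground truth (µm).
    """

    boundary: np.ndarray       # (N, 2) µm, closed outline (first != last)
    centerline: np.ndarray     # (M, 2) µm, pole to pole
    half_widths: np.ndarray    # (M,) µm local radius profile
    length: float
    width: float
    curvature: float

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def poles(self) -> np.ndarray:
        return np.vstack([self.centerline[0], self.centerline[-1]])


def _bend(xy: np.ndarray, curvature: float) -> np.ndarray:
    """Map straight-frame points through a constant-curvature arc.

    Arc length along y=0 is preserved and perpendicular offsets stay
    perpendicular; curvature 0 is the identity.
    """
    if curvature == 0.0:
        return xy
    rho = 1.0 / curvature
    phi = xy[:, 0] / rho
    r = rho - xy[:, 1]
    return np.column_stack([r * np.sin(phi), rho - r * np.cos(phi)])


def _spherocylinder_outline(length: float, width: float, n_vertices: int) -> np.ndarray:
    """Closed outline sampled uniformly in arc length (straight frame)."""
    R = width / 2.0
    c = length - width          # cylinder section length
    P = 2.0 * c + 2.0 * math.pi * R
    s = np.linspace(0.0, P, n_vertices, endpoint=False)
    pts = np.empty((n_vertices, 2))
    for i, si in enumerate(s):
        if si < c:                                   # top side, left to right
            pts[i] = (-c / 2.0 + si, R)
        elif si < c + math.pi * R:                   # right cap
            th = (si - c) / R                        # 0..pi from top
            pts[i] = (c / 2.0 + R * math.sin(th), R * math.cos(th))
        elif si < 2.0 * c + math.pi * R:             # bottom side, right to left
            pts[i] = (c / 2.0 - (si - c - math.pi * R), -R)
        else:                                        # left cap
            th = (si - 2.0 * c - math.pi * R) / R    # 0..pi from bottom
            pts[i] = (-c / 2.0 - R * math.sin(th), -R * math.cos(th))
    return pts


def simulate_cells(spec: CellSimSpec, *, n_vertices: int = 400,
                   n_centerline: int = 201) -> list[SimulatedCell]:
    """Sample cell outlines with ground truth poles/centerline/half-widths."""
    rng = np.random.default_rng(spec.seed)
    cells = []
    for _ in range(spec.n_cells):
        length = max(rng.normal(*spec.length_um), 3.0 * spec.width_um[0])
        width = float(np.clip(rng.normal(*spec.width_um), 0.2, length * 0.9))
        R = width / 2.0
        outline = _spherocylinder_outline(length, width, n_vertices)
        ax = np.linspace(-length / 2.0, length / 2.0, n_centerline)
        c_half = (length - width) / 2.0
        hw = np.where(
            np.abs(ax) <= c_half,
            R,
            np.sqrt(np.maximum(R * R - (np.abs(ax) - c_half) ** 2, 0.0)),
        )
        hw = np.maximum(hw, 1e-6)
        cl = np.column_stack([ax, np.zeros_like(ax)])
        cells.append(
            SimulatedCell(
                boundary=_bend(outline, spec.bend_curvature),
                centerline=_bend(cl, spec.bend_curvature),
                half_widths=hw,
                length=float(length),
                width=float(width),
                curvature=spec.bend_curvature,
            )
        )
    return cells


def _sample_straight(cell: SimulatedCell, pattern: LocalizationPattern,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample the pattern in the straight cell frame, (n, 3) in µm."""
    n = pattern.n_points
    R = cell.radius
    c = cell.length - cell.width          # cylinder section length
    if pattern.kind == "membrane_shell":
        area_cyl = 2.0 * math.pi * R * c
        area_caps = 4.0 * math.pi * R * R     # two hemispheres
        on_cyl = rng.random(n) < area_cyl / (area_cyl + area_caps)
        x = np.empty(n); y = np.empty(n); z = np.empty(n)
        m = on_cyl.sum()
        x[on_cyl] = rng.uniform(-c / 2.0, c / 2.0, m)
        th = rng.uniform(0.0, 2.0 * math.pi, m)
        y[on_cyl], z[on_cyl] = R * np.cos(th), R * np.sin(th)
        mc = n - m
        v = rng.normal(size=(mc, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sign = np.where(v[:, 0] >= 0, 1.0, -1.0)
        x[~on_cyl] = sign * c / 2.0 + R * v[:, 0]
        y[~on_cyl], z[~on_cyl] = R * v[:, 1], R * v[:, 2]
        pts = np.column_stack([x, y, z])
    elif pattern.kind in ("uniform_volume", "nucleoid_depleted"):
        pts = _sample_volume(n, R, c, rng)
        if pattern.kind == "nucleoid_depleted":
            # nucleoid emulated as a coaxial cylinder (radius 0.6 R over the
            # central 60% of the cell length) that excludes localizations
            def in_nucleoid(p):
                r = np.hypot(p[:, 1], p[:, 2])
                return (r < 0.6 * R) & (np.abs(p[:, 0]) < 0.3 * cell.length)

            bad = in_nucleoid(pts)
            while bad.any():
                pts[bad] = _sample_volume(int(bad.sum()), R, c, rng)
                bad = in_nucleoid(pts)
    else:  # pragma: no cover - guarded by LocalizationPattern
        raise ValueError(pattern.kind)
    if pattern.position_noise_nm > 0:
        pts = pts + rng.normal(0.0, pattern.position_noise_nm / 1000.0, pts.shape)
    return pts


def _sample_volume(n: int, R: float, c: float, rng: np.random.Generator) -> np.ndarray:
    vol_cyl = math.pi * R * R * c
    vol_sph = 4.0 / 3.0 * math.pi * R**3
    in_cyl = rng.random(n) < vol_cyl / (vol_cyl + vol_sph)
    x = np.empty(n); y = np.empty(n); z = np.empty(n)
    m = int(in_cyl.sum())
    x[in_cyl] = rng.uniform(-c / 2.0, c / 2.0, m)
    r = R * np.sqrt(rng.random(m))
    th = rng.uniform(0.0, 2.0 * math.pi, m)
    y[in_cyl], z[in_cyl] = r * np.cos(th), r * np.sin(th)
    ms = n - m
    v = rng.normal(size=(ms, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    rr = R * rng.random(ms) ** (1.0 / 3.0)
    b = v * rr[:, None]
    x[~in_cyl] = np.where(b[:, 0] >= 0, c / 2.0, -c / 2.0) + b[:, 0]
    y[~in_cyl], z[~in_cyl] = b[:, 1], b[:, 2]
    return np.column_stack([x, y, z])


def simulate_localizations(
    cell: SimulatedCell, pattern: LocalizationPattern
) -> pd.DataFrame:
    """Sample a localization list (columns x_nm, y_nm, z_nm) for one cell.

    Membrane-shell points lie exactly on the spherocylinder surface before
    noise; uniform-volume points are uniform in the enclosed volume.  Bent
    cells sample in the straight frame and map in-plane coordinates through
    the bend (z is unchanged).
    """
    rng = np.random.default_rng(pattern.seed)
    pts = _sample_straight(cell, pattern, rng)
    xy = _bend(pts[:, :2], cell.curvature)
    out = np.column_stack([xy, pts[:, 2]]) * 1000.0
    return pd.DataFrame(out, columns=["x_nm", "y_nm", "z_nm"])


# ---------------------------------------------------------------------------
# toy proteome


_HYDROPHOBIC = "AILVFM"
_GENERAL_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(length: int, rng: np.random.Generator,
                    tm_spans: Sequence[tuple[int, int]] = ()) -> str:
    aa = list(rng.choice(list(_GENERAL_AA), size=length))
    aa[0] = "M"
    for s, e in tm_spans:
        for i in range(s - 1, e):
            aa[i] = str(rng.choice(list(_HYDROPHOBIC)))
    return "".join(aa)


def simulate_proteome(
    n_genes: int,
    composition: Mapping[str, float] | None = None,
    usage: Mapping[str, float] = ECOLI_CODON_USAGE,
    seed: int = 0,
    *,
    length_range: tuple[int, int] = (80, 400),
    operon_fraction: float = 0.3,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a toy annotated proteome/transcriptome.

    ``composition`` maps location labels to fractions (must sum to 1);
    default mirrors a roughly E. coli-like mix.  Inner-membrane proteins
    get 2-4 transmembrane spans; periplasmic/outer-membrane/extracellular
    proteins are signal-peptide positive.  Returns the protein records and
    an annotation table (start, end, strand, location, copies_per_cell,
    operon_id) with non-overlapping gene coordinates.
    """
    if composition is None:
        composition = {
            "cytoplasm": 0.55,
            "inner membrane": 0.22,
            "periplasm": 0.1,
            "outer membrane": 0.06,
            "extracellular": 0.02,
            "unknown": 0.05,
        }
    fractions = np.array([composition.get(loc, 0.0) for loc in LOCATIONS])
    if not math.isclose(fractions.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"composition fractions sum to {fractions.sum()}, not 1")
    rng = np.random.default_rng(seed)
    records, rows = [], []
    genome_pos = 1000
    operon_id = 0
    operon_left = 0
    for i in range(n_genes):
        loc = str(rng.choice(LOCATIONS, p=fractions))
        length = int(rng.integers(*length_range))
        tm_spans: tuple[tuple[int, int], ...] = ()
        signalp = False
        if loc == "inner membrane":
            n_tm = int(rng.integers(2, 5))
            spans = []
            pos = int(rng.integers(5, 25))
            for _ in range(n_tm):
                w = int(rng.integers(18, 24))
                if pos + w > length - 2:
                    break
                spans.append((pos, pos + w - 1))
                pos += w + int(rng.integers(5, 30))
            while len(spans) < 2:   # guarantee >= 2 TM spans
                length += 60
                base = (spans[-1][1] + 10) if spans else 10
                spans.append((base, base + 19))
            tm_spans = tuple(spans)
        elif loc in ("periplasm", "outer membrane", "extracellular"):
            signalp = True
        seq = _random_protein(length, rng, tm_spans)
        cds = "".join(sample_codon(a, usage, rng) for a in seq)
        gene = f"g{i:04d}"
        records.append(
            ProteinRecord(gene, seq, cds, tm_spans, signalp, loc)
        )
        if operon_left == 0:
            operon_id += 1
            operon_left = int(rng.integers(1, 5)) if rng.random() < operon_fraction else 1
        operon_left -= 1
        start = genome_pos
        end = start + len(cds) - 1
        genome_pos = end + int(rng.integers(50, 400))
        rows.append(
            {
                "gene": gene,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "location": loc,
                "copies_per_cell": float(np.exp(rng.normal(1.5, 1.5))),
                "operon_id": f"op{operon_id:04d}",
            }
        )
    annotation = pd.DataFrame(rows).set_index("gene")
    return records, annotation


# ---------------------------------------------------------------------------
# phase-contrast-like image


def phase_image(
    cell: SimulatedCell,
    pixel_um: float = 0.05,
    pad_um: float = 0.6,
    edge_sigma_um: float = 0.08,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Render a sigmoid-edged phase-contrast-like image of one cell.

    Cells appear dark on a bright background with a smooth intensity edge
    centered on the true outline.  Returns (image, pixel size, origin) —
    image[i, j] sits at x = origin[0] + j*pixel, y = origin[1] + i*pixel.
    """
    import shapely
    from shapely.geometry import Polygon

    poly = Polygon(cell.boundary)
    minx, miny, maxx, maxy = poly.bounds
    x0, y0 = minx - pad_um, miny - pad_um
    nx = int(math.ceil((maxx - minx + 2 * pad_um) / pixel_um))
    ny = int(math.ceil((maxy - miny + 2 * pad_um) / pixel_um))
    xs = x0 + pixel_um * np.arange(nx)
    ys = y0 + pixel_um * np.arange(ny)
    XX, YY = np.meshgrid(xs, ys)
    pts = shapely.points(XX.ravel(), YY.ravel())
    dist = shapely.distance(poly.exterior, pts).reshape(ny, nx)
    inside = shapely.contains_xy(poly, XX.ravel(), YY.ravel()).reshape(ny, nx)
    signed = np.where(inside, -dist, dist)
    image = 1.0 / (1.0 + np.exp(-signed / edge_sigma_um))   # dark inside
    return image, pixel_um, np.array([x0, y0])
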