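"""Multi-core fiber phased-array model.

A fiber bundle (e.g. Fujikura FIGH-350S: ~10,000 single-mode cores inside a
~350 um facet) acts as a discrete phased array: each core transmits one
piston phase.  This module provides

* synthetic core maps (random-dart placement with a minimum spacing),
* sampling a full-resolution phase image at the core centers,
* rendering a per-core phase vector back onto the grid as filled disks of
  uniform amplitude (the binary core-map amplitude of the facet),
* a simulated analog of digital optical phase conjugation (DOPC): per-core
  optical-path-difference (OPD) phase offsets and their conjugate
  compensation layer.

Phase layers displayed on the SLM stack additively at the facet plane, so a
hologram carries its OPD offsets as separate layers that are summed before
wrapping; a distortion followed by its exact conjugate cancels to the bit.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import FileFormatError, GeometryError, OutOfBoundsError, PackingError
from .fields import ComplexField, propagate

__all__ = [
    "CoreMap",
    "CoreHologram",
    "OPDMap",
    "make_synthetic_core_map",
    "sample_core_phases",
    "render_core_field",
    "core_pixel_indices",
    "disk_pixel_indices",
    "apply_opd",
    "conjugate_compensation",
    "random_opd",
    "reconstruct_far_field",
    "save_core_map",
    "load_core_map",
]

TWO_PI = 2.0 * np.pi


def wrap_phase(phi: np.ndarray | float) -> np.ndarray:
    """Wrap phases into [0, 2*pi)."""
    return np.mod(phi, TWO_PI)


@dataclass(frozen=True)
class CoreMap:
    """Fiber-core center positions (um) with a common core radius.

    ``centers`` is an (n, 2) array of (x, y) physical coordinates relative
    to the facet center; all cores must fit inside the facet disk and be
    pairwise separated by more than twice the core radius so the rendered
    disks never overlap.
    """

    centers: np.ndarray
    core_radius: float
    facet_diameter: float

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 1:
            raise GeometryError("centers must be an (n, 2) array with n >= 1")
        if not self.core_radius > 0:
            raise GeometryError("core radius must be positive")
        if not self.facet_diameter > 0:
            raise GeometryError("facet diameter must be positive")
        r = np.hypot(c[:, 0], c[:, 1])
        if np.any(r > self.facet_diameter / 2.0 - self.core_radius + 1e-9):
            raise GeometryError("all cores must lie inside the facet disk")
        object.__setattr__(self, "centers", c)

    @property
    def n_cores(self) -> int:
        return self.centers.shape[0]

    def min_center_distance(self) -> float:
        """Smallest pairwise center distance (inf for a single core)."""
        if self.n_cores < 2:
            return np.inf
        d, _ = cKDTree(self.centers).query(self.centers, k=2)
        return float(d[:, 1].min())

    def validate_spacing(self, min_spacing: float | None = None) -> None:
        """Raise if cores overlap (or violate an explicit minimum spacing)."""
        required = 2.0 * self.core_radius if min_spacing is None else min_spacing
        if self.min_center_distance() < required:
            raise GeometryError(
                f"core spacing {self.min_center_distance():.3f} um below required "
                f"{required:.3f} um")


@dataclass(frozen=True)
class CoreHologram:
    """Per-core piston phases in [0, 2*pi), plus optional additive phase layers.

    ``base`` holds the wrapped encoded phases.  OPD distortions and their
    conjugate compensations are kept as separate offset layers; ``phases``
    sums the layers first (so an exact conjugate pair cancels identically)
    and wraps once.
    """

    base: np.ndarray
    offsets: tuple = ()

    def __post_init__(self):
        b = np.asarray(self.base, dtype=float).ravel()
        if b.size < 1 or not np.all(np.isfinite(b)):
            raise GeometryError("hologram phases must be a non-empty finite vector")
        object.__setattr__(self, "base", wrap_phase(b))
        for off in self.offsets:
            if np.asarray(off).shape != b.shape:
                raise GeometryError("offset layer length must match the hologram")

    @property
    def n_cores(self) -> int:
        return self.base.size

    @property
    def phases(self) -> np.ndarray:
        """Effective wrapped phases including all offset layers."""
        if not self.offsets:
            return self.base
        total = np.sum(np.stack([np.asarray(o, dtype=float) for o in self.offsets]),
                       axis=0)
        return wrap_phase(self.base + total)


@dataclass(frozen=True)
class OPDMap:
    """Per-core optical-path-difference phase offsets (radians, unwrapped)."""

    phases: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.phases, dtype=float).ravel()
        if p.size < 1 or not np.all(np.isfinite(p)):
            raise GeometryError("OPD offsets must be a non-empty finite vector")
        object.__setattr__(self, "phases", p)


def make_synthetic_core_map(n_cores: int, core_radius: float = 1.0,
                            min_spacing: float = 3.3,
                            facet_diameter: float = 350.0,
                            seed: int | None = 0,
                            method: str = "auto",
                            max_attempts: int | None = None) -> CoreMap:
    """Generate a synthetic core distribution; reproducible for a fixed seed.

    Two placement strategies:

    ``"darts"``
        Random-dart placement with rejection until the spacing constraint
        holds.  Fully disordered, but jams near ~55% exclusion-disk
        coverage, so it cannot reach close-packed densities.
    ``"hex"``
        Jittered hexagonal lattice: sites of a hexagonal lattice inside the
        facet, each displaced by an independent random jitter small enough
        to preserve the minimum spacing, then randomly thinned to
        ``n_cores``.  This is what dense real bundles (FIGH-350S: ~10,000
        cores at ~3.3 um pitch in a 350 um facet) look like.
    ``"auto"`` (default)
        Darts when the requested density is comfortably below the dart
        jamming limit, hexagonal otherwise.

    Defaults emulate a FIGH-350S-like bundle.  A single requested core is
    placed at the facet center.
    """
    if n_cores < 1:
        raise PackingError("n_cores must be >= 1")
    if min_spacing <= 2.0 * core_radius:
        raise PackingError("min_spacing must exceed twice the core radius "
                           "(disks must not overlap)")
    r_max = facet_diameter / 2.0 - core_radius
    if r_max <= 0:
        raise PackingError("facet too small for the core radius")
    if n_cores == 1:
        return CoreMap(np.zeros((1, 2)), core_radius, facet_diameter)

    coverage = (n_cores * np.pi * (min_spacing / 2.0) ** 2
                / (np.pi * (r_max + min_spacing / 2) ** 2))
    if method == "auto":
        method = "darts" if coverage <= 0.45 else "hex"
    if method == "hex":
        return _hex_core_map(n_cores, core_radius, min_spacing, facet_diameter,
                             r_max, seed)
    if method != "darts":
        raise PackingError(f"unknown placement method {method!r}")
    if coverage > 0.547:  # random sequential adsorption jamming coverage
        raise PackingError(
            f"requested exclusion coverage {coverage:.2f} exceeds the random-dart "
            "jamming limit (~0.55): reduce the density or use method='hex'")

    rng = np.random.default_rng(seed)
    budget = max_attempts if max_attempts is not None else max(200_000, 400 * n_cores)
    placed = np.empty((n_cores, 2))
    count = 0
    min_sq = min_spacing ** 2
    # coarse grid acceleration for neighbor queries
    cell = min_spacing
    grid: dict[tuple[int, int], list[int]] = {}
    attempts = 0
    while count < n_cores:
        if attempts >= budget:
            raise PackingError(
                f"placed only {count}/{n_cores} cores within the attempt budget; "
                f"min_spacing={min_spacing} um in facet_diameter={facet_diameter} um "
                "is too dense")
        attempts += 1
        # uniform point in the allowed disk
        rr = r_max * np.sqrt(rng.random())
        th = TWO_PI * rng.random()
        p = np.array([rr * np.cos(th), rr * np.sin(th)])
        ci, cj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    d = placed[k] - p
                    if d[0] * d[0] + d[1] * d[1] < min_sq:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed[count] = p
            grid.setdefault((ci, cj), []).append(count)
            count += 1
    return CoreMap(placed, core_radius, facet_diameter)


def _hex_core_map(n_cores, core_radius, min_spacing, facet_diameter, r_max, seed):
    """Jittered hexagonal placement for densities darts cannot reach."""
    rng = np.random.default_rng(seed)
    # search the largest lattice constant that still yields enough sites
    lo, hi = min_spacing, facet_diameter
    sites = None
    for _ in range(40):
        a = 0.5 * (lo + hi)
        cand = _hex_sites(a, r_max)
        if cand.shape[0] >= n_cores:
            sites, lo = cand, a
        else:
            hi = a
    if sites is None:
        raise PackingError(
            f"cannot place {n_cores} cores at spacing {min_spacing} um inside a "
            f"{facet_diameter} um facet even on a hexagonal lattice")
    a = lo
    jitter = 0.5 * (a - min_spacing)  # keeps pairwise distance >= min_spacing
    if jitter > 0:
        rr = jitter * np.sqrt(rng.random(sites.shape[0]))
        th = TWO_PI * rng.random(sites.shape[0])
        sites = sites + np.c_[rr * np.cos(th), rr * np.sin(th)]
        inside = np.hypot(sites[:, 0], sites[:, 1]) <= r_max - 1e-9
        sites = sites[inside]
        if sites.shape[0] < n_cores:
            raise PackingError("jittered lattice lost too many edge sites; "
                               "reduce the density slightly")
    keep = rng.permutation(sites.shape[0])[:n_cores]
    return CoreMap(sites[np.sort(keep)], core_radius, facet_diameter)


def _hex_sites(a: float, r_max: float) -> np.ndarray:
    """Hexagonal lattice sites with constant ``a`` inside a disk of radius r_max."""
    dy = a * np.sqrt(3.0) / 2.0
    n_rows = int(np.floor(r_max / dy))
    pts = []
    for row in range(-n_rows, n_rows + 1):
        y = row * dy
        x0 = 0.0 if row % 2 == 0 else a / 2.0
        half_w = np.sqrt(max(r_max ** 2 - y ** 2, 0.0))
        n_cols = int(np.floor((half_w + x0) / a)) + 1
        for col in range(-n_cols, n_cols + 1):
            x = x0 + col * a
            if x * x + y * y <= r_max * r_max:
                pts.append((x, y))
    return np.asarray(pts) if pts else np.empty((0, 2))


# ---------------------------------------------------------------------------
# physical <-> pixel mapping


def _pixel_axes(shape: tuple[int, int], pitch_x: float, pitch_y: float):
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch_x
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch_y
    return x, y


def core_pixel_indices(core_map: CoreMap, shape: tuple[int, int],
                       pitch_x: float, pitch_y: float) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-pixel (row, col) index of each core center; errors if outside."""
    ny, nx = shape
    cx, cy = core_map.centers[:, 0], core_map.centers[:, 1]
    jx = np.rint(cx / pitch_x + (nx - 1) / 2.0).astype(int)
    iy = np.rint(cy / pitch_y + (ny - 1) / 2.0).astype(int)
    bad = (jx < 0) | (jx >= nx) | (iy < 0) | (iy >= ny)
    if np.any(bad):
        k = int(np.flatnonzero(bad)[0])
        raise OutOfBoundsError(
            f"core {k} at ({cx[k]:.2f}, {cy[k]:.2f}) um maps outside the "
            f"{ny}x{nx} grid")
    return iy, jx


def disk_pixel_indices(core_map: CoreMap, shape: tuple[int, int],
                       pitch_x: float, pitch_y: float):
    """Pixels covered by each core disk.

    Returns (rows, cols, core_ids): flat parallel arrays listing every pixel
    whose center lies within ``core_radius`` of a core center.  Raises if
    any core covers no pixel (radius below ~pitch/sqrt(2)) or if two cores
    claim the same pixel (overlap).
    """
    ny, nx = shape
    x, y = _pixel_axes(shape, pitch_x, pitch_y)
    r = core_map.core_radius
    rows_l, cols_l, ids_l = [], [], []
    half_x = int(np.ceil(r / pitch_x)) + 1
    half_y = int(np.ceil(r / pitch_y)) + 1
    iy_c, jx_c = core_pixel_indices(core_map, shape, pitch_x, pitch_y)
    r2 = r * r
    for k in range(core_map.n_cores):
        cx, cy = core_map.centers[k]
        j0, j1 = max(0, jx_c[k] - half_x), min(nx, jx_c[k] + half_x + 1)
        i0, i1 = max(0, iy_c[k] - half_y), min(ny, iy_c[k] + half_y + 1)
        dx = x[j0:j1] - cx
        dy = y[i0:i1] - cy
        mask = (dy[:, None] ** 2 + dx[None, :] ** 2) <= r2
        ii, jj = np.nonzero(mask)
        if ii.size == 0:
            raise GeometryError(
                f"core {k} covers no pixel center: core radius {r} um is below "
                f"half the pixel diagonal at pitch ({pitch_x}, {pitch_y}) um")
        rows_l.append(ii + i0)
        cols_l.append(jj + j0)
        ids_l.append(np.full(ii.size, k, dtype=int))
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    ids = np.concatenate(ids_l)
    flat = rows * nx + cols
    if np.unique(flat).size != flat.size:
        raise GeometryError("core disks overlap on the pixel grid")
    return rows, cols, ids


def sample_core_phases(phase_image: np.ndarray, core_map: CoreMap,
                       pitch_x: float, pitch_y: float) -> CoreHologram:
    """Read one phase per core at the pixel nearest its center, wrapped."""
    phase_image = np.asarray(phase_image, dtype=float)
    iy, jx = core_pixel_indices(core_map, phase_image.shape, pitch_x, pitch_y)
    return CoreHologram(wrap_phase(phase_image[iy, jx]))


def render_core_field(holo: CoreHologram, core_map: CoreMap,
                      shape: tuple[int, int], pitch_x: float, pitch_y: float,
                      wavelength: float) -> ComplexField:
    """Paint each core as a unit-amplitude disk carrying its piston phase.

    The facet field is the binary core-map amplitude combined with the
    phased-array pattern: zero between cores, exp(i phi_k) on core k's disk.
    """
    if holo.n_cores != core_map.n_cores:
        raise GeometryError(f"hologram has {holo.n_cores} phases for "
                            f"{core_map.n_cores} cores")
    rows, cols, ids = disk_pixel_indices(core_map, shape, pitch_x, pitch_y)
    values = np.zeros(shape, dtype=np.complex128)
    values[rows, cols] = np.exp(1j * holo.phases[ids])
    return ComplexField(values, pitch_x=pitch_x, pitch_y=pitch_y,
                        wavelength=wavelength)


def reconstruct_far_field(holo: CoreHologram, core_map: CoreMap,
                          shape: tuple[int, int], pitch_x: float, pitch_y: float,
                          wavelength: float, z: float,
                          normalize: bool = True) -> np.ndarray:
    """Shared forward model: render the facet field, propagate z, take |U|^2.

    Every method under comparison (GS-through-cores, Core-GS, the network)
    is reconstructed through this same function.
    """
    fld = render_core_field(holo, core_map, shape, pitch_x, pitch_y, wavelength)
    intensity = np.abs(propagate(fld, z).values) ** 2
    if normalize:
        peak = intensity.max()
        if peak > 0:
            intensity = intensity / peak
    return intensity


# ---------------------------------------------------------------------------
# OPD distortion and conjugate compensation (simulated DOPC)


def random_opd(n_cores: int, seed: int | None = None) -> OPDMap:
    """Uniform [0, 2*pi) per-core phase distortion."""
    rng = np.random.default_rng(seed)
    return OPDMap(rng.uniform(0.0, TWO_PI, size=n_cores))


def apply_opd(holo: CoreHologram, opd: OPDMap) -> CoreHologram:
    """Stack a per-core phase offset layer onto a hologram.

    Layers add at the facet plane; they are summed before wrapping, so
    applying an OPD followed by its conjugate compensation reproduces the
    original hologram exactly.
    """
    if opd.phases.size != holo.n_cores:
        raise GeometryError("OPD length does not match the hologram")
    return replace(holo, offsets=holo.offsets + (opd.phases,))


def conjugate_compensation(opd: OPDMap) -> OPDMap:
    """The DOPC compensation layer: the negated (conjugate) offsets."""
    return OPDMap(-opd.phases)


# ---------------------------------------------------------------------------
# core-map file I/O


def save_core_map(path, core_map: CoreMap) -> None:
    """Write a core map; format chosen by suffix (.json or .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "units": "um",
            "core_radius": core_map.core_radius,
            "facet_diameter": core_map.facet_diameter,
            "centers": core_map.centers.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
    elif path.suffix.lower() == ".csv":
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["x_um", "y_um"])
        w.writerows(core_map.centers.tolist())
        path.write_text(buf.getvalue())
    else:
        raise FileFormatError(f"unsupported core-map suffix: {path.suffix}")


def load_core_map(path, core_radius: float | None = None,
                  facet_diameter: float | None = None) -> CoreMap:
    """Read a core map from JSON (self-describing) or CSV (x,y per row).

    CSV files carry only the centers; ``core_radius`` and ``facet_diameter``
    must then be supplied.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise FileFormatError(f"malformed core-map JSON: {e}") from e
        for key in ("core_radius", "facet_diameter", "centers"):
            if key not in payload:
                raise FileFormatError(f"core-map JSON missing field '{key}'")
        if payload.get("units", "um") != "um":
            raise FileFormatError(f"unsupported units '{payload['units']}' "
                                  "(expected 'um')")
        return CoreMap(np.asarray(payload["centers"], dtype=float),
                       float(payload["core_radius"]),
                       float(payload["facet_diameter"]))
    if path.suffix.lower() == ".csv":
        if core_radius is None or facet_diameter is None:
            raise FileFormatError("CSV core maps need explicit core_radius and "
                                  "facet_diameter")
        rows = []
        with path.open(newline="") as f:
            reader = csv.reader(f)
            for i, row in enumerate(reader):
                if not row:
                    continue
                if i == 0 and any(c.strip().lower().lstrip("#")
                                  in ("x", "x_um", "x[um]") for c in row[:1]):
                    continue  # header
                try:
                    rows.append((float(row[0]), float(row[1])))
                except (ValueError, IndexError) as e:
                    raise FileFormatError(
                        f"malformed core-map CSV row {i}: {row!r}") from e
        return CoreMap(np.asarray(rows, dtype=float), core_radius, facet_diameter)
    raise FileFormatError(f"unsupported core-map suffix: {path.suffix}")
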