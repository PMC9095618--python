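"""Synthetic target generation, preprocessing, and image/hologram file I/O.

The training corpus emulates a handwritten-character dataset without any
download: glyphs are random stroke compositions (polylines and quadratic
arcs drawn with a round brush on a 28x28 canvas, EMNIST-like stroke width)
and the test-style patterns are binary composites (rectangles, disks,
rings, smiley faces).  Preprocessing mirrors the experimental pipeline:
resize the character to the working window, zero-pad it centered into the
modulator grid, max-normalize.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .errors import FileFormatError

__all__ = [
    "DatasetSpec",
    "generate_targets",
    "preprocess_target",
    "read_image",
    "write_image",
    "write_hologram",
    "read_hologram_tiff",
    "read_hologram_png",
]

TWO_PI = 2.0 * np.pi
KINDS = ("glyphs", "binary-patterns", "disks", "mixed")


@dataclass(frozen=True)
class DatasetSpec:
    """What to synthesize: kind, count, native render size, stroke scale, seed."""

    kind: str = "glyphs"
    count: int = 100
    render_size: int = 28
    stroke_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.render_size < 16:
            raise ValueError("render size must be >= 16")


def generate_targets(spec: DatasetSpec) -> list[np.ndarray]:
    """Render ``spec.count`` images in [0, 1]; pure function of (spec, seed).

    Every image has at least 1% nonzero pixels (sparser draws are re-drawn).
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.count):
        kind = spec.kind
        if kind == "mixed":
            kind = ("glyphs", "binary-patterns", "disks")[rng.integers(3)]
        for _attempt in range(20):
            if kind == "glyphs":
                img = _render_glyph(rng, spec.render_size, spec.stroke_scale)
            elif kind == "binary-patterns":
                img = _render_pattern(rng, spec.render_size)
            else:
                img = _render_disk(rng, spec.render_size)
            if np.count_nonzero(img) >= 0.01 * img.size:
                break
        out.append(img.astype(np.float32))
    return out


def _brush(canvas: np.ndarray, x: float, y: float, radius: float) -> None:
    n = canvas.shape[0]
    r = int(np.ceil(radius))
    i0, i1 = max(0, int(y) - r), min(n, int(y) + r + 2)
    j0, j1 = max(0, int(x) - r), min(n, int(x) + r + 2)
    if i0 >= i1 or j0 >= j1:
        return
    yy, xx = np.mgrid[i0:i1, j0:j1]
    canvas[i0:i1, j0:j1] = np.maximum(
        canvas[i0:i1, j0:j1],
        ((yy - y) ** 2 + (xx - x) ** 2 <= radius ** 2).astype(float))


def _render_glyph(rng, size: int, stroke_scale: float) -> np.ndarray:
    """Random character-like figure: 2-4 strokes of connected arcs/segments."""
    canvas = np.zeros((size, size))
    margin = 0.15 * size
    span = size - 2 * margin
    radius = 0.045 * size * stroke_scale
    n_strokes = rng.integers(2, 5)
    for _ in range(n_strokes):
        # anchor points of one stroke
        n_anchor = rng.integers(2, 4)
        pts = margin + span * rng.random((n_anchor + 1, 2))
        for a, b in zip(pts[:-1], pts[1:]):
            ctrl = 0.5 * (a + b) + span * 0.3 * (rng.random(2) - 0.5)
            t = np.linspace(0.0, 1.0, int(3 * np.linalg.norm(b - a)) + 4)[:, None]
            curve = ((1 - t) ** 2) * a + 2 * t * (1 - t) * ctrl + t ** 2 * b
            for x, y in curve:
                _brush(canvas, x, y, radius)
    canvas = gaussian_filter(canvas, 0.5)
    peak = canvas.max()
    return canvas / peak if peak > 0 else canvas


def _render_pattern(rng, size: int) -> np.ndarray:
    """Binary test patterns: rectangles, rings, or a smiley composite."""
    canvas = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    choice = rng.integers(3)
    if choice == 0:  # 1-3 random filled rectangles
        for _ in range(rng.integers(1, 4)):
            h = rng.integers(size // 6, size // 2)
            w = rng.integers(size // 6, size // 2)
            i = rng.integers(0, size - h)
            j = rng.integers(0, size - w)
            canvas[i:i + h, j:j + w] = 1.0
    elif choice == 1:  # ring
        cy, cx = size / 2 + (rng.random(2) - 0.5) * size / 4
        r_out = size * (0.2 + 0.15 * rng.random())
        r_in = r_out * (0.4 + 0.3 * rng.random())
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        canvas[(d2 <= r_out ** 2) & (d2 >= r_in ** 2)] = 1.0
    else:  # smiley: face outline, two eyes, mouth arc
        cy = cx = size / 2
        r = size * 0.35
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        canvas[(d2 <= r ** 2) & (d2 >= (0.85 * r) ** 2)] = 1.0
        for sx in (-1, 1):
            ey, ex = cy - 0.35 * r, cx + sx * 0.4 * r
            canvas[(yy - ey) ** 2 + (xx - ex) ** 2 <= (0.12 * r) ** 2] = 1.0
        ang = np.arctan2(yy - cy, xx - cx)
        mouth = (d2 <= (0.65 * r) ** 2) & (d2 >= (0.45 * r) ** 2) & \
                (ang > np.pi / 6) & (ang < 5 * np.pi / 6)
        canvas[mouth] = 1.0
    return canvas


def _render_disk(rng, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = size / 2 + (rng.random(2) - 0.5) * size / 3
    r = size * (0.08 + 0.17 * rng.random())
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2).astype(float)


def preprocess_target(image: np.ndarray, work_size: tuple[int, int] = (48, 48),
                      slm_size: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Resize to the working window, zero-pad centered to the modulator grid.

    Mirrors the experimental preprocessing (characters resized to a square
    working window, then zero-padded into the full SLM resolution); at
    paper scale that is 512x512 into 1920x1080, the desk default is 48x48
    into 64x64.  Output is max-normalized to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    wy, wx = work_size
    sy, sx = slm_size
    if wy > sy or wx > sx:
        raise ValueError("work_size must fit inside slm_size")
    work = resize(image, (wy, wx), order=1, anti_aliasing=True,
                  preserve_range=True)
    out = np.zeros((sy, sx))
    i0 = (sy - wy) // 2
    j0 = (sx - wx) // 2
    out[i0:i0 + wy, j0:j0 + wx] = work
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# image / hologram files


def read_image(path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF), normalized to [0, 1]."""
    import imageio.v3 as iio

    try:
        arr = np.asarray(iio.imread(path), dtype=float)
    except Exception as e:  # noqa: BLE001 - backend-specific errors
        raise FileFormatError(f"cannot read image {path}: {e}") from e
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    peak = arr.max()
    return (arr / peak if peak > 0 else arr).astype(np.float32)


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] image as 8-bit grayscale PNG (or float TIFF by suffix)."""
    import imageio.v3 as iio

    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.astype(np.float32))
        return
    q = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, q)


def write_hologram(path_png, phases: np.ndarray, path_tiff=None) -> None:
    """Write a wrapped phase image: 8-bit PNG ([0, 2*pi) -> [0, 255], floor
    quantization) plus a lossless float32 TIFF alongside."""
    import imageio.v3 as iio
    import tifffile

    path_png = Path(path_png)
    phases = np.mod(np.asarray(phases, dtype=float), TWO_PI)
    q = np.clip(np.floor(phases / TWO_PI * 256.0), 0, 255).astype(np.uint8)
    iio.imwrite(path_png, q)
    if path_tiff is None:
        path_tiff = path_png.with_suffix(".tiff")
    tifffile.imwrite(Path(path_tiff), phases.astype(np.float32))


def read_hologram_tiff(path) -> np.ndarray:
    import tifffile

    try:
        return np.asarray(tifffile.imread(path), dtype=np.float32)
    except Exception as e:  # noqa: BLE001
        raise FileFormatError(f"cannot read hologram TIFF {path}: {e}") from e


def read_hologram_png(path) -> np.ndarray:
    """Recover phases from the 8-bit representation (bin centers)."""
    import imageio.v3 as iio

    q = np.asarray(iio.imread(path), dtype=float)
    return ((q + 0.5) / 256.0 * TWO_PI).astype(np.float32)
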