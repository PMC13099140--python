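"""Self-contained labeled stimulus ensembles: synthetic glyphs and MNIST IDX.

The glyph generator renders 10 fixed digit-like polyline templates as
antialiased strokes on a dark background with random affine jitter and
additive noise, emulating the gross statistics of handwritten-digit images
(sparse bright strokes, ~10 distinguishable classes) without any external
asset or download.  Real MNIST can be read from its standard IDX files.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlyphConfig",
    "GLYPH_TEMPLATES",
    "generate_glyphs",
    "read_idx_array",
    "read_idx",
    "split",
]


# Polyline templates in a unit box (x right, y down); one list of polylines
# per class.  Crude digit shapes — classes only need to be distinguishable.
GLYPH_TEMPLATES: list[list[list[tuple[float, float]]]] = [
    # 0: ring
    [[(0.5, 0.1), (0.8, 0.3), (0.8, 0.7), (0.5, 0.9), (0.2, 0.7), (0.2, 0.3), (0.5, 0.1)]],
    # 1: vertical stroke with serif
    [[(0.35, 0.25), (0.55, 0.1), (0.55, 0.9)]],
    # 2: top arc, diagonal, bottom bar
    [[(0.2, 0.3), (0.5, 0.1), (0.8, 0.3), (0.2, 0.9), (0.8, 0.9)]],
    # 3: two right-facing bumps
    [[(0.2, 0.15), (0.75, 0.15), (0.45, 0.5), (0.8, 0.75), (0.45, 0.92), (0.2, 0.8)]],
    # 4: open top, crossbar, vertical
    [[(0.65, 0.9), (0.65, 0.1), (0.2, 0.6), (0.85, 0.6)]],
    # 5: top bar, left edge, lower bowl
    [[(0.8, 0.1), (0.25, 0.1), (0.25, 0.5), (0.7, 0.5), (0.75, 0.75), (0.5, 0.9), (0.2, 0.85)]],
    # 6: descending curve into loop
    [[(0.7, 0.1), (0.3, 0.45), (0.25, 0.75), (0.5, 0.9), (0.75, 0.7), (0.5, 0.55), (0.3, 0.65)]],
    # 7: top bar and diagonal
    [[(0.2, 0.12), (0.8, 0.12), (0.45, 0.9)]],
    # 8: two stacked loops
    [
        [(0.5, 0.1), (0.72, 0.28), (0.5, 0.48), (0.28, 0.28), (0.5, 0.1)],
        [(0.5, 0.48), (0.78, 0.7), (0.5, 0.92), (0.22, 0.7), (0.5, 0.48)],
    ],
    # 9: loop with tail
    [[(0.7, 0.35), (0.5, 0.5), (0.3, 0.3), (0.5, 0.1), (0.7, 0.25), (0.65, 0.9)]],
]


@dataclass(frozen=True)
class GlyphConfig:
    """Settings of the glyph ensemble.

    ``jitter`` is (rotation degrees, translation pixels, scale fraction);
    ``stroke_width`` is the Gaussian stroke profile s.d. in pixels.
    """

    image_size: tuple[int, int] = (28, 28)
    n_classes: int = 10
    n_per_class: int = 200
    stroke_width: float = 1.1
    jitter: tuple[float, float, float] = (12.0, 2.0, 0.12)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= len(GLYPH_TEMPLATES):
            raise ValueError(f"n_classes must be in 1..{len(GLYPH_TEMPLATES)}")
        if self.n_per_class < 1 or self.noise_sd < 0:
            raise ValueError("n_per_class must be >= 1 and noise_sd >= 0")


def _render(
    polylines: list[np.ndarray], shape: tuple[int, int], width: float
) -> np.ndarray:
    """Rasterize polylines (pixel coords) as exp(-d^2 / 2 width^2) strokes."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)  # [P, 2]
    d2 = np.full(pix.shape[0], np.inf)
    for pts in polylines:
        a = pts[:-1]  # [S, 2]
        seg = pts[1:] - a
        seg_len2 = np.maximum((seg**2).sum(axis=1), 1e-12)
        # distance from every pixel to every segment
        diff = pix[:, None, :] - a[None, :, :]  # [P, S, 2]
        t = np.clip((diff * seg[None]).sum(axis=2) / seg_len2, 0.0, 1.0)
        proj = a[None] + t[:, :, None] * seg[None]
        dist2 = ((pix[:, None, :] - proj) ** 2).sum(axis=2).min(axis=1)
        d2 = np.minimum(d2, dist2)
    img = np.exp(-d2 / (2.0 * width**2)).reshape(H, W)
    return img


def _jittered_polylines(
    template: list[list[tuple[float, float]]],
    shape: tuple[int, int],
    jitter: tuple[float, float, float],
    rng: np.random.Generator,
) -> list[np.ndarray] | None:
    """Affine-perturbed template in pixel coordinates, or None if off-canvas."""
    H, W = shape
    rot_deg, trans_px, scale_frac = jitter
    theta = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    scale = 1.0 + rng.uniform(-scale_frac, scale_frac)
    shift = rng.uniform(-trans_px, trans_px, size=2)
    R = scale * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    margin = 1.5
    out = []
    for line in template:
        pts = np.asarray(line, dtype=float) - 0.5
        pts = pts @ R.T + 0.5
        pts = pts * np.array([W - 1.0, H - 1.0]) + shift
        if (
            pts[:, 0].min() < -margin
            or pts[:, 0].max() > W - 1 + margin
            or pts[:, 1].min() < -margin
            or pts[:, 1].max() > H - 1 + margin
        ):
            return None
        out.append(pts)
    return out


def generate_glyphs(cfg: GlyphConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render a class-balanced glyph ensemble; deterministic given the seed.

    Returns images [n, H, W] with pixel values in [0, 1] and integer labels.
    Jitter draws that push a stroke off-canvas are redrawn up to 10 times,
    then clipped to the canvas.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_size
    n = cfg.n_classes * cfg.n_per_class
    images = np.empty((n, H, W))
    labels = np.empty(n, dtype=int)
    i = 0
    for cls in range(cfg.n_classes):
        for _ in range(cfg.n_per_class):
            polylines = None
            for _attempt in range(10):
                polylines = _jittered_polylines(
                    GLYPH_TEMPLATES[cls], cfg.image_size, cfg.jitter, rng
                )
                if polylines is not None:
                    break
            if polylines is None:  # clip to canvas as a last resort
                polylines = _jittered_polylines(
                    GLYPH_TEMPLATES[cls], cfg.image_size, (0.0, 0.0, 0.0), rng
                )
                polylines = [
                    np.clip(p, 0, [W - 1, H - 1]) for p in polylines  # type: ignore[union-attr]
                ]
            img = _render(polylines, cfg.image_size, cfg.stroke_width)
            if cfg.noise_sd > 0:
                img = img + cfg.noise_sd * rng.standard_normal(img.shape)
            images[i] = np.clip(img, 0.0, 1.0)
            labels[i] = cls
            i += 1
    order = rng.permutation(n)
    return images[order], labels[order]


# ---------------------------------------------------------------------------
# MNIST IDX


_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4", 0x0D: ">f4", 0x0E: ">f8"}


def read_idx_array(path) -> np.ndarray:
    """Read one IDX-format file (big-endian header) into an array."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 4:
        raise ValueError(f"{path}: truncated IDX header at offset 0")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", data[:4])
    if zero1 != 0 or zero2 != 0 or dtype_code not in _IDX_DTYPES:
        raise ValueError(f"{path}: bad IDX magic number at offset 0")
    header_len = 4 + 4 * ndim
    if len(data) < header_len:
        raise ValueError(f"{path}: truncated IDX header at offset 4")
    dims = struct.unpack(f">{ndim}I", data[4:header_len])
    arr = np.frombuffer(data, dtype=_IDX_DTYPES[dtype_code], offset=header_len)
    expected = int(np.prod(dims))
    if arr.size != expected:
        raise ValueError(
            f"{path}: expected {expected} elements after offset {header_len}, "
            f"got {arr.size}"
        )
    return arr.reshape(dims)


def read_idx(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an MNIST-style image/label IDX file pair.

    Images are scaled to [0, 1]; counts must match between the two files.
    """
    images = read_idx_array(images_path)
    labels = read_idx_array(labels_path)
    if images.ndim != 3:
        raise ValueError(f"{images_path}: expected 3-D image tensor")
    if labels.ndim != 1:
        raise ValueError(f"{labels_path}: expected 1-D label vector")
    if images.shape[0] != labels.shape[0]:
        raise ValueError(
            f"image count {images.shape[0]} != label count {labels.shape[0]}"
        )
    return images.astype(float) / 255.0, labels.astype(int)


def split(
    images: np.ndarray,
    labels: np.ndarray,
    fractions: tuple[float, ...],
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified partition into len(fractions) subsets."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < len(fractions):
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than "
                f"{len(fractions)} partitions"
            )
        idx = rng.permutation(idx)
        bounds = np.floor(np.cumsum(fractions)[:-1] * len(idx)).astype(int)
        for part, chunk in zip(parts, np.split(idx, bounds)):
            part.extend(chunk.tolist())
    out = []
    for part in parts:
        sel = rng.permutation(np.asarray(part, dtype=int))
        out.append((images[sel], labels[sel]))
    return out
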