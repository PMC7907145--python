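"""Topographic 32x32 RGB images from per-channel features.

3-D electrode positions on the unit sphere are flattened with the azimuthal
equidistant projection (apex at z = +1), scattered feature values are
interpolated with the Clough-Tocher piecewise-cubic scheme on a regular grid
spanning the electrode bounding square (5% margin, out-of-hull pixels = 0),
and the three band grids are stacked as R/G/B (theta, alpha, beta) after a
fitted per-band min-max normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import QhullError

from eegtopo.features import FeatureFrame
from eegtopo.montage_layout import DEFAULT_60_LABELS, standard_positions

__all__ = [
    "Montage",
    "TopoImage",
    "ImageSequence",
    "IdentityNormalizer",
    "MinMaxNormalizer",
    "aep_project",
    "interpolate_grid",
    "assemble_rgb",
    "make_sequence",
    "default_montage",
]

GRID_SIZE = 32
_MARGIN = 0.05


@dataclass
class Montage:
    labels: List[str]
    positions3d: np.ndarray  # (n, 3) unit vectors, apex at z = +1
    positions2d: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions3d = np.asarray(self.positions3d, dtype=np.float64)
        if self.positions3d.shape != (len(self.labels), 3):
            raise ValueError("positions3d must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        norms = np.linalg.norm(self.positions3d, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-norm electrode position")
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("electrode positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def subset(self, labels: Sequence[str]) -> "Montage":
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels not in montage: {missing}")
        rows = [index[lab] for lab in labels]
        sub = Montage(list(labels), self.positions3d[rows])
        if self.positions2d is not None:
            sub.positions2d = self.positions2d[rows]
        return sub

    def to_json(self, path) -> None:
        entries = [
            {"label": lab, "x": float(p[0]), "y": float(p[1]), "z": float(p[2])}
            for lab, p in zip(self.labels, self.positions3d)
        ]
        with open(path, "w") as fh:
            json.dump(entries, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            entries = json.load(fh)
        labels = [e["label"] for e in entries]
        pos = np.array([[e["x"], e["y"], e["z"]] for e in entries])
        return cls(labels, pos)


def default_montage(labels: Sequence[str] = DEFAULT_60_LABELS) -> Montage:
    """Template 10-10 montage for the given labels, already projected."""
    return aep_project(Montage(list(labels), standard_positions(labels)))


def aep_project(montage: Montage) -> Montage:
    """Azimuthal equidistant projection with the tangent point at the apex.

    Each electrode at polar angle theta = arccos(z) and azimuth
    phi = atan2(y, x) maps to the planar point (theta cos phi, theta sin phi),
    so planar distance from the origin equals great-circle distance from the
    apex (unit-sphere radians).
    """
    p = montage.positions3d
    theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))
    phi = np.arctan2(p[:, 1], p[:, 0])
    montage.positions2d = np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
    return montage


def interpolate_grid(
    positions2d: np.ndarray, values: Sequence[float], grid_size: int = GRID_SIZE
) -> np.ndarray:
    """Clough-Tocher interpolation of scattered values onto a regular grid.

    The grid spans the square bounding box of the electrodes plus a 5%
    margin; pixels outside the convex hull are 0.
    """
    pts = np.asarray(positions2d, dtype=np.float64)
    vals = np.asarray(values, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("positions2d must be (n, 2)")
    if vals.shape != (pts.shape[0],):
        raise ValueError("need exactly one value per electrode")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 electrode positions")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) electrode positions")
    try:
        interp = CloughTocher2DInterpolator(pts, vals, fill_value=0.0)
    except QhullError as exc:  # pragma: no cover - rank check catches most cases
        raise ValueError(f"degenerate electrode positions: {exc}") from exc
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    center = (lo + hi) / 2.0
    half = float(np.max(hi - lo)) / 2.0 * (1.0 + 2 * _MARGIN)
    xs = np.linspace(center[0] - half, center[0] + half, grid_size)
    ys = np.linspace(center[1] + half, center[1] - half, grid_size)  # top row = +y
    gx, gy = np.meshgrid(xs, ys)
    grid = interp(gx, gy)
    return np.nan_to_num(grid, nan=0.0)


class IdentityNormalizer:
    """Pass-through (no scaling, no clipping); for raw-grid inspection."""

    def transform(self, stacked: np.ndarray) -> np.ndarray:
        return np.asarray(stacked, dtype=np.float64)


class MinMaxNormalizer:
    """Per-band affine map to [0, 1], fitted on training images only.

    A degenerate band (min == max) maps to all zeros; transformed values are
    clipped to [0, 1] so held-out frames stay bounded.
    """

    def __init__(self) -> None:
        self.lo: Optional[np.ndarray] = None
        self.hi: Optional[np.ndarray] = None

    def fit(self, images: np.ndarray) -> "MinMaxNormalizer":
        """``images``: array whose last axis is the band axis (size 3)."""
        arr = np.asarray(images, dtype=np.float64)
        flat = arr.reshape(-1, arr.shape[-1])
        self.lo = flat.min(axis=0)
        self.hi = flat.max(axis=0)
        return self

    @property
    def fitted(self) -> bool:
        return self.lo is not None

    def transform(self, stacked: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer must be fitted before use")
        arr = np.asarray(stacked, dtype=np.float64)
        span = self.hi - self.lo
        out = np.zeros_like(arr)
        ok = span > 0
        out[..., ok] = (arr[..., ok] - self.lo[ok]) / span[ok]
        return np.clip(out, 0.0, 1.0)


@dataclass
class TopoImage:
    pixels: np.ndarray  # (32, 32, 3), theta->R, alpha->G, beta->B
    window_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (grid, grid, 3)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")


@dataclass
class ImageSequence:
    trial_ref: str
    frames: List[TopoImage]
    label: Optional[int] = None

    def as_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])


def assemble_rgb(band_grids: Sequence[np.ndarray], normalizer, window_index: int = 0) -> TopoImage:
    """Stack three per-band grids into one normalized 3-channel image."""
    if len(band_grids) != 3:
        raise ValueError(f"expected 3 band grids, got {len(band_grids)}")
    shapes = {g.shape for g in band_grids}
    if len(shapes) != 1:
        raise ValueError(f"band grids have mismatched shapes: {sorted(shapes)}")
    stacked = np.stack(band_grids, axis=-1)
    return TopoImage(pixels=normalizer.transform(stacked), window_index=window_index)


def save_png(image: TopoImage, path) -> None:
    """8-bit PNG export of one frame (inspection only; the model consumes floats)."""
    try:
        from PIL import Image
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("PNG export requires pillow (pip install eegtopo[png])") from exc
    arr = np.clip(image.pixels * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def make_sequence(
    trial_frames: Sequence[FeatureFrame],
    montage: Montage,
    normalizer,
    trial_ref: str = "",
    label: Optional[int] = None,
    grid_size: int = GRID_SIZE,
) -> ImageSequence:
    """One TopoImage per FeatureFrame, order preserved."""
    if montage.positions2d is None:
        raise ValueError("montage must be projected first (aep_project)")
    images = []
    for frame in trial_frames:
        if frame.values.shape[0] != montage.n_channels:
            raise ValueError(
                f"frame has {frame.values.shape[0]} channels but montage has {montage.n_channels}"
            )
        grids = [
            interpolate_grid(montage.positions2d, frame.values[:, b], grid_size)
            for b in range(frame.values.shape[1])
        ]
        images.append(assemble_rgb(grids, normalizer, window_index=frame.window_index))
    return ImageSequence(trial_ref=trial_ref, frames=images, label=label)
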