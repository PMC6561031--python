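"""Synthetic epifluorescence rendering.

Cells are drawn as capsule-shaped diffuse fluorescence on a noisy camera
background; each true focus adds one diffraction-limited 2D Gaussian spot.
Output is a 16-bit image per channel and frame, plus the pixel-level truth
(spot centers in pixel coordinates), suitable for exercising the detection
stage against known ground truth. No phase contrast, drift, or 3D optics.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import OpticsConfig

__all__ = ["render_frame", "render_frames", "cell_masks", "write_stack"]


def _capsule_distance(yy, xx, x0, y0, length, width, angle):
    """Distance of each pixel-center (um coords) to the cell's axis segment."""
    half = max(1e-6, (length - width) / 2.0)
    dx, dy = np.cos(angle), np.sin(angle)
    px, py = xx - x0, yy - y0
    t = np.clip(px * dx + py * dy, -half, half)
    return np.hypot(px - t * dx, py - t * dy)


def _canvas(cells: pd.DataFrame, optics: OpticsConfig, pad: float = 2.0):
    if len(cells):
        reach = cells["length_um"].max() / 2.0 + pad
        x0 = cells["x_um"].min() - reach
        y0 = cells["y_um"].min() - reach
        x1 = cells["x_um"].max() + reach
        y1 = cells["y_um"].max() + reach
    else:
        x0 = y0 = 0.0
        x1 = y1 = 10.0
    w = int(np.ceil((x1 - x0) / optics.pixel_size))
    h = int(np.ceil((y1 - y0) / optics.pixel_size))
    return (x0, y0), (h, w)


def cell_masks(cells: pd.DataFrame, optics: OpticsConfig,
               origin: Optional[tuple] = None,
               shape: Optional[tuple] = None) -> np.ndarray:
    """Label image of cell outlines (0 = background, else cell_id + 1)."""
    if origin is None or shape is None:
        origin, shape = _canvas(cells, optics)
    labels = np.zeros(shape, dtype=np.int32)
    ys = (np.arange(shape[0]) + 0.5) * optics.pixel_size + origin[1]
    xs = (np.arange(shape[1]) + 0.5) * optics.pixel_size + origin[0]
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    for _, r in cells.iterrows():
        d = _capsule_distance(yy, xx, r["x_um"], r["y_um"], r["length_um"],
                              r["width_um"], r.get("angle_rad", 0.0))
        labels[d <= r["width_um"] / 2.0] = int(r["cell_id"]) + 1
    return labels


def render_frame(cells: pd.DataFrame, foci: pd.DataFrame,
                 optics: OpticsConfig = OpticsConfig(),
                 rng: Optional[np.random.Generator] = None,
                 seed: Optional[int] = None):
    """Render one channel of one frame.

    ``cells`` holds the geometry rows of a single frame; ``foci`` the true
    focus positions for the same frame/channel (columns axial_um,
    transverse_um relative to each cell). Returns ``(image_uint16, labels,
    spot_truth)`` where ``spot_truth`` lists pixel-coordinate spot centers.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    origin, shape = _canvas(cells, optics)
    img = np.full(shape, optics.background, dtype=float)
    img += rng.normal(0, optics.noise_sd, shape)

    labels = cell_masks(cells, optics, origin, shape)
    img[labels > 0] += optics.cell_fluor

    sigma_px = optics.psf_sigma / optics.pixel_size
    truth_rows = []
    if len(foci):
        geo = cells.drop_duplicates("cell_id").set_index("cell_id")
        for _, s in foci.iterrows():
            photons = float(s.get("photons", optics.spot_photons))
            amp = photons / (2 * np.pi * sigma_px ** 2)
            cell = geo.loc[s["cell_id"]]
            ang = float(cell.get("angle_rad", 0.0))
            half = cell["length_um"] / 2.0
            # focus world position: axial from the bottom pole, transverse offset
            ax = s["axial_um"] - half
            tr = s["transverse_um"]
            wx = cell["x_um"] + ax * np.cos(ang) - tr * np.sin(ang)
            wy = cell["y_um"] + ax * np.sin(ang) + tr * np.cos(ang)
            col = (wx - origin[0]) / optics.pixel_size - 0.5
            row = (wy - origin[1]) / optics.pixel_size - 0.5
            r0 = int(round(row)); c0 = int(round(col))
            rad = int(np.ceil(5 * sigma_px))
            rs = slice(max(0, r0 - rad), min(shape[0], r0 + rad + 1))
            cs = slice(max(0, c0 - rad), min(shape[1], c0 + rad + 1))
            yy, xx = np.mgrid[rs, cs]
            img[rs, cs] += amp * np.exp(-((yy - row) ** 2 + (xx - col) ** 2)
                                        / (2 * sigma_px ** 2))
            truth_rows.append({"cell_id": int(s["cell_id"]),
                               "row": row, "col": col})
    image = np.clip(np.round(img), 0, optics.saturation).astype(np.uint16)
    spot_truth = pd.DataFrame(truth_rows, columns=["cell_id", "row", "col"])
    return image, labels, spot_truth


def render_frames(cells: pd.DataFrame, foci: pd.DataFrame,
                  optics: OpticsConfig = OpticsConfig(),
                  seed: Optional[int] = None):
    """Render all frames of a cell table for one channel.

    Returns ``(stack, label_stack, spot_truth)``; frames are rendered on a
    common canvas so the stack is a single 3D array.
    """
    rng = np.random.default_rng(seed)
    frames = np.sort(cells["frame"].unique()) if len(cells) else [0]
    images, label_frames, truths = [], [], []
    for f in frames:
        img, labels, truth = render_frame(
            cells[cells["frame"] == f] if len(cells) else cells,
            foci[foci["frame"] == f] if len(foci) else foci,
            optics, rng=rng)
        truth["frame"] = f
        images.append(img)
        label_frames.append(labels)
        truths.append(truth)
    # pad to a common shape (colonies can grow between frames)
    hmax = max(i.shape[0] for i in images)
    wmax = max(i.shape[1] for i in images)
    stack = np.zeros((len(images), hmax, wmax), dtype=np.uint16)
    lstack = np.zeros((len(images), hmax, wmax), dtype=np.int32)
    for k, (img, lab) in enumerate(zip(images, label_frames)):
        stack[k, :img.shape[0], :img.shape[1]] = img
        lstack[k, :lab.shape[0], :lab.shape[1]] = lab
    return stack, lstack, pd.concat(truths, ignore_index=True)


def write_stack(path, stack: np.ndarray, optics: OpticsConfig) -> None:
    """Write a multi-page 16-bit TIFF with the pixel size in the metadata."""
    import json
    import tifffile

    tifffile.imwrite(path, stack,
                     metadata={"axes": "TYX",
                               "pixel_size_um": optics.pixel_size})
    sidecar = str(path) + ".meta.json"
    with open(sidecar, "w") as fh:
        json.dump({"pixel_size_um": optics.pixel_size,
                   "psf_sigma_um": optics.psf_sigma}, fh)
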