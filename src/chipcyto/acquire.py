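"""Virtual imaging: render FOV image pairs, detect cells, measure MFIs.

Each imaging position yields two rasters, a transmitted-light image (bright
background, cells as darker disks) used for cell detection and a
fluorescence image whose per-cell amplitude encodes the stained (or
post-bleach) MFI.  Detection is Otsu thresholding plus connected components
with an area filter — a deliberately simple surrogate for the instrument's
proprietary recognition algorithm; debris rejection is the [min, max] area
band.

The pipeline can skip this module entirely ("table mode", using the
simulator's MFI tables directly); "image mode" exercises the full
render -> detect -> measure path on rasters of at most 512x512 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from ._util import substream
from .errors import MeasurementError, ParameterError
from .simulate import ChipExperiment

DEFAULT_PIXEL_SIZE_UM = 0.5
DEFAULT_PSF_SIGMA_UM = 0.5
TRANSMITTED_BACKGROUND = 1000.0
TRANSMITTED_CONTRAST = 400.0


@dataclass
class FieldImagePair:
    """Transmitted + fluorescence raster of one FOV in one cycle."""

    fov_id: int
    transmitted: np.ndarray
    fluorescence: np.ndarray
    cycle: int
    marker: str
    pixel_size_um: float

    def __post_init__(self):
        if self.transmitted.shape != self.fluorescence.shape:
            raise ParameterError("transmitted and fluorescence rasters must share a shape")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel size must be > 0")


@dataclass
class Detection:
    """One detected cell in one FOV/cycle; centroid in chip coordinates (um)."""

    x: float
    y: float
    area_um2: float
    fov_id: int
    cycle: int
    pixels: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)  # component mask


def _disk_stamp(img, cx_px, cy_px, radius_px, amplitude):
    """Add an anti-aliased disk of given amplitude (in place)."""
    r = int(np.ceil(radius_px)) + 2
    x0, y0 = int(np.floor(cx_px)), int(np.floor(cy_px))
    ys = slice(max(y0 - r, 0), min(y0 + r + 1, img.shape[0]))
    xs = slice(max(x0 - r, 0), min(x0 + r + 1, img.shape[1]))
    yy, xx = np.mgrid[ys, xs]
    d = np.hypot(xx + 0.5 - cx_px, yy + 0.5 - cy_px)
    cover = np.clip(radius_px - d + 0.5, 0.0, 1.0)  # linear edge coverage
    img[ys, xs] += amplitude * cover


def render_fov(
    experiment: ChipExperiment,
    fov_id: int,
    cycle: int,
    channel: str = "stained",
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FieldImagePair:
    """Render the transmitted/fluorescence image pair of one FOV and cycle.

    Cells are disks (area = their true size) blurred by a Gaussian PSF.  The
    fluorescence amplitude above the FOV's additive background ``B_p`` equals
    the cell's simulated MFI minus ``B_p``, so a mean over the cell mask
    recovers the tabulated MFI.  Optional noise is additive Gaussian.
    """
    if experiment.mfi_stained is None:
        raise ParameterError("cycle stack not simulated yet")
    if not 0 <= fov_id < experiment.geometry.n_fov:
        raise KeyError(f"fov_id {fov_id} outside the {experiment.geometry.n_fov}-FOV grid")
    if not 0 <= cycle < experiment.n_cycles:
        raise KeyError(f"cycle {cycle} outside the {experiment.n_cycles}-cycle panel")
    if channel not in ("stained", "postbleach"):
        raise ParameterError("channel must be 'stained' or 'postbleach'")

    geom = experiment.geometry
    ox, oy = geom.fov_origin(fov_id)
    shape = (
        int(round(geom.fov_height_um / pixel_size_um)),
        int(round(geom.fov_width_um / pixel_size_um)),
    )
    if max(shape) > 512:
        raise ParameterError("FOV raster exceeds 512x512; use a larger pixel size")
    background = float(experiment.illum_offset[fov_id])
    fluor = np.full(shape, background)
    trans = np.full(shape, TRANSMITTED_BACKGROUND)

    x = experiment.positions[:, cycle, 0]
    y = experiment.positions[:, cycle, 1]
    mfi = experiment.mfi_stained if channel == "stained" else experiment.mfi_postbleach
    in_fov = (
        experiment.present[:, cycle]
        & (x >= ox) & (x < ox + geom.fov_width_um)
        & (y >= oy) & (y < oy + geom.fov_height_um)
    )
    for i in np.flatnonzero(in_fov):
        radius_px = np.sqrt(experiment.sizes_um2[i] / np.pi) / pixel_size_um
        cx, cy = (x[i] - ox) / pixel_size_um, (y[i] - oy) / pixel_size_um
        _disk_stamp(fluor, cx, cy, radius_px, max(mfi[i, cycle] - background, 0.0))
        _disk_stamp(trans, cx, cy, radius_px, -TRANSMITTED_CONTRAST)

    sigma_px = psf_sigma_um / pixel_size_um
    if sigma_px > 0:
        fluor = ndimage.gaussian_filter(fluor, sigma_px)
        trans = ndimage.gaussian_filter(trans, sigma_px)
    if noise_sd > 0:
        rng = substream(seed, "render", index=fov_id * 10007 + cycle)
        fluor = fluor + rng.normal(0.0, noise_sd, shape)
        trans = trans + rng.normal(0.0, noise_sd, shape)
    return FieldImagePair(fov_id, trans, fluor, cycle, experiment.panel[cycle], pixel_size_um)


def detect_cells(
    transmitted: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    min_area_um2: float = 20.0,
    max_area_um2: float = 400.0,
    fov_id: int = 0,
    cycle: int = 0,
    fov_origin_um: tuple[float, float] = (0.0, 0.0),
    threshold: float | None = None,
) -> list[Detection]:
    """Threshold (Otsu by default) + connected components on a transmitted image.

    Cells are darker than the bright-field background.  Components outside
    the [min_area, max_area] band are rejected as debris/aggregates.  A
    blank raster yields no detections.
    """
    img = np.asarray(transmitted, dtype=float)
    if img.size == 0:
        raise ParameterError("empty raster")
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img) if threshold is None else threshold
    mask = img < thr
    labels = sk_label(mask, connectivity=2)
    px_area = pixel_size_um**2
    out = []
    for region in regionprops(labels):
        area = region.area * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        cy, cx = region.centroid  # row, col in pixel-index coordinates
        out.append(
            Detection(
                x=fov_origin_um[0] + (cx + 0.5) * pixel_size_um,
                y=fov_origin_um[1] + (cy + 0.5) * pixel_size_um,
                area_um2=area,
                fov_id=fov_id,
                cycle=cycle,
                pixels=tuple(np.nonzero(labels == region.label)),
            )
        )
    return out


def measure_mfi(fluorescence: np.ndarray, detections: list[Detection]) -> np.ndarray:
    """Mean fluorescence over each detection's component mask."""
    img = np.asarray(fluorescence, dtype=float)
    out = np.empty(len(detections))
    for i, det in enumerate(detections):
        if det.pixels is None or len(det.pixels[0]) == 0:
            raise MeasurementError(f"detection {i} has an empty pixel mask")
        out[i] = img[det.pixels].mean()
    return out


def export_tiff(experiment: ChipExperiment, path, fov_id: int = 0, **render_kwargs) -> None:
    """Write a multi-page TIFF: per cycle, transmitted then fluorescence page."""
    pages = []
    for k in range(experiment.n_cycles):
        pair = render_fov(experiment, fov_id, k, **render_kwargs)
        pages.append(pair.transmitted.astype(np.float32))
        pages.append(pair.fluorescence.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
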