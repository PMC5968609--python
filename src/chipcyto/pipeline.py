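"""End-to-end glue: experiment -> detections -> tracks -> QC -> cell table.

Two interchangeable modes:

* ``table`` — uses the simulator's per-cell MFI tables and present flags
  directly (fast; the default for cohort-scale work);
* ``image`` — renders every FOV/cycle, detects cells on the transmitted
  raster and measures MFIs on the fluorescence raster, exercising the full
  imaging surrogate on small chips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import acquire
from .correct_qc import (
    CellRecord,
    assemble_cell_table,
    detections_from_experiment,
    flag_artificial,
    match_tracks,
    qc_summary,
    DEFAULT_MATCH_RADIUS_UM,
)
from .errors import ParameterError
from .simulate import ChipExperiment


def _detections_image_mode(experiment: ChipExperiment, pixel_size_um, psf_sigma_um) -> pd.DataFrame:
    rows = []
    geom = experiment.geometry
    for k in range(experiment.n_cycles):
        for fov in range(geom.n_fov):
            pair = acquire.render_fov(
                experiment, fov, k, "stained", pixel_size_um=pixel_size_um, psf_sigma_um=psf_sigma_um
            )
            post = acquire.render_fov(
                experiment, fov, k, "postbleach", pixel_size_um=pixel_size_um, psf_sigma_um=psf_sigma_um
            )
            dets = acquire.detect_cells(
                pair.transmitted,
                pixel_size_um=pixel_size_um,
                fov_id=fov,
                cycle=k,
                fov_origin_um=geom.fov_origin(fov),
            )
            if not dets:
                continue
            raw = acquire.measure_mfi(pair.fluorescence, dets)
            pb = acquire.measure_mfi(post.fluorescence, dets)
            for d, r, b in zip(dets, raw, pb):
                rows.append((k, d.x, d.y, d.area_um2, fov, r, b))
    det = pd.DataFrame(rows, columns=["cycle", "x", "y", "area_um2", "fov", "mfi_stained", "mfi_postbleach"])
    det.insert(0, "det_id", np.arange(len(det)))
    return det


def analyze_experiment(
    experiment: ChipExperiment,
    mode: str = "table",
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
    pixel_size_um: float = acquire.DEFAULT_PIXEL_SIZE_UM,
    psf_sigma_um: float = acquire.DEFAULT_PSF_SIGMA_UM,
) -> tuple[pd.DataFrame, list[CellRecord], dict]:
    """Run detection, tracking, QC and bleach subtraction on one experiment.

    Returns ``(cell_table, records, qc_summary_dict)`` where the cell table
    holds retained cells only, one column of corrected MFI per panel marker.
    """
    if experiment.mfi_stained is None:
        raise ParameterError("simulate_cycles must run before analysis")
    if mode == "table":
        det = detections_from_experiment(experiment)
    elif mode == "image":
        det = _detections_image_mode(experiment, pixel_size_um, psf_sigma_um)
    else:
        raise ParameterError("mode must be 'table' or 'image'")
    tracked = match_tracks(det, radius_um=match_radius_um)
    records = flag_artificial(tracked, experiment.n_cycles, panel=experiment.panel)
    table = assemble_cell_table(records, experiment.panel)
    return table, records, qc_summary(records)
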