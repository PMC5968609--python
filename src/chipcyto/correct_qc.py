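"""Bleach-subtraction correction, cross-cycle track matching, artificial-phenotype QC.

The post-bleach MFI of a cell contains everything that is not specific
stain: autofluorescence scaled by the local illumination gain plus the
additive illumination offset.  Subtracting it from the stained MFI of the
same cell and cycle therefore removes the additive offset exactly and the
autofluorescence term in expectation — this is the core correction of the
method and :func:`bleach_subtract` implements nothing else.

Because cells adhere non-covalently they can detach during fluid exchange
and sometimes re-adhere elsewhere.  A cell that disappears mid-run would
show zero expression for all later markers; a cell that appears mid-run
lacks all earlier ones.  Both are *artificial phenotypes*.
:func:`match_tracks` links detections across cycles by greedy
nearest-neighbour assignment within a radius, and :func:`flag_artificial`
retains only cells present in every cycle of a single consistent track.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import IntegrityError, PairingError, ParameterError
from .simulate import ChipExperiment

QC_RETAINED = "retained"
QC_PARTIAL = "excluded_partial_track"
QC_REATTACHED = "excluded_reattached"

DEFAULT_MATCH_RADIUS_UM = 5.0  # ~half a lymphocyte diameter


def bleach_subtract(raw_mfi, postbleach_mfi, floor: bool = True):
    """Corrected MFI = stained - post-bleach, floored at zero.

    Returns ``(corrected, was_negative)``.  ``was_negative`` flags values that
    fell below zero (measurement noise on weak signals); with ``floor=False``
    the signed differences are returned, which is the scale on which the
    correction is unbiased for truly negative markers.
    """
    raw = np.asarray(raw_mfi, dtype=float)
    post = np.asarray(postbleach_mfi, dtype=float)
    if raw.shape != post.shape:
        raise PairingError(f"raw shape {raw.shape} != post-bleach shape {post.shape}")
    if np.any(raw[~np.isnan(raw)] < 0) or np.any(post[~np.isnan(post)] < 0):
        raise PairingError("MFIs must be >= 0")
    diff = raw - post
    negative = diff < 0
    if floor:
        diff = np.maximum(diff, 0.0)
    return diff, negative


# ---------------------------------------------------------------------------
# detections table (shared by table mode and image mode)

DETECTION_COLUMNS = ["det_id", "cycle", "x", "y", "area_um2", "fov", "mfi_stained", "mfi_postbleach"]


def detections_from_experiment(experiment: ChipExperiment) -> pd.DataFrame:
    """Table-mode detections: one row per present cell per cycle.

    Carries ``true_cell`` (the simulator's cell index) for scoring only; the
    matcher never reads it.
    """
    if experiment.present is None:
        raise ParameterError("cycle stack not simulated yet")
    rows = []
    for k in range(experiment.n_cycles):
        idx = np.flatnonzero(experiment.present[:, k])
        x = experiment.positions[idx, k, 0]
        y = experiment.positions[idx, k, 1]
        rows.append(
            pd.DataFrame(
                {
                    "cycle": k,
                    "x": x,
                    "y": y,
                    "area_um2": experiment.sizes_um2[idx],
                    "fov": experiment.geometry.fov_index(x, y),
                    "mfi_stained": experiment.mfi_stained[idx, k],
                    "mfi_postbleach": experiment.mfi_postbleach[idx, k],
                    "true_cell": idx,
                }
            )
        )
    det = pd.concat(rows, ignore_index=True)
    det.insert(0, "det_id", np.arange(len(det)))
    return det


def match_tracks(detections: pd.DataFrame, radius_um: float = DEFAULT_MATCH_RADIUS_UM) -> pd.DataFrame:
    """Greedy nearest-neighbour linking of detections across consecutive cycles.

    Cycle-k track ends are linked to cycle-k+1 detections within
    ``radius_um``; candidate links are taken in order of increasing distance,
    ties broken by smaller detection id.  Unmatched later-cycle detections
    start new tracks (candidate reattached cells).  Returns the table with a
    ``track_id`` column.
    """
    if radius_um <= 0:
        raise ParameterError("matching radius must be > 0")
    det = detections.sort_values(["cycle", "det_id"]).reset_index(drop=True)
    cyc = det["cycle"].to_numpy()
    xy = det[["x", "y"]].to_numpy()
    det_ids = det["det_id"].to_numpy()
    cycles = sorted(np.unique(cyc))
    track_id = np.full(len(det), -1, dtype=int)

    first = np.flatnonzero(cyc == cycles[0])
    track_id[first] = np.arange(len(first))
    next_track = len(first)
    # open track ends: track -> position of its last detection
    ends = {int(t): xy[i] for i, t in zip(first, track_id[first])}

    for cur in cycles[1:]:
        cur_idx = np.flatnonzero(cyc == cur)
        if len(ends) and len(cur_idx):
            end_tracks = sorted(ends)
            end_pos = np.array([ends[t] for t in end_tracks])
            cur_pos = xy[cur_idx]
            # candidate links within the radius, globally sorted by distance;
            # ties broken by smaller detection id
            pairs = cKDTree(end_pos).query_ball_point(cur_pos, radius_um)
            cand = [
                (float(np.hypot(*(cur_pos[j] - end_pos[e]))), int(det_ids[cur_idx[j]]), j, e)
                for j, matches in enumerate(pairs)
                for e in matches
            ]
            cand.sort()
            used_end, used_det = set(), set()
            for _dist, _d_id, j, e in cand:
                if j in used_det or e in used_end:
                    continue
                used_det.add(j)
                used_end.add(e)
                t = end_tracks[e]
                track_id[cur_idx[j]] = t
                ends[t] = cur_pos[j]
        # unmatched detections of this cycle start new tracks; tracks with no
        # detection stay open at their last position (a later reappearance
        # within the radius would resume them)
        for i in cur_idx:
            if track_id[i] == -1:
                track_id[i] = next_track
                ends[next_track] = xy[i]
                next_track += 1
    det["track_id"] = track_id
    return det


@dataclass
class CellRecord:
    """One tracked cell with per-marker corrected MFIs and its QC verdict."""

    cell_id: int
    cycles: np.ndarray  # cycles in which the track was detected
    x: float
    y: float
    size_um2: float
    raw_mfi: dict[str, float] = field(default_factory=dict)
    postbleach_mfi: dict[str, float] = field(default_factory=dict)
    corrected_mfi: dict[str, float] = field(default_factory=dict)
    negative_corrected: dict[str, bool] = field(default_factory=dict)
    qc_status: str = QC_RETAINED
    true_cell: int | None = None  # simulator ground truth, scoring only


def flag_artificial(
    tracked: pd.DataFrame, n_cycles: int, panel: tuple[str, ...] | None = None
) -> list[CellRecord]:
    """Build CellRecords and assign QC status.

    retained            — detected in every one of the ``n_cycles`` cycles;
    excluded_reattached — track starts after the first cycle (the cell
                          appeared mid-run, so earlier markers are missing);
    excluded_partial_track — track ends early or has gaps (later markers
                          would read as spuriously negative).
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if panel is None:
        panel = tuple(f"marker_{k}" for k in range(n_cycles))
    df = tracked.sort_values(["track_id", "cycle"])
    tid = df["track_id"].to_numpy()
    cyc = df["cycle"].to_numpy()
    xs, ys = df["x"].to_numpy(), df["y"].to_numpy()
    areas = df["area_um2"].to_numpy()
    raw_all = df["mfi_stained"].to_numpy()
    post_all = df["mfi_postbleach"].to_numpy()
    corrected_all, neg_all = bleach_subtract(raw_all, post_all)
    truth = df["true_cell"].to_numpy() if "true_cell" in df.columns else None

    splits = np.flatnonzero(np.diff(tid)) + 1
    starts = np.concatenate(([0], splits))
    stops = np.concatenate((splits, [len(tid)]))
    records = []
    for s, e in zip(starts, stops):
        cycles = cyc[s:e]
        names = [panel[k] for k in cycles]
        if cycles[0] > 0:
            status = QC_REATTACHED
        elif len(cycles) < n_cycles:
            status = QC_PARTIAL
        else:
            status = QC_RETAINED
        true_cell = None
        if truth is not None:
            vals, counts = np.unique(truth[s:e], return_counts=True)
            true_cell = int(vals[np.argmax(counts)])
        records.append(
            CellRecord(
                cell_id=int(tid[s]),
                cycles=cycles,
                x=float(xs[e - 1]),
                y=float(ys[e - 1]),
                size_um2=float(areas[s:e].mean()),
                raw_mfi=dict(zip(names, raw_all[s:e])),
                postbleach_mfi=dict(zip(names, post_all[s:e])),
                corrected_mfi={m: float(v) for m, v in zip(names, corrected_all[s:e])},
                negative_corrected={m: bool(v) for m, v in zip(names, neg_all[s:e])},
                qc_status=status,
                true_cell=true_cell,
            )
        )
    return records


def assemble_cell_table(records: list[CellRecord], panel: tuple[str, ...]) -> pd.DataFrame:
    """Marker x cell corrected-MFI table of the retained cells only."""
    retained = [r for r in records if r.qc_status == QC_RETAINED]
    ids = [r.cell_id for r in retained]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate cell ids among retained records")
    cols = ["cell_id", "x", "y", "size_um2", *panel]
    if not retained:
        return pd.DataFrame(columns=cols)
    rows = []
    for r in retained:
        missing = [m for m in panel if m not in r.corrected_mfi]
        if missing:
            raise IntegrityError(f"retained cell {r.cell_id} lacks markers {missing}")
        rows.append([r.cell_id, r.x, r.y, r.size_um2, *(r.corrected_mfi[m] for m in panel)])
    return pd.DataFrame(rows, columns=cols)


def qc_summary(records: list[CellRecord]) -> dict:
    """Counts per QC status plus the negative-corrected-value rate (noise diagnostic)."""
    counts = {QC_RETAINED: 0, QC_PARTIAL: 0, QC_REATTACHED: 0}
    n_neg = n_val = 0
    for r in records:
        counts[r.qc_status] += 1
        n_neg += sum(r.negative_corrected.values())
        n_val += len(r.negative_corrected)
    return {
        "n_tracks": len(records),
        "counts": counts,
        "exclusion_rate": 1.0 - counts[QC_RETAINED] / len(records) if records else float("nan"),
        "negative_corrected_rate": n_neg / n_val if n_val else float("nan"),
    }


def write_qc_summary(records: list[CellRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump(qc_summary(records), fh, indent=2)


def write_cell_table(table: pd.DataFrame, path) -> None:
    # %.17g round-trips doubles exactly
    table.to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
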