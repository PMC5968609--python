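"""Chip sufficiency assessment, cohort-stratified reporting, protocol time budgets.

A chip is analyzable only if enough cells landed per microscope field of
view; the operating cut-off is a mean of at least 20 cells per FOV (a
per-FOV-minimum aggregation is available by configuration).  The stratified
report tabulates, per cellularity band, how many chips met the cut-off —
cumulative ">=" bands deliberately overlap, matching how such tables are
printed clinically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import percentage
from .errors import ParameterError
from .simulate import ChipExperiment, ChipGeometry

DEFAULT_MIN_CELLS_PER_FOV = 20.0

#: (label, kind, operator, threshold); kind selects the stratifying variable.
DEFAULT_STRATA: tuple[tuple[str, str, str, float], ...] = (
    ("concentration < 5/ul", "concentration", "<", 5.0),
    ("concentration >= 5/ul", "concentration", ">=", 5.0),
    ("concentration >= 10/ul", "concentration", ">=", 10.0),
    ("concentration >= 30/ul", "concentration", ">=", 30.0),
    ("concentration >= 50/ul", "concentration", ">=", 50.0),
    ("absolute < 10000", "absolute", "<", 10000.0),
    ("absolute >= 10000", "absolute", ">=", 10000.0),
    ("absolute >= 50000", "absolute", ">=", 50000.0),
    ("absolute >= 100000", "absolute", ">=", 100000.0),
    ("all samples", "all", ">=", 0.0),
)


@dataclass(frozen=True)
class SufficiencyPolicy:
    """Cell-density cut-off and how it is aggregated over FOVs."""

    min_cells_per_fov: float = DEFAULT_MIN_CELLS_PER_FOV
    aggregation: str = "mean"  # mean | min

    def __post_init__(self):
        if not self.min_cells_per_fov > 0:
            raise ParameterError("min_cells_per_fov must be > 0")
        if self.aggregation not in ("mean", "min"):
            raise ParameterError("aggregation must be 'mean' or 'min'")


def sufficient_from_count(
    cell_count: int, geometry: ChipGeometry, policy: SufficiencyPolicy | None = None
) -> tuple[bool, float]:
    """Sufficiency from a total cell count (mean aggregation only)."""
    policy = policy or SufficiencyPolicy()
    mean = cell_count / geometry.n_fov
    return mean >= policy.min_cells_per_fov, mean


def assess_sufficiency(
    experiment: ChipExperiment, policy: SufficiencyPolicy | None = None
) -> tuple[bool, float]:
    """Is the chip dense enough to analyze?  Returns (flag, mean cells/FOV)."""
    policy = policy or SufficiencyPolicy()
    mean = experiment.mean_cells_per_fov
    if policy.aggregation == "mean":
        return mean >= policy.min_cells_per_fov, mean
    fov = experiment.geometry.fov_index(experiment.positions0[:, 0], experiment.positions0[:, 1])
    counts = pd.Series(fov).value_counts().reindex(range(experiment.geometry.n_fov), fill_value=0)
    return counts.min() >= policy.min_cells_per_fov, mean


@dataclass
class StratifiedReport:
    """Per-stratum chip counts, sufficient counts, and one-decimal percentages."""

    rows: pd.DataFrame  # stratum, n, sufficient_n, percentage

    @classmethod
    def from_counts(cls, counts: Sequence[tuple[str, int, int]]) -> "StratifiedReport":
        """Build directly from (stratum label, n, sufficient_n) triples."""
        recs = []
        for label, n, suff in counts:
            if suff > n:
                raise ParameterError(f"stratum {label!r}: sufficient_n {suff} > n {n}")
            recs.append((label, n, suff, percentage(suff, n) if n else float("nan")))
        return cls(pd.DataFrame(recs, columns=["stratum", "n", "sufficient_n", "percentage"]))

    def to_text(self) -> str:
        return self.rows.to_string(index=False)


def stratified_report(
    cohort: Iterable[tuple[float, float, bool]],
    strata: Sequence[tuple[str, str, str, float]] = DEFAULT_STRATA,
) -> StratifiedReport:
    """Stratify (concentration, absolute count, sufficient flag) records.

    Bands are cumulative where printed as ">=", so a 60/ul sample counts in
    every ">=" concentration row.  An empty cohort yields an empty report.
    """
    records = list(cohort)
    if not records:
        return StratifiedReport(pd.DataFrame(columns=["stratum", "n", "sufficient_n", "percentage"]))
    df = pd.DataFrame(records, columns=["concentration", "absolute", "sufficient"])
    counts = []
    for label, kind, op, thr in strata:
        if kind == "all":
            sel = df
        else:
            sel = df[df[kind] < thr] if op == "<" else df[df[kind] >= thr]
        counts.append((label, len(sel), int(sel["sufficient"].sum())))
    return StratifiedReport.from_counts(counts)


@dataclass(frozen=True)
class ProtocolTiming:
    """Bleaching time budget of the iterative protocol."""

    bleach_seconds_per_position: float = 30.0
    positions: int = 50
    cycles: int = 1

    def __post_init__(self):
        for name in ("bleach_seconds_per_position", "positions", "cycles"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")


def time_budget(timing: ProtocolTiming) -> dict[str, float]:
    """Bleaching minutes per staining-imaging-bleaching cycle and in total."""
    per_cycle = timing.positions * timing.bleach_seconds_per_position / 60.0
    return {
        "bleach_minutes_per_cycle": per_cycle,
        "bleach_minutes_total": per_cycle * timing.cycles,
    }
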