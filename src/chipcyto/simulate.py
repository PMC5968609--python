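"""Synthetic CSF samples and virtual chip experiments.

This module stands in for the wet lab and the instrument: it draws virtual
cerebrospinal-fluid (CSF) samples from a cohort model (normocellular < 5
leukocytes/ul versus pleocytosis >= 5/ul), applies the centrifugation cell
loss observed during chip preparation (~59.3% of cells lost on average),
immobilizes the recovered cells on a virtual microfluidic chip, and then
plays out the iterative stain -> image -> bleach cycles, one marker per
cycle, including the failure modes the analysis must be robust to:

* per-cell autofluorescence ``A_i`` (lognormal) that survives bleaching,
* per-field illumination inhomogeneity: a multiplicative gain ``L_p`` and an
  additive offset ``B_p`` per field of view (FOV),
* cell detachment during fluid exchange, with optional reattachment at a new
  random position (the source of "artificial phenotypes"),
* additive measurement noise.

For a cell ``i`` at FOV ``p`` in the cycle staining marker ``m``::

    stained MFI     = L_p * (g_m * E_im + A_i) + B_p + noise
    post-bleach MFI = L_p * (rho * g_m * E_im + A_i) + B_p + noise'

where ``E_im`` is the true expression level (0 for a marker the cell does not
express), ``g_m`` the stain gain and ``rho`` the residual-dye fraction after
bleaching.  Subtracting the post-bleach from the stained MFI cancels ``B_p``
exactly and ``A_i`` in expectation, which is the correction the downstream
modules implement and test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._util import substream
from .errors import ParameterError, SchemaError

EXPRESSION_STATES = ("negative", "low", "positive", "high")

#: Default lognormal parameters (natural-log mean, sd) of true expression per
#: ordinal state, in arbitrary fluorescence units.  "negative" means the
#: epitope is absent: E = 0 (any signal on such cells is autofluorescence).
#: low / positive / high sit roughly 1-2 decades apart.
DEFAULT_STATE_PARAMS: dict[str, tuple[float, float]] = {
    "negative": (-math.inf, 0.0),
    "low": (math.log(300.0), 0.25),
    "positive": (math.log(2000.0), 0.25),
    "high": (math.log(20000.0), 0.25),
}


@dataclass(frozen=True)
class MarkerExpression:
    """Expression of one marker in one population: ordinal state + lognormal law."""

    state: str
    log_mean: float
    log_sd: float

    def __post_init__(self):
        if self.state not in EXPRESSION_STATES:
            raise ParameterError(f"unknown expression state {self.state!r}")
        if self.state != "negative" and not self.log_sd > 0:
            raise ParameterError("log_sd must be > 0 for expressed markers")


def expression(state: str, log_mean: float | None = None, log_sd: float | None = None) -> MarkerExpression:
    """MarkerExpression for an ordinal state with default lognormal parameters."""
    mu, sd = DEFAULT_STATE_PARAMS[state]
    return MarkerExpression(state, mu if log_mean is None else log_mean, sd if log_sd is None else log_sd)


@dataclass(frozen=True)
class PopulationProfile:
    """One leukocyte population: its share of cells and marker expression map."""

    name: str
    fraction: float
    expression: Mapping[str, MarkerExpression]
    size_class: str = "lymphocyte"  # lymphocyte | monocyte (sets cell area mode)

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ParameterError(f"fraction of {self.name!r} outside [0, 1]")
        if self.size_class not in ("lymphocyte", "monocyte"):
            raise ParameterError(f"unknown size class {self.size_class!r}")


def validate_composition(composition: Sequence[PopulationProfile]) -> None:
    """Check fractions sum to 1 and all profiles share one marker set."""
    if not composition:
        raise ParameterError("composition must contain at least one population")
    total = sum(p.fraction for p in composition)
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"population fractions sum to {total}, expected 1")
    markers = set(composition[0].expression)
    for p in composition[1:]:
        if set(p.expression) != markers:
            raise ParameterError(f"profile {p.name!r} does not cover the shared marker set")


@dataclass(frozen=True)
class CSFSample:
    """A virtual patient CSF sample."""

    sample_id: str
    concentration: float  # leukocytes per ul
    volume_ml: float
    composition: tuple[PopulationProfile, ...]

    def __post_init__(self):
        if self.concentration < 0:
            raise ParameterError("concentration must be >= 0")
        if not self.volume_ml > 0:
            raise ParameterError("volume must be > 0")

    @property
    def absolute_count(self) -> int:
        """Total leukocytes = concentration x volume (ul)."""
        return int(round(self.concentration * self.volume_ml * 1000.0))

    @property
    def pleocytic(self) -> bool:
        return self.concentration >= 5.0


@dataclass(frozen=True)
class PreanalyticsParams:
    """Centrifugation / resuspension losses before chip loading."""

    loss_probability: float = 0.593
    resuspension_volume_ul: float = 50.0

    def __post_init__(self):
        if not 0.0 <= self.loss_probability <= 1.0:
            raise ParameterError("loss_probability must be in [0, 1]")


@dataclass(frozen=True)
class ChipGeometry:
    """FOV grid of the chip.  Coordinates: x rightward, y downward, um, origin top-left."""

    rows: int = 8
    cols: int = 8
    fov_width_um: float = 250.0
    fov_height_um: float = 250.0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ParameterError("FOV grid must be at least 1x1")
        if not (self.fov_width_um > 0 and self.fov_height_um > 0):
            raise ParameterError("FOV dimensions must be > 0")

    @property
    def n_fov(self) -> int:
        return self.rows * self.cols

    @property
    def width_um(self) -> float:
        return self.cols * self.fov_width_um

    @property
    def height_um(self) -> float:
        return self.rows * self.fov_height_um

    def fov_index(self, x, y):
        """FOV id (row-major) of chip coordinates; vectorized."""
        col = np.clip((np.asarray(x) // self.fov_width_um).astype(int), 0, self.cols - 1)
        row = np.clip((np.asarray(y) // self.fov_height_um).astype(int), 0, self.rows - 1)
        return row * self.cols + col

    def fov_origin(self, fov_id: int) -> tuple[float, float]:
        row, col = divmod(int(fov_id), self.cols)
        return col * self.fov_width_um, row * self.fov_height_um


@dataclass(frozen=True)
class CycleKinetics:
    """Optics and chemistry parameters of one stain-image-bleach cycle."""

    stain_gain: float = 1.0
    residual_dye: float = 0.0  # rho: fraction of dye surviving the bleach
    autofluorescence_log_mean: float = math.log(100.0)
    autofluorescence_log_sd: float = 0.5
    illum_gain_range: tuple[float, float] = (0.8, 1.2)  # L_p per FOV
    illum_offset_range: tuple[float, float] = (0.0, 200.0)  # B_p per FOV
    detach_probability: float = 0.02  # per present cell per fluid exchange
    reattach_probability: float = 0.3  # given detachment
    noise_sd: float = 10.0

    def __post_init__(self):
        if not 0.0 <= self.residual_dye <= 1.0:
            raise ParameterError("residual_dye must be in [0, 1]")
        for name in ("detach_probability", "reattach_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if not self.illum_gain_range[0] > 0:
            raise ParameterError("illumination gain must be > 0")


NOISE_FREE = dict(
    autofluorescence_log_sd=1e-12,
    illum_gain_range=(1.0, 1.0),
    illum_offset_range=(0.0, 0.0),
    detach_probability=0.0,
    noise_sd=0.0,
)


@dataclass
class ChipExperiment:
    """Immobilized cells plus (after :func:`simulate_cycles`) the cycle stack.

    Arrays are indexed by cell then cycle; cells absent in a cycle carry NaN
    MFIs there.  ``reattach_cycle[i] == k`` means cell i detached and
    reappeared at a new position from cycle k on (-1: never reattached).
    """

    geometry: ChipGeometry
    sample_id: str
    true_phenotype: np.ndarray  # (n,) population names
    true_expression: pd.DataFrame  # n x markers, true E in AU
    sizes_um2: np.ndarray  # (n,)
    positions0: np.ndarray  # (n, 2) x, y in um at loading
    seed: int
    panel: tuple[str, ...] = ()
    positions: np.ndarray | None = None  # (n, cycles, 2)
    present: np.ndarray | None = None  # (n, cycles) bool
    reattach_cycle: np.ndarray | None = None  # (n,)
    mfi_stained: np.ndarray | None = None  # (n, cycles)
    mfi_postbleach: np.ndarray | None = None  # (n, cycles)
    autofluorescence: np.ndarray | None = None  # (n,)
    illum_gain: np.ndarray | None = None  # (n_fov,)
    illum_offset: np.ndarray | None = None  # (n_fov,)
    n_clamped: int = 0  # negative sampled MFIs clamped to zero

    @property
    def n_cells(self) -> int:
        return len(self.sizes_um2)

    @property
    def n_cycles(self) -> int:
        return len(self.panel)

    @property
    def mean_cells_per_fov(self) -> float:
        return self.n_cells / self.geometry.n_fov

    def to_long_frame(self) -> pd.DataFrame:
        """One row per cell x cycle: the documented tabular export schema."""
        if self.mfi_stained is None:
            raise ParameterError("cycle stack not simulated yet")
        n, c = self.mfi_stained.shape
        cell = np.repeat(np.arange(n), c)
        cyc = np.tile(np.arange(c), n)
        x = self.positions[:, :, 0].ravel()
        y = self.positions[:, :, 1].ravel()
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "cell_id": cell,
                "cycle": cyc,
                "marker": np.asarray(self.panel, dtype=object)[cyc],
                "fov": self.geometry.fov_index(x, y),
                "x": x,
                "y": y,
                "size_um2": np.repeat(self.sizes_um2, c),
                "mfi_stained": self.mfi_stained.ravel(),
                "mfi_postbleach": self.mfi_postbleach.ravel(),
                "present": self.present.ravel(),
                "true_phenotype": np.repeat(self.true_phenotype, c),
            }
        )


# ---------------------------------------------------------------------------
# cohort generation

#: Two-component lognormal cellularity mixture (per ul).  Normocellular mode
#: has median ~1.8/ul (resampled into [0, 5)); the pleocytic mode is 5/ul
#: plus a lognormal excess with median ~10/ul.
NORMO_LOG_MEAN, NORMO_LOG_SD = math.log(1.8), 0.55
PLEO_EXCESS_LOG_MEAN, PLEO_EXCESS_LOG_SD = math.log(10.0), 1.0
VOLUME_RANGE_ML = (1.0, 15.0)
VOLUME_LOG_MEAN, VOLUME_LOG_SD = math.log(4.0), 0.4


def generate_cohort(
    n_samples: int,
    pleocytic_fraction: float,
    composition_presets: Mapping[str, Sequence[PopulationProfile]],
    seed: int,
) -> list[CSFSample]:
    """Draw a cohort of virtual CSF samples.

    Each sample gets a concentration from the two-component cellularity
    mixture, a collection volume in [1, 15] ml and a composition preset
    (chosen uniformly among ``composition_presets``).  Deterministic given
    ``seed``.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    if not 0.0 <= pleocytic_fraction <= 1.0:
        raise ParameterError("pleocytic_fraction must be in [0, 1]")
    presets = {k: tuple(v) for k, v in composition_presets.items()}
    for comp in presets.values():
        validate_composition(comp)
    rng = substream(seed, "cohort")
    names = sorted(presets)
    samples = []
    for i in range(n_samples):
        pleo = rng.random() < pleocytic_fraction
        if pleo:
            conc = 5.0 + rng.lognormal(PLEO_EXCESS_LOG_MEAN, PLEO_EXCESS_LOG_SD)
        else:
            conc = rng.lognormal(NORMO_LOG_MEAN, NORMO_LOG_SD)
            while conc >= 5.0:  # truncate the normocellular mode below 5/ul
                conc = rng.lognormal(NORMO_LOG_MEAN, NORMO_LOG_SD)
        vol = float(np.clip(rng.lognormal(VOLUME_LOG_MEAN, VOLUME_LOG_SD), *VOLUME_RANGE_ML))
        preset = names[rng.integers(len(names))]
        samples.append(
            CSFSample(
                sample_id=f"S{i:04d}",
                concentration=float(conc),
                volume_ml=vol,
                composition=presets[preset],
            )
        )
    return samples


def apply_preanalytics(sample: CSFSample, params: PreanalyticsParams, seed: int) -> int:
    """Cells surviving centrifugation: Binomial(absolute count, 1 - loss)."""
    n = sample.absolute_count
    if n == 0:
        return 0
    rng = substream(seed, "preanalytics")
    return int(rng.binomial(n, 1.0 - params.loss_probability))


# ---------------------------------------------------------------------------
# chip loading

SIZE_PARAMS = {"lymphocyte": (60.0, 8.0), "monocyte": (120.0, 15.0)}  # um^2 mean, sd
_MIN_AREA_UM2 = 15.0


def _draw_positions(n, geometry, rng, min_separation, max_retries=50):
    pos = np.column_stack(
        [rng.uniform(0, geometry.width_um, n), rng.uniform(0, geometry.height_um, n)]
    )
    if min_separation <= 0 or n < 2:
        return pos
    for _ in range(max_retries):
        pairs = cKDTree(pos).query_pairs(min_separation, output_type="ndarray")
        if len(pairs) == 0:
            return pos
        redraw = np.unique(pairs[:, 1])  # keep the first cell of each colliding pair
        pos[redraw, 0] = rng.uniform(0, geometry.width_um, len(redraw))
        pos[redraw, 1] = rng.uniform(0, geometry.height_um, len(redraw))
    raise ParameterError(
        f"could not place {n} cells with min separation {min_separation} um "
        f"on a {geometry.width_um:.0f}x{geometry.height_um:.0f} um chip"
    )


def load_chip(
    recovered_count: int,
    composition: Sequence[PopulationProfile],
    geometry: ChipGeometry,
    seed: int,
    sample_id: str = "chip",
    min_separation_um: float = 2.0,
    adhesion_weights: Mapping[str, float] | None = None,
) -> ChipExperiment:
    """Immobilize ``recovered_count`` cells on the chip.

    Phenotypes are multinomial in the composition fractions (optionally
    reweighted by per-population ``adhesion_weights``, modelling selective
    adhesion, e.g. stickier monocytes), true expression is drawn per
    population profile, positions are uniform with collision re-draws, and
    sizes follow the lymphocyte/monocyte area modes.
    """
    if recovered_count < 0:
        raise ParameterError("recovered_count must be >= 0")
    validate_composition(composition)
    rng = substream(seed, "loading")
    markers = tuple(composition[0].expression)
    n = int(recovered_count)

    fractions = np.array([p.fraction for p in composition], dtype=float)
    if adhesion_weights is not None:
        w = np.array([adhesion_weights.get(p.name, 1.0) for p in composition])
        if np.any(w < 0):
            raise ParameterError("adhesion weights must be >= 0")
        fractions = fractions * w
        fractions /= fractions.sum()

    which = rng.choice(len(composition), size=n, p=fractions)
    phenotype = np.array([composition[i].name for i in which], dtype=object)

    expr = np.zeros((n, len(markers)))
    for i, prof in enumerate(composition):
        idx = np.flatnonzero(which == i)
        if len(idx) == 0:
            continue
        for j, m in enumerate(markers):
            e = prof.expression[m]
            if e.state != "negative":
                expr[idx, j] = rng.lognormal(e.log_mean, e.log_sd, len(idx))

    sizes = np.empty(n)
    for cls, (mu, sd) in SIZE_PARAMS.items():
        idx = np.flatnonzero(
            np.array([composition[i].size_class == cls for i in which])
        )
        sizes[idx] = np.maximum(rng.normal(mu, sd, len(idx)), _MIN_AREA_UM2)

    pos = _draw_positions(n, geometry, rng, min_separation_um)
    return ChipExperiment(
        geometry=geometry,
        sample_id=sample_id,
        true_phenotype=phenotype,
        true_expression=pd.DataFrame(expr, columns=list(markers)),
        sizes_um2=sizes,
        positions0=pos,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# iterative stain-image-bleach cycles


def simulate_cycles(
    experiment: ChipExperiment,
    panel: Sequence[str],
    kinetics: CycleKinetics,
    seed: int,
) -> ChipExperiment:
    """Fill the cycle stack: one marker per cycle, in panel order.

    Before every cycle each attached cell detaches with
    ``detach_probability``; a detached cell reattaches with
    ``reattach_probability`` at a new uniform position and is measured again
    from the *next* cycle on (it has no measurements for earlier cycles —
    the artificial-phenotype hazard).  Negative sampled MFIs are clamped to
    zero and counted in ``n_clamped``.
    """
    panel = tuple(panel)
    missing = [m for m in panel if m not in experiment.true_expression.columns]
    if missing:
        raise SchemaError(f"panel markers absent from composition profiles: {missing}")
    rng = substream(seed, "cycles")
    geom = experiment.geometry
    n, c = experiment.n_cells, len(panel)

    A = rng.lognormal(kinetics.autofluorescence_log_mean, kinetics.autofluorescence_log_sd, n)
    L = rng.uniform(*kinetics.illum_gain_range, geom.n_fov)
    B = rng.uniform(*kinetics.illum_offset_range, geom.n_fov)

    positions = np.repeat(experiment.positions0[:, None, :], max(c, 1), axis=1).astype(float)
    present = np.zeros((n, c), dtype=bool)
    reattach_cycle = np.full(n, -1, dtype=int)
    attached = np.ones(n, dtype=bool)
    pending = np.full(n, -1, dtype=int)  # cycle from which a reattaching cell returns

    stained = np.full((n, c), np.nan)
    post = np.full((n, c), np.nan)
    n_clamped = 0

    for k in range(c):
        # fluid exchange before this cycle's staining
        returning = pending == k
        if returning.any():
            attached[returning] = True
            pending[returning] = -1
        detach = attached & (rng.random(n) < kinetics.detach_probability)
        if detach.any():
            attached[detach] = False
            re = detach & (rng.random(n) < kinetics.reattach_probability)
            if re.any():
                idx = np.flatnonzero(re)
                newpos = np.column_stack(
                    [rng.uniform(0, geom.width_um, len(idx)), rng.uniform(0, geom.height_um, len(idx))]
                )
                positions[idx, k + 1 :, :] = newpos[:, None, :]
                pending[idx] = k + 1
                first = reattach_cycle[idx] == -1
                reattach_cycle[idx[first]] = k + 1

        present[:, k] = attached
        idx = np.flatnonzero(attached)
        if len(idx) == 0:
            continue
        fov = geom.fov_index(positions[idx, k, 0], positions[idx, k, 1])
        E = experiment.true_expression[panel[k]].to_numpy()[idx]
        g = kinetics.stain_gain
        s = L[fov] * (g * E + A[idx]) + B[fov] + rng.normal(0.0, kinetics.noise_sd, len(idx))
        b = (
            L[fov] * (kinetics.residual_dye * g * E + A[idx])
            + B[fov]
            + rng.normal(0.0, kinetics.noise_sd, len(idx))
        )
        n_clamped += int((s < 0).sum() + (b < 0).sum())
        stained[idx, k] = np.maximum(s, 0.0)
        post[idx, k] = np.maximum(b, 0.0)

    return replace(
        experiment,
        panel=panel,
        positions=positions,
        present=present,
        reattach_cycle=reattach_cycle,
        mfi_stained=stained,
        mfi_postbleach=post,
        autofluorescence=A,
        illum_gain=L,
        illum_offset=B,
        n_clamped=n_clamped,
    )


def export_experiment_csv(experiment: ChipExperiment, path) -> None:
    """Write the long-format per cell x cycle table."""
    experiment.to_long_frame().to_csv(path, index=False)
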