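"""Bland-Altman agreement between the chip pipeline and a reference method.

The difference is taken as ``reference - chip``, so a *negative* bias means
the chip reads higher than the reference — the convention under which a
chip that over-counts monocytes shows a negative monocyte bias.  Limits of
agreement are bias +/- 1.96 x SD of the paired differences (sample SD,
n - 1); no small-sample t-correction is applied.

:func:`recovery_experiment` is the end-to-end check the study design
implies but printed data cannot support: simulate a paired cohort where the
reference values are the ground-truth population percentages of each
virtual patient and the chip values come from the full
simulate -> correct -> QC -> gate pipeline, then quantify agreement per
population and for the CD4:CD8 ratio.  Chips below the density cut-off are
excluded (and counted), mirroring how paucicellular patients drop out of a
real cross-validation subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import substream
from .errors import SampleSizeError
from .phenotype import apply_gates, default_gate_tree
from .pipeline import analyze_experiment
from .presets import STANDARD_PANEL, composition_preset, top_level_fractions
from .report import SufficiencyPolicy, assess_sufficiency
from .simulate import (
    ChipGeometry,
    CSFSample,
    CycleKinetics,
    PopulationProfile,
    PreanalyticsParams,
    apply_preanalytics,
    generate_cohort,
    load_chip,
    simulate_cycles,
)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman bias and 95% limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(reference, chip) -> AgreementResult:
    """Agreement statistics for paired measurements of one quantity."""
    ref = np.asarray(reference, dtype=float)
    other = np.asarray(chip, dtype=float)
    if ref.shape != other.shape:
        raise SampleSizeError("reference and chip arrays must be paired")
    if ref.ndim != 1 or len(ref) < 2:
        raise SampleSizeError("Bland-Altman needs at least 2 pairs")
    if not (np.isfinite(ref).all() and np.isfinite(other).all()):
        raise SampleSizeError("paired values must be finite")
    d = ref - other
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, len(d))


def read_paired_csv(path) -> pd.DataFrame:
    """Read a 3-column paired table: id, reference, chip."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise SampleSizeError("paired CSV needs columns: id, reference, chip")
    df.columns = ["id", "reference", "chip", *df.columns[3:]]
    return df


def plot_bland_altman(reference, chip, result: AgreementResult, path, title="") -> None:
    """Difference-vs-average plot with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, dtype=float)
    other = np.asarray(chip, dtype=float)
    avg, diff = (ref + other) / 2.0, ref - other
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(avg, diff, s=18)
    ax.axhline(result.bias, color="k")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel("average of both methods")
    ax.set_ylabel("reference - chip")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# end-to-end recovery experiment


@dataclass(frozen=True)
class RecoveryConfig:
    """Simulated paired-cohort configuration."""

    n_patients: int = 12
    preset: str = "ms_like"
    cellularity: str = "mixed"  # normocellular | pleocytic | mixed
    pleocytic_fraction: float = 0.245  # used when cellularity == "mixed"
    panel: tuple[str, ...] = STANDARD_PANEL
    geometry: ChipGeometry = field(default_factory=lambda: ChipGeometry(4, 4, 250.0, 250.0))
    kinetics: CycleKinetics = field(default_factory=CycleKinetics)
    preanalytics: PreanalyticsParams = field(default_factory=PreanalyticsParams)
    policy: SufficiencyPolicy = field(default_factory=SufficiencyPolicy)
    max_cells: int = 12000  # cap on cells loaded per chip (chip capacity)
    composition_jitter: float = 200.0  # Dirichlet concentration; 0 disables
    adhesion_weights: dict | None = None
    chip_offset_pct: float = 0.0  # systematic offset added to chip percentages


@dataclass
class RecoveryResult:
    agreement: dict[str, AgreementResult]
    pooled: AgreementResult | None
    paired: pd.DataFrame  # patient, quantity, reference, chip
    n_excluded: int
    n_analyzed: int

    def to_json(self) -> str:
        payload = {
            q: vars(a) for q, a in self.agreement.items()
        }
        if self.pooled is not None:
            payload["pooled_percentages"] = vars(self.pooled)
        payload["n_excluded"] = self.n_excluded
        payload["n_analyzed"] = self.n_analyzed
        return json.dumps(payload, indent=2)


def _jitter_composition(composition, strength, rng) -> tuple[PopulationProfile, ...]:
    if strength <= 0:
        return tuple(composition)
    base = np.array([p.fraction for p in composition])
    jittered = rng.dirichlet(base * strength)
    return tuple(replace(p, fraction=float(f)) for p, f in zip(composition, jittered))


def recovery_experiment(config: RecoveryConfig, seed: int) -> RecoveryResult:
    """Simulate a paired chip-vs-reference cohort and assess agreement.

    For each virtual patient the reference values are the ground-truth
    population percentages (what an ideal reference cytometer would report);
    the chip values are the percentages produced by the full pipeline on the
    virtual chip.  Quantities: T, B, monocyte percentages and the CD4:CD8
    ratio.  Deterministic given ``seed``.
    """
    rng = substream(seed, "recovery")
    mix = {"normocellular": 0.0, "pleocytic": 1.0, "mixed": config.pleocytic_fraction}[config.cellularity]
    base = composition_preset(config.preset)
    cohort = generate_cohort(
        config.n_patients, mix, {config.preset: base}, seed=int(rng.integers(2**31))
    )
    tree = default_gate_tree(config.panel)
    rows = []
    n_excluded = 0
    for i, sample in enumerate(cohort):
        comp = _jitter_composition(base, config.composition_jitter, rng)
        sample = CSFSample(sample.sample_id, sample.concentration, sample.volume_ml, comp)
        sub = int(rng.integers(2**31))
        recovered = apply_preanalytics(sample, config.preanalytics, seed=sub)
        recovered = min(recovered, config.max_cells)
        exp = load_chip(
            recovered, comp, config.geometry, seed=sub,
            sample_id=sample.sample_id, adhesion_weights=config.adhesion_weights,
        )
        ok, _ = assess_sufficiency(exp, config.policy)
        if not ok:
            n_excluded += 1
            continue
        exp = simulate_cycles(exp, config.panel, config.kinetics, seed=sub)
        table, _, _ = analyze_experiment(exp)
        if len(table) == 0:
            n_excluded += 1
            continue
        labels = apply_gates(table, tree)
        n = len(labels)
        counts = labels["label"].value_counts()
        leaf = labels["leaf"].value_counts()
        truth = top_level_fractions(comp)
        chip_pct = {
            pop: 100.0 * counts.get(pop, 0) / n + config.chip_offset_pct
            for pop in ("T", "B", "monocyte")
        }
        ref_pct = {pop: 100.0 * truth.get(pop, 0.0) for pop in ("T", "B", "monocyte")}
        for pop in ("T", "B", "monocyte"):
            rows.append((sample.sample_id, pop, ref_pct[pop], chip_pct[pop]))
        cd4 = sum(v for k, v in leaf.items() if k.endswith("/CD4"))
        cd8 = sum(v for k, v in leaf.items() if k.endswith("/CD8"))
        tcd4 = sum(p.fraction for p in comp if p.name.startswith("CD4"))
        tcd8 = sum(p.fraction for p in comp if p.name.startswith("CD8"))
        if cd8 > 0 and tcd8 > 0:
            rows.append((sample.sample_id, "CD4:CD8", tcd4 / tcd8, cd4 / cd8))
    paired = pd.DataFrame(rows, columns=["patient", "quantity", "reference", "chip"])
    agreement = {}
    for q, grp in paired.groupby("quantity"):
        if len(grp) >= 2:
            agreement[q] = bland_altman(grp["reference"], grp["chip"])
    pct = paired[paired["quantity"] != "CD4:CD8"]
    pooled = bland_altman(pct["reference"], pct["chip"]) if len(pct) >= 2 else None
    return RecoveryResult(agreement, pooled, paired, n_excluded, config.n_patients - n_excluded)
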