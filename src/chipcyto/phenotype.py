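"""Hierarchical gating of corrected MFIs into CSF immune populations.

Gating operates on the log scale ``v = log10(1 + corrected MFI)``.  Each
marker has three thresholds ``theta_low < theta_pos < theta_high`` defining
four ordinal bands:

====== ============================
neg    v < theta_low
low    theta_low <= v < theta_pos
pos    v >= theta_pos
high   v >= theta_high
====== ============================

("pos" deliberately includes "high"; the additional predicate ``low_or_pos``
means any detectable expression, v >= theta_low — this is what "CD19 low or
positive" needs.)  The default gate tree reconstructs the populations a CSF
immunophenotyping panel names: CD3+ T cells (CD4, CD8, central-memory
CD27+ CD45RA- subsets), CD19-expressing B cells with plasmablasts
(CD19low CD27+ CD38high) and class-switched memory cells (CD27+ IgG+),
CD14+ monocytes, CD56+ NK cells, and lineage-negative HLA-DRhigh dendritic
cells.  Rules are evaluated first-match-wins at each level, so every cell
receives exactly one leaf label or "unclassified".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._util import log_intensity, percentage, round_half_up
from .errors import ParameterError, SampleSizeError, SchemaError

UNCLASSIFIED = "unclassified"

PREDICATES = ("neg", "low", "pos", "high", "low_or_pos")


@dataclass(frozen=True)
class MarkerThresholds:
    """Log10(1+MFI) band boundaries for one marker."""

    low: float = 1.7
    pos: float = 2.9
    high: float = 3.8

    def __post_init__(self):
        if not self.low < self.pos < self.high:
            raise ParameterError("thresholds must satisfy low < pos < high")


@dataclass(frozen=True)
class GateRule:
    """One population: marker -> band predicates, all of which must hold."""

    name: str
    predicates: dict[str, str]
    parent: str | None = None

    def __post_init__(self):
        for marker, p in self.predicates.items():
            if p not in PREDICATES:
                raise ParameterError(f"unknown predicate {p!r} for marker {marker!r}")


@dataclass(frozen=True)
class GateTree:
    """Ordered first-match-wins rules plus per-marker thresholds."""

    rules: tuple[GateRule, ...]
    thresholds: dict[str, MarkerThresholds] = field(default_factory=dict)

    def thresholds_for(self, marker: str) -> MarkerThresholds:
        return self.thresholds.get(marker, MarkerThresholds())

    @property
    def markers(self) -> set[str]:
        return {m for r in self.rules for m in r.predicates}

    def top_rules(self):
        return [r for r in self.rules if r.parent is None]

    def children(self, parent: str):
        return [r for r in self.rules if r.parent == parent]


def default_gate_tree(markers, thresholds: dict[str, MarkerThresholds] | None = None) -> GateTree:
    """The shipped CSF gate tree, restricted to the markers actually present.

    Sub-gates that need extended-panel markers (e.g. switched-memory B cells
    need IgG) are included only when those markers are available.
    """
    markers = set(markers)
    rules = [
        GateRule("T", {"CD3": "pos"}),
        GateRule("CD4", {"CD4": "pos"}, parent="T"),
        GateRule("CD8", {"CD8": "pos"}, parent="T"),
        GateRule("Tcm", {"CD27": "pos", "CD45RA": "neg"}, parent="T"),
        GateRule("B", {"CD19": "low_or_pos", "CD3": "neg"}),
        GateRule("plasmablast", {"CD19": "low", "CD27": "pos", "CD38": "high"}, parent="B"),
        GateRule("switched_memory", {"CD27": "pos", "IgG": "pos"}, parent="B"),
        GateRule("monocyte", {"CD14": "pos"}),
        GateRule("NK", {"CD56": "pos", "CD3": "neg"}),
        GateRule(
            "DC",
            {"CD3": "neg", "CD14": "neg", "CD19": "neg", "CD56": "neg", "HLA-DR": "high"},
        ),
    ]
    rules = [r for r in rules if set(r.predicates) <= markers]
    return GateTree(tuple(rules), thresholds or {})


def _predicate_mask(values_log, predicate, thr: MarkerThresholds):
    if predicate == "neg":
        return values_log < thr.low
    if predicate == "low":
        return (values_log >= thr.low) & (values_log < thr.pos)
    if predicate == "pos":
        return values_log >= thr.pos
    if predicate == "high":
        return values_log >= thr.high
    if predicate == "low_or_pos":
        return values_log >= thr.low
    raise ParameterError(f"unknown predicate {predicate!r}")


def apply_gates(cell_table: pd.DataFrame, tree: GateTree) -> pd.DataFrame:
    """Assign each cell a top-level ``label`` and a deepest-path ``leaf``.

    Rules at each level are evaluated in order; the first match wins, so the
    labelling is independent of row order.
    """
    missing = sorted(tree.markers - set(cell_table.columns))
    if missing:
        raise SchemaError(f"cell table lacks marker columns {missing}")
    n = len(cell_table)
    logv = {m: log_intensity(cell_table[m].to_numpy()) for m in tree.markers}

    def rule_mask(rule):
        mask = np.ones(n, dtype=bool)
        for marker, pred in rule.predicates.items():
            mask &= _predicate_mask(logv[marker], pred, tree.thresholds_for(marker))
        return mask

    label = np.full(n, UNCLASSIFIED, dtype=object)
    leaf = np.full(n, UNCLASSIFIED, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in tree.top_rules():
        hit = unassigned & rule_mask(rule)
        if not hit.any():
            continue
        label[hit] = rule.name
        leaf[hit] = rule.name
        sub_unassigned = hit.copy()
        for child in tree.children(rule.name):
            sub_hit = sub_unassigned & rule_mask(child)
            leaf[sub_hit] = f"{rule.name}/{child.name}"
            sub_unassigned &= ~sub_hit
        unassigned &= ~hit
    out = pd.DataFrame({"label": label, "leaf": leaf})
    if "cell_id" in cell_table.columns:
        out.insert(0, "cell_id", cell_table["cell_id"].to_numpy())
    return out


@dataclass
class GateResult:
    """Population counts/percentages and the clinically reported ratios."""

    n: int
    counts: dict[str, int]
    percentages: dict[str, float]  # one decimal, half-up
    leaf_counts: dict[str, int]
    cd4_cd8_ratio: float | None
    b_monocyte_ratio: float | None
    plasmablast_pct_of_b: float | None
    undefined_ratios: set[str]

    @classmethod
    def from_percentages(cls, percentages: dict[str, float]) -> "GateResult":
        """Ratios from externally supplied population percentages (no counts)."""
        undefined = set()
        cd4, cd8 = percentages.get("CD4"), percentages.get("CD8")
        b, mono = percentages.get("B"), percentages.get("monocyte")
        ratio_cd = _ratio(cd4, cd8, "CD4:CD8", undefined)
        ratio_bm = _ratio(b, mono, "B:monocyte", undefined)
        return cls(
            n=0,
            counts={},
            percentages=dict(percentages),
            leaf_counts={},
            cd4_cd8_ratio=ratio_cd,
            b_monocyte_ratio=ratio_bm,
            plasmablast_pct_of_b=None,
            undefined_ratios=undefined,
        )


def _ratio(num, den, name, undefined: set) -> float | None:
    if num is None or den is None or den == 0:
        undefined.add(name)
        return None
    return round_half_up(num / den, 2)


def population_stats(labels: pd.DataFrame) -> GateResult:
    """Summarize gated labels: percentages (one decimal) and ratios.

    Ratios are computed from the rounded percentages, matching how they are
    reported clinically; zero denominators are flagged undefined, never
    infinite.
    """
    if len(labels) == 0:
        raise SampleSizeError("population_stats needs at least one retained cell")
    n = len(labels)
    counts = labels["label"].value_counts().to_dict()
    leaf_counts = labels["leaf"].value_counts().to_dict()
    percentages = {k: percentage(v, n) for k, v in counts.items()}
    undefined: set[str] = set()

    def leaf_pct(name):
        c = sum(v for k, v in leaf_counts.items() if k == name or k.endswith("/" + name))
        return percentage(c, n)

    cd4_cd8 = _ratio(leaf_pct("CD4"), leaf_pct("CD8"), "CD4:CD8", undefined)
    b_mono = _ratio(percentages.get("B", 0.0), percentages.get("monocyte", 0.0), "B:monocyte", undefined)
    n_b = counts.get("B", 0)
    pb = sum(v for k, v in leaf_counts.items() if k.endswith("/plasmablast"))
    pb_pct = percentage(pb, n_b) if n_b else None
    if n_b == 0:
        undefined.add("plasmablast%ofB")
    return GateResult(
        n=n,
        counts=counts,
        percentages=percentages,
        leaf_counts=leaf_counts,
        cd4_cd8_ratio=cd4_cd8,
        b_monocyte_ratio=b_mono,
        plasmablast_pct_of_b=pb_pct,
        undefined_ratios=undefined,
    )


def gate_tree_from_config(cfg: dict) -> GateTree:
    """Build a GateTree from a plain mapping (the YAML/JSON schema).

    ``cfg`` has two keys: ``rules`` (ordered list of {name, predicates,
    parent?}) and optional ``thresholds`` ({marker: {low, pos, high}}).
    """
    rules = tuple(
        GateRule(r["name"], dict(r["predicates"]), r.get("parent")) for r in cfg["rules"]
    )
    thresholds = {
        m: MarkerThresholds(t["low"], t["pos"], t["high"])
        for m, t in cfg.get("thresholds", {}).items()
    }
    return GateTree(rules, thresholds)


def load_gate_tree(path) -> GateTree:
    """Load a gate tree from a YAML (or JSON) document."""
    import yaml

    with open(path) as fh:
        return gate_tree_from_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# light-chain clonality

DEFAULT_KAPPA_LAMBDA_BOUNDS = (0.26, 1.65)  # conventional clinical interval


@dataclass
class ClonalityResult:
    kappa_count: int
    lambda_count: int
    kappa_lambda_ratio: float | None
    call: str  # kappa | lambda | polyclonal | indeterminate


def light_chain_clonality(
    b_cell_table: pd.DataFrame,
    ratio_bounds: tuple[float, float] = DEFAULT_KAPPA_LAMBDA_BOUNDS,
    min_cells: int = 10,
    kappa_marker: str = "kappa",
    lambda_marker: str = "lambda",
    thresholds: MarkerThresholds | None = None,
) -> ClonalityResult:
    """Call light-chain restriction among B cells from the kappa:lambda ratio."""
    for m in (kappa_marker, lambda_marker):
        if m not in b_cell_table.columns:
            raise SchemaError(f"B-cell table lacks light-chain column {m!r}")
    thr = thresholds or MarkerThresholds()
    lo, hi = ratio_bounds
    if not 0 < lo < hi:
        raise ParameterError("ratio bounds must satisfy 0 < lower < upper")
    k = int((log_intensity(b_cell_table[kappa_marker].to_numpy()) >= thr.pos).sum())
    l = int((log_intensity(b_cell_table[lambda_marker].to_numpy()) >= thr.pos).sum())
    if len(b_cell_table) < min_cells:
        return ClonalityResult(k, l, k / l if l else None, "indeterminate")
    if l == 0:
        return ClonalityResult(k, l, None, "kappa" if k > 0 else "indeterminate")
    ratio = k / l
    call = "lambda" if ratio < lo else "kappa" if ratio > hi else "polyclonal"
    return ClonalityResult(k, l, ratio, call)


# ---------------------------------------------------------------------------
# exploratory clustering


@dataclass
class ClusterResult:
    order: np.ndarray  # leaf order of the dendrogram
    labels: np.ndarray  # cluster assignment per cell
    linkage: np.ndarray
    markers: list[str]
    dropped_markers: list[str]


def cluster_heatmap(
    cell_table: pd.DataFrame,
    markers: list[str] | None = None,
    n_clusters: int | None = None,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of cells on z-scored log intensities.

    Constant markers are dropped from the z-scoring with a warning.  The
    returned leaf order groups cells with similar marker profiles, ready for
    a heatmap; ``n_clusters`` cuts the dendrogram (default: 1 cluster when
    all distances are 0, else 2).
    """
    if markers is None:
        markers = [c for c in cell_table.columns if c not in ("cell_id", "x", "y", "size_um2")]
    if len(cell_table) < 2:
        raise SampleSizeError("clustering needs at least 2 cells")
    logv = log_intensity(cell_table[markers].to_numpy())
    sd = logv.std(axis=0)
    keep = sd > 1e-12  # tolerance: constant columns leave float residue
    dropped = [m for m, k in zip(markers, keep) if not k]
    if dropped:
        warnings.warn(f"constant markers dropped from clustering: {dropped}", stacklevel=2)
    kept = [m for m, k in zip(markers, keep) if k]
    if kept:
        z = (logv[:, keep] - logv[:, keep].mean(axis=0)) / sd[keep]
        dist = pdist(z, metric=metric)
    else:  # all cells identical
        dist = np.zeros(len(cell_table) * (len(cell_table) - 1) // 2)
    Z = hierarchy.linkage(dist, method=method)
    order = np.asarray(hierarchy.leaves_list(Z))
    if n_clusters is None:
        labels = hierarchy.fcluster(Z, t=1e-12, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusterResult(order, labels, Z, kept, dropped)


def export_heatmap(result: ClusterResult, cell_table: pd.DataFrame, path) -> None:
    """Render the cells x markers heatmap in dendrogram order to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = log_intensity(cell_table[result.markers].to_numpy())[result.order]
    fig, ax = plt.subplots(figsize=(max(4, len(result.markers) * 0.5), 6))
    im = ax.imshow(data, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xticks(range(len(result.markers)), result.markers, rotation=90, fontsize=7)
    ax.set_ylabel("cells (cluster order)")
    fig.colorbar(im, label="log10(1 + corrected MFI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_2d(cell_table: pd.DataFrame, marker_x: str, marker_y: str, path, labels=None) -> None:
    """2D log-intensity plot of one marker pair (the hypothesis-driven view)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for m in (marker_x, marker_y):
        if m not in cell_table.columns:
            raise SchemaError(f"cell table lacks marker {m!r}")
    x = log_intensity(cell_table[marker_x].to_numpy())
    y = log_intensity(cell_table[marker_y].to_numpy())
    fig, ax = plt.subplots(figsize=(5, 5))
    if labels is None:
        ax.scatter(x, y, s=6, alpha=0.6)
    else:
        for lab in pd.unique(labels):
            sel = np.asarray(labels) == lab
            ax.scatter(x[sel], y[sel], s=6, alpha=0.6, label=str(lab))
        ax.legend(fontsize=7, markerscale=2)
    ax.set_xlabel(f"{marker_x} log10(1+MFI)")
    ax.set_ylabel(f"{marker_y} log10(1+MFI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
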