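"""Shipped marker panels and CSF composition presets.

The standard 11-marker surface panel (CD3, CD4, CD8, CD14, CD19, CD24, CD27,
CD38, CD45RA, CD56, HLA-DR) covers the routine CSF leukocyte populations;
the extended panel adds the immunoglobulin isotypes and light chains used to
work up a suspected B-cell clone (IgA, IgD, IgM, IgG, kappa, lambda).

Three composition presets are shipped:

``ms_like``
    An inflammatory CSF resembling the worked clinical example: 79% T cells
    with a CD4:CD8 ratio of 2.7 (CD4 cells of central-memory phenotype,
    CD27+ CD45RA-), 12% B cells of which 15% are plasmablasts
    (CD19low CD27+ CD38high), 1.5% monocytes, plus NK cells and
    HLA-DRhigh lineage-negative dendritic cells.
``control``
    A non-inflammatory CSF: T-cell dominated, very few B cells.
``lymphoma_like``
    A monoclonal IgM+ lambda-restricted B-cell expansion (84% B cells).

Polyclonal B-cell populations are represented as kappa/lambda sub-profiles
in a roughly 60:40 mix so light-chain clonality is testable.
"""

from __future__ import annotations

from .simulate import MarkerExpression, PopulationProfile, expression

STANDARD_PANEL: tuple[str, ...] = (
    "CD3",
    "CD4",
    "CD8",
    "CD14",
    "CD19",
    "CD24",
    "CD27",
    "CD38",
    "CD45RA",
    "CD56",
    "HLA-DR",
)

EXTENDED_PANEL: tuple[str, ...] = STANDARD_PANEL + ("IgA", "IgD", "IgM", "IgG", "kappa", "lambda")


def _profile(name, fraction, size_class="lymphocyte", **states) -> PopulationProfile:
    """Build a profile over the extended panel; unspecified markers are negative."""
    expr: dict[str, MarkerExpression] = {}
    for marker in EXTENDED_PANEL:
        state = states.get(marker.replace("-", "_"), "negative")
        expr[marker] = expression(state)
    return PopulationProfile(name, fraction, expr, size_class)


def ms_like() -> tuple[PopulationProfile, ...]:
    return (
        _profile("CD4_Tcm", 0.576, CD3="positive", CD4="positive", CD27="positive", CD38="low"),
        _profile("CD8_T", 0.214, CD3="positive", CD8="positive", CD27="positive", CD45RA="positive"),
        _profile(
            "B_switched_kappa", 0.0612,
            CD19="positive", CD24="positive", CD27="positive", CD38="low",
            HLA_DR="positive", IgG="positive", kappa="positive",
        ),
        _profile(
            "B_switched_lambda", 0.0408,
            CD19="positive", CD24="positive", CD27="positive", CD38="low",
            HLA_DR="positive", IgG="positive", **{"lambda": "positive"},
        ),
        _profile(
            "plasmablast_kappa", 0.0108,
            CD19="low", CD27="positive", CD38="high", HLA_DR="positive",
            IgG="low", kappa="positive",
        ),
        _profile(
            "plasmablast_lambda", 0.0072,
            CD19="low", CD27="positive", CD38="high", HLA_DR="positive",
            IgG="low", **{"lambda": "positive"},
        ),
        _profile("monocyte", 0.015, size_class="monocyte", CD14="positive", CD4="low", HLA_DR="positive"),
        _profile("NK", 0.045, CD56="positive", CD38="low"),
        _profile("DC", 0.030, size_class="monocyte", HLA_DR="high", CD4="low"),
    )


def control() -> tuple[PopulationProfile, ...]:
    return (
        _profile("CD4_Tcm", 0.40, CD3="positive", CD4="positive", CD27="positive", CD38="low"),
        _profile("CD4_naive", 0.27, CD3="positive", CD4="positive", CD27="positive", CD45RA="positive"),
        _profile("CD8_T", 0.23, CD3="positive", CD8="positive", CD27="positive", CD45RA="positive"),
        _profile(
            "B_naive_kappa", 0.012,
            CD19="positive", CD24="positive", HLA_DR="positive",
            IgD="positive", IgM="positive", kappa="positive",
        ),
        _profile(
            "B_naive_lambda", 0.008,
            CD19="positive", CD24="positive", HLA_DR="positive",
            IgD="positive", IgM="positive", **{"lambda": "positive"},
        ),
        _profile("monocyte", 0.04, size_class="monocyte", CD14="positive", CD4="low", HLA_DR="positive"),
        _profile("NK", 0.03, CD56="positive", CD38="low"),
        _profile("DC", 0.01, size_class="monocyte", HLA_DR="high", CD4="low"),
    )


def lymphoma_like() -> tuple[PopulationProfile, ...]:
    return (
        _profile(
            "B_lymphoma_lambda", 0.84,
            CD19="positive", CD24="positive", HLA_DR="positive",
            IgM="positive", **{"lambda": "positive"},
        ),
        _profile("CD4_Tcm", 0.08, CD3="positive", CD4="positive", CD27="positive", CD38="low"),
        _profile("CD8_T", 0.04, CD3="positive", CD8="positive", CD27="positive", CD45RA="positive"),
        _profile("monocyte", 0.02, size_class="monocyte", CD14="positive", CD4="low", HLA_DR="positive"),
        _profile("NK", 0.01, CD56="positive", CD38="low"),
        _profile("DC", 0.01, size_class="monocyte", HLA_DR="high", CD4="low"),
    )


COMPOSITION_PRESETS = {
    "ms_like": ms_like,
    "control": control,
    "lymphoma_like": lymphoma_like,
}


def composition_preset(name: str) -> tuple[PopulationProfile, ...]:
    try:
        return COMPOSITION_PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown composition preset {name!r}; available: {sorted(COMPOSITION_PRESETS)}") from None


#: Top-level gated population each simulated population should land in.
TOP_LEVEL_OF = {
    "CD4_Tcm": "T",
    "CD4_naive": "T",
    "CD8_T": "T",
    "B_switched_kappa": "B",
    "B_switched_lambda": "B",
    "B_naive_kappa": "B",
    "B_naive_lambda": "B",
    "B_lymphoma_lambda": "B",
    "plasmablast_kappa": "B",
    "plasmablast_lambda": "B",
    "monocyte": "monocyte",
    "NK": "NK",
    "DC": "DC",
}


def top_level_fractions(composition) -> dict[str, float]:
    """Configured fractions aggregated to gated top-level populations."""
    out: dict[str, float] = {}
    for p in composition:
        out[TOP_LEVEL_OF[p.name]] = out.get(TOP_LEVEL_OF[p.name], 0.0) + p.fraction
    return out
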