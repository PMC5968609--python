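# Methods

This note documents the models, defaults and numerical choices behind
`chipcyto`, and what the simulation-based tests do and do not establish
about real chip-cytometry data.

## Measurement model

For cell *i* at field of view (FOV) *p*, in the cycle staining marker *m*:

```
stained MFI     = L_p (g_m E_im + A_i) + B_p + ε
post-bleach MFI = L_p (ρ g_m E_im + A_i) + B_p + ε′
```

* `E_im ≥ 0` — true expression in arbitrary fluorescence units; `E = 0` for a
  marker the cell does not express.  Expressed markers are lognormal per
  population with ordinal levels *low* (median 300 AU), *positive* (median
  2000 AU) and *high* (median 20 000 AU), log-SD 0.25 — roughly one decade
  between levels, which is what ordinal gating assumes.  A *negative* marker
  contributes no specific signal at all; the fluorescence a negative cell
  shows comes entirely from autofluorescence.
* `A_i` — per-cell autofluorescence, lognormal (median 100 AU, log-SD 0.5),
  drawn once per cell and fully retained by bleaching (the residual-dye
  fraction `ρ` applies to stain only, default 0).
* `L_p ∈ [0.8, 1.2]`, `B_p ∈ [0, 200]` AU — multiplicative gain and additive
  offset per FOV, constant across cycles.  Constant-per-FOV illumination is
  the simplest model under which the bleach-subtraction claim is falsifiable;
  smooth intra-FOV fields are deliberately not modelled.
* `ε` — additive Gaussian measurement noise, SD 10 AU.  Negative sampled
  MFIs are clamped to 0 and counted.

Bleach subtraction computes `MFI_corr = stained − post-bleach`.  It cancels
`B_p` exactly, `L_p A_i` in expectation *and per cell up to noise* (the same
`A_i` enters both terms), leaving `L_p g_m E_im (1 − ρ) + (ε − ε′)`.
Corrected values are floored at 0 for gating, with the negativity rate logged
as a noise diagnostic; statistical checks of unbiasedness use the unfloored
differences (`floor=False`), because flooring adds the positive bias
E[max(ε−ε′, 0)] by construction.  Whether the instrument subtracts the same
cycle's post-bleach image or the previous cycle's is ambiguous in practice;
same-cycle is implemented (the alternative only changes which `ε′` is paired).

## Cohort and preanalytics

Cellularity is a two-component lognormal mixture: a normocellular mode with
median 1.8 cells/µl (log-SD 0.55, resampled into [0, 5)) and a pleocytic mode
of 5/µl plus a lognormal excess (median 10/µl, log-SD 1.0).  The default
mixture weight is 24.5% pleocytic.  Collection volumes are lognormal (median
4 ml, log-SD 0.4) clipped to [1, 15] ml.  Centrifugation loss is per-cell
Bernoulli with probability 0.593, so the recovered count is
Binomial(N, 0.407).  Optional per-population adhesion weights reweight the
loading composition, modelling selective adhesion (e.g. stickier monocytes).

## Detachment and artificial phenotypes

Before every cycle — detachment is driven by fluid exchange, approximated as
once per cycle — each attached cell detaches with probability 0.02 (default);
a detached cell reattaches with probability 0.3 at a uniform random position
and is measured again from the next cycle on.  QC retains only cells present
in all cycles on one spatially consistent track: tracks starting after cycle
1 are `excluded_reattached`, tracks ending early (or with gaps) are
`excluded_partial_track`.  Track matching is greedy nearest-neighbour linking
between consecutive cycles within a 5 µm radius (≈ half a lymphocyte
diameter; cells are stationary unless they reattach), candidates taken in
order of increasing distance, ties broken by smaller detection id; unmatched
later-cycle detections open new tracks.  Recall for reattached cells is
limited only by the chance that a reattachment lands within the matching
radius of a vacated track end; at realistic densities this keeps recall
above 95%.

## Imaging surrogate

Image mode renders each FOV as a transmitted-light raster (background 1000,
cells as darker disks, contrast 400) and a fluorescence raster (background
`B_p`, disk amplitude = stained MFI − `B_p`), both convolved with a Gaussian
PSF (σ 0.5 µm) at 0.5 µm/px on rasters of at most 512×512.  Detection is Otsu
thresholding plus 8-connected components with a 20–400 µm² area band as the
debris filter; MFI is the mean over the component mask.  This is an explicit
surrogate for the instrument's proprietary recognition software, not a
reproduction of it; the PSF and mask-edge effects bias the recovered MFI low
by a few percent, so the round-trip tolerance is stated at 15%.  Table mode
bypasses imaging and feeds the simulator's MFI tables directly, which is what
cohort-scale analyses use.

## Gating

Gating operates on `v = log10(1 + MFI_corr)` with per-marker thresholds
θ_low = 1.7, θ_pos = 2.9, θ_high = 3.8 — geometric midpoints between the
expression levels above (no automatic mixture fitting; real data would need
per-marker calibration).  Bands: neg `v < θ_low`, low `[θ_low, θ_pos)`, pos
`≥ θ_pos`, high `≥ θ_high`, plus `low_or_pos` (`≥ θ_low`) for "any detectable
expression".  The default tree (first-match-wins at each level): T = CD3 pos
with children CD4 pos, CD8 pos, Tcm = CD27 pos & CD45RA neg; B = CD19
low-or-pos & CD3 neg with children plasmablast = CD19 low & CD27 pos & CD38
high and switched-memory = CD27 pos & IgG pos (included only when IgG is in
the panel); monocyte = CD14 pos; NK = CD56 pos & CD3 neg; DC = lineage
(CD3/CD14/CD19/CD56) neg & HLA-DR high; everything else `unclassified`.
Because evaluation is first-match-wins among siblings, a CD4⁺ central-memory
T cell lands at leaf `T/CD4`.  Published gating strategies for this modality
are not printed anywhere; this tree is a reconstruction of the populations
the field names, and is fully replaceable by a YAML/JSON document.

Population percentages are rounded half-up to one decimal and ratios are
computed from the rounded percentages (two decimals), matching clinical
reporting style; zero denominators yield flagged undefined ratios, never
infinities.  Light-chain clonality calls use the conventional clinical κ:λ
interval (0.26–1.65) — a documented convention, not a measured quantity —
with a 10-cell minimum below which the call is `indeterminate`.

## Sufficiency and agreement

A chip is analyzable when its mean cells/FOV is at least 20 (the mean is the
default aggregation; a per-FOV minimum is available — which of the two the
visual assessment corresponds to is not documented).  Stratified reports use
cumulative `≥` bands (5, 10, 30, 50 cells/µl; 10 000, 50 000, 100 000
absolute) so rows overlap by design, and recompute every percentage from the
counts they print.

Bland-Altman differences are `reference − chip`; a negative bias therefore
means the chip reads high.  Limits of agreement use 1.96 (normal quantile),
sample SD with n − 1, no small-sample t-correction.  The recovery experiment
pools the per-population percentage differences across patients for its
overall statistic (per-patient averaging is the noted alternative); CD4:CD8
ratios are compared in ratio units separately.  Per-patient compositions are
jittered with a Dirichlet (concentration = 200 × base fractions) so the
reference varies realistically across patients; chips below the sufficiency
cut-off are excluded and counted.

## Problem sizes and determinism

Cohort-scale checks run at 3000–12 000 cells/chip and 10–20 virtual patients
or seeds; chip capacity is capped at 12 000 cells in the recovery experiment.
These sizes make every binomial check well-powered while keeping the whole
suite and the acceptance script desk-scale.  All randomness flows from one
user seed through named substreams (cohort / preanalytics / loading / cycles
/ render / recovery), so stages are independently reproducible and identical
seeds yield byte-identical experiment tables.

## What the simulation does not show

The simulator draws statistically idealized cells: expression is exactly
lognormal within populations, illumination is constant per FOV, detachment is
independent of phenotype and position, cells do not move unless they
reattach, and there is no focus drift, stage-repositioning error, debris,
doublets or erythrocytes.  Passing tests therefore demonstrate that the
*algorithms* are correct under their stated assumptions — e.g. that bleach
subtraction is exactly offset-invariant, or that QC structurally rules out
artificial phenotypes — not that real chips meet those assumptions.  In
particular the gate thresholds and the κ:λ bounds would need recalibration
on real intensity distributions, and the agreement statistics quantify only
sampling and processing noise, not inter-method biology.
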