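# Methods

## Measurement model

A duplex ddPCR reaction partitions a 20 µl mix into droplets of volume
*V*; each droplet receives an independent Poisson number of target (WPRE,
read on FAM) and reference (TERT, read on HEX) template molecules at rate
λ = c·V. The negative-droplet fraction therefore estimates e^−λ, and the
absolute concentration is c = −ln(n_neg/n_total)/V in copies/µl of
reaction mix. Target and reference occupancy are treated as independent:
the assay digests genomic DNA with EcoRI before partitioning, which places
the two loci on separate fragments (the target amplicon carries no EcoRI
site), so droplet co-occupancy carries no linkage information.

The bulk vector copy number is the concentration ratio scaled by two
reference copies per diploid genome, VCN_bulk = 2·c_WPRE/c_TERT. Because
VCN is a ratio, the gDNA input mass and reaction volume cancel and are
carried only as metadata.

## Transduced-cell adjustment

Under a Poisson integration model — every cell equally susceptible, each
integration independent, growth unaffected by copy load — per-cell copies
are k ~ Poisson(λ) with λ estimated by VCN_bulk. The transduced fraction
is 1 − e^−λ and the mean copy number among transduced cells is the
zero-truncated Poisson mean VCN_adj = λ/(1 − e^−λ), which is always
≥ max(1, VCN_bulk) and approaches VCN_bulk as λ grows. `adjust_vcn` uses
`expm1` so the identity VCN_adj·(1 − e^−VCN_bulk) = VCN_bulk holds to
machine precision down to λ ≈ 1e−6. A bulk VCN of exactly zero returns
NaN with transduction 0 rather than the mathematical limit 1: a sample
with no detected vector has no transduced population to describe, and a
release report should say so rather than print a copy number.

The per-cell distribution report exposes both the all-cells Poisson pmf
(λ = VCN_bulk; this is what makes "fraction of cells with VCN 0"
well-defined, and is the report default) and the zero-truncated variant
describing transduced cells only, whose mean equals VCN_adj. Internally
the support is extended until the cdf reaches 1 − 1e−9 so normalisation
checks are meaningful; the displayed table defaults to the smallest k
with cdf ≥ 0.9999.

These model assumptions are idealisations: real transduction shows
cell-to-cell susceptibility differences and possible selection against
high-copy cells, so the adjustment is a best estimate when the true
per-cell distribution is unmeasured, bracketed in practice between the
bulk value and the sorted-positive-population value.

## Droplet calling

Classification is per-channel with a scalar threshold, matching the
single-threshold display of the instrument software; a droplet is positive
iff its amplitude lies strictly above the threshold (ties negative —
conservative against contamination). Automatic thresholds: `otsu`
maximises between-class variance on a 256-bin histogram; `midpoint`
returns the mean of the two cluster centers of the exact 1-D two-group
split (the histogram-free equivalent). All-identical amplitudes raise a
degenerate-input error. No droplet-quality filtering is applied (the
instrument pre-filters); wells below a configurable minimum accepted
droplet count (default 10,000) are flagged, not rejected.

## Confidence intervals and replicate pooling

The 95% CI on a concentration is a Wilson score interval on the
negative-droplet fraction mapped through −ln(·)/V (endpoints swap because
the map is decreasing); Wilson was chosen for its behaviour at extreme
fractions, where the Wald interval collapses. The VCN_bulk CI is the
conservative ratio of interval endpoints. Replicate wells of a sample are
combined by an accepted-droplet-weighted mean (more droplets, more
information), with the unweighted sample SD and CV% reported as
dispersion. Reported VCN values are rounded to two decimals with full
precision retained in a parallel field.

A fully positive well (no negative droplets) raises a saturation error —
the concentration is unbounded and the sample must be diluted; a zero
reference concentration raises a reference-failure error.

## Assay limits and validation statistics

Limits use the standard parametric forms on blank (NTC) replicates with
the sample (n−1) SD: LoB = mean + 1.645·SD, LLoD = max(LoB + 3.3·SD,
lowest dilution tested), LLoQ = max(LoB + 10·SD, lowest dilution tested),
all in copies/µl of reaction mix. The MAX rule keeps a claimed limit from
falling below the lowest concentration the dilution series actually
probed. Flagging against limits is strictly-below: a value equal to a
limit counts as quantifiable. Dilution linearity is ordinary least squares
on a linear or log-log scale (natural log; the base moves slope and
intercept, never R²). Inter-assay repeatability is CV% = 100·SD/mean per
dilution condition; the two-way ANOVA sometimes quoted alongside such
panels is a routine omnibus test and is not part of the assay math here.

## Simulator

`simulate_well` draws per-droplet occupancies k ~ Poisson(c·V) per channel
and amplitudes from a positive Gaussian (k ≥ 1) or negative Gaussian
(k = 0), with an optional uniform "rain" band between the cluster means;
defaults (negative mean 1000, positive mean 8000, SD 400, 20,000 droplets,
V = 0.85 nl — the QX200 convention, configurable since instruments differ)
give the cleanly separated four-cluster landscape of a healthy duplex
well. Published amplitude statistics for these assays are not available,
so the Gaussian parameters are a design choice, not a calibration.
`simulate_dilution_series` scales the target concentration by each factor
while holding the reference fixed, emulating serial dilution of product
gDNA into same-donor PBMC gDNA. `simulate_cell_product` draws per-cell
copies k_i ~ Poisson(λ) and exposes the template totals a product
contributes to a reaction (WPRE = Σk_i, TERT = 2·n_cells), closing the
loop for end-to-end tests. Every generator takes a mandatory seed and is
bit-reproducible.

What the simulator does not emulate: rain from partial amplification or
droplet coalescence beyond the uniform band, amplitude drift across a
plate, droplet-volume variation, probe cross-talk between channels, and
non-Poisson integration biology. Passing tests therefore demonstrate the
statistical chain is correct under the stated model, not that real
products obey the model.

## Problem sizes and numerical choices

The test suite and acceptance script run at the assay's native scale:
20,000-droplet wells, 10^5–10^6-cell products, 100 replicate seeds for
coverage experiments, concentrations spanning the validated 5–2500
copies/µl range — sizes at which the whole suite completes in seconds.
CI coverage is asserted at ≥ 93% (binomial fluctuation around the nominal
95% over 1000 runs), mid-range estimator bias at < 2%, distribution
normalisation at 1e−9, and the adjustment inverse identity at 1e−10
relative error. Fixed calling thresholds (the midpoint 4500 of the
configured cluster means) are used inside simulation experiments where
the amplitude model is known; automatic thresholding is exercised
separately.

## Limitations

- The adjustment inherits all Poisson-model assumptions; products with
  strongly heterogeneous susceptibility will sit outside its guarantees.
- The reference gene is assumed strictly diploid; TERT amplification
  (rare in healthy T cells) would bias VCN downward.
- Per-channel scalar thresholds cannot separate diagonal rain clouds; a
  2-D cluster model is out of scope.
- Limits computed from synthetic blanks characterise the formulas, not
  any particular instrument's blank distribution.
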