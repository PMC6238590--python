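# Methods

## The model

Brown adipocytes in culture catabolize triglyceride (TAG), glucose and
glycogen; a plate respirometer measures their oxygen consumption rate
(OCR) and proton production rate (PPR), and supernatant assays measure
glycerol, free fatty acid (FFA) and lactate release plus tracer glucose
uptake. This package implements the closed bookkeeping that connects
those measurements into a per-condition flux table, for wild-type (WT)
and UCP1-ablated (Ucp1-KO) cells, in the basal state and under
isoproterenol (β-adrenergic stimulation), with and without oligomycin
(ATP-synthase inhibition). All internal rates are nmol·h⁻¹·cm⁻² of
culture area; per-cell, per-µg-protein and mass bases are derived views
(89 µg protein and 82,916 pg DNA = 13,819 cells per cm², at 6 pg DNA
per cell).

### Respiration components

Traces are segmented at injection times; each inter-injection phase is
averaged after discarding the first measurement cycle (mixing
transient; `skip_first=1`, configurable — instrument software does not
document its own rule). Components follow the standard protocol
algebra: coupled = basal − post-oligomycin; non-mitochondrial =
post-antimycin A; maximal capacity = post-FCCP; the isoproterenol
response is measured against the phase immediately preceding the
injection, which makes both injection orders (iso-then-oligo and
oligo-then-iso) comparable. Oligomycin sensitivity of the iso response,
1 − (induced under oligomycin)/(induced free), is clamped into [0, 1]
with a flag; all other negative derived components are preserved and
flagged rather than clamped, because they are data.

### Proton sources

Three molecular species acidify an unbuffered medium:

* **CO₂** — respiratory CO₂ hydrates to carbonic acid and dissociates;
  with an overall pKa of 6.093 at 37 °C. The CO₂-derived proton flux is
  OCR × 0.65, where 0.65 = (16/23, the CO₂/O₂ of complete palmitate
  oxidation) × (0.934, the realized hydrated fraction). The
  Henderson–Hasselbalch fraction at pH 7.4 would be 0.953 (giving
  0.663); we keep the fixed 0.65 as the default because it is the
  model's stated constant, and expose `hydrated_fraction` for the
  pH-derived path.
* **Lactate** and **exported FFAs** — quantitatively dissociated at
  physiological pH, one H⁺ per molecule. Only exported FFAs count:
  oxidized and re-esterified FFAs never reach the medium.

The respiratory quotient used for CO₂ *production* defaults to 0.7. A
documented `table_calibrated` mode uses 0.62, because every CO₂/OCR
ratio in the reference dataset lies in 0.613–0.625; the basis of that
calibration is not stated in the source and we do not guess at it.

### Lipid bookkeeping

One TAG yields one glycerol and three FFAs; glycerol is not re-used by
adipocytes, so glycerol release counts lipolysis. FFA β-oxidation is
bounded from OCR assuming exclusive palmitate oxidation — default
stoichiometric mode OCR/23 (which reproduces the reference table's
oxidation rows exactly); the energetic alternative, OCR × 431 µJ/nmol
O₂ ÷ 9.8 µJ/pmol palmitate, agrees within 1.2%. Then

```
FFA_reesterified = 3·glycerol − (FFA_exported + FFA_oxidized)
TAG_hydrolyzed   = (FFA_exported + FFA_oxidized + FFA_reesterified)/3
```

Substituting the first into the second gives TAG_hydrolyzed ≡ glycerol
release exactly; this identity is the primary oracle for both
operations in the tests. Negative re-esterification estimates are
returned as-is with a below-zero flag and rendered `<0` in display
output. Re-esterification is the putative UCP1-independent ATP sink: it
is the only quantity that is iso-induced, oligomycin-sensitive and
KO-specific.

### Glucose and glycogen

Lactate release / 2 is a deliberate *lower* bound on glycolytic glucose
demand (pyruvate oxidized instead of reduced is ignored). Demand minus
measured uptake is the inferred internal-store mobilization. A glycogen
time course gives the store flux directly: least-squares slope of
content (µg/cm²) vs time, converted to glucose units via the 162 g/mol
anhydroglucose residue (not free glucose's 180 — the store is a
polymer; the source does not state its conversion).

### Flux-table assembly

Derived quantities are computed per well, then aggregated to mean ± SD
(sample SD, n−1). This order was chosen because the reference table's
printed means are mutually inconsistent at the mean level by ~1% in
exactly the way per-replicate computation predicts (e.g. its WT-iso
re-esterification, 10.9, vs 10.8 recomputed from the printed means).
Package tests against those printed group means therefore accept ≤2%
relative deviation; closed-form identities are tested exactly.

## The synthetic generator

`simulate_experiment` emulates one plate study: per genotype, traces
under both injection orders (5 phases × 4 cycles of 6 min, injections
mid-gap between phases), per-well metabolite rates, and glycogen time
courses over a 1-h window. Phase OCR levels and metabolite rates
default to the published condition means; maximal (FCCP) OCR is set 25%
above each genotype's highest block OCR and non-mitochondrial OCR to
3 nmol·h⁻¹·cm⁻², since neither has a printed value. The iso-state
glycogen flux defaults to −54 glucose-unit nmol·h⁻¹·cm⁻² with an
initial store of 13.8 µg/cm² (1 ng/cell).

PPR traces are generated *from* the acidification model, so a
decomposition of simulated data has zero structural residual and any
residual isolates a pipeline bug; `unexplained_ppr` injects a constant
extra acidification to exercise residual reporting. Noise is one
mean-one lognormal factor per well and quantity (default sd 0.10 — a
typical plate CV; the source reports no well-level dispersion) plus
additive Gaussian jitter on individual trace points (default
1 pmol·min⁻¹). A seed is required and fixes every draw.

What the generator does **not** emulate: instrument drift, edge-well
effects, carry-over between injections, FCCP dose–response, buffering
kinetics, or any correlation between metabolite wells and respirometry
wells. Passing recovery tests therefore demonstrate the bookkeeping and
its error propagation, not robustness to instrument artifacts.

## Numerical choices and degenerate inputs

* Display rounding is one decimal, half-away-from-zero.
* Phase means with no usable cycles after skipping raise an error
  naming the phase; empty input files are errors, not empty results.
* Missing measurements (e.g. glucose uptake in oligomycin blocks) stay
  absent (NaN), never zero.
* A fold change over a zero baseline is reported as undefined while the
  difference is still returned.
* Unknown configuration keys are rejected (typo safety); the effective
  configuration is echoed to the log on every CLI run.

## Problem sizes

Default analyses use 6 wells per condition; the recovery experiment
spans 3–48 wells to show the 1/√n error scaling. Traces are 20 points
per well. These sizes match a single-plate study design and keep every
analysis script and the full test suite in the seconds range.

## Known limitations

* Palmitate/tripalmitin is the sole reference lipid species; the ~0.6%
  gap between 28.2 nmol × 807.3 g/mol (= 22.77 µg) and the published
  22.9 µg mass figure suggests a slightly different molar mass was used
  upstream; we fix 807.3 and document the discrepancy rather than
  back-fit.
* The oxidation bound assumes all O₂ reduces fatty-acid substrate; with
  mixed fuels it overstates FFA oxidation.
* The glycogen inference is a budget argument, not a tracer
  measurement; amino-acid-derived gluconeogenesis is out of scope.
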