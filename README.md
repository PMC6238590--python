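# adipoflux

Quantitative substrate-flux bookkeeping for brown adipocyte plate
respirometry.

Brown adipocytes dissipate energy as heat — classically through UCP1,
and, as this model quantifies, also through an ATP-consuming futile
cycle of lipolysis and FFA re-esterification. `adipoflux` turns the raw
readouts of a plate-based extracellular-flux experiment (oxygen
consumption and proton production traces with an oligomycin /
isoproterenol / FCCP / antimycin A injection protocol) plus supernatant
metabolite rates (glycerol, FFA, lactate, glucose uptake) into an
interconnected per-condition flux table:

* respiration components: coupled, leak, maximal, non-mitochondrial,
  isoproterenol-induced, and its oligomycin sensitivity;
* proton-source decomposition of extracellular acidification,
  PPR ≈ OCR·0.65 (carbonic acid) + lactate + exported FFA;
* lipid bookkeeping per condition, with one triglyceride giving one
  glycerol and three FFAs:
  `FFA_reesterified = 3·glycerol − (FFA_exported + FFA_oxidized)`,
  `TAG_hydrolyzed = (FFA_exported + FFA_oxidized + FFA_reesterified)/3`,
  and the oxidation bound `FFA_oxidized ≤ OCR/23`;
* glycogen budget: glycolytic demand `lactate/2` vs measured glucose
  uptake, and the store flux from a glycogen time course (162 g/mol
  anhydroglucose units).

A synthetic plate-experiment generator with known ground truth
(`adipoflux.simulate`) makes every stage testable end-to-end and
supports parameter-recovery experiments. All rates are nmol·h⁻¹·cm⁻²;
per-cell, per-protein and mass views use the culture conversion factors
(89 µg protein, 82,916 pg DNA = 13,819 cells per cm²).

## Worked example

```python
from adipoflux import (
    MetaboliteRates, lipid_fluxes, decompose_ppr, oligo_sensitivity,
)

# isoproterenol-stimulated WT cells, rates in nmol/h/cm²
rates = MetaboliteRates(glycerol_release=28.2, ffa_release=66.6,
                        lactate_release=98.4, glucose_uptake=3.5)
fluxes = lipid_fluxes(rates, ocr=165.6)
print(f"FFA oxidized      {fluxes.ffa_oxidized:.1f}")
print(f"FFA re-esterified {fluxes.ffa_reesterified:.1f}")
print(f"TAG hydrolyzed    {fluxes.tag_hydrolyzed:.1f}")

ppr = decompose_ppr(ocr=165.6, lactate_release=98.4, ffa_release=66.6)
print(f"modeled PPR       {ppr.modeled_total:.1f} "
      f"(CO2 {ppr.from_co2:.1f} + lactate {ppr.from_lactate:.1f} "
      f"+ FFA {ppr.from_ffa:.1f})")

s = oligo_sensitivity(151.8 - 44.4, 48.0 - 20.4)  # Ucp1-KO iso response
print(f"KO oligomycin sensitivity {s.value:.3f}")
```

prints

```
FFA oxidized      7.2
FFA re-esterified 10.8
TAG hydrolyzed    28.2
modeled PPR       272.6 (CO2 107.6 + lactate 98.4 + FFA 66.6)
KO oligomycin sensitivity 0.743
```

Of the 84.6 nmol FFA liberated per hour and cm², only 7.2 (≈8.5%) is
β-oxidized even assuming pure lipid fuel; 10.8 is re-esterified — the
futile cycle — and the rest is exported. The KO cells' isoproterenol
response is three-quarters oligomycin-sensitive (ATP-driven), whereas
the same calculation for WT cells clamps to zero sensitivity
(UCP1-mediated leak).

## Analysis pipeline

Numbered drivers under `analysis/` rebuild the study end to end on
synthetic data and write their tables under `results/`:

```sh
python analysis/01_simulate_plate_experiment.py --seed 1
python analysis/02_respiration_components.py
python analysis/03_proton_sources.py
python analysis/04_lipid_glycogen_fluxes.py
python analysis/05_parameter_recovery.py
```

The same stages are available as a CLI (`adipoflux simulate|segment|
ppr|fluxes|report`, each accepting `--config` YAML and `--seed`), with
CSV in, TSV/JSON out; negative re-esterification cells render as `<0`
in the display TSV while the JSON keeps the signed value and a flag.

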