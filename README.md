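# cnspbpk

A minimal physiologically based pharmacokinetic (PBPK) model of antibiotic
distribution into the human brain, built for the situation encountered in
neurocritical care: patients on intermittent intravenous antibiotic
infusions whose brain extracellular fluid (ECF) is sampled by microdialysis
or whose cerebrospinal fluid (CSF) drains through an external ventricular
drain (EVD) into a collection bag. The package is aimed at clinical
pharmacologists and PK modellers who want to simulate CNS exposure, fit the
model to sparse multi-stream patient data, and ask what happens to brain
concentrations when pathophysiology (barrier disruption, oedema,
hypoperfusion) or CSF drainage changes.

## Model

Five physiological compartments — blood, lumped non-CNS tissue, brain
vasculature, brain ECF and cranial CSF — plus an absorbing EVD bag. All
transfer is linear and passive:

```
V_B    dC_B/dt  = Input + fd·CO·C_T/Kp + Q_brain·C_V − C_B·(fd·CO + Q_brain + CL)
V_T    dC_T/dt  = fd·CO·(C_B − C_T/Kp)
V_V    dC_V/dt  = Q_brain·C_B + PS_ECF·C_E + C_C·(PS_CSF + Q_sink)
                  − C_V·(Q_brain + PS_ECF + PS_CSF)
V_ECF  dC_E/dt  = PS_ECF·C_V − C_E·(PS_ECF + Q_bulk)
V_CSF  dC_C/dt  = PS_CSF·C_V + Q_bulk·C_E − C_C·(PS_CSF + Q_sink + Q_EVD)
V_EVD  dC_EVD/dt = Q_EVD·C_C
```

`PS_ECF` and `PS_CSF` are the bidirectional permeability–surface clearances
of the blood–brain and blood–CSF barriers (the latter half the former, from
the half surface area), `Q_bulk` the ECF→CSF bulk flow and `Q_sink` CSF
reabsorption. A drain substitutes for blocked reabsorption:
`Q_sink = max(Q_sink,physio − Q_EVD, 0)`. Volumes and flows are fixed to
literature physiology; drug parameters default to metronidazole, a
high-permeability antibiotic with purely passive CNS distribution.

Microdialysate observations are interval collections, predicted as the
time-average of `C_E` over each collection interval; EVD-bag observations
are predicted as `Q_EVD·∫C_C dt / V_EVD` per interval. Population fitting
uses a log-normal random effect on clearance with a Laplace-approximated
marginal likelihood (proportional + additive residual error for plasma,
proportional for the CNS streams), with bootstrap confidence intervals.
Caco-2 apparent permeabilities can be screened with the efflux ratio and
scaled to an in-vivo `PS` via barrier surface area and brain weight.

## Worked example

```python
from cnspbpk import (DosingRegimen, DrugParameters, SystemParameters,
                     derive_patient_physiology, evd_dose_fraction, simulate)

sys_p = SystemParameters()            # literature physiology
drug = DrugParameters()               # metronidazole defaults
phys = derive_patient_physiology(90.0, sys_p, drug.fd)   # 90 kg patient
regimen = DosingRegimen(dose=500, infusion_duration=0.5, tau=8)

res = simulate(sys_p, drug, phys, regimen, evd=0.02)     # steady state, q8h
print(f"mean blood conc over tau : {res.auc('blood', 0, 8) / 8:.3f} mg/L")
print(f"mean ECF conc over tau   : {res.auc('ecf', 0, 8) / 8:.3f} mg/L")
print(f"mean CSF conc over tau   : {res.auc('csf', 0, 8) / 8:.3f} mg/L")
print(f"dose recovered in EVD bag: {evd_dose_fraction(res, 0.02):.3f} %")
```

prints

```
mean blood conc over tau : 8.562 mg/L
mean ECF conc over tau   : 8.544 mg/L
mean CSF conc over tau   : 8.522 mg/L
dose recovered in EVD bag: 0.273 %
```

The three mean concentrations are nearly identical — the model's central
statement about a freely diffusing antibiotic: CNS exposure mirrors blood
exposure, and the drain removes a negligible 0.27% of each dose. (Without
a drain the mean blood concentration is exactly dose-rate/CL =
500/(8·7.28) = 8.585 mg/L.)

A synthetic cohort with the study design (4 microdialysis + 4 EVD
subjects, 500 mg q8h, sparse plasma sampling) and a population fit:

```python
from cnspbpk import (CohortDesign, FitConfig, PopulationTruth,
                     fit_population, generate_cohort, patients_from_frame)

frame = generate_cohort(CohortDesign(), PopulationTruth(), sys_p, seed=1)
patients = patients_from_frame(frame)
fit = fit_population(patients, sys_p, drug, FitConfig(n_starts=2))
print(fit.theta, round(fit.cv_percent, 1))
```

A command-line interface mirrors the library:
`cnspbpk simulate|permeability|generate|fit|vpc|sensitivity --help`.

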