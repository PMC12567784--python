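# nanopbtk

Physiologically based toxicokinetic (PBTK) simulation of inhaled 20 nm
titanium dioxide nanoparticles (TiO₂-NPs) in the rat.

Inhaled nanoparticles deposit in the upper airway, tracheobronchial and
alveolar regions; a small fraction crosses the air–blood barrier and is
redistributed by the circulation, while the rest is cleared up the
mucociliary escalator and swallowed. `nanopbtk` implements a 23-state
mass-balance ODE model of this process for toxicologists and exposure
modellers who need organ content–time curves, elimination half-lives and
parameter-sensitivity rankings for rat inhalation scenarios.

## Model

Every systemic organ *o* (liver, kidney, spleen, rest of body) is split into
capillary blood, tissue and a phagocytic-cell (PC) pool, with
permeability-limited exchange and saturable, time-dependent endocytosis:

```
dM_o,cab/dt = Q_o (M_art/V_art − M_o,cab/V_o,cab) − X_o Q_o (M_o,cab/V_o,cab − M_o,tis/(P_o V_o,tis))
dM_o,tis/dt = X_o Q_o (M_o,cab/V_o,cab − M_o,tis/(P_o V_o,tis)) − (K_o,up(t) M_o,tis − K_o,out M_o,PCs)
dM_o,PCs/dt = K_o,up(t) M_o,tis − K_o,out M_o,PCs
```

with the Hill uptake rate

```
K_o,up(t) = K_o,max · tⁿ⁰ / (K_o,50ⁿ⁰ + tⁿ⁰)
```

where t is time since exposure onset. The respiratory tract adds upper
airway, tracheobronchial, alveolar-surface and alveolar-PC pools, a lung
interstitium with its own PC pool, and the lung capillary in series between
venous and arterial blood. Excretion routes are hepatobiliary (liver PCs →
feces), urinary (kidney tissue → urine) and mucociliary (tracheobronchial →
feces). Because K_up depends on time rather than mass, the system is linear
in the state, and the summed derivatives equal the external source exactly —
both properties are enforced by the test suite.

Dosing is either a bolus (instantaneous regional deposits in ng) or a
continuous source EC·BR·FR per region (aerosol concentration EC in ng/L,
breathing rate BR in L/min, deposition fractions FR). Evaluation utilities
provide AAFE, relative error, R², the 0.5–2× fold band, log-linear
half-life regression, normalized local sensitivities d ln y / d ln θ,
0.5×/2× perturbation studies and log-space least-squares calibration.

## Worked example

`examples/01_simulate_calibration_scenario.py` simulates the calibration
exposure (2 h inhalation represented as a bolus of 40 ng tracheobronchial +
892 ng alveolar deposit) and prints whole-organ contents:

```
deposited dose: 932 ng
mass-balance residual: 4.89e-12 ng

observable                 4 h        24 h       168 h       674 h
tracheobronchial          11.6      0.0237    0.000299    1.83e-05
alveolar                   299         146        50.5        1.81
lung                       558         561         194        6.99
liver                     28.9        67.8        23.8       0.853
kidney                   0.627        3.98        2.68      0.0939
spleen                    1.33        6.69        16.2        2.95

peaks (value, time, first time at half peak):
  lung          624 ng at    8.6 h, half at   102.5 h
  liver        69.2 ng at   17.9 h, half at   116.1 h
  kidney       5.07 ng at   53.6 h, half at   175.9 h
  spleen       16.3 ng at  149.1 h, half at   420.2 h
```

The tracheobronchial pool empties within a day (mucociliary clearance at
0.31/h), the alveolar surface drains into the lung interstitium, which
peaks at 624 ng around 9 h and dominates the body burden, and the secondary
organs fill from — and empty with — the circulating concentration set by the
lung. Other examples score the model against synthetic noisy data
(AAFE 1.06, log-R² 1.00 at 20 % noise), rank parameter sensitivities
(P_lu is the dominant systemic parameter), run 0.5×/2× perturbations, and
recover a twofold-displaced P_lu to 0.004 %.

A command-line interface mirrors the library:

```
nanopbtk simulate --preset kreyling --t-end 1500 --out result.csv
nanopbtk fixtures generate --preset kreyling --noise-cv 0.2 --seed 42 --out observed.csv
nanopbtk evaluate --result result.csv --observed observed.csv
nanopbtk sensitivity --param P_lu --output liver --times 24,168,674
```

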