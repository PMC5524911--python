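# cardioavatar

A personalized lumped-parameter (0D) model of the pulmonary venous
system, left heart and systemic arterial circulation, with:

- a time-varying elastance (double-Hill) left atrium and ventricle,
  diode heart valves (linear mitral resistance/inertance; aortic valve
  with an energy-loss/pressure-recovery quadratic term), viscoelastic
  RLCRv aortic segments and three-element Windkessel vascular beds;
- a fixed-step implicit simulation engine (trapezoidal rule + chord
  Newton, numba-compiled; 1 ms steps over a 20 s horizon by default);
- two-stage subject personalization: stage one derives twelve parameters
  from non-invasive measurements (five volumetric flow waveforms at the
  mitral valve, aortic valve, distal ascending aorta, arch and abdominal
  aorta; brachial cuff pressures; LV end-systolic volume; aortic
  valve/root geometry), stage two fits the remaining 36 parameters
  (32 free + 4 within ±10%) by bounded Levenberg–Marquardt against the
  measured waveforms, with two closure parameters re-derived from the
  systemic-resistance and total-compliance constraints at every step;
- profile-likelihood identifiability analysis with a chi-square(1) 95%
  threshold and three-way classification (identifiable / practically /
  structurally non-identifiable);
- a virtual-subject generator that emulates the measurement bundle from
  a known ground-truth parameter set (40 frames/cycle, additive Gaussian
  flow noise, cuff pressures as extrema of the simulated aortic root
  pressure), making the whole pipeline testable end to end.

## Command line

```bash
# generate a virtual subject (waveform CSVs + subject.json [+ truth.json])
avatar synth --seed 7 --noise-sd 1 --out subjectdir/ --with-truth

# forward-simulate a parameter file and write the final cycle
avatar simulate --params subjectdir/truth.json --out cycle.csv

# two-stage personalization against a subject bundle
avatar fit --subject subjectdir/subject.json --out fit.json

# profile-likelihood analysis of a completed fit
avatar profile --fit fit.json --subject subjectdir/subject.json \
               --params all --out pl.json

# pressure summary + PV loop of a fitted model
avatar report --fit fit.json --out report.json
```

`--config run.yaml` on the group overrides solver defaults (`dt`,
`duration`, `sigma`, `seed`, `confidence`, `max_iterations`,
`verbosity`).

## Package layout

```
src/cardioavatar/
  parameters.py       50-parameter model description, roles, literature values
  _core.py            numba kernels: circuit RHS + implicit integrator
  model.py            constitutive equations, simulation, PV loop, summaries
  measurements.py     measurement bundle, waveform/cuff index calculators
  initialization.py   stage-one estimates, closure relations
  estimation.py       bounded LM fit (sine-transformed MINPACK)
  identifiability.py  profile likelihood, CI walk, classification
  synthetic.py        virtual subjects, velocity-plane fixtures
  cli.py              click CLI (synth / simulate / fit / profile / report)
```
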