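# fumet — kinetic modeling of 5-fluorouracil metabolism in yeast

5-fluorouracil (5-FU) is an anticancer prodrug that is metabolized through the
pyrimidine salvage pathways into fluorinated nucleotides, which poison RNA and
DNA synthesis. In *Saccharomyces cerevisiae* the anabolic (phosphorylating)
half of this network runs on ATP, so when the ATP pool collapses — as it does
under oxidative stress — the system tips into net catabolism: triphosphates
drain back through monophosphates and nucleosides toward free 5-FU, and
FdUMP, the thymidylate-synthase inhibitor, can appear through routes that are
silent under ATP-rich conditions.

`fumet` is a tested Python pipeline for studying this switch *in silico*. Its
core is a 22-reaction / 16-species kinetic ODE model of intracellular 5-FU
metabolism (free base, nucleosides, mono-/di-/tri-phosphates of the ribo-,
deoxyribo- and thymidylate series, fluorine incorporated into RNA and DNA,
plus the ATP/ADP pair), with three rate-law families:

* irreversible Michaelis–Menten: `v = V·S/(Km+S)`
* reversible Michaelis–Menten: `v = (Vf·S/Kms − Vr·P/Kmp)/(1 + S/Kms + P/Kmp)`
* reversible Ping Pong Bi Bi (Cleland form) for the ATP-driven kinases,
  parameterized by `Keq, Kia, Kiq, Kma, Kmb, Kmp, Kmq, Vf, Vr`

Around the model the package provides:

* **simulation** (`fumet.simulator`) — stiff integration over the 17-h
  observation window with either a forced ATP-collapse curve (relative ATP
  halves by ~1 h, < 5% by 4 h) or dynamic ATP/ADP with a bulk ATPase sink;
  per-reaction flux traces, phase-wise dominant-flux reports, and a long-run
  steady-state solver. Total fluorine is conserved structurally and its
  drift is checked on every run.
* **estimation** (`fumet.estimation`) — weighted-least-squares fitting of the
  model to grouped ¹⁹F observables by Hooke–Jeeves pattern search (iteration
  limit 50, tolerance 1e-5, rho 0.2, standard-deviation weights), chained
  into a staged multi-attempt protocol with per-parameter bfv/avg/stds and
  dev/stds statistics. Searches run in log10 parameter space.
* **metabolic control analysis** (`fumet.mca`) — analytic elasticities,
  flux- and concentration-control coefficients at the steady state with
  link-matrix reduction; the summation theorems (FCC rows → 1, CCC rows → 0)
  hold to machine precision and are verified on every analysis.
* **dose–response** (`fumet.dose_response`) — the Hill dose–survival model
  `survival = 100%/(1+(dose/EC50)^h)`, nonlinear least-squares EC50/Hill
  estimation with standard errors and a 95% confidence band, and the
  Lorentzian linewidth → T2 NMR helper.
* **synthetic data** (`fumet.synthetic`) — seeded generators for study-shaped
  inputs: hourly ¹⁹F observable groups (1–17 h, 1 mM total fluorine),
  relative ³¹P ATP curves, and five-replicate dose–survival tables.
* **I/O and CLI** (`fumet.io`, `fumet.cli`) — CSV schemas for time courses
  and survival tables, YAML parameter overrides, SBML Level 3 export/import,
  and a `fumet` command with `build / simulate / fit / mca / ec50 / synth /
  report` subcommands.

The model ships with the published best-fit kinetic constants as defaults,
including the parameter-sharing scheme (the same enzyme acting on different
substrates shares parameters by reference) and the fixed phosphohydrolase
Michaelis constants (15 µM for UTP/dTTP, 12.5 µM for UDP/dTDP). The full
parameter census is 113 (16 initial concentrations + rate-law parameters);
77 are free after sharing and fixing.

## Worked example

```python
import numpy as np
from fumet import build_network, simulate, steady_state
from fumet.mca import control_coefficients

net = build_network()
traj = simulate(net, t_grid=np.arange(0.0, 17.5, 0.5))
print(traj.observables().loc[[1.0, 4.0, 17.0]].round(1))

ss = steady_state(net, tol=1e-9)
print("persistent:", ss.nonvanishing)
res = control_coefficients(net, ss)
print("active cycle:", res.active_reactions,
      "FCC row-sum dev:", f"{res.fcc_rowsum_max_dev:.1e}")
```

prints

```
       5FU  FUDR+  FUMP+  FUDP+/FUTP+    FNA  totalF
time
1.0  109.5   34.5    7.8        135.9  712.3  1000.0
4.0   52.6   18.4    7.8         70.5  850.7  1000.0
17.0   0.0    0.0    7.8         81.3  910.8  1000.0
persistent: ('5FU', 'FUDR', 'FdTMP', 'FDNA', 'ADP')
active cycle: ('R1', 'R7', 'R9') FCC row-sum dev: 7.3e-13
```

Total fluorine stays at 1000 µM (1 mM, the normalization of the measured
spectra) throughout. The long-run state keeps nonzero free 5-FU, its
nucleoside FUDR and ADP, with a residual salvage cycle circulating through
uracil phosphoribosyltransferase (R1), the hypothetical 5′-nucleotidase (R7)
and uridine hydrolase (R9) — the asymptotic behavior expected once ATP is
gone. The numbered scripts under `analysis/` run the full study pipeline
(simulation and flux phases, parameter recovery, control analysis,
dose–response) and write their tables under `results/`.

Dose–survival example:

```python
import numpy as np
from fumet.synthetic import generate_dose_survival
from fumet.dose_response import fit_dose_response

tab = generate_dose_survival(18.0, 0.51, np.geomspace(1, 1e4, 8),
                             replicates=5, noise_sd=0.1, seed=11)
fit = fit_dose_response(tab["dose_um"], tab["survival_pct"])
print(f"EC50 = {fit.ec50:.1f} ± {fit.ec50_se:.1f} µM, "
      f"Hill = {fit.hill:.3f} ± {fit.hill_se:.3f}")
# EC50 = 18.7 ± 1.3 µM, Hill = 0.533 ± 0.020
```

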