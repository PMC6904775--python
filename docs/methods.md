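# Methods

## Model

The state vector holds 16 concentrations (µM): 14 fluorinated species — 5FU,
FUDR, FdUDR, FUMP, FdUMP, FdTMP, FUDP, FdUDP, FdTDP, FUTP, FdUTP, FdTTP,
FRNA, FDNA — plus ATP and ADP. Twenty-two reactions connect them; every
reaction converts exactly one fluorinated species into exactly one other, so
the fluorinated-species indicator is a left null vector of the stoichiometry
matrix and total fluorine is conserved by construction, independent of the
kinetics. The seven kinase reactions additionally consume ATP and produce
ADP 1:1 and use the reversible Ping Pong Bi Bi rate law in Cleland's form

    v = Vf·Vr·(A·B − P·Q/Keq) / (Vr·Kmb·A + Vr·Kma·B + Vr·A·B
        + Vf·Kmq·P/Keq + Vf·Kmp·Q/Keq + Vf·P·Q/Keq
        + Vr·Kma·B·Q/Kiq + Vf·Kmq·A·P/(Kia·Keq)),

with A = ATP, P = ADP. This algebraic form was chosen because its parameter
list is exactly the nine constants the published parameter table carries per
kinase; the original source typesets its rate formulas as images, so the
specific reversible form is a design choice of this package, not a verbatim
transcription. The remaining reactions use irreversible or reversible
Michaelis–Menten kinetics. Reactions 7, 15 (5′-nucleotidase activity) and 17
(RNA-residue return) are flagged hypothetical: they represent return routes
not confirmed enzymatically in yeast.

Parameter handling mirrors the study design: the same enzyme acting on
different substrates is treated as invariant, implemented as by-reference
aliases (reaction 11 ≡ 3, 15 ≡ 7, 18 ≡ 3, 20 ≡ 13, 21 ≡ 5, 22 ≡ 6, and the
phosphohydrolase V of reaction 6 ≡ reaction 5), and the phosphohydrolase
Michaelis constants are fixed at their literature values (15 µM for the
triphosphates, 12.5 µM for the diphosphates). Counting 16 initial
concentrations plus 2/4/9 rate-law parameters per irreversible-MM /
reversible-MM / ping-pong reaction gives the 113-parameter census; removing
aliases and fixed values leaves 77 free. Two table entries (reaction 13 Kia
= 9.4e4 µM, reaction 17 Vf = 81.19 µM/h) come from visibly misaligned rows
of the published table and are marked low-confidence in the code.

Initial concentrations: the study's own initial-state table is not available
in the extracted source, so the shipped default is this package's choice,
normalized to Σ fluorinated = 1000 µM (the 1 mM normalization of the
measured spectra) with mass predominantly in the di-/tri-phosphate (505 µM)
and nucleic-acid (260 µM) pools to match the early-time observable
distribution, a small FdTTP/FdTDP stock left from the pre-incubation period,
and ATP/ADP at 1000/200 µM. All defaults are overridable via the YAML
config.

## ATP handling

The measured relative ATP level starts at 1, halves within about an hour and
is near zero by 4 h. Two treatments are available:

* **forced** (default): ATP(t)/ATP(0) = 1/(1+(t/t_half)^s) with t_half = 1 h
  and s = 2.5, giving exactly 0.5 at 1 h and 0.030 at 4 h; ADP takes up the
  balance. The functional form of the study's own fitted ATP-catabolism
  curve is not stated, so this monotone generalized-logistic decay is a
  documented package choice constrained by the two anchor points. Only the
  14 fluorinated species are integrated; ATP/ADP enter the kinetics as
  inputs.
* **dynamic**: ATP and ADP are state variables and a first-order bulk ATPase
  sink ATP → ADP (default k = 0.75 h⁻¹, chosen to halve ATP by ~1 h and
  reach < 5% by 4 h) is appended. The sink stands for all non-fluorinated
  ATP turnover and is explicitly not one of the 22 model reactions. With
  k = 0 the kinases alone exchange ATP/ADP and the pair's sum is conserved —
  the property the tests assert.

## Numerics

The rate constants span ~28 orders of magnitude, making the system extremely
stiff (Jacobian entries up to ~1e15 h⁻¹ near depleted pools). Integration
uses LSODA (BDF available) with the analytic Jacobian assembled from the
closed-form rate-law derivatives, at rtol 1e-8 / atol 1e-9 µM. The
right-hand side deliberately does **not** clamp small negative excursions:
the rate laws extend smoothly through values of order −atol, whereas a hard
max(x, 0) introduces a derivative kink at zero that collapses the stiff
solvers' step size (observed: four orders of magnitude slowdown). Negative
values are clipped only in the returned trajectory, with a warning whenever
they exceed 10·atol; total-fluorine drift is recorded per run (typically
~1e-15 relative).

The steady-state solver relaxes the ATP-clamped system (forced mode: ATP at
its asymptote 0, ADP at the pool total) over geometrically expanding
horizons up to 1e6 h, then polishes with a damped Gauss–Newton iteration
(least-squares step, backtracking line search, projection to non-negative
concentrations) until ‖dx/dt‖∞ < 1e-8 µM/h by default. Non-convergence is
reported as an explicit result object, never silently.

## Fitting protocol

The objective is weighted least squares over the grouped observables (and
optionally the relative ATP series): residuals divided by the standard
deviation of each observed series, per-series weights normalized so the
largest is 1. Because total fluorine is constant by conservation, its
sample standard deviation is numerical noise; every series' sd is therefore
floored at 5% of the series' scale before weighting, which keeps a constant
series from dominating the objective through integrator noise. Simulation
failures inside the search return +inf with a logged cause so the pattern
search can continue.

Optimization is Hooke–Jeeves pattern search — exploratory coordinate moves
plus accelerating pattern moves, step shrink factor rho = 0.2, iteration
limit 50, step tolerance 1e-5 — run in log10 parameter space (bounds default
to ±3 decades around the start). The staged protocol pre-minimizes the
objective below 0.15, then chains further attempts, each starting from the
previous adjustment, until the attempt-to-attempt variation falls below
1e-6; the five most accurate attempts are kept and summarized per parameter
as best-fit value, attempt mean, sample standard deviation and
|bfv−avg|/stds (0 when the spread is zero). With noisy data the 0.15
pre-minimization threshold may be unreachable on this weighting scale; the
protocol then warns and proceeds, bounded by the attempt budget.

The parameter-recovery oracle (a 6-step unbranched MM chain, free maximal
rates, hourly noiseless observables over 1–17 h) runs the same machinery
with the step tolerance tightened to 1e-9 decades: the step tolerance bounds
how precisely parameters can be placed, and hence the terminal objective
(~1e-4 at tolerance 1e-5, ~1e-12 at 1e-9); the routine-fitting default stays
at 1e-5. The chain's initial mass is spread along the chain so every step
carries identifiable flux. On 5%-noise data the recovered rates stay within
a few percent and the pooled predicted-vs-observed R² exceeds 0.99.

## Metabolic control analysis

MCA is defined at a steady state; the default reference is the long-run
fixed point above. Scaled elasticities are computed analytically (and
cross-checked against central finite differences to 1e-4); entries that
would log-differentiate a zero rate are reported as undefined, not
NaN-propagated.

At the ATP-depleted fixed point most species sit at zero behind irreversible
steps, and pure sink coordinates (FDNA, and FdTMP once ATP is gone) make the
full Jacobian singular, so control coefficients are computed on the *active
subnetwork*: reactions with |steady flux| above threshold (default 1e-6
µM/h) and the species they touch. Conserved moieties of the active network
are removed by link-matrix reduction (QR-based independent-row selection)
and the standard matrix formulas applied: Γ = −L(N_r E L)⁻¹ N_r for
concentration control, C^J = I + EΓ for flux control, scaled by the
reference fluxes/concentrations. These satisfy the summation theorems (FCC
rows → 1, CCC rows → 0) to machine precision; an enzyme-perturbation route
(scale Vf and Vr jointly by 1±1e-4, re-solve, central log-differences) is
provided and agrees with the matrix formulas on test pathways, but is too
sensitive to steady-state re-solve error to certify 1e-6 theorem residuals
on the boundary fixed point. Control rows for zero-flux reactions are 0/0
in log scale and are listed as unavailable. With the shipped defaults the
active subnetwork is the salvage triangle 5FU → FUMP → FUDR → 5FU (reactions
1, 7, 9).

## Synthetic data

The generators emulate the *shape* of the study's data: 17 hourly samples
(t = 0 is excluded, mirroring the missing zero-time spectrum) of the six
¹⁹F-indistinguishable observable groups — {5FU}, {FUDR, FdUDR},
{FUMP, FdUMP, FdTMP}, {FUDP, FdUDP, FdTDP, FUTP, FdUTP, FdTTP},
{FRNA, FDNA}, total fluorine — normalized to 1 mM; a relative ³¹P ATP curve
anchored at 1; and five-replicate dose–survival tables. FdTMP is grouped
with the monophosphates (it is a fluorinated monophosphate); the grouping of
the deoxy/thymidylate phosphates follows the pathway diagram rather than an
explicit list in the source. Noise is relative Gaussian per point, default
5% for time courses (the order of the integration error of a 1-h spectrum)
and 10% for survival; every generator is bit-reproducible from its seed.
What the generators do *not* emulate: spectral overlap beyond the fixed
grouping, baseline/phasing artifacts, line-shape changes, the minor
2′-O-methyl metabolite, or cell growth — so passing recovery tests show the
pipeline is self-consistent under the stated noise model, not that the
original experimental values are reproduced (the original data exist only as
figures, and the fitted constants of the real model are not desk-checkable).

## Dose–response and NMR helpers

Survival follows 100%/(1+(dose/EC50)^h); the exponent sign convention is
fixed so survival is 100% at zero dose and decreases with dose (consistent
with the reported positive Hill exponent ~0.51). Fitting is nonlinear least
squares in (log10 EC50, h) with standard errors from the Jacobian covariance
(delta method for EC50) and a pointwise t-based 95% confidence band.
Monotone-increasing "survival" data fail an explicit identifiability check.
T2 = 1/(π·Δν½) assumes a Lorentzian line; 17 Hz ↦ 18.7 ms ≈ 20 ms at one
significant figure.

## Known limitations

* The reversible ping-pong algebra and the forced ATP curve are documented
  reconstructions (see above), not verbatim transcriptions of the source
  model.
* The boundary steady state supports only the three-reaction salvage cycle;
  control coefficients for the silent 19 reactions are undefined there by
  construction.
* Hooke–Jeeves is a local search; the staged protocol refines but does not
  globalize. Strongly correlated parameter pairs (V, Km of a saturated
  step) can stall it on a curved ridge — the recovery oracle conditions the
  problem so all freed parameters are identifiable.
* SBML round-tripping relies on a model-level annotation for the sharing/
  fixing scheme and observable grouping; SBML core alone cannot express
  them. The exported kinetic laws are standard content MathML, so external
  simulators can still consume the file.
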