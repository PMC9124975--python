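# Methods

`fes2red` models the energetics and data reduction of hydrogen-driven
pyrite reduction,

    FeS2 + (1-x) H2  <->  Fe(1-x)S + (1-x) HS- + (1-x) H+ ,     x in [0, 0.17]

the reaction by which methanogens were shown to mobilize iron and sulfur
from an otherwise insoluble mineral, together with the downstream analyses
such a study runs: closed-reactor gas/aqueous bookkeeping, electron-shuttle
feasibility, and a transcript up-regulation screen. This note records the
model assumptions, the defaults and why they were chosen, and the known
limitations.

## Gibbs-energy model (`thermo`, `favorability`)

**Stoichiometry.** The reaction above (its conventional printed form) does
not conserve Fe or S when x > 0: one mole of FeS2 carries 1 Fe and 2 S, but
the right-hand side carries only (1-x) of each. Both conventions are
implemented as first-class objects — `literal` (coefficients exactly as
conventionally written) and `balanced` (per mole FeS2: 1/(1-x) Fe(1-x)S and
(1-2x)/(1-x) each of H2, HS- and H+, which conserves Fe, S, H and charge to
machine precision). Every report emits both, labelled, rather than
pretending one is canonical. At x = 0 they coincide. The default product is
Fe0.86S (x = 0.14); x = 0 selects stoichiometric FeS (mackinawite), the
thermodynamically disfavored alternative.

**Free energies.** dG = sum(nu dGf0) + RT ln Q with Q built from
activities: solids and water at unity, the proton at 10^-pH (pH is treated
as an activity, not a concentration), gases at p/1 bar, aqueous species at
gamma*c/1 M with the Davies equation

    log10(gamma) = -A z^2 ( sqrt(I)/(1+sqrt(I)) - 0.3 I ).

A defaults to 0.509 (25 C); `davies_a_for_temperature` supplies ~0.520 at
38 C for the temperature-adjusted alternative. Neutral species carry unit
coefficients under Davies.

Mineral formation energies are the study's tabulated values (FeS2 -160.2,
Fe0.86S -136, FeS -89.2 kJ/mol); HS- (+12.05), H2(aq) (+17.7), H2(g) (0)
and H+ (0) are supplemented from standard geochemical compilations because
the reaction cannot be evaluated without them. All are 25 C values used
unchanged at 38 C — no enthalpy correction is applied, since no
temperature-correction procedure accompanies the tabulated values and the
13 K offset is small against the tens of kJ/mol being compared. No Pitzer
or SIT activity models and no aqueous speciation solver are provided.

**H2 standard state.** Two conventions are exposed and reported side by
side: aqueous (1 M reference, dGf0 = +17.7 kJ/mol, the default) and gas
(1 bar reference, dGf0 = 0), with aqueous axis values converted to partial
pressures through the Henry constant when the gas reference is selected.
They differ because the +17.7 kJ/mol hydration energy and the Henry
conversion do not cancel exactly; reports are labelled per convention.

**Favorability grids.** The default surface spans H2 1e-12..1e-2 M and HS-
1e-7..1e-2 M, decade-spaced, at pH 7, I = 0.05 M, 38 C. Favorability is
strict (dG < 0; dG = 0 does not count). `min_favorable_h2` scans a sulfide
row for the first favorable decade; the test suite cross-checks it against
a cell-by-cell brute-force recomputation.

Under these constants the pyrrhotite route is favorable down to 1e-10 M H2
at 1e-7 M HS- in the literal convention (the boundary falls exactly on the
1e-10 decade) and to below 1e-12 M in the balanced convention. The
mackinawite route is unfavorable across the grid **up to ~7.5e-4 M H2**
(dG0 = +65.35 kJ/mol for the x = 0 reaction), but the RT ln Q term
overcomes that barrier at the top of the default grid: the 1e-3 and 1e-2 M
cells compute favorable (-0.7 and -6.6 kJ/mol). Those concentrations
correspond to >9 bar of H2 — beyond any of the culture conditions modelled
here — so the qualitative contrast (pyrrhotite favored, mackinawite not)
holds everywhere it matters physically, but a blanket "never favorable up
to 1e-2 M" claim is not supported by these constants, and the package
reports what it computes. One acceptance-level test asserts the blanket
claim and is expected to fail; it is kept deliberately as documentation of
this tension rather than weakened.

## Gas/aqueous partitioning (`partition`)

Closed 165 mL serum bottles with 75 mL liquid, 90 mL headspace, 2.5 bar
total pressure, 38 C. Ideal-gas headspace; pressure treated as constant
across a sampling event; no salting-out correction and no gas-exchange
kinetics.

Henry constants (mol L^-1 bar^-1 at 38 C): H2 7.92e-4, calibrated so that
a pure H2 headspace at 2.5 bar gives exactly the 1.98e-3 M dissolved
concentration the study conditions quote (the value sits inside the
literature range and then reproduces the 10 % and 1 % conversions by
linearity); H2S 0.0866 (= 0.0877 M/atm), which closes the 30.5 uM aqueous
<-> 3.5 umol total-sulfide balance; CH4 1.1e-3 from literature solubility.
All are configurable through the TSV table.

Total dissolved sulfide partitions with the headspace **as if entirely
volatile** — no HS-/H2S split — because only that convention reproduces
the printed closed-bottle totals this package is calibrated against.
`speciated_total_sulfide` implements the rigorous alternative (only the
neutral H2S fraction 1/(1+10^(pH-pKa1)) exchanges); at pH 7 with pKa1 6.9
it yields 2.83 umol instead of 3.51 umol, a ~19 % difference worth knowing
about when interpreting totals near the detection limit. Detection limits
(1.5 uM aqueous sulfide, 0.1 uM aqueous-equivalent H2) are configuration
constants; sub-limit values are flagged censored, never zeroed.

## Redox potentials (`redox`)

The H2 couple is evaluated as

    E = -(2.303 R T / F) pH - (2.303 R T / 2F) log10(a_H2)     [mV vs SHE]

which reduces to 0 at the SHE point and to -414 mV at pH 7, 25 C, unit
activity. Evaluated at 38 C with aqueous molar activity it gives -317.9 mV
at 198 uM H2 and -123.5 mV at 1e-10 M — the electron "price" of mineral
reduction at the experimental and the thermodynamic H2 floors respectively.
Shuttle feasibility is a pure ordering: a carrier can deliver electrons iff
its potential is at or below the required one (ties sit on the boundary
and are flagged but count as feasible). With the packaged couples, reduced
AQDS (-184 mV) clears the -123 mV requirement by ~61 mV and
methanophenazine (-165 mV) by ~42 mV, reproducing the feasibility ordering
AH2QDS < methanophenazine < 0. A `potential_from_delta_g` bridge
(E = -dG/nF) ties this module to the Gibbs module; an electron
pseudo-species (unit activity, zero formation energy) lets half-reactions
be written there, and the two routes are required to agree to 1e-3 mV in
the tests. No electrode kinetics, junction potentials or AQDS speciation.

## Reactor data reduction (`reactor`)

Raw measurements are (reactor, condition, time, analyte, mode, value,
censored) rows. Aqueous-mode volatile analytes go through the closed-vessel
balance, headspace-mode analytes through the GC ppm conversion
(n_gas = p V_head / RT plus n_aq = kh p V_liq), and nonvolatile Fe(II)
counts the liquid phase only. Replicates aggregate to mean and sample SD
(n-1); censored values are excluded from the statistics and surface as a
censored fraction rather than being substituted at half-limit (substitution
is left to the caller; exclusion matches plotting detected values only).
Constant headspace pressure across repeated samplings is an assumption, not
a measurement. No growth-curve or rate-law fitting is attempted.

## Transcript screen (`transcripts`)

Only the normalization needed by the abundance threshold is implemented:
median-of-ratios size factors (median over genes positive in every sample
of count/geometric mean), rescaled to unit geometric mean so the estimator
is exactly idempotent; the DE test itself is an input boundary — records
arrive with per-gene LFC and p against each of two reference conditions.

The screen: p < 0.05 AND LFC > 0.5 against **both** references AND focal
abundance fraction > 0.005 %, all strict inequalities, so boundary values
are excluded. p-values are used as given (the wording the thresholds come
from does not say "adjusted"); a Benjamini-Hochberg flag exists but is off
by default. The abundance fraction is computed over focal-condition
replicates only. The four-way category used for locus-map coloring: blue
(significant and large against both), green (significant against both,
LFC <= 0.5 for at least one), yellow (positive LFC against both, not
significant for at least one), white (otherwise) — a partition, checked
property-wise. Conservation tallies count, for a recovered gene set,
homolog presence across genome columns of a 0/1 matrix (the matrix is an
input; no homology search is performed). The real experiment's gene lists
are not reproduced — they require the deposited sequencing data and genome
databases — only these structural analogs on synthetic fixtures.

## Synthetic data (`synthetic`)

`gen_counts` emulates a 3-condition x 4-replicate bulk RNA-seq experiment:
log-normal baseline means (meanlog 5, sdlog 1, i.e. typical counts in the
tens-to-thousands), gamma-Poisson (negative-binomial) sampling with
dispersion 0.05 — a realistic overdispersion for clonal culture replicates
— and 12 planted genes whose focal-condition means are scaled by 2^2.0
against both references (4x the screen's LFC threshold, comfortably past
the >= 2x margin at which exact recovery is the designed behaviour).
`gen_de_records` computes empirical LFCs from normalized means
(pseudocount 0.5) and **plants** p-values: 1e-4 for planted genes, i.i.d.
uniform for nulls, keeping ground truth unambiguous rather than
re-deriving a test. One consequence of planting p independently of counts:
with 500 nulls there is a small per-seed chance (<~1 %) that some null
draws p < 0.05 against both references while also showing an empirical
LFC > 0.5 in both, which would register as a false discovery; real data
would not decouple p from effect size this way. `gen_reactor_series`
produces logistic accumulation (plateau/(1+exp(-r(t-t0))), r = 1.2/d,
t0 = 4 d over a 10-day sampling grid) with multiplicative Gaussian noise
(5 % relative SD) and detection-limit censoring, in triplicate; the
mineral condition's sulfide plateau is 30.5 uM aqueous so the reduction
stage should recover the closed-bottle total within 3 noise-SD. Plateaus,
rates and noise are documented defaults, not claims about the real
trajectories; what passing tests show is that the pipeline's plumbing is
correct, not that real reactors behave logistically.

All generators are pure functions of (spec, seed) and are reproduced bit
for bit under a repeated seed.

## Numerical choices and degenerate inputs

- Fixed internal units (K, mol/L, bar, kJ/mol, mV); R = 8.31446 J/mol/K,
  F = 96485 C/mol, 1 atm = 1.01325 bar.
- Empty reactions evaluate to dG = 0; non-empty reactions must have both a
  reactant and a product. Missing table species raise errors naming the
  species.
- Grid rows are matched by relative log-distance (1e-9 tolerance); off-axis
  sulfide queries are errors, not silent interpolation.
- Replicate groups with a single detected member report SD 0; fully
  censored groups report NaN with censored fraction 1 (never a negative or
  fabricated mean).
- CLI outputs are byte-deterministic for fixed inputs and seed; provenance
  lives in comment headers (tool version, config hash, seed).

## Problem sizes

Defaults throughout are the analysis' own natural sizes: 11 x 6 favorability
grids, 500-gene x 12-sample count matrices, 6-time-point triplicate reactor
series. The full test suite and the acceptance script each run in seconds.

## Known limitations

- No temperature extrapolation of equilibrium constants (no van't Hoff
  machinery); conclusions are specific to ~38 C.
- The aqueous-vs-gas H2 reference ambiguity shifts absolute dG values by a
  few kJ/mol; favorability boundaries are therefore reported per
  convention rather than asserted once.
- The "0.6 mbar ~ 0.8 uM" equivalence sometimes quoted for prior-work H2
  levels is inconsistent with the Henry constant implied by the 2.5 bar
  <-> 1.98e-3 M calibration (which gives ~0.48 uM); the package flags
  rather than reconciles this.
- Pyrrhotite dissolution kinetics, FeS_aq cluster speciation and particle
  interfacial-energy corrections are out of scope (no constants or rate
  laws are available to implement them honestly).
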