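# fes2red

Thermodynamics and data reduction for hydrogen-driven pyrite (FeS2)
reduction — the process by which anaerobic methanogens mobilize iron and
sulfur from a mineral long considered biologically unavailable.

Pyrite is nearly insoluble, yet methanogens grown with FeS2 as their sole
Fe and S source reduce it to soluble sulfide and a pyrrhotite-like solid:

    FeS2 + (1-x) H2  <->  Fe(1-x)S + (1-x) HS- + (1-x) H+ ,   x in [0, 0.17]

`fes2red` is a small library (plus CLI) for researchers in microbial
geochemistry who want to ask, quantitatively: *when is that reaction
downhill, what electron carriers could drive it, and what do closed-reactor
and transcriptomic measurements of cultures doing it actually say?* It
provides:

- **`fes2red.thermo`** — species tables, Davies-equation activity
  coefficients, and dG = sum(nu dGf0) + RT ln Q evaluation for the
  reaction above in both its literal and element-balanced stoichiometries;
- **`fes2red.favorability`** — dG grids over [H2] x [HS-], minimum
  favorable H2 scans, and pyrrhotite-vs-mackinawite product comparison;
- **`fes2red.partition`** — Henry's-law conversions and closed serum-bottle
  (liquid + headspace) mass balance for H2, CH4 and total sulfide;
- **`fes2red.redox`** — Nernst potentials for the H2 couple
  (E = -(2.303RT/F) pH - (2.303RT/2F) log10 a_H2) and feasibility ordering
  of electron shuttles such as reduced AQDS and methanophenazine;
- **`fes2red.reactor`** — reduction of raw time-series measurements
  (colorimetric aqueous assays, headspace GC ppm) to total-amount
  trajectories with replicate statistics and detection-limit censoring;
- **`fes2red.transcripts`** — median-of-ratios normalization and the
  dual-reference up-regulation screen (p < 0.05, LFC > 0.5 against both
  reference conditions, > 0.005 % abundance), four-way gene categorization
  and cross-genome conservation tallies;
- **`fes2red.synthetic`** — seeded generators for every input the pipeline
  consumes (negative-binomial count matrices with planted up-regulated
  genes; logistic reactor series with noise and censoring), so the whole
  pipeline is testable with no external data.

See `docs/methods.md` for the model assumptions and defaults.

## Worked example

```python
from fes2red import (
    Conditions, builtin_species_table, builtin_henry_table,
    pyrrhotite_reaction, build_grid, min_favorable_h2,
    aqueous_from_headspace, h2_couple_potential, PAPER_GEOMETRY,
)

table = builtin_species_table()
cond = Conditions()                      # pH 7, I = 0.05 M, 38 C

rxn = pyrrhotite_reaction(0.14, "literal")     # Fe0.86S product
grid = build_grid(rxn, table, cond)            # H2 1e-12..1e-2 M x HS- 1e-7..1e-2 M
print(min_favorable_h2(grid, hs=1e-7))         # 1e-10

henry = builtin_henry_table()
print(aqueous_from_headspace(1.0, PAPER_GEOMETRY, henry["h2"]))   # 0.00198
print(aqueous_from_headspace(0.1, PAPER_GEOMETRY, henry["h2"]))   # 0.000198

print(round(h2_couple_potential(cond, 1.98e-4), 1))   # -317.9
print(round(h2_couple_potential(cond, 1e-10), 1))     # -123.5
```

Reading: at 1e-7 M sulfide the reduction is thermodynamically favorable
down to 1e-10 M dissolved H2 (the scan returns the first favorable decade);
a pure 2.5 bar H2 headspace dissolves to 1.98e-3 M and a 10 % headspace to
1.98e-4 M — the lowest concentration at which reduction was detectable in
abiotic experiments, more than six decades above the thermodynamic floor.
At that floor, electrons need a potential of -123.5 mV or lower, which
reduced AQDS (-184 mV) and methanophenazine (-165 mV) both satisfy.

The same analyses are scriptable from the shell:

```sh
fes2red favorability --x 0.14 --out grid.tsv
fes2red nernst --ph 7 --temp-c 38 --h2-molar 1.98e-4
fes2red simulate counts --seed 17 --out counts.tsv --truth truth.tsv --de de.tsv
fes2red filter-genes --de de.tsv --out hits.tsv
```

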