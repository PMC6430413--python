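# acetome

A metabolism-and-expression (ME) modeling toolkit with a self-contained
toy acetogen. The package builds a gene-expression reaction network
(transcription, translation, mRNA turnover, complex assembly with
metal-cofactor delivery, translocation) on top of an ordinary metabolic
network, couples catalysis to macromolecule synthesis through
growth-rate-dependent (affine-in-mu) constraints, and maximizes growth by
bisection over LP feasibility. On top of the solver sit the phenotype
analyses: substrate-uptake sweeps, overflow-onset detection, metal
limitation with per-enzyme activities, and expression-growth correlation
with permutation p-values.

## Layout

| module | contents |
| --- | --- |
| `acetome.netcore` | network data model, cobra-json I/O (SBML read-only), element/charge balancing, plain FBA (HiGHS) |
| `acetome.expression` | expression annex schema and the E-matrix reaction builders |
| `acetome.coupling_solve` | ME problem assembly (affine coefficients), bisection growth maximization, problem serialization |
| `acetome.phenotype` | uptake/metal sweeps, overflow onset, secretion ratios, correlation pipeline |
| `acetome.toyme` | the programmatically generated toy acetogen and synthetic expression datasets |

The toy acetogen covers Wood-Ljungdahl carbon fixation with
nickel-dependent CODH4/CODH_ACS, acetate and ethanol (AOR_CL + ALCD2x)
branches, Rnf + ATP synthase energy conservation, Nfn bifurcation, a
cardiolipin loop that sheds glycerol with an expensive recycle path,
Fe-S (NifU/IscS/SufBC/ErpA) and Hyp nickel delivery, and minimal
transcription/translation machinery. Its stoichiometry table is exact on
elements and charge, as is every emitted expression reaction.

## CLI

```bash
acetome toy --substrates co,fructose --seed 42 -o toy_model/
acetome validate toy_model/network.json
acetome fba toy_model/network.json --set EX_co_e:-20,0
acetome build-me toy_model/network.json toy_model/annex.json \
    --set EX_co_e:-20,0 -o me.json
acetome solve me.json --report solution.tsv
acetome sweep toy_model/ --exchange EX_co_e --grid 2:30:4 -o sweep.json
acetome metal toy_model/ --metal EX_ni2_e --grid 0:1:0.25 -o metal.json
acetome correlate sweep.json --n-perm 1000 --seed 7 -o corr.tsv
```

## Conventions worth knowing

- Exchange fluxes: negative = uptake, positive = secretion; uptake caps
  are lower bounds.
- All coupling coefficients are affine in mu (`a + b*mu`); fixing mu
  yields an ordinary LP (HiGHS via `scipy.optimize.linprog`).
- `maximize_growth` bisects to `mu_tol` (default 1e-6/h), asserts
  feasibility monotonicity along the way, and finishes with a
  parsimonious solve (minimum total expression flux plus a small
  metabolic-flux term).
- Secretion below 1e-6 mmol/gDW/h is treated as LP noise by the
  overflow-onset detector.
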