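# limbgrn

Reverse-engineering the gene regulatory network for proximodistal (PD)
patterning of the vertebrate limb bud — on a growing, hourly-remeshed 2D
tissue domain.

During limb outgrowth three nested expression domains mark the future
segments: *Meis1/2* (stylopod), *Hoxa11* (zeugopod) and *Hoxa13* (autopod).
They are positioned by two opposing morphogen gradients: retinoic acid (RA)
diffusing in from the flank, and FGFs produced along the apical ectodermal
ridge (AER), with FGF inducing the RA-degrading enzyme Cyp26b1.  `limbgrn`
asks which wiring of these signals into the Hox genes best explains the
spatiotemporal expression patterns, by simulating candidate networks as
reaction–diffusion systems

    dc/dt = P(c, x, t) + D ∇²c − λ c        (per mesh element, per species)

on a growing triangular mesh (finite-volume discretization, mass-conserving
remeshing every hour), scoring each simulation against staged expression
data with a shape-based objective

    score = Σ_genes Σ_stages  w · (1/N) Σ_elements (c_exp − c_sim)²

(both fields passed through a sigmoid rescaling x^μ/(k^μ+x^μ), so domain
*shape* rather than stain intensity is what counts), and minimizing over
each topology's free parameters from 27 starting points.  The candidate
topologies A–D wire RA (inhibiting) and/or FGF (activating) into Hoxa11 and
Hoxa13; the selected "crossover" Model C — FGF sets Hoxa11's *proximal*
boundary while RA sets Hoxa13 and hence Hoxa11's *distal* boundary — is the
one whose late Hoxa11 domain reproduces the observed geometry: a proximal
boundary more curved than the distal one, because FGF isoclines follow the
curved AER while RA isoclines stay parallel to the straight flank.

The experimental inputs (a clonal-fate-map growth model and WMISH stains
mapped onto it) are not publicly distributed, so the package ships a
synthetic stand-in for both: a parametric growing bud and an expression
dataset generated from a known ground-truth network.  That turns every
analysis into a recovery experiment — model selection must re-identify the
true topology, fitting must re-identify its parameters — and the classical
perturbation experiments (RA-soaked bead, AER removal, ectopic Meis) and
single-cell analyses (two-signal vs progress-zone behaviour) are run
in silico on the fitted circuit.

## Worked example

```python
import limbgrn as lg

# synthetic growth domain: hourly meshes + mass-conserving transfer maps
series = lg.build_growth_series(n_hours=27, target_edge=65.0)

# ground truth (crossover Model C) and a staged, noisy dataset
traj = lg.generate_ground_truth(series, "C", hours=(0, 27))
data = lg.sample_observations(traj, noise_sd=0.05, seed=7)

# score the truth parameters against the data
report = lg.total_score(traj, data)
print(series.meshes[0].n_elements, "->", series.meshes[-1].n_elements,
      "elements;", data.counts(), "score", round(report.total, 3))
```

prints

```
79 -> 261 elements; {'M': 4, 'H11': 26, 'H13': 32} score 0.185
```

i.e. the domain grows from 79 to 261 elements over the 27-h window
(stages mE10:09 → mE11:12), the dataset holds 4/26/32 staged observations
of Meis/Hoxa11/Hoxa13, and the truth parameters score 0.185 against their
own noisy observations (the noise floor; a wrong topology fits 10–20×
worse).  Model selection then runs the 27-start protocol per topology:

```python
table = lg.select_models(["A", "B", "C", "D"], data, series, seed=11,
                         n_starts=27, budget=36, refine_top=1,
                         refine_budget=300)
print(table[["best_score", "rank"]])
```

ranks the crossover model first and the anti-crossover Model D last.  The
same protocols are exposed on the command line (`limbgrn generate-domain`,
`generate-data`, `simulate`, `score`, `fit`, `select`, `ablate`, `perturb`,
`cell`, `pipeline`); see `limbgrn --help`.

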