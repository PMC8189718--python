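# allokit

Graph-theoretic analysis of allosteric conformational ensembles at
thermodynamic equilibrium: coarse graining, effective higher-order
cooperativities, generalised Monod–Wyman–Changeux (MWC) binding functions,
higher-order free-energy measures, constructive realization of arbitrary
cooperativity patterns, and stochastic fitting of Hill-like binding curves.

## Who this is for

Biophysicists and systems biologists modelling ligand binding to
macromolecules (haemoglobin-style oligomers, transcription-factor/DNA
assemblies, GPCRs) that interconvert among many conformations. The package
answers questions like: *given per-conformation association constants and
conformational equilibria, what cooperativity does the ensemble as a whole
exhibit — at every order, not just pairwise? And conversely, which
ensembles produce a prescribed cooperativity pattern or a desired
switch-like binding curve?*

## The model

An ensemble with `N` conformations and `n` binding sites is an
*allostery graph*: vertices `(c, S)` (conformation `c`, bound subset `S`),
"vertical" binding edges with equilibrium labels `x·K[c,i,S]` (`x` the
ligand concentration) and "horizontal" conformational-exchange edges whose
labels are pinned by detailed balance to the path products `λ_c` of the
empty-binding layer. Steady-state probabilities follow from path products
of equilibrium labels (`Pr_v ∝ μ_v`), equivalently from the kernel of the
graph Laplacian, which the package keeps as an independent oracle.

Intrinsic higher-order cooperativities (HOCs) within a conformation are
`ω[c,i,S] = K[c,i,S] / K[c,i,∅]`. Coarse-graining the ensemble over its
horizontal layers yields a single effective binding hypercube whose labels
define **effective** association constants and HOCs as λ-weighted
conformational averages:

    Kϕ[i,S] = ⟨K[c,i,S]·μ_S(c)⟩ / ⟨μ_S(c)⟩,    ωϕ[i,S] = Kϕ[i,S] / Kϕ[i,∅]

Fractional saturation is the logarithmic derivative of the effective
partition polynomial `Ψ(x) = Σ_s a_s x^s`:

    f(x) = (x / nΨ) dΨ/dx

which reduces to the classical MWC formula for two conformations with
identical independent sites. Two further results are implemented
constructively:

* **Flexibility**: any positive target pattern `(β_i, α[i,S])` of effective
  bare constants and HOCs is realizable, to arbitrary accuracy, by an
  ensemble with *no* intrinsic cooperativity (one conformation per site
  subset, accuracy controls `ε, δ`).
* **Hill-function fitting**: a two-step stochastic search (shape-window
  screening, then annealed Monte Carlo) over 4-conformation, 6-site
  ensembles minimising the mean deviation `δ(g, H_h)` between the
  normalized binding curve and a Hill function `H_h(x) = x^h/(1+x^h)`.

## Worked example

Realize the "maroon" four-site cooperativity pattern (mixed positive and
negative HOCs spanning `0.013` to `90`) with an ensemble of 16
conformations that has no intrinsic cooperativity at all:

```python
from allokit.examples import four_site_patterns
from allokit.flexibility import construct, verify
from allokit.effective import effective_params
from allokit.binding import partition_polynomial, normalize

targets, delta, eps = four_site_patterns()["maroon"]
ensemble = construct(targets, eps=eps, delta=delta)
report = verify(targets, ensemble)
print({i: round(v, 5) for i, v in report.Kphi.items()})
print(report.omegaphi[(1, frozenset({2}))])
print(report.max_error)
```

prints

```
{1: 1.57772, 2: 24.01324, 3: 89.9589, 4: 0.01569}
0.08484554069822357
0.0010482654052809026
```

The realized effective bare constants `Kϕ` sit within 0.105% of every
target (`β₁ = 1.5777`, …), the realized effective pairwise HOC
`ωϕ[1,{2}] = 0.08485` matches its target `α = 0.084815`, and the maximum
relative error over all 15 targets is 0.00105 — comfortably below the 0.01
accuracy the controls `(δ = 1e-7, ε = 1e-12)` were chosen for. Continuing,

```python
g = normalize(partition_polynomial(effective_params(ensemble.graph)))
print(g.u05)   # 0.02210... : half-saturating ligand concentration
print(g(1.0))  # 0.5 by construction
```

The same pipeline is scriptable from the shell:

```sh
allokit construct --targets targets.json --eps 1e-12 --delta 1e-7 \
        --out ens.json --report errors.csv
allokit effective --ensemble ens.json --out effective.csv
allokit bind --ensemble ens.json --normalize --out curve.csv
```

## Layout

| module | contents |
| --- | --- |
| `allokit.graphcore` | labelled digraphs, equilibrium labels, cycle condition, steady states, Laplacian oracle |
| `allokit.allostery` | product-structured allostery graphs, association-constant tables |
| `allokit.effective` | coarse graining, effective association constants and HOCs |
| `allokit.binding` | binding polynomials, saturation, normalization, shape, Hill error |
| `allokit.homeasures` | HOCs ↔ residual free energies ↔ mutant-cycle couplings |
| `allokit.flexibility` | the constructive realization theorem and its verifier |
| `allokit.hillfit` | two-step stochastic Hill-function search |
| `allokit.interface` / `allokit.cli` | JSON/CSV formats, fixtures, `allokit` command |

See `docs/methods.md` for the modelling assumptions, numerical choices and
limitations.
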