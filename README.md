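# ubisax

SAXS-restrained coarse-grained conformational ensembles of linear
multidomain protein chains — built around the use case of linear (M1)
polyubiquitin, chains of 76-residue ubiquitin domains joined head-to-tail
by 6-residue linkers.

## Who this is for

Structural biologists and simulators who want to (i) forward-model
small-angle x-ray scattering from bead structures, (ii) restrain or
reweight a simulated ensemble toward experimental SAXS data with a
Bayesian noise model, (iii) enhance conformational sampling of
rigid-domain/flexible-linker chains with metadynamics, and (iv) analyze
the resulting ensembles: free-energy surfaces, compact/open populations,
inter-domain contacts, polymer scaling, and binding-competence estimates.

## The model in brief

**Forward model.** Scattering of a bead structure follows the Debye
equation, the exact orientational average for point scatterers

```
I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sin(q·rᵢⱼ)/(q·rᵢⱼ),          I(0) = (Σᵢ fᵢ)²
```

with per-bead-class effective scattering lengths (electrons in excess of
displaced solvent for the built-in residue table). Ensemble curves are
weighted averages of per-frame curves; Guinier (`ln I ≈ ln I₀ − q²Rg²/3`)
and Kratky (`q²I(q)`) analytics are included.

**Restraint score.** Experimental points dᵢ on an equidistant q grid are
compared with the ensemble-averaged forward model fᵢ under a long-tailed
"outlier" noise likelihood obtained by marginalizing the noise level,

```
Eᵢ = −ln[(1 − e^(−λᵢ))/λᵢ],     λᵢ = (dᵢ − s·fᵢ − o)² / 2σᵢ²,
```

which reduces to the Gaussian score λ/2 for small residuals and grows only
logarithmically for outliers. The data scaling s ∈ [0.9, 1.1] and offset
o ∈ [−1, 1] are sampled under flat priors; σᵢ combines a noise parameter
with the standard error of the ensemble average (maximum block-wise SE).
Ensembles can also be reweighted post hoc toward the same restraint points
by a maximum-entropy update (the Gaussian limit of this score).

**Sampling.** Metropolis Monte Carlo over rigid domains and flexible
linkers (pivot, linker-bead and domain-spin moves) under a surrogate
potential, biased by well-tempered parallel-bias metadynamics on the
chain's collective variables: all pairwise core-center distances,
inter-domain torsions, the backbone radius of gyration, and one
"alphabeta" torsional similarity per linker (4/9/16 CVs for 2/3/4
domains). Final-bias reweighting `w ∝ exp(+V_PB/kT)` recovers unbiased
statistics.

**Polymer scaling.** Chain-length dependence of the mean end-to-end
distance is summarized as `e2e(N) = A·Nᵛ` and compared with the Flory
self-avoiding-walk exponent ν ≈ 0.588; the fixed-exponent mode
extrapolates other linkage chemistries from a measured prefactor, and
`min_chain_length_for_two_dimers` inverts the law to ask how long a chain
must be for two domain pairs to bridge a partner of given span.

## Worked example

Closure of the restraint loop on synthetic ensembles with known ground
truth — generate a 20%-compact two-domain ensemble, synthesize a noisy
SAXS curve from it, then reweight an independent 50%-compact ensemble
toward that curve:

```python
import numpy as np
from ubisax.analysis import WeightedEnsemble, compact_fraction
from ubisax.metainference import RestraintSet, reweight_to_saxs
from ubisax.saxs import FormFactorTable, restraint_grid
from ubisax.synthetic import GeneratorConfig, synth_chain_ensemble, synth_saxs

table = FormFactorTable.uniform()
grid = restraint_grid(0.05, 2.0, 21)
truth = synth_chain_ensemble(GeneratorConfig(
    n_domains=2, frames=400, mode="two_state", p_compact=0.2, seed=1))
data = synth_saxs(truth, grid, table, noise_fraction=0.02, seed=2)
cand = synth_chain_ensemble(GeneratorConfig(
    n_domains=2, frames=400, mode="two_state", p_compact=0.5, seed=3))
w = reweight_to_saxs(cand.frames, cand.weights,
                     RestraintSet(data.q, data.intensity, data.sigma), table)
rew = WeightedEnsemble(cand.frames, w, cand.topology)
print("compact fraction, prior ensemble:   %.3f" % compact_fraction(cand, 0, 1))
print("compact fraction, reweighted:       %.3f" % compact_fraction(rew, 0, 1))
print("compact fraction, generating truth: %.3f" % compact_fraction(truth, 0, 1))
```

prints

```
compact fraction, prior ensemble:   0.500
compact fraction, reweighted:       0.258
compact fraction, generating truth: 0.198
```

i.e. the SAXS restraints pull the mis-specified prior most of the way to
the generating population. The same machinery on self-avoiding chains of
1–6 domains (2000 frames each) gives `e2e(N) = 2.40·N^0.66`, a
Flory-compatible exponent for the surrogate geometry, and inverting the
published-scale law `3.81·N^0.62` for an 11.4 nm partner span yields a
minimum chain length of 8 domains.

A command-line surface mirrors the library:

```
ubisax synth --n-domains 2 --frames 100 --seed 7      # ensemble + SAXS
ubisax simulate --n-domains 2 --steps 2000 --seed 7   # metadynamics MC
ubisax score --traj synth_traj.pdb --saxs-file synth_saxs.dat
ubisax reweight --traj synth_traj.pdb --saxs-file synth_saxs.dat
ubisax analyze --traj synth_traj.pdb --fes dist:torsion
```

## Scope

The package deliberately does not reimplement any molecular force field:
sampling runs on a documented surrogate potential (hard-core domains,
harmonic linkers, optional attraction), and the synthetic generators
produce rigid-shell domain chains designed to exercise the statistics of
the analyses, not side-chain chemistry. See `docs/methods.md` for the full
model description, parameter defaults and limitations.
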