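# thermotrait

Thermal performance curves, trait-based community assembly and diversity
statistics for microbial thermal-gradient experiments.

## The problem

A standard experimental design in microbial thermal ecology works at three
levels. First, bacterial isolates are grown in monoculture across a ladder
of assay temperatures while a plate reader logs optical density (OD600)
every couple of hours; each well yields a logistic growth curve and each
taxon a thermal performance curve (TPC) — growth rate rising with
temperature to an optimum T_opt and collapsing beyond it. Second, the same
taxa are pooled into replicate synthetic communities incubated along a
thermal gradient; end-point colony counts give each community's
composition, richness and evenness. Third, statistics connect the levels:
do taxon-level thermal traits (T_opt, growth rate at the assay temperature)
predict who dominates where, and does the resulting community structure
predict ecosystem function (biomass production)?

`thermotrait` implements that entire analysis chain as a tested, seeded,
reusable pipeline, plus a synthetic-data generator with known ground truth
so every estimation step can be checked for parameter recovery.

## The models

Per well, logistic growth by non-linear least squares:

    N(t) = K / (1 + A e^{-rt}),   A = (K - N0)/N0

Per taxon, the Sharpe–Schoolfield TPC fitted to ln growth rate across
temperature from 1000 random starts, keeping the lowest-AIC fit:

    ln r(T) = E_a (1/kT_c - 1/kT) + ln r(T_c) - ln(1 + e^{E_h (1/kT_h - 1/kT)})

with Boltzmann's constant k = 8.62×10⁻⁵ eV K⁻¹ and the closed-form optimum

    T_opt = E_h T_h / (E_h + k T_h ln(E_h/E_a - 1)).

Per community, relative abundances, richness R, Shannon H′ = −Σ pᵢ ln pᵢ,
Pielou J = H′/ln R, rank-abundance curves, and a >25%-prevalence rare-taxon
filter. Inference: sequential quadratic→linear→null model selection for
diversity and function against temperature, ANCOVA of abundance on thermal
traits with temperature as a factor, PCA of composition, and PERMANOVA on
Bray–Curtis dissimilarities with Bonferroni-corrected pairwise tests.
See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Fit a thermal performance curve to mean growth rates measured at the nine
assay temperatures:

```python
from thermotrait import fit_tpc

temps = [0.0, 15, 20, 25, 30, 35, 40, 45, 50]          # degC
rates = [0.021, 0.224, 0.337, 0.470, 0.578, 0.492, 0.192, 0.051, 0.010]
fit = fit_tpc(temps, rates, n_starts=1000, seed=42)
print(f"E_a  = {fit.ea_ev:.3f} eV")
print(f"E_h  = {fit.eh_ev:.3f} eV")
print(f"T_h  = {fit.th_k:.2f} K")
print(f"T_opt = {fit.topt_c:.2f} degC")
print(f"AIC = {fit.aic:.2f}, quasi-r2 = {fit.quasi_r2:.4f}")
```

prints

```
E_a  = 0.852 eV
E_h  = 3.280 eV
T_h  = 306.54 K
T_opt = 30.83 degC
AIC = -22.32, quasi-r2 = 0.9860
```

E_a says the rate roughly doubles per ~8 °C on the rising limb; the curve
peaks at 30.8 °C and half the enzyme pool is inactivated by ~33 °C
(306.5 K), giving the sharp high-temperature collapse. The quasi-r² near 1
says the unimodal model explains almost all variation in ln rate.

The same analysis from the shell, end to end on simulated data:

```sh
thermotrait run --seed 101 --out run/ --simulate
cat run/summary.txt
```

which reports the model chosen for richness and evenness against
temperature (quadratic under thermal selection: diversity peaks at benign
temperatures and collapses at 10 and 35 °C), the PERMANOVA pseudo-F and
permutation p for compositional change, and the trait–abundance ANCOVA
F statistics. Individual stages are available as `thermotrait simulate |
fit-growth | fit-tpc | diversity | stats`.

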