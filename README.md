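# tetrafit

Statistical-thermodynamic modelling of small-molecule activators binding to
tetrameric ion channels, built around the KCNQ2 potassium channel and its
activator ztz240 as the worked system.

Concentration-response curves of channel activators are almost always fitted
with the empirical Hill equation, which says nothing about how many ligands
are bound, how they cooperate, or how much current each binding state
carries.  `tetrafit` implements an equilibrium alternative for a channel
with four equivalent activator sites: the five binding configurations
CF0..CF4 get statistical weights

    W_k = g_k · γ^C(k,2) · μ^C(k,3) · ν^C(k,4) · (K_A [L])^k

(g_k the configuration multiplicity, 1/4/6/4/1 for a homomer; K_A the site
association constant; γ, μ, ν the pair/triple/quadruple cooperativity
coefficients, i.e. Boltzmann factors of the coupling energies), occupancy
probabilities p_k = W_k/ΣW_j, and the measured normalized potentiation is
the conductance-weighted sum

    ΔI/ΔImax = a·p1 + b·p2 + c·p3 + d·p4.

Fitting this eight-parameter curve to ordinary dose-response data yields a
binding affinity, per-order cooperativities (convertible to coupling
energies in kcal/mol) and per-state conductances.  The same machinery
predicts heteromeric channels assembled from wild-type and binding-deficient
mutant subunits (e.g. KCNQ2 F137A) by swapping in the ensemble's aggregate
multiplicities — producing the characteristic bi-sigmoid curve that a Hill
fit cannot represent.

Intended users: ion-channel pharmacologists and modellers analysing
steady-state whole-cell concentration-response data.

## Worked example

```python
import numpy as np
import tetrafit as tf

p = tf.ZTZ240_KCNQ2_BEST_FIT            # bundled reference parameter set

print(f"K_D  = {tf.kd(p)*1e6:.2f} uM")
print(f"EC50 = {tf.ec50(p)*1e6:.2f} uM")
e = tf.coefficients_to_energies(p)
print(f"quadruple coupling energy M = {e.m:+.2f} kcal/mol")

# predict the 1:1 WT-F137A heteromeric channel, no refitting
tab = tf.predict_curve(p, tf.PUBLISHED_HETEROMER_DEGENERACIES,
                       10.0**np.array([-8.0, -6.0, -5.0, -4.0]))
print(tab[["log10_conc", "response", "p1", "p4", "avg_occupancy"]]
      .round(4).to_string(index=False))

# refit the bundled wild-type dataset and compare with the Hill baseline
wt = tf.table1_fixture("wt")
fit = tf.fit_thermo(wt, tf.WT_DEGENERACIES, n_starts=50, seed=1)
hill = tf.fit_hill(wt, n_starts=50, seed=1)
print(f"thermo fit: SSE={fit.sse:.3e}  R2={fit.r_square:.4f}")
print(f"hill  fit: SSE={hill.sse:.3e}  R2={hill.r_square:.4f}")
```

prints

```
K_D  = 5.54 uM
EC50 = 9.00 uM
quadruple coupling energy M = -2.47 kcal/mol
 log10_conc  response     p1     p4  avg_occupancy
       -8.0    0.0087 0.0281 0.0000         0.0281
       -6.0    0.2302 0.6779 0.0002         0.8551
       -5.0    0.3586 0.3439 0.1108         1.9553
       -4.0    0.9114 0.0027 0.8821         3.8422
thermo fit: SSE=4.041e-05  R2=0.9999
hill  fit: SSE=7.232e-03  R2=0.9903
```

Reading this: one ztz240 molecule dissociates from a KCNQ2 subunit at
~5.5 µM; four simultaneously bound molecules are stabilized by ~2.5 kcal/mol
of favourable coupling (ν = 65.2, the dominant cooperative effect); at 10 µM
the heteromeric ensemble is mostly singly- or fully-liganded and delivers
36% of its maximal potentiation; and the thermodynamic model fits the
wild-type data two orders of magnitude more tightly (by SSE) than the best
free-amplitude Hill curve.

The probabilities also explain the heteromer's bi-sigmoid curve: the p1
shoulder responds at sub-micromolar ligand while the cooperative p4 state
only takes over above ~10 µM, giving two separated rises in log
concentration (`tf.inflection_count` counts them).

## Command line

```sh
tetrafit fit      --input data.csv --n-starts 50 --seed 1 --out-prefix run
tetrafit hill     --input data.csv --out-prefix run
tetrafit predict  --ensemble heteromer --grid "-9:-3:121" --out-prefix run
tetrafit simulate --noise-sd 0.02 --n-replicates 5 --seed 3 --out-prefix run
tetrafit compare  --seed 1 --out-prefix run
```

Input tables are CSV/TSV with a header; concentrations in a molar
(`concentration_M`) or log10 (`log10_conc`) column, responses normalized
(`response`) or as raw current ratios (`i_over_i0`, normalized on the fly).
Omitting `--input` uses the bundled wild-type dataset.  Every artifact
embeds the tool version, seed and resolved configuration, and identical
invocations reproduce outputs byte for byte.

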