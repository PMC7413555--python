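# viscocurve

Simulation and analysis of displacement-controlled indentation of
linear viscoelastic materials — the force curves measured every day in
AFM and instrumented nanoindentation of cells, tissues and soft
polymers.

Soft biological samples are viscoelastic: the force measured during an
approach–retraction cycle depends on the indentation rate, the probe
shape and the material's relaxation modulus `E(t)`, and routinely gets
misread when fitted with a purely elastic (Hertzian) model.
`viscocurve` predicts those curves exactly within linear
viscoelasticity and extracts the simple, experimentally accessible
features that let you tell relaxation models apart without inverse
fitting.

## The model

For a rigid axisymmetric probe (flat cylinder, sphere or cone) driven
with a prescribed depth history `δ(t)` with a single contact-radius
maximum at `t_m`, the force follows the Lee–Radok hereditary integral
during approach and Ting's extension during retraction:

```
F_appr(t) = C_geom ∫₀ᵗ      E(t−ξ) ∂δⁿ/∂ξ dξ ,          0 ≤ t ≤ t_m
F_retr(t) = C_geom ∫₀^t₁(t) E(t−ξ) ∂δⁿ/∂ξ dξ ,          t > t_m
∫_{t₁(t)}^{t} E(t−ξ) ∂δ/∂ξ dξ = 0                        (defines t₁)
```

with `n = 1, 1.5, 2` and `C_geom = 2R_cyl, (4/3)√R, (2/π)tan α` for
cylinder, sphere and cone. The auxiliary time `t₁(t)` is the approach
instant with the same contact radius as the current retraction
instant; contact is lost (`t_detach`, the indentation time `t_ind`)
when the defining equation loses its root.

The relaxation-modulus catalogue covers the classical spring/dashpot
networks (Kelvin–Voigt, Maxwell, standard linear solid, generalized
Maxwell) and the fractional ones built from springpots
(`E(t) = E_α1 t^−α`), including series combinations whose kernels are
Mittag-Leffler functions. A fast, ~1e-10-accurate Mittag-Leffler
implementation on the negative real axis is included.

From each simulated (or measured) curve three metrics are extracted:

* **apparent Young's modulus** — fixed-exponent Hertz fit of the
  approach segment; tracks the time average of `E(t)` over the first
  quarter of the cycle,
* **curve exponent** — free power-law fit `F = A δᵐ`; drops below the
  Hertzian `n` by up to 1 when relaxation is strong (by `α` for a
  springpot),
* **normalized hysteresis area (NHA)** — dissipated fraction of the
  indentation work, 0 (spring) to 1 (dashpot); approximated by minus
  twice the log-log slope of the time-averaged modulus.

## Worked example

Simulate a standard linear solid (`E0 = 1000 Pa`, `E∞ = 300 Pa`,
`τ_rel = 10 ms`) probed by a 5 µm sphere with a 100 nm triangular ramp
of 0.1 s total cycle time, then analyze the resulting curve:

```
$ viscocurve simulate --model sls --param E0=1000 --param E_inf=300 --param tau=0.01 \
    --probe sphere --dimension 5e-6 --ramp triangular --delta-max 100nm --t-m 0.05 \
    --n-steps 1000 -o sls_curve.tsv
$ viscocurve analyze sls_curve.tsv --probe sphere --dimension 5e-6
metric  value
YM_Pa   5.292930e+02
NHA     0.634492
exponent        1.181865
```

The apparent modulus (529 Pa) sits between the instantaneous and
long-term moduli because the cycle time straddles the relaxation time,
and it is close to the quarter-cycle average of the relaxation
function (`<E>(0.1 s) = 557 Pa`, 5% above the fitted value). The NHA
of 0.63 says most of the indentation work is dissipated, and the
exponent 1.18 has dropped from the spherical Hertz value 1.5 — the
signature a purely elastic analysis would misread as strain-softening.

The same pipeline is available from Python
(`build_model / make_history / make_probe / simulate_curve /
analyze_curve / sweep_indentation_time`), including indentation-time
sweeps that reproduce the characteristic YM/NHA/exponent fingerprints
of each model.

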