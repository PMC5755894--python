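# aedes-capacity

Estimation of the environmental carrying capacity of *Aedes aegypti* from
routine sticky-trap surveillance, using a temperature-driven
stage-structured population model.

Municipal dengue-control programs monitor *Ae. aegypti* with networks of
sticky traps that catch gravid females; the weekly observable is the **IMFA**
(Mean Female *Aedes* Index), females captured per inspected trap.  This
package turns those indices into an estimate of a latent ecological
quantity: the **carrying capacity K**, the maximum egg load an area can
sustain.  It is aimed at entomological-surveillance analysts and
vector-ecology modellers.

## The model

Five compartments — eggs *E*, larvae *L*, pupae *P*, adults *A*, and the
cumulative trapped count — forced by daily mean temperature *T(t)*:

    dE/dt = σ₀ A (1 − E/K) − (σ₁ + μ₁) E
    dL/dt = σ₁ E − (σ₂ + μ₂) L
    dP/dt = σ₂ L − (σ₃ + μ₃) P
    dA/dt = σ₃ P − μ₄ A − c A
    dTrapped/dt = c A,        c = α Tₙ / Hₙ

Oviposition (σ₀) saturates as eggs approach K; the development rates
σ₁ (egg eclosion), σ₂ (pupation) and σ₃ (adult emergence) respond to
temperature through the Sharpe–Schoolfield enzyme-kinetics formula

    σᵢ(T) = ρᵢ (T/298) exp[(aᵢ/R)(1/298 − 1/T)] / (1 + exp[(bᵢ/R)(1/τᵢ − 1/T)])

with *T* in Kelvin and R = 1.987 cal K⁻¹ mol⁻¹.  The capture rate *c*
scales trap attractiveness α (default 0.2/day) by the density of traps per
household.  All biological rates are fixed at literature values
(`src/aedes_capacity/data/thermal_params.yaml`); **K is the only fitted
parameter**, chosen to minimise the mean squared error between the model's
weekly index

    imfa_model(w) = [Trapped(7w) − Trapped(7(w−1))] / Tₙ

at the forcing-driven steady state and the loess-smoothed observed index
(degree 2, span 0.08).

At constant temperature the model has a closed-form equilibrium; the
package exposes it together with the inverse relation
K = Φ_E A\* R₀/(R₀ − 1), which shows K is linear in adult abundance and
conditional on the trapping process — the reason estimates from different
trap densities or attractiveness are not directly comparable.

A synthetic-data generator produces seasonal temperature forcings and
Poisson-noised weekly trap counts with known ground truth, so the whole
pipeline — smoothing, calibration, good/poor-fit classification, the ROC
trap-count threshold, and the census-descriptor screen — is testable end to
end without any external data.

## Worked example

`examples/03_fit_carrying_capacity.py` generates four years of weekly
observations for one area (16 traps, Poisson counting noise) from a known
K = 2500 eggs and recovers it:

```
true K        : 2500 eggs
estimated K   : 2476 eggs (-0.9%)
attained MSE  : 0.0081 (index^2), RMSE 0.090
converged     : True within bounds (10.0, 100000.0)
```

The estimate lands within 1% of the truth; the MSE is in squared index
units (per-trap weekly captures).  The other scripts in `examples/` walk
through the thermal response curves, the seasonal simulation, the
sampling-effort ROC (how many traps an area needs before its fit is
trustworthy), and the descriptor association screen.

A thin CLI wraps the same library calls:

```bash
aedes-capacity simulate --n-areas 20 --seed 1 --out-dir city
aedes-capacity fit-neighborhoods --imfa city/imfa.csv \
    --temperature city/temperature.csv --out-dir results
aedes-capacity roc --fits results/fits.csv
```

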