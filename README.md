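# follisim

A spatio-temporal simulator of hormone signalling in the growing bovine
ovarian follicle, for reproductive biologists and systems-biology modellers
who want a quantitative, literature-parameterised sandbox for
folliculogenesis.

The dominant antral follicle grows from ~5 mm to ~15-20 mm over five days
while follicle-stimulating hormone (FSH) and luteinizing hormone (LH)
delivered through the vascularised theca diffuse inward, bind their
receptors, and — together with estradiol and insulin-like growth factor
(IGF) signalling — shape the expression patterns of those very receptors.
`follisim` models this as eleven coupled reaction–diffusion equations on a
uniformly growing 1D cross-section with theca, granulosa, cumulus–oocyte
complex (COC) and follicular-fluid compartments.

## Model

On the stationary coordinate ξ ∈ [−1, 1] with domain length Λ(t) = Λ(0) + v t,
each species c_i obeys

    ∂c_i/∂t + (v/Λ) c_i = (D_i/ℓ(t)²) ∂²c_i/∂ξ² + R_i(c),   ∂c_i/∂ξ|_{ξ=±1} = 0,

where (v/Λ)c is the dilution from uniform growth and ℓ(t) the physical
length per unit ξ. The species are F, L (gonadotropins), A (androgens),
E (estradiol), free receptors R_f, R_l, R_e, bound complexes C_f, C_l, C_e,
and the lumped IGF-receptor complex I. Regulation enters through Hill
activities σ_i = c_iⁿ/(c_iⁿ + K_iⁿ) of the bound complexes, with combined
gonadotropin activity σ_G = σ_F + σ_L. Blood exchange at rate Δ delivers
F, L and androgen precursors in the theca and removes all soluble hormones
there; aromatase converts A to E in the cellular block at a
Michaelis–Menten rate gated by IGF, estrogen and gonadotropin signalling;
soluble hormones are not degraded in the cell-free fluid. All parameters
ship as literature-derived defaults in internal units (nM, s, mm),
including the 500× membrane-reaction-volume scaling for the gonadotropin
receptors.

## Worked example

```python
from follisim import (FollicleGeometry, default_parameters, run_simulation,
                      fluid_average, compartment_average)

params = default_parameters()
geom = FollicleGeometry(variant="antrum")
result = run_simulation(params, geom)          # 5 days, daily outputs, ~5 s

for label, series in [
    ("androgens (fluid)", fluid_average(result, "A")),
    ("estradiol (fluid)", fluid_average(result, "E")),
    ("estradiol (granulosa)", compartment_average(result, "E", "granulosa")),
]:
    print(label, [round(v, 1) for v in series.values])
```

prints

```
androgens (fluid) [0.0, 80.5, 81.3, 85.3, 87.4, 88.8]
estradiol (fluid) [0.0, 51.6, 65.6, 66.7, 65.1, 62.4]
estradiol (granulosa) [0.0, 151.6, 193.0, 209.8, 221.7, 230.2]
```

Androgens delivered by the theca fill the antral fluid and plateau near
their delivery equilibrium; estradiol, produced by the granulosa from those
androgens, climbs to ~230 nM inside the granulosa layer by day 5 — the
concentration range measured in dominant-follicle fluid — while the fluid
average itself stays lower because the theca's blood exchange continuously
drains estradiol (see `docs/methods.md` for the transport analysis).
Granulosa total LH receptor rises with a multi-day delay
(`follisim.observables.expression_timecourses`), reflecting the slow
build-up of IGF signalling that gates its expression.

Figure-style scenario presets and the parameter-noise robustness bands are
available from the command line:

```bash
follisim run --scenario fig5_steroids --out out/
follisim robustness --scenario fig5_steroids --n-runs 100 --sd 0.2 --seed 1 --out bands.csv
follisim params
```

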