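# dosetrait

Trait-based dose optimization for bioprocess experiments: fit
Gamma-family penalized-spline dose–response curves (GAMs) and extract the
dosage traits that tell you how much of a substrate to feed — and how much
is too much.

The package grew out of mixotrophic-cultivation work on the red microalga
*Porphyridium purpureum*, where organic carbon sources (glucose, sodium
acetate, glycerol) boost both cell biomass and arachidonic-acid (ARA)
production up to a source-specific dosage and depress them beyond it. It
ships those dose–response tables (final-day biomass in g L⁻¹ and fatty-acid
concentrations in mg L⁻¹ at dosages 0–1.0 %, triplicate means ± SD) as
packaged fixtures, and reproduces the published trait values from them.
The same machinery applies to any positive, unimodal-above-baseline
dose–response table.

## Model and traits

For a response *y* at dosage *x* the model is a generalized additive model
with a Gamma observation distribution,

    g(E[y]) = α + s(x),    y ~ Gamma,

with log link *g* (fitted means are guaranteed positive) and a low-rank
penalized regression spline *s* (thin-plate by default, natural cubic as an
alternative). To avoid overfitting on small dose grids the centered smooth
has fewer than five free basis functions (`k = 4`) and the smoothing
parameter λ is chosen by generalized cross-validation,
GCV(λ) = n·D(λ)/(n − 1.4·edf(λ))², in which each effective degree of
freedom is charged a 1.4× inflation. Fitting is penalized IRLS; λ is
selected on a 101-point log grid refined by golden-section search.

From the fitted curve *f* four traits are extracted:

- **p_max** — maximum potential dosage: the stationary maximizer of *f*
  (root of *f*′, analytic from the basis);
- **t_max** — maximum tolerance dosage: the dosage beyond the peak at which
  *f* falls back to the control level *f*(0);
- **μ** — mean safe dosage: μ = ∫₀^{t_max} x f(x) dx / ∫₀^{t_max} f(x) dx
  (the curve acts as an unnormalized density over the tolerated range);
- **σ** — breadth of the mean safe dosage: the corresponding *f*-weighted
  standard deviation of dosage (composite Simpson quadrature).

## Worked example

Fit every packaged table and print traits plus the fitted-versus-measured
comparison:

```sh
$ dosetrait run --out report.json
glucose/biomass: p_max=0.62 t_max=0.95 mu=0.49 sigma=0.26
glycerol/ara_concentration: p_max=0.39 t_max=0.74 mu=0.37 sigma=0.19
glycerol/biomass: p_max=0.39 t_max=0.71 mu=0.36 sigma=0.19
sodium_acetate/ara_concentration: p_max=0.25 t_max=0.57 mu=0.28 sigma=0.15
sodium_acetate/biomass: p_max=0.25 t_max=0.54 mu=0.27 sigma=0.15
```

Reading the glucose row: biomass peaks at a 0.62 % w/v glucose dosage,
stays at or above the unsupplemented control up to 0.95 %, and the safe
dosage is 0.49 ± 0.26 % — a broad tolerance, so glucose dosing is
forgiving. Sodium acetate peaks much lower (0.25 %) with the narrowest
breadth (0.15 %): effective but unforgiving. The comparison table appended
to the output pairs fitted responses with the measured mean at the nearest
tested dosage, e.g. the fitted glucose biomass maximum 15.94 g L⁻¹ against
the measured 15.36 g L⁻¹ at the 0.5 % group.

The same from Python:

```python
from dosetrait import load_paper_fixture, fit_gamma_gam, extract_traits

curve = fit_gamma_gam(load_paper_fixture("glycerol", "ara_concentration"))
traits = extract_traits(curve)
print(traits.rounded())   # {'p_max': 0.39, 't_max': 0.74, 'mu': 0.37, 'sigma': 0.19}
```

Other entry points: `dosetrait fit --input your.csv` for your own tables
(CSV with `dose,response[,sd,n,replicate]` columns, control row at dose 0),
`dosetrait synth` to generate synthetic dose–response data with known true
traits, and `dosetrait traits --curve report.json` to re-print a stored
report.

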