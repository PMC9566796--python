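# swotahp

Quantitative SWOT-AHP strategic analysis for health-policy and other
multi-criteria decision studies.

A SWOT analysis sorts the factors bearing on a development strategy into
internal **S**trengths and **W**eaknesses and external **O**pportunities and
**T**hreats, but by itself says nothing about how much each factor matters.
This package quantifies a SWOT study the way decision analysts do with the
analytic hierarchy process (AHP): an expert panel scores the relative
importance of the factors within each group on the Saaty 1–9 scale, the
resulting pairwise-comparison matrices yield priority weights, and signed
expert intensity scores turn the weights into a geometric strategy
recommendation. It is written for analysts running Delphi/AHP studies who
want the whole chain — matrix validation, consistency testing, strength
synthesis, strategy geometry, sensitivity analysis — reproducible from
plain CSV/YAML inputs.

## The model

For each group, a positive reciprocal judgment matrix $A$ ($a_{ii}=1$,
$a_{ji}=1/a_{ij}$, entries on the Saaty scale) is reduced to weights by the
**sum-product method**: divide each column by its sum, then average each
row,

$$w_i = \frac{1}{n}\sum_{j=1}^{n} \frac{a_{ij}}{\sum_k a_{kj}}.$$

Consistency is diagnosed with $\lambda_{\max} = \frac1n \sum_i (Aw)_i/w_i$,
$CI = (\lambda_{\max}-n)/(n-1)$ and $CR = CI/RI$ (random index $RI$ tabulated
by order $n$); a matrix passes when $CR < 0.1$. Each factor's strength is
its signed intensity times its weight, $S_i = I_i \, w_i$ (intensities are
positive for S/O, negative for W/T), and the group totals
$S', W', O', T'$ place the **strategy quadrilateral** at
$(S',0), (0,O'), (W',0), (0,T')$. Its centroid
$P = \big(\tfrac{S'+W'}4,\ \tfrac{O'+T'}4\big)$ defines the strategic
azimuth $\theta = \operatorname{atan2}(Y, X)$, which selects one of eight
strategy zones (two per quadrant), and the strategic intensity coefficient

$$\rho = \frac{U}{U+V}, \qquad U = O'S', \quad V = T'W',$$

grades how aggressively to pursue it ($\rho \approx 0.5$: maintain the
current intensity of development).

## Worked example

The package bundles a complete published-style study — new media platforms
empowering public-health promotion, with 4 strengths, 3 weaknesses,
4 opportunities and 3 threats scored by a 10-expert Delphi panel:

```bash
swotahp run src/swotahp/data/new_media_health/config.yaml
```

prints (abridged):

```
group  factor  weight   AW       lambda_max  CI      CR      pass
S      S1      0.0672  0.2804  4.23008   0.0767  0.0862  yes
...
W      W1      0.0978  0.2935  3.00198   0.0010  0.0019  yes
...
group  factor  intensity  strength   total
S      S4              6    3.5739  4.8013
...
Strategy
centroid P(X, Y) = (0.21079, -0.04968)
azimuth theta    = -13.261 deg (346.739 deg normalized), quadrant 4
zone             = resistant strategic area / aggressive type
U = 22.1961, V = 19.0847, rho = 0.53769 -> maintain
```

Reading: every comparison matrix passes the CR < 0.1 consistency test; the
dominant strength is algorithmic user profiling (weight 0.5956 of the S
group) and the dominant threat is audiences substituting media content for
hospitals. The centroid lies in the fourth quadrant — strengths and threats
are both large — so the recommended posture is the *resistant* area's
aggressive type: lean on the strengths while containing the threats, and,
with ρ ≈ 0.54 near the middle of its range, keep the current intensity of
development rather than escalating or retrenching.

The same study is available programmatically:

```python
from swotahp import load_example_study, run_pipeline
report = run_pipeline(load_example_study())
report.strategy.theta_deg   # -13.261...
report.strategy.rho         # 0.5377...
```

Monte-Carlo sensitivity analysis of the strategy outputs under judgment
noise is exposed as `swotahp simulate` / `simulate_strategy_distribution`:
expert matrices are regenerated from latent weights with multiplicative
log-normal noise, replicates failing the consistency test are rejected and
counted, and the θ/ρ/zone distributions summarize how robust the
recommendation is to panel disagreement.

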