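# soilpah

Source apportionment and probabilistic cancer-risk assessment of polycyclic
aromatic hydrocarbons (PAHs) in surface soils, built around the compiled
record of 41 soil surveys from the Beijing–Tianjin region.

## What it does, and for whom

Environmental-health analysts who compile soil PAH measurements face three
linked questions: *how contaminated* is the soil (classification of totals),
*where did the PAHs come from* (receptor modelling), and *how much cancer
risk* does the mixture pose (exposure modelling). This package implements
that chain end to end:

1. **Study table** — a bundled compilation of 41 published surveys (11 urban,
   11 suburban, 19 rural): total concentration of the 16 US-EPA priority
   PAHs, BaP-equivalent toxicity, and a four-level contamination class
   (&lt;200 / 200–600 / 600–1000 / &gt;1000 ng g⁻¹).
2. **Diagnostic ratios** — isomer ratios BaA/(BaA+Chr), Flt/(Flt+Pyr),
   Ant/(Ant+Phe) with conventional petrogenic/combustion thresholds.
3. **PCA–MLR** — eigenvalue&gt;1 retention, varimax rotation, and regression
   of standardized totals on component scores to apportion total PAHs.
4. **PMF** — uncertainty-weighted positive matrix factorization
   `X = G·F + E` minimizing `Q = Σ (e_ij/u_ij)²` with the equation-based
   uncertainty `u_ij = 5/6·MDL` below the detection limit and
   `√((EF·x_ij)² + MDL²)` above it, factor-count scan 3–8, and marker-based
   source labelling (vehicular emission, coal combustion, biomass
   combustion, petrogenic).
5. **TEQ apportionment** — BaP-equivalents `BaP_TEQ = Σ TEF_i·C_i`
   attributed to sources through `(PAH_i)_kp = S_kp·f_ip`, so each source's
   share of carcinogenic potency (not just mass) is quantified.
6. **ILCR** — three-pathway incremental lifetime cancer risk (ingestion,
   dermal, inhalation) with USEPA adult exposure constants, plus
   probabilistic risk: maximum-likelihood fits of candidate distributions
   (log-normal, gamma, Pareto, normal, Weibull; Anderson–Darling selection)
   propagated through 10⁴ Monte Carlo draws, reporting the 95th percentile.

Per-compound concentration matrices underlying published receptor-model
studies are rarely deposited, so the factorization stages are exercised on
synthetic mixtures with known ground truth (see `soilpah.synthetic`); the
classification and risk stages run directly on the bundled study table.

## Worked example

Classify the bundled study table and assess risk:

```
$ soilpah classify
{
  "urban":    {"n": 11, "bapeq_mean": 121.6, "total_min": 360.0, "total_max": 1989.0, "contaminated_or_worse": 7},
  "suburban": {"n": 11, "bapeq_mean": 78.2,  "total_min": 142.0, "total_max": 1490.0, "contaminated_or_worse": 7},
  "rural":    {"n": 19, "bapeq_mean": 48.6,  "total_min": 175.7, "total_max": 1295.8, "contaminated_or_worse": 6}
}
```

Urban soils average 121.6 ng g⁻¹ BaP-equivalents and 7 of 11 urban studies
fall in the contaminated-or-worse classes. The full synthetic chain
(simulate → PMF → TEQ → risk) is driven by the numbered scripts under
`analysis/`; running `python analysis/05_pmf.py` after `02_simulate.py`
prints:

```
recommended factor count: 4

fit: Q = 574.1, pooled r^2 = 0.9846
factor                  share %   true %   cosine
biomass_combustion         14.8     14.3    0.999
coal_combustion            13.8     11.6    0.992
vehicular_emission         67.3     70.7    1.000
petrogenic                  4.1      3.4    0.985
```

i.e. the factor scan selects the true number of sources, and the recovered
profiles (cosine similarity ≥ 0.985 to the generating profiles) and mass
shares (within ~3 points) match the known truth. `analysis/07_risk.py` then
reports the probabilistic risk from the compiled BaP-equivalents:

```
urban: best fit lognormal, 95th-percentile ILCR = 1.42e-06 (low risk)
```

The 95th-percentile incremental lifetime cancer risk for adults exposed to
urban soils sits between 10⁻⁶ and 10⁻⁴ — the low-risk band.

The same stages are available as CLI subcommands (`soilpah simulate`,
`ratios`, `pca`, `pmf`, `teq`, `risk`, `all`) or via
`soilpah.pipeline.run_pipeline` with a YAML config.

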