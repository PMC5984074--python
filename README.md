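# pedigrowth

Pedigree quantitative genetics of growth and obesity in captive primate
colonies.

Longitudinal colonies — hundreds of related monkeys weighed and measured for
decades — are one of the few settings where the ontogeny of obesity can be
separated into growth patterns, genetic predisposition and dietary exposure.
`pedigrowth` implements the full analytic chain for such data:

1. **Phenotypes** — BMI from matched weight/crown-rump length, waist-based
   obesity (upper 20th percentile or a fixed 40.5 cm cut-off), chronic
   obesity (≥3 consecutive obese measures, pregnant visits excluded), adult
   trait averaging from age 5, diet-exposure cohorts (gestation / PN1 / PN2 /
   adult) from a 165-day gestation window against a diet-era timeline, and
   rank-based inverse-normal + age-adjustment pre-transforms.
2. **Obesogenic-growth clusters** — KmL-style k-means on body-weight
   trajectories (age-binned, missing values imputed), stratified by sex, with
   the number of clusters chosen by the Calinski–Harabasz criterion
   CH = [B/(k−1)]/[W/(n−k)].
3. **Growth curves** — nonlinear mixed-effects fits of the three-parameter
   logistic S(t) = θ₁/(1+exp(−(θ₂+θ₃t))) (asymptote θ₁, rate θ₃, midpoint
   −θ₂/θ₃) per sex × cluster, with subject random effects on all three
   parameters (Laplace-approximated ML) and per-animal parameter extraction.
4. **Heritability** — maximum-likelihood variance decomposition on the
   pedigree, Ω = 2Φσ²_g + Hσ²_c + Iσ²_e, giving h² and the maternal
   household share c² with boundary likelihood-ratio tests and backward
   covariate screening; a probit liability-threshold model handles binary
   chronic obesity.
5. **Linkage** — variance-components scans on a 1-cM IBD grid
   (Ω += Πσ²_q), LOD = (lnL_alt − lnL_null)/ln 10, suggestive/significant
   classification at 1.9/3.3, genetic-map interpolation, oracle IBD from
   gene-dropping or a marker-based approximation, and Monte-Carlo power
   analysis.
6. **Synthetic colony generator** — matrilineal demography with male
   removal, harem breeding, a 2000–2015 measurement calendar, planted
   heavy/light growth structure, and polygenic + QTL + household trait
   architectures, so every stage is testable against known truth.

The statistical core follows a Model/Results design: `PolygenicModel(...)`,
`LiabilityThresholdModel(...)`, `LogisticGrowthME(...)`,
`TrajectoryKMeans(...)` each return a results object with estimates,
uncertainties, diagnostics and `summary()`.

## Worked example

```python
import numpy as np
from pedigrowth import (SimConfig, simulate_pedigree, kinship_matrix,
                        PolygenicModel, inverse_normal_transform,
                        simulate_growth_measurements)
from pedigrowth.simulate import adult_phenotyped_ids, simulate_trait
from pedigrowth.trajectories import TrajectoryKMeans

cfg = SimConfig(seed=42)
ped = simulate_pedigree(cfg)
ids = adult_phenotyped_ids(ped, cfg)
print(f"colony: {len(ped)} animals, {len(ids)} adult-phenotyped")

order, phi_full = kinship_matrix(ped)
pos = {v: k for k, v in enumerate(order)}
phi = phi_full[np.ix_([pos[i] for i in ids], [pos[i] for i in ids])]

y, _ = simulate_trait(ped, SimConfig(seed=0, h2=0.65),
                      cfg.streams()["phenotypes"], ids=ids, phi=(order, phi_full))
X = np.column_stack([np.ones(len(ids)),
                     [1.0 if ped[i].sex == "M" else 0.0 for i in ids]])
fit = PolygenicModel(inverse_normal_transform(y), X, phi=phi).fit()
print(f"planted h2 = 0.65 -> estimated h2 = {fit.h2:.3f} (SE {fit.se_h2:.3f})")

meas, _ = simulate_growth_measurements(ped, cfg, cfg.streams()["schedule"])
meas["sex"] = meas["id"].map({i.id: i.sex for i in ped.individuals})
first = meas.groupby("id")["age"].min(); last = meas.groupby("id")["age"].max()
young = first[first <= 2].index.intersection(last[last >= 4].index)
res = TrajectoryKMeans(meas[(meas["sex"] == "F") & meas["id"].isin(young)]).fit(seed=42)
print(res.summary())
```

prints

```
colony: 922 animals, 605 adult-phenotyped
planted h2 = 0.65 -> estimated h2 = 0.687 (SE 0.068)
Trajectory k-means: selected k=2 (CH=414.3)
  CH profile: k=2: 414.3  k=3: 272.0  k=4: 217.9  k=5: 188.3  k=6: 166.9
  cluster sizes (1=heavy): {1: 84, 2: 102}
```

A trait planted with narrow-sense heritability 0.65 on the simulated colony
is recovered at ĥ² = 0.69 ± 0.07, and the Calinski–Harabasz criterion picks
exactly two female growth clusters — the planted heavy/light dichotomy —
with the heavy cluster labelled 1.

A configuration-driven pipeline wraps the same stages
(`pedigrowth all --config cfg.yaml --seed 1 --outdir out/`), writing
cohort, heritability and linkage-peak reports as TSV, a Manhattan-style scan
plot, and a manifest with the config hash and seed; identical configs give
byte-identical reports.

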