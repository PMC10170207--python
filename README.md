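# gencontrib

Expected individual genetic contributions (IGC) from genealogical
pedigrees, their long-run stabilization, and how well classical fitness
proxies predict them.

`gencontrib` is aimed at evolutionary biologists and human-demography
researchers working with linked genealogies (church registers, studbooks,
long-term pedigree studies).  Given a table of individuals with parent
links, sexes, birth/death years and birth/marriage places for two (or more)
local populations, it:

1. validates the pedigree and classifies individuals as residents,
   immigrants, emigrants or inter-parish movers;
2. reconstructs, per parish and calendar year, the set of individuals
   forming the local gene pool;
3. computes each focal individual's **expected genetic contribution**: with
   the focal's parents severed, the additive-relationship coefficient to
   every descendant (offspring 0.5, grandchild via one child 0.25, ...)
   summed over the individuals present in a year and divided by the pool
   size — a proportion of the year's gene pool;
4. detects when 10-year birth cohorts' IGC **stabilize** (Pearson
   correlation with final-year IGC ≥ 0.95 throughout the final two
   generations);
5. computes four fitness proxies — lifespan, lifetime reproductive success
   (LRS), LRS counting only adult-surviving offspring (LRS_SA, adulthood =
   sex-specific 5th percentile of age at first reproduction), and the
   number of grandoffspring — with eligibility flags, lineage-fate and
   extinction-stage accounting;
6. fits hierarchical **zero-inflated beta** regressions of stabilized IGC
   on each proxy, and a beta regression of mean offspring IGC on LRS (the
   bias test), by Hamiltonian Monte Carlo; reports posterior medians, 95%
   credible intervals, Bayesian R², pairwise ΔR², and the probability of
   direction (pd).

The model for an IGC value $y_i \in [0,1)$ is

$$y_i = 0 \text{ w.p. } \pi_i, \qquad y_i \sim \mathrm{Beta}(\mu_i\phi,\ (1-\mu_i)\phi) \text{ w.p. } 1-\pi_i,$$

with $\operatorname{logit}(\pi_i)$ and $\operatorname{logit}(\mu_i)$ linear
in the proxy (raw scale), parish and sex, plus a random intercept and random
proxy slope per parish-specific 10-year birth cohort.  Bayesian
$R^2 = \operatorname{Var}_i(\hat y_i) / (\operatorname{Var}_i(\hat y_i) + \overline{\sigma^2_{\mathrm{res},i}})$
per posterior draw, with $\hat y_i = (1-\pi_i)\mu_i$ and the zero/beta
mixture residual variance.

A fully-tested synthetic-data module simulates a two-parish pre-industrial
population (high childhood mortality, marriage-linked migration, remarriage)
and provides the gene-dropping Monte-Carlo oracle used to validate the
expectation computation.

## Worked example

Expected contributions on a toy family (two founders, two children who
marry each other, one outbred grandchild):

```python
from gencontrib import PedigreeTable, IndividualRecord as R, expected_contribution_vector

ped = PedigreeTable([
    R("f", sex="M"), R("m", sex="F"),
    R("c1", sire_id="f", dam_id="m"), R("c2", sire_id="f", dam_id="m"),
    R("g",  sire_id="c1", dam_id="c2"),   # both parents are f's children
    R("x",  sex="F"), R("g2", sire_id="c1", dam_id="x"),
])
v = expected_contribution_vector(ped, "f")
print(v["c1"], v["g2"], v["g"])   # 0.5 0.25 0.5
```

The full pipeline on the bundled synthetic two-parish population:

```bash
gencontrib run --seed 1 --out-dir runs/demo --fast
```

prints (abridged) from `report.json`:

```
cutoffs            ParishA: 1750   ParishB: 1710
n_model            3022
pct extinct        82.4
R² (median)        lifespan 0.108   lrs 0.351   lrs_sa 0.483
                   grandoffspring 0.620   null 0.034
ΔR² (mode)         grandoffspring − lifespan = 0.516
slopes             lrs 0.070 (pd 1.00)   grandoffspring 0.050 (pd 1.00)
bias slope         0.117 (pd 1.00)
```

Reading: 3022 individuals born before the detected stabilization cutoffs
carry stabilized IGC; 82% of their lineages are extinct in the final-year
gene pool.  The number of grandoffspring explains the most variation in
IGC (R² ≈ 0.62), followed by LRS_SA and LRS, with lifespan far behind and
the proxy-free null model explaining almost nothing — and the slight
positive slope of mean offspring IGC on LRS shows LRS is a nearly unbiased
(here slightly under-estimating) predictor.  Run artifacts (per-stage CSV/
JSON plus a manifest with config, seed and hashes) land in `runs/demo/`.

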