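# paleodiv

Occurrence-based diversity analysis for fossil compilations: replicate
rarefaction of occurrence records to a shared quota, and incidence-based
beta-diversity partitioning into turnover and nestedness.

The package targets the kind of question quantitative paleobiologists ask of
regional fossil compilations — *how did taxonomic diversity change across a
major environmental perturbation?* — where the record is a table of
occurrences (a taxon found at a locality within a time interval), sampling
effort is wildly uneven between intervals, regions and organism groups, and
raw richness counts are therefore incomparable. The built-in vocabulary
follows the Mediterranean Late Miocene–Early Pliocene setting (Tortonian /
pre-evaporitic Messinian / Zanclean intervals bracketing the Messinian
salinity crisis; Western Mediterranean, Eastern Mediterranean and Po
Plain–Northern Adriatic regions; 13 organism groups from calcareous
nannoplankton to marine mammals), but every stage is a general tool.

## The statistics at the core

**Rarefaction.** For strata being compared, with occurrence counts
$N_1, \dots, N_k$, all strata are repeatedly subsampled without replacement
to the shared quota $q = \lfloor 0.8 \cdot \min_i N_i \rfloor$ (10,000
replicates by default), and richness $S$ is summarised per stratum by the
replicate median, quartiles and Tukey whiskers. The engine is validated
against the exact hypergeometric expectation
$\mathbb{E}[S] = \sum_i \left[ 1 - \binom{N-n_i}{q} / \binom{N}{q} \right]$.

**Beta partition.** For assemblages $A$ and $B$ with $a = |A \cap B|$,
$b = |A \setminus B|$, $c = |B \setminus A|$:

$$\beta_{sor} = \frac{b+c}{2a+b+c}, \qquad
  \beta_{sim} = \frac{\min(b,c)}{a+\min(b,c)}, \qquad
  \beta_{nes} = \beta_{sor} - \beta_{sim}$$

— total dissimilarity (Sørensen), its richness-independent turnover
component (Simpson), and the nestedness-resultant remainder. The identity
$\beta_{sor} = \beta_{sim} + \beta_{nes}$ holds exactly; the rarefied form
applies the partition per replicate and reports per-index medians.

**Inference.** One-tailed Wilcoxon rank-sum and signed-rank tests compare
the replicate richness lists of two strata (exact enumeration in the
small-sample tie-free regime, normal approximation with tie and continuity
corrections otherwise). Every result carries an explicit caveat: replicates
are pseudo-replicates of one dataset, so these p-values quantify resampling
noise, not independent evidence.

**Synthetic scenarios.** `paleodiv.synthetic` generates occurrence datasets
with exact ground truth: interval taxon pools evolve by programmed turnover
(taxa replaced by novel ones) and nested loss (taxa lost outright), then
occurrences are drawn with uniform or geometric-series abundances across
regions and localities, with a reworked fraction. True richness and true
pairwise $(\beta_{sor}, \beta_{sim}, \beta_{nes})$ are stored beside the
data, so every pipeline stage can be tested against known answers.

## Worked example

```python
import paleodiv as pv
from paleodiv.synthetic import ScenarioSpec, GroupScenario

spec = ScenarioSpec(
    groups=(GroupScenario("ostracods", 120, 2500),
            GroupScenario("bivalves", 150, 2000)),
    turnover_frac=0.35, nested_loss_frac=0.10,
    abundance_model="uniform", localities=150, reworked_frac=0.05, seed=42,
)
model = pv.DiversityAnalysis.from_scenario(spec, replicates=1000)
res = model.fit(seed=0)
print(res.richness_[["group", "interval", "n_occurrences", "quota",
                     "median", "pct_vs_tortonian"]])
print(res.beta_[["group", "pair", "beta_sor", "beta_sim", "beta_nes"]])
```

prints (abridged):

```
    group                 interval  n_occurrences  quota  median  pct_vs_tortonian
ostracods                tortonian           2222   1757   120.0               NaN
ostracods messinian_pre_evaporitic           2239   1757   108.0             -10.0
ostracods                 zanclean           2197   1757    97.0             -19.2
 bivalves                tortonian           1814   1430   150.0               NaN
 bivalves messinian_pre_evaporitic           1812   1430   134.0             -10.7
 bivalves                 zanclean           1788   1430   121.0             -19.3

    group pair  beta_sor  beta_sim  beta_nes
ostracods  T–M     0.421     0.389     0.032
ostracods  M–Z     0.424     0.392     0.033
ostracods  T–Z     0.677     0.639     0.038
```

Each scenario programs ~10% pure loss plus 35% replacement per interval
step: the rarefied medians recover the programmed decline (−10% per step)
and the beta partition matches the generator's exact truth (for ostracods,
true T–M $\beta_{sor} = 0.4211$, $\beta_{sim} = 0.3889$,
$\beta_{nes} = 0.0322$) to the third decimal. `res.summary()` renders all
tables; `res.to_output_dir("out/")` writes them with a provenance manifest;
`res.plot_richness()` / `res.plot_beta()` draw the box-statistics and
dissimilarity panels.

## Command line

```bash
paleodiv simulate --out sim --seed 3            # synthetic dataset + truth
paleodiv validate sim/occurrences.csv           # schema/vocabulary check
paleodiv all sim/occurrences.csv --out run --seed 5 --replicates 10000
```

Exit codes: 0 success, 1 validation error, 2 run finished but no comparison
was evaluable (a stratum must hold ≥ 15 occurrences to enter a comparison).

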