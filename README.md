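# refstab

Reference-gene stability analysis for RT-qPCR cycle-threshold (Ct) data.

Quantifying a gene's expression by RT-qPCR requires normalizing against one
or more *reference genes* assumed to be stably expressed across the
experimental conditions. That assumption fails often enough — a "housekeeping"
gene stable across developmental stages may be strongly dysregulated by an
insecticide treatment — that candidate reference genes must be screened per
experiment. `refstab` implements the standard screening workflow used in
entomology and molecular-biology labs:

- **Delta-Ct**: mean SD of pairwise Ct differences between each candidate and
  every other candidate (cycles; lower = more stable).
- **geNorm**: the M value — mean SD of log₂ expression ratios against all
  other candidates — with iterative worst-gene exclusion and the pairwise
  variation curve V_n/V_{n+1} that decides how many reference genes are
  enough (V < 0.15 ⇒ adding a gene is unnecessary).
- **NormFinder**: model-based decomposition of log-quantities into sample,
  gene, and (optionally) experimental-group effects; stability is the
  estimated gene-specific variation plus shrunken intergroup bias.
- **BestKeeper**: descriptive screen on raw Ct — SD, percent CV, and Pearson
  correlation with the per-sample geometric-mean index.
- **Consensus**: RefFinder-style geometric mean of the four per-method ranks,
  plus selection of the optimal reference-gene number (geNorm V-curve) and
  identity (consensus head).
- **Validation**: multi-reference 2^−ΔΔCt relative quantification of a target
  gene, with pooled Student's *t* or one-way ANOVA + Tukey HSD and compact
  letter displays.
- **Standard curves**: Ct vs log₁₀(dilution) regression and the efficiency
  formula E = (10^(−1/slope) − 1) × 100.
- **Synthetic data**: a seeded generator producing Ct datasets with a known
  ground-truth stability structure (per-gene condition effects, per-sample
  loading offsets, per-well technical noise), so the whole pipeline is
  testable end to end without instrument data.

## Worked example

Simulate a 15-candidate screen (six treatment groups, 3 biological × 3
technical replicates) and run the full analysis:

```sh
refstab simulate --seed 7 --out sim_ct.csv --truth truth.json
refstab report --input sim_ct.csv --out report/
```

`report/consensus.tsv` begins:

```
gene        rank_delta_ct  rank_genorm  rank_normfinder  rank_bestkeeper  geomean  final_rank
beta-actin  2              1            2                1                1.41421  1
EF1a        1              3            1                4                1.86121  2
EF2         4              2            5                2                2.9907   3
```

and `report/recommendation.json` reads:

```json
{
  "single_best": "beta-actin",
  "optimal_n": 2,
  "combination": ["beta-actin", "EF1a"],
  "v_used": 0.08146659679589231,
  "fallback": false
}
```

The geomean column is the geometric mean of the four method ranks (lower =
more stable). Here V₂ = 0.081 < 0.15, so two reference genes suffice, and the
two top consensus genes are recommended. The generator's ground truth
(`truth.json`) assigns condition-effect SDs rising from 0.0 to 1.4 cycles
across the candidates; the consensus head (`beta-actin`, `EF1a`, `EF2`, ...)
recovers that planted ordering.

The same steps are available as library calls
(`refstab.simulate_ct`, `refstab.run_all_methods`, `refstab.reffinder_geomean`,
`refstab.select_optimal`), and `refstab express` computes 2^−ΔΔCt fold
changes of a target gene for chosen reference genes and a calibrator group.

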