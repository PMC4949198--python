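# wqagree

Inter-observer reliability and agreement analysis for the Welfare
Quality® assessment protocol for growing pigs.

On-farm welfare assessment only works if two trained observers scoring
the same animals at the same time — but independently — reach the same
farm-level conclusions. `wqagree` is for animal-welfare scientists and
assessment-scheme auditors who need to quantify that: it scores raw
protocol records into farm-level measures and evaluates each measure with
four complementary reliability/agreement statistics.

## What it computes

**Protocol scoring** turns one observer's visit record into farm-level
measures:

- **QBA score** — 20 expressive adjectives each marked on a 0–125 mm
  visual analogue scale, combined as a weighted sum
  `score = c + Σₖ wₖ·Nₖ` (intercept `c = −4.5367`; the weights `wₖ` come
  from the protocol document and are always supplied by configuration).
- **Behaviour fractions** — instantaneous scan sampling sorts pigs into
  positive social, negative social, pen investigation, enrichment use,
  other active, or resting; each fraction is expressed relative to total
  *active* (non-resting) behaviour, with positive+negative pooled as
  "social behaviour".
- **Individual-parameter prevalences** — per-animal clinical scores on
  0/2 or 0/1/2 scales (bursitis, wounds, tail biting, …) summarised as
  the fraction of assessed animals per score category; coughs and sneezes
  as counts per pig.

**Agreement engine** — each measure's paired farm-level values (observer
A vs. the pooled partner column BC) form a complete n×2 table analysed
with:

- **RS** — Spearman rank correlation (midranks for ties);
- **ICC** — intraclass correlation, agreement form, from the two-way
  ANOVA variance components of `x_ij = μ + αᵢ + βⱼ + εᵢⱼ`:
  `ICC = σ²_obj / (σ²_obj + σ²_observers + σ²_residual)`;
- **SDC** — smallest detectable change,
  `1.96·√2·√(σ²_observers + σ²_residual)`;
- **LoA** — Bland–Altman 95 % limits of agreement,
  `mean(d) ± 1.96·sd(d)` with `d = A − BC`.

Labels follow the conventional cut-offs: RS/ICC ≥ 0.4 acceptable,
≥ 0.7 good; SDC ≤ 0.1 and LoA within [−0.1, 0.1] acceptable on the
fraction scale. Score categories whose mean prevalence is ≤ 0.5 % are
excluded as too rare for a meaningful reliability estimate.

Because real paired-visit field datasets are rarely shareable, the
package ships a synthetic-data generator that mirrors a realistic study
design (29 paired visits on 24 farms, split 19/10 over two observer
pairs) with known ground-truth variance components, so every statistic is
testable by parameter recovery.

## Worked example

```python
import wqagree as wq

protocol = wq.default_protocol()          # built-in scales, synthetic QBA weights
config = wq.SimulationConfig(seed=3)      # 29 paired visits, default noise
assessments, pairs = wq.simulate_dataset(config, protocol.parameters)
tables = wq.build_measure_tables(assessments, pairs,
                                 protocol.qba, protocol.parameters)
kept, excluded = wq.filter_rare_measures(tables)
print(f"{len(tables)} measures, {len(kept)} kept, {len(excluded)} excluded as rare")
for mid in ("qba:score", "bo:social behaviour", "ip:bursitis:0"):
    r = wq.evaluate_measure(next(t for t in kept if t.measure_id == mid))
    print(f"{mid}: RS={r.rs:.2f} ICC={r.icc:.2f} SDC={r.sdc:.3f} "
          f"LoA=({r.loa_lower:.3f}, {r.loa_upper:.3f}) -> {r.labels}")
```

prints

```
64 measures, 62 kept, 2 excluded as rare
qba:score: RS=0.79 ICC=0.76 SDC=1.156 LoA=(-1.296, 0.959) -> {'rs': 'good', 'icc': 'good', 'sdc': 'acceptable', 'loa': 'acceptable'}
bo:social behaviour: RS=0.81 ICC=0.83 SDC=0.040 LoA=(-0.040, 0.041) -> {'rs': 'good', 'icc': 'good', 'sdc': 'acceptable', 'loa': 'acceptable'}
ip:bursitis:0: RS=0.94 ICC=0.93 SDC=0.073 LoA=(-0.072, 0.073) -> {'rs': 'good', 'icc': 'good', 'sdc': 'acceptable', 'loa': 'acceptable'}
```

Reading the social-behaviour row: the observers rank farms almost
identically (RS 0.81), 83 % of the total variance is genuine between-farm
variation (ICC 0.83), a change of 4 percentage points in the
social-behaviour fraction is distinguishable from measurement error
(SDC 0.040), and 95 % of between-observer differences fall within ±4
percentage points (LoA) — good reliability and acceptable agreement.
The QBA score's SDC of 1.156 score units is ≈4.8 % of the theoretical
score range, hence acceptable after normalisation.

The same analysis runs from the shell on CSV files:

```sh
wqagree simulate --seed 3 --out data/
wqagree validate data/ --config data/protocol.yaml
wqagree compare data/ --config data/protocol.yaml --out report/
```

`report/report.csv` is the rounded display table (one row per measure
with RS, ICC, SDC, LoA and labels); `report_full.csv` keeps full
precision, `excluded.csv` lists rare categories with reasons, and
`bland_altman.csv` exports (average, difference) points for plotting.

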