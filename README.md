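# lulctrends

Annual land-use/land-cover mapping from 16-day composite vegetation-index
time series, with decade-scale change-trend analysis — exercised end-to-end
on synthetic scenes with known ground truth.

The pipeline has six stages, one module each:

| Module | What it does |
| --- | --- |
| `lulctrends.scene` | Synthetic landscapes (nearest-seed municipality tessellation), true cover trajectories with prescribed linear trends, composite cubes (EVI/red/NIR/MIR + reliability flags) from class phenology curves, and paired-interpreter reference samples with a minimum-spacing constraint. |
| `lulctrends.samples` | Consensus labeling of two interpreters' percent-cover estimates (average on majority/year agreement, expert resolution otherwise), the ≥80% / 20–80%-woody class-assignment rules, and the eight→five class grouping. |
| `lulctrends.features` | 120 temporal statistics per pixel-year (mean, sd, min, max, range × 4 bands × six calendar windows) with reliability filtering, the ≥3-composite window-validity rule, and the full / annual-only / none feature tiers. |
| `lulctrends.classifier` | Per-biome random-forest pairs (1999 trees, node size 5, √p), proximity-based outlier removal, tiered pixel routing with No-Data rules, five-class annual maps, and out-of-bag confusion-matrix accuracy reports. |
| `lulctrends.trends` | Per-municipality class areas, the >1% No-Data year-exclusion rule, OLS area-vs-year regressions with Pearson R and exact-t p-values, and regression-based net change. |
| `lulctrends.aggregate` | Country/biome/ecoregion/municipality rollups, gain/loss partitions, top-k hotspot tables with national shares, percent change, and the rank-sum gainer/loser size comparison. |

## CLI

```sh
lulctrends simulate --rows 60 --cols 60 --municipalities 12 --seed 1 \
    --cloud-rate 0.05 --out-dir scene/           # scene + cube + samples
lulctrends classify --cube-dir scene/cube --samples scene/samples.csv \
    --partition scene/ --out-dir maps/           # train + annual maps
lulctrends trends --maps-dir maps/ --partition scene/ --out trends.csv
lulctrends report --trends trends.csv --partition scene/
```

`simulate` also accepts a `--config key=value` file. Rasters are plain
multi-band TIFFs (band order EVI₁..₂₃, red₁..₂₃, NIR₁..₂₃, MIR₁..₂₃,
reliability₁..₂₃ for cubes; single-band integer for partitions and maps,
where 0 = No Data, 1 = woody, 2 = mixed woody/plant, 3 = ag/herb,
4 = bare/built, 5 = water).

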