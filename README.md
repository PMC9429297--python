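# carenet

Annual social-network analysis of per-patient message-board networks of
healthcare professionals.

In an SNS-based information-sharing system, each patient has a group in
which professionals post messages and mark them as viewed. `carenet` turns
the resulting logs into one unweighted directed graph per patient group per
year (a link u→v means v viewed a message posted by u), computes ten
structural measures per analyzable network (≥10 nodes by default), and
tests year-to-year differences per care-requirement band (long-term-care
levels 1–3 = LIGHT, 4–5 = HEAVY) with the Steel–Dwass all-pairs
nonparametric procedure. Because no real logs are available, a synthetic
log generator with configurable structural targets (density, reciprocity,
hub-induced disassortativity, demographics) stands in for them.

## Modules

| module | contents |
|---|---|
| `carenet.io_model` | domain types; event-log (CSV/JSONL), metadata, network and results-table readers/writers |
| `carenet.netbuild` | log events → per-group-year directed networks; analyzable-network filter |
| `carenet.metrics`  | the ten measures from first principles (BFS distances, Brandes betweenness, triangle census, endpoint-degree Pearson, Freeman centralization); every convention is a `MetricConfig` knob |
| `carenet.steel_dwass` | tie-corrected pairwise rank statistics, from-scratch studentized-range survival function (Gauss–Legendre quadrature), all-pairs test, permutation oracle |
| `carenet.synth` | synthetic cohort generator (groups, rosters, POST/VIEW_MARK events) |
| `carenet.cli` | end-to-end pipeline with run log and conservation checks |

## CLI

```sh
# generate a synthetic cohort (CSV event log + metadata)
carenet synth --out cohort/ --seed 1 --preset paper2018

# full pipeline: networks, metrics, summary/demographic tables, comparisons
carenet run --events cohort/events.csv --groups cohort/groups.csv \
            --professionals cohort/professionals.csv --out results/

# one-step paper-scale demo (synth + run)
carenet demo --out demo/ --seed 1
```

Stage-by-stage subcommands `build`, `measure`, `compare` are also
available; `carenet <cmd> --help` lists the options (filter threshold,
significance level, centrality aggregation mode, YAML config file,
`--both-aggregations` to emit Freeman-centralization and mean-normalized
centrality tables side by side).

Outputs: `metrics.csv` (one row per network), `summary.csv` (mean(SD) per
metric per year×band), `demographics.csv`, `comparisons.csv` (Steel–Dwass
statistic, p, and verdict per metric/stratum/year pair), network dumps
(`.net` plain-text node+link lists; GraphML via `carenet.io_model.write_graphml`),
and `run_log.json` with the counts at every stage.

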