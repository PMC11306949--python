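# aagraph

Attribute association graphs for case/control cohort exploration.

Given a participant-by-variable table, variable metadata, and a declarative
cohort definition, `aagraph` splits participants into a disease and a control
group, discretizes metric variables into low/normal/high bands around a
data-driven reference range (mean ± 1 sample SD, optionally overridden with
clinical intervals), and derives one binary attribute per category value or
band. Every attribute becomes a graph node carrying per-group counts,
missing-value-adjusted shares, and two comparison scores: the absolute share
difference δ and the share quotient γ. Directed edges carry conditional
co-occurrence statistics: the relative conditional share q (fraction of
source-attribute members also holding the target attribute) and its signed
difference δ′ and quotient γ′ against the target's unconditional share.

Nodes receive a frequency label (`highly_frequent` / `frequent` /
`infrequent` at p ≥ 0.5 / ≥ 0.1) and a distinction label
(`highly_related`/`highly_inverse` at δ ≥ 0.2 or γ ≥ 2.0,
`related`/`inverse` at δ ≥ 0.1 or γ ≥ 1.5, else `unrelated`); edges get a
conditional-difference type with the same cut points on δ′/γ′. The graph can
be pruned with configurable rules and exported to property-graph bulk-import
CSVs plus a Cypher load script, GraphML, and JSON, with a `style.json`
carrying the color/size/width encoding. Companion outputs: dashboard-ready
binned distributions with small-bin summarization, normalized group
averages, conditional bin averages, and Pearson correlations with one-tailed
95% Fisher-transform confidence bounds.

A synthetic cohort generator with analytically known ground truth
(group-dependent category probabilities, per-group normal metrics, MCAR
missingness, planted conditional dependencies) makes the full pipeline
testable without any external data.

## CLI

The `aag` entry point (equivalently `python -m aagraph.cli`) offers:

```sh
# generate a synthetic cohort (data.csv, meta.yaml, cohort.yaml, truth.json)
aag simulate --spec sim.yaml --seed 7 --out sim/

# build the unfiltered graph
aag build --data sim/data.csv --meta sim/meta.yaml --cohort sim/cohort.yaml \
    --out run/ [--config config.yaml] [--overrides ranges.yaml]

# prune it (rules from the config's filter block)
aag filter --graph run/graph.json --out run/

# property-graph CSVs + load.cypher + GraphML + style.json
aag export --graph run/graph.json --out run/export/

# dashboard payload and attribute-vs-group correlation table
aag dashboard --data ... --meta ... --cohort ... --pair chol,probnp --out run/
aag correlate --data ... --meta ... --cohort ... --out run/
```

Every command writes a `manifest.json` with input digests and the effective
configuration. All thresholds, the edge-type aggregation rule, filter rules,
and dashboard binning options live in a YAML config (see
`aagraph.config.RunConfig` for the schema and defaults). The filter
defaults are deliberately conservative stand-ins — the reference method's
exact pruning procedure is not public.

Input formats: data as CSV/TSV with a `participant_id` column and explicit
missing markers (default `""`, `NA`, `NaN`); metadata as CSV or YAML with
`name`, `data_kind` (`metric`/`binary`/`categorical`), `description`,
`categories`, `broad_labels`, `vocab_code`; cohort definitions as YAML/JSON
"any-of" criterion lists (`equals`, `not_equals`, `less_than`,
`greater_than`, `in_set`). A participant is in the disease group iff any
criterion holds on a non-missing value.

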