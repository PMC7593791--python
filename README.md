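# clubnet

Rich-club and diverse-club analysis of parcellated functional connectomes.

`clubnet` turns per-subject parcellated time series (T timepoints × 90
regions, AAL-90 labels bundled) into subject-level brain networks and runs
a complete club-organization analysis:

- **Connectivity** — pairwise Pearson correlation matrices, binarized over a
  sparsity grid (5–50% in 5% steps) keeping only positive correlations, with
  deterministic tie-breaking.
- **Graph metrics** — clustering coefficient (Cp), characteristic path
  length (Lp), global/local efficiency (Eg, Eloc), and their normalized
  forms γ, λ and small-worldness σ against Maslov–Sneppen degree-preserving
  null ensembles; per-metric AUC across the sparsity grid.
- **Communities** — seeded consensus Louvain partitions and
  Guimerà–Amaral participation coefficients.
- **Clubs** — rich club (top 15% of regions by reference-group-averaged
  degree, i.e. 13 of 90) and diverse club (top 15% by averaged
  participation coefficient) at the reference sparsity (15%); edge
  classification into club / feeder / local connections and per-subject
  connection strengths; overlap-node analysis.
- **Statistics** — covariate-adjusted (age + sex) group ANCOVA with
  Bonferroni-corrected pairwise t-tests, chi-square for sex, and partial
  correlations between altered metrics and cognitive scores.
- **Synthetic cohorts** — a fully seeded generator that plants modular
  communities, high-degree hubs, evenly-spread connectors, group-specific
  hub–hub attenuation and a cognition score coupled to overlap-node path
  length, so the whole pipeline is testable without any real data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests with independent brute-force oracles,
property tests (hypothesis), and end-to-end acceptance checks
(`tests/test_acceptance.py`). Full run takes ~2 minutes on one core.

## CLI

Simulate a cohort and run the full pipeline:

```sh
clubnet simulate --seed 7 --out demo_cohort
clubnet run --cohort-dir demo_cohort --out demo_results \
    --n-null 50 --community-runs 20 --seed 7
```

A cohort directory contains `manifest.csv`
(`subject_id,group,age,sex,mmse,gds,lmt_immediate,lmt_delayed`; groups are
HC / SCD / aMCI) plus one TSV time-series file per subject whose header row
holds the region labels. Outputs are written as deterministic TSV/JSON
files: `metrics.tsv` (per-subject metric AUCs), `nodal_metrics.tsv` (at the
reference sparsity, including participation), `clubs.json` (club node sets
by atlas label), `strengths.tsv`, `stats.tsv`, plus the effective
`config.yaml` and a `run.log`.

`clubnet metrics`, `clubnet clubs` and `clubnet stats` run individual
stages; all options can also come from a YAML config file via `--config`.
Note the library default is `n_null: 1000` nulls per network, which is
expensive at full cohort size — pass a smaller `--n-null` for desk-scale
runs.

## Package layout

| module | role |
| --- | --- |
| `clubnet.io` | manifest / time-series / result-table reading and writing, AAL-90 atlas |
| `clubnet.synthetic` | seeded cohort generator with planted structure |
| `clubnet.connectome` | Pearson connectivity, sparsity thresholding |
| `clubnet.graph_metrics` | global & nodal metrics, null ensembles, AUC |
| `clubnet.community` | consensus Louvain, participation coefficient |
| `clubnet.club` | club selection, edge classification, strengths, overlap |
| `clubnet.stats` | ANCOVA, adjusted t, Bonferroni, chi-square, partial correlation |
| `clubnet.pipeline` / `clubnet.cli` | orchestration and command line |
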