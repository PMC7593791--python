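"""End-to-end orchestration: cohort directory -> result tables.

Stage order mirrors the analysis design: connectivity, thresholding over
the sparsity grid, global metrics with degree-preserving null
normalization and AUC summaries, community detection and participation at
the reference sparsity, reference-group-averaged rankings, club selection,
edge classification and strengths, overlap analysis, covariate-adjusted
group statistics, and partial correlations against cognitive scores.

Every source of randomness is derived from the single config seed via
``SeedSequence`` spawn keys, so identical config + cohort give identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import club as club_mod
from . import community as community_mod
from . import graph_metrics as gm
from .connectome import (
    BinaryNetwork,
    ConnectivityMatrix,
    SparsityGrid,
    binarize_by_sparsity,
    pearson_connectivity,
)
from .errors import ValidationError
from .io import (
    RegionAtlas,
    ResultBundle,
    SubjectRecord,
    TimeSeriesMatrix,
    read_manifest,
    read_timeseries,
    scores_frame,
    write_results,
)
from .stats import (
    adjusted_pairwise_t,
    ancova_group_test,
    bonferroni,
    chi_square_independence,
    partial_correlation,
)

log = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma")
SCORE_NAMES = ("mmse", "gds", "lmt_immediate", "lmt_delayed")
GROUP_PAIRS = (("HC", "SCD"), ("HC", "aMCI"), ("SCD", "aMCI"))


@dataclass
class PipelineConfig:
    cohort_dir: str = "."
    output_dir: str = "results"
    sparsity_start: float = 0.05
    sparsity_stop: float = 0.50
    sparsity_step: float = 0.05
    reference_sparsity: float = 0.15
    club_fraction: float = 0.15
    reference_group: str = "HC"
    n_null: int = 1000
    community_runs: int = 100
    seed: int = 0
    strength_weighting: str = "pearson"
    force_all_correlations: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.club_fraction < 1:
            raise ValidationError("club_fraction must be in (0, 1)")
        if self.strength_weighting not in ("pearson", "binary"):
            raise ValidationError("strength_weighting must be pearson|binary")
        if self.reference_sparsity not in self.grid:
            raise ValidationError(
                f"reference_sparsity {self.reference_sparsity} not on the grid")

    @property
    def grid(self) -> SparsityGrid:
        return SparsityGrid.from_range(
            self.sparsity_start, self.sparsity_stop, self.sparsity_step)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _seed_for(config_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=config_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# cohort loading
# ---------------------------------------------------------------------------

def load_cohort_dir(
    cohort_dir: str | Path,
) -> tuple[list[SubjectRecord], dict[str, TimeSeriesMatrix], RegionAtlas]:
    cohort = Path(cohort_dir)
    manifest = cohort / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {cohort}")
    records = read_manifest(manifest)
    first = _ts_path(cohort, records[0].subject_id)
    header = pd.read_csv(first, sep="\t" if first.suffix == ".tsv" else ",",
                         nrows=0)
    atlas = RegionAtlas(tuple(str(c) for c in header.columns))
    tsmap = {
        r.subject_id: read_timeseries(_ts_path(cohort, r.subject_id), atlas,
                                      subject_id=r.subject_id)
        for r in records
    }
    return records, tsmap, atlas


def _ts_path(cohort: Path, subject_id: str) -> Path:
    for ext in (".tsv", ".csv", ".txt"):
        p = cohort / f"{subject_id}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no time-series file for subject {subject_id}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@dataclass
class ReferenceState:
    """Per-subject state at the reference sparsity."""

    network: BinaryNetwork
    nodal: gm.NodalMetrics
    partition: community_mod.CommunityPartition
    participation: np.ndarray


def connectivity_stage(
    tsmap: Mapping[str, TimeSeriesMatrix],
) -> dict[str, ConnectivityMatrix]:
    return {sid: pearson_connectivity(ts) for sid, ts in tsmap.items()}


def metric_auc_stage(
    conn: Mapping[str, ConnectivityMatrix],
    records: Sequence[SubjectRecord],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-subject AUC over the sparsity grid for each global metric."""
    grid = config.grid
    rows = []
    groups = {r.subject_id: r.group for r in records}
    for si, (sid, C) in enumerate(conn.items()):
        curves: dict[str, list[float]] = {m: [] for m in GLOBAL_METRIC_NAMES}
        for ti, s in enumerate(grid):
            G = binarize_by_sparsity(C, s)
            seed = _seed_for(config.seed, 1, si, ti)
            m = gm.global_metrics(G, n_null=config.n_null or None, seed=seed)
            for name, val in zip(
                GLOBAL_METRIC_NAMES,
                (m.Cp, m.Lp, m.Eg, m.Eloc, m.gamma, m.lambda_, m.sigma),
            ):
                curves[name].append(val)
        row = {"subject_id": sid, "group": groups.get(sid, "")}
        for name in GLOBAL_METRIC_NAMES:
            vals = np.asarray(curves[name])
            row[name] = (gm.auc_over_sparsity(vals, grid)
                         if np.isfinite(vals).all() else np.nan)
        rows.append(row)
        log.info("metrics stage: subject %s done", sid)
    return pd.DataFrame(rows)


def reference_stage(
    conn: Mapping[str, ConnectivityMatrix], config: PipelineConfig
) -> dict[str, ReferenceState]:
    """Nodal metrics, communities and participation at the reference sparsity."""
    out: dict[str, ReferenceState] = {}
    for si, (sid, C) in enumerate(conn.items()):
        G = binarize_by_sparsity(C, config.reference_sparsity)
        nodal = gm.nodal_metrics(G)
        part = community_mod.detect_communities(
            G, n_runs=config.community_runs, seed=_seed_for(config.seed, 2, si))
        pc = community_mod.participation_coefficient(G, part)
        out[sid] = ReferenceState(G, nodal, part, pc)
    return out


def club_stage(
    refstates: Mapping[str, ReferenceState],
    records: Sequence[SubjectRecord],
    config: PipelineConfig,
) -> tuple[club_mod.ClubDefinition, club_mod.ClubDefinition, club_mod.OverlapAnalysis]:
    ref_ids = [r.subject_id for r in records if r.group == config.reference_group]
    if not ref_ids:
        raise ValidationError(
            f"no subjects in reference group {config.reference_group!r}")
    deg_mean = club_mod.average_ranking_scores(
        [refstates[sid].nodal.degree for sid in ref_ids])
    pc_mean = club_mod.average_ranking_scores(
        [refstates[sid].participation for sid in ref_ids])
    rich = club_mod.select_club(
        deg_mean, config.club_fraction, criterion="degree",
        reference_group=config.reference_group,
        reference_sparsity=config.reference_sparsity)
    diverse = club_mod.select_club(
        pc_mean, config.club_fraction, criterion="participation",
        reference_group=config.reference_group,
        reference_sparsity=config.reference_sparsity)
    return rich, diverse, club_mod.overlap_analysis(rich, diverse)


def strength_stage(
    conn: Mapping[str, ConnectivityMatrix],
    refstates: Mapping[str, ReferenceState],
    clubs: Mapping[str, club_mod.ClubDefinition],
    records: Sequence[SubjectRecord],
    config: PipelineConfig,
) -> pd.DataFrame:
    groups = {r.subject_id: r.group for r in records}
    rows = []
    for sid, C in conn.items():
        G = refstates[sid].network
        for crit, cdef in clubs.items():
            cls = club_mod.classify_edges(G, cdef)
            st = club_mod.connection_strengths(
                C, G, cls, weighting=config.strength_weighting)
            rows.append({
                "subject_id": sid, "group": groups.get(sid, ""),
                "criterion": crit,
                "club_strength": st.club_strength,
                "feeder_strength": st.feeder_strength,
                "local_strength": st.local_strength,
            })
    return pd.DataFrame(rows)


def overlap_metric_stage(
    refstates: Mapping[str, ReferenceState],
    overlap: club_mod.OverlapAnalysis,
    records: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Per-subject mean nodal efficiency / path length over the three sets."""
    groups = {r.subject_id: r.group for r in records}
    sets = {
        "overlap": overlap.overlap_nodes,
        "rich_only": overlap.rich_only,
        "diverse_only": overlap.diverse_only,
    }
    rows = []
    for sid, state in refstates.items():
        row = {"subject_id": sid, "group": groups.get(sid, "")}
        for set_name, nodes in sets.items():
            means = club_mod.mean_nodal_metrics_over(state.nodal, nodes)
            row[f"{set_name}_nodal_efficiency"] = means["nodal_efficiency"]
            row[f"{set_name}_nodal_Lp"] = means["nodal_Lp"]
        rows.append(row)
    return pd.DataFrame(rows)


def nodal_table(
    refstates: Mapping[str, ReferenceState],
    records: Sequence[SubjectRecord],
    atlas: RegionAtlas,
) -> pd.DataFrame:
    groups = {r.subject_id: r.group for r in records}
    rows = []
    for sid, state in refstates.items():
        nd = state.nodal
        for i, label in enumerate(atlas.labels):
            rows.append({
                "subject_id": sid, "group": groups.get(sid, ""),
                "region": label,
                "degree": int(nd.degree[i]),
                "nodal_efficiency": nd.nodal_efficiency[i],
                "nodal_clustering": nd.nodal_clustering[i],
                "nodal_Lp": nd.nodal_Lp[i],
                "betweenness": nd.betweenness[i],
                "participation": state.participation[i],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _covariate_matrix(df: pd.DataFrame) -> np.ndarray:
    sex01 = (df["sex"] == "M").astype(float)  # F=0, M=1
    return np.column_stack([df["age"].to_numpy(float), sex01.to_numpy()])


def group_stats_table(
    metric_frame: pd.DataFrame,
    manifest: pd.DataFrame,
    metric_columns: Sequence[str],
    force_all_correlations: bool = False,
) -> pd.DataFrame:
    """ANCOVA + Bonferroni post hocs per metric, chi-square for sex,
    score comparisons, and partial correlations for altered metrics."""
    df = metric_frame.merge(
        manifest[["subject_id", "group", "age", "sex"] + list(SCORE_NAMES)],
        on=["subject_id", "group"], how="left")
    cov = _covariate_matrix(df)
    groups = df["group"].to_numpy()
    rows: list[dict] = []
    significant: list[str] = []

    def add(metric: str, contrast: str, res, p_adj=None) -> None:
        df1, df2 = (res.df if isinstance(res.df, tuple) else (res.df, np.nan))
        rows.append({
            "metric": metric, "contrast": contrast,
            "statistic": res.statistic_name, "value": res.value,
            "df1": df1, "df2": df2, "p_raw": res.p_raw,
            "p_bonferroni": p_adj if p_adj is not None else np.nan,
            "n": res.n, "covariates": ",".join(res.covariates),
        })

    for metric in metric_columns:
        y = df[metric].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 6 or np.unique(groups[ok]).size < 2:
            log.warning("skipping %s: insufficient data", metric)
            continue
        res = ancova_group_test(y[ok], groups[ok], cov[ok],
                                covariate_names=("age", "sex"))
        add(metric, "HC|SCD|aMCI", res)
        if res.p_raw < 0.05:
            significant.append(metric)
        pairs, t_results = [], []
        for pair in GROUP_PAIRS:
            if not all((groups[ok] == g).sum() >= 2 for g in pair):
                continue
            try:
                t_results.append(
                    adjusted_pairwise_t(y[ok], groups[ok], pair, cov[ok],
                                        covariate_names=("age", "sex")))
                pairs.append(pair)
            except ValidationError as exc:
                log.warning("pairwise %s on %s skipped: %s", pair, metric, exc)
        adj = bonferroni([t.p_raw for t in t_results], m=3)
        for pair, t_res, p_adj in zip(pairs, t_results, adj):
            add(metric, f"{pair[0]}-{pair[1]}", t_res, p_adj)

    # demographics: sex chi-square, age + scores via the same ANCOVA machinery
    try:
        table = pd.crosstab(df["sex"], df["group"]).to_numpy()
        add("sex", "HC|SCD|aMCI", chi_square_independence(table))
    except ValidationError as exc:
        log.warning("sex chi-square skipped: %s", exc)
    age = df["age"].to_numpy(float)
    add("age", "HC|SCD|aMCI", ancova_group_test(age, groups))
    for score in SCORE_NAMES:
        y = df[score].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 6:
            continue
        if ok.sum() < len(y):
            log.info("%s: %d subjects lack a score", score, int((~ok).sum()))
        try:
            add(score, "HC|SCD|aMCI",
                ancova_group_test(y[ok], groups[ok], cov[ok],
                                  covariate_names=("age", "sex")))
        except ValidationError as exc:
            log.warning("score %s skipped: %s", score, exc)

    # partial correlations for altered metrics vs cognitive scores
    targets = list(metric_columns) if force_all_correlations else significant
    for metric in targets:
        y = df[metric].to_numpy(float)
        for score in SCORE_NAMES:
            x = df[score].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 8:
                continue
            if ok.sum() < len(y):
                log.info("correlation %s~%s: excluded %d subjects with "
                         "missing scores", metric, score, int((~ok).sum()))
            try:
                res = partial_correlation(y[ok], x[ok], cov[ok],
                                          covariate_names=("age", "sex"))
            except ValidationError as exc:
                log.warning("correlation %s~%s skipped: %s", metric, score, exc)
                continue
            add(metric, f"corr:{score}", res)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, write: bool = True) -> ResultBundle:
    out_dir = Path(config.output_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setLevel(logging.INFO)
        logging.getLogger("clubnet").addHandler(handler)
    try:
        return _run(config, write, out_dir)
    finally:
        if write:
            logging.getLogger("clubnet").removeHandler(handler)


def _run(config: PipelineConfig, write: bool, out_dir: Path) -> ResultBundle:
    def stage(name, fn, *args, **kwargs):
        log.info("stage %s: start (seed=%d)", name, config.seed)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    records, tsmap, atlas = stage("load", load_cohort_dir, config.cohort_dir)
    manifest = scores_frame(records)
    conn = stage("connectivity", connectivity_stage, tsmap)
    metrics = stage("global_metrics", metric_auc_stage, conn, records, config)
    refstates = stage("reference", reference_stage, conn, config)
    rich, diverse, overlap = stage("clubs", club_stage, refstates, records, config)
    strengths = stage(
        "strengths", strength_stage, conn, refstates,
        {"rich": rich, "diverse": diverse}, records, config)
    overlap_df = stage(
        "overlap", overlap_metric_stage, refstates, overlap, records)

    # wide frame of everything that gets a group comparison
    strengths_wide = strengths.pivot_table(
        index=["subject_id", "group"], columns="criterion",
        values=["club_strength", "feeder_strength", "local_strength"],
        aggfunc="first", sort=False)
    strengths_wide.columns = [f"{crit}_{val}" for val, crit in
                              strengths_wide.columns]
    strengths_wide = strengths_wide.reset_index()
    analysis = metrics.merge(strengths_wide, on=["subject_id", "group"])
    analysis = analysis.merge(overlap_df, on=["subject_id", "group"])
    metric_cols = [c for c in analysis.columns
                   if c not in ("subject_id", "group")]
    stats_df = stage(
        "stats", group_stats_table, analysis, manifest, metric_cols,
        config.force_all_correlations)

    bundle = ResultBundle(
        metrics=metrics,
        nodal_metrics=nodal_table(refstates, records, atlas),
        clubs={
            "rich_club": rich.labels(atlas),
            "diverse_club": diverse.labels(atlas),
            "overlap": [atlas.labels[i] for i in overlap.overlap_nodes],
        },
        strengths=strengths,
        stats=stats_df,
    )
    if write:
        config.to_yaml(out_dir / "config.yaml")
        write_results(bundle, out_dir)
    return bundle
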