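"""Synthetic cohorts with planted network structure.

The generative model builds, per subject, a latent nonnegative weight
matrix with modular block structure (within-community weights above
between-community weights), planted hubs (rows elevated toward all nodes,
with an extra hub-hub bonus), and planted connectors (a fixed budget of
elevated edges spread evenly across every community).  Hub-hub weights are
multiplied by a per-group attenuation factor, which is the planted group
effect the analysis pipeline is expected to recover.

Time series are draws from a zero-mean multivariate normal whose
covariance is the latent matrix shifted to positive definiteness plus
isotropic noise, so the sample Pearson matrix converges to the latent
correlation structure as T grows.

The delayed-recall score is linearly coupled to a per-subject latent
path-length proxy of the planted overlap nodes (hub AND connector), plus a
group offset and unit normal noise.  All randomness derives from the single
cohort seed through documented ``SeedSequence`` spawn keys:
``(0,)`` structure/demographics, ``(1, i)`` subject i's latent jitter,
``(2, i)`` subject i's time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .io import (
    RegionAtlas,
    SubjectRecord,
    TimeSeriesMatrix,
    write_manifest,
    write_timeseries,
)

log = logging.getLogger(__name__)

DEFAULT_GROUP_SIZES = {"HC": 28, "SCD": 19, "aMCI": 29}
DEFAULT_ATTENUATION = {"HC": 1.0, "SCD": 0.9, "aMCI": 0.7}


def region_labels(n_regions: int) -> tuple[str, ...]:
    """AAL-90 labels when N=90, generic R001.. labels otherwise."""
    if n_regions == 90:
        return RegionAtlas.aal90().labels
    return tuple(f"R{i + 1:03d}" for i in range(n_regions))


def default_planted(
    n_regions: int, n_communities: int
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Deterministic default hub/connector node sets, spread over communities.

    Hubs and connectors share a few nodes so that the rich club and the
    diverse club overlap by construction, mirroring the structure the
    analysis is designed to detect.
    """
    blocks = np.array_split(np.arange(n_regions), n_communities)
    round_robin = [int(b[k]) for k in range(max(len(b) for b in blocks))
                   for b in blocks if k < len(b)]
    n_hubs = max(3, int(round(n_regions * 8 / 90)))
    n_overlap = max(1, (3 * n_hubs) // 8)
    hubs = round_robin[:n_hubs]
    rest = [v for v in round_robin[n_hubs:]]
    connectors = hubs[:n_overlap] + rest[: n_hubs - n_overlap]
    return tuple(hubs), tuple(sorted(connectors))


@dataclass
class CohortSpec:
    """All knobs of the synthetic-cohort generator (single master seed)."""

    n_regions: int = 90
    n_communities: int = 5
    planted_hubs: tuple[int, ...] | None = None
    planted_connectors: tuple[int, ...] | None = None
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    club_attenuation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION))
    n_timepoints: int = 140
    noise_sd: float = 0.3
    cognition_slope: float = 1.2
    seed: int = 0
    # latent weight tiers
    w_in: float = 0.25
    w_out: float = 0.05
    hub_boost: float = 0.10
    hub_hub_bonus: float = 0.30
    connector_weight: float = 0.45
    connector_degree_per_community: int = 4
    edge_jitter_sd: float = 0.05
    subject_scale_sd: float = 0.15
    lmt_intercept: float = 13.0
    group_lmt_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "SCD": 0.0, "aMCI": 0.0})

    def __post_init__(self) -> None:
        if self.n_regions < 6 or self.n_communities < 2:
            raise ValidationError("need n_regions >= 6 and n_communities >= 2")
        if self.n_regions < 2 * self.n_communities:
            raise ValidationError("communities would be too small")
        if self.planted_hubs is None or self.planted_connectors is None:
            hubs, conns = default_planted(self.n_regions, self.n_communities)
            if self.planted_hubs is None:
                self.planted_hubs = hubs
            if self.planted_connectors is None:
                self.planted_connectors = conns
        for name, nodes in (("planted_hubs", self.planted_hubs),
                            ("planted_connectors", self.planted_connectors)):
            if any(not 0 <= v < self.n_regions for v in nodes):
                raise ValidationError(f"{name} must be a subset of regions")
        for g, mult in self.club_attenuation.items():
            if not 0 < mult <= 1:
                raise ValidationError(
                    f"club_attenuation[{g}] must be in (0, 1], got {mult}")
        if any(v <= 0 for v in self.n_per_group.values()):
            raise ValidationError("group sizes must be positive")
        if self.n_timepoints < 3 or self.noise_sd < 0:
            raise ValidationError("invalid n_timepoints or noise_sd")

    @property
    def planted_overlap(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.planted_hubs) & set(self.planted_connectors)))

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group.values())

    def community_assignment(self) -> np.ndarray:
        blocks = np.array_split(np.arange(self.n_regions), self.n_communities)
        assign = np.empty(self.n_regions, dtype=int)
        for lab, b in enumerate(blocks):
            assign[b] = lab
        return assign


@dataclass
class LatentConnectome:
    weights: np.ndarray
    community_assignment: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or (np.diag(w) != 0).any() or not np.allclose(w, w.T):
            raise ValidationError(
                "latent weights must be symmetric, nonnegative, zero-diagonal")
        self.weights = w


def _structure_rng(spec: CohortSpec) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))


def _connector_targets(spec: CohortSpec) -> dict[int, np.ndarray]:
    """Per-connector target nodes, the same for every subject and group."""
    rng = _structure_rng(spec)
    assign = spec.community_assignment()
    targets: dict[int, np.ndarray] = {}
    for c in spec.planted_connectors:
        chosen: list[int] = []
        for s in range(spec.n_communities):
            pool = np.setdiff1d(np.flatnonzero(assign == s), [c])
            k = min(spec.connector_degree_per_community, pool.size)
            chosen.extend(rng.choice(pool, size=k, replace=False).tolist())
        targets[c] = np.array(sorted(chosen), dtype=int)
    return targets


def _base_weights(spec: CohortSpec, group: str) -> np.ndarray:
    """Deterministic tiered weight matrix before per-subject jitter."""
    n = spec.n_regions
    assign = spec.community_assignment()
    w = np.full((n, n), spec.w_out)
    same = assign[:, None] == assign[None, :]
    w[same] = spec.w_in
    hubs = np.asarray(spec.planted_hubs, dtype=int)
    w[hubs, :] += spec.hub_boost
    w[:, hubs] += spec.hub_boost
    hub_pairs = np.ix_(hubs, hubs)
    w[hub_pairs] += spec.hub_hub_bonus
    for c, tgt in _connector_targets(spec).items():
        w[c, tgt] = np.maximum(w[c, tgt], spec.connector_weight)
        w[tgt, c] = w[c, tgt]
    # balance each connector row so its weight mass is equal across
    # communities (scale every community segment down to the smallest);
    # factors are computed before attenuation so they are group-independent
    # and the planted group effect survives intact
    for c in spec.planted_connectors:
        row = w[c].copy()
        row[c] = 0.0
        masses = np.array([row[assign == s].sum()
                           for s in range(spec.n_communities)])
        target = masses.min()
        for s in range(spec.n_communities):
            if masses[s] > 0:
                row[assign == s] *= target / masses[s]
        w[c, :] = row
        w[:, c] = row
    att = spec.club_attenuation.get(group)
    if att is None:
        raise ValidationError(f"no club_attenuation for group {group!r}")
    w[hub_pairs] *= att
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 0.95)


def generate_latent_connectome(
    spec: CohortSpec, group: str, seed: int | np.random.SeedSequence
) -> LatentConnectome:
    """One subject's latent weight matrix (group effect + seeded jitter)."""
    w = _base_weights(spec, group)
    rng = np.random.default_rng(seed)
    n = spec.n_regions
    jitter = rng.normal(0.0, spec.edge_jitter_sd, size=(n, n))
    jitter = np.triu(jitter, 1)
    jitter = jitter + jitter.T
    w = w * np.exp(jitter)
    scale = float(np.exp(rng.normal(0.0, spec.subject_scale_sd)))
    overlap = np.asarray(spec.planted_overlap, dtype=int)
    if overlap.size:
        factor = np.ones((n, n))
        factor[overlap, :] *= scale
        factor[:, overlap] *= scale
        w = w * factor
    np.fill_diagonal(w, 0.0)
    return LatentConnectome(np.clip(w, 0.0, 0.98), spec.community_assignment())


def overlap_pathlength_proxy(latent: LatentConnectome, overlap_nodes) -> float:
    """1 / mean latent weight on the overlap-node rows (higher = 'longer')."""
    idx = np.asarray(list(overlap_nodes), dtype=int)
    if idx.size == 0:
        return 0.0
    n = latent.weights.shape[0]
    total = latent.weights[idx].sum()  # diagonal is zero already
    mean_w = total / (idx.size * (n - 1))
    return float(1.0 / mean_w)


def generate_timeseries(
    latent: LatentConnectome,
    T: int,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    subject_id: str = "",
    labels: tuple[str, ...] | None = None,
) -> TimeSeriesMatrix:
    """Draw T zero-mean Gaussian samples with latent-derived covariance."""
    w = latent.weights
    n = w.shape[0]
    if T < max(3, n // 2):
        log.warning("T=%d is small for N=%d regions", T, n)
    eig_min = float(np.linalg.eigvalsh(w).min())
    delta = abs(eig_min) + 0.01 if eig_min < 0.01 else 0.0
    sigma = w + (delta + noise_sd**2) * np.eye(n)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - by construction
        raise RuntimeError("covariance not positive definite after shift") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((T, n))
    values = z @ chol.T
    return TimeSeriesMatrix(
        values, labels or region_labels(n), subject_id=subject_id)


@dataclass
class Cohort:
    """A generated cohort plus the latent quantities used to build it."""

    spec: CohortSpec
    records: list[SubjectRecord]
    timeseries: dict[str, TimeSeriesMatrix]
    latents: dict[str, LatentConnectome]
    proxies: dict[str, float]


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))  # pragma: no cover


def generate_cohort_full(spec: CohortSpec) -> Cohort:
    """Generate subjects, time series and cognition for all three groups."""
    demo_rng = _structure_rng(spec)
    subjects: list[tuple[str, str]] = []
    for group, count in spec.n_per_group.items():
        for k in range(count):
            subjects.append((f"{group}{k + 1:03d}", group))
    latents: dict[str, LatentConnectome] = {}
    timeseries: dict[str, TimeSeriesMatrix] = {}
    proxies: dict[str, float] = {}
    labels = region_labels(spec.n_regions)
    for i, (sid, group) in enumerate(subjects):
        lat_seed = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, i))
        ts_seed = np.random.SeedSequence(entropy=spec.seed, spawn_key=(2, i))
        lat = generate_latent_connectome(spec, group, lat_seed)
        latents[sid] = lat
        proxies[sid] = overlap_pathlength_proxy(lat, spec.planted_overlap)
        timeseries[sid] = generate_timeseries(
            lat, spec.n_timepoints, spec.noise_sd, ts_seed,
            subject_id=sid, labels=labels)
    # standardize the proxy across the cohort so cognition_slope is the
    # effect size in noise-SD units (unit residual noise below)
    pvals = np.array([proxies[sid] for sid, _ in subjects])
    p_sd = pvals.std()
    z = (pvals - pvals.mean()) / p_sd if p_sd > 0 else np.zeros_like(pvals)
    records: list[SubjectRecord] = []
    for i, (sid, group) in enumerate(subjects):
        age = _truncated_normal(demo_rng, 71.0, 5.0, 55.0, 90.0)
        sex = "M" if demo_rng.random() < 0.5 else "F"
        lmt_del = (spec.lmt_intercept
                   + spec.cognition_slope * z[i]
                   + spec.group_lmt_offsets.get(group, 0.0)
                   + demo_rng.normal(0.0, 1.0))
        lmt_imm = lmt_del + 1.5 + demo_rng.normal(0.0, 1.0)
        mmse = _truncated_normal(demo_rng, 28.5, 1.5, 20.0, 30.0)
        gds = abs(demo_rng.normal(1.0, 1.0))
        records.append(SubjectRecord(
            subject_id=sid, group=group, age=age, sex=sex,
            mmse=round(mmse, 2), gds=round(gds, 2),
            lmt_immediate=round(lmt_imm, 2), lmt_delayed=round(lmt_del, 2),
        ))
    return Cohort(spec=spec, records=records, timeseries=timeseries,
                  latents=latents, proxies=proxies)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], dict[str, TimeSeriesMatrix]]:
    cohort = generate_cohort_full(spec)
    return cohort.records, cohort.timeseries


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write manifest.csv plus one TSV time-series file per subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.records, out / "manifest.csv")
    for sid, ts in cohort.timeseries.items():
        write_timeseries(ts, out / f"{sid}.tsv")
    log.info("wrote cohort of %d subjects to %s", len(cohort.records), out)
    return out


def null_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of a spec with every group effect switched off."""
    return replace(
        spec,
        club_attenuation={g: 1.0 for g in spec.club_attenuation},
        group_lmt_offsets={g: 0.0 for g in spec.group_lmt_offsets},
        cognition_slope=0.0,
    )
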