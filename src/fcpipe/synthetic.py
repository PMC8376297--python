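"""Synthetic connectome cohorts with planted, recoverable structure.

The generator emulates the study design the analysis modules expect:
three groups (healthy controls plus two patient groups, one with a
history of overt hepatic encephalopathy), paired pre/post-treatment
sessions for patients, a connected *disrupted* edge subnetwork whose
connectivity is lowered in patients before treatment, a *psychomotor*
edge subnetwork whose strength drives two behavioral scores (DST,
positively; NCT, negatively — lower completion time is better), and an
optional group-moderated brain-behavior slope.

Two generation modes are provided.  The default **direct-z** mode writes
Fisher-z edge values directly (shared base matrix + group/session
offsets + a per-subject latent strength factor + i.i.d. edge noise),
giving exact control over effect sizes.  The **time-series** mode draws
multivariate-normal BOLD series whose correlation structure is the tanh
of the subject's target z-matrix (shrunk toward the identity just enough
to be positive definite), exercising the Pearson/Fisher estimation path.

All randomness flows from one root seed; per-subject streams are keyed
by a subject counter, so enlarging a cohort never reshuffles existing
subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import edges as edgemod
from .atlas import default_labels
from .fc import ConnectivityMatrix, RoiTimeSeries

__all__ = [
    "SimulationConfig",
    "Subject",
    "Cohort",
    "plant_edge_set",
    "simulate_connectomes",
    "simulate_behavior",
    "simulate_cohort",
    "simulate_timeseries",
]

# RNG stream offsets: 0 = base matrix, 1/2 = planted edge sets,
# 1e6+k = subject k connectome noise, 2e6+k = behavior, 3e6+k = time series
_BASE_STREAM = 0
_DISRUPTED_STREAM = 1
_PMN_STREAM = 2
_SUBJECT_STREAM = 1_000_000
_BEHAVIOR_STREAM = 2_000_000
_TIMESERIES_STREAM = 3_000_000


def plant_edge_set(n_regions: int, n_edges: int, rng_seed) -> np.ndarray:
    """Sample ``n_edges`` distinct edges whose induced subgraph is connected.

    A node subset of size ``min(n_regions, n_edges + 1)`` is drawn, a
    random spanning tree laid over it, and the remaining edges added
    uniformly among the subset — so the result always forms a single
    connected component and exercises component logic downstream.

    Returns an ``(n_edges, 2)`` array of node pairs with ``i < j``.
    """
    max_edges = edgemod.edge_count(n_regions)
    if n_edges < 1:
        raise ValueError("need at least one edge")
    if n_edges > max_edges:
        raise ValueError(
            f"cannot plant {n_edges} edges among {n_regions} regions: "
            f"at most {max_edges} distinct edges exist"
        )
    rng = np.random.default_rng(rng_seed)
    k = min(n_regions, n_edges + 1)
    nodes = rng.choice(n_regions, size=k, replace=False)
    # random spanning tree: attach each node to a uniformly chosen predecessor
    order = rng.permutation(k)
    chosen: set[tuple[int, int]] = set()
    for pos in range(1, k):
        a = nodes[order[pos]]
        b = nodes[order[rng.integers(0, pos)]]
        chosen.add((min(a, b), max(a, b)))
    # grow with random extra edges inside the subset
    while len(chosen) < n_edges:
        a, b = rng.choice(nodes, size=2, replace=False)
        chosen.add((min(a, b), max(a, b)))
    pairs = np.array(sorted(chosen), dtype=np.int64)
    assert pairs.shape[0] == n_edges
    return pairs


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the cohort
    the analysis is designed for (32 controls, 36 + 28 patients, paired
    sessions, a 17-edge disrupted network and an 18-edge psychomotor
    network, disjoint by construction)."""

    n_regions: int = 116
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 32, "nonOHE": 36, "OHE": 28}
    )
    control_group: str = "HC"
    paired: bool = True
    disrupted_edges: np.ndarray | None = None  # default: planted 17-edge set
    n_disrupted_edges: int = 17
    delta_z: float = 0.5
    hyper_edges: np.ndarray | None = None  # +delta_z on patient post sessions
    hyper_groups: tuple[str, ...] | None = None  # None = all patient groups
    pmn_edges: np.ndarray | None = None  # default: planted 18-edge set
    n_pmn_edges: int = 18
    coupling_beta: float = 46.0  # score units per unit network strength
    moderation_gamma: float = 0.0  # extra slope for the moderated group
    moderation_group: str = "OHE"
    noise_sd_z: float = 0.1
    subject_strength_sd: float = 0.15  # per-subject latent on the PMN edges
    behavior_noise_sd: float = 7.0
    dst_intercept: float = 47.8
    nct_intercept: float = 40.4
    base_mean_z: float = 0.3
    base_sd_z: float = 0.15
    timepoints: int = 190
    sampling_interval: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects")
        if self.control_group not in self.group_sizes:
            raise ValueError(f"control group {self.control_group!r} not in group_sizes")
        for sd in (self.noise_sd_z, self.behavior_noise_sd, self.subject_strength_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        e = edgemod.edge_count(self.n_regions)
        for name in ("disrupted_edges", "pmn_edges", "hyper_edges"):
            pairs = getattr(self, name)
            if pairs is not None:
                idx = edgemod.pairs_to_index(np.asarray(pairs), self.n_regions)
                if np.unique(idx).size != idx.size:
                    raise ValueError(f"{name} contains duplicate edges")
                if idx.size > e:
                    raise ValueError(f"{name} exceeds the edge universe")

    def resolved(self) -> "SimulationConfig":
        """Concretize planted edge sets (disjoint by default) from the seed."""
        self.validate()
        cfg = self
        if cfg.disrupted_edges is None:
            cfg = replace(
                cfg,
                disrupted_edges=plant_edge_set(
                    cfg.n_regions, cfg.n_disrupted_edges, [cfg.seed, _DISRUPTED_STREAM]
                ),
            )
        if cfg.pmn_edges is None:
            taken = set(
                edgemod.pairs_to_index(np.asarray(cfg.disrupted_edges), cfg.n_regions)
            )
            for attempt in range(64):
                cand = plant_edge_set(
                    cfg.n_regions,
                    cfg.n_pmn_edges,
                    [cfg.seed, _PMN_STREAM + attempt],
                )
                if not taken & set(edgemod.pairs_to_index(cand, cfg.n_regions)):
                    break
            else:
                raise RuntimeError("could not plant a PMN disjoint from disrupted edges")
            cfg = replace(cfg, pmn_edges=cand)
        cfg.validate()
        return cfg


@dataclass
class Subject:
    subject_id: str
    group: str
    session: str  # "pre" or "post"
    matrix: ConnectivityMatrix | None = None
    timeseries: RoiTimeSeries | None = None
    nct: float | None = None  # seconds; higher = worse
    dst: float | None = None  # correct symbols in 90 s; higher = better


@dataclass
class Cohort:
    subjects: list[Subject]
    truth: dict
    n_regions: int

    def select(
        self, group: str | Iterable[str] | None = None, session: str | None = None
    ) -> list[Subject]:
        groups = None
        if group is not None:
            groups = {group} if isinstance(group, str) else set(group)
        return [
            s
            for s in self.subjects
            if (groups is None or s.group in groups)
            and (session is None or s.session == session)
        ]

    def edge_matrix(
        self, group: str | Iterable[str] | None = None, session: str | None = None
    ) -> np.ndarray:
        """(subjects, edges) stack of Fisher-z upper triangles."""
        subs = self.select(group, session)
        if not subs:
            raise ValueError(f"no subjects match group={group!r} session={session!r}")
        rows = []
        for s in subs:
            if s.matrix is None:
                raise ValueError(f"subject {s.subject_id} has no connectivity matrix")
            rows.append(edgemod.vectorize(s.matrix.z, check=False))
        return np.vstack(rows)

    def scores(
        self,
        score: str,
        group: str | Iterable[str] | None = None,
        session: str | None = None,
    ) -> np.ndarray:
        subs = self.select(group, session)
        vals = [getattr(s, score.lower()) for s in subs]
        if any(v is None for v in vals):
            raise ValueError(f"missing {score} scores; run simulate_behavior first")
        return np.array(vals, dtype=float)

    def phenotype(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "session": [s.session for s in self.subjects],
                "NCT": [s.nct for s in self.subjects],
                "DST": [s.dst for s in self.subjects],
            }
        )


def _iter_subject_slots(cfg: SimulationConfig):
    """Deterministic (counter, subject_id, group, sessions) enumeration."""
    counter = 0
    for group, size in cfg.group_sizes.items():
        sessions = (
            ("pre",)
            if group == cfg.control_group or not cfg.paired
            else ("pre", "post")
        )
        for k in range(size):
            yield counter, f"{group}-{k:03d}", group, sessions
            counter += 1


def _target_vectors(cfg: SimulationConfig):
    """Yield (subject_id, group, session, z-vector) for every subject-session."""
    cfg = cfg.resolved()
    e = edgemod.edge_count(cfg.n_regions)
    base_rng = np.random.default_rng([cfg.seed, _BASE_STREAM])
    base = base_rng.normal(cfg.base_mean_z, cfg.base_sd_z, size=e)
    dis_idx = edgemod.pairs_to_index(cfg.disrupted_edges, cfg.n_regions)
    pmn_idx = edgemod.pairs_to_index(cfg.pmn_edges, cfg.n_regions)
    hyper_idx = (
        edgemod.pairs_to_index(cfg.hyper_edges, cfg.n_regions)
        if cfg.hyper_edges is not None
        else None
    )
    hyper_groups = (
        set(cfg.hyper_groups)
        if cfg.hyper_groups is not None
        else {g for g in cfg.group_sizes if g != cfg.control_group}
    )
    for counter, sid, group, sessions in _iter_subject_slots(cfg):
        rng = np.random.default_rng([cfg.seed, _SUBJECT_STREAM + counter])
        latent = rng.normal(0.0, cfg.subject_strength_sd)
        for session in sessions:
            vec = base.copy()
            if group != cfg.control_group and session == "pre":
                vec[dis_idx] -= cfg.delta_z
            if (
                hyper_idx is not None
                and session == "post"
                and group in hyper_groups
            ):
                vec[hyper_idx] += cfg.delta_z
            vec[pmn_idx] += latent
            vec += rng.normal(0.0, cfg.noise_sd_z, size=e)
            yield sid, group, session, vec
    # stash resolved config details for the caller via generator attribute
    return


def _truth(cfg: SimulationConfig) -> dict:
    base_rng = np.random.default_rng([cfg.seed, _BASE_STREAM])
    e = edgemod.edge_count(cfg.n_regions)
    base = base_rng.normal(cfg.base_mean_z, cfg.base_sd_z, size=e)
    pmn_idx = edgemod.pairs_to_index(cfg.pmn_edges, cfg.n_regions)
    return {
        "disrupted_edges": np.asarray(cfg.disrupted_edges).tolist(),
        "pmn_edges": np.asarray(cfg.pmn_edges).tolist(),
        "hyper_edges": (
            np.asarray(cfg.hyper_edges).tolist() if cfg.hyper_edges is not None else None
        ),
        "delta_z": cfg.delta_z,
        "coupling_beta": cfg.coupling_beta,
        "moderation_gamma": cfg.moderation_gamma,
        "moderation_group": cfg.moderation_group,
        "noise_sd_z": cfg.noise_sd_z,
        "subject_strength_sd": cfg.subject_strength_sd,
        "behavior_noise_sd": cfg.behavior_noise_sd,
        "base_pmn_strength": float(base[pmn_idx].mean()),
        "seed": cfg.seed,
    }


def simulate_connectomes(config: SimulationConfig) -> Cohort:
    """Direct-z cohort: every subject-session gets a Fisher-z matrix.

    Each matrix is the shared base plus planted group/session offsets
    (``-delta_z`` on disrupted edges before treatment; ``+delta_z`` on
    hyperconnectivity edges, if configured, after treatment), a
    per-subject latent shift on the psychomotor edges, and i.i.d. edge
    noise.  Scores are left unset; see :func:`simulate_behavior`.
    """
    cfg = config.resolved()
    labels = default_labels(cfg.n_regions)
    subjects = [
        Subject(
            subject_id=sid,
            group=group,
            session=session,
            matrix=ConnectivityMatrix(edgemod.matricize(vec, cfg.n_regions), list(labels)),
        )
        for sid, group, session, vec in _target_vectors(cfg)
    ]
    return Cohort(subjects=subjects, truth=_truth(cfg), n_regions=cfg.n_regions)


def simulate_behavior(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Attach DST and NCT scores coupled to psychomotor-network strength.

    DST rises with strength (``+coupling_beta``); NCT falls with strength
    (negative coupling), so stronger connectivity means a faster, better
    completion time.  The moderated group's slope differs by
    ``moderation_gamma`` (DST) / ``-moderation_gamma`` (NCT).  Strength
    is centered on the base network strength recorded in the truth, so
    the intercepts are the population-mean scores.
    """
    cfg = config.resolved()
    pmn_idx = edgemod.pairs_to_index(cfg.pmn_edges, cfg.n_regions)
    if pmn_idx.size == 0:
        raise ValueError("pmn_edges is empty; behavior coupling is undefined")
    s0 = cohort.truth["base_pmn_strength"]
    counters = {}
    for counter, sid, _group, _sessions in _iter_subject_slots(cfg):
        counters[sid] = counter
    for subj in cohort.subjects:
        if subj.matrix is None:
            raise ValueError("cohort has no matrices; generate connectomes first")
        rng = np.random.default_rng(
            [
                cfg.seed,
                _BEHAVIOR_STREAM + counters[subj.subject_id],
                0 if subj.session == "pre" else 1,
            ]
        )
        strength = float(
            edgemod.vectorize(subj.matrix.z, check=False)[pmn_idx].mean()
        )
        sc = strength - s0
        moderated = float(subj.group == cfg.moderation_group)
        slope = cfg.coupling_beta + cfg.moderation_gamma * moderated
        noise_dst = rng.normal(0.0, cfg.behavior_noise_sd)
        noise_nct = rng.normal(0.0, cfg.behavior_noise_sd)
        subj.dst = cfg.dst_intercept + slope * sc + noise_dst
        subj.nct = cfg.nct_intercept - slope * sc + noise_nct
    return cohort


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Direct-z connectomes plus coupled behavior in one call."""
    return simulate_behavior(simulate_connectomes(config), config)


def _shrink_to_pd(corr: np.ndarray, min_eig: float = 1e-3) -> tuple[np.ndarray, float]:
    """Smallest convex shrinkage toward the identity with eigmin >= min_eig."""
    eig0 = float(np.linalg.eigvalsh(corr).min())
    if eig0 >= min_eig:
        return corr, 0.0
    lam = (min_eig - eig0) / (1.0 - eig0)
    shrunk = (1.0 - lam) * corr + lam * np.eye(corr.shape[0])
    if float(np.linalg.eigvalsh(shrunk).min()) <= 0.0:
        raise ValueError("target correlation not positive definite after shrinkage")
    return shrunk, float(lam)


def simulate_timeseries(config: SimulationConfig) -> Cohort:
    """Time-series cohort: BOLD series whose correlations match the target.

    Each subject-session's target z-matrix (as in direct-z mode) is
    mapped through tanh to a correlation matrix, shrunk toward the
    identity just enough for positive definiteness (factor recorded in
    the truth), and ``timepoints`` samples of a zero-mean multivariate
    normal are drawn.  The empirical Fisher-z connectivity converges to
    the target as the series lengthens.
    """
    cfg = config.resolved()
    if cfg.timepoints < 50:
        raise ValueError("need at least 50 timepoints")
    labels = default_labels(cfg.n_regions)
    subjects = []
    max_lam = 0.0
    counters = {}
    for counter, sid, _group, _sessions in _iter_subject_slots(cfg):
        counters[sid] = counter
    for sid, group, session, vec in _target_vectors(cfg):
        corr = np.tanh(edgemod.matricize(vec, cfg.n_regions))
        np.fill_diagonal(corr, 1.0)
        shrunk, lam = _shrink_to_pd(corr)
        max_lam = max(max_lam, lam)
        chol = np.linalg.cholesky(shrunk)
        rng = np.random.default_rng(
            [cfg.seed, _TIMESERIES_STREAM + counters[sid], 0 if session == "pre" else 1]
        )
        series = rng.standard_normal((cfg.timepoints, cfg.n_regions)) @ chol.T
        subjects.append(
            Subject(
                subject_id=sid,
                group=group,
                session=session,
                timeseries=RoiTimeSeries(series, cfg.sampling_interval, list(labels)),
            )
        )
    truth = _truth(cfg)
    truth["shrinkage_factor_max"] = max_lam
    return Cohort(subjects=subjects, truth=truth, n_regions=cfg.n_regions)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write one TSV per subject-session plus phenotype.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}_{s.session}.tsv"
        if s.matrix is not None:
            header = "\t".join(s.matrix.region_labels)
            np.savetxt(outdir / fname, s.matrix.z, delimiter="\t",
                       header=header, comments="")
        elif s.timeseries is not None:
            header = "\t".join(s.timeseries.region_labels)
            np.savetxt(outdir / fname, s.timeseries.values, delimiter="\t",
                       header=header, comments="")
        else:
            raise ValueError(f"subject {s.subject_id} has no data to write")
        files.append(fname)
    pheno = cohort.phenotype()
    pheno["file"] = files
    pheno.to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(cohort.truth, indent=2))
    return outdir
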