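"""End-to-end orchestration of the whole-brain connectome analysis.

`run_study` replicates the full comparison design on a cohort with three
groups (controls plus two patient groups) and pre/post sessions:

* NBS contrasts — controls vs each patient group before treatment
  (disruption), controls vs each patient group after treatment
  (residual impairment), and post vs pre within each patient group
  (recovery / hyperconnectivity), each with a permutation-corrected p.
* CPM on controls — a positive-tail model for the DST score and a
  negative-tail model for the NCT score, cross-validated; consensus
  edges across folds; their union is the psychomotor network (PMN).
* Post hoc application of the PMN to each patient group and session
  (fixed-network regressions), and a moderated regression testing
  whether the patient subgroup changes the strength-score slope after
  treatment.

Every stage is an ordinary library call; the CLI wraps these functions
without adding behavior.  One root seed fans out to per-stage seeds that
are recorded in the report.
"""

from __future__ import annotations

import logging
from typing import Any

import numpy as np

from . import cpm as cpmmod
from . import edges as edgemod
from . import nbs as nbsmod
from . import stats as statsmod
from .fc import connectivity_matrix, preprocess
from .synthetic import Cohort

logger = logging.getLogger(__name__)

__all__ = ["fc_from_timeseries", "run_nbs_contrast", "run_study", "stage_seed"]


def stage_seed(root_seed: int, stage: int) -> int:
    """Derive a per-stage seed from the root seed (recorded in reports)."""
    return int(np.random.default_rng([root_seed, stage]).integers(0, 2**31 - 1))


def fc_from_timeseries(
    cohort: Cohort,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    discard_volumes: int = 0,
) -> Cohort:
    """Fill in Fisher-z matrices from each subject's ROI time series."""
    for s in cohort.subjects:
        if s.matrix is not None:
            continue
        if s.timeseries is None:
            raise ValueError(f"subject {s.subject_id} has neither series nor matrix")
        ts = preprocess(
            s.timeseries, low_hz=low_hz, high_hz=high_hz, discard_volumes=discard_volumes
        )
        s.matrix = connectivity_matrix(ts)
    return cohort


def _component_json(
    comp: nbsmod.Component, corrected_p: float, labels: list[str]
) -> dict[str, Any]:
    return {
        "size_edges": comp.size,
        "n_nodes": int(comp.nodes.size),
        "corrected_p": float(corrected_p),
        "edges": [
            [labels[int(i)], labels[int(j)]] for i, j in comp.edge_pairs
        ],
    }


def run_nbs_contrast(
    cohort: Cohort,
    group_a,
    session_a: str,
    group_b,
    session_b: str,
    tail: str = "greater",
    primary_p: float = 1e-4,
    n_perm: int = 10_000,
    seed: int | None = None,
    paired: bool = False,
    **kwargs,
) -> nbsmod.NbsResult:
    """NBS between two (group, session) cells of a cohort."""
    a = cohort.edge_matrix(group_a, session_a)
    b = cohort.edge_matrix(group_b, session_b)
    if paired:
        ids_a = [s.subject_id for s in cohort.select(group_a, session_a)]
        ids_b = [s.subject_id for s in cohort.select(group_b, session_b)]
        common = [i for i in ids_a if i in set(ids_b)]
        a = a[[ids_a.index(i) for i in common]]
        b = b[[ids_b.index(i) for i in common]]
    return nbsmod.nbs_test(
        a, b, tail=tail, primary_p=primary_p, n_perm=n_perm, seed=seed,
        paired=paired, n_regions=cohort.n_regions, **kwargs
    )


def run_study(
    cohort: Cohort,
    control_group: str = "HC",
    patient_groups: tuple[str, ...] = ("nonOHE", "OHE"),
    moderation_group: str = "OHE",
    primary_p: float = 1e-4,
    n_perm: int = 1000,
    k: int = 5,
    threshold_p: float = 0.01,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, Any]:
    """Run the full comparison set and return a JSON-ready report."""
    labels = None
    for s in cohort.subjects:
        if s.matrix is not None:
            labels = s.matrix.region_labels
            break
    if labels is None:
        raise ValueError("cohort has no connectivity matrices; run fc first")

    report: dict[str, Any] = {"seed": seed, "stages": {}}

    # ---- NBS contrasts -------------------------------------------------
    nbs_out: dict[str, Any] = {}
    stage = 0
    has_post = any(s.session == "post" for s in cohort.subjects)
    contrasts = []
    for g in patient_groups:
        contrasts.append((f"{control_group}_vs_{g}_pre", control_group, "pre", g, "pre",
                          "greater", False))
        if has_post:
            contrasts.append((f"{control_group}_vs_{g}_post", control_group, "pre",
                              g, "post", "greater", False))
            contrasts.append((f"{g}_post_vs_pre", g, "post", g, "pre", "greater", False))
    for name, ga, sa, gb, sb, tail, paired in contrasts:
        stage += 1
        res = run_nbs_contrast(
            cohort, ga, sa, gb, sb, tail=tail, primary_p=primary_p,
            n_perm=n_perm, seed=stage_seed(seed, stage), paired=paired,
        )
        sig = res.significant(alpha)
        nbs_out[name] = {
            "n_components": len(res.components),
            "significant": [
                _component_json(c, p, labels) for c, p in sig
            ],
            "min_corrected_p": (
                float(res.corrected_p.min()) if res.corrected_p.size else None
            ),
            "seed": stage_seed(seed, stage),
        }
        if not sig:
            nbs_out[name]["summary"] = "no significant components"
    report["stages"]["nbs"] = nbs_out

    # ---- CPM on controls ----------------------------------------------
    hc = cohort.edge_matrix(control_group, "pre")
    dst = cohort.scores("dst", control_group, "pre")
    nct = cohort.scores("nct", control_group, "pre")
    cpm_seed = stage_seed(seed, 100)
    cpm_dst = cpmmod.cpm_crossval(hc, dst, k=k, threshold_p=threshold_p,
                                  tail="positive", seed=cpm_seed)
    cpm_nct = cpmmod.cpm_crossval(hc, nct, k=k, threshold_p=threshold_p,
                                  tail="negative", seed=cpm_seed)
    pmn = cpmmod.combine_networks(
        cpm_dst.consensus_positive, cpm_nct.consensus_negative, cohort.n_regions
    )
    report["stages"]["cpm"] = {
        "seed": cpm_seed,
        "dst_positive": {
            "r_pred_obs": cpm_dst.r_pred_obs,
            "p_pred_obs": cpm_dst.p_pred_obs,
            "fold_average_r": cpm_dst.fold_average_r,
            "n_consensus_edges": int(cpm_dst.consensus_positive.size),
        },
        "nct_negative": {
            "r_pred_obs": cpm_nct.r_pred_obs,
            "p_pred_obs": cpm_nct.p_pred_obs,
            "fold_average_r": cpm_nct.fold_average_r,
            "n_consensus_edges": int(cpm_nct.consensus_negative.size),
        },
        "pmn": {
            "n_edges": pmn.size,
            "n_nodes": int(pmn.nodes.size),
            "edges": [
                {
                    "pair": [labels[int(i)], labels[int(j)]],
                    "provenance": pmn.provenance[int(e)],
                }
                for e, (i, j) in zip(
                    pmn.edge_index,
                    edgemod.index_to_pairs(pmn.edge_index, cohort.n_regions),
                )
            ],
        },
    }

    # ---- post hoc PMN application --------------------------------------
    posthoc: dict[str, Any] = {}
    if pmn.size:
        sessions = ["pre"] + (["post"] if has_post else [])
        for g in patient_groups:
            for sess in sessions:
                subs = cohort.select(g, sess)
                if len(subs) < 3:
                    continue
                x = cohort.edge_matrix(g, sess)
                for score in ("dst", "nct"):
                    try:
                        y = cohort.scores(score, g, sess)
                    except ValueError:
                        continue
                    res = cpmmod.apply_network(x, pmn.edge_index, y)
                    posthoc[f"{g}_{sess}_{score}"] = {
                        "r": res.r, "F": res.F, "df": list(res.df),
                        "p": res.p, "beta": res.beta,
                    }
    report["stages"]["pmn_posthoc"] = posthoc

    # ---- moderated regression on post-treatment patients ---------------
    moderation: dict[str, Any] = {}
    if pmn.size and has_post:
        subs = cohort.select(patient_groups, "post")
        if len(subs) >= 6:
            x = cohort.edge_matrix(patient_groups, "post")
            strength = cpmmod.network_strength(x, pmn.edge_index)
            moderator = np.array(
                [float(s.group == moderation_group) for s in subs]
            )
            if np.unique(moderator).size == 2:
                mod_seed = stage_seed(seed, 200)
                for score in ("dst", "nct"):
                    y = cohort.scores(score, patient_groups, "post")
                    res = statsmod.moderated_regression(
                        y, strength, moderator, n_boot=n_boot, seed=mod_seed
                    )
                    moderation[score] = {
                        "coefficients": res.coefficients,
                        "ci": {k2: list(v) for k2, v in res.ci.items()},
                        "interaction_p": res.interaction_p,
                        "n_boot": res.n_boot,
                        "seed": mod_seed,
                    }
    report["stages"]["moderation"] = moderation
    return report
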