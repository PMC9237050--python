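"""Cohort-level orchestration: generate → preprocess → simulate → summarize.

Runs the full per-subject chain (threshold, homeostatic normalization,
threshold sweep, criticality profile, graph metrics, optional model FC at
the critical point), builds control-average reference curves, Euclidean
distances to them, longitudinal recovery indexes for paired patients, and
behavior correlations.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from neurocrit import synthetic
from neurocrit.connectome import (
    RawConnectome,
    graph_metrics,
    homeostatic_normalize,
    recovery_index,
    threshold_connectome,
)
from neurocrit.dynamics import (
    CriticalityProfile,
    ModelParams,
    profile_distance,
    simulate_sweep,
    simulate_trajectory,
)
from neurocrit.hemodynamics import HRFParams, fc_pearson, fc_summaries, states_to_bold
from neurocrit.synthetic import (
    HealthyCalibration,
    LesionSpec,
    Parcellation,
    contiguous_lesion,
    generate_behavior,
    generate_healthy_connectome,
    generate_parcellation,
    remodel_recovery,
)

logger = logging.getLogger("neurocrit")

CURVES = ("mean_A", "sd_A", "S1", "S2")


@dataclass
class AnalysisConfig:
    """Configuration for a synthetic-cohort end-to-end analysis."""

    n_nodes: int = 324
    n_networks: int = 10
    n_controls: int = 6
    n_patients: int = 6
    seed: int = 0
    calibration: HealthyCalibration = field(default_factory=HealthyCalibration)
    model: ModelParams = field(default_factory=ModelParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    min_streamlines: int = 3
    louvain_restarts: int = 20
    compute_fc: bool = False
    # lesion severity grid: per-patient lesion size and inter-hemispheric scale
    lesion_size_range: tuple[int, int] = (10, 60)
    lesion_scale_range: tuple[float, float] = (0.2, 0.8)
    lesion_dropout_range: tuple[float, float] = (0.05, 0.35)
    recovery_range: tuple[float, float] = (0.4, 0.9)
    rewire_fraction: float = 0.1
    behavior_coefficients: tuple[float, float, float] = (0.0, 1.0, 1.0)
    behavior_noise_sd: float = 0.3
    control_rescan_dropout: float = 0.02

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if "calibration" in raw:
            raw["calibration"] = HealthyCalibration(**raw["calibration"])
        if "model" in raw:
            m = dict(raw["model"])
            if "T_grid" in m:
                m["T_grid"] = np.asarray(m["T_grid"], dtype=float)
            raw["model"] = ModelParams(**m)
        if "hrf" in raw:
            raw["hrf"] = HRFParams(**raw["hrf"])
        for key in ("lesion_size_range", "lesion_scale_range",
                    "lesion_dropout_range", "recovery_range",
                    "behavior_coefficients"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CohortResults:
    per_subject: pd.DataFrame
    reference: dict                      # curve name -> control-average array
    profiles: dict                       # (subject_id, timepoint) -> profile
    recovery: pd.DataFrame
    parcellation: Parcellation
    config: AnalysisConfig

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_subject.to_csv(out / "per_subject.tsv", sep="\t", index=False)
        self.recovery.to_csv(out / "recovery.tsv", sep="\t", index=False)
        ref = pd.DataFrame({"T": self.config.model.T_grid, **self.reference})
        ref.to_csv(out / "reference_curves.tsv", sep="\t", index=False)


def build_cohort(config: AnalysisConfig) -> tuple[Parcellation, list]:
    """Generate the synthetic cohort: controls and lesioned/remodeled patients."""
    rng = np.random.default_rng(config.seed)
    parc = generate_parcellation(
        config.n_nodes, config.n_networks, seed=int(rng.integers(2**31))
    )
    records = []
    for c in range(config.n_controls):
        sid = f"con{c:03d}"
        base_seed = int(rng.integers(2**31))
        t1 = generate_healthy_connectome(
            parc, config.calibration, seed=base_seed, subject_id=sid, timepoint="t1"
        )
        t2 = synthetic.apply_lesion(
            t1,
            LesionSpec(
                edge_dropout=config.control_rescan_dropout,
                seed=int(rng.integers(2**31)),
            ),
        )
        t2 = dataclasses.replace(t2, timepoint="t2")
        records.append(("control", sid, t1, t2))
    for p in range(config.n_patients):
        sid = f"pat{p:03d}"
        base = generate_healthy_connectome(
            parc, config.calibration, seed=int(rng.integers(2**31)),
            subject_id=sid, timepoint="premorbid",
        )
        min_hemi = min(
            int((parc.hemisphere == "L").sum()), int((parc.hemisphere == "R").sum())
        )
        size = int(rng.integers(config.lesion_size_range[0],
                                config.lesion_size_range[1] + 1))
        size = min(size, min_hemi)
        spec = LesionSpec(
            lesioned_nodes=contiguous_lesion(parc, size,
                                             seed=int(rng.integers(2**31))),
            interhemispheric_scale=float(rng.uniform(*config.lesion_scale_range)),
            edge_dropout=float(rng.uniform(*config.lesion_dropout_range)),
            seed=int(rng.integers(2**31)),
        )
        t1 = dataclasses.replace(synthetic.apply_lesion(base, spec), timepoint="t1")
        recov = float(rng.uniform(*config.recovery_range))
        t2 = remodel_recovery(
            t1, base, recovery_fraction=recov,
            rewire_fraction=config.rewire_fraction,
            seed=int(rng.integers(2**31)),
        )
        t2 = dataclasses.replace(t2, timepoint="t2")
        records.append(("patient", sid, t1, t2))
    return parc, records


def _analyze_subject(
    conn: RawConnectome, config: AnalysisConfig, model_seed: int, louvain_seed: int
) -> tuple[CriticalityProfile, dict]:
    thr = threshold_connectome(conn, config.min_streamlines)
    norm = homeostatic_normalize(thr)
    params = dataclasses.replace(config.model, seed=model_seed)
    profile = simulate_sweep(norm, params)
    metrics = graph_metrics(
        norm, louvain_seed=louvain_seed, n_restarts=config.louvain_restarts
    )
    row = {
        "K": metrics.K,
        "Q": metrics.Q,
        "E_global": metrics.E_global,
        "H_SC": metrics.H_SC,
        "T_c": profile.T_c,
        "I1": profile.I1,
        "I2": profile.I2,
        "monotonic_s2": profile.monotonic_s2,
    }
    if config.compute_fc and np.isfinite(profile.T_c):
        params_fc = dataclasses.replace(params, seed=model_seed + 1)
        traj = simulate_trajectory(norm, profile.T_c, params_fc, seed=model_seed + 1)
        bold = states_to_bold(traj[config.model.burn_in:], config.hrf)
        fc = fc_summaries(fc_pearson(bold), conn.parcellation)
        row.update(
            mean_FC=fc.mean_fc, homotopic_FC=fc.homotopic_fc, H_FC=fc.entropy
        )
    return profile, row


def run_cohort_analysis(config: AnalysisConfig) -> CohortResults:
    """Execute the full cohort pipeline; deterministic for a fixed seed."""
    parc, records = build_cohort(config)
    seed_rng = np.random.default_rng(config.seed + 1)
    rows = []
    profiles: dict = {}
    for group, sid, *conns in records:
        for conn in conns:
            t0 = time.time()
            model_seed = int(seed_rng.integers(2**31))
            louvain_seed = int(seed_rng.integers(2**31))
            profile, row = _analyze_subject(conn, config, model_seed, louvain_seed)
            row.update(subject_id=sid, group=group, timepoint=conn.timepoint)
            rows.append(row)
            profiles[(sid, conn.timepoint)] = profile
            logger.info(
                "subject %s %s done in %.1fs", sid, conn.timepoint, time.time() - t0
            )
    df = pd.DataFrame(rows)

    # Control-average reference curves and per-curve Euclidean distances.
    control_keys = [
        (sid, tp) for (sid, tp) in profiles
        if df[(df.subject_id == sid)].iloc[0]["group"] == "control"
    ]
    reference = {
        c: np.mean([profiles[k].curve(c) for k in control_keys], axis=0)
        for c in CURVES
    }
    for curve in CURVES:
        df[f"d_{curve}"] = [
            profile_distance(profiles[(r.subject_id, r.timepoint)],
                             reference[curve], curve)
            for r in df.itertuples()
        ]

    # Synthetic behavior from the criticality integrals, standardized on controls.
    df["B"] = generate_behavior(
        df["I1"].to_numpy(),
        df["I2"].to_numpy(),
        coefficients=config.behavior_coefficients,
        noise_sd=config.behavior_noise_sd,
        seed=config.seed + 2,
        control_mask=(df["group"] == "control").to_numpy(),
    )

    # Longitudinal recovery indexes for subjects with both timepoints.
    rec_rows = []
    for sid, sub in df.groupby("subject_id"):
        t1 = sub[sub.timepoint == "t1"]
        t2 = sub[sub.timepoint == "t2"]
        if len(t1) != 1 or len(t2) != 1:
            logger.warning("subject %s lacks a paired timepoint; skipped", sid)
            continue
        t1, t2 = t1.iloc[0], t2.iloc[0]
        rec_rows.append(
            {
                "subject_id": sid,
                "group": t1["group"],
                **{
                    f"d{m}": recovery_index(t2[m], t1[m])
                    for m in ("K", "H_SC", "E_global", "Q", "I1", "I2")
                    if np.isfinite(t1[m]) and np.isfinite(t2[m])
                },
            }
        )
    recovery = pd.DataFrame(rec_rows)
    return CohortResults(
        per_subject=df,
        reference=reference,
        profiles=profiles,
        recovery=recovery,
        parcellation=parc,
        config=config,
    )


def correlate_outputs(
    results: CohortResults,
    pairs: list[tuple[str, str]],
    group: Optional[str] = None,
    timepoint: Optional[str] = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations (with BH-adjusted p-values) between result columns."""
    df = results.per_subject
    if group is not None:
        df = df[df.group == group]
    if timepoint is not None:
        df = df[df.timepoint == timepoint]
    rows = []
    for x, y in pairs:
        xv = df[x].to_numpy(dtype=float)
        yv = df[y].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        if ok.sum() < 3:
            rows.append({"x": x, "y": y, "rho": np.nan, "r2": np.nan,
                         "p": np.nan, "n": int(ok.sum())})
            continue
        r = stats.pearsonr(xv[ok], yv[ok])
        rows.append({"x": x, "y": y, "rho": float(r.statistic),
                     "r2": float(r.statistic) ** 2, "p": float(r.pvalue),
                     "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = stats.false_discovery_control(
            out.loc[valid, "p"].to_numpy()
        )
    out["significant"] = out["p_adj"] < fdr_alpha
    return out
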