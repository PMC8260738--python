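"""Configuration, dataset I/O and end-to-end pipeline orchestration.

``run_pipeline`` reproduces the analysis tables on a synthetic cohort:
simulate -> train the CRF on the game sessions -> (optionally)
leave-one-subject-out validation -> decode every sleep session ->
stage-wise likelihood aggregation -> band-power and seed-region
correlations -> ROI-level likelihood regression with conjunction ->
memory scoring and reactivation-memory correlation -> repeated-measures
ANOVAs with planned comparisons. All outputs carry the configuration
hash; everything is deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import behavior, crf, decode, stats
from .design import EXCLUDED, LabelSeries, RewardMapping, shift_labels
from .eeg import BandPowerSeries, resample_to_scans
from .simulate import (
    Cohort,
    CohortConfig,
    Hypnogram,
    ROITimeSeries,
    SleepData,
    ReactivationGroundTruth,
    Subject,
    SubjectRecord,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

_GAME_STATE = {"face": "Face", "maze": "Maze"}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects_sleep: int = 13
    n_subjects_game: int = 18
    cohort: CohortConfig = field(default_factory=CohortConfig)
    l2: float = 1e-3
    transitions_uniform: bool = True
    max_iter: int = 500
    label_shift: int = 0
    convolve_regressors: bool = False
    gg_correction: bool = False
    run_loo: bool = False
    wake_t_threshold: float = 3.0
    sleep_t_threshold: float = 2.0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d or {})

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# dataset I/O (plain-text directory tree, one folder per subject)


def save_cohort(cohort: Cohort, root) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cohort.seed,
        "config": cohort.config.to_jsonable(),
        "subjects": [],
    }
    for sub in cohort.subjects:
        d = root / sub.subject_id
        d.mkdir(exist_ok=True)
        sub.game_ts.to_frame().to_csv(d / "game_roits.csv", index=False)
        sub.game_labels.to_csv(d / "game_labels.csv")
        (d / "design.json").write_text(sub.design.to_json())
        if sub.sleep is not None:
            sub.sleep.roits.to_frame().to_csv(d / "sleep_roits.csv", index=False)
            (d / "hypnogram.txt").write_text(sub.sleep.hypnogram.to_text())
            sub.sleep.bandpower.to_frame().to_csv(d / "bandpower.csv", index=False)
            pd.DataFrame(sub.sleep.seed_regions).to_csv(d / "seed_regions.csv", index=False)
            (d / "truth.json").write_text(
                json.dumps(
                    {
                        "event_onsets": sub.sleep.truth.event_onsets.tolist(),
                        "event_state": sub.sleep.truth.event_state,
                        "amplitude": sub.sleep.truth.amplitude,
                        "event_dur_scans": sub.sleep.truth.event_dur_scans,
                        "delta_coupling": sub.sleep.truth.delta_coupling,
                    }
                )
            )
        if sub.record is not None:
            rec = sub.record
            (d / "record.json").write_text(
                json.dumps(
                    {
                        "subject_id": rec.subject_id,
                        "won_game": rec.won_game,
                        "face_truth": rec.face_truth.to_jsonable(),
                        "face_placement": rec.face_placement.to_jsonable()
                        if rec.face_placement
                        else None,
                        "maze_edges": [[list(a), list(b)] for a, b in rec.maze.graph.edges]
                        if rec.maze
                        else None,
                        "maze_goal": list(rec.maze.goal) if rec.maze else None,
                        "maze_final_node": list(rec.maze_final_node)
                        if rec.maze_final_node is not None
                        else None,
                        "memory_coupling": rec.memory_coupling,
                        "reactivation_strength": rec.reactivation_strength,
                    }
                )
            )
        manifest["subjects"].append({"id": sub.subject_id, "won_game": sub.won_game})
    (root / "cohort.json").write_text(json.dumps(manifest, indent=1))


def load_cohort(root) -> Cohort:
    root = Path(root)
    manifest = json.loads((root / "cohort.json").read_text())
    cfg = CohortConfig(**manifest["config"])
    subjects = []
    for entry in manifest["subjects"]:
        d = root / entry["id"]
        from .design import ExperimentDesign

        design = ExperimentDesign.from_json((d / "design.json").read_text())
        game_ts = ROITimeSeries(
            pd.read_csv(d / "game_roits.csv").to_numpy(float), tr=cfg.tr
        )
        game_labels = LabelSeries.from_csv(d / "game_labels.csv", tr=cfg.tr)
        sleep = None
        record = None
        if (d / "sleep_roits.csv").exists():
            hyp = Hypnogram.from_text((d / "hypnogram.txt").read_text())
            truth_d = json.loads((d / "truth.json").read_text())
            truth = ReactivationGroundTruth(
                event_onsets=np.asarray(truth_d["event_onsets"], int),
                event_state=truth_d["event_state"],
                amplitude=truth_d["amplitude"],
                event_dur_scans=truth_d["event_dur_scans"],
                delta_coupling=truth_d["delta_coupling"],
            )
            seeds_df = pd.read_csv(d / "seed_regions.csv")
            sleep = SleepData(
                roits=ROITimeSeries(pd.read_csv(d / "sleep_roits.csv").to_numpy(float), tr=cfg.tr),
                bandpower=BandPowerSeries.from_frame(pd.read_csv(d / "bandpower.csv")),
                truth=truth,
                seed_regions={c: seeds_df[c].to_numpy(float) for c in seeds_df.columns},
                hypnogram=hyp,
            )
        if (d / "record.json").exists():
            rd = json.loads((d / "record.json").read_text())
            maze = None
            if rd["maze_edges"] is not None:
                g = nx.Graph(
                    [(tuple(a), tuple(b)) for a, b in rd["maze_edges"]]
                )
                maze = behavior.MazeGraph(graph=g, goal=tuple(rd["maze_goal"]))
            record = SubjectRecord(
                subject_id=rd["subject_id"],
                won_game=rd["won_game"],
                face_truth=behavior.FaceGrid.from_jsonable(rd["face_truth"]),
                face_placement=behavior.FaceGrid.from_jsonable(rd["face_placement"])
                if rd["face_placement"]
                else None,
                maze=maze,
                maze_final_node=tuple(rd["maze_final_node"])
                if rd["maze_final_node"] is not None
                else None,
                memory_coupling=rd["memory_coupling"],
                reactivation_strength=rd["reactivation_strength"],
            )
        subjects.append(
            Subject(entry["id"], entry["won_game"], design, game_ts, game_labels, sleep, record)
        )
    return Cohort(config=cfg, patterns=None, subjects=subjects, seed=manifest["seed"])


# --------------------------------------------------------------------------
# pipeline stages


def train_cohort_model(cohort: Cohort, config: PipelineConfig) -> crf.CRFModel:
    """Fit the CRF on all subjects' game data (Excluded scans dropped),
    standardizing with the pooled training stats, which are stored on the
    returned model for reuse on sleep data."""
    mean, sd = crf.pooled_stats([s.game_ts.values for s in cohort.subjects])
    dataset = []
    for s in cohort.subjects:
        labels = shift_labels(s.game_labels, config.label_shift)
        keep = labels.labels != EXCLUDED
        feats = crf.featurize(s.game_ts.values[keep], (mean, sd))
        dataset.append((feats, LabelSeries(labels.labels[keep], labels.tr)))
    model = crf.fit_crf(
        dataset,
        transitions_uniform=config.transitions_uniform,
        l2=config.l2,
        max_iter=config.max_iter,
        seed=config.seed,
    )
    model.feature_mean, model.feature_sd = mean, sd
    return model


def subject_sleep_analysis(
    sub: Subject, model: crf.CRFModel, config: PipelineConfig
) -> dict:
    """Decode one subject's sleep and compute all per-subject tables."""
    mapping = RewardMapping(won_game=sub.won_game)
    lik = decode.decode_sleep(model, sub.sleep.roits)
    tr = sub.sleep.roits.tr
    stage_tab = decode.stage_mean_likelihood(lik, sub.sleep.hypnogram, mapping, tr)
    bp = resample_to_scans(sub.sleep.bandpower, tr, sub.sleep.roits.n_scans)
    band_corr = decode.likelihood_band_correlation(lik, bp, mapping)
    seed_corr = {
        name: decode.roi_state_correlation(series, lik, mapping)
        for name, series in sub.sleep.seed_regions.items()
    }

    won_state = _GAME_STATE[sub.won_game]
    sleep_reg = decode.likelihood_regression(
        sub.sleep.roits, lik, contrast=(won_state, "Rest"),
        convolve_hrf=config.convolve_regressors,
    )
    wake_lik = decode.decode_sleep(model, sub.game_ts)
    wake_reg = decode.likelihood_regression(
        sub.game_ts, wake_lik, contrast=(won_state, "Rest"),
        convolve_hrf=config.convolve_regressors,
    )
    wake_net = set(wake_reg.index[wake_reg["t"] > config.wake_t_threshold])
    sleep_net = set(sleep_reg.index[sleep_reg["t"] > config.sleep_t_threshold])
    conj = decode.conjunction(wake_net, sleep_net)
    # per-subject reactivation measure: mean N3 activity of the wake-defined
    # task network (the wake network is always nonempty at the generator's
    # SNR; the conjunction set is reported but can be empty when
    # reactivation is weak or absent)
    stages = sub.sleep.scan_stages()
    n3 = stages == "N3"
    if wake_net and n3.any():
        idx = [sub.sleep.roits.roi_names.index(r) for r in sorted(wake_net)]
        net_beta = float(sub.sleep.roits.values[np.ix_(n3, idx)].mean())
    else:
        net_beta = np.nan
    return {
        "likelihoods": lik,
        "stage_table": stage_tab,
        "band_corr": band_corr,
        "seed_corr": seed_corr,
        "wake_network": wake_net,
        "conjunction": conj,
        "network_beta": net_beta,
    }


def memory_analysis(cohort: Cohort, network_betas: dict[str, float]):
    """Score the delayed memory tests and correlate with reactivation."""
    rows = []
    for sub in cohort.subjects:
        rec = sub.record
        face = behavior.face_memory_score(rec.face_truth, rec.face_placement)
        maze_d = behavior.maze_memory_distance(rec.maze, rec.maze_final_node)
        rows.append(
            {
                "subject": sub.subject_id,
                "won_game": sub.won_game,
                "face_score": face,
                "maze_distance": maze_d,
                "network_beta": network_betas[sub.subject_id],
                "true_strength": rec.reactivation_strength,
            }
        )
    df = pd.DataFrame(rows)
    face_z, maze_z = behavior.zscore_memory(df["face_score"], df["maze_distance"])
    df["face_z"], df["maze_z"] = face_z, maze_z
    df["memory_z"] = (face_z + maze_z) / 2
    rho, p = behavior.reactivation_memory_correlation(df["network_beta"], df["memory_z"])
    return df, {"rho": rho, "p": p}


def cohort_stage_long(per_subject: dict[str, dict]) -> pd.DataFrame:
    """Tidy (subject, stage, state, value) table of stage-mean likelihoods."""
    rows = []
    for sid, res in per_subject.items():
        tab = res["stage_table"]
        for stage in tab.means.index:
            if tab.n_scans[stage] == 0:
                continue
            for state in tab.means.columns:
                rows.append(
                    {"subject": sid, "stage": stage, "state": state,
                     "value": tab.means.loc[stage, state]}
                )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full analysis on a synthetic cohort; optionally write the
    result bundle under ``outdir``. Returns the in-memory results."""
    t0 = time.time()
    results: dict = {"config_hash": config.hash}

    cohort = simulate_cohort(config.n_subjects_sleep, config.cohort, seed=config.seed)
    logger.info("simulated %d-subject cohort in %.1fs", len(cohort), time.time() - t0)

    if config.run_loo:
        subject_data = [(s.game_ts.values, s.game_labels) for s in cohort.subjects]
        cm, acc = crf.cross_validate(
            subject_data, transitions_uniform=config.transitions_uniform,
            l2=config.l2, max_iter=config.max_iter, seed=config.seed,
        )
        results["confusion"] = cm
        results["loo_accuracy"] = acc
        logger.info("LOO accuracy: %s", {k: round(v, 3) for k, v in acc.items()})

    model = train_cohort_model(cohort, config)
    results["model"] = model

    per_subject: dict[str, dict] = {}
    for sub in cohort.subjects:
        per_subject[sub.subject_id] = subject_sleep_analysis(sub, model, config)
    results["per_subject"] = per_subject

    stage_long = cohort_stage_long(per_subject)
    results["stage_long"] = stage_long
    complete = stage_long.groupby("subject")["stage"].nunique() == 4
    ok_subjects = complete[complete].index
    anova_df = stage_long[stage_long["subject"].isin(ok_subjects)]
    results["anova_state_stage"] = stats.rm_anova(
        anova_df, within=["state", "stage"], gg_correction=config.gg_correction
    )
    contrasts = {}
    for stage in ("W", "N1", "N2", "N3"):
        F, df2, p = stats.planned_comparison(
            anova_df, factor="state", levels=("Reward", "NoReward"), at={"stage": stage}
        )
        contrasts[stage] = {"F": F, "df2": df2, "p": p}
    results["reward_contrasts"] = contrasts

    band_long = pd.concat(
        [res["band_corr"].assign(subject=sid) for sid, res in per_subject.items()],
        ignore_index=True,
    )
    results["band_long"] = band_long
    results["anova_state_band"] = stats.rm_anova(
        band_long.rename(columns={"fisher_z": "value"}), within=["state", "band"]
    )

    seed_rows = []
    for sid, res in per_subject.items():
        for region, series in res["seed_corr"].items():
            for state, rho in series.items():
                seed_rows.append({"subject": sid, "region": region, "state": state, "value": rho})
    seed_long = pd.DataFrame(seed_rows)
    results["seed_long"] = seed_long
    results["anova_seed"] = {
        region: stats.rm_anova(seed_long[seed_long["region"] == region], within=["state"])
        for region in seed_long["region"].unique()
    }

    net_betas = {sid: res["network_beta"] for sid, res in per_subject.items()}
    memory_df, memory_corr = memory_analysis(cohort, net_betas)
    results["memory"] = memory_df
    results["memory_correlation"] = memory_corr

    results["runtime_s"] = time.time() - t0
    if outdir is not None:
        write_bundle(results, config, outdir)
    return results


def write_bundle(results: dict, config: PipelineConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash
    files = {}

    def save(df: pd.DataFrame, name: str, **kw):
        p = out / name
        df.to_csv(p, index=kw.pop("index", False))
        files[name] = h

    save(results["stage_long"], "stage_state_means.csv")
    save(results["band_long"], "band_fisher_z.csv")
    save(results["seed_long"], "seed_state_rho.csv")
    save(results["memory"], "memory.csv")
    save(results["anova_state_stage"].table, "anova_state_stage.csv")
    save(results["anova_state_band"].table, "anova_state_band.csv")
    for region, res in results["anova_seed"].items():
        save(res.table, f"anova_seed_{region}.csv")
    if "confusion" in results:
        save(results["confusion"].to_frame(), "confusion.csv", index=True)
    (out / "model.json").write_text(results["model"].to_json())
    summary = {
        "config_hash": h,
        "config": config.to_jsonable(),
        "reward_contrasts": results["reward_contrasts"],
        "memory_correlation": results["memory_correlation"],
        "loo_accuracy": results.get("loo_accuracy"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    (out / "manifest.json").write_text(
        json.dumps({"config_hash": h, "files": sorted(files)}, indent=1)
    )
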