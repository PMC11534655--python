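"""End-to-end orchestration: simulate -> analyze -> profile -> stats.

`simulate_study` draws a paired pre/post cohort of participants, each with
full signal-level data (ten IMTP trials and five sprints per session);
`run_pipeline` turns a study — in memory or loaded from manifests — into a
results bundle: per-trial IMTP metrics, per-session cycling metrics, a
pre/post summary table and a change-score correlation matrix. Every output
embeds the run configuration for provenance, and the whole chain is
deterministic given the seed.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import cycling, imtp, io, reference, stats, synthetic
from .types import (
    EXPLOSIVE_1S,
    MAX_5S,
    SprintSession,
    ValidationError,
)

IMTP_METRICS = ("imtp_pf", "rfd_0_100", "rfd_0_200", "rfd_avg", "rfd_peak")
CYCLING_METRICS = (
    "ppo_w",
    "ppo_per_bm",
    "rpm_peak",
    "t_peak_nm",
    "rtd_0_100",
    "rtd_0_200",
    "rtd_avg",
    "rtd_peak",
    "t0_nm",
    "pmax_w",
    "rpmmax_rpm",
    "rpmopt_rpm",
)

DEFAULT_PREDICTORS = (
    "t_peak_nm",
    "t0_nm",
    "rtd_0_100",
    "rtd_0_200",
    "rtd_avg",
    "rtd_peak",
    "imtp_pf",
    "rfd_0_100",
    "rfd_0_200",
    "rfd_avg",
    "rfd_peak",
)
DEFAULT_OUTCOMES = ("ppo_w", "pmax_w")


@dataclass
class RunConfig:
    """Analysis parameters, serialised alongside every output for provenance."""

    k_sd: float = 3.0
    extremum_lookback_s: float = 0.05
    rfd_window_ms: float = 20.0
    n_best: int = 3
    pct_change_convention: str = stats.RATIO_OF_MEANS
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.k_sd <= 0:
            raise ValidationError("k_sd: must be positive")
        if not (0 < self.extremum_lookback_s <= 0.5):
            raise ValidationError("extremum_lookback_s: must lie in (0, 0.5] s")
        if not (1 <= self.rfd_window_ms <= 500):
            raise ValidationError("rfd_window_ms: must lie in [1, 500] ms")
        if self.n_best < 1:
            raise ValidationError("n_best: must be >= 1")
        if self.pct_change_convention not in (
            stats.RATIO_OF_MEANS,
            stats.MEAN_OF_RATIOS,
        ):
            raise ValidationError("pct_change_convention: unknown convention")
        if not (0 < self.ci_level < 1):
            raise ValidationError("ci_level: must lie in (0, 1)")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SessionData:
    """Signal-level data for one participant-timepoint."""

    participant: str
    timepoint: str
    imtp_trials: list
    sprint: SprintSession


@dataclass
class StudyData:
    """A full pre/post study: one SessionData per participant-timepoint."""

    sessions: List[SessionData]

    def participants(self) -> List[str]:
        return sorted({s.participant for s in self.sessions})


#: multiplicative training effects applied at post, mirroring the modelled
#: study's group-level changes (net peak force +13.1%, T0 +10.2%,
#: RPMmax +0.8%, rise steepness +25% standing in for the RFD family).
DEFAULT_TRAINING_EFFECTS = {
    "pf": 0.131,
    "rise_rate": 0.25,
    "t0": 0.102,
    "rpmmax": 0.008,
}


def simulate_study(
    n_participants: int = 14,
    seed: int = 0,
    n_explosive: int = 5,
    n_max: int = 5,
    noise_sd: float = 20.0,
    torque_noise_sd: float = 5.0,
    effects: Optional[Dict[str, float]] = None,
    effect_sd: float = 0.05,
) -> StudyData:
    """Simulate a paired pre/post cohort with signal-level data.

    Participant abilities are drawn from the modelled population (net peak
    force 1811.7 ± 573.6 N, T0 165.2 ± 25.0 Nm, RPMmax 232.2 ± 19.4 rpm,
    body mass 76.8 kg); each participant's post session applies the group
    training effects plus participant-level variation of SD ``effect_sd``.
    """

    effects = dict(DEFAULT_TRAINING_EFFECTS, **(effects or {}))
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    trial_seeds = iter(root.generate_state(10 * n_participants * (n_explosive + n_max)))

    sessions = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        mass = float(np.clip(rng.normal(reference.MEAN_BODY_MASS_KG, 11.0), 50, 110))
        pf = float(np.clip(rng.normal(1811.7, 573.6), 600, None))
        rise = float(np.clip(rng.normal(60.0, 8.0), 35, None))
        t0 = float(np.clip(rng.normal(reference.PRE_T0_NM, 25.0), 1.6 * 0.6 * mass, None))
        rpmmax = float(np.clip(rng.normal(reference.PRE_RPMMAX_RPM, 19.4), 170, None))
        baseline = mass * 9.81

        ability = {"pf": pf, "rise_rate": rise, "t0": t0, "rpmmax": rpmmax}
        for tp in ("pre", "post"):
            if tp == "post":
                ability = {
                    k: v * (1.0 + float(rng.normal(effects[k], effect_sd)))
                    for k, v in ability.items()
                }
            trials = []
            for _ in range(n_explosive):
                gt = synthetic.IMTPGroundTruth(
                    baseline_force=baseline,
                    pf_true=ability["pf"],
                    rise_rate=ability["rise_rate"],
                    noise_sd=noise_sd,
                )
                trials.append(
                    synthetic.generate_imtp_trial(gt, int(next(trial_seeds) % 2**31))
                )
            for _ in range(n_max):
                gt = synthetic.IMTPGroundTruth.max_5s(
                    baseline_force=baseline,
                    pf_true=ability["pf"],
                    rise_rate=ability["rise_rate"] / 2.0,
                    noise_sd=noise_sd,
                )
                trials.append(
                    synthetic.generate_imtp_trial(gt, int(next(trial_seeds) % 2**31))
                )
            cgt = synthetic.CyclingGroundTruth(
                t0_true=ability["t0"],
                rpmmax_true=ability["rpmmax"],
                torque_noise_sd=torque_noise_sd,
                body_mass_kg=mass,
            )
            sprint = synthetic.generate_sprint_session(
                cgt, int(next(trial_seeds) % 2**31)
            )
            sprint.participant, sprint.timepoint = pid, tp
            sessions.append(
                SessionData(
                    participant=pid, timepoint=tp, imtp_trials=trials, sprint=sprint
                )
            )
    return StudyData(sessions=sessions)


def analyze_session(data: SessionData, config: RunConfig):
    """IMTP + cycling metrics for one session.

    Returns ``(metrics, per_trial)``: a flat metric dict (net PF from the
    best three 5-s trials, the RFD family from the best three 1-s trials,
    plus the full cycling summary) and a per-trial metrics frame.
    """

    per_trial_rows = []
    by_type = {EXPLOSIVE_1S: [], MAX_5S: []}
    for k, trial in enumerate(data.imtp_trials):
        m = imtp.analyze_imtp_trial(
            trial,
            k_sd=config.k_sd,
            extremum_lookback_s=config.extremum_lookback_s,
            rfd_window_ms=config.rfd_window_ms,
        )
        by_type[trial.trial_type].append(m)
        per_trial_rows.append(
            {
                "participant": data.participant,
                "timepoint": data.timepoint,
                "trial": k + 1,
                "trial_type": trial.trial_type,
                **m.as_dict(),
            }
        )

    metrics = {}
    if by_type[MAX_5S]:
        agg = imtp.aggregate_best_trials(by_type[MAX_5S], MAX_5S, config.n_best)
        metrics["imtp_pf"] = agg.peak_force_n
    if by_type[EXPLOSIVE_1S]:
        agg = imtp.aggregate_best_trials(
            by_type[EXPLOSIVE_1S], EXPLOSIVE_1S, config.n_best
        )
        metrics.update(
            rfd_0_100=agg.rfd_0_100,
            rfd_0_200=agg.rfd_0_200,
            rfd_avg=agg.rfd_avg,
            rfd_peak=agg.rfd_peak,
        )

    cyc = cycling.profile_session(
        data.sprint,
        expected_conditions=synthetic.DEFAULT_CONDITIONS,
        k_sd=config.k_sd,
        rtd_window_ms=config.rfd_window_ms,
    )
    metrics.update({k: v for k, v in cyc.as_dict().items() if k in CYCLING_METRICS})
    return metrics, pd.DataFrame(per_trial_rows)


@dataclass
class ResultsBundle:
    """Everything one pipeline run produces, with the config embedded."""

    config: dict
    per_trial: pd.DataFrame
    session_metrics: pd.DataFrame  # tidy: participant, timepoint, metric, value
    summary: pd.DataFrame
    correlations: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "per_trial": self.per_trial.to_dict(orient="records"),
            "session_metrics": self.session_metrics.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, allow_nan=True)

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.per_trial.to_csv(os.path.join(out_dir, "imtp_per_trial.csv"), index=False)
        self.session_metrics.to_csv(
            os.path.join(out_dir, "session_metrics.csv"), index=False
        )
        self.summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
        self.correlations.to_csv(
            os.path.join(out_dir, "change_correlations.csv"), index=False
        )
        with open(os.path.join(out_dir, "run_config.json"), "w") as fh:
            json.dump(self.config, fh, indent=2, sort_keys=True)


def run_pipeline(
    study: StudyData,
    config: Optional[RunConfig] = None,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    outcomes: Sequence[str] = DEFAULT_OUTCOMES,
) -> ResultsBundle:
    """Analyze every session of a study and assemble cohort statistics.

    Cohort stages (summary table, change correlations) require at least
    two participants with both timepoints; partial cohorts degrade to
    per-session metrics with a warning.
    """

    config = config or RunConfig()
    if not study.sessions:
        raise ValidationError("study contains no sessions")

    tidy_rows, per_trial_frames = [], []
    for data in sorted(study.sessions, key=lambda s: (s.participant, s.timepoint)):
        metrics, per_trial = analyze_session(data, config)
        per_trial_frames.append(per_trial)
        for name, value in metrics.items():
            tidy_rows.append(
                {
                    "participant": data.participant,
                    "timepoint": data.timepoint,
                    "metric": name,
                    "value": value,
                }
            )
    session_metrics = pd.DataFrame(tidy_rows)
    per_trial = pd.concat(per_trial_frames, ignore_index=True)

    counts = session_metrics.groupby("participant")["timepoint"].nunique()
    paired = counts[counts == 2]
    if len(paired) >= 2:
        summary = stats.build_summary_table(
            session_metrics,
            pct_change_convention=config.pct_change_convention,
            level=config.ci_level,
        )
        avail = set(session_metrics["metric"])
        if len(paired) >= 3:
            correlations = stats.change_correlation_matrix(
                session_metrics,
                predictors=[p for p in predictors if p in avail],
                outcomes=[o for o in outcomes if o in avail],
            )
        else:
            warnings.warn(
                "fewer than 3 paired participants; skipping change correlations",
                stacklevel=2,
            )
            correlations = pd.DataFrame()
    else:
        warnings.warn(
            "fewer than 2 participants with both timepoints; skipping cohort stats",
            stacklevel=2,
        )
        summary = pd.DataFrame()
        correlations = pd.DataFrame()

    return ResultsBundle(
        config=config.as_dict(),
        per_trial=per_trial,
        session_metrics=session_metrics,
        summary=summary,
        correlations=correlations,
    )


def load_study(manifest_paths: Sequence[str], base_dir=".") -> StudyData:
    """Build a StudyData from session manifests on disk."""
    if not manifest_paths:
        raise ValidationError("no manifests given")
    sessions = []
    for path in manifest_paths:
        manifest = io.read_manifest(path)
        trials, sprint = io.load_session(manifest, base_dir=base_dir)
        sessions.append(
            SessionData(
                participant=manifest["participant"],
                timepoint=manifest["timepoint"],
                imtp_trials=trials,
                sprint=sprint,
            )
        )
    return StudyData(sessions=sessions)


def write_study(study: StudyData, out_dir) -> List[str]:
    """Write a study to disk as CSVs plus one manifest per session.

    Returns the manifest paths; ``load_study`` on them reproduces the
    study (bit-exact floats).
    """

    os.makedirs(out_dir, exist_ok=True)
    manifest_paths = []
    for data in study.sessions:
        tag = f"{data.participant}_{data.timepoint}"
        imtp_entries = []
        for k, trial in enumerate(data.imtp_trials):
            rel = f"{tag}_imtp{k + 1}.csv"
            io.write_force_trial(trial, os.path.join(out_dir, rel))
            imtp_entries.append(
                {
                    "path": rel,
                    "trial_type": trial.trial_type,
                    "baseline_window_s": list(trial.baseline_window_s),
                }
            )
        sprint_entries = []
        for tr in data.sprint.trials:
            stem = f"{tag}_{tr.start_type}_{tr.resistance_nm_per_kg:.1f}"
            strokes_rel = f"{stem}_strokes.csv"
            io.write_strokes(tr.strokes, os.path.join(out_dir, strokes_rel))
            entry = {
                "start_type": tr.start_type,
                "resistance_nm_per_kg": tr.resistance_nm_per_kg,
                "strokes_path": strokes_rel,
            }
            if tr.trace is not None:
                trace_rel = f"{stem}_trace.csv"
                io.write_torque_trace(tr.trace, os.path.join(out_dir, trace_rel))
                entry["trace_path"] = trace_rel
            sprint_entries.append(entry)
        manifest = {
            "participant": data.participant,
            "timepoint": data.timepoint,
            "body_mass_kg": data.sprint.body_mass_kg,
            "imtp_trials": imtp_entries,
            "sprints": sprint_entries,
        }
        mpath = os.path.join(out_dir, f"{tag}_manifest.json")
        io.write_manifest(manifest, mpath)
        manifest_paths.append(mpath)
    return manifest_paths
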