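"""Synthetic EEG-fMRI cohorts with known reactivation ground truth.

The generator emulates the statistical structure the decoding analysis
assumes, at the study's nominal dimensions: a two-run game session
(8 x 60-s face blocks, 8 x 60-s maze blocks, 3-s pre-cues, 90-s rests,
TR = 2.1 s) producing 58-ROI BOLD-like time courses with state-specific
activation patterns, HRF-convolved boxcars and AR(1) Gaussian noise; a
sleep session with a Markov-chain hypnogram (20-s epochs) containing
sustained N3; Poisson reactivation events during N3 that re-inject the
Reward game's activation pattern; six log band-power series with
stage-dependent levels and a low-delta elevation coupled to the events;
hippocampus/VTA seed channels with event-locked gain; and delayed memory
scores whose expectation increases with reactivation strength.

Everything is deterministic under a master seed; per-subject and per-stage
randomness is drawn from named substreams of that seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt
from scipy.stats import gamma as _gamma

from . import behavior
from .design import (
    STATES,
    ExperimentDesign,
    LabelSeries,
    build_game_schedule,
    labels_from_schedule,
)

SLEEP_STAGES = ("W", "N1", "N2", "N3")
EPOCH_LEN = 20.0

_GAME_STATE = {"face": "Face", "maze": "Maze"}


class GenerationError(RuntimeError):
    pass


def _child_seed(seed: int, *tags: int) -> int:
    """Reproducible substream seed, kept below 2**31."""
    ss = np.random.SeedSequence([int(seed)] + [int(t) for t in tags])
    return int(ss.generate_state(1)[0] % (2**31))


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6),
    sampled at the TR and normalized to unit sum so that a sustained block
    plateaus at the pattern amplitude."""
    t = np.arange(0.0, duration + tr / 2, tr)
    h = _gamma.pdf(t, a=6.0) - _gamma.pdf(t, a=16.0) / 6.0
    return h / h.sum()


@dataclass
class ROITimeSeries:
    """Scans x ROIs matrix of BOLD-like signal."""

    values: np.ndarray
    tr: float
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.roi_names:
            self.roi_names = [f"roi{i:02d}" for i in range(self.values.shape[1])]

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.roi_names)


@dataclass
class StatePatterns:
    """S x N matrix of per-state ROI activation amplitudes (Rest row = 0)."""

    weights: np.ndarray
    states: tuple[str, ...] = STATES

    def row(self, state: str) -> np.ndarray:
        return self.weights[self.states.index(state)]


def default_patterns(
    n_rois: int = 58,
    game_amp: float = 1.0,
    pre_amp: float = 0.25,
    seed: int = 0,
) -> StatePatterns:
    """Random non-collinear game patterns; faint pre-cue patterns; Rest = 0.

    The pre-cue screens are visually minimal, so their patterns are given a
    small amplitude — the trained classifier then confuses them with Rest,
    as observed for the real data.
    """
    rng = np.random.default_rng(seed)
    w = np.zeros((len(STATES), n_rois))
    unit = lambda v: v / np.linalg.norm(v) * math.sqrt(n_rois)
    w[STATES.index("Face")] = game_amp * unit(rng.normal(size=n_rois))
    w[STATES.index("Maze")] = game_amp * unit(rng.normal(size=n_rois))
    w[STATES.index("PreFace")] = pre_amp * unit(rng.normal(size=n_rois))
    w[STATES.index("PreMaze")] = pre_amp * unit(rng.normal(size=n_rois))
    return StatePatterns(weights=w)


def _ar1_noise(rng: np.random.Generator, shape, noise_sd: float, ar1: float) -> np.ndarray:
    if noise_sd == 0:
        return np.zeros(shape)
    eps = rng.normal(0.0, noise_sd * math.sqrt(1.0 - ar1**2), size=shape)
    return lfilter([1.0], [1.0, -ar1], eps, axis=0)


def state_boxcars(design: ExperimentDesign, n_scans: int | None = None) -> np.ndarray:
    """T x S occupancy indicators at scan onsets (win block keeps its game
    state: the signal is real even though the label is Excluded)."""
    if n_scans is None:
        n_scans = design.n_scans
    onsets = np.arange(n_scans) * design.tr
    ind = np.zeros((n_scans, len(STATES)))
    for b in design.blocks:
        sel = (onsets >= b.onset - 1e-9) & (onsets < b.end - 1e-9)
        ind[sel, STATES.index(b.state)] = 1.0
    return ind


def simulate_game_session(
    design: ExperimentDesign,
    patterns: StatePatterns,
    noise_sd: float = 1.0,
    ar1: float = 0.3,
    seed: int = 0,
) -> tuple[ROITimeSeries, LabelSeries]:
    """BOLD-like game-session data: HRF-convolved state boxcars times the
    activation patterns, plus AR(1) Gaussian noise per ROI."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n_scans = design.n_scans
    ind = state_boxcars(design, n_scans)
    h = canonical_hrf(design.tr)
    conv = np.column_stack([np.convolve(ind[:, s], h)[:n_scans] for s in range(ind.shape[1])])
    signal = conv @ patterns.weights
    rng = np.random.default_rng(seed)
    noise = _ar1_noise(rng, signal.shape, noise_sd, ar1)
    ts = ROITimeSeries(values=signal + noise, tr=design.tr)
    return ts, labels_from_schedule(design, n_scans)


@dataclass
class Hypnogram:
    """Scored sleep stages, one per 20-s epoch."""

    epochs: np.ndarray      # array of stage codes in SLEEP_STAGES
    epoch_len: float = EPOCH_LEN

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=object)
        if len(self.epochs) == 0:
            raise ValueError("hypnogram must be nonempty")

    @property
    def total_seconds(self) -> float:
        return len(self.epochs) * self.epoch_len

    def stage_at(self, t: float) -> str:
        idx = int(t // self.epoch_len)
        if t < 0 or idx >= len(self.epochs):
            raise ValueError(f"time {t} s beyond hypnogram end ({self.total_seconds} s)")
        return self.epochs[idx]

    def minutes_in(self, stage: str) -> float:
        return float(np.sum(self.epochs == stage)) * self.epoch_len / 60.0

    def to_text(self) -> str:
        return "\n".join(self.epochs) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Hypnogram":
        return cls(epochs=np.array([l.strip() for l in text.strip().splitlines()], dtype=object))


def default_stage_chain() -> np.ndarray:
    """Epoch-to-epoch stage transition matrix (rows: W, N1, N2, N3).

    Tuned so a ~1-h record descends through N1/N2 into sustained N3 within
    10-15 min, with occasional returns to lighter sleep.
    """
    return np.array(
        [
            [0.90, 0.10, 0.00, 0.00],
            [0.05, 0.80, 0.15, 0.00],
            [0.01, 0.04, 0.90, 0.05],
            [0.00, 0.01, 0.06, 0.93],
        ]
    )


def simulate_hypnogram(
    total_min: float = 60.0,
    stage_chain: np.ndarray | None = None,
    min_n3_min: float = 10.0,
    seed: int = 0,
    start_stage: str = "W",
    require_all_stages: bool = True,
    max_retries: int = 100,
) -> Hypnogram:
    """Markov-sampled hypnogram, resampled until cumulative N3 time (and,
    by default, presence of every stage) is reached."""
    chain = default_stage_chain() if stage_chain is None else np.asarray(stage_chain, float)
    if chain.shape != (4, 4) or not np.allclose(chain.sum(axis=1), 1.0):
        raise ValueError("stage_chain must be 4x4 with rows summing to 1")
    n_epochs = int(round(total_min * 60.0 / EPOCH_LEN))
    start = SLEEP_STAGES.index(start_stage)
    for attempt in range(max_retries):
        rng = np.random.default_rng(_child_seed(seed, attempt))
        idx = np.empty(n_epochs, dtype=int)
        idx[0] = start
        for e in range(1, n_epochs):
            idx[e] = rng.choice(4, p=chain[idx[e - 1]])
        epochs = np.array([SLEEP_STAGES[i] for i in idx], dtype=object)
        hyp = Hypnogram(epochs=epochs)
        if hyp.minutes_in("N3") < min_n3_min:
            continue
        if require_all_stages and not all(s in epochs for s in SLEEP_STAGES):
            continue
        return hyp
    raise GenerationError(
        f"no hypnogram with >= {min_n3_min} min N3 in {max_retries} attempts"
    )


@dataclass
class ReactivationGroundTruth:
    """Injected-event bookkeeping for recovery tests."""

    event_onsets: np.ndarray        # scan indices of event starts
    event_state: str                # the Reward game's state label
    amplitude: float
    event_dur_scans: int
    delta_coupling: float

    @property
    def n_events(self) -> int:
        return len(self.event_onsets)


#: log10 band-power baselines per sleep stage (band x stage), loosely shaped
#: like real spectra: delta rises toward N3, alpha/beta dominate wake,
#: sigma (spindles) peaks in N2.
_BAND_BASE = {
    "low_delta": {"W": 0.0, "N1": 0.3, "N2": 0.8, "N3": 1.3},
    "high_delta": {"W": 0.1, "N1": 0.3, "N2": 0.6, "N3": 0.9},
    "theta": {"W": 0.2, "N1": 0.4, "N2": 0.5, "N3": 0.5},
    "alpha": {"W": 0.8, "N1": 0.5, "N2": 0.3, "N3": 0.2},
    "sigma": {"W": 0.2, "N1": 0.3, "N2": 0.7, "N3": 0.4},
    "beta": {"W": 0.7, "N1": 0.4, "N2": 0.2, "N3": 0.1},
}


@dataclass
class SleepData:
    roits: ROITimeSeries
    bandpower: "object"             # eeg.BandPowerSeries
    truth: ReactivationGroundTruth
    seed_regions: dict[str, np.ndarray]
    hypnogram: Hypnogram

    def scan_stages(self) -> np.ndarray:
        onsets = np.arange(self.roits.n_scans) * self.roits.tr
        return np.array([self.hypnogram.stage_at(t) for t in onsets], dtype=object)


def simulate_sleep_session(
    hyp: Hypnogram,
    patterns: StatePatterns,
    reward_state: str = "Face",
    react_amp: float = 1.0,
    event_rate_per_min_n3: float = 3.0,
    event_dur_scans: int = 3,
    delta_coupling: float = 1.0,
    noise_sd: float = 1.0,
    ar1: float = 0.3,
    tr: float = 2.1,
    seed: int = 0,
    hippo_gain: float = 1.0,
    vta_gain: float = 0.7,
) -> SleepData:
    """Sleep-session data with Reward-pattern reactivation events in N3.

    Events start independently at each N3 scan with probability
    rate x TR / 60, last ``event_dur_scans`` scans, and are convolved with
    the canonical HRF before multiplying the Reward game's ROI pattern.
    The low-delta log-power series is elevated in N3 by its stage baseline
    and further elevated around events in proportion to ``delta_coupling``;
    hippocampus and VTA channels receive the event response with their own
    gains.
    """
    from .eeg import BAND_NAMES, BandPowerSeries

    if react_amp < 0:
        raise ValueError("react_amp must be nonnegative")
    total_s = hyp.total_seconds
    n_scans = int(math.ceil(total_s / tr - 1e-9))
    onsets = np.arange(n_scans) * tr
    stages = np.array([hyp.stage_at(t) for t in onsets], dtype=object)
    n3 = np.flatnonzero(stages == "N3")

    rng_ev = np.random.default_rng(_child_seed(seed, 1))
    p_event = min(1.0, event_rate_per_min_n3 * tr / 60.0)
    starts = n3[rng_ev.random(len(n3)) < p_event] if (react_amp > 0 and len(n3)) else np.array([], int)

    u = np.zeros(n_scans)
    for s in starts:
        u[s : s + event_dur_scans] += react_amp
    h = canonical_hrf(tr)
    resp = np.convolve(u, h)[:n_scans]

    rng_bold = np.random.default_rng(_child_seed(seed, 2))
    ridx = list(patterns.states).index(reward_state)
    values = np.outer(resp, patterns.weights[ridx]) + _ar1_noise(
        rng_bold, (n_scans, patterns.weights.shape[1]), noise_sd, ar1
    )
    roits = ROITimeSeries(values=values, tr=tr)

    # band power on the 2-s Welch epoch grid
    bp_times = np.arange(2.0, total_s - 2.0 + 1e-9, 2.0)
    bp_stages = np.array([hyp.stage_at(t) for t in bp_times], dtype=object)
    rng_bp = np.random.default_rng(_child_seed(seed, 3))
    cols = []
    resp_on_grid = np.interp(bp_times, onsets, resp)
    for band in BAND_NAMES:
        base = np.array([_BAND_BASE[band][s] for s in bp_stages])
        noise = _ar1_noise(rng_bp, (len(bp_times),), 0.15, 0.5)
        col = base + noise
        if band == "low_delta":
            col = col + delta_coupling * resp_on_grid
        cols.append(col)
    bandpower = BandPowerSeries(epoch_times=bp_times, log_power=np.column_stack(cols))

    rng_seed = np.random.default_rng(_child_seed(seed, 4))
    seed_regions = {
        "hippocampus": hippo_gain * resp + _ar1_noise(rng_seed, (n_scans,), noise_sd, ar1),
        "vta": vta_gain * resp + _ar1_noise(rng_seed, (n_scans,), noise_sd, ar1),
    }

    truth = ReactivationGroundTruth(
        event_onsets=starts,
        event_state=reward_state,
        amplitude=react_amp,
        event_dur_scans=event_dur_scans,
        delta_coupling=delta_coupling,
    )
    return SleepData(roits=roits, bandpower=bandpower, truth=truth,
                     seed_regions=seed_regions, hypnogram=hyp)


def synthesize_raw_eeg(
    duration_s: float,
    fs: float = 100.0,
    band_amps: dict[str, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Raw single-channel EEG as a sum of band-limited Gaussian noise.

    A testing aid for the spectral pipeline, not a physiological model (no
    spindles, K-complexes or 1/f background beyond the band mixture).
    """
    from .eeg import BANDS

    band_amps = band_amps or {b: 1.0 for b in BANDS}
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    out = np.zeros(n)
    for band, amp in band_amps.items():
        lo, hi = BANDS[band]
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out += amp * sosfiltfilt(sos, rng.normal(size=n))
    return out


@dataclass
class SubjectRecord:
    """Behavioral record: ground-truth layouts, realized memory responses."""

    subject_id: str
    won_game: str
    face_truth: behavior.FaceGrid
    face_placement: behavior.FaceGrid | None = None
    maze: behavior.MazeGraph | None = None
    maze_final_node: object = None
    memory_coupling: float = 0.0
    reactivation_strength: float = 0.0


def simulate_memory(
    record: SubjectRecord,
    reactivation_strength: float,
    coupling: float = 0.15,
    noise_sd: float = 0.1,
    seed: int = 0,
    base_accuracy: float = 0.25,
    base_maze_frac: float = 0.85,
) -> SubjectRecord:
    """Realize memory responses whose expectation improves linearly with
    ``reactivation_strength * coupling`` (within clipping bounds).

    Face: a fraction ``base_accuracy + coupling*strength + noise`` of the 18
    faces is placed exactly; the rest are shuffled over the remaining
    cells. Maze: the final position is a node whose goal distance shrinks
    linearly with the same drive.
    """
    if not np.isfinite(coupling):
        raise ValueError("coupling must be finite")
    rng = np.random.default_rng(seed)
    drive = coupling * reactivation_strength

    acc = float(np.clip(base_accuracy + drive + (rng.normal(0, noise_sd) if noise_sd else 0.0), 0, 1))
    n_exact = int(round(acc * behavior.N_FACES))
    face_order = rng.permutation(behavior.N_FACES)
    exact = set(face_order[:n_exact].tolist())
    placements: dict[int, tuple[int, int]] = {}
    used = set()
    for fid in sorted(exact):
        placements[fid] = record.face_truth.placements[fid]
        used.add(placements[fid])
    all_cells = [(r, c) for r in range(behavior.N_ROWS) for c in range(behavior.N_COLS)]
    free = [cell for cell in all_cells if cell not in used]
    rng.shuffle(free)
    for fid in range(behavior.N_FACES):
        if fid not in exact:
            placements[fid] = free.pop()
    face_placement = behavior.FaceGrid(placements=placements)

    maze = record.maze
    final = None
    if maze is not None:
        import networkx as nx

        dists = nx.single_source_shortest_path_length(maze.graph, maze.goal)
        dmax = max(dists.values())
        frac = float(np.clip(base_maze_frac - drive + (rng.normal(0, noise_sd) if noise_sd else 0.0), 0, 1))
        target = int(round(dmax * frac))
        by_d: dict[int, list] = {}
        for node, d in dists.items():
            by_d.setdefault(d, []).append(node)
        avail = sorted(by_d)
        d_real = min(avail, key=lambda d: abs(d - target))
        final = sorted(by_d[d_real])[rng.integers(len(by_d[d_real]))]

    return replace(
        record,
        face_placement=face_placement,
        maze_final_node=final,
        memory_coupling=coupling,
        reactivation_strength=reactivation_strength,
    )


@dataclass
class CohortConfig:
    """Generator defaults: the study's nominal conditions."""

    n_rois: int = 58
    n_game_blocks: int = 8
    game_dur: float = 60.0
    rest_dur: float = 90.0
    pre_dur: float = 3.0
    tr: float = 2.1
    game_amp: float = 1.0
    pre_amp: float = 0.25
    pattern_jitter: float = 0.1
    noise_sd: float = 1.0
    ar1: float = 0.3
    sleep_total_min: float = 60.0
    min_n3_min: float = 10.0
    react_amp: float = 1.0
    react_amp_subject_sd: float = 0.5
    event_rate_per_min_n3: float = 3.0
    event_dur_scans: int = 3
    delta_coupling: float = 1.0
    hippo_gain: float = 1.0
    vta_gain: float = 0.7
    memory_coupling: float = 1.0
    memory_noise_sd: float = 0.1
    include_sleep: bool = True

    def to_jsonable(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class Subject:
    subject_id: str
    won_game: str
    design: ExperimentDesign
    game_ts: ROITimeSeries
    game_labels: LabelSeries
    sleep: SleepData | None
    record: SubjectRecord | None


@dataclass
class Cohort:
    config: CohortConfig
    patterns: StatePatterns
    subjects: list[Subject]
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)


def simulate_cohort(
    n_subjects: int = 13,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Full cohort: game sessions for everyone; sleep sessions, seed-region
    channels and memory records when ``config.include_sleep``.

    Half of the subjects (rounded up) win the face game. The activation
    patterns are shared across the cohort (the classifier is trained across
    subjects) with a small per-subject jitter.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    cfg = config or CohortConfig()
    base = default_patterns(cfg.n_rois, cfg.game_amp, cfg.pre_amp, seed=_child_seed(seed, 0))
    rng = np.random.default_rng(_child_seed(seed, 1))
    won = np.array(["face"] * ((n_subjects + 1) // 2) + ["maze"] * (n_subjects // 2), dtype=object)
    won = won[rng.permutation(n_subjects)]
    maze_map = behavior.build_grid_maze(seed=_child_seed(seed, 2))

    subjects = []
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        s_seed = _child_seed(seed, 10 + i)
        jitter = np.random.default_rng(_child_seed(s_seed, 0)).normal(
            scale=cfg.pattern_jitter, size=base.weights.shape
        )
        jitter[STATES.index("Rest")] = 0.0
        patterns = StatePatterns(weights=base.weights + jitter)

        design = build_game_schedule(
            cfg.n_game_blocks, cfg.game_dur, cfg.rest_dur, cfg.pre_dur,
            seed=_child_seed(s_seed, 1), won_game=won[i], tr=cfg.tr,
        )
        game_ts, game_labels = simulate_game_session(
            design, patterns, cfg.noise_sd, cfg.ar1, seed=_child_seed(s_seed, 2)
        )

        sleep = None
        record = None
        if cfg.include_sleep:
            hyp = simulate_hypnogram(
                cfg.sleep_total_min, min_n3_min=cfg.min_n3_min, seed=_child_seed(s_seed, 3)
            )
            # subjects differ in how strongly they reactivate; this
            # between-subject spread is what the memory correlation sees
            amp_rng = np.random.default_rng(_child_seed(s_seed, 7))
            subj_amp = cfg.react_amp * max(
                0.0, 1.0 + (amp_rng.normal(0.0, cfg.react_amp_subject_sd) if cfg.react_amp_subject_sd else 0.0)
            )
            sleep = simulate_sleep_session(
                hyp, patterns,
                reward_state=_GAME_STATE[won[i]],
                react_amp=subj_amp,
                event_rate_per_min_n3=cfg.event_rate_per_min_n3,
                event_dur_scans=cfg.event_dur_scans,
                delta_coupling=cfg.delta_coupling,
                noise_sd=cfg.noise_sd,
                ar1=cfg.ar1,
                tr=cfg.tr,
                seed=_child_seed(s_seed, 4),
                hippo_gain=cfg.hippo_gain,
                vta_gain=cfg.vta_gain,
            )
            n3_scans = int(np.sum(sleep.scan_stages() == "N3"))
            strength = (
                sleep.truth.amplitude * cfg.event_dur_scans * sleep.truth.n_events / max(n3_scans, 1)
            )
            grid_rng = np.random.default_rng(_child_seed(s_seed, 5))
            cells = [(r, c) for r in range(behavior.N_ROWS) for c in range(behavior.N_COLS)]
            order = grid_rng.permutation(len(cells))
            truth_grid = behavior.FaceGrid({f: cells[order[f]] for f in range(behavior.N_FACES)})
            record = SubjectRecord(
                subject_id=sid, won_game=won[i], face_truth=truth_grid, maze=maze_map
            )
            record = simulate_memory(
                record, strength, cfg.memory_coupling, cfg.memory_noise_sd,
                seed=_child_seed(s_seed, 6),
            )

        subjects.append(
            Subject(sid, won[i], design, game_ts, game_labels, sleep, record)
        )
    return Cohort(config=cfg, patterns=base, subjects=subjects, seed=seed)
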