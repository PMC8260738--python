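"""Experimental block design of the game session and per-scan labeling.

The game session alternates two 60-s games ("face" and "maze", 8 blocks
each) in a pseudo-random order with no more than two consecutive blocks of
the same game. Every game block is announced by a 3-s pre-cue and followed
by 90 s of rest. The last block of the game the subject eventually wins is
flagged; its scans (and the scans of the rest period that follows it) are
excluded from classifier training, because the win event itself must not
contaminate the Reward-state pattern.

Scans are assigned to blocks by the half-open interval convention: a scan
whose onset time falls in [block onset, block onset + duration) belongs to
that block. A scan whose onset coincides with a boundary therefore belongs
to the later block.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical state order. Index order is also the tie-break order used by
#: Viterbi decoding (lower index wins an exact tie).
STATES: tuple[str, ...] = ("Face", "Maze", "Rest", "PreFace", "PreMaze")

#: Sentinel label for scans dropped from training (win block + its rest).
EXCLUDED = "Excluded"

GAMES = ("face", "maze")

_GAME_STATE = {"face": "Face", "maze": "Maze"}
_PRE_STATE = {"face": "PreFace", "maze": "PreMaze"}


class DesignError(ValueError):
    """Raised when a requested schedule cannot satisfy its constraints."""


@dataclass(frozen=True)
class Block:
    state: str
    onset: float          # seconds from session start
    duration: float       # seconds
    run: int
    is_win_block: bool = False

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class ExperimentDesign:
    """Ordered, non-overlapping blocks of a game session."""

    blocks: list[Block]
    tr: float
    n_scans_per_run: list[int] = field(default_factory=list)

    @property
    def total_duration(self) -> float:
        return self.blocks[-1].end if self.blocks else 0.0

    @property
    def n_scans(self) -> int:
        """Number of scan onsets falling strictly inside [0, total_duration)."""
        return int(math.ceil(self.total_duration / self.tr - 1e-9))

    def validate(self) -> None:
        prev_end = 0.0
        for b in self.blocks:
            if b.onset < prev_end - 1e-9:
                raise DesignError(f"overlapping blocks at t={b.onset}")
            prev_end = b.end
        if sum(b.is_win_block for b in self.blocks) != 1:
            raise DesignError("exactly one block must be flagged is_win_block")

    def to_json(self) -> str:
        return json.dumps(
            {
                "tr": self.tr,
                "n_scans_per_run": self.n_scans_per_run,
                "blocks": [
                    {
                        "state": b.state,
                        "onset": b.onset,
                        "duration": b.duration,
                        "run": b.run,
                        "is_win_block": b.is_win_block,
                    }
                    for b in self.blocks
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        d = json.loads(text)
        blocks = [Block(**b) for b in d["blocks"]]
        return cls(blocks=blocks, tr=d["tr"], n_scans_per_run=list(d["n_scans_per_run"]))


@dataclass
class LabelSeries:
    """One state label per scan; ``Excluded`` marks scans dropped from training."""

    labels: np.ndarray    # dtype object/str, length = n scans
    tr: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"label": self.labels}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tr: float) -> "LabelSeries":
        import pandas as pd

        return cls(labels=pd.read_csv(path)["label"].to_numpy(dtype=object), tr=tr)


@dataclass(frozen=True)
class RewardMapping:
    """Relabeling of game states by reward status (which game was won)."""

    won_game: str

    def __post_init__(self) -> None:
        if self.won_game not in GAMES:
            raise ValueError(f"won_game must be one of {GAMES}, got {self.won_game!r}")

    @property
    def mapping(self) -> dict[str, str]:
        if self.won_game == "face":
            return {
                "Face": "Reward",
                "Maze": "NoReward",
                "PreFace": "PreR",
                "PreMaze": "PreNR",
                "Rest": "Rest",
            }
        return {
            "Maze": "Reward",
            "Face": "NoReward",
            "PreMaze": "PreR",
            "PreFace": "PreNR",
            "Rest": "Rest",
        }


#: Reward-mapped state order matching STATES under either mapping.
REWARD_STATES: tuple[str, ...] = ("Reward", "NoReward", "Rest", "PreR", "PreNR")


def _game_sequence(n_per_type: int, won_game: str, rng: np.random.Generator,
                   max_consecutive: int = 2, max_tries: int = 2000) -> list[str]:
    """Pseudo-random interleaving of the two games, ≤2 consecutive repeats.

    The winning game must occupy the final slot (the session ends on the win).
    """
    games = ["face"] * n_per_type + ["maze"] * n_per_type
    for _ in range(max_tries):
        seq = list(rng.permutation(games))
        if seq[-1] != won_game:
            continue
        ok = all(
            not all(s == seq[i] for s in seq[i : i + max_consecutive + 1])
            for i in range(len(seq) - max_consecutive)
        )
        if ok:
            return seq
    raise DesignError(
        f"could not build a schedule with {n_per_type} blocks/type and "
        f"max {max_consecutive} consecutive repeats"
    )


def build_game_schedule(
    n_game_blocks_per_type: int = 8,
    game_dur: float = 60.0,
    rest_dur: float = 90.0,
    pre_dur: float = 3.0,
    seed: int = 0,
    won_game: str = "face",
    tr: float = 2.1,
    n_runs: int = 2,
) -> ExperimentDesign:
    """Build the pseudo-random block schedule of one game session.

    Each game block contributes pre-cue (3 s) + game (60 s) + rest (90 s);
    with 8 blocks per game the session spans 2 × 8 × 153 = 2448 s, split
    into ``n_runs`` runs for bookkeeping. The last block of ``won_game``
    carries ``is_win_block``.
    """
    if n_game_blocks_per_type < 1:
        raise DesignError("need at least one block per game type")
    if min(game_dur, rest_dur, pre_dur) <= 0:
        raise DesignError("durations must be positive")
    if won_game not in GAMES:
        raise DesignError(f"won_game must be one of {GAMES}")

    rng = np.random.default_rng(seed)
    seq = _game_sequence(n_game_blocks_per_type, won_game, rng)
    last_idx = max(i for i, g in enumerate(seq) if g == won_game)

    per_block = pre_dur + game_dur + rest_dur
    total = per_block * len(seq)
    run_len = total / n_runs

    blocks: list[Block] = []
    t = 0.0
    for i, g in enumerate(seq):
        run = min(int(t / run_len), n_runs - 1)
        win = i == last_idx
        blocks.append(Block(_PRE_STATE[g], t, pre_dur, run))
        blocks.append(Block(_GAME_STATE[g], t + pre_dur, game_dur, run, is_win_block=win))
        blocks.append(Block("Rest", t + pre_dur + game_dur, rest_dur, run))
        t += per_block

    design = ExperimentDesign(blocks=blocks, tr=tr)
    n_total = design.n_scans
    # scans partitioned by the run of the block containing each onset
    counts = [0] * n_runs
    for i in range(n_total):
        onset = i * tr
        counts[min(int(onset / run_len), n_runs - 1)] += 1
    design.n_scans_per_run = counts
    design.validate()
    return design


def labels_from_schedule(design: ExperimentDesign, n_scans: int | None = None) -> LabelSeries:
    """Label each scan by the block containing its onset (half-open intervals).

    Scans inside the win block or its trailing rest block are ``Excluded``;
    scans outside every block are ``Rest``.
    """
    if n_scans is None:
        n_scans = design.n_scans
    labels = np.full(n_scans, "Rest", dtype=object)
    win_seen = False
    for bi, b in enumerate(design.blocks):
        lo = int(math.ceil(b.onset / design.tr - 1e-9))
        hi = int(math.ceil(b.end / design.tr - 1e-9))
        lo, hi = max(lo, 0), min(hi, n_scans)
        if lo >= hi:
            continue
        if b.is_win_block:
            labels[lo:hi] = EXCLUDED
            win_seen = True
        elif win_seen and b.state == "Rest":
            labels[lo:hi] = EXCLUDED
            win_seen = False
        else:
            labels[lo:hi] = b.state
    return LabelSeries(labels=labels, tr=design.tr)


def shift_labels(labels: LabelSeries, n_scans_shift: int) -> LabelSeries:
    """Delay labels by an integer number of scans (hemodynamic-lag option).

    A positive shift moves every label later; the leading gap is filled
    with Rest. The default analysis uses no shift (training on block
    timing, as the hemodynamics are absorbed by the HRF-shaped features).
    """
    if n_scans_shift == 0:
        return LabelSeries(labels=labels.labels.copy(), tr=labels.tr)
    if n_scans_shift < 0:
        raise ValueError("n_scans_shift must be nonnegative")
    shifted = np.concatenate(
        [np.full(n_scans_shift, "Rest", dtype=object), labels.labels[:-n_scans_shift]]
    )
    return LabelSeries(labels=shifted, tr=labels.tr)


def apply_reward_mapping(obj, mapping: RewardMapping):
    """Relabel states by reward status; numeric content is untouched.

    Accepts a :class:`LabelSeries` or any object with ``states`` (column
    labels) such as :class:`sleepreact.crf.StateLikelihoods`; returns a new
    object of the same type.
    """
    m = mapping.mapping
    if isinstance(obj, LabelSeries):
        relabeled = np.array([m.get(l, l) for l in obj.labels], dtype=object)
        return LabelSeries(labels=relabeled, tr=obj.tr)
    if hasattr(obj, "states") and hasattr(obj, "probs"):
        new = obj.__class__(probs=obj.probs.copy(), states=[m.get(s, s) for s in obj.states])
        return new
    raise TypeError(f"cannot reward-map object of type {type(obj)!r}")
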