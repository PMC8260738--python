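"""Delayed memory tests: face-grid placement scoring and maze distance.

Face memory is tested by asking the subject to replace each of 18 faces on
a 3-row x 6-column grid. Each face earns 3 points for the exact cell, else
1 point for the correct column, else 0.5 point for the correct row, else 0
(the credits are exclusive per face; on a grid a wrong cell cannot match
both row and column, so the hierarchy is unambiguous). Maze memory is the
shortest-path distance from the subject's position after 30 s of
navigation to the goal node. Scores are z-scored over the cohort (maze
distances negated first) so that larger z means better memory for both
tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import stats as _stats

N_FACES = 18
N_ROWS = 3
N_COLS = 6


@dataclass
class FaceGrid:
    """Assignment of each face id (0..17) to one (row, column) cell."""

    placements: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.placements) != set(range(N_FACES)):
            raise ValueError(f"placement must cover all {N_FACES} faces")
        cells = list(self.placements.values())
        for r, c in cells:
            if not (0 <= r < N_ROWS and 0 <= c < N_COLS):
                raise ValueError(f"cell ({r},{c}) outside the {N_ROWS}x{N_COLS} grid")
        if len(set(cells)) != len(cells):
            raise ValueError("grid cells may not be reused")

    def to_jsonable(self) -> dict:
        return {str(k): list(v) for k, v in self.placements.items()}

    @classmethod
    def from_jsonable(cls, d: dict) -> "FaceGrid":
        return cls({int(k): (int(v[0]), int(v[1])) for k, v in d.items()})


def face_memory_score(truth: FaceGrid, placement: FaceGrid) -> float:
    """Total rubric points (3 / 1 / 0.5 / 0 per face; range 0..54)."""
    total = 0.0
    for fid in range(N_FACES):
        tr, tc = truth.placements[fid]
        pr, pc = placement.placements[fid]
        if (pr, pc) == (tr, tc):
            total += 3.0
        elif pc == tc:
            total += 1.0
        elif pr == tr:
            total += 0.5
    return total


@dataclass
class MazeGraph:
    """Undirected maze map with a goal node; edges may carry a 'weight'."""

    graph: nx.Graph
    goal: object

    def __post_init__(self) -> None:
        if self.goal not in self.graph:
            raise ValueError("goal node not in graph")


def build_grid_maze(rows: int = 7, cols: int = 7, seed: int = 0) -> MazeGraph:
    """Random spanning-tree maze on a grid; goal at one corner.

    A spanning tree of the grid graph gives unique corridors and graph
    distances that spread subjects out, standing in for the (unpublished)
    game map.
    """
    g = nx.grid_2d_graph(rows, cols)
    tree = nx.random_spanning_tree(g, seed=seed)
    return MazeGraph(graph=nx.Graph(tree.edges), goal=(0, 0))


def maze_memory_distance(maze: MazeGraph, position_after_30s) -> float | None:
    """Shortest-path length from the position to the goal; None if unreachable."""
    if position_after_30s not in maze.graph:
        raise ValueError(f"node {position_after_30s!r} not in maze")
    weighted = any("weight" in d for _, _, d in maze.graph.edges(data=True))
    try:
        return float(
            nx.shortest_path_length(
                maze.graph,
                position_after_30s,
                maze.goal,
                weight="weight" if weighted else None,
            )
        )
    except nx.NetworkXNoPath:
        return None


def zscore_memory(face_scores, maze_distances) -> tuple[np.ndarray, np.ndarray]:
    """Cohort z-scores per task; maze distances are negated before z-scoring
    so that a larger z always indexes better performance."""
    face = np.asarray(face_scores, dtype=float)
    maze = -np.asarray(maze_distances, dtype=float)
    if len(face) < 3 or len(maze) < 3:
        raise ValueError("cohort must have at least 3 subjects")
    out = []
    for v in (face, maze):
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in memory scores")
        out.append((v - v.mean()) / sd)
    return out[0], out[1]


def reactivation_memory_correlation(network_betas, memory_z) -> tuple[float, float]:
    """Spearman correlation between per-subject reactivation-network activity
    and memory z-scores (exact permutation p for small cohorts)."""
    x = np.asarray(network_betas, dtype=float)
    y = np.asarray(memory_z, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 subjects")
    return _stats.spearman(x, y)
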