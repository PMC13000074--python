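"""Offline evaluation of the observed treatment policy per sub-phenotype.

Treatments are discretized on a 5x5 grid: bin 0 of each axis is reserved
for zero dose, bins 1-4 split the nonzero training doses at their
quartiles (IV fluid volume per window; max norepinephrine-equivalent
vasopressor rate). States are the discovered clusters. Each patient
trajectory becomes SARSA tuples (s, a, r, s', a') with zero intermediate
reward and a terminal reward of +100 (alive at 90 days) / -100 (died).

The behaviour policy's Q-function is estimated two ways: tabular on-policy
SARSA with a visit-count learning-rate schedule, and exact policy
evaluation on the empirical MDP (a linear solve), which serves as the
oracle the stochastic estimate is checked against. "Optimal regions" mark,
per state, the sufficiently visited actions whose Q reaches that state's
upper quantile — the analogue of the highlighted decision regions in
treatment-frequency maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BINS = 5
N_ACTIONS = N_BINS * N_BINS


@dataclass
class ActionGrid:
    """Dose discretization; bin 0 = zero dose, bins 1-4 = nonzero quartiles."""

    fluid_edges: np.ndarray  # 3 interior quartile edges of nonzero doses
    vaso_edges: np.ndarray

    def __post_init__(self) -> None:
        for name, e in (("fluid_edges", self.fluid_edges), ("vaso_edges", self.vaso_edges)):
            e = np.asarray(e, float)
            if e.shape != (3,) or not (np.diff(e) > 0).all():
                raise ValueError(f"{name} must be 3 strictly increasing values")

    @classmethod
    def from_training_doses(cls, fluid: np.ndarray, vaso: np.ndarray) -> "ActionGrid":
        """Quartile edges of the nonzero training doses."""
        f = np.asarray(fluid, float)
        v = np.asarray(vaso, float)
        fe = np.percentile(f[f > 0], [25, 50, 75])
        ve = np.percentile(v[v > 0], [25, 50, 75])
        return cls(fluid_edges=fe, vaso_edges=ve)


@dataclass
class SarsaConfig:
    gamma: float = 0.99
    alpha0: float = 0.1
    alpha_decay: float = 0.01  # alpha(s,a) = alpha0 / (1 + visits * decay)
    epochs: int = 500
    tol: float = 1e-4
    reward_survived: float = 100.0
    reward_died: float = -100.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        if not 0 < self.alpha0 <= 1:
            raise ValueError("alpha0 must lie in (0, 1]")


@dataclass
class QTable:
    q: np.ndarray  # (K, 25); NaN where unvisited
    visits: np.ndarray  # (K, 25) int
    n_states: int

    def frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.n_states):
            for a in range(N_ACTIONS):
                rows.append(
                    (s, a // N_BINS, a % N_BINS, self.q[s, a], int(self.visits[s, a]))
                )
        return pd.DataFrame(rows, columns=["state", "vaso_bin", "fluid_bin", "q", "visits"])


def discretize_actions(fluid, vaso, grid: ActionGrid):
    """Flat action index = vaso_bin * 5 + fluid_bin, each in 0..4."""
    f = np.atleast_1d(np.asarray(fluid, float))
    v = np.atleast_1d(np.asarray(vaso, float))
    if (f < 0).any() or (v < 0).any():
        raise ValueError("doses must be nonnegative")
    fb = np.searchsorted(grid.fluid_edges, f, side="right") + 1
    fb[f <= 0] = 0
    vb = np.searchsorted(grid.vaso_edges, v, side="right") + 1
    vb[v <= 0] = 0
    idx = vb * N_BINS + fb
    return idx if np.ndim(fluid) else int(idx[0])


@dataclass
class TrajectoryTuples:
    """Per-patient SARS'A' tuples, time ordered; one terminal per patient."""

    patients: list[np.ndarray] = field(default_factory=list)
    # each array has rows (s, a, r, s_next, a_next, terminal) with
    # s_next = -1 and a_next = -1 on the terminal row
    n_states: int = 0

    def all_rows(self) -> np.ndarray:
        return np.vstack(self.patients)


def build_tuples(
    assignment: pd.DataFrame,
    actions: pd.DataFrame,
    died_90d: pd.Series,
    grid: ActionGrid,
    config: SarsaConfig | None = None,
) -> TrajectoryTuples:
    """Assemble SARSA tuples over cluster states.

    ``assignment`` maps (patient_id, window) -> cluster; ``actions`` carries
    per-(patient_id, window) fluid_total and vaso_max columns. Rewards are 0
    except on each patient's final window: +100 survived / -100 died.
    """
    config = config or SarsaConfig()
    config.validate()
    merged = assignment.merge(actions, on=["patient_id", "window"], how="left")
    if merged[["fluid_total", "vaso_max"]].isna().any().any():
        bad = merged.loc[merged["fluid_total"].isna(), "patient_id"].unique()
        raise ValueError(f"missing actions for patients: {bad[:5]}")
    out = TrajectoryTuples(n_states=int(assignment["cluster"].max()) + 1)
    for pid, g in merged.sort_values("window").groupby("patient_id"):
        s = g["cluster"].to_numpy()
        a = discretize_actions(g["fluid_total"].to_numpy(), g["vaso_max"].to_numpy(), grid)
        n = len(g)
        r_term = config.reward_survived if died_90d.loc[pid] == 0 else config.reward_died
        rows = np.zeros((n, 6))
        rows[:, 0] = s
        rows[:, 1] = a
        rows[:-1, 3] = s[1:]
        rows[:-1, 4] = a[1:]
        rows[-1, 2] = r_term
        rows[-1, 3] = -1
        rows[-1, 4] = -1
        rows[-1, 5] = 1
        out.patients.append(rows)
    return out


def sarsa_evaluate(tuples: TrajectoryTuples, config: SarsaConfig | None = None) -> QTable:
    """Tabular on-policy TD(0) evaluation of the behaviour policy.

    Q(s,a) += alpha(s,a) * [r + gamma * Q(s',a') - Q(s,a)], with
    Q(terminal, .) = 0 so the terminal target is the reward alone. Passes
    over patient trajectories are shuffled each epoch; stops when the
    largest update in an epoch falls below ``tol`` or at ``epochs``.
    """
    config = config or SarsaConfig()
    config.validate()
    if not tuples.patients:
        raise ValueError("no trajectories supplied")
    K = tuples.n_states
    Q = np.zeros((K, N_ACTIONS))
    updates = np.zeros((K, N_ACTIONS), int)  # drives the alpha schedule
    visits = np.zeros((K, N_ACTIONS), int)  # dataset (single-pass) counts
    rng = np.random.default_rng(config.seed)
    for rows in tuples.patients:
        np.add.at(visits, (rows[:, 0].astype(int), rows[:, 1].astype(int)), 1)
    order = np.arange(len(tuples.patients))
    for _ in range(config.epochs):
        rng.shuffle(order)
        max_delta = 0.0
        for i in order:
            for s, a, r, s2, a2, term in tuples.patients[i]:
                s, a = int(s), int(a)
                target = r if term else r + config.gamma * Q[int(s2), int(a2)]
                alpha = config.alpha0 / (1.0 + updates[s, a] * config.alpha_decay)
                delta = alpha * (target - Q[s, a])
                Q[s, a] += delta
                updates[s, a] += 1
                max_delta = max(max_delta, abs(delta))
        if max_delta < config.tol:
            break
    Q = np.where(visits > 0, Q, np.nan)
    return QTable(q=Q, visits=visits, n_states=K)


def exact_policy_eval(tuples: TrajectoryTuples, gamma: float = 0.99) -> QTable:
    """Exact Q of the behaviour policy on the empirical MDP.

    Builds empirical transition frequencies from (s,a) to the observed next
    pair (s',a') (their frequency already folds the behaviour policy in),
    mean rewards per (s,a), and solves Q = R + gamma * F Q over visited
    pairs. The residual of the solve is checked to near machine precision.
    """
    if not tuples.patients:
        raise ValueError("no trajectories supplied")
    rows = tuples.all_rows()
    K = tuples.n_states
    pair_idx = {}
    for s, a in zip(rows[:, 0].astype(int), rows[:, 1].astype(int)):
        pair_idx.setdefault((s, a), len(pair_idx))
    n = len(pair_idx)
    F = np.zeros((n, n))
    R = np.zeros(n)
    counts = np.zeros(n)
    for s, a, r, s2, a2, term in rows:
        i = pair_idx[(int(s), int(a))]
        counts[i] += 1
        R[i] += r
        if not term:
            j = pair_idx[(int(s2), int(a2))]
            F[i, j] += 1
    R /= counts
    F /= counts[:, None]
    Q = np.linalg.solve(np.eye(n) - gamma * F, R)
    resid = np.abs(Q - (R + gamma * F @ Q)).max()
    if resid > 1e-8:
        raise RuntimeError(f"policy-evaluation solve residual too large: {resid}")
    q = np.full((K, N_ACTIONS), np.nan)
    visits = np.zeros((K, N_ACTIONS), int)
    for (s, a), i in pair_idx.items():
        q[s, a] = Q[i]
        visits[s, a] = int(counts[i])
    return QTable(q=q, visits=visits, n_states=K)


def optimal_regions(qtable: QTable, visit_min: int = 10, quantile: float = 0.9) -> np.ndarray:
    """Per-state 5x5 boolean grids of top-quantile, well-visited actions.

    Actions with fewer than ``visit_min`` visits are never marked; a state
    with no sufficiently visited action yields an all-False grid.
    """
    K = qtable.n_states
    out = np.zeros((K, N_BINS, N_BINS), bool)
    for s in range(K):
        ok = (qtable.visits[s] >= visit_min) & ~np.isnan(qtable.q[s])
        if not ok.any():
            continue
        vals = qtable.q[s][ok]
        thresh = np.quantile(vals, quantile)
        if thresh <= vals.min() and vals.max() > vals.min():
            # heavy ties at the bottom: fall back to strictly-above so the
            # region keeps only genuinely better actions
            marked = ok & (qtable.q[s] > thresh)
        else:
            marked = ok & (qtable.q[s] >= thresh)
        out[s] = marked.reshape(N_BINS, N_BINS)  # [vaso_bin, fluid_bin]
    return out
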