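"""Markov-chain simulation of linear and branching clonal evolution.

Four driver mutations x1..x4 accumulate along one of two topologies:

* linear — states pi0 = {} to pi4 = {x1,x2,x3,x4}, acquired strictly in
  order;
* branching — identical through pi2 = {x1,x2}, after which x3 and x4
  arise independently (pi3 = {x1,x2,x3}, pi4 = {x1,x2,x4}).

Over an elapsed time dt the chance of gaining k more mutations follows
a multi-mutation law in q = 1 - exp(-f*dt), where f is the fitness of a
new mutation: staying put has probability e^(-f*dt) and advancing j-i
steps has probability q^(j-i) - q^(j-i+1), truncated to the finite
state list (see the stochasticity notes on each function).  The chain
is advanced in unit (monthly) steps of that law and observed at the
sampling times: interval-sized jumps would hide the within-interval
order of acquisition and destroy the ordering signal the calibration
measures.  Each simulated patient starts with no mutations at t = 0 and
is sampled at three later time points; cohorts of such patients
calibrate how reliably the full ordering pipeline recovers the
generating topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tedg.evograph import (
    OrderGraph,
    build_sequential_network,
    deconvolve,
    extract_tedg,
    pool_isn,
    simplify_isn,
)
from tedg.mcf_adjust import MCFProfile

LESIONS = ("x1", "x2", "x3", "x4")

LINEAR_STATES = (
    frozenset(),
    frozenset({"x1"}),
    frozenset({"x1", "x2"}),
    frozenset({"x1", "x2", "x3"}),
    frozenset({"x1", "x2", "x3", "x4"}),
)
BRANCHING_STATES = (
    frozenset(),
    frozenset({"x1"}),
    frozenset({"x1", "x2"}),
    frozenset({"x1", "x2", "x3"}),
    frozenset({"x1", "x2", "x4"}),
)

#: Defining edge sets against which a reconstruction is scored.
TRUE_EDGES = {
    "linear": {("x1", "x2"), ("x2", "x3"), ("x3", "x4")},
    "branching": {("x1", "x2"), ("x2", "x3"), ("x2", "x4")},
}


@dataclass(frozen=True)
class EvolutionModel:
    """Simulator specification.

    kind : "linear" or "branching".
    fitness : per-mutation fitness f, per month (> 0).
    time_points : sampling times in months; patients start mutation-free
        at time 0.
    branch_policy : how the branching rows are made stochastic —
        "split" (each terminal branch gets half the advance mass; rows
        are exactly stochastic by construction) or "renormalize" (the
        printed branch masses are kept proportional and the row scaled
        to 1).
    step_months : granularity at which the chain is advanced between
        samples; the default of 1 month makes acquisition effectively
        one-at-a-time while samples remain sparse.
    """

    kind: str = "linear"
    fitness: float = 0.1
    time_points: tuple[float, ...] = (10.0, 20.0, 30.0)
    branch_policy: str = "split"
    step_months: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "branching"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.fitness <= 0:
            raise ValueError("fitness must be > 0")
        if self.branch_policy not in ("renormalize", "split"):
            raise ValueError(
                f"unknown branch_policy {self.branch_policy!r}")
        times = tuple(self.time_points)
        if len(times) < 1 or any(t <= 0 for t in times) or \
                any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time_points must be positive and increasing")
        if self.step_months <= 0:
            raise ValueError("step_months must be > 0")

    @property
    def states(self) -> tuple[frozenset, ...]:
        return LINEAR_STATES if self.kind == "linear" else BRANCHING_STATES

    @property
    def true_edges(self) -> set[tuple[str, str]]:
        return set(TRUE_EDGES[self.kind])


@dataclass
class PatientTrajectory:
    patient_id: str
    #: list of (time, state index, lesion -> present)
    trajectory: list[tuple[float, int, dict[str, bool]]]


@dataclass
class SimCohort:
    model: EvolutionModel
    patients: list[PatientTrajectory]
    seed: int


def transition_matrix(model: EvolutionModel, dt: float) -> np.ndarray:
    """One-interval 5x5 transition matrix over states pi0..pi4.

    With q = 1 - exp(-f*dt): staying is 1 - q, advancing j - i > 0 steps
    is q^(j-i) - q^(j-i+1), and regression (j < i) is impossible.

    Linear: the advance probabilities over a finite ladder sum to
    1 - q^(5-i); the remainder q^(5-i) is absorbed into the terminal
    state, which preserves the printed off-diagonal ratios and makes
    every row stochastic.  Branching: advancing to either terminal
    branch state carries mass q^(3-i); under "split" (default) each
    branch receives q^(3-i)/2, which is exactly stochastic; under
    "renormalize" both receive the full printed mass and the row is
    scaled to sum to 1.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    q = 1.0 - np.exp(-model.fitness * dt)
    P = np.zeros((5, 5))
    if model.kind == "linear":
        for i in range(4):
            P[i, i] = 1.0 - q
            for j in range(i + 1, 4):
                P[i, j] = q ** (j - i) - q ** (j - i + 1)
            P[i, 4] = q ** (4 - i)  # telescoped advance + remainder
        P[4, 4] = 1.0
    else:
        for i in range(3):
            P[i, i] = 1.0 - q
            for j in range(i + 1, 3):
                P[i, j] = q ** (j - i) - q ** (j - i + 1)
            branch_mass = q ** (3 - i)
            if model.branch_policy == "split":
                P[i, 3] = P[i, 4] = branch_mass / 2.0
            else:
                P[i, 3] = P[i, 4] = branch_mass
        P[3, 3] = 1.0
        P[4, 4] = 1.0
        if model.branch_policy == "renormalize":
            P /= P.sum(axis=1, keepdims=True)
    rowsums = P.sum(axis=1)
    assert np.all(np.abs(rowsums - 1.0) < 1e-12)
    return P


def simulate_patient(model: EvolutionModel, rng: np.random.Generator,
                     patient_id: str) -> PatientTrajectory:
    """Advance one patient in ``step_months`` increments, recording the
    state at each sampling time."""
    P = transition_matrix(model, model.step_months)
    cum = np.cumsum(P, axis=1)
    state = 0
    now = 0.0
    traj = []
    for t in model.time_points:
        while now < t - 1e-9:
            state = int(np.searchsorted(cum[state], rng.random(),
                                        side="right"))
            now += model.step_months
        presence = {x: x in model.states[state] for x in LESIONS}
        traj.append((t, state, presence))
    return PatientTrajectory(patient_id=patient_id, trajectory=traj)


def simulate_cohort(model: EvolutionModel, n_patients: int,
                    seed: int = 0) -> SimCohort:
    """Simulate a cohort; deterministic in (model, n_patients, seed).

    Each patient draws from an independent counter-derived substream,
    so cohorts of different sizes share their common prefix.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    patients = []
    for i in range(n_patients):
        rng = np.random.default_rng([seed, i])
        patients.append(simulate_patient(model, rng, f"P{i + 1:03d}"))
    return SimCohort(model=model, patients=patients, seed=seed)


def cohort_profiles(cohort: SimCohort) -> dict[str, list[MCFProfile]]:
    """Presence vectors as binary MCF profiles (present = 1, absent = 0)."""
    out: dict[str, list[MCFProfile]] = {}
    for patient in cohort.patients:
        profiles = []
        for t, _state, presence in patient.trajectory:
            profiles.append(MCFProfile(
                patient_id=patient.patient_id, sample_time=t,
                mcf={x: 1.0 if p else 0.0 for x, p in presence.items()},
                method="fish"))
        out[patient.patient_id] = profiles
    return out


def reconstruct_and_score(cohort: SimCohort, model: EvolutionModel,
                          beta: float = 0.2,
                          tree_method: str = "undirected_prim") -> bool:
    """Run the full ordering pipeline and score against the true model.

    Returns True iff the extracted backbone's directed edge set equals
    the model's defining edges (linear chain or branching fork).
    """
    networks = []
    for pid, profiles in sorted(cohort_profiles(cohort).items()):
        networks.append(build_sequential_network(profiles, threshold=0.05))
    isn = pool_isn(networks)
    simplified = simplify_isn(isn)
    if simplified.number_of_edges() == 0:
        return False
    dec = deconvolve(simplified, beta)
    tedg = extract_tedg(dec, tree_method)
    return set(tedg.edges) == model.true_edges


def accuracy(model: EvolutionModel, n_patients: int, beta: float = 0.2,
             reps: int = 100, seed: int = 0,
             tree_method: str = "undirected_prim") -> float:
    """Fraction of replicate cohorts whose backbone matches the model."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    hits = 0
    for r in range(reps):
        cohort = simulate_cohort(model, n_patients,
                                 seed=_derive_seed(seed, r))
        if reconstruct_and_score(cohort, model, beta, tree_method):
            hits += 1
    return hits / reps


def _derive_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0]
               % (2 ** 31))


def calibration_grid(model: EvolutionModel, beta_grid: list[float],
                     n_grid: list[int], reps: int = 10,
                     seed: int = 0) -> np.ndarray:
    """Accuracy over a beta x cohort-size grid.

    Returns a matrix of shape (len(beta_grid), len(n_grid)); entry
    (i, j) is the reconstruction accuracy at beta_grid[i] with
    n_grid[j] patients.
    """
    if not beta_grid or not n_grid:
        raise ValueError("grids must be non-empty")
    out = np.zeros((len(beta_grid), len(n_grid)))
    for i, beta in enumerate(beta_grid):
        for j, n in enumerate(n_grid):
            out[i, j] = accuracy(model, n, beta, reps=reps,
                                 seed=_derive_seed(seed, i * 1000 + j))
    return out
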