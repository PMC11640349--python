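"""Synthetic TDS / temporal-liking panels with known ground truth.

Panelist button-press behavior in a TDS task is generated by a
semi-Markov chain over the attribute set: after an initial latency the
panelist selects a first dominant attribute, dwells on it for a random
(gamma-distributed) time, then transitions to another attribute according
to a zero-diagonal stochastic matrix, until the trial's random 20-30 s
duration elapses.  Explicit dwell distributions (rather than a plain
Markov chain) match how panel behavior is usually modeled and produce
realistic dominance curves.

Temporal liking is driven by a latent hedonic state: a first-order
low-pass (time constant tau) of baseline + w[dominant attribute], where w
is a per-attribute hedonic weight vector — the generator's ground truth.
The simulated panelist enters a first rating shortly after their first
dominance selection and re-rates whenever the rounded, clamped latent
state has drifted from the last entered score.  TDS and liking are
separate tasks, as in the protocol the generator emulates, so a liking
trial simulates a fresh (unrecorded) dominance trajectory internally.

The default "strawberry-like" preset favors sweet/juicy/watery early,
drifts toward sour/light/green late, and assigns positive hedonic weights
to sweet, fruity and juicy and negative ones to green and light — so
end-to-end sensitivity analyses have a known sign pattern to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sensory_io import (
    DEFAULT_ATTRIBUTES,
    AttributeSet,
    PanelEventLog,
    PressEvent,
    Trial,
)

__all__ = [
    "SemiMarkovParams",
    "LikingGroundTruth",
    "strawberry_params",
    "strawberry_truth",
    "simulate_tds_trial",
    "simulate_liking_events",
    "simulate_liking_trial",
    "simulate_panel",
    "ground_truth_ranking",
]


@dataclass(frozen=True)
class SemiMarkovParams:
    """Generative model of TDS button-press behavior.

    Latency to the first press is lognormal(latency_mu, latency_sigma) in
    log-seconds; per-attribute dwell times are gamma(shape, scale) seconds;
    trial duration is uniform on ``duration_s``.
    """

    attributes: AttributeSet
    initial_distribution: np.ndarray          # (n,)
    transition_matrix: np.ndarray             # (n, n), zero diagonal, rows sum to 1
    dwell_shape: np.ndarray                   # (n,)
    dwell_scale: np.ndarray                   # (n,) seconds
    latency_mu: float = 0.0                   # lognormal median 1 s
    latency_sigma: float = 0.6
    duration_s: tuple[float, float] = (20.0, 30.0)

    def __post_init__(self) -> None:
        n = self.attributes.n
        object.__setattr__(self, "initial_distribution",
                           np.asarray(self.initial_distribution, float))
        object.__setattr__(self, "transition_matrix",
                           np.asarray(self.transition_matrix, float))
        object.__setattr__(self, "dwell_shape", np.asarray(self.dwell_shape, float))
        object.__setattr__(self, "dwell_scale", np.asarray(self.dwell_scale, float))
        P = self.transition_matrix
        if P.shape != (n, n):
            raise ValueError("transition matrix must be (n, n)")
        if np.any(np.diag(P) != 0):
            raise ValueError("transition matrix must have a zero diagonal")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition matrix rows must be stochastic")
        if (self.initial_distribution.shape != (n,)
                or np.any(self.initial_distribution < 0)
                or abs(self.initial_distribution.sum() - 1) > 1e-9):
            raise ValueError("initial distribution must be a probability vector")
        if np.any(self.dwell_shape <= 0) or np.any(self.dwell_scale <= 0):
            raise ValueError("dwell parameters must be positive")
        if not 0 < self.duration_s[0] <= self.duration_s[1]:
            raise ValueError("duration bounds must be positive and ordered")


@dataclass(frozen=True)
class LikingGroundTruth:
    """Latent hedonic model driving synthetic liking ratings.

    ``weights[a]`` is the liking contribution of attribute a while
    dominant (score units); the latent state low-passes
    baseline + weights[dominant] with time constant ``tau_s``.  A rating
    is (re-)entered when the rounded clamped latent differs from the last
    entered score by at least ``report_threshold``.
    """

    attributes: AttributeSet
    weights: np.ndarray                       # (n,)
    tau_s: float = 2.0
    baseline: float = 5.0
    report_threshold: int = 1
    noise_sd: float = 0.3
    #: first liking report trails the first dominance onset by a lognormal
    #: delay (log-seconds); median ~3 s, long right tail — panelists take a
    #: while to commit to a first score, some most of the trial
    lag_mu: float = 1.1
    lag_sigma: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if self.weights.shape != (self.attributes.n,):
            raise ValueError("weights must match the attribute set")
        if self.tau_s <= 0:
            raise ValueError("tau must be positive")
        if self.report_threshold < 0:
            raise ValueError("report threshold must be >= 0")


# early / late attribute groups for the strawberry-like preset
_EARLY = ("aromatic", "juicy", "sweet", "fruity", "watery")
_LATE = ("light", "green", "sour")


def strawberry_params(attributes: AttributeSet | None = None) -> SemiMarkovParams:
    """Strawberry-like TDS behavior: first selections concentrated on
    sweet/juicy/watery, transitions drifting from the early flavor group
    toward the late one (light/green/sour), mean dwell about 3 s."""
    attrs = attributes or AttributeSet(DEFAULT_ATTRIBUTES)
    n = attrs.n
    init = dict(zip(DEFAULT_ATTRIBUTES, [0.05, 0.25, 0.30, 0.10, 0.02, 0.20, 0.03, 0.05]))
    p0 = np.array([init[a] for a in attrs.names])
    P = np.zeros((n, n))
    for i, a in enumerate(attrs.names):
        early_targets = [j for j, b in enumerate(attrs.names) if b in _EARLY and j != i]
        late_targets = [j for j, b in enumerate(attrs.names) if b in _LATE and j != i]
        if a in _EARLY:   # mostly move within the early group, leak to late
            P[i, early_targets] = 0.70 / len(early_targets)
            P[i, late_targets] = 0.30 / len(late_targets)
        else:             # late attributes mostly stay late
            P[i, late_targets] = 0.80 / len(late_targets)
            P[i, early_targets] = 0.20 / len(early_targets)
    return SemiMarkovParams(
        attributes=attrs,
        initial_distribution=p0,
        transition_matrix=P,
        dwell_shape=np.full(n, 2.0),
        dwell_scale=np.full(n, 1.5),
    )


def strawberry_truth(attributes: AttributeSet | None = None) -> LikingGroundTruth:
    """Strawberry-like hedonic ground truth: sweet and fruity most liked,
    green and light most disliked, sour/watery/aromatic near neutral."""
    attrs = attributes or AttributeSet(DEFAULT_ATTRIBUTES)
    w = dict(zip(
        DEFAULT_ATTRIBUTES,
        #  aromatic juicy sweet fruity light watery green  sour
        [0.2, 1.0, 1.8, 1.4, -1.2, 0.0, -1.6, -0.2],
    ))
    return LikingGroundTruth(attrs, np.array([w[a] for a in attrs.names]))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _dominance_path(
    params: SemiMarkovParams, rng: np.random.Generator
) -> tuple[float, list[tuple[float, int]]]:
    """Draw (duration, [(onset_s, attribute_index), ...]) for one trial."""
    duration = float(rng.uniform(*params.duration_s))
    t = float(rng.lognormal(params.latency_mu, params.latency_sigma))
    path: list[tuple[float, int]] = []
    if t >= duration:
        return duration, path
    state = int(rng.choice(params.attributes.n, p=params.initial_distribution))
    while t < duration:
        path.append((t, state))
        t += float(rng.gamma(params.dwell_shape[state], params.dwell_scale[state]))
        state = int(rng.choice(params.attributes.n, p=params.transition_matrix[state]))
    return duration, path


def _path_to_trial(
    participant_id: str,
    trial_index: int,
    duration: float,
    events: list[PressEvent],
) -> Trial:
    evs = [PressEvent(0.0, "start"), *events, PressEvent(duration, "stop")]
    return Trial(participant_id, trial_index, evs, duration_s=duration)


def simulate_tds_trial(
    params: SemiMarkovParams,
    rng: np.random.Generator,
    participant_id: str = "p01",
    trial_index: int = 1,
) -> Trial:
    """One TDS task: start, a press at each dominance onset, stop."""
    duration, path = _dominance_path(params, rng)
    events = [
        PressEvent(t, "tds_select", params.attributes.names[a])
        for t, a in path
        if 0.0 <= t < duration
    ]
    return _path_to_trial(participant_id, trial_index, duration, events)


def _latent_liking(
    duration: float,
    path: list[tuple[float, int]],
    truth: LikingGroundTruth,
    dt: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent hedonic state on a fine time grid (exact piecewise-constant
    first-order response).  The latent is initialized at its first target
    (baseline + weight of the first dominant attribute) — a panelist's
    first impression — and thereafter relaxes toward the current target
    with time constant tau whenever dominance changes.  Before the first
    dominance onset there is no tasting experience and no rating; the
    recorded zeros come from the reporting layer, not from a low latent."""
    ts = np.arange(0.0, duration, dt)
    onsets = [t for t, _ in path]
    states = [a for _, a in path]
    target = np.zeros_like(ts)
    x0 = 0.0
    if path:
        k = np.searchsorted(np.asarray(onsets), ts, side="right") - 1
        active = k >= 0
        target[active] = truth.baseline + truth.weights[np.asarray(states)[k[active]]]
        x0 = truth.baseline + truth.weights[states[0]]
        target[~active] = x0
    decay = np.exp(-dt / truth.tau_s)
    latent = np.empty_like(ts)
    x = x0
    for i in range(ts.size):
        x = target[i] + (x - target[i]) * decay
        latent[i] = x
    return ts, latent


def simulate_liking_events(
    trial_or_path,
    truth: LikingGroundTruth,
    rng: np.random.Generator,
) -> list[PressEvent]:
    """Liking press events implied by a dominance trajectory.

    Accepts either a TDS :class:`Trial` or a ``(duration, path)`` tuple as
    produced internally.  The first rating appears one reaction lag after
    the first dominance onset; re-ratings occur whenever the rounded,
    clamped latent state differs from the last entered score by at least
    the report threshold.  Entered scores carry rating noise and are
    clamped to 1..9.
    """
    if isinstance(trial_or_path, Trial):
        duration = trial_or_path.duration_s
        attrs = truth.attributes
        path = [
            (ev.time_s, attrs.index(ev.value))
            for ev in trial_or_path.tds_events
        ]
    else:
        duration, path = trial_or_path
    if not path:
        return []
    ts, latent = _latent_liking(duration, path, truth)
    first_t = path[0][0] + rng.lognormal(truth.lag_mu, truth.lag_sigma)
    events: list[PressEvent] = []
    last_score: int | None = None
    for t, x in zip(ts, latent):
        if t < first_t or t <= 0 or t >= duration:
            continue
        score = int(np.clip(round(x), 1, 9))
        changed = last_score is None or (
            score != last_score and abs(score - last_score) >= truth.report_threshold
        )
        if changed:
            noisy = int(np.clip(round(x + rng.normal(0.0, truth.noise_sd)), 1, 9))
            events.append(PressEvent(float(t), "liking_score", noisy))
            last_score = score
    return events


def simulate_liking_trial(
    params: SemiMarkovParams,
    truth: LikingGroundTruth,
    rng: np.random.Generator,
    participant_id: str = "p01",
    trial_index: int = 1,
) -> Trial:
    """One temporal-liking task: the dominance trajectory is simulated but
    unrecorded; only the liking ratings it provokes are logged."""
    duration, path = _dominance_path(params, rng)
    events = simulate_liking_events((duration, path), truth, rng)
    return _path_to_trial(participant_id, trial_index, duration, events)


def _jitter_participant(
    params: SemiMarkovParams,
    truth: LikingGroundTruth,
    behavior_jitter: float,
    weight_jitter: float,
    rng: np.random.Generator,
) -> tuple[SemiMarkovParams, LikingGroundTruth]:
    """Participant-level heterogeneity.

    Each participant carries a per-attribute usage propensity
    g_a ~ lognormal(0, behavior_jitter) that multiplies the columns of the
    transition matrix and the initial distribution (rows renormalized,
    diagonal kept zero) — panelists differ strongly in how often they cite
    each attribute, as real TDS panels do.  Hedonic weights get
    independent multiplicative noise of sd ``weight_jitter``.
    """
    if behavior_jitter == 0 and weight_jitter == 0:
        return params, truth
    n = params.attributes.n
    g = rng.lognormal(0.0, behavior_jitter, size=n)
    P = params.transition_matrix * g[None, :]
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    p0 = params.initial_distribution * g
    p0 /= p0.sum()
    w = truth.weights * (1.0 + rng.normal(0.0, weight_jitter, size=n))
    return (
        replace(params, transition_matrix=P, initial_distribution=p0),
        replace(truth, weights=w),
    )


def simulate_panel(
    params: SemiMarkovParams | None = None,
    truth: LikingGroundTruth | None = None,
    n_participants: int = 31,
    n_trials: int = 3,
    seed: int | np.random.Generator = 0,
    behavior_jitter: float = 1.2,
    weight_jitter: float = 0.3,
) -> PanelEventLog:
    """Simulate a full panel: each participant performs the TDS task and
    the liking task ``n_trials`` times each (defaults 31 x 3, i.e. 93 TDS
    and 93 liking trials).  TDS trials use indices 1..n_trials and liking
    trials n_trials+1..2*n_trials.  Deterministic given the seed."""
    params = params or strawberry_params()
    truth = truth or strawberry_truth()
    if n_participants < 1 or n_trials < 1:
        raise ValueError("need at least one participant and one trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = max(2, len(str(n_participants)))
    trials: list[Trial] = []
    for i in range(n_participants):
        pid = f"p{i + 1:0{width}d}"
        pp, pt = _jitter_participant(params, truth, behavior_jitter, weight_jitter, rng)
        for j in range(n_trials):
            trials.append(simulate_tds_trial(pp, rng, pid, j + 1))
        for j in range(n_trials):
            trials.append(simulate_liking_trial(pp, pt, rng, pid, n_trials + j + 1))
    return PanelEventLog(trials)


def ground_truth_ranking(truth: LikingGroundTruth) -> list[str]:
    """Attributes sorted by descending hedonic weight (stable ties)."""
    order = np.argsort(-truth.weights, kind="stable")
    return [truth.attributes.names[i] for i in order]
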