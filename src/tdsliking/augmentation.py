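"""Per-participant averaging and bootstrap data augmentation.

A panel produces only one averaged tasting experience per participant,
far too little to train a time-series regressor.  Following the standard
bootstrap treatment of sensory panels, each participant's repeated trials
are first collapsed to a single mean TDS curve set and liking curve; a
bootstrap dataset then draws N participants with replacement from the
N-participant panel and averages the drawn curves.  Resampling the
*participant* (not the trial) preserves the within-participant coupling
between sensations and liking.  Repeating the draw yields arbitrarily many
training/validation curve pairs whose variability reflects the panel's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensory_io import (
    AttributeSet,
    CurvePair,
    LikingCurve,
    PanelEventLog,
    TDSCurveSet,
    TimeGrid,
    liking_curve,
    normalize_trial,
    tds_curves,
)

__all__ = [
    "ParticipantCurves",
    "BootstrapDataset",
    "DatasetCollection",
    "participant_average",
    "bootstrap_indices",
    "bootstrap_dataset",
    "generate_datasets",
]


@dataclass
class ParticipantCurves:
    participant_id: str
    pair: CurvePair


@dataclass
class BootstrapDataset:
    """One resampled curve pair plus the multiset of drawn participants."""

    pair: CurvePair
    source_indices: np.ndarray


@dataclass
class DatasetCollection:
    """Bootstrap datasets partitioned into disjoint per-model folds.

    ``train`` and ``validation`` are flat lists; model k owns the
    contiguous slices returned by :meth:`fold`.  No dataset is shared
    between models.
    """

    train: list[BootstrapDataset]
    validation: list[BootstrapDataset]
    n_models: int
    seed: int

    def fold(self, k: int) -> tuple[list[BootstrapDataset], list[BootstrapDataset]]:
        if not 0 <= k < self.n_models:
            raise IndexError(f"model index {k} out of range [0, {self.n_models})")
        nt = len(self.train) // self.n_models
        nv = len(self.validation) // self.n_models
        return (
            self.train[k * nt:(k + 1) * nt],
            self.validation[k * nv:(k + 1) * nv],
        )


def participant_average(
    log: PanelEventLog,
    grid: TimeGrid | None = None,
    attributes: AttributeSet | None = None,
) -> list[ParticipantCurves]:
    """Collapse each participant's trials to one mean curve pair.

    TDS trials feed the dominance proportions, liking trials the liking
    curve; every participant must have at least one trial of each task.
    Output order is stable (sorted by participant id).
    """
    grid = grid or TimeGrid()
    attributes = attributes or AttributeSet()
    tds_by = log.by_participant("tds")
    lik_by = log.by_participant("liking")
    pids = sorted(set(tds_by) | set(lik_by))
    out: list[ParticipantCurves] = []
    for pid in pids:
        if pid not in tds_by or pid not in lik_by:
            missing = "TDS" if pid not in tds_by else "liking"
            raise ValueError(f"participant {pid!r} has no {missing} trials")
        tds_trials = [normalize_trial(t) for t in tds_by[pid]]
        lik_trials = [normalize_trial(t) for t in lik_by[pid]]
        pair = CurvePair(
            tds_curves(tds_trials, grid, attributes),
            liking_curve(lik_trials, grid),
        )
        out.append(ParticipantCurves(pid, pair))
    return out


def bootstrap_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n participant indices uniformly with replacement."""
    if n < 1:
        raise ValueError("need at least one participant")
    return rng.integers(0, n, size=n)


def bootstrap_dataset(
    participants: list[ParticipantCurves],
    rng: np.random.Generator,
) -> BootstrapDataset:
    """One bootstrap resample: draw N of N participants with replacement
    and average their TDS matrices and liking vectors pointwise."""
    idx = bootstrap_indices(len(participants), rng)
    grid = participants[0].pair.grid
    attributes = participants[0].pair.tds.attributes
    tds = np.mean([participants[i].pair.tds.proportions for i in idx], axis=0)
    lik = np.mean([participants[i].pair.liking.values for i in idx], axis=0)
    pair = CurvePair(TDSCurveSet(grid, attributes, tds), LikingCurve(grid, lik))
    return BootstrapDataset(pair, idx)


def generate_datasets(
    participants: list[ParticipantCurves],
    n_train: int = 1600,
    n_val: int = 160,
    n_models: int = 16,
    seed: int = 0,
) -> DatasetCollection:
    """Generate the full train/validation collection for an ensemble.

    Defaults produce 1600 training and 160 validation datasets split into
    16 folds of 100/10 — one fold per model, disjoint across models.  A
    single master seed spawns one child stream per model, so the whole
    collection is a pure function of (participants, sizes, seed).
    """
    if n_train % n_models or n_val % n_models:
        raise ValueError("n_train and n_val must be divisible by n_models")
    if not participants:
        raise ValueError("need at least one participant")
    children = np.random.SeedSequence(seed).spawn(n_models)
    train: list[BootstrapDataset] = []
    val: list[BootstrapDataset] = []
    for child in children:
        rng = np.random.default_rng(child)
        train.extend(bootstrap_dataset(participants, rng) for _ in range(n_train // n_models))
        val.extend(bootstrap_dataset(participants, rng) for _ in range(n_val // n_models))
    return DatasetCollection(train, val, n_models, seed)
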