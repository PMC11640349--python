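"""Step-response sensitivity analysis of trained liking models.

A trained ESN is a black box; these probes make its input-output mapping
interpretable.  Feed the model a constant ("step") TDS input — one
attribute's dominance held at 1 and the rest at 0, or a pair held at 0.5
each — and record the maximum of the output series:

* elemental sensitivity y(a): maximum response to attribute a alone,
  i.e. how favorable the model considers a sustained, fully dominant a;
* pairwise maximum y(a, b): response to a and b sharing dominance; by
  construction y(a, a) = y(a);
* interactive sensitivity
      s(a) = (1 / (n - 1)) * sum_b [ y(a, b) - y(b) ],
  the mean lift (or penalty) attribute a adds to its partners.  If a
  leaves every partner unchanged, s(a) = 0; adding a constant to the
  whole y-matrix leaves s unchanged.

Per-model matrices from an ensemble of K independently trained models are
aggregated as mean +/- 95% CI, with a paired two-tailed t-test of s(a)
against 0 (df = K - 1) and Bonferroni correction by the number of
attributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .esn import ESNResults
from .sensory_io import AttributeSet

__all__ = [
    "StepInput",
    "SensitivityMatrix",
    "AggregateSensitivity",
    "make_step",
    "max_response",
    "sensitivity_matrix",
    "interactive_sensitivity",
    "aggregate",
    "STRAWBERRY_REFERENCE",
    "strawberry_reference_matrix",
]


@dataclass(frozen=True)
class StepInput:
    """Constant TDS input: active attribute(s) at a fixed magnitude for all
    t >= 0, every other channel at 0.  Column sums are 1 at every step."""

    attributes: AttributeSet
    active: tuple[str, ...]
    matrix: np.ndarray  # (m, n)


@dataclass
class SensitivityMatrix:
    """Symmetric n x n matrix of pairwise maximum step responses y(a, b);
    the diagonal holds the elemental sensitivities y(a)."""

    attributes: AttributeSet
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = self.attributes.n
        if self.y.shape != (n, n):
            raise ValueError("matrix shape must be (n, n)")
        if not np.allclose(self.y, self.y.T, atol=1e-12):
            raise ValueError("sensitivity matrix must be symmetric")

    @property
    def elemental(self) -> np.ndarray:
        return np.diag(self.y).copy()

    def to_frame(self) -> pd.DataFrame:
        names = list(self.attributes.names)
        return pd.DataFrame(self.y, index=names, columns=names)


def make_step(attributes: AttributeSet, active: str | Sequence[str], m: int = 101) -> StepInput:
    """Build a step input for one attribute (magnitude 1) or a pair
    (magnitude 0.5 each).  The degenerate pair (a, a) equals the single-
    attribute step, so y(a, a) = y(a) holds by construction."""
    labels = (active,) if isinstance(active, str) else tuple(active)
    if not 1 <= len(labels) <= 2:
        raise ValueError("active must name one or two attributes")
    if m < 1:
        raise ValueError("step length must be >= 1")
    u = np.zeros((m, attributes.n))
    for lab in labels:
        u[:, attributes.index(lab)] += 1.0 / len(labels)
    return StepInput(attributes, labels, u)


def max_response(results: ESNResults, step: StepInput) -> float:
    """Maximum of the model's output series under a step input, taken over
    the whole response including the initial transient.  Unclipped: may be
    negative or exceed 9."""
    return float(np.max(results.predict(step.matrix)))


def sensitivity_matrix(results: ESNResults, m: int | None = None) -> SensitivityMatrix:
    """Probe all n(n+1)/2 unordered attribute pairs of one trained model.

    Step length defaults to the model's training grid so the probe explores
    the same transient regime as training.
    """
    attrs = results.model.attributes
    m = m or results.grid.m
    n = attrs.n
    y = np.zeros((n, n))
    for i, a in enumerate(attrs.names):
        for j in range(i, n):
            b = attrs.names[j]
            y[i, j] = y[j, i] = max_response(results, make_step(attrs, (a, b), m))
    return SensitivityMatrix(attrs, y)


def interactive_sensitivity(matrix: SensitivityMatrix | np.ndarray) -> np.ndarray:
    """Interactive sensitivities s(a) from a pairwise maximum-response
    matrix: s(a) = (1/(n-1)) * sum_b (y(a,b) - y(b)).  The b = a term
    vanishes because y(a, a) = y(a)."""
    y = matrix.y if isinstance(matrix, SensitivityMatrix) else np.asarray(matrix, float)
    n = y.shape[0]
    if y.ndim != 2 or y.shape != (n, n):
        raise ValueError("need a square matrix")
    if n < 2:
        raise ValueError("interactive sensitivity needs at least 2 attributes")
    return (y - np.diag(y)[None, :]).sum(axis=1) / (n - 1)


@dataclass
class AggregateSensitivity:
    """Ensemble summary over K models.

    Pairwise table: mean y(a,b) with 95% CI half-widths (Student t,
    df = K - 1).  Interactive table: mean s(a), CI half-width, t statistic
    of the paired test against 0, raw and Bonferroni-adjusted (factor n)
    two-tailed p-values.
    """

    attributes: AttributeSet
    n_models: int
    y_mean: np.ndarray
    y_ci: np.ndarray
    s_mean: np.ndarray
    s_ci: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    s_per_model: np.ndarray  # (K, n)

    @property
    def df(self) -> int:
        return self.n_models - 1

    def pairwise_frame(self) -> pd.DataFrame:
        names = list(self.attributes.names)
        data = [
            [f"{self.y_mean[i, j]:.2f} ± {self.y_ci[i, j]:.2f}" if j <= i else ""
             for j in range(len(names))]
            for i in range(len(names))
        ]
        return pd.DataFrame(data, index=names, columns=names)

    def interactive_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensitivity": np.round(self.s_mean, 2),
                "ci95": np.round(self.s_ci, 2),
                "t": np.round(self.t, 3),
                "p": self.p_raw,
                "p_adj": np.minimum(np.round(self.p_adj, 3), 1.0),
            },
            index=list(self.attributes.names),
        )

    def summary(self) -> str:
        return (
            f"Step-response sensitivity over {self.n_models} models "
            f"(df = {self.df}, Bonferroni factor {self.attributes.n})\n\n"
            "Mean pairwise maximum responses y(a, b) ± 95% CI "
            "(diagonal: elemental sensitivities y(a)):\n"
            f"{self.pairwise_frame().to_string()}\n\n"
            "Interactive sensitivities s(a), paired two-tailed t-test vs 0:\n"
            f"{self.interactive_frame().to_string()}"
        )


def aggregate(matrices: Sequence[SensitivityMatrix]) -> AggregateSensitivity:
    """Aggregate per-model sensitivity matrices across an ensemble."""
    if len(matrices) < 2:
        raise ValueError("aggregation needs at least 2 models")
    attrs = matrices[0].attributes
    if any(m.attributes != attrs for m in matrices):
        raise ValueError("all matrices must share the attribute set")
    K = len(matrices)
    n = attrs.n
    stack = np.stack([m.y for m in matrices])  # (K, n, n)
    tq = stats.t.ppf(0.975, K - 1)
    y_sd = stack.std(axis=0, ddof=1)
    s_per_model = np.stack([interactive_sensitivity(m) for m in matrices])  # (K, n)
    s_mean = s_per_model.mean(axis=0)
    s_sd = s_per_model.std(axis=0, ddof=1)
    se = s_sd / np.sqrt(K)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, s_mean / np.where(se > 0, se, 1.0),
                     np.sign(s_mean) * np.inf)
    t = np.where((se == 0) & (s_mean == 0), 0.0, t)
    p_raw = 2 * stats.t.sf(np.abs(t), K - 1)
    return AggregateSensitivity(
        attributes=attrs,
        n_models=K,
        y_mean=stack.mean(axis=0),
        y_ci=tq * y_sd / np.sqrt(K),
        s_mean=s_mean,
        s_ci=tq * se,
        t=t,
        p_raw=p_raw,
        p_adj=np.minimum(1.0, n * p_raw),
        s_per_model=s_per_model,
    )


# ---------------------------------------------------------------------------
# reference data: strawberry ensemble
# ---------------------------------------------------------------------------

#: Mean pairwise maximum liking outputs y(a, b) reported for an
#: eight-attribute strawberry panel, averaged over a 16-model ESN ensemble
#: (liking-score units; attributes alphabetical; diagonal = elemental
#: sensitivities y(a)).  Lower triangle as printed; mirrored on load.
STRAWBERRY_REFERENCE: dict[tuple[str, str], float] = {
    ("aromatic", "aromatic"): 5.35,
    ("fruity", "aromatic"): 6.26, ("fruity", "fruity"): 7.17,
    ("green", "aromatic"): 4.71, ("green", "fruity"): 5.73, ("green", "green"): 4.46,
    ("juicy", "aromatic"): 5.82, ("juicy", "fruity"): 6.88, ("juicy", "green"): 5.47,
    ("juicy", "juicy"): 6.44,
    ("light", "aromatic"): 4.57, ("light", "fruity"): 5.52, ("light", "green"): 4.21,
    ("light", "juicy"): 5.23, ("light", "light"): 4.17,
    ("sour", "aromatic"): 5.48, ("sour", "fruity"): 6.57, ("sour", "green"): 5.06,
    ("sour", "juicy"): 6.25, ("sour", "light"): 4.93, ("sour", "sour"): 5.78,
    ("sweet", "aromatic"): 6.09, ("sweet", "fruity"): 7.11, ("sweet", "green"): 5.76,
    ("sweet", "juicy"): 7.09, ("sweet", "light"): 5.61, ("sweet", "sour"): 6.75,
    ("sweet", "sweet"): 7.25,
    ("watery", "aromatic"): 5.58, ("watery", "fruity"): 6.66, ("watery", "green"): 5.13,
    ("watery", "juicy"): 6.22, ("watery", "light"): 4.90, ("watery", "sour"): 5.95,
    ("watery", "sweet"): 6.81, ("watery", "watery"): 6.04,
}


def strawberry_reference_matrix() -> SensitivityMatrix:
    """The strawberry reference ensemble means as a SensitivityMatrix."""
    names = tuple(sorted({a for a, _ in STRAWBERRY_REFERENCE}))
    attrs = AttributeSet(names)
    y = np.zeros((attrs.n, attrs.n))
    for (a, b), v in STRAWBERRY_REFERENCE.items():
        i, j = attrs.index(a), attrs.index(b)
        y[i, j] = y[j, i] = v
    return SensitivityMatrix(attrs, y)
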