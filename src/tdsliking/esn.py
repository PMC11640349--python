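"""Leaky echo state network for TDS -> temporal-liking regression.

The model is a classical reservoir computer: an input layer feeding the n
dominance-proportion channels into a fixed, sparse, randomly weighted
recurrent reservoir of leaky-integrator tanh units, and a single linear
readout trained by ridge regression.  Only the readout is learned; the
reservoir provides a rich, fading memory of the input history, which is
what lets a linear readout map sensation dynamics onto a lagged, smoothed
hedonic response.

State update (x(0) = 0, no washout):

    x(k) = (1 - alpha) x(k-1) + alpha tanh(W x(k-1) + W_in u(k) + b)

with leaking rate alpha, recurrent matrix W rescaled to a prescribed
spectral radius rho, input matrix W_in and bias b.  The readout is
y(k) = w . (x(k), 1), fitted by ridge with an unpenalized intercept
(liking scores have a large positive mean).

API shape follows statsmodels: :class:`LeakyESN` is the model object
(construction fixes the random reservoir), ``fit`` returns an
:class:`ESNResults` carrying the trained readout, per-curve fit metrics
and ``summary()``; :func:`tune` random-searches hyperparameters and
returns the best results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import FitMetrics, score_curve
from .sensory_io import AttributeSet, CurvePair, TDSCurveSet, TimeGrid

__all__ = [
    "ReservoirConfig",
    "SearchSpace",
    "LeakyESN",
    "ESNResults",
    "init_model",
    "run_reservoir",
    "fit_readout",
    "predict",
    "tune",
]

#: Hyperparameter search ranges used for the strawberry ensemble.  Leaking
#: rate and spectral radius are single values; the rest are (low, high)
#: intervals.  Bias scaling and the ridge coefficient span two orders of
#: magnitude and are sampled log-uniformly.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "leaking_rate": (0.01, 0.01),
    "spectral_radius": (0.90, 0.90),
    "input_scaling": (0.01, 1.43),
    "bias_scaling": (0.03, 18.30),
    "input_connectivity": (0.01, 0.10),
    "reservoir_connectivity": (0.05, 0.88),
    "ridge_coefficient": (0.01, 3.48),
}

_LOG_UNIFORM = {"bias_scaling", "ridge_coefficient"}


@dataclass(frozen=True)
class ReservoirConfig:
    """Full hyperparameter set of one reservoir model.

    Defaults: the leaking rate and spectral radius are the fixed values
    used for the strawberry ensemble; ranged parameters default to the
    midpoint of their search interval (geometric midpoint for the
    log-sampled ones).
    """

    n_neurons: int = 128
    leaking_rate: float = 0.01
    spectral_radius: float = 0.90
    input_scaling: float = 0.72
    bias_scaling: float = 0.74
    input_connectivity: float = 0.055
    reservoir_connectivity: float = 0.465
    ridge_coefficient: float = 0.19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0 < self.leaking_rate <= 1:
            raise ValueError("leaking rate must lie in (0, 1]")
        if self.spectral_radius <= 0:
            raise ValueError("spectral radius must be positive")
        for name in ("input_connectivity", "reservoir_connectivity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.ridge_coefficient < 0:
            raise ValueError("ridge coefficient must be non-negative")


@dataclass(frozen=True)
class SearchSpace:
    """Random-search space over reservoir hyperparameters."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    budget: int = 200
    n_neurons: int = 128
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "SearchSpace":
        """Load search ranges from a YAML mapping of
        ``name: value`` (fixed) or ``name: [low, high]`` entries.
        Unlisted parameters keep their default ranges; values outside the
        default ranges are allowed with a warning."""
        import warnings

        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ranges = dict(DEFAULT_RANGES)
        for name, val in raw.items():
            if name not in ranges:
                raise KeyError(f"unknown hyperparameter {name!r}")
            lo, hi = (val, val) if np.isscalar(val) else (val[0], val[1])
            dlo, dhi = DEFAULT_RANGES[name]
            if lo < min(dlo, dhi) or hi > max(dlo, dhi):
                warnings.warn(
                    f"{name} range [{lo}, {hi}] lies outside the default "
                    f"search range [{dlo}, {dhi}]", stacklevel=2,
                )
            ranges[name] = (float(lo), float(hi))
        return cls(ranges=ranges, **overrides)

    def sample(self, rng: np.random.Generator) -> ReservoirConfig:
        """Draw one candidate config: log-uniform for bias scaling and the
        ridge coefficient, uniform for everything else; the reservoir seed
        is drawn from the same stream."""
        kw: dict[str, float] = {}
        for name, (lo, hi) in self.ranges.items():
            if lo == hi:
                kw[name] = lo
            elif name in _LOG_UNIFORM:
                kw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                kw[name] = float(rng.uniform(lo, hi))
        return ReservoirConfig(
            n_neurons=self.n_neurons,
            seed=int(rng.integers(0, 2**31 - 1)),
            **kw,
        )


def _sparse_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], connectivity: float
) -> np.ndarray:
    """Dense matrix with exactly round(connectivity * size) nonzero entries
    drawn uniform(-1, 1) at uniformly chosen positions."""
    size = int(np.prod(shape))
    k = int(round(connectivity * size))
    out = np.zeros(size)
    pos = rng.choice(size, size=k, replace=False)
    out[pos] = rng.uniform(-1.0, 1.0, size=k)
    return out.reshape(shape)


def _sparse_uniform_balanced(
    rng: np.random.Generator, shape: tuple[int, int], connectivity: float
) -> np.ndarray:
    """Like :func:`_sparse_uniform` but with the nonzero count balanced
    across columns (each gets floor or ceil of k / n_cols, the remainder
    assigned to random columns).  Used for the input matrix so that every
    input channel reaches the reservoir even at the sparsest connectivity —
    a channel with no connections would be invisible to the model and to
    any sensitivity probe."""
    rows, cols = shape
    k = int(round(connectivity * rows * cols))
    per_col = np.full(cols, k // cols)
    extra = rng.choice(cols, size=k % cols, replace=False)
    per_col[extra] += 1
    out = np.zeros(shape)
    for j in range(cols):
        pos = rng.choice(rows, size=min(per_col[j], rows), replace=False)
        out[pos, j] = rng.uniform(-1.0, 1.0, size=pos.size)
    return out


class LeakyESN:
    """Leaky echo state network with a fixed random reservoir.

    Construction draws and freezes all random weights from
    ``config.seed``; the same (config, seed) always yields bitwise
    identical matrices.  ``fit`` trains only the linear readout.
    """

    def __init__(self, config: ReservoirConfig, attributes: AttributeSet | None = None):
        self.config = config
        self.attributes = attributes or AttributeSet()
        n, n_in = config.n_neurons, self.attributes.n
        rng = np.random.default_rng(config.seed)
        W = _sparse_uniform(rng, (n, n), config.reservoir_connectivity)
        radius = np.max(np.abs(np.linalg.eigvals(W)))
        if radius == 0:  # all-zero draw (possible at tiny sizes): one retry
            W = _sparse_uniform(rng, (n, n), config.reservoir_connectivity)
            radius = np.max(np.abs(np.linalg.eigvals(W)))
            if radius == 0:
                raise ValueError(
                    "reservoir matrix has spectral radius 0 after masking; "
                    "cannot rescale to the configured spectral radius"
                )
        self.W = W * (config.spectral_radius / radius)
        self.W_in = _sparse_uniform_balanced(
            rng, (n, n_in), config.input_connectivity
        ) * config.input_scaling
        self.b = rng.uniform(-1.0, 1.0, size=n) * config.bias_scaling

    # -- dynamics -----------------------------------------------------------

    def states(self, u: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        """Run the reservoir over an input series.

        ``u`` is (m, n_in) for one sequence or (batch, m, n_in) for a batch
        (the batch shares no state; it is vectorized over sequences).
        Returns the states x(1..m) with matching leading shape; the initial
        state x(0) (default zero) is not recorded.
        """
        u = np.asarray(u, dtype=float)
        single = u.ndim == 2
        if single:
            u = u[None]
        if u.ndim != 3 or u.shape[2] != self.W_in.shape[1]:
            raise ValueError(
                f"input must be (m, {self.W_in.shape[1]}) or (batch, m, {self.W_in.shape[1]})"
            )
        batch, m, _ = u.shape
        n = self.config.n_neurons
        alpha = self.config.leaking_rate
        x = np.zeros((batch, n)) if x0 is None else np.broadcast_to(
            np.asarray(x0, dtype=float), (batch, n)
        ).copy()
        drive = u @ self.W_in.T + self.b  # (batch, m, n)
        out = np.empty((batch, m, n))
        for k in range(m):
            x = (1 - alpha) * x + alpha * np.tanh(x @ self.W.T + drive[:, k])
            out[:, k] = x
        return out[0] if single else out

    # -- training -----------------------------------------------------------

    def _design(self, inputs: np.ndarray) -> np.ndarray:
        """Stacked reservoir states with a constant-1 intercept column."""
        st = self.states(inputs)  # (batch, m, n)
        flat = st.reshape(-1, st.shape[-1])
        return np.hstack([flat, np.ones((flat.shape[0], 1))])

    def fit(self, train_pairs: Sequence[CurvePair]) -> "ESNResults":
        """Ridge-train the readout on curve pairs sharing one grid.

        Solves argmin ||X w - y||^2 + lambda ||w_states||^2 by normal
        equations; the intercept column is not penalized.
        """
        if not train_pairs:
            raise ValueError("need at least one training pair")
        grid = train_pairs[0].grid
        if any(p.grid != grid for p in train_pairs):
            raise ValueError("all training pairs must share the grid")
        inputs = np.stack([p.tds.proportions for p in train_pairs])
        y = np.concatenate([p.liking.values for p in train_pairs])
        X = self._design(inputs)
        lam = self.config.ridge_coefficient
        A = X.T @ X
        A[np.diag_indices(A.shape[0] - 1)] += lam  # leave intercept unpenalized
        try:
            w = np.linalg.solve(A, X.T @ y)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular readout system; use a ridge coefficient > 0"
            ) from None
        return ESNResults(self, w, grid, n_train=len(train_pairs))


@dataclass
class ESNResults:
    """A trained readout on a fixed reservoir.

    ``readout`` has length n_neurons + 1; the last entry is the intercept.
    """

    model: LeakyESN
    readout: np.ndarray
    grid: TimeGrid
    n_train: int

    @property
    def config(self) -> ReservoirConfig:
        return self.model.config

    def predict(self, tds: TDSCurveSet | np.ndarray) -> np.ndarray:
        """Predicted liking series for one TDS input (length m).

        The output is not clipped: step probes may drive it outside the
        1-9 score range.
        """
        u = tds.proportions if isinstance(tds, TDSCurveSet) else np.asarray(tds, float)
        st = self.model.states(u)
        return st @ self.readout[:-1] + self.readout[-1]

    def score(self, pairs: Sequence[CurvePair]) -> list[FitMetrics]:
        """Per-curve RMSE and R^2 against observed liking."""
        return [
            score_curve(p.liking.values, self.predict(p.tds)) for p in pairs
        ]

    def rmse(self, pairs: Sequence[CurvePair]) -> float:
        """Mean per-curve RMSE (the tuning loss)."""
        return float(np.mean([m.rmse for m in self.score(pairs)]))

    def summary(self, val_pairs: Sequence[CurvePair] | None = None) -> str:
        cfg = self.config
        lines = [
            "Leaky ESN temporal-liking model",
            "=" * 46,
            f"reservoir neurons      {cfg.n_neurons}",
            f"leaking rate           {cfg.leaking_rate:g}",
            f"spectral radius        {cfg.spectral_radius:g}",
            f"input scaling          {cfg.input_scaling:.4g}",
            f"bias scaling           {cfg.bias_scaling:.4g}",
            f"input connectivity     {cfg.input_connectivity:.4g}",
            f"reservoir connectivity {cfg.reservoir_connectivity:.4g}",
            f"ridge coefficient      {cfg.ridge_coefficient:.4g}",
            f"seed                   {cfg.seed}",
            f"training curve sets    {self.n_train}",
        ]
        if val_pairs:
            ms = self.score(val_pairs)
            r2 = [m.r2 for m in ms if m.r2_defined]
            lines += [
                f"validation curve sets  {len(val_pairs)}",
                f"validation RMSE (mean) {np.mean([m.rmse for m in ms]):.3f}",
                f"validation R2 (median) {np.median(r2):.3f}" if r2 else "validation R2  undefined",
            ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        """Archive config and all matrices as named arrays (.npz)."""
        cfg = self.config
        np.savez(
            path,
            W=self.model.W,
            W_in=self.model.W_in,
            b=self.model.b,
            readout=self.readout,
            grid_m=np.array(self.grid.m),
            n_train=np.array(self.n_train),
            attributes=np.array(self.model.attributes.names),
            config=np.array([
                cfg.n_neurons, cfg.leaking_rate, cfg.spectral_radius,
                cfg.input_scaling, cfg.bias_scaling, cfg.input_connectivity,
                cfg.reservoir_connectivity, cfg.ridge_coefficient, cfg.seed,
            ]),
        )

    @classmethod
    def load(cls, path: str) -> "ESNResults":
        with np.load(path, allow_pickle=False) as z:
            c = z["config"]
            cfg = ReservoirConfig(
                n_neurons=int(c[0]), leaking_rate=float(c[1]),
                spectral_radius=float(c[2]), input_scaling=float(c[3]),
                bias_scaling=float(c[4]), input_connectivity=float(c[5]),
                reservoir_connectivity=float(c[6]), ridge_coefficient=float(c[7]),
                seed=int(c[8]),
            )
            model = LeakyESN(cfg, AttributeSet(tuple(str(a) for a in z["attributes"])))
            # archived matrices are authoritative (guards against RNG drift)
            model.W = z["W"]
            model.W_in = z["W_in"]
            model.b = z["b"]
            return cls(model, z["readout"], TimeGrid(int(z["grid_m"])), int(z["n_train"]))


def tune(
    space: SearchSpace,
    train_pairs: Sequence[CurvePair],
    val_pairs: Sequence[CurvePair],
    attributes: AttributeSet | None = None,
) -> ESNResults:
    """Random hyperparameter search minimizing mean validation RMSE.

    Samples ``space.budget`` configs, trains each, scores it on the
    validation pairs and returns the results object of the argmin (ties
    go to the earlier sample).
    """
    if space.budget < 1:
        raise ValueError("search budget must be >= 1")
    if not val_pairs:
        raise ValueError("need at least one validation pair")
    rng = np.random.default_rng(space.seed)
    best: ESNResults | None = None
    best_loss = np.inf
    for _ in range(space.budget):
        cfg = space.sample(rng)
        res = LeakyESN(cfg, attributes).fit(train_pairs)
        loss = res.rmse(val_pairs)
        if loss < best_loss:
            best, best_loss = res, loss
    assert best is not None
    return best


# -- thin functional aliases -------------------------------------------------

def init_model(config: ReservoirConfig, attributes: AttributeSet | None = None) -> LeakyESN:
    return LeakyESN(config, attributes)


def run_reservoir(model: LeakyESN, u: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
    return model.states(u, x0=x0)


def fit_readout(model: LeakyESN, train_pairs: Sequence[CurvePair]) -> ESNResults:
    return model.fit(train_pairs)


def predict(results: ESNResults, tds: TDSCurveSet | np.ndarray) -> np.ndarray:
    return results.predict(tds)
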