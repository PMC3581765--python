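"""Contralateral MLP regression of wrist angles from EMG features.

One small multilayer perceptron per wrist DoF maps the 70-dimensional TDAR
feature vector (7 channels x 10 features) to the contralateral joint angle.
The hidden layer has three tanh units and the output is linear; inputs are
z-scored with statistics from the training rows only; training is full-batch
L-BFGS, deterministic given the seed.

Cross-validation follows the study design: per run, the data are split into
five contiguous blocks (randomly assigned to folds), 4/5 training and 1/5
testing. Contiguous blocks — rather than window-wise random sampling — keep
the test honest under the 60% window overlap; train windows whose sample
span overlaps a test block are additionally dropped (guard band).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .features import WindowSpec

__all__ = [
    "SCENARIO_RUNS",
    "SCENARIO_DOFS",
    "SCENARIOS",
    "MlpConfig",
    "MlpModel",
    "TrainTestSplit",
    "train_mlp",
    "predict",
    "make_folds",
    "assemble",
    "save_model",
    "load_model",
]

#: Analysis scenarios -> movement runs used (per the run protocol table).
SCENARIO_RUNS = {
    "DoF12": (1, 2),
    "DoF13": (3, 4),
    "DoF23": (5, 6),
    "DoF123": (1, 2, 3, 4, 5, 6, 7),
}
#: DoFs evaluated in each scenario (the articulated ones).
SCENARIO_DOFS = {
    "DoF12": (1, 2),
    "DoF13": (1, 3),
    "DoF23": (2, 3),
    "DoF123": (1, 2, 3),
}
SCENARIOS = tuple(SCENARIO_RUNS)


@dataclass(frozen=True)
class MlpConfig:
    hidden_units: int = 3
    activation: str = "tanh"
    solver: str = "lbfgs"
    max_iter: int = 400
    alpha: float = 1e-4
    tol: float = 1e-6


@dataclass
class MlpModel:
    """A trained per-DoF regressor with its input standardization.

    Weights are stored as plain arrays (hidden ``w1``/``b1``, output
    ``w2``/``b2``) so prediction and serialization do not depend on the
    training backend. ``degenerate_constant`` is set instead when the
    training targets had zero variance.
    """

    dof: int
    seed: int
    mean: np.ndarray
    scale: np.ndarray
    w1: np.ndarray | None = None
    b1: np.ndarray | None = None
    w2: np.ndarray | None = None
    b2: np.ndarray | None = None
    activation: str = "tanh"
    degenerate_constant: float | None = None
    config: MlpConfig = field(default_factory=MlpConfig)

    @property
    def input_dim(self) -> int:
        return self.mean.shape[0]


def _standardize_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # zero-variance column guard
    return mean, scale


def train_mlp(
    features: np.ndarray,
    targets: np.ndarray,
    dof: int,
    seed: int,
    config: MlpConfig = MlpConfig(),
) -> MlpModel:
    """Fit one MLP mapping feature rows to the angle of one DoF (degrees).

    ``targets`` may be (n, 3) (a column is selected by ``dof``) or (n,).
    Training is deterministic given ``seed``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if y.ndim == 2:
        y = y[:, dof - 1]
    if dof not in (1, 2, 3):
        raise ValueError("dof must be 1, 2, or 3")
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and targets row counts differ")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite features or targets")
    mean, scale = _standardize_params(x)
    if y.std() == 0:
        return MlpModel(dof=dof, seed=seed, mean=mean, scale=scale,
                        degenerate_constant=float(y[0]), config=config)
    xs = (x - mean) / scale
    reg = MLPRegressor(
        hidden_layer_sizes=(config.hidden_units,),
        activation=config.activation,
        solver=config.solver,
        max_iter=config.max_iter,
        alpha=config.alpha,
        tol=config.tol,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        # hitting the iteration cap is an accepted stopping rule here
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        reg.fit(xs, y)
    if not all(np.all(np.isfinite(c)) for c in reg.coefs_):
        raise RuntimeError("MLP training diverged (non-finite weights)")
    return MlpModel(
        dof=dof, seed=seed, mean=mean, scale=scale,
        w1=reg.coefs_[0].copy(), b1=reg.intercepts_[0].copy(),
        w2=reg.coefs_[1].copy(), b2=reg.intercepts_[1].copy(),
        activation=config.activation, config=config,
    )


_ACTIVATIONS = {
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "identity": lambda z: z,
}


def predict(model: MlpModel, features: np.ndarray) -> np.ndarray:
    """Angle estimates (degrees), one per feature row."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model input dim {model.input_dim}"
        )
    if model.degenerate_constant is not None:
        return np.full(x.shape[0], model.degenerate_constant)
    xs = (x - model.mean) / model.scale
    h = _ACTIVATIONS[model.activation](xs @ model.w1 + model.b1)
    return (h @ model.w2 + model.b2).ravel()


# ---------------------------------------------------------------------------
# Folds and scenario assembly
# ---------------------------------------------------------------------------

RunKey = tuple[str, int]  # (position, run_index)


@dataclass
class Fold:
    """Per-(position, run) window-index partition for one CV fold."""

    index: int
    train: dict[RunKey, np.ndarray]
    test: dict[RunKey, np.ndarray]
    n_windows: dict[RunKey, int]


@dataclass
class TrainTestSplit:
    """Row selections for one (scenario, training config, fold) evaluation."""

    scenario: str
    training_positions: tuple[str, ...]
    fold: int
    train: dict[RunKey, np.ndarray]
    test_intra: dict[str, dict[RunKey, np.ndarray]]
    test_inter: dict[str, dict[RunKey, np.ndarray]]


def _guard_windows(spec: WindowSpec, rate_hz: float) -> int:
    """Windows whose span overlaps a neighbor: floor((win-1)/step)."""
    win = spec.window_samples(rate_hz)
    step = spec.step_samples(rate_hz)
    return (win - 1) // step


def make_folds(
    run_lengths: dict[RunKey, int],
    k: int = 5,
    seed: int = 0,
    guard: int | None = None,
    spec: WindowSpec | None = None,
    rate_hz: float = 1024.0,
) -> list[Fold]:
    """Contiguous-block k-fold splits per run, block-to-fold assignment seeded.

    Each run is partitioned into ``k`` contiguous blocks whose sizes differ by
    at most one; fold i tests one block of every run (a seeded permutation
    decides which) and trains on the rest minus ``guard`` windows adjacent to
    each test-block boundary, so no training window's sample span overlaps a
    test window's span.
    """
    if guard is None:
        guard = _guard_windows(spec or WindowSpec(), rate_hz)
    rng = np.random.default_rng(seed)
    assignments: dict[RunKey, list[np.ndarray]] = {}
    perms: dict[RunKey, np.ndarray] = {}
    for key in sorted(run_lengths):
        n = run_lengths[key]
        if n < k * (2 * guard + 1):
            raise ValueError(
                f"run {key} with {n} windows too short for {k} contiguous blocks"
            )
        assignments[key] = np.array_split(np.arange(n), k)
        perms[key] = rng.permutation(k)
    folds = []
    for i in range(k):
        train: dict[RunKey, np.ndarray] = {}
        test: dict[RunKey, np.ndarray] = {}
        for key in sorted(run_lengths):
            blocks = assignments[key]
            ti = int(perms[key][i])
            test_idx = blocks[ti]
            lo, hi = test_idx[0], test_idx[-1]
            keep = np.concatenate([b for j, b in enumerate(blocks) if j != ti])
            keep = keep[(keep < lo - guard) | (keep > hi + guard)]
            train[key] = np.sort(keep)
            test[key] = test_idx
        folds.append(Fold(index=i, train=train, test=test,
                          n_windows=dict(run_lengths)))
    return folds


def assemble(
    scenario: str,
    training_positions: tuple[str, ...] | list[str],
    fold: Fold,
    positions: tuple[str, ...] = ("POS1", "POS2", "POS3"),
) -> TrainTestSplit:
    """Select train/test rows for a scenario, training position set, and fold.

    Training rows are the fold's training blocks of the scenario's runs at the
    training position(s) (concatenated when pooled). Intra-position test rows
    are the fold's test blocks at each training position; inter-position test
    rows are ALL windows of the scenario's runs at every other position.
    """
    if scenario not in SCENARIO_RUNS:
        raise ValueError(f"unknown scenario {scenario!r}")
    training_positions = tuple(training_positions)
    if not training_positions or any(p not in positions for p in training_positions):
        raise ValueError(f"training positions must be a non-empty subset of {positions}")
    runs = SCENARIO_RUNS[scenario]
    train: dict[RunKey, np.ndarray] = {}
    test_intra: dict[str, dict[RunKey, np.ndarray]] = {}
    for p in training_positions:
        for r in runs:
            train[(p, r)] = fold.train[(p, r)]
        test_intra[p] = {(p, r): fold.test[(p, r)] for r in runs}
    test_inter: dict[str, dict[RunKey, np.ndarray]] = {}
    for p in positions:
        if p in training_positions:
            continue
        test_inter[p] = {
            (p, r): np.arange(fold.n_windows[(p, r)]) for r in runs
        }
    return TrainTestSplit(
        scenario=scenario,
        training_positions=training_positions,
        fold=fold.index,
        train=train,
        test_intra=test_intra,
        test_inter=test_inter,
    )


# ---------------------------------------------------------------------------
# Model serialization (portable JSON)
# ---------------------------------------------------------------------------


def save_model(path: str | Path, model: MlpModel) -> None:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    payload = {
        "dof": model.dof,
        "seed": model.seed,
        "activation": model.activation,
        "mean": arr(model.mean),
        "scale": arr(model.scale),
        "w1": arr(model.w1),
        "b1": arr(model.b1),
        "w2": arr(model.w2),
        "b2": arr(model.b2),
        "degenerate_constant": model.degenerate_constant,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> MlpModel:
    d = json.loads(Path(path).read_text())

    def arr(v):
        return None if v is None else np.asarray(v, dtype=float)

    return MlpModel(
        dof=int(d["dof"]), seed=int(d["seed"]),
        mean=arr(d["mean"]), scale=arr(d["scale"]),
        w1=arr(d["w1"]), b1=arr(d["b1"]), w2=arr(d["w2"]), b2=arr(d["b2"]),
        activation=d["activation"],
        degenerate_constant=d["degenerate_constant"],
    )
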