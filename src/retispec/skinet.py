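"""SKiNET: supervised Kohonen self-organizing map with discriminant feature
extraction (SOMDI).

The model is a hexagonal grid of neurons.  Each neuron carries two weight
vectors: a *spectral* weight vector (one value per wavenumber channel) and a
nonnegative *class* weight vector (one value per class).  Training presents
spectra one at a time; the best matching unit (BMU) is found by **cosine
similarity against the spectral weights only** — class weights ride along as
appended one-hot label components updated by the same neighborhood rule but
excluded from the match, so the class information never influences the
unsupervised topology.  After training:

* classification: a query's BMU votes with its class weights;
* SOMDI: for each class, the spectral weights of the neurons that this class
  "owns" (class-weight argmax, restricted to neurons that activated during
  training) are averaged, weighted by the class weight, and contrasted
  against the mean weight of all activated neurons — peaks of the resulting
  profile are the wavenumbers that drive the class separation.

Defaults follow the published configuration: 10x10 grid (20x20 supported),
nine epochs, initial learning rate 0.3, initial neighborhood radius
two-thirds of the grid edge length, cosine similarity, learning rate and
radius decaying linearly to (0.01*alpha0, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SOMConfig",
    "SOMModel",
    "SOMDIResult",
    "ConfusionMatrix",
    "hex_grid_coords",
    "stratified_split",
    "find_bmu",
    "total_steps",
    "train",
    "somdi",
    "predict",
    "predict_batch",
    "kfold_cv",
    "evaluate_repeated",
]


@dataclass
class SOMConfig:
    """Training configuration for the supervised SOM."""

    rows: int = 10
    cols: int = 10
    epochs: int = 9
    steps: int | None = None  # overrides epochs * n_samples when set
    alpha0: float = 0.3
    radius0: float | None = None  # default: (2/3) * max(rows, cols)
    metric: str = "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.alpha0 <= 1.0:
            raise ValueError("alpha0 must be in (0, 1]")
        if self.radius0 is None:
            self.radius0 = (2.0 / 3.0) * max(self.rows, self.cols)
        if self.radius0 <= 0:
            raise ValueError("radius0 must be > 0")
        if self.metric != "cosine":
            raise ValueError("only the cosine similarity metric is supported")
        if self.steps is not None and self.steps < 1:
            raise ValueError("steps must be >= 1 when given")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols


def hex_grid_coords(rows: int, cols: int) -> np.ndarray:
    """Hex-center positions for an offset grid with unit spacing: odd rows
    are shifted half a cell, row pitch is sqrt(3)/2."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = c + 0.5 * (r % 2)
    y = r * (math.sqrt(3.0) / 2.0)
    return np.stack([x.ravel(), y.ravel()], axis=1).astype(float)


@dataclass
class SOMModel:
    config: SOMConfig
    weights: np.ndarray        # (n_neurons, n_channels) spectral weights
    class_weights: np.ndarray  # (n_neurons, n_classes), nonnegative
    grid_coords: np.ndarray    # (n_neurons, 2) hex centers
    class_names: list
    activation_counts: np.ndarray  # (n_neurons, n_classes) training tally
    axis: np.ndarray | None = None  # wavenumbers of the weight channels

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite spectral weights")
        if np.any(self.class_weights < 0):
            raise ValueError("class weights must be nonnegative")
        if self.grid_coords.shape[0] != self.weights.shape[0]:
            raise ValueError("one grid coordinate required per neuron")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class SOMDIResult:
    """Per-class discriminant profiles over the spectral axis."""

    class_names: list
    axis: np.ndarray
    profiles: np.ndarray  # (n_classes, n_channels)
    peaks: dict = field(default_factory=dict)  # class -> [(wavenumber, intensity)]

    def profile(self, class_name) -> np.ndarray:
        return self.profiles[self.class_names.index(class_name)]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = spectra of true class i predicted as class j."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")
        if self.counts.shape != (len(self.class_names),) * 2:
            raise ValueError("counts must be square over class_names")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per class, reserve round(test_fraction * n) items uniformly at random
    as test; return (train_idx, test_idx) index arrays partitioning the data."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 items")
        n_test = int(math.floor(test_fraction * idx.size + 0.5))
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))


# ---------------------------------------------------------------------------
# BMU search and training
# ---------------------------------------------------------------------------

def total_steps(config: SOMConfig, n_samples: int) -> int:
    """Total weight updates a training run will perform: epochs * n_samples
    unless ``config.steps`` overrides it."""
    return config.steps if config.steps is not None else config.epochs * n_samples


def _bmu_index(weights: np.ndarray, x: np.ndarray) -> int:
    xnorm = float(np.linalg.norm(x))
    if xnorm == 0.0:
        raise ValueError("zero-norm input has no cosine direction")
    wnorm = np.linalg.norm(weights, axis=1)
    sims = (weights @ x) / (np.where(wnorm == 0.0, np.inf, wnorm) * xnorm)
    return int(np.argmax(sims))  # argmax takes the lowest index on ties


def find_bmu(model: SOMModel, x: np.ndarray) -> int:
    """Best matching unit by cosine similarity over spectral weights only."""
    return _bmu_index(model.weights, np.asarray(x, dtype=float))


def train(config: SOMConfig, X: np.ndarray, labels, axis: np.ndarray | None = None
          ) -> SOMModel:
    """Train the supervised SOM.

    Spectral weights start uniform within the per-channel data range (seeded);
    class weights start uniform over classes.  At step t of T, one training
    spectrum is presented, its BMU found from spectral weights alone, and
    every neuron n is pulled toward the sample by
    ``w_n += alpha(t) * h(n, bmu, t) * (x - w_n)`` with a Gaussian
    neighborhood h over hex-center distance; the class weights are pulled
    toward the sample's one-hot label by the same rule.  alpha decays
    linearly from alpha0 to 0.01*alpha0 and the radius from radius0 to 1.
    T = epochs * |X| unless ``config.steps`` overrides (shuffled epochs when
    T <= epochs*|X|, sampling with replacement beyond that).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValueError("X must be (n_samples, n_channels) aligned with labels")
    if axis is not None and np.asarray(axis).size != X.shape[1]:
        raise ValueError("axis length must match the number of channels")
    class_names = [c for c in np.unique(labels)]
    n, n_ch, n_cls = X.shape[0], X.shape[1], len(class_names)
    y_idx = np.searchsorted(np.unique(labels), labels)
    onehot = np.eye(n_cls)[y_idx]

    rng = np.random.default_rng(config.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    W = rng.uniform(size=(config.n_neurons, n_ch)) * (hi - lo) + lo
    CW = np.full((config.n_neurons, n_cls), 1.0 / n_cls)
    coords = hex_grid_coords(config.rows, config.cols)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    T = total_steps(config, n)
    if T <= config.epochs * n:
        order = np.concatenate(
            [rng.permutation(n) for _ in range(math.ceil(T / n))])[:T]
    else:
        order = rng.integers(0, n, size=T)

    alpha0, radius0 = config.alpha0, float(config.radius0)
    for t in range(T):
        frac = t / (T - 1) if T > 1 else 0.0
        alpha = alpha0 * (1.0 - 0.99 * frac)
        radius = radius0 + (1.0 - radius0) * frac
        i = order[t]
        x = X[i]
        bmu = _bmu_index(W, x)
        h = np.exp(-d2[bmu] / (2.0 * radius * radius))
        h[h < 1e-6] = 0.0
        lr = (alpha * h)[:, None]
        W += lr * (x - W)
        CW += lr * (onehot[i] - CW)
        if t % 1000 == 999 and not np.all(np.isfinite(W)):
            raise FloatingPointError(f"non-finite weights at training step {t}")
    if not np.all(np.isfinite(W)):
        raise FloatingPointError("non-finite weights after training")

    counts = np.zeros((config.n_neurons, n_cls))
    for i in range(n):
        counts[_bmu_index(W, X[i]), y_idx[i]] += 1
    return SOMModel(config, W, np.clip(CW, 0.0, None), coords, class_names,
                    counts, None if axis is None else np.asarray(axis, float))


# ---------------------------------------------------------------------------
# SOMDI and prediction
# ---------------------------------------------------------------------------

def somdi(model: SOMModel) -> SOMDIResult:
    """Discriminant profile per class.

    For class c, take the neurons whose class-weight argmax is c and that
    activated at least once in training; average class_weight[c] * spectral
    weight over them and subtract the mean spectral weight of all activated
    neurons.  Peaks (local maxima, ranked by height) mark the wavenumbers
    most responsible for the class's clustering.
    """
    activated = model.activation_counts.sum(axis=1) > 0
    if not activated.any():
        raise ValueError("model has no activated neurons; was it trained?")
    owner = np.argmax(model.class_weights, axis=1)
    global_mean = model.weights[activated].mean(axis=0)
    axis = (model.axis if model.axis is not None
            else np.arange(model.weights.shape[1], dtype=float))
    profiles = np.zeros((model.n_classes, model.weights.shape[1]))
    peaks: dict = {}
    for k, cls in enumerate(model.class_names):
        sel = activated & (owner == k)
        if not sel.any():
            warnings.warn(f"no activated neuron owned by class {cls!r}; "
                          "zero SOMDI profile", UserWarning)
            peaks[cls] = []
            continue
        weighted = model.class_weights[sel, k][:, None] * model.weights[sel]
        profiles[k] = weighted.mean(axis=0) - global_mean
        locs, props = find_peaks(profiles[k], height=0.0)
        order = np.argsort(props["peak_heights"])[::-1]
        peaks[cls] = [(float(axis[locs[j]]), float(props["peak_heights"][j]))
                      for j in order]
    return SOMDIResult(model.class_names, axis, profiles, peaks)


def predict(model: SOMModel, x: np.ndarray):
    """Class label for one spectrum: argmax of the BMU's class weights.

    A BMU that never activated during training abstains; the label then comes
    from the nearest (hex grid distance) activated neuron.
    """
    bmu = find_bmu(model, np.asarray(x, dtype=float))
    activated = model.activation_counts.sum(axis=1) > 0
    if not activated[bmu]:
        if not activated.any():
            raise ValueError("no activated neurons; cannot predict")
        d = np.linalg.norm(model.grid_coords - model.grid_coords[bmu], axis=1)
        d[~activated] = np.inf
        bmu = int(np.argmin(d))
    return model.class_names[int(np.argmax(model.class_weights[bmu]))]


def predict_batch(model: SOMModel, X: np.ndarray) -> np.ndarray:
    return np.array([predict(model, x) for x in np.asarray(X, dtype=float)])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _derived_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2 ** 31))


def kfold_cv(config: SOMConfig, X: np.ndarray, labels, k: int = 10,
             seed: int | None = None) -> dict:
    """Stratified k-fold cross-validated accuracy of the supervised SOM."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} items (smallest has {counts.min()})")
    seed = config.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    accs = []
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        cfg = SOMConfig(rows=config.rows, cols=config.cols, epochs=config.epochs,
                        steps=config.steps, alpha0=config.alpha0,
                        radius0=config.radius0, seed=_derived_seed(seed, fold))
        model = train(cfg, X[tr], labels[tr])
        pred = predict_batch(model, X[te])
        accs.append(float(np.mean(pred == labels[te])))
    accs = np.array(accs)
    return {"accuracies": accs, "mean": float(accs.mean()),
            "sd": float(accs.std(ddof=1))}


def evaluate_repeated(config: SOMConfig, X_train, y_train, X_test, y_test,
                      n_repeats: int = 10) -> dict:
    """Train `n_repeats` SOMs from distinct seeded initializations, classify
    the held-out test set each time, and average the confusion matrices."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train, y_test = np.asarray(y_train), np.asarray(y_test)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    class_names = [c for c in np.unique(np.concatenate([y_train, y_test]))]
    k = len(class_names)
    mats, accs, models = [], [], []
    for r in range(n_repeats):
        cfg = SOMConfig(rows=config.rows, cols=config.cols, epochs=config.epochs,
                        steps=config.steps, alpha0=config.alpha0,
                        radius0=config.radius0, seed=_derived_seed(config.seed, r))
        model = train(cfg, X_train, y_train)
        pred = predict_batch(model, X_test)
        m = np.zeros((k, k))
        for yt, yp in zip(y_test, pred):
            m[class_names.index(yt), class_names.index(yp)] += 1
        mats.append(m)
        accs.append(float(np.trace(m) / m.sum()))
        models.append(model)
    mean_cm = ConfusionMatrix(np.mean(mats, axis=0), class_names)
    return {"confusion": mean_cm,
            "per_repeat": [ConfusionMatrix(m, class_names) for m in mats],
            "accuracies": np.array(accs), "models": models}
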