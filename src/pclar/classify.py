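"""Particle classification from angular polarization profiles.

Each particle's q(θ) and u(θ) (1458 angles each) are concatenated into a
1×2916 vector, affinely mapped from [−1, 1] to [0, 1] and realigned row-major
into a 54×54 grayscale image — a lossless, reversible re-arrangement that
turns the angular oscillation structure into stripes and speckles a small
neural network separates well.

Angular selection strategies restrict the classifier's input to study how
much the continuously large angular range contributes: the single backmost
angle (120°), three discrete angles (60°, 90°, 120°), either half-range
(60°–90° or 90°–120°), or the full range.

Because the laboratory specimens are not publicly available, a synthetic
six-class benchmark mirrors their property spread at desk scale: polystyrene
spheres of 5 and 10 μm, a porous-sphere proxy (smoothed and damped 10 μm PS),
a 10 μm silica sphere, and two microalgae effective-sphere proxies of 20 and
30 μm with low index contrast; per-particle size jitter and additive (q, u)
noise emulate population spread and measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier

from .mie import OpticalContext, SphereParticle, simulate_pclar
from .profiles import N_ANGLES, PCLARProfile, default_angle_grid

__all__ = [
    "IMAGE_SIDE",
    "FEATURE_LENGTH",
    "STRATEGIES",
    "BENCHMARK_CLASSES",
    "LabeledDataset",
    "ConfusionMatrix",
    "ScatteringClassifier",
    "realign_features",
    "unrealign_features",
    "apply_strategy",
    "strategy_feature_length",
    "make_benchmark_dataset",
    "split_dataset",
    "train_classifier",
    "evaluate",
    "mixture_composition",
]

IMAGE_SIDE = 54
FEATURE_LENGTH = 2 * N_ANGLES  # 2916 = 54²

STRATEGIES = ("single_120", "discrete_60_90_120", "range_60_90",
              "range_90_120", "full_60_120")


def realign_features(profile: PCLARProfile | tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """[q, u] → 54×54 grayscale image (values in [0, 1], row-major)."""
    q, u = (profile.q, profile.u) if isinstance(profile, PCLARProfile) else profile
    if len(q) != N_ANGLES or len(u) != N_ANGLES:
        raise ValueError(f"profile must have {N_ANGLES} angles")
    vec = np.concatenate([q, u])
    return ((vec + 1.0) / 2.0).reshape(IMAGE_SIDE, IMAGE_SIDE)


def unrealign_features(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`realign_features` (exact bijection)."""
    if image.shape != (IMAGE_SIDE, IMAGE_SIDE):
        raise ValueError(f"image must be {IMAGE_SIDE}x{IMAGE_SIDE}")
    vec = image.reshape(-1) * 2.0 - 1.0
    return vec[:N_ANGLES].copy(), vec[N_ANGLES:].copy()


def _nearest_pixel(theta: float) -> int:
    grid = default_angle_grid()
    return int(np.argmin(np.abs(grid - theta)))


def apply_strategy(profile: PCLARProfile, strategy: str) -> np.ndarray:
    """Feature vector of one profile under an angular selection strategy.

    All outputs use the same fixed affine map [−1, 1] → [0, 1] so absolute
    polarization levels stay class-informative.  The two half-ranges
    partition the angle grid exactly: pixels with θ ≤ 90° (1..729) belong to
    60°–90°, the rest (730..1458) to 90°–120°.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if len(profile) != N_ANGLES:
        raise ValueError(f"profile must have {N_ANGLES} angles")
    q, u = profile.q, profile.u
    if strategy == "full_60_120":
        return realign_features(profile).reshape(-1)
    if strategy == "single_120":
        k = _nearest_pixel(120.0)
        sel = np.array([q[k], u[k]])
    elif strategy == "discrete_60_90_120":
        ks = [_nearest_pixel(a) for a in (60.0, 90.0, 120.0)]
        sel = np.concatenate([q[ks], u[ks]])
    elif strategy == "range_60_90":
        mask = profile.theta_deg <= 90.0
        sel = np.concatenate([q[mask], u[mask]])
    else:  # range_90_120
        mask = profile.theta_deg > 90.0
        sel = np.concatenate([q[mask], u[mask]])
    return (sel + 1.0) / 2.0


def strategy_feature_length(strategy: str) -> int:
    return {"single_120": 2, "discrete_60_90_120": 6, "range_60_90": 1458,
            "range_90_120": 1458, "full_60_120": FEATURE_LENGTH}[strategy]


@dataclass
class LabeledDataset:
    """Profiles stored as (n, 1458) q and u arrays with integer labels."""

    q: np.ndarray
    u: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    split: np.ndarray | None = None  # "train"/"test" tag per sample

    def __len__(self) -> int:
        return len(self.labels)

    def features(self, strategy: str = "full_60_120") -> np.ndarray:
        out = np.empty((len(self), strategy_feature_length(strategy)))
        for i in range(len(self)):
            prof = PCLARProfile(theta_deg=default_angle_grid(),
                                q=self.q[i], u=self.u[i])
            out[i] = apply_strategy(prof, strategy)
        return out

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(q=self.q[mask], u=self.u[mask],
                              labels=self.labels[mask],
                              class_names=self.class_names,
                              split=None if self.split is None else self.split[mask])


#: class name → (diameter μm, refractive index, structural proxy tag)
BENCHMARK_CLASSES: dict[str, tuple[float, complex, str]] = {
    "PS5": (5.0, 1.598 + 0.0j, "sphere"),
    "PS10": (10.0, 1.598 + 0.0j, "sphere"),
    "PSH": (10.0, 1.598 + 0.0j, "porous_proxy"),
    "SiO2": (10.0, 1.451 + 0.003j, "sphere"),
    "EU": (20.0, 1.37 + 0.004j, "sphere"),
    "CY": (30.0, 1.35 + 0.004j, "sphere"),
}

_PSH_SMOOTH_PIXELS = 49  # ≈2° boxcar: damps the sharp oscillations of solid PS10


def _smooth(v: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    pad = np.pad(v, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def make_benchmark_dataset(n_per_class: int = 1000,
                           seed: int = 0,
                           context: OpticalContext | None = None,
                           classes: dict[str, tuple[float, complex, str]] | None = None,
                           size_cv: float = 0.03,
                           noise_sigma: float = 0.02) -> LabeledDataset:
    """Simulated population of labelled profiles over the benchmark classes.

    Per particle the diameter is jittered log-normally with coefficient of
    variation ``size_cv`` and independent Gaussian noise of s.d.
    ``noise_sigma`` is added to q and u (clipped to [−1, 1]).  The porous
    proxy additionally smooths the parent profile over ≈2° and damps its
    amplitude by a random factor in [0.7, 0.9], emulating the weaker angular
    oscillations of a structured particle.
    """
    context = context or OpticalContext()
    classes = classes or BENCHMARK_CLASSES
    rng = np.random.default_rng(seed)
    theta = default_angle_grid()
    names = list(classes)
    n_total = n_per_class * len(names)
    Q = np.empty((n_total, N_ANGLES))
    U = np.empty((n_total, N_ANGLES))
    y = np.empty(n_total, dtype=int)
    row = 0
    for ci, name in enumerate(names):
        d0, n_p, kind = classes[name]
        for _ in range(n_per_class):
            d = d0 * rng.lognormal(mean=0.0, sigma=size_cv)
            prof = simulate_pclar(SphereParticle(d, n_p), context, theta)
            q, u = prof.q.copy(), prof.u.copy()
            if kind == "porous_proxy":
                damp = rng.uniform(0.7, 0.9)
                q = damp * _smooth(q, _PSH_SMOOTH_PIXELS)
                u = damp * _smooth(u, _PSH_SMOOTH_PIXELS)
            q = np.clip(q + rng.normal(0.0, noise_sigma, N_ANGLES), -1, 1)
            u = np.clip(u + rng.normal(0.0, noise_sigma, N_ANGLES), -1, 1)
            Q[row], U[row], y[row] = q, u, ci
            row += 1
    return LabeledDataset(q=Q, u=U, labels=y, class_names=names)


def split_dataset(ds: LabeledDataset, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class random split (default 80/20: 1000 → 800 train / 200 test)."""
    rng = np.random.default_rng(seed)
    split = np.empty(len(ds), dtype=object)
    for ci in np.unique(ds.labels):
        idx = np.flatnonzero(ds.labels == ci)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"
    ds.split = split
    return ds.subset(split == "train"), ds.subset(split == "test")


@dataclass
class ConfusionMatrix:
    """Counts, per-class accuracy and overall accuracy of a classifier."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def per_class_accuracy(self) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, np.diag(self.counts) / totals, np.nan)

    def to_text(self) -> str:
        header = "true\\pred," + ",".join(self.class_names)
        lines = [header]
        for i, name in enumerate(self.class_names):
            lines.append(name + "," + ",".join(str(c) for c in self.counts[i]))
        lines.append(f"overall_accuracy,{self.overall_accuracy:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class ScatteringClassifier:
    """A small dense network over realigned profile features.

    The feature image is flattened before the dense layers; low-dimensional
    strategies (2 or 6 values) feed the same head directly.  Deterministic
    for a fixed seed.
    """

    strategy: str = "full_60_120"
    hidden_layers: tuple[int, ...] = (128,)
    max_epochs: int = 60
    seed: int = 0
    model: MLPClassifier | None = None
    class_names: list[str] | None = None

    def fit(self, train: LabeledDataset) -> "ScatteringClassifier":
        X = train.features(self.strategy)
        y = train.labels
        if len(np.unique(y)) < 2:
            raise ValueError("training requires at least two classes")
        counts = np.bincount(y)
        if counts[counts > 0].min() < 10:
            raise ValueError("each class needs at least 10 training examples")
        self.model = MLPClassifier(hidden_layer_sizes=self.hidden_layers,
                                   activation="relu", solver="adam",
                                   max_iter=self.max_epochs,
                                   random_state=self.seed)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # convergence warnings at capped epochs
            self.model.fit(X, y)
        if not np.all(np.isfinite(self.model.loss_curve_)):
            raise RuntimeError("training diverged: non-finite loss")
        self.class_names = train.class_names
        return self

    def predict(self, ds: LabeledDataset) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not trained")
        return self.model.predict(ds.features(self.strategy))

    def predict_profiles(self, profiles: list[PCLARProfile]) -> np.ndarray:
        X = np.stack([apply_strategy(p, self.strategy) for p in profiles])
        return self.model.predict(X)


def train_classifier(train: LabeledDataset, strategy: str = "full_60_120",
                     seed: int = 0, **kwargs) -> ScatteringClassifier:
    return ScatteringClassifier(strategy=strategy, seed=seed, **kwargs).fit(train)


def evaluate(clf: ScatteringClassifier, test: LabeledDataset) -> ConfusionMatrix:
    pred = clf.predict(test)
    n = len(test.class_names)
    counts = _sk_confusion(test.labels, pred, labels=np.arange(n))
    return ConfusionMatrix(counts=counts, class_names=test.class_names)


def mixture_composition(clf: ScatteringClassifier,
                        profiles: list[PCLARProfile]) -> dict[str, dict[str, float]]:
    """Classify each particle of a mixture and report per-class counts,
    proportions, and multinomial standard errors √(p(1−p)/n)."""
    pred = clf.predict_profiles(profiles)
    n = len(pred)
    out: dict[str, dict[str, float]] = {}
    for ci, name in enumerate(clf.class_names):
        k = int(np.count_nonzero(pred == ci))
        p = k / n
        out[name] = {"count": k, "proportion": p,
                     "stderr": float(np.sqrt(p * (1 - p) / n))}
    return out
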