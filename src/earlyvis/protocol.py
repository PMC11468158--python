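"""Training and evaluation protocol for the linear readout.

One *run* of the face/non-face task is: split each class's image ids 50/50
into train and test halves; resample 1,500 ids per class with replacement
from the training half; train the readout for 10 epochs of SGD (learning
rate 0.01, momentum 0.9, batch size 64, binary cross-entropy with logits,
Kaiming-uniform weight init, zero bias), composing every presentation
afresh — jitter always, scale/rotation/background per the condition — so the
model effectively never sees the same input twice; then resample 1,500 ids
per class from the test half, compose them once, and score the fraction
correct. A condition is summarized by the median accuracy over (by default)
100 independent runs.

The gender-task variant splits 50/10/40 into train/validation/test, resamples
400 per class for train and test, uses a fixed 80+80 validation set, and
early-stops SGD when validation accuracy fails to improve for 5 consecutive
epochs (40 epochs maximum), returning the best-validation-epoch head.

Sensitivity is reported as d' = Z(hit rate) - Z(false-alarm rate), or the
symmetric shortcut 2 * Z(hit rate); empirical rates of exactly 0 or 1 are
clipped to the rate corresponding to the 5.15 cap, and d' itself is clipped
at +/-5.15 (99.5% correct).

For desk-scale sweeps the per-presentation composition can be replaced by a
precomputed augmentation pool (``cache_augmentations=K``): each base image is
composed and featurized K times with independent transforms up front, and
presentations sample from that pool. Training then costs only the readout
updates, while the stimulus statistics per presentation are unchanged up to
pool-size granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from . import models as md
from . import stimuli as st
from .rng import substream

D_PRIME_CAP = 5.15

__all__ = [
    "ReadoutHead", "TrainConfig", "Condition", "RunResult", "ConditionResult",
    "StimulusSet", "Presenter", "FeaturePool", "init_head", "split_sets",
    "resample_epoch_list", "train_on_features", "train_head", "evaluate",
    "dprime", "run_condition", "train_with_validation",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ReadoutHead:
    """Trainable weight vector + bias of the binary classifier (face = 1)."""

    weights: np.ndarray
    bias: float

    def logits(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 (face) iff the logit is strictly positive."""
        return (self.logits(X) > 0).astype(np.int64)

    def copy(self) -> "ReadoutHead":
        return ReadoutHead(self.weights.copy(), float(self.bias))


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 10  # face task
    max_epochs: int = 40  # gender task (with early stopping)
    patience: int = 5
    shuffle: bool = True


@dataclass(frozen=True)
class Condition:
    """One cell of the condition grid: nuisance ranges, background, sizes."""

    scale_min: float = 1.0
    rot_max: float = 0.0
    background: st.BackgroundKind = st.BackgroundKind.MID_GRAY
    n_train_per_class: int = 1500
    n_test_per_class: int = 1500
    n_runs: int = 100

    def transform_spec(self) -> st.TransformSpec:
        return st.TransformSpec(scale_min=self.scale_min, rot_max=self.rot_max)


@dataclass
class RunResult:
    accuracy: float
    hit_rate: float
    false_alarm_rate: float
    weight_signs: np.ndarray
    seed_bundle: dict
    train_ids: dict[str, np.ndarray] | None = None
    test_ids: dict[str, np.ndarray] | None = None

    @property
    def dprime(self) -> float:
        return dprime(self.hit_rate, self.false_alarm_rate)


@dataclass
class ConditionResult:
    condition: Condition
    runs: list[RunResult]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.runs])

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.accuracies, [25, 75])
        return float(q3 - q1)


# ---------------------------------------------------------------------------
# stimulus sets and presentation sampling


class StimulusSet:
    """Foreground pools for both classes plus a shared scene pool.

    The non-face set is expected to have been luminance-matched (+15%)
    already; ``StimulusSet.synthetic`` does this at construction time.
    """

    def __init__(self, faces: list[st.AlphaImage], nonfaces: list[st.AlphaImage],
                 scene_pool: st.ScenePool | None = None):
        if not faces or not nonfaces:
            raise ValueError("both classes need at least one image")
        self.faces = faces
        self.nonfaces = nonfaces
        self.scene_pool = scene_pool or st.ScenePool(seed=0, n_scenes=50)

    @classmethod
    def synthetic(cls, n_per_class: int, seed: int = 0, n_scenes: int = 50,
                  fg_params: dict | None = None) -> "StimulusSet":
        faces = [st.gen_foreground("face", seed * 1_000_003 + i, fg_params)
                 for i in range(n_per_class)]
        nonfaces = [st.gen_foreground("nonface", seed * 1_000_003 + i, fg_params)
                    for i in range(n_per_class)]
        nonfaces, _ = st.match_luminance(faces, nonfaces)
        return cls(faces, nonfaces, st.ScenePool(seed=seed + 1, n_scenes=n_scenes))

    def images(self, label: str) -> list[st.AlphaImage]:
        return self.faces if label == "face" else self.nonfaces


def split_sets(face_ids, nonface_ids, seed: int) -> tuple[dict, dict]:
    """Random disjoint 50/50 split per class (odd cardinality: extra id trains)."""
    rng = substream(seed, "split")
    train, test = {}, {}
    for label, ids in (("face", face_ids), ("nonface", nonface_ids)):
        ids = np.asarray(list(ids))
        if ids.size == 0:
            raise ValueError(f"empty id list for class {label!r}")
        perm = rng.permutation(ids.size)
        n_train = (ids.size + 1) // 2
        train[label] = np.sort(ids[perm[:n_train]])
        test[label] = np.sort(ids[perm[n_train:]])
    return train, test


def resample_epoch_list(ids, n: int, seed: int) -> np.ndarray:
    """Sample ``n`` ids with replacement; fixed per run (not per epoch)."""
    ids = np.asarray(list(ids))
    if n <= 0:
        raise ValueError("n must be positive")
    if ids.size == 0:
        raise ValueError("empty id list")
    rng = substream(seed, "resample")
    return ids[rng.integers(0, ids.size, size=n)]


class Presenter:
    """Composes per-presentation stimuli for a fixed resampled id list.

    The id list is fixed for the lifetime of the presenter (one run); the
    nuisance transforms and backgrounds are redrawn on every epoch, so
    repeated presentations of one id differ in location, scale, rotation and
    background.
    """

    def __init__(self, stimset: StimulusSet, condition: Condition,
                 ids_by_class: dict[str, np.ndarray], n_per_class: int, seed: int):
        self.stimset = stimset
        self.condition = condition
        self.seed = seed
        self.spec = condition.transform_spec()
        self.presentation_ids: dict[str, np.ndarray] = {
            label: resample_epoch_list(ids_by_class[label], n_per_class,
                                       substream(seed, "resample", label).integers(2**31))
            for label in ("face", "nonface")
        }

    @property
    def n_presentations(self) -> int:
        return sum(len(v) for v in self.presentation_ids.values())

    def labels(self) -> np.ndarray:
        return np.concatenate([
            np.ones(len(self.presentation_ids["face"]), dtype=np.int64),
            np.zeros(len(self.presentation_ids["nonface"]), dtype=np.int64),
        ])

    def source_ids(self) -> np.ndarray:
        return np.concatenate([self.presentation_ids["face"],
                               self.presentation_ids["nonface"]])

    def compose_epoch(self, epoch: int) -> np.ndarray:
        """Freshly composed (N, 340, 340) stimuli for one epoch, label order
        faces-then-nonfaces (shuffling is the trainer's job)."""
        rng = substream(self.seed, "augment", epoch)
        bg_kind = self.condition.background
        out = np.empty((self.n_presentations, st.CANVAS_SIZE, st.CANVAS_SIZE))
        i = 0
        for label in ("face", "nonface"):
            pool = self.stimset.images(label)
            for idx in self.presentation_ids[label]:
                fg = pool[int(idx)]
                bg = st.gen_background(bg_kind, fg=fg, seed=int(rng.integers(2**31)),
                                       scene_pool=self.stimset.scene_pool)
                img, _ = st.transform_and_compose(fg, bg, self.spec, rng=rng)
                out[i] = img.pixels
                i += 1
        return out


class FeaturePool:
    """Precomputed augmented features: K composed variants per base image.

    ``features[label]`` has shape (n_images, K, n_units). Presentations
    sample a (base image, variant) pair uniformly, approximating fresh
    per-presentation augmentation with pool-size granularity.
    """

    def __init__(self, features: dict[str, np.ndarray]):
        self.features = features
        self.n_units = features["face"].shape[-1]
        self.K = features["face"].shape[1]

    @classmethod
    def build(cls, model: md.ModelSpec, stimset: StimulusSet, condition: Condition,
              seed: int, K: int, batch: int = 32) -> "FeaturePool":
        spec = condition.transform_spec()
        feats: dict[str, np.ndarray] = {}
        for label in ("face", "nonface"):
            pool = stimset.images(label)
            rng = substream(seed, "pool", label)
            imgs = np.empty((len(pool) * K, st.CANVAS_SIZE, st.CANVAS_SIZE))
            i = 0
            for fg in pool:
                for _ in range(K):
                    bg = st.gen_background(condition.background, fg=fg,
                                           seed=int(rng.integers(2**31)),
                                           scene_pool=stimset.scene_pool)
                    img, _ = st.transform_and_compose(fg, bg, spec, rng=rng)
                    imgs[i] = img.pixels
                    i += 1
            cols = [md.featurize_batch(model, imgs[j:j + batch], dtype=np.float32)
                    for j in range(0, len(imgs), batch)]
            X = np.concatenate(cols, axis=0)
            feats[label] = X.reshape(len(pool), K, X.shape[-1])
        return cls(feats)

    def sample_epoch(self, presentation_ids: dict[str, np.ndarray],
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        Xs, ys = [], []
        for label, y in (("face", 1), ("nonface", 0)):
            ids = presentation_ids[label]
            k = rng.integers(0, self.K, size=len(ids))
            Xs.append(self.features[label][ids, k])
            ys.append(np.full(len(ids), y, dtype=np.int64))
        return np.concatenate(Xs), np.concatenate(ys)

    def masked(self, unit_mask: np.ndarray) -> "FeaturePool":
        """Pool restricted to the units surviving a lesion."""
        return FeaturePool({k: v[..., unit_mask] for k, v in self.features.items()})

    def standardized(self, eps: float = 1e-8) -> "FeaturePool":
        """Pool with per-unit z-scored features (opt-in; raw units are the
        default convention for the readout)."""
        stacked = np.concatenate([v.reshape(-1, v.shape[-1])
                                  for v in self.features.values()])
        mu = stacked.mean(axis=0)
        sd = stacked.std(axis=0) + eps
        return FeaturePool({k: (v - mu) / sd for k, v in self.features.items()})


# ---------------------------------------------------------------------------
# SGD core


def init_head(n_units: int, rng: np.random.Generator) -> ReadoutHead:
    """Kaiming-uniform weights over fan-in (bound sqrt(6 / fan_in)), zero bias."""
    bound = np.sqrt(6.0 / n_units)
    return ReadoutHead(weights=rng.uniform(-bound, bound, size=n_units), bias=0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _sgd_epoch(head: ReadoutHead, vel_w: np.ndarray, vel_b: float,
               X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
               rng: np.random.Generator) -> float:
    """One epoch of minibatch SGD with classical momentum; returns vel_b."""
    n = len(y)
    order = rng.permutation(n) if cfg.shuffle else np.arange(n)
    for start in range(0, n, cfg.batch_size):
        sel = order[start:start + cfg.batch_size]
        Xb = X[sel]
        zb = Xb @ head.weights + head.bias
        g = _sigmoid(zb) - y[sel]  # d(BCE-with-logits)/d(logit)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite loss gradient during training")
        grad_w = Xb.T @ g / len(sel)
        grad_b = g.mean()
        vel_w *= cfg.momentum
        vel_w -= cfg.learning_rate * grad_w
        vel_b = cfg.momentum * vel_b - cfg.learning_rate * grad_b
        head.weights += vel_w
        head.bias += vel_b
    return vel_b


def train_on_features(epoch_fn, n_units: int, cfg: TrainConfig, seed: int,
                      n_epochs: int | None = None) -> ReadoutHead:
    """Train a readout on features served per epoch by ``epoch_fn(epoch, rng)``.

    ``epoch_fn`` returns (X, y) for the given epoch; it is called once per
    epoch so augmentation can be redrawn. Deterministic given the seed.
    """
    rng_init = substream(seed, "init")
    head = init_head(n_units, rng_init)
    vel_w = np.zeros_like(head.weights)
    vel_b = 0.0
    rng_order = substream(seed, "order")
    for epoch in range(n_epochs if n_epochs is not None else cfg.epochs):
        X, y = epoch_fn(epoch, substream(seed, "epoch", epoch))
        vel_b = _sgd_epoch(head, vel_w, vel_b, np.asarray(X, dtype=np.float64),
                           np.asarray(y, dtype=np.float64), cfg, rng_order)
    return head


def train_head(model: md.ModelSpec, presenter: Presenter, cfg: TrainConfig,
               seed: int, pool: FeaturePool | None = None) -> ReadoutHead:
    """Train the readout for one run (fresh composition or pooled features)."""
    labels = presenter.labels().astype(np.float64)

    if pool is not None:
        def epoch_fn(epoch, rng):
            return pool.sample_epoch(presenter.presentation_ids, rng)
    else:
        def epoch_fn(epoch, rng):
            imgs = presenter.compose_epoch(epoch)
            return md.featurize_batch(model, imgs, dtype=np.float32), labels

    return train_on_features(epoch_fn, model.n_units, cfg, seed)


# ---------------------------------------------------------------------------
# evaluation


def _score(head: ReadoutHead, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if X.shape[1] != head.weights.shape[0]:
        raise ValueError("feature length does not match the readout head")
    pred = head.predict(X)
    acc = float((pred == y).mean())
    faces = y == 1
    hit = float(pred[faces].mean()) if faces.any() else float("nan")
    fa = float(pred[~faces].mean()) if (~faces).any() else float("nan")
    return acc, hit, fa


def evaluate(head: ReadoutHead, model: md.ModelSpec, presenter: Presenter,
             pool: FeaturePool | None = None, seed_bundle: dict | None = None,
             ) -> RunResult:
    """Compose the test presentations once, score accuracy/hit/false-alarm."""
    y = presenter.labels()
    if pool is not None:
        X, y = pool.sample_epoch(presenter.presentation_ids,
                                 substream(presenter.seed, "test-sample"))
    else:
        X = md.featurize_batch(model, presenter.compose_epoch(0), dtype=np.float32)
    acc, hit, fa = _score(head, X, y)
    return RunResult(accuracy=acc, hit_rate=hit, false_alarm_rate=fa,
                     weight_signs=np.sign(head.weights).astype(np.int8),
                     seed_bundle=seed_bundle or {})


def dprime(hit_rate: float, false_alarm_rate: float | None = None) -> float:
    """Signal-detection sensitivity, clipped at +/-5.15 (99.5% correct).

    Two-rate form Z(hit) - Z(fa); with ``false_alarm_rate`` omitted, the
    symmetric shortcut 2 * Z(hit). Rates of exactly 0 or 1 are clipped to
    the rate corresponding to the cap.
    """
    p_cap = norm.cdf(D_PRIME_CAP / 2.0)

    def z(p: float) -> float:
        return float(norm.ppf(np.clip(p, 1.0 - p_cap, p_cap)))

    if false_alarm_rate is None:
        d = 2.0 * z(hit_rate)
    else:
        d = z(hit_rate) - z(false_alarm_rate)
    return float(np.clip(d, -D_PRIME_CAP, D_PRIME_CAP))


# ---------------------------------------------------------------------------
# full runs


def run_condition(model: md.ModelSpec, cond: Condition, stimset: StimulusSet,
                  master_seed: int, cfg: TrainConfig | None = None,
                  cache_augmentations: int = 0,
                  pool: FeaturePool | None = None) -> ConditionResult:
    """Repeat split -> train -> evaluate ``cond.n_runs`` times.

    ``cache_augmentations=K`` builds (or reuses ``pool``) a K-variant
    feature pool once and trains every run from it; 0 composes and
    featurizes every presentation afresh.
    """
    cfg = cfg or TrainConfig()
    if cache_augmentations > 0 and pool is None:
        pool = FeaturePool.build(model, stimset, cond,
                                 substream(master_seed, "pool-seed").integers(2**31),
                                 cache_augmentations)
    if pool is not None and pool.n_units != model.n_units:
        raise ValueError("feature pool does not match the model's unit count")

    face_ids = np.arange(len(stimset.faces))
    nonface_ids = np.arange(len(stimset.nonfaces))
    runs = []
    for r in range(cond.n_runs):
        run_seed = int(substream(master_seed, "run", r).integers(2**31))
        train_ids, test_ids = split_sets(face_ids, nonface_ids, run_seed)
        tr = Presenter(stimset, cond, train_ids, cond.n_train_per_class,
                       seed=int(substream(run_seed, "train-presenter").integers(2**31)))
        te = Presenter(stimset, cond, test_ids, cond.n_test_per_class,
                       seed=int(substream(run_seed, "test-presenter").integers(2**31)))
        head = train_head(model, tr, cfg, seed=run_seed, pool=pool)
        res = evaluate(head, model, te, pool=pool,
                       seed_bundle={"master_seed": master_seed, "run": r,
                                    "run_seed": run_seed})
        res.train_ids = train_ids
        res.test_ids = test_ids
        runs.append(res)
    return ConditionResult(condition=cond, runs=runs)


def train_with_validation(model: md.ModelSpec | None, epoch_fn, val_data,
                          n_units: int, cfg: TrainConfig, seed: int,
                          ) -> tuple[ReadoutHead, dict]:
    """Early-stopped training for the gender-task protocol.

    ``epoch_fn(epoch, rng) -> (X, y)`` serves training features;
    ``val_data = (X_val, y_val)`` is the fixed validation set. Training runs
    up to ``cfg.max_epochs`` and stops once validation accuracy has failed
    to improve for ``cfg.patience`` consecutive epochs; the head from the
    best validation epoch is returned, with a small training log.
    """
    X_val, y_val = val_data
    if len(y_val) == 0:
        raise ValueError("validation set is empty")
    rng_init = substream(seed, "init")
    head = init_head(n_units, rng_init)
    vel_w = np.zeros_like(head.weights)
    vel_b = 0.0
    rng_order = substream(seed, "order")
    best_head = head.copy()
    best_acc = -np.inf
    best_epoch = -1
    bad_epochs = 0
    history = []
    for epoch in range(cfg.max_epochs):
        X, y = epoch_fn(epoch, substream(seed, "epoch", epoch))
        vel_b = _sgd_epoch(head, vel_w, vel_b, np.asarray(X, dtype=np.float64),
                           np.asarray(y, dtype=np.float64), cfg, rng_order)
        acc, _, _ = _score(head, np.asarray(X_val, dtype=np.float64),
                           np.asarray(y_val))
        history.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_head = head.copy()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    log = {"epochs_run": len(history), "best_epoch": best_epoch,
           "best_val_accuracy": best_acc, "val_history": history}
    return best_head, log
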