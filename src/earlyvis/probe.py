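"""Layerwise probing: stage feature arithmetic and per-stage linear heads.

The reference architecture is the canonical five-convolution feature stack
(AlexNet-style) over 224x224 inputs:

    conv(64, k11, s4, p2) - relu - maxpool(k3, s2)
    conv(192, k5, s1, p2) - relu - maxpool(k3, s2)
    conv(384, k3, s1, p1) - relu
    conv(256, k3, s1, p1) - relu
    conv(256, k3, s1, p1) - relu - maxpool(k3, s2)

Binary probe heads are attached after layers 3, 6, 8, 10 and 13 (counting
every conv/relu/pool as one layer; a cut *after layer k* includes layer k's
nonlinearity or pooling). The flattened feature counts at those cuts are
pure convolution arithmetic — floor((n + 2p - k) / s) + 1 per layer — and
need no weights: 46,656 / 32,448 / 64,896 / 43,264 / 9,216.

``train_stage_probes`` attaches an independently trained head to every stage
of *any* staged feature extractor (a callable returning per-stage feature
vectors), reusing the protocol module's SGD loop on frozen features; heads
are trained concurrently but independently, and training one head never
mutates another or the extractor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import ReadoutHead, TrainConfig, _score, train_on_features
from .rng import substream

__all__ = ["LayerSpec", "ConvStackSpec", "ProbeStageSpec", "stage_feature_counts",
           "train_stage_probes", "CANONICAL_STACK", "CANONICAL_CUTS"]


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # {"conv", "relu", "maxpool"}
    channels: int = 0  # output channels (conv only)
    kernel: int = 0
    stride: int = 1
    padding: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "relu", "maxpool"):
            raise ValueError(f"unknown layer kind: {self.kind!r}")
        if self.kind == "conv" and self.channels <= 0:
            raise ValueError("conv layer needs a positive channel count")
        if self.kind in ("conv", "maxpool") and self.kernel <= 0:
            raise ValueError(f"{self.kind} layer needs a positive kernel size")


CANONICAL_STACK: tuple[LayerSpec, ...] = (
    LayerSpec("conv", 64, 11, 4, 2),
    LayerSpec("relu"),
    LayerSpec("maxpool", kernel=3, stride=2),
    LayerSpec("conv", 192, 5, 1, 2),
    LayerSpec("relu"),
    LayerSpec("maxpool", kernel=3, stride=2),
    LayerSpec("conv", 384, 3, 1, 1),
    LayerSpec("relu"),
    LayerSpec("conv", 256, 3, 1, 1),
    LayerSpec("relu"),
    LayerSpec("conv", 256, 3, 1, 1),
    LayerSpec("relu"),
    LayerSpec("maxpool", kernel=3, stride=2),
)

CANONICAL_CUTS: tuple[int, ...] = (3, 6, 8, 10, 13)


@dataclass(frozen=True)
class ConvStackSpec:
    layers: tuple[LayerSpec, ...] = CANONICAL_STACK
    input_size: int = 224


@dataclass(frozen=True)
class ProbeStageSpec:
    cut_points: tuple[int, ...] = CANONICAL_CUTS
    feature_counts: tuple[int, ...] = ()


def stage_feature_counts(spec: ConvStackSpec = ConvStackSpec(),
                         cut_points: tuple[int, ...] = CANONICAL_CUTS,
                         ) -> ProbeStageSpec:
    """Flattened feature count (channels x height x width) at each cut point.

    Spatial size after a conv/pool layer: floor((n + 2p - k) / s) + 1;
    relu preserves shape. Exact integer arithmetic, no weights involved.
    """
    n = spec.input_size
    channels = None
    sizes: dict[int, tuple[int, int]] = {}
    for depth, layer in enumerate(spec.layers, start=1):
        if layer.kind == "conv":
            n = (n + 2 * layer.padding - layer.kernel) // layer.stride + 1
            channels = layer.channels
        elif layer.kind == "maxpool":
            n = (n + 2 * layer.padding - layer.kernel) // layer.stride + 1
        if n <= 0:
            raise ValueError(f"feature map vanishes at layer {depth}")
        sizes[depth] = (channels, n)
    counts = []
    for cut in cut_points:
        if cut not in sizes:
            raise ValueError(f"cut point {cut} beyond stack depth {len(spec.layers)}")
        c, s = sizes[cut]
        if c is None:
            raise ValueError(f"no conv layer before cut point {cut}")
        counts.append(c * s * s)
    return ProbeStageSpec(cut_points=tuple(cut_points), feature_counts=tuple(counts))


@dataclass
class StageProbeResult:
    stage: int
    head: ReadoutHead
    train_accuracy: float
    test_accuracy: float
    hit_rate: float
    false_alarm_rate: float


def train_stage_probes(extractor, train_data, test_data, cfg: TrainConfig,
                       seed: int) -> list[StageProbeResult]:
    """Train one binary head per stage of a staged feature extractor.

    ``extractor(img) -> list of per-stage 1-D feature vectors`` (frozen:
    never trained, never mutated). ``train_data`` / ``test_data`` are
    (images, labels) pairs; images are featurized once per stage and each
    head is trained independently with the shared SGD loop. Heads for
    different stages never interact.
    """
    X_imgs, y = train_data
    Xt_imgs, yt = test_data
    y = np.asarray(y, dtype=np.int64)
    yt = np.asarray(yt, dtype=np.int64)

    train_feats = [np.stack(cols) for cols in zip(*(extractor(im) for im in X_imgs))]
    test_feats = [np.stack(cols) for cols in zip(*(extractor(im) for im in Xt_imgs))]

    results = []
    for stage, (Xs, Xs_t) in enumerate(zip(train_feats, test_feats), start=1):
        n_units = Xs.shape[1]
        head = train_on_features(lambda e, rng: (Xs, y), n_units, cfg,
                                 seed=int(substream(seed, "stage", stage).integers(2**31)))
        tr_acc, _, _ = _score(head, Xs.astype(np.float64), y)
        te_acc, hit, fa = _score(head, Xs_t.astype(np.float64), yt)
        results.append(StageProbeResult(stage=stage, head=head,
                                        train_accuracy=tr_acc, test_accuracy=te_acc,
                                        hit_rate=hit, false_alarm_rate=fa))
    return results
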