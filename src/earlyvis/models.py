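"""The four early-vision model variants as feature extractors.

Each variant maps a 340x340 grayscale stimulus to a fixed-length activation
vector that a linear readout classifies:

* ``V1S`` — V1 simple cells: Gabor bank followed by half-rectification
  (7,088 units, per channel 144/144/1024/5776);
* ``V1C`` — V1 complex cells: rectified simple cells summed over the four
  spatial phases at each (channel, location, orientation) (1,772 units);
* ``V1L`` — V1 linear receptive fields: the simple-cell bank with the
  rectification removed; the 180/270-degree phases are dropped because a
  linear unit at phase + 180 deg is exactly the negation of the unit at
  phase (the readout's signed weights make them redundant) (3,544 units);
* ``LGN`` — center-surround difference-of-Gaussians bank with
  half-rectification (886 units, per channel 18/18/128/722).

Feature extraction is pure and deterministic; no normalization is applied to
the activations by default (z-scoring is an explicit opt-in,
``FeaturePool.standardized`` on the protocol side). ``input_scale`` divides
pixel luminance before filtering;
the default 255 maps stimuli to [0, 1], the convention under which the
readout's published optimizer settings are well-behaved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import filterbank as fb

VARIANTS = ("V1S", "V1C", "V1L", "LGN")

__all__ = ["ModelSpec", "make_model", "unit_count", "featurize", "featurize_batch",
           "VARIANTS"]


@dataclass
class ModelSpec:
    """A wired model variant: filter bank plus ordered post-operations.

    ``unit_mask`` (boolean, length = bank output after post_ops) supports
    lesion studies: masked-out units are removed from the activation vector.
    """

    variant: str
    bank: fb.FilterBank
    post_ops: tuple[str, ...]
    input_scale: float = 255.0
    unit_mask: np.ndarray | None = None

    @property
    def n_units_full(self) -> int:
        """Unit count of the unlesioned architecture."""
        n = self.bank.n_units
        if "pool_phases" in self.post_ops:
            n //= len(self.bank.phases)
        return n

    @property
    def n_units(self) -> int:
        if self.unit_mask is None:
            return self.n_units_full
        return int(self.unit_mask.sum())

    def channel_unit_slices(self) -> list[slice]:
        """Per-channel slices in the (unlesioned) activation vector."""
        div = len(self.bank.phases) if "pool_phases" in self.post_ops else 1
        out, start = [], 0
        for c in self.bank.channels:
            n = c.n_units // div
            out.append(slice(start, start + n))
            start += n
        return out

    def unit_channels(self) -> np.ndarray:
        """Channel index of every (unlesioned) activation-vector position."""
        ch = np.empty(self.n_units_full, dtype=np.int64)
        for ci, sl in enumerate(self.channel_unit_slices()):
            ch[sl] = ci
        return ch


_WIRING = {
    # variant: (family, phases, post_ops)
    "V1S": ("gabor", fb.PHASES, ("half_rectify",)),
    "V1C": ("gabor", fb.PHASES, ("half_rectify", "pool_phases")),
    "V1L": ("gabor", (0.0, 90.0), ()),
    "LGN": ("dog", fb.PHASES, ("half_rectify",)),
}


def make_model(variant: str, W: int = fb.CANVAS,
               wavelengths: tuple = fb.WAVELENGTHS,
               config: fb.BankConfig | None = None,
               input_scale: float = 255.0) -> ModelSpec:
    """Build one of the four model variants over the given canvas."""
    if variant not in _WIRING:
        raise ValueError(f"unknown model variant: {variant!r} (expected one of {VARIANTS})")
    family, phases, post_ops = _WIRING[variant]
    bank = fb.build_bank(family, W=W, wavelengths=wavelengths, phases=phases, config=config)
    return ModelSpec(variant=variant, bank=bank, post_ops=post_ops, input_scale=input_scale)


def unit_count(m: ModelSpec) -> tuple[tuple[int, ...], int]:
    """Per-channel unit counts and total for the (unlesioned) architecture."""
    div = len(m.bank.phases) if "pool_phases" in m.post_ops else 1
    per = tuple(c.n_units // div for c in m.bank.channels)
    return per, sum(per)


def featurize_batch(m: ModelSpec, batch: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Activation vectors for a (B, W, W) stimulus stack; returns (B, n_units)."""
    batch = np.asarray(batch, dtype=dtype)
    if m.input_scale != 1.0:
        batch = batch / m.input_scale
    v = m.bank.apply_batch(batch, dtype=dtype)
    for op in m.post_ops:
        if op == "half_rectify":
            v = fb.half_rectify(v)
        elif op == "pool_phases":
            v = fb.pool_phases(v, m.bank)
        else:  # pragma: no cover
            raise ValueError(f"unknown post-op: {op!r}")
    if m.unit_mask is not None:
        v = v[:, m.unit_mask]
    return v


def featurize(m: ModelSpec, img) -> np.ndarray:
    """Activation vector for a single stimulus (GrayImage or array)."""
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img)
    return featurize_batch(m, pixels[None])[0]
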