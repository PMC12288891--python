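"""Learned-style embedding features from phase patches.

Each 96 x 96 phase patch is affinely mapped from the nominal phase range
[-2, 6] rad to [0, 1], replicated to 3 channels, and passed through an
18-layer residual convolutional backbone (resnet18-style topology: 7x7
stem, four stages of two basic blocks at 64/128/256/512 channels, global
average pooling) with the classification head removed, yielding a 512-d
embedding per cell.

The supported weight mode is ``"seeded-random"``: He-initialised random
weights drawn from a seeded generator, with per-channel RMS activation
normalisation in place of trained batch-norm statistics.  This keeps the
embedding fully deterministic and self-contained; random convolutional
features preserve coarse structural information, and the morphology
features carry the discriminative signal in the default pipeline.
Requesting ``"pretrained-natural-images"`` raises, since no trained
weights are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["EmbeddingSpec", "embed_patches", "EmbeddingModel"]

_STAGES = (64, 128, 256, 512)  # channel widths of the four residual stages


@dataclass(frozen=True)
class EmbeddingSpec:
    backbone: str = "resnet18-style"
    weights_source: str = "seeded-random"  # or "pretrained-natural-images"
    embed_dim: int = 512
    input_range: tuple[float, float] = (-2.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be > 0")
        if self.weights_source not in ("seeded-random", "pretrained-natural-images"):
            raise ValueError(f"unknown weights_source {self.weights_source!r}")


def _he(rng: np.random.Generator, out_c: int, in_c: int, k: int) -> np.ndarray:
    sd = np.sqrt(2.0 / (in_c * k * k))
    return rng.normal(0.0, sd, size=(out_c, in_c, k, k))


def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1,
          pad: int = 1) -> np.ndarray:
    """Valid conv of (C,H,W) with (O,C,k,k) after zero padding."""
    k = w.shape[2]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return np.einsum("chwij,ocij->ohw", win, w, optimize=True)


def _rms_norm(x: np.ndarray) -> np.ndarray:
    # per-channel RMS over the spatial grid; keeps activations O(1)
    rms = np.sqrt(np.mean(x * x, axis=(1, 2), keepdims=True) + 1e-6)
    return x / rms


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _maxpool3s2(x: np.ndarray) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))[:, ::2, ::2]
    return win.max(axis=(3, 4))


class EmbeddingModel:
    """Seeded-random residual backbone; weights are built once per spec."""

    def __init__(self, spec: EmbeddingSpec):
        if spec.weights_source == "pretrained-natural-images":
            raise RuntimeError(
                "pretrained natural-image weights are not bundled with this "
                "package; use EmbeddingSpec(weights_source='seeded-random')")
        self.spec = spec
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
        self.stem = _he(rng, _STAGES[0], 3, 7)
        self.blocks: list[dict[str, np.ndarray | None]] = []
        in_c = _STAGES[0]
        for si, out_c in enumerate(_STAGES):
            for bi in range(2):
                stride = 2 if (si > 0 and bi == 0) else 1
                blk = {
                    "w1": _he(rng, out_c, in_c, 3),
                    "w2": _he(rng, out_c, out_c, 3),
                    "down": _he(rng, out_c, in_c, 1) if (stride != 1 or in_c != out_c) else None,
                    "stride": stride,
                }
                self.blocks.append(blk)
                in_c = out_c

    def embed_one(self, patch: np.ndarray) -> np.ndarray:
        lo, hi = self.spec.input_range
        x01 = (np.asarray(patch, dtype=np.float64) - lo) / (hi - lo)
        x = np.repeat(x01[None], 3, axis=0)
        x = _relu(_rms_norm(_conv(x, self.stem, stride=2, pad=3)))
        x = _maxpool3s2(x)
        for blk in self.blocks:
            y = _relu(_rms_norm(_conv(x, blk["w1"], stride=blk["stride"], pad=1)))
            y = _rms_norm(_conv(y, blk["w2"], stride=1, pad=1))
            if blk["down"] is not None:
                sc = _conv(x, blk["down"], stride=blk["stride"], pad=0)
            else:
                sc = x
            x = _relu(y + sc)
        emb = x.mean(axis=(1, 2))
        return emb[: self.spec.embed_dim]


def embed_patches(patches, spec: EmbeddingSpec | None = None) -> np.ndarray:
    """Embed cell patches (or raw 96x96 arrays) into feature vectors.

    Returns an (n, embed_dim) float64 array; deterministic for a fixed
    spec (weights depend only on the spec seed).
    """
    spec = spec or EmbeddingSpec()
    model = EmbeddingModel(spec)
    arrays = [p.patch if hasattr(p, "patch") else np.asarray(p) for p in patches]
    out = np.empty((len(arrays), spec.embed_dim), dtype=np.float64)
    for i, a in enumerate(arrays):
        out[i] = model.embed_one(a)
    return out
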