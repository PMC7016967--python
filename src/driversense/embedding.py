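"""Uniform image-embedding contract: 224x224x3 image -> 4096-vector.

Topomaps, spectrograms and face crops all pass through the same interface,
mirroring how penultimate-layer activations of a pretrained CNN (VGG-16 for
generic images, VGG-Faces for faces) are used as off-the-shelf features.
Pretrained backbones require torch + downloaded weights; the shipped
:class:`StubEmbedder` is a seeded random projection with half-wave
rectification — deterministic, Lipschitz, and dependency-free — so the full
pipeline runs anywhere.  Swapping backbones never changes downstream shapes.
"""

from __future__ import annotations

import numpy as np

INPUT_SHAPE = (224, 224, 3)
OUTPUT_DIM = 4096


def resize_to_input(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Bicubic-resize an RGB float image to 224x224x3, clipped to [0, 1]."""
    from PIL import Image

    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("empty image")
    chans = [
        np.asarray(
            Image.fromarray(image[:, :, c].astype(np.float32), mode="F")
            .resize((size, size), Image.BICUBIC),
            dtype=float)
        for c in range(3)
    ]
    return np.clip(np.stack(chans, axis=-1), 0.0, 1.0)


class StubEmbedder:
    """Deterministic stand-in backbone: pooled seeded Gaussian projection.

    The image is 7x7 average-pooled to 32x32x3, flattened, projected through
    a fixed N(0, 1/d) matrix drawn once from ``seed``, and half-wave
    rectified.  Linear + ReLU, so the map is Lipschitz with constant
    ||W||_2 / 49 per-pixel.
    """

    name = "stub"
    input_shape = INPUT_SHAPE
    output_dim = OUTPUT_DIM

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._W: np.ndarray | None = None

    def _weights(self) -> np.ndarray:
        if self._W is None:
            rng = np.random.default_rng(self.seed)
            d = 32 * 32 * 3
            self._W = rng.standard_normal((OUTPUT_DIM, d)).astype(np.float32)
            self._W /= np.sqrt(d)
        return self._W

    def embed(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self.input_shape:
            raise ValueError(
                f"embedder expects {self.input_shape} input, got {image.shape}; "
                "resize with resize_to_input first")
        pooled = image.reshape(32, 7, 32, 7, 3).mean(axis=(1, 3))
        out = self._weights() @ pooled.ravel().astype(np.float32)
        return np.maximum(out, 0.0).astype(float)


class CNNEmbedder:
    """Pretrained-CNN backbone (VGG-16 / VGG-Faces penultimate layer).

    Requires torch/torchvision with downloaded weights; inputs get the
    backbone's standard per-channel normalization.  Absent weights raise an
    explicit error pointing at the stub fallback.
    """

    input_shape = INPUT_SHAPE
    output_dim = OUTPUT_DIM

    def __init__(self, name: str = "vgg16", weight_path: str | None = None):
        self.name = name
        self.weight_path = weight_path
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                f"backbone {name!r} needs torch/torchvision with pretrained "
                "weights, which are not installed; use the deterministic "
                "'stub' embedder instead (StubEmbedder or embedder='stub')"
            ) from exc
        import torch
        from torchvision import models

        if name == "vgg16" and weight_path is None:
            net = models.vgg16(weights=models.VGG16_Weights.IMAGENET1K_V1)
        else:
            net = models.vgg16()
            if weight_path is None:
                raise RuntimeError(
                    f"backbone {name!r} needs a weight_path (no bundled "
                    "weights); use the 'stub' embedder if none is available")
            net.load_state_dict(torch.load(weight_path, map_location="cpu"))
        # penultimate fully-connected layer = classifier[:-3] output (4096)
        net.classifier = net.classifier[:-3]
        net.eval()
        self._net = net
        self._mean = np.array([0.485, 0.456, 0.406])
        self._std = np.array([0.229, 0.224, 0.225])

    def embed(self, image: np.ndarray) -> np.ndarray:
        import torch

        image = np.asarray(image, dtype=float)
        if image.shape != self.input_shape:
            raise ValueError(f"embedder expects {self.input_shape} input")
        x = (image - self._mean) / self._std
        t = torch.from_numpy(x.transpose(2, 0, 1)[None]).float()
        with torch.no_grad():
            v = self._net(t).numpy().ravel()
        return v.astype(float)


def get_embedder(name: str = "stub", seed: int = 0,
                 weight_path: str | None = None):
    """Embedder factory keyed by config name: {stub, vgg16, vggfaces}."""
    if name == "stub":
        return StubEmbedder(seed=seed)
    if name in ("vgg16", "vggfaces"):
        return CNNEmbedder(name=name, weight_path=weight_path)
    raise ValueError(f"unknown embedder {name!r}")
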