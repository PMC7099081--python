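"""Twin-subnetwork model, Euclidean embedding distance, and contrastive loss.

A Siamese network passes two images through one shared-weight subnetwork
G_w and compares the embeddings by their Euclidean distance
D_w(X1, X2) = ||G_w(X1) - G_w(X2)||_2.  Training minimizes the contrastive
loss L = (1 - Y) D^2 + Y max(0, m - D)^2, where Y = 1 for pairs whose
ordinal grade differs and m is the margin beyond which dissimilar pairs
stop contributing.  Weight sharing is by construction: there is a single
parameter store, and "both twins" are the same forward function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "SubnetworkSpec",
    "ContrastiveParams",
    "SiameseNetwork",
    "LinearEmbedder",
    "euclidean_distance",
    "contrastive_loss",
    "contrastive_loss_grad",
    "batch_loss",
    "build_backbone",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class SubnetworkSpec:
    """Architecture of the shared subnetwork.

    backbone
        ``"small_cnn"`` — four stride-2 conv blocks, global average pooling
        and a linear head; the desk-scale default.
        ``"residual_small"`` — a deeper variant with residual blocks, kept
        as the high-capacity option.
    k_out
        Embedding length (3 in retina mode, 5 in knee mode by convention;
        freely configurable).
    input_size
        (H, W) the model expects after preprocessing.
    pretrained
        Hook for externally supplied initial weights; no weights ship with
        the package, so the default is False and initialization is seeded.
    """

    backbone: str = "small_cnn"
    k_out: int = 3
    input_size: tuple[int, int] = (64, 64)
    channels: tuple[int, ...] = (8, 16, 32, 32)
    pretrained: bool = False

    def __post_init__(self):
        if self.k_out < 1:
            raise ValueError("k_out must be >= 1")
        if self.backbone not in ("small_cnn", "residual_small"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass(frozen=True)
class ContrastiveParams:
    """Contrastive-loss hyperparameters; margin defaults to 2.0."""

    margin: float = 2.0

    def __post_init__(self):
        if not self.margin > 0:
            raise ValueError("margin must be > 0")


def build_backbone(spec: SubnetworkSpec, rng: np.random.Generator, dtype=np.float32) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_prev = 1
    if spec.backbone == "small_cnn":
        for c in spec.channels:
            layers += [nn.Conv2d(c_prev, c, stride=2, rng=rng, dtype=dtype), nn.ReLU()]
            c_prev = c
    else:  # residual_small
        for c in spec.channels:
            layers += [nn.Conv2d(c_prev, c, stride=2, rng=rng, dtype=dtype), nn.ReLU(),
                       nn.ResidualBlock(c, rng=rng, dtype=dtype)]
            c_prev = c
    layers += [nn.GlobalAvgPool(), nn.Linear(c_prev, spec.k_out, rng=rng, dtype=dtype)]
    return nn.Sequential(layers)


class SiameseNetwork:
    """One shared subnetwork; ``embed`` is the twin forward pass.

    Because there are no stochastic layers, embeddings are deterministic
    given fixed weights; the two "twins" are literally the same function.
    """

    def __init__(self, spec: SubnetworkSpec, params: ContrastiveParams | None = None,
                 seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.params = params or ContrastiveParams()
        self.seed = seed
        self.dtype = dtype
        self.net = build_backbone(spec, np.random.default_rng(seed), dtype=dtype)

    # -- forward ---------------------------------------------------------
    def embed_batch(self, images: np.ndarray) -> np.ndarray:
        """Embed a stack of images (N, H, W) -> (N, k_out)."""
        images = np.asarray(images, dtype=self.dtype)
        if images.ndim != 3:
            raise ValueError("expected a stack of 2-D grayscale images (N, H, W)")
        if images.shape[1:] != tuple(self.spec.input_size):
            raise ValueError(
                f"image size {images.shape[1:]} does not match model input {tuple(self.spec.input_size)}"
            )
        return self.net.forward(images[:, None, :, :])

    def embed(self, image: np.ndarray) -> np.ndarray:
        """Embed a single image (H, W) -> (k_out,)."""
        return self.embed_batch(np.asarray(image)[None])[0]

    def distance(self, image_a: np.ndarray, image_b: np.ndarray) -> float:
        return euclidean_distance(self.embed(image_a), self.embed(image_b))

    def weights_fingerprint(self) -> bytes:
        """Cheap token that changes whenever the head weights change; used
        for embedding-cache invalidation."""
        params = self.net.params()
        tail = sorted(params)[-2:]
        return b"".join(params[k].value.tobytes() for k in tail)

    # -- persistence -----------------------------------------------------
    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)


class LinearEmbedder:
    """Frozen affine embedding e = M @ vec(image) + b.

    A transparent reference model: every downstream quantity (distances,
    severity scores, occlusion maps) has a closed form under it, which makes
    it the oracle of choice for exact tests and worked examples.  Not
    trainable.
    """

    def __init__(self, matrix: np.ndarray, bias: np.ndarray | None = None,
                 input_size: tuple[int, int] = (64, 64)):
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.bias = np.zeros(self.matrix.shape[0]) if bias is None else np.asarray(bias, np.float64)
        self.spec = SubnetworkSpec(k_out=self.matrix.shape[0], input_size=tuple(input_size))

    def embed_batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.shape[1:] != tuple(self.spec.input_size):
            raise ValueError("image size does not match embedder input size")
        return images.reshape(images.shape[0], -1) @ self.matrix.T + self.bias

    def embed(self, image: np.ndarray) -> np.ndarray:
        return self.embed_batch(np.asarray(image)[None])[0]


def euclidean_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """l2 norm of the embedding difference, D_w."""
    e1 = np.asarray(e1, dtype=np.float64)
    e2 = np.asarray(e2, dtype=np.float64)
    if e1.shape != e2.shape:
        raise ValueError(f"embedding length mismatch: {e1.shape} vs {e2.shape}")
    return float(np.linalg.norm(e1 - e2))


def contrastive_loss(d: float, y: int, params: ContrastiveParams) -> float:
    """(1-Y) D^2 + Y max(0, m - D)^2 for a single pair."""
    if y not in (0, 1):
        raise ValueError("pair label Y must be 0 or 1")
    if d < 0:
        raise ValueError("distance must be non-negative")
    if y == 0:
        return float(d * d)
    return float(max(0.0, params.margin - d) ** 2)


def contrastive_loss_grad(d: np.ndarray, y: np.ndarray, params: ContrastiveParams) -> np.ndarray:
    """dL/dD for a vector of pairs (used by the training loop)."""
    d = np.asarray(d, dtype=np.float64)
    y = np.asarray(y)
    return np.where(y == 0, 2.0 * d, -2.0 * np.maximum(0.0, params.margin - d))


def batch_loss(pairs: list[tuple[float, int]], params: ContrastiveParams) -> float:
    """Arithmetic mean of per-pair contrastive losses."""
    if len(pairs) == 0:
        raise ValueError("batch must be non-empty")
    return float(np.mean([contrastive_loss(d, y, params) for d, y in pairs]))


# -- checkpointing -------------------------------------------------------

def save_checkpoint(path: str | Path, model: SiameseNetwork, *, kind: str = "siamese",
                    preprocessing: dict | None = None, train_seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Write a self-describing .npz checkpoint (weights + JSON metadata)."""
    meta = {
        "format": "siamscore-checkpoint",
        "version": CHECKPOINT_VERSION,
        "kind": kind,
        "spec": asdict(model.spec),
        "contrastive": asdict(model.params),
        "preprocessing": preprocessing or {},
        "train_seed": train_seed,
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path: str | Path) -> tuple[SiameseNetwork, dict]:
    """Load a checkpoint; returns (model, metadata)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != "siamscore-checkpoint":
            raise ValueError(f"{path} is not a siamscore checkpoint")
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    spec_d = dict(meta["spec"])
    spec_d["input_size"] = tuple(spec_d["input_size"])
    spec_d["channels"] = tuple(spec_d["channels"])
    model = SiameseNetwork(SubnetworkSpec(**spec_d), ContrastiveParams(**meta["contrastive"]))
    model.load_state_dict(state)
    return model, meta
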