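"""A small sequential CNN with explicit forward/backward passes."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Conv2D, Dense, Layer, MaxPool2, ReLU, softmax


class SequentialCNN:
    """Conv/BN/ReLU blocks with interleaved max-pooling and a dense softmax head.

    Parameters
    ----------
    conv_plan : sequence of (filters, kernel) pairs, one per conv block.
    pool_positions : 1-based conv block indices after which a 2x2/stride-2
        max-pool is inserted.
    input_shape : (rows, cols, channels) of one input image.
    n_classes : size of the softmax output.
    seed : seeds the weight initialisation.
    """

    def __init__(
        self,
        conv_plan: list[tuple[int, int]],
        pool_positions: tuple[int, ...],
        input_shape: tuple[int, int, int],
        n_classes: int,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        h, w, c = input_shape
        pools = set(pool_positions)
        for i, (filters, kernel) in enumerate(conv_plan, start=1):
            self.layers.append(Conv2D(c, filters, kernel, rng, first_layer=(i == 1)))
            self.layers.append(BatchNorm(filters))
            self.layers.append(ReLU())
            c = filters
            if i in pools:
                self.layers.append(MaxPool2())
                h, w = h // 2, w // 2
        self.feature_shape = (h, w, c)
        self.layers.append(Dense(h * w * c, n_classes, rng))
        self.n_classes = n_classes
        self.input_shape = input_shape

    # -- passes ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of shape (n, {self.input_shape[0]}, "
                f"{self.input_shape[1]}, {self.input_shape[2]}), got {x.shape}"
            )
        out = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode class probabilities, row per input image."""
        chunks = [
            softmax(self.forward_logits(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0) if chunks else np.empty((0, self.n_classes))

    def backward_from_probs(self, probs: np.ndarray, labels: np.ndarray) -> None:
        """Backpropagate the softmax cross-entropy gradient for integer labels."""
        n = probs.shape[0]
        dy = probs.astype(np.float32).copy()
        dy[np.arange(n), labels] -= 1.0
        dy /= np.float32(n)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def finalize_batchnorm(self, x: np.ndarray, batch_size: int = 128) -> None:
        """Recompute batch-norm inference statistics as population statistics
        over ``x`` (normalised inputs), with the current weights frozen.

        Batches are drawn interleaved (stride sampling) so that a
        class-sorted corpus still yields class-mixed batches: deeper layers
        see activations normalised by representative batch statistics, as
        they did during (shuffled) training.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for bn in bns:
            bn.start_stat_accumulation()
        n_batches = max(1, int(np.ceil(len(x) / batch_size)))
        for b in range(n_batches):
            self.forward_logits(x[b::n_batches], train=True)
        for bn in bns:
            bn.finish_stat_accumulation()
            bn._cache = None
        for l in self.layers:  # drop training caches created by the passes
            for attr in ("_cache", "_mask", "_x"):
                if hasattr(l, attr):
                    setattr(l, attr, None)

    def release_buffers(self) -> None:
        """Free the persistent workspace buffers (keeps weights)."""
        for layer in self.layers:
            layer.release_buffers()

    # -- parameter access --------------------------------------------------

    def named_params(self):
        """Yield (key, layer, name) triples addressing every parameter array."""
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{li}.{name}", layer, name

    def l2_penalty_and_grad(self, l2: float) -> float:
        """Add 2*l2*w to each regularised weight gradient; return l2*sum(w^2)."""
        penalty = 0.0
        for layer in self.layers:
            for name in layer.weight_decay_keys:
                w = layer.params[name]
                penalty += float((w.astype(np.float64) ** 2).sum())
                layer.grads[name] += np.float32(2.0 * l2) * w
        return l2 * penalty

    # -- serialization -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for key, layer, name in self.named_params():
            state[f"p:{key}"] = layer.params[name]
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"rm:{li}"] = layer.running_mean
                state[f"rv:{li}"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.named_params():
            layer.params[name] = np.asarray(state[f"p:{key}"], dtype=np.float32)
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"rm:{li}"], dtype=np.float32)
                layer.running_var = np.asarray(state[f"rv:{li}"], dtype=np.float32)


class Adam:
    """Adaptive moment estimation over a SequentialCNN's parameters."""

    def __init__(
        self,
        net: SequentialCNN,
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(layer.params[n]) for k, layer, n in net.named_params()}
        self.v = {k: np.zeros_like(layer.params[n]) for k, layer, n in net.named_params()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for key, layer, name in self.net.named_params():
            g = layer.grads[name]
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[name] -= np.float32(self.lr) * (m / bc1) / (
                np.sqrt(v / bc2) + self.eps
            )
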