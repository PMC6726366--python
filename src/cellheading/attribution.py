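"""Attribution: which pixels drive the direction prediction.

Three complementary views of a trained network's decision:

* **Guided backpropagation (GBP)** — the gradient of one strongly
  activated neuron of the last convolutional layer with respect to the
  input, with the backward signal through every ReLU zeroed where the
  forward activation was non-positive *or* the incoming signal is
  negative.  Highlights the local image structure exciting that neuron.
* **Deep Taylor decomposition (DTD)** — decomposes the pre-softmax
  class score into non-negative per-pixel relevances using the z⁺ rule
  in hidden layers, winner-take-all routing through max pooling, and
  the z^B rule (box constraints 0 ≤ x ≤ 1) at the input layer; biases
  are excluded, so with zero biases the pixel relevances sum to the
  class score.
* **Occlusion** — slides a mask over the image, records how the class
  score drops, and min-max normalizes the negated scores to [0, 255].

All computations here run in float64 for tight conservation, on a
single patch at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Network
from .nn import Conv2D, Dense, Dropout, Flatten, MaxPool2, ReLU

_EPS = 1e-12


@dataclass(frozen=True)
class Activation:
    feature_map: int
    position: tuple[int, int]     # (row, col) in the feature-map grid
    value: float


@dataclass(frozen=True)
class SaliencyMap:
    values: np.ndarray            # (S, S) signed
    target: Activation


@dataclass(frozen=True)
class RelevanceMap:
    values: np.ndarray            # (S, S) non-negative
    output_relevance: float       # R_f, the decomposed class score
    class_index: int


@dataclass(frozen=True)
class OcclusionMap:
    values: np.ndarray            # (S, S) uint8 in [0, 255]
    mask_size: int
    class_index: int


def _forward_cached(net: Network, patch: np.ndarray) -> list[np.ndarray]:
    """Eval-mode forward of one patch, returning each layer's output
    (and priming the per-layer caches the backward rules reuse)."""
    x = np.asarray(patch, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, :, :, None]
    net.astype(np.float64)
    outs = []
    h = x
    for layer in net.layers:
        h = layer.forward(h, train=False)
        outs.append(h)
    return outs


def _last_conv_relu_index(net: Network) -> int:
    idx = max(i for i, l in enumerate(net.layers) if isinstance(l, Conv2D))
    assert isinstance(net.layers[idx + 1], ReLU)
    return idx + 1


def select_max_activations(net: Network, patch: np.ndarray) -> list[Activation]:
    """Spatial maximum of every feature map of the last conv layer.

    Ties within a map resolve to the first position in row-major scan
    order; the returned list is ranked by activation value (descending,
    ties by map index).
    """
    outs = _forward_cached(net, patch)
    act = outs[_last_conv_relu_index(net)][0]        # (H, W, C)
    H, W, C = act.shape
    flat = act.reshape(H * W, C)
    pos = flat.argmax(axis=0)
    vals = flat[pos, np.arange(C)]
    ranked = sorted(range(C), key=lambda m: (-vals[m], m))
    return [
        Activation(m, (int(pos[m] // W), int(pos[m] % W)), float(vals[m]))
        for m in ranked
    ]


def guided_backprop(net: Network, patch: np.ndarray,
                    target: Activation) -> SaliencyMap:
    """Backpropagate one last-conv activation to pixel space with the
    guided-ReLU rule (both the forward mask and the sign of the
    incoming backward signal gate the flow).

    A non-positive target activation yields an all-zero map, since the
    very first gate closes.
    """
    outs = _forward_cached(net, patch)
    start = _last_conv_relu_index(net)
    act = outs[start][0]
    H, W, C = act.shape
    grad = np.zeros((1, H, W, C), dtype=np.float64)
    grad[0, target.position[0], target.position[1], target.feature_map] = 1.0
    for i in range(start, -1, -1):
        layer = net.layers[i]
        if isinstance(layer, ReLU):
            grad = layer.backward(grad, guided=True)
        elif isinstance(layer, Conv2D):
            grad = layer.input_grad_with(
                grad, layer.params["W"], layer._xshape
            )
        else:
            grad = layer.backward(grad)
    return SaliencyMap(values=grad[0, :, :, 0], target=target)


def _zplus_dense(layer: Dense, R: np.ndarray) -> np.ndarray:
    a = layer._x
    Wp = np.maximum(layer.params["W"], 0.0)
    z = a @ Wp
    s = np.where(z > 0, R / np.maximum(z, _EPS), 0.0)
    return a * (s @ Wp.T)


def _zplus_conv(layer: Conv2D, R: np.ndarray) -> np.ndarray:
    a = layer._x
    Wp = np.maximum(layer.params["W"], 0.0)
    z = layer.conv_with(a, Wp)
    s = np.where(z > 0, R / np.maximum(z, _EPS), 0.0)
    return a * layer.input_grad_with(s, Wp, a.shape)


def _zB_dense(layer: Dense, R: np.ndarray, low: float, high: float) -> np.ndarray:
    x = layer._x
    W = layer.params["W"]
    Wp = np.maximum(W, 0.0)
    Wm = np.minimum(W, 0.0)
    z = x @ W - low * Wp.sum(axis=0) - high * Wm.sum(axis=0)
    s = np.where(z > 0, R / np.maximum(z, _EPS), 0.0)
    return x * (s @ W.T) - low * (s @ Wp.T) - high * (s @ Wm.T)


def _zB_conv(layer: Conv2D, R: np.ndarray, low: float, high: float) -> np.ndarray:
    x = layer._x
    Wfull = layer.params["W"]
    Wp = np.maximum(Wfull, 0.0)
    Wm = np.minimum(Wfull, 0.0)
    ones = np.ones_like(x)
    z = (layer.conv_with(x, Wfull)
         - low * layer.conv_with(ones, Wp)
         - high * layer.conv_with(ones, Wm))
    s = np.where(z > 0, R / np.maximum(z, _EPS), 0.0)
    return (x * layer.input_grad_with(s, Wfull, x.shape)
            - low * layer.input_grad_with(s, Wp, x.shape)
            - high * layer.input_grad_with(s, Wm, x.shape))


def deep_taylor(net: Network, patch: np.ndarray,
                class_index: int | None = None,
                input_bounds: tuple[float, float] = (0.0, 1.0)) -> RelevanceMap:
    """Pixel-wise relevance of the (pre-softmax) class score.

    By default decomposes the predicted class, mirroring attribution of
    the model's own decision.  If the class score is non-positive there
    is no positive evidence to decompose and the map is all zeros.
    """
    import warnings

    outs = _forward_cached(net, patch)
    logits = outs[-1][0]
    if class_index is None:
        class_index = int(np.argmax(logits))
    r_f = float(logits[class_index])
    S = net.spec.input_px
    if r_f <= 0:
        warnings.warn("class score is non-positive; returning a zero relevance map")
        return RelevanceMap(np.zeros((S, S)), r_f, class_index)

    R = np.zeros((1, logits.size))
    R[0, class_index] = r_f
    # the z^B rule applies to whichever parametric layer reads the
    # box-constrained input (the first conv, or the first dense in a
    # purely fully connected stack)
    first_param = min(i for i, l in enumerate(net.layers)
                      if isinstance(l, (Conv2D, Dense)))
    for i in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[i]
        if isinstance(layer, Dense):
            if i == first_param:
                R = _zB_dense(layer, R, *input_bounds)
            else:
                R = _zplus_dense(layer, R)
        elif isinstance(layer, Conv2D):
            if i == first_param:
                R = _zB_conv(layer, R, *input_bounds)
            else:
                R = _zplus_conv(layer, R)
        elif isinstance(layer, MaxPool2):
            R = layer.route(R)
        elif isinstance(layer, Flatten):
            R = R.reshape(layer._xshape)
        elif isinstance(layer, (ReLU, Dropout)):
            continue
    return RelevanceMap(values=np.maximum(R[0, :, :, 0], 0.0),
                        output_relevance=r_f, class_index=class_index)


def occlusion_map(net: Network, patch: np.ndarray, true_label: int | None = None,
                  mask_size: int = 7, fill: str = "mean",
                  use_softmax: bool = False, batch_size: int = 256) -> OcclusionMap:
    """Occlusion-sensitivity map.

    For every pixel, the ``mask_size``² window centered there (cropped
    at the borders) is replaced by the patch mean (or zero), the image
    is re-classified, and the negated class score is recorded; the map
    is then min-max normalized to integers in [0, 255].  The class
    defaults to ``true_label`` when given, else the unoccluded
    prediction.  A constant map (e.g. from a constant predictor)
    normalizes to all zeros.
    """
    if mask_size % 2 != 1:
        raise ValueError("mask_size must be odd")
    patch = np.asarray(patch, dtype=np.float32)
    S = patch.shape[0]
    if mask_size >= S:
        raise ValueError("mask must be smaller than the patch")
    net.astype(np.float32)
    if true_label is None:
        base = net.logits(patch[None, :, :, None])
        cls = int(np.argmax(base[0]))
    else:
        cls = int(true_label)
    half = mask_size // 2
    fill_value = float(patch.mean()) if fill == "mean" else 0.0
    scores = np.empty(S * S, dtype=np.float64)
    coords = [(i, j) for i in range(S) for j in range(S)]
    for start in range(0, len(coords), batch_size):
        chunk = coords[start:start + batch_size]
        batch = np.repeat(patch[None], len(chunk), axis=0)
        for b, (i, j) in enumerate(chunk):
            batch[b, max(0, i - half):i + half + 1, max(0, j - half):j + half + 1] = fill_value
        logit = net.logits(batch[..., None])
        if use_softmax:
            from .nn import softmax
            out = softmax(logit)[:, cls]
        else:
            out = logit[:, cls]
        scores[start:start + len(chunk)] = -out.astype(np.float64)
    smap = scores.reshape(S, S)
    rng_ = smap.max() - smap.min()
    if rng_ <= 0:
        values = np.zeros((S, S), dtype=np.uint8)
    else:
        values = np.rint(255.0 * (smap - smap.min()) / rng_).astype(np.uint8)
    return OcclusionMap(values=values, mask_size=mask_size, class_index=cls)
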