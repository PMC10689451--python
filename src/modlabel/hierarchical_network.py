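"""Hierarchical network with learned stochastic gain modulation.

A four-stage feedforward model of a visual hierarchy:

* an encoding layer of fixed, oriented Gabor filters tiling the image, with
  exponential activation and per-unit modulator couplings,

      h^(0)_n = exp(w^(0)_n . s + m_t c_n),

* one or more locally connected processing layers (untied weights over a
  spatial grid of patches) with rectifying nonlinearity,
* multiplicative gains g_n >= 0 on the final processing layer,
* a fully connected 10-way decision layer.

Training proceeds in three stages: (1) pretraining of processing and
decision weights on a 10-class glyph-classification task with additive
pixel noise and L1 regularization (modulator off, gains 1); (2) learning a
fresh 10-way orientation readout on single positioned gratings, everything
else frozen; (3) task fine-tuning on binary orientation discrimination
with distractors, where only the encoding couplings c_n are trained by
gradient descent (slow scale, m = 1) while the top-layer gains are set on
a fast time scale by the modulator-correlation rule

      g_n = (1/T) sum_t m_t h^(2)_{n,t},   m_t ~ N(0, 0.1),

rectified at zero. Control variants retrain all weights, the decision
layer only, or the couplings with a constant (deterministic) modulator.

Everything is plain numpy with hand-written gradients; the architecture is
small and fixed, so no autodiff framework is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkScaleConfig:
    """Architecture of one network instance.

    The default is the desk-scale configuration (28x28 input, 288 Gabor
    encoding units, one locally connected processing layer, 10-way decision
    layer). ``full_scale()`` gives the reference configuration with 3136
    input pixels, 2560 encoding units and a 7840-unit final processing
    layer (decision layer: 78,410 trainable parameters).
    """

    image_size: int = 28
    n_orientations: int = 8
    grid_size: int = 6  # encoding RF centers per side
    gabor_sigma: float = 2.5
    gabor_wavelength: float = 6.0
    #: per processing layer: (patch_size in grid cells, stride, channels)
    processing: tuple = ((3, 1, 50),)
    n_classes: int = 10
    seed: int = 0

    @property
    def n_pixels(self) -> int:
        return self.image_size**2

    @property
    def n_encoding(self) -> int:
        return self.n_orientations * self.grid_size**2

    @classmethod
    def full_scale(cls) -> "NetworkScaleConfig":
        return cls(
            image_size=56,
            n_orientations=10,
            grid_size=16,
            gabor_sigma=3.0,
            gabor_wavelength=8.0,
            processing=((2, 1, 20), (2, 1, 40)),
        )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _gabor(size, cx, cy, theta, sigma, wavelength, phase=0.0):
    y, x = np.mgrid[0:size, 0:size].astype(float)
    xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    yr = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    env = np.exp(-(xr**2 + yr**2) / (2 * sigma**2))
    g = env * np.cos(2 * np.pi * xr / wavelength + phase)
    g -= g.mean() * (env > 1e-3)  # approximately zero-mean
    n = np.linalg.norm(g)
    return (g / n if n > 0 else g).ravel()


@dataclass
class _LocalLayer:
    W: np.ndarray  # (n_out, n_in), zero outside the connectivity mask
    b: np.ndarray
    mask: np.ndarray  # boolean (n_out, n_in)

    @property
    def n_params(self) -> int:
        return int(self.mask.sum() + len(self.b))


@dataclass
class NetworkModel:
    config: NetworkScaleConfig
    W0: np.ndarray  # fixed Gabor bank (n_encoding, n_pixels)
    couplings: np.ndarray  # c_n, (n_encoding,)
    layers: list  # of _LocalLayer
    W2: np.ndarray  # decision weights (n_classes, n_top)
    b2: np.ndarray
    gains: np.ndarray  # g_n >= 0 on the final processing layer
    #: (orientation, row, col) of each encoding unit, for targeting analyses
    encoding_geometry: np.ndarray = None
    task_classes: tuple = (0, 3)

    @property
    def n_top(self) -> int:
        return self.layers[-1].W.shape[0]

    def parameter_counts(self) -> dict:
        counts = {
            "couplings": int(len(self.couplings)),
            "processing": int(sum(l.n_params for l in self.layers)),
            "decision": int(self.W2.size + self.b2.size),
            "gains": int(len(self.gains)),
        }
        counts["total_trainable"] = counts["processing"] + counts["decision"]
        return counts

    # -- forward pass ----------------------------------------------------
    def forward(self, images: np.ndarray, m: float | np.ndarray = 0.0,
                cache: bool = False):
        """Class scores for a batch of images at modulator value(s) ``m``.

        Returns scores (B, n_classes); with ``cache=True`` also the layer
        activities needed for gradients.
        """
        S = np.atleast_2d(images)
        a0 = S @ self.W0.T
        m_arr = np.asarray(m, dtype=float)
        mc = np.multiply.outer(m_arr, self.couplings) if m_arr.ndim else m_arr * self.couplings
        h = np.exp(np.clip(a0 + mc, -8.0, 8.0))
        h0 = h
        zs, hs = [], [h]
        for layer in self.layers:
            z = h @ layer.W.T + layer.b
            h = np.maximum(z, 0.0)
            zs.append(z)
            hs.append(h)
        h_top = self.gains * h
        scores = h_top @ self.W2.T + self.b2
        if cache:
            return scores, {"S": S, "h0": h0, "zs": zs, "hs": hs, "h_top": h_top}
        return scores


def build_network(config: NetworkScaleConfig | None = None) -> NetworkModel:
    """Construct a network: Gabor bank, locally connected layers, readout."""
    cfg = config or NetworkScaleConfig()
    rng = np.random.default_rng(cfg.seed)
    size, G = cfg.image_size, cfg.grid_size
    centers = np.linspace(size / (2 * G), size - size / (2 * G), G)
    thetas = np.arange(cfg.n_orientations) * np.pi / cfg.n_orientations

    W0 = np.empty((cfg.n_encoding, cfg.n_pixels))
    geom = np.empty((cfg.n_encoding, 3), dtype=int)
    i = 0
    for oi, th in enumerate(thetas):
        for ri, cy in enumerate(centers):
            for ci, cx in enumerate(centers):
                W0[i] = _gabor(size, cx, cy, th, cfg.gabor_sigma, cfg.gabor_wavelength)
                geom[i] = (oi, ri, ci)
                i += 1

    layers = []
    in_grid, in_ch = G, cfg.n_orientations
    n_in = cfg.n_encoding
    # encoding units are indexed orientation-major: unit = o*G*G + r*G + c
    in_index = np.arange(n_in).reshape(in_ch, in_grid, in_grid)
    for patch, stride, channels in cfg.processing:
        out_grid = (in_grid - patch) // stride + 1
        n_out = out_grid**2 * channels
        mask = np.zeros((n_out, n_in), dtype=bool)
        W = np.zeros((n_out, n_in))
        o = 0
        fan_in = patch * patch * in_ch
        for orow in range(out_grid):
            for ocol in range(out_grid):
                rows = slice(orow * stride, orow * stride + patch)
                cols = slice(ocol * stride, ocol * stride + patch)
                idx = in_index[:, rows, cols].ravel()
                for ch in range(channels):
                    mask[o, idx] = True
                    W[o, idx] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=len(idx))
                    o += 1
        layers.append(_LocalLayer(W=W, b=np.zeros(n_out), mask=mask))
        in_grid, in_ch = out_grid, channels
        n_in = n_out
        # output units are position-major blocks of `channels`; rebuild the
        # (channel, row, col) index for the next layer
        in_index = np.transpose(
            np.arange(n_in).reshape(out_grid, out_grid, channels), (2, 0, 1)
        )

    n_top = n_in
    W2 = rng.normal(0.0, np.sqrt(1.0 / n_top), size=(cfg.n_classes, n_top))
    return NetworkModel(
        config=cfg,
        W0=W0,
        couplings=np.zeros(cfg.n_encoding),
        layers=layers,
        W2=W2,
        b2=np.zeros(cfg.n_classes),
        gains=np.ones(n_top),
        encoding_geometry=geom,
    )


# ---------------------------------------------------------------------------
# task datasets
# ---------------------------------------------------------------------------

# stroke skeletons for 10 procedurally generated glyph classes, in [0, 1]^2
_GLYPH_STROKES = [
    [((0.2, 0.1), (0.8, 0.1)), ((0.8, 0.1), (0.8, 0.9)), ((0.8, 0.9), (0.2, 0.9)), ((0.2, 0.9), (0.2, 0.1))],
    [((0.5, 0.1), (0.5, 0.9))],
    [((0.2, 0.1), (0.8, 0.1)), ((0.8, 0.1), (0.2, 0.9)), ((0.2, 0.9), (0.8, 0.9))],
    [((0.2, 0.1), (0.8, 0.5)), ((0.8, 0.5), (0.2, 0.9))],
    [((0.2, 0.1), (0.2, 0.5)), ((0.2, 0.5), (0.8, 0.5)), ((0.8, 0.1), (0.8, 0.9))],
    [((0.8, 0.1), (0.2, 0.1)), ((0.2, 0.1), (0.2, 0.5)), ((0.2, 0.5), (0.8, 0.9))],
    [((0.8, 0.1), (0.2, 0.5)), ((0.2, 0.5), (0.2, 0.9)), ((0.2, 0.9), (0.8, 0.9)), ((0.8, 0.9), (0.8, 0.5))],
    [((0.2, 0.1), (0.8, 0.1)), ((0.8, 0.1), (0.4, 0.9))],
    [((0.2, 0.5), (0.8, 0.1)), ((0.8, 0.1), (0.2, 0.1)), ((0.2, 0.1), (0.8, 0.5)), ((0.8, 0.5), (0.2, 0.9)), ((0.2, 0.9), (0.8, 0.9))],
    [((0.2, 0.9), (0.8, 0.5)), ((0.8, 0.5), (0.8, 0.1)), ((0.8, 0.1), (0.2, 0.1)), ((0.2, 0.1), (0.2, 0.5))],
]


def _render_glyph(cls: int, patch: int = 12, n_points: int = 40) -> np.ndarray:
    img = np.zeros((patch, patch))
    for (x0, y0), (x1, y1) in _GLYPH_STROKES[cls]:
        ts = np.linspace(0, 1, n_points)
        xs = (x0 + ts * (x1 - x0)) * (patch - 1)
        ys = (y0 + ts * (y1 - y0)) * (patch - 1)
        xi = np.clip(np.round(xs).astype(int), 0, patch - 1)
        yi = np.clip(np.round(ys).astype(int), 0, patch - 1)
        img[yi, xi] = 1.0
    return img


@dataclass
class TaskDataset:
    images: np.ndarray  # (N, n_pixels)
    labels: np.ndarray
    task: str
    meta: dict = field(default_factory=dict)


def make_glyph_dataset(
    n: int,
    image_size: int = 28,
    noise_sd: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> TaskDataset:
    """Randomly positioned glyphs of 10 procedurally generated classes.

    The glyphs stand in for handwritten-digit images so pretraining needs
    no external dataset; they are line-stroke renderings placed at random
    offsets with additive i.i.d. pixel noise.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    patch = 12
    protos = [_render_glyph(c, patch) for c in range(10)]
    X = np.zeros((n, image_size, image_size))
    y = rng.integers(0, 10, size=n)
    for i in range(n):
        ox, oy = rng.integers(0, image_size - patch, size=2)
        X[i, oy:oy + patch, ox:ox + patch] = protos[y[i]]
    X += rng.normal(0.0, noise_sd, size=X.shape)
    return TaskDataset(X.reshape(n, -1), y, "glyph-classification")


def _grating_patch(patch: int, theta: float, wavelength: float, sigma: float,
                   phase: float = 0.0) -> np.ndarray:
    y, x = np.mgrid[0:patch, 0:patch].astype(float)
    cx = cy = (patch - 1) / 2.0
    xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    env = np.exp(-((x - cx)**2 + (y - cy)**2) / (2 * sigma**2))
    return env * np.cos(2 * np.pi * xr / wavelength + phase)


def _place_grating(img, pos_row, pos_col, theta, image_size, grid_size,
                   patch=11, wavelength=6.0, sigma=2.5, amplitude=1.0):
    centers = np.linspace(image_size / (2 * grid_size),
                          image_size - image_size / (2 * grid_size), grid_size)
    cy, cx = centers[pos_row], centers[pos_col]
    g = amplitude * _grating_patch(patch, theta, wavelength, sigma)
    half = patch // 2
    r0, c0 = int(round(cy)) - half, int(round(cx)) - half
    r1, c1 = r0 + patch, c0 + patch
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, image_size), min(c1, image_size)
    img[rr0:rr1, cc0:cc1] += g[rr0 - r0:patch - (r1 - rr1), cc0 - c0:patch - (c1 - cc1)]


def make_orientation_dataset(
    n: int,
    config: NetworkScaleConfig,
    noise_sd: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> TaskDataset:
    """Single oriented gratings at random grid positions; 10-way labels."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_cls = config.n_classes
    thetas = np.arange(n_cls) * np.pi / n_cls
    X = np.zeros((n, config.image_size, config.image_size))
    y = rng.integers(0, n_cls, size=n)
    for i in range(n):
        r, c = rng.integers(0, config.grid_size, size=2)
        _place_grating(X[i], r, c, thetas[y[i]], config.image_size, config.grid_size,
                       wavelength=config.gabor_wavelength, sigma=config.gabor_sigma)
    X += rng.normal(0.0, noise_sd, size=X.shape)
    return TaskDataset(X.reshape(n, -1), y, "positioned-orientation")


def make_binary_orientation_dataset(
    n: int,
    config: NetworkScaleConfig,
    task_position: tuple[int, int] = (2, 2),
    task_classes: tuple[int, int] = (0, 3),
    n_distractors: int = 5,
    noise_sd: float = 0.2,
    distractor_classes: str = "any",
    rng: np.random.Generator | int | None = None,
) -> TaskDataset:
    """Binary orientation discrimination at a fixed location with distractors.

    The target grating (one of two orientation classes) appears at
    ``task_position``; distractor gratings appear at other grid positions.
    With ``distractor_classes="task"`` the distractors are drawn from the
    two task orientations themselves, so only spatial location
    disambiguates the target; with ``"any"`` they take any of the 10
    orientations. Labels are 0/1.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_cls = config.n_classes
    thetas = np.arange(n_cls) * np.pi / n_cls
    G = config.grid_size
    positions = [(r, c) for r in range(G) for c in range(G) if (r, c) != tuple(task_position)]
    X = np.zeros((n, config.image_size, config.image_size))
    y = rng.integers(0, 2, size=n)
    for i in range(n):
        _place_grating(X[i], task_position[0], task_position[1],
                       thetas[task_classes[y[i]]], config.image_size, G,
                       wavelength=config.gabor_wavelength, sigma=config.gabor_sigma)
        d_idx = rng.choice(len(positions), size=n_distractors, replace=False)
        for j in d_idx:
            r, c = positions[j]
            if distractor_classes == "task":
                th = thetas[task_classes[rng.integers(0, 2)]]
            else:
                th = thetas[rng.integers(0, n_cls)]
            _place_grating(X[i], r, c, th, config.image_size, G,
                           wavelength=config.gabor_wavelength, sigma=config.gabor_sigma)
    X += rng.normal(0.0, noise_sd, size=X.shape)
    return TaskDataset(
        X.reshape(n, -1), y, "binary-orientation-with-distractors",
        meta={"task_position": tuple(task_position), "task_classes": tuple(task_classes)},
    )


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_dscores(scores, labels, classes=None):
    """Cross-entropy (optionally restricted to a subset of classes)."""
    B = scores.shape[0]
    if classes is None:
        p = _softmax(scores)
        loss = -np.mean(np.log(p[np.arange(B), labels] + 1e-12))
        d = p
        d[np.arange(B), labels] -= 1.0
        return loss, d / B
    sub = scores[:, list(classes)]
    p = _softmax(sub)
    loss = -np.mean(np.log(p[np.arange(B), labels] + 1e-12))
    dsub = p
    dsub[np.arange(B), labels] -= 1.0
    d = np.zeros_like(scores)
    d[:, list(classes)] = dsub / B
    return loss, d


def _backward(net: NetworkModel, cache, dscores, *, need_weights=False,
              need_couplings=False, m=0.0):
    """Gradients of the loss for the cached forward pass."""
    grads = {}
    h_top = cache["h_top"]
    grads["W2"] = dscores.T @ h_top
    grads["b2"] = dscores.sum(axis=0)
    dh_top = dscores @ net.W2
    dh = net.gains * dh_top  # gains are set, not backpropagated through
    if need_weights:
        grads["layers"] = []
    for li in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[li]
        dz = dh * (cache["zs"][li] > 0)
        if need_weights:
            gW = dz.T @ cache["hs"][li]
            gW[~layer.mask] = 0.0
            grads["layers"].insert(0, (gW, dz.sum(axis=0)))
        dh = dz @ layer.W
    if need_couplings:
        # dh0/dc_n = m * h0_n
        grads["couplings"] = np.asarray(m, dtype=float) * (dh * cache["h0"]).sum(axis=0)
    return grads


def mg_gain_rule(h_top: np.ndarray, modulator: np.ndarray) -> np.ndarray:
    """Gains from modulator/response correlation: g = (1/T) sum m_t h_t, >= 0."""
    h_top = np.atleast_2d(h_top)
    if h_top.shape[0] == 0:
        raise ValueError("need at least one fast time step")
    m = np.asarray(modulator, dtype=float)
    return np.clip(m @ h_top / len(m), 0.0, None)


def estimate_gains(
    net: NetworkModel,
    images: np.ndarray,
    n_fast: int = 100,
    m_var: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Fast-time-scale gain estimation: present each stimulus for ``n_fast``
    modulator draws m_t ~ N(0, m_var) and apply the correlation rule,
    averaged over stimuli."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    S = np.atleast_2d(images)
    B = S.shape[0]
    m = rng.normal(0.0, np.sqrt(m_var), size=(n_fast,))
    # (n_fast * B) forward passes batched together
    a0 = S @ net.W0.T  # (B, E)
    mc = np.multiply.outer(m, net.couplings)  # (T, E)
    h = np.exp(np.clip(a0[None, :, :] + mc[:, None, :], -8.0, 8.0))
    h = h.reshape(n_fast * B, -1)
    for layer in net.layers:
        h = np.maximum(h @ layer.W.T + layer.b, 0.0)
    h = h.reshape(n_fast, B, -1)
    g = np.stack([mg_gain_rule(h[:, b, :], m) for b in range(B)])
    return g.mean(axis=0)


class StageOrderError(RuntimeError):
    pass


def train_stage(
    net: NetworkModel,
    dataset: TaskDataset,
    stage: str,
    *,
    epochs: int = 20,
    batch_size: int = 32,
    lr: float = 0.1,
    l1: float = 1e-4,
    lr_couplings: float = 0.01,
    n_fast: int = 100,
    m_var: float = 0.1,
    fast_batch: int = 16,
    gain_update_every: int = 2,
    gain_floor: float = 0.02,
    gain_ema: float = 0.7,
    deterministic_modulator: bool = False,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Run one training stage in place; returns a history dict.

    Stages: ``pretrain`` (processing + decision weights, glyph task, L1
    penalty), ``readout`` (fresh decision layer on the 10-way orientation
    task, everything else frozen), ``couplings`` (encoding couplings only,
    binary task, gains set by the MG rule on the fast scale; with
    ``deterministic_modulator`` the modulator is constant m = 1 and gains
    stay 1), ``weights`` and ``decision`` (control variants retraining all
    weights / the decision layer only on the binary task).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X, y = dataset.images, dataset.labels
    n = len(y)
    history = {"loss": [], "stage": stage}

    stage_specs = {
        "pretrain": dict(weights=True, decision=True, couplings=False, classes=None),
        "readout": dict(weights=False, decision=True, couplings=False, classes=None),
        "couplings": dict(weights=False, decision=False, couplings=True, classes="task"),
        "weights": dict(weights=True, decision=True, couplings=False, classes="task"),
        "decision": dict(weights=False, decision=True, couplings=False, classes="task"),
    }
    if stage not in stage_specs:
        raise ValueError(f"unknown stage {stage!r}")
    if stage == "pretrain" and dataset.task != "glyph-classification":
        raise StageOrderError("pretraining expects the glyph-classification task")
    if stage == "readout" and dataset.task != "positioned-orientation":
        raise StageOrderError("readout stage expects the positioned-orientation task")
    if stage in ("couplings", "weights", "decision"):
        if dataset.task != "binary-orientation-with-distractors":
            raise StageOrderError(f"stage {stage!r} expects the binary task")
    spec = stage_specs[stage]
    if spec["classes"] == "task":
        classes = dataset.meta.get("task_classes", net.task_classes)
        net.task_classes = tuple(classes)
    else:
        classes = None

    if stage == "readout" or stage == "decision":
        # fresh readout: the decision-layer control relearns it de novo
        r2 = np.random.default_rng(rng.integers(2**31))
        net.W2 = r2.normal(0.0, np.sqrt(1.0 / net.n_top), size=net.W2.shape)
        net.b2 = np.zeros_like(net.b2)
    if stage == "weights":
        # the full-retraining control relearns every connection de novo
        r2 = np.random.default_rng(rng.integers(2**31))
        for layer in net.layers:
            fan_in = layer.mask[0].sum()
            fresh = r2.normal(0.0, np.sqrt(2.0 / fan_in), size=layer.W.shape)
            layer.W = np.where(layer.mask, fresh, 0.0)
            layer.b = np.zeros_like(layer.b)
        net.W2 = r2.normal(0.0, np.sqrt(1.0 / net.n_top), size=net.W2.shape)
        net.b2 = np.zeros_like(net.b2)

    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb, yb = X[idx], y[idx]
            m_slow = 0.0
            if stage == "couplings":
                m_slow = 1.0
                if not deterministic_modulator and step % gain_update_every == 0:
                    sub = rng.choice(n, size=min(fast_batch, n), replace=False)
                    g_raw = estimate_gains(
                        net, X[sub], n_fast=n_fast, m_var=m_var, rng=rng
                    )
                    # softened normalization: with no co-fluctuation signal
                    # (couplings ~ 0) the gains stay near 1, so the frozen
                    # readout is undisturbed; as the correlations grow the
                    # gains approach g / mean(g) and become selective
                    g_new = (g_raw + gain_floor) / (g_raw.mean() + gain_floor)
                    net.gains = gain_ema * net.gains + (1 - gain_ema) * g_new
            scores, cache = net.forward(Xb, m=m_slow, cache=True)
            loss, dscores = _loss_and_dscores(scores, yb, classes)
            grads = _backward(
                net, cache, dscores,
                need_weights=spec["weights"],
                need_couplings=spec["couplings"],
                m=m_slow,
            )
            if spec["decision"] or spec["weights"]:
                net.W2 -= lr * (grads["W2"] + l1 * np.sign(net.W2))
                net.b2 -= lr * grads["b2"]
            if spec["weights"]:
                for layer, (gW, gb) in zip(net.layers, grads["layers"]):
                    layer.W -= lr * (gW + l1 * np.sign(layer.W) * layer.mask)
                    layer.b -= lr * gb
            if spec["couplings"]:
                net.couplings -= lr_couplings * grads["couplings"]
                np.clip(net.couplings, -3.0, 3.0, out=net.couplings)
            history["loss"].append(loss)
            step += 1

    if stage == "couplings" and not deterministic_modulator:
        # final gain estimate with the learned couplings, on more stimuli
        sub = rng.choice(n, size=min(4 * fast_batch, n), replace=False)
        g_raw = estimate_gains(net, X[sub], n_fast=n_fast, m_var=m_var, rng=rng)
        net.gains = (g_raw + gain_floor) / (g_raw.mean() + gain_floor)
    return history


def evaluate_binary(
    net: NetworkModel,
    dataset: TaskDataset,
    m: float = 0.0,
    n_fast: int = 0,
    m_var: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Held-out accuracy on the binary task (argmax over the two task-class
    scores).

    With ``n_fast > 0`` the modulator fluctuates during the presentation
    (m_t ~ N(0, m_var)) and the decision integrates the class scores over
    the fast time steps; otherwise the modulator is held at ``m``.
    """
    classes = dataset.meta.get("task_classes", net.task_classes)
    if n_fast > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        ms = rng.normal(0.0, np.sqrt(m_var), size=n_fast)
        scores = np.mean([net.forward(dataset.images, m=mi) for mi in ms], axis=0)
    else:
        scores = net.forward(dataset.images, m=m)
    pred = np.argmax(scores[:, list(classes)], axis=1)
    return float(np.mean(pred == dataset.labels))


def evaluate_multiclass(net: NetworkModel, dataset: TaskDataset) -> float:
    scores = net.forward(dataset.images, m=0.0)
    return float(np.mean(np.argmax(scores, axis=1) == dataset.labels))


# ---------------------------------------------------------------------------
# variant comparison
# ---------------------------------------------------------------------------

def _clone_net(net: NetworkModel) -> NetworkModel:
    import copy

    return copy.deepcopy(net)


def pretrain_and_readout(
    config: NetworkScaleConfig,
    seed: int,
    n_pretrain: int = 8000,
    n_readout: int = 4000,
    pretrain_epochs: int = 30,
    readout_epochs: int = 12,
) -> NetworkModel:
    """Stages 1-2: build, pretrain on glyphs, learn the orientation readout."""
    net = build_network(NetworkScaleConfig(**{**config.__dict__, "seed": seed}))
    rng = np.random.default_rng(seed + 101)
    glyphs = make_glyph_dataset(n_pretrain, config.image_size, rng=rng)
    train_stage(net, glyphs, "pretrain", epochs=pretrain_epochs, rng=rng)
    orient = make_orientation_dataset(n_readout, config, rng=rng)
    train_stage(net, orient, "readout", epochs=readout_epochs, rng=rng)
    return net


def run_comparison(
    config: NetworkScaleConfig | None = None,
    variants=("stochastic-modulator", "weight-retraining",
              "decision-layer-retraining", "deterministic-modulator"),
    train_sizes=(250, 500, 1000, 2000, 4000),
    seeds=(0, 1, 2),
    n_test: int = 500,
    criterion: float = 0.80,
    epochs: int = 20,
    **task_kwargs,
) -> dict:
    """Sample-efficiency comparison of fine-tuning strategies.

    All variants start from the same pretrained network per seed. Returns
    per-variant held-out accuracy (seeds x sizes) and the samples-to-
    criterion (first training-set size whose median accuracy over seeds
    exceeds the criterion).
    """
    config = config or NetworkScaleConfig()
    train_sizes = list(train_sizes)
    acc = {v: np.full((len(seeds), len(train_sizes)), np.nan) for v in variants}
    for si, seed in enumerate(seeds):
        base = pretrain_and_readout(config, seed)
        test_set = make_binary_orientation_dataset(
            n_test, config, rng=np.random.default_rng(seed + 900), **task_kwargs
        )
        for ni, n_train in enumerate(train_sizes):
            train_set = make_binary_orientation_dataset(
                n_train, config, rng=np.random.default_rng(seed + 300 + ni),
                **task_kwargs
            )
            for variant in variants:
                net = _clone_net(base)
                rng = np.random.default_rng(seed + 500 + ni)
                if variant == "stochastic-modulator":
                    train_stage(net, train_set, "couplings", epochs=epochs, rng=rng)
                    acc[variant][si, ni] = evaluate_binary(net, test_set)
                elif variant == "deterministic-modulator":
                    train_stage(net, train_set, "couplings", epochs=epochs,
                                deterministic_modulator=True, rng=rng)
                    acc[variant][si, ni] = evaluate_binary(net, test_set, m=1.0)
                elif variant == "weight-retraining":
                    train_stage(net, train_set, "weights", epochs=epochs, rng=rng)
                    acc[variant][si, ni] = evaluate_binary(net, test_set)
                elif variant == "decision-layer-retraining":
                    train_stage(net, train_set, "decision", epochs=epochs, rng=rng)
                    acc[variant][si, ni] = evaluate_binary(net, test_set)
                else:
                    raise ValueError(f"unknown variant {variant!r}")
    out = {"train_sizes": train_sizes, "accuracy": acc, "criterion": criterion}
    out["samples_to_criterion"] = {}
    for v in variants:
        med = np.median(acc[v], axis=0)
        above = [n for n, a in zip(train_sizes, med) if a > criterion]
        out["samples_to_criterion"][v] = above[0] if above else None
    return out
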