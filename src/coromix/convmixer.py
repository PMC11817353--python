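"""Multi-input multi-scale ConvMixer implemented in NumPy.

The network classifies a 12-lead ECG record from its twelve spectrogram
images.  Every (lead, patch-scale) pair owns an independent *branch* — 24
branches at the default two scales — consisting of:

    patch embedding:  stride-P convolution, GeLU, BatchNorm
    D mixer blocks:   [depthwise KxK conv -> GeLU -> BatchNorm] + residual,
                      then pointwise 1x1 conv -> GeLU -> BatchNorm
    global average pooling to H channel means

Note the printed operation order — BatchNorm *after* GeLU, and the residual
connection only around the depthwise stage — is followed exactly.  The
pooled branch outputs are concatenated and pass through a linear embedding
layer (``fc_embed``, 1000 wide by default, the feature tap for the
downstream ensemble) and a softmax output over the 7 occlusion classes.

Forward, backward, and the SGD-with-momentum trainer are hand-written and
validated against central-difference numerical gradients, so no deep
learning framework is required.  All arithmetic is float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .ecg_io import CLASS_NAMES

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


class ConfigurationError(ValueError):
    pass


class DegenerateTrainingSetError(ValueError):
    def __init__(self, msg: str = "degenerate-training-set"):
        super().__init__(msg)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden`` defaults to a desk-scale 32 channels; the reference
    configuration uses 750 (see docs/methods.md for the trade-off).
    """

    input_size: int = 64
    patch_sizes: tuple[int, ...] = (16, 8)
    hidden: int = 32
    kernel: int = 3
    depth: int = 4
    n_leads: int = 12
    n_classes: int = 7
    embed_dim: int = 1000

    def __post_init__(self) -> None:
        for p in self.patch_sizes:
            if self.input_size % p != 0:
                raise ConfigurationError(
                    f"input_size {self.input_size} not divisible by patch size {p}"
                )
        if self.kernel % 2 != 1:
            raise ConfigurationError("depthwise kernel size must be odd")
        if min(self.hidden, self.depth, self.kernel, self.embed_dim) < 1:
            raise ConfigurationError("hidden, depth, kernel, embed_dim must be >= 1")

    @property
    def n_scales(self) -> int:
        return len(self.patch_sizes)

    @property
    def n_branches(self) -> int:
        return self.n_leads * self.n_scales

    @property
    def concat_dim(self) -> int:
        return self.n_branches * self.hidden


@dataclass(frozen=True)
class TrainOptions:
    """SGDM options.  ``weight_decay`` is L2 regularization on convolution
    and fully connected weight matrices (not biases or BN parameters),
    matching the default of the reference SGDM trainer."""

    epochs: int = 100
    minibatch: int = 128
    initial_lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    validation_fraction: float = 0.1
    validation_frequency: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.minibatch < 1 or self.validation_frequency < 1:
            raise ValueError("epochs, minibatch, validation_frequency must be >= 1")
        if self.initial_lr < 0 or not 0 <= self.validation_fraction < 1:
            raise ValueError("invalid learning rate or validation fraction")


# ---------------------------------------------------------------------------
# primitive layers (forward returns (out, cache); backward consumes cache)


def _gelu(x: np.ndarray) -> np.ndarray:
    from scipy.special import erf

    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    from scipy.special import erf

    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / np.sqrt(
        2.0 * np.pi
    )


def _bn_forward(x, gamma, beta, running, train):
    """BatchNorm over all axes but the last (channels).

    ``train`` is one of True (batch stats, running stats updated by
    momentum), False (running stats), or the string ``"calib"`` (batch
    stats, and the batch moments are accumulated for precise recalibration
    of the running statistics).
    """
    axes = tuple(range(x.ndim - 1))
    if train:
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        if train == "calib":
            running.setdefault("acc", []).append((mu, var))
        else:
            running["mean"] = (1 - BN_MOMENTUM) * running["mean"] + BN_MOMENTUM * mu
            running["var"] = (1 - BN_MOMENTUM) * running["var"] + BN_MOMENTUM * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mu) * inv
    out = gamma * xhat + beta
    return out, (xhat, inv, gamma, train, axes, x.shape)


def _bn_backward(dout, cache):
    xhat, inv, gamma, train, axes, shape = cache
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma
    if not train:
        return dxhat * inv, dgamma, dbeta
    m = np.prod([shape[a] for a in axes])
    dx = (
        dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
    ) * inv
    return dx, dgamma, dbeta


def _patchify(x, P):
    n, s, _, c = x.shape
    g = s // P
    return (
        x.reshape(n, g, P, g, P, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, g, g, P * P * c)
    )


def _unpatchify(dpatches, P, s, c):
    n, g = dpatches.shape[0], dpatches.shape[1]
    return (
        dpatches.reshape(n, g, g, P, P, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, s, s, c)
    )


def _depthwise_forward(x, W, b):
    """Same-padded depthwise convolution, odd kernel, channels-last."""
    K = W.shape[0]
    r = K // 2
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (r, r), (r, r), (0, 0)))
    out = np.zeros_like(x)
    for u in range(K):
        for v in range(K):
            out += W[u, v] * xp[:, u : u + h, v : v + w, :]
    return out + b, (xp, W, h, w)


def _depthwise_backward(dout, cache):
    xp, W, h, w = cache
    K = W.shape[0]
    r = K // 2
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for u in range(K):
        for v in range(K):
            dW[u, v] = (dout * xp[:, u : u + h, v : v + w, :]).sum(axis=(0, 1, 2))
            dxp[:, u : u + h, v : v + w, :] += W[u, v] * dout
    db = dout.sum(axis=(0, 1, 2))
    dx = dxp[:, r : r + h, r : r + w, :]
    return dx, dW, db


# ---------------------------------------------------------------------------
# model


def _bn_params(H):
    return {"gamma": np.ones(H), "beta": np.zeros(H)}


def _bn_state(H):
    return {"mean": np.zeros(H), "var": np.ones(H)}


class MIMSConvMixer:
    """The trainable model: parameter store plus forward/backward passes.

    Branches are ordered scale-major: branch ``s * n_leads + l`` applies
    patch size ``patch_sizes[s]`` to the image of lead ``l``.  Inputs are
    arrays of shape ``(batch, n_leads, input_size, input_size, 3)``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.branches: list[dict] = []
        self.bn_states: list[dict] = []
        for s in range(c.n_scales):
            P = c.patch_sizes[s]
            for _lead in range(c.n_leads):
                fan = P * P * 3
                params = {
                    "patch_W": rng.normal(0, np.sqrt(2.0 / fan), (fan, c.hidden)),
                    "patch_b": np.zeros(c.hidden),
                    "bn0": _bn_params(c.hidden),
                    "blocks": [],
                }
                states = {"bn0": _bn_state(c.hidden), "blocks": []}
                for _ in range(c.depth):
                    params["blocks"].append(
                        {
                            "dw_W": rng.normal(
                                0, np.sqrt(2.0 / (c.kernel**2)),
                                (c.kernel, c.kernel, c.hidden),
                            ),
                            "dw_b": np.zeros(c.hidden),
                            "bn1": _bn_params(c.hidden),
                            "pw_W": rng.normal(
                                0, np.sqrt(2.0 / c.hidden), (c.hidden, c.hidden)
                            ),
                            "pw_b": np.zeros(c.hidden),
                            "bn2": _bn_params(c.hidden),
                        }
                    )
                    states["blocks"].append(
                        {"bn1": _bn_state(c.hidden), "bn2": _bn_state(c.hidden)}
                    )
                self.branches.append(params)
                self.bn_states.append(states)
        self.head = {
            "emb_W": rng.normal(
                0, np.sqrt(2.0 / c.concat_dim), (c.concat_dim, c.embed_dim)
            ),
            "emb_b": np.zeros(c.embed_dim),
            "out_W": rng.normal(
                0, np.sqrt(2.0 / c.embed_dim), (c.embed_dim, c.n_classes)
            ),
            "out_b": np.zeros(c.n_classes),
        }
        self.trained = False

    # -- parameter bookkeeping ------------------------------------------------

    def _param_arrays(self):
        """Yield (path, array) for every learnable parameter."""
        for bi, br in enumerate(self.branches):
            yield f"b{bi}.patch_W", br["patch_W"]
            yield f"b{bi}.patch_b", br["patch_b"]
            yield f"b{bi}.bn0.gamma", br["bn0"]["gamma"]
            yield f"b{bi}.bn0.beta", br["bn0"]["beta"]
            for di, blk in enumerate(br["blocks"]):
                for key in ("dw_W", "dw_b", "pw_W", "pw_b"):
                    yield f"b{bi}.d{di}.{key}", blk[key]
                for bn in ("bn1", "bn2"):
                    yield f"b{bi}.d{di}.{bn}.gamma", blk[bn]["gamma"]
                    yield f"b{bi}.d{di}.{bn}.beta", blk[bn]["beta"]
        for key in ("emb_W", "emb_b", "out_W", "out_b"):
            yield f"head.{key}", self.head[key]

    def parameters(self) -> dict[str, np.ndarray]:
        return dict(self._param_arrays())

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        for k, v in params.items():
            own[k][...] = v

    def count_parameters(self) -> int:
        """Number of learnable scalars (BN running stats excluded)."""
        return sum(int(a.size) for _, a in self._param_arrays())

    def branch_parameter_count(self, branch: int = 0) -> int:
        prefix = f"b{branch}."
        return sum(
            int(a.size) for k, a in self._param_arrays() if k.startswith(prefix)
        )

    # -- forward / backward ---------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 4:
            X = X[None]
        c = self.config
        expected = (c.n_leads, c.input_size, c.input_size, 3)
        if X.ndim != 5 or X.shape[1:] != expected:
            raise ValueError(
                f"expected input of shape (batch, {', '.join(map(str, expected))}), "
                f"got {X.shape}"
            )
        return X

    def _branch_forward(self, x, bi, train):
        c = self.config
        P = c.patch_sizes[bi // c.n_leads]
        br, st = self.branches[bi], self.bn_states[bi]
        cache = {"P": P}
        patches = _patchify(x, P)
        z = patches @ br["patch_W"] + br["patch_b"]
        cache["patches"], cache["z0"] = patches, z
        a = _gelu(z)
        h, cache["bn0"] = _bn_forward(a, br["bn0"]["gamma"], br["bn0"]["beta"],
                                      st["bn0"], train)
        cache["blocks"] = []
        for blk, bst in zip(br["blocks"], st["blocks"]):
            bc = {"x_in": h}
            u, bc["dw"] = _depthwise_forward(h, blk["dw_W"], blk["dw_b"])
            bc["u"] = u
            g1 = _gelu(u)
            n1, bc["bn1"] = _bn_forward(g1, blk["bn1"]["gamma"], blk["bn1"]["beta"],
                                        bst["bn1"], train)
            t = n1 + h  # residual around the depthwise stage
            v = t @ blk["pw_W"] + blk["pw_b"]
            bc["t"], bc["v"] = t, v
            g2 = _gelu(v)
            h, bc["bn2"] = _bn_forward(g2, blk["bn2"]["gamma"], blk["bn2"]["beta"],
                                       bst["bn2"], train)
            cache["blocks"].append(bc)
        gap = h.mean(axis=(1, 2))
        cache["grid"] = h.shape[1]
        return gap, cache

    def forward(self, X: np.ndarray, train: bool = False):
        """Returns (probs, embed, caches)."""
        X = self._check_input(X)
        c = self.config
        gaps, caches = [], []
        for bi in range(c.n_branches):
            lead = bi % c.n_leads
            gap, cache = self._branch_forward(X[:, lead], bi, train)
            gaps.append(gap)
            caches.append(cache)
        concat = np.concatenate(gaps, axis=1)
        embed = concat @ self.head["emb_W"] + self.head["emb_b"]
        logits = embed @ self.head["out_W"] + self.head["out_b"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, embed, {"concat": concat, "embed": embed, "branches": caches}

    def _branch_backward(self, dgap, bi, cache):
        br = self.branches[bi]
        grads = {}
        g = cache["grid"]
        dh = np.broadcast_to(
            dgap[:, None, None, :] / (g * g),
            (dgap.shape[0], g, g, dgap.shape[1]),
        ).copy()
        for bi_d in range(len(br["blocks"]) - 1, -1, -1):
            blk, bc = br["blocks"][bi_d], cache["blocks"][bi_d]
            dg2, dgam2, dbet2 = _bn_backward(dh, bc["bn2"])
            dv = dg2 * _gelu_grad(bc["v"])
            dt = dv @ blk["pw_W"].T
            dpw_W = bc["t"].reshape(-1, bc["t"].shape[-1]).T @ dv.reshape(
                -1, dv.shape[-1]
            )
            dpw_b = dv.sum(axis=(0, 1, 2))
            dn1 = dt
            dres = dt  # residual path
            dg1, dgam1, dbet1 = _bn_backward(dn1, bc["bn1"])
            du = dg1 * _gelu_grad(bc["u"])
            dx, ddw_W, ddw_b = _depthwise_backward(du, bc["dw"])
            dh = dx + dres
            grads[f"d{bi_d}.pw_W"] = dpw_W
            grads[f"d{bi_d}.pw_b"] = dpw_b
            grads[f"d{bi_d}.bn2.gamma"] = dgam2
            grads[f"d{bi_d}.bn2.beta"] = dbet2
            grads[f"d{bi_d}.dw_W"] = ddw_W
            grads[f"d{bi_d}.dw_b"] = ddw_b
            grads[f"d{bi_d}.bn1.gamma"] = dgam1
            grads[f"d{bi_d}.bn1.beta"] = dbet1
        da, dgam0, dbet0 = _bn_backward(dh, cache["bn0"])
        dz = da * _gelu_grad(cache["z0"])
        patches = cache["patches"]
        grads["patch_W"] = patches.reshape(-1, patches.shape[-1]).T @ dz.reshape(
            -1, dz.shape[-1]
        )
        grads["patch_b"] = dz.sum(axis=(0, 1, 2))
        grads["bn0.gamma"] = dgam0
        grads["bn0.beta"] = dbet0
        return grads

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and gradients for a labeled minibatch."""
        X = self._check_input(X)
        y = np.asarray(y, dtype=int)
        probs, _, fw = self.forward(X, train=True)
        n = X.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        embed, concat = fw["embed"], fw["concat"]
        grads["head.out_W"] = embed.T @ dlogits
        grads["head.out_b"] = dlogits.sum(axis=0)
        dembed = dlogits @ self.head["out_W"].T
        grads["head.emb_W"] = concat.T @ dembed
        grads["head.emb_b"] = dembed.sum(axis=0)
        dconcat = dembed @ self.head["emb_W"].T
        H = self.config.hidden
        for bi in range(self.config.n_branches):
            dgap = dconcat[:, bi * H : (bi + 1) * H]
            bgrads = self._branch_backward(dgap, bi, fw["branches"][bi])
            for k, v in bgrads.items():
                grads[f"b{bi}.{k}"] = v
        return loss, probs, grads

    # -- batch-norm recalibration ---------------------------------------------

    def _bn_running_dicts(self):
        for st in self.bn_states:
            yield st["bn0"]
            for bst in st["blocks"]:
                yield bst["bn1"]
                yield bst["bn2"]

    def calibrate_bn(self, X: np.ndarray, batch_size: int = 64) -> None:
        """Set BN running statistics to population statistics ("precise BN").

        Small training minibatches leave momentum-averaged running
        statistics far from the statistics the weights were trained under;
        this pass re-estimates them from full forward passes, combining
        batch moments as ``var = E[var_b] + Var[mu_b]``.
        """
        X = self._check_input(X)
        for running in self._bn_running_dicts():
            running.pop("acc", None)
        weights = []
        for i in range(0, X.shape[0], batch_size):
            batch = X[i : i + batch_size]
            weights.append(batch.shape[0])
            self.forward(batch, train="calib")
        w = np.asarray(weights, dtype=float)[:, None]
        w /= w.sum()
        for running in self._bn_running_dicts():
            acc = running.pop("acc", [])
            if not acc:
                continue
            mus = np.stack([a[0] for a in acc])
            vars_ = np.stack([a[1] for a in acc])
            mean = (w * mus).sum(axis=0)
            running["mean"] = mean
            running["var"] = (w * vars_).sum(axis=0) + (w * (mus - mean) ** 2).sum(axis=0)

    # -- inference ------------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        X = self._check_input(X)
        out = [
            self.forward(X[i : i + batch_size], train=False)[0]
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def extract_features(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Activations of the ``fc_embed`` layer, shape (n, embed_dim)."""
        X = self._check_input(X)
        out = [
            self.forward(X[i : i + batch_size], train=False)[1]
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        arrays = {k.replace(".", "__"): v for k, v in self._param_arrays()}
        for bi, st in enumerate(self.bn_states):
            arrays[f"state__b{bi}__bn0__mean"] = st["bn0"]["mean"]
            arrays[f"state__b{bi}__bn0__var"] = st["bn0"]["var"]
            for di, bst in enumerate(st["blocks"]):
                for bn in ("bn1", "bn2"):
                    arrays[f"state__b{bi}__d{di}__{bn}__mean"] = bst[bn]["mean"]
                    arrays[f"state__b{bi}__d{di}__{bn}__var"] = bst[bn]["var"]
        cfg = asdict(self.config)
        cfg["patch_sizes"] = list(cfg["patch_sizes"])
        np.savez(path, __config__=json.dumps({"config": cfg, "trained": self.trained}),
                 **arrays)

    @classmethod
    def load(cls, path) -> "MIMSConvMixer":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__config__"]))
        cfg = meta["config"]
        cfg["patch_sizes"] = tuple(cfg["patch_sizes"])
        model = cls(ModelConfig(**cfg), seed=0)
        params = {
            k.replace("__", "."): data[k]
            for k in data.files
            if not k.startswith(("state__", "__config__"))
        }
        model.set_parameters(params)
        for bi, st in enumerate(model.bn_states):
            st["bn0"]["mean"][...] = data[f"state__b{bi}__bn0__mean"]
            st["bn0"]["var"][...] = data[f"state__b{bi}__bn0__var"]
            for di, bst in enumerate(st["blocks"]):
                for bn in ("bn1", "bn2"):
                    bst[bn]["mean"][...] = data[f"state__b{bi}__d{di}__{bn}__mean"]
                    bst[bn]["var"][...] = data[f"state__b{bi}__d{di}__{bn}__var"]
        model.trained = meta["trained"]
        return model


def build_model(config: ModelConfig, seed: int = 0) -> MIMSConvMixer:
    """Construct an untrained model with seeded initialization."""
    return MIMSConvMixer(config, seed=seed)


def count_parameters(model: MIMSConvMixer) -> int:
    return model.count_parameters()


@dataclass
class TrainHistory:
    """Per-iteration training curves, plus periodic validation points."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_iterations: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def train_model(
    model: MIMSConvMixer,
    X: np.ndarray,
    y: np.ndarray,
    opts: TrainOptions,
) -> TrainHistory:
    """SGD-with-momentum training on cross-entropy; returns the history.

    A ``validation_fraction`` tail of a seeded shuffle is held out and
    scored every ``validation_frequency`` iterations.  Deterministic for a
    fixed seed on a fixed platform.
    """
    X = model._check_input(X)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise DegenerateTrainingSetError(
            "degenerate-training-set: need at least 2 classes"
        )
    rng = np.random.default_rng(opts.seed)
    order = rng.permutation(X.shape[0])
    n_val = int(round(opts.validation_fraction * X.shape[0]))
    val_idx, train_idx = order[: n_val], order[n_val:]
    if train_idx.size == 0:
        raise DegenerateTrainingSetError("degenerate-training-set: empty train split")
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]

    velocity = {k: np.zeros_like(v) for k, v in model.parameters().items()}
    params = model.parameters()
    history = TrainHistory()
    iteration = 0
    for _epoch in range(opts.epochs):
        perm = rng.permutation(Xt.shape[0])
        for start in range(0, Xt.shape[0], opts.minibatch):
            idx = perm[start : start + opts.minibatch]
            loss, probs, grads = model.loss_and_grads(Xt[idx], yt[idx])
            acc = float(np.mean(probs.argmax(axis=1) == yt[idx]))
            for k, g in grads.items():
                if opts.weight_decay and k.endswith("_W"):
                    g = g + opts.weight_decay * params[k]
                velocity[k] = opts.momentum * velocity[k] + g
                params[k] -= opts.initial_lr * velocity[k]
            history.loss.append(float(loss))
            history.accuracy.append(acc)
            iteration += 1
            if n_val > 0 and iteration % opts.validation_frequency == 0:
                model.calibrate_bn(Xt)
                vp = model.predict_proba(Xv)
                vl = -float(
                    np.mean(np.log(vp[np.arange(len(yv)), yv] + 1e-300))
                )
                history.val_iterations.append(iteration)
                history.val_loss.append(vl)
                history.val_accuracy.append(
                    float(np.mean(vp.argmax(axis=1) == yv))
                )
    model.calibrate_bn(Xt)
    model.trained = True
    return history


def predict(model: MIMSConvMixer, inputs: np.ndarray) -> np.ndarray:
    """Class probabilities for one record's 12 images (or a batch)."""
    single = np.asarray(inputs).ndim == 4
    probs = model.predict_proba(inputs)
    return probs[0] if single else probs


def predict_label(model: MIMSConvMixer, inputs: np.ndarray) -> str:
    return CLASS_NAMES[int(np.argmax(predict(model, inputs)))]
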