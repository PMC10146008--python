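"""Neural blood-pressure estimators and leave-one-out evaluation.

The estimators are small fully-connected / gated networks trained by
full-batch Adam on mean-squared error with L2 weight decay and early
stopping on a 15% validation split. Feature z-scoring is fit on the
training split only; targets stay in mmHg (the output layer is linear).

Canonical architectures:

* ``morph_ffnn``  -- 21 -> [35, 20] sigmoid -> 2   (SBP, DBP jointly)
* ``morph_deep``  -- 7 -> [70, 100, 150] sigmoid -> 2
* ``morph_lstm``  -- 7 -> LSTM [64, 512] relu -> 2
* ``morph_gru``   -- 7 -> GRU [128, 256, 512] relu -> 2
* ``final_sbp`` / ``final_dbp`` -- 8 -> [10] sigmoid -> 1

The composite estimator chains three subnetworks: a deep morphology net
maps the 7 mPTP features to a first (SBP, DBP) estimate, then each of two
single-hidden-layer nets maps [7 dynamics features + the corresponding
morphology estimate] to the final pressure.

Recurrent layers see each subject as a length-1 sequence of its static
feature vector with zero initial state; under that reading the recurrent
(hidden-to-hidden) weights and the LSTM forget gate receive no gradient and
cannot influence the output, so they are omitted from the parameterisation.

An optional MacKay-style Bayesian-regularisation trainer (Gauss-Newton with
evidence-driven alpha/beta updates) is provided for the small
single-hidden-layer final nets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConfigError,
    DataError,
    InsufficientDataError,
    LeakageError,
    SchemaError,
    StateError,
)

# ---------------------------------------------------------------------------
# specs and configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    input_dim: int
    hidden: tuple[int, ...]
    hidden_activation: str = "sigmoid"      # "sigmoid" | "relu"
    output_dim: int = 2
    layer_kind: str = "dense"               # "dense" | "lstm" | "gru"

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden) or self.input_dim <= 0 or self.output_dim <= 0:
            raise ConfigError("all layer widths must be positive")
        if self.hidden_activation not in ("sigmoid", "relu"):
            raise ConfigError(f"unknown activation {self.hidden_activation!r}")
        if self.layer_kind not in ("dense", "lstm", "gru"):
            raise ConfigError(f"unknown layer kind {self.layer_kind!r}")


CANONICAL_SPECS: dict[str, NetworkSpec] = {
    "morph_ffnn": NetworkSpec("morph_ffnn", 21, (35, 20), "sigmoid", 2, "dense"),
    "morph_deep": NetworkSpec("morph_deep", 7, (70, 100, 150), "sigmoid", 2, "dense"),
    "morph_lstm": NetworkSpec("morph_lstm", 7, (64, 512), "relu", 2, "lstm"),
    "morph_gru": NetworkSpec("morph_gru", 7, (128, 256, 512), "relu", 2, "gru"),
    "final_sbp": NetworkSpec("final_sbp", 8, (10,), "sigmoid", 1, "dense"),
    "final_dbp": NetworkSpec("final_dbp", 8, (10,), "sigmoid", 1, "dense"),
}


@dataclass(frozen=True)
class TrainingConfig:
    val_fraction: float = 0.15
    early_stop_patience: int = 50
    max_epochs: int = 2000
    l2_lambda: float = 1e-4
    learning_rate: float = 1e-2
    seed: int = 0
    bayes_reg: bool = False    # MacKay evidence trainer (single-hidden dense only)

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 0.5:
            raise ConfigError("val_fraction must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# layers (forward + manual backprop)
# ---------------------------------------------------------------------------


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    if name == "relu":
        return np.maximum(z, 0.0)
    return z  # linear


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "relu":
        return (z > 0).astype(float)
    return np.ones_like(z)


class _DenseLayer:
    """x @ W + b followed by an elementwise activation."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.params = [rng.normal(0.0, scale, size=(n_in, n_out)),
                       np.zeros(n_out)]
        self.activation = activation

    @property
    def weight_mask(self) -> list[bool]:   # True entries get L2 decay
        return [True, False]

    def forward(self, x: np.ndarray):
        W, b = self.params
        z = x @ W + b
        a = _act(self.activation, z)
        return a, (x, z, a)

    def backward(self, grad_a: np.ndarray, cache):
        x, z, a = cache
        W, _ = self.params
        gz = grad_a * _act_grad(self.activation, z, a)
        return gz @ W.T, [x.T @ gz, gz.sum(axis=0)]


class _LSTMLayer:
    """Single-step LSTM cell with zero initial state.

    c = sigmoid(x Wi + bi) * act(x Wg + bg);  h = sigmoid(x Wo + bo) * act(c).
    """

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.params = [rng.normal(0.0, scale, size=(n_in, n_out)) for _ in range(3)] \
            + [np.zeros(n_out) for _ in range(3)]
        self.activation = activation

    @property
    def weight_mask(self) -> list[bool]:
        return [True, True, True, False, False, False]

    def forward(self, x: np.ndarray):
        Wi, Wo, Wg, bi, bo, bg = self.params
        zi, zo, zg = x @ Wi + bi, x @ Wo + bo, x @ Wg + bg
        i, o = _act("sigmoid", zi), _act("sigmoid", zo)
        g = _act(self.activation, zg)
        c = i * g
        ac = _act(self.activation, c)
        h = o * ac
        return h, (x, zi, zo, zg, i, o, g, c, ac)

    def backward(self, grad_h: np.ndarray, cache):
        x, zi, zo, zg, i, o, g, c, ac = cache
        Wi, Wo, Wg, _, _, _ = self.params
        go = grad_h * ac * _act_grad("sigmoid", zo, o)
        gc = grad_h * o * _act_grad(self.activation, c, ac)
        gi = gc * g * _act_grad("sigmoid", zi, i)
        gg = gc * i * _act_grad(self.activation, zg, g)
        grad_x = gi @ Wi.T + go @ Wo.T + gg @ Wg.T
        return grad_x, [x.T @ gi, x.T @ go, x.T @ gg,
                        gi.sum(axis=0), go.sum(axis=0), gg.sum(axis=0)]


class _GRULayer:
    """Single-step GRU cell with zero initial state: h = (1 - z) * n."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.params = [rng.normal(0.0, scale, size=(n_in, n_out)) for _ in range(2)] \
            + [np.zeros(n_out) for _ in range(2)]
        self.activation = activation

    @property
    def weight_mask(self) -> list[bool]:
        return [True, True, False, False]

    def forward(self, x: np.ndarray):
        Wz, Wn, bz, bn = self.params
        zz, zn = x @ Wz + bz, x @ Wn + bn
        z = _act("sigmoid", zz)
        n = _act(self.activation, zn)
        h = (1.0 - z) * n
        return h, (x, zz, zn, z, n)

    def backward(self, grad_h: np.ndarray, cache):
        x, zz, zn, z, n = cache
        Wz, Wn, _, _ = self.params
        gzz = grad_h * (-n) * _act_grad("sigmoid", zz, z)
        gzn = grad_h * (1.0 - z) * _act_grad(self.activation, zn, n)
        grad_x = gzz @ Wz.T + gzn @ Wn.T
        return grad_x, [x.T @ gzz, x.T @ gzn, gzz.sum(axis=0), gzn.sum(axis=0)]


_LAYER_CLASSES = {"dense": _DenseLayer, "lstm": _LSTMLayer, "gru": _GRULayer}


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class NeuralEstimator:
    """A network defined by a NetworkSpec, with fit/predict and a scaler.

    Deterministic: (data, config, seed) fully determine the trained weights
    and every subsequent prediction.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        hidden_cls = _LAYER_CLASSES[spec.layer_kind]
        self.layers: list = []
        n_in = spec.input_dim
        for width in spec.hidden:
            self.layers.append(hidden_cls(n_in, width, spec.hidden_activation, rng))
            n_in = width
        self.layers.append(_DenseLayer(n_in, spec.output_dim, "linear", rng))
        self.scaler_mean_: np.ndarray | None = None
        self.scaler_sd_: np.ndarray | None = None
        self.training_log: dict = {}
        self.trained = False

    # -- parameter plumbing -------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_params(self, flat: list[np.ndarray]) -> None:
        it = iter(flat)
        for layer in self.layers:
            layer.params = [next(it).copy() for _ in layer.params]

    # -- forward / backward -------------------------------------------------
    def _forward(self, X: np.ndarray):
        caches = []
        a = X
        for layer in self.layers:
            a, cache = layer.forward(a)
            caches.append(cache)
        return a, caches

    def _backward(self, grad_out: np.ndarray, caches):
        grads: list[list[np.ndarray]] = [None] * len(self.layers)
        g = grad_out
        for li in range(len(self.layers) - 1, -1, -1):
            g, layer_grads = self.layers[li].backward(g, caches[li])
            grads[li] = layer_grads
        return [g for layer_grads in grads for g in layer_grads]

    # -- training -----------------------------------------------------------
    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise SchemaError(
                f"{self.spec.name} expects {self.spec.input_dim} features, "
                f"got shape {X.shape}"
            )
        return X

    def fit(self, X: np.ndarray, y: np.ndarray,
            cfg: TrainingConfig | None = None) -> "NeuralEstimator":
        cfg = cfg or TrainingConfig()
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[1] != self.spec.output_dim:
            raise SchemaError(
                f"{self.spec.name} has {self.spec.output_dim} outputs, "
                f"targets have {y.shape[1]} columns"
            )
        bad_rows = np.nonzero(~np.all(np.isfinite(X), axis=1)
                              | ~np.all(np.isfinite(y), axis=1))[0]
        if bad_rows.size:
            raise DataError(f"missing/non-finite values in rows {bad_rows.tolist()}")
        n = X.shape[0]
        if n < 20:
            raise InsufficientDataError(f"need >= 20 rows to train, got {n}")

        # 85/15 split, then z-score scaler from the training split only
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        val_idx = np.sort(perm[:n_val])
        train_idx = np.sort(perm[n_val:])
        self.train_indices_ = train_idx
        self.val_indices_ = val_idx
        self.scaler_mean_ = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        self.scaler_sd_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.scaler_mean_) / self.scaler_sd_
        Xtr, ytr = Xs[train_idx], y[train_idx]
        Xva, yva = Xs[val_idx], y[val_idx]

        # start the linear output at the training-target mean
        self.layers[-1].params[1] = ytr.mean(axis=0).astype(float)

        if cfg.bayes_reg:
            self._fit_bayes(Xtr, ytr, Xva, yva, cfg)
        else:
            self._fit_adam(Xtr, ytr, Xva, yva, cfg)
        self.trained = True
        return self

    def _loss(self, X: np.ndarray, y: np.ndarray) -> float:
        pred, _ = self._forward(X)
        return float(np.mean(np.sum((pred - y) ** 2, axis=1)))

    def _fit_adam(self, Xtr, ytr, Xva, yva, cfg: TrainingConfig) -> None:
        params = [p for layer in self.layers for p in layer.params]
        masks = [m for layer in self.layers for m in layer.weight_mask]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best_params = self.get_params()
        best_epoch = 0
        stale = 0
        for epoch in range(1, cfg.max_epochs + 1):
            pred, caches = self._forward(Xtr)
            grad_out = 2.0 * (pred - ytr) / Xtr.shape[0]
            grads = self._backward(grad_out, caches)
            for k, (p, g, is_w) in enumerate(zip(params, grads, masks)):
                if is_w and cfg.l2_lambda > 0:
                    g = g + 2.0 * cfg.l2_lambda * p
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** epoch)
                vhat = v[k] / (1 - b2 ** epoch)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_loss = self._loss(Xva, yva)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = self.get_params()
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
        self.set_params(best_params)
        self.training_log = {"epochs": epoch, "best_epoch": best_epoch,
                             "val_loss": best_val, "trainer": "adam",
                             "seed": cfg.seed}

    # -- MacKay Bayesian-regularisation trainer (small dense nets) ---------
    def _fit_bayes(self, Xtr, ytr, Xva, yva, cfg: TrainingConfig) -> None:
        if (self.spec.layer_kind != "dense" or len(self.spec.hidden) != 1
                or self.spec.output_dim != 1):
            raise ConfigError(
                "bayes_reg trainer supports single-hidden-layer dense nets "
                "with one output only"
            )
        n, _ = Xtr.shape
        alpha, beta = 1e-3, 1.0
        k = self.n_params

        def flatten(ps):
            return np.concatenate([p.ravel() for p in ps])

        def unflatten(w):
            out, pos = [], 0
            for p in self.get_params():
                out.append(w[pos:pos + p.size].reshape(p.shape))
                pos += p.size
            return out

        def jacobian() -> tuple[np.ndarray, np.ndarray]:
            # y = sigma(X W1 + b1) @ w2 + b2
            (W1, b1), (W2, b2) = (self.layers[0].params, self.layers[1].params)
            z1 = Xtr @ W1 + b1
            h = _act("sigmoid", z1)
            pred = h @ W2 + b2
            sg = h * (1 - h)                       # (n, H)
            dW1 = (sg * W2.T)[:, None, :] * Xtr[:, :, None]   # (n, in, H)
            db1 = sg * W2.T                                   # (n, H)
            J = np.concatenate([dW1.reshape(n, -1), db1, h,
                                np.ones((n, 1))], axis=1)
            return J, pred.ravel()

        w = flatten(self.get_params())
        mu = 1e-3
        ident = np.eye(k)
        best_val = np.inf
        best_params = self.get_params()
        for it in range(200):
            J, pred = jacobian()
            e = ytr.ravel() - pred
            ed, ew = float(e @ e), float(w @ w)
            H = beta * (J.T @ J) + (alpha + mu) * ident
            g = beta * (J.T @ e) - alpha * w
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            w_new = w + step
            self.set_params(unflatten(w_new))
            J2, pred2 = jacobian()
            e2 = ytr.ravel() - pred2
            obj_new = beta * float(e2 @ e2) + alpha * float(w_new @ w_new)
            obj_old = beta * ed + alpha * ew
            if obj_new < obj_old:
                w = w_new
                mu = max(mu / 3.0, 1e-8)
                # evidence updates
                Hg = beta * (J2.T @ J2) + alpha * ident
                gamma = k - alpha * float(np.trace(np.linalg.inv(Hg)))
                ew2 = float(w @ w)
                alpha = gamma / (2.0 * ew2) if ew2 > 0 else alpha
                beta = (n - gamma) / (2.0 * float(e2 @ e2)) if e2 @ e2 > 0 else beta
                alpha = float(np.clip(alpha, 1e-8, 1e4))
                beta = float(np.clip(beta, 1e-8, 1e8))
                val_loss = self._loss(Xva, yva)
                if val_loss < best_val:
                    best_val = val_loss
                    best_params = self.get_params()
            else:
                self.set_params(unflatten(w))
                mu *= 3.0
                if mu > 1e8:
                    break
        self.set_params(best_params)
        self.training_log = {"epochs": it + 1, "val_loss": best_val,
                             "trainer": "bayes_reg", "alpha": alpha,
                             "beta": beta, "seed": cfg.seed}

    # -- inference ----------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError(f"{self.spec.name} has not been trained")
        X = self._check_X(X)
        Xs = (X - self.scaler_mean_) / self.scaler_sd_
        out, _ = self._forward(Xs)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite prediction")
        return out


def build_network(spec: NetworkSpec | str, seed: int = 0) -> NeuralEstimator:
    """Untrained estimator from a canonical spec name or a custom spec."""
    if isinstance(spec, str):
        try:
            spec = CANONICAL_SPECS[spec]
        except KeyError:
            raise ConfigError(f"unknown canonical network {spec!r}") from None
    return NeuralEstimator(spec, seed=seed)


def train(est: NeuralEstimator, features: np.ndarray, targets: np.ndarray,
          cfg: TrainingConfig | None = None) -> NeuralEstimator:
    """Fit an estimator (functional alias for ``est.fit``)."""
    return est.fit(features, targets, cfg)


def predict_bp(est: NeuralEstimator, features: np.ndarray) -> np.ndarray:
    """Apply a trained estimator; mmHg, one or two columns per its spec."""
    return est.predict(features)


# ---------------------------------------------------------------------------
# composite (three-subnetwork) model
# ---------------------------------------------------------------------------


def composite_estimate(
    morph7: np.ndarray,
    dyn7: np.ndarray,
    nets: dict[str, NeuralEstimator],
    dyn7_dbp: np.ndarray | None = None,
) -> np.ndarray:
    """Two-stage estimate: deep morphology net, then per-pressure final nets.

    Stage 1 maps the 7 morphology features to (SBP_m, DBP_m); stage 2 feeds
    [7 dynamics features, SBP_m] to ``final_sbp`` and [dyn7, DBP_m] to
    ``final_dbp``. When ``dyn7_dbp`` is given, the DBP path uses it instead
    of ``dyn7`` (trough-IBI routing: peak-interval features estimate SBP,
    trough-interval features DBP). Returns an (n, 2) array of (SBP, DBP).
    """
    for key in ("morph_deep", "final_sbp", "final_dbp"):
        if key not in nets:
            raise StateError(f"composite requires a {key!r} network")
        if not nets[key].trained:
            raise StateError(f"{key!r} network is untrained")
    dyn7_dbp = dyn7 if dyn7_dbp is None else dyn7_dbp
    stage1 = nets["morph_deep"].predict(morph7)
    sbp = nets["final_sbp"].predict(np.column_stack([dyn7, stage1[:, 0]]))
    dbp = nets["final_dbp"].predict(np.column_stack([dyn7_dbp, stage1[:, 1]]))
    return np.column_stack([sbp.ravel(), dbp.ravel()])


class CompositeModel:
    """Trainable wrapper around the three-subnetwork estimator.

    ``fit`` expects X as [morph7 | dyn7] (14 columns, dynamics shared
    between pressures) or [morph7 | dyn7_peaks | dyn7_troughs] (21 columns,
    peak-IBI features routed to SBP and trough-IBI features to DBP), and y
    as (n, 2) = (SBP, DBP) mmHg, so it drops into the generic LOO loop.
    """

    def __init__(self, seed: int = 0, cfg: TrainingConfig | None = None,
                 stage1_spec: NetworkSpec | str = "morph_deep"):
        self.seed = int(seed)
        self.cfg = cfg or TrainingConfig(seed=seed)
        self.nets = {
            "morph_deep": build_network(stage1_spec, seed=seed),
            "final_sbp": build_network("final_sbp", seed=seed + 1),
            "final_dbp": build_network("final_dbp", seed=seed + 2),
        }

    @staticmethod
    def _split(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if X.shape[1] == 14:
            return X[:, :7], X[:, 7:], X[:, 7:]
        if X.shape[1] == 21:
            return X[:, :7], X[:, 7:14], X[:, 14:]
        raise SchemaError(
            "composite expects 14 columns (morph7|dyn7) or 21 "
            "(morph7|dyn7_peaks|dyn7_troughs)"
        )

    def fit(self, X: np.ndarray, y: np.ndarray,
            cfg: TrainingConfig | None = None) -> "CompositeModel":
        cfg = cfg or self.cfg
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        morph7, dyn_s, dyn_d = self._split(X)
        self.nets["morph_deep"].fit(morph7, y, replace(cfg, seed=cfg.seed))
        stage1 = self.nets["morph_deep"].predict(morph7)
        self.nets["final_sbp"].fit(
            np.column_stack([dyn_s, stage1[:, 0]]), y[:, 0],
            replace(cfg, seed=cfg.seed + 1))
        self.nets["final_dbp"].fit(
            np.column_stack([dyn_d, stage1[:, 1]]), y[:, 1],
            replace(cfg, seed=cfg.seed + 2))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        morph7, dyn_s, dyn_d = self._split(X)
        return composite_estimate(morph7, dyn_s, self.nets, dyn7_dbp=dyn_d)


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------


def loo_evaluate(
    features: np.ndarray,
    targets: np.ndarray,
    builder,
    cfg: TrainingConfig | None = None,
    subject_ids: list[str] | None = None,
) -> np.ndarray:
    """Leave-one-subject-out estimates (one feature row per subject).

    For each subject the model from ``builder(seed)`` is trained on every
    other subject (with the 85/15 train/validation split inside) and applied
    to the held-out row. Training rows identical to the held-out row are
    treated as leakage and rejected.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = X.shape[0]
    if n < 5:
        raise InsufficientDataError(f"need >= 5 subjects for LOO, got {n}")
    if subject_ids is not None and len(set(subject_ids)) != n:
        raise LeakageError("duplicate subject ids in LOO cohort")
    cfg = cfg or TrainingConfig()
    squeeze = np.asarray(targets).ndim == 1
    preds = np.empty((n, y.shape[1]))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if np.any(np.all(Xtr == X[i], axis=1)):
            raise LeakageError(
                f"training fold contains a row identical to held-out subject {i}"
            )
        fold_cfg = replace(cfg, seed=cfg.seed + i)
        model = builder(cfg.seed + i)
        model.fit(Xtr, ytr if y.shape[1] > 1 else ytr.ravel(), fold_cfg)
        preds[i] = np.asarray(model.predict(X[i: i + 1])).reshape(-1)[: y.shape[1]]
    return preds.ravel() if squeeze else preds
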