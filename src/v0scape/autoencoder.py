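"""Denoising autoencoder with a 3x3 grid-neighborhood loss.

Reduces aligned C-alpha configurations (flattened to one vector per frame,
Angstrom units) to a 2D latent space.  The architecture is a mirrored MLP:

    input -> 1024 -> h2 -> 2 -> h2 -> 1024 -> input

with ReLU non-linearities on the hidden layers, 20% inverted dropout on each
hidden layer during training, additive Gaussian input corruption (the
denoising part), and an L1 reconstruction loss.  An auxiliary L2 term maps
the 2D latent space onto a 3x3 grid of nodes: every encoded frame is
assigned to its nearest node, and reconstructions are pulled toward the
input-space centroid of their node's co-assigned members, pre-forming
clusters of structurally similar frames.

Training uses half of the shuffled frames; the other half is held out and
the holdout mean absolute per-coordinate reconstruction error (MAE, in
Angstrom) is the reported quality measure.  The whole procedure is a pure
function of (data, config, seed) — no global RNG state is touched.

Implemented directly on NumPy (forward/backward passes and Adam updates are
a few dense matmuls each); this keeps the package dependency-light and fully
deterministic on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajio import AtomSelection, Ensemble, select_atoms


class DataError(ValueError):
    pass


class StateError(RuntimeError):
    pass


@dataclass
class AutoencoderConfig:
    hidden1: int = 1024
    hidden2: int = 128
    latent_dim: int = 2          # fixed by design; kept explicit for reports
    dropout: float = 0.20
    corruption_sigma: float = 0.3  # Angstrom, matches thermal noise scale
    lambda_grid: float = 0.1
    grid_shape: tuple[int, int] = (3, 3)
    # The grid term switches on after this fraction of the epochs: before
    # the latent space has spread, all frames share one node and the term
    # would pull every reconstruction toward the global mean, collapsing
    # states instead of pre-forming clusters.
    grid_warmup_fraction: float = 0.3
    epochs: int = 500
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    # A 2D bottleneck can project two distinct states onto one latent
    # point at unlucky initializations and never escape that plateau.
    # Several candidate initializations are trained for a short pilot
    # phase and the one with the lowest training reconstruction loss is
    # continued — selection uses the training half only.
    n_restarts: int = 3
    pilot_fraction: float = 0.1
    # Max allowed per-frame C-alpha centroid drift (A).  Genuine
    # conformational change moves the centroid by a few A; residual global
    # translations are an order of magnitude larger.
    centroid_tolerance: float = 8.0

    def __post_init__(self):
        if self.latent_dim != 2:
            raise DataError("the latent space is 2D by design")
        if not (0.0 <= self.dropout < 1.0):
            raise DataError("dropout must lie in [0, 1)")
        if self.epochs < 1:
            raise DataError("epochs must be >= 1")


def _init_layers(dims: list[int], rng: np.random.Generator):
    """He-initialized weight/bias pairs for a ReLU MLP."""
    layers = []
    for fan_in, fan_out in zip(dims, dims[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        layers.append([W.astype(np.float32),
                       np.zeros(fan_out, dtype=np.float32)])
    return layers


@dataclass
class LatentModel:
    """Trained autoencoder plus its training provenance."""

    config: AutoencoderConfig
    layers: list            # [(W, b), ...] encoder then decoder
    feature_mean: np.ndarray
    calpha_indices: np.ndarray
    train_mask: np.ndarray  # boolean over the frames seen at fit time
    holdout_mae: float
    n_features: int

    # -- inference -----------------------------------------------------
    def _forward_eval(self, X: np.ndarray, upto: int | None = None):
        """Deterministic forward pass (dropout off). ``upto`` limits layers."""
        h = X.astype(np.float32)
        n_enc = 3
        layers = self.layers if upto is None else self.layers[:upto]
        for i, (W, b) in enumerate(layers):
            h = h @ W + b
            is_latent = i == n_enc - 1
            is_output = i == len(self.layers) - 1
            if not is_latent and not is_output:
                h = np.maximum(h, 0.0)
        return h

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self._forward_eval(X - self.feature_mean, upto=3)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward_eval(X - self.feature_mean) + self.feature_mean

    def features_from(self, ensemble: Ensemble) -> np.ndarray:
        X = ensemble.coords[:, self.calpha_indices, :]
        return X.reshape(ensemble.n_frames, -1)

    def save(self, path) -> None:
        import json

        arrays = {}
        for i, (W, b) in enumerate(self.layers):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez_compressed(
            path,
            feature_mean=self.feature_mean,
            calpha_indices=self.calpha_indices,
            train_mask=self.train_mask,
            meta=np.frombuffer(
                json.dumps(
                    {
                        "holdout_mae": self.holdout_mae,
                        "n_features": self.n_features,
                        "config": {
                            k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in vars(self.config).items()
                        },
                    }
                ).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "LatentModel":
        import json

        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        cfgd = meta["config"]
        cfgd["grid_shape"] = tuple(cfgd["grid_shape"])
        layers = []
        i = 0
        while f"W{i}" in data:
            layers.append([data[f"W{i}"], data[f"b{i}"]])
            i += 1
        return cls(
            config=AutoencoderConfig(**cfgd),
            layers=layers,
            feature_mean=data["feature_mean"],
            calpha_indices=data["calpha_indices"],
            train_mask=data["train_mask"],
            holdout_mae=float(meta["holdout_mae"]),
            n_features=int(meta["n_features"]),
        )


@dataclass
class Embedding:
    """Per-frame 2D latent coordinates with the train/holdout flag."""

    latent: np.ndarray      # (n_frames, 2)
    is_train: np.ndarray    # (n_frames,) bool; False for frames unseen at fit

    def __post_init__(self):
        if not np.all(np.isfinite(self.latent)):
            raise DataError("non-finite latent coordinates")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _grid_nodes(Z: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """3x3 lattice spanning the current latent range."""
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    gx = np.linspace(lo[0], hi[0], shape[0])
    gy = np.linspace(lo[1], hi[1], shape[1])
    return np.array([[x, y] for x in gx for y in gy], dtype=np.float32)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train_autoencoder(
    ensemble: Ensemble,
    calpha_selection: AtomSelection | None = None,
    cfg: AutoencoderConfig | None = None,
) -> LatentModel:
    """Fit the denoising autoencoder on half of the shuffled frames.

    Frames must already be rigid-body aligned; a per-frame centroid drift
    beyond ``cfg.centroid_tolerance`` raises, since residual global motion
    would dominate the latent space.
    """
    cfg = cfg or AutoencoderConfig()
    if calpha_selection is None:
        calpha_selection = select_atoms(
            ensemble.topology, "calpha", require_nonempty=True
        )
    coords = ensemble.coords[:, calpha_selection.indices, :]
    centroids = coords.mean(axis=1)
    drift = np.linalg.norm(centroids - centroids.mean(axis=0), axis=1)
    if drift.max() > cfg.centroid_tolerance:
        raise DataError(
            f"frames appear unaligned: centroid drift {drift.max():.2f} A "
            f"exceeds {cfg.centroid_tolerance} A; run kabsch_align first"
        )

    N = ensemble.n_frames
    if N < 4:
        raise DataError("need at least 4 frames for a train/holdout split")
    X = coords.reshape(N, -1).astype(np.float32)
    D = X.shape[1]

    rng_split = np.random.default_rng(cfg.seed)
    perm = rng_split.permutation(N)
    train_idx = perm[: N // 2]
    train_mask = np.zeros(N, dtype=bool)
    train_mask[train_idx] = True

    mean = X[train_idx].mean(axis=0)
    Xc = X - mean
    Xtr = Xc[train_idx]

    dims = [D, cfg.hidden1, cfg.hidden2, cfg.latent_dim,
            cfg.hidden2, cfg.hidden1, D]
    n_layers = len(dims) - 1
    latent_layer = 2  # output index of the layer producing z
    keep = 1.0 - cfg.dropout
    n_train = len(Xtr)
    warmup = int(cfg.grid_warmup_fraction * cfg.epochs)

    model = LatentModel(
        config=cfg, layers=None, feature_mean=mean,
        calpha_indices=calpha_selection.indices, train_mask=train_mask,
        holdout_mae=np.nan, n_features=D,
    )

    def run_epochs(cand, first_epoch, last_epoch):
        layers, params, opt, rng = (
            cand["layers"], cand["params"], cand["opt"], cand["rng"]
        )
        for _epoch in range(first_epoch, last_epoch):
            grid_active = cfg.lambda_grid > 0 and _epoch >= warmup
            if grid_active:
                model.layers = layers
                nodes = _grid_nodes(model._forward_eval(Xtr, upto=3),
                                    cfg.grid_shape)
            order = rng.permutation(n_train)
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start: start + cfg.batch_size]
                x = Xtr[idx]
                B = len(x)
                xin = x
                if cfg.corruption_sigma > 0:
                    xin = x + rng.normal(
                        0.0, cfg.corruption_sigma, size=x.shape
                    ).astype(np.float32)

                # forward with inverted dropout on hidden activations
                acts = [xin]
                masks = [None]
                h = xin
                for i, (W, b) in enumerate(layers):
                    h = h @ W + b
                    hidden = i not in (latent_layer, n_layers - 1)
                    m = None
                    if hidden:
                        h = np.maximum(h, 0.0)
                        if cfg.dropout > 0:
                            m = (rng.random(h.shape) < keep).astype(
                                np.float32)
                            h = h * m / keep
                    acts.append(h)
                    masks.append(m)
                xhat = acts[-1]

                # output gradient: L1 reconstruction
                g = np.sign(xhat - x).astype(np.float32) / (B * D)

                # Grid term: each node exerts a local (Gaussian-windowed)
                # influence on the latent codes in its cell.  Frames whose
                # input is MORE similar to the node's member centroid than the
                # typical within-node deviation are drawn toward the node
                # (condensing clusters of alike structures); frames LESS
                # similar are pushed off it until the window decays — so mixed
                # nodes resolve instead of locking, and both effects saturate
                # within about one lattice spacing (no runaway).  The gradient
                # touches the encoder only; reconstruction is never distorted.
                gz = None
                if grid_active:
                    z = acts[latent_layer + 1]
                    d2 = ((z[:, None, :] - nodes[None]) ** 2).sum(-1)  # (B, 9)
                    nd = ((nodes[:, None, :] - nodes[None]) ** 2).sum(-1)
                    np.fill_diagonal(nd, np.inf)
                    tau_g = max(float(np.min(nd, axis=1).mean()), 1e-12)
                    assign = np.argmin(d2, axis=1)
                    occupied = np.unique(assign)
                    cent = np.stack(
                        [x[assign == a].mean(axis=0) for a in occupied]
                    )
                    # input-space squared distance to each occupied centroid
                    q = (
                        (x ** 2).sum(1)[:, None]
                        - 2.0 * x @ cent.T
                        + (cent ** 2).sum(1)[None]
                    )
                    own = q[np.arange(B),
                            np.searchsorted(occupied, assign)]
                    qbar = max(float(own.mean()), 1e-12)
                    rel = np.clip((q - qbar) / qbar, -5.0, 5.0)
                    w = np.exp(-d2[:, occupied] / tau_g)
                    coeff = rel * w  # (B, n_occupied)
                    gz = (cfg.lambda_grid / B) * (-2.0 / tau_g) * (
                        coeff.sum(axis=1, keepdims=True) * z
                        - coeff @ nodes[occupied]
                    )
                    gz = gz.astype(np.float32)

                # backward
                grads = [None] * (2 * n_layers)
                for i in range(n_layers - 1, -1, -1):
                    W, _ = layers[i]
                    h_in = acts[i]
                    grads[2 * i] = h_in.T @ g
                    grads[2 * i + 1] = g.sum(axis=0)
                    if i > 0:
                        g = g @ W.T
                        if gz is not None and i - 1 == latent_layer:
                            g = g + gz
                        hidden = (i - 1) not in (latent_layer, n_layers - 1)
                        if hidden:
                            if masks[i] is not None:
                                g = g * masks[i] / keep
                            g = g * (acts[i] > 0)
                opt.step(params, grads)

    def new_candidate(seed_seq):
        rng = np.random.default_rng(seed_seq)
        layers = _init_layers(dims, rng)
        params = [a for lay in layers for a in lay]
        return {"layers": layers, "params": params,
                "opt": _Adam(params, cfg.learning_rate), "rng": rng}

    def training_loss(layers):
        model.layers = layers
        return float(np.mean(np.abs(model._forward_eval(Xtr) - Xtr)))

    seeds = np.random.SeedSequence(cfg.seed).spawn(max(cfg.n_restarts, 1))
    if cfg.n_restarts > 1:
        pilot = max(1, int(round(cfg.pilot_fraction * cfg.epochs)))
        pilot = min(pilot, cfg.epochs)
        best, best_loss = None, np.inf
        for seq in seeds:
            cand = new_candidate(seq)
            run_epochs(cand, 0, pilot)
            loss = training_loss(cand["layers"])
            if loss < best_loss:
                best, best_loss = cand, loss
        run_epochs(best, pilot, cfg.epochs)
        winner = best
    else:
        winner = new_candidate(seeds[0])
        run_epochs(winner, 0, cfg.epochs)

    model.layers = winner["layers"]

    holdout = Xc[~train_mask]
    recon = model._forward_eval(holdout)
    model.holdout_mae = float(np.mean(np.abs(recon - holdout)))
    return model


def embed_frames(model: LatentModel, ensemble: Ensemble) -> Embedding:
    """Deterministically encode every frame to 2D (inference mode)."""
    if model.layers is None or np.isnan(model.holdout_mae):
        raise StateError("model is not trained")
    X = model.features_from(ensemble)
    if X.shape[1] != model.n_features:
        raise DataError(
            f"feature dimension {X.shape[1]} does not match the trained "
            f"model ({model.n_features})"
        )
    latent = model.encode(X.astype(np.float32))
    is_train = (
        model.train_mask
        if len(model.train_mask) == ensemble.n_frames
        else np.zeros(ensemble.n_frames, dtype=bool)
    )
    return Embedding(latent=np.asarray(latent, dtype=float),
                     is_train=is_train)
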