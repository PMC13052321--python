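"""Wasserstein GAN with gradient penalty (WGAN-GP) for tabular patient data.

Both sub-networks are two-hidden-layer perceptrons with leaky-ReLU hidden
activations and linear outputs; the critic additionally carries dropout on
its hidden activations.  The critic estimates the Wasserstein-1 distance
between the real and generated distributions; a gradient penalty keeps it
approximately 1-Lipschitz.  Training is full-batch with an optimistic Adam
optimizer and a 5:1 critic:generator update ratio.

The networks are small enough that forward, backward and the double
backpropagation needed for the gradient penalty are written out explicitly
in numpy.  For a leaky-ReLU network the activation pattern is piecewise
constant, so the parameter gradient of the input-gradient norm has an exact
closed form (the activation masks are treated as constants, which holds
almost everywhere).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .encode import CONCENTRATION_COLUMNS

__all__ = ["MLP2", "OAdam", "WGANGP", "critic_loss", "generator_loss", "gradient_penalty"]


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _dleaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, 1.0, slope)


class MLP2:
    """Two-hidden-layer perceptron, leaky-ReLU hidden units, linear output.

    Parameters are stored row-major (``W`` has shape ``(n_out, n_in)``), and
    exposed as the flat list ``[W1, b1, W2, b2, W3, b3]`` for the optimizer.
    """

    def __init__(self, n_in: int, hidden: tuple[int, int], n_out: int, slope: float, rng: np.random.Generator):
        h1, h2 = hidden
        self.slope = slope
        self.W1, self.b1 = _glorot(rng, h1, n_in), np.zeros(h1)
        self.W2, self.b2 = _glorot(rng, h2, h1), np.zeros(h2)
        self.W3, self.b3 = _glorot(rng, n_out, h2), np.zeros(n_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    @params.setter
    def params(self, values) -> None:
        self.W1, self.b1, self.W2, self.b2, self.W3, self.b3 = values

    def forward(self, x: np.ndarray, masks=None):
        """Forward pass; returns (output, cache).

        ``masks`` are inverted-dropout multipliers for the two hidden layers
        (already scaled by 1/(1-p)); ``None`` means no dropout.  The cache
        stores the combined activation-derivative/dropout factors ``c1, c2``
        so backward passes need no recomputation.
        """
        m1, m2 = (1.0, 1.0) if masks is None else masks
        z1 = x @ self.W1.T + self.b1
        c1 = _dleaky(z1, self.slope) * m1
        a1 = z1 * c1
        z2 = a1 @ self.W2.T + self.b2
        c2 = _dleaky(z2, self.slope) * m2
        a2 = z2 * c2
        out = a2 @ self.W3.T + self.b3
        cache = (x, a1, a2, c1, c2)
        return out, cache

    def backward(self, cache, grad_out: np.ndarray):
        """Backprop of sum(grad_out * output) w.r.t. params and input."""
        x, a1, a2, c1, c2 = cache
        dW3 = grad_out.T @ a2
        db3 = grad_out.sum(axis=0)
        g2 = (grad_out @ self.W3) * c2
        dW2 = g2.T @ a1
        db2 = g2.sum(axis=0)
        g1 = (g2 @ self.W2) * c1
        dW1 = g1.T @ x
        db1 = g1.sum(axis=0)
        dx = g1 @ self.W1
        return [dW1, db1, dW2, db2, dW3, db3], dx

    def input_gradient(self, cache) -> np.ndarray:
        """Per-row gradient of the (scalar) output w.r.t. the input."""
        x, a1, a2, c1, c2 = cache
        if self.W3.shape[0] != 1:
            raise ValueError("input_gradient requires a scalar-output network")
        v2 = self.W3 * c2                                      # (n, h2)
        v1 = (v2 @ self.W2) * c1                               # (n, h1)
        return v1 @ self.W1                                    # (n, d)

    def grad_penalty_param_grads(self, cache, r: np.ndarray):
        """Gradient w.r.t. params of sum_i g_i . r_i, g_i the input gradient.

        ``r`` carries the upstream derivative of the penalty w.r.t. ``g``.
        The leaky-ReLU activation pattern is piecewise constant, so the
        derivative flows only through the explicit weight factors; biases get
        zero gradient (exact almost everywhere).
        """
        x, a1, a2, c1, c2 = cache
        v2 = self.W3 * c2                      # (n, h2)
        v1 = (v2 @ self.W2) * c1               # (n, h1)
        p = c1 * (r @ self.W1.T)               # (n, h1)
        q = c2 * (p @ self.W2.T)               # (n, h2)
        dW1 = v1.T @ r
        dW2 = v2.T @ p
        dW3 = q.sum(axis=0, keepdims=True)
        z = np.zeros
        return [dW1, z(self.b1.shape), dW2, z(self.b2.shape), dW3, z(self.b3.shape)]


def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_out, n_in))


class OAdam:
    """Optimistic Adam: theta <- theta - lr * (2 d_t - d_{t-1}),
    d_t = m_hat_t / (sqrt(v_hat_t) + eps).

    The extra (optimistic) look-ahead term counteracts the cycling that plain
    adaptive-moment updates exhibit in adversarial saddle-point problems.
    """

    def __init__(self, shapes, lr=1e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.prev = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            d = (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
            p -= self.lr * (2.0 * d - self.prev[i])
            self.prev[i] = d


def gradient_penalty(critic: MLP2, x_hat: np.ndarray, gp_lambda: float, masks=None):
    """lambda * mean_i (||grad_x f(x_hat_i)||_2 - 1)^2 and its param grads."""
    _, cache = critic.forward(x_hat, masks=masks)
    g = critic.input_gradient(cache)
    norms = np.sqrt((g * g).sum(axis=1))
    value = gp_lambda * np.mean((norms - 1.0) ** 2)
    n = x_hat.shape[0]
    safe = np.maximum(norms, 1e-12)
    r = (2.0 * gp_lambda / n) * ((norms - 1.0) / safe)[:, None] * g
    grads = critic.grad_penalty_param_grads(cache, r)
    return value, grads


def critic_loss(critic: MLP2, real: np.ndarray, fake: np.ndarray, gp_lambda: float,
                rng: np.random.Generator | None = None, masks=None, u=None):
    """Critic loss mean f(fake) - mean f(real) + gradient penalty; with grads.

    ``u`` (per-row interpolation coefficients) and dropout ``masks`` may be
    supplied explicitly for testing; otherwise ``u`` is drawn from ``rng``.
    """
    if real.shape[1] != fake.shape[1]:
        raise ValueError("real and fake batches must have the same width")
    if gp_lambda < 0:
        raise ValueError("gp_lambda must be non-negative")
    if u is None:
        if rng is None:
            rng = np.random.default_rng()
        u = rng.uniform(size=(min(real.shape[0], fake.shape[0]), 1))
    n_pairs = u.shape[0]
    x_hat = u * real[:n_pairs] + (1.0 - u) * fake[:n_pairs]

    out_f, cache_f = critic.forward(fake, masks=masks)
    out_r, cache_r = critic.forward(real, masks=masks)
    if not (np.all(np.isfinite(out_f)) and np.all(np.isfinite(out_r))):
        raise FloatingPointError("non-finite critic activations")
    loss = float(out_f.mean() - out_r.mean())
    gf, _ = critic.backward(cache_f, np.full_like(out_f, 1.0 / out_f.shape[0]))
    gr, _ = critic.backward(cache_r, np.full_like(out_r, -1.0 / out_r.shape[0]))
    gp_value, gp_grads = gradient_penalty(critic, x_hat, gp_lambda, masks=masks)
    grads = [a + b + c for a, b, c in zip(gf, gr, gp_grads)]
    return loss + gp_value, grads, {"wasserstein": -loss, "gp": gp_value}


def generator_loss(critic: MLP2, generator: MLP2, z: np.ndarray):
    """Generator loss -mean f(G(z)); returns (loss, generator param grads)."""
    fake, cache_g = generator.forward(z)
    out, cache_c = critic.forward(fake)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite critic activations")
    loss = float(-out.mean())
    _, dfake = critic.backward(cache_c, np.full_like(out, -1.0 / out.shape[0]))
    grads, _ = generator.backward(cache_g, dfake)
    return loss, grads


class WGANGP(BaseEstimator):
    """WGAN-GP over a scaled feature table; ``fit`` then ``sample``.

    Parameters
    ----------
    latent_dim : size of the standard-normal latent vector.
    generator_hidden, critic_hidden : widths of the two hidden layers.
    leaky_slope : negative-side slope of the leaky-ReLU activations.
    dropout : dropout rate on the critic's hidden activations (critic
        updates only; the generator sees the deterministic critic).
    learning_rate, beta1, beta2 : optimistic-Adam settings, shared by both
        networks.
    n_critic : critic updates per generator update.
    epochs : generator updates (one epoch = ``n_critic`` critic updates
        followed by one generator update, full batch).
    gp_lambda : gradient-penalty weight.
    """

    def __init__(self, latent_dim=16, generator_hidden=(64, 64), critic_hidden=(64, 32),
                 leaky_slope=0.2, dropout=0.3, learning_rate=1e-4, n_critic=5,
                 epochs=150_000, gp_lambda=10.0, beta1=0.5, beta2=0.9,
                 random_state=None):
        self.latent_dim = latent_dim
        self.generator_hidden = generator_hidden
        self.critic_hidden = critic_hidden
        self.leaky_slope = leaky_slope
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.n_critic = n_critic
        self.epochs = epochs
        self.gp_lambda = gp_lambda
        self.beta1 = beta1
        self.beta2 = beta2
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None, scaler=None, trace_every=1):
        """Train on a scaled feature table (DataFrame or array).

        ``scaler`` (a fitted :class:`~pkgan.encode.FeatureScaler`) enables the
        post-training convergence monitor on the decoded concentration scale.
        """
        if self.n_critic < 1 or self.epochs < 0 or self.gp_lambda < 0 or self.latent_dim < 1:
            raise ValueError("invalid training configuration")
        if isinstance(X, pd.DataFrame):
            self.columns_ = list(X.columns)
            x_real = X.to_numpy(dtype=float)
        else:
            x_real = np.asarray(X, dtype=float)
            self.columns_ = None
        if not np.all(np.isfinite(x_real)):
            raise ValueError("training table contains non-finite values")
        n, d = x_real.shape
        rng = np.random.default_rng(self.random_state)
        self.generator_ = MLP2(self.latent_dim, tuple(self.generator_hidden), d, self.leaky_slope, rng)
        self.critic_ = MLP2(d, tuple(self.critic_hidden), 1, self.leaky_slope, rng)
        opt_c = OAdam([p.shape for p in self.critic_.params], self.learning_rate, self.beta1, self.beta2)
        opt_g = OAdam([p.shape for p in self.generator_.params], self.learning_rate, self.beta1, self.beta2)
        keep = 1.0 - self.dropout
        trace_e, trace_c, trace_g = [], [], []
        for epoch in range(self.epochs):
            try:
                for _ in range(self.n_critic):
                    z = rng.standard_normal((n, self.latent_dim))
                    fake, _ = self.generator_.forward(z)
                    masks = None
                    if self.dropout > 0:
                        m1 = (rng.uniform(size=(n, self.critic_hidden[0])) < keep) / keep
                        m2 = (rng.uniform(size=(n, self.critic_hidden[1])) < keep) / keep
                        masks = (m1, m2)
                    c_loss, c_grads, _ = critic_loss(
                        self.critic_, x_real, fake, self.gp_lambda, rng=rng, masks=masks
                    )
                    opt_c.step(self.critic_.params, c_grads)
                z = rng.standard_normal((n, self.latent_dim))
                g_loss, g_grads = generator_loss(self.critic_, self.generator_, z)
                opt_g.step(self.generator_.params, g_grads)
            except FloatingPointError as err:
                raise FloatingPointError(f"training diverged at epoch {epoch}: {err}") from err
            if epoch % trace_every == 0:
                trace_e.append(epoch)
                trace_c.append(c_loss)
                trace_g.append(g_loss)
        self.loss_trace_ = pd.DataFrame(
            {"epoch": trace_e, "critic_loss": trace_c, "generator_loss": trace_g}
        )
        self.n_features_in_ = d
        self._run_monitor(scaler, rng)
        return self

    def _run_monitor(self, scaler, rng) -> None:
        """Divergence monitor: finite losses, distinct probe rows, and (when a
        scaler is available) a grossly unimodal mean concentration profile."""
        diag: dict[str, object] = {}
        finite = bool(np.isfinite(self.loss_trace_[["critic_loss", "generator_loss"]].to_numpy()).all()) if len(self.loss_trace_) else True
        diag["losses_finite"] = finite
        ok = finite
        if self.epochs > 0:
            probe = self.sample(50, random_state=rng.integers(2**31))
            x = probe.to_numpy(dtype=float) if isinstance(probe, pd.DataFrame) else probe
            from scipy.spatial.distance import pdist

            distinct = int((pdist(x) > 1e-6).sum())
            diag["probe_distinct_pairs"] = distinct
            diag["probe_all_pairs"] = x.shape[0] * (x.shape[0] - 1) // 2
            ok = ok and distinct >= 0.9 * diag["probe_all_pairs"]
            if scaler is not None and self.columns_ is not None:
                decoded = scaler.inverse_transform(
                    pd.DataFrame(x, columns=self.columns_)
                )
                profile = decoded[CONCENTRATION_COLUMNS].mean(axis=0).to_numpy()
                diag["mean_profile"] = profile.tolist()
                diag["profile_unimodal"] = _grossly_unimodal(profile)
                ok = ok and diag["profile_unimodal"]
        self.diagnostics_ = diag
        self.converged_ = bool(ok)
        if not ok:
            warnings.warn(f"WGAN-GP convergence monitor flagged this run: {diag}", stacklevel=2)

    # ------------------------------------------------------------------
    def sample(self, n: int, random_state=None):
        """Draw ``n`` artificial rows (scaled scale) from the generator."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(random_state)
        z = rng.standard_normal((n, self.latent_dim))
        out, _ = self.generator_.forward(z)
        if self.columns_ is not None:
            return pd.DataFrame(out, columns=self.columns_)
        return out

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: .npz weights + JSON sidecar with the configuration."""
        path = Path(path)
        arrays = {}
        for net, name in ((self.generator_, "g"), (self.critic_, "c")):
            for i, p in enumerate(net.params):
                arrays[f"{name}{i}"] = p
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "format_version": 1,
            "params": self.get_params(),
            "columns": self.columns_,
            "n_features_in": self.n_features_in_,
            "converged": getattr(self, "converged_", None),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=str))

    @classmethod
    def load(cls, path) -> "WGANGP":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        params = sidecar["params"]
        for key in ("generator_hidden", "critic_hidden"):
            params[key] = tuple(_parse_tuple(params[key]))
        self = cls(**{k: params[k] for k in cls().get_params()})
        d = sidecar["n_features_in"]
        rng = np.random.default_rng(0)
        self.generator_ = MLP2(self.latent_dim, tuple(self.generator_hidden), d, self.leaky_slope, rng)
        self.critic_ = MLP2(d, tuple(self.critic_hidden), 1, self.leaky_slope, rng)
        data = np.load(path.with_suffix(".npz"))
        self.generator_.params = [data[f"g{i}"] for i in range(6)]
        self.critic_.params = [data[f"c{i}"] for i in range(6)]
        self.columns_ = sidecar["columns"]
        self.n_features_in_ = d
        self.converged_ = sidecar.get("converged")
        self.loss_trace_ = pd.DataFrame(columns=["epoch", "critic_loss", "generator_loss"])
        return self


def _parse_tuple(value):
    if isinstance(value, str):
        return [int(v) for v in value.strip("()[] ").split(",") if v.strip()]
    return [int(v) for v in value]


def _grossly_unimodal(profile: np.ndarray, tol: float = 0.25) -> bool:
    """True when the sequence rises to a single peak then falls, allowing
    wiggles up to ``tol`` times the profile's range."""
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        return False
    rng_ = profile.max() - profile.min()
    if rng_ <= 0:
        return True
    k = int(np.argmax(profile))
    slack = tol * rng_
    before = np.diff(profile[: k + 1])
    after = np.diff(profile[k:])
    return bool(np.all(before >= -slack) and np.all(after <= slack))
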