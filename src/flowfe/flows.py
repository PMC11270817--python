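"""Invertible maps between a uniform base box and configuration space.

All maps follow one direction convention:

* ``forward``  : base -> configuration  (z -> r), used for sampling the model.
* ``inverse``  : configuration -> base  (r -> z), used for density evaluation.

Both directions return the log of the absolute Jacobian determinant of the
direction actually applied, so that for any map
``logdet_fwd(z) + logdet_inv(forward(z)) == 0``.

The trainable map is a stack of rational-quadratic spline coupling layers.
Each layer is *oriented* in the normalizing (r -> z) direction: its analytic,
differentiable spline is applied when evaluating densities, and the exact
per-bin quadratic solve inverts it when sampling.  Gradients of the maximum
likelihood loss are computed by hand-written reverse-mode differentiation in
double precision; no autodiff framework is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "BaseUniform",
    "FlowMap",
    "IdentityMap",
    "AffineMap",
    "GaussianCDFMap",
    "SplineCouplingLayer",
    "SplineCouplingFlow",
    "ComposedTransform",
    "compose_maps",
    "flow_log_q",
    "flow_sample",
    "save_flow",
    "load_flow",
]

# Softplus offset chosen so that zero raw parameters give unit knot
# derivatives, hence an identity spline at initialization.
_DERIV_SHIFT = float(np.log(np.e - 1.0))
# Minimum relative bin width/height; keeps knots strictly increasing.
_MIN_BIN = 1e-4


# ---------------------------------------------------------------------------
# base distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseUniform:
    """Uniform base distribution on the box [lower, upper]^dim.

    Its log density is the constant ``-dim * ln(upper - lower)`` inside the
    box and ``-inf`` outside.
    """

    dim: int
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not self.upper > self.lower:
            raise ValueError("upper must exceed lower")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    @property
    def log_density(self) -> float:
        return -self.dim * float(np.log(self.length))

    def contains(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return np.all((z >= self.lower) & (z <= self.upper), axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))


# ---------------------------------------------------------------------------
# map interface and analytic maps
# ---------------------------------------------------------------------------


class FlowMap:
    """Abstract invertible map with exact log-Jacobians in both directions."""

    dim: int

    def forward(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """base -> configuration; returns (r, log|det dr/dz|) per row."""
        raise NotImplementedError

    def inverse(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """configuration -> base; returns (z, log|det dz/dr|) per row."""
        raise NotImplementedError


def _as2d(x: np.ndarray, dim: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != dim:
        raise ValueError(f"expected vectors of dimension {dim}, got {x.shape[1]}")
    return x


class IdentityMap(FlowMap):
    def __init__(self, dim: int):
        self.dim = dim

    def forward(self, z):
        z = _as2d(z, self.dim)
        return z.copy(), np.zeros(len(z))

    def inverse(self, r):
        r = _as2d(r, self.dim)
        return r.copy(), np.zeros(len(r))


class AffineMap(FlowMap):
    """Elementwise affine map r = shift + scale * z with constant Jacobian."""

    def __init__(self, scale, shift):
        self.scale = np.atleast_1d(np.asarray(scale, dtype=float))
        self.shift = np.atleast_1d(np.asarray(shift, dtype=float))
        if np.any(self.scale <= 0):
            raise ValueError("scales must be positive")
        if self.scale.shape != self.shift.shape:
            raise ValueError("scale/shift shape mismatch")
        self.dim = len(self.scale)
        self._logdet = float(np.sum(np.log(self.scale)))

    def forward(self, z):
        z = _as2d(z, self.dim)
        return self.shift + self.scale * z, np.full(len(z), self._logdet)

    def inverse(self, r):
        r = _as2d(r, self.dim)
        return (r - self.shift) / self.scale, np.full(len(r), -self._logdet)


class GaussianCDFMap(FlowMap):
    """Exact map between the unit box and a product of 1D Gaussians.

    ``forward`` sends z in (0,1)^D to r = mean + std * Phi^{-1}(z); the
    push-forward of the uniform base is then exactly N(mean, diag(std^2)).
    Used as the "perfect map" in analytic test systems.
    """

    def __init__(self, mean, std):
        self.mean = np.atleast_1d(np.asarray(mean, dtype=float))
        self.std = np.atleast_1d(np.asarray(std, dtype=float))
        if np.any(self.std <= 0):
            raise ValueError("std must be positive")
        self.dim = len(self.mean)

    def forward(self, z):
        z = _as2d(z, self.dim)
        t = ndtri(np.clip(z, 1e-300, 1.0 - 1e-16))
        r = self.mean + self.std * t
        # dr/dz = std / N(t; 0, 1)
        log_phi = -0.5 * t**2 - 0.5 * np.log(2.0 * np.pi)
        logdet = np.sum(np.log(self.std) - log_phi, axis=1)
        return r, logdet

    def inverse(self, r):
        r = _as2d(r, self.dim)
        t = (r - self.mean) / self.std
        z = ndtr(t)
        log_phi = -0.5 * t**2 - 0.5 * np.log(2.0 * np.pi)
        logdet = np.sum(log_phi - np.log(self.std), axis=1)
        return z, logdet


# ---------------------------------------------------------------------------
# rational-quadratic spline machinery
# ---------------------------------------------------------------------------


def _softmax(x: np.ndarray) -> np.ndarray:
    m = x - x.max(axis=-1, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=-1, keepdims=True)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class SplineCouplingLayer:
    """One coupling layer of monotone rational-quadratic splines.

    The coordinates listed in ``cond_idx`` pass through unchanged and feed a
    small perceptron that emits, for every coordinate in ``trans_idx``, the
    knot widths, heights and derivatives of a strictly monotone spline on
    [lower, upper] that fixes both interval endpoints.  ``spline_forward`` is
    the analytic spline; ``spline_inverse`` solves the per-bin quadratic.
    """

    def __init__(
        self,
        dim: int,
        trans_idx: np.ndarray,
        cond_idx: np.ndarray,
        n_bins: int = 16,
        hidden: int = 64,
        lower: float = 0.0,
        upper: float = 1.0,
        rng: np.random.Generator | None = None,
    ):
        if n_bins < 2:
            raise ValueError("need at least 2 spline bins")
        self.dim = dim
        self.trans_idx = np.asarray(trans_idx, dtype=int)
        self.cond_idx = np.asarray(cond_idx, dtype=int)
        self.n_bins = n_bins
        self.hidden = hidden
        self.lower = float(lower)
        self.upper = float(upper)
        if rng is None:
            rng = np.random.default_rng(0)
        dc, dt, B, H = len(self.cond_idx), len(self.trans_idx), n_bins, hidden
        out = dt * (3 * B + 1)
        scale1 = 1.0 / np.sqrt(max(dc, 1))
        scale2 = 1.0 / np.sqrt(H)
        # Final layer zero-initialized: the layer starts as the identity map.
        self.params = {
            "W1": rng.normal(0.0, scale1, size=(dc, H)),
            "b1": np.zeros(H),
            "W2": rng.normal(0.0, scale2, size=(H, H)),
            "b2": np.zeros(H),
            "W3": np.zeros((H, out)),
            "b3": np.zeros(out),
        }

    # -- conditioner -------------------------------------------------------

    def _conditioner(self, x_cond: np.ndarray):
        L = self.upper - self.lower
        x_in = 2.0 * (x_cond - self.lower) / L - 1.0
        h1 = np.tanh(x_in @ self.params["W1"] + self.params["b1"])
        h2 = np.tanh(h1 @ self.params["W2"] + self.params["b2"])
        raw = h2 @ self.params["W3"] + self.params["b3"]
        N = x_cond.shape[0]
        dt, B = len(self.trans_idx), self.n_bins
        raw = raw.reshape(N, dt, 3 * B + 1)
        cache = {"x_in": x_in, "h1": h1, "h2": h2}
        return raw, cache

    def _knots(self, raw: np.ndarray):
        """Raw conditioner output -> knot geometry (all shapes (N, dt, ...))."""
        B = self.n_bins
        L = self.upper - self.lower
        raw_w, raw_h, raw_d = raw[..., :B], raw[..., B : 2 * B], raw[..., 2 * B :]
        sw = _softmax(raw_w)
        sh = _softmax(raw_h)
        scale = 1.0 - B * _MIN_BIN
        w = L * (scale * sw + _MIN_BIN)
        h = L * (scale * sh + _MIN_BIN)
        d = _softplus(raw_d + _DERIV_SHIFT)
        zeros = np.zeros(w.shape[:-1] + (1,))
        xpos = self.lower + np.concatenate([zeros, np.cumsum(w, axis=-1)], axis=-1)
        ypos = self.lower + np.concatenate([zeros, np.cumsum(h, axis=-1)], axis=-1)
        xpos[..., -1] = self.upper  # kill cumulative rounding
        ypos[..., -1] = self.upper
        knots = {"w": w, "h": h, "d": d, "xpos": xpos, "ypos": ypos,
                 "sw": sw, "sh": sh, "raw_d": raw_d}
        return knots

    # -- analytic spline (normalizing direction) ---------------------------

    def _check_domain(self, x: np.ndarray) -> None:
        if np.any(x < self.lower - 1e-12) or np.any(x > self.upper + 1e-12):
            raise ValueError("coordinate outside the spline interval")

    def _bin_of(self, pos: np.ndarray, x: np.ndarray) -> np.ndarray:
        # pos: (N, dt, B+1) strictly increasing; x: (N, dt)
        k = np.sum(pos[..., 1:-1] <= x[..., None], axis=-1)
        return np.clip(k, 0, self.n_bins - 1)

    @staticmethod
    def _gather(a: np.ndarray, k: np.ndarray) -> np.ndarray:
        return np.take_along_axis(a, k[..., None], axis=-1)[..., 0]

    def _local(self, knots, k):
        g = self._gather
        return {
            "xk": g(knots["xpos"], k),
            "wk": g(knots["w"], k),
            "yk": g(knots["ypos"], k),
            "hk": g(knots["h"], k),
            "d0": g(knots["d"], k),
            "d1": g(knots["d"], k + 1),
        }

    def spline_forward(self, x_t: np.ndarray, knots) -> tuple[np.ndarray, np.ndarray, dict]:
        """Monotone spline y(x) per transformed coordinate.

        Returns (y, ln y'(x), cache) with shapes (N, dt).
        """
        self._check_domain(x_t)
        x_t = np.clip(x_t, self.lower, self.upper)
        k = self._bin_of(knots["xpos"], x_t)
        loc = self._local(knots, k)
        xi = np.clip((x_t - loc["xk"]) / loc["wk"], 0.0, 1.0)
        s = loc["hk"] / loc["wk"]
        d0, d1 = loc["d0"], loc["d1"]
        beta = d0 + d1 - 2.0 * s
        omxi = 1.0 - xi
        xiomxi = xi * omxi
        A = s * xi**2 + d0 * xiomxi
        Q = s + beta * xiomxi
        y = loc["yk"] + loc["hk"] * A / Q
        N2 = d1 * xi**2 + 2.0 * s * xiomxi + d0 * omxi**2
        ln_deriv = 2.0 * np.log(s) + np.log(N2) - 2.0 * np.log(Q)
        y = np.clip(y, self.lower, self.upper)
        cache = {"k": k, "xi": xi, "s": s, "A": A, "Q": Q, "N2": N2,
                 "beta": beta, "loc": loc}
        return y, ln_deriv, cache

    def spline_inverse(self, y_t: np.ndarray, knots) -> tuple[np.ndarray, np.ndarray]:
        """Exact inverse x(y); returns (x, ln y'(x)) for the paired point."""
        self._check_domain(y_t)
        y_t = np.clip(y_t, self.lower, self.upper)
        k = self._bin_of(knots["ypos"], y_t)
        loc = self._local(knots, k)
        s = loc["hk"] / loc["wk"]
        d0, d1 = loc["d0"], loc["d1"]
        beta = d0 + d1 - 2.0 * s
        t = np.clip((y_t - loc["yk"]) / loc["hk"], 0.0, 1.0)
        # a xi^2 + b xi + c = 0 with the root in [0, 1]
        a = s - d0 + t * beta
        b = d0 - t * beta
        c = -s * t
        disc = np.maximum(b**2 - 4.0 * a * c, 0.0)
        xi = 2.0 * c / (-b - np.sqrt(disc))
        xi = np.clip(np.where(np.isfinite(xi), xi, t), 0.0, 1.0)
        # Newton polish: the closed-form root loses digits when a bin is
        # nearly linear (a ~ 0); two steps restore machine precision.
        for _ in range(2):
            xiomxi = xi * (1.0 - xi)
            A = s * xi**2 + d0 * xiomxi
            Q = s + beta * xiomxi
            resid = A / Q - t
            A_xi = 2.0 * s * xi + d0 * (1.0 - 2.0 * xi)
            Q_xi = beta * (1.0 - 2.0 * xi)
            slope = (A_xi * Q - A * Q_xi) / Q**2
            xi = np.clip(xi - resid / np.maximum(slope, 1e-12), 0.0, 1.0)
        x = loc["xk"] + xi * loc["wk"]
        omxi = 1.0 - xi
        xiomxi = xi * omxi
        Q = s + beta * xiomxi
        N2 = d1 * xi**2 + 2.0 * s * xiomxi + d0 * omxi**2
        ln_deriv = 2.0 * np.log(s) + np.log(N2) - 2.0 * np.log(Q)
        return x, ln_deriv

    # -- layer-level passes (r -> z is the analytic direction) -------------

    def normalize(self, r: np.ndarray):
        """r -> z step with caches for backprop; returns (z, ln|det|, cache)."""
        r = _as2d(r, self.dim)
        x_c = r[:, self.cond_idx]
        x_t = r[:, self.trans_idx]
        raw, mlp_cache = self._conditioner(x_c)
        knots = self._knots(raw)
        y, ln_deriv, sp_cache = self.spline_forward(x_t, knots)
        z = r.copy()
        z[:, self.trans_idx] = y
        logdet = ln_deriv.sum(axis=1)
        cache = {"mlp": mlp_cache, "knots": knots, "spline": sp_cache,
                 "x_c": x_c, "x_t": x_t}
        return z, logdet, cache

    def generate(self, z: np.ndarray):
        """z -> r step (quadratic-solve inverse); returns (r, ln|det|)."""
        z = _as2d(z, self.dim)
        x_c = z[:, self.cond_idx]
        y_t = z[:, self.trans_idx]
        raw, _ = self._conditioner(x_c)
        knots = self._knots(raw)
        x, ln_deriv_fwd = self.spline_inverse(y_t, knots)
        r = z.copy()
        r[:, self.trans_idx] = x
        return r, -ln_deriv_fwd.sum(axis=1)

    # -- hand-written reverse-mode pass ------------------------------------

    def backward(self, cache, g_out: np.ndarray, g_logdet: np.ndarray):
        """Backprop through ``normalize``.

        g_out: (N, D) gradient w.r.t. the layer output z;
        g_logdet: (N,) gradient w.r.t. this layer's per-sample log|det|.
        Returns (g_in, param_grads).
        """
        knots = cache["knots"]
        sp = cache["spline"]
        loc = sp["loc"]
        k = sp["k"]
        B = self.n_bins
        L = self.upper - self.lower

        g_y = g_out[:, self.trans_idx]            # (N, dt)
        g_L = g_logdet[:, None]                   # broadcast over dt

        xi, s, A, Q, N2, beta = sp["xi"], sp["s"], sp["A"], sp["Q"], sp["N2"], sp["beta"]
        d0, d1 = loc["d0"], loc["d1"]
        wk, hk = loc["wk"], loc["hk"]
        omxi = 1.0 - xi
        xiomxi = xi * omxi

        A_xi = 2.0 * s * xi + d0 * (1.0 - 2.0 * xi)
        Q_xi = beta * (1.0 - 2.0 * xi)
        N2_xi = 2.0 * (d1 * xi + s * (1.0 - 2.0 * xi) - d0 * omxi)
        y_xi = hk * (A_xi * Q - A * Q_xi) / Q**2
        L_xi = N2_xi / N2 - 2.0 * Q_xi / Q

        A_s = xi**2
        Q_s = 1.0 - 2.0 * xiomxi
        N2_s = 2.0 * xiomxi
        y_s = hk * (A_s * Q - A * Q_s) / Q**2
        L_s = 2.0 / s + N2_s / N2 - 2.0 * Q_s / Q

        y_d0 = hk * xiomxi * (Q - A) / Q**2
        L_d0 = omxi**2 / N2 - 2.0 * xiomxi / Q
        y_d1 = -hk * A * xiomxi / Q**2
        L_d1 = xi**2 / N2 - 2.0 * xiomxi / Q

        P_xi = g_y * y_xi + g_L * L_xi
        P_s = g_y * y_s + g_L * L_s

        g_xt = P_xi / wk
        g_xk = -P_xi / wk
        g_wk = -P_xi * xi / wk - P_s * s / wk
        g_yk = g_y
        g_hk = g_y * (A / Q) + P_s / wk
        g_d0 = g_y * y_d0 + g_L * L_d0
        g_d1 = g_y * y_d1 + g_L * L_d1

        # scatter bin-local grads onto knot vectors: x_k = a + sum_{j<k} w_j
        j = np.arange(B)
        is_k = j[None, None, :] == k[..., None]
        lt_k = j[None, None, :] < k[..., None]
        g_w_vec = is_k * g_wk[..., None] + lt_k * g_xk[..., None]
        g_h_vec = is_k * g_hk[..., None] + lt_k * g_yk[..., None]

        jd = np.arange(B + 1)
        g_d_vec = (jd[None, None, :] == k[..., None]) * g_d0[..., None] \
            + (jd[None, None, :] == (k + 1)[..., None]) * g_d1[..., None]

        # chain through the knot parameterization
        scale = 1.0 - B * _MIN_BIN
        sw, sh = knots["sw"], knots["sh"]
        g_sw = L * scale * g_w_vec
        g_sh = L * scale * g_h_vec
        g_raw_w = sw * (g_sw - np.sum(sw * g_sw, axis=-1, keepdims=True))
        g_raw_h = sh * (g_sh - np.sum(sh * g_sh, axis=-1, keepdims=True))
        g_raw_d = _sigmoid(knots["raw_d"] + _DERIV_SHIFT) * g_d_vec
        g_raw = np.concatenate([g_raw_w, g_raw_h, g_raw_d], axis=-1)
        N = g_raw.shape[0]
        g_raw = g_raw.reshape(N, -1)

        # backprop the conditioner MLP
        mlp = cache["mlp"]
        h1, h2, x_in = mlp["h1"], mlp["h2"], mlp["x_in"]
        grads = {}
        grads["W3"] = h2.T @ g_raw
        grads["b3"] = g_raw.sum(axis=0)
        g_h2 = g_raw @ self.params["W3"].T
        g_a2 = g_h2 * (1.0 - h2**2)
        grads["W2"] = h1.T @ g_a2
        grads["b2"] = g_a2.sum(axis=0)
        g_h1 = g_a2 @ self.params["W2"].T
        g_a1 = g_h1 * (1.0 - h1**2)
        grads["W1"] = x_in.T @ g_a1
        grads["b1"] = g_a1.sum(axis=0)
        g_xc_mlp = (g_a1 @ self.params["W1"].T) * (2.0 / L)

        g_in = np.zeros_like(g_out)
        g_in[:, self.trans_idx] = g_xt
        g_in[:, self.cond_idx] = g_out[:, self.cond_idx] + g_xc_mlp
        return g_in, grads


class SplineCouplingFlow(FlowMap):
    """Stack of spline coupling layers with alternating masks.

    For dim >= 2 the even/odd coordinate split alternates between layers; in
    one dimension every layer is an unconditional trainable spline (the
    conditioner degenerates to its bias path).
    """

    def __init__(
        self,
        dim: int,
        n_layers: int = 4,
        n_bins: int = 16,
        hidden: int = 64,
        lower: float = 0.0,
        upper: float = 1.0,
        seed: int = 0,
    ):
        self.dim = dim
        self.lower = float(lower)
        self.upper = float(upper)
        self.meta = {"dim": dim, "n_layers": n_layers, "n_bins": n_bins,
                     "hidden": hidden, "lower": lower, "upper": upper, "seed": seed}
        rng = np.random.default_rng(seed)
        idx = np.arange(dim)
        self.layers: list[SplineCouplingLayer] = []
        for ell in range(n_layers):
            if dim == 1:
                trans, cond = idx, np.array([], dtype=int)
            elif ell % 2 == 0:
                trans, cond = idx[idx % 2 == 0], idx[idx % 2 == 1]
            else:
                trans, cond = idx[idx % 2 == 1], idx[idx % 2 == 0]
            self.layers.append(
                SplineCouplingLayer(dim, trans, cond, n_bins=n_bins, hidden=hidden,
                                    lower=lower, upper=upper, rng=rng)
            )

    # FlowMap interface -----------------------------------------------------

    def inverse(self, r):
        r = _as2d(r, self.dim)
        logdet = np.zeros(len(r))
        z = r
        for layer in self.layers:
            z, ld, _ = layer.normalize(z)
            logdet += ld
        return z, logdet

    def forward(self, z):
        z = _as2d(z, self.dim)
        logdet = np.zeros(len(z))
        r = z
        for layer in reversed(self.layers):
            r, ld = layer.generate(r)
            logdet += ld
        return r, logdet

    # parameters ------------------------------------------------------------

    def get_params(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_params(self, params: list[dict[str, np.ndarray]]) -> None:
        for layer, p in zip(self.layers, params):
            for k in layer.params:
                layer.params[k] = p[k].copy()

    # training objective -----------------------------------------------------

    def neg_log_likelihood_and_grad(self, r: np.ndarray, base: BaseUniform):
        """Mean negative log-likelihood -<ln q(r)> and its parameter gradient.

        ln q(r) = -D ln L + log|det J_{r->z}|(r); the backward pass threads
        gradients through every spline and conditioner.
        """
        r = _as2d(r, self.dim)
        N = len(r)
        caches = []
        z = r
        logdet = np.zeros(N)
        for layer in self.layers:
            z, ld, cache = layer.normalize(z)
            caches.append(cache)
            logdet += ld
        loss = -(base.log_density + logdet.mean())

        g_out = np.zeros_like(r)
        g_logdet = np.full(N, -1.0 / N)
        grads: list[dict[str, np.ndarray]] = [None] * len(self.layers)
        for ell in range(len(self.layers) - 1, -1, -1):
            g_out, grads[ell] = self.layers[ell].backward(caches[ell], g_out, g_logdet)
        return loss, grads


# ---------------------------------------------------------------------------
# map composition and model density helpers
# ---------------------------------------------------------------------------


class ComposedTransform:
    """Transform between two states' coordinates through the shared base.

    ``transform`` applies r_i -> z (inner map's normalizing pass) and then
    z -> r_j (outer map's generating pass); the log-Jacobian is the sum of
    the two stage log-determinants.
    """

    def __init__(self, inner: FlowMap, outer: FlowMap):
        if inner.dim != outer.dim:
            raise ValueError("cannot compose maps of different dimension")
        self.inner = inner
        self.outer = outer
        self.dim = inner.dim

    def transform(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z, ld1 = self.inner.inverse(x)
        y, ld2 = self.outer.forward(z)
        return y, ld1 + ld2

    def inverse_transform(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z, ld1 = self.outer.inverse(y)
        x, ld2 = self.inner.forward(z)
        return x, ld1 + ld2


def compose_maps(map_i: FlowMap, map_j: FlowMap) -> ComposedTransform:
    """Build the coordinate transform r_i -> r_j = forward_j(inverse_i(r_i))."""
    return ComposedTransform(map_i, map_j)


def flow_log_q(
    flow: FlowMap, base: BaseUniform, r: np.ndarray, chunk: int = 65536
) -> np.ndarray:
    """Exact normalized model log-density ln q(r) per row.

    q is the push-forward of the uniform base through the map; points whose
    inverse image leaves the base box have zero density.  Large batches are
    processed in chunks to bound the memory of the inverse pass.
    """
    r = _as2d(r, flow.dim)
    out = np.full(len(r), -np.inf)
    in_dom = np.all((r >= base.lower) & (r <= base.upper), axis=1)
    idx = np.flatnonzero(in_dom)
    for start in range(0, len(idx), chunk):
        sel = idx[start : start + chunk]
        z, logdet_inv = flow.inverse(r[sel])
        ok = base.contains(z)
        out[sel] = np.where(ok, base.log_density + logdet_inv, -np.inf)
    return out


def flow_sample(
    flow: FlowMap, base: BaseUniform, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n model samples r = forward(z), z ~ uniform box; returns (r, ln q(r))."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = base.sample(n, rng)
    r, logdet_fwd = flow.forward(z)
    return r, base.log_density - logdet_fwd


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_flow(flow: SplineCouplingFlow, path: str) -> None:
    payload = {
        "format": "flowfe-spline-flow/1",
        "meta": flow.meta,
        "params": [
            {k: v.tolist() for k, v in layer.params.items()} for layer in flow.layers
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_flow(path: str) -> SplineCouplingFlow:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "flowfe-spline-flow/1":
        raise ValueError("unrecognized checkpoint format")
    meta = payload["meta"]
    flow = SplineCouplingFlow(**meta)
    params = [
        {k: np.asarray(v, dtype=float) for k, v in layer.items()}
        for layer in payload["params"]
    ]
    flow.set_params(params)
    return flow
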