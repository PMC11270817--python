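"""Free-energy estimators for flow-remapped metastable-state ensembles.

The six estimators compared throughout the package act on the generalized
work function ``phi_i(r) = u_i(r) + ln q_i(r)``, where u_i is the restricted
reduced potential of state i and q_i the exactly normalized model density of
its flow.  Identities behind them (p = Z^-1 e^{-u}, f = -ln Z):

* ``AV``    : f ~= <phi>, exact when q == p (phi is then constant = f);
              AVMD averages over data samples (r ~ p), AVBG over model
              samples (r ~ q).
* ``EXPMD`` : f = ln <exp(+phi)>_p   (one-directional, data side).
* ``EXPBG`` : f = -ln <exp(-phi)>_q  (one-directional, model side).
* ``BAR``   : root of the two-distribution mixture identity
              1 = <p_M^{-1} p>_{p_M}, p_M = (N_p p + N_q q)/(N_p + N_q).
* ``MBAR``  : the K-state generalization, solved self-consistently on
              remapped potentials; free energies are determined up to a
              common constant (gauge fixed to f_1 = 0).

Uncertainties: delta-method standard errors for AV/EXP and the standard
asymptotic covariance of the self-consistent mixture estimator for BAR/MBAR,
evaluated through the SVD of the weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .flows import BaseUniform, ComposedTransform, FlowMap, flow_log_q
from .model_systems import ClusterAssigner, ReducedPotential

__all__ = [
    "PENALTY",
    "RestrictedPotential",
    "restricted_u",
    "WorkFunctionValues",
    "FreeEnergyEstimate",
    "work_function",
    "estimate_AV",
    "estimate_EXP",
    "estimate_BAR",
    "estimate_MBAR",
    "remapped_potential",
    "entropy_decomposition",
    "overfit_diagnostics",
]

PENALTY = 1e20
# anything at or above this is treated as an infinite energy in weight space
_PENALTY_CUT = 1e18


@dataclass(frozen=True)
class RestrictedPotential:
    """Reduced potential of one metastable state with integration limits.

    ``u_i(r) = u(r)`` when the deterministic cluster rule assigns r to the
    target state, and ``u(r) + penalty`` (1e20 by convention) otherwise, so
    the Boltzmann weight of misassigned configurations underflows to exactly
    zero during reweighting.
    """

    potential: ReducedPotential
    state: int
    assigner: ClusterAssigner
    penalty: float = PENALTY

    @property
    def dim(self) -> int:
        return self.potential.dim

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.atleast_2d(np.asarray(r, dtype=float))
        u = self.potential(r)
        in_state = np.asarray(self.assigner(r)) == self.state
        return np.where(in_state, u, u + self.penalty)


def restricted_u(rp: RestrictedPotential, r: np.ndarray) -> np.ndarray:
    """Evaluate the restricted potential (functional form of the dataclass)."""
    return rp(r)


def _weight_energy(u: np.ndarray) -> np.ndarray:
    """Reported penalized energies -> +inf in the weight path (no overflow)."""
    return np.where(u >= _PENALTY_CUT, np.inf, u)


# ---------------------------------------------------------------------------
# work function and the direct estimators
# ---------------------------------------------------------------------------


@dataclass
class WorkFunctionValues:
    """Per-configuration phi_i = u_i + ln q_i with its origin tag.

    ``origin`` is "MD" for data samples (drawn from p_i) or "BG" for
    model-generated samples (drawn from q_i).  Rows where u_i is penalized or
    ln q_i = -inf are non-finite; their count is kept for reporting.
    """

    phi: np.ndarray
    origin: str  # "MD" | "BG"
    n_nonfinite: int = 0

    def finite(self) -> np.ndarray:
        return self.phi[np.isfinite(self.phi)]


@dataclass
class FreeEnergyEstimate:
    value: float
    stderr: float
    estimator: str  # AVMD | AVBG | EXPMD | EXPBG | BAR | MBAR
    split: str = ""  # T | V | M (model-only)
    n_samples: int = 0

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


def work_function(
    flow: FlowMap,
    base: BaseUniform,
    potential_i: RestrictedPotential,
    batch: np.ndarray,
    origin: str,
    log_q: np.ndarray | None = None,
) -> WorkFunctionValues:
    """phi_i(r) = u_i(r) + ln q_i(r) per row of the batch.

    ``log_q`` may be supplied when the batch was generated by the flow itself
    (ln q is then a by-product of sampling); otherwise it is computed by the
    exact inverse pass.  Penalized rows become +inf, zero-density rows -inf.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if len(batch) == 0:
        raise ValueError("empty batch")
    u = _weight_energy(potential_i(batch))
    if log_q is None:
        log_q = flow_log_q(flow, base, batch)
    with np.errstate(invalid="ignore"):
        phi = u + log_q
    # +inf + (-inf) is undefined; such rows carry zero weight either way
    phi = np.where(np.isnan(phi), np.inf if origin == "BG" else -np.inf, phi)
    n_bad = int(np.sum(~np.isfinite(phi)))
    return WorkFunctionValues(phi=phi, origin=origin, n_nonfinite=n_bad)


def estimate_AV(phi: WorkFunctionValues) -> FreeEnergyEstimate:
    """f ~= <phi>; exact in the perfect-map limit where phi is constant.

    Non-finite rows (model samples that left the state or the domain) are
    excluded; the estimate is the sample mean with its standard error.
    """
    vals = phi.finite()
    if len(vals) < 2:
        raise ValueError("need at least 2 finite work-function values")
    label = "AVMD" if phi.origin == "MD" else "AVBG"
    se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    return FreeEnergyEstimate(float(np.mean(vals)), se, label, n_samples=len(vals))


def estimate_EXP(phi: WorkFunctionValues, direction: str | None = None) -> FreeEnergyEstimate:
    """One-directional exponential averaging.

    EXPMD: f = ln <exp(phi)>_p over data samples; EXPBG: f = -ln <exp(-phi)>_q
    over model samples.  Model samples with zero target weight (penalized phi)
    stay in the denominator count — they are genuine draws from q whose
    integrand vanishes.  Log-sum-exp throughout; delta-method stderr.
    """
    if direction is None:
        direction = phi.origin
    direction = {"MD": "MD", "BG": "BG"}[direction]
    x = phi.phi
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    sgn = 1.0 if direction == "MD" else -1.0
    expo = sgn * x  # exponent of each weight
    expo = np.where(np.isfinite(expo), expo, -np.inf)  # zero-weight rows
    m = float(np.max(expo))
    if not np.isfinite(m):
        raise ValueError("no overlap: all reweighting factors underflow")
    lw = logsumexp(expo) - np.log(n)
    value = sgn * lw
    # delta method: var(ln <w>) = var(w) / (n <w>^2), computed in log space
    l2 = logsumexp(2.0 * expo) - np.log(n)
    var_ratio = np.expm1(np.clip(l2 - 2.0 * lw, 0.0, 700.0))
    se = float(np.sqrt(max(var_ratio, 0.0) / n))
    label = "EXPMD" if direction == "MD" else "EXPBG"
    return FreeEnergyEstimate(float(value), se, label, n_samples=n)


# ---------------------------------------------------------------------------
# BAR
# ---------------------------------------------------------------------------


def _bar_residual(f: float, phi_all: np.ndarray, log_np: float, log_nq: float) -> float:
    """g(f) = sum_pooled 1/(N_p + N_q e^{phi-f}) - 1, strictly increasing in f."""
    expo = np.where(np.isfinite(phi_all), phi_all, np.inf)
    log_terms = -np.logaddexp(log_np, log_nq + expo - f)
    return float(np.exp(logsumexp(log_terms))) - 1.0


def estimate_BAR(
    phi_p: WorkFunctionValues,
    phi_q: WorkFunctionValues,
    tol: float = 1e-10,
) -> FreeEnergyEstimate:
    """Two-directional (Bennett) estimate from both sample sets.

    Solves the self-consistent mixture identity
    ``sum_pooled 1/(N_p + N_q e^{phi(r) - f}) = 1`` by monotone bisection,
    bracketed by the two one-directional EXP estimates.  The solution is
    invariant to scaling N_p and N_q by a common factor.  Standard error is
    the K = 2 case of the asymptotic mixture-estimator covariance.
    """
    pp = phi_p.phi[np.isfinite(phi_p.phi)]
    if len(pp) < 2:
        raise ValueError("need at least 2 finite data-side work values")
    pq = phi_q.phi
    if np.sum(np.isfinite(pq)) < 2:
        raise ValueError("no overlap: fewer than 2 finite model-side work values")
    n_p, n_q = len(pp), len(pq)
    log_np, log_nq = np.log(n_p), np.log(n_q)
    phi_all = np.concatenate([pp, pq])

    f_md = estimate_EXP(WorkFunctionValues(pp, "MD")).value
    try:
        f_bg = estimate_EXP(WorkFunctionValues(pq, "BG")).value
    except ValueError:
        raise ValueError("no overlap between the two sample sets")
    lo, hi = min(f_md, f_bg) - 1.0, max(f_md, f_bg) + 1.0
    g_lo = _bar_residual(lo, phi_all, log_np, log_nq)
    g_hi = _bar_residual(hi, phi_all, log_np, log_nq)
    n_expand = 0
    while g_lo > 0.0 and n_expand < 200:
        lo -= 2.0**n_expand
        g_lo = _bar_residual(lo, phi_all, log_np, log_nq)
        n_expand += 1
    n_expand = 0
    while g_hi < 0.0 and n_expand < 200:
        hi += 2.0**n_expand
        g_hi = _bar_residual(hi, phi_all, log_np, log_nq)
        n_expand += 1
    if g_lo > 0.0 or g_hi < 0.0:
        raise ValueError(
            "BAR root not bracketed: the two sample sets do not overlap "
            f"(EXPMD={f_md:.3g}, EXPBG={f_bg:.3g})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _bar_residual(mid, phi_all, log_np, log_nq) < 0.0:
            lo = mid
        else:
            hi = mid
    f = 0.5 * (lo + hi)

    # overlap diagnostic: at the root, the model-side samples must carry a
    # non-negligible share of the mixture identity, else the equation is
    # degenerate across the gap and the root is meaningless
    q_share = float(np.exp(logsumexp(
        -np.logaddexp(log_np, log_nq + np.where(np.isfinite(pq), pq, np.inf) - f)
    )))
    if q_share < 1e-6:
        raise ValueError(
            "no overlap between the two sample sets: model-side mixture share "
            f"{q_share:.2e} at the root (EXPMD={f_md:.3g}, EXPBG={f_bg:.3g})"
        )

    # asymptotic stderr via the 2-state mixture covariance, in the gauge where
    # the model side has zero potential: u_p = phi (then f_p = f, f_q = 0)
    u2 = np.vstack([
        np.where(np.isfinite(phi_all), phi_all, np.inf),
        np.zeros(n_p + n_q),
    ])
    theta = _mixture_covariance(u2, np.array([n_p, n_q]), np.array([f, 0.0]))
    se = float(np.sqrt(max(theta[0, 0] + theta[1, 1] - 2.0 * theta[0, 1], 0.0)))
    return FreeEnergyEstimate(float(f), se, "BAR", n_samples=n_p + n_q)


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------


def _mbar_log_weights(u_mat: np.ndarray, counts: np.ndarray, f: np.ndarray) -> np.ndarray:
    """ln W_ni (N x K): normalized mixture weights of each state at each sample."""
    log_c = np.log(counts)
    a = f[:, None] - u_mat  # (K, N)
    log_denom = logsumexp(a + log_c[:, None], axis=0)  # (N,)
    return (a - log_denom[None, :]).T


def _mixture_covariance(u_mat: np.ndarray, counts: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the self-consistent mixture free energies.

    Standard estimator Theta = W^T (I - W N W^T)^+ W computed in its K x K
    reduced form through the SVD of the (N x K) weight matrix W.
    """
    W = np.exp(_mbar_log_weights(u_mat, counts, f))
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    V = Vt.T
    core = np.eye(len(S)) - (S[:, None] * Vt) @ (counts[:, None] * V) * S[None, :]
    theta = (V * S[None, :]) @ np.linalg.pinv(core, rcond=1e-12) @ (S[:, None] * Vt)
    return theta


def estimate_MBAR(
    u_mat: np.ndarray,
    counts: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 50000,
    return_theta: bool = False,
):
    """Multistate self-consistent estimate from remapped potentials.

    ``u_mat[i, n]`` is the (remapped, restricted) reduced potential of state i
    evaluated at pooled sample n; ``counts[k]`` is the number of samples drawn
    from state k (pooled in order).  Solves

        f_i = -ln sum_n exp(-u_in) / sum_k N_k exp(f_k - u_kn)

    by log-sum-exp self-consistent iteration with Aitken-style acceleration
    left to the iteration count, polished until the update is below ``tol``.
    Free energies are reported in the gauge f_1 = 0 together with the
    asymptotic covariance of the gauged vector.
    """
    u_mat = np.asarray(u_mat, dtype=float)
    counts = np.asarray(counts, dtype=float)
    K, N = u_mat.shape
    if K < 2:
        raise ValueError("MBAR needs at least 2 states")
    if int(counts.sum()) != N:
        raise ValueError("counts must sum to the number of pooled samples")
    u_mat = np.where(u_mat >= _PENALTY_CUT, np.inf, u_mat)
    finite = np.isfinite(u_mat)
    if not np.all(finite.any(axis=0)):
        raise ValueError("some samples have no finite reduced potential in any state")

    _check_overlap_graph(finite, counts)

    log_c = np.log(counts)
    f = np.zeros(K)
    for _ in range(max_iter):
        log_denom = logsumexp(f[:, None] - u_mat + log_c[:, None], axis=0)
        f_new = -logsumexp(-u_mat - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError("MBAR self-consistent iteration did not converge")

    theta = _mixture_covariance(u_mat, counts, f)
    # covariance of differences from the gauge state f_1
    cov = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cov[i, j] = theta[i, j] - theta[i, 0] - theta[0, j] + theta[0, 0]
    if return_theta:
        return f, cov, theta
    return f, cov


def _check_overlap_graph(finite: np.ndarray, counts: np.ndarray) -> None:
    """States must form one connected component through shared finite samples."""
    K = finite.shape[0]
    parent = list(range(K))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # also connect each sample to its state of origin
    origin = np.repeat(np.arange(K), counts.astype(int))
    for n in range(finite.shape[1]):
        states = np.flatnonzero(finite[:, n])
        anchor = origin[n]
        for s in states:
            ri, rj = find(anchor), find(s)
            if ri != rj:
                parent[ri] = rj
    roots = {find(i) for i in range(K)}
    if len(roots) > 1:
        comps = {}
        for i in range(K):
            comps.setdefault(find(i), []).append(i + 1)
        raise ValueError(
            "disconnected overlap graph; components: "
            + ", ".join(str(c) for c in comps.values())
        )


# ---------------------------------------------------------------------------
# remapped potentials (targeted MBAR inputs)
# ---------------------------------------------------------------------------


def remapped_potential(
    transform: ComposedTransform,
    potential_i: RestrictedPotential,
    batch_k: np.ndarray,
    base: BaseUniform | None = None,
) -> np.ndarray:
    """Effective potential u_{k->i}(r_k) = u_i(T_{k->i}(r_k)) - ln gamma.

    ``transform`` carries state k's coordinates through the shared base into
    state i's coordinates; gamma is the absolute Jacobian determinant of that
    composed map.  Rows whose intermediate base image leaves the box, or whose
    image is not assigned to state i, come back as +inf (zero weight).
    """
    batch_k = np.atleast_2d(np.asarray(batch_k, dtype=float))
    z, ld_inner = transform.inner.inverse(batch_k)
    ok = np.ones(len(batch_k), dtype=bool)
    if base is not None:
        ok &= base.contains(z)
    r_i, ld_outer = transform.outer.forward(z)
    u_i = _weight_energy(potential_i(r_i))
    out = u_i - (ld_inner + ld_outer)
    out = np.where(ok & np.isfinite(out), out, np.inf)
    return out


# ---------------------------------------------------------------------------
# entropy decomposition
# ---------------------------------------------------------------------------


def entropy_decomposition(
    delta_f: np.ndarray,
    mean_u: np.ndarray,
    delta_f_err: np.ndarray | None = None,
    mean_u_err: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Configurational entropy differences from free energies and energies.

    With f_i = <u_i>_{p_i} - s_i it holds that
    ``Delta s_ij = C_ij - Delta f_ij`` where ``C_ij = <u_j>_{p_j} - <u_i>_{p_i}``
    and ``Delta f_ij = f_j - f_i``.  The energy means come straight from the
    MD-origin data and are independent of the maps; uncertainties of the two
    terms are propagated in quadrature.
    """
    delta_f = np.asarray(delta_f, dtype=float)
    mean_u = np.asarray(mean_u, dtype=float)
    K = len(mean_u)
    if delta_f.shape != (K, K):
        raise ValueError("delta_f must be a K x K antisymmetric matrix")
    C = mean_u[None, :] - mean_u[:, None]
    ds = C - delta_f
    if delta_f_err is None:
        delta_f_err = np.zeros_like(delta_f)
    if mean_u_err is None:
        mean_u_err = np.zeros(K)
    u_var = mean_u_err[None, :] ** 2 + mean_u_err[:, None] ** 2
    ds_err = np.sqrt(np.asarray(delta_f_err, dtype=float) ** 2 + u_var)
    return ds, ds_err


# ---------------------------------------------------------------------------
# overfitting diagnostics on a convergence trace
# ---------------------------------------------------------------------------


def overfit_diagnostics(trace: pd.DataFrame) -> dict:
    """Training-progress heuristics read off a convergence trace.

    Reports, per state, the batch maximizing AVMD on the validation split (the
    early-stopping heuristic); per validation-split BAR/MBAR series, whether
    the analytic error bars grow monotonically in trend over the last half of
    training (the overfitting alarm); and the train-vs-validation estimate gap
    series for every estimator evaluated on both splits.
    """
    required = {"batch", "estimator", "split", "target", "value", "stderr"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"trace is missing columns: {sorted(missing)}")
    if trace["batch"].nunique() < 2:
        raise ValueError("trace needs at least 2 evaluation events")

    report: dict = {"avmd_v_argmax": {}, "stderr_growth": {}, "tv_gap": {}}

    av = trace[(trace["estimator"] == "AVMD") & (trace["split"] == "V")]
    for target, grp in av.groupby("target"):
        grp = grp.sort_values("batch")
        report["avmd_v_argmax"][str(target)] = int(
            grp.loc[grp["value"].idxmax(), "batch"]
        )

    for est in ("BAR", "MBAR"):
        sel = trace[(trace["estimator"] == est) & (trace["split"] == "V")]
        for target, grp in sel.groupby("target"):
            grp = grp.sort_values("batch")
            se = grp["stderr"].to_numpy()
            half = se[len(se) // 2 :]
            growing = bool(
                len(half) >= 3
                and np.polyfit(np.arange(len(half)), half, 1)[0] > 0
                and half[-1] > 1.2 * (half[0] + 1e-12)
            )
            report["stderr_growth"][f"{est}:{target}"] = {
                "flag": growing,
                "terminal_stderr": float(se[-1]),
                "initial_stderr": float(se[0]),
            }

    for (est, target), grp in trace[trace["split"].isin(["T", "V"])].groupby(
        ["estimator", "target"]
    ):
        piv = grp.pivot_table(index="batch", columns="split", values="value")
        if {"T", "V"} <= set(piv.columns):
            gap = (piv["T"] - piv["V"]).dropna()
            if len(gap):
                report["tv_gap"][f"{est}:{target}"] = {
                    "terminal_gap": float(gap.iloc[-1]),
                    "max_abs_gap": float(gap.abs().max()),
                }

    flags = [k for k, v in report["stderr_growth"].items() if v["flag"]]
    report["flags"] = flags if flags else ["no flags"]
    return report
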