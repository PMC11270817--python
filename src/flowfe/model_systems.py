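"""Self-contained model systems with known or quadrature-computable free energies.

These stand in for molecular-dynamics data: each system exposes a global
reduced potential u(r) (in units of k_B T) on a bounded box, a deterministic
cluster rule partitioning the box into metastable states, and a local
Metropolis sampler that is ergodic *within* one state only.  Ground-truth
state free energies f_i = -ln \\int_i exp(-u) dr come from grid quadrature
(low dimension) or closed form (Gaussian mixtures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NO_STATE",
    "ReducedPotential",
    "ClusterAssigner",
    "NearestWellAssigner",
    "ToySystem3D",
    "build_toy_system",
    "default_toy_well_table",
    "GaussianMixtureSystem",
    "quadrature_free_energy",
    "quadrature_mean_energy",
    "sample_state",
    "save_samples",
    "load_samples",
]

NO_STATE = -1  # sentinel label for out-of-domain configurations


class ReducedPotential:
    """A deterministic reduced potential u(r) on a bounded box.

    Subclasses implement ``energy`` on (N, D) arrays; values are in units of
    k_B T and must be finite on the interior of the domain.
    """

    dim: int
    lower: float
    upper: float

    def energy(self, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if r.ndim == 1:
            return self.energy(r[None, :])[0]
        return self.energy(r)


class ClusterAssigner:
    """Deterministic, total map from configurations to state labels."""

    def assign(self, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if r.ndim == 1:
            return int(self.assign(r[None, :])[0])
        return self.assign(r)


@dataclass(frozen=True)
class NearestWellAssigner(ClusterAssigner):
    """Nearest-well-center rule; ties resolved toward the lowest well index.

    Configurations outside the box get the sentinel ``NO_STATE`` label.
    """

    centers: np.ndarray
    groups: np.ndarray  # state label of each well
    lower: float = 0.0
    upper: float = 1.0

    def assign(self, r: np.ndarray) -> np.ndarray:
        r = np.atleast_2d(np.asarray(r, dtype=float))
        d2 = np.sum((r[:, None, :] - self.centers[None, :, :]) ** 2, axis=2)
        # argmin returns the first (lowest-index) minimizer: the tie-break rule
        well = np.argmin(d2, axis=1)
        labels = self.groups[well].astype(int)
        inside = np.all((r >= self.lower) & (r <= self.upper), axis=1)
        return np.where(inside, labels, NO_STATE)


# ---------------------------------------------------------------------------
# toy 3D system: six narrow harmonic wells grouped into three 2-modal states
# ---------------------------------------------------------------------------


@dataclass
class ToySystem3D(ReducedPotential):
    """Six isotropic harmonic wells in a unit box, grouped into three states.

    The global potential is the soft-min over wells,
    ``u(r) = -ln sum_w exp(-(offset_w + k_w/2 |r - c_w|^2))``,
    which is smooth and finite everywhere on the box.  Each of the three
    metastable states is the union of two well basins (2-modal), delimited by
    the nearest-well-group cluster rule.
    """

    centers: np.ndarray          # (6, 3)
    stiffness: np.ndarray        # (6,)
    offsets: np.ndarray          # (6,) reduced energy offset of each well
    groups: np.ndarray           # (6,) state label in {1, 2, 3}
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        self.dim = self.centers.shape[1]
        self.assigner = NearestWellAssigner(
            self.centers, self.groups, self.lower, self.upper
        )

    @property
    def state_labels(self) -> np.ndarray:
        return np.unique(self.groups)

    def well_energies(self, r: np.ndarray) -> np.ndarray:
        r = np.atleast_2d(np.asarray(r, dtype=float))
        d2 = np.sum((r[:, None, :] - self.centers[None, :, :]) ** 2, axis=2)
        return self.offsets[None, :] + 0.5 * self.stiffness[None, :] * d2

    def energy(self, r: np.ndarray) -> np.ndarray:
        uw = self.well_energies(r)
        m = uw.min(axis=1, keepdims=True)
        return (m - np.log(np.sum(np.exp(m - uw), axis=1, keepdims=True)))[:, 0]

    def min_energy(self) -> float:
        """Energy at the deepest well center (global minimum up to soft-min overlap)."""
        return float(np.min(self.energy(self.centers)))

    def to_json(self, path: str) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "stiffness": self.stiffness.tolist(),
            "offsets": self.offsets.tolist(),
            "groups": self.groups.tolist(),
            "lower": self.lower,
            "upper": self.upper,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ToySystem3D":
        with open(path) as fh:
            payload = json.load(fh)
        return build_toy_system(payload)


def default_toy_well_table() -> dict:
    """Default well table: stiffness 100 wells at the corners of a centred
    side-0.5 cube (pairwise separation 0.5 = 5 local standard deviations),
    with staggered energy offsets so the three states differ in free energy."""
    centers = [
        [0.25, 0.25, 0.25], [0.75, 0.75, 0.75],   # state 1
        [0.75, 0.25, 0.25], [0.25, 0.75, 0.75],   # state 2
        [0.25, 0.75, 0.25], [0.75, 0.25, 0.75],   # state 3
    ]
    return {
        "centers": centers,
        "stiffness": [100.0] * 6,
        "offsets": [0.0, 0.5, 1.0, 1.5, 0.75, 0.25],
        "groups": [1, 1, 2, 2, 3, 3],
        "lower": 0.0,
        "upper": 1.0,
    }


def build_toy_system(params: dict | None = None) -> ToySystem3D:
    """Validate a well table and construct the toy system.

    Requires exactly six wells with positive stiffness, grouped two per state
    into three states, and centers separated by at least five local standard
    deviations (sigma = 1/sqrt(k)) so the states do not overlap.
    """
    if params is None:
        params = default_toy_well_table()
    centers = np.asarray(params["centers"], dtype=float)
    stiffness = np.asarray(params["stiffness"], dtype=float)
    offsets = np.asarray(params.get("offsets", np.zeros(len(centers))), dtype=float)
    groups = np.asarray(params["groups"], dtype=int)
    if centers.shape[0] != 6:
        raise ValueError(f"toy system needs exactly 6 wells, got {centers.shape[0]}")
    if centers.shape[1] != 3:
        raise ValueError("toy system wells live in 3 dimensions")
    if len(stiffness) != 6 or len(offsets) != 6 or len(groups) != 6:
        raise ValueError("well table columns must all have 6 entries")
    if np.any(stiffness <= 0):
        raise ValueError("well stiffnesses must be positive")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) != 3 or np.any(counts != 2):
        raise ValueError("wells must be grouped two per state into 3 states")
    sigma = 1.0 / np.sqrt(stiffness)
    for i in range(6):
        for j in range(i + 1, 6):
            dist = float(np.linalg.norm(centers[i] - centers[j]))
            if dist < 5.0 * max(sigma[i], sigma[j]):
                raise ValueError(
                    f"wells {i} and {j} are separated by {dist:.3f} "
                    f"< 5 sigma = {5 * max(sigma[i], sigma[j]):.3f}"
                )
    return ToySystem3D(
        centers, stiffness, offsets, groups,
        lower=float(params.get("lower", 0.0)), upper=float(params.get("upper", 1.0)),
    )


# ---------------------------------------------------------------------------
# Gaussian-mixture systems with closed-form free energies
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixtureSystem(ReducedPotential):
    """Per-state Gaussian mixtures with analytic state free energies.

    State i has density proportional to
    ``sum_c mass_ic N(r; mu_ic, sigma_ic^2 I)``; its configuration integral
    is ``Z_i = sum_c mass_ic`` so ``f_i = -ln sum_c mass_ic`` in closed form.
    The global potential is the soft-min over the per-state potentials and
    the cluster rule is nearest component mean.
    """

    means: list          # per state: (C, D) array
    sigmas: list         # per state: (C,) isotropic std devs
    masses: list         # per state: (C,) positive component masses
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        self.means = [np.atleast_2d(np.asarray(m, dtype=float)) for m in self.means]
        self.sigmas = [np.atleast_1d(np.asarray(s, dtype=float)) for s in self.sigmas]
        self.masses = [np.atleast_1d(np.asarray(w, dtype=float)) for w in self.masses]
        self.n_states = len(self.means)
        self.dim = self.means[0].shape[1]
        for s in range(self.n_states):
            if np.any(self.sigmas[s] <= 0) or np.any(self.masses[s] <= 0):
                raise ValueError("sigmas and masses must be positive")
        all_means = np.concatenate(self.means, axis=0)
        all_state = np.concatenate(
            [np.full(len(self.means[s]), s + 1) for s in range(self.n_states)]
        )
        self.assigner = NearestWellAssigner(all_means, all_state, self.lower, self.upper)

    @property
    def state_labels(self) -> np.ndarray:
        return np.arange(1, self.n_states + 1)

    def state_energy(self, label: int, r: np.ndarray) -> np.ndarray:
        """u_i(r) = -ln sum_c mass_ic N(r; mu, sigma^2 I) for state i."""
        s = label - 1
        r = np.atleast_2d(np.asarray(r, dtype=float))
        mu, sig, mass = self.means[s], self.sigmas[s], self.masses[s]
        d2 = np.sum((r[:, None, :] - mu[None, :, :]) ** 2, axis=2)
        log_norm = -0.5 * self.dim * np.log(2.0 * np.pi * sig**2)
        logp = np.log(mass)[None, :] + log_norm[None, :] - 0.5 * d2 / sig[None, :] ** 2
        m = logp.max(axis=1, keepdims=True)
        return -(m + np.log(np.sum(np.exp(logp - m), axis=1, keepdims=True)))[:, 0]

    def energy(self, r: np.ndarray) -> np.ndarray:
        us = np.stack(
            [self.state_energy(lbl, r) for lbl in self.state_labels], axis=1
        )
        m = us.min(axis=1, keepdims=True)
        return (m - np.log(np.sum(np.exp(m - us), axis=1, keepdims=True)))[:, 0]

    def analytic_free_energy(self, label: int) -> float:
        """f_i = -ln Z_i with Z_i the closed-form configuration integral."""
        return -float(np.log(np.sum(self.masses[label - 1])))

    def analytic_entropy(self, label: int) -> float:
        """Differential entropy s_i = <-ln p_i> for a single-component state."""
        s = label - 1
        if len(self.masses[s]) != 1:
            raise ValueError("closed-form entropy implemented for 1-component states")
        sig = float(self.sigmas[s][0])
        return 0.5 * self.dim * (1.0 + np.log(2.0 * np.pi * sig**2))

    def exact_sample(self, label: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Direct (non-MCMC) sample from state ``label``'s normalized density."""
        s = label - 1
        mass = self.masses[s]
        comp = rng.choice(len(mass), size=n, p=mass / mass.sum())
        eps = rng.standard_normal((n, self.dim))
        return self.means[s][comp] + self.sigmas[s][comp, None] * eps


# ---------------------------------------------------------------------------
# quadrature ground truth
# ---------------------------------------------------------------------------


def quadrature_free_energy(
    potential: ReducedPotential,
    state: int | None = None,
    assigner: ClusterAssigner | None = None,
    grid: int = 128,
    chunk: int = 262144,
) -> float:
    """Midpoint-rule estimate of f = -ln sum_g exp(-u(r_g)) dV over a state.

    ``state=None`` integrates over the whole box.  Restricted to D <= 3 —
    grid quadrature is a low-dimensional ground-truth facility only.
    """
    D = potential.dim
    if D > 3:
        raise ValueError("quadrature ground truth is only available for D <= 3")
    if grid < 64:
        raise ValueError("grid resolution must be >= 64 per dimension")
    a, b = potential.lower, potential.upper
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("quadrature requires a bounded domain")
    edges = np.linspace(a, b, grid + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dvol = ((b - a) / grid) ** D
    axes = np.meshgrid(*([mids] * D), indexing="ij")
    pts = np.stack([ax.ravel() for ax in axes], axis=1)
    log_terms_max = -np.inf
    # two-pass log-sum-exp over chunks: first find the max, then accumulate
    chunks = range(0, len(pts), chunk)
    neg_u = []
    for start in chunks:
        block = pts[start : start + chunk]
        if state is not None:
            keep = assigner(block) == state
            block = block[keep]
        if len(block) == 0:
            neg_u.append(None)
            continue
        v = -potential(block)
        neg_u.append(v)
        log_terms_max = max(log_terms_max, float(v.max()))
    if not np.isfinite(log_terms_max):
        raise ValueError(f"no grid point assigned to state {state}")
    total = 0.0
    for v in neg_u:
        if v is not None:
            total += float(np.sum(np.exp(v - log_terms_max)))
    return -(log_terms_max + np.log(total) + D * np.log((b - a) / grid))


def quadrature_mean_energy(
    potential: ReducedPotential,
    state: int | None = None,
    assigner: ClusterAssigner | None = None,
    grid: int = 128,
    chunk: int = 262144,
) -> float:
    """Boltzmann-weighted mean reduced energy <u>_i of a state, by quadrature."""
    D = potential.dim
    if D > 3:
        raise ValueError("quadrature ground truth is only available for D <= 3")
    a, b = potential.lower, potential.upper
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("quadrature requires a bounded domain")
    edges = np.linspace(a, b, grid + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    axes = np.meshgrid(*([mids] * D), indexing="ij")
    pts = np.stack([ax.ravel() for ax in axes], axis=1)
    num = 0.0
    den = 0.0
    offset = None
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        if state is not None:
            block = block[assigner(block) == state]
        if len(block) == 0:
            continue
        u = potential(block)
        if offset is None:
            offset = float(u.min())
        w = np.exp(offset - u)
        num += float(np.sum(w * u))
        den += float(np.sum(w))
    if den == 0.0:
        raise ValueError(f"no grid point assigned to state {state}")
    return num / den


# ---------------------------------------------------------------------------
# local Metropolis sampler
# ---------------------------------------------------------------------------


def sample_state(
    potential: ReducedPotential,
    state: int,
    assigner: ClusterAssigner,
    n: int,
    seed: int | np.random.Generator,
    x0: np.ndarray | None = None,
    step: float = 0.1,
    burn_in: int = 1000,
    thin: int = 5,
    adapt: bool = True,
    jump_fraction: float = 0.1,
) -> np.ndarray:
    """Locally ergodic Metropolis random walk confined to one metastable state.

    Gaussian proposals; any proposal whose cluster label differs from the
    target state is rejected outright, so the chain samples the state's
    restricted Boltzmann distribution.  When the assigner exposes several
    well centers for the state (multimodal states), a fraction of moves are
    symmetric between-well translations r -> r + (c_other - c_nearest), which
    make the chain ergodic across all basins of the state.  During burn-in
    the local step size adapts toward ~40% acceptance and is then frozen.
    Fully reproducible from the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D = potential.dim
    centers = getattr(assigner, "centers", None)
    groups = getattr(assigner, "groups", None)
    state_centers = None
    if centers is not None and groups is not None:
        state_centers = np.asarray(centers, dtype=float)[np.asarray(groups) == state]
    if x0 is None:
        # default: start at the lowest-energy well/component center of the state
        if state_centers is None or len(state_centers) == 0:
            raise ValueError(f"x0 required: no stored well centers for state {state}")
        x0 = state_centers[int(np.argmin(potential(state_centers)))]
    x = np.asarray(x0, dtype=float).copy()
    if int(assigner(x)) != state:
        raise ValueError("initial configuration is not assigned to the target state")

    do_jumps = state_centers is not None and len(state_centers) >= 2
    u = float(potential(x))
    out = np.empty((n, D))
    n_acc = 0
    n_try = 0
    total_steps = burn_in + n * thin
    for it in range(total_steps):
        if do_jumps and rng.uniform() < jump_fraction:
            # symmetric basin-hop: translate by the offset to another well of
            # the same state (an involution for 2-modal states)
            d2 = np.sum((state_centers - x) ** 2, axis=1)
            near = int(np.argmin(d2))
            others = [w for w in range(len(state_centers)) if w != near]
            target = others[int(rng.integers(len(others)))]
            prop = x + (state_centers[target] - state_centers[near])
            count_local = False
        else:
            prop = x + step * rng.standard_normal(D)
            count_local = True
            n_try += 1
        accept = False
        if int(assigner(prop)) == state:
            u_prop = float(potential(prop))
            if np.log(rng.uniform()) < u - u_prop:
                accept = True
        if accept:
            x, u = prop, u_prop
            if count_local:
                n_acc += 1
        if adapt and it < burn_in and count_local and n_try >= 50:
            rate = n_acc / n_try
            step *= 1.1 if rate > 0.4 else 0.9
            n_acc = n_try = 0
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            out[(it - burn_in) // thin] = x
    return out


# ---------------------------------------------------------------------------
# sample-file I/O (CSV + JSON sidecar)
# ---------------------------------------------------------------------------


def save_samples(path: str, samples: np.ndarray, state: int, seed: int,
                 settings: dict | None = None) -> None:
    import pandas as pd

    samples = np.atleast_2d(samples)
    cols = [f"x{i + 1}" for i in range(samples.shape[1])]
    pd.DataFrame(samples, columns=cols).to_csv(path, index=False)
    sidecar = {"state": int(state), "seed": int(seed), "settings": settings or {}}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_samples(path: str) -> tuple[np.ndarray, dict]:
    import pandas as pd

    samples = pd.read_csv(path).to_numpy(dtype=float)
    try:
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
    except FileNotFoundError:
        sidecar = {}
    return samples, sidecar
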