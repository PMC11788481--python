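"""Well-tempered metadynamics: collective variables, hills, bias, PMF.

Two collective variables are supported, matching the two biased stages
of the coalescence workflow:

* ``RgSystemCV`` — radius of gyration of the chain-center beads of the
  whole system (used to collapse a dilute solution into one cluster);
* ``ClusterDistanceCV`` — minimum-image distance between the chain-center
  centroids of two labeled clusters (used to drive fusion).

The bias is a sum of Gaussians deposited along the CV.  In well-tempered
mode the height of each new hill is damped by exp(-V(s)/(kB ΔT)) with
ΔT = (γ-1) T, and the free-energy profile is recovered as
F(s) = -(T+ΔT)/ΔT · V(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL_PER_MOL_K
from .state import SystemState, min_image


@dataclass
class WellTemperedParams:
    """Hill height w0 (kcal/mol), width sigma_G (CV units), deposition
    pace (steps) and bias factor gamma = (T + ΔT)/T > 1."""

    w0: float = 0.3
    sigma_G: float = 2.0
    pace: int = 1000
    gamma: float = 10.0
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if min(self.w0, self.sigma_G, self.pace) <= 0:
            raise ValueError("w0, sigma_G and pace must be positive")
        if self.gamma <= 1:
            raise ValueError("well-tempered bias factor gamma must exceed 1")

    @property
    def delta_T(self) -> float:
        return (self.gamma - 1.0) * self.T


@dataclass
class HillStore:
    """Deposited Gaussians: centers, widths, heights and deposit steps."""

    centers: list = field(default_factory=list)
    widths: list = field(default_factory=list)
    heights: list = field(default_factory=list)
    steps: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.centers)

    def append(self, center: float, width: float, height: float, step: int) -> None:
        if width <= 0 or height <= 0:
            raise ValueError("hill width and height must be positive")
        self.centers.append(float(center))
        self.widths.append(float(width))
        self.heights.append(float(height))
        self.steps.append(int(step))
        self._cache = None

    def _arrays(self):
        cache = getattr(self, "_cache", None)
        if cache is None or len(cache[0]) != len(self.centers):
            cache = (np.asarray(self.centers), np.asarray(self.widths),
                     np.asarray(self.heights))
            self._cache = cache
        return cache

    def potential(self, s) -> np.ndarray | float:
        """Bias potential V(s) = Σ w_k exp(-(s-s_k)^2 / (2 σ_k^2))."""
        s = np.asarray(s, dtype=float)
        if len(self) == 0:
            return np.zeros(s.shape) if s.ndim else 0.0
        c, w, h = self._arrays()
        v = np.sum(h * np.exp(-0.5 * ((s[..., None] - c) / w) ** 2), axis=-1)
        return v if s.ndim else float(v)

    def derivative(self, s) -> np.ndarray | float:
        s = np.asarray(s, dtype=float)
        if len(self) == 0:
            return np.zeros(s.shape) if s.ndim else 0.0
        c, w, h = self._arrays()
        z = (s[..., None] - c) / w
        d = np.sum(-h * z / w * np.exp(-0.5 * z ** 2), axis=-1)
        return d if s.ndim else float(d)

    def potential_and_derivative(self, s: float) -> tuple[float, float]:
        """V(s) and dV/ds at a scalar point in one pass over the hills."""
        if len(self) == 0:
            return 0.0, 0.0
        c, w, h = self._arrays()
        z = (s - c) / w
        g = h * np.exp(-0.5 * z * z)
        return float(np.sum(g)), float(np.sum(-z / w * g))


def deposit_hill(store: HillStore, params: WellTemperedParams, s: float,
                 step: int = 0) -> float:
    """Append a well-tempered hill at s; returns the deposited height.

    The first hill has height w0 exactly; subsequent heights at a visited
    point decay geometrically (standard metadynamics is the γ→∞ limit).
    """
    v = store.potential(s)
    height = params.w0 * np.exp(-v / (KB_KCAL_PER_MOL_K * params.delta_T))
    store.append(s, params.sigma_G, height, step)
    return float(height)


def pmf_estimate(store: HillStore, grid, params: WellTemperedParams):
    """Free-energy profile on ``grid``: -(γ/(γ-1)) V(s), shifted to min 0."""
    if params.gamma <= 1:
        raise ValueError("PMF reconstruction requires gamma > 1")
    grid = np.asarray(grid, dtype=float)
    pmf = -(params.gamma / (params.gamma - 1.0)) * store.potential(grid)
    return pmf - pmf.min()


# ---------------------------------------------------------------------------
# collective variables


class RgSystemCV:
    """Radius of gyration of the chain-center beads of the whole system.

    Operates on raw (unwrapped) coordinates — the run loop keeps
    coordinates unwrapped precisely so that cluster-level CVs stay
    continuous; set ``minimum_image`` to fold centers about the first one
    when analyzing wrapped snapshots of a compact cluster.
    """

    kind = "rg_system"

    def __init__(self, center_ids: np.ndarray, minimum_image: bool = False):
        self.center_ids = np.asarray(center_ids, dtype=np.int64)
        self.minimum_image = minimum_image
        if len(self.center_ids) == 0:
            raise ValueError("rg_system CV needs at least one chain center")

    def _unwrapped_centers(self, state: SystemState) -> np.ndarray:
        pos = state.positions[self.center_ids]
        if self.minimum_image:
            return pos[0] + min_image(pos - pos[0], state.box_length)
        return pos

    def value(self, state: SystemState) -> float:
        pos = self._unwrapped_centers(state)
        d = pos - pos.mean(axis=0)
        return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))

    def value_and_gradient(self, state: SystemState):
        """CV value and dS/dr as a dense (N, 3) array (zero off-centers)."""
        pos = self._unwrapped_centers(state)
        d = pos - pos.mean(axis=0)
        m = len(pos)
        s = float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))
        grad = np.zeros_like(state.positions)
        if s > 1e-12:
            grad[self.center_ids] = d / (m * s)
        return s, grad


class ClusterDistanceCV:
    """Minimum-image distance between the chain-center centroids of two
    labeled clusters."""

    kind = "cluster_distance"

    def __init__(self, center_ids_1: np.ndarray, center_ids_2: np.ndarray,
                 minimum_image: bool = False):
        self.ids1 = np.asarray(center_ids_1, dtype=np.int64)
        self.ids2 = np.asarray(center_ids_2, dtype=np.int64)
        self.minimum_image = minimum_image
        if len(self.ids1) == 0 or len(self.ids2) == 0:
            raise ValueError("both cluster label groups must be non-empty")

    def _centroid(self, state: SystemState, ids: np.ndarray) -> np.ndarray:
        pos = state.positions[ids]
        if self.minimum_image:
            ref = pos[0]
            return ref + min_image(pos - ref, state.box_length).mean(axis=0)
        return pos.mean(axis=0)

    def value_and_gradient(self, state: SystemState):
        c1 = self._centroid(state, self.ids1)
        c2 = self._centroid(state, self.ids2)
        dvec = c1 - c2
        if self.minimum_image:
            dvec = min_image(dvec, state.box_length)
        s = float(np.linalg.norm(dvec))
        grad = np.zeros_like(state.positions)
        if s > 1e-12:
            u = dvec / s
            grad[self.ids1] += u / len(self.ids1)
            grad[self.ids2] -= u / len(self.ids2)
        return s, grad

    def value(self, state: SystemState) -> float:
        return self.value_and_gradient(state)[0]


def cv_value(state: SystemState, cv) -> float:
    """Scalar value of a collective variable on a state."""
    return cv.value(state)


# ---------------------------------------------------------------------------
# bias hook for the dynamics engine


class MetadynamicsBias:
    """History-dependent Gaussian bias along one CV.

    Implements the hook interface of :func:`condfuse.dynamics.run`:
    ``bead_forces`` (called every step) and ``due``/``deposit_from_state``
    (hill deposition at the pace cadence).
    """

    def __init__(self, cv, params: WellTemperedParams,
                 store: HillStore | None = None):
        self.cv = cv
        self.params = params
        self.store = store if store is not None else HillStore()

    def cv_value(self, state: SystemState) -> float:
        return self.cv.value_and_gradient(state)[0]

    def bead_forces(self, state: SystemState):
        s, grad = self.cv.value_and_gradient(state)
        v, dvds = self.store.potential_and_derivative(s)
        return -dvds * grad, v

    def due(self, step: int) -> bool:
        return step % self.params.pace == 0

    def deposit_from_state(self, state: SystemState) -> float:
        s = self.cv.value_and_gradient(state)[0]
        return deposit_hill(self.store, self.params, s, step=state.step)

    def pmf(self, grid):
        return pmf_estimate(self.store, grid, self.params)


class SteeringBias:
    """Moving harmonic restraint on a CV (steered dynamics).

    V = k/2 (s - s0(t))², with the anchor s0 moved linearly from
    ``s_from`` to ``s_to`` between steps ``t_start`` and ``t_end`` and
    held at ``s_to`` afterwards.  Used as the desk-scale stand-in for the
    very long history-dependent runs that drive collapse and fusion at
    production scale.
    """

    def __init__(self, cv, k: float, s_from: float, s_to: float,
                 t_start: int, t_end: int):
        if k <= 0 or t_end <= t_start:
            raise ValueError("need k > 0 and t_end > t_start")
        self.cv = cv
        self.k = k
        self.s_from = s_from
        self.s_to = s_to
        self.t_start = t_start
        self.t_end = t_end

    def anchor(self, step: int) -> float:
        if step <= self.t_start:
            return self.s_from
        if step >= self.t_end:
            return self.s_to
        frac = (step - self.t_start) / (self.t_end - self.t_start)
        return self.s_from + frac * (self.s_to - self.s_from)

    def cv_value(self, state: SystemState) -> float:
        return self.cv.value_and_gradient(state)[0]

    def bead_forces(self, state: SystemState):
        s, grad = self.cv.value_and_gradient(state)
        ds = s - self.anchor(state.step)
        return -(self.k * ds) * grad, 0.5 * self.k * ds * ds

    def due(self, step: int) -> bool:
        return False

    def deposit_from_state(self, state: SystemState) -> float:  # pragma: no cover
        raise NotImplementedError("steering deposits no hills")


class HarmonicWallBias:
    """One-sided harmonic walls confining a CV to [lower, upper]."""

    def __init__(self, cv, k: float, lower: float | None = None,
                 upper: float | None = None):
        if k <= 0:
            raise ValueError("wall stiffness must be positive")
        self.cv = cv
        self.k = k
        self.lower = lower
        self.upper = upper

    def cv_value(self, state: SystemState) -> float:
        return self.cv.value_and_gradient(state)[0]

    def bead_forces(self, state: SystemState):
        s, grad = self.cv.value_and_gradient(state)
        ds = 0.0
        if self.upper is not None and s > self.upper:
            ds = s - self.upper
        elif self.lower is not None and s < self.lower:
            ds = s - self.lower
        return -(self.k * ds) * grad, 0.5 * self.k * ds * ds

    def due(self, step: int) -> bool:
        return False

    def deposit_from_state(self, state: SystemState) -> float:  # pragma: no cover
        raise NotImplementedError("walls deposit no hills")


class CompositeBias:
    """Sum of bias hooks sharing one CV (e.g. metadynamics + wall)."""

    def __init__(self, *hooks):
        if not hooks:
            raise ValueError("need at least one hook")
        self.hooks = hooks

    def cv_value(self, state: SystemState) -> float:
        return self.hooks[0].cv_value(state)

    def bead_forces(self, state: SystemState):
        total_f = None
        total_e = 0.0
        for hook in self.hooks:
            f, e = hook.bead_forces(state)
            total_f = f if total_f is None else total_f + f
            total_e += e
        return total_f, total_e

    def due(self, step: int) -> bool:
        return any(h.due(step) for h in self.hooks)

    def deposit_from_state(self, state: SystemState):
        for h in self.hooks:
            if hasattr(h, "store"):
                h.deposit_from_state(state)


# ---------------------------------------------------------------------------
# 1-D overdamped reference engine (for validating the bias machinery
# against analytic potentials)


def run_overdamped_1d(
    grad_U,
    params: WellTemperedParams,
    n_steps: int,
    dt: float,
    kT: float = 1.0,
    s0: float = 0.0,
    seed: int | np.random.Generator = 0,
    store: HillStore | None = None,
) -> HillStore:
    """Well-tempered metadynamics of one overdamped particle on an
    analytic 1-D potential (Euler-Maruyama, mobility 1).

    ``grad_U`` is dU/ds in the same energy unit as ``params.w0`` and
    ``kT``; set kT = 1 and quote energies in kT to work in reduced units,
    with ``params.T`` adjusted so that kB·T equals 1 in those units.
    Returns the hill store, from which :func:`pmf_estimate` reconstructs
    the free-energy profile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    store = store if store is not None else HillStore()
    s = float(s0)
    noise_sigma = np.sqrt(2.0 * kT * dt)
    # kB ΔT = (γ-1) kB T = (γ-1) kT in whatever unit kT is quoted
    kb_dT = (params.gamma - 1.0) * kT
    centers = np.empty(0)
    widths = np.empty(0)
    heights = np.empty(0)
    for step in range(1, n_steps + 1):
        if len(centers):
            z = (s - centers) / widths
            g = np.exp(-0.5 * z * z)
            dv = float(np.sum(-heights * z / widths * g))
        else:
            dv = 0.0
        s += -(grad_U(s) + dv) * dt + noise_sigma * rng.standard_normal()
        if step % params.pace == 0:
            if len(centers):
                z = (s - centers) / widths
                v = float(np.sum(heights * np.exp(-0.5 * z * z)))
            else:
                v = 0.0
            store.append(s, params.sigma_G, params.w0 * np.exp(-v / kb_dT), step)
            centers = np.asarray(store.centers)
            widths = np.asarray(store.widths)
            heights = np.asarray(store.heights)
    return store
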