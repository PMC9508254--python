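"""Spatial null models for tree stem maps.

Five planar point processes are provided, each encoding a different
ecological hypothesis about how trees arrange themselves in a plot:

* **CSR** — complete spatial randomness (homogeneous Poisson): trees are
  placed independently; the count in any region is Poisson.
* **Matérn cluster process** — dispersal limitation: Poisson "parent" trees
  each spawn a Poisson(``mu``) number of offspring uniformly inside a disc
  of radius ``r_d``; the parents die and only offspring remain.
* **Thomas cluster process** — as Matérn, but offspring are displaced from
  the parent by an isotropic Gaussian kernel.
* **Gibbs hard-core process (HC)** — competitive exclusion: no two trees may
  stand closer than the hard-core distance ``r_g``.
* **Strauss process** — softened exclusion: a tree with ``m`` neighbours
  closer than ``r_g`` is penalised by a factor ``p**m`` rather than
  forbidden outright.

Patterns are *marked*: after simulation, crown radii are attached by random
labelling (marks independent of locations), either uniform or gamma
distributed.  All simulators are reproducible: the same seed and
configuration yield a bit-identical pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit
from scipy import stats

from .errors import ConvergenceError, DataError, ParameterError

__all__ = [
    "Window",
    "NullModelConfig",
    "MarkedPattern",
    "CrownDistribution",
    "MODEL_NAMES",
    "GAUSS_SCALE_FACTOR",
    "simulate",
    "simulate_csr",
    "simulate_matern",
    "simulate_thomas",
    "simulate_hardcore",
    "simulate_strauss",
    "assign_crown_radii",
    "fit_crown_gamma",
    "estimate_intensity",
]

MODEL_NAMES = ("CSR", "MATERN", "THOMAS", "HARDCORE", "STRAUSS")

#: Gaussian dispersal scale per unit dispersal radius.  ``r_d`` is read as the
#: radius containing 95% of offspring, so sigma = r_d / sqrt(2 ln 20).
GAUSS_SCALE_FACTOR = 1.0 / math.sqrt(2.0 * math.log(20.0))


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, in metres."""

    xmin: float = 0.0
    xmax: float = 200.0
    ymin: float = 0.0
    ymax: float = 200.0

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ParameterError(
                f"degenerate window [{self.xmin},{self.xmax}]x[{self.ymin},{self.ymax}]"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def dilate(self, margin: float) -> "Window":
        """Window grown by ``margin`` on every side (edge-effect buffering)."""
        return Window(self.xmin - margin, self.xmax + margin,
                      self.ymin - margin, self.ymax + margin)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ((x >= self.xmin) & (x <= self.xmax)
                & (y >= self.ymin) & (y <= self.ymax))

    @staticmethod
    def from_points(x: np.ndarray, y: np.ndarray, pad: float = 0.0) -> "Window":
        return Window(float(np.min(x)) - pad, float(np.max(x)) + pad,
                      float(np.min(y)) - pad, float(np.max(y)) + pad)


@dataclass(frozen=True)
class NullModelConfig:
    """Parameters of one spatial null model.

    Parameters
    ----------
    model:
        One of ``CSR``, ``MATERN``, ``THOMAS``, ``HARDCORE``, ``STRAUSS``.
    kappa:
        Point intensity per m².  For cluster models parents are simulated
        at ``kappa / mu`` so that the *tree* (offspring) intensity is
        ``kappa``, matching the other models; set ``kappa_is_parent`` to
        read ``kappa`` as the parent intensity instead.  For Gibbs models
        ``kappa`` is the activity of the Strauss/hard-core density
        (realized intensity is lower because of inhibition) unless
        ``fixed_n`` is set.
    mu:
        Mean offspring count per parent (cluster models).
    r_d:
        Dispersal radius, m.  Matérn offspring are uniform in a disc of this
        radius; for Thomas it is the 95% dispersal radius of the Gaussian
        kernel (``sigma = r_d * GAUSS_SCALE_FACTOR``) unless ``sigma`` is
        given explicitly.
    r_g:
        Hard-core / interaction distance, m (Gibbs models).
    p:
        Strauss retention probability per close neighbour, in [0, 1].
    seed:
        Default RNG seed used when :func:`simulate` is called without one.
    kappa_is_parent:
        Reinterpret ``kappa`` as the parent intensity of a cluster model
        (the offspring intensity is then ``kappa * mu``).
    fixed_n:
        Simulate Gibbs models conditionally on exactly ``round(kappa * area)``
        points via a fixed-count replacement chain instead of the
        birth–death chain.
    """

    model: str = "CSR"
    kappa: float = 0.015
    mu: float = 3.0
    r_d: float = 5.0
    r_g: float = 4.0
    p: float = 0.5
    seed: Optional[int] = None
    sigma: Optional[float] = None
    kappa_is_parent: bool = False
    fixed_n: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", str(self.model).upper())
        if self.model not in MODEL_NAMES:
            raise ParameterError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if not self.kappa > 0:
            raise ParameterError(f"kappa must be positive, got {self.kappa}")
        if self.model in ("MATERN", "THOMAS"):
            if not self.mu > 0:
                raise ParameterError(f"mu must be positive, got {self.mu}")
            if not self.r_d > 0:
                raise ParameterError(f"r_d must be positive, got {self.r_d}")
        if self.model in ("HARDCORE", "STRAUSS") and not self.r_g > 0:
            raise ParameterError(f"r_g must be positive, got {self.r_g}")
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"p must lie in [0, 1], got {self.p}")

    @property
    def gauss_sigma(self) -> float:
        """Gaussian dispersal scale used by the Thomas process."""
        return self.r_d * GAUSS_SCALE_FACTOR if self.sigma is None else self.sigma

    def with_(self, **kwargs) -> "NullModelConfig":
        return replace(self, **kwargs)


@dataclass
class MarkedPattern:
    """A planar point pattern with optional crown-radius marks."""

    x: np.ndarray
    y: np.ndarray
    window: Window
    radii: Optional[np.ndarray] = None
    provenance: str = "empirical"
    ids: Optional[np.ndarray] = None
    # cluster-process bookkeeping: parent coordinates and, per point, the
    # index of the parent that produced it
    parents: Optional[np.ndarray] = field(default=None, repr=False)
    parent_index: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise DataError("x and y must have equal length")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != self.x.shape:
                raise DataError("radii must match point count")
            if np.any(~(self.radii > 0) & ~np.isnan(self.radii)):
                raise DataError("crown radii must be positive (or NaN for missing)")
        if not np.all(self.window.contains(self.x, self.y)):
            raise DataError("points outside the window")

    @property
    def n(self) -> int:
        return self.x.size

    def __len__(self) -> int:
        return self.n

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def min_pairwise_distance(self) -> float:
        if self.n < 2:
            return math.inf
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.coords).query(self.coords, k=2)
        return float(d[:, 1].min())


@dataclass(frozen=True)
class CrownDistribution:
    """Crown-radius mark distribution: ``uniform(lo, hi)`` or ``gamma(shape, rate)``."""

    kind: str = "uniform"
    lo: float = 2.0
    hi: float = 5.0
    shape: float = math.nan
    rate: float = math.nan

    def __post_init__(self) -> None:
        kind = str(self.kind).lower()
        object.__setattr__(self, "kind", kind)
        if kind == "uniform":
            if not self.lo < self.hi:
                raise ParameterError(f"uniform crown bounds need lo < hi, got [{self.lo}, {self.hi}]")
            if self.lo < 0:
                raise ParameterError("crown radii cannot be negative")
        elif kind == "gamma":
            if not (self.shape > 0 and self.rate > 0):
                raise ParameterError(
                    f"gamma crown parameters must be positive, got shape={self.shape}, rate={self.rate}"
                )
        else:
            raise ParameterError(f"unknown crown distribution kind {kind!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, n)
        return rng.gamma(shape=self.shape, scale=1.0 / self.rate, size=n)

    @property
    def mean(self) -> float:
        if self.kind == "uniform":
            return 0.5 * (self.lo + self.hi)
        return self.shape / self.rate


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate(config: NullModelConfig, window: Window, seed=None) -> MarkedPattern:
    """Draw one (unlabelled) pattern from the configured null model."""
    dispatch = {
        "CSR": simulate_csr,
        "MATERN": simulate_matern,
        "THOMAS": simulate_thomas,
        "HARDCORE": simulate_hardcore,
        "STRAUSS": simulate_strauss,
    }
    return dispatch[config.model](config, window, seed=seed)


def simulate_csr(config: NullModelConfig, window: Window, seed=None) -> MarkedPattern:
    """Homogeneous Poisson pattern with intensity ``kappa``."""
    if config.model != "CSR":
        raise ParameterError(f"config is for {config.model}, not CSR")
    rng = _rng(config.seed if seed is None else seed)
    n = rng.poisson(config.kappa * window.area)
    x = rng.uniform(window.xmin, window.xmax, n)
    y = rng.uniform(window.ymin, window.ymax, n)
    return MarkedPattern(x, y, window, provenance="CSR")


def _cluster_offspring(config, window, rng, margin):
    """Parents in the dilated window; returns parent coords, offspring counts."""
    kappa_parent = config.kappa if config.kappa_is_parent else config.kappa / config.mu
    dil = window.dilate(margin)
    n_par = rng.poisson(kappa_parent * dil.area)
    px = rng.uniform(dil.xmin, dil.xmax, n_par)
    py = rng.uniform(dil.ymin, dil.ymax, n_par)
    n_off = rng.poisson(config.mu, n_par)
    return px, py, n_off


def simulate_matern(config: NullModelConfig, window: Window, seed=None) -> MarkedPattern:
    """Matérn cluster process: offspring uniform in a disc of radius ``r_d``."""
    if config.model != "MATERN":
        raise ParameterError(f"config is for {config.model}, not MATERN")
    rng = _rng(config.seed if seed is None else seed)
    px, py, n_off = _cluster_offspring(config, window, rng, margin=config.r_d)
    parent_index = np.repeat(np.arange(px.size), n_off)
    m = parent_index.size
    # uniform in the disc: sqrt-radius transform
    rad = config.r_d * np.sqrt(rng.uniform(size=m))
    theta = rng.uniform(0.0, 2.0 * np.pi, m)
    x = px[parent_index] + rad * np.cos(theta)
    y = py[parent_index] + rad * np.sin(theta)
    keep = window.contains(x, y)
    return MarkedPattern(
        x[keep], y[keep], window, provenance="MATERN",
        parents=np.column_stack([px, py]), parent_index=parent_index[keep],
    )


def simulate_thomas(config: NullModelConfig, window: Window, seed=None) -> MarkedPattern:
    """Thomas cluster process: isotropic Gaussian offspring displacement."""
    if config.model != "THOMAS":
        raise ParameterError(f"config is for {config.model}, not THOMAS")
    rng = _rng(config.seed if seed is None else seed)
    sigma = config.gauss_sigma
    px, py, n_off = _cluster_offspring(config, window, rng, margin=4.0 * sigma)
    parent_index = np.repeat(np.arange(px.size), n_off)
    m = parent_index.size
    disp = rng.normal(0.0, sigma, (m, 2)) if sigma > 0 else np.zeros((m, 2))
    x = px[parent_index] + disp[:, 0]
    y = py[parent_index] + disp[:, 1]
    keep = window.contains(x, y)
    return MarkedPattern(
        x[keep], y[keep], window, provenance="THOMAS",
        parents=np.column_stack([px, py]), parent_index=parent_index[keep],
    )


# ---------------------------------------------------------------------------
# Gibbs (inhibition) models
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_birth_death(xs, ys, n0, beta_area, gamma, rg2,
                       xmin, xw, ymin, yw, u_kind, u_x, u_y, u_pick, u_acc):
    """Birth–death Metropolis–Hastings chain for the Strauss density
    beta^n * gamma^{s(x)} with s(x) the number of pairs closer than r_g.
    gamma = 0 is the hard-core model.  Returns the final point count."""
    n = n0
    steps = u_kind.size
    for t in range(steps):
        if u_kind[t] < 0.5:  # birth
            x = xmin + xw * u_x[t]
            y = ymin + yw * u_y[t]
            m = 0
            for j in range(n):
                dx = xs[j] - x
                dy = ys[j] - y
                if dx * dx + dy * dy < rg2:
                    m += 1
            if gamma == 0.0:
                ratio = beta_area / (n + 1) if m == 0 else 0.0
            else:
                ratio = beta_area / (n + 1) * gamma ** m
            if u_acc[t] < ratio and n < xs.size:
                xs[n] = x
                ys[n] = y
                n += 1
        elif n > 0:  # death
            i = int(u_pick[t] * n)
            if i >= n:
                i = n - 1
            m = 0
            for j in range(n):
                if j == i:
                    continue
                dx = xs[j] - xs[i]
                dy = ys[j] - ys[i]
                if dx * dx + dy * dy < rg2:
                    m += 1
            if gamma == 0.0:
                # a hard-core state never contains close pairs, so m == 0
                ratio = n / beta_area if m == 0 else 1e300
            else:
                ratio = n / beta_area / gamma ** m
            if u_acc[t] < ratio:
                xs[i] = xs[n - 1]
                ys[i] = ys[n - 1]
                n -= 1
    return n


@njit(cache=True)
def _gibbs_fixed_n(xs, ys, gamma, rg2, xmin, xw, ymin, yw,
                   u_x, u_y, u_pick, u_acc, min_steps, hard):
    """Fixed-count replacement chain: remove a uniformly chosen point and
    propose a uniform replacement, accepted with probability gamma^m (m =
    close neighbours of the proposal; hard core accepts only m == 0).
    Returns (steps_used, remaining_violation_pairs)."""
    n = xs.size
    viol = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = xs[j] - xs[i]
            dy = ys[j] - ys[i]
            if dx * dx + dy * dy < rg2:
                viol += 1
    cap = u_x.size
    t = 0
    while t < cap:
        if t >= min_steps and (not hard or viol == 0):
            break
        i = int(u_pick[t] * n)
        if i >= n:
            i = n - 1
        x = xmin + xw * u_x[t]
        y = ymin + yw * u_y[t]
        m_new = 0
        for j in range(n):
            if j == i:
                continue
            dx = xs[j] - x
            dy = ys[j] - y
            if dx * dx + dy * dy < rg2:
                m_new += 1
        accept = m_new == 0 if hard else (u_acc[t] < gamma ** m_new if m_new else True)
        if accept:
            m_old = 0
            for j in range(n):
                if j == i:
                    continue
                dx = xs[j] - xs[i]
                dy = ys[j] - ys[i]
                if dx * dx + dy * dy < rg2:
                    m_old += 1
            xs[i] = x
            ys[i] = y
            viol += m_new - m_old
        t += 1
    return t, viol


_BD_STEPS = 30_000
_FIXED_N_CAP = 1_000_000


def _simulate_gibbs(config: NullModelConfig, window: Window, gamma: float, seed) -> MarkedPattern:
    rng = _rng(config.seed if seed is None else seed)
    hard = gamma == 0.0
    name = "HARDCORE" if hard else "STRAUSS"
    rg2 = config.r_g * config.r_g
    if config.fixed_n:
        n = int(round(config.kappa * window.area))
        if n < 1:
            raise ParameterError("kappa * area rounds to zero points")
        # feasibility guard: disc packing cannot exceed ~0.9069 coverage
        packing = n * math.pi * rg2 / 4.0 / window.area
        if hard and packing > 0.9:
            raise ParameterError(
                f"{n} points at spacing {config.r_g} m cannot pack into the window "
                f"(packing fraction {packing:.2f})"
            )
        xs = rng.uniform(window.xmin, window.xmax, n)
        ys = rng.uniform(window.ymin, window.ymax, n)
        min_steps = 10 * n
        cap = max(_FIXED_N_CAP, min_steps)
        u_x = rng.uniform(size=cap)
        u_y = rng.uniform(size=cap)
        u_pick = rng.uniform(size=cap)
        u_acc = rng.uniform(size=cap)
        steps, viol = _gibbs_fixed_n(
            xs, ys, gamma, rg2, window.xmin, window.width, window.ymin, window.height,
            u_x, u_y, u_pick, u_acc, min_steps, hard,
        )
        if hard and viol > 0:
            raise ConvergenceError(
                f"hard-core chain still has {viol} close pairs after {steps} proposals"
            )
        return MarkedPattern(xs, ys, window, provenance=name)

    beta_area = config.kappa * window.area
    cap_points = int(4 * beta_area + 100)
    xs = np.empty(cap_points)
    ys = np.empty(cap_points)
    steps = max(_BD_STEPS, int(50 * beta_area))
    u_kind = rng.uniform(size=steps)
    u_x = rng.uniform(size=steps)
    u_y = rng.uniform(size=steps)
    u_pick = rng.uniform(size=steps)
    u_acc = rng.uniform(size=steps)
    n = _gibbs_birth_death(
        xs, ys, 0, beta_area, gamma, rg2,
        window.xmin, window.width, window.ymin, window.height,
        u_kind, u_x, u_y, u_pick, u_acc,
    )
    return MarkedPattern(xs[:n].copy(), ys[:n].copy(), window, provenance=name)


def simulate_hardcore(config: NullModelConfig, window: Window, seed=None) -> MarkedPattern:
    """Gibbs hard-core pattern: minimum pairwise distance >= ``r_g``."""
    if config.model != "HARDCORE":
        raise ParameterError(f"config is for {config.model}, not HARDCORE")
    return _simulate_gibbs(config, window, gamma=0.0, seed=seed)


def simulate_strauss(config: NullModelConfig, window: Window, seed=None) -> MarkedPattern:
    """Strauss pattern: close pairs penalised by ``p`` per violation."""
    if config.model != "STRAUSS":
        raise ParameterError(f"config is for {config.model}, not STRAUSS")
    return _simulate_gibbs(config, window, gamma=config.p, seed=seed)


# ---------------------------------------------------------------------------
# Crown-radius marks
# ---------------------------------------------------------------------------

def assign_crown_radii(pattern: MarkedPattern, dist: CrownDistribution,
                       seed=None) -> MarkedPattern:
    """Attach i.i.d. crown radii (random labelling); point order unchanged."""
    rng = _rng(seed)
    radii = dist.sample(pattern.n, rng)
    return MarkedPattern(
        pattern.x.copy(), pattern.y.copy(), pattern.window, radii=radii,
        provenance=pattern.provenance, ids=None if pattern.ids is None else pattern.ids.copy(),
        parents=pattern.parents, parent_index=pattern.parent_index,
    )


def fit_crown_gamma(radii) -> CrownDistribution:
    """Maximum-likelihood gamma fit (origin fixed at zero) to crown radii."""
    radii = np.asarray(radii, dtype=float)
    radii = radii[~np.isnan(radii)]
    if radii.size < 10:
        raise DataError(f"need at least 10 crown radii to fit, got {radii.size}")
    if np.any(radii <= 0):
        raise DataError("crown radii must all be positive")
    if np.ptp(radii) == 0:
        raise DataError("constant crown radii: gamma fit is degenerate")
    shape, _, scale = stats.gamma.fit(radii, floc=0.0)
    return CrownDistribution(kind="gamma", shape=float(shape), rate=float(1.0 / scale))


def estimate_intensity(pattern: MarkedPattern) -> float:
    """Point intensity per m²: count divided by window area."""
    if pattern.n == 0:
        warnings.warn("empty pattern: intensity estimate is 0", stacklevel=2)
        return 0.0
    return pattern.n / pattern.window.area
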