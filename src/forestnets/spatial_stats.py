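"""Second-order point-pattern statistics with Monte-Carlo envelopes.

Ripley's K, Besag's L and the pair correlation function g summarize how the
pair density of a pattern deviates from complete spatial randomness:
K(r) = pi r**2, L(r) = r and g(r) = 1 under CSR; g > 1 signals aggregation,
g < 1 regularity.

Estimators (for a rectangular window W with N points):

    K(r) = |W| / (N (N-1)) * sum_{i != j} e_ij * 1[d_ij <= r]
    g(r) = |W| / (2 pi r N (N-1)) * sum_{i != j} e_ij * k_h(r - d_ij)

with Ripley's isotropic edge correction ``e_ij`` (the reciprocal of the
fraction of the circle centred at i with radius d_ij lying inside W) by
default, the translation correction or no correction by flag, and an
Epanechnikov kernel ``k_h`` with Stoyan's bandwidth h = 0.15 / sqrt(lambda).

Envelopes are pointwise min–max bands of the statistic over ``n_sim``
simulations of a null model, the classical rank-1 Monte-Carlo acceptance
band for an observed curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError, ParameterError
from .point_process import MarkedPattern, NullModelConfig, Window, simulate

__all__ = [
    "RadialFunction", "EnvelopeResult", "default_r_grid",
    "ripley_k", "besag_l", "pcf", "mc_envelope", "null_envelope",
]


@dataclass
class RadialFunction:
    """A statistic evaluated on an ascending grid of distances (metres)."""

    r: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r.shape != self.values.shape:
            raise DataError("r grid and values must align")
        if self.r.size and np.any(np.diff(self.r) <= 0):
            raise DataError("r grid must be strictly ascending")


@dataclass
class EnvelopeResult:
    """Pointwise min–max simulation envelope plus the observed curve."""

    r: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    observed: Optional[RadialFunction]
    n_sim: int
    null_model: NullModelConfig
    statistic: str = "L"


def default_r_grid(window: Window, n: int = 513, include_zero: bool = True) -> np.ndarray:
    """513 distances from 0 to a quarter of the shorter window side."""
    r_max = 0.25 * min(window.width, window.height)
    grid = np.linspace(0.0, r_max, n)
    return grid if include_zero else grid[1:]


# ---------------------------------------------------------------------------
# edge corrections
# ---------------------------------------------------------------------------

def isotropic_weights(cx, cy, d, window: Window) -> np.ndarray:
    """Ripley isotropic correction: 1 / (fraction of the circle of radius d
    centred at (cx, cy) lying inside the window).

    Closed form for a rectangle via the two nearest borders and their shared
    corner; valid while the circle cannot reach an opposite border
    (d < min(width, height) / 2), which the default r grids guarantee.
    """
    cx = np.asarray(cx, float)
    cy = np.asarray(cy, float)
    d = np.asarray(d, float)
    d1 = np.minimum(cx - window.xmin, window.xmax - cx)  # nearest vertical side
    d2 = np.minimum(cy - window.ymin, window.ymax - cy)  # nearest horizontal side
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(d > d1, np.arccos(np.clip(d1 / d, -1.0, 1.0)), 0.0)
        a2 = np.where(d > d2, np.arccos(np.clip(d2 / d, -1.0, 1.0)), 0.0)
    corner = d * d > d1 * d1 + d2 * d2
    alpha = np.where(corner, 0.5 * np.pi + a1 + a2, 2.0 * a1 + 2.0 * a2)
    frac = 1.0 - alpha / (2.0 * np.pi)
    return 1.0 / frac


def translation_weights(dx, dy, window: Window) -> np.ndarray:
    """Translation correction: |W| over the area of W shifted by the pair vector."""
    wx = window.width - np.abs(np.asarray(dx, float))
    wy = window.height - np.abs(np.asarray(dy, float))
    if np.any(wx <= 0) or np.any(wy <= 0):
        raise ParameterError("pair separation exceeds the window size")
    return window.area / (wx * wy)


def _pair_data(pattern: MarkedPattern, r_max: float, correction: str):
    """Sorted pair distances and summed ordered-pair correction weights."""
    n = pattern.n
    if n < 2:
        raise DataError("need at least 2 points")
    tree = cKDTree(pattern.coords)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0), np.empty(0)
    i, j = pairs[:, 0], pairs[:, 1]
    dx = pattern.x[i] - pattern.x[j]
    dy = pattern.y[i] - pattern.y[j]
    d = np.hypot(dx, dy)
    if correction == "isotropic":
        w = (isotropic_weights(pattern.x[i], pattern.y[i], d, pattern.window)
             + isotropic_weights(pattern.x[j], pattern.y[j], d, pattern.window))
    elif correction == "translation":
        w = 2.0 * translation_weights(dx, dy, pattern.window)
    elif correction == "none":
        w = np.full(d.size, 2.0)
    else:
        raise ParameterError(f"unknown edge correction {correction!r}")
    order = np.argsort(d)
    return d[order], w[order]


def ripley_k(pattern: MarkedPattern, r=None, correction: str = "isotropic") -> RadialFunction:
    """Ripley's K function of a pattern on a grid of distances."""
    window = pattern.window
    r = default_r_grid(window) if r is None else np.asarray(r, dtype=float)
    r_max = float(r.max()) if r.size else 0.0
    if r_max > 0.25 * min(window.width, window.height) + 1e-9:
        warnings.warn(
            f"r extends to {r_max:.1f} m, beyond a quarter of the shorter window side; "
            "estimates there are unreliable", stacklevel=2)
    if r_max >= 0.5 * min(window.width, window.height):
        raise ParameterError("r grid must stay below half the shorter window side")
    d, w = _pair_data(pattern, r_max, correction)
    n = pattern.n
    if d.size == 0:
        return RadialFunction(r, np.zeros_like(r), label="K")
    cumw = np.concatenate([[0.0], np.cumsum(w)])
    idx = np.searchsorted(d, r, side="right")
    k = window.area / (n * (n - 1)) * cumw[idx]
    return RadialFunction(r, k, label="K")


def besag_l(k: RadialFunction, centered: bool = False) -> RadialFunction:
    """Besag's variance-stabilizing transform L(r) = sqrt(K(r) / pi).

    ``centered=True`` returns L(r) - r, which is 0 under CSR.
    """
    if np.any(k.values < -1e-12):
        raise DataError("K must be non-negative")
    vals = np.sqrt(np.maximum(k.values, 0.0) / np.pi)
    if centered:
        vals = vals - k.r
    return RadialFunction(k.r, vals, label="L-r" if centered else "L")


def stoyan_bandwidth(pattern: MarkedPattern) -> float:
    """Stoyan's rule of thumb h = 0.15 / sqrt(intensity)."""
    lam = pattern.n / pattern.window.area
    if lam <= 0:
        raise DataError("empty pattern")
    return 0.15 / np.sqrt(lam)


def pcf(pattern: MarkedPattern, r=None, bandwidth: Optional[float] = None,
        correction: str = "isotropic") -> RadialFunction:
    """Kernel estimate of the pair correlation function g(r).

    Epanechnikov kernel; the grid must exclude r = 0 (1/r divergence).
    """
    window = pattern.window
    r = default_r_grid(window, include_zero=False) if r is None \
        else np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("pcf grid must be strictly positive (g diverges at r=0)")
    h = stoyan_bandwidth(pattern) if bandwidth is None else float(bandwidth)
    if not h > 0:
        raise ParameterError("bandwidth must be positive")
    d, w = _pair_data(pattern, float(r.max()) + h, correction)
    n = pattern.n
    g = np.zeros_like(r)
    if d.size:
        lo = np.searchsorted(d, r - h, side="left")
        hi = np.searchsorted(d, r + h, side="right")
        for idx, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                u = (r[idx] - d[a:b]) / h
                g[idx] = np.sum(w[a:b] * 0.75 * (1.0 - u * u)) / h
    g *= window.area / (2.0 * np.pi * r * n * (n - 1))
    return RadialFunction(r, g, label="g")


# ---------------------------------------------------------------------------
# Monte-Carlo envelopes
# ---------------------------------------------------------------------------

def _statistic(pattern, stat: str, r, correction):
    if stat in ("L", "L-r"):
        k = ripley_k(pattern, r=r, correction=correction)
        return besag_l(k, centered=(stat == "L-r")).values
    if stat == "K":
        return ripley_k(pattern, r=r, correction=correction).values
    if stat in ("g", "G"):
        return pcf(pattern, r=r, correction=correction).values
    raise ParameterError(f"unknown statistic {stat!r}")


def null_envelope(null_config: NullModelConfig, window: Window, statistic: str = "L",
                  r=None, n_sim: int = 199, seed: int = 0,
                  correction: str = "isotropic") -> EnvelopeResult:
    """Pointwise min–max band of a statistic over ``n_sim`` null simulations.

    Replicate ``i`` draws from the stream keyed by ``(seed, i)``.
    """
    if n_sim < 1:
        raise ParameterError("n_sim must be at least 1")
    if r is None:
        r = default_r_grid(window, include_zero=statistic in ("K", "L", "L-r"))
    r = np.asarray(r, dtype=float)
    lo = np.full(r.shape, np.inf)
    hi = np.full(r.shape, -np.inf)
    for i in range(n_sim):
        pat = simulate(null_config, window, seed=np.random.default_rng([seed, i]))
        vals = _statistic(pat, statistic, r, correction)
        np.minimum(lo, vals, out=lo)
        np.maximum(hi, vals, out=hi)
    return EnvelopeResult(r, lo, hi, None, n_sim, null_config, statistic)


def mc_envelope(observed_pattern: MarkedPattern, null_config: NullModelConfig,
                statistic: str = "L", r=None, n_sim: int = 199, seed: int = 0,
                correction: str = "isotropic",
                estimate_intensity_from_observed: bool = False) -> EnvelopeResult:
    """Monte-Carlo envelope test: the observed curve against a null band.

    With ``estimate_intensity_from_observed`` the null model's ``kappa`` is
    replaced by the observed tree density before simulating.
    """
    cfg = null_config
    if estimate_intensity_from_observed:
        lam = observed_pattern.n / observed_pattern.window.area
        cfg = cfg.with_(kappa=lam)
    if r is None:
        r = default_r_grid(observed_pattern.window,
                           include_zero=statistic in ("K", "L", "L-r"))
    env = null_envelope(cfg, observed_pattern.window, statistic, r=r,
                        n_sim=n_sim, seed=seed, correction=correction)
    obs = RadialFunction(env.r, _statistic(observed_pattern, statistic, env.r, correction),
                         label=statistic)
    env.observed = obs
    return env
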