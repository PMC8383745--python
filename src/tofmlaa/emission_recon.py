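"""TOF MLEM/OSEM activity reconstruction with fixed attenuation.

The multiplicative update for Poisson TOF data with attenuation factors
``a = exp(-chi mu)`` (normalization folded in) and additive expectation
``s_t`` is

    lam <- lam / (H^T a) * sum_t H_t^T [ a y_t / (a H_t lam + s_t) ]

Because the TOF bin weights of the projector sum to one for every sample,
``sum_t H_t^T a`` equals the non-TOF backprojection ``H^T a`` exactly, and
the sensitivity image is computed that way.  With a full (non-subset)
update the Poisson log-likelihood is non-decreasing; ordered subsets
partition projection angles in bit-reversed interleaved order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .scanner_model import Projector, Sinogram, TOFSinogram

#: relative floor applied to the sensitivity denominator
SENS_FLOOR_REL = 1e-12


def loglikelihood(y_t: np.ndarray, ybar_t: np.ndarray) -> float:
    """Poisson log-likelihood sum_t (y_t log ybar_t - ybar_t), constant terms dropped.

    Bins with ``ybar = 0`` and ``y = 0`` contribute 0; a measured count in a
    bin with zero expectation makes the likelihood -inf.
    """
    y = np.asarray(y_t, dtype=np.float64)
    m = np.asarray(ybar_t, dtype=np.float64)
    if y.shape != m.shape:
        raise ValueError("data and expectation shapes differ")
    pos = m > 0
    if np.any(y[~pos] > 0):
        return -np.inf
    return float(np.sum(y[pos] * np.log(m[pos])) - m.sum())


def bit_reversed_order(n: int) -> np.ndarray:
    """Permutation of range(n) by bit-reversal (stable for non powers of two)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    bits = max(1, int(np.ceil(np.log2(n))))
    rev = []
    for i in range(2 ** bits):
        r = int(f"{i:0{bits}b}"[::-1], 2)
        if r < n:
            rev.append(r)
    return np.asarray(rev[:n], dtype=np.int64)


def angle_subsets(n_angles: int, n_subsets: int) -> List[np.ndarray]:
    """Interleaved angle partition, processed in bit-reversed subset order."""
    if not 1 <= n_subsets <= n_angles:
        raise ValueError("need 1 <= n_subsets <= n_angles")
    order = bit_reversed_order(n_subsets)
    return [np.arange(s, n_angles, n_subsets) for s in order]


@dataclass
class EmissionState:
    """Current activity estimate with its iteration count and likelihood trace."""

    lam: np.ndarray
    iteration: int = 0
    loglik: List[float] = field(default_factory=list)


def _as_values(x):
    if isinstance(x, (Sinogram, TOFSinogram)):
        return x.values
    return np.asarray(x, dtype=np.float64)


def mlem_update(state: EmissionState, y_t, a, s_t, projector: Projector,
                subset: Optional[np.ndarray] = None,
                fov_mask: Optional[np.ndarray] = None) -> EmissionState:
    """One multiplicative update (full data, or one angle subset).

    ``a`` holds attenuation factors with normalization folded in; voxels
    whose sensitivity vanishes inside the mask are left unchanged (with a
    warning) rather than divided by ~0.
    """
    yv = _as_values(y_t)
    av = _as_values(a)
    sv = _as_values(s_t) if s_t is not None else 0.0
    lam = state.lam
    if fov_mask is None:
        fov_mask = np.ones(lam.shape, dtype=bool)

    sens = projector.back(av, angle_subset=subset)
    floor = SENS_FLOOR_REL * max(sens.max(), 1e-300)
    dead = fov_mask & (sens <= floor)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} voxels with ~zero sensitivity masked out")

    fwd = projector.forward_tof(lam, angle_subset=subset)
    ybar = av[..., None] * fwd + sv
    ratio = np.zeros_like(ybar)
    pos = ybar > 0
    ratio[pos] = yv[pos] / ybar[pos]
    back = projector.back_tof(av[..., None] * ratio, angle_subset=subset)

    new = lam.copy()
    ok = fov_mask & (sens > floor)
    new[ok] = lam[ok] * back[ok] / sens[ok]
    new[~fov_mask] = 0.0
    return EmissionState(lam=new, iteration=state.iteration + 1, loglik=list(state.loglik))


def osem(y_t, a, s_t, projector: Projector, n_iter: int, n_subsets: int = 1,
         fov_mask: Optional[np.ndarray] = None, init: Optional[np.ndarray] = None,
         track_loglik: bool = False) -> EmissionState:
    """Run ``n_iter`` full iterations of OSEM (MLEM when ``n_subsets == 1``).

    The initial estimate defaults to one inside the mask and zero outside.
    When ``track_loglik`` is set, the TOF log-likelihood of the current
    estimate is appended after every full iteration.
    """
    yv = _as_values(y_t)
    av = _as_values(a)
    sv = _as_values(s_t) if s_t is not None else np.zeros_like(yv)
    n_angles = projector.geometry.n_angles
    subsets = angle_subsets(n_angles, n_subsets)
    if fov_mask is None:
        rr = projector.grid.radius_map()
        fov_mask = rr <= projector.geometry.fov_radius
    if init is None:
        lam0 = np.where(fov_mask, 1.0, 0.0)
    else:
        lam0 = np.asarray(init, dtype=np.float64).copy()
        if np.any(lam0 < 0):
            raise ValueError("initial activity must be nonnegative")
    state = EmissionState(lam=lam0)
    for _ in range(n_iter):
        for sub in subsets:
            state = mlem_update(state, yv, av, sv, projector, subset=sub, fov_mask=fov_mask)
        if track_loglik:
            ybar = av[..., None] * projector.forward_tof(state.lam) + sv
            state.loglik.append(loglikelihood(yv, ybar))
    return state
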