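"""Attenuation reconstruction from non-TOF sinograms: XMLTR and MLTR.

With activity projection ``p = H lam`` (normalization folded in), current
line integrals ``q = chi mu``, ``b = p exp(-q)`` and expectation
``ybar = b + s``, the additive updates are

    XMLTR:  mu <- mu + chi^T[ b (1 - y/ybar) ] / chi^T[ b (1 - y s / ybar^2) chi1 ]
    MLTR:   mu <- mu + chi^T[ b (1 - y/ybar) ] / chi^T[ b^2 / ybar chi1 ]

where ``chi1`` is the forward projection of the all-ones image restricted
to the attenuation support.  The two denominators coincide when ``s = 0``
and are numerically similar once ``y ~ ybar``.  The update is followed by
a nonnegativity clamp, and attenuation is only estimated inside the object
support (outside voxels are pinned to zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .emission_recon import angle_subsets
from .scanner_model import Projector, Sinogram


@dataclass
class TransmissionState:
    """Current attenuation estimate and iteration count."""

    mu: np.ndarray
    iteration: int = 0


def _as_values(x):
    if isinstance(x, Sinogram):
        return x.values
    return np.asarray(x, dtype=np.float64)


def _one_update(mu: np.ndarray, y, s, p, projector: Projector, support: np.ndarray,
                method: str, subset: Optional[np.ndarray], damping: float,
                chi1: Optional[np.ndarray] = None) -> np.ndarray:
    yv, sv, pv = _as_values(y), _as_values(s), _as_values(p)
    if np.any(pv < 0) or np.any(sv < 0):
        raise ValueError("activity projection and additive term must be nonnegative")
    if np.any(mu < 0):
        raise ValueError("attenuation estimate must be nonnegative")

    q = projector.forward(mu, angle_subset=subset)
    b = pv * np.exp(-q)
    ybar = b + sv
    pos = ybar > 0
    frac = np.zeros_like(ybar)
    frac[pos] = yv[pos] / ybar[pos]
    num_sino = b * (1.0 - frac)

    if chi1 is None:
        chi1 = projector.forward(support.astype(np.float64), angle_subset=subset)
    if method == "xmltr":
        w = np.zeros_like(ybar)
        w[pos] = yv[pos] * sv[pos] / ybar[pos] ** 2
        den_sino = b * (1.0 - w) * chi1
    elif method == "mltr":
        # written as b * (b/ybar) so that s = 0 reproduces the exact
        # scatter-free denominator b * chi1 bit-for-bit
        d = np.zeros_like(ybar)
        d[pos] = b[pos] / ybar[pos]
        den_sino = b * d * chi1
    else:
        raise ValueError(f"unknown transmission update method {method!r}")

    num = projector.back(num_sino, angle_subset=subset)
    den = projector.back(den_sino, angle_subset=subset)

    ok = support & (den > 0)
    skipped = support & ~ok & (num != 0)
    if skipped.any():
        warnings.warn(f"non-positive curvature in {int(skipped.sum())} voxels; update skipped there")
    new = mu.copy()
    new[ok] = mu[ok] + damping * num[ok] / den[ok]
    np.clip(new, 0.0, None, out=new)
    new[~support] = 0.0
    return new


def xmltr_update(state: TransmissionState, y, s, p, projector: Projector,
                 support: np.ndarray, subset: Optional[np.ndarray] = None,
                 damping: float = 1.0, chi1: Optional[np.ndarray] = None) -> TransmissionState:
    """One XMLTR update (exact scatter-dependent denominator)."""
    mu = _one_update(state.mu, y, s, p, projector, support, "xmltr", subset, damping, chi1)
    return TransmissionState(mu=mu, iteration=state.iteration + 1)


def mltr_update(state: TransmissionState, y, s, p, projector: Projector,
                support: np.ndarray, subset: Optional[np.ndarray] = None,
                damping: float = 1.0, chi1: Optional[np.ndarray] = None) -> TransmissionState:
    """One classic MLTR update (squared-projection denominator)."""
    mu = _one_update(state.mu, y, s, p, projector, support, "mltr", subset, damping, chi1)
    return TransmissionState(mu=mu, iteration=state.iteration + 1)


def transmission_recon(y, s, p, projector: Projector, support: np.ndarray,
                       n_iter: int = 1, n_subsets: int = 8, method: str = "xmltr",
                       damping: float = 1.0, init: Optional[np.ndarray] = None) -> TransmissionState:
    """Run ``n_iter`` full iterations of subsetted XMLTR/MLTR from ``init`` (default 0)."""
    subsets = angle_subsets(projector.geometry.n_angles, n_subsets)
    mu0 = np.zeros(projector.grid.shape) if init is None else np.asarray(init, dtype=np.float64).copy()
    state = TransmissionState(mu=mu0)
    sup_img = support.astype(np.float64)
    chi1_cache = [projector.forward(sup_img, angle_subset=sub) for sub in subsets]
    for _ in range(n_iter):
        for sub, chi1 in zip(subsets, chi1_cache):
            state = _update_dispatch(state, y, s, p, projector, support, sub, damping, chi1, method)
    return state


def _update_dispatch(state, y, s, p, projector, support, sub, damping, chi1, method):
    if method == "xmltr":
        return xmltr_update(state, y, s, p, projector, support, sub, damping, chi1)
    return mltr_update(state, y, s, p, projector, support, sub, damping, chi1)
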