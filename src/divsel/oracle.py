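"""Deterministic single-locus expectation model.

Infinite-population recursion matching the simulator's reproduction scheme
at one selected locus: selection steps follow p' = p(1+s)/(1+ps) in X
(Y stays neutral) and migration generations mix the two frequencies
symmetrically on the same schedule as the stochastic simulator.  Used to
quantify drift and to validate the simulator and the summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from divsel.simulator import FixedParams
from divsel.sumstats import fst_per_locus, sign_fst_per_locus

__all__ = [
    "DetTrajectory",
    "det_step_selection",
    "det_step_migration",
    "det_trajectory",
    "det_final_frequency",
]


def det_step_selection(p, s):
    """One generation of selection in the infinite-population limit.

    ``p' = p(1+s) / (1 + p s)``; 0 and 1 are fixed points.  Accepts scalars
    or arrays (broadcast elementwise).
    """
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    denom = 1.0 + p * s
    if np.any(denom <= 0):
        raise ValueError("1 + p*s must be positive")
    out = p * (1.0 + s) / denom
    return float(out) if out.ndim == 0 else out


def det_step_migration(pX, pY, m):
    """Symmetric migration mixing: preserves the mean frequency."""
    pX = np.asarray(pX, dtype=float)
    pY = np.asarray(pY, dtype=float)
    if np.any(np.asarray(m) < 0) or np.any(np.asarray(m) >= 1):
        raise ValueError("m must be in [0, 1)")
    nX = (1.0 - m) * pX + m * pY
    nY = (1.0 - m) * pY + m * pX
    if nX.ndim == 0:
        return float(nX), float(nY)
    return nX, nY


@dataclass
class DetTrajectory:
    """Deterministic frequency trajectories over t = 0 .. t_final."""

    pX: np.ndarray
    pY: np.ndarray
    s: float
    m: float
    t_star: int
    n_cycles: int
    p0: float

    @property
    def t_final(self) -> int:
        return self.pX.size - 1

    def final_stats(self) -> dict[str, float]:
        """Deterministic FST, signFST and pX - pY at the final generation."""
        pX = np.array([self.pX[-1]])
        pY = np.array([self.pY[-1]])
        return {
            "FST": float(fst_per_locus(pX, pY)[0]),
            "signFST": float(sign_fst_per_locus(pX, pY)[0]),
            "pdiff": float(pX[0] - pY[0]),
        }


def det_trajectory(
    p0: float, s: float, m: float, fixed: FixedParams
) -> DetTrajectory:
    """Deterministic trajectory on the simulator's schedule.

    Selection acts on pX (pY unchanged) at every generation not divisible
    by ``t_star``; migration mixing acts at generations ``c * t_star``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    t_final = fixed.t_final
    pX = np.empty(t_final + 1)
    pY = np.empty(t_final + 1)
    pX[0] = pY[0] = p0
    for t in range(1, t_final + 1):
        if t % fixed.t_star == 0:
            pX[t], pY[t] = det_step_migration(pX[t - 1], pY[t - 1], m)
        else:
            pX[t] = det_step_selection(pX[t - 1], s)
            pY[t] = pY[t - 1]
    return DetTrajectory(
        pX=pX, pY=pY, s=s, m=m, t_star=fixed.t_star,
        n_cycles=fixed.n_cycles, p0=p0,
    )


def det_final_frequency(s, m, fixed: FixedParams, p0: float = 0.5):
    """Vectorized final-generation (pX, pY) for arrays of s and m."""
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    pX = np.broadcast_to(np.asarray(p0, dtype=float), np.broadcast_shapes(s.shape, m.shape)).copy()
    pY = pX.copy()
    for t in range(1, fixed.t_final + 1):
        if t % fixed.t_star == 0:
            pX, pY = det_step_migration(pX, pY, m)
        else:
            pX = det_step_selection(pX, s)
    return pX, pY
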