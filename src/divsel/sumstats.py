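"""Per-locus summary statistics and the FST outlier scan.

Implements two-population FST with its signed variant, the allele-frequency
difference pX - pY, extended haplotype homozygosity (EHH) profiles and the
cross-population XP-EHH log-ratio, plus the empirical 95%-quantile FST
outlier scan used to shortlist candidate loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from divsel.simulator import PopulationPair

__all__ = [
    "STAT_ORDER",
    "SummaryVector",
    "OutlierSet",
    "allele_freq",
    "fst_per_locus",
    "sign_fst_per_locus",
    "ehh_profile",
    "xp_ehh",
    "fst_outlier_scan",
    "summarize",
]

#: Fixed concatenation order for ABC distance vectors.
STAT_ORDER = ("signFST", "pdiff", "FST", "XPEHH")

#: Default EHH cutoff defining the XP-EHH integration domain.
XPEHH_CUTOFF = 0.05


def allele_freq(pop: np.ndarray) -> np.ndarray:
    """Frequency of allele 1 at each locus (column means)."""
    return np.asarray(pop, dtype=float).mean(axis=0)


def fst_per_locus(pX: np.ndarray, pY: np.ndarray) -> np.ndarray:
    """Two-population FST per locus.

    ``FST = sigma_p^2 / (pbar * (1 - pbar))`` with the two-population
    (divisor-2) variance ``sigma_p^2 = (pX - pY)^2 / 4``.  Monomorphic loci
    (``pbar`` of 0 or 1) return 0.  Values lie in [0, 1].
    """
    pX = np.asarray(pX, dtype=float)
    pY = np.asarray(pY, dtype=float)
    pbar = (pX + pY) / 2.0
    denom = pbar * (1.0 - pbar)
    num = (pX - pY) ** 2 / 4.0
    out = np.zeros_like(pbar)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, 0.0, 1.0)


def sign_fst_per_locus(pX: np.ndarray, pY: np.ndarray) -> np.ndarray:
    """FST carrying the sign of pX - pY; range [-1, 1]."""
    fst = fst_per_locus(pX, pY)
    return np.where(np.asarray(pX) < np.asarray(pY), -fst, fst)


def ehh_profile(pop: np.ndarray, core_locus: int) -> np.ndarray:
    """EHH of ``core_locus`` (1-based) at distances v = 0 .. L-1.

    At distance v, haplotypes are grouped by their allele string over the
    two-sided window [core - v, core + v] clipped to the chromosome; with
    group sizes ``n_z`` and core-allele counts ``n0``, ``n1``,
    ``EHH(v) = sum_z n_z^2 / (n0^2 + n1^2)``.  EHH(0) = 1 exactly and the
    profile is non-increasing in v.
    """
    pop = np.asarray(pop)
    Ne, L = pop.shape
    if not 1 <= core_locus <= L:
        raise ValueError(f"core_locus must be in [1, {L}], got {core_locus}")
    c = core_locus - 1
    core = pop[:, c].astype(np.int64)
    n1 = int(core.sum())
    n0 = Ne - n1
    denom = float(n0 * n0 + n1 * n1)
    ehh = np.empty(L, dtype=float)
    ehh[0] = 1.0
    codes = core
    for v in range(1, L):
        lo, hi = c - v, c + v
        key = codes
        if lo >= 0:
            key = key * 2 + pop[:, lo]
        if hi <= L - 1:
            key = key * 2 + pop[:, hi]
        _, codes = np.unique(key, return_inverse=True)
        counts = np.bincount(codes).astype(float)
        ehh[v] = float((counts * counts).sum()) / denom
    return ehh


def xp_ehh(
    popX: np.ndarray, popY: np.ndarray, cutoff: float = XPEHH_CUTOFF
) -> np.ndarray:
    """Cross-population XP-EHH per core locus.

    EHH values below ``cutoff`` are zeroed in both profiles before a
    unit-step rectangle integration over v; the statistic is the log of the
    ratio of the two integrals.  The v = 0 term equals 1 in both
    populations, so both integrals are >= 1 and the log is finite.
    """
    popX = np.asarray(popX)
    popY = np.asarray(popY)
    if popX.shape[1] != popY.shape[1]:
        raise ValueError("populations must have the same number of loci")
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    L = popX.shape[1]
    out = np.empty(L, dtype=float)
    for core in range(1, L + 1):
        ex = ehh_profile(popX, core)
        ey = ehh_profile(popY, core)
        ex = np.where(ex < cutoff, 0.0, ex)
        ey = np.where(ey < cutoff, 0.0, ey)
        out[core - 1] = np.log(ex.sum() / ey.sum())
    return out


@dataclass(frozen=True)
class OutlierSet:
    """Result of the FST outlier scan."""

    loci: tuple[int, ...]
    cutoff_value: float


def fst_outlier_scan(fst_vector: np.ndarray, quantile: float = 0.95) -> OutlierSet:
    """Loci whose FST lies strictly above the empirical ``quantile``.

    The cutoff is the linearly interpolated empirical quantile; membership
    requires a strictly larger FST, so a constant vector yields an empty
    set.  Returned loci are 1-based.
    """
    fst_vector = np.asarray(fst_vector, dtype=float)
    cutoff = float(np.quantile(fst_vector, quantile))
    loci = tuple(int(i) + 1 for i in np.nonzero(fst_vector > cutoff)[0])
    return OutlierSet(loci=loci, cutoff_value=cutoff)


@dataclass
class SummaryVector:
    """Per-locus summary statistics for one dataset.

    Only the requested statistics are populated; ``stat_names`` records
    which, in the fixed concatenation order of :data:`STAT_ORDER`.
    """

    L: int
    stat_names: tuple[str, ...]
    fst: np.ndarray | None = None
    sign_fst: np.ndarray | None = None
    pdiff: np.ndarray | None = None
    xp_ehh: np.ndarray | None = None

    _BY_NAME = {
        "signFST": "sign_fst",
        "pdiff": "pdiff",
        "FST": "fst",
        "XPEHH": "xp_ehh",
    }

    def get(self, name: str) -> np.ndarray:
        vec = getattr(self, self._BY_NAME[name])
        if vec is None:
            raise KeyError(f"statistic {name!r} was not computed")
        return vec

    def vector(self, loci: Iterable[int] | None = None) -> np.ndarray:
        """Concatenated statistics, optionally restricted to 1-based loci."""
        idx = None if loci is None else np.asarray(list(loci), dtype=int) - 1
        parts = []
        for name in self.stat_names:
            vec = self.get(name)
            parts.append(vec if idx is None else vec[idx])
        return np.concatenate(parts) if parts else np.empty(0)


def summarize(
    pair: PopulationPair,
    stat_set: Iterable[str] = ("signFST",),
    xpehh_cutoff: float = XPEHH_CUTOFF,
) -> SummaryVector:
    """Compute the requested per-locus statistics for a population pair."""
    requested = set(stat_set)
    unknown = requested - set(STAT_ORDER)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    if not requested:
        raise ValueError("stat_set must be nonempty")
    names = tuple(n for n in STAT_ORDER if n in requested)
    pX = allele_freq(pair.X)
    pY = allele_freq(pair.Y)
    sv = SummaryVector(L=pair.L, stat_names=names)
    if "FST" in requested:
        sv.fst = fst_per_locus(pX, pY)
    if "signFST" in requested:
        sv.sign_fst = sign_fst_per_locus(pX, pY)
    if "pdiff" in requested:
        sv.pdiff = pX - pY
    if "XPEHH" in requested:
        sv.xp_ehh = xp_ehh(pair.X, pair.Y, cutoff=xpehh_cutoff)
    return sv
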