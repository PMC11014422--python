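"""Forward-in-time simulation of two populations under divergent selection.

Each population is a haploid binary haplotype matrix of shape (Ne, L).
Evolution proceeds in migration-selection cycles of ``t_star`` generations:
``t_star - 1`` generations of isolated, fitness-weighted asexual
reproduction, then one generation of symmetric migration followed by
fitness-free (sexual or asexual) reproduction.  The run ends at
``t_final = n_cycles * t_star - 1``, i.e. just before the migration that
would start the next cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FixedParams",
    "DrawnParams",
    "PopulationPair",
    "found_populations",
    "sample_crossover_count",
    "sample_crossovers",
    "recombine_offspring",
    "fitness_vector",
    "reproduction_probabilities",
    "selection_generation",
    "migrate_swap",
    "migration_generation",
    "migration_times",
    "run_simulation",
]


@dataclass(frozen=True)
class FixedParams:
    """Fixed, known parameters of the model.

    Parameters
    ----------
    r : float
        Recombination rate in Morgans per bp per generation, ``0 < r < 1``.
    t_star : int
        Generations per migration-selection cycle (>= 2).
    n_cycles : int
        Number of cycles (>= 1).
    Ne : int
        Effective (census) population size per population (>= 2).
    L : int
        Number of SNPs (>= 2).
    snp_spacing : int
        Base pairs between adjacent SNPs (>= 1).
    """

    r: float
    t_star: int
    n_cycles: int
    Ne: int
    L: int
    snp_spacing: int

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError(f"r must be in (0, 1), got {self.r}")
        if self.t_star < 2:
            raise ValueError(f"t_star must be >= 2, got {self.t_star}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.Ne < 2:
            raise ValueError(f"Ne must be >= 2, got {self.Ne}")
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if self.snp_spacing < 1:
            raise ValueError(f"snp_spacing must be >= 1, got {self.snp_spacing}")

    @property
    def t_final(self) -> int:
        """Final generation index: ``n_cycles * t_star - 1``."""
        return self.n_cycles * self.t_star - 1

    @property
    def genome_length(self) -> int:
        """Total simulated genome length in bp, ``L * snp_spacing``."""
        return self.L * self.snp_spacing

    @property
    def expected_crossovers(self) -> float:
        """Mean of the binomial crossover count, ``(L*snp_spacing - 1) * r``."""
        return (self.genome_length - 1) * self.r


@dataclass(frozen=True)
class DrawnParams:
    """One joint draw of the unknown parameters.

    ``sel_loci`` are 1-based SNP indices (0, 1 or 2 of them); ``sel_coeffs``
    are the aligned signed selection coefficients acting in population X;
    ``sel_alleles`` gives the favoured/disfavoured reference allele at each
    selected locus (allele 1 by convention).  ``m`` is the symmetric
    migration rate applied at migration generations and ``sex`` the mode of
    reproduction at those generations (0 = asexual cloning, 1 = sexual with
    recombination).
    """

    sel_loci: tuple[int, ...] = ()
    sel_coeffs: tuple[float, ...] = ()
    sel_alleles: tuple[int, ...] = ()
    m: float = 0.0
    sex: int = 0

    def __post_init__(self) -> None:
        loci = tuple(int(i) for i in self.sel_loci)
        coeffs = tuple(float(s) for s in self.sel_coeffs)
        alleles = tuple(int(a) for a in self.sel_alleles)
        if not alleles:
            alleles = (1,) * len(loci)
        object.__setattr__(self, "sel_loci", loci)
        object.__setattr__(self, "sel_coeffs", coeffs)
        object.__setattr__(self, "sel_alleles", alleles)
        if len(loci) != len(coeffs) or len(loci) != len(alleles):
            raise ValueError("sel_loci, sel_coeffs and sel_alleles must align")
        if len(set(loci)) != len(loci):
            raise ValueError("sel_loci must be distinct")
        if any(i < 1 for i in loci):
            raise ValueError("sel_loci are 1-based, must be >= 1")
        if any(a not in (0, 1) for a in alleles):
            raise ValueError("sel_alleles must be 0 or 1")
        if not 0.0 <= self.m < 1.0:
            raise ValueError(f"m must be in [0, 1), got {self.m}")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")

    @property
    def n_selected(self) -> int:
        return len(self.sel_loci)


@dataclass
class PopulationPair:
    """State of the two evolving populations at generation ``t``."""

    X: np.ndarray
    Y: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.Y = np.asarray(self.Y, dtype=np.uint8)
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have identical shape")
        if self.X.ndim != 2:
            raise ValueError("population matrices must be 2-D (Ne, L)")

    @property
    def Ne(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# Recombination
# ---------------------------------------------------------------------------

def sample_crossover_count(fixed: FixedParams, rng: np.random.Generator) -> int:
    """Draw the raw crossover count ``Binomial(L*snp_spacing - 1, r)``."""
    return int(rng.binomial(fixed.genome_length - 1, fixed.r))


def sample_crossovers(fixed: FixedParams, rng: np.random.Generator) -> np.ndarray:
    """Sample crossover breakpoints for a single offspring.

    The number of crossovers is ``Binomial(L*snp_spacing - 1, r)``; bp
    positions are uniform on ``[1, L*snp_spacing - 1]`` and mapped to the
    SNP interval ``k = ceil(pos / snp_spacing)`` clipped to ``[1, L-1]``.
    A breakpoint ``k`` means the parent switch occurs between SNP ``k`` and
    SNP ``k+1`` (1-based).  Duplicate intervals collapse to a single switch.

    Returns a sorted array of unique SNP-interval breakpoints.
    """
    n_r = sample_crossover_count(fixed, rng)
    if n_r == 0:
        return np.empty(0, dtype=np.int64)
    pos = rng.integers(1, fixed.genome_length - 1, size=n_r, endpoint=True)
    k = np.clip(-(-pos // fixed.snp_spacing), 1, fixed.L - 1)
    return np.unique(k)


def _apply_breakpoints(
    p1: np.ndarray, p2: np.ndarray, breakpoints: Sequence[int]
) -> np.ndarray:
    """Copy from p1, switching parents after each breakpoint (no role swap)."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    L = p1.shape[-1]
    bps = np.asarray(breakpoints, dtype=np.int64)
    if bps.size and (bps.min() < 1 or bps.max() > L - 1):
        raise ValueError("breakpoints must lie in [1, L-1]")
    which = np.zeros(L, dtype=np.int64)
    which[bps] = 1  # switch takes effect from SNP k+1 (0-based column k)
    which = np.cumsum(which) % 2
    return np.where(which == 0, p1, p2).astype(np.uint8)


def recombine_offspring(
    p1: np.ndarray,
    p2: np.ndarray,
    breakpoints: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine two parental genomes into one offspring genome.

    With probability 0.5 the parental roles are swapped; the offspring then
    starts on the (possibly swapped) first parent and alternates at each
    breakpoint.
    """
    if rng.random() < 0.5:
        p1, p2 = p2, p1
    return _apply_breakpoints(p1, p2, breakpoints)


def _recombine_batch(
    P1: np.ndarray,
    P2: np.ndarray,
    fixed: FixedParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized recombination of n parental pairs (rows of P1 with P2).

    Statistically identical to n calls of ``sample_crossovers`` +
    ``recombine_offspring`` but consumes the random stream in batch order.
    """
    n, L = P1.shape
    swap = rng.random(n) < 0.5
    A = np.where(swap[:, None], P2, P1)
    B = np.where(swap[:, None], P1, P2)
    n_r = rng.binomial(fixed.genome_length - 1, fixed.r, size=n)
    total = int(n_r.sum())
    if total == 0:
        return A.astype(np.uint8)
    rows = np.repeat(np.arange(n), n_r)
    pos = rng.integers(1, fixed.genome_length - 1, size=total, endpoint=True)
    k = np.clip(-(-pos // fixed.snp_spacing), 1, L - 1)
    keys = np.unique(rows * L + k)  # dedup: one switch per (offspring, interval)
    flips = np.zeros((n, L), dtype=np.int8)
    flips[keys // L, keys % L] = 1
    which = np.cumsum(flips, axis=1) % 2
    return np.where(which == 0, A, B).astype(np.uint8)


# ---------------------------------------------------------------------------
# Founding
# ---------------------------------------------------------------------------

def found_populations(
    fixed: FixedParams,
    rng: np.random.Generator,
    shared_ancestry: bool = False,
) -> PopulationPair:
    """Found the two F2 populations at generation t = 0.

    F1 pools X and Y each consist of Ne constant haplotypes (all-0 or all-1,
    probability 0.5 per carrier).  Each F2 offspring recombines one
    uniformly chosen parent from the X F1 pool with one from the Y F1 pool.

    With ``shared_ancestry=True`` a single F2 pool of 2*Ne offspring is
    built and split in half between X and Y (the lab-protocol variant);
    the default builds the two F2 populations independently.
    """
    Ne, L = fixed.Ne, fixed.L
    f1_x = np.repeat(rng.integers(0, 2, size=Ne).astype(np.uint8)[:, None], L, axis=1)
    f1_y = np.repeat(rng.integers(0, 2, size=Ne).astype(np.uint8)[:, None], L, axis=1)

    def _f2(n: int) -> np.ndarray:
        i = rng.integers(0, Ne, size=n)
        j = rng.integers(0, Ne, size=n)
        return _recombine_batch(f1_x[i], f1_y[j], fixed, rng)

    if shared_ancestry:
        pool = _f2(2 * Ne)
        X, Y = pool[:Ne], pool[Ne:]
    else:
        X = _f2(Ne)
        Y = _f2(Ne)
    return PopulationPair(X=X, Y=Y, t=0)


# ---------------------------------------------------------------------------
# Reproduction
# ---------------------------------------------------------------------------

def fitness_vector(
    pop: np.ndarray, drawn: DrawnParams, which: str
) -> np.ndarray:
    """Additive absolute fitness of each carrier in population ``which``.

    In X each selected locus contributes ``1 + s_i`` to carriers of the
    selected allele and ``1`` otherwise; in Y selection never acts, so every
    selected locus contributes ``1``.  With no selected loci the empty sum
    is replaced by a constant fitness of 1 (normalization makes the
    constant irrelevant).
    """
    if which not in ("X", "Y"):
        raise ValueError(f"which must be 'X' or 'Y', got {which!r}")
    pop = np.asarray(pop)
    n = pop.shape[0]
    k = drawn.n_selected
    if k == 0 or which == "Y":
        return np.full(n, float(max(k, 1)))
    omega = np.full(n, float(k))
    for locus, s, allele in zip(drawn.sel_loci, drawn.sel_coeffs, drawn.sel_alleles):
        omega += (pop[:, locus - 1] == allele) * s
    return omega


def reproduction_probabilities(omega: np.ndarray) -> np.ndarray:
    """Normalize fitnesses to offspring probabilities (sum to 1)."""
    omega = np.asarray(omega, dtype=float)
    total = omega.sum()
    if total <= 0:
        raise ValueError("total fitness must be positive")
    return omega / total


def selection_generation(
    pop: np.ndarray,
    drawn: DrawnParams,
    which: str,
    fixed: FixedParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation of fitness-weighted asexual reproduction.

    Offspring counts are ``Multinomial(Ne, p)`` with p the normalized
    fitnesses; each offspring is a clonal copy of its parent.
    """
    pop = np.asarray(pop, dtype=np.uint8)
    Ne = pop.shape[0]
    p = reproduction_probabilities(fitness_vector(pop, drawn, which))
    counts = rng.multinomial(Ne, p)
    return np.repeat(pop, counts, axis=0)


def migrate_swap(
    pair: PopulationPair, m: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap ``round(Ne*m)`` uniformly chosen carriers between X and Y.

    The migrant sets in the two directions are drawn independently without
    replacement; population sizes are conserved.  Returns the
    post-migration matrices before reproduction.
    """
    Ne = pair.Ne
    n_mig = int(np.rint(Ne * m))
    if n_mig >= Ne:
        raise ValueError("round(Ne*m) must be < Ne")
    X, Y = pair.X.copy(), pair.Y.copy()
    if n_mig > 0:
        ix = rng.choice(Ne, size=n_mig, replace=False)
        iy = rng.choice(Ne, size=n_mig, replace=False)
        X[ix], Y[iy] = pair.Y[iy], pair.X[ix]
    return X, Y


def migration_generation(
    pair: PopulationPair,
    drawn: DrawnParams,
    fixed: FixedParams,
    rng: np.random.Generator,
) -> PopulationPair:
    """Symmetric migration followed by fitness-free reproduction.

    ``round(Ne*m)`` uniformly chosen carriers (drawn independently in each
    direction, without replacement) are swapped between X and Y; each
    post-migration population then produces Ne offspring by uniform cloning
    (sex=0) or by recombining two uniformly chosen parents (sex=1).
    """
    Ne = pair.Ne
    X, Y = migrate_swap(pair, drawn.m, rng)

    def _reproduce(pop: np.ndarray) -> np.ndarray:
        if drawn.sex == 0:
            return pop[rng.integers(0, Ne, size=Ne)]
        i = rng.integers(0, Ne, size=Ne)
        j = rng.integers(0, Ne, size=Ne)
        return _recombine_batch(pop[i], pop[j], fixed, rng)

    return PopulationPair(X=_reproduce(X), Y=_reproduce(Y), t=pair.t + 1)


def migration_times(fixed: FixedParams) -> list[int]:
    """Generations at which migration occurs: t_star, 2*t_star, ...

    The run halts at ``t_final = n_cycles*t_star - 1`` before the final
    migration, so there are ``n_cycles - 1`` migration events.
    """
    return [c * fixed.t_star for c in range(1, fixed.n_cycles)]


def run_simulation(
    fixed: FixedParams,
    drawn: DrawnParams,
    rng: np.random.Generator,
    shared_ancestry: bool = False,
    on_generation: Callable[[PopulationPair], None] | None = None,
) -> PopulationPair:
    """Run the full migration-selection cycle schedule to ``t_final``.

    Selection (on X; neutral resampling on Y) acts at every generation not
    divisible by ``t_star``; migration plus fitness-free reproduction acts
    at generations ``c * t_star``.  ``on_generation`` is called with the
    state after every generation (including t = 0).
    """
    if drawn.sel_loci and max(drawn.sel_loci) > fixed.L:
        raise ValueError("sel_loci must lie in [1, L]")
    pair = found_populations(fixed, rng, shared_ancestry=shared_ancestry)
    if on_generation is not None:
        on_generation(pair)
    for t in range(1, fixed.t_final + 1):
        if t % fixed.t_star == 0:
            pair = migration_generation(pair, drawn, fixed, rng)
        else:
            X = selection_generation(pair.X, drawn, "X", fixed, rng)
            Y = selection_generation(pair.Y, drawn, "Y", fixed, rng)
            pair = PopulationPair(X=X, Y=Y, t=t)
        if on_generation is not None:
            on_generation(pair)
    return pair
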