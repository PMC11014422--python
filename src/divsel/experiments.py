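"""Priors, scenario definitions, inference methods and evaluation.

Two inference methods are provided.  Method 1 fixes the admissible selected
loci to {L/3, L/2, 2L/3} and re-uses one shared reference table for all ABC
iterations.  Method 2 lets the true loci fall anywhere on the genome, runs
an FST outlier scan on each pseudo-observed dataset, and builds a fresh
reference table whose selected loci are restricted to the outlier set.
Evaluation bins posterior-median errors and decomposes mean squared error
into variance plus squared bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from divsel.abc import (
    ReferenceTable,
    abc_rejection,
    regression_adjust,
)
from divsel.oracle import det_final_frequency
from divsel.simulator import DrawnParams, FixedParams, run_simulation
from divsel.sumstats import (
    SummaryVector,
    fst_outlier_scan,
    fst_per_locus,
    sign_fst_per_locus,
    summarize,
)

__all__ = [
    "PriorSpec",
    "ScenarioSpec",
    "EvalReport",
    "candidate_loci_for",
    "scenario",
    "sample_prior",
    "build_reference_table",
    "run_method1",
    "run_method2",
    "evaluate",
    "single_locus_assessment",
]

#: (m, sex) combinations used in the experiments: asexual only without
#: migration; sexual reproduction with m of 0, 0.2 or 0.5.
DEFAULT_M_SEX_PAIRS = ((0.0, 0), (0.0, 1), (0.2, 1), (0.5, 1))


@dataclass(frozen=True)
class PriorSpec:
    """Joint prior over selected loci, coefficients, migration and sex.

    ``combo_mode`` controls the locus draw: ``"uniform_subsets"`` draws
    uniformly over all subsets of ``candidate_loci`` of size 0..max_loci
    (seven combinations for three candidates); ``"uniform_count"`` first
    draws the number of selected loci uniformly on {0..max_loci} (clipped
    to the candidate set size), then positions without replacement.
    """

    s_bound: float
    candidate_loci: tuple[int, ...]
    m_sex_pairs: tuple[tuple[float, int], ...] = DEFAULT_M_SEX_PAIRS
    max_loci: int = 2
    combo_mode: str = "uniform_subsets"

    def __post_init__(self) -> None:
        if self.s_bound <= 0:
            raise ValueError("s_bound must be positive")
        if self.combo_mode not in ("uniform_subsets", "uniform_count"):
            raise ValueError(f"unknown combo_mode {self.combo_mode!r}")

    @property
    def locus_combos(self) -> tuple[tuple[int, ...], ...]:
        """All admissible subsets of candidate loci of size 0..max_loci."""
        combos: list[tuple[int, ...]] = []
        for k in range(self.max_loci + 1):
            combos.extend(itertools.combinations(self.candidate_loci, k))
        return tuple(combos)


def candidate_loci_for(L: int) -> tuple[int, int, int]:
    """Fixed-loci candidate set {L/3, L/2, 2L/3}, rounded to SNP indices."""
    return (round(L / 3), round(L / 2), round(2 * L / 3))


def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> DrawnParams:
    """One joint draw from the prior."""
    if prior.combo_mode == "uniform_subsets":
        combos = prior.locus_combos
        loci = combos[rng.integers(len(combos))]
    else:
        n_cand = len(prior.candidate_loci)
        k = min(int(rng.integers(0, prior.max_loci + 1)), n_cand)
        if k:
            picked = rng.choice(n_cand, size=k, replace=False)
            loci = tuple(sorted(prior.candidate_loci[i] for i in picked))
        else:
            loci = ()
    coeffs = tuple(rng.uniform(-prior.s_bound, prior.s_bound) for _ in loci)
    m, sex = prior.m_sex_pairs[rng.integers(len(prior.m_sex_pairs))]
    return DrawnParams(sel_loci=loci, sel_coeffs=coeffs, m=float(m), sex=int(sex))


@dataclass(frozen=True)
class ScenarioSpec:
    """One evaluation scenario: fixed parameters, prior and ABC sizes."""

    name: str
    fixed: FixedParams
    prior: PriorSpec
    n_abc: int
    n_sim: int
    method: str  # "fixed_loci" or "outlier_scan"


# Full-scale scenario table: Ne = 10,000, SNP spacing 165 bp throughout.
_SCENARIO_TABLE = {
    1: dict(L=100, r=3.0e-4, t_star=5, n_cycles=4, s_bound=0.25, n_abc=100),
    2: dict(L=100, r=3.0e-4, t_star=50, n_cycles=4, s_bound=0.025, n_abc=100),
    3: dict(L=100, r=3.0e-4, t_star=50, n_cycles=2, s_bound=0.025, n_abc=100),
    4: dict(L=1500, r=2.0e-5, t_star=50, n_cycles=4, s_bound=0.025, n_abc=10),
}


def scenario(
    name: int,
    method: str = "outlier_scan",
    Ne: int = 10_000,
    n_sim: int = 100_000,
    n_abc: int | None = None,
) -> ScenarioSpec:
    """Instantiate one of the four evaluation scenarios.

    Defaults are the full-scale values; pass smaller ``Ne``, ``n_sim`` and
    ``n_abc`` for desk-scale runs.
    """
    if name not in _SCENARIO_TABLE:
        raise ValueError(f"scenario must be 1-4, got {name}")
    if method not in ("fixed_loci", "outlier_scan"):
        raise ValueError(f"unknown method {method!r}")
    row = _SCENARIO_TABLE[name]
    fixed = FixedParams(
        r=row["r"], t_star=row["t_star"], n_cycles=row["n_cycles"],
        Ne=Ne, L=row["L"], snp_spacing=165,
    )
    if method == "fixed_loci":
        prior = PriorSpec(
            s_bound=row["s_bound"],
            candidate_loci=candidate_loci_for(row["L"]),
            combo_mode="uniform_subsets",
        )
    else:
        prior = PriorSpec(
            s_bound=row["s_bound"],
            candidate_loci=tuple(range(1, row["L"] + 1)),
            combo_mode="uniform_count",
        )
    return ScenarioSpec(
        name=f"scenario{name}",
        fixed=fixed,
        prior=prior,
        n_abc=row["n_abc"] if n_abc is None else n_abc,
        n_sim=n_sim,
        method=method,
    )


def _flatten_params(
    drawn: DrawnParams, candidate_loci: Sequence[int]
) -> np.ndarray:
    """Numeric parameter vector: s per candidate locus, then m and sex."""
    s = np.zeros(len(candidate_loci) + 2)
    lookup = dict(zip(drawn.sel_loci, drawn.sel_coeffs))
    for j, locus in enumerate(candidate_loci):
        s[j] = lookup.get(locus, 0.0)
    s[-2] = drawn.m
    s[-1] = drawn.sex
    return s


def _param_names(candidate_loci: Sequence[int]) -> tuple[str, ...]:
    return tuple(f"s@{locus}" for locus in candidate_loci) + ("m", "sex")


def build_reference_table(
    fixed: FixedParams,
    prior: PriorSpec,
    n_sim: int,
    rng: np.random.Generator,
    stats: Sequence[str] = ("signFST",),
    stat_loci: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Simulate ``n_sim`` datasets and summarize them.

    Returns ``(params, stat_matrix, param_names)`` where the statistic
    vectors are optionally restricted to the 1-based ``stat_loci``.
    """
    cand = prior.candidate_loci
    params = np.empty((n_sim, len(cand) + 2))
    rows = []
    for i in range(n_sim):
        drawn = sample_prior(prior, rng)
        pair = run_simulation(fixed, drawn, rng)
        sv = summarize(pair, stats)
        rows.append(sv.vector(loci=stat_loci))
        params[i] = _flatten_params(drawn, cand)
    return params, np.asarray(rows), _param_names(cand)


@dataclass
class EvalReport:
    """Per-locus, per-iteration posterior-median records with aggregation."""

    records: pd.DataFrame
    s_bound: float

    def aggregate(
        self, n_bins: int = 20, by: Sequence[str] = ()
    ) -> pd.DataFrame:
        return evaluate(self.records, self.s_bound, n_bins=n_bins, by=by)


def evaluate(
    records: pd.DataFrame,
    s_bound: float,
    n_bins: int = 20,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Bin true coefficients and decompose the posterior-median error.

    Within each bin (and optional extra grouping columns) the error
    ``e = median - true_s`` is summarized as ``mse = mean(e^2)``,
    ``variance = var(e)`` (population form) and ``bias2 = mean(e)^2``, so
    that ``mse = variance + bias2`` holds exactly.
    """
    df = records.copy()
    edges = np.linspace(-s_bound, s_bound, n_bins + 1)
    df["s_bin"] = np.clip(np.digitize(df["true_s"], edges) - 1, 0, n_bins - 1)
    df["error"] = df["median"] - df["true_s"]
    keys = list(by) + ["s_bin"]
    rows = []
    for key, g in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        b = int(key[-1])
        e = g["error"].to_numpy()
        row = dict(zip(keys, key))
        row.update(
            n=e.size,
            bin_center=(edges[b] + edges[b + 1]) / 2,
            mse=float(np.mean(e**2)),
            variance=float(np.var(e)),
            bias2=float(np.mean(e) ** 2),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _abc_posteriors(
    params: np.ndarray,
    stat_matrix: np.ndarray,
    obs_vec: np.ndarray,
    param_names: tuple[str, ...],
    tolerance: float,
    kernel: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior medians of the rejection and regression-adjusted stages."""
    table = ReferenceTable(
        params=params, stats=stat_matrix, obs=obs_vec, param_names=param_names
    )
    rejected = abc_rejection(table, tolerance)
    mask = np.array([not n.startswith(("m", "sex")) for n in param_names])
    adjusted = regression_adjust(rejected, kernel=kernel, adjust=mask)
    return rejected.posterior_median, adjusted.posterior_median


def _abc_medians(
    params: np.ndarray,
    stat_matrix: np.ndarray,
    obs_vec: np.ndarray,
    param_names: tuple[str, ...],
    tolerance: float,
    kernel: str,
    adjust_method: str,
) -> np.ndarray:
    """Run rejection (+ optional regression) and return posterior medians."""
    if adjust_method not in ("rejection", "regression"):
        raise ValueError(f"unknown adjustment method {adjust_method!r}")
    med_rej, med_reg = _abc_posteriors(
        params, stat_matrix, obs_vec, param_names, tolerance, kernel
    )
    return med_rej if adjust_method == "rejection" else med_reg


def run_method1(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    stats: Sequence[str] = ("signFST",),
    tolerance: float = 0.001,
    kernel: str = "gaussian",
    adjust_method: str = "regression",
) -> EvalReport:
    """Fixed-candidate-loci inference with one shared reference table.

    Builds ``n_sim`` simulations once, then for each of ``n_abc``
    pseudo-observed datasets runs rejection plus regression adjustment and
    records the posterior medians at the candidate loci.
    """
    if spec.method != "fixed_loci":
        raise ValueError("run_method1 requires a fixed_loci scenario")
    cand = spec.prior.candidate_loci
    params, stat_matrix, param_names = build_reference_table(
        spec.fixed, spec.prior, spec.n_sim, rng, stats=stats
    )
    rows = []
    for it in range(spec.n_abc):
        drawn = sample_prior(spec.prior, rng)
        pair = run_simulation(spec.fixed, drawn, rng)
        obs_vec = summarize(pair, stats).vector()
        med_rej, med_reg = _abc_posteriors(
            params, stat_matrix, obs_vec, param_names, tolerance, kernel
        )
        med = med_rej if adjust_method == "rejection" else med_reg
        truth = _flatten_params(drawn, cand)
        for j, locus in enumerate(cand):
            rows.append(
                dict(
                    iteration=it,
                    locus=locus,
                    true_s=truth[j],
                    median=med[j],
                    median_rejection=med_rej[j],
                    m=drawn.m,
                    sex=drawn.sex,
                    n_loci=drawn.n_selected,
                )
            )
    return EvalReport(records=pd.DataFrame(rows), s_bound=spec.prior.s_bound)


def run_method2(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    stats: Sequence[str] = ("signFST",),
    tolerance: float = 0.001,
    kernel: str = "gaussian",
    adjust_method: str = "regression",
    outlier_quantile: float = 0.95,
) -> EvalReport:
    """Outlier-scan-constrained inference with fresh tables per iteration.

    Per pseudo-observed dataset: scan its FST vector for outlier loci,
    simulate a fresh reference table whose selected loci are restricted to
    the outlier set, run ABC on the statistics at those loci, and record
    medians.  True selected loci missed by the scan are recorded with a
    zero estimate (``detected = False``) since the restricted model pins
    them to no selection.
    """
    if spec.method != "outlier_scan":
        raise ValueError("run_method2 requires an outlier_scan scenario")
    need = tuple(set(stats) | {"FST"})
    rows = []
    for it in range(spec.n_abc):
        drawn = sample_prior(spec.prior, rng)
        pair = run_simulation(spec.fixed, drawn, rng)
        sv = summarize(pair, need)
        scan = fst_outlier_scan(sv.fst, quantile=outlier_quantile)
        truth = dict(zip(drawn.sel_loci, drawn.sel_coeffs))
        base = dict(iteration=it, m=drawn.m, sex=drawn.sex, n_loci=drawn.n_selected)
        if scan.loci:
            table_prior = replace(
                spec.prior, candidate_loci=scan.loci, combo_mode="uniform_count"
            )
            params, stat_matrix, param_names = build_reference_table(
                spec.fixed, table_prior, spec.n_sim, rng,
                stats=stats, stat_loci=scan.loci,
            )
            # drop the FST vector if it was only needed for the scan
            obs_sv = SummaryVector(
                L=sv.L,
                stat_names=tuple(n for n in sv.stat_names if n in set(stats)),
                fst=sv.fst, sign_fst=sv.sign_fst,
                pdiff=sv.pdiff, xp_ehh=sv.xp_ehh,
            )
            obs_vec = obs_sv.vector(loci=scan.loci)
            med = _abc_medians(
                params, stat_matrix, obs_vec, param_names,
                tolerance, kernel, adjust_method,
            )
            for j, locus in enumerate(scan.loci):
                rows.append(
                    dict(
                        **base, locus=locus, true_s=truth.get(locus, 0.0),
                        median=med[j], detected=True,
                    )
                )
        for locus, s in truth.items():
            if locus not in scan.loci:
                rows.append(
                    dict(**base, locus=locus, true_s=s, median=0.0, detected=False)
                )
    return EvalReport(records=pd.DataFrame(rows), s_bound=spec.prior.s_bound)


# ---------------------------------------------------------------------------
# Single-locus summary-statistic assessment
# ---------------------------------------------------------------------------

_SINGLE_LOCUS_STATS = ("signFST", "pdiff", "FST")


def _single_locus_stat(name: str, pX: np.ndarray, pY: np.ndarray) -> np.ndarray:
    if name == "signFST":
        return sign_fst_per_locus(pX, pY)
    if name == "pdiff":
        return pX - pY
    if name == "FST":
        return fst_per_locus(pX, pY)
    raise ValueError(f"unknown statistic {name!r}")


def single_locus_assessment(
    rng: np.random.Generator,
    mode: str = "empirical",
    stats: Sequence[str] = _SINGLE_LOCUS_STATS,
    n_sim: int = 10_000,
    n_abc: int = 100,
    Ne: int = 1_000,
    s_bound: float = 0.25,
    t_star: int = 5,
    n_cycles: int = 4,
    r: float = 3.0e-4,
    snp_spacing: int = 165,
    tolerance: float = 0.001,
    kernel: str = "gaussian",
    vary_m_sex: bool = False,
) -> dict[str, float]:
    """Mean squared error of ABC estimates of s at a single selected locus.

    Builds an ``n_sim``-row reference table for one locus under selection;
    ``mode="deterministic"`` fills the table with the noiseless
    single-locus expectation model, while ``mode="empirical"`` simulates a
    3-SNP genome and selects the middle SNP.  By default m = 0 and sex = 0
    throughout (the isolated single-locus drift comparison); with
    ``vary_m_sex`` migration and reproduction mode are instead drawn per
    simulation from the admissible (m, sex) pairs.  ``n_abc`` rows are redrawn from
    the table as observed datasets with known s; per summary statistic the
    regression-adjusted posterior median is compared to the true s and the
    MSE over iterations returned.
    """
    if mode not in ("deterministic", "empirical"):
        raise ValueError(f"mode must be deterministic or empirical, got {mode!r}")
    fixed = FixedParams(
        r=r, t_star=t_star, n_cycles=n_cycles, Ne=Ne, L=3, snp_spacing=snp_spacing
    )
    s_true = rng.uniform(-s_bound, s_bound, size=n_sim)
    if vary_m_sex:
        pick = rng.integers(0, len(DEFAULT_M_SEX_PAIRS), size=n_sim)
        m_true = np.array([DEFAULT_M_SEX_PAIRS[k][0] for k in pick])
        sex_true = np.array([DEFAULT_M_SEX_PAIRS[k][1] for k in pick])
    else:
        m_true = np.zeros(n_sim)
        sex_true = np.zeros(n_sim, dtype=int)
    if mode == "deterministic":
        pX, pY = det_final_frequency(s_true, m_true, fixed)
    else:
        locus = 2  # middle SNP of the 3-SNP genome
        pX = np.empty(n_sim)
        pY = np.empty(n_sim)
        for i in range(n_sim):
            drawn = DrawnParams(
                sel_loci=(locus,), sel_coeffs=(s_true[i],),
                m=float(m_true[i]), sex=int(sex_true[i]),
            )
            pair = run_simulation(fixed, drawn, rng)
            pX[i] = pair.X[:, locus - 1].mean()
            pY[i] = pair.Y[:, locus - 1].mean()
    stat_cols = {name: _single_locus_stat(name, pX, pY) for name in stats}
    obs_idx = rng.choice(n_sim, size=n_abc, replace=False)
    params = s_true[:, None]
    mse: dict[str, float] = {}
    for name, col in stat_cols.items():
        col2 = col[:, None]
        errs = np.empty(n_abc)
        for k, i_obs in enumerate(obs_idx):
            med = _abc_medians(
                params, col2, col2[i_obs], ("s",), tolerance, kernel, "regression"
            )
            errs[k] = med[0] - s_true[i_obs]
        mse[name] = float(np.mean(errs**2))
    return mse
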