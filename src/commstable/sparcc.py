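"""SparCC basis correlations for compositional count data.

OTU counts are compositional: only relative abundances are observed, which
induces spurious negative correlation between taxa.  SparCC estimates the
correlations of the *basis* (unobserved absolute) abundances from the
variances of pairwise log-ratios.  For fractions f_i the log-ratio variance

    t_ij = Var_samples[ log(f_i / f_j) ]

relates to basis variances w_i^2 and basis correlations rho_ij by
t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j.  Under the sparsity approximation
(most pairs uncorrelated) the basis variances solve the linear system

    sum_{j != i} t_ij = (D - 2) w_i^2 + sum_j w_j^2        for every i,

after which rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j), clipped to
[-1, 1].  Strongly correlated pairs violate the approximation, so the
estimator iteratively excludes the strongest pair from the row sums and
re-solves.  Sampling noise in the fractions is handled by averaging over
posterior Dirichlet draws, and significance by pseudo p-values against
column-permuted null tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .correlations import EdgeTable, _pair_arrays
from .tables import CountTable, RelAbundTable

VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class SparccConfig:
    """Knobs of the SparCC estimator (defaults follow common usage).

    n_fraction_draws : posterior Dirichlet draws averaged (median) per run.
    exclusion_threshold : |rho| above which the strongest pair is excluded.
    exclusion_iterations : maximum number of excluded pairs.
    n_bootstraps : number of null tables for pseudo p-values.
    fraction_mode : "dirichlet" (default) or "ml" for the deterministic
        (counts + 1)/(total + D) point estimate (single draw).
    """

    n_fraction_draws: int = 20
    exclusion_threshold: float = 0.1
    exclusion_iterations: int = 10
    n_bootstraps: int = 100
    seed: int = 0
    fraction_mode: str = "dirichlet"

    def __post_init__(self) -> None:
        if self.n_fraction_draws < 1:
            raise ValueError("n_fraction_draws must be >= 1")
        if not 0 < self.exclusion_threshold <= 1:
            raise ValueError("exclusion_threshold must lie in (0, 1]")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if self.fraction_mode not in ("dirichlet", "ml"):
            raise ValueError("fraction_mode must be 'dirichlet' or 'ml'")


@dataclass
class SparccResult:
    """Basis correlations, basis variances, log-ratio variances, pseudo p."""

    otu_ids: list[str]
    rho: np.ndarray
    omega_sq: np.ndarray
    tij: np.ndarray
    p: np.ndarray | None = None
    flagged_otus: list[str] = field(default_factory=list)

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.otu_ids, columns=self.otu_ids)


def estimate_fractions(t: CountTable, seed: int | np.random.Generator = 0) -> RelAbundTable:
    """One posterior draw of OTU fractions per sample, Dirichlet(counts + 1).

    The +1 prior keeps every fraction strictly positive so log-ratios are
    always defined, even for zero counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = t.counts.to_numpy(dtype=float)
    draws = rng.gamma(counts + 1.0)
    draws /= draws.sum(axis=1, keepdims=True)
    return RelAbundTable(pd.DataFrame(draws, index=t.counts.index,
                                      columns=t.counts.columns))


def _ml_fractions(t: CountTable) -> RelAbundTable:
    counts = t.counts.to_numpy(dtype=float) + 1.0
    counts /= counts.sum(axis=1, keepdims=True)
    return RelAbundTable(pd.DataFrame(counts, index=t.counts.index,
                                      columns=t.counts.columns))


def _log_ratio_variances(values: np.ndarray) -> np.ndarray:
    """t_ij = Var(log f_i - log f_j), computed from the log-fraction covariance."""
    logf = np.log(values)
    cov = np.cov(logf, rowvar=False, ddof=1)
    var = np.diag(cov)
    tij = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(tij, 0.0)
    return np.maximum(tij, 0.0)


def _solve_basis(tij: np.ndarray, excluded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the sparsity-approximation system for basis variances.

    ``excluded`` is a boolean pair mask; an excluded pair (i, j) is removed
    from the row sums of both i and j, which decrements the corresponding
    coefficients of the system.
    """
    d = tij.shape[0]
    m = np.ones((d, d)) + np.eye(d) * (d - 2)
    t_eff = np.where(excluded, 0.0, tij)
    n_excl = excluded.sum(axis=1)
    m[np.diag_indices(d)] -= n_excl
    m[excluded] -= 1.0
    rhs = t_eff.sum(axis=1)
    omega_sq = np.linalg.solve(m, rhs)
    flagged = omega_sq < VARIANCE_FLOOR
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} basis variances floored at "
                      f"{VARIANCE_FLOOR}", RuntimeWarning, stacklevel=3)
    omega_sq = np.maximum(omega_sq, VARIANCE_FLOOR)
    return omega_sq, flagged


def _rho_from(tij: np.ndarray, omega_sq: np.ndarray) -> np.ndarray:
    omega = np.sqrt(omega_sq)
    rho = (omega_sq[:, None] + omega_sq[None, :] - tij) / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def basis_correlations(f: RelAbundTable) -> SparccResult:
    """Single-pass SparCC estimate (no exclusion) from strictly positive fractions."""
    values = f.values.to_numpy(dtype=float)
    d = values.shape[1]
    if d < 4:
        raise ValueError("SparCC's sparsity approximation needs >= 4 OTUs")
    if values.min() <= 0:
        raise ValueError("fractions must be strictly positive")
    tij = _log_ratio_variances(values)
    excluded = np.zeros_like(tij, dtype=bool)
    omega_sq, flagged = _solve_basis(tij, excluded)
    rho = _rho_from(tij, omega_sq)
    return SparccResult(f.otu_ids, rho, omega_sq, tij,
                        flagged_otus=[o for o, fl in zip(f.otu_ids, flagged) if fl])


def _basis_with_exclusion(tij: np.ndarray, threshold: float,
                          iterations: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = tij.shape[0]
    excluded = np.zeros((d, d), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        omega_sq, flagged = _solve_basis(tij, excluded)
        rho = _rho_from(tij, omega_sq)
        for _ in range(iterations):
            mag = np.abs(rho)
            mag[np.tril_indices(d)] = 0.0
            mag[excluded] = 0.0
            i, j = np.unravel_index(np.argmax(mag), mag.shape)
            if mag[i, j] < threshold:
                break
            excluded[i, j] = excluded[j, i] = True
            omega_sq, fl = _solve_basis(tij, excluded)
            flagged |= fl
            rho = _rho_from(tij, omega_sq)
    return rho, omega_sq, flagged


def sparcc(t: CountTable, cfg: SparccConfig = SparccConfig()) -> SparccResult:
    """Full SparCC run: fraction draws, iterative exclusion, median aggregation."""
    rng = np.random.default_rng(cfg.seed)
    n_draws = 1 if cfg.fraction_mode == "ml" else cfg.n_fraction_draws
    rhos, omegas, tijs = [], [], []
    flagged = np.zeros(len(t.otu_ids), dtype=bool)
    for _ in range(n_draws):
        f = (_ml_fractions(t) if cfg.fraction_mode == "ml"
             else estimate_fractions(t, rng))
        tij = _log_ratio_variances(f.values.to_numpy(dtype=float))
        if tij.shape[0] < 4:
            raise ValueError("SparCC's sparsity approximation needs >= 4 OTUs")
        rho, omega_sq, fl = _basis_with_exclusion(
            tij, cfg.exclusion_threshold, cfg.exclusion_iterations)
        rhos.append(rho)
        omegas.append(omega_sq)
        tijs.append(tij)
        flagged |= fl
    rho = np.median(rhos, axis=0)
    np.fill_diagonal(rho, 1.0)
    return SparccResult(
        t.otu_ids, rho, np.median(omegas, axis=0), np.median(tijs, axis=0),
        flagged_otus=[o for o, fl in zip(t.otu_ids, flagged) if fl])


def sparcc_pseudo_pvalues(t: CountTable, observed: SparccResult,
                          cfg: SparccConfig = SparccConfig()) -> np.ndarray:
    """Two-tailed pseudo p-values against column-permuted null tables.

    Each null table permutes every OTU's counts independently across samples,
    destroying pairwise association while preserving marginals; the add-one
    estimator p = (1 + #{|rho_null| >= |rho_obs|}) / (B + 1) never returns 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    counts = t.counts.to_numpy()
    exceed = np.zeros_like(observed.rho)
    abs_obs = np.abs(observed.rho)
    for b in range(cfg.n_bootstraps):
        null = np.column_stack([rng.permutation(counts[:, k])
                                for k in range(counts.shape[1])])
        null_table = CountTable(pd.DataFrame(null, index=t.counts.index,
                                             columns=t.counts.columns))
        null_cfg = replace(cfg, seed=int(rng.integers(2 ** 31)))
        rho_null = sparcc(null_table, null_cfg).rho
        exceed += np.abs(rho_null) >= abs_obs
    p = (1.0 + exceed) / (cfg.n_bootstraps + 1.0)
    np.fill_diagonal(p, 1.0)
    return np.minimum(p, 1.0)


def sparcc_edges(t: CountTable, cfg: SparccConfig = SparccConfig()) -> EdgeTable:
    """Run SparCC and emit the shared edge-table format (p = pseudo p-value)."""
    result = sparcc(t, cfg)
    result.p = sparcc_pseudo_pvalues(t, result, cfg)
    iu, ju, a, b = _pair_arrays(t.otu_ids)
    rho = result.rho[iu, ju]
    p = result.p[iu, ju]
    df = pd.DataFrame({
        "otu_a": a, "otu_b": b, "method": "sparcc",
        "statistic": rho,
        "direction": np.sign(rho).astype(int),
        "p_raw": p,
        "p": p,
    })
    return EdgeTable("sparcc", df)
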