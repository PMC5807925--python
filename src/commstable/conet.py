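"""CoNet-style ensemble co-occurrence detection.

Four measures (Pearson, Spearman, Bray-Curtis, symmetrised Kullback-Leibler)
are scored over all OTU pairs of a relative-abundance table.  Initial
per-measure thresholds are widened in lock-step until the set of pairs
top-ranked by *all four* measures reaches the requested number of positive
(co-presence) and negative (exclusion) candidate edges.  Each candidate is
then tested with the ReBoot procedure: the two OTUs' abundances are permuted
independently across samples, every sample's composition renormalised, and
the measure recomputed, so the null distribution retains the spurious
association induced by compositionality alone.  A bootstrap over samples
screens out unstable edges, per-measure p-values are merged by their minimum,
and the merged values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .correlations import EdgeTable, _pair_arrays
from .tables import RelAbundTable

MEASURES = ("pearson", "spearman", "bray_curtis", "kl")
#: high score means co-presence (+1) or exclusion (-1, i.e. a distance)
POLARITY = {"pearson": +1, "spearman": +1, "bray_curtis": -1, "kl": -1}


@dataclass(frozen=True)
class ConetConfig:
    measures: tuple[str, ...] = MEASURES
    target_pos_edges: int = 2000
    target_neg_edges: int = 2000
    n_permutations: int = 1000
    n_bootstraps: int = 1000
    seed: int = 0
    kl_pseudocount: float | None = None  # default 1/(2 n_samples)
    bootstrap_screen: bool = True

    def __post_init__(self) -> None:
        if self.target_pos_edges < 1 or self.target_neg_edges < 1:
            raise ValueError("edge targets must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")


@dataclass(frozen=True)
class MeasureScores:
    measure: str
    scores: pd.DataFrame  # symmetric, OTUs x OTUs
    polarity: int  # +1 correlation-like, -1 distance-like


@dataclass
class ThresholdSelection:
    pos_pairs: list[tuple[str, str]]
    neg_pairs: list[tuple[str, str]]
    thresholds: dict[str, tuple[float, float]]  # measure -> (exclusion cut, co-presence cut)


def _kl_pseudocount(n_samples: int, cfg_value: float | None) -> float:
    return 1.0 / (2 * n_samples) if cfg_value is None else cfg_value


def _normalise_otu_profiles(values: np.ndarray, pseudocount: float) -> np.ndarray:
    """Rescale each OTU's sample profile to sum 1, add pseudocount, renormalise."""
    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero OTU profile cannot be normalised")
    p = values / totals
    p = p + pseudocount
    return p / p.sum(axis=0)


def measure_scores(r: RelAbundTable, measure: str,
                   kl_pseudocount: float | None = None) -> MeasureScores:
    """Pairwise score matrix for one of the four ensemble measures."""
    values = r.values.to_numpy(dtype=float)
    n = values.shape[0]
    if measure == "pearson":
        mat = np.corrcoef(values, rowvar=False)
    elif measure == "spearman":
        mat = np.corrcoef(stats.rankdata(values, axis=0), rowvar=False)
    elif measure == "bray_curtis":
        from scipy.spatial.distance import pdist, squareform

        mat = squareform(pdist(values.T, metric="braycurtis"))
    elif measure == "kl":
        p = _normalise_otu_profiles(values, _kl_pseudocount(n, kl_pseudocount))
        logp = np.log(p)
        h = (p * logp).sum(axis=0)  # sum p log p per OTU
        cross = p.T @ logp  # cross[i, j] = sum_s p_si log p_sj
        kl = h[:, None] - cross
        mat = 0.5 * (kl + kl.T)
        np.fill_diagonal(mat, 0.0)
    else:
        raise ValueError(f"unknown measure: {measure!r}")
    df = pd.DataFrame(mat, index=r.otu_ids, columns=r.otu_ids)
    return MeasureScores(measure, df, POLARITY[measure])


def select_initial_thresholds(scores: dict[str, MeasureScores],
                              cfg: ConetConfig) -> ThresholdSelection:
    """Lock-step rank expansion to the target concordant candidate counts.

    Per measure, pairs are ranked toward co-presence (high correlation / low
    distance) and toward exclusion; the common rank cutoff is the smallest
    at which the pairs top-ranked in every measure number at least the
    target (or all pairs are exhausted).
    """
    measures = list(cfg.measures)
    any_scores = scores[measures[0]]
    otu_ids = list(any_scores.scores.columns)
    iu, ju, a, b = _pair_arrays(otu_ids)
    m_pairs = len(iu)

    pos_rank = np.zeros((len(measures), m_pairs))
    for k, name in enumerate(measures):
        vals = scores[name].scores.to_numpy()[iu, ju]
        toward_pos = vals * scores[name].polarity  # high = co-presence
        order = np.argsort(-toward_pos, kind="stable")
        ranks = np.empty(m_pairs)
        ranks[order] = np.arange(m_pairs)
        pos_rank[k] = ranks

    def pick(rank_matrix: np.ndarray, target: int) -> tuple[np.ndarray, int]:
        worst = rank_matrix.max(axis=0)
        order = np.argsort(worst, kind="stable")
        if m_pairs <= target:
            cutoff = m_pairs
        else:
            cutoff = int(worst[order[target - 1]]) + 1
        members = worst < cutoff
        return members, cutoff

    if m_pairs < cfg.target_pos_edges + cfg.target_neg_edges:
        warnings.warn(
            f"only {m_pairs} pairs available for "
            f"{cfg.target_pos_edges}+{cfg.target_neg_edges} target edges; "
            "returning all concordant pairs", RuntimeWarning, stacklevel=2)
    pos_members, pos_cut = pick(pos_rank, cfg.target_pos_edges)
    neg_rank = (m_pairs - 1) - pos_rank
    neg_members, neg_cut = pick(neg_rank, cfg.target_neg_edges)

    # a pair top-ranked in both directions (possible when the targets approach
    # the pair universe) goes to the side that ranks it better; ties positive
    both = pos_members & neg_members
    pos_better = pos_rank.max(axis=0) <= neg_rank.max(axis=0)
    pos_members &= ~both | pos_better
    neg_members &= ~both | ~pos_better

    thresholds = {}
    for k, name in enumerate(measures):
        vals = scores[name].scores.to_numpy()[iu, ju]
        toward_pos = vals * scores[name].polarity
        srt = np.sort(toward_pos)
        upper = srt[max(0, m_pairs - pos_cut)] * scores[name].polarity
        lower = srt[min(m_pairs - 1, neg_cut - 1)] * scores[name].polarity
        thresholds[name] = (float(lower), float(upper))

    pairs = list(zip(a, b))
    return ThresholdSelection(
        pos_pairs=[pairs[i] for i in np.flatnonzero(pos_members)],
        neg_pairs=[pairs[i] for i in np.flatnonzero(neg_members)],
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# ReBoot null and measure kernels on (n_draws, n_samples) row pairs
# ---------------------------------------------------------------------------

def _rowwise_measure(u: np.ndarray, v: np.ndarray, measure: str,
                     kl_pseudocount: float) -> np.ndarray:
    """Measure between paired rows of two (n_draws, n_samples) arrays."""
    if measure == "spearman":
        u = stats.rankdata(u, axis=1)
        v = stats.rankdata(v, axis=1)
        measure = "pearson"
    if measure == "pearson":
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        num = (uc * vc).sum(axis=1)
        den = np.sqrt((uc ** 2).sum(axis=1) * (vc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return out
    if measure == "bray_curtis":
        num = np.abs(u - v).sum(axis=1)
        den = (u + v).sum(axis=1)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if measure == "kl":
        su = u.sum(axis=1, keepdims=True)
        sv = v.sum(axis=1, keepdims=True)
        if (su == 0).any() or (sv == 0).any():
            raise ValueError("all-zero OTU profile cannot be normalised")
        p = u / su + kl_pseudocount
        q = v / sv + kl_pseudocount
        p /= p.sum(axis=1, keepdims=True)
        q /= q.sum(axis=1, keepdims=True)
        logratio = np.log(p) - np.log(q)
        return 0.5 * ((p * logratio).sum(axis=1) - (q * logratio).sum(axis=1))
    raise ValueError(f"unknown measure: {measure!r}")


def _reboot_draws(values: np.ndarray, i: int, j: int, n_permutations: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Permuted, renormalised fraction pairs for the ReBoot null.

    The two columns are permuted independently; after permutation each
    sample's composition is renormalised to sum 1 (only the pair's fractions
    are needed: the rest of the composition is unchanged, so the new
    denominator is rest + f_i' + f_j').
    """
    f_i, f_j = values[:, i], values[:, j]
    rest = 1.0 - f_i - f_j
    perm_i = rng.permuted(np.broadcast_to(f_i, (n_permutations, f_i.size)), axis=1)
    perm_j = rng.permuted(np.broadcast_to(f_j, (n_permutations, f_j.size)), axis=1)
    denom = rest[None, :] + perm_i + perm_j
    return perm_i / denom, perm_j / denom


def _reboot_null_scores(values: np.ndarray, i: int, j: int, measure: str,
                        n_permutations: int, rng: np.random.Generator,
                        kl_pseudocount: float) -> tuple[float, np.ndarray]:
    """Observed score and the ReBoot null for one pair under one measure."""
    u, v = _reboot_draws(values, i, j, n_permutations, rng)
    obs = float(_rowwise_measure(values[None, :, i], values[None, :, j],
                                 measure, kl_pseudocount)[0])
    null = _rowwise_measure(u, v, measure, kl_pseudocount)
    return obs, null


def _pseudo_p(obs: float, null: np.ndarray) -> tuple[float, int]:
    """Two-sided add-one p relative to the null mean, plus raw direction."""
    mu = float(null.mean())
    dev = abs(obs - mu)
    if null.std() == 0:
        return 1.0, int(np.sign(obs - mu))
    n_extreme = int((np.abs(null - mu) >= dev - 1e-15).sum())
    p = (1.0 + n_extreme) / (null.size + 1.0)
    return min(p, 1.0), int(np.sign(obs - mu))


def reboot_pvalue(r: RelAbundTable, pair: tuple[str, str], measure: str,
                  n_permutations: int = 1000, seed: int = 0,
                  kl_pseudocount: float | None = None) -> tuple[float, int]:
    """ReBoot permutation-renormalisation p-value and direction for one pair.

    Direction is the sign of (observed - null mean), mapped through the
    measure's polarity: for distances an observed score *below* the null mean
    means co-presence (+1).
    """
    values = r.values.to_numpy(dtype=float)
    idx = {o: k for k, o in enumerate(r.otu_ids)}
    i, j = idx[pair[0]], idx[pair[1]]
    rng = np.random.default_rng(seed)
    pc = _kl_pseudocount(values.shape[0], kl_pseudocount)
    obs, null = _reboot_null_scores(values, i, j, measure, n_permutations,
                                    rng, pc)
    p, raw_dir = _pseudo_p(obs, null)
    return p, raw_dir * POLARITY[measure]


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _evaluate_candidate(values: np.ndarray, i: int, j: int, cfg: ConetConfig,
                        rng: np.random.Generator,
                        boot_idx: np.ndarray | None, pc: float
                        ) -> tuple[dict, dict, dict]:
    """ReBoot p, polarity-mapped direction and bootstrap-screen support for
    one candidate pair under every measure (one shared set of null draws)."""
    u, v = _reboot_draws(values, i, j, cfg.n_permutations, rng)
    if cfg.bootstrap_screen and boot_idx is not None:
        boot_u, boot_v = values[boot_idx, i], values[boot_idx, j]
    p_by, dir_by, support = {}, {}, {}
    for m in cfg.measures:
        obs = float(_rowwise_measure(values[None, :, i],
                                     values[None, :, j], m, pc)[0])
        null = _rowwise_measure(u, v, m, pc)
        p, raw_dir = _pseudo_p(obs, null)
        p_by[m] = p
        dir_by[m] = raw_dir * POLARITY[m]
        if cfg.bootstrap_screen and boot_idx is not None:
            boot = _rowwise_measure(boot_u, boot_v, m, pc)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            support[m] = not (lo <= null.mean() <= hi)
        else:
            support[m] = True
    return p_by, dir_by, support


def conet_edges(r: RelAbundTable, cfg: ConetConfig = ConetConfig()) -> EdgeTable:
    """Full ensemble run; emits an edge table with p = BH q-value.

    Candidate edges come from the lock-step threshold selection; each is
    ReBoot-tested under all four measures.  A measure supports the edge if
    the ReBoot null mean falls outside the central 95% bootstrap interval of
    its observed score; edges with no supporting measure, or with supporting
    measures disagreeing on direction, are dropped.  Merged p = min over
    supporting measures, then BH across retained edges.
    """
    values = r.values.to_numpy(dtype=float)
    n = values.shape[0]
    idx = {o: k for k, o in enumerate(r.otu_ids)}
    pc = _kl_pseudocount(n, cfg.kl_pseudocount)

    scores = {m: measure_scores(r, m, cfg.kl_pseudocount) for m in cfg.measures}
    sel = select_initial_thresholds(scores, cfg)
    candidates = sel.pos_pairs + sel.neg_pairs
    if not candidates:
        return EdgeTable("conet", pd.DataFrame(
            columns=["otu_a", "otu_b", "method", "statistic", "direction",
                     "p_raw", "p"]))

    ss = np.random.SeedSequence(cfg.seed)
    boot_rng = np.random.default_rng(ss.spawn(1)[0])
    boot_idx = boot_rng.integers(0, n, size=(cfg.n_bootstraps, n))
    pair_rngs = [np.random.default_rng(s) for s in ss.spawn(len(candidates))]

    rows = []
    for (otu_a, otu_b), rng in zip(candidates, pair_rngs):
        i, j = idx[otu_a], idx[otu_b]
        per_measure_p, per_measure_dir, supported = _evaluate_candidate(
            values, i, j, cfg, rng, boot_idx, pc)
        passing = [m for m in cfg.measures if supported[m]]
        if not passing:
            continue
        dirs = {per_measure_dir[m] for m in passing}
        if len(dirs) != 1 or dirs == {0}:
            continue
        merged = min(per_measure_p[m] for m in passing)
        rows.append((otu_a, otu_b, dirs.pop(), merged,
                     float(scores["pearson"].scores.loc[otu_a, otu_b])
                     if "pearson" in scores else np.nan))

    if not rows:
        return EdgeTable("conet", pd.DataFrame(
            columns=["otu_a", "otu_b", "method", "statistic", "direction",
                     "p_raw", "p"]))
    df = pd.DataFrame(rows, columns=["otu_a", "otu_b", "direction", "p_raw",
                                     "statistic"])
    df["method"] = "conet"
    df["p"] = bh_fdr(df["p_raw"].to_numpy())
    return EdgeTable("conet", df)
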