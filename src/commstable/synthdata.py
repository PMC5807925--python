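"""Synthetic data with known ground truth for every pipeline stage.

Count tables are generated from a latent Gaussian copula with log-normal
marginals: per sample, latent log-abundances are drawn from a multivariate
normal whose correlation matrix is block-diagonal (``rho_within`` inside
planted co-occurrence blocks, zero elsewhere), exponentiated, normalised to a
composition, and turned into counts by multinomial sampling at a random
sequencing depth.  The latent correlation is therefore a known recovery
target for the correlation estimators.  Background OTUs make prevalence
filtering and FDR calibration meaningful.  Replicate "cohorts" share the
latent structure but have independent sampling noise and OTU dropout, which
emulates the situation of several populations harbouring the same underlying
co-occurrence structure.  Graph generators (planted partition, power-law
degree sequences) supply fixtures with known community/degree structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .communities import Partition, _canonical_ids
from .netbuild import Network
from .tables import CountTable, RepSeqSet, SampleMetadata


@dataclass(frozen=True)
class BlockSpec:
    """Study conditions for a planted-block compositional count table.

    Defaults match the package's reference simulation: 400 samples, four
    co-occurrence blocks of 12 OTUs at latent correlation 0.7, 60 background
    OTUs, sequencing depths uniform in 20,000-60,000 (comfortably above the
    10,000-count quality threshold), and per-OTU log-normal baselines with
    mean 0 and spread 1.
    """

    n_samples: int = 400
    block_sizes: tuple[int, ...] = (12, 12, 12, 12)
    n_background_otus: int = 60
    rho_within: float = 0.7
    depth_range: tuple[int, int] = (20_000, 60_000)
    lognormal_mu_sd: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b < 2 for b in self.block_sizes):
            raise ValueError("block sizes must be >= 2")
        if not 0 <= self.rho_within < 1:
            raise ValueError("rho_within must lie in [0, 1)")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("invalid depth range")

    @property
    def n_otus(self) -> int:
        return sum(self.block_sizes) + self.n_background_otus


@dataclass(frozen=True)
class TruthSet:
    """Ground truth accompanying a simulated table.

    ``latent_log_abundance`` holds the pre-sampling latent draws (samples x
    all OTUs, before dropout) so planted correlations can be verified exactly;
    count-scale correlations are attenuated by multinomial noise.
    """

    block_of: dict[str, int]  # otu -> block id, 0 = background
    latent_corr: np.ndarray
    dropped_otus: frozenset = frozenset()
    latent_log_abundance: np.ndarray | None = None

    def block_partition(self, include_background: bool = False) -> Partition:
        """The planted blocks as a Partition (background OTUs optional,
        each background OTU its own singleton if included)."""
        groups: dict[int, set] = {}
        singles = []
        for otu, b in self.block_of.items():
            if otu in self.dropped_otus:
                continue
            if b == 0:
                if include_background:
                    singles.append({otu})
                continue
            groups.setdefault(b, set()).add(otu)
        assignment = _canonical_ids(list(groups.values()) + singles)
        return Partition(assignment, float("nan"), float("nan"))


def _latent_correlation(spec: BlockSpec) -> np.ndarray:
    d = spec.n_otus
    corr = np.eye(d)
    start = 0
    for size in spec.block_sizes:
        corr[start:start + size, start:start + size] = spec.rho_within
        start += size
    np.fill_diagonal(corr, 1.0)
    return corr


def _otu_ids(spec: BlockSpec) -> list[str]:
    return [f"OTU_{k:04d}" for k in range(spec.n_otus)]


def _block_of(spec: BlockSpec) -> dict[str, int]:
    ids = _otu_ids(spec)
    out = {}
    start, block = 0, 1
    for size in spec.block_sizes:
        for k in range(start, start + size):
            out[ids[k]] = block
        start += size
        block += 1
    for k in range(start, spec.n_otus):
        out[ids[k]] = 0
    return out


def _draw_table(spec: BlockSpec, mu: np.ndarray, chol: np.ndarray,
                rng: np.random.Generator, keep: np.ndarray,
                dataset_tag: str) -> tuple[CountTable, np.ndarray]:
    d = spec.n_otus
    z = rng.standard_normal((spec.n_samples, d)) @ chol.T
    latent = mu + z
    weights = np.exp(latent)[:, keep]
    probs = weights / weights.sum(axis=1, keepdims=True)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1,
                          size=spec.n_samples)
    counts = np.vstack([rng.multinomial(dep, p)
                        for dep, p in zip(depths, probs)])
    ids = np.asarray(_otu_ids(spec))[keep]
    samples = [f"{dataset_tag}S{k:04d}" for k in range(spec.n_samples)]
    return CountTable(pd.DataFrame(counts, index=samples, columns=ids)), latent


def simulate_replicate_datasets(spec: BlockSpec, n_datasets: int = 3,
                                dropout: float = 0.1,
                                seed: int | None = None
                                ) -> list[tuple[CountTable, TruthSet]]:
    """Replicate cohorts sharing one latent block structure.

    Each dataset gets an independent OTU dropout mask (every OTU kept with
    probability 1 - dropout) and independent latent draws and count noise.
    ``n_datasets=1`` with ``dropout=0`` reproduces a single-table simulation.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    structure_rng = np.random.default_rng(ss.spawn(1)[0])
    mu = structure_rng.normal(*spec.lognormal_mu_sd, size=spec.n_otus)
    corr = _latent_correlation(spec)
    chol = np.linalg.cholesky(corr)
    block_of = _block_of(spec)
    ids = np.asarray(_otu_ids(spec))

    out = []
    for child in ss.spawn(n_datasets + 1)[1:]:
        rng = np.random.default_rng(child)
        keep = rng.random(spec.n_otus) >= dropout
        if not keep.any():
            keep[rng.integers(spec.n_otus)] = True
        table, latent = _draw_table(spec, mu, chol, rng, keep,
                                    dataset_tag=f"d{len(out)}_")
        truth = TruthSet(block_of, corr,
                         dropped_otus=frozenset(ids[~keep]),
                         latent_log_abundance=latent)
        out.append((table, truth))
    return out


def simulate_block_table(spec: BlockSpec) -> tuple[CountTable, TruthSet]:
    """One compositional count table with planted co-occurrence blocks."""
    return simulate_replicate_datasets(spec, n_datasets=1, dropout=0.0,
                                       seed=spec.seed)[0]


def planted_partition_graph(sizes: list[int], p_in: float, p_out: float,
                            seed: int = 0) -> tuple[Network, Partition]:
    """Stochastic block model draw plus its true block partition."""
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    blocks = len(sizes)
    p = np.full((blocks, blocks), p_out)
    np.fill_diagonal(p, p_in)
    g = nx.stochastic_block_model(sizes, p.tolist(), seed=int(seed))
    g = nx.Graph(g)  # drop SBM metadata/partition attribute
    groups = []
    start = 0
    for size in sizes:
        groups.append(set(range(start, start + size)))
        start += size
    truth = Partition(_canonical_ids(groups), float("nan"), float("nan"))
    return Network(g), truth


def power_law_degree_fixture(n_nodes: int, exponent: float = -2.0,
                             seed: int = 0, k_max: int | None = None,
                             max_retries: int = 50
                             ) -> tuple[list[int], Network]:
    """Graphical degree sequence following p(k) ~ k**exponent, realised as a
    simple graph (Havel-Hakimi + seeded double-edge swaps).

    The sequence is built deterministically by rounding the expected count of
    nodes at each degree, so its binned log-log degree-frequency curve lies on
    the target slope; the seed only randomises the wiring.
    """
    if exponent >= -1:
        raise ValueError("exponent must be < -1")
    from .communities import random_graph_from_degree_sequence

    k_max = k_max or max(3, int(round(n_nodes ** 0.5 / 2)))
    ks = np.arange(1, k_max + 1)
    weights = ks.astype(float) ** exponent
    counts = np.round(weights / weights.sum() * n_nodes).astype(int)
    counts[counts == 0] = 1
    degrees: list[int] = []
    for k, c in zip(ks, counts):
        degrees.extend([int(k)] * int(c))
    degrees = degrees[:n_nodes] if len(degrees) > n_nodes else degrees
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        if sum(degrees) % 2 == 0 and nx.is_graphical(degrees):
            net = random_graph_from_degree_sequence(
                degrees, seed=int(rng.integers(2 ** 31)))
            return degrees, net
        # fix parity / graphicality by bumping a random low-degree node
        idx = int(rng.integers(len(degrees)))
        degrees[idx] += 1 if degrees[idx] < k_max else -1
    raise RuntimeError("could not build a graphical power-law sequence")


# ---------------------------------------------------------------------------
# Companion inputs: sequences and host metadata
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_rep_seqs(truth: TruthSet, seed: int = 0, length: int = 150,
                      within_divergence: float = 0.03) -> RepSeqSet:
    """Representative sequences: one random ancestor per block, members are
    point-mutated copies; background OTUs are independent random sequences."""
    rng = np.random.default_rng(seed)
    blocks = sorted({b for b in truth.block_of.values() if b != 0})
    ancestors = {b: rng.integers(4, size=length) for b in blocks}
    seqs = {}
    for otu in sorted(truth.block_of):
        b = truth.block_of[otu]
        if b == 0:
            idx = rng.integers(4, size=length)
        else:
            idx = ancestors[b].copy()
            n_mut = rng.binomial(length, within_divergence)
            pos = rng.choice(length, size=n_mut, replace=False)
            idx[pos] = (idx[pos] + rng.integers(1, 4, size=n_mut)) % 4
        seqs[otu] = "".join(_BASES[idx])
    return RepSeqSet(seqs)


def simulate_metadata(t: CountTable, seed: int = 0) -> SampleMetadata:
    """Host covariates with realistic adult-cohort marginals: age ~ N(50, 13),
    BMI ~ N(26, 4.5), roughly balanced sex, depth = observed sample totals."""
    rng = np.random.default_rng(seed)
    n = len(t.sample_ids)
    df = pd.DataFrame({
        "age": np.clip(rng.normal(50, 13, n), 18, 95).round(1),
        "bmi": np.clip(rng.normal(26, 4.5, n), 15, 55).round(2),
        "sex": rng.choice(["male", "female"], size=n),
        "depth": t.depths().to_numpy(),
    }, index=t.counts.index)
    return SampleMetadata(df)


def plant_abundance_effect(t: CountTable, otus: list[str],
                           covariate: pd.Series, beta_log10: float,
                           seed: int = 0) -> CountTable:
    """Scale the counts of ``otus`` by 10**(beta_log10 * centred covariate)
    per sample, re-rounding to integers — plants a log10-linear association
    between the OTU group's abundance and the covariate."""
    rng = np.random.default_rng(seed)
    x = covariate.loc[t.counts.index].to_numpy(dtype=float)
    factor = 10.0 ** (beta_log10 * (x - x.mean()))
    counts = t.counts.to_numpy(dtype=float).copy()
    cols = [t.otu_ids.index(o) for o in otus]
    counts[:, cols] = counts[:, cols] * factor[:, None]
    floor = np.floor(counts)
    counts = floor + (rng.random(counts.shape) < (counts - floor))
    return CountTable(pd.DataFrame(counts.astype(np.int64),
                                   index=t.counts.index,
                                   columns=t.counts.columns))
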