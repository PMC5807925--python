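"""Pearson and Spearman co-occurrence edge tables.

Both estimators run pairwise over all OTUs of a relative-abundance table and
emit a simplified edge table: direction of association (+1 / -1), the raw
statistic, and a two-tailed p-value Bonferroni-adjusted over the number of
pairs.  Neither measure accounts for compositionality; they enter the
ensemble alongside SparCC and the CoNet-style detector, and an edge must
survive all four to reach the final network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

EDGE_COLUMNS = ["otu_a", "otu_b", "method", "statistic", "direction",
                "p_raw", "p"]


@dataclass(frozen=True)
class EdgeTable:
    """Per-method co-occurrence edges over all unordered OTU pairs.

    ``edges`` columns: otu_a, otu_b (otu_a < otu_b lexicographically),
    method, statistic, direction (+1/-1, 0 sentinel for undefined), p_raw,
    p (adjusted).
    """

    method: str
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.edges
        missing = set(EDGE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        if (df["otu_a"] >= df["otu_b"]).any():
            raise ValueError("pairs must satisfy otu_a < otu_b")
        keys = list(zip(df["otu_a"], df["otu_b"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate pairs in edge table")
        p = df["p"].to_numpy()
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")

    def pair_index(self) -> pd.DataFrame:
        return self.edges.set_index(["otu_a", "otu_b"])

    def to_tsv(self, path: str | Path) -> None:
        self.edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EdgeTable":
        df = pd.read_csv(path, sep="\t")
        methods = df["method"].unique()
        if len(methods) != 1:
            raise ValueError("edge table file must contain a single method")
        return cls(str(methods[0]), df)


def bonferroni(p: np.ndarray | list[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


def _pair_arrays(otu_ids: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pair indices in the table's column order, plus the
    lexicographically sorted (otu_a, otu_b) labels for each pair."""
    ids = np.asarray(otu_ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    a, b = ids[iu], ids[ju]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return iu, ju, a2, b2


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p via the t transform with n-2 degrees of freedom."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def _corr_edges(values: np.ndarray, otu_ids: list[str], method: str) -> EdgeTable:
    n, d = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if d < 2:
        raise ValueError("need at least 2 OTUs")
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    iu, ju, a, b = _pair_arrays(otu_ids)
    rho = r[iu, ju]
    degenerate = (sd[iu] == 0) | (sd[ju] == 0)
    p_raw = _corr_pvalues(np.where(degenerate, 0.0, rho), n)
    p_raw[degenerate] = 1.0
    direction = np.sign(np.where(degenerate, 0.0, rho)).astype(int)
    df = pd.DataFrame({
        "otu_a": a, "otu_b": b, "method": method,
        "statistic": np.where(degenerate, np.nan, rho),
        "direction": direction,
        "p_raw": p_raw,
        "p": bonferroni(p_raw),
    })
    return EdgeTable(method, df)


def pearson_edges(r) -> EdgeTable:
    """Pearson r over all OTU pairs with Bonferroni-adjusted two-tailed p.

    Zero-variance OTUs yield sentinel edges (p = 1, direction 0) rather than
    being dropped, so the pair universe stays identical across methods.
    """
    return _corr_edges(r.values.to_numpy(dtype=float), r.otu_ids, "pearson")


def spearman_edges(r) -> EdgeTable:
    """Spearman rho (mid-ranks) with two-tailed t-approximation p-values."""
    ranked = stats.rankdata(r.values.to_numpy(dtype=float), axis=0)
    return _corr_edges(ranked, r.otu_ids, "spearman")
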