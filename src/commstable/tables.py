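"""OTU count tables: I/O, filtering, rarefaction, diversity and sparsity.

The count table is the raw input to the whole pipeline: an integer matrix of
OTU counts per sample.  Samples are rows, OTUs are columns throughout the
package.  Low-quality samples (shallow sequencing) and rare OTUs are removed
before anything else; co-occurrence estimation additionally restricts to
prevalent OTUs (present in at least a fixed fraction of samples) because the
resulting sub-tables are less sparse and more amenable to correlation
measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a table violates its invariants."""


class EmptyTableError(ValidationError):
    """Raised when a filter removes every sample (or every OTU)."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass(frozen=True)
class CountTable:
    """Integer OTU counts, samples x OTUs.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; index = sample ids, columns = OTU ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "OTU")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")
            object.__setattr__(self, "counts", df.astype(np.int64))
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Total counts (sequencing depth) per sample."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class RelAbundTable:
    """Per-sample proportions on the same axes as a :class:`CountTable`."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "OTU")
        v = self.values.to_numpy()
        if v.size:
            if v.min() < 0 or v.max() > 1 + 1e-9:
                raise ValidationError("relative abundances must lie in [0, 1]")
            sums = v.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("each sample must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SampleMetadata:
    """Host covariates per sample: age (years), bmi (kg/m^2), sex, depth."""

    data: pd.DataFrame  # index = sample_id; columns include age, bmi, sex, depth

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("age", "bmi"):
            if col in self.data:
                vals = pd.to_numeric(self.data[col], errors="coerce")
                if (vals.dropna() < 0).any():
                    raise ValidationError(f"{col} must be non-negative")


@dataclass(frozen=True)
class TaxonomyTable:
    """Greengenes-style lineage strings per OTU (k__...; p__...; ...)."""

    lineages: pd.Series  # index = otu_id, values = lineage string

    RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
    PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

    def __post_init__(self) -> None:
        _check_unique(self.lineages.index, "OTU")

    def ranks(self, otu_id: str) -> list[str]:
        """Split a lineage into its ranked labels (may be empty at low ranks)."""
        parts = [p.strip() for p in str(self.lineages.loc[otu_id]).split(";")]
        parts += [""] * (len(self.RANKS) - len(parts))
        return parts[: len(self.RANKS)]


@dataclass(frozen=True)
class RepSeqSet:
    """Representative DNA sequence per OTU."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"empty sequence for {otu}")
            if set(seq.upper()) - set("ACGTN"):
                raise ValidationError(f"non-ACGTN characters in sequence for {otu}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv",
                     orientation: str = "auto") -> CountTable:
    """Read an OTU count table from TSV or BIOM.

    TSV orientation is normalised to samples x OTUs.  With
    ``orientation="auto"`` a leading ``#OTU ID`` header cell (the classic
    BIOM TSV dialect) marks rows as OTUs; otherwise rows are taken as samples.
    """
    path = Path(path)
    if format == "biom":
        import biom

        table = biom.load_table(str(path))
        # biom convention: observations (OTUs) x samples
        df = pd.DataFrame(
            table.matrix_data.toarray().T,
            index=list(table.ids("sample")),
            columns=list(table.ids("observation")),
        )
        return CountTable(df)
    if format != "tsv":
        raise ValueError(f"unknown format: {format!r}")

    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # pragma: no cover - pandas gives the detail
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    first_cell = open(path).readline().split("\t")[0].strip()
    rows_are_otus = orientation == "otus" or (
        orientation == "auto" and first_cell.lstrip("#").lower().startswith("otu")
    )
    if rows_are_otus:
        df = df.T
    if df.isna().any().any():
        raise ValidationError(f"missing values in {path}")
    return CountTable(df)


def write_count_table(t: CountTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = t.counts.T
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        import biom

        table = biom.Table(t.counts.to_numpy().T, t.otu_ids, t.sample_ids)
        with open(path, "w") as fh:
            fh.write(table.to_json("commstable"))
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "sex" in df:
        df["sex"] = df["sex"].fillna("unknown").astype(str).str.lower()
    return SampleMetadata(df)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, header=None,
                     names=["otu_id", "lineage"])
    return TaxonomyTable(df["lineage"])


def read_rep_seqs(path: str | Path) -> RepSeqSet:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return RepSeqSet(seqs)


def write_rep_seqs(seqs: RepSeqSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu, seq in seqs.sequences.items():
            fh.write(f">{otu}\n{seq}\n")


# ---------------------------------------------------------------------------
# Filtering and normalisation
# ---------------------------------------------------------------------------

def filter_low_quality(t: CountTable, min_sample_depth: int = 10_000,
                       min_otu_samples: int = 2) -> CountTable:
    """Drop shallow samples, then OTUs occurring in too few samples.

    Defaults: samples with fewer than 10,000 total counts are removed, and
    OTUs present (count > 0) in fewer than 2 of the remaining samples are
    removed.
    """
    keep_samples = t.depths() >= min_sample_depth
    if not keep_samples.any():
        raise EmptyTableError("all samples fall below the depth threshold")
    df = t.counts.loc[keep_samples]
    occupancy = (df > 0).sum(axis=0)
    df = df.loc[:, occupancy >= min_otu_samples]
    return CountTable(df)


def prevalence_filter(t: CountTable, min_fraction: float = 0.25) -> CountTable:
    """Keep OTUs with nonzero counts in at least ``min_fraction`` of samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    occupancy = (t.counts > 0).mean(axis=0)
    return CountTable(t.counts.loc[:, occupancy >= min_fraction])


def rarefy(t: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` counts without replacement."""
    rng = np.random.default_rng(seed)
    counts = t.counts.to_numpy()
    out = np.empty_like(counts)
    for i, (sample, row) in enumerate(zip(t.sample_ids, counts)):
        total = int(row.sum())
        if total < depth:
            raise ValueError(
                f"sample {sample!r} has depth {total} < requested {depth}")
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(pd.DataFrame(out, index=t.counts.index,
                                   columns=t.counts.columns))


def relative_abundance(t: CountTable) -> RelAbundTable:
    totals = t.depths()
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValidationError(f"zero-total samples: {bad[:5]}")
    return RelAbundTable(t.counts.div(totals, axis=0))


# ---------------------------------------------------------------------------
# Diversity and sparsity
# ---------------------------------------------------------------------------

def _shannon(p: np.ndarray, base: float | None = None) -> float:
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h if base is None else h / np.log(base)


def _inv_simpson(p: np.ndarray) -> float:
    return float(1.0 / (p ** 2).sum())


def alpha_diversity(t: CountTable, metric: str = "shannon", depth: int = 10_000,
                    n_reps: int = 10, seed: int = 0,
                    log_base: float | None = None) -> pd.Series:
    """Per-sample diversity, averaged over ``n_reps`` rarefactions.

    Shannon H = -sum p_i ln p_i (natural log by default; ``log_base``
    overrides).  Inverse Simpson = 1 / sum p_i^2, the effective number of
    equally abundant OTUs.
    """
    if metric not in ("shannon", "inv_simpson"):
        raise ValueError(f"unknown metric: {metric!r}")
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    acc = np.zeros(len(t.sample_ids))
    for s in seeds:
        rare = rarefy(t, depth, int(s % (2 ** 31)))
        p = rare.counts.to_numpy() / depth
        for i, row in enumerate(p):
            acc[i] += (_shannon(row, log_base) if metric == "shannon"
                       else _inv_simpson(row))
    return pd.Series(acc / n_reps, index=t.counts.index, name=metric)


def sparsity(t: CountTable) -> float:
    """Fraction of zero cells in the count matrix."""
    values = t.counts.to_numpy()
    if values.size == 0:
        raise ValidationError("empty table")
    return float((values == 0).mean())
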