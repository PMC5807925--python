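"""Community characterisation and host-association regressions.

A community's abundance in a sample is the summed read count of its member
OTUs divided by the sample's total reads.  Log10-transformed abundances (with
a 1e-6 pseudocount) are regressed on BMI, age, sex and sequencing depth; the
BMI and age coefficients are extracted and FDR-adjusted per phenotype across
communities.  Communities are further characterised by their taxonomy make-up
and the mean pairwise global-alignment identity of their representative
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .communities import Partition
from .conet import bh_fdr
from .tables import CountTable, RepSeqSet, SampleMetadata, TaxonomyTable


@dataclass(frozen=True)
class CommunityAbundanceTable:
    """Per-sample relative abundance of each community (samples x communities).

    Community columns need not sum to 1: OTUs outside the network still count
    toward each sample's total reads.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("community abundances must lie in [0, 1]")


@dataclass(frozen=True)
class AssociationResult:
    community_id: int
    phenotype: str
    beta: float
    p: float
    q: float


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


def community_abundance(t: CountTable, part: Partition) -> CommunityAbundanceTable:
    """Sum member-OTU counts per community, divided by sample totals."""
    missing = set(part.assignment) - set(t.otu_ids)
    if missing:
        raise ValueError(f"partition OTUs absent from table: "
                         f"{sorted(map(str, missing))[:5]}")
    totals = t.depths()
    if (totals == 0).any():
        raise ValueError("zero-depth sample")
    cols = {}
    for cid, members in sorted(part.communities().items()):
        cols[cid] = t.counts[sorted(members, key=str)].sum(axis=1) / totals
    return CommunityAbundanceTable(pd.DataFrame(cols))


def log_abundance(a: CommunityAbundanceTable, pseudo: float = 1e-6) -> pd.DataFrame:
    """Elementwise log10(abundance + pseudo)."""
    return np.log10(a.values + pseudo)


def associate(log_abund: pd.DataFrame, metadata: SampleMetadata
              ) -> tuple[list[AssociationResult], list[int]]:
    """OLS of log community abundance on bmi + age + sex + depth.

    Returns (results, excluded): per community and phenotype in {bmi, age}
    the coefficient, two-tailed p and BH q (adjusted per phenotype across
    communities); constant-abundance communities are excluded from the FDR
    family and listed separately.  Samples with missing covariates are
    dropped listwise.
    """
    import statsmodels.formula.api as smf

    meta = metadata.data
    covars = ["bmi", "age", "sex", "depth"]
    missing_cols = [c for c in covars if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks covariates: {missing_cols}")
    samples = log_abund.index.intersection(meta.index)
    meta = meta.loc[samples, covars].copy()
    meta["sex"] = meta["sex"].fillna("unknown").astype(str)
    meta[["bmi", "age", "depth"]] = meta[["bmi", "age", "depth"]].apply(
        pd.to_numeric, errors="coerce")
    keep = meta[["bmi", "age", "depth"]].notna().all(axis=1)
    meta = meta.loc[keep]

    fits, excluded = {}, []
    for cid in log_abund.columns:
        y = log_abund.loc[meta.index, cid]
        if np.isclose(y.std(ddof=0), 0.0):
            excluded.append(int(cid))
            continue
        frame = meta.assign(abund=y.to_numpy())
        model = smf.ols("abund ~ bmi + age + C(sex) + depth", data=frame).fit()
        fits[int(cid)] = model

    results: list[AssociationResult] = []
    for phenotype in ("bmi", "age"):
        cids = sorted(fits)
        p = np.array([fits[c].pvalues[phenotype] for c in cids])
        q = bh_fdr(p) if len(p) else p
        for c, pv, qv in zip(cids, p, q):
            results.append(AssociationResult(
                community_id=c, phenotype=phenotype,
                beta=float(fits[c].params[phenotype]),
                p=float(pv), q=float(qv)))
    return results, excluded


def taxonomy_summary(part: Partition, tax: TaxonomyTable, level: str
                     ) -> pd.DataFrame:
    """OTU counts per taxon per community at a taxonomic rank.

    OTUs unassigned at the requested rank are bucketed under their assigned
    lineage prefix (e.g. ``k__Bacteria;p__Firmicutes;c__``).
    """
    if level not in TaxonomyTable.RANKS:
        raise ValueError(f"unknown rank: {level!r}")
    depth = TaxonomyTable.RANKS.index(level)
    rows = []
    for cid, members in part.communities().items():
        for otu in members:
            ranks = tax.ranks(otu)
            label = ranks[depth]
            if not label or label in TaxonomyTable.PREFIXES:
                label = ";".join(ranks[: depth + 1])
            rows.append((cid, label))
    df = pd.DataFrame(rows, columns=["community_id", "taxon"])
    return (df.groupby(["community_id", "taxon"]).size()
              .rename("n_otus").reset_index())


def _identity(seq_a: str, seq_b: str, scoring: AlignmentScoring,
              denominator: str = "alignment") -> float:
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=scoring.match,
        mismatch_score=scoring.mismatch, open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    if denominator == "shorter":
        length = min(len(seq_a), len(seq_b))
    return counts.identities / length


def mean_pairwise_identity(part: Partition, seqs: RepSeqSet,
                           scoring: AlignmentScoring = AlignmentScoring(),
                           denominator: str = "alignment") -> pd.Series:
    """Mean global-alignment identity between member OTU sequences.

    Identity = identical aligned positions / alignment length (gap columns
    count toward the length; ``denominator="shorter"`` divides by the shorter
    sequence length instead).  Singleton communities get NaN.
    """
    out = {}
    for cid, members in sorted(part.communities().items()):
        members = sorted(members, key=str)
        missing = [o for o in members if o not in seqs.sequences]
        if missing:
            raise ValueError(f"missing sequences: {missing[:5]}")
        if len(members) < 2:
            out[cid] = float("nan")
            continue
        idents = [_identity(seqs.sequences[a], seqs.sequences[b], scoring,
                            denominator)
                  for i, a in enumerate(members) for b in members[i + 1:]]
        out[cid] = float(np.mean(idents))
    return pd.Series(out, name="mean_identity")


def abundance_size_correlation(t: CountTable, part: Partition
                               ) -> tuple[float, float]:
    """Spearman correlation between an OTU's mean relative abundance and the
    size of its parent community."""
    otus = sorted(part.assignment, key=str)
    if len(otus) < 3:
        raise ValueError("need at least 3 OTUs")
    rel = t.counts.div(t.depths(), axis=0)
    mean_ab = rel[otus].mean(axis=0).to_numpy()
    sizes = part.communities()
    size_of = np.array([len(sizes[part.assignment[o]]) for o in otus],
                       dtype=float)
    if np.all(size_of == size_of[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(mean_ab, size_of)
    return float(rho), float(p)
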