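"""Tissue correction: advanced-stage counts referenced to early-stage means.

The core normalization of the package.  For each primary site the mean
early-stage count of every gene defines a reference profile; each
advanced-stage sample of that site is then expressed as the natural-log
ratio of its count to the site's reference mean.  The resulting matrix
measures how far each advanced tumour has moved from the early-stage
state of its own tissue, removing tissue-of-origin level differences
that otherwise dominate cross-cancer clustering.

Formally, with A the gene-by-advanced-sample count matrix, E the
gene-by-early-sample count matrix and one-hot site indicator matrices
P_A and P_E, the reference mean for gene i at site I is

    G[i, I] = (1 / m_I) * sum_k E[i, k] over early samples k of site I,

where m_I is the number of early samples at site I, and the corrected
value for advanced sample j of site I is

    L[i, j] = ln( (A[i, j] + c) / (G[i, I] + c) )

with pseudocount c (default 1) keeping the ratio finite at zero counts.
The divisor cohort is configurable: any stage label (e.g. matched normal
tissue) can serve as the reference, with identical arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stagenorm.io_formats import GenomicMatrix, SampleMetadata, UnitError


class StagingError(ValueError):
    """Raised when samples cannot be split into valid stage/site groups."""


@dataclass
class StagedExpressionSet:
    """Counts split by stage plus one-hot primary-site indicators.

    ``A`` (genes x advanced samples) and ``E`` (genes x reference
    samples) share the same gene index.  ``P_A`` and ``P_E`` are
    site-by-sample binary DataFrames whose columns each sum to exactly
    one: every sample belongs to exactly one primary site.
    """

    A: pd.DataFrame
    E: pd.DataFrame
    P_A: pd.DataFrame
    P_E: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.A.index.equals(self.E.index):
            raise StagingError("A and E must share gene ids and row order")
        for name, P, X in (("P_A", self.P_A, self.A), ("P_E", self.P_E, self.E)):
            if not P.columns.equals(X.columns):
                raise StagingError(f"{name} columns must match the expression columns")
            colsums = P.to_numpy().sum(axis=0)
            if not np.all(colsums == 1):
                raise StagingError(f"every column of {name} must sum to exactly 1")
        if not self.P_A.index.equals(self.P_E.index):
            raise StagingError("P_A and P_E must share site labels")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.A.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.P_A.index)

    def site_of_advanced(self) -> pd.Series:
        """Map each advanced sample to its site label."""
        return self.P_A.idxmax(axis=0)


@dataclass
class ReferenceMeans:
    """Per-site early-stage mean counts G (genes x sites) and group sizes m."""

    G: pd.DataFrame
    m: pd.Series

    def __post_init__(self) -> None:
        if (self.G.to_numpy() < 0).any():
            raise StagingError("reference means must be non-negative")
        if (self.m <= 0).any():
            raise StagingError("every site needs at least one reference sample")


@dataclass
class TissueCorrectedMatrix:
    """Natural-log ratios of advanced counts to site reference means."""

    L: pd.DataFrame
    site_of_sample: pd.Series
    pseudocount: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.L.to_numpy()).all():
            raise StagingError("corrected matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.L.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.L.columns)

    def to_genomic_matrix(self) -> GenomicMatrix:
        return GenomicMatrix(values=self.L.copy(), unit="log_ratio")


def build_staged_set(
    matrix: GenomicMatrix,
    metadata: Sequence[SampleMetadata],
    divisor_stage: str = "early",
    numerator_stage: str = "advanced",
) -> StagedExpressionSet:
    """Split a count matrix into numerator (A) and reference (E) cohorts.

    Column order within each stage follows the matrix; each site must
    contribute at least one reference sample or its divisor would be
    undefined.
    """
    if matrix.unit != "raw_count":
        raise UnitError(f"build_staged_set expects raw_count, got {matrix.unit!r}")
    meta_by_id = {m.sample_id: m for m in metadata}
    missing = [s for s in matrix.sample_ids if s not in meta_by_id]
    if missing:
        raise StagingError(f"samples without metadata: {missing[:5]}")

    adv_cols = [s for s in matrix.sample_ids if meta_by_id[s].stage == numerator_stage]
    ref_cols = [s for s in matrix.sample_ids if meta_by_id[s].stage == divisor_stage]
    if not adv_cols:
        raise StagingError(f"no samples with stage {numerator_stage!r}")
    if not ref_cols:
        raise StagingError(f"no samples with stage {divisor_stage!r}")

    sites = list(dict.fromkeys(meta_by_id[s].primary_site for s in adv_cols + ref_cols))
    ref_sites = {meta_by_id[s].primary_site for s in ref_cols}
    no_ref = [st for st in sites if st not in ref_sites]
    if no_ref:
        raise StagingError(
            f"sites without {divisor_stage!r} reference samples (divisor undefined): {no_ref}"
        )

    def one_hot(cols: list[str]) -> pd.DataFrame:
        P = pd.DataFrame(0, index=sites, columns=cols, dtype=int)
        for s in cols:
            P.loc[meta_by_id[s].primary_site, s] = 1
        return P

    return StagedExpressionSet(
        A=matrix.values[adv_cols],
        E=matrix.values[ref_cols],
        P_A=one_hot(adv_cols),
        P_E=one_hot(ref_cols),
    )


def reference_means(staged: StagedExpressionSet) -> ReferenceMeans:
    """Arithmetic mean of each gene's reference counts per site.

    ``m[I]`` is the column sum of the reference site-indicator matrix,
    i.e. the number of reference samples at site I.
    """
    P = staged.P_E.to_numpy(dtype=float)  # (t, r)
    m = P.sum(axis=1)
    if (m == 0).any():
        bad = [site for site, cnt in zip(staged.site_ids, m) if cnt == 0]
        raise StagingError(f"sites with zero reference samples: {bad}")
    sums = staged.E.to_numpy() @ P.T  # (s, t)
    G = pd.DataFrame(sums / m, index=staged.gene_ids, columns=staged.site_ids)
    return ReferenceMeans(G=G, m=pd.Series(m, index=staged.site_ids))


def tissue_correct(
    staged: StagedExpressionSet, pseudocount: float = 1.0
) -> TissueCorrectedMatrix:
    """Log-ratio normalize each advanced sample against its site reference.

    With ``pseudocount=0`` any zero numerator or denominator raises a
    domain error rather than emitting non-finite values; the default
    pseudocount of 1 keeps ratios finite and leaves large counts
    essentially unchanged.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    ref = reference_means(staged)
    site_of = staged.site_of_advanced()
    A = staged.A.to_numpy(dtype=float)
    G_cols = ref.G[site_of.to_numpy()].to_numpy()  # (genes, advanced samples)

    num = A + pseudocount
    den = G_cols + pseudocount
    if pseudocount == 0.0:
        bad = np.argwhere((num == 0.0) | (den == 0.0))
        if len(bad):
            pairs = [
                (staged.gene_ids[i], site_of.iloc[j]) for i, j in bad[:10]
            ]
            raise StagingError(
                f"zero counts at pseudocount=0 for (gene, site) pairs: {pairs}"
            )
    L = pd.DataFrame(
        np.log(num / den), index=staged.gene_ids, columns=staged.A.columns
    )
    return TissueCorrectedMatrix(L=L, site_of_sample=site_of, pseudocount=pseudocount)
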