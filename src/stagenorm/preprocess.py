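"""Unit conversion and the three gene filters, applied in a fixed order.

The upstream portal distributes expression as log2(x+1) of mapped read
counts; the pipeline inverts that transform once, restricts the matrix
to protein-coding genes, and then applies an arm-specific filter: the
uncorrected arm drops genes with low counts in nearly all samples, the
tissue-corrected arm drops all-zero rows.  All filters preserve row
order and are idempotent.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np

from stagenorm.io_formats import GenomicMatrix, UnitError

logger = logging.getLogger(__name__)

BiotypeTable = Mapping[str, str]

PROTEIN_CODING = "protein_coding"


def to_raw_counts(matrix: GenomicMatrix) -> GenomicMatrix:
    """Invert log2(x+1) back to integer read counts.

    Values derive from integer counts, so round-to-nearest reconstructs
    them exactly; negatives from floating error are clipped to zero.
    """
    if matrix.unit != "log2_plus1":
        raise UnitError(f"to_raw_counts expects unit log2_plus1, got {matrix.unit!r}")
    counts = np.round(np.exp2(matrix.values.to_numpy()) - 1.0)
    counts = np.clip(counts, 0.0, None)
    frame = matrix.values.copy()
    frame.loc[:, :] = counts
    return matrix.with_values(frame, unit="raw_count")


def filter_protein_coding(matrix: GenomicMatrix, biotypes: BiotypeTable) -> GenomicMatrix:
    """Keep only rows annotated protein_coding; order preserved.

    Genes absent from the biotype table are dropped and counted in a log
    message — an unannotated gene cannot be confirmed protein-coding.
    """
    keep = []
    n_unannotated = 0
    for g in matrix.gene_ids:
        bt = biotypes.get(g)
        if bt is None:
            n_unannotated += 1
        elif bt == PROTEIN_CODING:
            keep.append(g)
    if n_unannotated:
        logger.info("filter_protein_coding: %d genes had no biotype annotation", n_unannotated)
    if not keep:
        logger.warning("filter_protein_coding: no protein-coding genes retained")
    return matrix.with_values(matrix.values.loc[keep])


def filter_low_counts(
    matrix: GenomicMatrix, min_count: int = 10, max_low_fraction: float = 0.90
) -> GenomicMatrix:
    """Drop genes whose count is below ``min_count`` in more than
    ``max_low_fraction`` of samples (strict inequality on the fraction)."""
    if matrix.unit != "raw_count":
        raise UnitError(f"filter_low_counts expects unit raw_count, got {matrix.unit!r}")
    arr = matrix.values.to_numpy()
    low_fraction = (arr < min_count).mean(axis=1)
    keep = low_fraction <= max_low_fraction
    return matrix.with_values(matrix.values.loc[keep])


def filter_zero_rows(matrix: GenomicMatrix) -> GenomicMatrix:
    """Drop rows whose sum is exactly zero.

    Applied literally even to signed log-ratio matrices, where a row
    could in principle cancel to zero; such rows are vanishingly rare.
    """
    sums = matrix.values.sum(axis=1)
    keep = sums != 0.0
    return matrix.with_values(matrix.values.loc[keep])
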