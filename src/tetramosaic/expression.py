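"""Reproductive-tissue expression filtering of candidate genes.

Candidate non-parental genes are prioritised by whether they are expressed
in reproductive tissues (anther, ovary, pistil, embryo, spikelet), where a
gene influencing pollen fertility or seed setting would have to act.
Expression arrives as a gene x tissue matrix (rows = gene ids, columns =
tissue codes); a database-derived gene list is a second, independent
evidence source, and the two are intersected.

The threshold defaults to 0 with a strict inequality: any positive signal
counts as expressed, the weakest assumption when units (FPKM/TPM) and a
cutoff are not fixed.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

__all__ = ["REPRODUCTIVE_TISSUES", "expressed_in", "evidence_intersection"]

log = logging.getLogger(__name__)

#: default reproductive tissue codes
REPRODUCTIVE_TISSUES = ("anther", "ovary", "pistil", "embryo", "spikelet")


def expressed_in(
    matrix: pd.DataFrame,
    tissues: Iterable[str],
    threshold: float = 0.0,
) -> set[str]:
    """Genes with expression strictly above ``threshold`` in at least one
    of the requested tissues.

    Raises ``KeyError`` listing the available columns if a requested
    tissue is absent from the matrix.
    """
    tissues = list(tissues)
    unknown = [t for t in tissues if t not in matrix.columns]
    if unknown:
        raise KeyError(
            f"unknown tissues {unknown}; available: {list(matrix.columns)}"
        )
    mask = (matrix[tissues] > threshold).any(axis=1)
    return set(matrix.index[mask])


def evidence_intersection(
    a: set[str], b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Intersect two evidence sources: returns (both, a-only, b-only)."""
    both = a & b
    log.info("evidence intersection: |a|=%d |b|=%d |both|=%d",
             len(a), len(b), len(both))
    return both, a - b, b - a
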