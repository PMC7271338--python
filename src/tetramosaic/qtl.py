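"""Co-localization of shared non-parental variants with published QTLs.

QTL intervals (e.g. Gramene positions inferred from associated-marker
alignments) arrive as a TSV with 1-based inclusive coordinates on the same
assembly as the variant calls. A QTL is overlapped when at least one
variant position falls inside its interval — point-in-interval, no
flanking window. Nested or duplicated QTLs are counted independently by
id; category tallies count distinct overlapped QTLs per trait category.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from tetramosaic.shared import IntervalRecord
from tetramosaic.vcfio import Key

__all__ = ["read_qtl_table", "overlap_qtls"]

QTL_COLUMNS = ["qtl_id", "chrom", "start", "end", "trait_name", "category"]


def read_qtl_table(path: str | Path) -> list[IntervalRecord]:
    """Read a QTL table TSV (qtl_id, chrom, start, end, trait_name, category)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(QTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        if row.start > row.end:
            raise ValueError(
                f"QTL {row.qtl_id}: start {row.start} > end {row.end}"
            )
        records.append(
            IntervalRecord(str(row.chrom), int(row.start), int(row.end),
                           str(row.qtl_id), category=str(row.category))
        )
    return records


def overlap_qtls(
    keys: Iterable[Key],
    qtls: Sequence[IntervalRecord],
) -> tuple[pd.DataFrame, Counter]:
    """Tally variant hits per QTL and overlapped QTLs per category.

    Parameters
    ----------
    keys
        Variant keys ``(chrom, pos, ref, alt)`` — typically the shared
        non-parental set.
    qtls
        QTL intervals, 1-based inclusive.

    Returns
    -------
    hits : DataFrame with columns qtl_id, n_variants, category for every
        QTL with at least one variant inside its interval.
    category_tally : Counter of distinct overlapped QTLs per category.
    """
    trees: dict[str, IntervalTree] = {}
    for q in qtls:
        if q.start > q.end:
            raise ValueError(f"QTL {q.id}: start > end")
        trees.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end + 1, q)
    n_variants: Counter = Counter()
    category: dict[str, str] = {}
    for chrom, pos, _ref, _alt in keys:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree[pos]:
            q = hit.data
            n_variants[q.id] += 1
            category[q.id] = q.category
    hits = pd.DataFrame(
        [(qid, n, category[qid]) for qid, n in sorted(n_variants.items())],
        columns=["qtl_id", "n_variants", "category"],
    )
    category_tally = Counter(category.values())
    return hits, category_tally
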