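"""Parental-origin classification of offspring variants.

Each variant observed in a derived (sister) line is classified against the
two parents of the cross into one of four origin classes:

maternal
    sister carries the alt, the maternal parent carries it, the paternal
    parent does not — positive evidence for a maternally inherited block.
paternal
    the mirror image.
non-parental
    sister carries an alt found in neither parent — a candidate de-novo /
    non-parental allele.
uninformative
    everything else: the sister lacks the alt, both parents carry it, or
    any of the three genotypes is missing. A reliable marker requires both
    parents genotyped; absence of the alt in the sister is not counted as
    evidence for the other parent by default, because in a tetraploid an
    absent call is confounded with allele dosage and calling sensitivity.
    Pass ``absence_informative=True`` for the stricter interpretation in
    which sister alt-absence at a parent-differential site supports the
    alt-absent parent.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Sequence

from tetramosaic.vcfio import CallSet, Key, Presence, VariantSite

__all__ = ["Origin", "MarkerCall", "classify_marker", "classify_all"]

log = logging.getLogger(__name__)


class Origin(enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    NON_PARENTAL = "non-parental"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class MarkerCall:
    """Origin classification of one variant in one sister line."""

    key: Key
    sister: str
    origin: Origin

    @property
    def chrom(self) -> str:
        return self.key[0]

    @property
    def pos(self) -> int:
        return self.key[1]


def classify_marker(
    site: VariantSite,
    mother: str,
    father: str,
    sister: str,
    absence_informative: bool = False,
) -> MarkerCall:
    """Classify one site in one sister against the two parents.

    Raises ``KeyError`` if any of the three sample ids is absent from the
    site's presence map.
    """
    for sample in (mother, father, sister):
        if sample not in site.presence:
            raise KeyError(f"sample {sample!r} not present at {site.key}")
    m = site.presence[mother]
    f = site.presence[father]
    s = site.presence[sister]

    origin = Origin.UNINFORMATIVE
    if Presence.MISSING not in (m, f, s):
        if s is Presence.PRESENT:
            if m is Presence.PRESENT and f is Presence.ABSENT:
                origin = Origin.MATERNAL
            elif f is Presence.PRESENT and m is Presence.ABSENT:
                origin = Origin.PATERNAL
            elif m is Presence.ABSENT and f is Presence.ABSENT:
                origin = Origin.NON_PARENTAL
        elif absence_informative:
            # sister lacks an allele only one parent carries: weak evidence
            # for having inherited the block from the alt-absent parent
            if m is Presence.PRESENT and f is Presence.ABSENT:
                origin = Origin.PATERNAL
            elif f is Presence.PRESENT and m is Presence.ABSENT:
                origin = Origin.MATERNAL
    return MarkerCall(site.key, sister, origin)


def classify_all(
    calls: CallSet,
    mother: str,
    father: str,
    sisters: Sequence[str],
    absence_informative: bool = False,
) -> dict[str, list[MarkerCall]]:
    """Classify every site for every sister.

    Returns a mapping sister id -> list of :class:`MarkerCall` (one per
    site, in call-set order, uninformative calls included). Per-class
    tallies are logged per sister.
    """
    out: dict[str, list[MarkerCall]] = {s: [] for s in sisters}
    for site in calls:
        for sister in sisters:
            out[sister].append(
                classify_marker(site, mother, father, sister, absence_informative)
            )
    for sister, stream in out.items():
        tally = Counter(c.origin.value for c in stream)
        log.info("marker classes for %s: %s", sister, dict(tally))
    return out


def iter_informative(stream: Sequence[MarkerCall]) -> Iterator[MarkerCall]:
    """Yield only origin-informative calls (maternal/paternal/non-parental)."""
    return (c for c in stream if c.origin is not Origin.UNINFORMATIVE)
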