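"""VCF-backed variant call sets: reading, writing, filtering, concordance.

The unit of all downstream marker logic is the :class:`VariantSite` — one
biallelic variant keyed by ``(chrom, pos, ref, alt)`` with a per-sample
alt-allele presence state. Tetraploid dosage is deliberately not modelled:
genotypes collapse to alt-present / alt-absent / missing, because upstream
callers run in diploid mode on these materials and the block logic only
uses variant presence.

Coordinates are VCF 1-based positions throughout this module; the window
arithmetic in :mod:`tetramosaic.blocks` converts to 0-based half-open with
``pos - 1``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "Presence",
    "VariantSite",
    "CallSet",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "concordance",
]

#: variant key type: (chrom, pos, ref, alt)
Key = tuple[str, int, str, str]


class Presence(enum.Enum):
    """Alt-allele presence state of one sample at one site."""

    PRESENT = "present"
    ABSENT = "absent"
    MISSING = "missing"


class VcfParseError(ValueError):
    """Raised for malformed VCF records, naming the offending record."""


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant with per-sample alt presence.

    Parameters
    ----------
    chrom, pos, ref, alt
        The variant key; ``pos`` is 1-based as in VCF.
    qual
        Site quality score (``None`` if the VCF QUAL column is missing).
    effect
        Functional effect label carried in INFO (e.g. ``nonsynonymous``),
        or ``None`` when un-annotated.
    presence
        Mapping sample id -> :class:`Presence`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    effect: str | None = None
    presence: Mapping[str, Presence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> Key:
        return (self.chrom, self.pos, self.ref, self.alt)


class CallSet:
    """An ordered, key-unique collection of :class:`VariantSite`.

    Sites are kept sorted by ``(chrom, pos, ref, alt)``; duplicate keys are
    rejected. ``samples`` is the ordered sample-id list shared by all sites.
    """

    def __init__(
        self,
        samples: Sequence[str],
        sites: Iterable[VariantSite] = (),
        provenance: str = "",
    ) -> None:
        self.samples = list(samples)
        self.provenance = provenance
        self._sites: list[VariantSite] = sorted(sites, key=lambda s: s.key)
        self._by_key: dict[Key, VariantSite] = {}
        for s in self._sites:
            if s.key in self._by_key:
                raise ValueError(f"duplicate variant key {s.key}")
            self._by_key[s.key] = s

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self):
        return iter(self._sites)

    def __contains__(self, key: Key) -> bool:
        return key in self._by_key

    def __getitem__(self, key: Key) -> VariantSite:
        return self._by_key[key]

    def keys(self) -> list[Key]:
        return [s.key for s in self._sites]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        if self.samples != other.samples or len(self) != len(other):
            return False
        for a, b in zip(self._sites, other._sites):
            if a.key != b.key or a.qual != b.qual or a.effect != b.effect:
                return False
            if dict(a.presence) != dict(b.presence):
                return False
        return True

    def subset_samples(self, samples: Sequence[str]) -> "CallSet":
        """Project onto a subset of samples (sites retained unchanged)."""
        missing = set(samples) - set(self.samples)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        sites = [
            VariantSite(
                s.chrom, s.pos, s.ref, s.alt, s.qual, s.effect,
                {sm: s.presence.get(sm, Presence.MISSING) for sm in samples},
            )
            for s in self._sites
        ]
        return CallSet(samples, sites, provenance=self.provenance)


def _presence_from_gt(alleles: tuple | None) -> Presence:
    if alleles is None or all(a is None for a in alleles):
        return Presence.MISSING
    return Presence.PRESENT if any(a not in (None, 0) for a in alleles) else Presence.ABSENT


def read_vcf(
    path: str | Path,
    min_qual: float = 30.0,
    biallelic_only: bool = True,
    provenance: str | None = None,
) -> CallSet:
    """Read a VCF into a :class:`CallSet`, applying site-level filters.

    Sites with QUAL below ``min_qual`` are dropped (a missing QUAL counts
    as 0). With ``biallelic_only`` multi-allelic records are dropped.
    Unsorted input is sorted on load with a warning. The effect label is
    taken from the INFO key ``EFF`` when present.
    """
    path = Path(path)
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        record_no = 0
        try:
            for rec in vcf:
                record_no += 1
                if rec.alts is None:
                    continue
                if biallelic_only and len(rec.alts) != 1:
                    continue
                qual = rec.qual
                if (qual if qual is not None else 0.0) < min_qual:
                    continue
                eff = rec.info.get("EFF")
                if isinstance(eff, tuple):
                    eff = eff[0]
                presence = {
                    sm: _presence_from_gt(rec.samples[sm].get("GT"))
                    for sm in samples
                }
                sites.append(
                    VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                                qual=qual, effect=eff, presence=presence)
                )
        except (ValueError, OSError) as exc:  # pysam raises ValueError on bad records
            raise VcfParseError(
                f"malformed VCF record near data line {record_no + 1} of {path}: {exc}"
            ) from exc
    keys = [s.key for s in sites]
    if keys != sorted(keys):
        warnings.warn(f"{path} is not coordinate-sorted; sorting on load", stacklevel=2)
    return CallSet(samples, sites, provenance=provenance or str(path))


def write_vcf(callset: CallSet, path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a :class:`CallSet` as an uncompressed VCF 4.2 file.

    Output is deterministic for identical inputs (no timestamps). GT is
    written as 0/1 (alt-present), 0/0 (alt-absent) or ./. (missing).
    """
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for s in callset:
        # contig length must cover every position written
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos)
    for chrom in sorted(contigs):
        header.contigs.add(chrom, length=contigs[chrom])
    header.info.add("EFF", 1, "String", "Functional effect label")
    header.formats.add("GT", 1, "String", "Genotype")
    for sm in callset.samples:
        header.add_sample(sm)
    gt_code = {Presence.PRESENT: (0, 1), Presence.ABSENT: (0, 0), Presence.MISSING: (None,)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in callset:
            rec = out.new_record(
                contig=s.chrom, start=s.pos - 1, stop=s.pos,
                alleles=(s.ref, s.alt), qual=s.qual,
            )
            if s.effect is not None:
                rec.info["EFF"] = s.effect
            for sm in callset.samples:
                rec.samples[sm]["GT"] = gt_code[s.presence.get(sm, Presence.MISSING)]
            out.write(rec)


def concordance(
    a: CallSet,
    b: CallSet,
    keys: Iterable[Key] | None = None,
) -> float:
    """Percentage agreement in alt-presence between two call sets.

    Compared units are (variant key, sample) pairs over the samples common
    to both call sets, restricted to ``keys`` when given and otherwise the
    union of both key sets. A pair matches when both call sets report the
    same presence state; pairs where either state is missing (including a
    key absent from one call set entirely) are excluded from the
    denominator. The result is ``100 * matches / compared`` rounded half-up
    to 2 decimals, and is symmetric in ``a`` and ``b``.

    Raises
    ------
    ValueError
        If no pair is comparable (the rate is undefined).
    """
    from tetramosaic._util import round_half_up

    shared_samples = [sm for sm in a.samples if sm in set(b.samples)]
    if not shared_samples:
        raise ValueError("call sets share no samples; concordance undefined")
    if keys is None:
        key_list = sorted(set(a.keys()) | set(b.keys()))
    else:
        key_list = sorted(set(keys))
    compared = matches = 0
    for key in key_list:
        sa = a[key] if key in a else None
        sb = b[key] if key in b else None
        for sm in shared_samples:
            pa = sa.presence.get(sm, Presence.MISSING) if sa else Presence.MISSING
            pb = sb.presence.get(sm, Presence.MISSING) if sb else Presence.MISSING
            if pa is Presence.MISSING or pb is Presence.MISSING:
                continue
            compared += 1
            if pa is pb:
                matches += 1
    if compared == 0:
        raise ValueError("zero comparable sites; concordance rate undefined")
    return round_half_up(100.0 * matches / compared, 2)
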