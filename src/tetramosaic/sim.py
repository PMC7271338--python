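"""Synthetic pedigrees, trait tables and expression matrices with planted truth.

The generator emulates the statistical structure the genome-composition
analysis assumes, at desk scale:

* two divergent parental lines, each carrying private alt alleles at a
  configurable per-bp rate;
* recombinant sister lines whose chromosomes are mosaics of maternal and
  paternal segments (breakpoints snapped to window boundaries by default,
  so inferred window types can be compared to truth exactly), with an
  optional per-chromosome inheritance bias emulating the observed
  whole-chromosome maternal/paternal skews;
* non-parental variant hotspots shared by every sister (and absent from
  both parents), plus line-private novel variants at a low rate;
* nonsynonymous / synonymous effect labels at a configurable fraction.

Parental private variants are never placed inside a declared hotspot
interval: hotspots model distinct rearrangement blocks, not windows of
mixed ancestry, and keeping them free of parental markers makes the
planted truth exactly recoverable under the 75%-support window rule.
Novel variants never collide with parental variant positions, keeping the
marker categories disjoint.

This is a test harness emulating block structure, not a biological model
of the breeding program's recombination process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tetramosaic.vcfio import CallSet, Key, Presence, VariantSite, write_vcf

__all__ = [
    "SimConfig",
    "Hotspot",
    "TruthTable",
    "PedigreeSim",
    "default_config",
    "simulate_pedigree",
    "simulate_traits",
    "simulate_expression",
]

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Hotspot:
    """A non-parental variant hotspot shared by all sisters.

    ``start``/``end`` are 0-based half-open bp on ``chrom``.
    """

    chrom: str
    start: int
    end: int
    n_variants: int


@dataclass
class SimConfig:
    """Pedigree simulation parameters.

    Defaults are the desk-scale study conditions: 13 sister lines, two
    1-Mb chromosomes tiled in 10-kb windows, dense parental markers
    (2 per kb per parent), a handful of recombination breakpoints per
    chromosome, and a low line-private novel-variant rate.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_sisters: int = 13
    parental_variant_rate: float = 2e-3
    recomb_breakpoints_per_chrom: int = 3
    inheritance_bias: dict[str, float] = field(default_factory=dict)
    np_hotspots: list[Hotspot] = field(default_factory=list)
    private_novel_rate: float = 1e-5
    nonsyn_fraction: float = 0.5
    seed: int = 0
    window_size: int = 10_000
    snap_breakpoints: bool = True
    mother: str = "96025"
    father: str = "Jackson-4x"

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chroms}

    @property
    def sisters(self) -> list[str]:
        return [f"NTR{i + 1:02d}" for i in range(self.n_sisters)]

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_sisters) < 1:
            raise ConfigError("counts must be positive")
        for name, rate in [
            ("parental_variant_rate", self.parental_variant_rate),
            ("private_novel_rate", self.private_novel_rate),
        ]:
            if rate < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.nonsyn_fraction <= 1.0:
            raise ConfigError("nonsyn_fraction must be in [0, 1]")
        chroms = set(self.chroms)
        for chrom, p in self.inheritance_bias.items():
            if chrom not in chroms:
                raise ConfigError(f"inheritance_bias names unknown chromosome {chrom!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"inheritance_bias[{chrom!r}]={p} not in [0, 1]")
        for h in self.np_hotspots:
            if h.chrom not in chroms:
                raise ConfigError(f"hotspot on unknown chromosome {h.chrom!r}")
            if not (0 <= h.start < h.end <= self.chrom_length_bp):
                raise ConfigError(
                    f"hotspot {h.chrom}:{h.start}-{h.end} outside chromosome bounds"
                )
            if h.n_variants < 0:
                raise ConfigError("hotspot n_variants must be >= 0")
            if h.n_variants > h.end - h.start:
                raise ConfigError(
                    f"hotspot {h.chrom}:{h.start}-{h.end} cannot hold "
                    f"{h.n_variants} distinct positions"
                )


@dataclass
class TruthTable:
    """Planted truth for one simulated pedigree.

    ``block_origin`` maps (sister, chrom, window_index) to the inherited
    origin of the underlying segment; ``np_sites_shared`` are the hotspot
    variant keys carried by every sister; ``np_sites_private`` maps each
    sister to her private novel variant keys (disjoint from the shared
    set by construction).
    """

    block_origin: dict[tuple[str, str, int], str]
    np_sites_shared: set[Key]
    np_sites_private: dict[str, set[Key]]

    def shared_np_windows(self, window_size: int) -> set[tuple[str, int]]:
        """Windows containing at least one planted shared hotspot variant."""
        return {
            (chrom, (pos - 1) // window_size)
            for chrom, pos, _r, _a in self.np_sites_shared
        }


@dataclass
class PedigreeSim:
    """Simulation output: the multi-sample call set plus planted truth."""

    callset: CallSet
    truth: TruthTable
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCFs (combined, parents-only, sisters-only) and truth TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        paths = {
            "combined_vcf": outdir / "combined.vcf",
            "parents_vcf": outdir / "parents.vcf",
            "sisters_vcf": outdir / "sisters.vcf",
            "truth_blocks": outdir / "truth_blocks.tsv",
            "truth_np_shared": outdir / "truth_np_shared.tsv",
            "truth_np_private": outdir / "truth_np_private.tsv",
        }
        lengths = cfg.chrom_lengths
        write_vcf(self.callset, paths["combined_vcf"], lengths)
        write_vcf(self.callset.subset_samples([cfg.mother, cfg.father]),
                  paths["parents_vcf"], lengths)
        write_vcf(self.callset.subset_samples(cfg.sisters),
                  paths["sisters_vcf"], lengths)
        rows = [
            {"sister": s, "chrom": c, "window_index": i, "origin": o}
            for (s, c, i), o in sorted(self.truth.block_origin.items())
        ]
        pd.DataFrame(rows).to_csv(paths["truth_blocks"], sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.np_sites_shared),
            columns=["chrom", "pos", "ref", "alt"],
        ).to_csv(paths["truth_np_shared"], sep="\t", index=False)
        priv_rows = [
            {"sister": s, "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3]}
            for s in sorted(self.truth.np_sites_private)
            for k in sorted(self.truth.np_sites_private[s])
        ]
        pd.DataFrame(
            priv_rows, columns=["sister", "chrom", "pos", "ref", "alt"]
        ).to_csv(paths["truth_np_private"], sep="\t", index=False)
        return paths


def default_config(seed: int = 0) -> SimConfig:
    """Desk-scale default configuration with 140 planted shared hotspots.

    70 windows per chromosome (of 100) are chosen as single-window
    hotspots of 5 variants each — 140 shared non-parental windows covering
    1.4 Mb, mirroring the block structure the analysis is designed to
    recover. Chromosome 2 is given a strong maternal inheritance bias to
    emulate whole-chromosome skew.
    """
    cfg = SimConfig(seed=seed, inheritance_bias={"chr02": 0.95})
    rng = np.random.default_rng(seed + 1_000_003)
    n_windows = cfg.chrom_length_bp // cfg.window_size
    hotspots = []
    for chrom in cfg.chroms:
        picks = np.sort(rng.choice(n_windows, size=70, replace=False))
        for w in picks:
            hotspots.append(
                Hotspot(chrom, int(w) * cfg.window_size,
                        (int(w) + 1) * cfg.window_size, 5)
            )
    cfg.np_hotspots = hotspots
    return cfg


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _effects(rng: np.random.Generator, n: int, nonsyn_fraction: float) -> list[str]:
    draws = rng.random(n) < nonsyn_fraction
    return ["nonsynonymous" if d else "synonymous" for d in draws]


def _segment_origins(
    rng: np.random.Generator, cfg: SimConfig, chrom: str
) -> list[tuple[int, int, str]]:
    """Draw one sister chromosome's mosaic: [(start, end, origin), ...] in
    0-based half-open bp."""
    L = cfg.chrom_length_bp
    k = cfg.recomb_breakpoints_per_chrom
    if cfg.snap_breakpoints:
        boundaries = np.arange(cfg.window_size, L, cfg.window_size)
    else:
        boundaries = np.arange(1, L)
    k = min(k, len(boundaries))
    bps = np.sort(rng.choice(boundaries, size=k, replace=False)) if k else np.array([], int)
    p_maternal = cfg.inheritance_bias.get(chrom, 0.5)
    edges = [0, *bps.tolist(), L]
    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        origin = "maternal" if rng.random() < p_maternal else "paternal"
        segments.append((int(a), int(b), origin))
    return segments


def _origin_at(segments: list[tuple[int, int, str]], pos0: int) -> str:
    for a, b, origin in segments:
        if a <= pos0 < b:
            return origin
    raise ValueError(f"position {pos0} outside segments")


def _window_origin(
    segments: list[tuple[int, int, str]], w_start: int, w_end: int
) -> str:
    """Origin of the segment covering the majority of a window (earlier
    segment wins ties). Exact when breakpoints are window-aligned."""
    best, best_cov = None, -1
    for a, b, origin in segments:
        cov = min(b, w_end) - max(a, w_start)
        if cov > best_cov:
            best, best_cov = origin, cov
    return best


def simulate_pedigree(config: SimConfig) -> PedigreeSim:
    """Simulate two parents and ``n_sisters`` recombinant sister lines.

    Returns the multi-sample :class:`~tetramosaic.vcfio.CallSet` (samples:
    mother, father, sisters) together with the planted
    :class:`TruthTable`. Deterministic given ``config.seed``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sisters = cfg.sisters
    ws = cfg.window_size

    sites: list[VariantSite] = []
    block_origin: dict[tuple[str, str, int], str] = {}
    np_shared: set[Key] = set()
    np_private: dict[str, set[Key]] = {s: set() for s in sisters}

    for chrom in cfg.chroms:
        L = cfg.chrom_length_bp
        hotspots = [h for h in cfg.np_hotspots if h.chrom == chrom]
        in_hotspot = np.zeros(L, dtype=bool)
        for h in hotspots:
            in_hotspot[h.start:h.end] = True
        used = np.zeros(L, dtype=bool)  # index = pos - 1

        # parental private variants, drawn outside hotspot intervals
        allowed = np.flatnonzero(~in_hotspot) + 1  # 1-based positions
        n_m = int(rng.poisson(cfg.parental_variant_rate * len(allowed)))
        n_p = int(rng.poisson(cfg.parental_variant_rate * len(allowed)))
        n_m = min(n_m, len(allowed))
        n_p = min(n_p, len(allowed) - n_m)
        par_pos = rng.choice(allowed, size=n_m + n_p, replace=False)
        maternal_pos = np.sort(par_pos[:n_m])
        paternal_pos = np.sort(par_pos[n_m:])
        used[par_pos - 1] = True

        # sister mosaics and truth windows
        segs = {s: _segment_origins(rng, cfg, chrom) for s in sisters}
        n_windows = -(-L // ws)
        for s in sisters:
            for i in range(n_windows):
                block_origin[(s, chrom, i)] = _window_origin(
                    segs[s], i * ws, min((i + 1) * ws, L)
                )

        def add_sites(positions, presence_fn, effects):
            refs, alts = _draw_alleles(rng, len(positions))
            for pos, ref, alt, eff in zip(positions, refs, alts, effects):
                pos = int(pos)
                presence = presence_fn(pos)
                sites.append(
                    VariantSite(chrom, pos, str(ref), str(alt), qual=60.0,
                                effect=eff, presence=presence)
                )

        def parental_presence(parent_origin):
            def fn(pos):
                p = {
                    cfg.mother: Presence.PRESENT if parent_origin == "maternal" else Presence.ABSENT,
                    cfg.father: Presence.PRESENT if parent_origin == "paternal" else Presence.ABSENT,
                }
                for s in sisters:
                    carried = _origin_at(segs[s], pos - 1) == parent_origin
                    p[s] = Presence.PRESENT if carried else Presence.ABSENT
                return p
            return fn

        add_sites(maternal_pos, parental_presence("maternal"),
                  _effects(rng, len(maternal_pos), cfg.nonsyn_fraction))
        add_sites(paternal_pos, parental_presence("paternal"),
                  _effects(rng, len(paternal_pos), cfg.nonsyn_fraction))

        # shared non-parental hotspot variants
        def shared_presence(pos):
            p = {cfg.mother: Presence.ABSENT, cfg.father: Presence.ABSENT}
            p.update({s: Presence.PRESENT for s in sisters})
            return p

        for h in hotspots:
            span = np.arange(h.start + 1, h.end + 1)  # 1-based
            free = span[~used[span - 1]]
            if len(free) < h.n_variants:
                raise ConfigError(
                    f"hotspot {h.chrom}:{h.start}-{h.end} has only "
                    f"{len(free)} free positions for {h.n_variants} variants"
                )
            pos = np.sort(rng.choice(free, size=h.n_variants, replace=False))
            used[pos - 1] = True
            refs, alts = _draw_alleles(rng, len(pos))
            effs = _effects(rng, len(pos), cfg.nonsyn_fraction)
            for p_, r_, a_ in zip(pos, refs, alts):
                np_shared.add((chrom, int(p_), str(r_), str(a_)))
            for p_, r_, a_, e_ in zip(pos, refs, alts, effs):
                sites.append(
                    VariantSite(chrom, int(p_), str(r_), str(a_), qual=60.0,
                                effect=e_, presence=shared_presence(int(p_)))
                )

        # line-private novel variants
        for s in sisters:
            n_priv = rng.poisson(cfg.private_novel_rate * L)
            free = np.flatnonzero(~used) + 1
            if n_priv > len(free):
                n_priv = len(free)
            if n_priv == 0:
                continue
            pos = np.sort(rng.choice(free, size=n_priv, replace=False))
            used[pos - 1] = True
            refs, alts = _draw_alleles(rng, len(pos))
            effs = _effects(rng, len(pos), cfg.nonsyn_fraction)

            private = {cfg.mother: Presence.ABSENT, cfg.father: Presence.ABSENT}
            private.update({t: Presence.ABSENT for t in sisters})
            private[s] = Presence.PRESENT
            for p_, r_, a_, e_ in zip(pos, refs, alts, effs):
                np_private[s].add((chrom, int(p_), str(r_), str(a_)))
                sites.append(
                    VariantSite(chrom, int(p_), str(r_), str(a_), qual=60.0,
                                effect=e_, presence=dict(private))
                )

    callset = CallSet([cfg.mother, cfg.father, *sisters], sites,
                      provenance=f"simulated pedigree (seed={cfg.seed})")
    truth = TruthTable(block_origin, np_shared, np_private)
    return PedigreeSim(callset, truth, cfg)


def simulate_traits(
    group_specs: Sequence[tuple[str, Mapping[str, float], Mapping[str, float], int]],
    seed: int = 0,
):
    """Draw replicate trait tables from per-group normal models.

    ``group_specs`` is a list of (group name, per-trait means, per-trait
    sds, n_replicates). With sd=0 every replicate equals the group mean.
    Deterministic given ``seed``.
    """
    from tetramosaic.traits import TraitTable

    rng = np.random.default_rng(seed)
    rows = []
    for name, means, sds, n_rep in group_specs:
        if n_rep < 2:
            raise ValueError(
                f"group {name!r}: n_replicates={n_rep} < 2, no variance estimable"
            )
        if set(means) != set(sds):
            raise ValueError(f"group {name!r}: mean and sd trait sets differ")
        bad = [t for t, sd in sds.items() if sd < 0]
        if bad:
            raise ValueError(f"group {name!r}: negative sd for {bad}")
        draws = {
            t: means[t] + sds[t] * rng.standard_normal(n_rep) for t in means
        }
        for i in range(n_rep):
            rows.append({"line": name, "replicate": i + 1,
                         **{t: float(draws[t][i]) for t in means}})
    return TraitTable(pd.DataFrame(rows))


def simulate_expression(
    genes: Sequence[str],
    tissues: Sequence[str],
    expressed_map: Mapping[str, Sequence[str]],
    baseline: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x tissue expression matrix with planted expressed cells.

    Cells listed in ``expressed_map`` are strictly above ``baseline``;
    all other cells are at or below it (uniform on [0, baseline]).
    """
    if not tissues:
        raise ValueError("tissues must be non-empty")
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    tissue_set = set(tissues)
    for gene, ts in expressed_map.items():
        unknown = set(ts) - tissue_set
        if unknown:
            raise ValueError(
                f"expressed_map[{gene!r}] names unknown tissues {sorted(unknown)}"
            )
    rng = np.random.default_rng(seed)
    mat = rng.uniform(0.0, baseline, size=(len(genes), len(tissues))) \
        if baseline > 0 else np.zeros((len(genes), len(tissues)))
    df = pd.DataFrame(mat, index=list(genes), columns=list(tissues))
    for gene, ts in expressed_map.items():
        if gene not in df.index:
            raise ValueError(f"expressed_map names unknown gene {gene!r}")
        for t in ts:
            df.loc[gene, t] = baseline + float(rng.uniform(0.5, 5.0))
    return df
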