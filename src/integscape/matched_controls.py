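"""Matched random control generation for integration-site sets.

Two modes mirror the two detection chemistries:

* **uniform** — for inverse-/TAIL-PCR sets: a large pool of fixed-length
  random genomic locations (optionally restricted to a mappability track) is
  sampled without replacement into N replicate control sets of the
  experimental size. Defaults: a pool of one million 50-bp locations
  (matching typical junction-read length) resampled 1000 times.

* **re_matched** — for linker-mediated-PCR NGS sets, where a site can only be
  recovered if a restriction fragment of mappable length spans it: each
  experimental site is keyed by (nearest enzyme, distance in bp); every
  control replicate places, for each site, one random point at exactly that
  distance from a uniformly chosen genome-wide occurrence of the same enzyme.
  Matching is constructive (place at the key distance) rather than rejective;
  a rejective variant is provided for cross-validation on small genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_core import (
    FeatureTrack,
    Genome,
    GenomicInterval,
    IntegrationSite,
    as_intervals,
    scan_motif_sites,
)
from .site_filtering import DEFAULT_RE_MOTIFS


@dataclass(frozen=True)
class SiteMatchKey:
    """Restriction-match key: nearest enzyme and exact distance in bp."""

    enzyme: str
    distance: int


@dataclass
class RestrictionIndex:
    """Sorted motif-occurrence positions per enzyme per chromosome."""

    positions: dict[str, dict[str, np.ndarray]]
    motifs: dict[str, str]

    @classmethod
    def build(cls, genome: Genome, motifs=None) -> "RestrictionIndex":
        motifs = dict(motifs or DEFAULT_RE_MOTIFS)
        positions = {}
        for enzyme, motif in motifs.items():
            track = scan_motif_sites(genome, motif, name=enzyme)
            per_chrom: dict[str, np.ndarray] = {}
            for iv in track.intervals:
                per_chrom.setdefault(iv.chrom, []).append(iv.start)
            positions[enzyme] = {
                chrom: np.asarray(sorted(pos), dtype=np.int64)
                for chrom, pos in per_chrom.items()
            }
        return cls(positions=positions, motifs=motifs)


@dataclass
class ControlSetCollection:
    """N replicate control site sets matched to one experimental set."""

    sets: list[list[GenomicInterval]]
    seed: int
    mode: str  # "uniform" | "re_matched"
    keys: list[SiteMatchKey] | None = None
    _arrays: list[dict[str, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def set_arrays(self) -> list[dict[str, np.ndarray]]:
        """Per-set {chrom: (n,2) start/end array}; cached (sets treated
        immutable after first query)."""
        if self._arrays is None:
            out = []
            for s in self.sets:
                by_chrom: dict[str, list[tuple[int, int]]] = {}
                for iv in s:
                    by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
                out.append(
                    {c: np.asarray(p, dtype=np.int64) for c, p in by_chrom.items()}
                )
            self._arrays = out
        return self._arrays


def uniform_controls(
    genome: Genome,
    mappability: FeatureTrack | None,
    set_size: int,
    n_sets: int,
    site_len: int = 50,
    pool_size: int = 1_000_000,
    seed: int = 0,
) -> ControlSetCollection:
    """Replicate control sets sampled from a pool of uniform random locations.

    The pool holds ``pool_size`` intervals of ``site_len`` bp drawn uniformly
    over the genome (chromosome chosen proportional to the number of valid
    start positions). If a mappability track is given, only pool intervals
    fully contained in an allowed region are retained. Each replicate is a
    sample of ``set_size`` pool entries without replacement.
    """
    if site_len < 1:
        raise ValueError("site_len must be >= 1")
    if pool_size < set_size:
        raise ValueError("pool_size must be >= set_size")
    rng = np.random.default_rng(seed)
    chroms = [c for c, L in genome.lengths.items() if L >= site_len]
    if not chroms:
        raise ValueError("no chromosome long enough for site_len")
    n_starts = np.array([genome.lengths[c] - site_len + 1 for c in chroms],
                        dtype=np.float64)
    chrom_idx = rng.choice(len(chroms), size=pool_size, p=n_starts / n_starts.sum())
    starts = (rng.random(pool_size) * n_starts[chrom_idx]).astype(np.int64)

    if mappability is not None:
        merged = mappability.merged_arrays()
        keep = np.zeros(pool_size, dtype=bool)
        for ci, chrom in enumerate(chroms):
            mask = chrom_idx == ci
            if chrom not in merged or not mask.any():
                continue
            ms, me = merged[chrom]
            if ms.size == 0:
                continue
            s = starts[mask]
            # contained: the covering region must start at or before s and
            # end at or after s + site_len
            idx = np.searchsorted(ms, s, side="right") - 1
            ok = idx >= 0
            contained = np.zeros(s.shape, dtype=bool)
            contained[ok] = me[idx[ok]] >= s[ok] + site_len
            keep[mask] = contained
        chrom_idx, starts = chrom_idx[keep], starts[keep]
        if chrom_idx.size < set_size:
            raise ValueError(
                f"mappability-filtered pool ({chrom_idx.size}) smaller than "
                f"set_size ({set_size})"
            )
    pool_n = chrom_idx.size
    sets = []
    for _ in range(n_sets):
        pick = rng.choice(pool_n, size=set_size, replace=False)
        sets.append(
            [
                GenomicInterval(chroms[chrom_idx[i]], int(starts[i]),
                                int(starts[i]) + site_len)
                for i in pick
            ]
        )
    return ControlSetCollection(sets=sets, seed=seed, mode="uniform")


def nearest_re_distance(
    site: IntegrationSite, index: RestrictionIndex
) -> SiteMatchKey:
    """Nearest restriction-site key for one insertion.

    The distance is the absolute bp offset from the insertion point to the
    closest motif start over all enzymes, in either direction. Ties over
    enzymes break by the index's enzyme order; ties between two equidistant
    occurrences of one enzyme are irrelevant to the key (same distance).
    """
    chrom = site.location.chrom
    p = site.insertion_point
    best: SiteMatchKey | None = None
    for enzyme, per_chrom in index.positions.items():
        pos = per_chrom.get(chrom)
        if pos is None or pos.size == 0:
            continue
        i = int(np.searchsorted(pos, p))
        cands = []
        if i < pos.size:
            cands.append(abs(int(pos[i]) - p))
        if i > 0:
            cands.append(abs(int(pos[i - 1]) - p))
        d = min(cands)
        if best is None or d < best.distance:
            best = SiteMatchKey(enzyme, d)
    if best is None:
        raise ValueError(
            f"no restriction occurrence on chromosome {chrom!r} for site at "
            f"{chrom}:{p}"
        )
    return best


def re_matched_controls(
    sites: list[IntegrationSite],
    index: RestrictionIndex,
    genome: Genome,
    n_sets: int = 1000,
    seed: int = 0,
    max_retries: int = 1000,
) -> ControlSetCollection:
    """Constructive restriction-matched controls.

    For each experimental site the (enzyme, distance) key is computed once;
    for each replicate a genome-wide occurrence of that enzyme is drawn
    uniformly and a 1-bp control point is placed at exactly the key distance
    on a uniformly chosen side. Placements falling off the chromosome are
    rejected and redrawn (bounded retries).
    """
    rng = np.random.default_rng(seed)
    keys = [nearest_re_distance(s, index) for s in sites]
    # flattened genome-wide occurrence lists per enzyme
    occ: dict[str, tuple[list[str], np.ndarray]] = {}
    for enzyme, per_chrom in index.positions.items():
        chrom_names: list[str] = []
        flat = []
        for chrom, pos in per_chrom.items():
            chrom_names.extend([chrom] * pos.size)
            flat.append(pos)
        occ[enzyme] = (
            chrom_names,
            np.concatenate(flat) if flat else np.empty(0, dtype=np.int64),
        )
    lengths = genome.lengths
    sets = []
    for _ in range(n_sets):
        one = []
        for site, key in zip(sites, keys):
            chrom_names, flat = occ[key.enzyme]
            if flat.size == 0:
                raise ValueError(f"no genome-wide occurrence for {key.enzyme}")
            placed = None
            for _attempt in range(max_retries):
                j = int(rng.integers(flat.size))
                side = 1 if rng.random() < 0.5 else -1
                p = int(flat[j]) + side * key.distance
                chrom = chrom_names[j]
                if 0 <= p < lengths[chrom]:
                    placed = GenomicInterval(chrom, p, p + 1,
                                             site.location.strand)
                    break
            if placed is None:
                raise RuntimeError(
                    f"could not place control for key {key} within "
                    f"{max_retries} retries"
                )
            one.append(placed)
        sets.append(one)
    return ControlSetCollection(sets=sets, seed=seed, mode="re_matched",
                                keys=keys)


def re_matched_controls_rejective(
    sites: list[IntegrationSite],
    index: RestrictionIndex,
    genome: Genome,
    n_sets: int,
    seed: int = 0,
    max_draws: int = 100_000,
) -> ControlSetCollection:
    """Rejective cross-check: draw uniform points until the nearest-enzyme
    key matches each experimental key exactly. Exponentially slow for large
    distances; intended only for validating the constructive sampler on toy
    genomes."""
    rng = np.random.default_rng(seed)
    keys = [nearest_re_distance(s, index) for s in sites]
    chroms = list(genome.sequences)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=np.float64)
    sets = []
    for _ in range(n_sets):
        one = []
        for site, key in zip(sites, keys):
            for _attempt in range(max_draws):
                ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
                p = int(rng.integers(int(lens[ci])))
                probe = IntegrationSite(
                    GenomicInterval(chroms[ci], p, p + 1, "+"),
                    vector=site.vector, fragment_count=0, method="NGS",
                )
                try:
                    if nearest_re_distance(probe, index) == key:
                        one.append(probe.location)
                        break
                except ValueError:
                    continue
            else:
                raise RuntimeError(f"rejective sampler exhausted for {key}")
        sets.append(one)
    return ControlSetCollection(sets=sets, seed=seed, mode="re_matched",
                                keys=keys)
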