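"""Synthetic genomes, annotations, and integration-site sets with planted
biases.

Every pipeline stage in this package is exercised against data from these
generators: an i.i.d. random genome with non-overlapping planted gene models,
derived feature tracks, an FPKM expression table with known
maternal/zygotic classes, and integration sites whose placement can be
biased toward feature tracks (fold reweighting), TSS windows, or windows of
high DNA flexibility (rejection sampling on the standardized 48-bp window
mean of a chosen step parameter). Fragment counts follow a lognormal
supporting-fragment model with an optional class of count-1 noise calls
planted next to restriction recognition sites, mimicking the artifact class
that motivates the stringent filter tier.

Default scales are deliberately small (megabase genomes, hundreds to a few
thousand sites) so that every stage runs in seconds while keeping the
statistical structure of the genome-scale analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_core import (
    FeatureTrack,
    GeneModel,
    Genome,
    GenomicInterval,
    IntegrationSite,
)
from .matched_controls import RestrictionIndex
from .sequence_profile import step_table, window_means

_EDGE_MARGIN = 30  # keep sites far enough from chromosome ends for 48-bp windows


@dataclass
class BiasSpec:
    """Planted biases for :func:`simulate_sites`.

    feature_folds
        track name -> fold f: the per-base placement weight inside the track
        is multiplied by f (then renormalized), so the downstream enrichment
        ratio approaches f / (1 + (f - 1) * coverage).
    tss_bias
        (fold, window_bp) applied to the window around every TSS.
    flexibility_bias
        (parameter, beta): accept candidate sites with probability
        proportional to exp(beta * z) where z is the candidate's 48-bp
        window-mean parameter standardized against 10^4 random windows.
    fragment_count_model
        (mu, sigma) of the lognormal supporting-fragment distribution.
    noise_singleton_fraction
        fraction of sites emitted as count-1 artifact calls placed adjacent
        to restriction recognition sites.
    tsd
        annotate sites as 8-bp target-site duplications (transposon vectors)
        rather than 1-bp points.
    """

    feature_folds: dict[str, float] = field(default_factory=dict)
    tss_bias: tuple[float, int] | None = None
    flexibility_bias: tuple[str, float] | None = None
    fragment_count_model: tuple[float, float] = (5.0, 1.2)
    noise_singleton_fraction: float = 0.0
    tsd: bool = True
    seed: int = 0

    def __post_init__(self):
        for name, f in self.feature_folds.items():
            if not np.isfinite(f) or f < 0:
                raise ValueError(f"fold for {name!r} must be finite and >= 0")
        if not 0 <= self.noise_singleton_fraction <= 1:
            raise ValueError("noise_singleton_fraction must be in [0, 1]")


def make_genome(length: int, gc_fraction: float = 0.4, seed: int = 0,
                n_chroms: int = 1) -> Genome:
    """An i.i.d. random genome with the requested GC content."""
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if length < n_chroms:
        raise ValueError("length must be >= n_chroms")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    per = length // n_chroms
    sequences = {}
    for i in range(n_chroms):
        n = per if i < n_chroms - 1 else length - per * (n_chroms - 1)
        draws = rng.choice(4, size=n, p=[at, gc, gc, at])
        sequences[f"chr{i + 1}"] = (
            np.frombuffer(b"ACGT", dtype=np.uint8)[draws].tobytes().decode()
        )
    return Genome(sequences)


def make_gene_models(
    genome: Genome,
    n_genes: int = 60,
    length_range: tuple[int, int] = (3000, 15000),
    exon_count_range: tuple[int, int] = (2, 6),
    exon_length_range: tuple[int, int] = (100, 500),
    utr_length_range: tuple[int, int] = (100, 400),
    seed: int = 0,
    min_gap: int = 2000,
    upstream_bp: int = 5000,
) -> tuple[list[GeneModel], dict[str, FeatureTrack]]:
    """Non-overlapping gene models plus exactly-consistent derived tracks.

    Gene spans are mostly intronic (exons of a few hundred bp inside spans of
    kilobases), mirroring vertebrate gene architecture where the genome-wide
    exonic fraction is a few percent. Derived tracks: ``gene_spans``,
    ``exons``, ``introns``, ``coding_exons``, ``five_prime_utr``,
    ``three_prime_utr``, ``upstream_5kb`` (strand-oriented promoter windows)
    and ``intergenic`` (beyond ``upstream_bp`` of every TSS and TTS).
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=np.float64)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise RuntimeError(
                f"could not place {n_genes} non-overlapping genes "
                f"(placed {len(genes)})"
            )
        chrom = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
        glen = int(rng.integers(length_range[0], length_range[1] + 1))
        if lengths[chrom] < glen + 2 * min_gap:
            continue
        start = int(rng.integers(min_gap, lengths[chrom] - glen - min_gap))
        end = start + glen
        if any(start < e + min_gap and s - min_gap < end
               for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_make_gene(
            f"gene{len(genes) + 1:04d}", chrom, start, end, strand,
            exon_count_range, exon_length_range, utr_length_range, rng,
        ))
    genes.sort(key=lambda g: (g.span.chrom, g.span.start))
    return genes, derive_tracks(genome, genes, upstream_bp=upstream_bp)

_MIN_INTRON = 100


def _make_gene(gene_id, chrom, start, end, strand, exon_count_range,
               exon_length_range, utr_length_range, rng) -> GeneModel:
    glen = end - start
    k = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
    exon_lens = rng.integers(exon_length_range[0], exon_length_range[1] + 1,
                             size=k)
    # shrink exon count until exons plus minimal introns fit the span
    while k > 1 and exon_lens[:k].sum() + _MIN_INTRON * (k - 1) > glen:
        k -= 1
    exon_lens = exon_lens[:k]
    if k == 1:
        exon_lens = np.array([min(int(exon_lens[0]), glen)])
    intron_total = glen - int(exon_lens.sum())
    if k > 1:
        extra = intron_total - _MIN_INTRON * (k - 1)
        props = rng.dirichlet(np.ones(k - 1))
        intron_lens = _MIN_INTRON + (props * extra).astype(int)
        intron_lens[-1] += extra - int((props * extra).astype(int).sum())
    else:
        intron_lens = np.empty(0, dtype=int)
    exons = []
    pos = start
    for i in range(k):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        pos += int(exon_lens[i])
        if i < k - 1:
            pos += int(intron_lens[i])
    # single-exon genes: pin the exon to the span so TSS/TTS stay exonic
    if k == 1:
        exons = [GenomicInterval(chrom, start, end, strand)]
    utr5 = int(rng.integers(*utr_length_range))
    utr3 = int(rng.integers(*utr_length_range))
    first, last = exons[0], exons[-1]
    left_utr = utr5 if strand == "+" else utr3
    right_utr = utr3 if strand == "+" else utr5
    cds_start = first.start + min(left_utr, len(first) - 1)
    cds_end = last.end - min(right_utr, len(last) - 1)
    if cds_start >= cds_end:
        cds_start, cds_end = first.start, last.end
    return GeneModel(gene_id=gene_id, span=GenomicInterval(chrom, start, end, strand),
                     exons=exons, cds_start=cds_start, cds_end=cds_end)


def derive_tracks(genome: Genome, genes: list[GeneModel],
                  upstream_bp: int = 5000) -> dict[str, FeatureTrack]:
    spans, exons, introns, coding, utr5, utr3, upstream = ([] for _ in range(7))
    for g in genes:
        spans.append(g.span)
        s = g.span
        for ex in g.exons:
            exons.append(ex)
            lo, hi = ex.start, min(ex.end, g.cds_start)
            if lo < hi:
                (utr5 if s.strand == "+" else utr3).append(
                    GenomicInterval(s.chrom, lo, hi, s.strand))
            lo, hi = max(ex.start, g.cds_start), min(ex.end, g.cds_end)
            if lo < hi:
                coding.append(GenomicInterval(s.chrom, lo, hi, s.strand))
            lo, hi = max(ex.start, g.cds_end), ex.end
            if lo < hi:
                (utr3 if s.strand == "+" else utr5).append(
                    GenomicInterval(s.chrom, lo, hi, s.strand))
        introns.extend(g.introns)
        if s.strand == "+":
            lo, hi = max(0, s.start - upstream_bp), s.start
        else:
            lo, hi = s.end, min(genome.lengths[s.chrom], s.end + upstream_bp)
        if lo < hi:
            upstream.append(GenomicInterval(s.chrom, lo, hi, s.strand))

    # intergenic: complement of span +/- upstream_bp on both sides
    intergenic = []
    for chrom, L in genome.lengths.items():
        blocks = sorted(
            (max(0, g.span.start - upstream_bp),
             min(L, g.span.end + upstream_bp))
            for g in genes if g.span.chrom == chrom
        )
        pos = 0
        for lo, hi in blocks:
            if lo > pos:
                intergenic.append(GenomicInterval(chrom, pos, lo))
            pos = max(pos, hi)
        if pos < L:
            intergenic.append(GenomicInterval(chrom, pos, L))
    return {
        "gene_spans": FeatureTrack("gene_spans", spans),
        "exons": FeatureTrack("exons", exons),
        "introns": FeatureTrack("introns", introns),
        "coding_exons": FeatureTrack("coding_exons", coding),
        "five_prime_utr": FeatureTrack("five_prime_utr", utr5),
        "three_prime_utr": FeatureTrack("three_prime_utr", utr3),
        "upstream_5kb": FeatureTrack("upstream_5kb", upstream),
        "intergenic": FeatureTrack("intergenic", intergenic),
    }


def _position_weights(genome: Genome, genes, tracks, bias: BiasSpec
                      ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-chromosome placement weights; edges zeroed so flanking windows
    always fit."""
    chroms = list(genome.sequences)
    weights = []
    for chrom in chroms:
        L = genome.lengths[chrom]
        w = np.ones(L, dtype=np.float64)
        w[:_EDGE_MARGIN] = 0.0
        w[L - _EDGE_MARGIN:] = 0.0
        weights.append(w)
    cidx = {c: i for i, c in enumerate(chroms)}
    for name, fold in bias.feature_folds.items():
        if name not in tracks:
            raise KeyError(f"unknown track {name!r} in feature_folds")
        for chrom, (starts, ends) in tracks[name].merged_arrays().items():
            w = weights[cidx[chrom]]
            for s, e in zip(starts, ends):
                w[s:e] *= fold
    if bias.tss_bias is not None:
        fold, window = bias.tss_bias
        for g in genes:
            w = weights[cidx[g.span.chrom]]
            lo = max(0, g.tss - window)
            hi = min(len(w), g.tss + window + 1)
            w[lo:hi] *= fold
    flat = np.concatenate(weights)
    total = flat.sum()
    if total <= 0:
        raise ValueError("all placement weight is zero")
    return chroms, flat, np.array([genome.lengths[c] for c in chroms])


def _draw_positions(rng, flat_cum, n):
    u = rng.random(n) * flat_cum[-1]
    return np.searchsorted(flat_cum, u, side="right")


def _window_mean_stats(genome: Genome, parameter: str, rng, n_sample=10_000):
    """Genome-wide mean/sd of the 48-bp window-mean step parameter, used to
    standardize the flexibility-bias acceptance score."""
    table = step_table()
    chroms = list(genome.sequences)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=np.float64)
    windows = []
    for _ in range(n_sample):
        ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
        p = int(rng.integers(_EDGE_MARGIN, int(lens[ci]) - _EDGE_MARGIN))
        windows.append(genome.sequences[chroms[ci]][p - 20:p + 28])
    wm = window_means(windows, table, parameter)
    return float(wm.mean()), float(wm.std())


def simulate_sites(
    genome: Genome,
    genes: list[GeneModel],
    tracks: dict[str, FeatureTrack],
    n_sites: int,
    bias: BiasSpec,
    vector: str = "Ds",
    method: str = "NGS",
    max_total_draws: int = 5_000_000,
) -> list[IntegrationSite]:
    """Integration sites with the planted biases of ``bias``.

    Placement is uniform per base, reweighted by the feature folds and TSS
    bias; the flexibility bias is then applied by rejection sampling with
    acceptance probability exp(beta * (z - 4)) for clipped standardized
    window scores z in [-4, 4] (an exact bound for the exponential tilt).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(bias.seed)
    chroms, flat, chrom_lens = _position_weights(genome, genes, tracks, bias)
    flat_cum = np.cumsum(flat)
    bounds = np.cumsum(chrom_lens)

    n_noise = int(round(bias.noise_singleton_fraction * n_sites))
    n_signal = n_sites - n_noise

    if bias.flexibility_bias is None:
        flat_idx = _draw_positions(rng, flat_cum, n_signal)
    else:
        parameter, beta = bias.flexibility_bias
        mu, sd = _window_mean_stats(genome, parameter, rng)
        table = step_table()
        accepted: list[int] = []
        total = 0
        cat = "".join(genome.sequences[c] for c in chroms)
        while len(accepted) < n_signal:
            batch = max(1024, 4 * (n_signal - len(accepted)))
            total += batch
            if total > max_total_draws:
                raise RuntimeError(
                    "flexibility-bias rejection sampling exhausted its draw "
                    "budget; use a smaller |beta|"
                )
            cand = _draw_positions(rng, flat_cum, batch)
            wins = [cat[p - 20:p + 28] for p in cand]
            z = (window_means(wins, table, parameter) - mu) / sd
            z = np.clip(z, -4.0, 4.0)
            acc = np.exp(beta * z - abs(beta) * 4.0)
            keep = rng.random(batch) < acc
            accepted.extend(int(p) for p in cand[keep])
        flat_idx = np.asarray(accepted[:n_signal])

    sites: list[IntegrationSite] = []
    mu_c, sd_c = bias.fragment_count_model
    counts = np.maximum(2, np.round(rng.lognormal(mu_c, sd_c, n_signal))).astype(int)
    site_len = 8 if bias.tsd else 1
    for p, count in zip(flat_idx, counts):
        ci = int(np.searchsorted(bounds, p, side="right"))
        chrom = chroms[ci]
        local = int(p) - (int(bounds[ci - 1]) if ci else 0)
        local = min(local, genome.lengths[chrom] - site_len - _EDGE_MARGIN)
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(
            IntegrationSite(
                GenomicInterval(chrom, local, local + site_len, strand),
                vector=vector, fragment_count=int(count), method=method,
            )
        )

    if n_noise:
        sites.extend(
            _noise_singletons(genome, n_noise, site_len, vector, method, rng)
        )
    return sites


def _noise_singletons(genome, n_noise, site_len, vector, method, rng):
    """Count-1 artifact calls planted within 10 bp of restriction recognition
    sites, emulating the enzyme-adjacent artifact class of linker-mediated
    PCR libraries."""
    index = RestrictionIndex.build(genome)
    occs = [
        (chrom, int(p))
        for per in index.positions.values()
        for chrom, pos in per.items()
        for p in pos
    ]
    if not occs:
        raise RuntimeError("no restriction occurrences to anchor noise sites")
    out = []
    for _ in range(n_noise):
        chrom, occ = occs[int(rng.integers(len(occs)))]
        offset = int(rng.integers(-10, 11))
        p = occ + offset
        p = max(_EDGE_MARGIN,
                min(p, genome.lengths[chrom] - site_len - _EDGE_MARGIN))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(
            IntegrationSite(
                GenomicInterval(chrom, p, p + site_len, strand),
                vector=vector, fragment_count=1, method=method,
            )
        )
    return out


DEFAULT_TIMEPOINTS = ("2cell", "128cell", "1000cell", "dome", "shield", "bud")
DEFAULT_CLASS_FRACTIONS = {
    "maternal_only": 0.20,
    "zygotic_only": 0.30,
    "maternal_zygotic": 0.35,
    "silent": 0.15,
}


def make_expression_table(
    genes: list[GeneModel],
    timepoints=DEFAULT_TIMEPOINTS,
    class_fractions=None,
    zga_index: int = 2,
    seed: int = 0,
):
    """FPKM table across timepoints with exactly recoverable expression
    classes: expressed values are drawn >= 1, unexpressed values < 1, so the
    threshold-1 classifier recovers every planted class."""
    import pandas as pd

    from .gene_context import ExpressionTable

    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = list(fractions)
    assign = rng.choice(len(classes), size=len(genes),
                        p=[fractions[c] for c in classes])
    n_t = len(timepoints)
    values = np.empty((len(genes), n_t))
    for i, ci in enumerate(assign):
        cls = classes[ci]
        expressed_pre = cls in ("maternal_only", "maternal_zygotic")
        expressed_post = cls in ("zygotic_only", "maternal_zygotic")
        for j in range(n_t):
            on = expressed_pre if j < zga_index else expressed_post
            values[i, j] = (
                1.0 + rng.lognormal(1.0, 1.0) if on else rng.uniform(0.0, 0.9)
            )
    df = pd.DataFrame(values, index=[g.gene_id for g in genes],
                      columns=list(timepoints))
    df.index.name = "gene_id"
    return ExpressionTable(df, zga_index=zga_index)
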