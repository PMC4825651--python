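"""Gene assignment, subregion classification, metagene/anchor profiles, and
expression-class association for integration sites.

Assignment rules
----------------
Two assignment windows are used:

* region/metagene analyses assign a site to every gene whose strand-oriented
  window ``[TSS - upstream_bp, TTS]`` overlaps it (default 5 kb upstream);
  sites hitting no window are intergenic;
* expression association assigns within +/- ``flank_bp`` of the TSS-TTS span
  (default 5 kb on both sides).

When several genes (or several subregion features) overlap one site, all are
counted. Metagene position normalizes the unspliced gene span to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, GenomicInterval, IntegrationSite, as_intervals

REGIONS = (
    "upstream",
    "five_prime_utr",
    "coding_exon",
    "intron",
    "three_prime_utr",
    "downstream",
)

EXPRESSION_CLASSES = ("maternal_only", "zygotic_only", "maternal_zygotic", "silent")


@dataclass
class GeneAssignment:
    site_index: int
    gene_id: str
    regions: tuple[str, ...]
    metagene_pct: float | None
    tss_offset: int | None
    tts_offset: int | None


def _site_interval(site) -> GenomicInterval:
    return site.location if isinstance(site, IntegrationSite) else site


def _site_point(site) -> int:
    if isinstance(site, IntegrationSite):
        return site.insertion_point
    iv = site
    return iv.start if len(iv) == 1 else iv.midpoint


def gene_window(gene: GeneModel, upstream_bp: int, downstream_bp: int = 0
                ) -> GenomicInterval:
    """Strand-oriented assignment window around a gene span."""
    s = gene.span
    if s.strand == "+":
        lo, hi = s.start - upstream_bp, s.end + downstream_bp
    else:
        lo, hi = s.start - downstream_bp, s.end + upstream_bp
    return GenomicInterval(s.chrom, max(0, lo), hi, s.strand)


def classify_region(site, gene: GeneModel, upstream_bp: int = 5000,
                    downstream_bp: int = 0) -> set[str]:
    """All gene subregions overlapped by a site (>= 1 bp rule).

    Exonic sequence splits into 5'-UTR / coding exon / 3'-UTR at the CDS
    bounds (strand-aware); non-exonic span is intron; the upstream (and,
    if enabled, downstream) windows flank the span.
    """
    iv = _site_interval(site)
    span = gene.span
    out: set[str] = set()
    if iv.chrom != span.chrom:
        return out

    def hits(lo: int, hi: int) -> bool:
        return lo < hi and iv.start < hi and lo < iv.end

    # flanking windows
    if span.strand == "+":
        up = (span.start - upstream_bp, span.start)
        down = (span.end, span.end + downstream_bp)
    else:
        up = (span.end, span.end + upstream_bp)
        down = (span.start - downstream_bp, span.start)
    if upstream_bp and hits(max(0, up[0]), up[1]):
        out.add("upstream")
    if downstream_bp and hits(max(0, down[0]), down[1]):
        out.add("downstream")

    for ex in gene.exons:
        utr_left = (ex.start, min(ex.end, gene.cds_start))
        coding = (max(ex.start, gene.cds_start), min(ex.end, gene.cds_end))
        utr_right = (max(ex.start, gene.cds_end), ex.end)
        left_label = "five_prime_utr" if span.strand == "+" else "three_prime_utr"
        right_label = "three_prime_utr" if span.strand == "+" else "five_prime_utr"
        if hits(*utr_left):
            out.add(left_label)
        if hits(*coding):
            out.add("coding_exon")
        if hits(*utr_right):
            out.add(right_label)
    for intron in gene.introns:
        if hits(intron.start, intron.end):
            out.add("intron")
    return out


def metagene_position(site, gene: GeneModel) -> float:
    """Position within the gene span as a percentage of normalized length.

    0 at the TSS base, 100 at the TTS base, measured along the gene's
    orientation from the site's point coordinate (midpoint for 8-bp
    target-site-duplication intervals).
    """
    p = _site_point(site)
    span = gene.span
    if _site_interval(site).chrom != span.chrom or not (span.start <= p < span.end):
        raise ValueError(
            f"site point {p} outside gene {gene.gene_id} span "
            f"{span.chrom}:{span.start}-{span.end}"
        )
    L = len(span)
    if L == 1:
        return 0.0
    d = p - span.start if span.strand == "+" else span.end - 1 - p
    return 100.0 * d / (L - 1)


def assign_to_genes(
    sites, genes: list[GeneModel], upstream_bp: int = 5000,
    downstream_bp: int = 0,
) -> list[GeneAssignment]:
    """Assign each site to every gene whose window overlaps it.

    Returns one :class:`GeneAssignment` per (site, gene) pair; sites with no
    assignment are intergenic and simply absent from the output.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    out = []
    for i, site in enumerate(sites):
        iv = _site_interval(site)
        p = _site_point(site)
        for g in by_chrom.get(iv.chrom, []):
            w = gene_window(g, upstream_bp, downstream_bp)
            if not (iv.start < w.end and w.start < iv.end):
                continue
            span = g.span
            in_span = span.start <= p < span.end
            sign = 1 if span.strand == "+" else -1
            out.append(
                GeneAssignment(
                    site_index=i,
                    gene_id=g.gene_id,
                    regions=tuple(sorted(
                        classify_region(site, g, upstream_bp, downstream_bp))),
                    metagene_pct=metagene_position(site, g) if in_span else None,
                    tss_offset=sign * (p - g.tss),
                    tts_offset=sign * (p - g.tts),
                )
            )
    return out


def anchor_profile(
    sites, genes: list[GeneModel], anchor: str = "TSS",
    window_bp: int = 1000, bin_bp: int = 50,
) -> pd.DataFrame:
    """Histogram of strand-oriented site offsets around gene TSS or TTS.

    Offsets are signed along the gene orientation (negative = upstream of the
    anchor); one entry per (site, gene) pair within ``window_bp``. Columns:
    ``bin_lo``, ``bin_hi`` (offset bounds), ``count``.
    """
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be 'TSS' or 'TTS'")
    if window_bp <= 0 or bin_bp <= 0:
        raise ValueError("window_bp and bin_bp must be positive")
    offsets = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    for site in sites:
        iv = _site_interval(site)
        p = _site_point(site)
        for g in by_chrom.get(iv.chrom, []):
            a = g.tss if anchor == "TSS" else g.tts
            off = (p - a) if g.span.strand == "+" else (a - p)
            if -window_bp <= off <= window_bp:
                offsets.append(off)
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    counts, _ = np.histogram(offsets, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionTable:
    """Per-gene FPKM across developmental timepoints.

    ``zga_index`` is the column index of the first post-ZGA (zygotic genome
    activation) timepoint; columns before it are maternal. A gene is called
    expressed at a timepoint when FPKM >= ``threshold`` (default 1, the
    conventional detection floor).
    """

    fpkm: pd.DataFrame  # index: gene_id, columns: timepoints
    zga_index: int
    threshold: float = 1.0

    def __post_init__(self):
        if not 0 < self.zga_index < len(self.fpkm.columns):
            raise ValueError("zga_index must split the timepoint columns")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def overall(self) -> pd.Series:
        """Summed FPKM across timepoints (the 'overall expression level')."""
        return self.fpkm.sum(axis=1)

    @property
    def classes(self) -> pd.Series:
        pre = (self.fpkm.iloc[:, : self.zga_index] >= self.threshold).any(axis=1)
        post = (self.fpkm.iloc[:, self.zga_index:] >= self.threshold).any(axis=1)
        out = np.where(
            pre & post, "maternal_zygotic",
            np.where(pre, "maternal_only", np.where(post, "zygotic_only", "silent")),
        )
        return pd.Series(out, index=self.fpkm.index, name="class")


def read_expression(path, zga_index: int, threshold: float = 1.0) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df, zga_index=zga_index, threshold=threshold)


def write_expression(expr: ExpressionTable, path) -> None:
    expr.fpkm.to_csv(path, sep="\t", index_label="gene_id")


def _flatten_gene_ids(assignments) -> set[str]:
    if assignments and isinstance(assignments[0], list):
        return {a.gene_id for lst in assignments for a in lst}
    return {a.gene_id for a in assignments}


def expression_association(
    assignments: list[GeneAssignment],
    expr: ExpressionTable,
    control_assignments,
) -> pd.DataFrame:
    """Expression summary of targeted genes vs control-targeted genes.

    Rows ``experimental``/``control``; columns: gene counts, mean and median
    overall FPKM, expression-class composition, and the number of genes
    missing from the table (counted as silent with overall 0).
    """
    overall = expr.overall
    classes = expr.classes
    rows = {}
    for label, gene_ids in (
        ("experimental", _flatten_gene_ids(assignments)),
        ("control", _flatten_gene_ids(control_assignments)),
    ):
        present = sorted(g for g in gene_ids if g in overall.index)
        n_missing = len(gene_ids) - len(present)
        vals = np.concatenate([overall.loc[present].to_numpy(),
                               np.zeros(n_missing)])
        cls = list(classes.loc[present]) + ["silent"] * n_missing
        n = len(gene_ids)
        row = {
            "n_genes": n,
            "n_missing_from_table": n_missing,
            "mean_fpkm": float(vals.mean()) if n else np.nan,
            "median_fpkm": float(np.median(vals)) if n else np.nan,
        }
        for c in EXPRESSION_CLASSES:
            row[f"frac_{c}"] = (cls.count(c) / n) if n else np.nan
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")
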