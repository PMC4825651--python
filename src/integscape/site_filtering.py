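"""Fragment-count filtering of putative NGS insertions and site deduplication.

Linker-mediated-PCR sequencing of insertion junctions yields putative sites
supported by varying numbers of distinct fragments; low-count calls are
dominated by artifacts. Two regimes are implemented:

* *selected* sets (stable reporter-selected lines): a site is high-confidence
  only when supported by strictly more than ``selected_gt`` fragments
  (default 50).
* *unselected* sets (pooled injected embryos, inserts diluted across pools):
  the general cut-off drops to ``unselected_ge`` (default 7, inclusive), but
  sites whose neighbourhood contains a recognition sequence of one of the
  restriction enzymes used in the library preparation are held to the
  stringent ``re_ge`` (default 50, inclusive) — enzyme recognition sequences
  are highly prevalent among single-fragment artifact calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic_core import Genome, IntegrationSite

DEFAULT_RE_MOTIFS = {"MseI": "TTAA", "BfaI": "CTAG", "Csp6I": "GTAC"}

SELECTED_GT = 50      # strict: keep iff count > 50
UNSELECTED_GE = 7     # inclusive: keep iff count >= 7
RE_GE = 50            # inclusive: RE-adjacent sites need count >= 50
RE_WINDOW_BP = 20     # half-width of the neighbourhood scanned for RE motifs


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped: int
    n_kept_with_re_motif: int = 0
    fraction_re: float = 0.0

    def __post_init__(self):
        assert self.n_kept + self.n_dropped == self.n_input


def filter_selected(
    sites: list[IntegrationSite], threshold_gt: int = SELECTED_GT
) -> tuple[list[IntegrationSite], FilterReport]:
    """High-confidence filter for reporter-selected sets.

    NGS sites pass iff ``fragment_count > threshold_gt``; sites detected by
    TAIL-PCR or inverse-PCR are trusted unconditionally (they were validated
    by mapping, not fragment support).
    """
    kept = [
        s for s in sites
        if s.method != "NGS" or s.fragment_count > threshold_gt
    ]
    report = FilterReport(len(sites), len(kept), len(sites) - len(kept))
    return kept, report


def site_has_re_motif(
    site: IntegrationSite,
    genome: Genome,
    re_motifs=None,
    window_bp: int = RE_WINDOW_BP,
) -> bool:
    """True if any restriction recognition sequence occurs within
    ``window_bp`` of the insertion point (scanned on the forward strand;
    the default motifs are palindromic)."""
    motifs = list((re_motifs or DEFAULT_RE_MOTIFS).values())
    seq = genome.sequences[site.location.chrom]
    p = site.insertion_point
    lo = max(0, p - window_bp)
    hi = min(len(seq), p + window_bp)
    window = seq[lo:hi]
    return any(m in window for m in motifs)


def filter_unselected(
    sites: list[IntegrationSite],
    genome: Genome,
    re_motifs=None,
    window_bp: int = RE_WINDOW_BP,
    threshold_ge: int = UNSELECTED_GE,
    re_threshold_ge: int = RE_GE,
) -> tuple[list[IntegrationSite], FilterReport]:
    """Two-tier filter for unselected (pooled) NGS sets.

    Sites with a restriction recognition motif within ``window_bp`` of the
    insertion point require ``fragment_count >= re_threshold_ge``; all others
    require ``fragment_count >= threshold_ge``. The report tracks what
    fraction of the kept set is RE-adjacent.
    """
    kept = []
    n_kept_re = 0
    for s in sites:
        has_re = site_has_re_motif(s, genome, re_motifs, window_bp)
        cutoff = re_threshold_ge if has_re else threshold_ge
        if s.fragment_count >= cutoff:
            kept.append(s)
            n_kept_re += has_re
    report = FilterReport(
        n_input=len(sites),
        n_kept=len(kept),
        n_dropped=len(sites) - len(kept),
        n_kept_with_re_motif=n_kept_re,
        fraction_re=(n_kept_re / len(kept)) if kept else 0.0,
    )
    return kept, report


def merge_unique_sites(
    site_lists: list[list[IntegrationSite]], tolerance_bp: int = 5
) -> list[IntegrationSite]:
    """Collapse multi-method detections of the same insertion to unique sites.

    Sites on the same chromosome and strand whose insertion points fall within
    ``tolerance_bp`` of each other (single-linkage chaining) merge into one
    record that keeps the location of the highest-fragment-count member and
    the union of detection methods (comma-joined, sorted). Output is sorted
    by (chrom, position, strand) and therefore independent of input order.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    pool = [s for lst in site_lists for s in lst]
    by_key: dict[tuple[str, str], list[IntegrationSite]] = {}
    for s in pool:
        by_key.setdefault((s.location.chrom, s.location.strand), []).append(s)
    merged: list[IntegrationSite] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda s: (s.insertion_point,
                                                   -s.fragment_count))
        cluster: list[IntegrationSite] = []
        for s in group:
            if cluster and s.insertion_point - cluster[-1].insertion_point > tolerance_bp:
                merged.append(_collapse(cluster))
                cluster = []
            cluster.append(s)
        if cluster:
            merged.append(_collapse(cluster))
    merged.sort(key=lambda s: (s.location.chrom, s.location.start,
                               s.location.strand))
    return merged


def _collapse(cluster: list[IntegrationSite]) -> IntegrationSite:
    best = max(cluster, key=lambda s: s.fragment_count)
    methods = sorted({m for s in cluster for m in s.method.split(",")})
    return IntegrationSite(
        location=best.location,
        vector=best.vector,
        fragment_count=best.fragment_count,
        method=",".join(methods),
    )
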