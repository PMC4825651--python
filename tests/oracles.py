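"""Independent brute-force oracles used to cross-check the fast paths."""

from __future__ import annotations


def brute_overlap_count(site_ivs, track_ivs) -> int:
    """O(n*m) all-pairs 1-bp overlap rule; each site counted at most once."""
    n = 0
    for s in site_ivs:
        for t in track_ivs:
            if s.chrom == t.chrom and s.start < t.end and t.start < s.end:
                n += 1
                break
    return n


def naive_motif_scan(seq: str, motif: str) -> list[int]:
    """Every start position where the motif matches exactly."""
    return [
        i for i in range(len(seq) - len(motif) + 1)
        if seq[i:i + len(motif)] == motif
    ]


def brute_nearest_re(point: int, chrom: str, index) -> tuple[str, int]:
    """Exhaustive distance scan over every occurrence, enzyme order as the
    index's; strictly smaller distance wins, first enzyme wins ties."""
    best = None
    for enzyme, per_chrom in index.positions.items():
        for p in per_chrom.get(chrom, []):
            d = abs(int(p) - point)
            if best is None or d < best[1]:
                best = (enzyme, d)
    if best is None:
        raise ValueError("no occurrence")
    return best


def single_linkage_clusters(points: list[int], tol: int) -> int:
    """Number of single-linkage clusters of 1-D points at the given radius."""
    if not points:
        return 0
    pts = sorted(points)
    k = 1
    for a, b in zip(pts, pts[1:]):
        if b - a > tol:
            k += 1
    return k


def brute_enrichment(x_exp: int, ctrl_counts: list[int]):
    """Direct transcription of the ratio / P-value definitions."""
    nz = [c for c in ctrl_counts if c > 0]
    ratio = sum(x_exp / c for c in nz) / len(nz) if nz else float("nan")
    n = len(ctrl_counts)
    p_enrich = sum(c >= x_exp for c in ctrl_counts) / n
    p_deplete = sum(c <= x_exp for c in ctrl_counts) / n
    return ratio, p_enrich, p_deplete, n - len(nz)
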