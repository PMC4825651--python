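"""Genome, interval and annotation primitives.

All coordinates are 0-based half-open (BED semantics). GFF3 input/output is
1-based inclusive and converted at the boundary. Genomes are held in memory as
uppercase strings over the alphabet ``{A, C, G, T, N}``; the datasets this
package targets (insertion-site analyses against a single reference assembly)
comfortably fit in RAM at that representation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files (message carries the line number)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Genome:
    """A reference genome as a mapping of chromosome name to sequence."""

    sequences: dict[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains illegal characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def contains(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.sequences and iv.end <= len(self.sequences[iv.chrom])


@dataclass
class FeatureTrack:
    """A named collection of genomic intervals (may overlap one another).

    Tracks are treated as immutable once queried: the merged per-chromosome
    coordinate arrays used for fast overlap lookups are cached on first use.
    """

    name: str
    intervals: list[GenomicInterval]
    _merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    def merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) of the union of intervals, sorted."""
        if self._merged is None:
            by_chrom: dict[str, list[GenomicInterval]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            merged = {}
            for chrom, ivs in by_chrom.items():
                ivs.sort(key=lambda iv: (iv.start, iv.end))
                starts, ends = [], []
                for iv in ivs:
                    if ends and iv.start <= ends[-1]:
                        ends[-1] = max(ends[-1], iv.end)
                    else:
                        starts.append(iv.start)
                        ends.append(iv.end)
                merged[chrom] = (
                    np.asarray(starts, dtype=np.int64),
                    np.asarray(ends, dtype=np.int64),
                )
            self._merged = merged
        return self._merged

    def total_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self.merged_arrays().values())
        )


@dataclass
class GeneModel:
    """A gene as an unspliced span with exons and CDS bounds.

    ``cds_start``/``cds_end`` are genomic half-open coordinates of the coding
    region, irrespective of strand. TSS/TTS follow the strand: the TSS is the
    5' end of the span, the TTS its 3' end.
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: span must be stranded")
        prev_end = self.span.start
        for ex in sorted(self.exons, key=lambda e: e.start):
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end
        self.exons = sorted(self.exons, key=lambda e: e.start)
        if not (self.span.start <= self.cds_start < self.cds_end <= self.span.end):
            raise ValueError(f"gene {self.gene_id}: CDS outside span")

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site (0-based base)."""
        return self.span.start if self.span.strand == "+" else self.span.end - 1

    @property
    def tts(self) -> int:
        """Genomic position of the transcription termination site."""
        return self.span.end - 1 if self.span.strand == "+" else self.span.start

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for left, right in itertools.pairwise(self.exons):
            if right.start > left.end:
                out.append(
                    GenomicInterval(self.span.chrom, left.end, right.start,
                                    self.span.strand)
                )
        return out


@dataclass(frozen=True)
class IntegrationSite:
    """One mapped insertion event.

    ``location`` is a length-1 interval at the insertion point, or a length-8
    interval covering the target-site duplication for transposon vectors.
    """

    location: GenomicInterval
    vector: str
    fragment_count: int
    method: str

    def __post_init__(self):
        if self.fragment_count < 0:
            raise ValueError("fragment_count must be non-negative")
        if self.location.strand not in ("+", "-"):
            raise ValueError("integration sites must be stranded")

    @property
    def insertion_point(self) -> int:
        """The point coordinate used for distances and window anchoring.

        For 8-bp target-site-duplication intervals this is the interval
        midpoint; overlap queries always use the full interval.
        """
        if len(self.location) == 1:
            return self.location.start
        return self.location.midpoint


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA header: {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def extract_window(genome: Genome, iv: GenomicInterval) -> str:
    """Genome substring for an interval, reverse-complemented on '-' strand."""
    try:
        seq = genome.sequences[iv.chrom]
    except KeyError:
        raise KeyError(f"unknown chromosome {iv.chrom!r}") from None
    if iv.start < 0 or iv.end > len(seq):
        raise IndexError(
            f"window {iv.chrom}:{iv.start}-{iv.end} outside chromosome "
            f"(length {len(seq)})"
        )
    sub = seq[iv.start:iv.end]
    return reverse_complement(sub) if iv.strand == "-" else sub


def scan_motif_sites(genome: Genome, motif: str, name: str | None = None) -> FeatureTrack:
    """All exact occurrences of a motif, as a FeatureTrack.

    Overlapping occurrences are all reported. The forward strand is scanned;
    for non-palindromic motifs reverse-strand occurrences are found by
    scanning the reverse complement pattern on the forward text, and
    duplicates removed. N bases never match.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} must be over ACGT")
    patterns = {motif, reverse_complement(motif)}
    intervals = []
    for chrom, seq in genome.sequences.items():
        hits: set[int] = set()
        for pat in patterns:
            pos = seq.find(pat)
            while pos != -1:
                hits.add(pos)
                pos = seq.find(pat, pos + 1)
        intervals.extend(
            GenomicInterval(chrom, p, p + len(motif)) for p in sorted(hits)
        )
    return FeatureTrack(name or motif, intervals)


# ---------------------------------------------------------------------------
# BED


def read_bed(path, name: str | None = None) -> FeatureTrack:
    """Read BED3..BED6 into a FeatureTrack (0-based half-open, as native)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    import os

    return FeatureTrack(
        name or os.path.splitext(os.path.basename(str(path)))[0], intervals
    )


def write_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Integration-site tables

SITE_COLUMNS = ["chrom", "start", "end", "strand", "vector", "fragment_count", "method"]


def read_sites(path) -> list[IntegrationSite]:
    """Read a TSV site table with the fixed header columns."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing site-table columns {missing}")
    sites = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sites.append(
                IntegrationSite(
                    location=GenomicInterval(
                        str(row.chrom), int(row.start), int(row.end), str(row.strand)
                    ),
                    vector=str(row.vector),
                    fragment_count=int(row.fragment_count),
                    method=str(row.method),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return sites


def write_sites(sites: list[IntegrationSite], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "chrom": s.location.chrom,
                "start": s.location.start,
                "end": s.location.end,
                "strand": s.location.strand,
                "vector": s.vector,
                "fragment_count": s.fragment_count,
                "method": s.method,
            }
            for s in sites
        ],
        columns=SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_genes_gff(path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive, converted on read)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from None
    genes = []
    for g in db.features_of_type("gene"):
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        cds = list(db.children(g, featuretype="CDS", order_by="start"))
        if cds:
            cds_start = min(c.start - 1 for c in cds)
            cds_end = max(c.end for c in cds)
        else:
            cds_start, cds_end = span.start, span.end
        genes.append(
            GeneModel(
                gene_id=g.id, span=span, exons=exons or [span],
                cds_start=cds_start, cds_end=cds_end,
            )
        )
    return genes


def write_genes_gff(genes: list[GeneModel], path, source: str = "integscape") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{s.chrom}\t{source}\tgene\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{s.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{s.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
                cs, ce = max(ex.start, g.cds_start), min(ex.end, g.cds_end)
                if cs < ce:
                    fh.write(
                        f"{s.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                        f"{s.strand}\t0\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                    )


# ---------------------------------------------------------------------------
# Overlap counting


def as_intervals(sites) -> list[GenomicInterval]:
    """Normalize a list of sites/intervals to GenomicInterval."""
    return [s.location if isinstance(s, IntegrationSite) else s for s in sites]


def overlap_count(sites, track: FeatureTrack) -> int:
    """Number of sites sharing >= 1 bp with any track interval.

    Each site counts at most once regardless of how many track intervals it
    touches. Uses merged sorted interval arrays with binary search.
    """
    merged = track.merged_arrays()
    count = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in as_intervals(sites):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in by_chrom.items():
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        if starts.size == 0:
            continue
        arr = np.asarray(pairs, dtype=np.int64)
        count += int(_overlap_mask(arr[:, 0], arr[:, 1], starts, ends).sum())
    return count


def _overlap_mask(site_starts, site_ends, starts, ends) -> np.ndarray:
    """Vectorized overlap test of sites against merged disjoint intervals."""
    idx = np.searchsorted(starts, site_ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(site_starts.shape, dtype=bool)
    hit[ok] = ends[idx[ok]] > site_starts[ok]
    return hit
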