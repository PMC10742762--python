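"""Putative G-quadruplex detection and G4Hunter scoring.

A putative G4 (pG4) is a match of the canonical four-tract pattern
``G{3,}(N{1,7}G{3,}){3,}`` — at least four runs of three or more guanines
separated by loops of one to seven bases (any base, including N, may sit in
a loop; N never extends a G-run).  The same scan applied to the C-pattern
yields minus-strand pG4s.  Overlapping same-strand matches are merged into
one maximal region; opposite-strand regions are never merged with each
other, so a locus may carry one "+" and one "-" region.

The G4Hunter score of a sequence is the mean per-base score where every
base inside a run of ``r`` consecutive G scores ``+min(r, 4)``, every base
inside a C-run scores ``-min(r, 4)`` and all other bases score 0.  The sign
therefore indicates which strand is G-rich and the value is bounded by
[-4, +4].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .io_formats import GenomeSequence, GenomicInterval


@dataclass(frozen=True)
class G4Params:
    """Pattern parameters; defaults are the canonical d(G3+N1-7)3G3+ rule."""

    min_tract: int = 3
    min_tracts: int = 4
    loop_min: int = 1
    loop_max: int = 7

    def __post_init__(self):
        if self.min_tract < 2:
            raise ValueError("min_tract must be >= 2")
        if self.min_tracts < 4:
            raise ValueError("min_tracts must be >= 4")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("need 0 <= loop_min <= loop_max")

    def pattern(self, base: str) -> re.Pattern:
        t, k = self.min_tract, self.min_tracts
        loop = f"[ACGTN]{{{self.loop_min},{self.loop_max}}}"
        return re.compile(f"{base}{{{t},}}(?:{loop}{base}{{{t},}}){{{k - 1},}}")


DEFAULT_PARAMS = G4Params()


@dataclass
class G4Region:
    """A detected G4 region.

    ``sequence`` is always the plus-strand genomic substring; for a minus
    strand region its reverse complement matches the G-pattern.  ``source``
    is "putative", "experimental" or "both".
    """

    interval: GenomicInterval
    sequence: str
    g4hunter_score: float
    source: str = "putative"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


def _run_lengths(seq: str, base: str):
    """Yield (start, length) of maximal runs of ``base``."""
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            yield i, j - i
            i = j
        else:
            i += 1


def g4hunter_score(seq: str) -> float:
    """Mean per-base G4Hunter score of ``seq``; raises on empty input."""
    if not seq:
        raise ValueError("g4hunter_score: empty sequence")
    total = 0
    for _, length in _run_lengths(seq, "G"):
        total += length * min(length, 4)
    for _, length in _run_lengths(seq, "C"):
        total -= length * min(length, 4)
    return total / len(seq)


def _merge(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]

def _scan_strand(seq: str, base: str, params: G4Params) -> list[tuple[int, int]]:
    # A match must open with base{min_tract}, so only starts of runs of the
    # tract base need to be probed; the greedy match at a run start is the
    # longest match beginning there, and merging unions overlapping hits.
    pat = params.pattern(base)
    t = params.min_tract
    spans = []
    for start, length in _run_lengths(seq, base):
        if length >= t:
            m = pat.match(seq, start)
            if m:
                spans.append((m.start(), m.end()))
    return _merge(spans)


def find_pg4(seq: str, params: G4Params = DEFAULT_PARAMS, chrom: str = ".") -> list[G4Region]:
    """Detect pG4 regions on both strands of ``seq`` (relative coordinates).

    Returns regions sorted by (start, strand); plus-strand hits are maximal
    merged matches of the G-pattern, minus-strand hits of the C-pattern.
    """
    regions: list[G4Region] = []
    for base, strand in (("G", "+"), ("C", "-")):
        for s, e in _scan_strand(seq, base, params):
            sub = seq[s:e]
            regions.append(
                G4Region(GenomicInterval(chrom, s, e, strand), sub, g4hunter_score(sub))
            )
    regions.sort(key=lambda r: (r.start, r.strand))
    return regions


def scan_genome(genome: GenomeSequence, params: G4Params = DEFAULT_PARAMS) -> list[G4Region]:
    """Concatenate per-chromosome pG4 scans in chromosome order (absolute coords)."""
    out: list[G4Region] = []
    for chrom in genome.chrom_names:
        out.extend(find_pg4(genome[chrom], params, chrom=chrom))
    return out


def intersect_experimental(
    pg4: list[G4Region], experimental: list[GenomicInterval]
) -> tuple[list[G4Region], list[G4Region]]:
    """Flag putative regions confirmed by >=1 bp overlap with experimental intervals.

    Returns ``(updated, experimental_only)``: putative regions overlapping any
    experimental interval get ``source="both"``, the rest stay "putative";
    experimental intervals with no putative partner are returned separately
    with ``source="experimental"``.  Strand is ignored when the experimental
    interval is unstranded, and must agree otherwise.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(experimental):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (i, iv.strand))

    hit_exp: set[int] = set()
    updated: list[G4Region] = []
    for region in pg4:
        tree = trees.get(region.chrom)
        matched = []
        if tree is not None:
            for hit in tree.overlap(region.start, region.end):
                idx, strand = hit.data
                if strand == "." or strand == region.strand:
                    matched.append(idx)
        if matched:
            updated.append(replace(region, source="both"))
            hit_exp.update(matched)
        else:
            updated.append(region)
    experimental_only = [
        G4Region(iv, "", 0.0, source="experimental")
        for i, iv in enumerate(experimental)
        if i not in hit_exp
    ]
    return updated, experimental_only


def write_g4_bed(regions: list[G4Region], path: str) -> None:
    """Write regions as BED6: name=source, score=round(100*|g4hunter_score|)."""
    from .io_formats import write_bed

    write_bed(
        [r.interval for r in regions],
        path,
        names=[r.source for r in regions],
        scores=[round(100 * abs(r.g4hunter_score)) for r in regions],
    )
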