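"""Genomic feature assignment and template/non-template strand relation.

Builds an interval index over gene-model features (CDS, 5'UTR, 3'UTR,
exon, intron, promoter) from a GTF, plus auxiliary unstranded BED sets
(enhancers, CpG islands), with intergenic as the fallback where no gene
span overlaps.  Introns are the transcript span minus its exons, UTRs are
derived from exon/CDS arithmetic when not explicit in the GTF, and the
promoter is the ``promoter_size`` bases upstream of the TSS on the gene's
orientation (clipped at chromosome edges).

The annotated gene strand is the sense (non-template) strand: a G4 on the
same strand as its gene is on the non-template strand, and a G4 on the
opposite strand sits on the template strand read by RNA polymerase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import Interval, IntervalTree

from .io_formats import GenomeSequence, GenomicInterval, read_bed
from .context_position import SUBSTITUTION_TYPES

GENE_FEATURES = ["CDS", "UTR5", "UTR3", "exon", "intron", "promoter"]
ALL_FEATURES = GENE_FEATURES + ["enhancer", "CpG", "lncRNA", "intergenic"]


@dataclass
class AnnotationLabel:
    feature: str
    gene_strand: str | None = None  # None for features with no defining gene strand


@dataclass
class FeatureIndex:
    trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)
    gene_trees: dict[str, IntervalTree] = field(default_factory=dict)  # gene spans
    gene_strand: dict[str, str] = field(default_factory=dict)
    gene_biotype: dict[str, str] = field(default_factory=dict)
    promoter_size: int = 1000

    def _tree(self, feature: str, chrom: str) -> IntervalTree:
        return self.trees.setdefault(feature, {}).setdefault(chrom, IntervalTree())

    def add(self, feature: str, chrom: str, start: int, end: int, gene: str | None = None):
        if start < end:
            self._tree(feature, chrom).addi(start, end, gene)

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self.gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted(h.data for h in tree[pos])


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _subtract(span: tuple[int, int], parts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of ``span`` not covered by ``parts`` (parts assumed merged/sorted)."""
    out = []
    cursor = span[0]
    for s, e in parts:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def build_feature_index(
    gtf_path: str | None,
    enhancer_bed: str | None = None,
    cpg_bed: str | None = None,
    promoter_size: int = 1000,
    genome: GenomeSequence | None = None,
) -> FeatureIndex:
    """Build the interval index from a GTF and optional auxiliary BED sets.

    Transcripts with no exon records are skipped with a warning.  Explicit
    five_prime_utr/three_prime_utr records are honored when present;
    otherwise UTRs are computed from exon minus CDS-span arithmetic for
    coding transcripts.
    """
    index = FeatureIndex(promoter_size=promoter_size)
    if gtf_path is not None:
        with open(gtf_path) as fh:
            has_records = any(line.strip() and not line.startswith("#") for line in fh)
        if has_records:
            import pyranges as pr

            df = pr.read_gtf(gtf_path).df
            if len(df):
                _index_gene_models(index, df, promoter_size, genome)

    for feature, path in (("enhancer", enhancer_bed), ("CpG", cpg_bed)):
        if path:
            for iv in read_bed(path):
                index.add(feature, iv.chrom, iv.start, iv.end)
    return index


def _index_gene_models(index: FeatureIndex, df: pd.DataFrame, promoter_size: int, genome):
    df = df.copy()
    df["Chromosome"] = df["Chromosome"].astype(str)
    if "gene_biotype" not in df.columns:
        df["gene_biotype"] = "protein_coding"
    has_tid = df.get("transcript_id") is not None
    gene_spans: dict[str, list] = {}

    tx_rows = df[df["Feature"].isin(["transcript", "exon", "CDS", "five_prime_utr", "three_prime_utr"])]
    for tid, tdf in tx_rows.groupby("transcript_id", dropna=True):
        exons = [(int(r.Start), int(r.End)) for r in tdf[tdf["Feature"] == "exon"].itertuples()]
        if not exons:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        exons = _merge_spans(exons)
        cds = _merge_spans(
            [(int(r.Start), int(r.End)) for r in tdf[tdf["Feature"] == "CDS"].itertuples()]
        )
        chrom = str(tdf["Chromosome"].iloc[0])
        strand = str(tdf["Strand"].iloc[0])
        gene = str(tdf["gene_id"].iloc[0])
        biotype = str(tdf["gene_biotype"].iloc[0])
        span = (exons[0][0], exons[-1][1])
        trows = tdf[tdf["Feature"] == "transcript"]
        if len(trows):
            span = (
                min(span[0], int(trows["Start"].iloc[0])),
                max(span[1], int(trows["End"].iloc[0])),
            )
        index.gene_strand[gene] = strand
        index.gene_biotype[gene] = biotype
        gene_spans.setdefault(gene, []).append((chrom, span[0], span[1]))

        for s, e in exons:
            index.add("exon", chrom, s, e, gene)
        for s, e in cds:
            index.add("CDS", chrom, s, e, gene)
        for s, e in _subtract(span, exons):
            index.add("intron", chrom, s, e, gene)

        utr5 = [(int(r.Start), int(r.End)) for r in tdf[tdf["Feature"] == "five_prime_utr"].itertuples()]
        utr3 = [(int(r.Start), int(r.End)) for r in tdf[tdf["Feature"] == "three_prime_utr"].itertuples()]
        if not (utr5 or utr3) and cds:
            cds_span = (cds[0][0], cds[-1][1])
            left = [(max(s, span[0]), min(e, cds_span[0])) for s, e in exons if s < cds_span[0]]
            right = [(max(s, cds_span[1]), e) for s, e in exons if e > cds_span[1]]
            left = [(s, e) for s, e in left if s < e]
            right = [(s, e) for s, e in right if s < e]
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
        for s, e in utr5:
            index.add("UTR5", chrom, s, e, gene)
        for s, e in utr3:
            index.add("UTR3", chrom, s, e, gene)

        # promoter upstream of the TSS on the gene's orientation
        if strand == "+":
            p_start, p_end = span[0] - promoter_size, span[0]
        else:
            p_start, p_end = span[1], span[1] + promoter_size
        p_start = max(0, p_start)
        if genome is not None and chrom in genome:
            p_end = min(p_end, genome.length(chrom))
        index.add("promoter", chrom, p_start, p_end, gene)

        if biotype == "lncRNA":
            for s, e in exons:
                index.add("lncRNA", chrom, s, e, gene)

    for gene, spans in gene_spans.items():
        for chrom, s, e in spans:
            index.gene_trees.setdefault(chrom, IntervalTree()).addi(s, e, gene)


def annotate_position(index: FeatureIndex, chrom: str, pos: int) -> list[AnnotationLabel]:
    """All feature labels overlapping a position; intergenic iff no gene feature does.

    A position may carry several labels (e.g. exon + UTR3 + CpG).  Unknown
    chromosomes yield intergenic.
    """
    labels: list[AnnotationLabel] = []
    gene_hit = False
    for feature in GENE_FEATURES + ["lncRNA"]:
        tree = index.trees.get(feature, {}).get(chrom)
        if tree is None:
            continue
        hits = tree[pos]
        if hits:
            gene_hit = True
            gene = sorted(h.data for h in hits if h.data)[0] if any(h.data for h in hits) else None
            labels.append(AnnotationLabel(feature, index.gene_strand.get(gene)))
    for feature in ("enhancer", "CpG"):
        tree = index.trees.get(feature, {}).get(chrom)
        if tree is not None and tree[pos]:
            labels.append(AnnotationLabel(feature, None))
    if not gene_hit and not index.genes_at(chrom, pos):
        labels.append(AnnotationLabel("intergenic", None))
    return labels


def strand_relation(g4_strand: str, gene_strand: str | None) -> str:
    """"non_template" when the G4 strand equals the annotated gene (sense) strand."""
    if g4_strand not in ("+", "-") or gene_strand not in ("+", "-"):
        return "unstranded"
    return "non_template" if g4_strand == gene_strand else "template"


def annotate_effects(effects, index: FeatureIndex) -> None:
    """Fill features / gene_strand / strand_relation in-place on effect records."""
    for effect in effects:
        labels = annotate_position(index, effect.snv.chrom, effect.snv.pos)
        effect.features = [l.feature for l in labels]
        gene_strands = [l.gene_strand for l in labels if l.gene_strand in ("+", "-")]
        effect.gene_strand = gene_strands[0] if gene_strands else None
        g4_strand = effect.g4.strand if effect.g4 else "."
        effect.strand_relation = strand_relation(g4_strand, effect.gene_strand)


def feature_summary(effects) -> pd.DataFrame:
    """Cross-tab of substitution type x feature: % of each type within a feature.

    A multi-label variant counts once per feature column, so columns are
    not mutually exclusive; each column sums to 100 over the 12 types.
    """
    counts: dict[str, dict[str, int]] = {}
    for effect in effects:
        sub = effect.substitution if not isinstance(effect, dict) else effect["substitution"]
        feats = effect.features if not isinstance(effect, dict) else (effect.get("features") or "").split(",")
        for feature in feats:
            if feature:
                counts.setdefault(feature, {}).setdefault(sub, 0)
                counts[feature][sub] += 1
    if not counts:
        return pd.DataFrame(index=pd.Index(SUBSTITUTION_TYPES, name="substitution"))
    cols = {}
    for feature in sorted(counts):
        total = sum(counts[feature].values())
        cols[feature] = [100.0 * counts[feature].get(sub, 0) / total for sub in SUBSTITUTION_TYPES]
    return pd.DataFrame(cols, index=pd.Index(SUBSTITUTION_TYPES, name="substitution"))
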