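"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  VCF (1-based) and GTF
(1-based inclusive) are converted at the boundary; BED is already 0-based
half-open and passes through unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass
class GenomeSequence:
    """An in-memory genome: ordered chromosome names and upper-case sequences."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}


@dataclass(frozen=True)
class GenomicInterval:
    """Strand-aware genomic interval, 0-based half-open.

    ``strand`` is "+", "-" or "." (unstranded records such as CpG islands).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SNV:
    """A single-nucleotide variant; ``pos`` is the 0-based substituted base."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."
    source: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise FormatError(f"SNV alleles must be in {{A,C,G,T}}: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise FormatError(f"SNV ref equals alt at {self.chrom}:{self.pos}")

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_fasta(path: str) -> GenomeSequence:
    """Load a multi-record FASTA; sequences are upper-cased, non-ACGT bases → N.

    Errors on duplicate record names, empty files and records with no sequence.
    """
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        name = rec.id
        if not name:
            raise FormatError(f"{path}: record with empty name")
        if name in seqs:
            raise FormatError(f"{path}: duplicate record name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {name!r} has no sequence")
        seq = "".join(b if b in "ACGTN" else "N" for b in seq)
        names.append(name)
        seqs[name] = seq
    if not names:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(chrom_names=names, sequences=seqs)


def write_fasta(genome: GenomeSequence, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_snvs(
    vcf_path: str,
    genome: GenomeSequence | None = None,
    source: str = "somatic_catalog",
    deduplicate: bool = True,
) -> list[SNV]:
    """Read SNVs from a VCF, dropping INDELs and splitting multi-allelic records.

    Only records with single-base REF and ALT (REF != ALT) are retained —
    insertion and deletion events are removed.  Multi-allelic records are
    split into one candidate per alt allele before filtering.  POS is
    converted from 1-based to 0-based.  When ``genome`` is supplied, every
    retained record's REF is verified against the genome base and a mismatch
    raises.  Duplicate (chrom, pos, ref, alt) records are collapsed with the
    multiplicity recorded in ``meta["n_records"]``.
    """
    out: list[SNV] = []
    seen: dict[tuple, SNV] = {}
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1:
                    continue  # INDEL (or symbolic allele): removed
                if ref not in VALID_BASES or alt not in VALID_BASES or ref == alt:
                    continue
                pos = rec.pos - 1
                if genome is not None and rec.chrom in genome:
                    base = genome[rec.chrom][pos] if 0 <= pos < genome.length(rec.chrom) else None
                    if base != ref:
                        raise FormatError(
                            f"{vcf_path}: REF mismatch at {rec.chrom}:{rec.pos} "
                            f"(VCF {ref!r} vs genome {base!r}, record id {rec.id})"
                        )
                snv = SNV(rec.chrom, pos, ref, alt, id=rec.id or ".", source=source)
                if deduplicate:
                    prev = seen.get(snv.key())
                    if prev is not None:
                        prev.meta["n_records"] = prev.meta.get("n_records", 1) + 1
                        continue
                    snv.meta["n_records"] = 1
                    seen[snv.key()] = snv
                out.append(snv)
    return out


def write_vcf(snvs: list[SNV], genome: GenomeSequence, path: str) -> None:
    """Write SNVs as a minimal sorted VCF 4.2 (POS converted back to 1-based)."""
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=g4snv\n")
        for name in genome.chrom_names:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snvs, key=lambda s: (order.get(s.chrom, 1 << 30), s.pos, s.alt)):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t.\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open; strand from column 6 if present)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(
    intervals: list[GenomicInterval],
    path: str,
    names: list[str] | None = None,
    scores: list[int] | None = None,
) -> None:
    """Write BED6 (name and score columns default to "." / 0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            score = scores[i] if scores else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# Column order of the per-variant effects table; kept in one place so the
# writer and the downstream summaries stay in sync.
EFFECT_COLUMNS = [
    "chrom",
    "pos",
    "id",
    "ref",
    "alt",
    "source",
    "substitution",
    "structural_class",
    "state_before",
    "state_after",
    "g4_chrom",
    "g4_start",
    "g4_end",
    "g4_strand",
    "g4_source",
    "g4hunter_ref",
    "g4hunter_alt",
    "mfe_ref",
    "mfe_alt",
    "delta_mfe",
    "ed_ref",
    "ed_alt",
    "delta_ed",
    "stability_class",
    "ref3",
    "alt3",
    "context_class",
    "in_loop",
    "relative_position",
    "is_transition",
    "features",
    "gene_strand",
    "strand_relation",
]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_effects_table(effects, path: str, comment: str | None = None) -> None:
    """Write one TSV row per SNV×G4 effect, sorted by (chrom, pos, alt).

    ``effects`` may hold objects exposing ``to_dict`` or plain dicts.  The
    same input always produces byte-identical output.
    """
    rows = [e.to_dict() if hasattr(e, "to_dict") else dict(e) for e in effects]
    rows.sort(key=lambda r: (r["chrom"], r["pos"], r["alt"]))
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(EFFECT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r.get(c)) for c in EFFECT_COLUMNS) + "\n")


def sha256_file(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
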