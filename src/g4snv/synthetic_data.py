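"""Desk-scale synthetic inputs with the statistical structure the analysis assumes.

The generator emits a small genome with planted canonical G4 motifs on both
strands, a matching gene-model GTF, and a VCF with a configurable
12-category substitution spectrum plus planted G4-loss, G4-gain and neutral
SNVs, together with truth tables for recovery testing.

Planted G4s are canonical four-tract d(G3 N1-7)3 G3 motifs whose loop bases
are drawn from {A, C, T} (never extending a tract) and screened against
accidental C-runs, so a plus plant can never carry a minus-strand match.
Gain sites are the same motifs with one tract made defective (G[ACT]G): the
planted gain SNV restores the tract.  Every plant is insulated from the
background by 8-nt A/T pads (longer than the maximum loop), so background
sequence cannot extend or merge into a planted motif, and every planted
loss / gain / neutral SNV is verified against the structural classifier at
generation time.  Background SNV positions exclude 61 bp around every plant
so truth labels stay exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import SNV, GenomeSequence, GenomicInterval, write_fasta, write_bed, write_vcf, revcomp
from .g4_detection import DEFAULT_PARAMS, _run_lengths
from .variant_effects import classify_structural, extract_windows
from .context_position import SUBSTITUTION_TYPES

# Default 12-category substitution spectrum: the intron-column proportions
# (percent) of a large somatic catalog; normalized to 1 at config time.
INTRON_SPECTRUM = {
    "G>A": 26.74, "G>T": 14.56, "C>T": 9.06, "T>G": 19.91,
    "A>G": 11.49, "G>C": 6.30, "C>G": 4.59, "C>A": 2.60,
    "T>C": 2.10, "T>A": 1.00, "A>T": 0.94, "A>C": 0.72,
}

_PAD = 8  # insulating pad length; must exceed the maximum loop length (7)


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset; the defaults define the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    gc_content: float = 0.4
    n_g4_plus: int = 60
    n_g4_minus: int = 60
    n_genes: int = 8
    substitution_weights: dict = field(default_factory=lambda: dict(INTRON_SPECTRUM))
    n_loss: int = 40
    n_gain: int = 40
    n_neutral: int = 60
    n_background: int = 500
    min_plant_gap: int = 100

    def __post_init__(self):
        missing = [t for t in SUBSTITUTION_TYPES if t not in self.substitution_weights]
        if missing:
            raise ValueError(f"substitution_weights missing types: {missing}")
        total = float(sum(self.substitution_weights.values()))
        if total <= 0:
            raise ValueError("substitution_weights must have positive sum")
        self.substitution_weights = {
            t: float(self.substitution_weights[t]) / total for t in SUBSTITUTION_TYPES
        }
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_loss + self.n_neutral > self.n_g4_plus + self.n_g4_minus:
            raise ValueError("planted loss+neutral SNVs exceed planted G4 count")


@dataclass
class Plant:
    """A planted motif: a true G4 ("g4") or a defective gain site ("gain_site")."""

    interval: GenomicInterval
    kind: str
    defect_pos: int | None = None  # genome coordinate of the defect base (gain sites)


@dataclass
class SyntheticTruth:
    g4s: list[Plant] = field(default_factory=list)
    gain_sites: list[Plant] = field(default_factory=list)
    snv_labels: list[dict] = field(default_factory=list)
    spectrum: dict = field(default_factory=dict)


def _make_loop(rng) -> str:
    """Loop of length 1-7 over {A,C,T} without a C-run of 3 (no minus-strand tract)."""
    while True:
        length = int(rng.integers(1, 8))
        loop = "".join(rng.choice(list("ACT"), size=length))
        if "CCC" not in loop:
            return loop


def _make_motif(rng, defective: bool) -> tuple[str, int | None]:
    """A four-tract motif; if defective, one middle tract is G[ACT]G.

    Returns (motif, defect_offset) where the offset points at the non-G base
    of the defective tract (None for true G4 motifs).
    """
    defect_tract = int(rng.integers(1, 3)) if defective else -1
    parts: list[str] = []
    defect_offset = None
    for t in range(4):
        if t == defect_tract:
            x = str(rng.choice(list("ACT")))
            defect_offset = sum(len(p) for p in parts) + 1
            parts.append("G" + x + "G")
        else:
            parts.append("GGG")
        if t < 3:
            parts.append(_make_loop(rng))
    return "".join(parts), defect_offset


def generate_genome(config: SimConfig) -> tuple[GenomeSequence, SyntheticTruth]:
    """Background i.i.d. sequence at the configured GC with planted motifs.

    Plants are placed left to right with gaps >= ``min_plant_gap`` and
    raises on infeasible packing.  The truth records every plant.
    """
    rng = np.random.default_rng([config.seed, 1])
    bases = np.array(list("ACGT"))
    p = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays = {
        c: rng.choice(bases, size=config.chrom_length, p=p) for c in chrom_names
    }

    specs = (
        [("g4", "+")] * config.n_g4_plus
        + [("g4", "-")] * config.n_g4_minus
        + [("gain_site", "+")] * ((config.n_gain + 1) // 2)
        + [("gain_site", "-")] * (config.n_gain // 2)
    )
    order = rng.permutation(len(specs))
    truth = SyntheticTruth(spectrum=dict(config.substitution_weights))
    cursors = {c: int(rng.integers(0, config.min_plant_gap)) for c in chrom_names}

    for k, idx in enumerate(order):
        kind, strand = specs[idx]
        chrom = chrom_names[k % config.n_chroms]
        motif, defect_offset = _make_motif(rng, defective=(kind == "gain_site"))
        if strand == "-":
            if defect_offset is not None:
                defect_offset = len(motif) - 1 - defect_offset
            motif = revcomp(motif)
        pad_left = "".join(rng.choice(list("AT"), size=_PAD))
        pad_right = "".join(rng.choice(list("AT"), size=_PAD))
        block = pad_left + motif + pad_right
        gap = config.min_plant_gap + int(rng.integers(0, config.min_plant_gap))
        start = cursors[chrom] + gap
        if start + len(block) > config.chrom_length:
            raise ValueError(
                f"infeasible packing: {len(specs)} plants do not fit in "
                f"{config.n_chroms} x {config.chrom_length} bp"
            )
        arrays[chrom][start : start + len(block)] = list(block)
        cursors[chrom] = start + len(block)
        m_start = start + _PAD
        plant = Plant(
            GenomicInterval(chrom, m_start, m_start + len(motif), strand),
            kind,
            defect_pos=(m_start + defect_offset) if defect_offset is not None else None,
        )
        (truth.g4s if kind == "g4" else truth.gain_sites).append(plant)

    genome = GenomeSequence(chrom_names, {c: "".join(arrays[c]) for c in chrom_names})
    truth.g4s.sort(key=lambda pl: (pl.interval.chrom, pl.interval.start))
    truth.gain_sites.sort(key=lambda pl: (pl.interval.chrom, pl.interval.start))
    return genome, truth


def generate_genes(config: SimConfig, genome: GenomeSequence) -> list[dict]:
    """Non-overlapping two-exon gene models on both strands.

    Genes are dealt round-robin across chromosomes into equal slots; roughly
    one in four is a non-coding lncRNA (exons only), the rest are
    protein-coding with UTR5 + CDS + UTR3 = exons.  Returns gene dictionaries
    (also consumed by :func:`write_gtf`).
    """
    rng = np.random.default_rng([config.seed, 2])
    genes: list[dict] = []
    if config.n_genes == 0:
        return genes
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for ci, chrom in enumerate(genome.chrom_names):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = genome.length(chrom) // n
        for s in range(n):
            gid += 1
            slot_start = s * slot
            span_len = int(rng.integers(min(2000, slot // 2), max(min(4000, slot - 200), 2001)))
            margin = max(1, slot - span_len - 100)
            gs = slot_start + 100 + int(rng.integers(0, margin))
            ge = min(gs + span_len, genome.length(chrom))
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "lncRNA" if gid % 4 == 0 else "protein_coding"
            e1_len = int(rng.integers(300, 600))
            intron_len = int(rng.integers(300, 800))
            exon1 = (gs, gs + e1_len)
            exon2 = (gs + e1_len + intron_len, ge)
            if exon2[0] >= exon2[1] - 50:
                exon2 = (exon1[1] + 100, exon1[1] + 400)
                ge = exon2[1]
            gene = {
                "gene_id": f"gene{gid}",
                "chrom": chrom,
                "start": gs,
                "end": ge,
                "strand": strand,
                "biotype": biotype,
                "exons": [exon1, exon2],
                "cds": [],
            }
            if biotype == "protein_coding":
                u5 = int(rng.integers(50, min(200, e1_len - 50)))
                u3 = int(rng.integers(50, min(200, exon2[1] - exon2[0] - 50)))
                if strand == "+":
                    cds_span = (gs + u5, ge - u3)
                else:
                    cds_span = (gs + u3, ge - u5)
                gene["cds"] = [
                    (max(es, cds_span[0]), min(ee, cds_span[1]))
                    for es, ee in gene["exons"]
                    if es < cds_span[1] and ee > cds_span[0]
                ]
            genes.append(gene)
    return genes


def write_gtf(genes: list[dict], path: str) -> None:
    """Write gene models as ENSEMBL-style GTF (1-based inclusive coordinates)."""

    def attrs(gene, with_tid=True):
        a = f'gene_id "{gene["gene_id"]}"; '
        if with_tid:
            a += f'transcript_id "{gene["gene_id"]}.t1"; '
        return a + f'gene_biotype "{gene["biotype"]}";'

    with open(path, "w") as fh:
        for gene in genes:
            c, st = gene["chrom"], gene["strand"]
            fh.write(
                f"{c}\tg4snv_sim\tgene\t{gene['start'] + 1}\t{gene['end']}\t.\t{st}\t.\t{attrs(gene, False)}\n"
            )
            fh.write(
                f"{c}\tg4snv_sim\ttranscript\t{gene['start'] + 1}\t{gene['end']}\t.\t{st}\t.\t{attrs(gene)}\n"
            )
            for s, e in gene["exons"]:
                fh.write(f"{c}\tg4snv_sim\texon\t{s + 1}\t{e}\t.\t{st}\t.\t{attrs(gene)}\n")
            for s, e in gene["cds"]:
                fh.write(f"{c}\tg4snv_sim\tCDS\t{s + 1}\t{e}\t.\t{st}\t0\t{attrs(gene)}\n")


def _tract_runs(genome: GenomeSequence, plant: Plant) -> list[tuple[int, int]]:
    """Genome-coordinate (start, length) of tract-base runs >= 3 inside a plant."""
    iv = plant.interval
    seq = genome[iv.chrom][iv.start : iv.end]
    base = "G" if iv.strand == "+" else "C"
    return [(iv.start + s, l) for s, l in _run_lengths(seq, base) if l >= 3]


def _verified_snv(genome, chrom, pos, ref, alts, expect, rng) -> SNV | None:
    """First alt (in rng order) whose structural classification matches ``expect``."""
    alts = [a for a in alts if a != ref]
    for a in rng.permutation(alts):
        snv = SNV(chrom, pos, ref, str(a), source="synthetic")
        cls = classify_structural(extract_windows(genome, snv))
        if cls.value == expect:
            return snv
    return None


def generate_variants(
    config: SimConfig, genome: GenomeSequence, truth: SyntheticTruth
) -> list[SNV]:
    """Plant loss/gain/neutral SNVs (classifier-verified) plus background SNVs.

    Loss SNVs break the center of a middle tract of a planted G4; gain SNVs
    restore the defective tract of a gain site; neutral SNVs substitute a
    loop base without changing pattern membership.  Background SNVs are
    drawn from the configured substitution spectrum at positions at least
    61 bp away from any plant.  Labels are appended to ``truth.snv_labels``.
    """
    rng = np.random.default_rng([config.seed, 3])
    if config.n_gain > len(truth.gain_sites):
        raise ValueError("not enough gain sites planted for n_gain")
    if config.n_loss + config.n_neutral > len(truth.g4s):
        raise ValueError("not enough planted G4s for n_loss + n_neutral")

    snvs: list[SNV] = []
    labels: list[tuple[SNV, str]] = []
    g4_order = rng.permutation(len(truth.g4s))
    loss_plants = [truth.g4s[i] for i in g4_order[: config.n_loss]]
    neutral_plants = [truth.g4s[i] for i in g4_order[config.n_loss : config.n_loss + config.n_neutral]]

    for plant in loss_plants:
        runs = _tract_runs(genome, plant)
        snv = None
        for run_idx in [1, 2, 0, 3][: len(runs)]:
            start, length = runs[run_idx]
            pos = start + length // 2
            ref = genome[plant.interval.chrom][pos]
            snv = _verified_snv(
                genome, plant.interval.chrom, pos, ref, list("ACGT"), "loss", rng
            )
            if snv:
                break
        if snv is None:
            raise ValueError(f"could not plant a loss SNV in {plant.interval}")
        labels.append((snv, "loss"))

    for plant in neutral_plants:
        iv = plant.interval
        tract_positions = set()
        for start, length in _tract_runs(genome, plant):
            tract_positions.update(range(start, start + length))
        loop_positions = [p for p in range(iv.start, iv.end) if p not in tract_positions]
        snv = None
        for p in rng.permutation(loop_positions):
            ref = genome[iv.chrom][int(p)]
            snv = _verified_snv(genome, iv.chrom, int(p), ref, list("ACT" if iv.strand == "+" else "AGT"), "retained", rng)
            if snv:
                break
        if snv is None:
            raise ValueError(f"could not plant a neutral SNV in {iv}")
        labels.append((snv, "neutral"))

    site_order = rng.permutation(len(truth.gain_sites))
    for i in site_order[: config.n_gain]:
        plant = truth.gain_sites[i]
        pos = plant.defect_pos
        ref = genome[plant.interval.chrom][pos]
        alt = "G" if plant.interval.strand == "+" else "C"
        snv = SNV(plant.interval.chrom, pos, ref, alt, source="synthetic")
        cls = classify_structural(extract_windows(genome, snv))
        if cls.value != "gain":
            raise ValueError(f"planted gain at {plant.interval} failed verification")
        labels.append((snv, "gain"))

    # background SNVs: spectrum-weighted, excluding 61 bp around every plant
    exclude: dict[str, np.ndarray] = {
        c: np.zeros(genome.length(c), dtype=bool) for c in genome.chrom_names
    }
    for plant in truth.g4s + truth.gain_sites:
        iv = plant.interval
        lo = max(0, iv.start - _PAD - 61)
        hi = min(genome.length(iv.chrom), iv.end + _PAD + 61)
        exclude[iv.chrom][lo:hi] = True
    for snv, _ in labels:
        exclude[snv.chrom][snv.pos] = True

    weights = np.array([config.substitution_weights[t] for t in SUBSTITUTION_TYPES])
    counts = rng.multinomial(config.n_background, weights)
    # one draw without replacement per ref base so positions are unique even
    # across substitution types sharing that base
    for base in "ACGT":
        base_types = [(t, c) for t, c in zip(SUBSTITUTION_TYPES, counts) if t[0] == base]
        needed = int(sum(c for _, c in base_types))
        if needed == 0:
            continue
        chrom_pos: list[tuple[str, np.ndarray]] = []
        for c in genome.chrom_names:
            arr = np.frombuffer(genome[c].encode(), dtype="S1")
            chrom_pos.append((c, np.nonzero((arr == base.encode()) & ~exclude[c])[0]))
        sizes = np.array([len(p) for _, p in chrom_pos])
        if sizes.sum() < needed:
            raise ValueError(f"not enough {base} positions for {needed} background SNVs")
        flat = rng.choice(int(sizes.sum()), size=needed, replace=False)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        picked = []
        for f in flat:
            ci = int(np.searchsorted(offsets, f, side="right")) - 1
            picked.append((chrom_pos[ci][0], int(chrom_pos[ci][1][f - offsets[ci]])))
        start = 0
        for t, count in base_types:
            for chrom, pos in picked[start : start + int(count)]:
                labels.append((SNV(chrom, pos, base, t[2], source="synthetic"), "background"))
            start += int(count)

    order = {c: i for i, c in enumerate(genome.chrom_names)}
    labels.sort(key=lambda x: (order[x[0].chrom], x[0].pos, x[0].alt))
    for i, (snv, label) in enumerate(labels, 1):
        snv.id = f"snv{i:06d}"
        snv.meta["truth"] = label
        snvs.append(snv)
        truth.snv_labels.append(
            {"id": snv.id, "chrom": snv.chrom, "pos": snv.pos, "ref": snv.ref, "alt": snv.alt, "label": label}
        )
    return snvs


def spectrum_estimate(vcf_path: str) -> dict[str, float]:
    """Observed frequency of each of the 12 substitution types in a VCF."""
    from .io_formats import read_snvs

    snvs = read_snvs(vcf_path, genome=None, deduplicate=False)
    if not snvs:
        raise ValueError(f"{vcf_path}: no SNVs found")
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for snv in snvs:
        counts[snv.substitution] += 1
    total = len(snvs)
    return {t: counts[t] / total for t in SUBSTITUTION_TYPES}


def generate_dataset(config: SimConfig, out_dir: str) -> dict:
    """Generate and write the full synthetic dataset; returns the output paths.

    Writes genome.fa, g4_truth.bed, genes.gtf, variants.vcf, truth.tsv and a
    config.json sidecar.  Identical configs produce byte-identical files.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    genome, truth = generate_genome(config)
    genes = generate_genes(config, genome)
    snvs = generate_variants(config, genome, truth)

    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "g4_truth_bed": os.path.join(out_dir, "g4_truth.bed"),
        "gtf": os.path.join(out_dir, "genes.gtf"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "truth_tsv": os.path.join(out_dir, "truth.tsv"),
        "config": os.path.join(out_dir, "config.json"),
    }
    write_fasta(genome, paths["genome"])
    write_bed(
        [p.interval for p in truth.g4s],
        paths["g4_truth_bed"],
        names=[p.kind for p in truth.g4s],
    )
    write_gtf(genes, paths["gtf"])
    write_vcf(snvs, genome, paths["vcf"])
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("id\tchrom\tpos\tref\talt\tlabel\n")
        for row in truth.snv_labels:
            fh.write(f"{row['id']}\t{row['chrom']}\t{row['pos']}\t{row['ref']}\t{row['alt']}\t{row['label']}\n")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"genome_obj": genome, "truth": truth, "genes": genes, "snvs": snvs, **paths}
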