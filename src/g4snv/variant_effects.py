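"""Two-pass structural classification of SNVs and folding-stability deltas.

For each variant a pair of windows (30 nt of flank on each side of the
substituted base) is built from the reference and alternate alleles.  The
pG4 detector is run on both windows, on both strands, and only regions
overlapping the variant base are considered: a region present in the
reference window but absent from the alternate is a **loss**, the reverse
is a **gain**, and everything else is **retained**.  Strand states before
and after encode which strands carry a variant-overlapping region
("0", "+", "-", "+-").

Stability is quantified by a pluggable folding backend returning a minimum
free energy (MFE, kcal/mol) and an ensemble diversity (ED) per sequence;
``delta_mfe = mfe(alt) - mfe(ref)`` so negative values indicate
stabilization by the variant.  A deterministic surrogate backend based on
G-run stacking capacity is provided so the pipeline and its tests need no
external folding engine; an external-command backend adapts any program
that reads sequences on stdin and prints "mfe<TAB>ed" per line.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io_formats import SNV, GenomeSequence, GenomicInterval, revcomp
from .g4_detection import DEFAULT_PARAMS, G4Params, G4Region, _run_lengths, find_pg4, g4hunter_score
from . import context_position as cp


@dataclass
class WindowPair:
    """Reference and alternate windows around a variant (same length)."""

    chrom: str
    start: int  # genome coordinate of the window's first base
    ref_window: str
    alt_window: str
    variant_offset: int
    truncated_left: bool = False
    truncated_right: bool = False


@dataclass
class StructuralClass:
    value: str  # loss | gain | retained
    strand_state_before: str  # 0 | + | - | +-
    strand_state_after: str


@dataclass
class StabilityResult:
    mfe_ref: float | None
    mfe_alt: float | None
    delta_mfe: float | None
    ed_ref: float | None
    ed_alt: float | None
    delta_ed: float | None
    stability_class: str | None  # further_stabilized | destabilized | no_change | unscored


@dataclass
class VariantG4Effect:
    """Full per-variant result bundling structure, stability, context and annotation."""

    snv: SNV
    structural: StructuralClass
    g4: G4Region | None = None
    stability: StabilityResult | None = None
    g4hunter_ref: float | None = None
    g4hunter_alt: float | None = None
    ref3: str | None = None
    alt3: str | None = None
    context_class: str | None = None
    in_loop: bool | None = None
    relative_position: float | None = None
    is_transition: bool | None = None
    features: list[str] = field(default_factory=list)
    gene_strand: str | None = None
    strand_relation: str | None = None

    @property
    def substitution(self) -> str:
        return self.snv.substitution

    def to_dict(self) -> dict:
        s = self.stability
        g = self.g4
        return {
            "chrom": self.snv.chrom,
            "pos": self.snv.pos,
            "id": self.snv.id,
            "ref": self.snv.ref,
            "alt": self.snv.alt,
            "source": self.snv.source,
            "substitution": self.snv.substitution,
            "structural_class": self.structural.value,
            "state_before": self.structural.strand_state_before,
            "state_after": self.structural.strand_state_after,
            "g4_chrom": g.chrom if g else None,
            "g4_start": g.start if g else None,
            "g4_end": g.end if g else None,
            "g4_strand": g.strand if g else None,
            "g4_source": g.source if g else None,
            "g4hunter_ref": self.g4hunter_ref,
            "g4hunter_alt": self.g4hunter_alt,
            "mfe_ref": s.mfe_ref if s else None,
            "mfe_alt": s.mfe_alt if s else None,
            "delta_mfe": s.delta_mfe if s else None,
            "ed_ref": s.ed_ref if s else None,
            "ed_alt": s.ed_alt if s else None,
            "delta_ed": s.delta_ed if s else None,
            "stability_class": s.stability_class if s else None,
            "ref3": self.ref3,
            "alt3": self.alt3,
            "context_class": self.context_class,
            "in_loop": self.in_loop,
            "relative_position": self.relative_position,
            "is_transition": self.is_transition,
            "features": ",".join(self.features) if self.features else None,
            "gene_strand": self.gene_strand,
            "strand_relation": self.strand_relation,
        }


def extract_windows(genome: GenomeSequence, snv: SNV, flank: int = 30) -> WindowPair:
    """Build the +/-``flank`` nt window pair around a variant, clipped at chromosome ends."""
    if snv.chrom not in genome:
        raise ValueError(f"chromosome {snv.chrom!r} not in genome")
    seq = genome[snv.chrom]
    if not (0 <= snv.pos < len(seq)):
        raise ValueError(f"position {snv.pos} outside chromosome {snv.chrom}")
    if seq[snv.pos] != snv.ref:
        raise ValueError(
            f"ref mismatch at {snv.chrom}:{snv.pos}: genome {seq[snv.pos]!r} vs SNV {snv.ref!r}"
        )
    start = max(0, snv.pos - flank)
    end = min(len(seq), snv.pos + flank + 1)
    offset = snv.pos - start
    ref_window = seq[start:end]
    alt_window = ref_window[:offset] + snv.alt + ref_window[offset + 1 :]
    return WindowPair(
        chrom=snv.chrom,
        start=start,
        ref_window=ref_window,
        alt_window=alt_window,
        variant_offset=offset,
        truncated_left=start > snv.pos - flank or snv.pos - flank < 0,
        truncated_right=end < snv.pos + flank + 1,
    )


def _overlapping_strands(window: str, offset: int, params: G4Params) -> dict[str, G4Region]:
    """Map strand -> the detected region overlapping the variant offset (if any)."""
    out: dict[str, G4Region] = {}
    for region in find_pg4(window, params):
        if region.start <= offset < region.end:
            out[region.strand] = region  # merged regions: at most one per strand
    return out


def _state(strands) -> str:
    has_plus, has_minus = "+" in strands, "-" in strands
    if has_plus and has_minus:
        return "+-"
    if has_plus:
        return "+"
    if has_minus:
        return "-"
    return "0"


def classify_structural(pair: WindowPair, params: G4Params = DEFAULT_PARAMS) -> StructuralClass:
    """Classify the variant's consequence on variant-overlapping pG4s.

    Loss: an overlapping region exists in the reference window but not the
    alternate on at least one strand; gain: the reverse; retained
    otherwise.  If a variant simultaneously destroys a region on one strand
    and creates one on the other, loss takes precedence.
    """
    before = _overlapping_strands(pair.ref_window, pair.variant_offset, params)
    after = _overlapping_strands(pair.alt_window, pair.variant_offset, params)
    lost = set(before) - set(after)
    gained = set(after) - set(before)
    if lost:
        value = "loss"
    elif gained:
        value = "gain"
    else:
        value = "retained"
    return StructuralClass(value, _state(before), _state(after))


# ---------------------------------------------------------------------------
# Folding backends

def surrogate_fold(sequence: str) -> tuple[float, int]:
    """Deterministic stand-in for a thermodynamic folding engine.

    Scores the guanine stacking capacity of the higher-scoring strand
    orientation: ``mfe = -0.5 * sum(min(run, 4)**2)`` over maximal G-runs
    (kcal/mol-like units) and ``ed`` = the number of G-runs of length >= 3
    in that orientation.  This is a surrogate for ranking variant-induced
    stability changes, not a thermodynamic model.
    """
    if not sequence:
        raise ValueError("surrogate_fold: empty sequence")

    def _energy(seq: str) -> tuple[float, int]:
        runs = [length for _, length in _run_lengths(seq, "G")]
        mfe = -0.5 * sum(min(r, 4) ** 2 for r in runs)
        ed = sum(1 for r in runs if r >= 3)
        return mfe, ed

    fwd = _energy(sequence)
    rev = _energy(revcomp(sequence))
    return fwd if fwd[0] <= rev[0] else rev


class NullBackend:
    """Backend returning (0, 0) for every sequence (stability disabled)."""

    def fold(self, sequence: str) -> tuple[float, float]:
        if not sequence:
            raise ValueError("fold: empty sequence")
        return 0.0, 0.0


class SurrogateBackend:
    def fold(self, sequence: str) -> tuple[float, float]:
        return surrogate_fold(sequence)


class ExternalCommandBackend:
    """Adapter for an external folding program.

    The command is invoked with sequences on stdin (one per line) and must
    print one "mfe<TAB>ed" line per input sequence.
    """

    def __init__(self, command: list[str] | str):
        self.command = command if isinstance(command, list) else [command]
        self._cache: dict[str, tuple[float, float]] = {}

    def fold(self, sequence: str) -> tuple[float, float]:
        return self.fold_many([sequence])[0]

    def fold_many(self, sequences: list[str]) -> list[tuple[float, float]]:
        todo = [s for s in sequences if s not in self._cache]
        if todo:
            proc = subprocess.run(
                self.command,
                input="\n".join(todo) + "\n",
                capture_output=True,
                text=True,
                check=True,
            )
            lines = proc.stdout.strip().splitlines()
            if len(lines) != len(todo):
                raise RuntimeError(
                    f"backend printed {len(lines)} lines for {len(todo)} sequences"
                )
            for seq, line in zip(todo, lines):
                mfe_s, ed_s = line.split("\t")[:2]
                self._cache[seq] = (float(mfe_s), float(ed_s))
        return [self._cache[s] for s in sequences]


def compute_stability(pair: WindowPair, backend, epsilon: float = 0.01) -> StabilityResult:
    """Fold both windows and classify the MFE change with tolerance ``epsilon``.

    ``delta_mfe < -epsilon`` → further_stabilized; ``> +epsilon`` →
    destabilized; otherwise no_change.  A backend failure flags the effect
    "unscored" rather than aborting.
    """
    try:
        mfe_ref, ed_ref = backend.fold(pair.ref_window)
        mfe_alt, ed_alt = backend.fold(pair.alt_window)
    except Exception:
        return StabilityResult(None, None, None, None, None, None, "unscored")
    delta_mfe = mfe_alt - mfe_ref
    delta_ed = ed_alt - ed_ref
    if delta_mfe < -epsilon:
        cls = "further_stabilized"
    elif delta_mfe > epsilon:
        cls = "destabilized"
    else:
        cls = "no_change"
    return StabilityResult(mfe_ref, mfe_alt, delta_mfe, ed_ref, ed_alt, delta_ed, cls)


# ---------------------------------------------------------------------------
# Two-pass analysis

def _lift_region(region: G4Region, chrom: str, window_start: int, source: str) -> G4Region:
    iv = GenomicInterval(
        chrom, window_start + region.start, window_start + region.end, region.strand
    )
    return G4Region(iv, region.sequence, region.g4hunter_score, source=source)


def analyze_variants(
    genome: GenomeSequence,
    snvs: list[SNV],
    g4_regions: list[G4Region],
    backend=None,
    params: G4Params = DEFAULT_PARAMS,
    flank: int = 30,
    epsilon: float = 0.01,
    gain_requires_alt_g: bool = True,
) -> tuple[list[VariantG4Effect], dict]:
    """Run the two-pass gain/loss analysis over a variant catalog.

    Pass 1 visits SNVs falling strictly inside a supplied G4 region and
    classifies loss/retained (or a cross-strand gain).  Pass 2 visits the
    remaining SNVs whose substitution can create a guanine on either strand
    (alt G on "+", alt C on "-"; all alts when ``gain_requires_alt_g`` is
    False) and emits an effect only when a gain is detected.  Returns the
    effects sorted by (chrom, pos, alt) plus a counts dictionary; SNVs on
    chromosomes absent from the genome are counted and skipped.
    """
    trees: dict[str, IntervalTree] = {}
    for i, region in enumerate(g4_regions):
        trees.setdefault(region.chrom, IntervalTree()).addi(region.start, region.end, i)

    counts = {
        "snvs_total": len(snvs),
        "snvs_skipped_unknown_chrom": 0,
        "snvs_in_g4": 0,
        "pass2_candidates": 0,
        "loss": 0,
        "gain": 0,
        "retained": 0,
    }
    effects: list[VariantG4Effect] = []

    for snv in snvs:
        if snv.chrom not in genome:
            counts["snvs_skipped_unknown_chrom"] += 1
            continue
        tree = trees.get(snv.chrom)
        hits = sorted(tree[snv.pos], key=lambda h: h.data) if tree is not None else []
        pair = None
        if hits:
            counts["snvs_in_g4"] += 1
            pair = extract_windows(genome, snv, flank)
            structural = classify_structural(pair, params)
            # primary region for context/position: prefer the strand that
            # carried the variant-overlapping state before mutation
            regions = [g4_regions[h.data] for h in hits]
            primary = max(regions, key=lambda r: abs(r.g4hunter_score))
            for r in regions:
                if r.strand in structural.strand_state_before:
                    primary = r
                    break
            effect = VariantG4Effect(snv, structural, g4=primary)
        else:
            if gain_requires_alt_g and snv.alt not in ("G", "C"):
                continue
            counts["pass2_candidates"] += 1
            pair = extract_windows(genome, snv, flank)
            structural = classify_structural(pair, params)
            if structural.value != "gain":
                continue
            new = _overlapping_strands(pair.alt_window, pair.variant_offset, params)
            gained_strand = next(
                s for s in ("+", "-") if s in new and s not in structural.strand_state_before
            )
            gained = _lift_region(new[gained_strand], snv.chrom, pair.start, "predicted_alt")
            effect = VariantG4Effect(snv, structural, g4=gained)

        counts[effect.structural.value] += 1
        effect.g4hunter_ref = g4hunter_score(pair.ref_window)
        effect.g4hunter_alt = g4hunter_score(pair.alt_window)
        if backend is not None:
            effect.stability = compute_stability(pair, backend, epsilon)

        # context / position analytics
        strand_for_context = effect.g4.strand if effect.g4 else "+"
        effect.ref3, effect.alt3, effect.context_class = cp.context_for_region(
            genome, snv, strand_for_context
        )
        effect.is_transition = cp.is_transition(snv.ref, snv.alt)
        if effect.g4 is not None and effect.g4.start <= snv.pos < effect.g4.end:
            if effect.g4.sequence:
                effect.in_loop, effect.relative_position = cp.locate_in_g4(snv, effect.g4)
        effects.append(effect)

    effects.sort(key=lambda e: (e.snv.chrom, e.snv.pos, e.snv.alt))
    return effects, counts
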