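"""Per-variant sequence-context analytics.

Covers the trinucleotide (3-mer) context of a variant and its
tetrad-forming / tetrad-breaking classification, transition/transversion
status, tract-vs-loop localization inside a G4, and the relative position
of the variant within the (merged) G4 region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import SNV, GenomeSequence, revcomp
from .g4_detection import G4Region, _run_lengths

# The 12 substitution types in the row order used by the feature summary
# (overall descending frequency in a typical somatic catalog).
SUBSTITUTION_TYPES = [
    "G>A", "G>T", "C>T", "T>G", "A>G", "G>C",
    "C>G", "C>A", "T>C", "T>A", "A>T", "A>C",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(ref: str, alt: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    if ref == alt:
        raise ValueError("is_transition: ref equals alt")
    return frozenset((ref, alt)) in _TRANSITIONS


def trinucleotide_context(genome: GenomeSequence, snv: SNV) -> tuple[str, str]:
    """(ref3, alt3): the 3-mer centered on the variant, N-padded at chromosome ends."""
    seq = genome[snv.chrom]
    left = seq[snv.pos - 1] if snv.pos >= 1 else "N"
    right = seq[snv.pos + 1] if snv.pos + 1 < len(seq) else "N"
    return left + snv.ref + right, left + snv.alt + right


def classify_context(ref3: str, alt3: str) -> str:
    """Classify a 3-mer change as tetrad_forming / tetrad_breaking / neutral.

    A change is tetrad-forming when it completes a GGG from a G(A|C|T)G
    context and tetrad-breaking when it disrupts an existing GGG.
    """
    if alt3 == "GGG" and len(ref3) == 3 and ref3[0] == "G" and ref3[2] == "G" and ref3[1] in "ACT":
        return "tetrad_forming"
    if ref3 == "GGG" and alt3 != "GGG":
        return "tetrad_breaking"
    return "neutral"


def context_for_region(genome: GenomeSequence, snv: SNV, g4_strand: str) -> tuple[str, str, str]:
    """(ref3, alt3, context_class) with tetrad logic applied on the G-rich strand.

    For a minus-strand G4 the 3-mers are reverse-complemented before
    classification so "GGG formation" always refers to the G-rich strand;
    the returned 3-mers are the strand-oriented ones used for the call.
    """
    ref3, alt3 = trinucleotide_context(genome, snv)
    if g4_strand == "-":
        ref3, alt3 = revcomp(ref3), revcomp(alt3)
    return ref3, alt3, classify_context(ref3, alt3)


def locate_in_g4(snv: SNV, region: G4Region) -> tuple[bool, float]:
    """(in_loop, relative_position) of a variant inside a G4 region.

    A base is in a loop when it does not sit inside a maximal run of >=3
    consecutive G (for "+" regions; C for "-" regions) of the region
    sequence.  The relative position is the 1-based offset of the variant
    within the merged region divided by the region length, so it lies in
    (0, 1] and the last base maps to exactly 1.0.
    """
    if snv.chrom != region.chrom or not (region.start <= snv.pos < region.end):
        raise ValueError(
            f"SNV {snv.chrom}:{snv.pos} outside region "
            f"{region.chrom}:{region.start}-{region.end}"
        )
    offset = snv.pos - region.start
    tract_base = "G" if region.strand == "+" else "C"
    in_tract = any(
        s <= offset < s + length
        for s, length in _run_lengths(region.sequence, tract_base)
        if length >= 3
    )
    relative_position = (offset + 1) / len(region.sequence)
    return (not in_tract), relative_position


def position_histogram(effects, bins: int = 10) -> pd.DataFrame:
    """Binned densities of relative_position per (substitution type, strand relation).

    Returns a tidy frame with columns substitution, strand_relation,
    bin_start, bin_end, count and density (fractions summing to 1 within
    each group).  Bin edges are uniform on [0, 1].
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    edges = np.linspace(0.0, 1.0, bins + 1)
    groups: dict[tuple[str, str], list[float]] = {}
    for e in effects:
        rp = getattr(e, "relative_position", None) if not isinstance(e, dict) else e.get("relative_position")
        if rp is None:
            continue
        sub = e["substitution"] if isinstance(e, dict) else e.substitution
        rel = (e.get("strand_relation") if isinstance(e, dict) else getattr(e, "strand_relation", None)) or "unstranded"
        groups.setdefault((sub, rel), []).append(rp)
    rows = []
    if not groups:
        # all-zero histogram with a single unkeyed group
        for b in range(bins):
            rows.append(("all", "unstranded", edges[b], edges[b + 1], 0, 0.0))
    for (sub, rel), values in sorted(groups.items()):
        # right-closed bins (0, 1/b], (1/b, 2/b], ... matching the (0,1] domain
        idx = np.clip(np.ceil(np.asarray(values) * bins).astype(int) - 1, 0, bins - 1)
        counts = np.bincount(idx, minlength=bins)
        total = counts.sum()
        for b in range(bins):
            dens = counts[b] / total if total else 0.0
            rows.append((sub, rel, edges[b], edges[b + 1], int(counts[b]), dens))
    return pd.DataFrame(
        rows,
        columns=["substitution", "strand_relation", "bin_start", "bin_end", "count", "density"],
    )
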