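# Methods

## The analysis in brief

`g4snv` asks what a single-nucleotide variant does to a G-quadruplex (G4)
forming region. A putative G4 (pG4) is a sequence able to fold four stacked
guanine tetrads: four runs of at least three G separated by loops of one to
seven bases, the canonical d(G≥3 N1–7)3 G≥3 rule. The pipeline detects pG4s on
both strands of a reference genome, optionally restricts them to loci confirmed
by an experimental G4 map, and then classifies each SNV in a two-pass scheme:
first-pass SNVs lying inside a detected G4 are tested for **loss** of the
structure, and remaining SNVs whose substitution creates a guanine on either
strand are tested for **gain** of a new structure. Around the classification
the package computes a folding-stability delta, the trinucleotide context of
the change, loop-versus-tract localization, the relative position of the
variant within the G4, genomic-feature annotation with template/non-template
strand relation, and enrichment statistics.

## pG4 detection

The scanner matches `G{t,}(N{l,L}G{t,}){k-1,}` with defaults `t=3` tracts of
three guanines, `k=4` tracts, loops of `l=1` to `L=7` bases. Loop characters
may be any base (including N and further G); N never extends a tract.
The minus strand is scanned with the equivalent C-pattern, so a locus may carry
one "+" and one "−" region, which are never merged with each other.
Overlapping same-strand matches are merged into a single maximal region, and
the merged locus is treated as one sequence for all downstream position
arithmetic. The implementation anchors a greedy regular-expression match at
every start of a G-run of length ≥ t (every match must begin with such a run)
and unions overlapping hits; the test suite proves this equal to a brute-force
oracle that enumerates all substrings.

The G4Hunter score of a sequence is the mean per-base score where each base in
a G-run of length r contributes +min(r, 4) and each base in a C-run
−min(r, 4); it is bounded by [−4, +4], antisymmetric under reverse complement,
and its sign indicates which strand is G-rich.

## Variant classification

For each variant a ±30 nt window pair is built (61 nt when untruncated;
chromosome edges truncate rather than pad, because N-padding would perturb
scores). The detector runs on the reference and alternate windows and only
regions overlapping the substituted base are compared, per strand: a region
present before and absent after is a loss, the reverse a gain, anything else
retained. Strand states before/after are encoded 0, +, −, +-. In the rare
event that one substitution destroys a region on one strand while creating one
on the other, loss takes precedence in the single reported class (both strand
states are still emitted, so the event remains visible).

Pass 2 gain candidacy: the analysis runs on both strands, so a substitution
"leading to a G" means alt = G for a plus-strand gain or alt = C (a guanine on
the minus strand) for a minus-strand gain. Candidacy is therefore alt ∈ {G, C};
setting `gain_requires_alt_g = False` widens pass 2 to every substitution for
sensitivity analysis. Pass-2 variants that do not produce a gain emit no
record, so the effect table is exactly: variants inside a G4 (loss/retained)
plus variants gaining one.

A variant must lie strictly inside `[start, end)` of a region to count as
loss/retained; window-only proximity is not sufficient.

## Stability backends

`delta_mfe = mfe(alt_window) − mfe(ref_window)`, so negative values mean the
variant stabilizes the structure. The class boundary uses
ε = 0.01 kcal/mol: below −ε further_stabilized, above +ε destabilized,
otherwise no_change. ε exists because floating-point backends rarely return
exactly equal energies; it is far below any meaningful energy difference.

Three backends satisfy the `fold(sequence) -> (mfe, ensemble_diversity)`
contract:

* **null** — returns (0, 0); disables stability classing.
* **surrogate** (default) — a deterministic G-stacking score:
  `mfe = −0.5 · Σ min(run, 4)²` over maximal G-runs of the higher-scoring
  orientation of the window, `ed` = number of G-runs ≥ 3 in that orientation.
  It is a monotone proxy for tetrad-stacking capacity, not a thermodynamic
  model: it ranks variant-induced changes correctly by construction (removing
  a tract raises mfe, completing one lowers it) and keeps the pipeline and its
  tests free of any external folding engine.
* **external-command** — adapts any program that reads one sequence per line
  on stdin and prints `mfe<TAB>ed` per line (e.g. a wrapper around an RNA
  folding package), with per-sequence caching.

A backend failure on a sequence flags that effect `unscored` and the pipeline
continues.

## Context and position analytics

The 3-mer context is the base before and after the variant; ends of
chromosomes pad with N. A change is *tetrad_forming* when alt3 = GGG arises
from G[ACT]G and *tetrad_breaking* when ref3 = GGG is disrupted. For
minus-strand G4s both 3-mers are reverse-complemented before classification so
"GGG formation" always refers to the G-rich strand.

A base is *in a loop* when it is not inside a maximal run of ≥3 tract bases
(G for "+", C for "−" regions) of the merged region sequence; spare-tire
guanines sitting in loops therefore count as loop. The relative position is
the 1-based offset of the variant divided by the region length, giving values
in (0, 1] with the last base at exactly 1.0 (the 0-based alternative maps the
first base to 0 and never reaches 1; the 1-based form was chosen so the two
boundary bases are distinguishable and documented here for figure
comparisons). Position histograms use right-closed uniform bins
(0, 1/b], …, matching that domain. Multi-G4 loci merged by the scanner are one
sequence for this arithmetic.

## Feature annotation

Gene models come from a GTF (parsed with pyranges): exons and CDS as given,
introns as transcript span minus exons, UTRs from exon/CDS arithmetic oriented
by strand when not explicit, promoters as the 1 kb (configurable) upstream of
the TSS on the gene's orientation, clipped at chromosome edges. lncRNA labels
follow `gene_biotype`. Enhancers and CpG islands arrive as unstranded BEDs.
A position takes every overlapping label; intergenic appears only where no
gene-derived feature overlaps. Summary tables count a multi-label variant once
per feature column, so columns are proportions within a feature and are not
mutually exclusive.

The annotated gene strand is the sense (non-template) strand, so a G4 on the
same strand as its gene is *non_template* and on the opposite strand
*template*.

## Statistics

* Gene-set enrichment: upper-tail hypergeometric P(X ≥ k) (scipy's survival
  function; verified against exact big-integer enumeration to ≤1e-12 for all
  N ≤ 30), BH step-up FDR across terms. The default universe is the set of
  G4-bearing genes rather than all genes: the question asked is "among genes
  that carry a G4, are mutated ones enriched for a term", which removes the
  trivial enrichment of G4-prone gene classes.
* Kruskal–Wallis with tie correction (scipy) and Dunn's post hoc implemented
  directly (z on mean ranks with tie-corrected pooled variance, two-sided
  normal p, BH across all pairs) since no installed package provides it.
* Ti/Tv comparison: Pearson chi-square on the 2×2 table without Yates
  correction — at catalog-scale counts the correction is immaterial, and the
  uncorrected statistic is the documented, reproducible choice.
* Interval enrichment: the observed statistic is the number of query regions
  overlapping ≥1 feature; the null re-places each region uniformly on its own
  chromosome (length preserved), which keeps chromosome composition fixed;
  the empirical p uses the +1 correction so it is never zero and never below
  1/(n_permutations+1).

## Synthetic data generator

The generator emulates the inputs the analysis consumes: an i.i.d. background
genome at configurable GC (default 0.40, a genome-like value), planted
canonical G4 motifs on both strands, defective "gain sites" (three intact
tracts plus one G[ACT]G tract), two-exon gene models with UTR/CDS/intron
structure on both strands, and a VCF whose background substitution types
follow a 12-category spectrum. The default spectrum is the intron-column
proportions of a large somatic catalog (G→A 26.74%, T→G 19.91%, …), the
fullest published form of the spectrum the pipeline is meant to reproduce.

Truth labels are guaranteed, not hoped for: loop bases are drawn from
{A, C, T} and screened against C-runs, every plant is insulated by 8-nt A/T
pads (longer than the maximum loop, so background sequence can never extend or
merge into a plant), planted loss SNVs hit the center of a middle tract,
planted gains restore the defective tract, planted neutrals substitute loop
bases — and each planted SNV is re-verified through the actual structural
classifier at generation time, with resampling on failure. Background SNVs
exclude ±61 bp around plants and are position-unique. Identical configs
(including seed) produce byte-identical FASTA/GTF/VCF output; a JSON sidecar
records the full config.

What the generator does **not** emulate: real mutation rate heterogeneity
(CpG deamination hotspots, replication timing), linkage between variants,
sample multiplicities or disease metadata, chromatin context, INDELs, and
non-canonical (bulged, two-tetrad) G4s. Passing recovery tests therefore
demonstrates the correctness of the machinery on sequences with exactly the
assumed structure, not detection performance on real genomes.

## Problem sizes and numerical choices in the test suite

The acceptance-style property tests use: 1,000 random 300-nt sequences at 40%
GC for detector/oracle equivalence; 200/200/400 planted losses/gains/neutrals
(800 plants over 4×60 kb) for recovery; n = 10,000 background SNVs for
spectrum recovery judged at the 99% binomial CI per type; all ~41k valid
hypergeometric cases with N ≤ 30; and, for permutation-test calibration, 500
null replicates of 800 query intervals against unrelated features at 399
permutations each. The query-set size in the calibration is deliberately
large: the overlap count is a discrete statistic, and its p-value distribution
is only near-uniform when the statistic's support is fine relative to 1/n —
with small query sets the ties make the empirical p visibly conservative and a
uniformity check would reject for that benign reason.

## Known limitations

* The pattern scanner targets canonical motifs only; imperfect G4s scored
  highly by threshold-based scanners are out of scope.
* The surrogate backend orders stability changes correctly for tract
  gain/loss but its magnitudes are not kcal/mol in any calibrated sense; use
  the external-command backend with a real folding engine when absolute
  energies matter.
* Window-based classification can disagree with genome-scale scanning for
  G4s longer than the window; the window (±30 nt) follows the analysis design
  and is configurable.
* Promoter/enhancer definitions are conventions (1 kb upstream; user BEDs),
  and are echoed in the run report for reproducibility.
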