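"""Statistical machinery: hypergeometric gene-set enrichment with BH-FDR,
permutation-based interval enrichment, Ti/Tv comparison, Kruskal-Wallis with
Dunn's post hoc, and the stability x mutation-type cross-tab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float


def geneset_enrichment(
    query_genes, term_to_genes: dict[str, set], universe=None
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query gene set.

    ``universe`` defaults to the union of the query and all term genes (in
    the pipeline it is the set of G4-bearing genes).  Terms are restricted
    to the universe; results are sorted by p then term id, with BH-FDR
    across all tested terms.
    """
    query = set(query_genes)
    if universe is None:
        universe = set().union(query, *term_to_genes.values()) if term_to_genes else set(query)
    universe = set(universe)
    query &= universe
    n, N = len(query), len(universe)
    rows = []
    for term in sorted(term_to_genes):
        genes = set(term_to_genes[term]) & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        rows.append((term, k, K, n, N, hypergeom_upper(k, K, n, N)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df["fdr"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def read_gene_sets(path: str) -> dict[str, set]:
    """Read term->genes from a two-column TSV (term, gene) or a GMT file."""
    term_to_genes: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            if len(fields) == 2:
                term_to_genes.setdefault(fields[0], set()).add(fields[1])
            else:  # GMT: term, description, genes...
                term_to_genes.setdefault(fields[0], set()).update(g for g in fields[2:] if g)
    return term_to_genes


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = groups - 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    try:
        h, p = stats.kruskal(*groups)
    except ValueError:
        # all values identical: H = 0 by convention
        h, p = 0.0, 1.0
    return float(h), len(groups) - 1, float(p)


def dunn_posthoc(groups, labels=None) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie correction and BH-FDR.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal p,
    BH-adjusted across all C(k, 2) pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var) if var > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((labels[i], labels[j], z, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def titv(effects) -> tuple[float | None, int, int]:
    """Transition:transversion ratio over effect records (None when tv = 0)."""
    ts = tv = 0
    for e in effects:
        flag = e["is_transition"] if isinstance(e, dict) else e.is_transition
        if flag:
            ts += 1
        else:
            tv += 1
    ratio = ts / tv if tv else None
    return ratio, ts, tv


def titv_chisq(ts1: int, tv1: int, ts2: int, tv2: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 Ti/Tv table."""
    table = np.array([[ts1, tv1], [ts2, tv2]])
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _merged_arrays(features: list[GenomicInterval]):
    """Per-chromosome merged (starts, ends) arrays for fast overlap queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in features:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arrays = {}
    for chrom, spans in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(spans):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arrays[chrom] = (
            np.array([m[0] for m in merged]),
            np.array([m[1] for m in merged]),
        )
    return arrays


def _count_overlaps(starts, ends, fs, fe) -> int:
    """Count query intervals [s,e) overlapping any merged feature interval."""
    if fs.size == 0 or starts.size == 0:
        return 0
    idx = np.searchsorted(fs, ends, side="left") - 1
    valid = idx >= 0
    hits = np.zeros(starts.shape, dtype=bool)
    hits[valid] = fe[idx[valid]] > starts[valid]
    return int(hits.sum())


def interval_enrichment(
    query_regions: list[GenomicInterval],
    feature_regions: list[GenomicInterval],
    genome_lengths: dict[str, int],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Permutation test for overlap of query regions with a feature set.

    The observed statistic is the number of query regions overlapping at
    least one feature.  The null re-places each query region uniformly on
    its own chromosome (length preserved) ``n_permutations`` times; the
    empirical p uses the +1 correction, so it is never smaller than
    1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    arrays = _merged_arrays(feature_regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in query_regions:
        if len(iv) > genome_lengths.get(iv.chrom, 0):
            raise ValueError(f"region {iv} longer than its chromosome")
        by_chrom.setdefault(iv.chrom, []).append(iv)

    observed = 0
    null_counts = np.zeros(n_permutations, dtype=int)
    empty = (np.array([]), np.array([]))
    for chrom, ivs in by_chrom.items():
        fs, fe = arrays.get(chrom, empty)
        starts = np.array([iv.start for iv in ivs])
        lengths = np.array([len(iv) for iv in ivs])
        observed += _count_overlaps(starts, starts + lengths, fs, fe)
        max_start = genome_lengths[chrom] - lengths  # inclusive
        rand = rng.integers(0, max_start + 1, size=(n_permutations, len(ivs)))
        for t in range(n_permutations):
            null_counts[t] += _count_overlaps(rand[t], rand[t] + lengths, fs, fe)

    expected_mean = float(null_counts.mean()) if n_permutations else 0.0
    if not feature_regions:
        return observed, expected_mean, 1.0
    empirical_p = (1 + int(np.sum(null_counts >= observed))) / (n_permutations + 1)
    return observed, expected_mean, float(empirical_p)


def stability_crosstab(effects) -> pd.DataFrame:
    """Counts and percentages of mutation class x stability class (six rows).

    Percentages are over all classified effects and sum to 100; effects
    without a stability call (no backend / unscored) are excluded.
    """
    order = [
        ("transition", "further_stabilized"),
        ("transition", "destabilized"),
        ("transition", "no_change"),
        ("transversion", "further_stabilized"),
        ("transversion", "destabilized"),
        ("transversion", "no_change"),
    ]
    counts = {key: 0 for key in order}
    for e in effects:
        if isinstance(e, dict):
            flag, stab = e.get("is_transition"), e.get("stability_class")
        else:
            flag = e.is_transition
            stab = e.stability.stability_class if e.stability else None
        if flag is None or stab not in ("further_stabilized", "destabilized", "no_change"):
            continue
        counts[("transition" if flag else "transversion", stab)] += 1
    total = sum(counts.values())
    rows = [
        (mut, stab, counts[(mut, stab)], 100.0 * counts[(mut, stab)] / total if total else 0.0)
        for mut, stab in order
    ]
    return pd.DataFrame(rows, columns=["mutation_class", "stability_class", "count", "percentage"])
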