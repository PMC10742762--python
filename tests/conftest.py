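"""Shared fixtures and the independent brute-force pG4 oracle."""

from __future__ import annotations

import re

import pytest

from g4snv.io_formats import GenomeSequence


# --- independent oracle -----------------------------------------------------
# Brute force: enumerate all substrings and keep those fully matching the
# canonical pattern, then union-merge per strand.  Deliberately naive; kept
# independent of the scanning strategy inside the package.

G_PATTERN = re.compile(r"G{3,}(?:[ACGTN]{1,7}G{3,}){3,}")
C_PATTERN = re.compile(r"C{3,}(?:[ACGTN]{1,7}C{3,}){3,}")


def _union(spans):
    merged = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def brute_force_pg4(seq: str):
    """All (start, end, strand) merged intervals matching the four-tract rule."""
    out = []
    for pattern, strand in ((G_PATTERN, "+"), (C_PATTERN, "-")):
        spans = []
        n = len(seq)
        for i in range(n):
            best = None
            for j in range(i + 15, n + 1):
                if pattern.fullmatch(seq, i, j):
                    best = j
            if best is not None:
                spans.append((i, best))
        out.extend((s, e, strand) for s, e in _union(spans))
    return sorted(out)


@pytest.fixture
def toy_genome():
    """A 300 nt chromosome with one planted canonical G4 at offset 100."""
    motif = "GGGAGGGTGGGCGGG"
    seq = "AT" * 50 + motif + "TA" * ((300 - 100 - len(motif)) // 2) + "T"
    seq = seq[:300].ljust(300, "A")
    return GenomeSequence(["chr1"], {"chr1": seq})


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic dataset shared across tests (seed 11)."""
    from g4snv.synthetic_data import SimConfig, generate_dataset

    out = tmp_path_factory.mktemp("smallsim")
    config = SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length=60_000,
        n_g4_plus=15,
        n_g4_minus=15,
        n_genes=6,
        n_loss=8,
        n_gain=8,
        n_neutral=8,
        n_background=150,
    )
    return generate_dataset(config, str(out))
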