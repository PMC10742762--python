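"""End-to-end orchestration: scan → intersect → two-pass effects →
annotation → summary tables and a machine-readable run report.

Every output TSV carries a header plus a leading comment line with the
package version and a hash of the configuration; two runs with identical
config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .io_formats import (
    read_bed,
    read_fasta,
    read_snvs,
    sha256_file,
    write_effects_table,
)
from .g4_detection import G4Params, intersect_experimental, scan_genome, write_g4_bed
from .variant_effects import (
    ExternalCommandBackend,
    NullBackend,
    SurrogateBackend,
    analyze_variants,
)
from .context_position import position_histogram
from .genome_annotation import annotate_effects, build_feature_index, feature_summary
from .stats_enrichment import (
    dunn_posthoc,
    geneset_enrichment,
    interval_enrichment,
    kruskal_wallis,
    read_gene_sets,
    stability_crosstab,
    titv,
)
from .synthetic_data import spectrum_estimate


@dataclass
class PipelineConfig:
    genome: str = ""
    vcfs: dict = field(default_factory=dict)  # source name -> path
    experimental_bed: str | None = None
    gtf: str | None = None
    enhancer_bed: str | None = None
    cpg_bed: str | None = None
    gene_sets: str | None = None
    tf_peaks_bed: str | None = None
    out_dir: str = "g4snv_out"
    min_tract: int = 3
    min_tracts: int = 4
    loop_min: int = 1
    loop_max: int = 7
    flank: int = 30
    epsilon_kcal: float = 0.01
    backend: str = "surrogate"  # null | surrogate | external-command
    backend_command: str | None = None
    gain_requires_alt_g: bool = True
    use_putative_only: bool = False
    promoter_size: int = 1000
    n_permutations: int = 999
    position_bins: int = 10
    seed: int = 0

    def g4_params(self) -> G4Params:
        return G4Params(self.min_tract, self.min_tracts, self.loop_min, self.loop_max)

    def analysis_params(self) -> dict:
        # the output location is not part of the analysis fingerprint
        params = dataclasses.asdict(self)
        params.pop("out_dir", None)
        return params

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        if path.endswith((".yaml", ".yml")):
            import yaml

            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        else:
            with open(path) as fh:
                data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def validate(config: PipelineConfig) -> list[str]:
    """Fail-fast validation; returns a list of problems (empty = runnable)."""
    problems: list[str] = []
    paths = {"genome": config.genome}
    for name, path in config.vcfs.items():
        paths[f"vcf:{name}"] = path
    for attr in ("experimental_bed", "gtf", "enhancer_bed", "cpg_bed", "gene_sets", "tf_peaks_bed"):
        value = getattr(config, attr)
        if value:
            paths[attr] = value
    for name, path in paths.items():
        if not path:
            problems.append(f"{name}: no path configured")
        elif not os.path.exists(path):
            problems.append(f"{name}: file not found: {path}")
    if config.flank < 1:
        problems.append(f"flank must be >= 1 (got {config.flank})")
    if config.epsilon_kcal < 0:
        problems.append("epsilon_kcal must be >= 0")
    if config.n_permutations < 1:
        problems.append("n_permutations must be >= 1")
    if config.backend not in ("null", "surrogate", "external-command"):
        problems.append(f"unknown backend {config.backend!r}")
    if config.backend == "external-command" and not config.backend_command:
        problems.append("backend-command required for the external-command backend")
    try:
        config.g4_params()
    except ValueError as exc:
        problems.append(str(exc))

    if not problems and config.genome and config.vcfs:
        genome = read_fasta(config.genome)
        for name, path in config.vcfs.items():
            import pysam

            with pysam.VariantFile(path) as vf:
                contigs = set(vf.header.contigs)
            missing = sorted(contigs - set(genome.chrom_names))
            if missing and not (contigs & set(genome.chrom_names)):
                problems.append(
                    f"vcf:{name}: no contig overlap with genome "
                    f"(VCF has {missing[:3]}, genome has {genome.chrom_names[:3]})"
                )
    return problems


def _make_backend(config: PipelineConfig):
    if config.backend == "null":
        return NullBackend()
    if config.backend == "surrogate":
        return SurrogateBackend()
    return ExternalCommandBackend(config.backend_command.split())


def _write_df(df: pd.DataFrame, path: str, comment: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON)."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    stamp = f"g4snv {__version__} config={config.config_hash()}"

    genome = read_fasta(config.genome)
    params = config.g4_params()
    pg4 = scan_genome(genome, params)

    if config.experimental_bed:
        experimental = read_bed(config.experimental_bed)
        pg4, _ = intersect_experimental(pg4, experimental)
        regions = pg4 if config.use_putative_only else [r for r in pg4 if r.source == "both"]
    else:
        regions = pg4
    write_g4_bed(pg4, os.path.join(config.out_dir, "pg4.bed"))

    snvs = []
    for source, path in sorted(config.vcfs.items()):
        snvs.extend(read_snvs(path, genome, source=source))

    backend = _make_backend(config)
    effects, counts = analyze_variants(
        genome,
        snvs,
        regions,
        backend=backend,
        params=params,
        flank=config.flank,
        epsilon=config.epsilon_kcal,
        gain_requires_alt_g=config.gain_requires_alt_g,
    )

    index = None
    if config.gtf:
        index = build_feature_index(
            config.gtf,
            enhancer_bed=config.enhancer_bed,
            cpg_bed=config.cpg_bed,
            promoter_size=config.promoter_size,
            genome=genome,
        )
        annotate_effects(effects, index)

    write_effects_table(effects, os.path.join(config.out_dir, "effects.tsv"), comment=stamp)

    # strand-state transition counts (before -> after)
    trans = {}
    for e in effects:
        key = (e.structural.strand_state_before, e.structural.strand_state_after)
        trans[key] = trans.get(key, 0) + 1
    trans_df = pd.DataFrame(
        [(b, a, n) for (b, a), n in sorted(trans.items())],
        columns=["state_before", "state_after", "count"],
    )
    _write_df(trans_df, os.path.join(config.out_dir, "strand_states.tsv"), stamp)

    _write_df(stability_crosstab(effects), os.path.join(config.out_dir, "stability_crosstab.tsv"), stamp)
    _write_df(
        feature_summary(effects),
        os.path.join(config.out_dir, "feature_spectrum.tsv"),
        stamp,
        index=True,
    )
    _write_df(
        position_histogram(effects, bins=config.position_bins),
        os.path.join(config.out_dir, "position_histograms.tsv"),
        stamp,
    )

    # overall mutation spectrum of the input catalogs
    spectrum = {}
    for source, path in sorted(config.vcfs.items()):
        spectrum[source] = spectrum_estimate(path)
    spec_df = pd.DataFrame(spectrum)
    spec_df.index.name = "substitution"
    _write_df(spec_df, os.path.join(config.out_dir, "mutation_spectrum.tsv"), stamp, index=True)

    report = {
        "version": __version__,
        "config": config.analysis_params(),
        "config_hash": config.config_hash(),
        "input_checksums": {
            name: sha256_file(path)
            for name, path in [("genome", config.genome)]
            + [(f"vcf:{s}", p) for s, p in sorted(config.vcfs.items())]
            if path
        },
        "counts": {
            **counts,
            "pg4_total": len(pg4),
            "pg4_used": len(regions),
            "effects": len(effects),
        },
    }
    ratio, ts, tv = titv(effects)
    report["titv"] = {"ratio": ratio, "transitions": ts, "transversions": tv}

    # stability comparison across gene features (Kruskal-Wallis + Dunn)
    if index is not None:
        groups, labels = [], []
        for feature in ("UTR3", "UTR5", "CDS", "promoter"):
            values = [
                e.stability.delta_mfe
                for e in effects
                if feature in e.features
                and e.stability
                and e.stability.delta_mfe is not None
                and e.stability.delta_mfe != 0
            ]
            if values:
                groups.append(values)
                labels.append(feature)
        if len(groups) >= 2:
            h, df_, p = kruskal_wallis(groups)
            dunn = dunn_posthoc(groups, labels)
            report["delta_mfe_by_feature"] = {
                "H": h,
                "df": df_,
                "p": p,
                "dunn": dunn.to_dict(orient="records"),
            }

    if config.gene_sets and index is not None:
        term_map = read_gene_sets(config.gene_sets)
        universe = sorted(
            {g for r in regions for g in index.genes_at(r.chrom, r.start)}
            | {g for r in regions for g in index.genes_at(r.chrom, r.end - 1)}
        )
        query = sorted({g for e in effects for g in index.genes_at(e.snv.chrom, e.snv.pos)})
        enr = geneset_enrichment(query, term_map, universe or None)
        _write_df(enr, os.path.join(config.out_dir, "geneset_enrichment.tsv"), stamp)
        report["geneset_enrichment_terms"] = int(len(enr))

    if config.tf_peaks_bed:
        peaks = read_bed(config.tf_peaks_bed)
        observed, expected, p = interval_enrichment(
            [r.interval for r in regions],
            peaks,
            genome.lengths(),
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        report["tf_peak_enrichment"] = {
            "observed_overlap": observed,
            "expected_mean": expected,
            "empirical_p": p,
        }

    with open(os.path.join(config.out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
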