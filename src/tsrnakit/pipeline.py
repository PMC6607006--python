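"""End-to-end orchestration of the tsRNA analysis stages.

A ``RunConfig`` captures every stage parameter plus a single top-level
seed; stage seeds are derived from it, so a completed run is reproducible
bit-for-bit from the config written next to its outputs.  The default
config is a self-contained desk-scale study: a simulated tRNA reference
and small-RNA libraries for two cell states, preprocessing, alignment and
tsRNA calling, per-cluster quantification and differential abundance,
a pulldown enrichment analysis, and the emPAI/binding interactome stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .align import Target, align_reads, write_sam
from .calling import (
    call_tsrnas,
    calls_to_tsv,
    count_tsrnas,
    coverage_matrix,
    per_base_coverage,
    trna_fraction_by_length,
)
from .containers import CountMatrix
from .differential import nb_test, normalize_counts, size_factors
from .interactome import clean_empai, empai_enriched, fit_kd, geneset_enrichment
from .preprocess import preprocess_reads, read_fastq, write_fastq
from .pulldown import analyze_pulldown, summarize_states
from .reference import cluster_by_prefix, load_trna_fasta, write_clusters_tsv
from .simulate import (
    LibraryConfig,
    random_contigs,
    simulate_binding_series,
    simulate_empai_table,
    simulate_pulldown_counts,
    simulate_small_rna_library,
    simulate_trna_reference,
    write_library,
    write_reference,
)

log = logging.getLogger("tsrnakit.pipeline")

__all__ = ["RunConfig", "run_pipeline", "config_hash"]


@dataclass
class RunConfig:
    """Fully-resolved parameters of one pipeline run."""

    seed: int = 1
    outdir: str = "tsrnakit-run"

    # reference simulation
    n_genes: int = 60
    n_anticodons: int = 12
    n_decoys: int = 2
    decoy_length: int = 2500
    rrna_length: int = 1500

    # small-RNA libraries: two conditions x replicates
    conditions: Dict[str, List[str]] = field(
        default_factory=lambda: {
            "LIF": ["LIF_rep1", "LIF_rep2"],
            "RA": ["RA_rep1", "RA_rep2"],
        }
    )
    n_reads: int = 3000
    tsrna_fraction: float = 0.4
    mirna_fraction: float = 0.2
    rrna_fraction: float = 0.1
    error_rate: float = 0.001
    read_len: int = 50

    # preprocessing / alignment
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 5
    min_len: int = 6
    length_lo: int = 18
    length_hi: int = 35
    max_mismatches: int = 2
    prefix_len: int = 50
    write_sam: bool = False

    # pulldown
    pulldown_n_transcripts: int = 2000
    pulldown_n_enriched: int = 60
    pulldown_true_fc: float = 4.0
    pulldown_baseline_mean: float = 200.0
    pulldown_dispersion: float = 0.01
    min_norm: float = 200.0
    fc_cutoff: float = 2.0
    alpha: float = 0.05

    # interactome
    empai_n_proteins: int = 400
    empai_n_enriched: int = 30
    empai_cv: float = 0.05
    binding_kd_nM: float = 33.0
    binding_cv: float = 0.02
    binding_replicates: int = 3

    # optional externally supplied inputs (paths); when set, the
    # corresponding simulation stage is skipped
    input_fastq: Optional[Dict[str, str]] = None
    input_reference_fasta: Optional[str] = None
    input_reference_annotation: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Hash of the analysis-relevant config (output location excluded)."""
    d = config.to_dict()
    d.pop("outdir", None)
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stage_seed(base: int, k: int) -> int:
    return (base * 1009 + k * 9176) % (2**31 - 1)


def _header(config: RunConfig) -> str:
    return f"tsrnakit v{__version__} config={config_hash(config)}"


def _write_tsv(df: pd.DataFrame, path, config: RunConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(config)}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, outdir: Optional[str] = None) -> dict:
    """Execute every stage as configured; returns a dict of artifacts.

    All outputs are written under ``outdir``; a fully-resolved copy of the
    config is written next to them.  Deterministic given the config.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_yaml(out / "run_config.yaml")
    artifacts: dict = {"outdir": str(out)}

    # ------------------------------------------------------------- reference
    log.info("stage=reference building tRNA reference and clusters")
    if config.input_reference_fasta:
        if not Path(config.input_reference_fasta).exists():
            raise FileNotFoundError(
                f"input_reference_fasta: {config.input_reference_fasta!r} "
                "does not exist"
            )
        if not config.input_reference_annotation or not Path(
            config.input_reference_annotation
        ).exists():
            raise FileNotFoundError(
                "input_reference_annotation: missing or does not exist"
            )
        genes = load_trna_fasta(
            config.input_reference_fasta, config.input_reference_annotation
        )
    else:
        genes, ref_manifest = simulate_trna_reference(
            config.n_genes, config.n_anticodons, _stage_seed(config.seed, 1)
        )
        write_reference(genes, out / "trna.fasta", out / "trna_annotation.tsv")
        ref_manifest.to_csv(out / "reference_manifest.tsv", sep="\t", index=False)
    clusters = cluster_by_prefix(genes, config.prefix_len)
    write_clusters_tsv(clusters, out / "clusters.tsv")
    artifacts["clusters"] = str(out / "clusters.tsv")
    log.info("stage=reference n_genes=%d n_clusters=%d", len(genes), len(clusters))

    decoys = random_contigs(
        config.n_decoys, config.decoy_length, _stage_seed(config.seed, 2), "decoy"
    )
    rrna = random_contigs(1, config.rrna_length, _stage_seed(config.seed, 3), "rRNA")

    trna_targets = [
        Target(c.cluster_id, c.representative_sequence, both_strands=False)
        for c in clusters
    ]
    decoy_targets = [Target(t, s, both_strands=True) for t, s in decoys]

    # ---------------------------------------------------- libraries + calling
    sample_names = [s for reps in config.conditions.values() for s in reps]
    groups = {
        s: cond for cond, reps in config.conditions.items() for s in reps
    }
    cluster_ids = sorted(c.cluster_id for c in clusters)
    producing = {
        cond: cluster_ids[i : i + 5]
        for i, cond in enumerate(sorted(config.conditions))
    }

    counts_per_sample = {}
    for si, sample in enumerate(sample_names):
        log.info("stage=simulate sample=%s", sample)
        if config.input_fastq:
            path = config.input_fastq.get(sample)
            if not path or not Path(path).exists():
                raise FileNotFoundError(
                    f"input_fastq[{sample}]: missing or does not exist"
                )
            reads = read_fastq(path)
        else:
            weights = {
                c: 1.0 / len(producing[groups[sample]])
                for c in producing[groups[sample]]
            }
            lib_cfg = LibraryConfig(
                n_reads=config.n_reads,
                tsrna_fraction=config.tsrna_fraction,
                mirna_fraction=config.mirna_fraction,
                rrna_fraction=config.rrna_fraction,
                producing_cluster_weights=weights,
                adapter=config.adapter,
                error_rate=config.error_rate,
                read_len=config.read_len,
                seed=_stage_seed(config.seed, 10 + si),
            )
            reads, manifest = simulate_small_rna_library(
                lib_cfg, clusters, decoys, rrna
            )
            write_library(
                reads,
                manifest,
                out / f"{sample}.fastq",
                out / f"{sample}.manifest.tsv",
            )

        log.info("stage=preprocess sample=%s n_reads=%d", sample, len(reads))
        cleaned, report = preprocess_reads(
            reads,
            rrna,
            adapter=config.adapter,
            min_overlap=config.min_overlap,
            min_len=config.min_len,
            length_lo=config.length_lo,
            length_hi=config.length_hi,
            max_mismatches=config.max_mismatches,
        )
        report.write_tsv(out / f"{sample}.preprocess_report.tsv")
        write_fastq(cleaned, out / f"{sample}.clean.fastq")

        log.info("stage=align sample=%s n_clean=%d", sample, len(cleaned))
        trna_aln = align_reads(cleaned, trna_targets, config.max_mismatches)
        decoy_aln = align_reads(cleaned, decoy_targets, config.max_mismatches)
        if config.write_sam:
            write_sam(
                trna_aln, trna_targets, cleaned, out / f"{sample}.trna.sam"
            )

        calls = call_tsrnas(trna_aln, clusters)
        calls_to_tsv(calls, out / f"{sample}.calls.tsv")
        profiles = per_base_coverage(calls, clusters)
        _write_tsv(coverage_matrix(profiles), out / f"{sample}.coverage.tsv", config)
        frac = trna_fraction_by_length(
            trna_aln + decoy_aln, trna_aln, config.length_lo, config.length_hi
        )
        _write_tsv(frac, out / f"{sample}.trna_fraction.tsv", config)

        counts = count_tsrnas(calls, group_by="cluster", species_filter="5prime")
        counts_per_sample[sample] = counts["count"]

    # ------------------------------------------------------------ diffexp
    log.info("stage=diffexp")
    count_df = (
        pd.DataFrame(counts_per_sample).fillna(0).astype(int).sort_index()
    )
    raw = CountMatrix(data=count_df, normalized=False)
    raw.to_tsv(out / "tsrna_counts.tsv", header_comment=_header(config))
    present = count_df[(count_df > 0).all(axis=1)]
    if len(present) and len(config.conditions) == 2:
        sf = size_factors(raw)
        _write_tsv(sf.to_frame(), out / "size_factors.tsv", config)
        norm = normalize_counts(raw, sf)
        norm.to_tsv(out / "tsrna_counts_normalized.tsv", header_comment=_header(config))
        de = nb_test(raw, sf, groups)
        _write_tsv(de, out / "tsrna_differential.tsv", config)
        artifacts["differential"] = str(out / "tsrna_differential.tsv")
    else:
        log.warning("stage=diffexp skipped (no shared features or not 2 groups)")

    # ------------------------------------------------------------ pulldown
    log.info("stage=pulldown")
    pd_counts, pd_manifest = simulate_pulldown_counts(
        config.pulldown_n_transcripts,
        config.pulldown_n_enriched,
        true_fc=config.pulldown_true_fc,
        baseline_mean=config.pulldown_baseline_mean,
        dispersion=config.pulldown_dispersion,
        seed=_stage_seed(config.seed, 20),
    )
    pd_counts.to_tsv(out / "pulldown_counts.tsv", header_comment=_header(config))
    pd_manifest.to_csv(out / "pulldown_manifest.tsv", sep="\t")
    result = analyze_pulldown(
        pd_counts,
        min_value=config.min_norm,
        fc_cutoff=config.fc_cutoff,
        alpha=config.alpha,
    )
    _write_tsv(result, out / "pulldown_enrichment.tsv", config)
    _write_tsv(
        summarize_states(result).to_frame("n"), out / "pulldown_summary.tsv", config
    )
    artifacts["pulldown"] = str(out / "pulldown_enrichment.tsv")

    # ---------------------------------------------------------- interactome
    log.info("stage=interactome")
    empai_table, empai_manifest = simulate_empai_table(
        config.empai_n_proteins,
        config.empai_n_enriched,
        seed=_stage_seed(config.seed, 30),
        cv=config.empai_cv,
    )
    empai_table.to_csv(out / "empai_raw.tsv", sep="\t", index=False)
    records = empai_enriched(clean_empai(empai_table))
    empai_df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "adj_LIF": round(r.adj_LIF, 6),
                "adj_RA": round(r.adj_RA, 6),
                "log2_ratio": round(r.log2_ratio, 6),
                "discarded_bead_dominant": r.discarded_bead_dominant,
                "enriched_RA": r.enriched_RA,
                "enriched_LIF": r.enriched_LIF,
            }
            for r in records
        ]
    ).set_index("protein_id")
    _write_tsv(empai_df, out / "empai_enrichment.tsv", config)

    hits = [r.protein_id for r in records if r.enriched_RA]
    background = [r.protein_id for r in records if not r.discarded_bead_dominant]
    planted = set(empai_manifest.index[empai_manifest["cls"] == "enriched_RA"])
    gene_sets = {
        "planted_RA_set": planted,
        "random_set": set(background[:: max(1, len(background) // 50)]),
    }
    gsea = geneset_enrichment(hits, background, gene_sets)
    _write_tsv(gsea, out / "empai_geneset_enrichment.tsv", config)

    series = simulate_binding_series(
        config.binding_kd_nM,
        cv=config.binding_cv,
        n_replicates=config.binding_replicates,
        seed=_stage_seed(config.seed, 40),
    )
    fits = []
    for i, s in enumerate(series):
        f = fit_kd(s)
        fits.append(
            {
                "replicate": i + 1,
                "kd_nM": round(f.kd_nM, 6),
                "bmax": round(f.bmax, 6),
                "rss": round(f.residual_sum_squares, 9),
                "converged": f.converged,
            }
        )
    _write_tsv(
        pd.DataFrame(fits).set_index("replicate"), out / "kd_fits.tsv", config
    )
    artifacts["kd_fits"] = str(out / "kd_fits.tsv")
    log.info("stage=done outdir=%s", out)
    return artifacts
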