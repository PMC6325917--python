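"""End-to-end orchestration of the synthetic-fixture analysis.

``run_pipeline`` drives every stage — simulate, dedup, count, correlate,
callpeaks, scanfbe, diff, blocks, ortho-overlap — from one YAML-style
config with a single root seed, and writes a run manifest (parameter echo,
software version, SHA-256 of every output) sufficient to verify that a
rerun with the same seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .annotation import GeneIndex, read_fasta, read_gff3
from .blocks import (build_binding_matrix, cluster_rnas, pca_projection,
                     write_block_tables)
from .counts import (CountsMatrix, build_counts_matrix, correlation_report,
                     normalize_rpm)
from .differential import (call_gender_enriched, estimate_size_factors,
                           filter_testable_genes, test_differential_binding,
                           write_results)
from .motif import peak_fbe_fraction
from .orthology import (OrthologMap, build_groups, compute_overlap,
                        filter_degree, groups_to_tsv)
from .peaks import PeakConfig, call_peaks, write_peaks_bed
from .preprocess import collapse_duplicates, read_sam
from .synthetic_data import (GENDERS, SyntheticConfig, generate_ortholog_fixture,
                             generate_transcriptome, simulate_study,
                             write_dataset)

_STAGES = ("simulate", "dedup", "count", "correlate", "callpeaks",
           "scanfbe", "diff", "blocks", "ortho_overlap")


@dataclass
class PipelineConfig:
    """Validated stage parameters for one pipeline run."""

    outdir: str = "fbfsubnet_run"
    seed: int = 0
    synthetic: dict[str, Any] = field(default_factory=dict)
    peaks: dict[str, Any] = field(default_factory=dict)
    differential: dict[str, Any] = field(default_factory=dict)
    blocks: dict[str, Any] = field(default_factory=dict)
    orthology: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, Any] | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        for block, cls in (("synthetic", SyntheticConfig), ("peaks", PeakConfig)):
            raw = getattr(self, block)
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"unknown {block} keys: {sorted(unknown)}")
        known_diff = {"padj_max", "min_fold", "min_mean_reads", "strict_fold"}
        known_blocks = {"k", "method", "min_rpm"}
        known_orth = {"max_orthologs", "n_mammal", "mammal_per_worm",
                      "target_transfer", "iterate"}
        for name, raw, known in (("differential", self.differential, known_diff),
                                 ("blocks", self.blocks, known_blocks),
                                 ("orthology", self.orthology, known_orth)):
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
        if self.inputs is not None:
            for key in ("annotation", "genome", "samples"):
                if key not in self.inputs:
                    raise ValueError(f"inputs block missing field: {key}")
            for key in ("annotation", "genome"):
                if not Path(self.inputs[key]).exists():
                    raise ValueError(
                        f"inputs.{key}: file not found: {self.inputs[key]}"
                    )

    def synthetic_config(self) -> SyntheticConfig:
        raw = dict(self.synthetic)
        raw.setdefault("seed", self.seed)
        return SyntheticConfig(**raw)

    def peak_config(self) -> PeakConfig:
        return PeakConfig(**self.peaks)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage on (by default) synthetic data; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }

    def record(stage: str, outputs: dict[str, Path], **params: Any) -> None:
        manifest["stages"].append({
            "name": stage,
            "outputs": {str(p.relative_to(outdir)): _sha256(p)
                        for p in outputs.values()},
            "params": params,
        })

    try:
        stage = "simulate"
        syn = config.synthetic_config()
        if config.inputs is None:
            genes, genome, truth = generate_transcriptome(syn)
            samples = simulate_study(syn, truth, genes)
            paths = write_dataset(outdir / "fixtures", syn, genes, genome,
                                  truth, samples)
            sample_reads = {name: s.reads for name, s in samples.items()}
            sample_meta = {name: (s.gender, s.antibody)
                           for name, s in samples.items()}
            record(stage, paths, **dataclasses.asdict(syn))
        else:
            genes = read_gff3(config.inputs["annotation"])
            genome = read_fasta(config.inputs["genome"])
            sample_reads = {}
            sample_meta = {}
            for name, spec in config.inputs["samples"].items():
                sample_reads[name] = read_sam(spec["sam"])
                sample_meta[name] = (spec["gender"], spec["antibody"])
            record(stage, {}, source="user-supplied inputs")
        index = GeneIndex(genes)
        programs = {g.gene_id: g.program for g in genes}

        stage = "dedup"
        dedup = {name: collapse_duplicates(reads)
                 for name, reads in sample_reads.items()}
        dedup_stats = {
            name: {"input_reads": len(sample_reads[name]),
                   "unique_molecules": len(reads)}
            for name, reads in dedup.items()
        }
        p = outdir / "dedup_stats.json"
        p.write_text(json.dumps(dedup_stats, indent=2, sort_keys=True))
        record(stage, {"stats": p})

        stage = "count"
        matrix = build_counts_matrix(dedup, index)
        p = outdir / "counts.tsv"
        matrix.to_tsv(p)
        record(stage, {"counts": p})

        stage = "correlate"
        fbf_cols = [s for s in matrix.samples if sample_meta[s][1] == "FBF"]
        fbf_matrix = CountsMatrix(matrix.counts[fbf_cols],
                                  matrix.library_sizes[fbf_cols])
        report = correlation_report(
            fbf_matrix, {s: sample_meta[s][0] for s in fbf_cols}
        )
        p = outdir / "correlations.json"
        p.write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True))
        record(stage, {"correlations": p})

        stage = "callpeaks"
        pk_cfg = config.peak_config()
        peaks_by_gender = {}
        peak_paths = {}
        for gender in GENDERS:
            fbf = [r for s in fbf_cols if sample_meta[s][0] == gender
                   for r in dedup[s]]
            controls = [dedup[s] for s in matrix.samples
                        if sample_meta[s] == (gender, "control")]
            called = call_peaks(fbf, controls, index, genome, pk_cfg)
            peaks_by_gender[gender] = called
            p = outdir / f"peaks_{gender}.bed"
            write_peaks_bed(called, p)
            peak_paths[gender] = p
        record(stage, peak_paths, **dataclasses.asdict(pk_cfg))

        stage = "scanfbe"
        fbe_stats = {
            gender: {
                "n_peaks": len(pk),
                "fbe_fraction_total": peak_fbe_fraction(pk),
                "fbe_fraction_top500": peak_fbe_fraction(pk, top_n=500)
                if len(pk) >= 500 else None,
            }
            for gender, pk in peaks_by_gender.items()
        }
        p = outdir / "fbe_fractions.json"
        p.write_text(json.dumps(fbe_stats, indent=2, sort_keys=True))
        record(stage, {"fbe": p})

        stage = "diff"
        dcfg = config.differential
        testable = filter_testable_genes(
            matrix, programs, dcfg.get("min_mean_reads", 20.0), samples=fbf_cols
        )
        results = []
        if testable:
            factors = estimate_size_factors(
                CountsMatrix(fbf_matrix.counts.loc[:],
                             fbf_matrix.library_sizes)
            )
            results = test_differential_binding(
                fbf_matrix, factors,
                {s: sample_meta[s][0] for s in fbf_cols}, genes=testable,
            )
            call_gender_enriched(results, dcfg.get("padj_max", 0.01),
                                 dcfg.get("min_fold", 2.0),
                                 dcfg.get("strict_fold", False))
        p = outdir / "differential.tsv"
        write_results(results, p)
        record(stage, {"differential": p}, n_testable=len(testable))

        stage = "blocks"
        target_genes = sorted({
            p_.gene_id for pk in peaks_by_gender.values() for p_ in pk
            if p_.gene_id in matrix.counts.index
        })
        rpm = normalize_rpm(matrix)
        control_cols = [s for s in matrix.samples
                        if sample_meta[s][1] == "control"]
        control_mean = rpm[control_cols].mean(axis=1)
        block_outputs: dict[str, Path] = {}
        k = config.blocks.get("k", 5)
        n_dropped = 0
        bmat = build_binding_matrix(rpm[fbf_cols], control_mean, target_genes)
        n_dropped = len(bmat.dropped)
        if bmat.n_rnas >= k:
            assignment = cluster_rnas(bmat, k=k,
                                      method=config.blocks.get("method", "average"))
            block_outputs = write_block_tables(bmat, assignment, outdir / "blocks")
            scores, evr = pca_projection(bmat)
            p = outdir / "blocks" / "pca_scores.tsv"
            scores.assign(block=assignment.blocks).to_csv(
                p, sep="\t", index_label="gene_id"
            )
            block_outputs["pca"] = p
        record(stage, block_outputs, k=k, n_targets=len(target_genes),
               n_dropped=n_dropped)

        stage = "ortho_overlap"
        ocfg = config.orthology
        edge_df, mam_targets = generate_ortholog_fixture(
            sorted(matrix.counts.index), set(target_genes),
            n_mammal=ocfg.get("n_mammal"),
            mammal_per_worm=ocfg.get("mammal_per_worm", 1.3),
            target_transfer=ocfg.get("target_transfer", 0.6),
            seed=config.seed + 7,
        )
        omap = OrthologMap(
            edges=list(edge_df.itertuples(index=False, name=None)),
            provenance="synthetic",
        )
        filtered = filter_degree(omap, ocfg.get("max_orthologs", 10),
                                 iterate=ocfg.get("iterate", False))
        groups = build_groups(filtered)
        overlap = compute_overlap(groups, set(target_genes), mam_targets)
        gp = outdir / "ortholog_groups.tsv"
        groups_to_tsv(groups, gp)
        op = outdir / "overlap.json"
        op.write_text(json.dumps(overlap.to_json_dict(), indent=2, sort_keys=True))
        record(stage, {"groups": gp, "overlap": op})
    except Exception as exc:  # halt with the stage name
        raise StageError(stage, exc) from exc

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
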