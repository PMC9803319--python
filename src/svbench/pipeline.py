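"""End-to-end pipeline driver: simulate → perturb → normalize → evaluate.

A single run seed deterministically derives a sub-seed for every stochastic
stage, so identical configurations produce byte-identical truth sets and
reports.  Each run writes a JSON manifest recording the tool version, all
parameter values, derived seeds, and SHA-256 checksums of the inputs and
outputs, from which the run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .evaluate import evaluate_callset, round_half_up
from .perturb import PerturbationConfig, perturb_truth
from .simulate import (
    BinScheme,
    PlacementConfig,
    apply_variants,
    build_bin_scheme,
    pack_bins_into_genomes,
    place_variants,
    write_truth,
)
from .variants import DedupPolicy, FilterConfig, resolve_overlaps
from .vcfio import write_sv_vcf

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "read_fasta", "write_fasta"]


def derive_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, stable across platforms (< 2^31)."""
    return zlib.crc32(f"{run_seed}:{stage}".encode()) & 0x7FFFFFFF


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class RunConfig:
    """All parameters of one benchmark run; every stage seed derives from ``seed``."""

    seed: int = 0
    out_dir: str = "svbench_out"
    reference_fasta: Optional[str] = None
    # simulator design
    min_size: int = 100
    max_size: int = 280_000
    n_bins: int = 5
    per_bin_count: int = 30
    max_fraction: float = 0.01
    min_gap: int = 500
    # mock caller error model
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0
    split_prob: float = 0.0
    # normalization & evaluation
    min_call_size: int = 100
    min_recip: float = 0.5
    strata_edges: Optional[list[int]] = None
    n_genomes: Optional[int] = None  # cap on mock genomes actually materialized


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, reference: Optional[dict[str, str]] = None) -> dict:
    """Run simulate → perturb → normalize → evaluate and write reports.

    Returns the manifest dictionary (also written to ``manifest.json``).  On
    stage failure a FAILED marker naming the stage is left in the output
    directory and the exception is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if reference is None:
            if config.reference_fasta is None:
                raise ValueError("need a reference (FASTA path or in-memory dict)")
            stage = "read_reference"
            reference = read_fasta(config.reference_fasta)
        ref_length = sum(len(s) for s in reference.values())
        contig_lengths = {c: len(s) for c, s in reference.items()}

        stage = "simulate"
        scheme = build_bin_scheme(
            config.min_size, config.max_size, config.n_bins, config.per_bin_count
        )
        placement = PlacementConfig(
            max_fraction=config.max_fraction,
            min_gap=config.min_gap,
            seed=derive_seed(config.seed, "pack"),
        )
        specs = pack_bins_into_genomes(scheme, ref_length, placement)
        if config.n_genomes is not None:
            specs = specs[: config.n_genomes]
        genome_reports = []
        manifest_files = {}
        for spec in specs:
            g_seed = derive_seed(config.seed, f"place:{spec.genome_id}")
            truth = place_variants(
                reference, spec, PlacementConfig(
                    max_fraction=config.max_fraction,
                    min_gap=config.min_gap,
                    seed=g_seed,
                )
            )
            truth_vcf = out / f"{spec.genome_id}.truth.vcf"
            write_truth(
                truth, truth_vcf, out / f"{spec.genome_id}.truth.bed",
                contig_lengths=contig_lengths, scheme=scheme, config=placement,
            )
            mutated = apply_variants(reference, truth)
            write_fasta(mutated, out / f"{spec.genome_id}.fa")

            stage = f"perturb:{spec.genome_id}"
            perturbation = PerturbationConfig(
                fn_rate=config.fn_rate,
                fp_rate=config.fp_rate,
                jitter_sd=config.jitter_sd,
                split_prob=config.split_prob,
                seed=derive_seed(config.seed, f"perturb:{spec.genome_id}"),
            )
            calls = perturb_truth(truth, perturbation, contig_lengths)

            stage = f"normalize:{spec.genome_id}"
            filt = FilterConfig(min_size=config.min_call_size)
            kept = [v for v in calls.variants if filt.passes(v)]
            calls.variants = kept
            calls = resolve_overlaps(
                calls, DedupPolicy(seed=derive_seed(config.seed, f"dedup:{spec.genome_id}"))
            )
            calls_vcf = out / f"{spec.genome_id}.calls.vcf"
            write_sv_vcf(calls, calls_vcf, contig_lengths=contig_lengths)

            stage = f"evaluate:{spec.genome_id}"
            results = evaluate_callset(calls, truth, min_recip=config.min_recip) \
                if truth.variants else {}
            genome_reports.append(
                {
                    "genome_id": spec.genome_id,
                    "n_truth": len(truth.variants),
                    "n_calls": len(calls.variants),
                    "per_type": {
                        t: {
                            "tp": r.tp, "fp": r.fp, "fn": r.fn,
                            "precision": r.precision, "recall": r.recall,
                            "f1": r.f1, "jaccard": r.jaccard,
                        }
                        for t, r in results.items()
                    },
                }
            )
            for p in (truth_vcf, calls_vcf):
                manifest_files[str(p.name)] = _sha256(p)

        stage = "report"
        # pooled counts over all mock genomes
        pooled: dict[str, dict[str, float]] = {}
        for t in ("DEL", "DUP", "INV"):
            tp = sum(g["per_type"].get(t, {}).get("tp", 0) for g in genome_reports)
            fp = sum(g["per_type"].get(t, {}).get("fp", 0) for g in genome_reports)
            fn = sum(g["per_type"].get(t, {}).get("fn", 0) for g in genome_reports)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            pooled[t] = {
                "tp": tp, "fp": fp, "fn": fn,
                "precision": prec, "recall": rec, "f1": f1,
            }
        report = {"genomes": genome_reports, "pooled": pooled}
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        tsv_lines = ["genome\tsv_type\ttp\tfp\tfn\tprecision\trecall\tf1\tjaccard"]
        for g in genome_reports:
            for t, r in g["per_type"].items():
                tsv_lines.append(
                    "\t".join(
                        [
                            g["genome_id"], t,
                            str(r["tp"]), str(r["fp"]), str(r["fn"]),
                            f"{round_half_up(r['precision'])}",
                            f"{round_half_up(r['recall'])}",
                            f"{round_half_up(r['f1'])}",
                            f"{round_half_up(r['jaccard'])}",
                        ]
                    )
                )
        (out / "report.tsv").write_text("\n".join(tsv_lines) + "\n")
        manifest = {
            "tool": "svbench",
            "version": __version__,
            "config": asdict(config),
            "derived_seeds": {
                "pack": derive_seed(config.seed, "pack"),
                **{
                    f"place:{s.genome_id}": derive_seed(config.seed, f"place:{s.genome_id}")
                    for s in specs
                },
            },
            "n_genomes": len(specs),
            "files": manifest_files,
            "report_sha256": _sha256(report_path),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
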