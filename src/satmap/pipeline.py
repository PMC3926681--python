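"""Pipeline orchestration: configuration, staged execution, reports.

``run_pipeline`` executes the saturation workflow in order — simulate (or
load) reads, clean, partition, sweep-assemble, compute sweep statistics,
build the saturation matrix, emit a depth recommendation — writing every
artifact plus a machine-readable manifest under the configured output
directory.  Stages whose artifacts already exist for the same
configuration are skipped on rerun, so a run is resumable.  Every number
in a rendered report is read back from the raw artifacts; reports do no
arithmetic of their own beyond formatting.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, readqc, seqio
from .assembler import AssemblyParams, assemble_internal
from .metrics import assembly_stats, stats_table, sweep_result
from .readqc import QualityPolicy, QuantumSchedule, clean_library, partition_quanta
from .saturation import build_matrix, recommend_depth
from .simdata import (
    ReadSimSpec,
    SyntheticTranscriptomeSpec,
    gen_transcriptome,
    simulate_reads,
    write_paired_fastq,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable parameters for a full pipeline run."""

    outdir: str = "satmap_run"
    seed: int = 1
    # input reads: either simulate=True or paths to existing FASTQ pairs
    simulate: bool = True
    fq1: Optional[str] = None
    fq2: Optional[str] = None
    # simulation
    n_transcripts: int = 300
    length_median_bp: int = 450
    length_sigma: float = 0.45
    expression_orders: float = 4.0
    tissue_specific_fraction: float = 0.1
    per_base_error_rate: float = 0.005
    # cleaning
    min_phred: int = 20
    min_length_bp: int = 30
    # partitioning / assembly
    quantum_targets: tuple[int, ...] = (1_000_000, 2_000_000, 4_000_000)
    k_values: tuple[int, ...] = (21, 25, 29)
    min_transcript_bp: int = 100
    min_kmer_count: int = 2
    # mapping / recommendation
    e_threshold: float = 1.0e-5
    target_pct: float = 90.0
    engine: str = "internal"
    adapter_cmd: Optional[str] = None
    threads: int = 1

    def __post_init__(self) -> None:
        self.quantum_targets = tuple(int(t) for t in self.quantum_targets)
        self.k_values = tuple(int(k) for k in self.k_values)
        if not self.simulate and not (self.fq1 and self.fq2):
            raise ValueError("config must either simulate reads or name fq1/fq2")
        if self.engine not in ("internal", "external"):
            raise ValueError(f"unknown engine {self.engine!r}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the artifact manifest (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    digest = config.digest()

    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_digest") == digest and all(
            Path(p).exists() for p in old.get("artifacts", {}).values()
        ):
            return old  # resume: nothing to recompute

    manifest: dict = {
        "version": __version__,
        "config_digest": digest,
        "seed": config.seed,
        "artifacts": {},
        "parameters": asdict(config),
    }

    def artifact(name: str, path: Path) -> Path:
        manifest["artifacts"][name] = str(path)
        return path

    # --- reads ------------------------------------------------------------
    try:
        if config.simulate:
            t_spec = SyntheticTranscriptomeSpec(
                n_transcripts=config.n_transcripts,
                length_median_bp=config.length_median_bp,
                length_sigma=config.length_sigma,
                expression_orders=config.expression_orders,
                tissue_specific_fraction=config.tissue_specific_fraction,
                seed=config.seed,
            )
            r_spec = ReadSimSpec(
                per_base_error_rate=config.per_base_error_rate,
                target_bases=int(config.quantum_targets[-1] * 1.15),
                seed=config.seed,
            )
            transcriptome = gen_transcriptome(t_spec)
            transcriptome.to_fasta(artifact("reference_fasta", outdir / "reference.fasta"))
            pd.DataFrame(transcriptome.abundance_rows()).to_csv(
                artifact("abundance_tsv", outdir / "abundance.tsv"), sep="\t", index=False
            )
            raw_pairs = simulate_reads(transcriptome, r_spec)
            p1, p2 = write_paired_fastq(raw_pairs, str(outdir / "reads"))
            artifact("fq1", Path(p1))
            artifact("fq2", Path(p2))
        else:
            raw_pairs = readqc.read_paired_fastq(config.fq1, config.fq2)
    except (OSError, ValueError) as exc:
        raise StageError("reads", str(exc)) from exc

    # --- clean ------------------------------------------------------------
    try:
        policy = QualityPolicy(min_phred=config.min_phred, min_length_bp=config.min_length_bp)
        pool = clean_library(raw_pairs, policy)
        paths = readqc.write_pool(pool, str(outdir / "clean"))
        artifact("cleaning_report", Path(paths["report"]))
    except ValueError as exc:
        raise StageError("clean", str(exc)) from exc

    # --- partition + sweep assembly ----------------------------------------
    try:
        schedule = QuantumSchedule(config.quantum_targets)
        quanta = partition_quanta(pool, schedule, seed=config.seed)
    except ValueError as exc:
        raise StageError("partition", str(exc)) from exc

    try:
        assemblies = {}
        stats = []
        sweeps = {}
        for target, quantum in zip(schedule.targets, quanta):
            seqs = [s for f, r in quantum for s in (f.sequence, r.sequence)]
            per_k = []
            for k in config.k_values:
                params = AssemblyParams(
                    k=k,
                    min_transcript_bp=config.min_transcript_bp,
                    min_kmer_count=config.min_kmer_count,
                )
                asm = assemble_internal(seqs, params, label=(target, k))
                asm.to_fasta(outdir / f"assembly_d{target}_k{k}.fasta")
                assemblies[(target, k)] = asm
                st = assembly_stats(asm)
                per_k.append(st)
                stats.append(st)
            sweeps[target] = sweep_result(target, per_k)
        grid = stats_table(stats)
        grid.to_csv(artifact("sweep_tsv", outdir / "sweep_stats.tsv"), sep="\t", index=False)
        sweep_summary = {
            str(d): {
                "peaked": s.peaked,
                "optimized_k": s.optimized_k,
                "optimized_n50_bp": s.optimized_n50_bp,
                "boundary_k": s.boundary_k,
                "boundary_n50_bp": s.boundary_n50_bp,
            }
            for d, s in sweeps.items()
        }
        (outdir / "sweeps.json").write_text(json.dumps(sweep_summary, indent=2) + "\n")
        artifact("sweeps_json", outdir / "sweeps.json")
    except ValueError as exc:
        raise StageError("assemble", str(exc)) from exc

    # --- saturation matrix + recommendation --------------------------------
    try:
        top = schedule.targets[-1]
        top_sweep = sweeps[top]
        full_k = top_sweep.optimized_k if top_sweep.peaked else top_sweep.boundary_k
        matrix = build_matrix(
            assemblies, assemblies[(top, full_k)], config.e_threshold, sweeps=sweeps
        )
        (outdir / "saturation_matrix.tsv").write_text(matrix.to_tsv())
        artifact("matrix_tsv", outdir / "saturation_matrix.tsv")
        matrix.to_dataframe().to_csv(
            artifact("matrix_cells_tsv", outdir / "saturation_cells.tsv"),
            sep="\t",
            index=False,
        )
        try:
            rec = recommend_depth(matrix, sweeps, target_pct=config.target_pct)
            rec_payload = {
                "target_pct": rec.target_pct,
                "recommended_range_bases": rec.recommended_range_bases,
                "rationale": rec.rationale,
                "explanation": rec.explanation,
            }
        except ValueError as exc:
            rec_payload = {"target_pct": config.target_pct, "error": str(exc)}
        (outdir / "recommendation.json").write_text(json.dumps(rec_payload, indent=2) + "\n")
        artifact("recommendation_json", outdir / "recommendation.json")
    except ValueError as exc:
        raise StageError("saturate", str(exc)) from exc

    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# reporting


def _round2(x: float) -> str:
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def render_reports(manifest: dict) -> str:
    """Human-readable summary assembled from the manifest's raw artifacts."""
    arts = manifest.get("artifacts", {})
    lines = [f"satmap {manifest.get('version', '?')} run report", "=" * 40]

    report = arts.get("cleaning_report")
    if report and Path(report).exists():
        df = pd.read_csv(report, sep="\t")
        lines.append("\nRead cleaning")
        for _, row in df.iterrows():
            lines.append(
                f"  {row['category']}: {int(row['reads']):,} reads "
                f"({_round2(row['reads_pct_of_raw'])}%), "
                f"{int(row['bases']):,} nt ({_round2(row['bases_pct_of_raw'])}%)"
            )

    sweeps = arts.get("sweeps_json")
    if sweeps and Path(sweeps).exists():
        data = json.loads(Path(sweeps).read_text())
        lines.append("\nK-mer sweeps (per datasize)")
        for d, s in sorted(data.items(), key=lambda kv: int(kv[0])):
            if s["peaked"]:
                lines.append(
                    f"  {int(d):,} nt: optimized k={s['optimized_k']} "
                    f"(N50 {s['optimized_n50_bp']} bp)"
                )
            else:
                lines.append(
                    f"  {int(d):,} nt: no optimum (N50 maximal at boundary "
                    f"k={s['boundary_k']}, {s['boundary_n50_bp']} bp)"
                )

    cells = arts.get("matrix_cells_tsv")
    if cells and Path(cells).exists():
        df = pd.read_csv(cells, sep="\t")
        if df.empty:
            lines.append("\nSaturation matrix: no cells")
        else:
            lines.append("\nSaturation matrix (pct of full transcriptome mapped)")
            pivot = df.pivot(index="k", columns="datasize_bases", values="pct_mapped")
            header = "  k    " + "  ".join(f"{d:>12,}" for d in pivot.columns)
            lines.append(header)
            for k in pivot.index:
                row = "  ".join(f"{_round2(pivot.at[k, d]):>12}" for d in pivot.columns)
                lines.append(f"  {k:<5}{row}")

    rec = arts.get("recommendation_json")
    if rec and Path(rec).exists():
        payload = json.loads(Path(rec).read_text())
        lines.append("\nDepth recommendation")
        rng = payload.get("recommended_range_bases")
        if rng:
            lines.append(
                f"  target {payload['target_pct']}% coverage: "
                f"generate between {rng[0]:,} and {rng[1]:,} nt"
            )
        else:
            lines.append(f"  {payload.get('explanation', payload.get('error', 'unavailable'))}")
    return "\n".join(lines) + "\n"
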