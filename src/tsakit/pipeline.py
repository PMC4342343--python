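"""Pipeline configuration, orchestration, logging and report tables.

One configuration object holds every named threshold of the analysis (ORF
minimum length, E-value edges, the 0.5 signal-peptide cut-off, the
window-17 hydropathy TM rule, the first-60-aa single-TM allowance, the
50 nt / 97% / 0.1 decontamination rule, EM tolerances), is serialisable to
YAML, and drives a deterministic stage chain:

    metrics -> orfs -> unigenes -> tpm -> secretome -> peptides -> decontam

Without input files the pipeline runs on a simulated truth-labelled bundle,
which makes ``tsakit run`` a self-contained smoke test of every stage.
Reports are TSV; a MANIFEST records stage completion, and the run log is
machine-parsable ``key=value`` lines mirrored to stderr and to file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .core import compute_assembly_metrics, metrics_to_tsv, read_fasta, write_fasta
from .decontam import decontaminate
from .orfs import (
    completeness_summary,
    find_orfs,
    length_histogram,
    longest_orf_per_group,
    write_protein_fasta,
)
from .prohormone import derive_peptides, peptides_to_frame, predict_cleavage_sites
from .quantify import compute_tpm, em_allocate, write_expression_tsv
from .secretome import (
    ProteinSeq,
    calls_to_frame,
    deduplicate_proteins,
    secretome_filter,
    write_secretome_fasta,
)
from .simulate import (
    SimConfig,
    apply_contamination_tpm,
    generate_reads,
    generate_transcriptome,
    inject_contamination,
)
from .unigenes import best_hit_per_component, evalue_bin_summary, read_outfmt6

DEFAULT_EVALUE_EDGES = (1e-1, 1e-6, 1e-20, 1e-75, 1e-100, 1e-125, 1e-150, 1e-175, 1e-200, 0.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "tsakit_out"
    # inputs; None means "simulate"
    assembly: str | None = None
    other_assembly: str | None = None
    expression: str | None = None
    hits: str | None = None
    # stage toggles
    stages: tuple[str, ...] = (
        "metrics", "orfs", "unigenes", "tpm", "secretome", "peptides", "decontam"
    )
    # thresholds
    min_orf_aa: int = 100
    evalue_cutoff: float = 1e-6
    evalue_edges: tuple[float, ...] = DEFAULT_EVALUE_EDGES
    sp_threshold: float = 0.5
    tm_window: int = 17
    tm_threshold: float = 1.6
    tm_min_span: int = 15
    tm_nterm_limit: int = 60
    decontam_min_len: int = 50
    decontam_min_identity: float = 97.0
    decontam_max_ratio: float = 0.1
    em_tol: float = 1e-3
    em_max_iter: int = 1000
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.sp_threshold <= 1:
            raise ValueError("sp_threshold must lie in [0, 1]")
        if self.tm_window % 2 == 0 or self.tm_window < 1:
            raise ValueError("tm_window must be odd and positive")
        if self.min_orf_aa < 1:
            raise ValueError("min_orf_aa must be >= 1")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("sim", None)
        cfg = cls(**{k: _tuplify(v) for k, v in data.items()})
        if sim is not None:
            cfg.sim = SimConfig(**{k: _tuplify(v) for k, v in sim.items()})
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output destination excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(_listify(d), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tuplify(v):
    if isinstance(v, list):
        return tuple(_tuplify(x) for x in v)
    return v


def _listify(v):
    if isinstance(v, tuple):
        return [_listify(x) for x in v]
    if isinstance(v, dict):
        return {k: _listify(x) for k, x in v.items()}
    return v


class RunLog:
    """key=value run log mirrored to stderr and a file."""

    def __init__(self, path: Path):
        self.path = path
        self.fh = open(path, "w")

    def emit(self, **fields) -> None:
        line = " ".join(f"{k}={v}" for k, v in fields.items())
        print(line, file=sys.stderr)
        self.fh.write(line + "\n")
        self.fh.flush()

    def close(self) -> None:
        self.fh.close()


def run_pipeline(config: PipelineConfig) -> tuple[int, dict]:
    """Execute the toggled stages; returns (exit status, manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run.log")
    log.emit(event="start", tsakit=__version__, python=sys.version.split()[0],
             seed=config.seed, config_hash=config.config_hash())
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}
    status = 0
    truth = None
    try:
        if config.assembly:
            assembly = read_fasta(config.assembly)
        else:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            assembly, truth = generate_transcriptome(sim)
            write_fasta(assembly, out / "assembly.fasta")
            truth.to_json(out / "truth.json")
            log.emit(event="simulated", n_transcripts=len(assembly))

        orfs = None
        expr = None
        calls = None
        proteins = None

        for stage in config.stages:
            try:
                if stage == "metrics":
                    metrics = compute_assembly_metrics(assembly)
                    (out / "table1_metrics.tsv").write_text(metrics_to_tsv(metrics))
                elif stage == "orfs":
                    orfs = [o for rec in assembly for o in find_orfs(rec, config.min_orf_aa)]
                    completeness_summary(orfs).to_csv(
                        out / "fig1b_completeness.tsv", sep="\t", index=False
                    )
                    length_histogram([r.length for r in assembly], "nt").to_csv(
                        out / "fig1a_length_hist.tsv", sep="\t", index=False
                    )
                    length_histogram(
                        [(o.aa_length, o.completeness) for o in orfs], "aa"
                    ).to_csv(out / "fig1b_length_hist.tsv", sep="\t", index=False)
                    write_protein_fasta(orfs, out / "orfs.pep.fasta")
                elif stage == "unigenes":
                    if config.hits is None:
                        manifest["stages"][stage] = "skipped (no hits table)"
                        log.emit(event="stage_skipped", stage=stage)
                        continue
                    hits = read_outfmt6(config.hits)
                    bhpc = best_hit_per_component(hits, config.evalue_cutoff)
                    evalue_bin_summary(bhpc, config.evalue_edges).to_csv(
                        out / "fig2c_evalue_bins.tsv", sep="\t", index=False
                    )
                elif stage == "tpm":
                    expr = _quantify_stage(config, assembly, truth, out, log)
                elif stage == "secretome":
                    if orfs is None:
                        orfs = [
                            o for rec in assembly for o in find_orfs(rec, config.min_orf_aa)
                        ]
                    # start-bearing ORFs only (complete or 3'-truncated), THEN
                    # longest per subcomponent, mirroring the published
                    # extraction of evaluable N-termini
                    start_bearing = [
                        o for o in orfs if o.completeness in ("complete", "partial_3prime")
                    ]
                    best = longest_orf_per_group(start_bearing, "subcomponent")
                    proteins = deduplicate_proteins(
                        [ProteinSeq(o.transcript_id, o.peptide, o.completeness) for o in best]
                    )
                    calls = secretome_filter(
                        proteins,
                        sp_threshold=config.sp_threshold,
                        tm_window=config.tm_window,
                        tm_threshold=config.tm_threshold,
                        tm_min_span=config.tm_min_span,
                        tm_nterm_limit=config.tm_nterm_limit,
                    )
                    calls_to_frame(calls).to_csv(
                        out / "secretome_calls.tsv", sep="\t", index=False
                    )
                    write_secretome_fasta(proteins, calls, out / "secretome.fasta")
                elif stage == "peptides":
                    if calls is None or proteins is None:
                        manifest["stages"][stage] = "skipped (secretome stage off)"
                        log.emit(event="stage_skipped", stage=stage)
                        continue
                    seq_of = {p.protein_id: p.sequence for p in proteins}
                    peptides = []
                    for c in calls:
                        if c.verdict != "secreted" or c.sp_cleavage_pos is None:
                            continue
                        seq = seq_of[c.protein_id]
                        sites = predict_cleavage_sites(seq, c.sp_cleavage_pos)
                        peptides.extend(
                            derive_peptides(seq, c.sp_cleavage_pos, sites, c.protein_id)
                        )
                    peptides_to_frame(peptides).to_csv(
                        out / "peptides.tsv", sep="\t", index=False
                    )
                elif stage == "decontam":
                    _decontam_stage(config, assembly, truth, expr, out, log)
                else:
                    raise ValueError(f"unknown stage: {stage}")
                manifest["stages"].setdefault(stage, "ok")
                log.emit(event="stage_done", stage=stage)
            except Exception as exc:  # keep partial outputs, flag failure
                manifest["stages"][stage] = f"failed: {exc}"
                log.emit(event="stage_failed", stage=stage, error=repr(exc))
                status = 2
                break
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        log.emit(event="end", status=status)
        log.close()
    return status, manifest


def _quantify_stage(config, assembly, truth, out, log):
    from .quantify import read_expression_tsv

    if config.expression:
        expr = read_expression_tsv(config.expression)
    else:
        sub_len: dict[str, int] = {}
        for rec in assembly:
            sub_len[rec.subcomponent_id] = max(
                sub_len.get(rec.subcomponent_id, 0), rec.length
            )
        subs = sorted(sub_len)
        rng_theta = {s: 1.0 / len(subs) for s in subs}
        reads = generate_reads(assembly, rng_theta, n_reads=20000, ambiguity=0.1,
                               seed=config.seed)
        expr = em_allocate(reads, {s: float(sub_len[s]) for s in subs},
                           max_iter=config.em_max_iter, tol=config.em_tol)
        log.emit(event="quantified", n_genes=len(subs), n_reads=len(reads))
    write_expression_tsv(expr, out / "expression.tsv")
    return expr


def _decontam_stage(config, assembly, truth, expr, out, log):
    if config.other_assembly:
        other = read_fasta(config.other_assembly)
        expr_a = {r.subcomponent_id: r.tpm for r in expr} if expr else {}
        expr_b = expr_a  # caller-provided tables are required in CLI mode
    else:
        # synthetic round trip: contaminate a copy of this assembly into a
        # second one and clean the second
        sim_b = dataclasses.replace(config.sim, seed=config.seed + 1000,
                                    n_components=max(20, config.sim.n_components // 4),
                                    n_secreted=0, n_tm=0, n_mito=0, n_cytosolic=0)
        other, _ = generate_transcriptome(sim_b)
        contaminated, labels = inject_contamination(assembly, other, config.sim)
        base_tpm = {r.subcomponent_id: 100.0 for r in assembly}
        other_tpm = {r.subcomponent_id: 100.0 for r in other}
        cont_tpm = apply_contamination_tpm(other_tpm, base_tpm, labels)
        clean, verdicts = decontaminate(
            contaminated, assembly, cont_tpm, base_tpm,
            min_len=config.decontam_min_len,
            min_identity=config.decontam_min_identity,
            max_tpm_ratio=config.decontam_max_ratio,
        )
        write_fasta(clean, out / "decontaminated.fasta")
        verdicts.to_csv(out / "decontam_verdicts.tsv", sep="\t", index=False)
        log.emit(event="decontaminated", removed=int(verdicts["removed"].sum()),
                 planted=len(labels.contaminants))
        return
    clean, verdicts = decontaminate(
        assembly, other, expr_a, expr_b,
        min_len=config.decontam_min_len,
        min_identity=config.decontam_min_identity,
        max_tpm_ratio=config.decontam_max_ratio,
    )
    write_fasta(clean, out / "decontaminated.fasta")
    verdicts.to_csv(out / "decontam_verdicts.tsv", sep="\t", index=False)
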