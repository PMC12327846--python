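"""End-to-end orchestration: configuration, the full run, and the manifest.

A run consumes a genome FASTA, a GFF3 annotation, and one coverage track
(bedGraph) or alignment file (BED/SAM) per sample; the sample sheet maps
files to (sample, regulator, condition, replicate). Outputs: per-sample
peak tables, consolidated targets per regulator with annotation, the
replicate Pearson matrix, optional motif-scan hits and expression
correlation, a JSON summary, and a manifest (parameters, seed, input
checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import consolidate as _consolidate
from . import coverage as _coverage
from . import motifs as _motifs
from . import peaks as _peaks
from . import synthetic as _synthetic

log = logging.getLogger("chapkit")


@dataclass
class SampleRow:
    sample: str
    regulator: str
    condition: str
    replicate: int
    path: str  # bedGraph / BED / SAM for this sample


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    samples: list
    outdir: str = "chapkit_out"
    min_fold: float = 3.0
    sigma_ratio: float = 0.125
    merge_distance: float | None = None  # None -> expected_width / 2
    upstream_window: int = 500
    p_threshold: float = 1.0e-5
    circular: bool = True
    collapse: bool = True
    blacklist: list = field(default_factory=list)
    consensus: str | None = None
    expression: str | None = None
    seed: int = 0
    keep_going: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        rows = [SampleRow(**r) for r in d.pop("samples")]
        return cls(samples=rows, **d)

    def validate(self) -> None:
        for p in [self.genome, self.annotation] + [r.path for r in
                                                   self.samples]:
            if not Path(p).exists():
                row = next((r.sample for r in self.samples if r.path == p),
                           None)
                where = f" (sample row {row!r})" if row else ""
                raise FileNotFoundError(f"missing input {p}{where}")
        if self.min_fold < 0 or not (0 < self.sigma_ratio <= 1):
            raise ValueError("parameters out of documented range")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_track(row: SampleRow, genome_length: int, circular: bool,
                collapse: bool) -> _coverage.CoverageTrack:
    path = Path(row.path)
    if path.suffix in (".bedgraph", ".bg", ".bedGraph"):
        t = _coverage.read_track(path, length=genome_length,
                                 circular=circular)
    else:
        if path.suffix == ".sam":
            recs = _coverage.read_sam(path)
        else:
            recs = _coverage.read_bed(path)
        if collapse:
            recs = _coverage.collapse_alignments(recs)
        t = _coverage.compute_coverage(recs, genome_length, circular)
    t.sample, t.condition, t.replicate = row.sample, row.condition, \
        row.replicate
    return t


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the result bundle as a dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _synthetic.read_fasta(config.genome, circular=config.circular)
    genes = _annotate.read_gff3(config.annotation)
    L = len(genome)
    blacklist = [tuple(iv) for iv in config.blacklist]

    peaksets: dict = {}
    errors = []
    for row in config.samples:
        try:
            log.info("stage=callpeaks sample=%s condition=%s rep=%d",
                     row.sample, row.condition, row.replicate)
            track = _load_track(row, L, config.circular, config.collapse)
            ps = _peaks.call_peaks(track, min_fold=config.min_fold,
                                   blacklist=blacklist or None,
                                   sigma_ratio=config.sigma_ratio)
            peaksets[row.sample] = ps
            _peaks.write_peaks(ps, outdir / f"peaks_{row.sample}.bed",
                               chrom=genome.chrom_id)
        except Exception as e:
            msg = f"stage=callpeaks sample={row.sample}: {e}"
            if config.keep_going:
                log.error(msg)
                errors.append(msg)
            else:
                raise RuntimeError(msg) from e

    regulators = sorted({r.regulator for r in config.samples})
    conditions = sorted({r.condition for r in config.samples})
    targets_by_reg: dict = {}
    matrices: dict = {}
    summary: dict = {"n_samples": len(config.samples),
                     "regulators": regulators, "conditions": conditions,
                     "errors": errors, "per_regulator": {}}
    for reg in regulators:
        reg_sets = [peaksets[r.sample] for r in config.samples
                    if r.regulator == reg and r.sample in peaksets]
        if not reg_sets:
            continue
        targets = _consolidate.merge_replicates(reg_sets,
                                                config.merge_distance)
        targets = _annotate.annotate_targets(
            targets, genes, L, config.upstream_window, config.circular)
        for t in targets:
            t.regulator = reg
        targets_by_reg[reg] = targets
        _consolidate.write_targets(targets,
                                   outdir / f"targets_{reg}.tsv")
        if len(reg_sets) >= 2:
            mat = _consolidate.pearson_matrix(reg_sets,
                                              config.merge_distance)
            matrices[reg] = mat
            mat.to_csv(outdir / f"pearson_{reg}.tsv", sep="\t")
        n_up, n_in = _annotate.classify_counts(targets)
        parts = _consolidate.condition_specific_sets(targets, conditions)
        summary["per_regulator"][reg] = {
            "n_targets": len(targets),
            "n_upstream": n_up, "n_intragenic": n_in,
            "condition_classes": {k: len(v) for k, v in sorted(
                parts.items())},
        }

    if len(targets_by_reg) == 2:
        a, b = regulators
        shared, only_a, only_b = _consolidate.compare_regulons(
            targets_by_reg[a], targets_by_reg[b], mode="by_gene")
        summary["regulon_overlap"] = {"shared": len(shared),
                                      f"only_{a}": len(only_a),
                                      f"only_{b}": len(only_b)}

    hits = []
    if config.consensus:
        pwm = _motifs.consensus_to_pwm(config.consensus)
        hits = _motifs.scan(genome, pwm, p_threshold=config.p_threshold)
        pd.DataFrame(hits).to_csv(outdir / "motif_hits.tsv", sep="\t",
                                  index=False)
        summary["n_motif_hits"] = len(hits)

    if config.expression and targets_by_reg:
        expr = pd.read_csv(config.expression, sep="\t")
        for reg, targets in targets_by_reg.items():
            try:
                coef, p, table = \
                    _consolidate.intensity_expression_correlation(
                        targets, expr, seed=config.seed)
                summary.setdefault("expression_correlation", {})[reg] = {
                    "spearman": coef, "p_permutation": p,
                    "n_pairs": len(table)}
            except ValueError as e:
                log.warning("stage=correlate regulator=%s: %s", reg, e)

    for reg, targets in targets_by_reg.items():
        try:
            coef, p = _annotate.distance_intensity_trend(
                targets, seed=config.seed)
            summary["per_regulator"][reg]["distance_intensity"] = {
                "spearman": coef, "p_permutation": p}
        except ValueError:
            pass

    manifest = {
        "parameters": {k: v for k, v in asdict(config).items()
                       if k != "samples"},
        "samples": [asdict(r) for r in config.samples],
        "seed": config.seed,
        "inputs_sha256": {p: _sha256(p) for p in
                          [config.genome, config.annotation]
                          + [r.path for r in config.samples]},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)

    return {"peaksets": peaksets, "targets": targets_by_reg,
            "pearson": matrices, "motif_hits": hits, "summary": summary,
            "manifest": manifest}


# ---------------------------------------------------------------------------
# demo fixture
# ---------------------------------------------------------------------------

def write_demo(outdir, seed: int = 0, length: int = 100_000,
               n_genes: int = 40, n_peaks: int = 30,
               conditions=("iron", "heme"), replicates: int = 3,
               noise: str = "poisson") -> PipelineConfig:
    """Generate a self-contained demo dataset plus its pipeline config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = _synthetic.generate_genome(length, 0.54, n_genes,
                                               seed=seed)
    truth = _synthetic.plant_peaks(genome, genes, n_peaks,
                                   height_range=(100.0, 300.0),
                                   conditions=list(conditions), seed=seed,
                                   motif_fraction=0.5)
    genome = _synthetic.plant_motif(genome, truth, "TAGGTTAGSCTAACCTAA",
                                    seed=seed)
    truth.genome = genome
    _synthetic.write_fasta(genome, outdir / "genome.fa")
    _synthetic.write_gff3(genes, genome.chrom_id, outdir / "genes.gff3")
    truth.save(outdir / "truth.json")
    rows = []
    for cond in conditions:
        for rep in range(1, replicates + 1):
            track = _synthetic.simulate_coverage(truth, cond, rep, noise,
                                                 seed=seed)
            path = outdir / f"{cond}_rep{rep}.bedgraph"
            _coverage.write_track(track, path)
            rows.append(SampleRow(sample=f"{cond}_rep{rep}",
                                  regulator="regA", condition=cond,
                                  replicate=rep, path=str(path)))
    expr = _synthetic.simulate_expression(truth, "anti_proportional",
                                          noise_sd=0.5, seed=seed)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    return PipelineConfig(genome=str(outdir / "genome.fa"),
                          annotation=str(outdir / "genes.gff3"),
                          samples=rows, outdir=str(outdir / "results"),
                          consensus="TAGGTTAGSCTAACCTAA",
                          expression=str(outdir / "expression.tsv"),
                          seed=seed)
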