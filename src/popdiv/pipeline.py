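"""End-to-end orchestration: simulate/load -> filter -> annotate ->
diversity -> LD -> report, with every stage's output written to disk
before the next begins and full determinism under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import EffectCall, IMPACT, annotate_matrix, syn_nonsyn_ratio, tstv_ratio
from .diversity import subpop_diversity, windowed_pi
from .io_formats import (
    DEFAULT_YEAR_BINS,
    read_fasta,
    read_gff3,
    read_sample_meta,
    read_vcf,
    write_fasta,
    write_gff3,
    write_sample_meta,
    write_vcf,
)
from .ld import half_decay_distance, ld_curve
from .model import GenotypeMatrix
from .site_filters import chrom_counts, core_filter, mutated_in_all, simple_filter, split_snps_indels
from .simulate import SimConfig, simulate_population_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_report", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``vcf`` (with optional gff3/fasta/meta) or
    ``simulate`` must be set.
    """

    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    meta: str | None = None
    simulate: SimConfig | None = None
    max_missing: float = 0.10
    max_het: float = 0.10
    min_maf: float = 0.02
    flank: int = 5_000
    window: int = 100_000
    step: int | None = 10_000
    ld_max_dist: int = 1_000_000
    ld_bin_width: int = 1_000
    min_subpop_ld_samples: int = 20
    year_bins: dict = field(default_factory=lambda: dict(DEFAULT_YEAR_BINS))
    outdir: str = "popdiv_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.vcf is None) == (self.simulate is None):
            raise ValueError("exactly one of 'vcf' and 'simulate' must be configured")
        for name in ("max_missing", "max_het", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=SimConfig(**sim) if isinstance(sim, dict) else sim, **raw)
        return cfg

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Every number here is recomputable from the emitted stage files."""

    config_hash: str
    seed: int
    version: str
    n_input_sites: int
    n_simple_snps: int
    n_indels: int
    n_core_snps: int
    core_chrom_counts: dict[str, int]
    tstv: float
    syn_nonsyn: float
    mutated_in_all_count: int
    region_percent: dict[str, float]
    effect_counts: dict[str, int]
    subpop_rows: list[dict]
    ld_half_decay: dict[str, float | None]


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------- stage: input
    stage = "input"
    try:
        if config.simulate is not None:
            ds = simulate_population_dataset(config.simulate)
            matrix, meta, genome, genes = ds.matrix, ds.meta, ds.genome, ds.genes
            write_vcf(matrix, outdir / "input.vcf")
            write_fasta(genome, outdir / "genome.fasta")
            write_gff3(genes, outdir / "genes.gff3")
            write_sample_meta(meta, outdir / "meta.tsv")
            truth = {
                "ld_length_scale": ds.truth["ld_length_scale"],
                "positions": {c: [int(p) for p in v] for c, v in ds.truth["positions"].items()},
                "seed": config.simulate.seed,
            }
            (outdir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
        else:
            matrix = read_vcf(config.vcf)
            genes = read_gff3(config.gff3) if config.gff3 else []
            genome = read_fasta(config.fasta) if config.fasta else {}
            meta = read_sample_meta(config.meta, config.year_bins) if config.meta else []
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --------------------------------------------------------- stage: filter
    stage = "filter"
    try:
        snps, indels = split_snps_indels(matrix)
        simple = simple_filter(matrix)
        core = core_filter(
            simple,
            max_missing=config.max_missing,
            max_het=config.max_het,
            min_maf=config.min_maf,
        )
        write_vcf(core, outdir / "filtered.vcf")
        counts = chrom_counts(core)
        mut_all = mutated_in_all(simple)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------- stage: annotate
    stage = "annotate"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tstv = tstv_ratio(simple.sites) if simple.n_sites else float("nan")
        if genes and genome:
            ann_input = GenotypeMatrix(
                simple.sites + indels.sites,
                simple.samples,
                np.concatenate([simple.calls, indels.calls])
                if indels.n_sites
                else simple.calls,
            )
            table = annotate_matrix(ann_input, genes, genome, flank=config.flank)
            table.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
            region_pct = (
                table["region"].value_counts().sort_index() / len(table) * 100.0
            ).to_dict() if len(table) else {}
            effects = table.loc[table["effect"] != "", "effect"]
            effect_counts = effects.value_counts().to_dict()
            snp_eff = table.loc[(table["variant_class"] == "SNP") & (table["effect"] != "")]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                syn_nonsyn = syn_nonsyn_ratio(
                    [EffectCall(t, (), IMPACT.get(t, "")) for t in snp_eff["effect"]]
                )
        else:
            region_pct, effect_counts, syn_nonsyn = {}, {}, float("nan")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------ stage: diversity
    stage = "diversity"
    try:
        chrom_lengths = {c: len(s) for c, s in genome.items()} or None
        windows = windowed_pi(
            core, window=config.window, step=config.step, chrom_lengths=chrom_lengths
        )
        pd.DataFrame(
            [
                {"chrom": w.chrom, "start": w.start, "end": w.end,
                 "n_sites": w.n_sites, "pi": w.pi}
                for w in windows
            ]
        ).to_csv(outdir / "windows.tsv", sep="\t", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub_table = (
                subpop_diversity(
                    core, meta, window=config.window, step=config.step,
                    chrom_lengths=chrom_lengths,
                )
                if meta
                else pd.DataFrame(
                    columns=["subpop", "years", "n_accessions", "pi", "pi_x1e3", "pic"]
                )
            )
        sub_table.to_csv(outdir / "subpop_diversity.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------- stage: ld
    stage = "ld"
    try:
        curve = ld_curve(core, max_dist=config.ld_max_dist, bin_width=config.ld_bin_width)
        curve.to_frame().to_csv(outdir / "ld_curve.tsv", sep="\t", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            half: dict[str, float | None] = {"ALL": half_decay_distance(curve)}
            for m in {x.subpop for x in meta if x.subpop}:
                members = [x.sample for x in meta if x.subpop == m]
                if len(members) < config.min_subpop_ld_samples:
                    warnings.warn(
                        f"sub-population {m}: {len(members)} samples < "
                        f"{config.min_subpop_ld_samples}; LD skipped"
                    )
                    continue
                sub_curve = ld_curve(
                    core.take_samples(members),
                    max_dist=config.ld_max_dist,
                    bin_width=config.ld_bin_width,
                )
                half[m] = half_decay_distance(sub_curve)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --------------------------------------------------------- stage: report
    stage = "report"
    try:
        report = RunReport(
            config_hash=config.digest(),
            seed=config.seed,
            version=__version__,
            n_input_sites=matrix.n_sites,
            n_simple_snps=simple.n_sites,
            n_indels=indels.n_sites,
            n_core_snps=core.n_sites,
            core_chrom_counts={k: int(v) for k, v in counts.items()},
            tstv=float(tstv),
            syn_nonsyn=float(syn_nonsyn),
            mutated_in_all_count=int(len(mut_all)),
            region_percent={k: float(v) for k, v in region_pct.items()},
            effect_counts={k: int(v) for k, v in effect_counts.items()},
            subpop_rows=sub_table.to_dict("records"),
            ld_half_decay={k: (None if v is None else float(v)) for k, v in sorted(half.items())},
        )
        tsv, txt = render_report(report)
        (outdir / "report.tsv").write_text(tsv)
        (outdir / "report.txt").write_text(txt)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report


def _flat_items(report: RunReport):
    yield "config_hash", report.config_hash
    yield "seed", report.seed
    yield "version", report.version
    yield "n_input_sites", report.n_input_sites
    yield "n_simple_snps", report.n_simple_snps
    yield "n_indels", report.n_indels
    yield "n_core_snps", report.n_core_snps
    for chrom, n in sorted(report.core_chrom_counts.items()):
        yield f"core_snps[{chrom}]", n
    yield "tstv", report.tstv
    yield "syn_nonsyn", report.syn_nonsyn
    yield "mutated_in_all_count", report.mutated_in_all_count
    for k, v in sorted(report.region_percent.items()):
        yield f"region_percent[{k}]", v
    for k, v in sorted(report.effect_counts.items()):
        yield f"effect_count[{k}]", v
    for row in report.subpop_rows:
        sub = row["subpop"]
        yield f"subpop[{sub}].years", row["years"]
        yield f"subpop[{sub}].n_accessions", row["n_accessions"]
        yield f"subpop[{sub}].pi", row["pi"]
        yield f"subpop[{sub}].pic", row["pic"]
    for k, v in report.ld_half_decay.items():
        yield f"ld_half_decay_bp[{k}]", "NA" if v is None else v


def render_report(report: RunReport) -> tuple[str, str]:
    """(report.tsv text, report.txt text).

    The TSV carries raw full-precision values (floats via ``repr`` so a
    re-parse reproduces them exactly); the text summary displays π in
    the conventional ×10⁻³ units.
    """
    lines = ["key\tvalue"]
    for k, v in _flat_items(report):
        lines.append(f"{k}\t{v!r}" if isinstance(v, float) else f"{k}\t{v}")
    tsv = "\n".join(lines) + "\n"

    txt = [
        "popdiv run report",
        "=================",
        f"config {report.config_hash}  seed {report.seed}  version {report.version}",
        "",
        f"input sites          {report.n_input_sites}",
        f"simply filtered SNPs {report.n_simple_snps}",
        f"InDels               {report.n_indels}",
        f"core SNPs            {report.n_core_snps}",
        f"ts/tv                {report.tstv:.3f}",
        f"syn/nonsyn           {report.syn_nonsyn:.3f}",
        f"mutated in all       {report.mutated_in_all_count}",
        "",
        "core SNPs per chromosome",
    ]
    for chrom, n in sorted(report.core_chrom_counts.items()):
        txt.append(f"  {chrom:<8} {n}")
    if report.region_percent:
        txt += ["", "region percentages"]
        for k, v in sorted(report.region_percent.items()):
            txt.append(f"  {k:<12} {v:6.2f}%")
    if report.effect_counts:
        txt += ["", "coding effect counts"]
        for k, v in sorted(report.effect_counts.items()):
            txt.append(f"  {k:<36} {v}")
    txt += ["", "sub-population diversity (pi displayed as x1e-3)"]
    txt.append("  Sub   Years       Accessions  Pi(x1e-3)  PIC")
    for row in report.subpop_rows:
        txt.append(
            f"  {row['subpop']:<5} {row['years']:<11} {row['n_accessions']:<11} "
            f"{row['pi'] * 1e3:<10.2f} {row['pic']:.3f}"
        )
    txt += ["", "LD half-decay distance (bp)"]
    for k, v in report.ld_half_decay.items():
        txt.append(f"  {k:<5} {'undefined' if v is None else f'{v:.0f}'}")
    return tsv, "\n".join(txt) + "\n"
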