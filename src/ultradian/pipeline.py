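"""End-to-end orchestration from a single YAML config.

Stages run in the study's order: (optional) preprocessing of raw counts,
Zeitgeber conversion, fixed-period regression at 12 h and 24 h with the
permutation null, the Lomb-Scargle scan, the pencil decomposition with band
summary, and — when two cohorts are configured — the delta R^2 loss/gain
analysis, RRHO and peak-time populations. Every table is written as TSV
with a provenance header (config hash, seed, package version); the report
recomputes its counts from the written tables only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import classify_gain_loss, delta_r2_table, phase_population_table, rrho
from .io import read_matrix, read_subjects, write_matrix, write_table
from .nlr import bootstrap_stability, fit_transcriptome
from .preprocess import (
    ExpressionMatrix,
    GeneAnnotation,
    batch_adjust,
    filter_genes,
    log2_transform,
    to_cpm,
)
from .spectral import (
    bin_to_even_grid,
    concordance_with_nlr,
    lomb_scargle_table,
    pencil_table,
    summarize_bands,
)
from .synthetic import StudyDesign, generate_two_cohort_study, single_cohort_preset
from .zeitgeber import add_zt_column

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "PRESETS"]

#: Named synthetic presets: (kind, generator kwargs, run parameter overrides).
PRESETS = {
    # small two-cohort study for fast end-to-end runs
    "smoke": ("two_cohort", dict(n_genes=300, n_a=46, n_b=46), dict(n_perm=200)),
    # single cohort at study scale (13,914 genes x 104 subjects)
    "study-scale": ("single", dict(), dict()),
    # single cohort, reduced gene universe
    "single-small": ("single", dict(n_genes=1000, n_subjects=104), dict()),
}


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    preset: Optional[str] = None
    matrix_path: Optional[str] = None
    subjects_path: Optional[str] = None
    counts_path: Optional[str] = None
    annotation_path: Optional[str] = None
    periods: tuple = (12.0, 24.0)
    n_perm: int = 1000
    n_boot: int = 0
    alpha_single: float = 0.01
    alpha_two: float = 0.05
    log2_offset: float = 1.0
    ls_lo: float = 8.0
    ls_hi: float = 28.0
    ls_oversample: float = 8.0
    kernel_sigma: float = 1.0
    kernel_halfwidth: float = 6.0
    pencil_components: int = 4
    pencil_sv_tol: float = 1e-3
    rrho_step: Optional[int] = None
    raw: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (every stochastic stage uses it)")
        if not (0 < self.alpha_single <= 0.5 and 0 < self.alpha_two <= 0.5):
            raise ValueError("alpha values must be in (0, 0.5]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not (0 < self.ls_lo < self.ls_hi):
            raise ValueError("invalid Lomb-Scargle scan bounds")
        if self.preset is None and self.matrix_path is None and self.counts_path is None:
            raise ValueError("configure a synthetic preset or an input matrix")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; options: {sorted(PRESETS)}")

    def config_hash(self) -> str:
        # identifies the analysis parameters; where the run lands is not part
        # of its identity
        payload = {k: v for k, v in self.__dict__.items() if k not in ("raw", "outdir")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "raw"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "periods" in kwargs:
        kwargs["periods"] = tuple(float(p) for p in kwargs["periods"])
    cfg = PipelineConfig(raw=raw, **kwargs)
    cfg.validate()
    return cfg


def _provenance(cfg: PipelineConfig, stage: str) -> list[str]:
    return [
        f"ultradian {__version__}",
        f"stage: {stage}",
        f"config: {cfg.config_hash()}",
        f"seed: {cfg.seed}",
    ]


def _load_cohorts(cfg: PipelineConfig):
    """Materialize (label -> (matrix, subjects)) plus optional truth table."""
    if cfg.preset is not None:
        kind, gen_kwargs, overrides = PRESETS[cfg.preset]
        for k, v in overrides.items():
            setattr(cfg, k, v)
        if kind == "two_cohort":
            design = StudyDesign(**gen_kwargs)
            ma, mb, sa, sb, truth = generate_two_cohort_study(design, seed=cfg.seed)
            return {"A": (ma, sa), "B": (mb, sb)}, truth
        matrix, subjects, truth = single_cohort_preset(seed=cfg.seed, **gen_kwargs)
        return {"A": (matrix, subjects)}, truth

    subjects = read_subjects(cfg.subjects_path)
    if "zt" not in subjects.columns:
        subjects = add_zt_column(subjects)
    if cfg.counts_path is not None:
        counts = read_matrix(cfg.counts_path, stage="counts")
        annotation = GeneAnnotation(pd.read_csv(cfg.annotation_path, sep="\t"))
        cpm = to_cpm(counts)
        keep = filter_genes(cpm, annotation)
        cpm = ExpressionMatrix(cpm.data.loc[keep], "cpm", cpm.provenance + ["filtered"])
        matrix = log2_transform(cpm, offset=cfg.log2_offset)
    else:
        matrix = read_matrix(cfg.matrix_path, stage="log2")
    matrix = ExpressionMatrix(
        matrix.data[subjects["subject_id"].tolist()], matrix.stage, matrix.provenance
    )
    if subjects["site"].nunique() > 1:
        matrix = batch_adjust(matrix, subjects["site"].tolist())
    cohorts = {}
    for label, grp in subjects.groupby("cohort", sort=True):
        sub = ExpressionMatrix(matrix.data[grp["subject_id"].tolist()], matrix.stage)
        cohorts[str(label)] = (sub, grp.reset_index(drop=True))
    return cohorts, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the report counts dictionary."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    with open(os.path.join(cfg.outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(
            {k: v for k, v in cfg.__dict__.items() if k != "raw"},
            fh,
            default_flow_style=False,
        )

    cohorts, truth = _load_cohorts(cfg)
    if truth is not None:
        write_table(
            truth.to_frame(),
            os.path.join(cfg.outdir, "truth.tsv"),
            _provenance(cfg, "synthetic"),
        )

    rng = np.random.default_rng(cfg.seed)
    report: dict = {"cohorts": {}, "config_hash": cfg.config_hash()}
    fits: dict = {}
    for label, (matrix, subjects) in cohorts.items():
        t0 = time.perf_counter()
        write_table(
            subjects, os.path.join(cfg.outdir, f"subjects_{label}.tsv"), _provenance(cfg, "subjects")
        )
        write_matrix(
            matrix, os.path.join(cfg.outdir, f"expression_{label}.tsv"), _provenance(cfg, "expression")
        )
        zt = subjects["zt"].to_numpy(dtype=float)
        entry: dict = {"n_subjects": int(len(subjects)), "n_genes": int(matrix.data.shape[0])}

        for period in cfg.periods:
            seed = int(rng.integers(2**31))
            tab = fit_transcriptome(matrix, zt, period, n_perm=cfg.n_perm, seed=seed)
            write_table(
                tab,
                os.path.join(cfg.outdir, f"nlr_{int(period)}h_{label}.tsv"),
                _provenance(cfg, f"nlr-{int(period)}h"),
            )
            fits[(label, period)] = tab
            alpha = cfg.alpha_single if len(cohorts) == 1 else cfg.alpha_two
            entry[f"significant_{int(period)}h"] = int((tab["p"] < alpha).sum())

        ls = lomb_scargle_table(matrix, zt, (cfg.ls_lo, cfg.ls_hi), cfg.ls_oversample)
        write_table(ls, os.path.join(cfg.outdir, f"lombscargle_{label}.tsv"), _provenance(cfg, "ls"))

        binned, _hours = bin_to_even_grid(matrix, zt, cfg.kernel_sigma, cfg.kernel_halfwidth)
        pencil = pencil_table(
            binned, matrix.data.index, cfg.pencil_components, cfg.pencil_sv_tol
        )
        write_table(pencil, os.path.join(cfg.outdir, f"pencil_{label}.tsv"), _provenance(cfg, "pencil"))
        bands = summarize_bands(pencil)
        write_table(bands, os.path.join(cfg.outdir, f"bands_{label}.tsv"), _provenance(cfg, "bands"))
        entry["rc_12h"] = int(bands["has12"].sum())
        entry["rc_24h"] = int(bands["has24"].sum())
        entry["rc_both"] = int(bands["both"].sum())

        alpha = cfg.alpha_single if len(cohorts) == 1 else cfg.alpha_two
        conc = concordance_with_nlr(fits[(label, 12.0)], ls, bands, alpha=alpha)
        entry["concordance"] = conc

        phases = phase_population_table(fits[(label, 12.0)], alpha=alpha)
        write_table(phases, os.path.join(cfg.outdir, f"phases_{label}.tsv"), _provenance(cfg, "phases"))
        entry["me"] = int((phases["population"] == "ME").sum())
        entry["an"] = int((phases["population"] == "AN").sum())

        if cfg.n_boot >= 10:
            stab = bootstrap_stability(
                matrix, zt, 12.0, n_boot=cfg.n_boot, alpha=alpha,
                n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
            )
            write_table(
                stab, os.path.join(cfg.outdir, f"stability_{label}.tsv"), _provenance(cfg, "bootstrap")
            )

        logger.info("cohort %s done in %.1f s", label, time.perf_counter() - t0)
        report["cohorts"][label] = entry

    if len(cohorts) == 2:
        (la, (ma, sa)), (lb, (mb, sb)) = sorted(cohorts.items())
        deltas = delta_r2_table(
            ma, sa["zt"].to_numpy(float), mb, sb["zt"].to_numpy(float),
            period=12.0, n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
        )
        write_table(deltas, os.path.join(cfg.outdir, "delta_r2.tsv"), _provenance(cfg, "delta-r2"))
        classes, counts = classify_gain_loss(
            fits[(la, 12.0)], fits[(lb, 12.0)], deltas, alpha=cfg.alpha_two
        )
        write_table(classes, os.path.join(cfg.outdir, "gain_loss.tsv"), _provenance(cfg, "gain-loss"))
        report["differential"] = counts

        pa = fits[(la, 12.0)].set_index("gene_id")["p"]
        pb = fits[(lb, 12.0)].set_index("gene_id")["p"]
        grid = rrho(pa, pb, step=cfg.rrho_step)
        grid.index.name = "rank_a"
        write_table(
            grid.reset_index(), os.path.join(cfg.outdir, "rrho.tsv"), _provenance(cfg, "rrho")
        )
        report["rrho_max"] = float(grid.to_numpy().max())

    _write_report(cfg, report)
    return report


def _write_report(cfg: PipelineConfig, report: dict) -> None:
    lines = ["# Rhythm analysis report", "", f"Config hash: `{report['config_hash']}`", ""]
    for label, entry in report["cohorts"].items():
        lines.append(f"## Cohort {label}")
        lines.append("")
        lines.append(f"- {entry['n_genes']} genes x {entry['n_subjects']} subjects")
        for period in cfg.periods:
            key = f"significant_{int(period)}h"
            lines.append(f"- significant {int(period)} h rhythms: {entry[key]}")
        lines.append(
            f"- rhythmic components: {entry['rc_12h']} with 12 h, {entry['rc_24h']} with 24 h, "
            f"{entry['rc_both']} with both"
        )
        c = entry["concordance"]
        if c["n_significant"]:
            lines.append(
                f"- of {c['n_significant']} 12 h-significant genes, "
                f"{100 * c['frac_ls_12h']:.1f}% have a 12 h Lomb-Scargle period and "
                f"{100 * c['frac_pencil_12h']:.1f}% a 12 h RC"
            )
        lines.append(f"- peak-time populations: {entry['me']} ME, {entry['an']} AN")
        lines.append("")
    if "differential" in report:
        d = report["differential"]
        lines.append("## Two-cohort comparison (12 h)")
        lines.append("")
        lines.append(f"- rhythmic in A: {d['rhythmic_a']}; in B: {d['rhythmic_b']}")
        lines.append(f"- rhythmic in both: {d['rhythmic_both']}")
        lines.append(f"- lost in B: {d['lost']}; gained in B: {d['gained']}")
        lines.append(f"- RRHO peak -log10(p): {report['rrho_max']:.2f}")
        lines.append("")
    with open(os.path.join(cfg.outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines))
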