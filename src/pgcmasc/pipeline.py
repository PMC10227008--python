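"""End-to-end pipeline driver: simulate -> normalize -> DEG -> enrichment
-> repeat methylome, from one structured YAML configuration.

A single global seed deterministically spawns per-stage child seeds
(recorded in the run manifest) so that any stage can be re-run in
isolation and reproduce its outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CountMatrix, read_counts, write_counts, write_meth_coverage, write_repeat_annotation, write_gene_set
from .simulate import SimConfig, MethSimConfig, FamilySpec, gen_pgc_counts, gen_repeat_meth
from .tmm import tmm_factors
from .model import MasculinizationModel
from .repeats import assign_cpgs, coverage_ranking, methylation_ranking, locus_distributions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "normalize", "deg", "enrich", "repeats")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``contrasts`` is either the string ``"auto"`` (every adequately
    replicated dose-vs-vehicle cell) or a list of dicts with keys
    ``generation`` (optional), ``sex`` and ``dose``.
    """

    outdir: str = "pgcmasc_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)
    meth_sim: dict = field(default_factory=dict)
    counts_path: str | None = None
    metadata_path: str | None = None
    contrasts: object = "auto"
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    count_threshold: float = 100
    k_max: int = 200
    n_iter: int = 5000
    null_sizes: tuple = (50, 100, 200)
    alpha: float = 0.05
    top_n: int = 35
    min_cpg: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in __import__("dataclasses").fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
        for name in ("fdr_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("k_max", "n_iter", "top_n", "min_cpg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.contrasts != "auto":
            if not isinstance(self.contrasts, list) or not self.contrasts:
                raise ValueError("contrasts must be 'auto' or a non-empty list")
            for c in self.contrasts:
                if "sex" not in c or "dose" not in c:
                    raise ValueError(f"contrast missing sex/dose: {c}")
        if "simulate" not in self.stages and (self.counts_path is None or self.metadata_path is None):
            if any(s in self.stages for s in ("normalize", "deg", "enrich")):
                raise ValueError("without the simulate stage, counts_path and metadata_path are required")


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def run_pipeline(config: PipelineConfig, stages: list | None = None) -> dict:
    """Execute the configured stages, writing artifacts under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).  On a
    stage failure, partial outputs are kept, a ``FAILED`` marker naming the
    stage is written, and :class:`PipelineError` is raised.
    """
    config.validate()
    stages = list(stages if stages is not None else config.stages)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": stages,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "outputs": {},
    }
    report = {"contrasts": {}}
    current = "setup"
    try:
        cm = None
        if "simulate" in stages:
            current = "simulate"
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", seeds["simulate"])
            sim_cfg = SimConfig(**sim_kwargs)
            cm, truth = gen_pgc_counts(sim_cfg)
            write_counts(cm, out / "counts.tsv", out / "metadata.tsv", seed=sim_cfg.seed)
            write_gene_set(truth.male_specific_genes, out / "truth_male_specific.txt")
            write_gene_set(truth.female_specific_genes, out / "truth_female_specific.txt")
            write_gene_set(truth.masc_affected_genes, out / "truth_masc_affected.txt")
            _write_tsv(truth.log2fc, out / "truth_log2fc.tsv", index_label="gene_id")
            manifest["outputs"]["counts"] = "counts.tsv"

        if cm is None and any(s in stages for s in ("normalize", "deg", "enrich")):
            current = "load"
            cm = read_counts(config.counts_path, config.metadata_path)

        if "normalize" in stages:
            current = "normalize"
            norm = tmm_factors(cm)
            _write_tsv(norm.to_frame(), out / "tmm_factors.tsv")
            manifest["outputs"]["tmm_factors"] = "tmm_factors.tsv"

        if "deg" in stages or "enrich" in stages:
            current = "deg"
            model = MasculinizationModel(
                cm,
                fdr_threshold=config.fdr_threshold,
                lfc_threshold=config.lfc_threshold,
                count_threshold=config.count_threshold,
                k_max=config.k_max,
                null_sizes=config.null_sizes,
                n_iter=config.n_iter,
                alpha=config.alpha,
            )
            contrasts = None if config.contrasts == "auto" else config.contrasts
            current = "enrich" if "enrich" in stages else "deg"
            res = model.fit(contrasts=contrasts, seed=seeds["enrich"])

            _write_tsv(res.sex_sets.table, out / "sex_deg_table.tsv", index_label="gene_id")
            write_gene_set(res.sex_sets.male_specific, out / "male_specific.txt")
            write_gene_set(res.sex_sets.female_specific, out / "female_specific.txt")
            for name, rl in res.ranked.items():
                safe = name.replace(":", "_").replace("/", "_")
                _write_tsv(rl.table, out / f"ranked_{safe}.tsv", index_label="gene_id")
            manifest["outputs"]["sex_deg_table"] = "sex_deg_table.tsv"

            if "enrich" in stages:
                write_gene_set(res.universe.genes, out / "universe.txt")
                null_rows = []
                for sex_label, nulls in res.nulls.items():
                    for s, null in sorted(nulls.items()):
                        null_rows.append(
                            {
                                "set": sex_label,
                                "s": s,
                                "n_iter": null.n_iter,
                                "n_universe": null.n_universe,
                                "n_set": null.n_set,
                                "mean": null.draws.mean(),
                                "alpha_shape": null.alpha,
                                "beta_rate": null.beta,
                                "degenerate": null.degenerate,
                                "p_frac_gt_0.10": null.tail_empirical(0.10),
                            }
                        )
                _write_tsv(pd.DataFrame(null_rows), out / "nulls.tsv", index_label="row")
                for name, call in res.calls.items():
                    safe = name.replace(":", "_").replace("/", "_")
                    _write_tsv(call.table, out / f"enrichment_{safe}.tsv", index_label="k")
                    report["contrasts"][name] = call.summary
                manifest["outputs"]["nulls"] = "nulls.tsv"
                report["sex_deg_counts"] = {
                    "male": len(res.sex_sets.male_specific),
                    "female": len(res.sex_sets.female_specific),
                }
                report["universe_size"] = len(res.universe)
                (out / "summary.txt").write_text(res.summary() + "\n")

        if "repeats" in stages:
            current = "repeats"
            meth_kwargs = dict(config.meth_sim)
            meth_kwargs.setdefault("seed", seeds["repeats"])
            fams = meth_kwargs.pop("families", None)
            if fams is not None:
                meth_kwargs["families"] = [FamilySpec(**f) for f in fams]
            meth_cfg = MethSimConfig(**meth_kwargs)
            calls, ann, truth = gen_repeat_meth(meth_cfg)
            write_meth_coverage(calls, out / "meth_coverage.tsv", seed=meth_cfg.seed)
            write_repeat_annotation(ann, out / "repeat_annotation.tsv", seed=meth_cfg.seed)
            assigned = assign_cpgs(calls, ann)
            _write_tsv(coverage_ranking(assigned, config.top_n), out / "coverage_ranking.tsv", index_label="row")
            _write_tsv(
                methylation_ranking(assigned, config.top_n, config.min_cpg, "most"),
                out / "methylation_ranking_most.tsv",
                index_label="row",
            )
            _write_tsv(
                methylation_ranking(assigned, config.top_n, config.min_cpg, "least"),
                out / "methylation_ranking_least.tsv",
                index_label="row",
            )
            _write_tsv(truth.family, out / "meth_truth_family.tsv", index_label="row")
            manifest["outputs"]["coverage_ranking"] = "coverage_ranking.tsv"

    except Exception as exc:  # keep partial outputs, mark the failed stage
        (out / "FAILED").write_text(f"{current}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current, str(exc)) from exc

    manifest["report"] = report
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return manifest
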