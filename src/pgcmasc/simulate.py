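"""Synthetic data generators with ground-truth labels.

Two generators emulate the statistical structure the analysis assumes:

* :func:`gen_pgc_counts` — a bulk RNA-seq count matrix over a full
  (generation x sex x dose) design with negative-binomial noise,
  sex-dimorphic genes, and an optional "masculinization" effect that
  up-shifts a subset of male-specific genes in exposed female samples.
* :func:`gen_repeat_meth` — per-CpG methylation calls over synthetic repeat
  loci with high-methylation IAP-like, intermediate LINE1-like and
  low-methylation SINE-like families, plus exposure-induced
  hypermethylation of a locus subset.

Both are fully seeded: identical config + seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, DOSE_LEVELS, GENERATIONS

__all__ = [
    "SimConfig",
    "SimTruth",
    "FamilySpec",
    "MethSimConfig",
    "MethSimTruth",
    "gen_pgc_counts",
    "gen_repeat_meth",
]


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Configuration of the PGC count simulator.

    Defaults mirror the study design: 15,423 genes of which roughly 3,100
    exceed the 100-count expression threshold, doses 0/0.033/0.2/2
    mg/kg-day across generations F1-F3, and a two-fold-plus sex effect.
    """

    n_genes: int = 15423
    n_samples_per_cell: int = 3
    n_male_specific: int = 150
    n_female_specific: int = 150
    sex_log2fc: float = 1.5
    masc_effect: float = 0.0
    masc_fraction: float = 0.5
    libsize_mu: float = 0.0
    libsize_sigma: float = 0.2
    dispersion_shape: float = 2.0
    dispersion_rate: float = 10.0
    baseline_sigma: float = 2.0  # sd of log baseline means (natural log)
    universe_target: int = 3100
    count_threshold: int = 100
    generations: tuple = GENERATIONS
    doses: tuple = (0.0, 0.033, 0.2, 2.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_samples_per_cell", "universe_target"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_male_specific < 0 or self.n_female_specific < 0:
            raise ConfigError("effect-set sizes must be non-negative")
        if self.n_male_specific + self.n_female_specific > self.n_genes:
            raise ConfigError("sex-specific sets exceed the number of genes")
        if self.n_male_specific + self.n_female_specific > self.universe_target:
            raise ConfigError("sex-specific sets exceed the expressed pool")
        if not 0.0 <= self.masc_fraction <= 1.0:
            raise ConfigError("masc_fraction must lie in [0, 1]")
        if self.universe_target > self.n_genes:
            raise ConfigError("universe_target exceeds n_genes")
        if self.dispersion_shape <= 0 or self.dispersion_rate <= 0:
            raise ConfigError("dispersion prior parameters must be positive")


@dataclass
class SimTruth:
    """Ground-truth labels attached to a simulated count matrix."""

    male_specific_genes: set
    female_specific_genes: set
    masc_affected_genes: set
    log2fc: pd.DataFrame  # per-gene true log2FC per contrast
    dispersions: pd.Series  # per-gene NB dispersion
    baseline_means: pd.Series


def _baseline_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    # Log-normal baseline means calibrated by closed-form quantile matching:
    # the (1 - universe_target/n_genes) quantile of the mean distribution is
    # pinned to 0.36x the count threshold: the universe rule looks at the
    # MAX count over all samples, which at typical dispersion, library
    # spread and ~70 samples overshoots the mean by roughly 2.8-fold, so a
    # gene whose mean is ~0.36x the threshold already tends to pass.
    p = cfg.universe_target / cfg.n_genes
    z = stats.norm.ppf(1.0 - p)
    eff_threshold = 0.36 * cfg.count_threshold
    meanlog = np.log(eff_threshold) - cfg.baseline_sigma * z
    return rng.lognormal(meanlog, cfg.baseline_sigma, size=cfg.n_genes)


def gen_pgc_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate a PGC count matrix with known sex-dimorphic structure.

    Returns the count matrix (with generation/sex/dose metadata) and the
    truth labels.  Male-specific genes are shifted up by ``sex_log2fc/2`` in
    males and down by the same amount in females (and symmetrically for
    female-specific genes), so the configured between-sex difference equals
    ``sex_log2fc`` log2 units.  When ``masc_effect > 0``, a
    ``masc_fraction`` subset of male-specific genes is additionally shifted
    up by ``masc_effect`` log2 units in exposed (dose > 0) female samples.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    base = _baseline_means(cfg, rng)
    phi = rng.gamma(cfg.dispersion_shape, 1.0 / cfg.dispersion_rate, size=cfg.n_genes)

    # sex-specific genes live in the high-expression pool so they are part
    # of the expressed universe the enrichment analysis operates on
    pool = np.argsort(base)[::-1][: cfg.universe_target]
    n_fx = cfg.n_male_specific + cfg.n_female_specific
    chosen = rng.choice(pool, size=n_fx, replace=False)
    male_idx = chosen[: cfg.n_male_specific]
    female_idx = chosen[cfg.n_male_specific :]
    n_masc = int(round(cfg.masc_fraction * cfg.n_male_specific))
    masc_idx = rng.choice(male_idx, size=n_masc, replace=False) if n_masc else np.array([], dtype=int)

    # design: samples per (generation, sex, dose) cell
    sample_ids, gen_l, sex_l, dose_l = [], [], [], []
    dose_str = {v: k for k, v in DOSE_LEVELS.items()}
    for gen in cfg.generations:
        for sex in ("M", "F"):
            for dose in cfg.doses:
                for r in range(cfg.n_samples_per_cell):
                    sample_ids.append(f"{gen}_{sex}_{dose_str.get(dose, dose)}_{r + 1}")
                    gen_l.append(gen)
                    sex_l.append(sex)
                    dose_l.append(dose)
    n_samples = len(sample_ids)
    sex_arr = np.array(sex_l)
    dose_arr = np.array(dose_l)

    lib_factor = rng.lognormal(cfg.libsize_mu, cfg.libsize_sigma, size=n_samples)

    # per-gene per-sample log2 effects (sparse by construction)
    log2_eff = np.zeros((cfg.n_genes, n_samples))
    is_male_s = sex_arr == "M"
    half = cfg.sex_log2fc / 2.0
    log2_eff[np.ix_(male_idx, np.where(is_male_s)[0])] += half
    log2_eff[np.ix_(male_idx, np.where(~is_male_s)[0])] -= half
    log2_eff[np.ix_(female_idx, np.where(~is_male_s)[0])] += half
    log2_eff[np.ix_(female_idx, np.where(is_male_s)[0])] -= half
    exposed_female = (~is_male_s) & (dose_arr > 0)
    if cfg.masc_effect and n_masc:
        log2_eff[np.ix_(masc_idx, np.where(exposed_female)[0])] += cfg.masc_effect

    mu = base[:, None] * lib_factor[None, :] * np.exp2(log2_eff)
    # NB(mean mu, dispersion phi): numpy parameterization n=1/phi, p=1/(1+phi*mu)
    n_param = (1.0 / phi)[:, None]
    p_param = 1.0 / (1.0 + phi[:, None] * mu)
    counts = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"generation": gen_l, "sex": sex_l, "dose": dose_l}, index=pd.Index(sample_ids, name="sample_id")
    )
    cm = CountMatrix(counts_df, meta)

    lfc = pd.DataFrame(0.0, index=gene_ids, columns=["male_vs_female", "exposed_female_vs_vehicle_female"])
    lfc.iloc[male_idx, 0] = cfg.sex_log2fc
    lfc.iloc[female_idx, 0] = -cfg.sex_log2fc
    if cfg.masc_effect and n_masc:
        lfc.iloc[masc_idx, 1] = cfg.masc_effect

    truth = SimTruth(
        male_specific_genes=set(gene_ids[male_idx]),
        female_specific_genes=set(gene_ids[female_idx]),
        masc_affected_genes=set(gene_ids[masc_idx]),
        log2fc=lfc,
        dispersions=pd.Series(phi, index=gene_ids),
        baseline_means=pd.Series(base, index=gene_ids),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Repeat-methylome simulator
# ---------------------------------------------------------------------------


@dataclass
class FamilySpec:
    """One synthetic repeat family."""

    name: str
    rep_class: str  # e.g. "IAP", "LINE-1", "B1-B4"
    n_loci: int
    locus_length: int = 400
    baseline_meth: float = 0.5
    exposure_shift: float = 0.0
    shift_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_loci < 0 or self.locus_length <= 0:
            raise ConfigError(f"family {self.name}: invalid locus geometry")
        if not 0.0 <= self.baseline_meth <= 1.0:
            raise ConfigError(f"family {self.name}: baseline_meth outside [0,1]")
        if not 0.0 <= self.shift_fraction <= 1.0:
            raise ConfigError(f"family {self.name}: shift_fraction outside [0,1]")


def default_families() -> list:
    """Family panel mirroring the murine repeat landscape in germ cells:
    strongly methylated IAP-like elements resisting global demethylation,
    moderately methylated LINE1-like elements, and near-unmethylated
    SINE-like (B-family) elements."""
    return [
        FamilySpec("IAPEz-sim", "IAP", n_loci=200, locus_length=600, baseline_meth=0.80),
        FamilySpec("L1Md-sim", "LINE-1", n_loci=300, locus_length=800, baseline_meth=0.25),
        FamilySpec("B3-sim", "B1-B4", n_loci=400, locus_length=200, baseline_meth=0.05),
        FamilySpec("B1-sim", "B1-B4", n_loci=400, locus_length=150, baseline_meth=0.05),
    ]


@dataclass
class MethSimConfig:
    """Configuration of the repeat-methylome simulator."""

    families: list = field(default_factory=default_families)
    exposed: bool = False
    depth_mean: float = 20.0
    cpg_spacing: int = 20
    locus_gap: int = 100
    locus_noise_sd: float = 0.02
    genome_length: int = 2_000_000
    chrom: str = "chrSim"
    seed: int = 0

    def validate(self) -> None:
        for fam in self.families:
            fam.validate()
        if self.depth_mean <= 0 or self.cpg_spacing <= 0 or self.locus_gap < 0:
            raise ConfigError("invalid depth/spacing/gap")
        total = sum(f.n_loci * (f.locus_length + self.locus_gap) for f in self.families)
        if total > self.genome_length:
            raise ConfigError(
                f"family loci span {total} bp, exceeding genome length {self.genome_length}"
            )


@dataclass
class MethSimTruth:
    """True per-family and per-locus methylation levels."""

    family: pd.DataFrame  # family, rep_class, n_loci, true_mean_meth
    locus: pd.DataFrame  # locus_id, family, true_meth, shifted


def gen_repeat_meth(cfg: MethSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, MethSimTruth]:
    """Simulate per-CpG methylation calls over synthetic repeat loci.

    Loci are laid out sequentially and non-overlapping along one synthetic
    chromosome.  Each locus carries a true methylation fraction (family
    baseline plus, when ``exposed``, a hypermethylation shift on a random
    ``shift_fraction`` of loci, plus small locus-level noise); each CpG
    reports Binomial(depth, locus methylation) methylated reads with
    Poisson-distributed depth.  Zero-depth CpGs are not reported, matching
    real coverage files.

    Returns ``(calls, annotations, truth)`` where calls/annotations follow
    the :mod:`pgcmasc.io` conventions (0-based half-open).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ann_rows, call_rows, locus_rows, fam_rows = [], [], [], []
    cursor = 0
    for fam in cfg.families:
        if fam.n_loci == 0:
            continue
        shifted = np.zeros(fam.n_loci, dtype=bool)
        if cfg.exposed and fam.exposure_shift and fam.shift_fraction:
            n_shift = int(round(fam.shift_fraction * fam.n_loci))
            shifted[rng.choice(fam.n_loci, size=n_shift, replace=False)] = True
        true_meth = np.clip(
            fam.baseline_meth
            + fam.exposure_shift * shifted
            + rng.normal(0.0, cfg.locus_noise_sd, size=fam.n_loci),
            0.0,
            1.0,
        )
        n_cpg = max(1, fam.locus_length // cfg.cpg_spacing)
        for li in range(fam.n_loci):
            start = cursor
            end = start + fam.locus_length
            cursor = end + cfg.locus_gap
            locus_id = f"{fam.name}:{li}"
            ann_rows.append((cfg.chrom, start, end, fam.name, fam.rep_class, "+"))
            locus_rows.append((locus_id, fam.name, true_meth[li], bool(shifted[li])))
            pos = start + np.arange(n_cpg) * cfg.cpg_spacing
            depth = rng.poisson(cfg.depth_mean, size=n_cpg)
            keep = depth > 0
            meth = rng.binomial(depth[keep], true_meth[li])
            for p, d, m in zip(pos[keep], depth[keep], meth):
                call_rows.append((cfg.chrom, int(p), int(m), int(d - m)))
        fam_rows.append((fam.name, fam.rep_class, fam.n_loci, float(true_meth.mean())))

    calls = pd.DataFrame(call_rows, columns=["chrom", "pos", "meth", "unmeth"])
    ann = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "family", "rep_class", "strand"]
    )
    truth = MethSimTruth(
        family=pd.DataFrame(
            fam_rows, columns=["family", "rep_class", "n_loci", "true_mean_meth"]
        ),
        locus=pd.DataFrame(locus_rows, columns=["locus_id", "family", "true_meth", "shifted"]),
    )
    return calls, ann, truth
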