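"""Model/Results front end for the masculinization-enrichment analysis.

:class:`MasculinizationModel` wraps a count matrix plus metadata and, on
``fit()``, runs the full transcriptomic chain: TMM normalization,
sex-specific DEG calling on vehicle samples, p-value-ranked exposure
contrasts, the expressed-gene universe, permutation/gamma nulls and per-k
enrichment calls.  :class:`MasculinizationResults` carries the fitted
pieces, renders a text ``summary()`` and plots the enrichment curves.

Example
-------
>>> from pgcmasc import SimConfig, gen_pgc_counts
>>> from pgcmasc.model import MasculinizationModel
>>> cm, truth = gen_pgc_counts(SimConfig(n_genes=4000, universe_target=1500,
...                                      masc_effect=1.5, seed=7))
>>> res = MasculinizationModel(cm).fit(seed=7)
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, read_counts
from .diffexpr import SexDEGSets, RankedDEGList, call_sex_specific, rank_exposure_degs
from .enrichment import (
    EnrichmentCalls,
    EnrichmentCurve,
    EnrichmentNull,
    ExpressedUniverse,
    call_enrichment,
    enrichment_curve,
    expressed_universe,
    permutation_null,
)

__all__ = ["MasculinizationModel", "MasculinizationResults"]


class MasculinizationModel:
    """Transcriptomic sex-identity disturbance model for PGC count data.

    Parameters
    ----------
    data
        A validated :class:`~pgcmasc.io.CountMatrix`.
    fdr_threshold, lfc_threshold
        Sex-specific DEG criteria (defaults: FDR < 0.05, > two-fold).
    count_threshold
        Expressed-universe rule: max raw count must exceed this value.
    k_max
        Longest top-k prefix of each ranked exposure list examined.
    null_sizes, n_iter
        Permutation-null sampling sizes and iteration count.
    """

    def __init__(
        self,
        data: CountMatrix,
        fdr_threshold: float = 0.05,
        lfc_threshold: float = 1.0,
        count_threshold: float = 100,
        k_max: int = 200,
        null_sizes: tuple = (50, 100, 200),
        n_iter: int = 5000,
        alpha: float = 0.05,
    ) -> None:
        self.data = data
        self.fdr_threshold = fdr_threshold
        self.lfc_threshold = lfc_threshold
        self.count_threshold = count_threshold
        self.k_max = k_max
        self.null_sizes = tuple(null_sizes)
        self.n_iter = n_iter
        self.alpha = alpha

    @classmethod
    def from_tsv(cls, counts_path, metadata_path, **kwargs) -> "MasculinizationModel":
        return cls(read_counts(counts_path, metadata_path), **kwargs)

    def default_contrasts(self) -> list[dict]:
        """Every (generation, sex, dose) cell with >=2 exposed and >=2
        vehicle samples, dose vs vehicle within generation and sex."""
        meta = self.data.metadata
        out = []
        for gen in sorted(set(meta["generation"])):
            for sex in ("F", "M"):
                veh = ((meta["generation"] == gen) & (meta["sex"] == sex) & (meta["dose"] == 0)).sum()
                if veh < 2:
                    continue
                for dose in sorted(set(meta["dose"]) - {0.0}):
                    n = (
                        (meta["generation"] == gen)
                        & (meta["sex"] == sex)
                        & (meta["dose"] == dose)
                    ).sum()
                    if n >= 2:
                        out.append({"generation": gen, "sex": sex, "dose": dose})
        return out

    def fit(self, contrasts: list[dict] | None = None, seed: int | None = 0) -> "MasculinizationResults":
        """Run the full analysis and return a results object.

        ``contrasts`` is a list of dicts with keys ``generation`` (may be
        None to pool), ``sex`` and ``dose`` (scalar or list to pool);
        defaults to every adequately replicated dose-vs-vehicle cell.
        """
        sex_sets = call_sex_specific(self.data, self.fdr_threshold, self.lfc_threshold)
        universe = expressed_universe(self.data, self.count_threshold)
        rng = np.random.default_rng(seed)

        nulls_male = {
            s: permutation_null(universe, sex_sets.male_specific, s, self.n_iter, rng=rng)
            for s in self.null_sizes
        }
        nulls_female = {
            s: permutation_null(universe, sex_sets.female_specific, s, self.n_iter, rng=rng)
            for s in self.null_sizes
        }

        if contrasts is None:
            contrasts = self.default_contrasts()
        ranked, curves, calls = {}, {}, {}
        for spec in contrasts:
            rl = rank_exposure_degs(
                self.data,
                sex=spec["sex"],
                dose=spec["dose"],
                generation=spec.get("generation"),
            )
            curve = enrichment_curve(rl, sex_sets, universe, self.k_max)
            # male and female fractions are judged against their own nulls
            call_m = call_enrichment(curve, nulls_male, self.alpha)
            call_f = call_enrichment(curve, nulls_female, self.alpha)
            merged = call_m.table.copy()
            merged["flag_female"] = call_f.table["flag_female"]
            merged["null_q_gamma_female"] = call_f.table["null_q_gamma"]
            summary = dict(call_m.summary)
            summary["female_sustained"] = call_f.summary["female_sustained"]
            summary["female_flag_rate"] = call_f.summary["female_flag_rate"]
            ec = EnrichmentCalls(
                contrast=curve.contrast, alpha=self.alpha, table=merged, summary=summary
            )
            ranked[rl.contrast] = rl
            curves[rl.contrast] = curve
            calls[rl.contrast] = ec

        return MasculinizationResults(
            model=self,
            sex_sets=sex_sets,
            universe=universe,
            nulls={"male": nulls_male, "female": nulls_female},
            ranked=ranked,
            curves=curves,
            calls=calls,
            seed=seed,
        )


@dataclass
class MasculinizationResults:
    """Fitted artifacts of :class:`MasculinizationModel`."""

    model: MasculinizationModel
    sex_sets: SexDEGSets
    universe: ExpressedUniverse
    nulls: dict
    ranked: dict
    curves: dict
    calls: dict
    seed: int | None = None

    def summary(self) -> str:
        """Readable overview: set sizes, null calibration, per-contrast calls."""
        lines = []
        lines.append("Masculinization enrichment analysis")
        lines.append("=" * 62)
        lines.append(f"samples: {len(self.model.data.sample_ids)}  genes: {len(self.model.data.gene_ids)}")
        lines.append(
            f"sex-specific DEGs (FDR<{self.model.fdr_threshold}, |log2FC|>{self.model.lfc_threshold}): "
            f"male {len(self.sex_sets.male_specific)}, female {len(self.sex_sets.female_specific)}"
        )
        lines.append(
            f"expressed universe (max count > {self.model.count_threshold:g}): {len(self.universe)} genes"
        )
        for sex_label in ("male", "female"):
            for s, null in sorted(self.nulls[sex_label].items()):
                if null.degenerate:
                    lines.append(f"null[{sex_label}, s={s}]: degenerate")
                else:
                    lines.append(
                        f"null[{sex_label}, s={s}]: mean={null.draws.mean():.4f} "
                        f"gamma(shape={null.alpha:.2f}, rate={null.beta:.1f}) "
                        f"P(frac>0.10)={null.tail_empirical(0.10):.4f}"
                    )
        lines.append("-" * 62)
        lines.append(f"{'contrast':<28}{'male enr.':>12}{'female enr.':>14}")
        for name, call in self.calls.items():
            m = "sustained" if call.summary["male_sustained"] else f"{call.summary['male_flag_rate']:.2f}"
            f = (
                "sustained"
                if call.summary["female_sustained"]
                else f"{call.summary['female_flag_rate']:.2f}"
            )
            lines.append(f"{name:<28}{m:>12}{f:>14}")
        lines.append("(sustained = flagged at every k in the sustain range;")
        lines.append(" otherwise the fraction of flagged k values is shown)")
        return "\n".join(lines)

    def plot_enrichment(self, contrast: str, ax=None):
        """Two-line enrichment panel (male blue, female red) with the
        gamma-null 95% reference, mirroring the study's curve figures."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        curve = self.curves[contrast].table
        call = self.calls[contrast].table
        ax.plot(curve.index, 100 * curve["frac_male"], color="tab:blue", label="male-specific")
        ax.plot(curve.index, 100 * curve["frac_female"], color="tab:red", label="female-specific")
        ax.plot(
            call.index,
            100 * call["null_q_gamma"],
            color="gray",
            ls="--",
            lw=0.8,
            label="null 95% (male set)",
        )
        ax.set_xlabel("top-k exposure DEGs")
        ax.set_ylabel("% sex-specific DEGs")
        ax.set_title(contrast, fontsize=9)
        ax.legend(fontsize=7)
        return ax

    def curves_frame(self) -> pd.DataFrame:
        """All enrichment curves stacked into one long DataFrame."""
        frames = []
        for name, curve in self.curves.items():
            t = curve.table.copy()
            t["contrast"] = name
            frames.append(t.reset_index())
        return pd.concat(frames, ignore_index=True)
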