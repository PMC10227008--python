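"""Enrichment of sex-specific DEGs among top-ranked exposure DEGs.

The core statistic: for each k up to 200, the fraction of the k
smallest-p exposure DEGs that belong to a sex-specific gene set, compared
against a null built by repeatedly (5,000 times) sampling k-sized gene sets
without replacement from the expressed universe (genes whose maximum raw
count exceeds 100).  The null fractions are summarized both empirically and
through a gamma distribution fitted by moment matching
(shape = m^2/v, rate = m/v); an exact hypergeometric tail is available as
an analytic oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix
from .diffexpr import RankedDEGList, SexDEGSets

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressedUniverse",
    "EnrichmentCurve",
    "EnrichmentNull",
    "expressed_universe",
    "enrichment_curve",
    "permutation_null",
    "gamma_fit_mme",
    "hypergeom_tail",
    "call_enrichment",
]


@dataclass
class ExpressedUniverse:
    """Genes whose maximum raw count strictly exceeds a threshold."""

    genes: set
    max_counts: pd.Series
    threshold: float

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentCurve:
    """Cumulative sex-set membership fractions over the top-k ranked genes."""

    contrast: str
    table: pd.DataFrame  # index k; columns n_male, n_female, frac_male, frac_female

    @property
    def k_max(self) -> int:
        return int(self.table.index.max())


@dataclass
class EnrichmentNull:
    """Permutation null for one sampling size.

    ``draws`` holds ``n_iter`` fractions of sex-specific genes among ``s``
    genes sampled without replacement from the universe.  ``alpha``/``beta``
    are the moment-matched gamma shape and rate; they are None when the
    draws are degenerate (zero variance).
    """

    s: int
    n_iter: int
    n_universe: int
    n_set: int
    draws: np.ndarray
    seed: int | None
    alpha: float | None = None
    beta: float | None = None
    degenerate: bool = False

    def tail_empirical(self, q: float) -> float:
        """Empirical P(fraction > q)."""
        return float(np.mean(self.draws > q))

    def tail_gamma(self, q: float) -> float:
        if self.degenerate:
            raise ValueError("gamma fit unavailable for a degenerate null")
        return float(stats.gamma.sf(q, a=self.alpha, scale=1.0 / self.beta))

    def quantile_empirical(self, p: float) -> float:
        return float(np.quantile(self.draws, p))

    def quantile_gamma(self, p: float) -> float:
        if self.degenerate:
            raise ValueError("gamma fit unavailable for a degenerate null")
        return float(stats.gamma.ppf(p, a=self.alpha, scale=1.0 / self.beta))


def expressed_universe(cm: CountMatrix, threshold: float = 100) -> ExpressedUniverse:
    """Genes with max raw count strictly greater than ``threshold``."""
    max_counts = cm.counts.max(axis=1)
    genes = set(max_counts.index[max_counts > threshold])
    return ExpressedUniverse(genes=genes, max_counts=max_counts, threshold=threshold)


def enrichment_curve(
    ranked: RankedDEGList,
    sets: SexDEGSets,
    universe: ExpressedUniverse,
    k_max: int = 200,
) -> EnrichmentCurve:
    """Fractions of male-/female-specific genes among the top-k ranked genes.

    Both the ranked list and the sex sets are intersected with the
    expressed universe before counting, so the observed curve and the
    permutation null share one gene space.  A ranked list shorter than
    ``k_max`` truncates the curve with a warning.
    """
    ranked_in = [g for g in ranked.gene_ids if g in universe.genes]
    male = sets.male_specific & universe.genes
    female = sets.female_specific & universe.genes
    if len(ranked_in) < k_max:
        logger.warning(
            "ranked list has %d universe genes < k_max=%d; curve truncated",
            len(ranked_in),
            k_max,
        )
        k_max = len(ranked_in)
    top = ranked_in[:k_max]
    in_male = np.fromiter((g in male for g in top), dtype=bool, count=k_max)
    in_female = np.fromiter((g in female for g in top), dtype=bool, count=k_max)
    k = np.arange(1, k_max + 1)
    n_male = np.cumsum(in_male)
    n_female = np.cumsum(in_female)
    table = pd.DataFrame(
        {
            "n_male": n_male,
            "n_female": n_female,
            "frac_male": n_male / k,
            "frac_female": n_female / k,
        },
        index=pd.Index(k, name="k"),
    )
    return EnrichmentCurve(contrast=ranked.contrast, table=table)


def permutation_null(
    universe: ExpressedUniverse | set,
    sex_set: set,
    s: int,
    n_iter: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentNull:
    """Null distribution of sex-set fractions in random s-gene samples.

    ``n_iter`` samples of ``s`` genes are drawn without replacement from
    the universe; each draw yields the fraction of sampled genes belonging
    to ``sex_set`` (intersected with the universe).  A gamma distribution is
    fitted to the draws by moment matching unless they are degenerate
    (zero variance), in which case only empirical summaries are available.
    """
    genes = universe.genes if isinstance(universe, ExpressedUniverse) else set(universe)
    n = len(genes)
    if not 1 <= s <= n:
        raise ValueError(f"sample size {s} outside [1, {n}]")
    member = np.fromiter((g in sex_set for g in sorted(genes)), dtype=bool, count=n)
    k_set = int(member.sum())
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(n, size=s, replace=False)
        draws[i] = member[idx].sum() / s

    null = EnrichmentNull(
        s=s, n_iter=n_iter, n_universe=n, n_set=k_set, draws=draws, seed=seed
    )
    var = draws.var(ddof=1)
    if var <= 0.0:
        null.degenerate = True
        logger.warning("degenerate permutation null (zero variance); gamma fit skipped")
    else:
        null.alpha, null.beta = gamma_fit_mme(draws)
    return null


def gamma_fit_mme(draws: np.ndarray) -> tuple[float, float]:
    """Gamma (shape, rate) by moment matching: shape = m^2/v, rate = m/v.

    Uses the unbiased sample variance; raises on degenerate draws.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    m = x.mean()
    v = x.var(ddof=1)
    # guard against exactly-constant draws, including rounding residue
    if v <= 0.0 or v < 1e-12 * max(m * m, 1e-300):
        raise ValueError("zero variance: gamma moment matching undefined")
    return float(m * m / v), float(m / v)


def hypergeom_tail(n_universe: int, k_set: int, s: int, q: float) -> float:
    """Exact P(X/s > q) for X ~ Hypergeometric(N=n_universe, K=k_set, s).

    The analytic counterpart of the permutation null: the probability that
    more than a fraction q of an s-gene sample without replacement belongs
    to the k_set-sized gene set.
    """
    if not 0 <= k_set <= n_universe:
        raise ValueError("need 0 <= K <= N")
    if not 1 <= s <= n_universe:
        raise ValueError("need 1 <= s <= N")
    if not 0.0 <= q < 1.0:
        raise ValueError("need q in [0, 1)")
    # P(X > q*s) = P(X >= floor(q*s) + 1) = sf(floor(q*s))
    return float(stats.hypergeom.sf(int(np.floor(q * s)), n_universe, k_set, s))


@dataclass
class EnrichmentCalls:
    """Per-k significance flags for one curve against size-matched nulls."""

    contrast: str
    alpha: float
    table: pd.DataFrame  # per k: frac, q_gamma, q_empirical, flag per sex
    summary: dict = field(default_factory=dict)


def call_enrichment(
    curve: EnrichmentCurve,
    nulls: dict[int, EnrichmentNull],
    alpha: float = 0.05,
    sustain_range: tuple[int, int] = (1, 50),
) -> EnrichmentCalls:
    """Flag k values where the observed fraction exceeds the null quantile.

    Each k is compared with the null of the nearest calibrated sampling
    size (k below the smallest s uses that smallest s).  The gamma-fit
    1 - alpha quantile is the primary reference; the empirical quantile is
    used when the null is degenerate.  The summary records, per sex set,
    whether the flag holds at every k within ``sustain_range``.
    """
    sizes = np.array(sorted(nulls))
    if sizes.size == 0:
        raise ValueError("no nulls supplied")
    rows = []
    for k, row in curve.table.iterrows():
        s = int(sizes[np.argmin(np.abs(sizes - k))])
        null = nulls[s]
        if null.degenerate:
            q_gamma = np.nan
            q_ref = null.quantile_empirical(1 - alpha)
        else:
            q_gamma = null.quantile_gamma(1 - alpha)
            q_ref = q_gamma
        q_emp = null.quantile_empirical(1 - alpha)
        rows.append(
            {
                "k": k,
                "s": s,
                "frac_male": row["frac_male"],
                "frac_female": row["frac_female"],
                "null_q_gamma": q_gamma,
                "null_q_empirical": q_emp,
                "flag_male": row["frac_male"] > q_ref,
                "flag_female": row["frac_female"] > q_ref,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    lo, hi = sustain_range
    window = table.loc[(table.index >= lo) & (table.index <= hi)]
    summary = {
        "contrast": curve.contrast,
        "alpha": alpha,
        "sustain_range": [lo, hi],
        "male_sustained": bool(window["flag_male"].all()) if len(window) else False,
        "female_sustained": bool(window["flag_female"].all()) if len(window) else False,
        "male_flag_rate": float(table["flag_male"].mean()),
        "female_flag_rate": float(table["flag_female"].mean()),
    }
    return EnrichmentCalls(contrast=curve.contrast, alpha=alpha, table=table, summary=summary)
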