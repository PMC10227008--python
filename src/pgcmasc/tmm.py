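"""Trimmed-mean-of-M-values (TMM) between-sample normalization.

For each sample a scaling factor is computed against a reference sample as
2 to the power of a trimmed, inverse-variance-weighted mean of per-gene
log2 expression ratios (M-values), with the most extreme 30% of M-values
and 5% of average log abundances (A-values) trimmed from each tail.
Factors are then rescaled so their geometric mean equals one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["NormFactors", "select_reference", "tmm_pair_factor", "tmm_factors", "cpm"]


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors.

    ``effective_lib_sizes = lib_sizes * factors``; factors have geometric
    mean one, so effective library sizes preserve overall scale.
    """

    factors: pd.Series
    lib_sizes: pd.Series
    reference: str

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lib_size": self.lib_sizes,
                "factor": self.factors,
                "effective_lib_size": self.effective_lib_sizes,
            }
        ).rename_axis("sample_id")


def select_reference(cm: CountMatrix) -> str:
    """Pick the reference sample for TMM: the sample whose 75th percentile
    of counts-per-million is closest to the mean such percentile.

    Ties break deterministically by column order.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = cm.lib_sizes().to_numpy(dtype=float)
    if (lib == 0).any():
        bad = cm.sample_ids[lib == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    cpm_mat = cm.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    uq = np.percentile(cpm_mat, 75, axis=0)
    idx = int(np.argmin(np.abs(uq - uq.mean())))
    return str(cm.sample_ids[idx])


def tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float | None = None,
    n_ref: float | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM factor of one sample (``obs``) against a reference (``ref``).

    Genes with a zero count in either sample are excluded.  M and A values::

        M_g = log2((obs_g / N_obs) / (ref_g / N_ref))
        A_g = 0.5 * log2((obs_g / N_obs) * (ref_g / N_ref))

    Gene weights are inverse delta-method variances
    ``1 / ((N_obs - obs_g)/(N_obs*obs_g) + (N_ref - ref_g)/(N_ref*ref_g))``.
    The top and bottom ``trim_m`` of M and ``trim_a`` of A are trimmed
    before the weighted mean.  If fewer than 10 genes survive, the factor
    falls back to 1 with a warning.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("obs and ref must share gene order and length")
    n_obs = float(obs.sum()) if n_obs is None else float(n_obs)
    n_ref = float(ref.sum()) if n_ref is None else float(n_ref)
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    if o.size == 0:
        logger.warning("no genes shared between sample and reference; factor = 1")
        return 1.0

    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    # trim trim_m from each tail of M and trim_a from each tail of A (ranks)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = _rank(m)
    rank_a = _rank(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    sel &= var > 0
    if sel.sum() < 10:
        logger.warning("fewer than 10 genes survive TMM trimming; factor = 1")
        return 1.0
    w = 1.0 / var[sel]
    f = np.sum(w * m[sel]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), matching R's rank() for the trim rule."""
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """TMM factors for every sample, geometric-mean-normalized to one."""
    ref_id = select_reference(cm)
    lib = cm.lib_sizes().astype(float)
    ref_vec = cm.counts[ref_id].to_numpy(dtype=float)
    n_ref = float(lib[ref_id])
    raw = {}
    for s in cm.sample_ids:
        obs = cm.counts[s].to_numpy(dtype=float)
        raw[s] = tmm_pair_factor(obs, ref_vec, lib[s], n_ref, trim_m, trim_a)
    factors = pd.Series(raw, name="factor").loc[cm.sample_ids]
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(factors=factors, lib_sizes=lib, reference=ref_id)


def cpm(cm: CountMatrix, norm: NormFactors, prior: float = 0.5) -> pd.DataFrame:
    """Counts per million on effective library sizes with a pseudo-count.

    The pseudo-count is scaled proportionally to each sample's effective
    library size (as in standard practice) so that rescaling all counts and
    library sizes by a common factor leaves CPM values unchanged.
    """
    eff = norm.effective_lib_sizes.loc[cm.sample_ids].to_numpy(dtype=float)
    prior_j = prior * eff / eff.mean()
    mat = cm.counts.to_numpy(dtype=float)
    out = (mat + prior_j[None, :]) / (eff + 2.0 * prior_j)[None, :] * 1e6
    return pd.DataFrame(out, index=cm.gene_ids, columns=cm.sample_ids)
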