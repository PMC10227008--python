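"""Negative-binomial GLM likelihood-ratio differential expression.

Genes are modelled as NB(mean mu, dispersion phi) with a log link and an
offset equal to the log effective (TMM-scaled) library size.  For each
gene a full and a nested reduced design are fitted by iteratively
reweighted least squares (batched across genes, since all genes share the
design) and compared by the likelihood-ratio test against a chi-square
reference.  Dispersions come from a method-of-moments estimate with
empirical-Bayes shrinkage toward the across-gene median.

Sex-specific DEGs are genes with BH FDR < 0.05 and more than two-fold
difference between male and female vehicle-lineage samples; exposure
contrasts produce a complete p-value-ranked gene list with deterministic
tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io import CountMatrix
from .tmm import NormFactors, tmm_factors

logger = logging.getLogger(__name__)

__all__ = [
    "DispersionEstimates",
    "SexDEGSets",
    "RankedDEGList",
    "estimate_dispersions",
    "nb_glm_lrt",
    "bh_fdr",
    "call_sex_specific",
    "rank_exposure_degs",
]

_MIN_PHI_NB = 1e-8  # below this the Poisson likelihood is used


@dataclass
class DispersionEstimates:
    """Per-gene NB dispersions after empirical-Bayes shrinkage."""

    phi: pd.Series  # shrunk per-gene dispersion
    phi_raw: pd.Series  # method-of-moments estimate (floored at 0)
    phi_common: float  # median of raw estimates
    weight: float  # shrinkage weight on the common value


@dataclass
class SexDEGSets:
    """Disjoint male- and female-specific gene sets with the full table."""

    male_specific: set
    female_specific: set
    table: pd.DataFrame  # gene-indexed: log2fc (male-positive), lrt, pvalue, fdr


@dataclass
class RankedDEGList:
    """All tested genes for one exposure contrast, ordered by ascending p.

    Ties break by descending \\|log2FC\\| then lexicographic gene id, so the
    ranking is invariant to input gene order.
    """

    contrast: str
    table: pd.DataFrame  # ordered; columns log2fc, lrt, pvalue, fdr, rank

    @property
    def gene_ids(self) -> list:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    cm: CountMatrix,
    norm: NormFactors,
    groups: pd.Series | np.ndarray,
    n0: float = 10.0,
) -> DispersionEstimates:
    """Method-of-moments dispersions on size-factor-normalized counts.

    For gene g with normalized counts y, the raw estimate is
    ``(pooled within-group variance - mean) / mean**2`` floored at zero.
    The common dispersion is a single scalar maximizing the Cox-Reid
    adjusted profile likelihood pooled over all genes (the adjustment
    compensates the degrees of freedom spent on group means, which the
    per-gene moment estimates cannot); each gene is then shrunk toward it
    with weight ``w = n0 / (n0 + residual df)``.
    """
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    n = len(groups)
    k = len(labels)
    df_resid = n - k
    if df_resid <= 0:
        raise ValueError("dispersion estimation needs at least one group with >=2 samples")

    eff = norm.effective_lib_sizes.loc[cm.sample_ids].to_numpy(dtype=float)
    sf = eff / np.exp(np.mean(np.log(eff)))
    y = cm.counts.to_numpy(dtype=float) / sf[None, :]

    # pooled within-group variance per gene
    ss = np.zeros(y.shape[0])
    for gi in range(k):
        cols = inv == gi
        if cols.sum() < 2:
            continue
        sub = y[:, cols]
        ss += sub.var(axis=1, ddof=1) * (cols.sum() - 1)
    pooled_var = ss / df_resid
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(mean > 0, (pooled_var - mean) / np.maximum(mean, 1e-12) ** 2, 0.0)
    phi_raw = np.maximum(phi_raw, 0.0)

    phi_common = _common_dispersion_apl(cm.counts.to_numpy(dtype=float), sf, inv, k)
    w = n0 / (n0 + df_resid)
    phi = w * phi_common + (1.0 - w) * phi_raw
    idx = cm.gene_ids
    return DispersionEstimates(
        phi=pd.Series(phi, index=idx),
        phi_raw=pd.Series(phi_raw, index=idx),
        phi_common=phi_common,
        weight=w,
    )


def _common_dispersion_apl(
    y: np.ndarray, sf: np.ndarray, group_idx: np.ndarray, k: int
) -> float:
    """Scalar common dispersion by Cox-Reid adjusted profile likelihood.

    Group means are profiled out on the normalized scale; the adjustment
    subtracts half the log determinant of the working information, which
    for a group-means design factorizes into per-group weight sums.
    """
    from scipy.optimize import minimize_scalar

    yn = y / sf[None, :]
    mu_hat = np.zeros_like(yn)
    groups = [group_idx == gi for gi in range(k)]
    for cols in groups:
        mu_hat[:, cols] = yn[:, cols].mean(axis=1, keepdims=True)
    mu_fit = np.maximum(mu_hat * sf[None, :], 1e-8)
    expressed = y.sum(axis=1) > 0
    y_e, mu_e = y[expressed], mu_fit[expressed]

    def neg_apl(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        ll = (
            gammaln(y_e + r)
            - gammaln(r)
            - gammaln(y_e + 1.0)
            + r * np.log(r / (r + mu_e))
            + y_e * np.log(mu_e / (r + mu_e))
        ).sum()
        w = mu_e / (1.0 + phi * mu_e)
        cr = 0.5 * sum(np.log(w[:, cols].sum(axis=1)).sum() for cols in groups)
        return -(ll - cr)

    res = minimize_scalar(neg_apl, bounds=(np.log(1e-6), np.log(10.0)), method="bounded")
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# Batched NB GLM with log link
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; Poisson limit for phi below 1e-8."""
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)[:, None]
    pois = y * np.log(mu) - mu - gammaln(y + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 / np.maximum(phi, _MIN_PHI_NB)
        nb = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    out = np.where(phi < _MIN_PHI_NB, pois, nb)
    return out.sum(axis=1)


def _fit_nb_glm(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS fit of a log-link NB GLM shared-design model.

    Returns (beta [G x P], loglik [G], converged [G]).
    """
    g, s = y.shape
    p = x.shape[1]
    phi_col = np.asarray(phi, dtype=float)[:, None]

    mu = np.maximum(y.astype(float), 0.0) + 0.5
    eta = np.log(mu)
    beta = np.zeros((g, p))
    ll_old = np.full(g, -np.inf)
    converged = np.zeros(g, dtype=bool)
    ll = ll_old

    for _ in range(max_iter):
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        w = mu / (1.0 + phi_col * mu)  # IRLS working weights for NB log link
        z = (eta - offset[None, :]) + (y - mu) / mu
        xtwx = np.einsum("sp,gs,sq->gpq", x, w, x)
        xtwz = np.einsum("sp,gs,gs->gp", x, w, z)
        # ridge epsilon guards against singular designs for degenerate genes
        xtwx += np.eye(p)[None, :, :] * 1e-10
        beta = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]
        eta = np.clip(beta @ x.T + offset[None, :], -30.0, 30.0)
        ll = _nb_loglik(y, np.exp(eta), phi)
        delta = np.abs(ll - ll_old) / (np.abs(ll) + 1.0)
        converged = delta < tol
        if converged.all():
            break
        ll_old = ll

    return beta, ll, converged


def nb_glm_lrt(
    cm: CountMatrix,
    norm: NormFactors,
    phi: pd.Series,
    design_full: np.ndarray,
    design_reduced: np.ndarray,
    lfc_coef: int = 1,
) -> pd.DataFrame:
    """Likelihood-ratio test of a full vs nested reduced design per gene.

    ``lfc_coef`` names the full-design column whose coefficient is reported
    as the log2 fold change.  Genes that fail to converge are flagged and
    assigned p = 1.

    Returns a gene-indexed DataFrame with columns ``log2fc``, ``lrt``,
    ``pvalue``, ``fdr``, ``converged``.
    """
    x_full = np.asarray(design_full, dtype=float)
    x_red = np.asarray(design_reduced, dtype=float)
    if x_red.shape[1] >= x_full.shape[1]:
        raise ValueError("reduced design must have fewer parameters than full")
    y = cm.counts.to_numpy(dtype=float)
    offset = np.log(norm.effective_lib_sizes.loc[cm.sample_ids].to_numpy(dtype=float))
    phi_arr = phi.loc[cm.gene_ids].to_numpy(dtype=float)

    beta_f, ll_f, conv_f = _fit_nb_glm(y, x_full, offset, phi_arr)
    _, ll_r, conv_r = _fit_nb_glm(y, x_red, offset, phi_arr)
    converged = conv_f & conv_r
    if not converged.all():
        logger.warning("%d genes failed GLM convergence; assigned p = 1", (~converged).sum())

    lrt = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    df = x_full.shape[1] - x_red.shape[1]
    pvalue = chi2.sf(lrt, df)
    pvalue = np.where(converged, pvalue, 1.0)
    log2fc = beta_f[:, lfc_coef] / np.log(2.0)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "lrt": lrt,
            "pvalue": pvalue,
            "converged": converged,
        },
        index=cm.gene_ids,
    )
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# High-level contrasts
# ---------------------------------------------------------------------------

def _two_group_designs(indicator: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = indicator.size
    full = np.column_stack([np.ones(n), indicator.astype(float)])
    reduced = np.ones((n, 1))
    return full, reduced


def _run_two_group(
    cm: CountMatrix, indicator: np.ndarray, groups: np.ndarray
) -> pd.DataFrame:
    """Normalize, estimate dispersions and LRT-test a two-group contrast.

    Genes with zero counts across every sample of the contrast are excluded
    from testing (and hence from the BH family).
    """
    nonzero = cm.counts.sum(axis=1) > 0
    cm_nz = CountMatrix(cm.counts.loc[nonzero], cm.metadata)
    norm = tmm_factors(cm_nz)
    disp = estimate_dispersions(cm_nz, norm, groups)
    full, reduced = _two_group_designs(indicator)
    return nb_glm_lrt(cm_nz, norm, disp.phi, full, reduced)


def call_sex_specific(
    cm: CountMatrix,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> SexDEGSets:
    """Sex-specific DEGs from vehicle-lineage samples.

    Tests male vs female among dose-0 samples (pooled across generations);
    genes with FDR below ``fdr_threshold`` and log2 fold change above
    ``lfc_threshold`` toward one sex (i.e. more than two-fold at the
    default) are assigned to that sex's set.  The reported log2fc is
    male-positive.
    """
    veh = cm.select(dose=0.0)
    sexes = set(veh.metadata["sex"])
    if sexes != {"M", "F"}:
        raise ValueError(f"vehicle samples must include both sexes, found {sorted(sexes)}")
    is_male = (veh.metadata["sex"] == "M").to_numpy()
    table = _run_two_group(veh, is_male.astype(float), veh.metadata["sex"].to_numpy())
    sig = table["fdr"] < fdr_threshold
    male = set(table.index[sig & (table["log2fc"] > lfc_threshold)])
    female = set(table.index[sig & (table["log2fc"] < -lfc_threshold)])
    return SexDEGSets(male_specific=male, female_specific=female, table=table)


def rank_exposure_degs(
    cm: CountMatrix,
    sex: str,
    dose,
    generation=None,
    vehicle_dose: float = 0.0,
) -> RankedDEGList:
    """P-value-ranked gene list for a dose-vs-vehicle contrast.

    ``dose`` may be a single level or a list (doses pooled against
    vehicle); ``generation`` restricts the contrast or pools all
    generations when None.
    """
    doses = [dose] if np.isscalar(dose) else list(dose)
    sub = cm.select(generation=generation, sex=sex, dose=list(doses) + [vehicle_dose])
    exposed = (sub.metadata["dose"] != vehicle_dose).to_numpy()
    if exposed.sum() < 2 or (~exposed).sum() < 2:
        raise ValueError("each contrast group needs at least 2 samples")
    table = _run_two_group(sub, exposed.astype(float), exposed)

    table = table.copy()
    table["abs_lfc"] = table["log2fc"].abs()
    table["_gene"] = table.index
    table = table.sort_values(
        ["pvalue", "abs_lfc", "_gene"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns=["abs_lfc", "_gene"])
    table["rank"] = np.arange(1, len(table) + 1)
    gen_lab = generation if generation is not None else "all"
    dose_lab = "+".join(str(d) for d in doses)
    return RankedDEGList(contrast=f"{gen_lab}:{sex}:{dose_lab}_vs_{vehicle_dose}", table=table)
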