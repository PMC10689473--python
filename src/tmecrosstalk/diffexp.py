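"""Shrunken negative-binomial exact-test differential expression (sSeq style).

Per gene, a method-of-moments dispersion is estimated from size-factor-
adjusted counts and shrunk toward the mean of the positive per-gene
estimates with a data-driven weight (a James-Stein-type minimum-MSE
criterion). Significance comes from a conditional NB exact test on the two
group sums given their total: the two-sided p-value is the total
probability of all splits whose probability does not exceed that of the
observed split. A Mann-Whitney U fallback is provided for low-depth
contrasts. Genes pass through Benjamini-Hochberg FDR control, and a gene
is called significant when FDR < alpha and |log2FC| > lfc_min.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from tmecrosstalk.io import CountMatrix
from tmecrosstalk.preprocess import NormMatrix

log = logging.getLogger(__name__)

_PHI_POISSON = 1e-12  # below this the NB is treated as Poisson


def compute_size_factors(counts_or_matrix) -> np.ndarray:
    """Per-cell size factor: total counts over the median total."""
    mat = counts_or_matrix.values if hasattr(counts_or_matrix, "values") \
        else counts_or_matrix
    totals = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell; filter before testing")
    return totals / np.median(totals)


def _mm_dispersion(y: np.ndarray, groups: list[np.ndarray],
                   inv_sf_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group method-of-moments dispersion on adjusted counts.

    With y = k / sf, Var(y) = mu * (1/sf) + phi * mu^2, so
    phi_hat = (s^2 - mu_hat * mean(1/sf)) / mu_hat^2, clamped at 0.
    Returns (phi_hat, s2) per gene.
    """
    n_total = sum(g.shape[1] for g in groups)
    mu_pool = sum(g.sum(axis=1) for g in groups) / n_total
    ss = np.zeros_like(mu_pool)
    for g in groups:
        mu_g = g.mean(axis=1, keepdims=True)
        ss += ((g - mu_g) ** 2).sum(axis=1)
    dof = max(n_total - len(groups), 1)
    s2 = ss / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(mu_pool > 0,
                       (s2 - mu_pool * inv_sf_mean) / mu_pool ** 2, 0.0)
    return np.maximum(phi, 0.0), s2


def shrink_dispersions(phi_hat: np.ndarray, s2: np.ndarray,
                       mu_pool: np.ndarray, n_cells: int
                       ) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene dispersions toward the mean of the positive estimates.

    The shrinkage weight minimizes an estimated mean squared error: with the
    delta-method sampling variance Var(phi_hat_g) ~ 2 s_g^4 / ((n-1) mu_g^4),
    the optimal linear weight toward the common target xi is
    delta = sum_g Var(phi_hat_g) / sum_g (phi_hat_g - xi)^2, clipped to [0,1].
    Every shrunken value lies between phi_hat_g and xi.
    """
    positive = phi_hat > 0
    xi = float(phi_hat[positive].mean()) if positive.any() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        var_hat = np.where(mu_pool > 0,
                           2.0 * s2 ** 2 / (max(n_cells - 1, 1) * mu_pool ** 4),
                           0.0)
    denom = float(((phi_hat - xi) ** 2).sum())
    delta = 1.0 if denom == 0 else min(1.0, float(var_hat.sum()) / denom)
    phi_star = delta * xi + (1.0 - delta) * phi_hat
    return phi_star, xi, delta


def _sum_nb_params(mu0: float, phi: float, s: np.ndarray
                   ) -> tuple[float, float]:
    """Moment-matched NB for a sum of per-cell NB counts.

    Each cell c has mean mu0*s_c and variance mu0*s_c + phi*(mu0*s_c)^2;
    the group sum is approximated by an NB with the summed mean/variance.
    """
    m = mu0 * s.sum()
    v = m + phi * mu0 ** 2 * float((s ** 2).sum())
    return m, v


def _logpmf_range(t: int, mean: float, var: float) -> np.ndarray:
    a = np.arange(t + 1)
    if var <= mean * (1 + 1e-12) or mean <= 0:
        return st.poisson.logpmf(a, max(mean, 1e-300))
    r = mean ** 2 / (var - mean)
    p = r / (r + mean)
    return st.nbinom.logpmf(a, r, p)


def nb_exact_pvalue(k_a: int, k_b: int, mu0: float, phi: float,
                    sf_a: np.ndarray, sf_b: np.ndarray) -> float:
    """Conditional two-sided exact p-value for the split (k_a, k_b).

    All splits a + b = k_a + k_b are enumerated; the p-value is the
    normalized total probability of splits no more probable than the
    observed one. In the phi -> 0 limit this is the conditional binomial
    (Poisson) exact test.
    """
    t = k_a + k_b
    if t == 0 or mu0 <= 0:
        return 1.0
    m_a, v_a = _sum_nb_params(mu0, phi, sf_a)
    m_b, v_b = _sum_nb_params(mu0, phi, sf_b)
    lp = _logpmf_range(t, m_a, v_a) + _logpmf_range(t, m_b, v_b)[::-1]
    lp -= lp.max()
    probs = np.exp(lp)
    total = probs.sum()
    obs = probs[k_a]
    return float(probs[probs <= obs * (1.0 + 1e-12)].sum() / total)


def _decorate(df: pd.DataFrame, alpha: float, lfc_min: float) -> pd.DataFrame:
    tested = df["tested"].to_numpy()
    fdr = np.full(len(df), np.nan)
    if tested.any():
        fdr[tested] = multipletests(df.loc[tested, "p_value"],
                                    method="fdr_bh")[1]
    df["fdr"] = fdr
    df["significant"] = (tested & (fdr < alpha)
                         & (df["log2fc"].abs() > lfc_min))
    return df


def sseq_test(counts: CountMatrix, group_a, group_b, *,
              alpha: float = 0.05, lfc_min: float = 1.0,
              min_cells: int = 3, pseudocount: float = 1.0,
              dispersion_override: float | None = None,
              size_factors: np.ndarray | None = None) -> pd.DataFrame:
    """sSeq-style NB exact test of group A vs group B.

    ``group_a`` / ``group_b`` are boolean masks or index arrays over the
    cells of ``counts``. Genes detected in fewer than ``min_cells`` cells
    (both groups pooled) are reported with p = 1 and excluded from FDR.
    ``dispersion_override`` pins the shrunken dispersion (0 gives the
    conditional-binomial/Poisson limit).
    """
    a_idx = _as_index(group_a, counts.n_cells, "group_a")
    b_idx = _as_index(group_b, counts.n_cells, "group_b")
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both groups must be non-empty")

    sub = counts.values.tocsc()[:, np.concatenate([a_idx, b_idx])].toarray()
    ka_mat = sub[:, :len(a_idx)].astype(float)
    kb_mat = sub[:, len(a_idx):].astype(float)
    if size_factors is None:
        sf = compute_size_factors(sp.csr_matrix(sub))
    else:
        sf = np.asarray(size_factors, dtype=float)[
            np.concatenate([a_idx, b_idx])]
    sf_a, sf_b = sf[:len(a_idx)], sf[len(a_idx):]

    ya = ka_mat / sf_a[None, :]
    yb = kb_mat / sf_b[None, :]
    n_cells = ya.shape[1] + yb.shape[1]
    mu_a = ya.mean(axis=1)
    mu_b = yb.mean(axis=1)
    mu_pool = (ya.sum(axis=1) + yb.sum(axis=1)) / n_cells
    inv_sf_mean = float((1.0 / sf).mean())

    phi_hat, s2 = _mm_dispersion(ya, [ya, yb], inv_sf_mean)
    if dispersion_override is not None:
        phi_star = np.full_like(phi_hat, float(dispersion_override))
        xi = delta = np.nan
    else:
        phi_star, xi, delta = shrink_dispersions(phi_hat, s2, mu_pool, n_cells)

    detected = (sub > 0).sum(axis=1)
    tested = detected >= min_cells

    k_a = ka_mat.sum(axis=1).round().astype(np.int64)
    k_b = kb_mat.sum(axis=1).round().astype(np.int64)
    pvals = np.ones(counts.n_genes)
    for g in np.flatnonzero(tested):
        pvals[g] = nb_exact_pvalue(int(k_a[g]), int(k_b[g]),
                                   float(mu_pool[g]), float(phi_star[g]),
                                   sf_a, sf_b)

    log2fc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    zero_both = (k_a == 0) & (k_b == 0)
    log2fc[zero_both] = 0.0

    df = pd.DataFrame({
        "gene": counts.gene_ids,
        "mean_a": mu_a,
        "mean_b": mu_b,
        "log2fc": log2fc,
        "dispersion_mm": phi_hat,
        "dispersion_shrunk": phi_star,
        "p_value": pvals,
        "tested": tested,
    }).set_index("gene", drop=False)
    df.attrs["shrinkage_target"] = xi
    df.attrs["shrinkage_weight"] = delta
    return _decorate(df, alpha, lfc_min)


def mwu_test(norm: NormMatrix, group_a, group_b, *,
             alpha: float = 0.05, lfc_min: float = 1.0,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test per gene on log-normalized expression.

    Uses the exact null distribution where scipy selects it (small groups,
    no ties) and the tie-corrected normal approximation otherwise; decorated
    with the same log2FC / FDR / significance columns as ``sseq_test``.
    """
    a_idx = _as_index(group_a, norm.n_cells, "group_a")
    b_idx = _as_index(group_b, norm.n_cells, "group_b")
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both groups must be non-empty")
    xa = norm.values[:, a_idx]
    xb = norm.values[:, b_idx]

    pvals = np.ones(norm.n_genes)
    constant = (np.ptp(xa, axis=1) == 0) & (np.ptp(xb, axis=1) == 0) & \
               (xa[:, 0] == xb[:, 0])
    todo = ~constant
    if todo.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = st.mannwhitneyu(xa[todo], xb[todo], axis=1,
                                  alternative="two-sided")
        pvals[todo] = np.nan_to_num(res.pvalue, nan=1.0)

    mu_a = np.expm1(xa).mean(axis=1)
    mu_b = np.expm1(xb).mean(axis=1)
    log2fc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    df = pd.DataFrame({
        "gene": norm.gene_ids,
        "mean_a": mu_a,
        "mean_b": mu_b,
        "log2fc": log2fc,
        "dispersion_mm": np.nan,
        "dispersion_shrunk": np.nan,
        "p_value": pvals,
        "tested": np.ones(norm.n_genes, dtype=bool),
    }).set_index("gene", drop=False)
    return _decorate(df, alpha, lfc_min)


def one_vs_rest(counts: CountMatrix, labels, *, alpha: float = 0.05,
                lfc_min: float = 1.0, min_cells: int = 3
                ) -> dict[str, pd.DataFrame]:
    """sSeq test of each label against all remaining cells.

    Singleton labels are skipped with a warning. Result tables are sorted by
    ascending p-value (ties by descending log2FC).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != counts.n_cells:
        raise ValueError("labels length must equal cell count")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 labels")
    sf = compute_size_factors(counts)
    out: dict[str, pd.DataFrame] = {}
    for lab in uniq:
        mask = labels == lab
        if mask.sum() < 2:
            warnings.warn(f"label {lab!r} has < 2 cells; skipped")
            continue
        res = sseq_test(counts, mask, ~mask, alpha=alpha, lfc_min=lfc_min,
                        min_cells=min_cells, size_factors=sf)
        out[lab] = res.sort_values(["p_value", "log2fc"],
                                   ascending=[True, False])
    return out


def _as_index(group, n: int, name: str) -> np.ndarray:
    idx = np.asarray(group)
    if idx.dtype == bool:
        if idx.shape[0] != n:
            raise ValueError(f"{name} mask length {idx.shape[0]} != {n}")
        return np.flatnonzero(idx)
    return idx.astype(int)
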