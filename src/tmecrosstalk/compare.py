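"""Sample-level comparisons: pseudo-bulk correlation, within-sample
heterogeneity, and in-vivo/in-vitro log-fold-change concordance.

Pseudo-bulk vectors are per-sample means of normalized expression and are
compared by Pearson correlation. Heterogeneity is the mean pairwise cosine
distance among up to 500 randomly sampled cells per sample, with a paired
one-sided t test across patients carrying both tumor and tumoroid samples.
Concordance regresses in-vitro log2 fold changes (tumoroid vs organoid) on
in-vivo ones (tumor vs adjacent normal), for all genes and for the
receptor/ligand subset, and compares the two slopes with a one-sided
Z test: z = (b_all - b_rl) / sqrt(SE_all^2 + SE_rl^2), p = 1 - Phi(z).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats as st

from tmecrosstalk.io import RLDatabase
from tmecrosstalk.preprocess import NormMatrix

log = logging.getLogger(__name__)


def pseudobulk_corr(norm: NormMatrix, samples, subset_mask=None
                    ) -> pd.DataFrame:
    """Sample x sample Pearson matrix of per-sample mean expression.

    ``samples`` gives each cell's sample id; ``subset_mask`` optionally
    restricts to a compartment (e.g. epithelial cells). Samples with no
    cells after subsetting are dropped with a warning.
    """
    samples = np.asarray(samples)
    if subset_mask is not None:
        keep = np.asarray(subset_mask, dtype=bool)
        sub = norm.subset_cells(keep)
        samples = samples[keep]
    else:
        sub = norm
    uniq = [s for s in pd.unique(samples)]
    means, kept = [], []
    for s in uniq:
        mask = samples == s
        if not mask.any():
            log.warning("sample %s has no cells in subset; dropped", s)
            continue
        means.append(sub.values[:, mask].mean(axis=1))
        kept.append(s)
    if len(kept) < 2:
        raise ValueError("need >= 2 samples with cells")
    corr = np.corrcoef(np.stack(means))
    return pd.DataFrame(corr, index=kept, columns=kept)


def mean_pairwise_cosine_distance(x: np.ndarray) -> float:
    """Mean of 1 - cosine similarity over all unordered pairs of columns."""
    norms = np.linalg.norm(x, axis=0)
    valid = norms > 0
    x = x[:, valid] / norms[valid]
    n = x.shape[1]
    if n < 2:
        return np.nan
    gram = x.T @ x
    iu = np.triu_indices(n, k=1)
    return float((1.0 - gram[iu]).mean())


@dataclasses.dataclass
class HeterogeneityResult:
    per_sample: pd.DataFrame  # sample, statistic, n_used
    paired_t: float
    paired_p: float
    n_pairs: int


def heterogeneity(norm: NormMatrix, samples, *, n_sample: int = 500,
                  seed: int = 0, patients=None, tissue_classes=None,
                  pair_tissues: tuple[str, str] = ("tumor", "tumoroid")
                  ) -> HeterogeneityResult:
    """Within-sample transcriptional heterogeneity.

    For each sample, ``min(n_sample, n_cells)`` cells are drawn without
    replacement and the statistic is the mean pairwise cosine distance
    among them (zero-vector cells excluded). If per-cell ``patients`` and
    ``tissue_classes`` are given, a paired one-sided t test compares the
    statistic between the two ``pair_tissues`` across patients that carry
    both (alternative: first tissue more heterogeneous).
    """
    samples = np.asarray(samples)
    rng = np.random.default_rng(seed)
    rows = []
    sample_info: dict[str, tuple] = {}
    for s in pd.unique(samples):
        idx = np.flatnonzero(samples == s)
        if idx.size < 2:
            log.warning("sample %s has < 2 cells; skipped", s)
            continue
        take = rng.choice(idx, size=min(n_sample, idx.size), replace=False)
        stat = mean_pairwise_cosine_distance(norm.values[:, take])
        rows.append({"sample": s, "statistic": stat, "n_used": take.size})
        if patients is not None and tissue_classes is not None:
            pt = np.asarray(patients)[idx[0]]
            tc = np.asarray(tissue_classes)[idx[0]]
            sample_info[s] = (pt, tc)
    table = pd.DataFrame(rows, columns=["sample", "statistic", "n_used"])

    t_stat = p = np.nan
    n_pairs = 0
    if sample_info:
        by_patient: dict[str, dict[str, float]] = {}
        for _, row in table.iterrows():
            pt, tc = sample_info[row["sample"]]
            by_patient.setdefault(pt, {})[tc] = row["statistic"]
        a, b = pair_tissues
        xa = [v[a] for v in by_patient.values() if a in v and b in v]
        xb = [v[b] for v in by_patient.values() if a in v and b in v]
        n_pairs = len(xa)
        if n_pairs >= 2:
            t_stat, p = st.ttest_rel(xa, xb, alternative="greater")
    return HeterogeneityResult(per_sample=table, paired_t=float(t_stat),
                               paired_p=float(p), n_pairs=n_pairs)


@dataclasses.dataclass
class ConcordanceResult:
    pairs: pd.DataFrame  # gene, lfc_invivo, lfc_invitro, is_rl
    slope_all: float
    se_all: float
    slope_rl: float
    se_rl: float
    z: float
    p_value: float
    quadrant_counts: tuple[int, int, int, int]  # I, II, III, IV


def _ols_slope(x: np.ndarray, y: np.ndarray,
               intercept: bool = True) -> tuple[float, float]:
    import statsmodels.api as sm

    design = sm.add_constant(x) if intercept else x[:, None]
    fit = sm.OLS(y, design).fit()
    i = 1 if intercept else 0
    return float(fit.params[i]), float(fit.bse[i])


def lfc_concordance(pairs: pd.DataFrame, *, intercept: bool = True,
                    min_rl: int = 10) -> ConcordanceResult:
    """Slope comparison between all genes and the receptor/ligand subset.

    ``pairs`` must have columns gene, lfc_invivo, lfc_invitro, is_rl with
    finite values. Quadrants use strict signs (genes with a zero LFC are
    excluded from the quadrant counts).
    """
    pairs = pairs.dropna(subset=["lfc_invivo", "lfc_invitro"])
    x = pairs["lfc_invivo"].to_numpy(dtype=float)
    y = pairs["lfc_invitro"].to_numpy(dtype=float)
    is_rl = pairs["is_rl"].to_numpy(dtype=bool)

    slope_all, se_all = _ols_slope(x, y, intercept)
    if is_rl.sum() < min_rl:
        log.warning("receptor/ligand subset has %d < %d genes; "
                    "Z test skipped", int(is_rl.sum()), min_rl)
        slope_rl = se_rl = z = p = np.nan
    else:
        slope_rl, se_rl = _ols_slope(x[is_rl], y[is_rl], intercept)
        z = (slope_all - slope_rl) / np.hypot(se_all, se_rl)
        p = 1.0 - st.norm.cdf(z)

    q1 = int(((x > 0) & (y > 0)).sum())
    q2 = int(((x < 0) & (y > 0)).sum())
    q3 = int(((x < 0) & (y < 0)).sum())
    q4 = int(((x > 0) & (y < 0)).sum())
    return ConcordanceResult(
        pairs=pairs, slope_all=slope_all, se_all=se_all,
        slope_rl=float(slope_rl), se_rl=float(se_rl),
        z=float(z), p_value=float(p),
        quadrant_counts=(q1, q2, q3, q4))


def lfc_pairs_from_de(de_invivo: pd.DataFrame, de_invitro: pd.DataFrame,
                      rl: RLDatabase, *, min_cells_detected: int = 3
                      ) -> pd.DataFrame:
    """Build the LFC pair table from two DE results on a shared universe.

    Genes must have been tested in both contrasts (which enforces the
    detection filter applied at test time) and have finite fold changes.
    """
    shared = de_invivo.index.intersection(de_invitro.index)
    a = de_invivo.loc[shared]
    b = de_invitro.loc[shared]
    ok = a["tested"] & b["tested"] & \
        np.isfinite(a["log2fc"]) & np.isfinite(b["log2fc"])
    rl_genes = rl.receptors | rl.ligands
    return pd.DataFrame({
        "gene": shared[ok],
        "lfc_invivo": a.loc[ok, "log2fc"].to_numpy(),
        "lfc_invitro": b.loc[ok, "log2fc"].to_numpy(),
        "is_rl": [g in rl_genes for g in shared[ok]],
    }).reset_index(drop=True)
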