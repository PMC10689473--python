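"""AUC-recovery gene-set scoring and derived per-cell scores.

For each cell, genes are ranked by decreasing expression and a gene set is
scored by the area under its recovery curve within the top ``top_frac``
fraction of the ranking, normalized by the maximal achievable area — the
rank-based enrichment statistic popularized by AUCell. Raw scores lie in
[0, 1]; an optional per-set min-max rescaling maps them to [0, 100] for
ternary stem/transit-amplifying/colonocyte (SC/TA/CC) state assignment.
A threshold on the S / G2M score maximum yields per-group cycling
fractions.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from tmecrosstalk.io import GeneSetCollection
from tmecrosstalk.preprocess import NormMatrix


def auc_score(norm: NormMatrix, sets: GeneSetCollection | dict,
              top_frac: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Per-cell AUC recovery score for each gene set.

    Ties in expression are broken by a fixed random permutation of gene
    indices drawn once from ``seed``, making the ranking deterministic.
    Sets with no genes in the universe score NaN (undefined, not 0).
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    items = list(items)
    n_genes = norm.n_genes
    window = math.ceil(top_frac * n_genes)
    perm = np.random.default_rng(seed).permutation(n_genes)

    # rank matrix: ranks[c, g] = 1-based rank of gene g in cell c
    expr = norm.values.T  # cells x genes
    order = np.lexsort((perm[None, :].repeat(expr.shape[0], 0), -expr), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(expr.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n_genes + 1)[None, :]

    lookup = {g: i for i, g in enumerate(norm.gene_ids)}
    scores = {}
    for name, members in items:
        idx = [lookup[g] for g in members if g in lookup]
        if not idx:
            warnings.warn(f"gene set {name!r} has no genes in the universe")
            scores[name] = np.full(expr.shape[0], np.nan)
            continue
        s = len(idx)
        # a member at rank r contributes (window - r + 1) steps of recovery
        contrib = np.clip(window - ranks[:, idx] + 1, 0, None).sum(axis=1)
        kk = np.arange(1, window + 1)
        max_area = np.minimum(kk, s).sum()
        scores[name] = contrib / max_area
    return pd.DataFrame(scores, index=norm.cell_ids)


def rescale_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale each set's scores to [0, 100] over the scored cells.

    Constant (zero-range) sets map to 0 with a warning. Idempotent up to
    the affine map: rescaling twice equals rescaling once.
    """
    out = {}
    for name in scores.columns:
        col = scores[name].to_numpy(dtype=float)
        lo, hi = np.nanmin(col), np.nanmax(col)
        if hi == lo:
            warnings.warn(f"scores for {name!r} are constant; rescaled to 0")
            out[name] = np.zeros_like(col)
        else:
            out[name] = 100.0 * (col - lo) / (hi - lo)
    return pd.DataFrame(out, index=scores.index)


def ternary_assign(rescaled: pd.DataFrame,
                   sets: tuple[str, str, str] = ("SC", "TA", "CC")
                   ) -> pd.DataFrame:
    """Barycentric weights from three rescaled signature scores.

    weight_i = score_i / sum(scores); cells with all three scores zero are
    flagged unassigned (NaN weights).
    """
    missing = [s for s in sets if s not in rescaled.columns]
    if missing:
        raise ValueError(f"missing signature scores: {missing}")
    x = rescaled[list(sets)].to_numpy(dtype=float)
    total = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(total[:, None] > 0, x / total[:, None], np.nan)
    out = pd.DataFrame(w, index=rescaled.index, columns=list(sets))
    out["assigned"] = total > 0
    return out


def phase_fraction(scores: pd.DataFrame, labels,
                   s_set: str = "S", g2m_set: str = "G2M",
                   threshold: float | None = None,
                   reference_group: str | None = None) -> dict:
    """Per-group fraction of cycling cells from S / G2M scores.

    A cell is cycling when max(S score, G2M score) exceeds ``threshold``;
    by default the threshold is the 75th percentile of that maximum in the
    reference group (or the whole population when none is given).
    """
    labels = pd.Series(np.asarray(labels), index=scores.index)
    peak = scores[[s_set, g2m_set]].max(axis=1)
    if threshold is None:
        ref = peak if reference_group is None else \
            peak[labels == reference_group]
        if len(ref) == 0:
            raise ValueError(f"empty reference group {reference_group!r}")
        threshold = float(np.nanquantile(ref, 0.75))
    cycling = peak > threshold
    fractions = {}
    for grp in pd.unique(labels):
        mask = labels == grp
        fractions[grp] = float(cycling[mask].mean()) if mask.any() else np.nan
    result = {"threshold": threshold, "fractions": fractions}
    if len(fractions) == 2:
        a, b = fractions.values()
        result["difference"] = a - b
    return result
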