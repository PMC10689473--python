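"""Macrophage state identification and fate-bias state probabilities.

Macrophage clusters are merged into three states by whichever hallmark
gene — IL1B (inflammatory), SPP1 (pro-tumorigenic/immunosuppressive), or
C1QC (antigen-presenting) — has the highest cluster-mean expression.
State-specific signatures are then redefined by one-vs-rest differential
expression, and per-cell state probabilities come from an iterative
anchor-growing classifier in signature-score space: the top quartile of
each state's own-signature scores seeds the anchors, remaining cells are
classified by k-nearest-anchor voting under cosine distance, and each
iteration absorbs the most confident decile into the anchor set. The
resulting fate biases are non-negative and sum to one per cell.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st

from tmecrosstalk import diffexp, signatures as sigmod
from tmecrosstalk.io import CountMatrix
from tmecrosstalk.preprocess import NormMatrix, normalize

log = logging.getLogger(__name__)

HALLMARKS = ("IL1B", "SPP1", "C1QC")
UNASSIGNED = "unassigned"


def identify_states(counts: CountMatrix, clusters, *,
                    hallmarks: tuple[str, ...] = HALLMARKS,
                    n_sig: int = 50, alpha: float = 0.05,
                    min_lfc: float = 0.0
                    ) -> tuple[pd.Series, dict[str, list[str]]]:
    """Merge macrophage clusters into hallmark states and derive signatures.

    Each cluster is assigned to the hallmark gene with the highest
    cluster-mean normalized expression; clusters where all hallmark means
    are zero are flagged unassigned and excluded from signature derivation.
    One-vs-rest DE over the state labels yields the top ``n_sig``
    significantly upregulated genes per state; genes claimed by several
    states go to the one where they rank best.
    """
    missing = [h for h in hallmarks if h not in counts.gene_ids]
    if missing:
        raise ValueError(f"hallmark genes absent from matrix: {missing}")
    labels = np.asarray(clusters)
    norm = normalize(counts)
    hidx = norm.gene_index(hallmarks)

    # cluster-mean expression per hallmark, normalized by each hallmark's
    # overall mean so that baseline expression differences between the
    # marker genes do not dominate the assignment
    uniq_clusters = np.unique(labels)
    cluster_means = np.stack([
        norm.values[np.ix_(hidx, np.flatnonzero(labels == c))].mean(axis=1)
        for c in uniq_clusters], axis=1)  # hallmarks x clusters
    overall = cluster_means.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        enrich = np.where(overall > 0, cluster_means / overall, 0.0)
    state_of_cluster: dict = {}
    for j, c in enumerate(uniq_clusters):
        state_of_cluster[c] = UNASSIGNED if cluster_means[:, j].max() == 0 \
            else hallmarks[int(np.argmax(enrich[:, j]))]
    hard = pd.Series([state_of_cluster[c] for c in labels],
                     index=counts.cell_ids, name="state")

    assigned = hard != UNASSIGNED
    de = diffexp.one_vs_rest(
        counts.subset_cells(assigned.to_numpy()),
        hard[assigned].to_numpy(), alpha=alpha, lfc_min=min_lfc)

    # rank of each candidate gene within each state's DE list
    candidate_rank: dict[str, dict[str, int]] = {}
    for state, table in de.items():
        up = table[table["significant"] & (table["log2fc"] > 0)]
        candidate_rank[state] = {g: i for i, g in enumerate(up["gene"])}
    claimed: dict[str, str] = {}
    for state in candidate_rank:
        for gene, rank in candidate_rank[state].items():
            if gene not in claimed or \
                    rank < candidate_rank[claimed[gene]][gene]:
                claimed[gene] = state
    sigs: dict[str, list[str]] = {}
    for state in candidate_rank:
        genes = [g for g, r in sorted(candidate_rank[state].items(),
                                      key=lambda kv: kv[1])
                 if claimed[g] == state]
        sigs[state] = genes[:n_sig]
    return hard, sigs


def state_probability(norm: NormMatrix, labels: pd.Series,
                      state_signatures: dict[str, list[str]], *,
                      k: int = 25, anchor_quantile: float = 0.25,
                      absorb_frac: float = 0.10, top_frac: float = 0.05,
                      seed: int = 0) -> pd.DataFrame:
    """Iterative fate-bias classification in signature-score space.

    Anchors (top ``anchor_quantile`` of own-signature AUC score per state)
    carry probability 1 for their own state; every other cell's
    probabilities are the label fractions among its ``k`` nearest anchors
    (cosine distance on the per-state score vectors), recorded when the
    cell is absorbed. Each iteration absorbs the ``absorb_frac`` most
    confident remaining cells into the anchor set.
    """
    from sklearn.neighbors import NearestNeighbors

    states = list(state_signatures)
    scores = sigmod.auc_score(norm, state_signatures, top_frac=top_frac,
                              seed=seed)
    x = scores[states].to_numpy(dtype=float)
    x = x + 1e-12  # cosine distance undefined on all-zero vectors
    labels = pd.Series(np.asarray(labels), index=norm.cell_ids)

    n = x.shape[0]
    probs = np.zeros((n, len(states)))
    is_anchor = np.zeros(n, dtype=bool)
    anchor_label = np.full(n, -1)
    for si, state in enumerate(states):
        members = np.flatnonzero((labels == state).to_numpy())
        if members.size == 0:
            continue
        own = scores.iloc[members][state].to_numpy()
        cut = np.quantile(own, 1.0 - anchor_quantile)
        chosen = members[own >= cut]
        is_anchor[chosen] = True
        anchor_label[chosen] = si
        probs[chosen] = 0.0
        probs[chosen, si] = 1.0

    remaining = np.flatnonzero(~is_anchor)
    while remaining.size:
        n_anchors = int(is_anchor.sum())
        k_eff = min(k, n_anchors)
        if k_eff < k:
            warnings.warn(f"only {n_anchors} anchors; k reduced to {k_eff}")
        nn = NearestNeighbors(n_neighbors=k_eff, metric="cosine").fit(
            x[is_anchor])
        _, idx = nn.kneighbors(x[remaining])
        anchor_ids = np.flatnonzero(is_anchor)
        votes = np.zeros((remaining.size, len(states)))
        for si in range(len(states)):
            votes[:, si] = (anchor_label[anchor_ids[idx]] == si).mean(axis=1)
        conf = votes.max(axis=1)
        n_absorb = max(1, int(np.ceil(absorb_frac * remaining.size)))
        take = np.argsort(-conf, kind="stable")[:n_absorb]
        cells = remaining[take]
        probs[cells] = votes[take]
        is_anchor[cells] = True
        anchor_label[cells] = votes[take].argmax(axis=1)
        remaining = np.flatnonzero(~is_anchor & (anchor_label == -1))

    out = pd.DataFrame(probs, index=norm.cell_ids,
                       columns=[f"p_{s}" for s in states])
    out = out.div(out.sum(axis=1), axis=0)
    out["state"] = [states[i] for i in np.argmax(probs, axis=1)]
    return out


def state_by_condition(probs: pd.DataFrame, metadata: pd.DataFrame,
                       groupby: str,
                       contrasts: list[tuple[str, str]] | None = None
                       ) -> pd.DataFrame:
    """Per-group state-probability means and Welch t-tests for contrasts.

    ``metadata`` must be indexed by cell id and carry the ``groupby``
    column. Contrasts default to every pair of observed groups. Groups
    with fewer than two cells skip their contrasts.
    """
    if groupby not in metadata.columns:
        raise ValueError(f"metadata lacks grouping column {groupby!r}")
    groups = metadata.loc[probs.index, groupby]
    state_cols = [c for c in probs.columns if c.startswith("p_")]
    uniq = list(pd.unique(groups))
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    rows = []
    for a, b in contrasts:
        xa_all = probs[groups == a]
        xb_all = probs[groups == b]
        for col in state_cols:
            xa = xa_all[col].to_numpy()
            xb = xb_all[col].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                log.warning("contrast (%s, %s) skipped: group too small", a, b)
                continue
            t, p = st.ttest_ind(xa, xb, equal_var=False)
            rows.append({
                "state": col, "group_a": a, "group_b": b,
                "mean_a": xa.mean(), "mean_b": xb.mean(),
                "t": float(t), "p_value": float(p),
            })
    return pd.DataFrame(rows, columns=["state", "group_a", "group_b",
                                       "mean_a", "mean_b", "t", "p_value"])


def immune_state_correlation(mean_probs: pd.DataFrame,
                             fractions: pd.DataFrame,
                             samples: list | None = None) -> pd.DataFrame:
    """Correlate per-sample immune subtype fractions with state probabilities.

    ``mean_probs``: samples x states (per-sample mean state probability);
    ``fractions``: samples x immune subtypes (cell-fraction per sample).
    Returns Pearson r and an OLS fit (slope, intercept, slope SE, 95% CI)
    per (subtype, state); requires >= 3 shared samples. ``samples``
    optionally restricts the analysis (e.g. tumor-only).
    """
    import statsmodels.api as sm

    shared = mean_probs.index.intersection(fractions.index)
    if samples is not None:
        shared = shared.intersection(pd.Index(samples))
    if len(shared) < 3:
        raise ValueError("need >= 3 samples with both tables")
    rows = []
    for subtype in fractions.columns:
        fx = fractions.loc[shared, subtype].to_numpy(dtype=float)
        for state in mean_probs.columns:
            py = mean_probs.loc[shared, state].to_numpy(dtype=float)
            if np.std(fx) == 0 or np.std(py) == 0:
                rows.append({"subtype": subtype, "state": state,
                             "r": np.nan, "slope": np.nan,
                             "intercept": np.nan, "slope_se": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "p_value": np.nan, "n": len(shared)})
                continue
            r, _ = st.pearsonr(fx, py)
            fit = sm.OLS(py, sm.add_constant(fx)).fit()
            ci = fit.conf_int(alpha=0.05)
            rows.append({
                "subtype": subtype, "state": state, "r": float(r),
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "slope_se": float(fit.bse[1]),
                "ci_low": float(ci[1][0]), "ci_high": float(ci[1][1]),
                "p_value": float(fit.pvalues[1]), "n": len(shared),
            })
    return pd.DataFrame(rows)


def cross_species_score(norm: NormMatrix,
                        state_signatures: dict[str, list[str]],
                        orthologs: dict[str, str], *,
                        top_frac: float = 0.05, seed: int = 0
                        ) -> pd.DataFrame:
    """Score ortholog-mapped state signatures on another species' cells.

    Signatures losing more than half their genes in the one-to-one mapping
    trigger a warning; signatures mapping to nothing score NaN.
    """
    mapped: dict[str, list[str]] = {}
    for state, genes in state_signatures.items():
        hit = [orthologs[g] for g in genes if g in orthologs]
        if len(hit) < 0.5 * len(genes):
            warnings.warn(
                f"signature {state!r} lost {len(genes) - len(hit)}/"
                f"{len(genes)} genes in ortholog mapping")
        mapped[state] = hit if hit else ["__none__"]
    return sigmod.auc_score(norm, mapped, top_frac=top_frac, seed=seed)
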