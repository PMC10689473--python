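"""CODEX segmented-cell analysis: mixture denoising and neighborhoods.

Each channel's intensities are modeled as a two-component univariate
Gaussian mixture fit by EM; the lower-mean component is background, and
cells assigned to it (posterior of the signal component < 0.5) get a
denoised intensity of zero while the rest retain their raw value,
log1p-transformed. Neighborhood composition summarizes, for each reference
cell type, the average cell-type make-up of each cell's k nearest spatial
neighbors. Abundance differences between two samples are assessed with a
two-sample proportion test.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MixtureFit:
    means: tuple[float, float]  # (background, signal), ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    loglik_trace: list[float]
    converged: bool
    degenerate: bool


def fit_gmm2(x: np.ndarray, *, max_iter: int = 500, tol: float = 1e-8
             ) -> MixtureFit:
    """EM fit of a two-component univariate Gaussian mixture.

    Initialized at the 20th/80th percentiles with the pooled variance;
    the log-likelihood is asserted non-decreasing at every iteration.
    Degenerate fits (a component weight below 1e-3 or variance collapse)
    are flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError("need >= 50 finite intensities to fit the mixture")
    total_var = x.var()
    if total_var == 0:
        return MixtureFit((x[0], x[0]), (0.0, 0.0), (0.5, 0.5), [],
                          converged=False, degenerate=True)

    mu = np.array([np.percentile(x, 20), np.percentile(x, 80)])
    var = np.array([total_var, total_var])
    w = np.array([0.5, 0.5])
    trace: list[float] = []
    degenerate = False
    converged = False
    for _ in range(max_iter):
        log_comp = (np.log(w)[None, :]
                    - 0.5 * np.log(2 * np.pi * var)[None, :]
                    - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :])
        m = log_comp.max(axis=1, keepdims=True)
        log_mix = m.ravel() + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(log_mix.sum())
        if trace:
            # EM guarantees monotone log-likelihood up to rounding
            assert ll >= trace[-1] - 1e-8 * max(1.0, abs(trace[-1])), \
                "EM log-likelihood decreased"
            if abs(ll - trace[-1]) < tol:
                trace.append(ll)
                converged = True
                break
        trace.append(ll)
        resp = np.exp(log_comp - log_mix[:, None])
        nk = resp.sum(axis=0)
        if (nk / x.size < 1e-3).any():
            degenerate = True
            break
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if (var < 1e-12 * total_var).any():
            degenerate = True
            break
        w = nk / x.size
    order = np.argsort(mu)
    return MixtureFit(
        means=tuple(mu[order]), sds=tuple(np.sqrt(var[order])),
        weights=tuple(w[order]), loglik_trace=trace,
        converged=converged, degenerate=degenerate)


def gmm_denoise(table: pd.DataFrame, channel: str, *,
                log_transform: bool = True) -> tuple[pd.DataFrame, MixtureFit]:
    """Zero out background-assigned intensities of one channel.

    Cells whose posterior probability of the higher-mean (signal)
    component is below 0.5 get denoised intensity 0; the rest retain the
    raw value (log1p-transformed when ``log_transform``). A degenerate
    mixture fit falls back to retaining every cell, with a warning.
    """
    if channel not in table.columns:
        raise ValueError(f"channel column {channel!r} not in table")
    x = table[channel].to_numpy(dtype=float)
    fit = fit_gmm2(x)
    if fit.degenerate:
        warnings.warn(f"degenerate mixture fit for {channel}; "
                      "all intensities retained")
        retained = np.ones_like(x, dtype=bool)
    else:
        (m0, m1), (s0, s1), (w0, w1) = fit.means, fit.sds, fit.weights
        log_bg = np.log(w0) + st.norm.logpdf(x, m0, s0)
        log_sig = np.log(w1) + st.norm.logpdf(x, m1, s1)
        # posterior of the signal component; >= 0.5 retains the cell
        retained = log_sig >= log_bg
    denoised = np.where(retained, x, 0.0)
    if log_transform:
        denoised = np.log1p(denoised)
    out = table.copy()
    out[f"denoised_{channel}"] = denoised
    return out, fit


def denoise_all_channels(table: pd.DataFrame, *, log_transform: bool = True
                         ) -> tuple[pd.DataFrame, dict[str, MixtureFit]]:
    """Run ``gmm_denoise`` over every channel_* column."""
    fits = {}
    for ch in [c for c in table.columns if c.startswith("channel_")]:
        table, fits[ch] = gmm_denoise(table, ch, log_transform=log_transform)
    return table, fits


def neighborhood_composition(table: pd.DataFrame, k: int = 6,
                             type_column: str = "cell_type") -> pd.DataFrame:
    """Average neighbor-type composition of each cell type's k-NN.

    For each cell, its k nearest neighbors by Euclidean distance on (x, y)
    are found (self excluded, distance ties broken by row order / cell id);
    the matrix entry (reference type, neighbor type) is the mean fraction
    of that neighbor type around cells of the reference type. Rows sum
    to 1.
    """
    from sklearn.neighbors import NearestNeighbors

    if type_column not in table.columns:
        raise ValueError(f"table lacks type column {type_column!r}")
    if table[type_column].isna().any():
        raise ValueError("all cells must be labeled")
    n = len(table)
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    coords = table[["x", "y"]].to_numpy(dtype=float)
    labels = table[type_column].to_numpy()
    types = sorted(pd.unique(labels))
    t_index = {t: i for i, t in enumerate(types)}

    extra = min(n - 1, k + 5)  # headroom so ties can be re-broken stably
    nn = NearestNeighbors(n_neighbors=extra + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    comp = np.zeros((len(types), len(types)))
    counts = np.zeros(len(types))
    for i in range(n):
        cand = [(dist[i, j], idx[i, j]) for j in range(idx.shape[1])
                if idx[i, j] != i]
        cand.sort()  # (distance, cell id)
        neigh = [c[1] for c in cand[:k]]
        row = np.zeros(len(types))
        for j in neigh:
            row[t_index[labels[j]]] += 1
        comp[t_index[labels[i]]] += row / k
        counts[t_index[labels[i]]] += 1
    comp /= counts[:, None]
    return pd.DataFrame(comp, index=types, columns=types)


def fraction_test(counts_a: tuple[int, int], counts_b: tuple[int, int]
                  ) -> dict:
    """Two-sample proportion test: (hits, n) vs (hits, n).

    Chi-square with continuity correction; Fisher's exact test whenever
    any expected cell count is below 5. Two-sided.
    """
    ha, na = counts_a
    hb, nb = counts_b
    if na <= 0 or nb <= 0:
        raise ValueError("n must be positive in both groups")
    if ha > na or hb > nb:
        raise ValueError("hits cannot exceed n")
    tab = np.array([[ha, na - ha], [hb, nb - hb]], dtype=float)
    if ha / na == hb / nb:
        p = 1.0
        method = "identical"
    else:
        expected = st.contingency.expected_freq(tab)
        if (expected < 5).any():
            _, p = st.fisher_exact(tab.astype(int), alternative="two-sided")
            method = "fisher_exact"
        else:
            _, p, _, _ = st.chi2_contingency(tab, correction=True)
            method = "chi2_cc"
    return {"fraction_a": ha / na, "fraction_b": hb / nb,
            "p_value": float(p), "method": method}
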