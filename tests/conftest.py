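import numpy as np
import pytest

from tmecrosstalk import preprocess, synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """Two-patient cohort with three cell types; used across modules."""
    cfg = synthdata.SimConfig(
        n_patients=2, n_genes=400,
        cell_types={"epithelial": 30, "fibroblast": 20, "macrophage": 30},
        seed=101)
    counts, cells, truth = synthdata.simulate_counts(cfg)
    return cfg, counts, cells, truth


@pytest.fixture(scope="session")
def macrophage_scenario():
    """900 in-vivo macrophages per arm, three programs at fold 4."""
    cfg = synthdata.SimConfig(
        n_patients=1, n_genes=1000, cell_types={"macrophage": 900},
        state_fold=4.0, seed=55)
    counts, cells, truth = synthdata.simulate_counts(cfg)
    invivo = cells["tissue_class"].isin(["tumor", "normal_colon"]).to_numpy()
    sub = counts.subset_cells(invivo)
    norm = preprocess.normalize(sub)
    true_state = truth.state_weights.loc[list(sub.cell_ids)].idxmax(axis=1)
    return sub, norm, true_state


@pytest.fixture(scope="session")
def macrophage_states(macrophage_scenario):
    """Hard labels and signatures derived once for the state tests."""
    from tmecrosstalk import states

    sub, norm, true_state = macrophage_scenario
    clustering = preprocess.iff_cluster(norm, n_features=300, seed=0)
    hard, sigs = states.identify_states(sub, clustering.labels.to_numpy())
    return hard, sigs


@pytest.fixture(scope="session")
def crosstalk_run():
    """Planted receptor-ligand cohort and the mapped edges."""
    from tmecrosstalk import crosstalk

    cfg, rl = synthdata.crosstalk_scenario(seed=77)
    counts, cells, truth = synthdata.simulate_counts(cfg)
    edges, rl_lists = crosstalk.map_interactions(counts, cells, rl)
    return cfg, rl, counts, cells, truth, edges, rl_lists


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def build_qc_fixture():
    """12 cells with designed violations of each QC criterion.

    Thresholds scaled down (min_umi=50, min_genes=3, mito <= 0.20) so the
    fixture stays tiny; boundary semantics are what is under test. Gene 0
    is mitochondrial. Returns (CountMatrix, designed keep mask).
    """
    import scipy.sparse as sp

    from tmecrosstalk.io import CountMatrix

    designs = [(49, 4, 0.0, False),   # below UMI threshold
               (50, 4, 0.0, True),    # exactly at UMI threshold
               (200, 2, 0.0, False),  # too few expressed genes
               (200, 3, 0.0, True),   # exactly at gene threshold
               (200, 4, 0.25, False),  # mito fraction above 0.20
               (200, 4, 0.20, True),  # exactly at mito threshold
               (1000, 5, 0.1, True),
               (49, 2, 0.5, False),   # fails everything
               (60, 4, 0.0, True),
               (51, 3, 0.0, True),
               (200, 4, 0.21, False),
               (500, 6, 0.05, True)]
    cols, keep = [], []
    for total, n_expr, mito_frac, k in designs:
        col = np.zeros(6, dtype=int)
        mito = int(round(total * mito_frac))
        col[0] = mito
        rest = total - mito
        n_rest = n_expr - (1 if mito > 0 else 0)
        base = rest // n_rest
        col[1:1 + n_rest] = base
        col[1] += rest - base * n_rest
        cols.append(col)
        keep.append(k)
    cm = CountMatrix(sp.csr_matrix(np.stack(cols, axis=1)),
                     ["MT-ND1", "g1", "g2", "g3", "g4", "g5"],
                     [f"c{j}" for j in range(12)])
    return cm, np.array(keep)


@pytest.fixture
def qc_fixture():
    return build_qc_fixture()
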