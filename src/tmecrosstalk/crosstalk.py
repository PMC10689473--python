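"""Carcinoma-TME receptor-ligand interaction mapping and ECM correlations.

Per patient, genes significantly upregulated in carcinoma cells relative to
normal-adjacent epithelium (FDR < 0.05) are intersected with a curated
receptor-ligand database. For each upregulated epithelial receptor
(ligand), an interaction edge is emitted to every TME cell type whose
one-vs-rest differential expression marks the ligand (receptor) counterpart
as significantly upregulated. Receptors are ranked by patient support and
graph degree. A separate routine compares pairwise expression correlations
over a curated ECM network between two cell populations.
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

RECEPTOR_ON_EPITHELIUM = "receptor_on_epithelium"
LIGAND_ON_EPITHELIUM = "ligand_on_epithelium"


def upregulated_rl(de_per_patient: dict[str, pd.DataFrame], rl: RLDatabase,
                   *, alpha: float = 0.05, min_lfc: float = 0.0
                   ) -> dict[str, pd.DataFrame]:
    """Per-patient receptor/ligand genes upregulated in carcinoma cells.

    ``de_per_patient`` maps patient to a DE table (carcinoma vs
    normal-adjacent epithelium, group A = carcinoma). A gene qualifies when
    FDR < alpha, log2FC > min_lfc, and it appears in the database as a
    receptor or a ligand (possibly both).
    """
    receptors = rl.receptors
    ligands = rl.ligands
    out = {}
    for patient, de in de_per_patient.items():
        up = de[(de["tested"]) & (de["fdr"] < alpha)
                & (de["log2fc"] > min_lfc)]
        rows = []
        for gene in up["gene"]:
            if gene in receptors:
                rows.append({"gene": gene, "role": "receptor"})
            if gene in ligands:
                rows.append({"gene": gene, "role": "ligand"})
        out[patient] = pd.DataFrame(rows, columns=["gene", "role"])
    return out


def match_counterparts(rl_lists: dict[str, pd.DataFrame],
                       tme_de: dict[str, pd.DataFrame], rl: RLDatabase,
                       *, alpha: float = 0.05, min_lfc: float = 0.0
                       ) -> pd.DataFrame:
    """Emit interaction edges for epithelial RL genes with TME counterparts.

    For an epithelial receptor, an edge goes to every TME cell type whose
    one-vs-rest DE calls the paired ligand significantly upregulated (and
    symmetrically for epithelial ligands). ``n_patients`` counts the
    patients supporting the epithelial gene.
    """
    support: dict[tuple[str, str], set[str]] = {}
    for patient, table in rl_lists.items():
        for _, row in table.iterrows():
            support.setdefault((row["gene"], row["role"]), set()).add(patient)

    def tme_up(cell_type: str) -> set[str]:
        de = tme_de[cell_type]
        up = de[(de["tested"]) & (de["fdr"] < alpha)
                & (de["log2fc"] > min_lfc)]
        return set(up["gene"])

    tme_up_sets = {t: tme_up(t) for t in tme_de}
    rows = []
    for (gene, role), patients in sorted(support.items()):
        if role == "receptor":
            partners = rl.partners_of_receptor(gene)
            direction = RECEPTOR_ON_EPITHELIUM
        else:
            partners = rl.partners_of_ligand(gene)
            direction = LIGAND_ON_EPITHELIUM
        for partner in partners:
            for cell_type, up_genes in tme_up_sets.items():
                if partner in up_genes:
                    rows.append({
                        "epithelial_gene": gene,
                        "partner_gene": partner,
                        "tme_type": cell_type,
                        "n_patients": len(patients),
                        "patients": ",".join(sorted(patients)),
                        "direction": direction,
                    })
    return pd.DataFrame(rows, columns=[
        "epithelial_gene", "partner_gene", "tme_type", "n_patients",
        "patients", "direction"])


def map_interactions(counts, cells: pd.DataFrame, rl: RLDatabase, *,
                     alpha: float = 0.05, min_lfc: float = 0.0,
                     epithelial_type: str = "epithelial",
                     tumor_tissue: str = "tumor",
                     control_tissue: str = "normal_colon"
                     ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """End-to-end interaction mapping on a cohort count matrix.

    Runs per-patient carcinoma-vs-normal-epithelium sSeq DE, one-vs-rest DE
    over tumor TME cell types, and counterpart matching. Patients lacking
    either tissue are skipped with a warning. Returns the edge table and
    the per-patient epithelial up-lists.
    """
    from tmecrosstalk import diffexp

    tissue = cells["tissue_class"].to_numpy()
    ctype = cells["coarse_type"].to_numpy()
    patient = cells["patient"].to_numpy()
    de_pp = {}
    for p in pd.unique(patient):
        carc = (patient == p) & (tissue == tumor_tissue) & \
            (ctype == epithelial_type)
        ctrl = (patient == p) & (tissue == control_tissue) & \
            (ctype == epithelial_type)
        if carc.sum() == 0 or ctrl.sum() == 0:
            log.warning("patient %s lacks paired tissue; skipped", p)
            continue
        de_pp[p] = diffexp.sseq_test(counts, carc, ctrl, alpha=alpha,
                                     lfc_min=min_lfc)
    rl_lists = upregulated_rl(de_pp, rl, alpha=alpha, min_lfc=min_lfc)
    tme = (ctype != epithelial_type) & (tissue == tumor_tissue)
    tme_de = diffexp.one_vs_rest(counts.subset_cells(tme), ctype[tme],
                                 alpha=alpha, lfc_min=min_lfc)
    edges = match_counterparts(rl_lists, tme_de, rl, alpha=alpha,
                               min_lfc=min_lfc)
    return edges, rl_lists


def rank_receptors(edges: pd.DataFrame) -> pd.DataFrame:
    """Rank epithelial receptors by (n_patients desc, degree desc, gene asc).

    Degree is the number of distinct (partner gene, TME type) pairs.
    """
    rec = edges[edges["direction"] == RECEPTOR_ON_EPITHELIUM]
    if rec.empty:
        return pd.DataFrame(columns=["gene", "n_patients", "degree"])
    grouped = rec.groupby("epithelial_gene").agg(
        n_patients=("n_patients", "max"),
        degree=("partner_gene", "size"),
    ).reset_index().rename(columns={"epithelial_gene": "gene"})
    return grouped.sort_values(
        ["n_patients", "degree", "gene"],
        ascending=[False, False, True]).reset_index(drop=True)


def species_overlap(edges_a: pd.DataFrame, edges_b: pd.DataFrame,
                    orthologs: dict[str, str]) -> dict:
    """Overlap of epithelial receptors and ligands across two species.

    ``orthologs`` maps species-A symbols to species-B symbols (one-to-one
    rows only; ambiguous genes were dropped at read time). Species-A genes
    without an ortholog cannot be shared.
    """
    def genes(edges: pd.DataFrame, direction: str) -> set[str]:
        return set(edges.loc[edges["direction"] == direction,
                             "epithelial_gene"])

    out = {}
    for label, direction in (("receptors", RECEPTOR_ON_EPITHELIUM),
                             ("ligands", LIGAND_ON_EPITHELIUM)):
        a = genes(edges_a, direction)
        b = genes(edges_b, direction)
        mapped = {orthologs[g] for g in a if g in orthologs}
        shared = mapped & b
        out[label] = {
            "a_only": len(a) - len(shared),
            "b_only": len(b - shared),
            "shared": len(shared),
            "shared_genes": sorted(shared),
        }
    return out


@dataclasses.dataclass
class EcmCorrelationResult:
    edges: pd.DataFrame  # gene_a, gene_b, r_a, r_b, n_a, n_b
    statistic: float  # one-sided Wilcoxon statistic on |r_a| - |r_b|
    p_value: float


def ecm_network_corr(norm: NormMatrix, cells_a, cells_b,
                     ecm_edges: list[tuple[str, str]]) -> EcmCorrelationResult:
    """Pairwise Pearson correlations over an ECM network in two conditions.

    For each network edge, Pearson r is computed among the cells of each
    condition; the summary is a paired one-sided Wilcoxon signed-rank test
    that |r| in condition A exceeds condition B. Edges touching a
    zero-variance gene in either condition are excluded from the summary.
    """
    a = norm.subset_cells(_mask_to_idx(cells_a, norm.n_cells))
    b = norm.subset_cells(_mask_to_idx(cells_b, norm.n_cells))
    if a.n_cells < 3 or b.n_cells < 3:
        raise ValueError("need >= 3 cells per condition")
    lookup = {g: i for i, g in enumerate(norm.gene_ids)}

    def corr(sub: NormMatrix, g1: str, g2: str) -> float:
        x = sub.values[lookup[g1]]
        y = sub.values[lookup[g2]]
        if x.std() == 0 or y.std() == 0:
            return np.nan
        if g1 == g2:
            return 1.0
        return float(np.corrcoef(x, y)[0, 1])

    rows = []
    for g1, g2 in ecm_edges:
        if g1 not in lookup or g2 not in lookup:
            log.info("ECM edge (%s, %s) not in gene universe; skipped", g1, g2)
            continue
        rows.append({
            "gene_a": g1, "gene_b": g2,
            "r_a": corr(a, g1, g2), "r_b": corr(b, g1, g2),
            "n_a": a.n_cells, "n_b": b.n_cells,
        })
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r_a", "r_b",
                                        "n_a", "n_b"])
    valid = table.dropna(subset=["r_a", "r_b"])
    diffs = valid["r_a"].abs() - valid["r_b"].abs()
    diffs = diffs[diffs != 0]
    if len(diffs) < 5:
        stat, p = np.nan, np.nan
    else:
        stat, p = st.wilcoxon(diffs, alternative="greater")
    return EcmCorrelationResult(edges=table, statistic=float(stat),
                                p_value=float(p))


def _mask_to_idx(group, n: int) -> np.ndarray:
    idx = np.asarray(group)
    if idx.dtype == bool:
        if idx.shape[0] != n:
            raise ValueError("mask length mismatch")
        return np.flatnonzero(idx)
    return idx.astype(int)
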