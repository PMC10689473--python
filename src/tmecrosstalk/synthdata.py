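"""Synthetic single-cell and CODEX data with planted ground truth.

The generator emulates the structure of a patient-cohort colorectal-cancer
single-cell study: negative-binomial UMI counts over ~10 coarse cell types
with patient-paired tumor / normal-adjacent / tumoroid / organoid arms,
three macrophage expression programs (IL1B+/SPP1+/C1QC+), planted
carcinoma-upregulated receptor/ligand genes with TME counterparts, a
paired in-vitro arm whose per-gene log2 fold changes follow the in-vivo
ones with a configurable attenuation slope, and CODEX-like segmented cells
whose channel intensities come from a two-component (background/signal)
Gaussian mixture with spatially clustered cell types.

Counts follow the NB parameterization variance = mu + phi * mu^2 so that
the differential-expression machinery can be validated directly against
the generator's moments. Planted effects act multiplicatively on means
before library-size scaling, which makes the true log2 fold change exactly
the configured effect.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tmecrosstalk.io import CountMatrix

MACROPHAGE_STATES = ("IL1B", "SPP1", "C1QC")


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclasses.dataclass
class PlantedInteraction:
    """A receptor-ligand pair upregulated on carcinoma cells of some patients.

    ``epithelial_gene`` carries the planted log2 effect in carcinoma cells of
    ``patients``; ``partner_gene`` is made a marker of ``tme_type`` so that
    the TME side of the interaction is recoverable by one-vs-rest DE.
    """

    epithelial_gene: str
    partner_gene: str
    tme_type: str
    patients: tuple[int, ...]
    log2_effect: float = 2.0
    direction: str = "receptor_on_epithelium"


@dataclasses.dataclass
class CodexConfig:
    """Parameters of the CODEX-like segmented-cell simulation."""

    n_cells_per_type: int = 500
    cell_types: tuple[str, ...] = ("epithelial", "macrophage", "t_cell")
    # channel c is the marker of cell type c (one marker channel per type)
    mu_bg: float = 1.0
    sigma_bg: float = 0.2
    mu_sig: float = 5.0
    sigma_sig: float = 0.2
    marker_weight: float = 1.0  # P(cell of type t expresses its marker)
    cluster_scale: float = 30.0  # spatial SD of each type's Gaussian cluster
    field_size: float = 1000.0  # square field side, image units

    def validate(self) -> None:
        if self.mu_bg >= self.mu_sig:
            raise ConfigError("mixture means must satisfy mu_bg < mu_sig")
        if self.sigma_bg <= 0 or self.sigma_sig <= 0 or self.cluster_scale <= 0:
            raise ConfigError("sigmas and cluster scale must be positive")
        if not 0 <= self.marker_weight <= 1:
            raise ConfigError("marker weight must be in [0, 1]")
        if self.n_cells_per_type <= 0:
            raise ConfigError("n_cells_per_type must be positive")


@dataclasses.dataclass
class SimConfig:
    """Configuration of the cohort-structured count simulation.

    Defaults describe a small but realistic desk-scale cohort: 5 patients,
    2,000 genes, ~10 coarse cell types per tissue arm, NB dispersion 0.1,
    two-fold library-size spread, and macrophage programs at fold 4.
    """

    n_patients: int = 5
    cell_types: dict[str, int] = dataclasses.field(default_factory=lambda: {
        "epithelial": 60,
        "fibroblast": 30,
        "myofibroblast": 15,
        "endothelial": 15,
        "t_cell": 40,
        "b_cell": 20,
        "plasma": 15,
        "macrophage": 45,
        "dendritic": 15,
        "mast": 10,
    })  # cells per type, per patient, per tissue arm
    n_genes: int = 2000
    baseline_mean: np.ndarray | None = None  # per-gene; default drawn log-normal
    dispersion: float | np.ndarray = 0.1  # NB phi, variance = mu + phi mu^2
    libsize_range: tuple[float, float] = (0.5, 2.0)
    n_markers_per_type: int = 25
    type_fold: float = 8.0
    state_programs: dict[str, tuple[list[str], float]] | None = None
    state_program_size: int = 30  # used when state_programs is None
    state_fold: float = 4.0
    planted_rl: list[PlantedInteraction] = dataclasses.field(default_factory=list)
    counterpart_fold: float = 4.0  # TME-side marker fold for planted partners
    tumor_de_frac: float = 0.10  # fraction of genes with a random tumor effect
    tumor_effect_sd: float = 1.5  # SD of those log2 effects
    invitro_slope: float = 0.6
    invitro_noise_sd: float = 0.2
    codex: CodexConfig = dataclasses.field(default_factory=CodexConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise ConfigError("counts must be positive")
        if any(n <= 0 for n in self.cell_types.values()):
            raise ConfigError("per-type cell counts must be positive")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigError("libsize_range must be a positive interval")
        if not 0 < self.invitro_slope <= 1:
            raise ConfigError("invitro_slope must be in (0, 1]")
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp < 0).any():
            raise ConfigError("dispersion must be >= 0")
        self.codex.validate()


@dataclasses.dataclass
class SimTruth:
    """Planted ground truth for every downstream stage."""

    cell_type: pd.Series  # per-cell true type
    state_weights: pd.DataFrame  # macrophages x states, rows sum to 1
    tumor_log2_effect: pd.Series  # per-gene carcinoma-vs-normal effect
    state_log2_effect: pd.DataFrame  # genes x states
    rl_edges: list[PlantedInteraction]
    invitro_slope: float
    lfc_invivo: pd.Series  # true per-gene in-vivo log2 FC (tumor vs normal)
    lfc_invitro: pd.Series  # true per-gene in-vitro log2 FC
    codex_params: CodexConfig | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               phi: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + phi mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, phi[~pois] * mean[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Generate the cohort count matrix, cell metadata, and planted truth.

    Four tissue arms per patient are produced: ``tumor`` and ``normal_colon``
    (in vivo, all cell types) and ``tumoroid`` / ``organoid`` (in vitro,
    epithelial only). Carcinoma cells are the epithelial cells of tumor
    samples.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_cells, rng_counts = [
        np.random.default_rng(s) for s in ss.spawn(3)]

    genes = _gene_ids(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    if cfg.baseline_mean is None:
        baseline = np.exp(rng_genes.normal(-1.0, 1.0, size=cfg.n_genes))
    else:
        baseline = np.asarray(cfg.baseline_mean, dtype=float)
        if baseline.shape != (cfg.n_genes,):
            raise ConfigError("baseline_mean length must equal n_genes")
        if (baseline <= 0).any():
            raise ConfigError("baseline means must be positive")
    phi = np.broadcast_to(
        np.asarray(cfg.dispersion, dtype=float), (cfg.n_genes,))

    type_names = list(cfg.cell_types)
    # disjoint marker blocks per type, taken from the front of the universe
    type_markers: dict[str, np.ndarray] = {}
    cursor = 0
    for t in type_names:
        type_markers[t] = np.arange(cursor, cursor + cfg.n_markers_per_type)
        cursor += cfg.n_markers_per_type
    if cursor > cfg.n_genes:
        raise ConfigError("not enough genes for per-type marker blocks")

    # macrophage state programs; the hallmark gene heads its own program,
    # so IL1B/SPP1/C1QC are real members of the gene universe
    if cfg.state_programs is None:
        programs = {}
        for k, state in enumerate(MACROPHAGE_STATES):
            idx = np.arange(cursor + k * cfg.state_program_size,
                            cursor + (k + 1) * cfg.state_program_size)
            if idx[-1] >= cfg.n_genes:
                raise ConfigError("not enough genes for state programs")
            genes[idx[0]] = state
            programs[state] = ([genes[i] for i in idx], cfg.state_fold)
        gene_pos = {g: i for i, g in enumerate(genes)}
    else:
        programs = dict(cfg.state_programs)
        for state, (members, _) in programs.items():
            missing = [g for g in members if g not in gene_pos]
            if missing:
                raise ConfigError(
                    f"state {state!r} signature genes not in gene universe: "
                    f"{missing[:5]}")
    state_names = list(programs)
    state_effect = pd.DataFrame(
        0.0, index=genes, columns=state_names)
    for state, (members, fold) in programs.items():
        state_effect.loc[members, state] = np.log2(fold)

    # random carcinoma-vs-normal effects (beyond the planted RL genes)
    n_de = int(round(cfg.tumor_de_frac * cfg.n_genes))
    tumor_effect = np.zeros(cfg.n_genes)
    de_idx = rng_genes.choice(cfg.n_genes, size=n_de, replace=False)
    tumor_effect[de_idx] = rng_genes.normal(0, cfg.tumor_effect_sd, size=n_de)
    # planted RL epithelial genes override the random effect
    for edge in cfg.planted_rl:
        for g in (edge.epithelial_gene, edge.partner_gene):
            if g not in gene_pos:
                raise ConfigError(f"planted gene {g!r} not in gene universe")
        tumor_effect[gene_pos[edge.epithelial_gene]] = 0.0  # patient-specific below

    # in-vitro effect: attenuated in-vivo effect plus gene-level noise
    invitro_effect = (cfg.invitro_slope * tumor_effect
                      + rng_genes.normal(0, cfg.invitro_noise_sd,
                                         size=cfg.n_genes))

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    state_rows: list[tuple[str, str]] = []

    def type_mean(cell_type: str) -> np.ndarray:
        m = baseline.copy()
        m[type_markers[cell_type]] *= cfg.type_fold
        return m

    def emit(patient: int, tissue: str, cell_type: str, mean: np.ndarray,
             n: int, state: str | None = None) -> None:
        lo, hi = cfg.libsize_range
        libs = np.exp(rng_cells.uniform(np.log(lo), np.log(hi), size=n))
        grp = _nb_counts(rng_counts, np.outer(mean, libs), phi[:, None])
        blocks.append(grp)
        for j in range(n):
            cid = f"P{patient}_{tissue}_{cell_type}_{len(meta_rows):06d}"
            meta_rows.append({
                "cell_id": cid,
                "sample": f"P{patient}_{tissue}",
                "patient": f"P{patient}",
                "tissue_class": tissue,
                "coarse_type": cell_type,
            })
            if state is not None:
                state_rows.append((cid, state))

    for p in range(cfg.n_patients):
        for tissue in ("tumor", "normal_colon"):
            is_tumor = tissue == "tumor"
            for cell_type, n in cfg.cell_types.items():
                base = type_mean(cell_type)
                if cell_type == "epithelial" and is_tumor:
                    eff = tumor_effect.copy()
                    for edge in cfg.planted_rl:
                        if p in edge.patients:
                            eff[gene_pos[edge.epithelial_gene]] = edge.log2_effect
                    base = base * 2.0 ** eff
                if cell_type != "epithelial":
                    # TME-side counterparts are markers of their cell type
                    for edge in cfg.planted_rl:
                        if edge.tme_type == cell_type:
                            base = base.copy()
                            base[gene_pos[edge.partner_gene]] *= cfg.counterpart_fold
                if cell_type == "macrophage":
                    # split macrophages across the three planted programs
                    splits = np.array_split(np.arange(n), len(state_names))
                    for state, idx in zip(state_names, splits):
                        if len(idx) == 0:
                            continue
                        m = base * 2.0 ** state_effect[state].to_numpy()
                        emit(p, tissue, cell_type, m, len(idx), state=state)
                else:
                    emit(p, tissue, cell_type, base, n)
        # in-vitro arms: epithelial cells only
        n_epi = cfg.cell_types.get("epithelial", 0)
        if n_epi:
            emit(p, "organoid", "epithelial", type_mean("epithelial"), n_epi)
            emit(p, "tumoroid", "epithelial",
                 type_mean("epithelial") * 2.0 ** invitro_effect, n_epi)

    matrix = sp.csr_matrix(np.concatenate(blocks, axis=1))
    cells = pd.DataFrame(meta_rows)
    counts = CountMatrix(matrix, genes, cells["cell_id"].tolist())

    weights = pd.DataFrame(
        0.0, index=[cid for cid, _ in state_rows], columns=state_names)
    for cid, state in state_rows:
        weights.loc[cid, state] = 1.0

    truth = SimTruth(
        cell_type=cells.set_index("cell_id")["coarse_type"],
        state_weights=weights,
        tumor_log2_effect=pd.Series(tumor_effect, index=genes),
        state_log2_effect=state_effect,
        rl_edges=list(cfg.planted_rl),
        invitro_slope=cfg.invitro_slope,
        lfc_invivo=pd.Series(tumor_effect, index=genes),
        lfc_invitro=pd.Series(invitro_effect, index=genes),
    )
    return counts, cells, truth


def simulate_codex(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a CODEX-like segmented-cell table.

    Each cell type occupies a Gaussian spatial cluster in a square field;
    channel ``channel_<type>`` intensities come from the signal component
    N(mu_sig, sigma_sig^2) for cells of the matching type (with probability
    ``marker_weight``) and from the background component otherwise.
    """
    cfg.codex.validate()
    cx = cfg.codex
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])

    types = list(cx.cell_types)
    k = len(types)
    # well-separated cluster centers on a regular grid
    side = int(np.ceil(np.sqrt(k)))
    centers = [
        ((i % side + 0.5) * cx.field_size / side,
         (i // side + 0.5) * cx.field_size / side)
        for i in range(k)
    ]
    rows = []
    for t, (cx0, cy0) in zip(types, centers):
        xs = rng.normal(cx0, cx.cluster_scale, size=cx.n_cells_per_type)
        ys = rng.normal(cy0, cx.cluster_scale, size=cx.n_cells_per_type)
        express = rng.random((cx.n_cells_per_type, k)) < np.where(
            np.array(types) == t, cx.marker_weight, 0.0)
        intens = np.where(
            express,
            rng.normal(cx.mu_sig, cx.sigma_sig, size=(cx.n_cells_per_type, k)),
            rng.normal(cx.mu_bg, cx.sigma_bg, size=(cx.n_cells_per_type, k)),
        )
        intens = np.clip(intens, 0.0, None)
        for j in range(cx.n_cells_per_type):
            row = {"cell_id": f"{t}_{j:05d}", "x": xs[j], "y": ys[j],
                   "cell_type": t}
            for c, ch in enumerate(types):
                row[f"channel_{ch}"] = intens[j, c]
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = SimTruth(
        cell_type=table.set_index("cell_id")["cell_type"],
        state_weights=pd.DataFrame(),
        tumor_log2_effect=pd.Series(dtype=float),
        state_log2_effect=pd.DataFrame(),
        rl_edges=[],
        invitro_slope=cfg.invitro_slope,
        lfc_invivo=pd.Series(dtype=float),
        lfc_invitro=pd.Series(dtype=float),
        codex_params=cx,
    )
    return table, truth


def simulate_null_counts(n_genes: int, mu: float, phi: float,
                         n_a: int, n_b: int, seed: int
                         ) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Two groups of NB counts with identical per-gene means (null data).

    Returns the count matrix plus boolean masks for the two groups; used for
    type-I-error calibration of the differential-expression test.
    """
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    mean = np.full((n_genes, n), float(mu))
    counts = _nb_counts(rng, mean, np.full((n_genes, 1), float(phi)))
    cm = CountMatrix(sp.csr_matrix(counts), _gene_ids(n_genes),
                     [f"C{i:05d}" for i in range(n)])
    group_a = np.zeros(n, dtype=bool)
    group_a[:n_a] = True
    return cm, group_a, ~group_a


def crosstalk_scenario(seed: int, *, n_patients: int = 5,
                       n_planted: int = 10, log2_effect: float = 2.0,
                       n_genes: int = 2000, n_decoys: int = 20
                       ) -> tuple[SimConfig, "RLDatabaseLike"]:
    """A cohort with planted receptor-ligand interactions and a matching
    database of planted plus decoy pairs.

    Epithelial genes are drawn from the moderately expressed part of the
    transcriptome (baseline mean in [0.5, 2]) so that per-patient power
    reflects the planted effect rather than dropout. Patient subsets cycle
    through sizes 1..n_patients. Random background tumor effects are
    disabled so that the planted edges are the only true interactions.
    """
    from tmecrosstalk.io import RLDatabase

    rng = np.random.default_rng(seed)
    baseline = np.exp(rng.normal(-1.0, 1.0, size=n_genes))
    genes = _gene_ids(n_genes)
    tme_types = ("fibroblast", "t_cell", "macrophage", "endothelial")
    # reserve the front of the universe for type markers / state programs
    reserved = 10 * 25 + 3 * 30
    eligible = [i for i in range(reserved, n_genes)
                if 0.5 <= baseline[i] <= 2.0]
    picked = rng.choice(eligible, size=2 * (n_planted + n_decoys),
                        replace=False)
    planted = []
    pairs = []
    for i in range(n_planted):
        ep, partner = genes[picked[2 * i]], genes[picked[2 * i + 1]]
        n_aff = (i % n_patients) + 1
        direction = ("receptor_on_epithelium" if i % 2 == 0
                     else "ligand_on_epithelium")
        planted.append(PlantedInteraction(
            epithelial_gene=ep, partner_gene=partner,
            tme_type=tme_types[i % len(tme_types)],
            patients=tuple(range(n_aff)), log2_effect=log2_effect,
            direction=direction))
        pairs.append((ep, partner) if direction == "receptor_on_epithelium"
                     else (partner, ep))
    for j in range(n_decoys):
        a = genes[picked[2 * (n_planted + j)]]
        b = genes[picked[2 * (n_planted + j) + 1]]
        pairs.append((a, b))
    cfg = SimConfig(n_patients=n_patients, n_genes=n_genes,
                    baseline_mean=baseline, planted_rl=planted,
                    tumor_de_frac=0.0, seed=seed)
    return cfg, RLDatabase(pairs)


def simulate_lfc_pairs(n_genes: int, slope: float, noise_sd: float,
                       rl_frac: float, seed: int,
                       rl_slope: float | None = None) -> pd.DataFrame:
    """Paired in-vivo / in-vitro log2 fold changes with a known slope.

    In-vivo LFCs are N(0, 1.5^2); in-vitro LFCs are ``slope`` times the
    in-vivo value plus N(0, noise_sd^2) noise. A fraction ``rl_frac`` of
    genes is flagged as receptor/ligand; if ``rl_slope`` is given, that
    subset follows its own slope (otherwise the global one).
    """
    rng = np.random.default_rng(seed)
    lfc_vivo = rng.normal(0, 1.5, size=n_genes)
    is_rl = rng.random(n_genes) < rl_frac
    slopes = np.where(is_rl & (rl_slope is not None),
                      rl_slope if rl_slope is not None else slope, slope)
    lfc_vitro = slopes * lfc_vivo + rng.normal(0, noise_sd, size=n_genes)
    return pd.DataFrame({
        "gene": _gene_ids(n_genes),
        "lfc_invivo": lfc_vivo,
        "lfc_invitro": lfc_vitro,
        "is_rl": is_rl,
    })
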