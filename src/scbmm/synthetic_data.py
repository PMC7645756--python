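"""Multi-timepoint scRNA-seq count simulator with planted ground truth.

The generator emulates a 5-timepoint bone-marrow time course (D0, D3,
D6, D9, D12): ~10-17 cell types whose proportions shift over time (with
depletion of most types at the final day), negative-binomial counts
(Gamma-Poisson with a global dispersion), lognormal library sizes,
planted cell-type marker genes, planted differentially expressed genes
in chosen (cell type, timepoint) slots, ligand-receptor channels that
are "on" (expressed fraction >= 0.5 in sender/receiver types) only at
chosen timepoints, and spliced/unspliced layers with a known per-gene
steady-state ratio gamma for velocity recovery tests.

Everything is deterministic given the config seed, and the planted
structure is returned as a :class:`SimTruth` so every downstream stage
can be scored against the truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix, flag_mito_genes

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_timecourse",
    "simulate_velocity_layers",
    "write_truth",
    "read_truth",
    "study_scale_config",
]

# Bernoulli expression probabilities used to force ligand/receptor channel
# state.  With >= 50 cells per type these keep the realized expressed
# fraction >= 0.5 (active) / <= 0.05 (inactive) with probability >= 0.99.
LR_ON_PROB = 0.70
LR_OFF_PROB = 0.005


@dataclass
class DESpec:
    """One planted differential-expression slot."""

    cell_type: str
    timepoint: str
    gene_count: int
    log_fold: float  # natural log, applied at `timepoint` relative to baseline
    direction: str = "over"  # "over" multiplies by exp(+|lf|), "under" by exp(-|lf|)


@dataclass
class LRSpec:
    """One planted ligand-receptor channel."""

    ligand_gene: str
    receptor_gene: str
    sender_types: list[str]
    receiver_types: list[str]
    active_timepoints: list[str]


@dataclass
class VelocitySpec:
    n_velocity_genes: int = 60
    gamma_range: tuple[float, float] = (0.2, 2.0)
    noise_sd: float = 0.1  # lognormal sd on the Poisson rate; 0 = expectation mode


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the profiled time course: five sampling days, the
    per-day post-QC cell counts, ~14,000 genes, and progenitor-heavy
    composition that collapses at the last day.  Tests use smaller
    explicit values; the defaults document the real-data scale.
    """

    timepoints: tuple[str, ...] = ("D0", "D3", "D6", "D9", "D12")
    cells_per_timepoint: tuple[int, ...] = (6079, 4405, 5137, 6561, 4378)
    n_genes: int = 14000
    cell_types: tuple[str, ...] = (
        "Neutrophils",
        "Monocytes",
        "B cells",
        "pro- and pre-B",
        "T cells",
        "NK cells",
        "Dendritic cells",
        "GMP",
        "MDP",
        "ST-HSC & MLP",
    )
    # proportions per timepoint: rows = timepoints, cols = cell types.
    # None -> uniform except the last timepoint, where most types are
    # depleted in favor of the first (most abundant) type.
    proportions: tuple[tuple[float, ...], ...] | None = None
    n_marker_genes_per_type: int = 10
    marker_fold: float = 20.0
    # out-of-type mean count for marker genes: low enough that most other
    # cells are silent, so markers pass percent-expressed difference filters
    marker_base_mean: float = 0.15
    de_spec: tuple[DESpec, ...] = ()
    lr_spec: tuple[LRSpec, ...] = ()
    mito_fraction_genes: float = 0.005
    dispersion: float = 0.3
    depth_mean_log: float = np.log(3000.0)
    depth_sd_log: float = 0.25
    base_mean_log: float = -1.0  # lognormal location of per-gene baseline rates
    base_sd_log: float = 1.2
    velocity_spec: VelocitySpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce plain dicts/lists (e.g. from a JSON/YAML config file)
        self.timepoints = tuple(self.timepoints)
        self.cells_per_timepoint = tuple(self.cells_per_timepoint)
        self.cell_types = tuple(self.cell_types)
        if self.proportions is not None:
            self.proportions = tuple(tuple(row) for row in self.proportions)
        self.de_spec = tuple(
            s if isinstance(s, DESpec) else DESpec(**s) for s in self.de_spec
        )
        self.lr_spec = tuple(
            s if isinstance(s, LRSpec) else LRSpec(**s) for s in self.lr_spec
        )
        if self.velocity_spec is not None and not isinstance(self.velocity_spec, VelocitySpec):
            self.velocity_spec = VelocitySpec(**self.velocity_spec)
        if isinstance(self.velocity_spec, VelocitySpec):
            self.velocity_spec.gamma_range = tuple(self.velocity_spec.gamma_range)
        if len(self.cells_per_timepoint) != len(self.timepoints):
            raise ValueError("cells_per_timepoint length != number of timepoints")

    def resolved_proportions(self) -> np.ndarray:
        k = len(self.cell_types)
        t = len(self.timepoints)
        if self.proportions is not None:
            props = np.asarray(self.proportions, dtype=float)
        else:
            props = np.full((t, k), 1.0 / k)
            # depletion at the final timepoint: dominant type takes over
            last = np.full(k, 0.03)
            last[0] = 1.0 - 0.03 * (k - 1)
            props[-1] = last
        if props.shape != (t, k):
            raise ValueError(f"proportions shape {props.shape} != ({t}, {k})")
        if not np.allclose(props.sum(axis=1), 1.0):
            raise ValueError("cell-type proportions must sum to 1 per timepoint")
        return props

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class SimTruth:
    """Planted ground truth for scoring downstream recovery."""

    cell_type_of: dict[str, str] = field(default_factory=dict)
    markers: dict[str, list[str]] = field(default_factory=dict)
    de_truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cell_type", "timepoint", "gene", "log_fold"]
        )
    )
    active_channels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["ligand", "receptor", "sender", "receiver", "timepoint"]
        )
    )
    gamma_truth: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    config_hash: str = ""


def study_scale_config(**overrides) -> SimConfig:
    """The default, study-scale configuration (convenience constructor)."""
    return SimConfig(**overrides)


def _gene_names(n_genes: int, n_mito: int) -> list[str]:
    names = [f"Gene{i:05d}" for i in range(n_genes - n_mito)]
    names += [f"mt-Sim{i}" for i in range(n_mito)]
    return names


def _assign_special_genes(
    config: SimConfig, genes: list[str], base: np.ndarray, rng: np.random.Generator
):
    """Reserve disjoint gene groups: markers, DE genes, LR genes, velocity genes.

    LR genes named in lr_spec must already exist in `genes`.  Marker, DE
    and velocity genes are drawn from the detectably expressed part of
    the baseline distribution (above its 60th percentile): planted
    effects on near-silent genes would measure detection limits, not
    method behavior.
    """
    lr_genes = set()
    for ch in config.lr_spec:
        lr_genes.add(ch.ligand_gene)
        lr_genes.add(ch.receptor_gene)
    missing = lr_genes - set(genes)
    if missing:
        raise ValueError(f"lr_spec names genes absent from the simulation: {sorted(missing)}")

    floor = float(np.quantile(base, 0.60))
    pool = [
        g
        for g, b in zip(genes, base)
        if not g.startswith("mt-") and g not in lr_genes and b >= floor
    ]
    rng.shuffle(pool)
    cursor = 0

    markers: dict[str, list[str]] = {}
    for ct in config.cell_types:
        markers[ct] = pool[cursor : cursor + config.n_marker_genes_per_type]
        cursor += config.n_marker_genes_per_type

    de_assign: list[tuple[DESpec, list[str]]] = []
    for spec in config.de_spec:
        chosen = pool[cursor : cursor + spec.gene_count]
        cursor += spec.gene_count
        de_assign.append((spec, chosen))

    if cursor > len(pool):
        raise ValueError("not enough genes for the requested markers/DE slots")

    velocity_genes: list[str] = []
    if config.velocity_spec is not None:
        nv = config.velocity_spec.n_velocity_genes
        velocity_genes = pool[cursor : cursor + nv]
        cursor += nv
        if cursor > len(pool):
            raise ValueError("not enough genes for the requested velocity genes")

    return markers, de_assign, sorted(lr_genes), velocity_genes


def simulate_timecourse(config: SimConfig) -> tuple[list[CountMatrix], SimTruth]:
    """Draw one CountMatrix per timepoint plus the planted truth.

    Counts are Gamma-Poisson: per-gene baseline rates are lognormal,
    multiplied by planted marker / DE fold factors, scaled by a
    lognormal per-cell depth factor, then passed through a Gamma
    (shape 1/dispersion) mixing variable and a Poisson draw.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    props = config.resolved_proportions()

    n_mito = max(1, int(round(config.mito_fraction_genes * config.n_genes)))
    genes = _gene_names(config.n_genes, n_mito)
    gene_index = {g: i for i, g in enumerate(genes)}

    # baseline per-gene relative rates (shared across timepoints)
    base = rng.lognormal(config.base_mean_log, config.base_sd_log, size=config.n_genes)
    base /= base.sum()
    # mito genes get a modest constant share so mito fractions are nonzero
    mito_idx = np.array([i for i, g in enumerate(genes) if g.startswith("mt-")])
    base[mito_idx] = base.mean() * 5

    markers, de_assign, lr_genes, velocity_genes = _assign_special_genes(
        config, genes, base, rng
    )

    # marker genes: low baseline everywhere (most non-type cells silent),
    # multiplied by marker_fold inside their own type
    mean_depth = float(np.exp(config.depth_mean_log + config.depth_sd_log**2 / 2))
    marker_rate = config.marker_base_mean / mean_depth
    for ms in markers.values():
        for mg in ms:
            base[gene_index[mg]] = marker_rate

    # LR-channel genes are driven by Bernoulli presence, not the NB rate:
    # zero out their baseline so channel state is fully controlled.
    lr_idx = np.array([gene_index[g] for g in lr_genes], dtype=int)
    if len(lr_idx):
        base[lr_idx] = 0.0

    # velocity genes get boosted baseline so the gamma fit has signal
    vel_idx = np.array([gene_index[g] for g in velocity_genes], dtype=int)
    if len(vel_idx):
        base[vel_idx] = np.quantile(base[base > 0], 0.98)

    # per-channel activity lookup: (gene, type, timepoint) -> on/off
    def _channel_prob(gene: str, ct: str, tp: str) -> float:
        prob = LR_OFF_PROB
        for ch in config.lr_spec:
            if gene == ch.ligand_gene and ct in ch.sender_types and tp in ch.active_timepoints:
                prob = LR_ON_PROB
            if gene == ch.receptor_gene and ct in ch.receiver_types and tp in ch.active_timepoints:
                prob = LR_ON_PROB
        return prob

    truth = SimTruth(seed=config.seed, config_hash=config.content_hash())
    truth.markers = {ct: list(ms) for ct, ms in markers.items()}

    de_rows = []
    for spec, chosen in de_assign:
        sign = 1.0 if spec.direction == "over" else -1.0
        for g in chosen:
            de_rows.append(
                {
                    "cell_type": spec.cell_type,
                    "timepoint": spec.timepoint,
                    "gene": g,
                    "log_fold": sign * abs(spec.log_fold),
                }
            )
    truth.de_truth = pd.DataFrame(de_rows, columns=["cell_type", "timepoint", "gene", "log_fold"])

    ch_rows = []
    for ch in config.lr_spec:
        for tp in ch.active_timepoints:
            for s in ch.sender_types:
                for r in ch.receiver_types:
                    ch_rows.append(
                        {
                            "ligand": ch.ligand_gene,
                            "receptor": ch.receptor_gene,
                            "sender": s,
                            "receiver": r,
                            "timepoint": tp,
                        }
                    )
    truth.active_channels = pd.DataFrame(
        ch_rows, columns=["ligand", "receptor", "sender", "receiver", "timepoint"]
    )

    matrices: list[CountMatrix] = []
    shape_inv_disp = 1.0 / config.dispersion

    for t_i, tp in enumerate(config.timepoints):
        n_cells = config.cells_per_timepoint[t_i]
        # deterministic type assignment: largest-remainder apportionment
        quota = props[t_i] * n_cells
        counts_per_type = np.floor(quota).astype(int)
        remainder = n_cells - counts_per_type.sum()
        order = np.argsort(-(quota - counts_per_type), kind="stable")
        counts_per_type[order[:remainder]] += 1

        cell_types_vec = np.repeat(np.array(config.cell_types, dtype=object), counts_per_type)
        cell_ids = [f"{tp}_cell{j:05d}" for j in range(n_cells)]

        depth = rng.lognormal(config.depth_mean_log, config.depth_sd_log, size=n_cells)

        blocks = []
        start = 0
        for ct_i, ct in enumerate(config.cell_types):
            nk = counts_per_type[ct_i]
            if nk == 0:
                continue
            rates = base.copy()
            for mg in markers[ct]:
                rates[gene_index[mg]] *= config.marker_fold
            for spec, chosen in de_assign:
                if spec.cell_type != ct or spec.timepoint != tp:
                    continue
                sign = 1.0 if spec.direction == "over" else -1.0
                for g in chosen:
                    rates[gene_index[g]] *= float(np.exp(sign * abs(spec.log_fold)))

            # chunked Gamma-Poisson draw to bound peak memory
            sub_blocks = []
            for lo in range(0, nk, 512):
                hi = min(lo + 512, nk)
                mu = depth[start + lo : start + hi, None] * rates[None, :]
                lam = rng.gamma(shape_inv_disp, mu * config.dispersion)
                block = rng.poisson(lam)
                sub_blocks.append(sp.csr_matrix(block))
            block = sp.vstack(sub_blocks).tocsr()

            # overwrite LR channel genes with Bernoulli presence counts
            if len(lr_idx):
                block = block.tolil()
                for g in lr_genes:
                    prob = _channel_prob(g, ct, tp)
                    expressed = rng.random(nk) < prob
                    vals = np.where(expressed, 1 + rng.poisson(1.0, nk), 0)
                    block[:, gene_index[g]] = vals[:, None]
                block = block.tocsr()

            blocks.append(block)
            start += nk

        counts = sp.vstack(blocks).tocsr() if blocks else sp.csr_matrix((0, config.n_genes))
        counts.eliminate_zeros()

        cell_meta = pd.DataFrame(
            {
                "timepoint": pd.Categorical(
                    [tp] * n_cells, categories=list(config.timepoints), ordered=True
                ),
                "cell_type": cell_types_vec,
                "cluster": [f"c_{ct}" for ct in cell_types_vec],
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
        gene_meta = pd.DataFrame(
            {"is_mito": flag_mito_genes(genes)}, index=pd.Index(genes, name="gene_id")
        )
        cm = CountMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)
        matrices.append(cm)

        for cid, ct in zip(cell_ids, cell_types_vec):
            truth.cell_type_of[cid] = ct

    if config.velocity_spec is not None:
        gammas = rng.uniform(*config.velocity_spec.gamma_range, size=len(velocity_genes))
        truth.gamma_truth = {g: float(gm) for g, gm in zip(velocity_genes, gammas)}
        for cm in matrices:
            simulate_velocity_layers(cm, config, truth, rng)

    return matrices, truth


def simulate_velocity_layers(
    cm: CountMatrix,
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Attach spliced/unspliced layers with known per-gene gamma.

    spliced = the observed counts.  For each velocity gene g the
    unspliced signal is ``gamma[g] * spliced`` — exactly in expectation
    mode (``noise_sd == 0``), else a Poisson draw around a lognormally
    jittered rate.  Non-velocity genes get unspliced = 0.
    """
    if config.velocity_spec is None:
        raise ValueError("config.velocity_spec is not set")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vs = config.velocity_spec

    spliced = cm.counts.copy()
    unspliced = sp.lil_matrix(cm.counts.shape, dtype=np.float64)
    for g, gamma in truth.gamma_truth.items():
        gi = cm.gene_ids.get_loc(g)
        s_col = np.asarray(cm.counts[:, gi].todense()).ravel()
        lam = gamma * s_col
        if vs.noise_sd == 0:
            u_col = lam
        else:
            jitter = rng.lognormal(0.0, vs.noise_sd, size=len(lam))
            u_col = rng.poisson(lam * jitter).astype(np.float64)
        unspliced[:, gi] = u_col[:, None]

    cm.layers["spliced"] = spliced
    cm.layers["unspliced"] = unspliced.tocsr()
    return cm


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Serialize truth as TSV tables plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {"cell_id": list(truth.cell_type_of), "cell_type": list(truth.cell_type_of.values())}
    ).to_csv(path / "cell_types.tsv", sep="\t", index=False)

    marker_rows = [
        {"cell_type": ct, "gene": g} for ct, gs in truth.markers.items() for g in gs
    ]
    pd.DataFrame(marker_rows, columns=["cell_type", "gene"]).to_csv(
        path / "markers.tsv", sep="\t", index=False
    )

    truth.de_truth.to_csv(path / "de_truth.tsv", sep="\t", index=False)
    truth.active_channels.to_csv(path / "active_channels.tsv", sep="\t", index=False)

    pd.DataFrame(
        {"gene": list(truth.gamma_truth), "gamma": list(truth.gamma_truth.values())}
    ).to_csv(path / "gamma_truth.tsv", sep="\t", index=False)

    manifest = {"seed": truth.seed, "config_hash": truth.config_hash}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_truth(path: str | Path) -> SimTruth:
    """Read back what :func:`write_truth` wrote."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())

    ct = pd.read_csv(path / "cell_types.tsv", sep="\t")
    markers_df = pd.read_csv(path / "markers.tsv", sep="\t")
    markers: dict[str, list[str]] = {}
    for _, row in markers_df.iterrows():
        markers.setdefault(row["cell_type"], []).append(row["gene"])

    gamma_df = pd.read_csv(path / "gamma_truth.tsv", sep="\t")

    return SimTruth(
        cell_type_of=dict(zip(ct["cell_id"], ct["cell_type"])),
        markers=markers,
        de_truth=pd.read_csv(path / "de_truth.tsv", sep="\t"),
        active_channels=pd.read_csv(path / "active_channels.tsv", sep="\t"),
        gamma_truth=dict(zip(gamma_df["gene"], gamma_df["gamma"])),
        seed=manifest["seed"],
        config_hash=manifest["config_hash"],
    )
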