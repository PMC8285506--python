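"""Synthetic data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here: a
two-tissue single-cell count matrix with spike-ins and immunoglobulin
constant genes, a murine reference atlas with a planted covariant gene
block, a heavy-chain repertoire with planted clonal families, HLA bead
panels with planted positives, and an IP-MS intensity table with planted
enriched proteins.  Each generator returns its outputs together with a
:class:`TruthRecord` so downstream recovery can be scored exactly.

Counts follow a negative-binomial model with gene-level dispersion and
Bernoulli dropout — the minimal model reproducing the overdispersion of
plate-based scRNA-seq counts.  All randomness flows from a single seed;
each sub-generator draws from its own documented stream
(``default_rng([seed, k])``) so a partial run is reproducible regardless
of which generators are invoked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigError
from .sc import IGH_CONSTANT_GENES, SPIKEIN_PREFIX, QCConfig

# stream keys: one per sub-generator
_STREAM_SC = 1
_STREAM_ATLAS = 2
_STREAM_REPERTOIRE = 3
_STREAM_BEADS = 4
_STREAM_MS = 5

#: default murine subset panel: splenic transitional/follicular/GC/marginal-zone
#: plus B1 subsets; peritoneal-cavity (PC) subsets are the planted-high ones.
ATLAS_SUBSETS = ["T.Sp", "Fo.Sp", "GC.Sp", "MZ.Sp", "B1a.Sp", "B1a.PC", "B1b.PC"]

_V_GENES = ["IGHV1-2", "IGHV1-69", "IGHV3-7", "IGHV3-23", "IGHV3-30",
            "IGHV4-34", "IGHV4-59", "IGHV5-51"]
_D_GENES = ["IGHD2-2", "IGHD3-10", "IGHD3-22", "IGHD6-19", "none"]
_J_GENES = ["IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6"]
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SynthConfig:
    """Parameters of all generators; one object drives a full synthetic study.

    Defaults describe the study conditions the generators emulate: two
    tissues (kidney, tonsil) at 100 cells each, ~70% unswitched cells per
    tissue, 2,000 endogenous genes of which 10% are differential at
    log2 fold change 2, a 7-subset murine atlas with a 30-gene covariant
    block, a small clonal repertoire, a 30-bead screening panel with NBG 5
    positives that serum blocking pulls below the 2.2 threshold, and an
    IP-MS table with 8-fold planted enrichment.
    """

    seed: int = 0
    # single-cell dataset
    n_cells_per_group: int = 100
    n_genes: int = 2000
    n_spikeins: int = 20
    planted_deg_frac: float = 0.10
    planted_log2fc: float = 2.0
    dropout_rate: float = 0.1
    unswitched_frac: float = 0.7
    qc_fail_frac: float = 0.05
    plasma_frac: float = 0.05
    # reference atlas
    n_atlas_subsets: int = 7
    n_replicates: int = 3
    covariant_block_size: int = 30
    covariant_noise_sd: float = 30.0
    ortholog_coverage: float = 0.85
    # repertoire
    n_clones: int = 10
    clone_size_distribution: list[int] | None = None
    n_patients: int = 2
    cross_compartment_families: int = 1
    # bead panel
    n_beads: int = 30
    n_positive_beads: int = 3
    true_positive_nbg: float = 5.0
    blocking_effect: float = 0.2
    # IP-MS
    n_proteins: int = 200
    n_test_antibodies: int = 3
    n_control_antibodies: int = 2
    n_enriched_per_antibody: int = 5
    ms_fold: float = 8.0
    ms_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        positive = {
            "n_cells_per_group": self.n_cells_per_group,
            "n_genes": self.n_genes,
            "n_replicates": self.n_replicates,
            "n_beads": self.n_beads,
            "n_proteins": self.n_proteins,
            "n_patients": self.n_patients,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        if self.n_spikeins < 0:
            raise ConfigError("n_spikeins must be non-negative")
        if not 0 <= self.planted_deg_frac < 1:
            raise ConfigError("planted_deg_frac must be in [0, 1)")
        if self.planted_log2fc < 0:
            raise ConfigError("planted_log2fc must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.n_atlas_subsets < 2:
            raise ConfigError("n_atlas_subsets must be at least 2")
        if self.covariant_block_size > self.n_genes:
            raise ConfigError("covariant_block_size exceeds n_genes")
        if self.covariant_noise_sd < 0:
            raise ConfigError("covariant_noise_sd must be >= 0")
        if self.clone_size_distribution is not None:
            if any(s < 1 for s in self.clone_size_distribution):
                raise ConfigError("clone sizes must be >= 1")
        if not 0 < self.blocking_effect <= 1:
            raise ConfigError("blocking_effect must be in (0, 1]")
        if self.true_positive_nbg <= 2.2:
            raise ConfigError("true_positive_nbg must exceed the 2.2 threshold")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2 per condition")

    def rng(self, stream: int) -> np.random.Generator:
        """Generator for one documented sub-stream of the master seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthRecord:
    """Planted ground truth; only the fields a generator fills are set."""

    deg_genes: dict[str, str] = field(default_factory=dict)  # gene -> up/down
    qc_fail_cells: dict[str, str] = field(default_factory=dict)  # cell -> reason
    isotype: dict[str, str] = field(default_factory=dict)  # cell -> gene
    plasma_cells: list[str] = field(default_factory=list)
    covariant_genes: list[str] = field(default_factory=list)
    unmappable_block_genes: list[str] = field(default_factory=list)
    block_genes: list[str] = field(default_factory=list)
    clone_id: dict[str, str] = field(default_factory=dict)  # cell -> family id
    cross_compartment_clones: list[str] = field(default_factory=list)
    positive_beads: list[str] = field(default_factory=list)
    lost_binding_beads: list[str] = field(default_factory=list)
    enriched_proteins: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


def default_qc_config(config: SynthConfig) -> QCConfig:
    """QC thresholds matched to the synthetic gene-count scale.

    Synthetic matrices carry far fewer genes than a transcriptome, so the
    coverage window scales with ``n_genes``; the Ig-sum threshold keeps the
    published value of 5 (log2-CPM units), which planted cells clear by a
    wide margin.
    """
    return QCConfig(
        min_genes=max(len(IGH_CONSTANT_GENES) + 5, int(0.05 * config.n_genes)),
        max_genes=10 * config.n_genes,
        ig_logcpm_min=5.0,
    )


def make_sc_dataset(config: SynthConfig) -> tuple[ad.AnnData, TruthRecord]:
    """Two-tissue single-cell count matrix with planted structure.

    Plants: differential genes between kidney and tonsil (half up, half
    down, at ``planted_log2fc``); per-cell intended isotypes with the
    isotype's constant gene a strict maximum; a PRDM1-high plasma cluster;
    spike-in rows; and ``qc_fail_frac`` cells violating the coverage or
    Ig filters of :func:`default_qc_config`.  Cell metadata (tissue,
    patient, cohort, cluster_label) lives in ``obs``.
    """
    rng = config.rng(_STREAM_SC)
    qc = default_qc_config(config)

    n_per = config.n_cells_per_group
    tissues = ["kidney"] * n_per + ["tonsil"] * n_per
    n_cells = 2 * n_per
    cell_ids = [f"{t[0].upper()}{i:04d}" for i, t in enumerate(tissues)]

    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    marker = "PRDM1"
    genes[-1] = marker  # plasma marker is an ordinary endogenous gene slot
    ig_genes = list(IGH_CONSTANT_GENES)
    spikes = [f"{SPIKEIN_PREFIX}{i:05d}" for i in range(config.n_spikeins)]
    all_genes = genes + ig_genes + spikes

    # baseline negative-binomial parameters; deep full-length libraries put
    # a typical detected gene at tens of counts per cell
    mu = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=config.n_genes)
    disp_r = rng.uniform(1.0, 5.0, size=config.n_genes)

    # plant DEGs (PRDM1 slot excluded so the plasma marker stays clean)
    n_deg = int(round(config.planted_deg_frac * config.n_genes))
    deg_idx = rng.choice(config.n_genes - 1, size=min(n_deg, config.n_genes - 1),
                         replace=False)
    truth = TruthRecord()
    fold = 2.0 ** config.planted_log2fc
    mu_mat = np.tile(mu, (n_cells, 1))
    kidney = np.array([t == "kidney" for t in tissues])
    for j, g in enumerate(deg_idx):
        if j % 2 == 0:
            mu_mat[kidney, g] *= fold
            truth.deg_genes[genes[g]] = "up"
        else:
            mu_mat[kidney, g] /= fold
            truth.deg_genes[genes[g]] = "down"

    p = disp_r / (disp_r + mu_mat)
    counts = rng.negative_binomial(disp_r, p, size=(n_cells, config.n_genes))
    counts = counts.astype(float)
    counts *= rng.random(counts.shape) >= config.dropout_rate

    # isotype planting: intended constant gene is a strict maximum
    iso_counts = rng.integers(0, 50, size=(n_cells, len(ig_genes))).astype(float)
    switched_pool = [g for g in ig_genes if g not in ("IGHM", "IGHD")]
    for i in range(n_cells):
        unswitched = rng.random() < config.unswitched_frac
        if unswitched:
            iso = "IGHM" if rng.random() < 0.8 else "IGHD"
        else:
            iso = switched_pool[rng.integers(len(switched_pool))]
        iso_counts[i, ig_genes.index(iso)] = 300.0 + rng.integers(0, 100)
        truth.isotype[cell_ids[i]] = iso

    spike_counts = rng.poisson(20.0, size=(n_cells, config.n_spikeins)).astype(float)

    # plasma cluster: PRDM1-high kidney cells
    n_plasma = int(round(config.plasma_frac * n_per))
    plasma_rows = list(range(n_per - n_plasma, n_per))  # tail of kidney block
    prdm1_col = config.n_genes - 1
    counts[:, prdm1_col] = rng.poisson(0.2, size=n_cells)
    for i in plasma_rows:
        counts[i, prdm1_col] = 200.0 + rng.integers(0, 50)
        truth.plasma_cells.append(cell_ids[i])

    # planted QC failures: alternate low-coverage and low-Ig cells,
    # drawn from the head of each tissue block so plasma cells stay clean
    n_fail = int(round(config.qc_fail_frac * n_cells))
    fail_rows = list(range(0, n_fail // 2)) + list(range(n_per, n_per + (n_fail + 1) // 2))
    for j, i in enumerate(fail_rows):
        if j % 2 == 0:
            # leave room for the always-on Ig constant genes in the tally
            n_keep = max(0, qc.min_genes - len(IGH_CONSTANT_GENES) - 3)
            keep = rng.choice(config.n_genes, size=min(n_keep, config.n_genes),
                              replace=False)
            mask = np.zeros(config.n_genes, dtype=bool)
            mask[keep] = True
            counts[i, ~mask] = 0.0
            truth.qc_fail_cells[cell_ids[i]] = "low_gene_count"
        else:
            iso_counts[i, :] = 0.0
            truth.qc_fail_cells[cell_ids[i]] = "low_ig_expression"

    # deterministic fix-up: every non-planted cell passes QC by construction
    for i in range(n_cells):
        if cell_ids[i] in truth.qc_fail_cells:
            continue
        nz = counts[i] > 0
        deficit = qc.min_genes + 2 - int(nz.sum())
        if deficit > 0:
            counts[i, np.flatnonzero(~nz)[:deficit]] = 1.0

    X = np.hstack([counts, iso_counts, spike_counts])
    obs = pd.DataFrame(
        {
            "tissue": tissues,
            "patient": [f"P{(i % 4) + 1}" if t == "kidney" else f"T{(i % 2) + 1}"
                        for i, t in enumerate(tissues)],
            "cohort": "cohort1",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    switch = ["unswitched" if truth.isotype[c] in ("IGHM", "IGHD") else "switched"
              for c in cell_ids]
    obs["switch_state_true"] = switch
    obs["cluster_label"] = [
        "plasma" if c in truth.plasma_cells else f"{t}_{s}"
        for c, t, s in zip(cell_ids, tissues, switch)
    ]
    adata = ad.AnnData(
        X=X,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(all_genes, name="gene_id")),
    )
    adata.uns["layer"] = "raw_counts"
    adata.var["is_spikein"] = adata.var_names.str.startswith(SPIKEIN_PREFIX)
    return adata, truth


def make_atlas(
    config: SynthConfig, block_human_genes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, TruthRecord]:
    """Murine reference atlas with a planted covariant block.

    Returns ``(values, subset_map, ortholog_map, truth)`` where ``values``
    is genes x replicate-columns (linear scale), ``subset_map`` maps each
    replicate column to its subset, and ``ortholog_map`` is a two-column
    frame (mouse_gene, human_gene) with one-to-many entries.

    The seed gene ``Ahnak`` and ``covariant_block_size`` block genes share
    a peritoneal-B1-high subset profile plus additive noise of sd
    ``covariant_noise_sd``; replicate deviations are centered within each
    subset so subset means equal the planted profiles exactly, making the
    zero-noise case correlate at exactly 1.  Truth lists the block and the
    subset of block genes whose realized subset-mean correlation with the
    seed is >= 0.8 (recomputed here directly from the generated values).
    """
    rng = config.rng(_STREAM_ATLAS)
    n_sub = config.n_atlas_subsets
    if n_sub <= len(ATLAS_SUBSETS):
        # keep at least one peritoneal-cavity subset so the planted-high
        # profile is non-constant
        subsets = ATLAS_SUBSETS[: n_sub - 1] + [ATLAS_SUBSETS[-1]]
    else:
        subsets = ATLAS_SUBSETS + [f"S{i}.Sp" for i in range(n_sub - len(ATLAS_SUBSETS))]
    n_pc = max(1, sum(s.endswith(".PC") for s in subsets))

    genes = ["Ahnak"] + [f"Mgene{i:04d}" for i in range(config.n_genes - 1)]
    block = genes[1 : 1 + config.covariant_block_size]

    # seed profile: low outside, high in the trailing (PC-like) subsets
    seed_profile = np.full(n_sub, 30.0)
    seed_profile[-n_pc:] = 300.0

    profiles = rng.uniform(20.0, 120.0, size=(len(genes), n_sub))
    profiles[0] = seed_profile
    noise = rng.normal(0.0, config.covariant_noise_sd,
                       size=(len(block), n_sub)) if block else np.empty((0, n_sub))
    for j in range(len(block)):
        profiles[1 + j] = seed_profile + noise[j]
    profiles = np.clip(profiles, 0.5, None)

    rep_cols, rep_subset = [], []
    values = np.empty((len(genes), n_sub * config.n_replicates))
    for s_i, s in enumerate(subsets):
        dev = rng.normal(0.0, 2.0, size=(len(genes), config.n_replicates))
        dev -= dev.mean(axis=1, keepdims=True)  # subset mean stays exact
        block_cols = slice(s_i * config.n_replicates, (s_i + 1) * config.n_replicates)
        values[:, block_cols] = np.clip(profiles[:, [s_i]] + dev, 0.0, None)
        for r in range(config.n_replicates):
            rep_cols.append(f"{s}#{r + 1}")
            rep_subset.append(s)

    atlas = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=rep_cols)
    subset_map = pd.Series(rep_subset, index=rep_cols, name="subset")

    # ortholog map: block genes mapped to supplied human targets (or
    # uppercase names); the rest covered at ortholog_coverage with a few
    # one-to-many entries; trailing block genes deliberately left unmapped
    truth = TruthRecord()
    truth.block_genes = ["Ahnak"] + list(block)
    n_unmappable = min(2, len(block))
    unmappable = set(block[-n_unmappable:]) if n_unmappable else set()
    truth.unmappable_block_genes = sorted(unmappable)

    # mouse Mgene{i} maps to human GENE{i}: the same namespace the
    # single-cell generator uses, so signatures and DEG clusters share a
    # background universe
    def default_human(g: str) -> str:
        return "GENE" + g.removeprefix("Mgene")

    pairs: list[tuple[str, str]] = [("Ahnak", "AHNAK")]
    for j, g in enumerate(block):
        if g in unmappable:
            continue
        human = (block_human_genes[j % len(block_human_genes)]
                 if block_human_genes else default_human(g))
        pairs.append((g, human))
    others = genes[1 + len(block):]
    covered = rng.random(len(others)) < config.ortholog_coverage
    for g, c in zip(others, covered):
        if c:
            pairs.append((g, default_human(g)))
    for g in others[:5]:  # one-to-many examples
        pairs.append((g, default_human(g) + "B"))
    ortholog_map = pd.DataFrame(sorted(set(pairs)),
                                columns=["mouse_gene", "human_gene"])

    # realized covariant set, straight from the generated values
    sub_means = atlas.T.groupby(subset_map).mean().T  # genes x subsets
    seedv = sub_means.loc["Ahnak"].to_numpy()
    sm = sub_means.to_numpy()
    sd = sm.std(axis=1)
    with np.errstate(invalid="ignore"):
        r = np.where(
            sd > 0,
            ((sm - sm.mean(axis=1, keepdims=True))
             @ (seedv - seedv.mean())) / (sm.shape[1] * sd * seedv.std()),
            np.nan,
        )
    truth.covariant_genes = sorted(
        g for g, ri in zip(genes, r) if np.isfinite(ri) and ri >= 0.8
    )
    return atlas, subset_map, ortholog_map, truth


def make_repertoire(config: SynthConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """AIRR-style heavy-chain records drawn from planted clonal families.

    Family sizes come from ``clone_size_distribution`` (default: three
    expanded families of sizes 5, 3, 2, remainder singletons).  Families are
    distributed round-robin over patients; the first
    ``cross_compartment_families`` expanded families receive one
    plasma-compartment member.  Mutation counts are Poisson, with higher
    burden for switched records and an occasional very high (> 60) draw.
    """
    rng = config.rng(_STREAM_REPERTOIRE)
    sizes = config.clone_size_distribution
    if sizes is None:
        expanded = [5, 3, 2][: max(0, min(3, config.n_clones))]
        sizes = expanded + [1] * (config.n_clones - len(expanded))
    if len(sizes) == 0:
        raise ConfigError("clone_size_distribution must be non-empty")

    # distinct clonal keys, one per family
    keys = set()
    fam_keys = []
    while len(fam_keys) < len(sizes):
        key = (
            _V_GENES[rng.integers(len(_V_GENES))],
            _D_GENES[rng.integers(len(_D_GENES))],
            _J_GENES[rng.integers(len(_J_GENES))],
            int(rng.integers(8, 22)),
        )
        if key not in keys:
            keys.add(key)
            fam_keys.append(key)

    truth = TruthRecord()
    rows = []
    cross_budget = config.cross_compartment_families
    expanded_ids = [i for i, s in enumerate(sizes) if s >= 2]
    cross_fams = set(expanded_ids[:cross_budget])
    cell_no = 0
    for f_i, (size, (v, d, j, cl)) in enumerate(zip(sizes, fam_keys)):
        patient = f"P{(f_i % config.n_patients) + 1}"
        fam_id = f"{patient}_F{f_i:03d}"
        if f_i in cross_fams:
            truth.cross_compartment_clones.append(fam_id)
        junction = "".join(rng.choice(_AA, size=cl))
        for m in range(size):
            cell = f"IG{cell_no:04d}"
            cell_no += 1
            compartment = "plasma" if (f_i in cross_fams and m == 0) else "bcell"
            switched = rng.random() < 0.4
            isotype = ("IGHG1" if rng.random() < 0.7 else "IGHA1") if switched \
                else "IGHM"
            lam = 20.0 if switched else 4.0
            mut = int(rng.poisson(lam))
            if rng.random() < 0.03:
                mut += 65
            # point-mutate the junction within the family, length preserved
            jm = list(junction)
            if size > 1 and m > 0:
                pos = int(rng.integers(cl))
                jm[pos] = str(rng.choice(_AA))
            rows.append(
                {
                    "cell_id": cell,
                    "patient": patient,
                    "compartment": compartment,
                    "v_call": v + "*01",
                    "d_call": d if d == "none" else d + "*01",
                    "j_call": j + "*01",
                    "junction_aa": "".join(jm),
                    "cdr3_length": cl,
                    "isotype": isotype,
                    "switch_state": "switched" if switched else "unswitched",
                    "mutation_count": mut,
                }
            )
            truth.clone_id[cell] = fam_id
    records = pd.DataFrame(rows)
    return records, truth


def make_bead_panel(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Matched PBS / serum-blocked screening bead panels for one antibody.

    Signals are constructed by inverting the NBG definition: a planted
    positive bead gets sample signal ``S0 + nbg * (N - N0)`` with
    ``nbg = true_positive_nbg`` exactly.  In the serum condition the
    sample-specific excess of positive beads is multiplied by
    ``blocking_effect`` (polyreactive binding competed away by serum),
    so serum NBG = blocking_effect x PBS NBG.
    """
    rng = config.rng(_STREAM_BEADS)
    s0, n0 = 200.0, 100.0
    n_beads = config.n_beads
    n_pos = min(config.n_positive_beads, n_beads)

    bead_ids = [f"bead{i:03d}" for i in range(n_beads)]
    classes = ["class_I" if i < (n_beads + 1) // 2 else "class_II"
               for i in range(n_beads)]
    alleles = [f"A*{i + 1:02d}:01" if c == "class_I" else f"DRB1*{i + 1:02d}:01"
               for i, c in enumerate(classes)]
    n_sig = rng.uniform(800.0, 1200.0, size=n_beads)
    pos_idx = rng.choice(n_beads, size=n_pos, replace=False)
    nbg = rng.uniform(0.2, 1.5, size=n_beads)
    nbg[pos_idx] = config.true_positive_nbg
    s_pbs = s0 + nbg * (n_sig - n0)
    s_serum = s0 + nbg * np.where(np.isin(np.arange(n_beads), pos_idx),
                                  config.blocking_effect, 1.0) * (n_sig - n0)

    def panel(s_vals: np.ndarray) -> pd.DataFrame:
        rows = [{"bead_id": "NC", "bead_class": "negative_control",
                 "alleles": "", "S": s0, "N": n0}]
        for b, c, a, s, n in zip(bead_ids, classes, alleles, s_vals, n_sig):
            rows.append({"bead_id": b, "bead_class": c, "alleles": a,
                         "S": float(s), "N": float(n)})
        return pd.DataFrame(rows)

    truth = TruthRecord()
    truth.positive_beads = sorted(bead_ids[i] for i in pos_idx)
    truth.lost_binding_beads = sorted(
        bead_ids[i] for i in pos_idx
        if nbg[i] * config.blocking_effect < 2.2
    )
    return panel(s_pbs), panel(s_serum), truth


def make_ms_table(
    config: SynthConfig,
) -> tuple[pd.DataFrame, dict[str, list[str]], TruthRecord]:
    """IP-MS protein-group intensity table with planted enrichment.

    Returns ``(table, condition_map, truth)``.  The table carries one row
    per protein group: per-sample LFQ intensities (0 = not detected) and
    contaminant / reverse / site_only flag columns.  ``condition_map`` maps
    each antibody (condition) to its replicate sample columns; the control
    conditions are named ``CTRL1..``.  Planted proteins are ``ms_fold``-fold
    elevated in one test antibody's replicates; a few rows are flagged and
    a few detected in fewer than two replicates everywhere.
    """
    rng = config.rng(_STREAM_MS)
    proteins = [f"PROT{i:04d}" for i in range(config.n_proteins)]
    tests = [f"AB{i + 1}" for i in range(config.n_test_antibodies)]
    ctrls = [f"CTRL{i + 1}" for i in range(config.n_control_antibodies)]
    condition_map = {
        ab: [f"{ab}_r{r + 1}" for r in range(config.n_replicates)]
        for ab in tests + ctrls
    }
    samples = [s for cols in condition_map.values() for s in cols]

    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=config.n_proteins)
    X = np.empty((config.n_proteins, len(samples)))
    for j in range(len(samples)):
        noise = rng.lognormal(0.0, config.ms_noise_sd, size=config.n_proteins) \
            if config.ms_noise_sd > 0 else 1.0
        X[:, j] = base * noise

    truth = TruthRecord()
    pool = rng.permutation(config.n_proteins)
    k = config.n_enriched_per_antibody
    for a_i, ab in enumerate(tests):
        enriched = pool[a_i * k : (a_i + 1) * k]
        cols = [samples.index(s) for s in condition_map[ab]]
        X[np.ix_(enriched, cols)] *= config.ms_fold
        truth.enriched_proteins[ab] = sorted(proteins[i] for i in enriched)

    # sparse rows: detected in a single replicate of every condition
    sparse = pool[len(tests) * k : len(tests) * k + 3]
    for i in sparse:
        keep = {cols[0] for cols in condition_map.values()}
        for j, s in enumerate(samples):
            if s not in keep:
                X[i, j] = 0.0

    table = pd.DataFrame(X, index=pd.Index(proteins, name="protein_group"),
                         columns=samples)
    flagged = pool[-6:]
    table["contaminant"] = False
    table["reverse"] = False
    table["site_only"] = False
    flag_cols = ["contaminant", "reverse", "site_only"]
    for j, i in enumerate(flagged):
        table.iloc[i, table.columns.get_loc(flag_cols[j % 3])] = True
    return table, condition_map, truth


# ---------------------------------------------------------------------------
# writers


def write_repertoire(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as AIRR Rearrangement-style TSV."""
    records.to_csv(path, sep="\t", index=False)


def write_bead_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def write_atlas(
    atlas: pd.DataFrame, subset_map: pd.Series, values_path: str | Path,
    subsets_path: str | Path
) -> None:
    atlas.to_csv(values_path, sep="\t")
    subset_map.rename_axis("replicate").to_csv(subsets_path, sep="\t")
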