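"""Synthetic input generators with planted ground truth.

Every downstream stage of the pipeline consumes inputs that this module can
fabricate: a molecule-level table (cell label x UMI x feature x reads) for
UMI correction / cell calling / demultiplexing, per-sample targeted
gene-expression count matrices, a multi-sample AIRR rearrangement table,
and LDH optical-density plates.  Generators are fully deterministic given a
:class:`SimConfig` (whose ``seed`` drives all randomness) and record every
planted fact in a :class:`GroundTruth` so recovery can be asserted exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CytotoxicityPlate",
    "DEFAULT_PANEL_GENES",
    "generate_molecule_table",
    "generate_airr_table",
    "generate_gex_matrices",
    "generate_cytotox_plate",
    "split_tag_molecules",
    "is_tag_feature",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Targeted immune panel used by default; the three gating markers are mandatory.
DEFAULT_PANEL_GENES = (
    "CD8", "CD4", "FOXP3", "CD3E", "GZMB", "PRF1", "IFNG", "IL2RA", "IL7R",
    "CCR7", "SELL", "TNF", "LAG3", "PDCD1", "CTLA4", "TBX21", "EOMES",
    "KLRG1", "CX3CR1", "GNLY", "NKG7", "CCL5", "CST7", "HLA-DRA",
)

_TAG_PREFIX = "SampleTag"

#: Mean sample-tag reads captured per real cell (internal scale constant).
_TAG_READS_PER_CELL = 50

#: Mean reads per true cDNA molecule (controls molecule-table size).
_READS_PER_MOLECULE = 6.0

_TRAV = tuple(f"TRAV{i}*01" for i in (1, 2, 3, 8, 12, 13, 17, 21, 26, 38))
_TRAJ = tuple(f"TRAJ{i}*01" for i in (4, 6, 9, 12, 23, 31, 33, 42, 45, 49))
_TRBV = tuple(f"TRBV{i}*01" for i in (2, 4, 5, 6, 7, 9, 11, 19, 20, 28))
_TRBJ = tuple(f"TRBJ{i}-{j}*01" for i in (1, 2) for j in (1, 2, 3, 5, 7))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    The defaults describe a small but structurally faithful experiment: a
    heavy-tailed clonotype size distribution with a single planted dominant
    clonotype, an almost pure CD8+CD4-FOXP3- population, low-rate
    substitution errors on UMIs, a bimodal barcode-rank curve (real cells
    vs ambient noise barcodes) and noisy per-cell sample-tag counts.
    """

    seed: int = 0
    n_real_cells: int = 500
    n_noise_barcodes: int = 2000
    n_samples: int = 3
    reads_per_real_cell: float = 300.0
    reads_per_noise_barcode: float = 10.0
    umi_length: int = 8
    umi_error_rate: float = 0.02
    n_clonotypes: int = 300
    dominant_clone_size: int = 14
    clone_size_power: float = 2.2
    frac_cd8: float = 0.999
    multiplet_rate: float = 0.05
    tag_noise_rate: float = 0.02
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES

    def __post_init__(self) -> None:
        object.__setattr__(self, "panel_genes", tuple(self.panel_genes))

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        probs = {
            "umi_error_rate": self.umi_error_rate,
            "frac_cd8": self.frac_cd8,
            "multiplet_rate": self.multiplet_rate,
            "tag_noise_rate": self.tag_noise_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"invariant violated: 0 <= {name} <= 1 (got {p})")
        if self.dominant_clone_size < 3:
            raise ValueError(
                "invariant violated: dominant_clone_size >= max other clone size + 2 "
                f"requires dominant_clone_size >= 3 (got {self.dominant_clone_size})"
            )
        if self.reads_per_real_cell <= self.reads_per_noise_barcode:
            raise ValueError(
                "invariant violated: reads_per_real_cell > reads_per_noise_barcode "
                f"({self.reads_per_real_cell} <= {self.reads_per_noise_barcode})"
            )
        if self.reads_per_noise_barcode <= 0:
            raise ValueError("invariant violated: reads_per_noise_barcode > 0")
        if self.umi_length < 4:
            raise ValueError(f"invariant violated: umi_length >= 4 (got {self.umi_length})")
        if self.n_real_cells < self.dominant_clone_size:
            raise ValueError(
                "invariant violated: n_real_cells >= dominant_clone_size "
                f"({self.n_real_cells} < {self.dominant_clone_size})"
            )
        if self.n_clonotypes < 1:
            raise ValueError("invariant violated: n_clonotypes >= 1")
        if self.n_samples < 1:
            raise ValueError("invariant violated: n_samples >= 1")
        missing = {"CD8", "CD4", "FOXP3"} - set(self.panel_genes)
        if missing:
            raise ValueError(
                f"invariant violated: panel_genes must include CD8, CD4, FOXP3 (missing {sorted(missing)})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @property
    def tag_names(self) -> list[str]:
        return [f"{_TAG_PREFIX}{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    """Every planted fact of one synthetic experiment.

    ``true_umi_parent`` stores only the non-identity entries; an observed
    UMI absent from the map is its own parent (so at zero error rate the
    map is empty and the parent relation is the identity).
    """

    cell_to_sample: dict[str, str]
    real_cells: set[str]
    clonotype_of_cell: dict[str, str]
    dominant_clonotype_id: str
    true_affinity: dict[str, float]
    true_umi_parent: dict[tuple[str, str, str], str]
    is_cd8: dict[str, bool]

    def parent_of(self, cell: str, feature: str, umi: str) -> str:
        return self.true_umi_parent.get((cell, feature, umi), umi)

    def clone_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for clone in self.clonotype_of_cell.values():
            sizes[clone] = sizes.get(clone, 0) + 1
        return sizes

    def validate(self) -> None:
        sizes = self.clone_sizes()
        dom = sizes.pop(self.dominant_clonotype_id)
        if sizes and dom <= max(sizes.values()):
            raise ValueError("dominant clonotype is not strictly largest")
        if not self.real_cells <= set(self.cell_to_sample):
            raise ValueError("some real cells missing from cell_to_sample")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cell_to_sample": self.cell_to_sample,
            "real_cells": sorted(self.real_cells),
            "clonotype_of_cell": self.clonotype_of_cell,
            "dominant_clonotype_id": self.dominant_clonotype_id,
            "true_affinity": self.true_affinity,
            "true_umi_parent": {
                "|".join(k): v for k, v in self.true_umi_parent.items()
            },
            "is_cd8": self.is_cd8,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cell_to_sample=d["cell_to_sample"],
            real_cells=set(d["real_cells"]),
            clonotype_of_cell=d["clonotype_of_cell"],
            dominant_clonotype_id=d["dominant_clonotype_id"],
            true_affinity=d["true_affinity"],
            true_umi_parent={
                tuple(k.split("|")): v for k, v in d["true_umi_parent"].items()
            },
            is_cd8=d["is_cd8"],
        )


@dataclass(frozen=True)
class CytotoxicityPlate:
    """Optical densities (arbitrary absorbance units) for one LDH assay."""

    od_effector_plus_target: tuple[float, ...]
    od_effector_only: tuple[float, ...]
    od_max_lysis: tuple[float, ...]
    od_spontaneous: tuple[float, ...]

    def validate(self) -> None:
        for name in (
            "od_effector_plus_target",
            "od_effector_only",
            "od_max_lysis",
            "od_spontaneous",
        ):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} contains a negative optical density")


def is_tag_feature(feature: str) -> bool:
    return feature.startswith(_TAG_PREFIX)


def split_tag_molecules(molecules: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a molecule table into (gene molecules, sample-tag molecules)."""
    mask = molecules["feature"].str.startswith(_TAG_PREFIX)
    return (
        molecules.loc[~mask].reset_index(drop=True),
        molecules.loc[mask].reset_index(drop=True),
    )


def _plant_clone_sizes(config: SimConfig, rng: np.random.Generator) -> list[int]:
    """Dominant clone first, then a truncated discrete power law.

    Non-dominant sizes are capped at ``dominant_clone_size - 2`` so the
    dominant clone is strictly largest with a gap of at least 2 cells.
    """
    cap = config.dominant_clone_size - 2
    sizes = [config.dominant_clone_size]
    remaining = config.n_real_cells - config.dominant_clone_size
    while remaining > 0 and len(sizes) < config.n_clonotypes:
        s = min(int(rng.zipf(config.clone_size_power)), cap, remaining)
        sizes.append(s)
        remaining -= s
    # distribute any leftover cells round-robin over non-dominant clones
    while remaining > 0:
        grew = False
        for i in range(1, len(sizes)):
            if remaining == 0:
                break
            if sizes[i] < cap:
                sizes[i] += 1
                remaining -= 1
                grew = True
        if not grew:
            raise ValueError(
                "cannot place all cells: n_clonotypes too small for n_real_cells "
                "under the dominant-clone cap"
            )
    return sizes


def _random_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """``n`` random fixed-length UMI strings as an ``S{length}`` byte array."""
    idx = rng.integers(0, 4, size=(n, length))
    return _BASES[idx].view(f"S{length}").ravel()


def generate_molecule_table(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the molecule-level table and its ground truth.

    The returned frame has columns ``cell_label``, ``umi``, ``feature``,
    ``reads`` and contains both targeted-gene molecules and sample-tag
    molecules (features named ``SampleTagNN``); use
    :func:`split_tag_molecules` to separate them.

    Each true molecule may spawn one substitution-error UMI at Hamming
    distance 1 with probability ``umi_error_rate``; error molecules carry
    at most ``floor(parent_reads / 2)`` reads so the recursive correction
    parent rule provably reattaches them.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    L = config.umi_length

    real_labels = np.array([f"BC{i:06d}" for i in range(config.n_real_cells)])
    noise_labels = np.array(
        [f"BC{i:06d}" for i in range(config.n_real_cells, config.n_real_cells + config.n_noise_barcodes)]
    )

    # --- planted clonotype structure -----------------------------------
    sizes = _plant_clone_sizes(config, rng)
    clone_ids = [f"CT{i:04d}" for i in range(len(sizes))]
    dominant_id = clone_ids[0]
    cell_clone = np.repeat(clone_ids, sizes)
    rng.shuffle(cell_clone)
    clonotype_of_cell = dict(zip(real_labels, cell_clone))

    # --- sample assignment / multiplets --------------------------------
    # cells of the dominant clonotype are kept singlet so the planted
    # dominant clone is recoverable end to end (see package notes)
    dominant_cells = {c for c, ct in clonotype_of_cell.items() if ct == dominant_id}
    can_multiplet = config.n_samples >= 2
    samples = np.array(config.sample_ids)
    assigned = rng.choice(samples, size=config.n_real_cells)
    second = np.array([rng.choice([s for s in samples if s != a]) if can_multiplet else a
                       for a in assigned]) if can_multiplet else assigned.copy()
    is_multi = (rng.random(config.n_real_cells) < config.multiplet_rate) & can_multiplet
    is_multi &= ~np.isin(real_labels, sorted(dominant_cells))
    cell_to_sample = {
        lab: ("multiplet" if m else s)
        for lab, s, m in zip(real_labels, assigned, is_multi)
    }

    # --- CD8 status -----------------------------------------------------
    cd8 = rng.random(config.n_real_cells) < config.frac_cd8
    cd8 |= np.isin(real_labels, sorted(dominant_cells))  # dominant clone is effector
    is_cd8 = dict(zip(real_labels, (bool(v) for v in cd8)))

    # --- planted per-clonotype affinity --------------------------------
    affin = rng.uniform(0.0, 1.0, size=len(clone_ids))
    affin[0] = rng.uniform(0.4, 0.7)  # dominant clone: medium binding score
    true_affinity = dict(zip(clone_ids, affin.round(6).tolist()))

    # --- gene molecules -------------------------------------------------
    genes = np.array(config.panel_genes)
    gene_w = 1.0 / np.arange(2, len(genes) + 2)
    gene_w /= gene_w.sum()

    def _molecules_for(labels: np.ndarray, mean_reads: float, mean_mol_reads: float):
        totals = np.maximum(rng.poisson(mean_reads, size=len(labels)), 1)
        n_mol = np.maximum(np.rint(totals / mean_mol_reads).astype(int), 1)
        lab_rep = np.repeat(labels, n_mol)
        m = int(n_mol.sum())
        reads = 1 + rng.poisson(mean_mol_reads - 1.0, size=m)
        feats = genes[rng.choice(len(genes), size=m, p=gene_w)]
        umis = _random_umis(rng, m, L)
        return lab_rep, umis, feats, reads

    r_lab, r_umi, r_feat, r_reads = _molecules_for(
        real_labels, config.reads_per_real_cell, _READS_PER_MOLECULE
    )
    n_lab, n_umi, n_feat, n_reads = _molecules_for(
        noise_labels, config.reads_per_noise_barcode, 2.0
    )

    df = pd.DataFrame(
        {
            "cell_label": np.concatenate([r_lab, n_lab]),
            "umi": np.concatenate([r_umi, n_umi]).astype(str),
            "feature": np.concatenate([r_feat, n_feat]),
            "reads": np.concatenate([r_reads, n_reads]).astype(np.int64),
        }
    )
    # duplicate (cell, umi, feature) draws are one molecule by definition
    df = (
        df.groupby(["cell_label", "umi", "feature"], as_index=False, sort=False)["reads"]
        .sum()
    )

    # --- substitution-error UMIs ---------------------------------------
    true_umi_parent: dict[tuple[str, str, str], str] = {}
    if config.umi_error_rate > 0:
        eligible = df.index[df["reads"] >= 2].to_numpy()
        hit = eligible[rng.random(len(eligible)) < config.umi_error_rate]
        if len(hit):
            parents = df.loc[hit]
            pos = rng.integers(0, L, size=len(hit))
            shift = rng.integers(1, 4, size=len(hit))
            p_umi = parents["umi"].to_numpy().astype(f"S{L}").view("S1").reshape(len(hit), L)
            err = p_umi.copy()
            base_idx = np.searchsorted(_BASES, err[np.arange(len(hit)), pos])
            err[np.arange(len(hit)), pos] = _BASES[(base_idx + shift) % 4]
            err_umi = err.view(f"S{L}").ravel().astype(str)
            half = parents["reads"].to_numpy() // 2
            err_reads = rng.integers(1, half + 1)
            err_df = pd.DataFrame(
                {
                    "cell_label": parents["cell_label"].to_numpy(),
                    "umi": err_umi,
                    "feature": parents["feature"].to_numpy(),
                    "reads": err_reads.astype(np.int64),
                }
            )
            # drop error molecules that collide with an existing observed UMI
            key_existing = pd.MultiIndex.from_frame(df[["cell_label", "umi", "feature"]])
            key_err = pd.MultiIndex.from_frame(err_df[["cell_label", "umi", "feature"]])
            keep = ~key_err.isin(key_existing) & ~key_err.duplicated()
            err_df = err_df.loc[np.asarray(keep)]
            for row, parent in zip(err_df.itertuples(index=False), parents["umi"].to_numpy()[np.asarray(keep)]):
                true_umi_parent[(row.cell_label, row.feature, row.umi)] = parent
            df = pd.concat([df, err_df], ignore_index=True)

    # --- sample-tag molecules ------------------------------------------
    tags = np.array(config.tag_names)
    k = len(tags)
    tag_rows = []
    tag_totals = np.maximum(rng.poisson(_TAG_READS_PER_CELL, size=config.n_real_cells), 1)
    sample_pos = {s: i for i, s in enumerate(samples)}
    for ci, (lab, total) in enumerate(zip(real_labels, tag_totals)):
        target = cell_to_sample[lab]
        p = np.full(k, 0.0)
        if target == "multiplet":
            i1, i2 = sample_pos[assigned[ci]], sample_pos[second[ci]]
            spread = config.tag_noise_rate if k > 2 else 0.0
            p[:] = spread / (k - 2) if k > 2 else 0.0
            p[i1] = p[i2] = (1.0 - spread) / 2.0
        else:
            i1 = sample_pos[target]
            if k > 1:
                p[:] = config.tag_noise_rate / (k - 1)
            p[i1] = 1.0 - (config.tag_noise_rate if k > 1 else 0.0)
        counts = rng.multinomial(total, p)
        for t, c in zip(tags, counts):
            if c > 0:
                tag_rows.append((lab, t, int(c)))
    if tag_rows:
        tag_df = pd.DataFrame(tag_rows, columns=["cell_label", "feature", "reads"])
        tag_df["umi"] = _random_umis(rng, len(tag_df), L).astype(str)
        df = pd.concat(
            [df, tag_df[["cell_label", "umi", "feature", "reads"]]], ignore_index=True
        )

    df = df.reset_index(drop=True)

    truth = GroundTruth(
        cell_to_sample=cell_to_sample,
        real_cells=set(real_labels),
        clonotype_of_cell=clonotype_of_cell,
        dominant_clonotype_id=dominant_id,
        true_affinity=true_affinity,
        true_umi_parent=true_umi_parent,
        is_cd8=is_cd8,
    )
    truth.validate()
    return df, truth


def _random_junction(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 17))  # total length 10..18 with the C/F anchors
    body = "".join(_AA20[i] for i in rng.integers(0, 20, size=n))
    return f"C{body}F"


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=n))


def generate_airr_table(
    config: SimConfig,
    truth: GroundTruth,
    dropout_frac: float = 0.0,
    extra_chain_frac: float = 0.0,
) -> pd.DataFrame:
    """AIRR rearrangement rows (one chain per row) for every real cell.

    Each clonotype owns one fixed TRA and one fixed TRB chain (V call,
    J call, junction and full-length amino-acid sequence identical within
    the clonotype, distinct across clonotypes).  ``dropout_frac`` cells
    lose one chain and ``extra_chain_frac`` cells gain a second low-count
    chain, to exercise downstream pairing rules; cells of the dominant
    clonotype are exempt from dropout so the planted clone stays intact.
    """
    config.validate()
    if not 0.0 <= dropout_frac <= 1.0 or not 0.0 <= extra_chain_frac <= 1.0:
        raise ValueError("dropout_frac and extra_chain_frac must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    clones = sorted({*truth.clonotype_of_cell.values()})
    chains: dict[str, dict[str, tuple[str, str, str, str]]] = {}
    seen_junc: set[str] = set()
    for ct in clones:
        row = {}
        for locus, vs, js in (("TRA", _TRAV, _TRAJ), ("TRB", _TRBV, _TRBJ)):
            while True:
                junc = _random_junction(rng)
                if junc not in seen_junc:
                    seen_junc.add(junc)
                    break
            v = vs[int(rng.integers(0, len(vs)))]
            j = js[int(rng.integers(0, len(js)))]
            seq = _random_aa(rng, 20) + junc + _random_aa(rng, 20)
            row[locus] = (v, j, junc, seq)
        chains[ct] = row

    dominant_cells = {
        c for c, ct in truth.clonotype_of_cell.items()
        if ct == truth.dominant_clonotype_id
    }
    rows = []
    for cell in sorted(truth.real_cells):
        ct = truth.clonotype_of_cell[cell]
        drop_locus = None
        if cell not in dominant_cells and rng.random() < dropout_frac:
            drop_locus = "TRA" if rng.random() < 0.5 else "TRB"
        for locus in ("TRA", "TRB"):
            if locus == drop_locus:
                continue
            v, j, junc, seq = chains[ct][locus]
            dup = int(rng.integers(2, 30))
            rows.append((cell, locus, v, j, junc, seq, dup, True))
            if rng.random() < extra_chain_frac:
                # second, clearly lower-count chain of the same locus
                v2 = (_TRAV if locus == "TRA" else _TRBV)[int(rng.integers(0, 10))]
                j2 = (_TRAJ if locus == "TRA" else _TRBJ)[int(rng.integers(0, 10))]
                junc2 = _random_junction(rng)
                seq2 = _random_aa(rng, 20) + junc2 + _random_aa(rng, 20)
                rows.append((cell, locus, v2, j2, junc2, seq2, max(1, dup // 4), True))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "locus", "v_call", "j_call", "junction_aa",
            "sequence_aa", "duplicate_count", "productive",
        ],
    )


def generate_gex_matrices(config: SimConfig, truth: GroundTruth) -> list:
    """One targeted count matrix per sample (singlet cells only).

    Planted CD8+ cells have CD8 > 0 and CD4 = FOXP3 = 0; the remaining
    cells violate that pattern.  Non-marker panel genes follow an
    overdispersed (negative-binomial) count law.
    """
    from .expression import GexMatrix  # local import avoids a cycle

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    genes = list(config.panel_genes)
    g_idx = {g: i for i, g in enumerate(genes)}
    out = []
    for sample in config.sample_ids:
        cells = sorted(
            c for c, s in truth.cell_to_sample.items() if s == sample
        )
        n = len(cells)
        vals = rng.negative_binomial(2, 2.0 / 5.0, size=(n, len(genes))).astype(np.int64)
        cd8_col, cd4_col, fox_col = g_idx["CD8"], g_idx["CD4"], g_idx["FOXP3"]
        cd8 = np.array([truth.is_cd8[c] for c in cells], dtype=bool)
        vals[:, cd8_col] = np.where(cd8, 1 + rng.poisson(4.0, size=n), 0)
        vals[:, cd4_col] = np.where(cd8, 0, 1 + rng.poisson(4.0, size=n))
        vals[:, fox_col] = np.where(
            cd8, 0, np.where(rng.random(n) < 0.5, 1 + rng.poisson(2.0, size=n), 0)
        )
        out.append(
            GexMatrix(
                values=vals,
                cell_ids=list(cells),
                gene_names=list(genes),
                sample_ids=[sample] * n,
                stage="counts",
            )
        )
    return out


#: Noise-free plate geometry (arbitrary absorbance units).
_PLATE_OD = {"spontaneous": 0.20, "effector": 0.15, "max_lysis": 1.20}


def generate_cytotox_plate(
    true_pct: float, od_noise_sd: float, seed: int, replicates: int = 2
) -> CytotoxicityPlate:
    """LDH plate whose percent-cytotoxicity formula recovers ``true_pct``.

    ``od_noise_sd`` is expressed in percentage points of the assay dynamic
    range (max lysis minus spontaneous), i.e. well noise in OD units is
    ``od_noise_sd / 100 * (OD_max - OD_spont)``.
    """
    if not 0.0 <= true_pct <= 100.0:
        raise ValueError(f"true_pct must be in [0, 100] (got {true_pct})")
    if od_noise_sd < 0:
        raise ValueError(f"od_noise_sd must be non-negative (got {od_noise_sd})")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    span = _PLATE_OD["max_lysis"] - _PLATE_OD["spontaneous"]
    sd = od_noise_sd / 100.0 * span

    def wells(center: float) -> tuple[float, ...]:
        vals = center + rng.normal(0.0, sd, size=replicates) if sd > 0 else np.full(replicates, center)
        return tuple(np.maximum(vals, 0.0).tolist())

    et = _PLATE_OD["effector"] + true_pct / 100.0 * span
    plate = CytotoxicityPlate(
        od_effector_plus_target=wells(et),
        od_effector_only=wells(_PLATE_OD["effector"]),
        od_max_lysis=wells(_PLATE_OD["max_lysis"]),
        od_spontaneous=wells(_PLATE_OD["spontaneous"]),
    )
    plate.validate()
    return plate
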