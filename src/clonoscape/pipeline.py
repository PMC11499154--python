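"""End-to-end orchestration: simulate -> correct -> call cells -> demultiplex
-> normalize/gate -> clonotypes -> score -> select dominant.

One master seed (``SimConfig.seed``) drives every random stage, so an
identical configuration yields a byte-identical run report.  Stage wall
times are written to a separate ``timings.json`` so ``report.json`` stays
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import affinity, clonotypes, expression, molecules, synthetic
from .synthetic import GroundTruth, SimConfig

__all__ = ["StageParams", "PipelineConfig", "RunReport", "PipelineResult", "run_pipeline", "load_config", "demo_config"]

DEFAULT_PEPTIDE = "KVAELVHFL"


@dataclass(frozen=True)
class StageParams:
    """Tunable parameters of the non-simulation stages."""

    dbec_margin: float = 1.0
    knee_window: int = 5
    knee_tol: float = 0.01
    rsec_enabled: bool = True
    cd8_min: float = 0.0
    cd4_max: float = 0.0
    foxp3_max: float = 0.0
    min_cells: int = 2
    min_effector_frac: float = 0.5
    dropout_frac: float = 0.0
    extra_chain_frac: float = 0.0
    score_noise_sd: float = 0.05
    peptide: str = DEFAULT_PEPTIDE
    n_pca_components: int = 10
    n_pcs_umap: int = 4
    run_pca: bool = True
    run_umap: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stages: StageParams = field(default_factory=StageParams)

    @property
    def seed(self) -> int:
        return self.sim.seed

    def with_seed(self, seed: int) -> "PipelineConfig":
        return PipelineConfig(
            sim=dataclasses.replace(self.sim, seed=seed), stages=self.stages
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config with optional ``sim`` / ``stages`` sections."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimConfig(**raw.get("sim", {}))
    stages = StageParams(**raw.get("stages", {}))
    if "seed" in raw:
        sim = dataclasses.replace(sim, seed=int(raw["seed"]))
    return PipelineConfig(sim=sim, stages=stages)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Full-scale demo: ~5000 cells, ~3000 clonotypes, a 14-cell dominant
    clone, 99.9% CD8+ cells, and default noise levels."""
    return PipelineConfig(
        sim=SimConfig(
            seed=seed,
            n_real_cells=5000,
            n_noise_barcodes=5000,
            n_samples=3,
            reads_per_real_cell=300.0,
            reads_per_noise_barcode=10.0,
            n_clonotypes=3000,
            dominant_clone_size=14,
            frac_cd8=0.999,
            multiplet_rate=0.05,
            umi_error_rate=0.02,
            tag_noise_rate=0.02,
        ),
        stages=StageParams(),
    )


@dataclass
class RunReport:
    config: dict
    seed: int
    n_cells_called: int
    inflection_rank: int | None
    n_multiplets: int
    n_undetermined: int
    n_analysis_cells: int
    n_gated_cd8: int
    cd8_fraction: float
    n_clonotypes: int
    n_clonotypes_ge2: int
    n_cells_unpaired: int
    dominant: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PipelineResult:
    report: RunReport
    truth: GroundTruth
    cell_call: molecules.CellCallResult
    demux: molecules.DemuxResult
    gate_report: dict
    clonotype_table: pd.DataFrame
    abundant_table: pd.DataFrame
    dominant: clonotypes.DominantSelection
    embedding: expression.EmbeddingResult | None
    gex: expression.GexMatrix
    timings: dict[str, float]

    def dominant_is_planted(self) -> bool:
        """True when every recovered dominant member cell belongs to the
        planted dominant clonotype and the cell count matches its size."""
        truth = self.truth
        members = self.dominant.member_cells
        planted = {
            c for c, ct in truth.clonotype_of_cell.items()
            if ct == truth.dominant_clonotype_id
        }
        return set(members) == planted


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run every stage on freshly simulated inputs; optionally write artifacts."""
    timings: dict[str, float] = {}

    def _tick(name: str, t0: float) -> float:
        t1 = time.perf_counter()
        timings[name] = round(t1 - t0, 4)
        return t1

    t0 = time.perf_counter()
    sim, st = config.sim, config.stages

    mol, truth = synthetic.generate_molecule_table(sim)
    gene_mol, tag_mol = synthetic.split_tag_molecules(mol)
    t0 = _tick("simulate", t0)

    if st.rsec_enabled:
        gene_mol = molecules.rsec_correct(gene_mol)
    t0 = _tick("rsec", t0)

    dbec = molecules.dbec_filter(gene_mol, margin=st.dbec_margin)
    t0 = _tick("dbec", t0)

    call = molecules.call_cells(dbec.kept, window=st.knee_window, tol=st.knee_tol)
    valid = set(call.valid_labels)
    t0 = _tick("call_cells", t0)

    demux = molecules.demultiplex(tag_mol, valid)
    sample_ids = set(sim.sample_ids)
    analysis_cells = {c for c, s in demux.assignment.items() if s in sample_ids}
    t0 = _tick("demux", t0)

    gex_list = synthetic.generate_gex_matrices(sim, truth)
    merged = expression.merge_gex(gex_list)
    keep = [c for c in merged.cell_ids if c in analysis_cells]
    merged = merged.subset_cells(keep)
    log2m = expression.log2_zero_to_one(expression.cpm_normalize(merged))
    gated, gate_report = expression.gate_cd8(
        log2m, cd8_min=st.cd8_min, cd4_max=st.cd4_max, foxp3_max=st.foxp3_max
    )
    t0 = _tick("expression", t0)

    airr = synthetic.generate_airr_table(
        sim, truth, dropout_frac=st.dropout_frac, extra_chain_frac=st.extra_chain_frac
    )
    in_airr = set(airr["cell_id"])
    table, build_report = clonotypes.build_clonotypes(
        airr, {c for c in keep if c in in_airr}
    )
    t0 = _tick("clonotypes", t0)

    # binding scores through the external-predictor file dialect
    records = []
    truth_of_cell: dict[str, float] = {}
    for row in table.itertuples(index=False):
        for cell in row.member_cells:
            records.append(
                affinity.BindingRecord(
                    cell_index=cell,
                    cdr3a=row.cdr3a,
                    cdr3b=row.cdr3b,
                    peptide=st.peptide,
                    va=row.tra_v_call,
                    ja=row.tra_j_call,
                    vb=row.trb_v_call,
                    jb=row.trb_j_call,
                )
            )
            truth_of_cell[cell] = truth.true_affinity[truth.clonotype_of_cell[cell]]
    scored = affinity.score_records(
        records, truth_of_cell, noise_sd=st.score_noise_sd, seed=sim.seed
    )
    score_of_cell = {r.cell_index: r.score for r in scored}
    annotated = clonotypes.annotate_clonotypes(
        table, binding_score_of_cell=score_of_cell, effector_cells=gated
    )
    abundant = clonotypes.clonotype_abundance(annotated, min_cells=st.min_cells)
    dominant = clonotypes.select_dominant(
        annotated, min_effector_frac=st.min_effector_frac
    )
    t0 = _tick("scoring_selection", t0)

    embedding = None
    if st.run_pca:
        n_comp = min(st.n_pca_components, *log2m.values.shape)
        embedding = expression.pca_scree(log2m, n_components=n_comp)
        if st.run_umap:
            embedding = expression.umap_embed(
                embedding, n_pcs=min(st.n_pcs_umap, n_comp), seed=sim.seed
            )
    t0 = _tick("embedding", t0)

    report = RunReport(
        config={
            "sim": dataclasses.asdict(sim),
            "stages": dataclasses.asdict(st),
        },
        seed=sim.seed,
        n_cells_called=call.n_valid,
        inflection_rank=call.inflection_rank,
        n_multiplets=demux.n_multiplets,
        n_undetermined=sum(
            1 for s in demux.assignment.values() if s == "undetermined"
        ),
        n_analysis_cells=len(analysis_cells),
        n_gated_cd8=gate_report["n_gated"],
        cd8_fraction=gate_report["cd8_fraction"],
        n_clonotypes=len(table),
        n_clonotypes_ge2=len(abundant),
        n_cells_unpaired=build_report.n_excluded,
        dominant={
            "key": list(dominant.key),
            "n_cells": dominant.n_cells,
            "mean_binding_score": round(dominant.mean_binding_score, 6),
            "cdr3a": dominant.cdr3a,
            "cdr3b": dominant.cdr3b,
        },
    )

    result = PipelineResult(
        report=report,
        truth=truth,
        cell_call=call,
        demux=demux,
        gate_report=gate_report,
        clonotype_table=annotated,
        abundant_table=abundant,
        dominant=dominant,
        embedding=embedding,
        gex=log2m,
        timings=timings,
    )
    if out_dir is not None:
        _write_artifacts(result, airr, scored, Path(out_dir))
    return result


def _write_artifacts(
    result: PipelineResult,
    airr: pd.DataFrame,
    scored: list[affinity.BindingRecord],
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.report.to_json(out_dir / "report.json")
    (out_dir / "timings.json").write_text(json.dumps(result.timings, indent=1))
    (out_dir / "cell_calling.json").write_text(
        json.dumps(
            {
                "n_valid": result.cell_call.n_valid,
                "inflection_rank": result.cell_call.inflection_rank,
            }
        )
    )
    pd.DataFrame(
        sorted(result.demux.assignment.items()), columns=["cell_label", "assignment"]
    ).to_csv(out_dir / "demux.tsv", sep="\t", index=False)
    clonotypes.write_airr(airr, out_dir / "airr.tsv")
    tab = result.clonotype_table.copy()
    tab["member_cells"] = tab["member_cells"].map(",".join)
    tab.to_csv(out_dir / "clonotypes.tsv", sep="\t", index=False)
    (out_dir / "dominant.json").write_text(json.dumps(result.dominant.to_dict(), indent=1))
    result.gex.to_csv(out_dir / "normalized_log2cpm.csv")
    if result.embedding is not None:
        result.embedding.scree_frame().to_csv(out_dir / "scree.csv", index=False)
        if result.embedding.umap_coords is not None:
            pd.DataFrame(
                {
                    "cell_id": result.embedding.cell_ids,
                    "UMAP1": result.embedding.umap_coords[:, 0],
                    "UMAP2": result.embedding.umap_coords[:, 1],
                }
            ).to_csv(out_dir / "umap.csv", index=False)
    out_path = out_dir / "binding_scores.csv"
    rows = pd.DataFrame(
        [
            {
                "TRA": r.cdr3a, "TRB": r.cdr3b, "Peptide": r.peptide,
                "MHC": r.mhc_class, "TRAV": r.va, "TRAJ": r.ja,
                "TRBV": r.vb, "TRBJ": r.jb, "T-Cell-Type": r.t_cell_type,
                "cell_index": r.cell_index, "Score": r.score,
            }
            for r in scored
        ]
    )
    rows.to_csv(out_path, index=False)
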