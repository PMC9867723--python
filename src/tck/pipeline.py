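"""End-to-end pipeline driver: simulate/read -> preprocess -> statistics.

:func:`run_all` executes every stage in order — optional simulation,
preprocessing, activation-marker QC, the two-step differential procedure,
core-gene classification, MDS ordination, miRNA target matching and ORA —
writes one TSV/JSON artifact per stage into the output directory, and
returns a JSON-serialisable run report with all counts and the effective
configuration.  Given a seed, the run (and the report file) is
deterministic byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as tck_io
from . import enrichment, mirna, ordination, preprocess, simulate, stats
from .containers import CohortDesign, ExpressionMatrix, SchemaError

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Effective configuration of a full run.

    Defaults are the analysis constants the pipeline is built around:
    normexp offset 16, time-course gate 0.5 (log2), group gate 0.5 (log2),
    adjusted-p gate 0.05, PCC gate -0.5 and fold-change gate 0.3.
    """

    # thresholds
    tc_log2: float = 0.5
    grp_log2: float = 0.5
    alpha_adj: float = 0.05
    min_recurrence: int = 2
    # preprocessing
    offset: float = 16.0
    batch_correct: bool = True
    normexp_method: str = "mle"
    # miRNA gates
    theta_pcc: float = -0.5
    theta_fc: float = 0.3
    # ORA
    ora_min_size: int = 2
    # inputs (None -> simulate a synthetic cohort)
    matrix: str | None = None
    design: str | None = None
    gmt: list[str] = field(default_factory=list)
    targets: str | None = None
    reference: str | None = None
    # synthetic cohort
    sim: simulate.SimulationConfig | None = None
    drop_donor: str | None = "P5"
    drop_time_h: float | None = 4.0
    mirna_prefix: str = "MIR"
    marker_ids: list[str] = field(default_factory=list)
    # misc
    seed: int = 0
    gate_enabled: bool = True

    @property
    def thresholds(self) -> stats.Thresholds:
        return stats.Thresholds(
            tc_log2=self.tc_log2,
            grp_log2=self.grp_log2,
            alpha_adj=self.alpha_adj,
            min_recurrence=self.min_recurrence,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            d["sim"]["time_points_h"] = list(self.sim.time_points_h)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            if "time_points_h" in sim:
                sim["time_points_h"] = tuple(float(t) for t in sim["time_points_h"])
            cfg.sim = simulate.SimulationConfig(**sim)
        return cfg


def _axis_separation(coords: pd.DataFrame, groups: pd.Series) -> float:
    """Best single-axis threshold accuracy for separating the two groups."""
    best = 0.0
    g = (groups.loc[coords.index] == "PD").to_numpy()
    for col in coords.columns:
        x = coords[col].to_numpy()
        for thr in x:
            for side in (x <= thr, x > thr):
                acc = max((side == g).mean(), (side == ~g).mean())
                best = max(best, float(acc))
    return best


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write artifacts + ``report.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    report: dict = {
        "tck_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }

    # --- inputs ------------------------------------------------------------
    stage = "inputs"
    try:
        truth = None
        if config.matrix is not None:
            matrix = tck_io.read_matrix(config.matrix)
            design = tck_io.read_design(config.design)
            marker_ids = list(config.marker_ids)
        else:
            sim_cfg = config.sim or simulate.SimulationConfig(seed=config.seed)
            if config.sim is None:
                sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
            signals = simulate.default_signals(sim_cfg)
            matrix, design, truth = simulate.generate_cohort(sim_cfg, signals)
            if config.drop_donor is not None:
                matrix, design = simulate.drop_sample(
                    matrix, design, config.drop_donor, config.drop_time_h
                )
            simulate.write_fixture(matrix, design, truth, outdir / "fixture")
            marker_ids = truth.loc[
                truth["signal_class"] == "activation_shared", "feature_id"
            ].tolist()
        from .containers import check_matching

        check_matching(matrix, design)
        report["n_features"] = int(matrix.shape[0])
        report["n_samples"] = int(matrix.shape[1])
    except SchemaError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- preprocessing -----------------------------------------------------
    stage = "preprocess"
    try:
        log2m = preprocess.preprocess(
            matrix,
            design,
            offset=config.offset,
            batch_correct=config.batch_correct,
            normexp_method=config.normexp_method,
        )
        tck_io.write_matrix(log2m, outdir / "expression.log2.tsv", meta=meta)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- marker QC ---------------------------------------------------------
    stage = "marker_qc"
    try:
        if marker_ids:
            qc = stats.marker_qc(log2m, design, marker_ids)
            tck_io.write_table(qc["table"], outdir / "marker_qc.tsv", meta=meta)
            report["marker_qc"] = {
                "qc_pass": qc["qc_pass"],
                "induced": qc["induced"],
                "no_group_difference": qc["no_group_difference"],
                "markers_missing": qc["markers_missing"],
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- two-step differential analysis ------------------------------------
    stage = "differential"
    try:
        thresholds = config.thresholds
        gate = stats.timecourse_gate(log2m, design, thresholds)
        tck_io.write_table(
            gate.reset_index(names="feature_id"), outdir / "deviation.tsv", meta=meta
        )
        if config.gate_enabled:
            gated = gate.index[gate["passes_tc_gate"]]
        else:
            gated = log2m.feature_ids
        table = stats.differential_table(log2m, design, thresholds, gated)
        tck_io.write_table(table, outdir / "differential.tsv", meta=meta)
        core = stats.classify_core(table, thresholds)
        tck_io.write_table(core, outdir / "core_genes.tsv", meta=meta)
        venn = stats.window_venn(core)
        (outdir / "venn_counts.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
        report["n_gated"] = int(gate["passes_tc_gate"].sum())
        report["n_tested"] = int(len(gated))
        report["n_core"] = int(core["is_core"].sum())
        report["venn_counts"] = venn
        recur = core[core["is_core"] & (core["recurrence"] >= thresholds.min_recurrence)]
        report["n_core_recurrent"] = int(len(recur))
        report["n_core_recurrent_increased"] = int((recur["direction"] == "increased").sum())
        report["n_core_recurrent_decreased"] = int((recur["direction"] == "decreased").sum())
        report["n_core_recurrent_mixed"] = int((recur["direction"] == "mixed").sum())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- ordination ----------------------------------------------------------
    stage = "mds"
    try:
        dist = ordination.euclidean_distances(log2m, design, "per_donor_all_times")
        emb = ordination.classical_mds(dist, k=2)
        coords = emb.coordinates.copy()
        coords["group"] = dist.groups.loc[coords.index]
        tck_io.write_table(coords.reset_index(), outdir / "mds_coordinates.tsv", meta=meta)
        tck_io.write_table(
            pd.DataFrame({"eigenvalue": emb.eigenvalues}),
            outdir / "mds_eigenvalues.tsv",
            meta=meta,
        )
        report["mds"] = {
            "goodness_of_fit": round(emb.goodness_of_fit, 6),
            "axis_separation": round(
                _axis_separation(emb.coordinates, dist.groups), 6
            ),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- miRNA target matching ----------------------------------------------
    stage = "mirna"
    try:
        is_mirna = core["feature_id"].str.startswith(config.mirna_prefix)
        core_mirnas = core[
            is_mirna & core["is_core"] & core["direction"].isin(["increased", "decreased"])
        ]
        profiles = mirna.fc_profiles(table)
        gene_ids = [f for f in profiles.index if not f.startswith(config.mirna_prefix)]
        if len(core_mirnas) and len(gene_ids):
            gene_table = stats.differential_table(
                log2m, design, thresholds, pd.Index(gene_ids)
            ) if config.gate_enabled else table
            gene_profiles = mirna.fc_profiles(gene_table)
            gene_profiles = gene_profiles.loc[[g for g in gene_profiles.index
                                               if not g.startswith(config.mirna_prefix)]]
            matches = mirna.match_targets(
                profiles.loc[core_mirnas["feature_id"]],
                gene_profiles,
                core_mirnas.set_index("feature_id")["direction"],
                theta_pcc=config.theta_pcc,
                theta_fc=config.theta_fc,
            )
            if config.targets is not None:
                matches = mirna.intersect_validated(matches, tck_io.read_targets(config.targets))
            elif truth is not None:
                matches = mirna.intersect_validated(
                    matches, simulate.synthetic_target_table(truth)
                )
            tck_io.write_table(matches, outdir / "matches.tsv", meta=meta)
            full = matches[matches["match"]]
            report["mirna"] = {
                "n_core_mirnas": int(len(core_mirnas)),
                "n_matches": int(len(full)),
                "n_validated_matches": int(full["validated"].sum())
                if "validated" in full
                else None,
                "matches_per_mirna": {
                    m: int(c) for m, c in full["mirna_id"].value_counts().items()
                },
            }
        else:
            report["mirna"] = {"n_core_mirnas": int(len(core_mirnas)), "n_matches": 0}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- over-representation analysis ----------------------------------------
    stage = "ora"
    try:
        increased, decreased, excluded = enrichment.direction_split(
            core[~core["feature_id"].str.startswith(config.mirna_prefix)]
        )
        report["ora"] = {
            "n_increased": len(increased),
            "n_decreased": len(decreased),
            "n_excluded_mixed": len(excluded),
        }
        if config.gmt:
            collection = enrichment.GeneSetCollection.merge(
                [tck_io.read_gmt(p) for p in config.gmt]
            )
            reference = tck_io.read_reference(config.reference)
        elif truth is not None:
            sim_cfg = config.sim or simulate.SimulationConfig(seed=config.seed)
            collection = simulate.synthetic_gene_sets(sim_cfg, truth)
            reference = set(sim_cfg.gene_ids())
        else:
            collection = None
        if collection is not None:
            for label, genes in (("increased", increased), ("decreased", decreased)):
                if not genes:
                    report["ora"][f"n_enriched_{label}"] = 0
                    continue
                res = enrichment.ora(genes, collection, reference, config.ora_min_size)
                tck_io.write_table(res, outdir / f"ora_{label}.tsv", meta=meta)
                sig = res[res["p_adj"] <= config.alpha_adj]
                report["ora"][f"n_enriched_{label}"] = int(len(sig))
                report["ora"][f"top_set_{label}"] = (
                    str(res.iloc[0]["set_name"]) if len(res) else None
                )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
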