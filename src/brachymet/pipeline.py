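"""End-to-end orchestration: simulate -> preprocess -> ANOVA/DAM ->
annotate -> enrich -> classify, with per-stage logging and a run
manifest.  Identical config and seed give byte-identical outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import damstats, fragid, pathenrich, synthdata
from .featuretable import FeatureTable, preprocess, read_feature_table, write_feature_table
from .library import load_compound_library
from .synthdata import SimulationConfig

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "brachymet_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_dam: bool = True
    run_annotate: bool = True
    run_enrich: bool = True
    run_classify: bool = True
    # inputs when simulation is disabled
    feature_table: str | None = None
    design_table: str | None = None
    # stage parameters
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    p_max: float = 0.01
    min_abs_log2_fc: float = 1.0
    bh: bool = False
    tol_ppm: float = 5.0
    permutations: int = 2000
    fdr_max: float = pathenrich.FDR_MAX
    impact_min: float = pathenrich.IMPACT_MIN
    n_components: int = 3

    def validate(self) -> None:
        if self.run_enrich and not self.run_annotate:
            raise PipelineError("enrichment requires the annotation stage")
        if self.run_dam and not (self.run_simulate or
                                 (self.feature_table and self.design_table)):
            raise PipelineError("dam stage needs simulated or provided input tables")
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def run(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run report (per-stage row counts and the output
    manifest), which is also written as ``report.json`` next to the
    outputs together with the effective config.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": {}}
    manifest = report["outputs"]

    cfg_sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    cfg_dump = {**cfg.to_dict(), "simulation": dataclasses.asdict(cfg_sim)}
    cfg_dump.pop("out_dir")          # keep the effective config path-free
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_dump, sort_keys=True))

    library = load_compound_library()

    if cfg.run_simulate:
        table, truth = synthdata.simulate(cfg_sim, library=library)
        write_feature_table(table, out / "features.tsv", out / "design.tsv")
        pd.DataFrame([
            {"feature_id": t.feature_id, "line_shift": t.line_shift,
             **{f"dam_{o}": t.is_planted_dam[o] for o in t.is_planted_dam}}
            for t in truth]).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        manifest["features"] = "features.tsv"
        manifest["design"] = "design.tsv"
        manifest["ground_truth"] = "ground_truth.tsv"
        report["stages"]["simulate"] = {"n_features": table.n_features,
                                        "n_samples": table.n_samples}
        log.info("simulate: %d features x %d samples", table.n_features, table.n_samples)
    else:
        if not (cfg.feature_table and cfg.design_table):
            raise PipelineError("simulation disabled and no input tables given")
        table = read_feature_table(cfg.feature_table, cfg.design_table)
        report["stages"]["load"] = {"n_features": table.n_features,
                                    "n_samples": table.n_samples}

    prep = preprocess(table)
    report["stages"]["preprocess"] = {"n_features_in": table.n_features,
                                      "n_features_out": prep.n_features}

    dams = None
    if cfg.run_dam:
        anova = damstats.anova_all(prep)
        fcs = damstats.fold_change_per_organ(prep)
        dams = damstats.select_dams(anova, fcs, cfg.p_max, cfg.min_abs_log2_fc, cfg.bh)
        partition = damstats.effect_partition(anova, cfg.p_max)
        scores, explained = damstats.pca_scores(prep, cfg.n_components)
        anova.to_csv(out / "anova.tsv", sep="\t")
        dams.to_csv(out / "dams.tsv", sep="\t", index=False)
        scores.to_csv(out / "pca_scores.tsv", sep="\t")
        (out / "venn_counts.json").write_text(json.dumps(
            {"regions": partition.venn,
             "explained_variance": [float(v) for v in explained]}, indent=2))
        manifest.update(anova="anova.tsv", dams="dams.tsv",
                        pca="pca_scores.tsv",
                        venn="venn_counts.json")
        n_dam = int(dams.groupby("feature_id")["passes"].any().sum())
        report["stages"]["dam"] = {"n_tested": len(anova), "n_dam_features": n_dam}
        log.info("dam: %d features tested, %d DAMs", len(anova), n_dam)

    annotated = None
    if cfg.run_annotate:
        graph = pathenrich.load_pathway_graph()
        queries = list(zip(prep.features["mz"], prep.features["polarity"]))
        hits = pathenrich.annotate_mz_list(queries, graph, cfg.tol_ppm)
        per_feature = {fid: sorted(h) for fid, (q, h) in
                       zip(prep.features["feature_id"], hits.items())}
        annotated = per_feature
        pd.DataFrame([(f, ";".join(c)) for f, c in per_feature.items() if c],
                     columns=["feature_id", "compound_ids"]).to_csv(
            out / "annotations.tsv", sep="\t", index=False)
        manifest["annotations"] = "annotations.tsv"
        n_hit = sum(bool(c) for c in per_feature.values())
        report["stages"]["annotate"] = {"n_queries": len(per_feature),
                                        "n_annotated": n_hit}
        log.info("annotate: %d/%d m/z annotated", n_hit, len(per_feature))

    if cfg.run_enrich:
        reference = set().union(*annotated.values()) if annotated else set()
        if dams is not None:
            dam_ids = set(dams.loc[dams["passes"], "feature_id"])
            significant = set().union(
                *(annotated[f] for f in dam_ids if f in annotated)) if dam_ids else set()
        else:
            significant = reference
        significant &= reference
        rows = pathenrich.enrich_pathways(significant, reference, graph,
                                          cfg.permutations, cfg.seed)
        enr = pathenrich.enrichment_table(rows)
        enr["selected"] = (enr["fdr"] < cfg.fdr_max) & (enr["impact"] > cfg.impact_min)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["enrichment"] = "enrichment.tsv"
        report["stages"]["enrich"] = {
            "n_reference": len(reference), "n_significant": len(significant),
            "n_selected": int(enr["selected"].sum())}
        log.info("enrich: %d significant of %d reference compounds",
                 len(significant), len(reference))

    if cfg.run_classify:
        replay = fragid.replay_fixtures(library)
        replay.to_csv(out / "replay.tsv", sep="\t", index=False)
        manifest["replay"] = "replay.tsv"
        report["stages"]["classify"] = {
            "n_fixtures": len(replay),
            "n_agree": int(replay["agree"].sum()),
            "n_msi1": int((replay["msi_level"] == 1).sum())}
        log.info("classify: %d/%d fixtures agree", replay["agree"].sum(), len(replay))

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest["report"] = "report.json"
    return report
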