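"""End-to-end orchestration: simulate or ingest -> QC/filter -> diversity ->
enterotypes -> growth classes -> associations -> prediction.

One global seed deterministically derives a seed per stage (hash of
``(global_seed, stage_name)``), so a stage's randomness is isolated from
upstream changes in random consumption.  Every filter logs counts in/out and
the report carries them, so sample bookkeeping is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, association, cohort, diversity, enterotype, growth, predict
from .tables import (
    CountTable,
    RelAbundanceTable,
    read_count_table,
    read_metadata,
    read_taxonomy,
)

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    outdir: str = "weanotype_run"
    seed: int = 0
    # input: either explicit paths or the built-in simulator
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = True
    cohort_config: "cohort.CohortConfig | None" = None  # override simulator defaults
    # stage parameters
    min_reads: int = abundance.DEFAULT_MIN_READS
    min_prevalence: int = abundance.DEFAULT_MIN_PREVALENCE
    min_frac_total: float = abundance.DEFAULT_MIN_FRAC_TOTAL
    rarefaction_depth: int = abundance.DEFAULT_RAREFACTION_DEPTH
    beta_metric: str = "bray_curtis"
    n_perm_beta: int = 999
    k_range: tuple[int, int] = (2, 8)
    pseudocount: float = 1e-6
    n_silhouette_subsets: int = 100
    lower_frac: float = 0.40
    upper_frac: float = 0.40
    alpha_pre: float = 0.1
    n_perm_two_step: int = 5000
    p_max: int = 10
    preselect_m: int = 10
    run_silhouette: bool = True
    run_two_step: bool = True
    run_prediction: bool = True


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the report dict and
    writes per-stage TSVs plus ``report.json`` under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def run_stage(name, fn):
        try:
            value = fn()
        except Exception as exc:  # noqa: BLE001 - report which stage failed
            _write_report(report, out)
            raise StageError(name, exc) from exc
        report["stages"][name] = value if value is not None else {}
        return value

    state: dict = {}

    def ingest():
        if config.simulate and config.counts_path is None:
            cfg = config.cohort_config or cohort.calibrate_default_config()
            syn = cohort.generate(cfg, seed=stage_seed(config.seed, "simulate"))
            syn.write(out / "simulated")
            state.update(counts=syn.counts, taxonomy=syn.taxonomy, metadata=syn.metadata)
            return {
                "mode": "simulated",
                "n_samples": len(syn.counts.sample_ids),
                "n_otus": len(syn.counts.otu_ids),
                "calibration": {k: v for k, v in cfg.calibration.items()
                                if k != "expected_phylum_shares"},
            }
        state.update(
            counts=read_count_table(config.counts_path),
            taxonomy=read_taxonomy(config.taxonomy_path),
            metadata=read_metadata(config.metadata_path),
        )
        return {
            "mode": "files",
            "n_samples": len(state["counts"].sample_ids),
            "n_otus": len(state["counts"].otu_ids),
        }

    run_stage("ingest", ingest)

    def filter_stage():
        counts = state["counts"]
        n0 = len(counts.sample_ids)
        qc = abundance.qc_filter_samples(counts, config.min_reads)
        filtered = abundance.filter_otus(
            qc, state["taxonomy"], config.min_prevalence, config.min_frac_total
        )
        meta = state["metadata"].data.loc[filtered.data.index]
        state["filtered"] = filtered
        state["meta"] = meta
        per_age = meta["age_point"].value_counts().to_dict()
        return {
            "samples_in": n0,
            "samples_after_qc": len(qc.sample_ids),
            "otus_in": len(counts.otu_ids),
            "otus_after_filter": len(filtered.otu_ids),
            "samples_per_age": per_age,
        }

    run_stage("filter", filter_stage)

    def diversity_stage():
        filtered = state["filtered"]
        meta = state["meta"]
        rare = abundance.rarefy(filtered, config.rarefaction_depth,
                                seed=stage_seed(config.seed, "rarefy"))
        alpha_div = diversity.alpha(rare)
        alpha_div.join(meta[["age_point", "farm_id"]]).to_csv(out / "alpha.tsv", sep="\t")
        rel = abundance.to_relative(rare)
        dist = diversity.distance(rel, metric=config.beta_metric)
        dist.to_tsv(out / "beta_distances.tsv")
        seed = stage_seed(config.seed, "beta")
        perma_age = diversity.permanova(dist, meta["age_point"], config.n_perm_beta, seed)
        disp_age = diversity.dispersion_test(dist, meta["age_point"], config.n_perm_beta, seed)
        disp_farm = diversity.dispersion_test(dist, meta["farm_id"], config.n_perm_beta, seed)
        perma_farm = diversity.permanova(dist, meta["farm_id"], config.n_perm_beta, seed)
        by_age = alpha_div.groupby(meta["age_point"]).mean()
        return {
            "metric": config.beta_metric,
            "alpha_by_age": by_age.round(4).to_dict(),
            "permanova_age": {k: perma_age[k] for k in ("F", "p")},
            "dispersion_age": {k: disp_age[k] for k in ("F", "p")},
            "permanova_farm": {k: perma_farm[k] for k in ("F", "p")},
            "dispersion_farm": {k: disp_farm[k] for k in ("F", "p")},
            "dispersion_caveat": (
                "farm dispersions are heterogeneous; interpret the farm "
                "PERMANOVA location test with caution"
                if disp_farm["p"] < 0.05 else ""
            ),
        }

    run_stage("diversity", diversity_stage)

    def enterotype_stage():
        filtered = state["filtered"]
        taxonomy = state["taxonomy"]
        rel_genus = abundance.to_relative(abundance.aggregate(filtered, taxonomy, "genus"))
        state["rel_genus"] = rel_genus
        sol = enterotype.choose_k(rel_genus, config.k_range, config.pseudocount)
        if config.run_silhouette:
            sol = enterotype.silhouette_validation(
                rel_genus, sol, config.n_silhouette_subsets,
                seed=stage_seed(config.seed, "silhouette"),
            )
        state["solution"] = sol
        sol.labels.to_frame().to_csv(out / "enterotype_labels.tsv", sep="\t")
        sol.ch_curve.rename("CH").rename_axis("K").to_csv(out / "ch_curve.tsv", sep="\t")
        trans = enterotype.transitions(sol.labels, state["metadata"])
        trans.counts.to_csv(out / "transitions.tsv", sep="\t")
        return {
            "K": sol.k,
            "ch_curve": sol.ch_curve.round(2).to_dict(),
            "mean_silhouette": round(sol.mean_silhouette, 4),
            "silhouette_percentile": sol.silhouette_percentile,
            "weak_structure": sol.weak_structure,
            "shift_fraction": round(trans.shift_fraction, 4),
            "n_complete_pigs": trans.n_pigs,
        }

    run_stage("enterotype", enterotype_stage)

    def growth_stage():
        records = growth.compute_radg(state["metadata"])
        records = growth.classify_within_farm(records, config.lower_frac, config.upper_frac)
        state["growth"] = records
        records.to_csv(out / "growth.tsv", sep="\t")
        summary = growth.class_summary(records)
        return {"class_summary": summary.table.round(3).to_dict(orient="index")}

    run_stage("growth", growth_stage)

    def associate_stage():
        rel_genus = state["rel_genus"]
        taxonomy = state["taxonomy"]
        meta_obj = state["metadata"]
        rel_family = abundance.to_relative(
            abundance.aggregate(state["filtered"], taxonomy, "family")
        )
        meta = state["meta"]
        result: dict = {}
        pc = association.percent_change(rel_family, meta_obj)
        pc.to_csv(out / "family_percent_change.tsv", sep="\t")
        headline = pc["percent_change"].reindex(
            ["Prevotellaceae", "Bacteroidaceae", "Enterobacteriaceae",
             "Christensenellaceae", "Clostridiaceae", "Lachnospiraceae"]
        )
        result["family_percent_change"] = headline.round(1).to_dict()
        for age in ("d26", "d35"):
            sub = RelAbundanceTable(rel_family.data[meta["age_point"] == age])
            kw = association.kruskal_dunn(sub, meta["farm_id"])
            result[f"farm_effect_{age}"] = {
                "n_significant_raw": int((kw.table["p"] < 0.05).sum()),
                "n_significant_adj": int((kw.table["p_adj"] < 0.05).sum()),
            }
        if config.run_two_step:
            ts = association.two_step_radg(
                rel_genus, state["growth"], meta_obj,
                alpha_pre=config.alpha_pre, n_perm=config.n_perm_two_step,
                seed=stage_seed(config.seed, "two_step"),
            )
            ts.step1.to_csv(out / "two_step_step1.tsv", sep="\t")
            ts.step2.to_csv(out / "two_step_step2.tsv", sep="\t")
            result["two_step"] = {
                "n_retained": int(ts.step1["retained"].sum()),
                "interaction_significant": list(
                    ts.step2.index[ts.step2["p_interaction"] < 0.05]
                ),
            }
        return result

    run_stage("associate", associate_stage)

    if config.run_prediction:
        def predict_stage():
            taxonomy = state["taxonomy"]
            meta_obj = state["metadata"]
            records = state["growth"]
            rel_family = abundance.to_relative(
                abundance.aggregate(state["filtered"], taxonomy, "family")
            )
            rel_genus = state["rel_genus"]
            pre = predict.preselect_otus(
                abundance.to_relative(state["filtered"]), meta_obj, records,
                m=config.preselect_m,
            )
            rel_otu = abundance.to_relative(state["filtered"])
            picked = sorted(set(pre["d26"]) | set(pre["d35"]))
            joined = pd.concat(
                [rel_family.data, rel_genus.data, rel_otu.data[picked]], axis=1
            )
            joined = joined.loc[:, ~joined.columns.duplicated()]
            X = predict.build_feature_matrix(
                {"d26": joined, "d35": joined}, meta_obj
            )
            radg = records["radg"]
            X = X.loc[X.index.intersection(radg.index)]
            model = predict.best_subset(X, radg, p_max=config.p_max)
            per_farm, mean_r2 = predict.leave_one_farm_out(
                X, radg, records["farm_id"], model.features
            )
            base = predict.best_subset(
                records.loc[X.index, ["weight_d26"]], radg, p_max=1
            )
            base_farm, base_mean = predict.leave_one_farm_out(
                records.loc[X.index, ["weight_d26"]], radg,
                records["farm_id"], base.features,
            )
            model.coefficients.rename("estimate").rename_axis("variable").to_csv(
                out / "prediction_model.tsv", sep="\t")
            per_farm.to_csv(out / "prediction_cv.tsv", sep="\t")
            return {
                "selected": model.features,
                "in_sample_adjusted_r2": round(model.adjusted_r2, 4),
                "cv_mean_adjusted_r2": round(mean_r2, 4),
                "weight_only_cv_r2": round(base_mean, 4),
                "search": model.search,
            }

        run_stage("predict", predict_stage)

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=default, sort_keys=True))
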