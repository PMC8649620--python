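"""Orchestration of the full paired-tumor analysis.

Stage order mirrors the analysis narrative: simulate (or load) the cohort,
call and tabulate somatic events, paired differential expression, gene-set
enrichment and overlap, signature derivation with survival validation on
an independent cohort, and consensus subtyping of the pair-centered
profiles. Each stage writes its tables under the output directory and
contributes a section to the JSON run report; a stage failure aborts with
the stage name while preserving completed outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, diffexp, enrichment, io, somatic_events, survival, synthetic_data

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_tables"]


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None  # fixture directory when simulate is False
    alphas: tuple = (0.001, 0.01, 0.05)
    signature_alpha: float = 0.001
    # top-variable gene count for clustering; None selects the analysis's
    # standard fraction of the matrix (2000 of 16503 genes ~ 12%)
    top_variable: int | None = None
    marker_top_n: int = 200
    k_min: int = 2
    k_max: int = 10
    n_resamples: int = 250
    subsample_fraction: float = 0.8
    n_perm: int = 1000
    forced_k: int | None = None
    sim: synthetic_data.SimulationConfig = field(default=None)

    def __post_init__(self):
        if self.sim is None:
            self.sim = synthetic_data.SimulationConfig(seed=self.seed)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report["failed_stage"] = name
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    with _stage(report, "simulate"):
        if config.simulate:
            cohort = synthetic_data.generate_cohort(config.sim)
            somatic = synthetic_data.generate_somatic_tables(
                config.sim, cohort.pairing, cohort.expression
            )
            vexpr, vclin, vtruth = synthetic_data.generate_validation_cohort(
                config.sim, cohort.truth
            )
            synthetic_data.write_fixture(cohort, somatic, out / "fixture", force=True)
            expr = somatic.expression
            pairing, clinical = cohort.pairing, cohort.clinical
            truth = cohort.truth
        else:
            if config.input_dir is None:
                raise ValueError("simulate=False requires input_dir")
            d = Path(config.input_dir)
            expr = io.read_expression(d / "expression.tsv")
            pairing = io.read_pairing(d / "pairing.tsv")
            clinical = io.read_clinical(d / "clinical.tsv")
            somatic = synthetic_data.SomaticTables(
                io.read_maf(d / "variants.tsv"),
                io.read_cna(d / "cna.tsv"),
                io.read_breakpoints(d / "breakpoints.tsv"),
                io.read_annotation(d / "annotation.tsv"),
                expr,
                synthetic_data.SyntheticTruth(),
            )
            cohort = truth = vexpr = vclin = vtruth = None
        report["stages"].append("simulate")
        report["simulate"] = {
            "n_patients": int(pairing["patient_id"].nunique()),
            "n_pairs": int(len(pairing)),
            "n_genes": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
        }

    with _stage(report, "events"):
        ann = somatic.annotation
        events = somatic_events.call_snv_events(somatic.variants, ann)
        events += somatic_events.call_cna_events(somatic.cna, ann)
        stats = somatic_events.cohort_reference_stats(expr)
        events += somatic_events.call_sv_expression_events(
            somatic.breakpoints, expr, ann, stats
        )
        # the somatic tables cover the WGS subcohort: its samples are the
        # CNA matrix columns
        wgs_samples = set(somatic.cna.columns)
        sub_pairing = pairing[pairing["initial_sample_id"].isin(wgs_samples)]
        summaries = somatic_events.tabulate_paired_events(events, sub_pairing)
        gained = [s.gained_count for s in summaries]
        lost = [s.lost_count for s in summaries]
        test = somatic_events.paired_count_test(lost, gained)
        somatic_events.event_matrix(events).to_csv(out / "event_matrix.tsv", sep="\t")
        pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in summaries],
                "gained_count": gained,
                "lost_count": lost,
            }
        ).to_csv(out / "paired_events.tsv", sep="\t", index=False)
        report["stages"].append("events")
        report["events"] = {
            "n_events": len(events),
            "n_patients": len(summaries),
            "patients_with_gain": int(sum(g > 0 for g in gained)),
            "mean_gained": float(np.mean(gained)) if summaries else 0.0,
            "mean_lost": float(np.mean(lost)) if summaries else 0.0,
            "paired_t": test.t,
            "paired_p": test.p,
        }

    with _stage(report, "diffexp"):
        norm = diffexp.quantile_normalize(expr)
        stats_table = diffexp.moderated_paired_t(norm, pairing)
        io.write_gene_stats(stats_table, out / "gene_stats.tsv")
        counts = {}
        for alpha in config.alphas:
            n_sig = int((stats_table["p"] < alpha).sum())
            exp = diffexp.expected_by_chance(len(stats_table), alpha)
            counts[str(alpha)] = {"significant": n_sig, "chance_expected": exp.expected}
        sig_genes = stats_table.index[stats_table["p"] < config.signature_alpha]
        diffs = diffexp.paired_differences(norm, pairing)
        purity = clinical.set_index("sample_id")["purity"]
        adj = diffexp.purity_adjusted_association(
            diffs.loc[sig_genes], purity, pairing
        )
        adj.to_csv(out / "purity_adjusted.tsv", sep="\t")
        report["stages"].append("diffexp")
        report["diffexp"] = {
            "n_pairs": stats_table.attrs["n_pairs"],
            "d0": stats_table.attrs["d0"],
            "s0_sq": stats_table.attrs["s0_sq"],
            "counts_vs_chance": counts,
            "purity_robust": int((adj["p"] < 0.01).sum()),
            "n_signature_candidates": int(len(sig_genes)),
        }

    with _stage(report, "enrichment"):
        ranking = stats_table["t"].sort_values(ascending=False, kind="stable")
        rng = np.random.default_rng(config.seed + 7)
        decoys = {
            f"decoy_{i}": list(
                np.asarray(stats_table.index)[
                    rng.choice(len(stats_table), size=50, replace=False)
                ]
            )
            for i in range(3)
        }
        sets: dict[str, list] = {}
        if truth is not None:
            sets["planted_up"] = list(truth.planted_up)
            sets["planted_down"] = list(truth.planted_down)
            for k, prog in truth.subset_programs.items():
                sets[f"subset_program_{k}"] = list(prog)
        sets.update(decoys)
        io.write_gmt(sets, out / "gene_sets.gmt")
        gsea = enrichment.preranked_gsea(ranking, sets, config.n_perm, config.seed + 11)
        gsea.to_csv(out / "gsea.tsv", sep="\t", index=False)
        overlap = None
        if truth is not None:
            sig = survival.derive_signature(stats_table, config.signature_alpha)
            overlap_res = enrichment.hypergeometric_overlap(
                len(stats_table),
                sorted(sig.genes),
                list(truth.planted_up) + list(truth.planted_down),
            )
            overlap = vars(overlap_res)
        report["stages"].append("enrichment")
        report["enrichment"] = {
            "n_sets_tested": int(len(gsea)),
            "results": gsea.to_dict("records"),
            "signature_vs_planted_overlap": overlap,
        }

    with _stage(report, "signature_survival"):
        sig = survival.derive_signature(stats_table, config.signature_alpha)
        io.write_json(
            {
                "up_genes": sorted(sig.up_genes),
                "down_genes": sorted(sig.down_genes),
                "alpha": sig.alpha_used,
            },
            out / "signature.json",
        )
        surv_report: dict = {
            "n_up": len(sig.up_genes),
            "n_down": len(sig.down_genes),
        }
        if vexpr is not None:
            centered = survival.median_center(vexpr)
            scores = survival.score_cohort(centered, sig)
            scores.to_csv(out / "validation_scores.tsv", sep="\t", index_label="sample_id")
            vcl = vclin.set_index("sample_id").loc[scores.index]
            times = vcl["os_time"].to_numpy(float)
            evs = vcl["os_event"].to_numpy(int)
            z = (
                (scores["t_score"] - scores["t_score"].mean())
                / scores["t_score"].std(ddof=1)
            ).to_numpy()
            cox = survival.cox_fit(z, times, evs)
            cox_strat = survival.cox_fit(z, times, evs, strata=vcl["histology"].to_numpy())
            lr = survival.logrank_test(times, evs, scores["tertile"].to_numpy())
            lr_strat = survival.logrank_test(
                times, evs, scores["tertile"].to_numpy(), strata=vcl["histology"].to_numpy()
            )
            rho = float(
                pd.Series(scores["t_score"]).corr(
                    pd.Series({s: vtruth.true_scores[s] for s in scores.index}),
                    method="spearman",
                )
            )
            surv_report.update(
                {
                    "n_validation": int(len(scores)),
                    "cox_hr_per_sd": cox.hr,
                    "cox_p": cox.p_wald,
                    "cox_hr_per_sd_stratified": cox_strat.hr,
                    "cox_p_stratified": cox_strat.p_wald,
                    "logrank_tertiles_p": lr.p,
                    "logrank_tertiles_p_stratified": lr_strat.p,
                    "score_truth_spearman": rho,
                }
            )
        report["stages"].append("signature_survival")
        report["signature_survival"] = surv_report

    with _stage(report, "cluster"):
        diffs = clustering.pair_center(norm, pairing)
        if config.top_variable is None:
            n_var = min(2000, max(10, round(diffs.shape[0] * 2000 / 16503)))
        else:
            n_var = min(config.top_variable, diffs.shape[0])
        top = clustering.top_variable_genes(diffs, n_var)
        result = clustering.consensus_cluster(
            diffs.loc[top],
            config.k_min,
            config.k_max,
            config.n_resamples,
            config.subsample_fraction,
            config.seed + 13,
        )
        k = clustering.choose_k(result, forced_k=config.forced_k)
        labels = result.labels[k]
        pd.DataFrame(
            {"sample_id": labels.index, "k": k, "label": labels.to_numpy()}
        ).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "k": result.k_range,
                "cdf_area": [result.cdf_area[kk] for kk in result.k_range],
                "delta_area": [result.delta_area[kk] for kk in result.k_range],
            }
        ).to_csv(out / "delta_area.tsv", sep="\t", index=False)
        markers = clustering.subset_markers(diffs, labels, config.marker_top_n)
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        lr_sub, patient_labels = clustering.subset_survival(
            labels, clinical, pairing
        )
        cluster_report = {
            "chosen_k": k,
            "subset_sizes": labels.value_counts().sort_index().to_dict(),
            "delta_area": {str(kk): result.delta_area[kk] for kk in result.k_range},
            "subset_survival_p": lr_sub.p,
            "n_discordant_patients": int(patient_labels["discordant_tumors"].sum()),
        }
        if truth is not None and truth.subset_labels:
            from sklearn.metrics import adjusted_rand_score

            true_labels = [truth.subset_labels[s] for s in labels.index]
            cluster_report["ari_vs_truth"] = float(
                adjusted_rand_score(true_labels, labels.to_numpy())
            )
        report["stages"].append("cluster")
        report["cluster"] = cluster_report

    io.write_json(report, out / "run_report.json")
    return report


TABLE_SCHEMAS = {
    "pairing": io.PAIRING_COLUMNS,
    "clinical": io.CLINICAL_COLUMNS,
    "variants": io.MAF_COLUMNS,
    "breakpoints": io.BREAKPOINT_COLUMNS,
    "annotation": io.ANNOTATION_COLUMNS,
}


def validate_tables(paths: dict, strict: bool = False) -> list[str]:
    """Schema and cross-reference checks over a set of input tables.

    ``paths`` maps table names (expression, pairing, clinical, variants,
    cna, breakpoints, annotation) to file paths. Violations are returned
    as messages (and raised collectively when ``strict``).
    """
    violations: list[str] = []
    loaded: dict = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            violations.append(f"{name}: file not found: {path}")
            continue
        try:
            if name == "expression":
                loaded[name] = io.read_expression(path)
            elif name == "cna":
                loaded[name] = io.read_cna(path)
            elif name in TABLE_SCHEMAS:
                reader = {
                    "pairing": io.read_pairing,
                    "clinical": io.read_clinical,
                    "variants": io.read_maf,
                    "breakpoints": io.read_breakpoints,
                    "annotation": io.read_annotation,
                }[name]
                loaded[name] = reader(path)
            else:
                violations.append(f"{name}: unknown table kind")
        except Exception as exc:  # parse errors reported, not raised
            violations.append(f"{name}: {exc}")
    if "expression" in loaded and "pairing" in loaded:
        samples = set(loaded["expression"].columns)
        for col in ("initial_sample_id", "recurrent_sample_id"):
            for s in loaded["pairing"][col]:
                if s not in samples:
                    violations.append(f"pairing: sample {s!r} absent from expression")
    if "pairing" in loaded and "variants" in loaded:
        known = set(loaded["pairing"]["initial_sample_id"]) | set(
            loaded["pairing"]["recurrent_sample_id"]
        )
        for s in set(loaded["variants"]["sample_id"]) - known:
            violations.append(f"variants: sample {s!r} absent from pairing")
    if strict and violations:
        raise ValueError("table validation failed:\n" + "\n".join(violations))
    return violations
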