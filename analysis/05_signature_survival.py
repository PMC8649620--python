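#!/usr/bin/env python
"""Score the validation cohort for the recurrence/progression signature.

Derives the signature (p<0.001 genes split by direction), t-scores every
tumor of the independent validation cohort on median-centered expression,
and tests the score against overall survival: continuous Cox (plain and
histology-stratified), tertile log-rank, Kaplan-Meier curves per tertile,
and a per-gene stratified Cox scan.
"""

from pathlib import Path

from pairedprog import io, survival

COHORT = Path("results/cohort")
OUT = Path("results/survival")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stats = io.read_gene_stats(Path("results/diffexp/gene_stats.tsv"))
    sig = survival.derive_signature(stats, 0.001)
    io.write_json(
        {"up_genes": sorted(sig.up_genes), "down_genes": sorted(sig.down_genes),
         "alpha": sig.alpha_used},
        OUT / "signature.json",
    )
    print(f"signature: {len(sig.up_genes)} up + {len(sig.down_genes)} down genes "
          f"at p<{sig.alpha_used}")

    vexpr = io.read_expression(COHORT / "validation_expression.tsv")
    vclin = io.read_clinical(COHORT / "validation_clinical.tsv").set_index("sample_id")
    scores = survival.score_cohort(survival.median_center(vexpr), sig)
    scores.to_csv(OUT / "scores.tsv", sep="\t", index_label="sample_id")

    clin = vclin.loc[scores.index]
    times = clin["os_time"].to_numpy(float)
    events = clin["os_event"].to_numpy(int)
    z = ((scores["t_score"] - scores["t_score"].mean())
         / scores["t_score"].std(ddof=1)).to_numpy()
    cox = survival.cox_fit(z, times, events)
    cox_s = survival.cox_fit(z, times, events, strata=clin["histology"].to_numpy())
    lr = survival.logrank_test(times, events, scores["tertile"].to_numpy())
    lr_s = survival.logrank_test(times, events, scores["tertile"].to_numpy(),
                                 strata=clin["histology"].to_numpy())
    print(f"continuous Cox: HR per SD = {cox.hr:.2f} (p={cox.p_wald:.2g}); "
          f"stratified HR = {cox_s.hr:.2f} (p={cox_s.p_wald:.2g})")
    print(f"tertile log-rank: p={lr.p:.2g}; stratified p={lr_s.p:.2g}")

    for tert in ("low", "mid", "high"):
        mask = scores["tertile"] == tert
        km = survival.km_estimate(times[mask.to_numpy()], events[mask.to_numpy()])
        km.to_csv(OUT / f"km_{tert}.tsv", sep="\t", index=False)

    scan = survival.per_gene_outcome_scan(
        survival.median_center(vexpr), clin, sorted(sig.genes),
        strata_col="histology", sig=sig,
    )
    scan.to_csv(OUT / "per_gene_scan.tsv", sep="\t")
    n_assoc = int(((scan["p"] < 0.05) & scan["consistent"]).sum())
    print(f"per-gene scan: {n_assoc}/{len(sig)} signature genes individually "
          f"associate with outcome (p<0.05, stratified Cox, consistent direction)")

    io.write_json(
        {"cox_hr_per_sd": cox.hr, "cox_p": cox.p_wald,
         "cox_hr_stratified": cox_s.hr, "cox_p_stratified": cox_s.p_wald,
         "logrank_p": lr.p, "logrank_p_stratified": lr_s.p,
         "n_consistent_genes": n_assoc},
        OUT / "survival_results.json",
    )


if __name__ == "__main__":
    main()
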