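"""Synthetic paired-tumor cohort generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume: a cohort
of patients each contributing one initial tumor and one or more
recurrent/progressive tumors, with

* a histology baseline and a per-patient random effect shared by all of a
  patient's tumors (so the paired design genuinely removes between-patient
  variance),
* planted consistently-differential genes (up and down shifts in recurrent
  tumors),
* subset-specific expression programs among the recurrent tumors,
* somatic DNA events (SNV/indel, CNA, SV-proximity) gained or lost at
  recurrence at configured rates, on a small artificial genome whose gene
  spacing exercises the 1 Mb breakpoint window on both sides,
* and an independent validation cohort whose survival is tied to a latent
  signature score.

Every planted feature is recorded in a truth object so recovery tests can
compare called results against what was simulated. All outputs are
deterministic given the config seed.

Default cohort shape: 55 patients, ~15% with a second recurrent tumor
(about 63 recurrent/progressive tumors), 2000 genes across 6 histologic
types; somatic tables cover a 44-patient subcohort with event rates set so
patients gain on average ~3.15 events and lose ~1.52 at recurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "SimulationConfig",
    "EventRates",
    "SurvivalConfig",
    "SyntheticTruth",
    "Cohort",
    "SomaticTables",
    "generate_cohort",
    "generate_somatic_tables",
    "generate_validation_cohort",
    "write_fixture",
    "expected_gained_per_patient",
    "expected_lost_per_patient",
]

HISTOLOGIES = [
    "low_grade_glioma",
    "high_grade_glioma",
    "medulloblastoma",
    "ependymoma",
    "atrt",
    "meningioma",
]

# artificial genome: genes 3 Mb apart so 1 Mb windows never span two genes
GENE_SPACING_BP = 3_000_000
GENES_PER_CHROM = 500


@dataclass(frozen=True)
class EventRates:
    """Per-eligible-gene event probabilities for the somatic simulator.

    ``initial`` is the chance an eligible gene carries the event in the
    initial tumor; ``excess`` the chance a patient gains it (in one
    recurrent/progressive tumor) when absent initially; ``loss`` the chance
    an initial event is absent from all of the patient's later tumors.
    Defaults put the expected gained count near 3.15 and lost near 1.52 per
    patient on the default gene panel.
    """

    snv_hotspot: tuple[float, float] = (0.013, 0.010)
    inactivating: tuple[float, float] = (0.013, 0.010)
    amplification: tuple[float, float] = (0.0095, 0.0075)
    deep_deletion: tuple[float, float] = (0.0095, 0.0075)
    sv_altered_expression: tuple[float, float] = (0.028, 0.04125)
    loss: float = 0.5


@dataclass(frozen=True)
class SurvivalConfig:
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    hazard_ratio_per_sd: float = 2.0
    censoring_rate: float = 0.4


@dataclass
class SimulationConfig:
    n_patients: int = 55
    second_tumor_fraction: float = 0.15  # chance a patient has 2 later tumors
    n_genes: int = 2000
    n_histologies: int = 6
    histology_effect_sd: float = 1.0  # log2 units
    patient_effect_sd: float = 1.0
    baseline_mean: float = 5.0
    n_up: int = 30
    n_down: int = 30
    planted_effect: float = 1.0  # log2 mean shift in recurrent vs initial
    noise_sd: float = 1.0
    n_subsets: int = 3
    subset_effect: float = 2.0
    subset_program_size: int = 40
    purity_shift: float = 0.05
    n_wgs_patients: int | None = None  # defaults to min(44, n_patients)
    n_cancer_genes: int = 100
    event_rates: EventRates = field(default_factory=EventRates)
    subset_hr: float = 1.0  # hazard multiplier for subset 1 in the paired cohort
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    n_validation_patients: int = 300
    seed: int = 0

    def __post_init__(self):
        for name in ("n_patients", "n_genes", "n_histologies", "n_validation_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("planted gene counts must be >= 0")
        reserved = self.n_up + self.n_down + self.n_subsets * self.subset_program_size
        if reserved > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} cannot hold {self.n_up}+{self.n_down} planted "
                f"genes plus {self.n_subsets} x {self.subset_program_size} program genes"
            )
        if reserved + self.n_cancer_genes > self.n_genes:
            raise ValueError("n_genes too small for the cancer gene panel")
        for name in ("second_tumor_fraction", "purity_shift"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for f in fields(EventRates):
            v = getattr(self.event_rates, f.name)
            probs = v if isinstance(v, tuple) else (v,)
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"event rate {f.name} outside [0, 1]")
        for name in ("planted_effect", "subset_effect"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_wgs_patients is None:
            self.n_wgs_patients = min(44, self.n_patients)
        if self.n_wgs_patients > self.n_patients:
            raise ValueError("n_wgs_patients cannot exceed n_patients")
        if not 0 <= self.survival.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    planted_up: list = field(default_factory=list)
    planted_down: list = field(default_factory=list)
    subset_labels: dict = field(default_factory=dict)  # recurrent sample -> subset
    subset_programs: dict = field(default_factory=dict)  # subset -> gene list
    events_by_sample: dict = field(default_factory=dict)  # sample -> [(gene, type)]
    gained_by_patient: dict = field(default_factory=dict)
    lost_by_patient: dict = field(default_factory=dict)
    true_scores: dict = field(default_factory=dict)  # validation sample -> latent score

    def as_json(self) -> dict:
        return {
            "planted_up": self.planted_up,
            "planted_down": self.planted_down,
            "subset_labels": self.subset_labels,
            "subset_programs": self.subset_programs,
            "events_by_sample": {
                s: sorted(map(list, evs)) for s, evs in self.events_by_sample.items()
            },
            "gained_by_patient": {
                p: sorted(map(list, evs)) for p, evs in self.gained_by_patient.items()
            },
            "lost_by_patient": {
                p: sorted(map(list, evs)) for p, evs in self.lost_by_patient.items()
            },
            "true_scores": self.true_scores,
        }


@dataclass
class Cohort:
    expression: pd.DataFrame
    pairing: pd.DataFrame
    clinical: pd.DataFrame
    truth: SyntheticTruth


@dataclass
class SomaticTables:
    variants: pd.DataFrame
    cna: pd.DataFrame
    breakpoints: pd.DataFrame
    annotation: pd.DataFrame
    expression: pd.DataFrame  # with SV-concordant deviations applied
    truth: SyntheticTruth


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _survival_draw(rng, hazard: float, censoring_rate: float) -> tuple[float, int]:
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate >= 1.0:
        return float(np.round(t_event * rng.uniform(0.2, 0.8), 1)), 0
    if censoring_rate <= 0.0:
        return float(np.round(t_event, 1)), 1
    mu = hazard * censoring_rate / (1.0 - censoring_rate)
    t_cens = rng.exponential(1.0 / mu)
    if t_event <= t_cens:
        return float(np.round(t_event, 1)), 1
    return float(np.round(t_cens, 1)), 0


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the paired expression cohort.

    Expression = histology baseline + per-patient effect + planted
    recurrence shift (recurrent samples only) + subset program + Gaussian
    noise, all in log2 units. The pairing table covers every
    recurrent/progressive sample exactly once.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    truth = SyntheticTruth(
        planted_up=genes[: config.n_up],
        planted_down=genes[config.n_up : config.n_up + config.n_down],
    )
    offset = config.n_up + config.n_down
    for k in range(config.n_subsets):
        truth.subset_programs[str(k)] = genes[
            offset + k * config.subset_program_size : offset + (k + 1) * config.subset_program_size
        ]

    histologies = HISTOLOGIES[: config.n_histologies] + [
        f"histology_{i}" for i in range(len(HISTOLOGIES), config.n_histologies)
    ]
    hist_baseline = {
        h: config.baseline_mean
        + rng.normal(0.0, config.histology_effect_sd, size=config.n_genes)
        for h in histologies
    }

    pairing_rows = []
    clinical_rows = []
    columns = {}
    up_idx = np.arange(config.n_up)
    down_idx = np.arange(config.n_up, config.n_up + config.n_down)
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        hist = histologies[i % len(histologies)]
        patient_effect = rng.normal(0.0, config.patient_effect_sd, size=config.n_genes)
        base = hist_baseline[hist] + patient_effect
        n_rec = 2 if rng.random() < config.second_tumor_fraction else 1
        init_id = f"{pid}-T0"
        init_purity = float(np.round(rng.uniform(0.4, 0.9), 3))
        columns[init_id] = base + rng.normal(0.0, config.noise_sd, size=config.n_genes)
        subset0 = None
        for r in range(n_rec):
            rec_id = f"{pid}-R{r + 1}"
            status = "recurrence" if rng.random() < 0.5 else "progressive"
            subset = int(rng.integers(config.n_subsets)) if config.n_subsets > 0 else 0
            if subset0 is None:
                subset0 = subset
            col = base + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            col[up_idx] += config.planted_effect
            col[down_idx] -= config.planted_effect
            if config.n_subsets > 0:
                prog = truth.subset_programs[str(subset)]
                pidx = [genes.index(g) for g in prog]
                col[pidx] += config.subset_effect
                truth.subset_labels[rec_id] = subset
            columns[rec_id] = col
            pairing_rows.append((pid, init_id, rec_id, status, hist))
            # purity deviation spread calibrated so the paired purity shift
            # is only marginally detectable at cohort size, as observed for
            # expression-based purity estimates
            rec_purity = float(
                np.round(np.clip(init_purity + config.purity_shift + rng.normal(0, 0.15), 0, 1), 3)
            )
            clinical_rows.append((rec_id, pid, status, hist, rec_purity))
        hazard = config.survival.baseline_hazard * (
            config.subset_hr if subset0 == 0 else 1.0
        )
        os_time, os_event = _survival_draw(rng, hazard, config.survival.censoring_rate)
        clinical_rows.append((init_id, pid, "initial", hist, init_purity))
        # patient-level survival attached to every sample row of this patient
        for idx in range(len(clinical_rows) - 1, -1, -1):
            if clinical_rows[idx][1] != pid:
                break
            if len(clinical_rows[idx]) == 5:
                clinical_rows[idx] = clinical_rows[idx] + (os_time, os_event)

    expression = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    pairing = pd.DataFrame(pairing_rows, columns=io.PAIRING_COLUMNS)
    clinical = pd.DataFrame(
        clinical_rows,
        columns=["sample_id", "patient_id", "tumor_status", "histology", "purity", "os_time", "os_event"],
    )
    return Cohort(expression, pairing, clinical, truth)


def _make_annotation(config: SimulationConfig, genes: list[str], rng) -> pd.DataFrame:
    """Cancer gene panel annotation on the artificial genome.

    The last ``n_cancer_genes`` genes of the pool form the panel: roughly
    30% oncogenes, 30% tumor suppressors, 40% other. Oncogenes and tumor
    suppressors carry the COSMIC flag and two hotspot residues; the first
    two thirds of each of those groups are SV-eligible with alternating
    association signs. All genes get coordinates (3 Mb spacing, 1-based).
    """
    rows = []
    panel = genes[-config.n_cancer_genes :]
    n_onc = config.n_cancer_genes * 3 // 10
    n_tsg = config.n_cancer_genes * 3 // 10
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi // GENES_PER_CHROM + 1}"
        start = 1 + (gi % GENES_PER_CHROM) * GENE_SPACING_BP + GENE_SPACING_BP // 2
        role, cosmic, sign, residues = "other", False, "none", frozenset()
        if gene in panel:
            k = panel.index(gene)
            if k < n_onc:
                role, cosmic = "oncogene", True
                if k < 2 * n_onc // 3:
                    sign = "positive" if k % 2 == 0 else "negative"
                residues = frozenset({100, 250})
            elif k < n_onc + n_tsg:
                j = k - n_onc
                role, cosmic = "tumor_suppressor", True
                if j < 2 * n_tsg // 3:
                    sign = "negative" if j % 2 == 0 else "positive"
                residues = frozenset({100, 250})
        rows.append((gene, chrom, start, role, cosmic, sign, residues))
    ann = pd.DataFrame(rows, columns=io.ANNOTATION_COLUMNS)
    return ann.set_index("gene_id", drop=False)


_ELIGIBILITY = {
    "snv_hotspot": lambda a: a["role"] == "oncogene",
    "inactivating": lambda a: a["role"] == "tumor_suppressor",
    "amplification": lambda a: a["cosmic"],
    "deep_deletion": lambda a: a["cosmic"],
    "sv_altered_expression": lambda a: a["sv_association_sign"].isin(["positive", "negative"]),
}


def _eligible_genes(ann: pd.DataFrame) -> dict[str, list[str]]:
    return {etype: list(ann.index[rule(ann)]) for etype, rule in _ELIGIBILITY.items()}


def expected_gained_per_patient(config: SimulationConfig, ann: pd.DataFrame) -> float:
    elig = _eligible_genes(ann)
    return sum(
        getattr(config.event_rates, etype)[1] * len(genes) for etype, genes in elig.items()
    )


def expected_lost_per_patient(config: SimulationConfig, ann: pd.DataFrame) -> float:
    elig = _eligible_genes(ann)
    mean_initial = sum(
        getattr(config.event_rates, etype)[0] * len(genes) for etype, genes in elig.items()
    )
    return mean_initial * config.event_rates.loss


def generate_somatic_tables(
    config: SimulationConfig,
    pairing: pd.DataFrame,
    expression: pd.DataFrame,
) -> SomaticTables:
    """Simulate MAF-like, CNA, and breakpoint tables consistent with truth.

    Every planted event is materialized so the event callers can recover it
    exactly: hotspot missense rows for oncogene SNV events, frameshift rows
    for tumor-suppressor inactivating events, +2/-2 thresholded calls for
    CNA events, and breakpoints within the 1 Mb window paired with an
    expression value pushed 2 cohort-SDs from the cohort median in the
    gene's associated direction. Decoys that must NOT be called are also
    planted: silent and non-hotspot oncogene variants, +/-1 CNA calls, a +2
    call on a non-COSMIC gene, a breakpoint at distance 1,000,001 bp, and
    an in-window breakpoint whose expression deviation is forced to ~0; the
    first planted SV event sits at distance exactly 1,000,000 to exercise
    the inclusive boundary.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    genes = list(expression.index)
    ann = _make_annotation(config, genes, rng)
    elig = _eligible_genes(ann)
    patients = list(pd.unique(pairing["patient_id"]))[: config.n_wgs_patients]
    initial_of = pairing.drop_duplicates("patient_id").set_index("patient_id")[
        "initial_sample_id"
    ]
    recurrents_of = pairing.groupby("patient_id")["recurrent_sample_id"].apply(list)

    truth = SyntheticTruth()
    events_by_sample: dict[str, set] = {}
    sv_assignments: list[tuple[str, str]] = []  # (gene, sample) needing deviation
    rates = config.event_rates
    for pid in patients:
        init_sample = initial_of[pid]
        recs = recurrents_of[pid]
        # a gene carries at most one CNA state per patient (cannot be both
        # amplified and deep-deleted), so the thresholded call is unambiguous
        cna_conflict = {"amplification": "deep_deletion", "deep_deletion": "amplification"}
        initial_set = set()
        for etype, pool in elig.items():
            p_init, _ = getattr(rates, etype)
            for gene in pool:
                if rng.random() < p_init:
                    other = cna_conflict.get(etype)
                    if other and (gene, other) in initial_set:
                        continue
                    initial_set.add((gene, etype))
        lost = {ev for ev in initial_set if rng.random() < rates.loss}
        retained = initial_set - lost
        gained = set()
        for etype, pool in elig.items():
            _, p_excess = getattr(rates, etype)
            for gene in pool:
                if (gene, etype) not in initial_set and rng.random() < p_excess:
                    other = cna_conflict.get(etype)
                    if other and ((gene, other) in initial_set or (gene, other) in gained):
                        continue
                    gained.add((gene, etype))
        events_by_sample[init_sample] = set(initial_set)
        for r in recs:
            events_by_sample.setdefault(r, set()).update(retained)
        for ev in gained:
            target = recs[int(rng.integers(len(recs)))]
            events_by_sample[target].add(ev)
        truth.gained_by_patient[pid] = gained
        truth.lost_by_patient[pid] = lost
    truth.events_by_sample = events_by_sample

    wgs_samples = sorted(events_by_sample)
    variant_rows = []
    cna = pd.DataFrame(
        0, index=pd.Index(list(ann.index[ann["role"] != "other"]) , name="gene_id"),
        columns=wgs_samples, dtype=int,
    )
    bp_rows = []
    expr = expression.copy()
    stats0 = pd.DataFrame(
        {"median": expr.median(axis=1), "sd": expr.std(axis=1, ddof=1)}
    )
    first_sv = True
    for sample in wgs_samples:
        for gene, etype in sorted(events_by_sample[sample]):
            if etype == "snv_hotspot":
                variant_rows.append((sample, gene, "missense", "p.R100Q", True))
            elif etype == "inactivating":
                variant_rows.append((sample, gene, "frameshift_indel", "p.K210fs", False))
            elif etype == "amplification":
                cna.loc[gene, sample] = 2
            elif etype == "deep_deletion":
                cna.loc[gene, sample] = -2
            elif etype == "sv_altered_expression":
                start = int(ann.loc[gene, "start"])
                if first_sv:
                    offset = 1_000_000  # inclusive window boundary
                    first_sv = False
                else:
                    offset = int(rng.integers(-1_000_000, 1_000_001))
                pos = max(start + offset, 1)
                bp_rows.append((sample, ann.loc[gene, "chrom"], pos, "BND"))
                sign = 1.0 if ann.loc[gene, "sv_association_sign"] == "positive" else -1.0
                expr.loc[gene, sample] = (
                    stats0.loc[gene, "median"] + sign * 2.0 * stats0.loc[gene, "sd"]
                )
                sv_assignments.append((gene, sample))

    # --- decoys that exercise the negative side of every rule -------------
    decoy_sample = wgs_samples[0]
    onc = elig["snv_hotspot"][0]
    tsg = elig["inactivating"][0]
    variant_rows.append((decoy_sample, onc, "silent", "p.L50L", False))
    variant_rows.append((decoy_sample, onc, "nonsense", "p.Q80*", False))  # non-hotspot oncogene
    other_gene = ann.index[ann["role"] == "other"][0]
    variant_rows.append((decoy_sample, other_gene, "missense", "p.A10V", False))
    low_cna_gene = next(
        g for g in cna.index if all((g, t) not in events_by_sample[decoy_sample]
                                    for t in ("amplification", "deep_deletion"))
    )
    if cna.loc[low_cna_gene, decoy_sample] == 0:
        cna.loc[low_cna_gene, decoy_sample] = 1
    noncosmic = pd.Index([other_gene], name="gene_id")
    noncosmic_row = pd.DataFrame(0, index=noncosmic, columns=wgs_samples, dtype=int)
    noncosmic_row.loc[other_gene, decoy_sample] = 2  # ignored: not COSMIC
    cna = pd.concat([cna, noncosmic_row])

    sv_pool = elig["sv_altered_expression"]
    taken = set(sv_assignments)
    decoy_pairs = [
        (g, s) for g in sv_pool for s in wgs_samples[:3] if (g, s) not in taken
    ]
    # outside the window by one base, deviation forced large -> must not call
    g_far, s_far = decoy_pairs[0]
    start = int(ann.loc[g_far, "start"])
    bp_rows.append((s_far, ann.loc[g_far, "chrom"], start + 1_000_001, "BND"))
    sign = 1.0 if ann.loc[g_far, "sv_association_sign"] == "positive" else -1.0
    expr.loc[g_far, s_far] = stats0.loc[g_far, "median"] + sign * 2.0 * stats0.loc[g_far, "sd"]
    # inside the window, deviation forced to the median -> must not call
    g_near, s_near = next(p for p in decoy_pairs[1:] if p[0] != g_far)
    bp_rows.append((s_near, ann.loc[g_near, "chrom"], int(ann.loc[g_near, "start"]) + 500_000, "BND"))
    expr.loc[g_near, s_near] = stats0.loc[g_near, "median"]

    variants = pd.DataFrame(variant_rows, columns=io.MAF_COLUMNS)
    breakpoints = pd.DataFrame(bp_rows, columns=io.BREAKPOINT_COLUMNS)
    return SomaticTables(variants, cna, breakpoints, ann, expr, truth)


def generate_validation_cohort(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Independent cohort whose survival is tied to a latent signature score.

    Each sample gets a latent score z ~ N(0, 1); signature genes (the
    planted up/down sets, closing the loop with the paired analysis) load
    on z with unit weight against unit noise; survival times draw from an
    exponential with hazard proportional to HR^z, then censoring applies.
    """
    if not truth.planted_up or not truth.planted_down:
        raise ValueError("validation cohort requires planted up and down gene sets")
    rng = np.random.default_rng(config.seed + 2_000_003)
    n = config.n_validation_patients
    genes = _gene_ids(config.n_genes)
    samples = [f"V{i + 1:04d}" for i in range(n)]
    z = rng.normal(0.0, 1.0, size=n)
    values = rng.normal(0.0, 1.0, size=(config.n_genes, n))
    up_idx = [genes.index(g) for g in truth.planted_up]
    down_idx = [genes.index(g) for g in truth.planted_down]
    values[up_idx, :] += z
    values[down_idx, :] -= z
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    log_hr = math.log(config.survival.hazard_ratio_per_sd)
    rows = []
    vtruth = SyntheticTruth(
        planted_up=list(truth.planted_up), planted_down=list(truth.planted_down)
    )
    for i, s in enumerate(samples):
        hazard = config.survival.baseline_hazard * math.exp(log_hr * z[i])
        os_time, os_event = _survival_draw(rng, hazard, config.survival.censoring_rate)
        hist = HISTOLOGIES[int(rng.integers(len(HISTOLOGIES)))]
        purity = float(np.round(rng.uniform(0.3, 0.95), 3))
        rows.append((s, s, "initial", hist, purity, os_time, os_event))
        vtruth.true_scores[s] = float(z[i])
    clinical = pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "tumor_status", "histology", "purity", "os_time", "os_event"],
    )
    return expr, clinical, vtruth


FIXTURE_FILES = [
    "expression.tsv",
    "pairing.tsv",
    "clinical.tsv",
    "variants.tsv",
    "cna.tsv",
    "breakpoints.tsv",
    "annotation.tsv",
    "truth.json",
]


def write_fixture(
    cohort: Cohort,
    somatic: SomaticTables,
    directory: str | Path,
    force: bool = False,
) -> list[Path]:
    """Write the full cohort bundle as TSV/JSON files.

    Refuses to overwrite an existing fixture unless ``force`` is set.
    Returns the written paths (one per declared table).
    """
    if cohort.pairing.empty:
        raise ValueError("cannot write a fixture for an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    existing = [f for f in FIXTURE_FILES if (directory / f).exists()]
    if existing and not force:
        raise FileExistsError(f"fixture files already present (use force): {existing}")
    io.write_expression(somatic.expression, directory / "expression.tsv")
    io.write_pairing(cohort.pairing, directory / "pairing.tsv")
    io.write_clinical(cohort.clinical, directory / "clinical.tsv")
    somatic.variants.to_csv(directory / "variants.tsv", sep="\t", index=False)
    somatic.cna.to_csv(directory / "cna.tsv", sep="\t", index_label="gene_id")
    somatic.breakpoints.to_csv(directory / "breakpoints.tsv", sep="\t", index=False)
    io.write_annotation(somatic.annotation, directory / "annotation.tsv")
    merged = cohort.truth.as_json()
    merged.update(somatic.truth.as_json())
    merged["planted_up"] = cohort.truth.planted_up
    merged["planted_down"] = cohort.truth.planted_down
    merged["subset_labels"] = cohort.truth.subset_labels
    merged["subset_programs"] = cohort.truth.subset_programs
    io.write_json(merged, directory / "truth.json")
    return [directory / f for f in FIXTURE_FILES]
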