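"""Somatic alteration event calling and paired gain/loss tabulation.

An "event" is one called DNA alteration of a cancer-associated gene in one
tumor sample. Three callers feed the tabulation:

* SNV/indels — for oncogenes only missense changes at hotspot residues
  count; for tumor suppressors hotspot changes plus inactivating classes
  (nonsense, nonstop, frameshift or in-frame indel) count.
* Copy number — thresholded gene-level calls, where +2 (high-level
  amplification) and -2 (deep deletion) on COSMIC-listed genes count.
* Structural variants — a breakpoint within 1 Mb of an SV-eligible gene's
  start, with that sample's expression deviating more than 0.4 SD from the
  cohort median in the gene's globally associated direction.

Events are then compared within patients: a (gene, event type) pair present
in a recurrent/progressive tumor but absent from the initial tumor is a
*gained* event; one present in the initial tumor but absent from every
recurrent/progressive tumor of the patient is *lost*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SomaticEvent",
    "PairedEventSummary",
    "classify_snv_indel",
    "call_snv_events",
    "call_cna_events",
    "cohort_reference_stats",
    "call_sv_expression_events",
    "tabulate_paired_events",
    "paired_count_test",
    "event_matrix",
]

SV_WINDOW_BP = 1_000_000
SV_SD_THRESHOLD = 0.4

SNV_CLASSES = {
    "missense",
    "nonsense",
    "nonstop",
    "frameshift_indel",
    "inframe_indel",
    "silent",
    "other",
}
INACTIVATING_CLASSES = {"nonsense", "nonstop", "frameshift_indel", "inframe_indel"}

EVENT_TYPES = [
    "snv_hotspot",
    "inactivating",
    "amplification",
    "deep_deletion",
    "sv_altered_expression",
]


@dataclass(frozen=True)
class SomaticEvent:
    sample_id: str
    gene_id: str
    event_type: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_id, self.event_type)


def classify_snv_indel(variant, annotation) -> SomaticEvent | None:
    """Apply the role-aware SNV/indel rules to one variant record.

    ``variant`` and ``annotation`` are mappings (e.g. DataFrame rows).
    Silent variants and genes with role ``other`` never yield events;
    oncogenes only through hotspot residues; tumor suppressors through
    hotspots or inactivating classes.
    """
    cls = variant["variant_classification"]
    if cls not in SNV_CLASSES:
        raise ValueError(f"unknown variant classification: {cls!r}")
    if cls == "silent":
        return None
    role = annotation["role"]
    hotspot = bool(variant.get("is_hotspot", False)) if hasattr(variant, "get") else bool(
        variant["is_hotspot"]
    )
    sample = variant["sample_id"]
    gene = annotation["gene_id"]
    if role == "oncogene":
        return SomaticEvent(sample, gene, "snv_hotspot") if hotspot else None
    if role == "tumor_suppressor":
        if hotspot:
            return SomaticEvent(sample, gene, "snv_hotspot")
        if cls in INACTIVATING_CLASSES:
            return SomaticEvent(sample, gene, "inactivating")
        return None
    return None


def call_snv_events(variants: pd.DataFrame, annotation: pd.DataFrame) -> list[SomaticEvent]:
    """Classify every variant whose gene appears in the annotation."""
    events = []
    for _, row in variants.iterrows():
        gene = row["hugo_symbol"]
        if gene not in annotation.index:
            continue
        ev = classify_snv_indel(
            {
                "sample_id": row["sample_id"],
                "variant_classification": row["variant_classification"],
                "is_hotspot": bool(row["is_hotspot"]),
            },
            annotation.loc[gene],
        )
        if ev is not None:
            events.append(ev)
    return events


def call_cna_events(cna: pd.DataFrame, annotation: pd.DataFrame) -> list[SomaticEvent]:
    """Thresholded copy-number events on COSMIC-listed genes.

    +2 -> amplification, -2 -> deep deletion; |call| <= 1 is no event;
    genes without the COSMIC flag are ignored. Calls outside {-2..2} or
    non-integer raise.
    """
    values = cna.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.equal(np.mod(values, 1), 0)):
            raise ValueError("CNA calls must be integers")
        values = values.astype(int)
    if values.size and (values.max() > 2 or values.min() < -2):
        raise ValueError("CNA calls must lie in {-2..2}")
    cosmic = {
        g for g in cna.index if g in annotation.index and bool(annotation.loc[g, "cosmic"])
    }
    events = []
    for gi, gene in enumerate(cna.index):
        if gene not in cosmic:
            continue
        for si, sample in enumerate(cna.columns):
            call = values[gi, si]
            if call == 2:
                events.append(SomaticEvent(sample, gene, "amplification"))
            elif call == -2:
                events.append(SomaticEvent(sample, gene, "deep_deletion"))
    return events


def cohort_reference_stats(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median and SD over the reference cohort (all columns)."""
    return pd.DataFrame(
        {"median": expr.median(axis=1), "sd": expr.std(axis=1, ddof=1)}, index=expr.index
    )


def call_sv_expression_events(
    breakpoints: pd.DataFrame,
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    cohort_stats: pd.DataFrame,
) -> list[SomaticEvent]:
    """SV breakpoint-proximity events with concordant expression deviation.

    For each SV-eligible gene (``sv_association_sign`` positive or
    negative) and sample: an event iff some breakpoint on the gene's
    chromosome lies within 1,000,000 bp (unsigned, inclusive) of the
    annotated gene start AND the sample's expression deviation from the
    cohort median exceeds +0.4 SD (positive sign) or falls below -0.4 SD
    (negative sign); both deviation thresholds are strict. Genes missing
    from the expression matrix, or with zero cohort SD, are skipped with a
    log message.
    """
    eligible = annotation[annotation["sv_association_sign"].isin(["positive", "negative"])]
    by_sample = {s: g for s, g in breakpoints.groupby("sample_id")}
    events = []
    for gene, ann in eligible.iterrows():
        if gene not in expr.index:
            logger.warning("SV-eligible gene %s absent from expression matrix", gene)
            continue
        sd = float(cohort_stats.loc[gene, "sd"])
        if sd == 0 or math.isnan(sd):
            logger.warning("gene %s has zero cohort SD; ineligible for SV events", gene)
            continue
        median = float(cohort_stats.loc[gene, "median"])
        sign = ann["sv_association_sign"]
        for sample, bps in by_sample.items():
            if sample not in expr.columns:
                continue
            near = bps[
                (bps["chrom"] == ann["chrom"])
                & ((bps["pos_1based"] - ann["start"]).abs() <= SV_WINDOW_BP)
            ]
            if near.empty:
                continue
            dev = (float(expr.loc[gene, sample]) - median) / sd
            if (sign == "positive" and dev > SV_SD_THRESHOLD) or (
                sign == "negative" and dev < -SV_SD_THRESHOLD
            ):
                events.append(SomaticEvent(sample, gene, "sv_altered_expression"))
    return events


@dataclass(frozen=True)
class PairedEventSummary:
    patient_id: str
    gained: frozenset  # (gene, event_type) pairs
    lost: frozenset

    @property
    def gained_count(self) -> int:
        return len(self.gained)

    @property
    def lost_count(self) -> int:
        return len(self.lost)


def tabulate_paired_events(
    events: list[SomaticEvent], pairing: pd.DataFrame
) -> list[PairedEventSummary]:
    """Per-patient gained and lost (gene, event type) sets.

    gained = present in at least one recurrent/progressive tumor of the
    patient, absent from the initial tumor; lost = present in the initial
    tumor, absent from every recurrent/progressive tumor. Duplicate input
    events collapse (set semantics), so counts ignore duplicated rows.
    """
    sample_to_patient = {}
    initial_of = {}
    recurrents_of: dict[str, list[str]] = {}
    for _, row in pairing.iterrows():
        pid = row["patient_id"]
        sample_to_patient[row["initial_sample_id"]] = pid
        sample_to_patient[row["recurrent_sample_id"]] = pid
        initial_of[pid] = row["initial_sample_id"]
        recurrents_of.setdefault(pid, []).append(row["recurrent_sample_id"])
    per_sample: dict[str, set] = {}
    for ev in events:
        if ev.sample_id not in sample_to_patient:
            raise KeyError(f"event sample {ev.sample_id!r} not present in the pairing table")
        per_sample.setdefault(ev.sample_id, set()).add(ev.key)
    summaries = []
    for pid in initial_of:
        init = per_sample.get(initial_of[pid], set())
        rec_union: set = set()
        for s in recurrents_of[pid]:
            rec_union |= per_sample.get(s, set())
        summaries.append(
            PairedEventSummary(pid, frozenset(rec_union - init), frozenset(init - rec_union))
        )
    return summaries


@dataclass(frozen=True)
class PairedCountTest:
    t: float
    p: float
    mean_initial: float
    mean_recurrent: float
    n: int
    degenerate: bool = False


def paired_count_test(counts_initial, counts_recurrent) -> PairedCountTest:
    """Classical paired t-test on per-patient event counts.

    All-zero differences give t=0, p=1. Identical nonzero differences (zero
    variance, nonzero mean) make the statistic unbounded; the result is
    reported with t=inf-sign and the smallest positive p, flagged
    degenerate.
    """
    a = np.asarray(counts_initial, dtype=float)
    b = np.asarray(counts_recurrent, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired test requires n >= 2 patients")
    d = b - a
    if np.all(d == d[0]):
        if d[0] == 0:
            return PairedCountTest(0.0, 1.0, float(a.mean()), float(b.mean()), n)
        return PairedCountTest(
            math.copysign(math.inf, d[0]),
            float(np.finfo(float).tiny),
            float(a.mean()),
            float(b.mean()),
            n,
            degenerate=True,
        )
    t, p = stats.ttest_rel(b, a)
    return PairedCountTest(float(t), float(p), float(a.mean()), float(b.mean()), n)


def event_matrix(events: list[SomaticEvent], samples=None) -> pd.DataFrame:
    """Oncoprint-style gene x sample matrix of semicolon-joined event codes."""
    per: dict[tuple[str, str], set] = {}
    for ev in events:
        per.setdefault((ev.gene_id, ev.sample_id), set()).add(ev.event_type)
    genes = sorted({g for g, _ in per})
    cols = list(samples) if samples is not None else sorted({s for _, s in per})
    out = pd.DataFrame("", index=genes, columns=cols, dtype=object)
    for (g, s), types in per.items():
        if s in out.columns:
            out.loc[g, s] = ";".join(sorted(types))
    out.index.name = "gene_id"
    return out
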