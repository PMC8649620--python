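"""Consensus clustering of pair-centered differential expression profiles.

Each recurrent/progressive tumor is represented by its expression profile
centered on the patient's initial tumor, which removes histology and
patient baselines, so unsupervised structure reflects how tumors *changed*
at recurrence rather than what they were. Clustering follows the consensus
paradigm: repeated Ward-linkage hierarchical clustering of subsampled
samples on 1 - Pearson correlation distance, aggregated into a co-clustering
frequency matrix per k; final labels come from clustering the consensus
matrix itself. The CDF of consensus values per k, its area, and the
relative area increase between consecutive k ("delta area") guide model
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind

from .diffexp import paired_differences
from .survival import LogrankResult, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "pair_center",
    "top_variable_genes",
    "consensus_cluster",
    "choose_k",
    "subset_markers",
    "subset_survival",
    "ConsensusResult",
]

# identical contract to paired_differences; re-exported so the clustering
# stage and the differential-expression stage cannot drift apart
pair_center = paired_differences


def top_variable_genes(diff: pd.DataFrame, n: int) -> list:
    """Top n genes by across-sample standard deviation (stable tie order)."""
    if n > diff.shape[0]:
        raise ValueError(f"requested {n} genes but matrix has {diff.shape[0]}")
    sd = diff.std(axis=1, ddof=1)
    order = sd.sort_values(ascending=False, kind="stable").index
    return list(order[:n])


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns, as a square matrix."""
    corr = np.corrcoef(values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def _ward_labels(dist: np.ndarray, k: int) -> np.ndarray:
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    z = linkage(condensed, method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def _cdf_area(consensus: np.ndarray, n_bins: int = 100) -> float:
    """Area under the empirical CDF of off-diagonal consensus values."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cdf = np.searchsorted(np.sort(vals), edges[1:], side="right") / vals.size
    return float(np.sum(cdf * np.diff(edges)))


@dataclass
class ConsensusResult:
    k_range: list
    consensus: dict  # k -> samples x samples DataFrame in [0, 1]
    labels: dict  # k -> pd.Series of labels in 1..k
    cdf_area: dict  # k -> area under the consensus CDF
    delta_area: dict  # k -> relative area increase (total area at k_min)
    chosen_k: int | None
    seed: int
    n_resamples: int
    subsample_fraction: float
    notes: list = field(default_factory=list)


def consensus_cluster(
    diff: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus Ward hierarchical clustering over a range of k.

    Per resample, a fraction of the sample columns is drawn without
    replacement, clustered with Ward linkage (Ward.D2 semantics: squared
    distances internally) on 1 - Pearson distance, and cut at every k;
    consensus(i, j) = co-cluster count / co-sample count. Final labels per
    k come from Ward clustering of 1 - consensus. Deterministic given seed.
    """
    n = diff.shape[1]
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    if n < k_max + 2:
        raise ValueError(f"need at least k_max + 2 = {k_max + 2} samples, got {n}")
    rng = np.random.default_rng(seed)
    values = diff.to_numpy(dtype=float)
    ks = list(range(k_min, k_max + 1))
    m_sub = max(int(round(subsample_fraction * n)), k_max + 1)
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))
    for _ in range(n_resamples):
        cols = rng.choice(n, size=m_sub, replace=False)
        cols.sort()
        co_sample[np.ix_(cols, cols)] += 1.0
        dist = _correlation_distance(values[:, cols])
        for k in ks:
            lab = _ward_labels(dist, k)
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(cols, cols)] += same
    notes = []
    never = co_sample == 0
    np.fill_diagonal(never, False)
    if never.any():
        notes.append(f"{int(never.sum()) // 2} sample pairs never co-sampled; consensus 0")
    consensus = {}
    labels = {}
    areas = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in ks:
            c = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
            np.fill_diagonal(c, 1.0)
            c = (c + c.T) / 2.0
            consensus[k] = pd.DataFrame(c, index=diff.columns, columns=diff.columns)
            labels[k] = pd.Series(
                _ward_labels(1.0 - c, k), index=diff.columns, name=f"k{k}"
            )
            areas[k] = _cdf_area(c)
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            # relative increase; floored at 0 so small non-monotonicities from
            # resampling noise do not produce negative stability gains
            delta[k] = max((areas[k] - prev) / prev, 0.0) if prev > 0 else 0.0
    return ConsensusResult(
        ks, consensus, labels, areas, delta, None, seed, n_resamples, subsample_fraction, notes
    )


def proportion_ambiguous(consensus: pd.DataFrame, lo: float = 0.1, hi: float = 0.9) -> float:
    """PAC: fraction of off-diagonal consensus entries in the ambiguous band.

    A clustering that the resampling reproduces perfectly has consensus
    values at 0 or 1 only, hence PAC = 0; fuzzier structure pushes entries
    into the middle of [0, 1].
    """
    c = consensus.to_numpy()
    iu = np.triu_indices(c.shape[0], k=1)
    vals = c[iu]
    return float(((vals > lo) & (vals < hi)).mean())


def choose_k(
    result: ConsensusResult,
    forced_k: int | None = None,
    pac_threshold: float = 0.05,
) -> int:
    """Pick the number of clusters from consensus-matrix stability.

    A forced k overrides the rule (the headline analysis of this kind fixes
    k by inspection of the consensus diagnostics). The automatic rule uses
    the proportion of ambiguous consensus entries (PAC): the largest k whose
    consensus matrix is essentially unambiguous (PAC <= ``pac_threshold``)
    — i.e. the finest partition the resampling still reproduces. When no k
    qualifies, the k minimizing PAC is taken, with a warning. The decision
    is appended to ``result.notes``; the delta-area curve remains available
    in the result for reporting.
    """
    if forced_k is not None:
        result.chosen_k = forced_k
        result.notes.append(f"k={forced_k} forced")
        return forced_k
    pac = {k: proportion_ambiguous(result.consensus[k]) for k in result.k_range}
    stable = [k for k in result.k_range if pac[k] <= pac_threshold]
    if stable:
        k = max(stable)
        result.notes.append(f"k={k}: largest k with PAC <= {pac_threshold} (PAC={pac[k]:.3f})")
    else:
        k = min(pac, key=pac.get)
        logger.warning("no k with PAC <= %.3f; taking argmin PAC k=%d", pac_threshold, k)
        result.notes.append(f"no unambiguous k; argmin PAC k={k} (PAC={pac[k]:.3f})")
    result.chosen_k = k
    return k


def subset_markers(diff: pd.DataFrame, labels: pd.Series, top_n: int = 200) -> pd.DataFrame:
    """Top marker genes per subset: unpaired t of subset versus the rest.

    For each subset, a two-sample (equal-variance) t per gene comparing the
    centered values of the subset's samples against all other samples;
    genes are ranked by descending t and the top_n retained. Genes ranked
    for more than one subset are flagged.
    """
    labels = labels.reindex(diff.columns)
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"singleton subsets cannot be tested: {list(singletons.index)}")
    frames = []
    for subset in counts.index:
        inside = diff.loc[:, labels == subset].to_numpy()
        outside = diff.loc[:, labels != subset].to_numpy()
        t, p = ttest_ind(inside, outside, axis=1, equal_var=True)
        stats_k = pd.DataFrame({"subset": subset, "gene": diff.index, "t": t, "p": p})
        stats_k = stats_k.sort_values("t", ascending=False, kind="stable").head(top_n)
        frames.append(stats_k)
    out = pd.concat(frames, ignore_index=True)
    out["multi_subset"] = out.duplicated("gene", keep=False)
    return out


def subset_survival(
    labels: pd.Series, clinical: pd.DataFrame, pairing: pd.DataFrame
) -> tuple[LogrankResult, pd.DataFrame]:
    """Log-rank test of overall survival differences among subsets.

    Tumor-level labels are collapsed to patient level: a patient with
    multiple recurrent/progressive tumors takes the first tumor's label and
    is flagged when the tumors disagree. Returns the log-rank result and
    the patient-level label table.
    """
    sample_patient = pairing.set_index("recurrent_sample_id")["patient_id"]
    per_patient = {}
    flagged = {}
    for sample, lab in labels.items():
        patient = sample_patient[sample]
        if patient in per_patient:
            flagged[patient] = per_patient[patient] != lab
        else:
            per_patient[patient] = lab
            flagged.setdefault(patient, False)
    table = pd.DataFrame(
        {
            "label": pd.Series(per_patient),
            "discordant_tumors": pd.Series(flagged),
        }
    )
    n_flagged = int(table["discordant_tumors"].sum())
    if n_flagged:
        logger.warning("%d patients with tumors in different subsets", n_flagged)
    cl = clinical.drop_duplicates("patient_id").set_index("patient_id")
    cl = cl.loc[table.index]
    result = logrank_test(
        cl["os_time"].to_numpy(dtype=float),
        cl["os_event"].to_numpy(dtype=int),
        table["label"].to_numpy(),
    )
    return result, table
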