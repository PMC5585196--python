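"""Linear-SVM weight interpretation over the connectome feature space.

A trained linear machine assigns each selected edge a weight; its magnitude
|w| is read as the edge's contribution to the classification.  This module
ranks edges by |w|, computes top-k cumulative weight fractions, partitions
the weight mass into inter- vs intra-hemispheric sums, and compares the two
weight samples with a Wilcoxon rank-sum test (exact by enumeration for
small tie-free samples, normal approximation with tie and continuity
corrections otherwise).

For reporting, the interpretation model is retrained on the full cohort
using the pooled-scope selected edges (one weight table per task); per-fold
weight averaging is available via ``per_fold_average=True`` for sensitivity
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RoiTable, edge_classes, enumerate_edges
from .classify import (
    ClassifierConfig,
    LabeledFeatures,
    LinearModel,
    SEVERITY_TASKS,
    fit_linear_svm,
    one_vs_all_fit,
    scale_features,
    ttest_filter,
)
from .errors import InvalidInputError, UnsupportedModelError

#: aggregation rule for one-against-all machines (the report header records it)
OVA_AGGREGATION = "sum of |w| across class machines"


@dataclass
class WeightReport:
    task: str
    selected_edges: np.ndarray  # canonical edge indices
    magnitudes: np.ndarray  # |w| per selected edge (same order)
    ranking: np.ndarray  # selected-edge positions sorted by descending |w|
    inter_sum: float
    intra_sum: float
    inter_fraction_selected: float  # share of selected edges that are inter
    wilcoxon_statistic: float
    wilcoxon_p: float
    wilcoxon_method: str
    aggregation: str = OVA_AGGREGATION
    provenance: dict = field(default_factory=dict)

    def ranked_table(self, rois: RoiTable) -> pd.DataFrame:
        edges = enumerate_edges(len(rois))
        cls = edge_classes(rois)
        names = rois.names
        rows = []
        for rank, pos in enumerate(self.ranking, start=1):
            e = int(self.selected_edges[pos])
            i, j = edges[e]
            rows.append(
                {
                    "rank": rank,
                    "name_i": names[i],
                    "name_j": names[j],
                    "class": cls[e],
                    "weight": float(self.magnitudes[pos]),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("selected_edges", "magnitudes", "ranking"):
            d[k] = np.asarray(d[k]).tolist()
        with open(path, "w") as f:
            json.dump(d, f, indent=2, sort_keys=True)


def extract_weights(models, selected_edges, n_edges: int) -> np.ndarray:
    """Full-length |w| vector; unselected edges get 0.

    ``models`` is a single binary :class:`LinearModel` or a dict of
    one-against-all machines; for the latter, per-edge magnitudes are the
    sum of |w| across the class machines.
    """
    sel = np.asarray(selected_edges, dtype=int)
    if isinstance(models, LinearModel):
        mags = np.abs(models.w)
    elif isinstance(models, dict):
        for m in models.values():
            if not isinstance(m, LinearModel):
                raise UnsupportedModelError("machines must expose primal weights")
        mags = np.sum([np.abs(m.w) for m in models.values()], axis=0)
    else:
        raise UnsupportedModelError(
            f"cannot extract primal weights from {type(models).__name__}"
        )
    if mags.shape[0] != sel.shape[0]:
        raise InvalidInputError(
            f"model has {mags.shape[0]} weights but {sel.shape[0]} edges selected"
        )
    out = np.zeros(n_edges)
    out[sel] = mags
    return out


def rank_edges(selected_edges, magnitudes) -> np.ndarray:
    """Positions into selected_edges sorted by descending |w|.

    Ties break toward the lower canonical edge index, so rankings are
    deterministic.
    """
    sel = np.asarray(selected_edges)
    mag = np.asarray(magnitudes, dtype=float)
    order = np.lexsort((sel, -mag))
    return order


def top_k_fraction(magnitudes, ranking, k: int) -> tuple[np.ndarray, float]:
    """Top-k ranked positions and their share of the total weight mass."""
    mag = np.asarray(magnitudes, dtype=float)
    if k <= 0:
        raise InvalidInputError("k must be positive")
    if k > len(ranking):
        raise InvalidInputError(f"k={k} exceeds {len(ranking)} ranked edges")
    top = np.asarray(ranking[:k])
    total = mag.sum()
    frac = float(mag[top].sum() / total) if total > 0 else 0.0
    return top, frac


def partition_sums(selected_edges, magnitudes, rois: RoiTable) -> tuple[float, float, float]:
    """(inter_sum, intra_sum, interhemispheric fraction of selected edges)."""
    sel = np.asarray(selected_edges, dtype=int)
    mag = np.asarray(magnitudes, dtype=float)
    cls = edge_classes(rois)[sel]
    inter = cls == "inter"
    inter_sum = float(mag[inter].sum())
    intra_sum = float(mag[~inter].sum())
    frac = float(inter.mean()) if sel.size else 0.0
    return inter_sum, intra_sum, frac


def _exact_rank_sum_cdf(m: int, n: int):
    """DP distribution of the rank-sum of m items among ranks 1..m+n.

    Returns (support_offset, pmf) where pmf[s] = P(W = s + m(m+1)/2) * C(m+n, m).
    Counts of subsets of {1..N} of size m with each possible sum.
    """
    N = m + n
    max_sum = sum(range(N - m + 1, N + 1))
    # ways[j][s]: number of size-j subsets with sum s
    ways = np.zeros((m + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for rank in range(1, N + 1):
        for j in range(min(rank, m), 0, -1):
            ways[j, rank:] += ways[j - 1, : max_sum + 1 - rank]
    return ways[m]


def wilcoxon_rank_sum(sample_inter, sample_intra) -> tuple[float, float, str]:
    """Two-sided rank-sum test with midranks for ties.

    Exact by enumeration of the rank-sum distribution when m+n <= 20 and
    there are no ties; otherwise a normal approximation with tie correction
    and continuity correction.  Returns (statistic, p, method) where the
    statistic is the rank sum of the first sample.
    """
    x = np.asarray(sample_inter, dtype=float)
    y = np.asarray(sample_intra, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    m, n = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks for ties
    w = float(ranks[:m].sum())
    has_ties = np.unique(combined).size < combined.size
    if m + n <= 20 and not has_ties:
        counts = _exact_rank_sum_cdf(m, n)
        total = counts.sum()
        sums = np.arange(counts.size)
        lower = counts[sums <= w].sum() / total
        upper = counts[sums >= w].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return w, float(p), "exact"
    # normal approximation
    N = m + n
    mean = m * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((N) * (N - 1))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return w, 1.0, "normal"  # all values identical
    z = (w - mean - np.sign(w - mean) * 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w, p, "normal"


def build_weight_report(
    dataset: LabeledFeatures,
    task: str,
    rois: RoiTable,
    config: ClassifierConfig | None = None,
    per_fold_average: bool = False,
) -> WeightReport:
    """Train the interpretation model and assemble the weight report.

    Default: pooled t-test selection, full-cohort scaling and refit.  With
    ``per_fold_average=True``, weights are instead averaged across LOOCV
    folds (sensitivity analysis); selection stays pooled so the edge set is
    common to all folds.
    """
    config = config or ClassifierConfig()
    config.validate()
    n_edges_total = dataset.features.shape[1]
    sel = ttest_filter(dataset.features, dataset.groups, config.filter_alpha)
    if sel.size == 0:
        raise InvalidInputError("t-test filter selected no edges")
    labels = dataset.labels_for(task)

    def _fit(rows: np.ndarray) -> np.ndarray:
        x_scaled, _, _ = scale_features(dataset.features[np.ix_(rows, sel)])
        y = labels[rows]
        if task == "diagnosis":
            model = fit_linear_svm(x_scaled, y, config)
        else:
            model = one_vs_all_fit(x_scaled, y, config)
        return extract_weights(model, sel, n_edges_total)

    n_subj = dataset.features.shape[0]
    if per_fold_average:
        full = np.mean(
            [_fit(np.setdiff1d(np.arange(n_subj), [i])) for i in range(n_subj)],
            axis=0,
        )
    else:
        full = _fit(np.arange(n_subj))
    mags = full[sel]
    ranking = rank_edges(sel, mags)
    inter_sum, intra_sum, inter_frac = partition_sums(sel, mags, rois)
    cls = edge_classes(rois)[sel]
    if (cls == "inter").any() and (cls == "intra").any():
        w_stat, w_p, method = wilcoxon_rank_sum(
            mags[cls == "inter"], mags[cls == "intra"]
        )
    else:
        # selection fell entirely in one hemisphere class: no comparison
        w_stat, w_p, method = float("nan"), float("nan"), "not_applicable"
    return WeightReport(
        task=task,
        selected_edges=sel,
        magnitudes=mags,
        ranking=ranking,
        inter_sum=inter_sum,
        intra_sum=intra_sum,
        inter_fraction_selected=inter_frac,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
        wilcoxon_method=method,
        provenance={
            "selection": "pooled",
            "refit": "per_fold_average" if per_fold_average else "full_cohort",
            "filter_alpha": config.filter_alpha,
            "roi_table_hash": dataset.roi_table_hash,
        },
    )
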