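"""Differential-feature calling between culture stages.

A metabolite is differentially accumulated (DAM) between two stages when
its fold change (test-stage mean over reference-stage mean, after zero
imputation) is >= 2 or <= 0.5 and its PLS-DA VIP is >= 1; a per-feature
Welch test on log2 values (p < 0.05) is applied by default and can be
disabled.  Genes use |log2FC| >= 1 with a BH-adjusted p < 0.05 instead of
VIP.  Fold changes are computed on imputed raw-scale means; PLS-DA and the
t-test operate on log2(x+1), mean-centred, unit-variance features.

Also provides the descriptive summaries built on the DAM sets: three-way
Venn partition, compound-class composition, and hierarchical clustering
(1 - Pearson r distance, average linkage) for heatmap ordering.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .data_io import AbundanceMatrix, ComparisonSpec, FeatureAnnotation
from .plsda import PLSDiscriminantAnalysis

__all__ = [
    "Thresholds",
    "impute_zeros",
    "fold_change",
    "fit_plsda",
    "feature_test",
    "call_dams",
    "call_degs",
    "run_differential",
    "venn_partition",
    "class_composition",
    "hca_order",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ["feature_id", "comparison", "fc", "log2fc", "vip", "p", "fdr", "status"]


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for differential calling (boundaries inclusive)."""

    fc_up: float = 2.0
    fc_down: float = 0.5
    vip: float = 1.0
    p: float = 0.05
    p_filter: bool = True


def impute_zeros(
    data: AbundanceMatrix, rule: str = "half_min_positive", pseudocount: float = 1.0
) -> AbundanceMatrix:
    """Replace exact zeros so downstream ratios are finite.

    ``half_min_positive`` (default) substitutes half the global minimum
    positive value; ``pseudocount`` adds a constant to every cell.
    Non-zero entries are untouched under the default rule.
    """
    values = data.values
    if rule == "half_min_positive":
        arr = values.to_numpy()
        positive = arr[arr > 0]
        if positive.size == 0:
            raise ValueError("matrix is all zeros; imputation undefined")
        if (arr == 0).any():
            values = values.mask(values == 0, positive.min() / 2.0)
    elif rule == "pseudocount":
        values = values + pseudocount
    else:
        raise ValueError(f"unknown imputation rule {rule!r}")
    return AbundanceMatrix(values, data.design, data.annotations)


def fold_change(data: AbundanceMatrix, cmp: ComparisonSpec) -> pd.DataFrame:
    """Per-feature fold change and log2 fold change for a two-stage contrast.

    The matrix must already be imputed; a zero reference mean is an error.
    """
    cmp.validate(data.design)
    test_mean = data.stage_values(cmp.test_stage).mean(axis=1)
    ref_mean = data.stage_values(cmp.ref_stage).mean(axis=1)
    if (ref_mean == 0).any():
        bad = ref_mean.index[ref_mean == 0][0]
        raise ValueError(f"zero reference mean for {bad!r}; impute zeros first")
    fc = test_mean / ref_mean
    return pd.DataFrame({"fc": fc, "log2fc": np.log2(fc)})


def _two_stage_design(data: AbundanceMatrix, cmp: ComparisonSpec):
    cmp.validate(data.design)
    test_ids = data.design.samples_for_stage(cmp.test_stage)
    ref_ids = data.design.samples_for_stage(cmp.ref_stage)
    if len(test_ids) < 2 or len(ref_ids) < 2:
        raise ValueError("each compared stage needs at least 2 replicates")
    return test_ids, ref_ids


def fit_plsda(
    data: AbundanceMatrix, cmp: ComparisonSpec, n_components: int = 2
) -> PLSDiscriminantAnalysis:
    """Fit a two-class PLS-DA on log2(x+1) replicate profiles of the contrast."""
    test_ids, ref_ids = _two_stage_design(data, cmp)
    X = np.log2(data.values.loc[:, test_ids + ref_ids].to_numpy().T + 1.0)
    y = np.array([cmp.test_stage] * len(test_ids) + [cmp.ref_stage] * len(ref_ids))
    return PLSDiscriminantAnalysis(n_components=n_components, scale=True).fit(X, y)


def feature_test(data: AbundanceMatrix, cmp: ComparisonSpec, test: str = "welch") -> pd.Series:
    """Two-sided per-feature t-test on log2(x+1) values.

    ``welch`` (default) or ``student``.  Features with zero variance in both
    groups get p = 1 when the group means are equal (degenerate convention)
    and p = 0 when they differ.
    """
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test {test!r}")
    test_ids, ref_ids = _two_stage_design(data, cmp)
    a = np.log2(data.values.loc[:, test_ids].to_numpy() + 1.0)
    b = np.log2(data.values.loc[:, ref_ids].to_numpy() + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate near-constant groups are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    # zero variance in one group only: scipy yields nan for student; fall back to welch-like 0/1
    p = np.where(np.isnan(p), np.where(equal_means, 1.0, 0.0), p)
    return pd.Series(p, index=data.feature_ids, name="p")


def call_dams(
    fc: pd.Series,
    vip: pd.Series,
    p: pd.Series | None,
    thresholds: Thresholds = Thresholds(),
) -> pd.Series:
    """Assign up/down/unchanged per feature from fold change, VIP and optional p."""
    up = (fc >= thresholds.fc_up) & (vip >= thresholds.vip)
    down = (fc <= thresholds.fc_down) & (vip >= thresholds.vip)
    if thresholds.p_filter:
        if p is None:
            raise ValueError("p-filter enabled but no p-values supplied")
        sig = p < thresholds.p
        up &= sig
        down &= sig
    status = pd.Series("unchanged", index=fc.index, name="status")
    status[up] = "up"
    status[down] = "down"
    return status


def run_differential(
    data: AbundanceMatrix,
    cmp: ComparisonSpec,
    thresholds: Thresholds = Thresholds(),
    n_components: int = 2,
    imputation: str = "half_min_positive",
    test: str = "welch",
) -> pd.DataFrame:
    """Full DAM calling for one contrast; returns the standard result table.

    Columns: feature_id, comparison, fc, log2fc, vip, p, fdr, status.
    """
    imputed = impute_zeros(data, rule=imputation)
    fc = fold_change(imputed, cmp)
    model = fit_plsda(imputed, cmp, n_components=n_components)
    vip = pd.Series(model.vip_, index=imputed.feature_ids, name="vip")
    p = feature_test(imputed, cmp, test=test)
    fdr = pd.Series(
        multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index, name="fdr"
    )
    status = call_dams(fc["fc"], vip, p, thresholds)
    return pd.DataFrame(
        {
            "feature_id": fc.index,
            "comparison": cmp.label,
            "fc": fc["fc"],
            "log2fc": fc["log2fc"],
            "vip": vip,
            "p": p,
            "fdr": fdr,
            "status": status,
        }
    ).reset_index(drop=True)


def call_degs(
    data: AbundanceMatrix,
    cmp: ComparisonSpec,
    log2fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    imputation: str = "half_min_positive",
    precomputed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differential gene calling: |log2FC| >= threshold and BH FDR < threshold.

    A precomputed table (feature_id, log2fc, fdr or status) is passed through
    with statuses preserved or re-derived from its own columns.
    """
    if precomputed is not None:
        out = precomputed.copy()
        if "status" not in out.columns:
            up = (out["log2fc"] >= log2fc_threshold) & (out["fdr"] < fdr_threshold)
            down = (out["log2fc"] <= -log2fc_threshold) & (out["fdr"] < fdr_threshold)
            out["status"] = np.where(up, "up", np.where(down, "down", "unchanged"))
        if "comparison" not in out.columns:
            out["comparison"] = cmp.label
        return out
    imputed = impute_zeros(data, rule=imputation)
    fc = fold_change(imputed, cmp)
    p = feature_test(imputed, cmp, test="welch")
    fdr = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)
    up = (fc["log2fc"] >= log2fc_threshold) & (fdr < fdr_threshold)
    down = (fc["log2fc"] <= -log2fc_threshold) & (fdr < fdr_threshold)
    status = pd.Series(np.where(up, "up", np.where(down, "down", "unchanged")), index=fc.index)
    return pd.DataFrame(
        {
            "feature_id": fc.index,
            "comparison": cmp.label,
            "fc": fc["fc"],
            "log2fc": fc["log2fc"],
            "p": p,
            "fdr": fdr,
            "status": status,
        }
    ).reset_index(drop=True)


def venn_partition(dam_sets: Mapping[str, set]) -> dict[tuple[str, ...], set]:
    """Partition three differential sets into the 7 disjoint Venn regions.

    Keys are sorted tuples of the comparison labels a feature belongs to;
    regions are pairwise disjoint and their union is the union of the inputs.
    """
    if len(dam_sets) != 3:
        raise ValueError(f"expected 3 sets, got {len(dam_sets)}")
    labels = list(dam_sets)
    regions: dict[tuple[str, ...], set] = {}
    for r in range(1, 4):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(set(dam_sets[l]) for l in combo))
            outside = set.union(
                set(), *(set(dam_sets[l]) for l in labels if l not in combo)
            )
            regions[tuple(sorted(combo))] = inside - outside
    return regions


def class_composition(
    feature_ids: Sequence[str],
    annotations: Mapping[str, FeatureAnnotation],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Compound-class census of a feature set: counts and fractions, descending.

    Unannotated features (or empty class labels) count as ``other``.
    Fractions sum to 1 over the full (untruncated) census.
    """
    ids = list(feature_ids)
    if not ids:
        return pd.DataFrame(columns=["feature_class", "count", "fraction"])
    classes = []
    for fid in ids:
        ann = annotations.get(fid)
        cls = ann.feature_class if ann is not None and ann.feature_class else "other"
        classes.append(cls)
    counts = pd.Series(classes).value_counts()
    out = pd.DataFrame(
        {
            "feature_class": counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / len(ids),
        }
    )
    if top_k is not None:
        out = out.head(top_k)
    return out.reset_index(drop=True)


def _correlation_distance(arr: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r among rows; constant rows sit at the maximum (2.0)."""
    n = arr.shape[0]
    sd = arr.std(axis=1)
    constant = sd == 0
    centred = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centred / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return (dist + dist.T) / 2.0


def hca_order(
    data: AbundanceMatrix, feature_ids: Sequence[str] | None = None
) -> tuple[list[str], list[str], np.ndarray]:
    """Hierarchical clustering for heatmap ordering.

    Average linkage on 1 - Pearson r distance, applied to features and to
    samples; ties broken by input order (scipy's deterministic behaviour).
    Returns (ordered feature ids, ordered sample ids, feature linkage matrix).
    """
    sub = data if feature_ids is None else data.subset(list(feature_ids))
    if sub.n_features < 2:
        raise ValueError("need at least 2 features to cluster")
    arr = np.log2(sub.values.to_numpy() + 1.0)
    feat_link = hierarchy.linkage(squareform(_correlation_distance(arr), checks=False), "average")
    feat_order = [sub.feature_ids[i] for i in hierarchy.leaves_list(feat_link)]
    if sub.n_samples >= 2:
        samp_link = hierarchy.linkage(
            squareform(_correlation_distance(arr.T), checks=False), "average"
        )
        samp_order = [sub.values.columns[i] for i in hierarchy.leaves_list(samp_link)]
    else:
        samp_order = list(sub.values.columns)
    return feat_order, samp_order, feat_link
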