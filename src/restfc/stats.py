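"""Edge-wise and scalar one-way ANOVA with Bonferroni-corrected post-hoc tests.

The screening model is the classical fixed-effects one-way ANOVA computed
edge by edge, followed by pairwise pooled-variance t comparisons corrected
with a Bonferroni factor of G(G-1)/2 within each edge.  Because a study with
thousands of edges cannot realistically survive a Bonferroni correction over
the whole edge family at the reported per-edge p-values, the correction
family is configurable (``family_scope``): by default only the post-hoc
pairwise family inside each screened edge is corrected; stricter scopes
(Bonferroni over edges, or both) are available and reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator

from .connectivity import mad_outliers
from .containers import CohortManifest, SymmetricEdgeMatrix

__all__ = [
    "AnovaResult",
    "PosthocComparison",
    "one_way_anova",
    "posthoc_pairwise",
    "edgewise_screen",
    "scalar_anova_table",
    "EdgewiseAnovaScreen",
    "FAMILY_SCOPES",
]

#: Which family the Bonferroni factor spans:
#: ``none``            — no correction anywhere;
#: ``posthoc_only``    — the G(G-1)/2 pairwise tests inside each edge (default);
#: ``edges_bonferroni``— the edge-wise ANOVA screen, factor = number of edges;
#: ``both``            — both of the above.
FAMILY_SCOPES = ("posthoc_only", "edges_bonferroni", "both", "none")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    mse: float
    degenerate: bool = False


@dataclass(frozen=True)
class PosthocComparison:
    pair: tuple[str, str]
    t: float
    p_raw: float
    p_adjusted: float
    direction: int  # sign of mean(group_a) - mean(group_b)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical between/within decomposition; F = MSB / MSW.

    If the within-group variance is exactly zero with unequal means, the
    statistic diverges and p is reported as 0 with a degeneracy flag.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError(f"need >= 2 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} value(s); need >= 2")
    n_total = sum(g.size for g in arrays)
    g_count = len(arrays)
    grand = np.concatenate(arrays).mean()
    means = np.array([g.mean() for g in arrays])
    ssb = sum(g.size * (m - grand) ** 2 for g, m in zip(arrays, means))
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(arrays, means))
    df_b, df_w = g_count - 1, n_total - g_count
    msb, msw = ssb / df_b, ssw / df_w
    sds = tuple(float(g.std(ddof=1)) for g in arrays)
    if msw == 0:
        if msb == 0:
            return AnovaResult(0.0, 1.0, df_b, df_w, tuple(means), sds, 0.0)
        return AnovaResult(float("inf"), 0.0, df_b, df_w, tuple(means), sds, 0.0,
                           degenerate=True)
    f = msb / msw
    p = float(f_dist.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w, tuple(means), sds, float(msw))


def posthoc_pairwise(
    groups: Sequence[Sequence[float]],
    group_names: Sequence[str],
    anova: AnovaResult,
    bonferroni_factor: int | None = None,
) -> list[PosthocComparison]:
    """Pairwise t tests on the pooled within-group mean square.

    t = (mean_a - mean_b) / sqrt(MSW (1/n_a + 1/n_b)) with the ANOVA's
    within df; raw two-sided p-values are multiplied by the Bonferroni factor
    (all G(G-1)/2 pairs by default) and clamped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    g_count = len(arrays)
    if bonferroni_factor is None:
        bonferroni_factor = g_count * (g_count - 1) // 2
    out: list[PosthocComparison] = []
    for a in range(g_count):
        for b in range(a + 1, g_count):
            diff = arrays[a].mean() - arrays[b].mean()
            if anova.mse == 0:
                t = float("inf") if diff != 0 else 0.0
                p_raw = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(anova.mse * (1 / arrays[a].size + 1 / arrays[b].size))
                t = float(diff / se)
                p_raw = float(2 * t_dist.sf(abs(t), anova.df_within))
            out.append(
                PosthocComparison(
                    pair=(str(group_names[a]), str(group_names[b])),
                    t=t,
                    p_raw=p_raw,
                    p_adjusted=min(1.0, p_raw * bonferroni_factor),
                    direction=int(np.sign(diff)),
                )
            )
    return out


def _vectorized_anova(data: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """F and p for every column of ``data`` (n_subjects x n_edges) at once."""
    n_total, _ = data.shape
    sizes = np.bincount(group_idx, minlength=n_groups).astype(float)
    grand = data.mean(axis=0)
    means = np.stack([data[group_idx == g].mean(axis=0) for g in range(n_groups)])
    sds = np.stack([data[group_idx == g].std(axis=0, ddof=1) for g in range(n_groups)])
    ssb = (sizes[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = np.zeros_like(grand)
    for g in range(n_groups):
        ssw += ((data[group_idx == g] - means[g]) ** 2).sum(axis=0)
    df_b, df_w = n_groups - 1, n_total - n_groups
    msw = ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / msw
    f = np.where(msw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    p = np.where(np.isinf(f), 0.0, f_dist.sf(np.where(np.isfinite(f), f, 0.0), df_b, df_w))
    p = np.where(f == 0, 1.0, p)
    return f, p, means, sds, msw, df_b, df_w


def _stack_cohort(
    matrices: Mapping[str, SymmetricEdgeMatrix], manifest: CohortManifest
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], tuple[str, ...], str, np.ndarray, np.ndarray]:
    manifest.require_min_group_size(2)
    sids = [s for s in manifest.subject_ids if s in matrices]
    missing = set(manifest.subject_ids) - set(sids)
    if missing:
        raise ValueError(f"manifest subjects without matrices: {sorted(missing)}")
    kinds = {matrices[s].metric_kind for s in sids}
    if len(kinds) != 1:
        raise ValueError(f"mixed metric kinds in cohort: {sorted(kinds)}")
    labels = matrices[sids[0]].roi_labels
    for s in sids:
        if matrices[s].roi_labels != labels:
            raise ValueError(f"subject {s!r}: inconsistent ROI labels")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    data = np.stack([matrices[s].values[iu, ju] for s in sids])
    groups = manifest.groups
    gmap = {g: k for k, g in enumerate(groups)}
    by_subject = {e.subject_id: e.group for e in manifest.entries}
    group_idx = np.array([gmap[by_subject[s]] for s in sids])
    return data, group_idx, tuple(sids), groups, kinds.pop(), iu, ju


def edgewise_screen(
    matrices: Mapping[str, SymmetricEdgeMatrix],
    manifest: CohortManifest,
    alpha: float = 0.05,
    family_scope: str = "posthoc_only",
    outlier_policy: str = "none",
) -> pd.DataFrame:
    """ANOVA at every upper-triangle edge; post-hoc tests where screened in.

    Returns a long-format table sorted by ANOVA p: one row per (edge,
    post-hoc pair) for edges passing the screen, one pair-less row otherwise.
    ``family_scope`` picks the Bonferroni family (see FAMILY_SCOPES);
    ``outlier_policy='rescreen'`` additionally drops per-group scaled-MAD
    outliers at each significant edge and reports the re-run statistics in
    ``*_post_outlier`` columns alongside the originals.
    """
    if family_scope not in FAMILY_SCOPES:
        raise ValueError(f"family_scope must be one of {FAMILY_SCOPES}, got {family_scope!r}")
    if outlier_policy not in ("none", "rescreen"):
        raise ValueError(f"outlier_policy must be 'none' or 'rescreen', got {outlier_policy!r}")
    data, group_idx, sids, groups, metric_kind, iu, ju = _stack_cohort(matrices, manifest)
    n_groups = len(groups)
    n_edges = data.shape[1]
    f, p, means, sds, msw, df_b, df_w = _vectorized_anova(data, group_idx, n_groups)

    edge_factor = n_edges if family_scope in ("edges_bonferroni", "both") else 1
    posthoc_factor = (
        n_groups * (n_groups - 1) // 2
        if family_scope in ("posthoc_only", "both")
        else 1
    )
    p_screen = np.minimum(1.0, p * edge_factor)
    significant = p_screen < alpha

    labels = matrices[sids[0]].roi_labels
    sid_arr = np.array(sids)
    rows: list[dict] = []
    for e in range(n_edges):
        base = {
            "roi_i": int(iu[e]),
            "roi_j": int(ju[e]),
            "roi_i_label": labels[iu[e]],
            "roi_j_label": labels[ju[e]],
            "metric_kind": metric_kind,
            "F": float(f[e]),
            "p": float(p[e]),
            "p_screen": float(p_screen[e]),
            "df_between": df_b,
            "df_within": df_w,
            "significant": bool(significant[e]),
        }
        for k, g in enumerate(groups):
            base[f"mean_{g}"] = float(means[k, e])
            base[f"sd_{g}"] = float(sds[k, e])
        if not significant[e]:
            rows.append({**base, "pair": "", "t": np.nan,
                         "p_posthoc_raw": np.nan, "p_posthoc_adj": np.nan,
                         "direction": 0})
            continue
        edge_vals = [data[group_idx == k, e] for k in range(n_groups)]
        anova = AnovaResult(float(f[e]), float(p[e]), df_b, df_w,
                            tuple(means[:, e]), tuple(sds[:, e]), float(msw[e]),
                            degenerate=bool(np.isinf(f[e])))
        comps = posthoc_pairwise(edge_vals, groups, anova, posthoc_factor)
        post: dict = {}
        if outlier_policy == "rescreen":
            post = _rescreen_edge(data[:, e], group_idx, sid_arr, groups,
                                  (int(iu[e]), int(ju[e])))
        for comp in comps:
            rows.append({**base,
                         "pair": f"{comp.pair[0]}-{comp.pair[1]}",
                         "t": comp.t,
                         "p_posthoc_raw": comp.p_raw,
                         "p_posthoc_adj": comp.p_adjusted,
                         "direction": comp.direction,
                         **post})
    table = pd.DataFrame(rows).sort_values(
        ["p", "roi_i", "roi_j", "pair"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def _rescreen_edge(values, group_idx, sids, groups, edge):
    """MAD-screen each group at one edge, drop outliers, re-run the ANOVA."""
    kept_vals, excluded = [], []
    for k, g in enumerate(groups):
        mask = mad_outliers(values[group_idx == k], sids[group_idx == k],
                            edge=edge, group=g)
        keep = [v for s, v in zip(sids[group_idx == k], values[group_idx == k])
                if s not in mask.excluded_subject_ids]
        excluded += sorted(mask.excluded_subject_ids)
        kept_vals.append(keep)
    if any(len(kv) < 2 for kv in kept_vals):
        return {"n_excluded": len(excluded), "excluded_subjects": ";".join(excluded),
                "F_post_outlier": np.nan, "p_post_outlier": np.nan}
    res = one_way_anova(kept_vals)
    return {"n_excluded": len(excluded), "excluded_subjects": ";".join(excluded),
            "F_post_outlier": res.f, "p_post_outlier": res.p}


def scalar_anova_table(
    records: pd.DataFrame, manifest: CohortManifest, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-measure group summary: one row per scalar measure.

    ``records`` has one row per subject (column ``subject_id``) and one
    column per measure.  Output mirrors a mean (SD) / p / group-differences
    table: per-group mean and SD, ANOVA F and p, and the Bonferroni-corrected
    significant post-hoc pairs as ``'A>B; C>D'`` strings.
    """
    manifest.require_min_group_size(2)
    if "subject_id" not in records.columns:
        raise ValueError("records must have a subject_id column")
    by_subject = {e.subject_id: e.group for e in manifest.entries}
    groups = manifest.groups
    measures = [c for c in records.columns if c != "subject_id"]
    rows = []
    for measure in measures:
        sub = records.dropna(subset=[measure])
        vals = [
            sub.loc[sub.subject_id.map(by_subject) == g, measure].to_numpy(float)
            for g in groups
        ]
        res = one_way_anova(vals)
        row: dict = {"measure": measure, "F": res.f, "p": res.p,
                     "df_between": res.df_between, "df_within": res.df_within}
        for g, m, s in zip(groups, res.group_means, res.group_sds):
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = s
        sig_pairs = []
        if res.p < alpha:
            for comp in posthoc_pairwise(vals, groups, res):
                if comp.p_adjusted < alpha:
                    a, b = comp.pair
                    sig_pairs.append(f"{a}>{b}" if comp.direction > 0 else f"{a}<{b}")
        row["significant_pairs"] = "; ".join(sig_pairs)
        rows.append(row)
    return pd.DataFrame(rows)


class EdgewiseAnovaScreen(BaseEstimator):
    """Sklearn-style screen: fit edge features against group labels.

    ``fit(X, y)`` takes an ``(n_subjects, n_edges)`` feature matrix (e.g. the
    output of :class:`restfc.connectivity.PearsonConnectivity`) and group
    labels ``y``; fitted attributes expose per-edge F and p, the boolean
    screened-in mask, and the long-format results table.
    """

    def __init__(self, alpha: float = 0.05, family_scope: str = "posthoc_only"):
        self.alpha = alpha
        self.family_scope = family_scope

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_subjects, n_edges) aligned with y")
        if self.family_scope not in FAMILY_SCOPES:
            raise ValueError(f"family_scope must be one of {FAMILY_SCOPES}")
        groups, group_idx = np.unique(y, return_inverse=True)
        if groups.size < 2:
            raise ValueError("need at least 2 groups")
        counts = np.bincount(group_idx)
        if counts.min() < 2:
            raise ValueError("every group needs >= 2 subjects")
        f, p, means, sds, msw, df_b, df_w = _vectorized_anova(
            X, group_idx, groups.size
        )
        n_edges = X.shape[1]
        edge_factor = n_edges if self.family_scope in ("edges_bonferroni", "both") else 1
        self.groups_ = tuple(str(g) for g in groups)
        self._group_values = groups
        self.f_ = f
        self.p_ = p
        self.p_screen_ = np.minimum(1.0, p * edge_factor)
        self.significant_ = self.p_screen_ < self.alpha
        self.group_means_ = means
        self.group_sds_ = sds
        self.df_ = (df_b, df_w)
        self.n_features_in_ = n_edges
        return self

    def transform(self, X):
        """Restrict a feature matrix to the screened-in edges."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "significant_")
        return np.asarray(X, dtype=float)[:, self.significant_]

    def posthoc(self, X, y, edge: int) -> list[PosthocComparison]:
        """Pooled-MSE pairwise comparisons at one edge of the fitted screen."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "significant_")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        vals = [X[y == g, edge] for g in self._group_values]
        res = one_way_anova(vals)
        factor = (
            len(self.groups_) * (len(self.groups_) - 1) // 2
            if self.family_scope in ("posthoc_only", "both")
            else 1
        )
        return posthoc_pairwise(vals, self.groups_, res, factor)
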