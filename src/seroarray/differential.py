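"""Group-comparison statistics, the biomarker union, and multivariate signatures.

Differential calls use a Welch two-sample t-test per antigen on
log(x + 1)-transformed intensities (group sizes are unequal and raw RFUs
are right-skewed), Bonferroni-corrected over the antigens actually
tested; a call additionally requires a standardized mean difference of at
least two pooled SDs, so significance and effect size are gated jointly.
Candidate biomarkers from the linear, top-N, Venn-unique, differential
and cross-platform analyses are merged into one union with per-antigen
provenance.  Multivariate structure is probed by agglomerative
clustering (Euclidean or correlation distance), a correlation-based
k-means variant, and PCA, including the re-analysis restricted to the
top-k cancer-signature antigens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .normalize import AntigenMatrix
from .serology import FoldMatrix, fold_over_cutoff
from .simulate import SampleMeta

ANALYSIS_TAGS = ("Linear", "Top20", "Venn", "Differential", "Shotgun")
DEFAULT_KMEANS_SEED = 1234
KMEANS_RESTARTS = 25


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastResult:
    antigen_id: str
    mean_a: float
    mean_b: float
    t_stat: float
    p_raw: float
    p_adj: float
    sd_units: float
    call: str  # UP / DOWN / NS


def _resolve_groups(meta: Sequence[SampleMeta], label: str) -> list[str]:
    groups = label.split("+")
    known = {m.group for m in meta}
    for g in groups:
        if g not in known:
            raise StatsError(f"unknown group {g!r}")
    return [m.sample_id for m in meta if m.group in groups]


def differential_contrast(
    matrix: AntigenMatrix,
    meta: Sequence[SampleMeta] | None = None,
    group_a: str = "PCa",
    group_b: str = "BPH",
    alpha: float = 0.01,
) -> tuple[list[ContrastResult], list[str]]:
    """Welch t-test per antigen between two (possibly composite) groups.

    ``group_b`` accepts composite labels such as ``"BPH+DC"`` for a
    malignant-vs-all-benign contrast.  Antigens with fewer than two
    non-excluded values on either side are reported untested (second
    return value).  Reported group means are on the original RFU scale;
    the test and the pooled-SD standardized difference are computed on
    log(x + 1).
    """
    meta = list(meta) if meta is not None else matrix.meta
    ids_a = [s for s in _resolve_groups(meta, group_a) if s in set(matrix.sample_ids)]
    ids_b = [s for s in _resolve_groups(meta, group_b) if s in set(matrix.sample_ids)]
    if not ids_a or not ids_b:
        raise StatsError("both groups need at least one sample in the matrix")

    A = matrix.values.loc[ids_a].to_numpy(dtype=float)
    B = matrix.values.loc[ids_b].to_numpy(dtype=float)
    la, lb = np.log1p(A), np.log1p(B)
    na = np.sum(~np.isnan(la), axis=0)
    nb = np.sum(~np.isnan(lb), axis=0)
    testable = (na >= 2) & (nb >= 2)
    untested = [aid for aid, ok in zip(matrix.antigen_ids, testable) if not ok]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(la, lb, axis=0, equal_var=False, nan_policy="omit")
        mean_a_rfu = np.nanmean(A, axis=0)
        mean_b_rfu = np.nanmean(B, axis=0)
        mla, mlb = np.nanmean(la, axis=0), np.nanmean(lb, axis=0)
        va = np.nanvar(la, axis=0, ddof=1)
        vb = np.nanvar(lb, axis=0, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / np.maximum(na + nb - 2, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_units = (mla - mlb) / pooled

    m = int(np.sum(testable))
    results: list[ContrastResult] = []
    for j, aid in enumerate(matrix.antigen_ids):
        if not testable[j]:
            continue
        tj, pj = float(t[j]), float(p[j])
        sdj = float(sd_units[j])
        if va[j] == 0 and vb[j] == 0:
            # degenerate: no within-group variation anywhere
            tj, pj, sdj = 0.0, 1.0, 0.0 if mla[j] == mlb[j] else float("inf")
        if np.isnan(pj):
            tj, pj = 0.0, 1.0
        p_adj = min(1.0, m * pj)
        if p_adj <= alpha and sdj >= 2:
            call = "UP"
        elif p_adj <= alpha and sdj <= -2:
            call = "DOWN"
        else:
            call = "NS"
        results.append(
            ContrastResult(
                aid, float(mean_a_rfu[j]), float(mean_b_rfu[j]),
                tj, pj, p_adj, sdj, call,
            )
        )
    return results, untested


def contrast_table(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antigen_id": r.antigen_id, "mean_a": r.mean_a, "mean_b": r.mean_b,
                "t": r.t_stat, "p_raw": r.p_raw, "p_adj": r.p_adj,
                "sd_units": r.sd_units, "call": r.call,
            }
            for r in results
        ]
    )


@dataclass
class BiomarkerCallSet:
    """Union of candidate biomarkers with per-antigen provenance tags and
    the High/Low direction of the autoantibody response in the cancer
    group."""

    entries: dict[str, tuple[frozenset[str], str]]
    conflicts: dict[str, str] = field(default_factory=dict)

    @property
    def union(self) -> set[str]:
        return set(self.entries)

    def tags(self, antigen_id: str) -> frozenset[str]:
        return self.entries[antigen_id][0]

    def direction(self, antigen_id: str) -> str:
        return self.entries[antigen_id][1]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "antigen_id": aid,
                    "analyses": ";".join(sorted(tags)),
                    "direction": direction,
                }
                for aid, (tags, direction) in sorted(self.entries.items())
            ]
        )


def union_biomarkers(
    linear_calls: Mapping[str, Iterable[str]] | None = None,
    top_n_lists: Mapping[str, Iterable[str]] | None = None,
    venn_unique: Mapping[str, Iterable[str]] | None = None,
    contrasts: Sequence[ContrastResult] = (),
    shotgun_overlap: Iterable[str] = (),
    cancer_group: str = "PCa",
) -> BiomarkerCallSet:
    """Merge the per-analysis candidate lists into one annotated union.

    ``linear_calls``, ``top_n_lists`` and ``venn_unique`` are keyed by
    diagnosis group so direction can be inferred: a differential call
    dictates direction outright (UP -> High, DOWN -> Low); otherwise
    cancer-group evidence reads High and control-group-only evidence
    reads Low.  Antigens with both cancer and control support are
    reported as conflicts (the cancer side wins the recorded direction).
    """
    tag_sources: dict[str, set[str]] = {}
    high_votes: set[str] = set()
    low_votes: set[str] = set()

    def _ingest(tag: str, per_group: Mapping[str, Iterable[str]] | None) -> None:
        if not per_group:
            return
        for group, antigens in per_group.items():
            for aid in antigens:
                tag_sources.setdefault(aid, set()).add(tag)
                (high_votes if group == cancer_group else low_votes).add(aid)

    _ingest("Linear", linear_calls)
    _ingest("Top20", top_n_lists)
    _ingest("Venn", venn_unique)
    diff_direction: dict[str, str] = {}
    for r in contrasts:
        if r.call == "NS":
            continue
        tag_sources.setdefault(r.antigen_id, set()).add("Differential")
        diff_direction[r.antigen_id] = "High" if r.call == "UP" else "Low"
    for aid in shotgun_overlap:
        tag_sources.setdefault(aid, set()).add("Shotgun")
        high_votes.add(aid)

    entries: dict[str, tuple[frozenset[str], str]] = {}
    conflicts: dict[str, str] = {}
    for aid, tags in tag_sources.items():
        if aid in diff_direction:
            direction = diff_direction[aid]
        elif aid in high_votes:
            direction = "High"
        else:
            direction = "Low"
        if aid in high_votes and aid in low_votes:
            conflicts[aid] = "supported in both cancer and control groups"
        entries[aid] = (frozenset(tags), direction)
    return BiomarkerCallSet(entries, conflicts)


def membership_to_union(
    membership: Mapping[str, tuple[frozenset[str], str]]
) -> BiomarkerCallSet:
    """Re-derive a union from a published membership table by routing each
    antigen's tags through :func:`union_biomarkers` (High evidence lands
    in the cancer bucket, Low in the control bucket)."""
    linear: dict[str, set[str]] = {"PCa": set(), "BPH": set()}
    top20: dict[str, set[str]] = {"PCa": set(), "BPH": set()}
    venn: dict[str, set[str]] = {"PCa": set(), "BPH": set()}
    contrasts: list[ContrastResult] = []
    shotgun: set[str] = set()
    for aid, (tags, direction) in membership.items():
        bucket = "PCa" if direction == "High" else "BPH"
        if "Linear" in tags:
            linear[bucket].add(aid)
        if "Top20" in tags:
            top20[bucket].add(aid)
        if "Venn" in tags:
            venn[bucket].add(aid)
        if "Differential" in tags:
            call = "UP" if direction == "High" else "DOWN"
            contrasts.append(
                ContrastResult(aid, np.nan, np.nan, np.nan, 0.0, 0.0, np.nan, call)
            )
        if "Shotgun" in tags:
            shotgun.add(aid)
    return union_biomarkers(linear, top20, venn, contrasts, shotgun)


# ---------------------------------------------------------------------------
# multivariate signatures


def _imputed(matrix: AntigenMatrix) -> pd.DataFrame:
    """Mean-impute missing (excluded) cells per antigen — distance
    computations only; inference never sees imputed values."""
    values = matrix.values.copy()
    means = values.mean(axis=0, skipna=True).fillna(0.0)
    return values.fillna(means)


@dataclass
class HierarchicalResult:
    linkage: np.ndarray
    sample_ids: list[str]
    labels: pd.Series | None  # k-cut cluster labels, if k given
    metric: str


def hierarchical_cluster(
    matrix: AntigenMatrix,
    metric: str = "euclidean",
    linkage_method: str = "average",
    k: int | None = None,
) -> HierarchicalResult:
    """Deterministic agglomerative clustering of samples."""
    if metric not in ("euclidean", "correlation"):
        raise StatsError(f"unsupported metric {metric!r}")
    X = _imputed(matrix).to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise StatsError("need at least 2 samples to cluster")
    if k is not None and k > X.shape[0]:
        raise StatsError(f"k={k} exceeds sample count {X.shape[0]}")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage_method)
    labels = None
    if k is not None:
        cut = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(cut, index=matrix.sample_ids, name="cluster")
    return HierarchicalResult(Z, matrix.sample_ids, labels, metric)


def kmeans_correlation(
    matrix: AntigenMatrix,
    k: int,
    seed: int = DEFAULT_KMEANS_SEED,
    restarts: int = KMEANS_RESTARTS,
) -> pd.Series:
    """k-means under correlation distance, best of ``restarts`` seeded runs.

    Row-standardizing each sample makes squared Euclidean distance
    proportional to (1 - Pearson correlation), so a plain k-means on the
    z-scored rows optimizes the correlation criterion.
    """
    X = _imputed(matrix).to_numpy(dtype=float)
    if k > X.shape[0]:
        raise StatsError(f"k={k} exceeds sample count {X.shape[0]}")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(Z)
    return pd.Series(labels, index=matrix.sample_ids, name="cluster")


def cluster_purity(
    labels: pd.Series, meta: Sequence[SampleMeta], group: str
) -> float:
    """Fraction of a group's samples sharing the group's modal cluster."""
    members = [m.sample_id for m in meta if m.group == group and m.sample_id in labels.index]
    if not members:
        raise StatsError(f"no samples in group {group!r}")
    counts = labels.loc[members].value_counts()
    return float(counts.iloc[0]) / len(members)


@dataclass
class PcaSignature:
    components: np.ndarray  # orthonormal rows (antigen loadings)
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # samples x components
    top_antigens: list[str]
    sub_scores: pd.DataFrame
    sub_explained_variance_ratio: np.ndarray
    labels: pd.Series  # k-cut labels on the top-k-restricted matrix


def pca_signature(
    matrix: AntigenMatrix,
    meta: Sequence[SampleMeta] | None = None,
    top_k: int = 10,
    cancer_group: str = "PCa",
    n_clusters: int = 3,
    fold_min: float = 2.0,
    seed: int = DEFAULT_KMEANS_SEED,
) -> PcaSignature:
    """Full-panel PCA plus the top-k cancer-signature re-analysis.

    The signature antigens are ranked lexicographically by (seropositive
    presence fraction among cancer samples under fold-over-cutoff, then
    mean cancer titre, then antigen id).  The matrix restricted to them is
    re-clustered by Euclidean average-linkage hierarchical clustering and
    re-decomposed; correlation-based distances are deliberately avoided
    here because a signature whose members are coherently elevated in one
    group becomes invisible once each sample's profile is re-centred.
    """
    meta = list(meta) if meta is not None else matrix.meta
    top_k = min(top_k, len(matrix.antigen_ids))
    X = _imputed(matrix)
    Xc = X - X.mean(axis=0)
    n_comp = min(Xc.shape[0] - 1, Xc.shape[1]) or 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xc.to_numpy(dtype=float))
    scores_df = pd.DataFrame(
        scores, index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )

    cancer_ids = [
        m.sample_id for m in meta
        if m.group == cancer_group and m.sample_id in set(matrix.sample_ids)
    ]
    if not cancer_ids:
        raise StatsError(f"no samples in group {cancer_group!r}")
    fm: FoldMatrix = fold_over_cutoff(matrix, fold_min=fold_min)
    presence = fm.positive.loc[[s for s in cancer_ids if s in fm.positive.index]].mean(axis=0)
    cancer_mean = matrix.values.loc[cancer_ids].mean(axis=0, skipna=True)
    ranking = pd.DataFrame({"presence": presence, "mean": cancer_mean}).fillna(0.0)
    ranking = ranking.loc[
        sorted(ranking.index, key=lambda a: (-ranking.at[a, "presence"],
                                             -ranking.at[a, "mean"], a))
    ]
    top_antigens = list(ranking.index[:top_k])

    sub = AntigenMatrix(
        matrix.values[top_antigens].copy(),
        matrix.flags[top_antigens].copy(),
        list(matrix.meta),
        dict(matrix.control_values_post),
    )
    labels = hierarchical_cluster(sub, "euclidean", k=n_clusters).labels
    Xs = _imputed(sub)
    Xs = Xs - Xs.mean(axis=0)
    n_sub = min(Xs.shape[0] - 1, Xs.shape[1]) or 1
    sub_pca = PCA(n_components=n_sub, svd_solver="full")
    sub_scores = sub_pca.fit_transform(Xs.to_numpy(dtype=float))
    sub_df = pd.DataFrame(
        sub_scores, index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(sub_scores.shape[1])],
    )
    return PcaSignature(
        pca.components_, pca.explained_variance_ratio_, scores_df,
        top_antigens, sub_df, sub_pca.explained_variance_ratio_, labels,
    )
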