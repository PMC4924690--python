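"""Linear quantitation of autoantibody responses.

Seropositivity is called by fold-over-cutoff: each array's adaptive
cutoff is its upper quartile of non-excluded antigen values, and an
antigen is seropositive when its value reaches ``fold_min`` (default 2)
times that cutoff.  On top of that sit the rank-based analyses: per-group
top-N lists by mean intensity, the three-way Venn partition of per-group
top-50 sets, ethnicity-stratified mean profiles within the cancer group,
and case-insensitive gene-symbol overlap with an external protein list
(e.g. urinary shotgun proteomics identifications).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import AntigenPanel
from .normalize import AntigenMatrix
from .simulate import SampleMeta

#: the seven regions of a three-set Venn partition, keyed by sorted member tuple
VENN_REGION_LABELS = {
    ("A",): "A_only",
    ("B",): "B_only",
    ("C",): "C_only",
    ("A", "B"): "A_B_only",
    ("A", "C"): "A_C_only",
    ("B", "C"): "B_C_only",
    ("A", "B", "C"): "all_three",
}


class AnalysisError(ValueError):
    pass


@dataclass
class FoldMatrix:
    fold: pd.DataFrame
    positive: pd.DataFrame  # boolean; False where excluded
    cutoffs: pd.Series  # per-array cutoff (RFU)
    fold_min: float


def fold_over_cutoff(
    matrix: AntigenMatrix, fold_min: float = 2.0, min_cutoff: float = 1.0
) -> FoldMatrix:
    """Per-array fold over the upper-quartile cutoff.

    Arrays whose antigens are all excluded have no definable cutoff and
    are skipped with a warning.
    """
    if matrix.values.empty:
        raise AnalysisError("empty antigen matrix")
    values = matrix.values
    usable = values.notna().any(axis=1)
    skipped = values.index[~usable].tolist()
    if skipped:
        warnings.warn(f"skipping fully-excluded arrays: {skipped}", stacklevel=2)
    values = values.loc[usable]
    cutoffs = values.quantile(0.75, axis=1).clip(lower=min_cutoff)
    fold = values.div(cutoffs, axis=0)
    positive = fold.ge(fold_min) & values.notna()
    return FoldMatrix(fold, positive, cutoffs, fold_min)


def top_n_by_group(
    matrix: AntigenMatrix, meta: Sequence[SampleMeta] | None = None, n: int = 20
) -> dict[str, pd.DataFrame]:
    """Per-group antigens ranked by group-mean intensity, descending.

    Excluded cells are omitted from means; ties break lexicographically on
    antigen id so the ranking is deterministic.  The group means travel
    with the ranking so an intensity-based cutoff rationale (e.g. "means
    around 500 RFU and higher") stays auditable.
    """
    meta = list(meta) if meta is not None else matrix.meta
    groups = _group_samples(matrix, meta)
    out: dict[str, pd.DataFrame] = {}
    for group, sids in groups.items():
        if not sids:
            raise AnalysisError(f"group {group!r} has no samples")
        means = matrix.values.loc[sids].mean(axis=0, skipna=True)
        table = (
            means.rename("mean_rfu")
            .rename_axis("antigen_id")
            .reset_index()
            .sort_values(["mean_rfu", "antigen_id"], ascending=[False, True])
        )
        out[group] = table.head(min(n, len(table))).reset_index(drop=True)
    return out


def _group_samples(
    matrix: AntigenMatrix, meta: Sequence[SampleMeta]
) -> dict[str, list[str]]:
    present = set(matrix.sample_ids)
    groups: dict[str, list[str]] = {}
    for m in meta:
        if m.sample_id in present:
            groups.setdefault(m.group, []).append(m.sample_id)
    return groups


@dataclass
class VennPartition:
    """Disjoint regions of three sets; sizes sum to the union size."""

    set_names: tuple[str, str, str]
    regions: dict[str, set[str]]

    @property
    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def unique_to(self, name: str) -> set[str]:
        letter = "ABC"[self.set_names.index(name)]
        return self.regions[f"{letter}_only"]


def venn3_partition(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition three named sets into the seven disjoint Venn regions."""
    names = tuple(sets)
    if len(names) != 3:
        raise AnalysisError(f"need exactly 3 sets, got {len(names)}")
    a, b, c = (set(sets[n]) for n in names)
    regions = {
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
        "A_B_only": (a & b) - c,
        "A_C_only": (a & c) - b,
        "B_C_only": (b & c) - a,
        "all_three": a & b & c,
    }
    return VennPartition(names, regions)


def venn_top_sets(
    matrix: AntigenMatrix,
    meta: Sequence[SampleMeta] | None = None,
    n: int = 50,
) -> VennPartition:
    """Three-way Venn partition of the per-group top-``n`` antigen sets."""
    meta = list(meta) if meta is not None else matrix.meta
    groups = _group_samples(matrix, meta)
    if len(groups) != 3:
        raise AnalysisError(f"need 3 groups for a 3-way Venn, got {sorted(groups)}")
    if n > len(matrix.antigen_ids):
        warnings.warn(
            f"top-{n} exceeds panel size {len(matrix.antigen_ids)}; capping",
            stacklevel=2,
        )
        n = len(matrix.antigen_ids)
    tops = top_n_by_group(matrix, meta, n)
    sets = {g: set(t["antigen_id"]) for g, t in tops.items()}
    return venn3_partition(sets)


@dataclass
class EthnicityProfile:
    group: str
    means: pd.DataFrame  # strata x antigens
    argmax: pd.Series  # per antigen: stratum label, or "tied(...)"
    stratum_sizes: dict[str, int]


def ethnicity_profile(
    matrix: AntigenMatrix,
    meta: Sequence[SampleMeta] | None = None,
    group: str = "PCa",
) -> EthnicityProfile:
    """Per-ethnicity mean antigen response within one diagnosis group.

    Strata with zero samples are excluded with a warning; stratum sizes
    are reported alongside because small, imbalanced strata (the study's
    3/6/11 split) limit what the per-stratum argmax can support.
    """
    meta = list(meta) if meta is not None else matrix.meta
    members = [m for m in meta if m.group == group and m.sample_id in set(matrix.sample_ids)]
    if not members:
        raise AnalysisError(f"no samples in group {group!r}")
    missing = [m.sample_id for m in members if m.ethnicity is None]
    if missing:
        raise AnalysisError(f"samples missing ethnicity: {missing}")
    strata: dict[str, list[str]] = {}
    for m in members:
        strata.setdefault(m.ethnicity, []).append(m.sample_id)
    empty = [s for s, ids in strata.items() if not ids]
    for s in empty:
        warnings.warn(f"stratum {s!r} has no samples; excluded", stacklevel=2)
        del strata[s]
    rows = {s: matrix.values.loc[ids].mean(axis=0, skipna=True) for s, ids in strata.items()}
    means = pd.DataFrame(rows).T.sort_index()

    def _argmax(col: pd.Series) -> str:
        top = col.max()
        winners = sorted(col.index[col == top])
        return winners[0] if len(winners) == 1 else "tied(" + ",".join(winners) + ")"

    argmax = means.apply(_argmax, axis=0)
    return EthnicityProfile(group, means, argmax, {s: len(ids) for s, ids in strata.items()})


def linear_standouts(
    fold: FoldMatrix,
    matrix: AntigenMatrix,
    meta: Sequence[SampleMeta] | None = None,
    k: int = 4,
) -> dict[str, list[str]]:
    """Per-group standout antigens by mean fold-over-cutoff.

    This is the tabular counterpart of the per-group radar plots: the
    ``k`` antigens with the largest group-mean fold, i.e. the responses
    that dominate a group's seropositivity profile.
    """
    meta = list(meta) if meta is not None else matrix.meta
    groups = _group_samples(matrix, meta)
    out: dict[str, list[str]] = {}
    for group, sids in groups.items():
        sids = [s for s in sids if s in fold.fold.index]
        means = fold.fold.loc[sids].mean(axis=0, skipna=True)
        ranked = sorted(means.index, key=lambda a: (-means.get(a, 0.0), a))
        out[group] = [a for a in ranked if not np.isnan(means.get(a, np.nan))][:k]
    return out


def cross_platform_overlap(
    panel: AntigenPanel, proteins: Iterable[str]
) -> set[str]:
    """Panel antigens whose gene symbol appears (case-insensitively) in an
    external protein list; antigens without a gene symbol never match."""
    wanted = {p.strip().lower() for p in proteins if p and p.strip()}
    return {
        f.antigen_id
        for f in panel.features
        if f.gene_symbol is not None and f.gene_symbol.lower() in wanted
    }
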