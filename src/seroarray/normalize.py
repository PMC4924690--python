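"""Control-anchored composite normalization across arrays.

Every subarray carries triplicate Cy5-BSA spots at three concentrations
(72 anchor spots per array).  Under the working assumption that these
positive controls share one distribution across arrays, the normalizer

1. quantile-normalizes each array's control distribution onto a baseline
   (the across-array mean of control order statistics), extending the
   resulting monotone piecewise-linear map to the antigen signals, then
2. rescales each array so its post-map control sum equals the across-array
   mean control sum ("total intensity" component), which makes the
   constant-control-sum postcondition exact even when arrays contribute
   unequal control counts after outlier removal.

Both steps are monotone within an array, so antigen rankings are never
reordered by normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import BSA_ROLES
from .simulate import SampleMeta
from .spots import EXCLUDED, ArrayQcSummary, CollapsedSignal

#: robust-outlier multiplier on the scaled MAD (per concentration, per array).
#: With only ~24 anchors per concentration the MAD estimate itself is noisy,
#: so a 3-sigma-style cut trims legitimate spots; genuine artifacts (specks,
#: saturation) sit orders of magnitude out, which k=5 still catches cleanly.
DEFAULT_MAD_K = 5.0
_MAD_SCALE = 1.4826  # normal-consistency factor


class NormalizationError(ValueError):
    """Raised when an array cannot be anchored (e.g. no usable controls)."""


@dataclass
class ControlProfile:
    sample_id: str
    control_values: np.ndarray  # net intensities of usable anchor spots

    @property
    def control_sum(self) -> float:
        return float(np.sum(self.control_values))


def extract_control_profiles(
    summaries: Sequence[ArrayQcSummary],
    mad_k: float = DEFAULT_MAD_K,
) -> tuple[list[ControlProfile], dict[str, list[float]]]:
    """Collect anchor-spot nets per array, dropping robust outliers.

    Within each array and concentration, values beyond ``mad_k`` scaled
    MADs from the median are dropped and reported (second return value,
    keyed by sample).  The surviving values are then reorganized onto a
    common quantile grid (one level per nominal anchor spot) so every
    array contributes an equal-count control profile regardless of how
    many spots were dropped; this keeps the downstream quantile map
    exactly idempotent.  An array with no usable anchors at all cannot be
    normalized and raises.
    """
    kept_by_array: dict[str, np.ndarray] = {}
    dropped: dict[str, list[float]] = {}
    n_nominal = 0
    for summ in summaries:
        kept: list[float] = []
        out: list[float] = []
        n_total = 0
        for role in BSA_ROLES:
            values = np.asarray(summ.control_nets.get(role, []), dtype=float)
            n_total += values.size
            if values.size == 0:
                continue
            med = float(np.median(values))
            mad = _MAD_SCALE * float(np.median(np.abs(values - med)))
            if mad > 0:
                mask = np.abs(values - med) <= mad_k * mad
            else:
                mask = values == med
            kept.extend(values[mask].tolist())
            out.extend(values[~mask].tolist())
        if n_total == 0:
            raise NormalizationError(f"{summ.sample_id}: array has no anchor spots")
        if not kept:
            raise NormalizationError(
                f"{summ.sample_id}: all anchor spots excluded; cannot normalize"
            )
        n_nominal = max(n_nominal, n_total)
        kept_by_array[summ.sample_id] = np.sort(np.asarray(kept))
        if out:
            dropped[summ.sample_id] = out

    levels = np.linspace(0.0, 1.0, n_nominal)
    profiles = [
        ControlProfile(sid, np.quantile(values, levels, method="linear"))
        for sid, values in kept_by_array.items()
    ]
    return profiles, dropped


@dataclass
class QuantileBaseline:
    """Across-array baseline quantile function plus per-array anchor maps."""

    levels: np.ndarray
    baseline: np.ndarray
    array_quantiles: dict[str, np.ndarray]

    def map_values(self, sample_id: str, values: np.ndarray) -> np.ndarray:
        """Monotone piecewise-linear map from an array's control scale to
        the baseline; beyond the control range the boundary segment's
        slope extrapolates."""
        x = self.array_quantiles[sample_id]
        y = self.baseline
        xs, idx = np.unique(x, return_index=True)
        ys = y[idx]
        # anchor at the origin: zero net signal normalizes to zero, so the
        # sub-control-range region (where most antigens live) is a pure
        # scaling toward 0 rather than an affine offset
        if xs[0] > 0:
            xs = np.concatenate(([0.0], xs))
            ys = np.concatenate(([0.0], ys))
        values = np.asarray(values, dtype=float)
        if xs.size == 1:
            # degenerate (single zero knot): identity
            return values.copy()
        out = np.interp(values, xs, ys)
        lo = values < xs[0]
        hi = values > xs[-1]
        slope_lo = (ys[1] - ys[0]) / (xs[1] - xs[0])
        # above the anchor range, extend proportionally along the chord
        # from the origin: the top empirical segment is governed by two
        # extreme order statistics and is far too noisy to extrapolate
        # the decade of signal that can sit beyond the brightest anchor
        slope_hi = ys[-1] / xs[-1] if xs[-1] > 0 else 1.0
        out[lo] = ys[0] + (values[lo] - xs[0]) * slope_lo
        out[hi] = values[hi] * slope_hi
        return out


def quantile_baseline(profiles: Sequence[ControlProfile]) -> QuantileBaseline:
    """Baseline = mean across arrays of control order statistics.

    Unequal control counts (after outlier removal) are reconciled by
    evaluating each array's empirical quantile function on a common grid
    of levels by linear interpolation.
    """
    if len(profiles) < 2:
        raise NormalizationError("quantile baseline requires at least 2 arrays")
    n_grid = max(p.control_values.size for p in profiles)
    levels = np.linspace(0.0, 1.0, n_grid)
    array_q: dict[str, np.ndarray] = {}
    for p in profiles:
        array_q[p.sample_id] = np.quantile(p.control_values, levels, method="linear")
    baseline = np.mean(np.vstack(list(array_q.values())), axis=0)
    return QuantileBaseline(levels, baseline, array_q)


@dataclass
class AntigenMatrix:
    """Samples x antigens normalized net intensities with QC flags."""

    values: pd.DataFrame  # float; NaN where EXCLUDED
    flags: pd.DataFrame  # frozenset[str] per cell
    meta: list[SampleMeta] = field(default_factory=list)
    control_values_post: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.flags.shape:
            raise NormalizationError("values/flags shape mismatch")
        if self.meta and len(self.meta) != len(self.values.index):
            raise NormalizationError("meta length does not match sample count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def antigen_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta_by_id(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.meta}

    def to_tsv(self, values_sink: str | IO[str], flags_sink: str | IO[str] | None = None) -> None:
        self.values.rename_axis("sample_id").to_csv(values_sink, sep="\t")
        if flags_sink is not None:
            joined = self.flags.map(lambda f: ";".join(sorted(f)))
            joined.rename_axis("sample_id").to_csv(flags_sink, sep="\t")


def apply_composite(
    collapsed: Mapping[str, Sequence[CollapsedSignal]],
    profiles: Sequence[ControlProfile],
    baseline: QuantileBaseline,
    meta: Sequence[SampleMeta] = (),
) -> AntigenMatrix:
    """Normalize collapsed antigen nets through the composite scheme.

    Arrays without a control profile are omitted with a warning rather
    than silently dropped; excluded antigens propagate as missing values
    with their flags carried through.
    """
    by_id = {p.sample_id: p for p in profiles}
    sample_ids = [sid for sid in collapsed if sid in by_id]
    skipped = [sid for sid in collapsed if sid not in by_id]
    if skipped:
        warnings.warn(
            f"omitting {len(skipped)} array(s) without control profiles: {skipped}",
            stacklevel=2,
        )
    if not sample_ids:
        raise NormalizationError("no normalizable arrays")

    antigen_ids = [s.antigen_id for s in collapsed[sample_ids[0]]]
    mapped_rows: dict[str, np.ndarray] = {}
    mapped_controls: dict[str, np.ndarray] = {}
    flag_rows: dict[str, list[frozenset[str]]] = {}
    for sid in sample_ids:
        sigs = collapsed[sid]
        nets = np.array(
            [s.net if s.net is not None else np.nan for s in sigs], dtype=float
        )
        mapped = baseline.map_values(sid, nets)
        mapped_rows[sid] = mapped
        mapped_controls[sid] = baseline.map_values(sid, by_id[sid].control_values)
        flag_rows[sid] = [s.flags for s in sigs]

    post_sums = {sid: float(np.sum(mapped_controls[sid])) for sid in sample_ids}
    target = float(np.mean(list(post_sums.values())))
    values = {}
    controls_post = {}
    for sid in sample_ids:
        factor = target / post_sums[sid]
        values[sid] = mapped_rows[sid] * factor
        controls_post[sid] = mapped_controls[sid] * factor

    vdf = pd.DataFrame.from_dict(values, orient="index", columns=antigen_ids)
    vdf = vdf.loc[sample_ids]
    fdf = pd.DataFrame.from_dict(flag_rows, orient="index", columns=antigen_ids)
    fdf = fdf.loc[sample_ids]
    kept_meta = [m for m in meta if m.sample_id in set(sample_ids)]
    return AntigenMatrix(vdf, fdf, kept_meta, controls_post)


def normalize_cohort(
    collapsed: Mapping[str, Sequence[CollapsedSignal]],
    summaries: Sequence[ArrayQcSummary],
    meta: Sequence[SampleMeta] = (),
    mad_k: float = DEFAULT_MAD_K,
) -> AntigenMatrix:
    """Convenience composition: profiles -> baseline -> composite map.

    A lone array has nothing to be equalized against: it passes through
    unchanged (identity map, unit scale factor).
    """
    profiles, _ = extract_control_profiles(summaries, mad_k=mad_k)
    if len(profiles) == 1:
        p = profiles[0]
        baseline = QuantileBaseline(
            np.linspace(0.0, 1.0, p.control_values.size),
            p.control_values.copy(),
            {p.sample_id: p.control_values.copy()},
        )
    else:
        baseline = quantile_baseline(profiles)
    return apply_composite(collapsed, profiles, baseline, meta)


def reapply_composite(matrix: AntigenMatrix) -> AntigenMatrix:
    """Run the composite normalization again on its own output.

    Used to check idempotence: the post-normalization controls already sit
    on the shared baseline, so the second pass must be a no-op.
    """
    from .spots import CollapsedSignal  # local import to avoid cycle confusion

    profiles = [
        ControlProfile(sid, np.sort(vals))
        for sid, vals in matrix.control_values_post.items()
    ]
    baseline = quantile_baseline(profiles)
    collapsed = {
        sid: [
            CollapsedSignal(
                aid,
                None if np.isnan(matrix.values.at[sid, aid]) else float(matrix.values.at[sid, aid]),
                0 if np.isnan(matrix.values.at[sid, aid]) else 1,
                matrix.flags.at[sid, aid],
            )
            for aid in matrix.antigen_ids
        ]
        for sid in matrix.sample_ids
    }
    return apply_composite(collapsed, profiles, baseline, matrix.meta)
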