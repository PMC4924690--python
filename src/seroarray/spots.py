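"""Spot-level QC, background correction and triplicate collapse.

Each antigen is printed three times per array.  A spot first passes
individual gates — signal-to-noise ratio against its local background,
pixel homogeneity (doughnut spots have high pixel CV), saturation and the
scanner validity window — then the surviving replicate net intensities are
collapsed to a single antigen-level value.  When the triplicate is too
variable, the replicate farthest from the median is discarded and the
remaining pair must agree within a relative variability bound
|S1 - S2| / (S1 + S2), else the antigen is excluded for that array.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .layout import BSA_ROLES, SlideLayout, SpotRole
from .simulate import ArrayScan, SpotRecord

# QC flags
DROPPED_OUTLIER = "DROPPED_OUTLIER"
HIGH_CV = "HIGH_CV"
LOW_SNR = "LOW_SNR"
SATURATED = "SATURATED"
NEG_NET = "NEG_NET"
EXCLUDED = "EXCLUDED"

#: saturated-pixel fraction beyond which a spot is unusable
SAT_FRAC_MAX = 0.5


class SpotQcError(ValueError):
    """Raised for structurally invalid spot groupings."""


@dataclass(frozen=True)
class QcThresholds:
    """Spot/triplicate QC gates.

    ``snr_min`` and the 200-65,550 RFU validity window follow the assay's
    stated acceptance rules; the CV and pair-variability bounds are not
    printed anywhere and are exposed here with conservative defaults.
    """

    snr_min: float = 2.0
    valid_low: float = 200.0
    valid_high: float = 65550.0
    pixel_cv_max: float = 0.25
    triplicate_cv_max: float = 0.15
    variability_max: float = 0.10
    bg_floor: float = 1.0

    def __post_init__(self) -> None:
        if not self.valid_low < self.valid_high:
            raise SpotQcError("valid_low must be below valid_high")
        for name in ("snr_min", "pixel_cv_max", "triplicate_cv_max",
                     "variability_max", "bg_floor"):
            if getattr(self, name) <= 0:
                raise SpotQcError(f"{name} must be positive")


@dataclass(frozen=True)
class CollapsedSignal:
    antigen_id: str
    net: float | None
    n_used: int
    flags: frozenset[str] = frozenset()

    @property
    def excluded(self) -> bool:
        return EXCLUDED in self.flags


def net_intensity(spot: SpotRecord) -> float:
    """Net spot signal: raw mean minus local background (may be negative)."""
    return spot.raw_mean - spot.bg_mean


def snr(spot: SpotRecord, thr: QcThresholds = QcThresholds()) -> float:
    """Signal-to-noise ratio: raw mean over (floored) local background."""
    return spot.raw_mean / max(spot.bg_mean, thr.bg_floor)


def pair_variability(s1: float, s2: float) -> float:
    """Relative disagreement of a replicate pair, |S1 - S2| / (S1 + S2)."""
    if s1 == s2:
        return 0.0
    if s1 + s2 <= 0:
        raise SpotQcError("pair variability undefined for non-positive sum")
    return abs(s1 - s2) / (s1 + s2)


def _screen_spot(spot: SpotRecord, thr: QcThresholds) -> set[str]:
    """Individual-spot gates; empty set means the spot is usable."""
    flags: set[str] = set()
    if spot.sat_frac >= SAT_FRAC_MAX or spot.raw_mean > thr.valid_high:
        flags.add(SATURATED)
    if snr(spot, thr) < thr.snr_min or spot.raw_mean < thr.valid_low:
        flags.add(LOW_SNR)
    if spot.pixel_cv > thr.pixel_cv_max:
        flags.add(HIGH_CV)
    return flags


def collapse_triplicate(
    spots: Sequence[SpotRecord], thr: QcThresholds = QcThresholds()
) -> CollapsedSignal:
    """Collapse one antigen's replicate spots to a single net intensity.

    Pipeline: screen each spot individually; if all three survive and
    their net CV exceeds ``triplicate_cv_max``, drop the replicate with
    the largest |net - median| (ties broken toward the brighter spot, the
    classical high-intensity-outlier rule); the surviving pair must agree
    within ``variability_max`` or the antigen is excluded.  Negative
    collapsed nets are floored to zero and flagged, preserving
    seronegativity rather than discarding the antigen.
    """
    if len(spots) != 3:
        raise SpotQcError(f"expected 3 replicate spots, got {len(spots)}")
    aids = {s.address.antigen_id for s in spots}
    if len(aids) != 1:
        raise SpotQcError(f"replicates span multiple antigens: {sorted(map(str, aids))}")
    reps = sorted(s.address.replicate for s in spots)
    if reps != [1, 2, 3]:
        raise SpotQcError(f"replicate indices {reps}, expected [1, 2, 3]")
    antigen_id = spots[0].address.antigen_id or ""

    flags: set[str] = set()
    survivors: list[SpotRecord] = []
    for s in spots:
        spot_flags = _screen_spot(s, thr)
        if spot_flags:
            flags |= spot_flags
        else:
            survivors.append(s)

    nets = sorted(net_intensity(s) for s in survivors)
    if not nets:
        return CollapsedSignal(antigen_id, None, 0, frozenset(flags | {EXCLUDED}))

    if len(nets) == 3:
        mean = statistics.fmean(nets)
        if mean == 0 and len(set(nets)) > 1:
            cv = float("inf")
        elif mean <= 0:
            cv = 0.0 if len(set(nets)) == 1 else float("inf")
        else:
            cv = statistics.stdev(nets) / mean
        if cv > thr.triplicate_cv_max:
            median = statistics.median(nets)
            # most extreme from the median; ties drop the brighter spot
            drop = max(nets, key=lambda v: (abs(v - median), v))
            nets.remove(drop)
            flags.add(DROPPED_OUTLIER)

    if len(nets) == 2:
        try:
            var = pair_variability(nets[0], nets[1])
        except SpotQcError:
            var = float("inf")
        if var > thr.variability_max:
            return CollapsedSignal(antigen_id, None, 0, frozenset(flags | {EXCLUDED}))

    net = statistics.fmean(nets)
    if net < 0:
        flags.add(NEG_NET)
        net = 0.0
    return CollapsedSignal(antigen_id, net, len(nets), frozenset(flags))


@dataclass
class ArrayQcSummary:
    """Per-array QC roll-up, including the control statistics the
    normalizer anchors on."""

    sample_id: str
    n_antigens: int
    n_excluded: int
    frac_excluded: float
    reassay: bool
    bsa_means: dict[SpotRole, float]
    control_nets: dict[SpotRole, list[float]]


def process_array(
    scan: ArrayScan,
    layout: SlideLayout,
    thr: QcThresholds = QcThresholds(),
    reassay_frac: float = 0.20,
) -> tuple[list[CollapsedSignal], ArrayQcSummary]:
    """QC one array: collapse every panel antigen and summarize controls.

    Arrays whose excluded-antigen fraction exceeds ``reassay_frac`` are
    flagged for re-assay, mirroring the wet-lab practice of repeating
    failed slides.
    """
    plexes = {s.address.plex for s in scan.spots}
    if len(plexes) != 1:
        raise SpotQcError(f"{scan.sample_id}: scan spans plexes {sorted(plexes)}")
    plex = plexes.pop()
    expected = {a.position for a in layout.plex_addresses(plex)}
    got = {s.address.position for s in scan.spots}
    if expected != got:
        raise SpotQcError(
            f"{scan.sample_id}: scan addresses do not match layout plex {plex}"
        )

    by_antigen: dict[str, list[SpotRecord]] = {}
    control_nets: dict[SpotRole, list[float]] = {r: [] for r in BSA_ROLES}
    for s in scan.spots:
        if s.address.role is SpotRole.ANTIGEN:
            by_antigen.setdefault(s.address.antigen_id, []).append(s)
        elif s.address.role in BSA_ROLES and not _screen_spot(s, thr) & {SATURATED}:
            control_nets[s.address.role].append(net_intensity(s))

    signals: list[CollapsedSignal] = []
    for aid in layout.panel.antigen_ids:
        reps = by_antigen.get(aid, [])
        signals.append(collapse_triplicate(reps, thr))

    n_excluded = sum(1 for s in signals if s.excluded)
    frac = n_excluded / len(signals) if signals else 0.0
    summary = ArrayQcSummary(
        sample_id=scan.sample_id,
        n_antigens=len(signals),
        n_excluded=n_excluded,
        frac_excluded=frac,
        reassay=frac > reassay_frac,
        bsa_means={
            r: (statistics.fmean(v) if v else float("nan"))
            for r, v in control_nets.items()
        },
        control_nets=control_nets,
    )
    return signals, summary
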