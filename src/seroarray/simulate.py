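"""Synthetic serum cohorts with the statistical structure the pipeline assumes.

No raw scans are deposited for the original study, so every downstream
stage is exercised against simulated spot-extraction tables.  The
generator draws per-sample antigen titres log-normally (autoantibody
responses are strictly positive and heavy right-tailed), applies
group- and ethnicity-specific multiplicative effects, adds truncated-normal
local background, multiplicative replicate (spot) noise, a log-normal
per-array gain factor (the inter-array bias the composite normalizer must
remove), and injects the classical print/scan artifacts: doughnut spots
(inflated pixel CV), speckles, saturated spots pinned at the 16-bit
ceiling, and high local background.

The module also loads the study's printed tables — the 67-patient cohort
roster and the 41-antigen analysis-membership table — which ship with the
package as plain-text fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .layout import (
    BSA_ROLES,
    N_PLEXES,
    SlideLayout,
    SpotAddress,
    SpotRole,
)

GROUPS = ("PCa", "BPH", "DC")
ETHNICITIES = ("B", "W", "MA")
#: 16-bit scanner ceiling (RFU)
INTENSITY_CEILING = 65535.0

_DIAGNOSIS_MAP = {"CANCER": "PCa", "BENIGN": "BPH", "NFM": "DC"}
_MEMBERSHIP_TAGS = {
    "linear": "Linear",
    "differential": "Differential",
    "venn": "Venn",
    "top 20": "Top20",
    "top20": "Top20",
    "shotgun": "Shotgun",
}
#: ethnicity mix of the study cohort, per diagnosis group (B, W, MA)
_ETHNICITY_MIX: dict[str, tuple[int, int, int]] = {
    "PCa": (3, 6, 11),
    "BPH": (9, 8, 15),
    "DC": (3, 0, 12),
}


class CohortError(ValueError):
    """Raised for invalid simulation configs or malformed cohort tables."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str
    age: int
    psa: float | None = None
    ethnicity: str | None = None
    gleason: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"{self.sample_id}: unknown group {self.group!r}")
        if self.ethnicity is not None and self.ethnicity not in ETHNICITIES:
            raise CohortError(f"{self.sample_id}: unknown ethnicity {self.ethnicity!r}")
        if self.gleason is not None and self.group != "PCa":
            raise CohortError(f"{self.sample_id}: Gleason score outside PCa")
        if self.psa is not None and self.psa < 0:
            raise CohortError(f"{self.sample_id}: negative PSA")


@dataclass(frozen=True)
class SpotRecord:
    address: SpotAddress
    raw_mean: float
    bg_mean: float
    pixel_cv: float
    sat_frac: float

    def __post_init__(self) -> None:
        if self.raw_mean < 0 or self.bg_mean < 0:
            raise CohortError("negative raw/background intensity")


@dataclass(frozen=True)
class ArrayScan:
    sample_id: str
    layout_ref: str
    spots: tuple[SpotRecord, ...]


@dataclass
class SimConfig:
    """Generator knobs; defaults emulate the study conditions.

    Titre scale (``baseline_log_mean``/``sd``) is set so that the strongest
    antigens reach group means of several hundred RFU, the regime in which
    a top-20 ranking is meaningful; background sits around 100 RFU, well
    inside the 200-65,550 RFU validity window once signal is added.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PCa": 20, "BPH": 32, "DC": 15}
    )
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    replicate_log_sd: float = 0.1
    background_mean: float = 100.0
    background_sd: float = 25.0
    gain_log_sd: float = 0.5
    bsa_base: float = 2000.0
    pos_igg_level: float = 12000.0
    pos_serum_level: float = 8000.0
    neg_lysate_level: float = 15.0
    effect_map: dict[str, dict[str, float]] = field(default_factory=dict)
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {
            "high_background": 0.005,
            "speckle": 0.005,
            "doughnut": 0.005,
            "saturated": 0.005,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise CohortError(f"unknown group {g!r} in n_per_group")
            if n < 0:
                raise CohortError("negative group count")
        for mode, p in self.artifact_rates.items():
            if mode not in ("high_background", "speckle", "doughnut", "saturated"):
                raise CohortError(f"unknown artifact mode {mode!r}")
            if not 0.0 <= p <= 1.0:
                raise CohortError(f"artifact rate {mode}={p} outside [0,1]")
        for aid, strata in self.effect_map.items():
            for stratum, fold in strata.items():
                if fold <= 0:
                    raise CohortError(f"non-positive fold for {aid}/{stratum}")
                group = stratum.split(":")[0]
                if group not in GROUPS:
                    raise CohortError(f"unknown stratum {stratum!r} for {aid}")
                if fold != 1.0 and self.n_per_group.get(group, 0) == 0:
                    raise CohortError(
                        f"effect on {aid} references empty group {group!r}"
                    )


def _apportion(n: int, weights: tuple[int, ...]) -> list[int]:
    """Largest-remainder apportionment of n samples over strata weights."""
    total = sum(weights)
    if total == 0:
        return [n] + [0] * (len(weights) - 1)
    quotas = [n * w / total for w in weights]
    counts = [math.floor(q) for q in quotas]
    for i in sorted(range(len(weights)), key=lambda i: quotas[i] - counts[i], reverse=True):
        if sum(counts) == n:
            break
        counts[i] += 1
    return counts


def _sample_effect_fold(cfg: SimConfig, aid: str, group: str, ethnicity: str) -> float:
    strata = cfg.effect_map.get(aid)
    if not strata:
        return 1.0
    fold = strata.get(group, 1.0)
    fold *= strata.get(f"{group}:{ethnicity}", 1.0)
    return fold


def simulate_cohort(
    layout: SlideLayout,
    cfg: SimConfig,
    return_truth: bool = False,
) -> tuple[list[SampleMeta], list[ArrayScan]] | tuple[
    list[SampleMeta], list[ArrayScan], dict
]:
    """Draw a synthetic cohort of single-plex scans, reproducible from cfg.seed.

    With ``return_truth`` the per-array gain factors and true titres are
    also returned, which parameter-recovery tests use as ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    antigen_ids = layout.panel.antigen_ids

    meta: list[SampleMeta] = []
    prefix = {"PCa": "PC", "BPH": "BPH", "DC": "DC"}
    for group in GROUPS:
        n = cfg.n_per_group.get(group, 0)
        counts = _apportion(n, _ETHNICITY_MIX[group])
        eths = [e for e, c in zip(ETHNICITIES, counts) for _ in range(c)]
        for i in range(n):
            age = int(rng.integers(45, 85))
            psa = float(np.round(rng.lognormal(1.8, 1.0), 2))
            gleason = int(rng.integers(6, 11)) if group == "PCa" else None
            meta.append(
                SampleMeta(
                    sample_id=f"{prefix[group]}{i + 1}",
                    group=group,
                    age=age,
                    psa=psa,
                    ethnicity=eths[i],
                    gleason=gleason,
                )
            )

    scans: list[ArrayScan] = []
    truth: dict = {"gain": {}, "titres": {}}
    level_of_role = {
        SpotRole.POS_IGG: cfg.pos_igg_level,
        SpotRole.POS_SERUM: cfg.pos_serum_level,
        SpotRole.NEG_LYSATE: cfg.neg_lysate_level,
        SpotRole.EMPTY: 0.0,
    }
    for sidx, sm in enumerate(meta):
        plex = sidx % N_PLEXES
        addresses = layout.plex_addresses(plex)
        gain = float(rng.lognormal(0.0, cfg.gain_log_sd))
        folds = np.array(
            [_sample_effect_fold(cfg, aid, sm.group, sm.ethnicity or "") for aid in antigen_ids]
        )
        titres = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, len(antigen_ids))
        titres = titres * folds
        titre_of = dict(zip(antigen_ids, titres))
        truth["gain"][sm.sample_id] = gain
        truth["titres"][sm.sample_id] = titre_of

        spots: list[SpotRecord] = []
        for addr in addresses:
            if addr.role is SpotRole.ANTIGEN:
                signal = titre_of[addr.antigen_id] * rng.lognormal(0.0, cfg.replicate_log_sd)
            elif addr.role in BSA_ROLES:
                conc_step = BSA_ROLES.index(addr.role) + 1  # 5/10/15 ng/mL -> 1:2:3
                signal = cfg.bsa_base * conc_step * rng.lognormal(0.0, cfg.replicate_log_sd)
            else:
                base = level_of_role[addr.role]
                signal = base * rng.lognormal(0.0, cfg.replicate_log_sd) if base > 0 else 0.0
            bg = max(0.0, rng.normal(cfg.background_mean, cfg.background_sd))
            raw = gain * (bg + signal)
            bg_val = gain * bg
            pixel_cv = abs(rng.normal(0.05, 0.02))
            sat_frac = 0.0

            draws = rng.random(4)
            if draws[0] < cfg.artifact_rates.get("doughnut", 0.0):
                pixel_cv += rng.uniform(0.3, 0.6)
            if draws[1] < cfg.artifact_rates.get("speckle", 0.0):
                raw *= rng.uniform(3.0, 10.0)
                pixel_cv += rng.uniform(0.2, 0.4)
            if draws[2] < cfg.artifact_rates.get("high_background", 0.0):
                bump = bg_val * rng.uniform(5.0, 20.0)
                bg_val += bump
                raw += bump
            if draws[3] < cfg.artifact_rates.get("saturated", 0.0):
                raw = INTENSITY_CEILING
                sat_frac = rng.uniform(0.9, 1.0)
            if raw >= INTENSITY_CEILING:
                raw = INTENSITY_CEILING
                sat_frac = max(sat_frac, 1.0)
            spots.append(
                SpotRecord(addr, float(raw), float(min(bg_val, INTENSITY_CEILING)),
                           float(pixel_cv), float(sat_frac))
            )
        scans.append(ArrayScan(sm.sample_id, layout.panel.version_tag, tuple(spots)))

    if return_truth:
        return meta, scans, truth
    return meta, scans


# ---------------------------------------------------------------------------
# fixture loaders


def _packaged(name: str):
    return resources.files("seroarray.data").joinpath(name)


def load_cohort_table(source: str | IO[str] | None = None) -> list[SampleMeta]:
    """Parse a cohort roster (``Code  Diagnosis  Age  PSA  Race  Gleason``).

    With no source, the packaged roster of the 67-patient study cohort is
    loaded.  Diagnosis tokens CANCER/BENIGN/NFM map onto PCa/BPH/DC and
    literal ``NA`` marks an absent optional field.
    """
    if source is None:
        with resources.as_file(_packaged("table2_cohort.tsv")) as p:
            return load_cohort_table(str(p))
    df = pd.read_csv(source, sep="\t", dtype="string")
    required = {"Code", "Diagnosis", "Age", "PSA", "Race", "Gleason"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"cohort table missing columns: {sorted(missing)}")
    out: list[SampleMeta] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        code = str(rec.Code)
        diag = str(rec.Diagnosis)
        if diag not in _DIAGNOSIS_MAP:
            raise CohortError(f"row {code!r}: unknown diagnosis token {diag!r}")
        try:
            age = int(str(rec.Age))
        except ValueError as exc:
            raise CohortError(f"row {code!r}: non-numeric age {rec.Age!r}") from exc

        def _opt(value, cast):
            if pd.isna(value) or str(value) == "NA":
                return None
            return cast(str(value))

        try:
            psa = _opt(rec.PSA, float)
            gleason = _opt(rec.Gleason, int)
        except ValueError as exc:
            raise CohortError(f"row {code!r}: unparseable numeric field") from exc
        out.append(
            SampleMeta(
                sample_id=code,
                group=_DIAGNOSIS_MAP[diag],
                age=age,
                psa=psa,
                ethnicity=_opt(rec.Race, str),
                gleason=gleason,
            )
        )
    return out


def load_membership_table(
    source: str | IO[str] | None = None,
) -> dict[str, tuple[frozenset[str], str]]:
    """Parse the analysis-membership table: antigen -> (tags, direction).

    Tags are drawn from {Linear, Differential, Venn, Top20, Shotgun};
    direction is High/Low autoantibody titre in the cancer group.  With no
    source, the packaged 41-antigen table is loaded.
    """
    if source is None:
        with resources.as_file(_packaged("table1_membership.tsv")) as p:
            return load_membership_table(str(p))
    df = pd.read_csv(source, sep="\t", dtype="string")
    required = {"antigen", "analyses", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"membership table missing columns: {sorted(missing)}")
    out: dict[str, tuple[frozenset[str], str]] = {}
    for rec in df.itertuples(index=False):
        name = str(rec.antigen)
        raw = str(rec.analyses).replace("&", ",")
        tags = set()
        for part in raw.split(","):
            token = part.strip().lower()
            if not token:
                continue
            if token not in _MEMBERSHIP_TAGS:
                raise CohortError(f"row {name!r}: unknown analysis tag {part.strip()!r}")
            tags.add(_MEMBERSHIP_TAGS[token])
        direction = str(rec.direction).strip().capitalize()
        if direction not in ("High", "Low"):
            raise CohortError(f"row {name!r}: unknown direction {rec.direction!r}")
        out[name] = (frozenset(tags), direction)
    return out


# ---------------------------------------------------------------------------
# scan-table round trip (models the spot-extraction export dialect)

SCAN_COLUMNS = [
    "sample_id", "plex", "subarray", "row", "col", "role", "antigen_id",
    "replicate", "raw_mean", "bg_mean", "pixel_cv", "sat_frac",
]


def write_scan_table(scan: ArrayScan, sink: str | IO[str]) -> None:
    rows = []
    for s in scan.spots:
        a = s.address
        rows.append(
            {
                "sample_id": scan.sample_id,
                "plex": a.plex,
                "subarray": a.subarray,
                "row": a.row,
                "col": a.col,
                "role": a.role.value,
                "antigen_id": a.antigen_id if a.antigen_id is not None else "",
                "replicate": a.replicate if a.replicate is not None else "",
                "raw_mean": repr(s.raw_mean),
                "bg_mean": repr(s.bg_mean),
                "pixel_cv": repr(s.pixel_cv),
                "sat_frac": repr(s.sat_frac),
            }
        )
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(sink, sep="\t", index=False)


def read_scan_table(source: str | IO[str], layout_ref: str = "") -> ArrayScan:
    df = pd.read_csv(
        source, sep="\t", dtype={"antigen_id": "string"},
        float_precision="round_trip",
    )
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"scan table missing columns: {sorted(missing)}")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise CohortError("scan table must cover exactly one sample")
    seen: set[tuple[int, int, int, int]] = set()
    spots: list[SpotRecord] = []
    for rec in df.itertuples(index=False):
        pos = (int(rec.plex), int(rec.subarray), int(rec.row), int(rec.col))
        if pos in seen:
            raise CohortError(f"duplicate spot address {pos}")
        seen.add(pos)
        aid = rec.antigen_id if isinstance(rec.antigen_id, str) and rec.antigen_id else None
        rep = int(rec.replicate) if not pd.isna(rec.replicate) else None
        addr = SpotAddress(*pos, SpotRole(rec.role), aid, rep)
        spots.append(
            SpotRecord(addr, float(rec.raw_mean), float(rec.bg_mean),
                       float(rec.pixel_cv), float(rec.sat_frac))
        )
    return ArrayScan(str(sample_ids[0]), layout_ref, tuple(spots))
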