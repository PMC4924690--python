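"""Antigen panel and physical slide layout for a 4-plex antigen microarray.

The slide carries four replicate array units ("plexes"); each plex is an
8-subarray grid whose subarrays hold 64 spots on an 8 x 8 raster.  A panel
of 123 tumour-associated antigens (a cocktail of cancer/testis antigens,
other TAAs and mutant-p53 variants) is printed in triplicate per plex, with
staggered replicate positions so a local printing defect cannot wipe out a
whole triplicate.  Each subarray additionally carries triplicate
biotinylated Cy5-BSA spots at three concentrations (5/10/15 ng/mL) that
serve as orientation marks and as the anchors for cross-array
normalization; biotinylated IgG and pooled serum act as positive assay
controls and a tag-only insect lysate as the negative control.

The exact spot-to-coordinate map of the physical slide is treated as an
input artifact: :func:`build_slide_layout` generates a valid map
pseudo-randomly from a seed under the printing constraints, and the map is
serialized alongside the data so every downstream stage addresses spots by
role and antigen identity only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

N_PLEXES = 4
N_SUBARRAYS = 8
SUBARRAY_ROWS = 8
SUBARRAY_COLS = 8
SPOTS_PER_SUBARRAY = SUBARRAY_ROWS * SUBARRAY_COLS
SPOTS_PER_PLEX = N_SUBARRAYS * SPOTS_PER_SUBARRAY  # 512
DEFAULT_PANEL_SIZE = 123
DEFAULT_PITCH_UM = 562.0
#: replicates printed per antigen and per control concentration
N_REPLICATES = 3


class LayoutError(ValueError):
    """Raised for structurally invalid panels or layouts."""


class SpotRole(str, Enum):
    ANTIGEN = "ANTIGEN"
    BSA_CY5_5 = "BSA_CY5_5"
    BSA_CY5_10 = "BSA_CY5_10"
    BSA_CY5_15 = "BSA_CY5_15"
    POS_IGG = "POS_IGG"
    POS_SERUM = "POS_SERUM"
    NEG_LYSATE = "NEG_LYSATE"
    EMPTY = "EMPTY"


BSA_ROLES: tuple[SpotRole, ...] = (
    SpotRole.BSA_CY5_5,
    SpotRole.BSA_CY5_10,
    SpotRole.BSA_CY5_15,
)
#: nominal printed concentrations (ng/mL) of the Cy5-BSA anchors
BSA_CONCENTRATION_NG_ML: dict[SpotRole, float] = {
    SpotRole.BSA_CY5_5: 5.0,
    SpotRole.BSA_CY5_10: 10.0,
    SpotRole.BSA_CY5_15: 15.0,
}
ASSAY_CONTROL_ROLES: tuple[SpotRole, ...] = (
    SpotRole.POS_IGG,
    SpotRole.POS_SERUM,
    SpotRole.NEG_LYSATE,
)


class FeatureClass(str, Enum):
    CTA = "CTA"
    TAA = "TAA"
    P53_VARIANT = "p53_variant"


@dataclass(frozen=True)
class AntigenFeature:
    """One printed antigen: identity, class and an optional gene symbol
    used for cross-platform (e.g. shotgun-proteomics) matching."""

    antigen_id: str
    display_name: str
    feature_class: FeatureClass
    gene_symbol: str | None = None


# The 41 antigens called as candidate biomarkers, with gene symbols where a
# clean one-to-one mapping exists (mutant p53 variants all map to TP53; the
# splice-/isoform-qualified entries keep the parent symbol).
_NAMED_ANTIGENS: list[tuple[str, str | None, FeatureClass]] = [
    ("DPPA4", "DPPA4", FeatureClass.CTA),
    ("CEACAM1 Isoform 1", "CEACAM1", FeatureClass.TAA),
    ("NY-ESO-1", "CTAG1B", FeatureClass.CTA),
    ("FGFR2", "FGFR2", FeatureClass.TAA),
    ("RAF", "RAF1", FeatureClass.TAA),
    ("ZNF165", "ZNF165", FeatureClass.CTA),
    ("TKTL1 (Isoform a)", "TKTL1", FeatureClass.CTA),
    ("MAPK3", "MAPK3", FeatureClass.TAA),
    ("CAMEL", "CTAG2", FeatureClass.CTA),
    ("LDHC", "LDHC", FeatureClass.CTA),
    ("BORIS BO", "CTCFL", FeatureClass.CTA),
    ("SPANXA1", "SPANXA1", FeatureClass.CTA),
    ("ROPN1A", "ROPN1", FeatureClass.CTA),
    ("p53 S392A", "TP53", FeatureClass.P53_VARIANT),
    ("p53 L344P", "TP53", FeatureClass.P53_VARIANT),
    ("p53 C141Y", "TP53", FeatureClass.P53_VARIANT),
    ("p53 K328R", "TP53", FeatureClass.P53_VARIANT),
    ("p53 S15A", "TP53", FeatureClass.P53_VARIANT),
    ("p53 T18A", "TP53", FeatureClass.P53_VARIANT),
    ("CDK2", "CDK2", FeatureClass.TAA),
    ("MAGEA11", "MAGEA11", FeatureClass.CTA),
    ("FES", "FES", FeatureClass.TAA),
    ("OIP5", "OIP5", FeatureClass.CTA),
    ("SSX2A", "SSX2", FeatureClass.CTA),
    ("GAGE5", "GAGE5", FeatureClass.CTA),
    ("MAGEB5", "MAGEB5", FeatureClass.CTA),
    ("EGFR", "EGFR", FeatureClass.TAA),
    ("CCDC33", "CCDC33", FeatureClass.CTA),
    ("CSAG2", "CSAG2", FeatureClass.CTA),
    ("DDX53", "DDX53", FeatureClass.CTA),
    ("CT47.11", "CT47A11", FeatureClass.CTA),
    ("p53", "TP53", FeatureClass.TAA),
    ("p53 Q136X", "TP53", FeatureClass.P53_VARIANT),
    ("MAGEB6", "MAGEB6", FeatureClass.CTA),
    ("PBK", "PBK", FeatureClass.TAA),
    ("CAML1", "CALM1", FeatureClass.TAA),
    ("COL6A1", "COL6A1", FeatureClass.TAA),
    ("GAGE1", "GAGE1", FeatureClass.CTA),
    ("PRKCZ", "PRKCZ", FeatureClass.TAA),
    ("p53 S46A", "TP53", FeatureClass.P53_VARIANT),
    ("MAGEB1", "MAGEB1", FeatureClass.CTA),
]


def antigen_id_from_name(name: str) -> str:
    """Canonical short token for a display name (``p53 S46A`` -> ``P53_S46A``)."""
    token = "".join(c if c.isalnum() else "_" for c in name.strip())
    token = "_".join(filter(None, token.split("_")))
    return token.upper()


@dataclass(frozen=True)
class AntigenPanel:
    features: tuple[AntigenFeature, ...]
    version_tag: str = "default"

    def __post_init__(self) -> None:
        ids = [f.antigen_id for f in self.features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LayoutError(f"duplicate antigen_id in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def antigen_ids(self) -> list[str]:
        return [f.antigen_id for f in self.features]

    @property
    def display_names(self) -> list[str]:
        return [f.display_name for f in self.features]

    def get(self, antigen_id: str) -> AntigenFeature:
        for f in self.features:
            if f.antigen_id == antigen_id:
                return f
        raise KeyError(antigen_id)


def build_default_panel(names: Sequence[str] | None = None) -> AntigenPanel:
    """Build the 123-feature antigen panel.

    Without ``names``, the panel holds the 41 named candidate-biomarker
    antigens plus deterministic placeholder cancer/testis antigens
    (``SYN_CTA_042`` ... ``SYN_CTA_123``) standing in for the remaining,
    unpublished panel members.  With ``names`` (123 unique display names),
    the panel uses exactly those, classified by naming convention.
    """
    if names is not None:
        names = list(names)
        if len(set(names)) != len(names):
            raise LayoutError("duplicate display names supplied")
        if len(names) != DEFAULT_PANEL_SIZE:
            raise LayoutError(
                f"panel requires exactly {DEFAULT_PANEL_SIZE} names, got {len(names)}"
            )
        feats = []
        for name in names:
            if name.lower().startswith("p53 "):
                cls = FeatureClass.P53_VARIANT
            else:
                cls = FeatureClass.CTA
            feats.append(AntigenFeature(antigen_id_from_name(name), name, cls))
        return AntigenPanel(tuple(feats), version_tag="custom")

    feats = [
        AntigenFeature(antigen_id_from_name(name), name, cls, gene)
        for name, gene, cls in _NAMED_ANTIGENS
    ]
    for i in range(len(feats) + 1, DEFAULT_PANEL_SIZE + 1):
        name = f"SYN_CTA_{i:03d}"
        feats.append(AntigenFeature(name, name, FeatureClass.CTA))
    return AntigenPanel(tuple(feats), version_tag="ct-panel-123")


@dataclass(frozen=True)
class SpotAddress:
    plex: int
    subarray: int
    row: int
    col: int
    role: SpotRole
    antigen_id: str | None = None
    replicate: int | None = None

    @property
    def position(self) -> tuple[int, int, int, int]:
        return (self.plex, self.subarray, self.row, self.col)


@dataclass(frozen=True)
class SlideLayout:
    panel: AntigenPanel
    addresses: tuple[SpotAddress, ...]
    pitch_um: float = DEFAULT_PITCH_UM

    def plex_addresses(self, plex: int) -> list[SpotAddress]:
        return [a for a in self.addresses if a.plex == plex]


def _adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    # 8-neighbourhood within one subarray raster
    return max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1 and a != b


def _place_plex(panel: AntigenPanel, rng: np.random.Generator) -> list[SpotAddress]:
    """Place one plex's 512 spots; raises LayoutError if staggering fails."""
    bsa: list[tuple[int, int, int, SpotRole, int]] = []
    free: list[tuple[int, int, int]] = []
    for sub in range(N_SUBARRAYS):
        cells = list(itertools.product(range(SUBARRAY_ROWS), range(SUBARRAY_COLS)))
        picks = rng.choice(len(cells), size=9, replace=False)
        bsa_cells = {cells[i] for i in picks}
        assignments = list(rng.permutation(sorted(bsa_cells)))
        for j, (r, c) in enumerate(assignments):
            role = BSA_ROLES[j // N_REPLICATES]
            bsa.append((sub, int(r), int(c), role, j % N_REPLICATES + 1))
        free.extend((sub, r, c) for r, c in cells if (r, c) not in bsa_cells)

    order = rng.permutation(len(free))
    pool = [free[i] for i in order]
    placed: dict[str, list[tuple[int, int, int]]] = {a: [] for a in panel.antigen_ids}
    antigen_spots: list[tuple[int, int, int, str, int]] = []
    # round-robin over replicates so early antigens do not crowd one subarray
    for rep in range(1, N_REPLICATES + 1):
        for aid in panel.antigen_ids:
            chosen = None
            for idx, (sub, r, c) in enumerate(pool):
                clash = any(
                    psub == sub and _adjacent((pr, pc), (r, c))
                    for psub, pr, pc in placed[aid]
                )
                if not clash:
                    chosen = idx
                    break
            if chosen is None:
                raise LayoutError("could not stagger antigen replicates")
            sub, r, c = pool.pop(chosen)
            placed[aid].append((sub, r, c))
            antigen_spots.append((sub, r, c, aid, rep))

    control_spots: list[tuple[int, int, int, SpotRole, int]] = []
    for role in ASSAY_CONTROL_ROLES:
        for rep in range(1, N_REPLICATES + 1):
            sub, r, c = pool.pop()
            control_spots.append((sub, r, c, role, rep))

    addresses: list[SpotAddress] = []
    for sub, r, c, role, rep in bsa:
        addresses.append(SpotAddress(0, sub, r, c, role, None, rep))
    for sub, r, c, aid, rep in antigen_spots:
        addresses.append(SpotAddress(0, sub, r, c, SpotRole.ANTIGEN, aid, rep))
    for sub, r, c, role, rep in control_spots:
        addresses.append(SpotAddress(0, sub, r, c, role, None, rep))
    for sub, r, c in pool:
        addresses.append(SpotAddress(0, sub, r, c, SpotRole.EMPTY))
    return addresses


def build_slide_layout(panel: AntigenPanel, seed: int = 0) -> SlideLayout:
    """Generate a valid 4-plex layout, a pure function of (panel, seed).

    The printer deposits replica arrays, so one plex map is generated and
    stamped onto all four plexes.  Capacity: 3 antigen replicates per
    feature plus 72 Cy5-BSA anchors must fit in 512 spots per plex.
    """
    if N_REPLICATES * len(panel) + 72 > SPOTS_PER_PLEX:
        raise LayoutError(
            f"panel of {len(panel)} antigens exceeds plex capacity "
            f"({N_REPLICATES * len(panel) + 72} > {SPOTS_PER_PLEX})"
        )
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        try:
            plex0 = _place_plex(panel, rng)
            break
        except LayoutError:
            continue
    else:  # pragma: no cover - placement failure is astronomically unlikely
        raise LayoutError("layout placement failed after 20 attempts")

    addresses: list[SpotAddress] = []
    for plex in range(N_PLEXES):
        for a in plex0:
            addresses.append(
                SpotAddress(plex, a.subarray, a.row, a.col, a.role, a.antigen_id, a.replicate)
            )
    return SlideLayout(panel, tuple(addresses))


def validate_layout(layout: SlideLayout) -> list[str]:
    """Check every layout invariant; returns violations (empty iff valid)."""
    violations: list[str] = []
    positions = [a.position for a in layout.addresses]
    if len(set(positions)) != len(positions):
        seen: set[tuple[int, int, int, int]] = set()
        for p in positions:
            if p in seen:
                violations.append(f"duplicate address {p}")
            seen.add(p)

    for plex in range(N_PLEXES):
        plex_addrs = layout.plex_addresses(plex)
        if len(plex_addrs) != SPOTS_PER_PLEX:
            violations.append(
                f"plex {plex}: {len(plex_addrs)} addresses, expected {SPOTS_PER_PLEX}"
            )
        counts: dict[str, list[SpotAddress]] = {}
        for a in plex_addrs:
            if a.role is SpotRole.ANTIGEN:
                if a.antigen_id is None:
                    violations.append(f"plex {plex}: ANTIGEN spot without antigen_id")
                    continue
                counts.setdefault(a.antigen_id, []).append(a)
            elif a.antigen_id is not None:
                violations.append(
                    f"plex {plex}: role {a.role.value} spot carries antigen_id"
                )
        for aid in layout.panel.antigen_ids:
            spots = counts.get(aid, [])
            if len(spots) != N_REPLICATES:
                violations.append(
                    f"plex {plex}: antigen {aid} printed {len(spots)}x, expected 3"
                )
            by_sub: dict[int, list[SpotAddress]] = {}
            for s in spots:
                by_sub.setdefault(s.subarray, []).append(s)
            for sub, group in by_sub.items():
                for s1, s2 in itertools.combinations(group, 2):
                    if _adjacent((s1.row, s1.col), (s2.row, s2.col)):
                        violations.append(
                            f"plex {plex}: replicates of {aid} adjacent in subarray {sub}"
                        )
        for aid in sorted(set(counts) - set(layout.panel.antigen_ids)):
            violations.append(f"plex {plex}: unknown antigen {aid} printed")

        for sub in range(N_SUBARRAYS):
            for role in BSA_ROLES:
                n = sum(
                    1 for a in plex_addrs if a.subarray == sub and a.role is role
                )
                if n != N_REPLICATES:
                    violations.append(
                        f"plex {plex} subarray {sub}: {role.value} printed {n}x, expected 3"
                    )
    return violations


LAYOUT_COLUMNS = ["plex", "subarray", "row", "col", "role", "antigen_id", "replicate"]


def write_layout(layout: SlideLayout, sink: str | IO[str]) -> None:
    rows = [
        {
            "plex": a.plex,
            "subarray": a.subarray,
            "row": a.row,
            "col": a.col,
            "role": a.role.value,
            "antigen_id": a.antigen_id if a.antigen_id is not None else "",
            "replicate": a.replicate if a.replicate is not None else "",
        }
        for a in layout.addresses
    ]
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(sink, sep="\t", index=False)


def read_layout(source: str | IO[str], panel: AntigenPanel) -> SlideLayout:
    df = pd.read_csv(source, sep="\t", dtype={"antigen_id": "string"})
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise LayoutError(f"layout table missing columns: {sorted(missing)}")
    addresses = []
    for rec in df.itertuples(index=False):
        aid = rec.antigen_id if isinstance(rec.antigen_id, str) and rec.antigen_id else None
        rep = int(rec.replicate) if not pd.isna(rec.replicate) else None
        addresses.append(
            SpotAddress(
                int(rec.plex), int(rec.subarray), int(rec.row), int(rec.col),
                SpotRole(rec.role), aid, rep,
            )
        )
    return SlideLayout(panel, tuple(addresses))
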