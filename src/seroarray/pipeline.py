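"""End-to-end orchestration: simulate or ingest, QC, normalize, analyze, report.

``run_pipeline`` executes the full chain and writes every analysis table
under the output directory together with a manifest recording the
configuration, seed and a content hash of each artifact, so a run is
fully reproducible and auditable from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .differential import (
    contrast_table,
    differential_contrast,
    kmeans_correlation,
    pca_signature,
    union_biomarkers,
)
from .layout import build_default_panel, build_slide_layout, read_layout, validate_layout
from .normalize import normalize_cohort
from .serology import (
    cross_platform_overlap,
    ethnicity_profile,
    fold_over_cutoff,
    linear_standouts,
    top_n_by_group,
    venn_top_sets,
)
from .simulate import (
    ArrayScan,
    SampleMeta,
    SimConfig,
    load_cohort_table,
    read_scan_table,
    simulate_cohort,
)
from .spots import QcThresholds, process_array

logger = logging.getLogger("seroarray")

CONTRASTS = (("PCa", "BPH"), ("PCa", "DC"), ("PCa", "BPH+DC"))


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | ingest
    outdir: str = "seroarray_out"
    layout_path: str | None = None
    scans_dir: str | None = None
    cohort_table: str | None = None
    layout_seed: int = 0
    seed: int = 0
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    sim: SimConfig = field(default_factory=SimConfig)
    fold_min: float = 2.0
    min_cutoff: float = 1.0
    top_n: int = 20
    venn_n: int = 50
    linear_k: int = 4
    alpha: float = 0.01
    top_k: int = 10
    n_clusters: int = 3
    shotgun_proteins: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        thr = QcThresholds(**raw.pop("thresholds", {}))
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(thresholds=thr, sim=sim, **raw)

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest":
            for name in ("layout_path", "scans_dir", "cohort_table"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"ingest mode requires existing {name} (got {p!r})")


def summarize_cohort(meta: Sequence[SampleMeta]) -> dict[str, Any]:
    """Group / ethnicity / PSA / age roll-up of a cohort roster."""
    groups: dict[str, int] = {}
    ethnicity: dict[str, dict[str, int]] = {}
    missing_psa = 0
    ages: list[int] = []
    for m in meta:
        groups[m.group] = groups.get(m.group, 0) + 1
        if m.ethnicity is not None:
            eth = ethnicity.setdefault(m.group, {})
            eth[m.ethnicity] = eth.get(m.ethnicity, 0) + 1
        if m.psa is None:
            missing_psa += 1
        ages.append(m.age)
    return {
        "total": len(meta),
        "per_group": groups,
        "ethnicity_per_group": ethnicity,
        "missing_psa": missing_psa,
        "age_range": [min(ages), max(ages)] if ages else [None, None],
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run the full analysis chain; returns the manifest (also written to
    ``outdir/manifest.json``).  On a stage failure, partial outputs are
    retained and the manifest marks the failing stage before the error is
    re-raised."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "status": "running",
        "artifacts": {},
    }
    stage = "setup"
    try:
        stage = "inputs"
        panel = build_default_panel()
        if cfg.mode == "simulate":
            layout = build_slide_layout(panel, seed=cfg.layout_seed)
            sim = SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
            meta, scans = simulate_cohort(layout, sim)
        else:
            layout = read_layout(cfg.layout_path, panel)
            violations = validate_layout(layout)
            if violations:
                raise PipelineError(f"invalid layout: {violations[:5]}")
            meta = load_cohort_table(cfg.cohort_table)
            scans = [
                read_scan_table(str(p), layout.panel.version_tag)
                for p in sorted(Path(cfg.scans_dir).glob("*.tsv"))
            ]
            roster = {m.sample_id: i for i, m in enumerate(meta)}
            scans.sort(key=lambda s: roster.get(s.sample_id, len(roster)))
        logger.info("inputs: %d samples, %d scans", len(meta), len(scans))

        stage = "spot_qc"
        collapsed = {}
        summaries = []
        for scan in scans:
            sigs, summ = process_array(scan, layout, cfg.thresholds)
            collapsed[scan.sample_id] = sigs
            summaries.append(summ)
        qc_rows = [
            {
                "sample_id": s.sample_id,
                "n_antigens": s.n_antigens,
                "n_excluded": s.n_excluded,
                "frac_excluded": s.frac_excluded,
                "reassay": s.reassay,
                **{f"bsa_mean_{r.value.rsplit('_', 1)[-1]}": v for r, v in s.bsa_means.items()},
            }
            for s in summaries
        ]
        _write_tsv(pd.DataFrame(qc_rows), outdir / "qc_summary.tsv")
        logger.info(
            "spot QC: %d arrays, %d flagged for re-assay",
            len(summaries), sum(s.reassay for s in summaries),
        )

        stage = "normalization"
        matrix = normalize_cohort(collapsed, summaries, meta)
        matrix.values.rename_axis("sample_id").to_csv(
            outdir / "antigen_matrix.tsv", sep="\t", float_format="%.6g"
        )

        stage = "fold_over_cutoff"
        fold = fold_over_cutoff(matrix, cfg.fold_min, cfg.min_cutoff)
        fold.fold.rename_axis("sample_id").to_csv(
            outdir / "fold_matrix.tsv", sep="\t", float_format="%.6g"
        )

        stage = "top_n"
        tops = top_n_by_group(matrix, meta, cfg.top_n)
        top_df = pd.concat(
            [t.assign(group=g, rank=range(1, len(t) + 1)) for g, t in tops.items()]
        )
        _write_tsv(top_df[["group", "rank", "antigen_id", "mean_rfu"]], outdir / "top_n.tsv")

        stage = "venn"
        venn = venn_top_sets(matrix, meta, cfg.venn_n)
        venn_rows = [
            {"region": region, "size": len(members), "antigens": ";".join(sorted(members))}
            for region, members in venn.regions.items()
        ]
        _write_tsv(pd.DataFrame(venn_rows), outdir / "venn_partition.tsv")

        stage = "contrasts"
        contrast_results = {}
        for a, b in CONTRASTS:
            res, untested = differential_contrast(matrix, meta, a, b, cfg.alpha)
            contrast_results[(a, b)] = res
            name = f"contrast_{a}_vs_{b.replace('+', '_')}.tsv"
            _write_tsv(contrast_table(res), outdir / name)
            logger.info(
                "contrast %s vs %s: %d tested, %d untested, %d called",
                a, b, len(res), len(untested),
                sum(1 for r in res if r.call != "NS"),
            )

        stage = "ethnicity"
        eth = ethnicity_profile(matrix, meta, "PCa")
        eth_df = eth.means.rename_axis("stratum").reset_index()
        _write_tsv(eth_df, outdir / "ethnicity_profile.tsv")

        stage = "union"
        linear = linear_standouts(fold, matrix, meta, cfg.linear_k)
        venn_unique = {g: venn.unique_to(g) for g in ("PCa", "BPH", "DC")}
        all_diff = [r for res in contrast_results.values() for r in res]
        shotgun = cross_platform_overlap(panel, cfg.shotgun_proteins)
        union = union_biomarkers(
            linear, {g: list(t["antigen_id"]) for g, t in tops.items()},
            venn_unique, all_diff, shotgun,
        )
        _write_tsv(union.table(), outdir / "biomarker_union.tsv")
        logger.info("biomarker union: %d antigens", len(union.union))

        stage = "signature"
        sig = pca_signature(
            matrix, meta, top_k=cfg.top_k, n_clusters=cfg.n_clusters
        )
        sig_df = sig.sub_scores.copy()
        sig_df.insert(0, "cluster", sig.labels)
        sig_df.insert(
            0, "group",
            [next(m.group for m in meta if m.sample_id == s) for s in sig_df.index],
        )
        sig_df = sig_df.rename_axis("sample_id").reset_index()
        sig_df.attrs["top_antigens"] = sig.top_antigens
        _write_tsv(sig_df, outdir / "signature.tsv")

        stage = "manifest"
        for p in sorted(outdir.glob("*.tsv")):
            manifest["artifacts"][p.name] = _sha256(p)
        manifest["status"] = "ok"
        manifest["cohort_summary"] = summarize_cohort(meta)
        manifest["signature_antigens"] = sig.top_antigens
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        for p in sorted(outdir.glob("*.tsv")):
            manifest["artifacts"][p.name] = _sha256(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(cfg: RunConfig) -> dict[str, Any]:
    d = asdict(cfg)
    return d
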