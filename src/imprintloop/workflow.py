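"""Pipeline orchestration: run configured stages in dependency order and
write a manifest plus a human-readable report.

Stages are selected by which inputs the YAML config provides:

* ``digest``  — FASTA + enzyme -> restriction-fragment BED
* ``quant``   — band TSV (+ optional fragment BED/primer BED) -> profile TSV
* ``diff``    — control + case band TSVs -> ROI TSV
* ``phase``   — SNP signal TSV -> allele-call TSV
* ``methqc``  — methylation TSV -> status/subtype TSV
* ``fish``    — spot TSV -> allele, nucleus and summary TSVs

Outputs are deterministic given inputs and seed; the manifest records a
sha256 checksum per output, the package version, the seed and a hash of the
resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .allelic import (
    MethylationRanges,
    SnpSignal,
    classify_sample,
    infer_subtype,
    quantify_allele_fraction,
)
from .differential import StatConfig, anova_profiles, classify_roi
from .errors import ValidationError
from .fish import FishConfig, compare_lines, process_line, read_spots, summarize_line
from .quant import build_looping_profile, profile_to_tsv, read_bands
from .region import ENZYMES, digest_sequence, fragments_to_bed, read_region_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved run configuration (paths + analysis parameters)."""

    outdir: Path
    seed: int = 0
    enzyme: str = "BglII"
    region_start: int = 0
    fasta: Path | None = None
    bands: Path | None = None
    control_bands: Path | None = None
    case_bands: Path | None = None
    anchor: str | None = None
    sample: str | None = None
    snp_signals: Path | None = None
    methylation: Path | None = None
    spots: Path | None = None
    fish: FishConfig = field(default_factory=FishConfig)
    stats: StatConfig = field(default_factory=StatConfig)
    ranges: MethylationRanges = field(default_factory=MethylationRanges)
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        paths = {
            k: Path(raw[k])
            for k in (
                "fasta", "bands", "control_bands", "case_bands",
                "snp_signals", "methylation", "spots",
            )
            if raw.get(k)
        }
        for k, p in paths.items():
            if not p.exists():
                raise ValidationError(f"config input {k!r} points to missing file: {p}")
        fish_cfg = FishConfig(**raw.get("fish", {}))
        stat_cfg = StatConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("stats", {}).items()
        })
        ranges = MethylationRanges(**{
            k: tuple(v) for k, v in raw.get("methylation_ranges", {}).items()
        })
        return cls(
            outdir=Path(raw.get("outdir", "imprintloop_out")),
            seed=int(raw.get("seed", 0)),
            enzyme=raw.get("enzyme", "BglII"),
            region_start=int(raw.get("region_start", 0)),
            anchor=raw.get("anchor"),
            sample=raw.get("sample"),
            fish=fish_cfg,
            stats=stat_cfg,
            ranges=ranges,
            raw=raw,
            **paths,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_digest(cfg: RunConfig, outdir: Path) -> Path:
    name, seq = read_region_fasta(cfg.fasta)
    frags = digest_sequence(seq, cfg.region_start, ENZYMES[cfg.enzyme], chrom=name)
    out = outdir / "fragments.bed"
    fragments_to_bed(frags, out)
    return out


def _stage_quant(cfg: RunConfig, outdir: Path) -> Path:
    df = read_bands(cfg.bands)
    sample = cfg.sample or sorted(df["sample"].unique())[0]
    anchor = cfg.anchor or sorted(df["anchor"].unique())[0]
    axis = list(dict.fromkeys(df.loc[df["anchor"] == anchor, "test"]))
    profile = build_looping_profile(df, sample, anchor, axis)
    out = outdir / f"profile_{sample}_{anchor}.tsv"
    profile_to_tsv(profile, out)
    return out


def _stage_diff(cfg: RunConfig, outdir: Path) -> Path:
    ctrl_df = read_bands(cfg.control_bands)
    case_df = read_bands(cfg.case_bands)
    anchor = cfg.anchor or sorted(ctrl_df["anchor"].unique())[0]

    def _assays(df: pd.DataFrame) -> dict[str, list[float]]:
        sub = df[(df["anchor"] == anchor) & (df["intensity_ctrl"] > 0)].copy()
        sub["frequency"] = sub["intensity_3c"] / sub["intensity_ctrl"]
        return {
            t: g["frequency"].tolist()
            for t, g in sub.groupby("test", sort=False)
        }

    ctrl, case = _assays(ctrl_df), _assays(case_df)
    shared = [t for t in ctrl if t in case]
    ctrl = {t: ctrl[t] for t in shared}
    case = {t: case[t] for t in shared}
    res = anova_profiles(ctrl, case)
    profile_max = max(
        max(sum(ctrl.values(), [])), max(sum(case.values(), []))
    )
    rows = []
    for _, r in res.posttests.iterrows():
        roi = classify_roi(
            (r["control_mean"], 0.0),
            (r["case_mean"], 0.0),
            r["p_adj"],
            cfg.stats,
            profile_max,
            anchor=anchor,
            test=r["fragment"],
        )
        rows.append(
            {
                "anchor": anchor,
                "test": roi.test,
                "control_mean": roi.control_mean,
                "case_mean": roi.case_mean,
                "p_adj": roi.p_adjusted,
                "stars": roi.star_code,
                "category": roi.category,
            }
        )
    out = outdir / f"roi_{anchor}.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def _stage_phase(cfg: RunConfig, outdir: Path) -> Path:
    df = pd.read_csv(cfg.snp_signals, sep="\t")
    rows = []
    for _, r in df.iterrows():
        sig = SnpSignal(
            r["snp_id"], r["allele_a"], r["allele_b"], r["signal_a"], r["signal_b"]
        )
        frac, cls = quantify_allele_fraction(sig)
        rows.append(
            {
                "interaction": r.get("interaction", ""),
                "snp_id": sig.snp_id,
                "fraction_a": frac,
                "major_fraction": max(frac, 1 - frac),
                "classification": cls,
            }
        )
    out = outdir / "allele_calls.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def _stage_methqc(cfg: RunConfig, outdir: Path) -> Path:
    df = pd.read_csv(cfg.methylation, sep="\t")
    records = [
        classify_sample(r["sample"], r["icr"], r["level_percent"], cfg.ranges)
        for _, r in df.iterrows()
    ]
    out_rows = [
        {"sample": m.sample, "icr": m.icr, "level_percent": m.level, "status": m.status}
        for m in records
    ]
    by_sample: dict[str, dict[str, str]] = {}
    for m in records:
        by_sample.setdefault(m.sample, {})[m.icr] = m.status
    subtype_rows = [
        {
            "sample": s,
            "subtype": infer_subtype(
                d.get("ICR1", "normal"), d.get("ICR2", "normal")
            ),
        }
        for s, d in by_sample.items()
    ]
    out = outdir / "methylation_status.tsv"
    pd.DataFrame(out_rows).to_csv(out, sep="\t", index=False)
    pd.DataFrame(subtype_rows).to_csv(outdir / "subtypes.tsv", sep="\t", index=False)
    return out


def _stage_fish(cfg: RunConfig, outdir: Path) -> Path:
    spots = read_spots(cfg.spots)
    label = cfg.sample or "line"
    result = process_line(spots, label, cfg.fish)
    summary = summarize_line(result.calls, label)
    result.allele_table().to_csv(outdir / "fish_alleles.tsv", sep="\t", index=False)
    result.nucleus_table().to_csv(outdir / "fish_nuclei.tsv", sep="\t", index=False)
    out = outdir / "fish_summary.tsv"
    summary.to_frame().to_csv(out, sep="\t", index=False)
    return out


_STAGES = (
    ("digest", lambda c: c.fasta, _stage_digest),
    ("quant", lambda c: c.bands, _stage_quant),
    ("diff", lambda c: c.control_bands and c.case_bands, _stage_diff),
    ("phase", lambda c: c.snp_signals, _stage_phase),
    ("methqc", lambda c: c.methylation, _stage_methqc),
    ("fish", lambda c: c.spots, _stage_fish),
)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute configured stages in dependency order; return the manifest.

    A stage failure keeps the partial manifest (already-finished outputs are
    recorded with an ``error`` entry for the failed stage).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "outputs": {},
    }
    for name, enabled, fn in _STAGES:
        if not enabled(cfg):
            continue
        try:
            out = fn(cfg, outdir)
            manifest["outputs"][name] = {"path": str(out), "sha256": _sha256(out)}
            logger.info("stage %s -> %s", name, out)
        except Exception as exc:
            manifest["outputs"][name] = {"error": str(exc)}
            manifest["failed"] = name
            logger.error("stage %s failed: %s", name, exc)
            break
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_report(outdir: str | Path, path: str | Path | None = None) -> Path:
    """Assemble a markdown summary of whatever stage outputs exist.

    Percentages print at 2 decimals.  Raises if no stage output is found.
    """
    outdir = Path(outdir)
    path = Path(path) if path else outdir / "report.md"
    sections = []

    frag_bed = outdir / "fragments.bed"
    if frag_bed.exists():
        n = sum(1 for _ in frag_bed.open())
        sections.append(f"## Restriction digest\n\n{n} fragments ({frag_bed.name}).\n")

    for p in sorted(outdir.glob("profile_*.tsv")):
        df = pd.read_csv(p, sep="\t")
        sections.append(
            f"## Looping profile {p.stem}\n\n"
            + df.to_markdown(index=False, floatfmt=".3f")
            + "\n"
        )
    for p in sorted(outdir.glob("roi_*.tsv")):
        df = pd.read_csv(p, sep="\t")
        sections.append(
            f"## Differential interactome {p.stem}\n\n"
            + df.to_markdown(index=False, floatfmt=".4f")
            + "\n"
        )
    for name, title in (
        ("allele_calls.tsv", "Allele-specificity calls"),
        ("methylation_status.tsv", "ICR methylation status"),
        ("subtypes.tsv", "Molecular subtype"),
    ):
        p = outdir / name
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            sections.append(f"## {title}\n\n" + df.to_markdown(index=False) + "\n")

    p = outdir / "fish_summary.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        for col in df.columns:
            if col.startswith("pct_") or col.endswith("_pct"):
                df[col] = df[col].map(lambda v: f"{v:.2f}")
        sections.append("## FISH nucleus categories\n\n" + df.to_markdown(index=False) + "\n")

    if not sections:
        raise ValidationError(f"no stage outputs found under {outdir}")
    path.write_text("# imprintloop report\n\n" + "\n".join(sections))
    return path
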