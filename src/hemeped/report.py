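"""End-to-end pipeline: pedigree in, consolidated segregation report out.

A run is a pure function of (input digest, config, seed): the manifest
records the config snapshot, input file digests, seed, stage timings and
library versions, and re-running with an identical manifest reproduces all
outputs bit-for-bit for the deterministic stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .errors import AnalysisError, PedigreeError
from .io import read_pedigree, write_pedigree
from .pairs import (PairTable, enumerate_pc_ar, extract_vertical_pairs,
                    lineage_annotation, pair_percentages)
from .pedigree import KindredMode, Pedigree, Sex
from .simulate import SimulationConfig, generate_pedigree
from .stats import (AnticipationReport, BirthOrderResult, PrevalenceTable,
                    WilcoxonResult, assess_anticipation, cocontravariation_scan,
                    compute_prevalence, haldane_smith_test, make_restrict,
                    wilcoxon_boe_control)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    input_digests: dict
    seed: Optional[int]
    stage_seconds: dict
    versions: dict


@dataclass
class ReportBundle:
    pedigree: Pedigree
    prevalence: dict                      # group name -> PrevalenceTable
    pairs: list
    pair_table: PairTable
    percentages: pd.DataFrame
    obsexp: pd.DataFrame
    boe: Optional[BirthOrderResult]
    boe_control: Optional[WilcoxonResult]
    anticipation: Optional[AnticipationReport]
    manifest: RunManifest
    exclusions: list = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _versions() -> dict:
    import networkx
    import numpy
    import scipy
    return {"hemeped": __version__, "numpy": numpy.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "networkx": networkx.__version__}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _resolve_pedigree(config: dict, digests: dict, seed: Optional[int]) -> Pedigree:
    src = config.get("input")
    if not src:
        raise PedigreeError("config has no 'input' section")
    if "simulate" in src:
        sim = dict(src["simulate"])
        if seed is not None:
            sim["seed"] = seed
        mode = KindredMode(sim.pop("mode", "nuclear"))
        cfg = SimulationConfig(mode=mode, **sim)
        return generate_pedigree(cfg).pedigree
    if "csv" in src:
        path = Path(src["csv"])
        digests[str(path)] = _sha256(path)
        return read_pedigree(path, "csv")
    if "ped" in src:
        path, sidecar = Path(src["ped"]), Path(src["sidecar"])
        digests[str(path)] = _sha256(path)
        digests[str(sidecar)] = _sha256(sidecar)
        return read_pedigree(path, "ped", sidecar=sidecar)
    raise PedigreeError("config 'input' must name csv, ped or simulate")


def run_pipeline(config, out_dir=None, seed: Optional[int] = None) -> ReportBundle:
    """Run every stage and (optionally) write the report bundle to ``out_dir``.

    ``config`` is a dict or a YAML path.  Raises on any validation error
    before writing partial output; every excluded pair or undefined statistic
    is logged with a reason and recorded in the bundle.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    analysis = config.get("analysis", {}) or {}
    seed = seed if seed is not None else config.get("seed")
    digests: dict = {}
    timings: dict = {}
    exclusions: list[str] = []

    t0 = time.perf_counter()
    ped = _resolve_pedigree(config, digests, seed)
    if not ped.affected:
        raise PedigreeError("pedigree contains no affected member")
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    prevalence = {}
    for group in ("LPD", "MPD"):
        try:
            prevalence[group] = compute_prevalence(ped, group)
        except AnalysisError as exc:
            exclusions.append(f"prevalence[{group}]: {exc}")
    timings["prevalence"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pairs = enumerate_pc_ar(
        ped, max_generations=int(analysis.get("max_generations", 5)),
        max_healthy_intermediates=int(analysis.get("max_healthy", 5)))
    table = extract_vertical_pairs(pairs, max_gap=int(analysis.get("vertical_gap", 2)))
    for pr in pairs:
        if pr.relation_class != "vertical" or pr.generation_gap > int(
                analysis.get("vertical_gap", 2)):
            exclusions.append(
                f"pair {pr.pc_id}-{pr.ar_id}: {pr.relation_class}, gap {pr.generation_gap}")
    pct = pair_percentages(table) if len(table) else pd.DataFrame()
    timings["pairs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    from .diagnoses import LineageGroup
    prev_by_group = {LineageGroup(g): t for g, t in prevalence.items()}
    obsexp = cocontravariation_scan(
        pairs, prev_by_group, df=int(analysis.get("df", 2)),
        alpha=float(analysis.get("alpha", 0.05)),
        exact_prevalence=bool(analysis.get("exact_prevalence", False)))
    timings["covariation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    boe_cfg = analysis.get("boe", {}) or {}
    restrict = make_restrict(
        sex=Sex(boe_cfg["sex"]) if "sex" in boe_cfg else None,
        diagnosis=boe_cfg.get("diagnosis"),
        lineage=boe_cfg.get("lineage"),
        lineage_map=lineage_annotation(pairs) if "lineage" in boe_cfg else None)
    sibs = ped.sibships()
    try:
        boe = haldane_smith_test(sibs, restrict)
    except AnalysisError as exc:
        boe = None
        exclusions.append(f"birth-order test: {exc}")
    control = wilcoxon_boe_control(sibs, restrict)
    if not control.defined:
        exclusions.append("birth-order Wilcoxon control: all scores zero, undefined")
    timings["boe"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reference = None
    if analysis.get("reference"):
        ref_path = Path(analysis["reference"])
        digests[str(ref_path)] = _sha256(ref_path)
        ref_df = pd.read_csv(ref_path)
        group = analysis.get("reference_group", "LPD")
        counts = {r.label: (int(r.total), int(r.male), int(r.female))
                  for r in ref_df.itertuples() if r.group == group}
        reference = PrevalenceTable.from_counts(counts, group)
    try:
        anticipation = assess_anticipation(ped, reference)
    except AnalysisError as exc:
        anticipation = None
        exclusions.append(f"anticipation: {exc}")
    timings["anticipation"] = time.perf_counter() - t0

    manifest = RunManifest(config=config, input_digests=digests, seed=seed,
                           stage_seconds={k: round(v, 4) for k, v in timings.items()},
                           versions=_versions())
    bundle = ReportBundle(ped, prevalence, pairs, table, pct, obsexp,
                          boe, control, anticipation, manifest, exclusions)
    for line in exclusions:
        logger.info("excluded: %s", line)
    if out_dir is not None:
        write_bundle(bundle, Path(out_dir))
    return bundle


# ---------------------------------------------------------------------------
def write_bundle(b: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pedigree(b.pedigree, out_dir / "pedigree.csv", "csv")
    b.pair_table.to_frame().to_csv(out_dir / "pairs.csv", index=False)
    if len(b.percentages):
        b.percentages.to_csv(out_dir / "pair_percentages.csv")
    if len(b.obsexp):
        b.obsexp.to_csv(out_dir / "obsexp.csv", index=False)
    if b.boe is not None:
        pd.DataFrame([{
            "rank_sum_observed": b.boe.rank_sum_observed,
            "null_mean": b.boe.rank_sum_null_mean,
            "null_variance": b.boe.rank_sum_null_variance,
            "ci95_low": b.boe.ci95[0], "ci95_high": b.boe.ci95[1],
            "z": b.boe.z, "decision": b.boe.decision,
            "n_sibships_informative": b.boe.n_sibships_informative,
            "wilcoxon_statistic": b.boe_control.statistic if b.boe_control else None,
            "wilcoxon_p": b.boe_control.p_value if b.boe_control else None,
        }]).to_csv(out_dir / "boe.csv", index=False)
    if b.anticipation is not None:
        b.anticipation.strata.to_csv(out_dir / "anticipation_strata.csv", index=False)
        if b.anticipation.prevalence_comparison is not None:
            b.anticipation.prevalence_comparison.to_csv(
                out_dir / "anticipation_prevalence.csv", index=False)
    (out_dir / "report.txt").write_text(format_report(b), encoding="utf-8")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(b.manifest), fh, indent=2, sort_keys=True, default=str)


def format_report(b: ReportBundle) -> str:
    """Plain-text report mirroring the reference table layout."""
    lines = [f"hemeped segregation report (pedigree: {b.pedigree.family_id}, "
             f"{len(b.pedigree)} members, {len(b.pedigree.affected)} affected)", ""]
    for group, prev in b.prevalence.items():
        lines.append(f"-- Prevalence, {group} (n={prev.group_total}) --")
        lines.append(prev.df.to_string())
        lines.append("")
    counts = b.pair_table.lineage_counts()
    total = len(b.pair_table)
    lines.append(f"-- Vertical pairs: {total} total, "
                 f"PA {counts['PA']}, MA {counts['MA']} --")
    if len(b.percentages):
        lines.append(b.percentages.to_string())
    lines.append("")
    if len(b.obsexp):
        lines.append("-- Observed vs expected affected relatives --")
        cols = ["pc_dx", "ar_dx", "obs_total", "obs_male", "obs_female",
                "exp_total", "exp_male", "exp_female", "chi_square", "p_value",
                "direction", "call"]
        lines.append(b.obsexp[cols].round(2).to_string(index=False))
        lines.append("")
    lines.append("-- Birth order effect (Haldane & Smith) --")
    if b.boe is not None:
        lines.append(
            f"rank sum {b.boe.rank_sum_observed:.1f}, null mean "
            f"{b.boe.rank_sum_null_mean:.2f}, CI95 "
            f"({b.boe.ci95[0]:.2f}, {b.boe.ci95[1]:.2f}), z={b.boe.z:.3f}, "
            f"decision: {b.boe.decision} "
            f"({b.boe.n_sibships_informative} informative sibships)")
    else:
        lines.append("undefined (no informative sibship)")
    if b.boe_control is not None and b.boe_control.defined:
        lines.append(f"Wilcoxon control: W={b.boe_control.statistic:.1f}, "
                     f"p={b.boe_control.p_value:.4f}")
    lines.append("")
    if b.anticipation is not None:
        lines.append("-- Anticipation --")
        lines.append(b.anticipation.strata.to_string(index=False))
        if b.anticipation.trend_defined:
            lines.append(f"onset trend: tau={b.anticipation.trend_statistic:.3f}, "
                         f"p={b.anticipation.trend_p:.4f}, slope "
                         f"{b.anticipation.onset_slope:+.2f} y/generation")
        else:
            lines.append("onset trend: undefined (<2 generation strata)")
        if b.anticipation.prevalence_comparison is not None:
            lines.append(b.anticipation.prevalence_comparison.round(3)
                         .to_string(index=False))
        lines.append("")
    if b.exclusions:
        lines.append(f"-- Exclusions ({len(b.exclusions)}) --")
        lines.extend(b.exclusions[:200])
    return "\n".join(lines) + "\n"
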