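"""Full triage pipeline: run every diagnostic on a reflection set and
aggregate the evidence into verdicts (ok / warning / severe)."""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .anomalous import bijvoet_pairs, measurability
from .intensity import (aniso_fit, detect_screw_axes, ice_ring_scan, moments,
                        normalize, nz_curves, wilson_fit)
from .patterson import find_tncs_peaks, native_patterson
from .reflections import (ReflectionSet, bin_by_resolution, completeness,
                          i_over_sigma, merge_equivalents, read_reflections)
from .twinning import britton, candidate_twin_laws, h_test, l_test, twin_correlation

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "Verdict", "TriageReport", "run_triage", "render_report"]

#: all verdict thresholds in one place; the report echoes them verbatim
DEFAULT_CONFIG: dict[str, Any] = {
    "n_shells": 20,
    "twin": {
        "mean_abs_l_warning": 0.465,
        "i2_ratio_warning": 1.7,
        "alpha_severe": 0.1,
    },
    "tncs": {"min_distance": 10.0, "threshold_pct": 20.0},
    "ice": {"z_threshold": 5.0},
    "screw": {"absent_cut": 1.0, "present_cut": 3.0},
    "aniso": {"delta_b_warning": 10.0, "ratio_warning": 0.5},
    "symmetry": {"correlation_warning": 0.95, "r_augmented_warning": 0.1},
    "anomalous": {"sigma_cut": 3.0, "useful_measurability": 0.05},
    "quality": {"min_i_over_sigma": 2.0, "min_completeness": 0.9},
    "wilson": {"fit_d_max": 4.5},
}


@dataclass
class Verdict:
    topic: str
    status: str                     # ok | warning | severe
    evidence: dict[str, Any]
    thresholds: dict[str, Any]

    def __post_init__(self):
        if self.status not in ("ok", "warning", "severe"):
            raise ValueError(f"bad status {self.status!r}")
        if not self.evidence:
            raise ValueError("verdict needs at least one evidence entry")


@dataclass
class TriageReport:
    schema_version: str
    tool_version: str
    seed: int
    config: dict
    input_meta: dict
    sections: dict[str, Any]
    skipped: dict[str, str]
    verdicts: list[Verdict]

    @property
    def worst_status(self) -> str:
        rank = {"ok": 0, "warning": 1, "severe": 2}
        worst = max((rank[v.status] for v in self.verdicts), default=0)
        return {0: "ok", 1: "warning", 2: "severe"}[worst]

    def verdict(self, topic: str) -> Optional[Verdict]:
        for v in self.verdicts:
            if v.topic == topic:
                return v
        return None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_triage(
    source,
    config: Optional[dict] = None,
    seed: int = 0,
    composition: Optional[dict[str, float]] = None,
) -> TriageReport:
    """Run the full triage battery on a file path or a ReflectionSet.

    Stages that lack their preconditions are skipped with a logged reason
    and listed under ``report.skipped`` — never silently.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val

    rset = source if isinstance(source, ReflectionSet) else read_reflections(source)
    sections: dict[str, Any] = {}
    skipped: dict[str, str] = {}
    verdicts: list[Verdict] = []

    if not rset.merged:
        rset, merge_stats = merge_equivalents(rset)
        sections["merging"] = merge_stats

    scheme = bin_by_resolution(rset, n_shells=cfg["n_shells"])
    comp_table = completeness(rset, scheme)
    ios_table = i_over_sigma(rset, scheme)
    sections["completeness"] = comp_table
    sections["i_over_sigma"] = ios_table
    overall_completeness = float(comp_table.iloc[-1]["completeness"])
    overall_ios = float(ios_table.iloc[-1]["i_over_sigma"])
    q = cfg["quality"]
    q_status = "ok"
    if overall_ios < q["min_i_over_sigma"] or overall_completeness < q["min_completeness"]:
        q_status = "warning"
    verdicts.append(Verdict("data_quality", q_status,
                            {"completeness": overall_completeness,
                             "i_over_sigma": overall_ios},
                            dict(q)))

    try:
        wf = wilson_fit(rset, composition, scheme=scheme,
                        fit_d_max=cfg["wilson"]["fit_d_max"])
        sections["wilson"] = wf
    except ValueError as exc:
        skipped["wilson"] = str(exc)
        logger.info("wilson fit skipped: %s", exc)

    norm = normalize(rset, scheme)
    mom = moments(norm)
    sections["moments"] = mom
    sections["nz"] = nz_curves(norm)

    scan = ice_ring_scan(rset, z_threshold=cfg["ice"]["z_threshold"])
    sections["ice_rings"] = scan
    if scan.performed:
        status = "warning" if scan.ice_rings else "ok"
        verdicts.append(Verdict("ice_rings", status,
                                {"n_flagged": len(scan.ice_rings),
                                 "rings": scan.ice_rings,
                                 "other_anomalies": scan.other_anomalies},
                                {"z_threshold": cfg["ice"]["z_threshold"]}))
    else:
        skipped["ice_rings"] = scan.note or "not performed"

    try:
        af = aniso_fit(rset, composition, fit_d_max=cfg["wilson"]["fit_d_max"])
        sections["anisotropy"] = af
        a = cfg["aniso"]
        status = ("warning"
                  if af.delta_B > a["delta_b_warning"] and af.ratio > a["ratio_warning"]
                  else "ok")
        verdicts.append(Verdict("anisotropy", status,
                                {"delta_B": af.delta_B, "ratio": af.ratio,
                                 "eigenvalues": af.eigenvalues.tolist()},
                                dict(a)))
    except ValueError as exc:
        skipped["anisotropy"] = str(exc)

    screws = detect_screw_axes(rset, absent_cut=cfg["screw"]["absent_cut"],
                               present_cut=cfg["screw"]["present_cut"])
    sections["screw_axes"] = screws
    found = [s for s in screws if s.get("verdict") == "screw present"]
    verdicts.append(Verdict("screw_axes", "ok",
                            {"detected": found or "none",
                             "n_hypotheses": len(screws)},
                            dict(cfg["screw"])))

    # twinning battery
    laws = candidate_twin_laws(rset.cell, rset.sg)
    sections["twin_laws"] = [
        {"operator": lw.operator.tolist(), "hkl": lw.hkl_triplet(),
         "kind": lw.kind, "description": lw.description,
         "metric_deviation": lw.metric_deviation}
        for lw in laws
    ]
    tw = cfg["twin"]
    l_result = None
    try:
        l_result = l_test(norm, seed=seed)
        sections["l_test"] = l_result
    except ValueError as exc:
        skipped["l_test"] = str(exc)

    per_law = []
    alpha_estimates = []
    sym_too_low_evidence = None
    for lw in laws:
        entry: dict[str, Any] = {"law": lw.hkl_triplet(), "kind": lw.kind}
        try:
            ht = h_test(rset, lw)
            br = britton(rset, lw)
            corr = twin_correlation(rset, lw)
            entry.update(h_test=ht, britton=br, correlation=corr)
            alpha_estimates += [ht.alpha_mean, br.alpha_estimate]
            s = cfg["symmetry"]
            if (corr["correlation"] > s["correlation_warning"]
                    and corr["r_augmented"] < s["r_augmented_warning"]):
                sym_too_low_evidence = {"law": lw.hkl_triplet(), **corr}
        except ValueError as exc:
            entry["skipped"] = str(exc)
        per_law.append(entry)
    sections["twinning_per_law"] = per_law

    twin_evidence: dict[str, Any] = {
        "i2_over_i_sq_acentric": mom.I2_over_I_sq_acentric,
        "alpha_estimates": alpha_estimates,
    }
    suspicious = mom.I2_over_I_sq_acentric < tw["i2_ratio_warning"]
    if l_result is not None:
        twin_evidence["mean_abs_l"] = l_result.mean_abs_L
        suspicious = suspicious or l_result.mean_abs_L < tw["mean_abs_l_warning"]
    status = "ok"
    if suspicious:
        status = "warning"
        if any(a > tw["alpha_severe"] for a in alpha_estimates):
            status = "severe"
    verdicts.append(Verdict("twinning", status, twin_evidence, dict(tw)))

    if sym_too_low_evidence is not None:
        verdicts.append(Verdict("symmetry_too_low", "warning",
                                sym_too_low_evidence, dict(cfg["symmetry"])))

    # tNCS
    grid = native_patterson(rset)
    peaks = find_tncs_peaks(grid, min_distance=cfg["tncs"]["min_distance"],
                            threshold_pct=cfg["tncs"]["threshold_pct"])
    sections["tncs_peaks"] = peaks
    verdicts.append(Verdict(
        "tncs", "warning" if peaks else "ok",
        {"n_peaks": len(peaks),
         "top_peak": dataclasses.asdict(peaks[0]) if peaks else None},
        dict(cfg["tncs"]),
    ))

    if rset.anomalous:
        try:
            pairs = bijvoet_pairs(rset)
            rep = measurability(pairs, sigma_cut=cfg["anomalous"]["sigma_cut"])
            sections["anomalous"] = rep
            useful = rep.measurability >= cfg["anomalous"]["useful_measurability"]
            verdicts.append(Verdict(
                "anomalous_signal", "ok",
                {"measurability": rep.measurability,
                 "useful": bool(useful),
                 "mean_delta_over_sigma": rep.mean_delta_over_sigma},
                dict(cfg["anomalous"]),
            ))
        except ValueError as exc:
            skipped["anomalous"] = str(exc)
    else:
        skipped["anomalous"] = "no Bijvoet-separated intensities in input"

    meta = {
        "cell": rset.cell.parameters(),
        "spacegroup": rset.sg.symbol,
        "crystal_family": rset.sg.crystal_family,
        "d_min": rset.d_min,
        "d_max": rset.d_max,
        "n_reflections": len(rset),
        "anomalous": rset.anomalous,
    }
    return TriageReport(
        schema_version="1", tool_version=__version__, seed=seed,
        config=cfg, input_meta=meta, sections=sections,
        skipped=skipped, verdicts=verdicts,
    )


def render_report(report: TriageReport, format: str = "text") -> str:
    """Serialize a report: complete JSON or a sectioned text summary
    with one verdict line first per topic."""
    if format == "json":
        return json.dumps(_jsonable(report), indent=2)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    lines = [f"refltriage {report.tool_version} — diffraction data triage",
             "=" * 56, ""]
    for v in report.verdicts:
        flag = {"ok": "   ok  ", "warning": "WARNING", "severe": "SEVERE "}[v.status]
        lines.append(f"[{flag}] {v.topic}")
    lines.append("")
    m = report.input_meta
    a, b, c, al, be, ga = m["cell"]
    lines += [
        "Input",
        "-----",
        f"  cell: {a:.2f} {b:.2f} {c:.2f}  {al:.1f} {be:.1f} {ga:.1f}",
        f"  space group: {m['spacegroup']} ({m['crystal_family']})",
        f"  resolution: {m['d_max']:.2f} – {m['d_min']:.2f} Å, "
        f"{m['n_reflections']} unique reflections",
        "",
    ]
    for v in report.verdicts:
        lines.append(f"{v.topic} [{v.status}]")
        for key, val in v.evidence.items():
            if isinstance(val, float):
                lines.append(f"  {key} = {val:.4g}")
            elif isinstance(val, (str, int, bool)) or val is None:
                lines.append(f"  {key} = {val}")
            else:
                lines.append(f"  {key} = {json.dumps(_jsonable(val))[:120]}")
        lines.append("")
    if report.skipped:
        lines.append("Not performed")
        lines.append("-------------")
        for stage, reason in report.skipped.items():
            lines.append(f"  {stage}: {reason}")
    return "\n".join(lines)
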