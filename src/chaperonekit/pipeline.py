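"""Workflow orchestration.

Ties the analysis stages into the end-to-end workflow: HDX differential
analysis feeding contact restraints, independent melt/ITC/occupancy
stages, and SAXS primary analysis, with a JSON summary, per-stage
tables, seed/config logging and deterministic re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import hdx as hdx_mod
from . import io as io_mod
from . import saxs as saxs_mod
from . import binding as binding_mod

logger = logging.getLogger("chaperonekit")

__all__ = ["RunConfig", "run_workflow"]


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Any stage whose inputs are absent is skipped with a warning; present
    paths are validated up front.
    """

    output_dir: str
    hdx_free: str | None = None
    hdx_bound: str | None = None
    hdx_threshold_pct: float = hdx_mod.DEFAULT_THRESHOLD_PCT
    hdx_construct_range: tuple[int, int] = (455, 768)
    saxs_curves: list[str] = field(default_factory=list)
    saxs_concentrations: list[float] = field(default_factory=list)
    saxs_dmax_grid: tuple[float, float, float] | None = None  # lo, hi, step
    itc_path: str | None = None
    melt_path: str | None = None
    lanes_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.hdx_free, self.hdx_bound, self.itc_path,
                  self.melt_path, self.lanes_path, *self.saxs_curves]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _hdx_stage(cfg: RunConfig, outdir: Path) -> dict:
    free = io_mod.read_uptake_csv(cfg.hdx_free)
    bound = io_mod.read_uptake_csv(cfg.hdx_bound)
    free = hdx_mod.qc_filter(free)
    bound = hdx_mod.qc_filter(bound)
    diffs = []
    for t in sorted(free["timepoint_s"].unique()):
        diffs.append(hdx_mod.differential_uptake(free, bound, timepoint=t))
    records = pd.concat(diffs, ignore_index=True)
    best = hdx_mod.select_max_difference(records)
    best = hdx_mod.classify(best, threshold_pct=cfg.hdx_threshold_pct)
    resmap = hdx_mod.consolidate_residues(best, cfg.hdx_construct_range,
                                          threshold_pct=cfg.hdx_threshold_pct)
    protected = hdx_mod.extract_intervals(resmap, "protected")
    deprotected = hdx_mod.extract_intervals(resmap, "deprotected")
    best.to_csv(outdir / "hdx_differential.csv", index=False)
    resmap.to_csv(outdir / "hdx_residue_map.csv", index=False)
    # Woods-plot-style table: peptide midpoint vs difference
    woods = best.assign(midpoint=(best["start"] + best["end"]) / 2.0)
    woods[["midpoint", "delta_D", "sd_pooled", "significant", "direction"]].to_csv(
        outdir / "hdx_woods.csv", index=False)
    if protected:
        restraints = saxs_mod.build_contact_restraints(protected, [],
                                                       name_a="kinase",
                                                       name_b="cochaperone")
        (outdir / "contact_restraints.txt").write_text(restraints.to_text())
    return {
        "n_peptides": int(best["peptide_id"].nunique()),
        "n_significant": int(best["significant"].sum()),
        "protected_intervals": protected,
        "deprotected_intervals": deprotected,
    }


def _saxs_stage(cfg: RunConfig, outdir: Path) -> dict:
    curves = []
    concs = cfg.saxs_concentrations or [None] * len(cfg.saxs_curves)
    for path, c in zip(cfg.saxs_curves, concs):
        curves.append(io_mod.read_dat(path, concentration=c))
    if len(curves) > 1 and all(c.concentration is not None for c in curves):
        curve = saxs_mod.extrapolate_zero_concentration(curves)
    else:
        curve = curves[0]
    g = saxs_mod.guinier_fit(curve)
    summary = {"Rg_nm": g.Rg, "I0": g.I0, "guinier_window": list(g.window)}
    if cfg.saxs_dmax_grid is not None:
        lo, hi, step = cfg.saxs_dmax_grid
        dmax, _ = saxs_mod.estimate_dmax(curve, np.arange(lo, hi + step / 2, step))
        pr = saxs_mod.ift_pr(curve, dmax)
        porod = saxs_mod.porod_volume(curve, g.I0, g.Rg)
        summary.update(Dmax_nm=dmax, Rg_real_nm=pr.Rg_real,
                       V_porod_nm3=porod.V_porod)
        pd.DataFrame({"r_nm": pr.r, "pr": pr.pr}).to_csv(outdir / "saxs_pr.csv",
                                                         index=False)
    io_mod.write_dat(curve, outdir / "saxs_merged.dat")
    return summary


def _itc_stage(cfg: RunConfig, outdir: Path) -> dict:
    tg = io_mod.read_itc_csv(cfg.itc_path)
    fit = binding_mod.fit_itc_single_site(tg)
    out = {"n": fit.n, "Kd_M": fit.Kd, "dH_kcal_mol": fit.dH,
           "dS_cal_mol_K": fit.dS, "c_value": fit.c_value,
           "reliable": fit.reliable}
    (outdir / "itc_fit.json").write_text(json.dumps(out, indent=2))
    return out


def _melt_stage(cfg: RunConfig, outdir: Path) -> dict:
    curve = io_mod.read_melt_csv(cfg.melt_path)
    res = binding_mod.tm_estimate(curve)
    out = {"Tm_C": res.Tm, "method": res.method}
    (outdir / "tm.json").write_text(json.dumps(out, indent=2))
    return out


def _occupancy_stage(cfg: RunConfig, outdir: Path) -> dict:
    lanes = pd.read_csv(cfg.lanes_path)
    occ = binding_mod.complex_occupancy(lanes)
    return {"occupancy_pct": occ}


def run_workflow(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the summary bundle (also written to ``summary.json``); a
    failed stage is recorded with its error, its dependents are skipped,
    and the bundle carries ``"ok": False``.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.digest(), "seed": cfg.seed, "ok": True}
    stages = [
        ("hdx", _hdx_stage, cfg.hdx_free is not None and cfg.hdx_bound is not None),
        ("saxs", _saxs_stage, bool(cfg.saxs_curves)),
        ("itc", _itc_stage, cfg.itc_path is not None),
        ("melt", _melt_stage, cfg.melt_path is not None),
        ("occupancy", _occupancy_stage, cfg.lanes_path is not None),
    ]
    for name, fn, enabled in stages:
        if not enabled:
            warnings.warn(f"stage {name!r} skipped: inputs not configured",
                          stacklevel=2)
            summary[name] = {"skipped": True}
            continue
        try:
            summary[name] = fn(cfg, outdir)
        except Exception as exc:  # stage failure: partial bundle
            logger.error("stage %s failed: %s", name, exc)
            summary[name] = {"error": str(exc)}
            summary["ok"] = False
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
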