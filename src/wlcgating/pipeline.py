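"""End-to-end analysis: structures in, forces/energies/paths report out.

Drives the full chain: identify the closed reference (the structure whose
linker range is resolved in all four chains, unless labelled), align its
pore axis to z, superpose every open structure onto it over the pore
domain, extract anchors, exclude folded-linker subunits, compute WLC
mechanics, per-structure and pooled statistics, spread metrics,
transition-state chimeras and the four gating path works, and the
stretched-linker outlier report.  Serializes per-linker and per-structure
CSV tables plus a JSON report in which every number carries a unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gating, geometry, structure_io
from .wlc import WLCParams

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis"]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class AnalysisConfig:
    """Settings of one analysis run; defaults are the published protocol."""

    pore_anchor: int = 99
    ring_anchor: int = 115
    selection: tuple[int, int] = (20, 83)
    linker_range: tuple[int, int] = (100, 114)
    wlc: WLCParams = field(default_factory=WLCParams)
    mad_multiplier: float = 2.5
    axis_method: str = "permutation"

    def __post_init__(self) -> None:
        lo, hi = self.selection
        if lo >= hi:
            raise ValueError("selection interval must be increasing")
        if self.pore_anchor >= self.ring_anchor:
            raise ValueError("pore anchor must precede ring anchor")
        if self.mad_multiplier <= 0:
            raise ValueError("MAD multiplier must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "wlc" in raw:
            raw["wlc"] = WLCParams(**raw["wlc"])
        for key in ("selection", "linker_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """All tables and derived quantities of one run."""

    per_linker: pd.DataFrame
    per_structure: pd.DataFrame
    pooled: gating.StructureSummary
    outliers: gating.OutlierReport
    spread: pd.DataFrame
    paths: dict[str, dict[str, gating.PathWork]]  # structure -> path -> work
    path_summary: pd.DataFrame
    loop_closure: dict[str, float]  # structure -> sum of 4 path means (kBT)
    closed_id: str
    closed_inferred: bool
    log: list[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "per_linker": outdir / "per_linker.csv",
            "per_structure": outdir / "per_structure.csv",
            "spread": outdir / "spread_metrics.csv",
            "paths": outdir / "path_works.csv",
            "report": outdir / "report.json",
            "log": outdir / "log.txt",
        }
        self.per_linker.to_csv(files["per_linker"], index=False,
                               float_format="%.6f", lineterminator="\n")
        self.per_structure.to_csv(files["per_structure"], index=False,
                                  float_format="%.6f", lineterminator="\n")
        self.spread.to_csv(files["spread"], index=False,
                           float_format="%.6f", lineterminator="\n")
        self.path_summary.to_csv(files["paths"], index=False,
                                 float_format="%.6f", lineterminator="\n")
        files["report"].write_text(json.dumps(self.to_json_dict(), indent=1,
                                              sort_keys=True) + "\n")
        files["log"].write_text("\n".join(self.log) + "\n")
        return files

    def to_json_dict(self) -> dict:
        def q(value: float, unit: str, ndigits: int = 1) -> dict:
            return {"value": round(float(value), ndigits), "unit": unit}

        pooled = {name: {"mean": q(self.pooled.mean[name], unit),
                         "sd": q(self.pooled.sd[name], unit)}
                  for name, unit in (("L", "A"), ("F", "pN"), ("F_z", "pN"),
                                     ("F_xy", "pN"), ("U", "kBT"))
                  if name in self.pooled.mean}
        paths = {}
        for pid in ("path1", "path2", "path3", "path4_elastic"):
            means = [pw[pid].mean for pw in self.paths.values()]
            if means:
                paths[pid] = {"mean_over_structures": q(np.mean(means), "kBT"),
                              "sd_over_structures": q(np.std(means, ddof=1)
                                                      if len(means) > 1 else 0.0,
                                                      "kBT")}
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "closed_structure": {"id": self.closed_id,
                                 "inferred": self.closed_inferred},
            "n_subunits_total": int(len(self.per_linker)),
            "n_pooled": int(self.outliers.n_pooled),
            "n_normal": int(self.outliers.n_normal),
            "pooled": pooled,
            "normal": {"L_mean": q(self.outliers.normal_mean_L, "A"),
                       "L_sd": q(self.outliers.normal_sd_L, "A")},
            "outliers": [{"structure": s, "chain": c,
                          "excess_energy": q(self.outliers.excess_energy[(s, c)],
                                             "kBT")}
                         for s, c in self.outliers.outlier_ids],
            "folded_subunits": [{"structure": s, "chain": c}
                                for s, c in self.outliers.folded_ids],
            "path_works": paths,
            "loop_closure_max_abs": q(max((abs(v) for v in
                                           self.loop_closure.values()),
                                          default=0.0), "kBT", 9),
        }


def _find_closed(structures, config) -> tuple[int, bool]:
    labelled = [i for i, s in enumerate(structures) if s.state_label == "closed"]
    if len(labelled) == 1:
        return labelled[0], False
    if len(labelled) > 1:
        raise ValueError("more than one structure labelled 'closed'")
    fully = [i for i, s in enumerate(structures)
             if all(structure_io.detect_resolved_linker(
                 s, config.linker_range).values())]
    if len(fully) != 1:
        raise ValueError(
            f"cannot infer the closed state: {len(fully)} structures have "
            "all linkers resolved; label one 'closed'")
    return fully[0], True


def run_analysis(structures: list[structure_io.StructureModel],
                 config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full gating analysis over one closed + N open structures."""
    config = config or AnalysisConfig()
    if not structures:
        raise ValueError("no input structures")
    log: list[str] = []
    closed_idx, inferred = _find_closed(structures, config)
    closed = structures[closed_idx]
    log.append(f"closed state: {closed.id}"
               + (" (inferred from resolved linkers)" if inferred else " (labelled)"))

    closed_aligned = geometry.align_pore_axis_to_z(
        closed, config.selection, method=config.axis_method)
    closed_anchors = structure_io.extract_anchors(
        closed_aligned, config.pore_anchor, config.ring_anchor)

    mechanics, folded_flags = [], {}
    rows, spread_rows = [], []
    summaries = []
    paths: dict[str, dict[str, gating.PathWork]] = {}
    loop: dict[str, float] = {}

    def spread_row(sid, state, anchors):
        pm = geometry.spread_metrics(anchors.pore, aligned=True)
        rm = geometry.spread_metrics(anchors.ring, aligned=True)
        spread_rows.append({"structure_id": sid, "state": state,
                            "pore_interresidue_A": pm.interresidue_distance,
                            "pore_radius_A": pm.radius,
                            "ring_interresidue_A": rm.interresidue_distance,
                            "ring_radius_A": rm.radius})

    spread_row(closed.id, "closed", closed_anchors)

    for i, structure in enumerate(structures):
        if i == closed_idx:
            continue
        moved, rmsd, _ = geometry.superpose_on_pore(
            structure, closed_aligned, config.selection)
        log.append(f"{structure.id}: superposed on {closed.id}, "
                   f"pore-domain RMSD {rmsd:.2f} A")
        anchors = structure_io.extract_anchors(
            moved, config.pore_anchor, config.ring_anchor)
        spread_row(structure.id, structure.state_label, anchors)
        resolved = structure_io.detect_resolved_linker(moved, config.linker_range)
        unfolded_ids = []
        for geom in geometry.linker_lengths(anchors):
            key = (structure.id, geom.chain_id)
            if resolved[geom.chain_id]:
                folded_flags[key] = True
                log.append(f"{structure.id}/{geom.chain_id}: excluded "
                           "(folded/ordered linker)")
                rows.append({"structure_id": structure.id,
                             "chain_id": geom.chain_id, "status": "folded",
                             "L_A": geom.L, "L_z_A": geom.L_z,
                             "L_xy_A": geom.L_xy, "F_pN": np.nan,
                             "F_z_pN": np.nan, "F_xy_pN": np.nan,
                             "U_kBT": np.nan, "k_pN_per_nm": np.nan})
                continue
            folded_flags[key] = False
            unfolded_ids.append(geom.chain_id)
            mech = gating.linker_mechanics(geom, config.wlc)
            mechanics.append(mech)
            log.append(f"{structure.id}/{geom.chain_id}: included "
                       f"(L={geom.L:.1f} A, F={mech.F:.1f} pN)")
            rows.append({"structure_id": structure.id,
                         "chain_id": geom.chain_id, "status": "included",
                         "L_A": mech.L, "L_z_A": mech.L_z, "L_xy_A": mech.L_xy,
                         "F_pN": mech.F, "F_z_pN": mech.F_z,
                         "F_xy_pN": mech.F_xy, "U_kBT": mech.U,
                         "k_pN_per_nm": mech.k})
        summaries.append(gating.structure_summary(
            [m for m in mechanics if m.structure_id == structure.id],
            structure.id))
        pw = gating.gating_paths(anchors, closed_anchors, config.wlc,
                                 include=unfolded_ids)
        paths[structure.id] = pw
        loop[structure.id] = sum(p.mean for p in pw.values())

    if not mechanics:
        raise ValueError("no unfolded linkers found in any open structure")

    pooled = gating.pooled_statistics(mechanics)
    outliers = gating.detect_outliers(mechanics, folded_flags,
                                      config.mad_multiplier, config.wlc)
    for s, c in outliers.outlier_ids:
        log.append(f"{s}/{c}: length outlier "
                   f"(excess energy {outliers.excess_energy[(s, c)]:.1f} kBT)")
        for row in rows:
            if row["structure_id"] == s and row["chain_id"] == c:
                row["status"] = "outlier"

    per_structure = pd.DataFrame(
        [{"structure_id": s.structure_id, "n_linkers": s.n_linkers,
          **{f"{k}_mean": v for k, v in s.mean.items()},
          **{f"{k}_sd": v for k, v in s.sd.items()}} for s in summaries])
    path_rows = []
    for sid, pw in paths.items():
        for pid, p in pw.items():
            path_rows.append({"structure_id": sid, "path_id": pid,
                              "mean_kBT": p.mean, "sd_kBT": p.sd,
                              "per_tetramer_kBT": p.per_tetramer})
    path_summary = pd.DataFrame(path_rows)

    return AnalysisReport(per_linker=pd.DataFrame(rows),
                          per_structure=per_structure, pooled=pooled,
                          outliers=outliers, spread=pd.DataFrame(spread_rows),
                          paths=paths, path_summary=path_summary,
                          loop_closure=loop, closed_id=closed.id,
                          closed_inferred=inferred, log=log)
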