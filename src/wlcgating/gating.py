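"""Gating mechanics: forces, energies, transition chimeras, path works,
outlier analysis and two-state thermodynamics.

Each unfolded linker is an entropic spring between the gating-ring anchor
(Ser115) and the bundle-crossing anchor (Ile99).  Its tension F decomposes
along the linker direction into a vertical component F_z (parallel to the
pore axis) and a radial component F_xy — the outward pull that opens and
holds open the bundle-crossing gate.  Hypothetical transition states are
chimeras that connect one state's gating ring to the other state's pore;
signed elastic-energy differences along closed → TS1 → open → TS2 → closed
give the work of each gating path, and elastic energy being a state
function forces the four path works to sum to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import AnchorSet, LinkerGeometry, linker_lengths
from .wlc import (Extension, WLCDomainError, WLCParams, angstrom, wlc_energy,
                  wlc_force, wlc_stiffness)

__all__ = [
    "LinkerMechanics",
    "OutlierReport",
    "PathWork",
    "StructureSummary",
    "ThermoResult",
    "binding_energy_from_kd",
    "build_transition_chimera",
    "delta_g_from_open_probability",
    "detect_outliers",
    "gating_paths",
    "linker_mechanics",
    "open_probability_from_delta_g",
    "path_work",
    "perturbed_linker_prediction",
    "pooled_statistics",
    "structure_summary",
]


@dataclass(frozen=True)
class LinkerMechanics:
    """WLC mechanics of one linker: lengths (Å), forces (pN), U (kBT), k (pN/nm)."""

    chain_id: str
    L: float
    L_z: float | None
    L_xy: float | None
    F: float
    F_z: float | None
    F_xy: float | None
    U: float
    k: float
    structure_id: str = ""
    warning_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class StructureSummary:
    """Mean ± sample SD of the linker quantities of one structure."""

    structure_id: str
    n_linkers: int
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass(frozen=True)
class PathWork:
    """Signed elastic work of one gating path (kBT; negative = released)."""

    path_id: str
    per_subunit: tuple[float, ...]
    mean: float
    sd: float
    per_tetramer: float
    annotation: str = ""


@dataclass(frozen=True)
class ThermoResult:
    """Two-state free-energy difference in kBT with its inputs echoed."""

    delta_g: float
    inputs: dict


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def linker_mechanics(geometry: LinkerGeometry,
                     params: WLCParams = WLCParams()) -> LinkerMechanics:
    """Force, components, stored energy and stiffness of one linker."""
    import warnings as _w

    L = geometry.L
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        F = wlc_force(angstrom(L), params)
        U = wlc_energy(0.0, angstrom(L), params)
        k = wlc_stiffness(angstrom(L), params)
    from .wlc import NearContourWarning
    flags = frozenset("near_contour" for w in caught
                      if issubclass(w.category, NearContourWarning))
    if geometry.L_z is None or L == 0.0:
        fz = fxy = None if geometry.L_z is None else 0.0
    else:
        fz, fxy = F * geometry.L_z / L, F * geometry.L_xy / L
    return LinkerMechanics(geometry.chain_id, L, geometry.L_z, geometry.L_xy,
                           F, fz, fxy, U, k, geometry.structure_id, flags)


_SUMMARY_FIELDS = ("L", "L_z", "L_xy", "F", "F_z", "F_xy", "U", "k")


def structure_summary(mechanics: list[LinkerMechanics],
                      structure_id: str) -> StructureSummary:
    """Arithmetic mean and sample SD per quantity over a structure's linkers.

    Folded-linker subunits are excluded upstream; at least one unfolded
    linker is required.
    """
    if not mechanics:
        raise WLCDomainError(f"no unfolded linkers for structure {structure_id!r}")
    mean, sd = {}, {}
    for name in _SUMMARY_FIELDS:
        vals = np.array([getattr(m, name) for m in mechanics
                         if getattr(m, name) is not None], dtype=float)
        if len(vals):
            mean[name] = float(np.mean(vals))
            sd[name] = _sd(vals)
    return StructureSummary(structure_id, len(mechanics), mean, sd)


def pooled_statistics(mechanics: list[LinkerMechanics]) -> StructureSummary:
    """Pooled per-linker statistics over all structures ("n = 23"-style)."""
    return structure_summary(mechanics, "pooled")


def _azimuths(points: np.ndarray) -> np.ndarray:
    return np.arctan2(points[:, 1], points[:, 0])


def _pairing_shift(open_ref: np.ndarray, closed_ref: np.ndarray) -> int:
    """Cyclic shift pairing closed subunits to open ones by azimuth."""
    az_o, az_c = _azimuths(open_ref), _azimuths(closed_ref)
    order_o, order_c = np.argsort(az_o), np.argsort(az_c)
    best, best_cost = 0, math.inf
    for s in range(4):
        cost = 0.0
        for k in range(4):
            d = az_o[order_o[k]] - az_c[order_c[(k + s) % 4]]
            cost += abs(math.atan2(math.sin(d), math.cos(d)))
        if cost < best_cost:
            best, best_cost = s, cost
    return best


def build_transition_chimera(open_anchors: AnchorSet, closed_anchors: AnchorSet,
                             which: str) -> AnchorSet:
    """Anchor set of a hypothetical transition state.

    TS1 connects the activated (open-state) gating ring to the closed
    pore: ring anchors from ``open_anchors``, pore anchors from
    ``closed_anchors``.  TS2 is the converse (apo ring above an open
    pore).  Chains are paired by minimal azimuthal offset; since the
    closed state is C4-symmetric, per-structure statistics do not depend
    on the pairing.
    """
    if which not in ("TS1", "TS2"):
        raise ValueError("which must be 'TS1' or 'TS2'")
    if not (open_anchors.aligned and closed_anchors.aligned):
        raise ValueError("transition chimeras require aligned anchor sets")
    if len(open_anchors) != 4 or len(closed_anchors) != 4:
        raise ValueError("transition chimeras require 4 chains per state")
    order_o = np.argsort(_azimuths(open_anchors.pore))
    order_c = np.argsort(_azimuths(closed_anchors.pore))
    s = _pairing_shift(open_anchors.pore, closed_anchors.pore)
    perm = np.empty(4, dtype=int)
    for k in range(4):
        perm[order_o[k]] = order_c[(k + s) % 4]
    closed_pore = closed_anchors.pore[perm]
    closed_ring = closed_anchors.ring[perm]
    if which == "TS1":
        pore, ring = closed_pore, open_anchors.ring
    else:
        pore, ring = open_anchors.pore, closed_ring
    return AnchorSet(f"{open_anchors.structure_id}:{which}",
                     list(open_anchors.chain_ids), pore, ring, aligned=True)


def path_work(from_anchors: AnchorSet, to_anchors: AnchorSet,
              params: WLCParams = WLCParams(), path_id: str = "",
              include: list[str] | None = None, annotation: str = "") -> PathWork:
    """Signed elastic work moving each linker between two anchor geometries.

    Per subunit: ``wlc_energy(0 → L_to) − wlc_energy(0 → L_from)``;
    positive work loads the springs.  ``include`` restricts to a subset of
    chain ids (e.g. to drop folded-linker subunits).
    """
    if from_anchors.chain_ids != to_anchors.chain_ids:
        raise ValueError("path endpoints must share chain ids in order")
    if include is not None:
        from_anchors = from_anchors.subset(include)
        to_anchors = to_anchors.subset(include)
    works = []
    for gf, gt in zip(linker_lengths(from_anchors), linker_lengths(to_anchors)):
        works.append(wlc_energy(0.0, angstrom(gt.L), params)
                     - wlc_energy(0.0, angstrom(gf.L), params))
    arr = np.array(works)
    return PathWork(path_id, tuple(works), float(np.mean(arr)), _sd(arr),
                    4.0 * float(np.mean(arr)), annotation)


def gating_paths(open_anchors: AnchorSet, closed_anchors: AnchorSet,
                 params: WLCParams = WLCParams(),
                 include: list[str] | None = None,
                 folding_gain: float | None = None) -> dict[str, PathWork]:
    """The four elastic path works of one gating cycle for one open structure.

    path1: closed → TS1 (gating ring activates, springs load).
    path2: TS1 → open (bundle-crossing opens, energy released).
    path3: open → TS2 (ring relaxes to apo, energy released).
    path4_elastic: TS2 → closed, elastic component only; the additional
    gain from linker folding/helix coiling is attached as an annotation
    when ``folding_gain`` (kBT) is given.
    """
    ts1 = build_transition_chimera(open_anchors, closed_anchors, "TS1")
    ts2 = build_transition_chimera(open_anchors, closed_anchors, "TS2")
    # Closed native lengths, in the chain order/pairing of the chimera:
    closed_native = AnchorSet(f"{open_anchors.structure_id}:closed",
                              list(open_anchors.chain_ids),
                              ts1.pore, ts2.ring, aligned=True)
    note = ("" if folding_gain is None else
            f"plus linker-folding gain >= {folding_gain:.1f} kBT (not elastic)")
    return {
        "path1": path_work(closed_native, ts1, params, "path1", include),
        "path2": path_work(ts1, open_anchors, params, "path2", include),
        "path3": path_work(open_anchors, ts2, params, "path3", include),
        "path4_elastic": path_work(ts2, closed_native, params, "path4_elastic",
                                   include, annotation=note),
    }


@dataclass(frozen=True)
class OutlierReport:
    """Stretched-linker outliers in a pooled set of linkers."""

    outlier_ids: tuple[tuple[str, str], ...]   # (structure_id, chain_id)
    excess_energy: dict[tuple[str, str], float]  # kBT above the normal mean
    folded_ids: tuple[tuple[str, str], ...]
    n_pooled: int
    n_normal: int
    normal_mean_L: float
    normal_sd_L: float
    median_L: float
    mad_L: float


def detect_outliers(mechanics: list[LinkerMechanics],
                    folded_flags: dict[tuple[str, str], bool] | None = None,
                    mad_multiplier: float = 2.5,
                    params: WLCParams = WLCParams()) -> OutlierReport:
    """Flag linkers whose length deviates from the pooled median by more
    than ``mad_multiplier`` × MAD.

    Folded-linker subunits (``folded_flags``) are reported separately and
    excluded from the pooled statistics.  Each outlier's excess energy is
    the elastic energy from the non-outlier mean length to its length.
    """
    folded_flags = folded_flags or {}
    folded = tuple(k for k, v in sorted(folded_flags.items()) if v)
    keys = [(m.structure_id, m.chain_id) for m in mechanics]
    pool = [(k, m) for k, m in zip(keys, mechanics) if k not in folded]
    if len(pool) < 4:
        raise WLCDomainError("outlier detection needs >= 4 pooled linkers")
    lengths = np.array([m.L for _, m in pool])
    med = float(np.median(lengths))
    mad = float(np.median(np.abs(lengths - med)))
    if mad > 0:
        is_out = np.abs(lengths - med) > mad_multiplier * mad
    else:
        is_out = np.zeros(len(lengths), dtype=bool)
    normal = lengths[~is_out]
    mean_normal = float(np.mean(normal))
    excess = {}
    for (key, m), flag in zip(pool, is_out):
        if flag and m.L > mean_normal:
            excess[key] = wlc_energy(angstrom(mean_normal), angstrom(m.L), params)
        elif flag:
            excess[key] = -wlc_energy(angstrom(m.L), angstrom(mean_normal), params)
    outlier_ids = tuple(k for (k, _), flag in zip(pool, is_out) if flag)
    return OutlierReport(outlier_ids, excess, folded, len(pool),
                         int(np.sum(~is_out)), mean_normal, _sd(normal),
                         med, mad)


def perturbed_linker_prediction(delta_residues: int, extension: Extension | float,
                                params: WLCParams = WLCParams()) -> tuple[float, float]:
    """(force pN, energy kBT) for a linker length-variant at fixed extension.

    Predicts what a chain shortened or lengthened by ``delta_residues``
    would exert if the anchor geometry stayed the same.  Shortening can
    push the fixed extension past the new contour length, which is a
    domain error.
    """
    new = params.with_delta_residues(delta_residues)
    return wlc_force(extension, new), wlc_energy(0.0, extension, new)


def delta_g_from_open_probability(p_open: float) -> ThermoResult:
    """Two-state gating free energy ΔG = −ln(P_O / (1 − P_O)) in kBT.

    Negative when the open state is favored (P_O > 1/2).
    """
    if not 0.0 < p_open < 1.0:
        raise WLCDomainError("open probability must lie strictly in (0, 1)")
    return ThermoResult(-math.log(p_open / (1.0 - p_open)), {"p_open": p_open})


def open_probability_from_delta_g(delta_g: float) -> float:
    """Inverse of :func:`delta_g_from_open_probability`."""
    return 1.0 / (1.0 + math.exp(delta_g))


def binding_energy_from_kd(kd: float, n_sites: int = 1) -> ThermoResult:
    """Standard binding free energy magnitude from a dissociation constant.

    Per site |ΔG⁰| = ln(1 M / K_D) in kBT (1 M standard state);
    ``delta_g`` carries the total over ``n_sites`` independent sites.
    """
    if kd <= 0:
        raise WLCDomainError("dissociation constant must be > 0")
    if n_sites < 1:
        raise WLCDomainError("n_sites must be >= 1")
    per_site = math.log(1.0 / kd)
    return ThermoResult(n_sites * per_site,
                        {"kd_molar": kd, "n_sites": n_sites,
                         "per_site_kbt": per_site})
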