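"""Docking configuration rules and post-docking statistics.

Docking itself runs externally (AutoDock-style engines); this module owns
everything around it.  On the input side it emits grid configurations
(cubic 40 Å or 60 Å boxes by ligand size, 0.375 Å spacing, centre 10 Å
above the heme plane), validates bias specifications (one heme-coordination
reward plus at most three additional site rewards) and enumerates
receptor × ligand docking tasks.  On the output side it normalises each
receptor's ligand panel to Z-scores of binding energy and pose population,
calls binders with the 0.9-of-true-positive rule (a ligand is a binder when
its energy and population Z-scores are both at least 90% as extreme as the
known true ligand's), and summarises selectivity and promiscuity across a
receptor panel.  A pchembl > 6 filter selects high-affinity assay records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DockRecord",
    "ZRecord",
    "BinderCall",
    "GridConfig",
    "BiasSite",
    "BiasSpec",
    "make_grid_config",
    "heme_normal_from_nitrogens",
    "validate_bias_spec",
    "affinity_filter",
    "zscore_table",
    "call_binders",
    "selectivity_matrix",
    "enumerate_tasks",
    "read_dock_table",
    "autodock_parameter_text",
]

GA_RUNS_DEFAULT = 100
RMSTOL_DEFAULT = 2.5  # Angstrom
GRID_SPACING = 0.375  # Angstrom
GRID_CENTER_OFFSET = 10.0  # Angstrom above the heme plane
SMALL_LIGAND_EDGE = 40.0
LARGE_LIGAND_EDGE = 60.0
SMALL_LIGAND_MAX_ATOMS = 35  # ligands with fewer atoms get the 40 A box


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DockRecord:
    """Best-pose result of one receptor-ligand docking run."""

    receptor: str
    ligand: str
    group: str
    energy_kcal: float  # best-pose binding energy; negative = favourable
    population: int  # runs in the best pose cluster
    runs: int = GA_RUNS_DEFAULT

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy_kcal):
            raise ValueError(f"{self.receptor}/{self.ligand}: non-finite energy")
        if not 0 <= self.population <= self.runs:
            raise ValueError(
                f"{self.receptor}/{self.ligand}: population {self.population} "
                f"outside [0, {self.runs}]"
            )


@dataclass(frozen=True)
class ZRecord:
    """A DockRecord with panel-normalised Z-scores."""

    record: DockRecord
    z_energy: float
    z_population: float


@dataclass(frozen=True)
class BinderCall:
    receptor: str
    ligand: str
    group: str
    is_binder: bool
    margin_energy: float  # z_energy / z_TP_energy (1 = as extreme as the TP)
    margin_population: float


# ---------------------------------------------------------------------------
# Grid configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridConfig:
    edge: float  # cubic box edge, Angstrom
    spacing: float
    center: tuple[float, float, float]

    def to_gpf(self) -> str:
        """AutoGrid-style parameter text."""
        npts = int(round(self.edge / self.spacing))
        cx, cy, cz = self.center
        return (
            f"npts {npts} {npts} {npts}\n"
            f"spacing {self.spacing}\n"
            f"gridcenter {cx:.3f} {cy:.3f} {cz:.3f}\n"
        )

    def to_json(self) -> str:
        return json.dumps(
            {"edge": self.edge, "spacing": self.spacing, "center": list(self.center)}
        )


def make_grid_config(
    n_atoms: int,
    heme_center: Sequence[float],
    heme_normal: Sequence[float],
) -> GridConfig:
    """Grid box for one ligand: 40 Å edge below 35 atoms, 60 Å at or above.

    The centre sits 10 Å from the heme centre along the supplied unit
    normal (the distal side of the porphyrin plane, where substrates bind).
    """
    if n_atoms < 1:
        raise ValueError("ligand must have at least one atom")
    normal = np.asarray(heme_normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise ValueError("heme_normal must be a unit vector")
    center = np.asarray(heme_center, dtype=float) + GRID_CENTER_OFFSET * normal
    edge = SMALL_LIGAND_EDGE if n_atoms < SMALL_LIGAND_MAX_ATOMS else LARGE_LIGAND_EDGE
    return GridConfig(edge=edge, spacing=GRID_SPACING, center=tuple(center))


def heme_normal_from_nitrogens(nitrogens: Sequence[Sequence[float]]) -> np.ndarray:
    """Unit normal of the least-squares plane through porphyrin nitrogens.

    Expects the four pyrrole nitrogen coordinates (more points are
    accepted).  The sign of the normal is arbitrary; callers orient it
    toward the distal pocket.
    """
    pts = np.asarray(nitrogens, dtype=float)
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 xyz points")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise ValueError("degenerate (collinear) nitrogen geometry")
    return vt[2] / np.linalg.norm(vt[2])


# ---------------------------------------------------------------------------
# Bias specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasSite:
    """One energy reward applied to matching ligand atoms during docking."""

    atom_selector: str
    reward_kcal: float  # <= 0: a reward lowers the energy


@dataclass(frozen=True)
class BiasSpec:
    heme: BiasSite
    additional: tuple[BiasSite, ...] = ()


MAX_ADDITIONAL_BIASES = 3


def validate_bias_spec(spec: BiasSpec) -> BiasSpec:
    """Check a bias spec: one heme site plus at most 3 additional rewards.

    All rewards must be non-positive (a positive value would be a penalty,
    not a reward).  Returns the spec unchanged when valid.
    """
    if spec.heme is None:
        raise ValueError("bias spec must include the heme-coordination bias")
    if len(spec.additional) > MAX_ADDITIONAL_BIASES:
        raise ValueError(
            f"at most {MAX_ADDITIONAL_BIASES} additional biases allowed, "
            f"got {len(spec.additional)}"
        )
    for site in (spec.heme, *spec.additional):
        if site.reward_kcal > 0:
            raise ValueError(
                f"bias reward must be <= 0 kcal/mol, got {site.reward_kcal} "
                f"at {site.atom_selector!r}"
            )
    return spec


# ---------------------------------------------------------------------------
# Affinity filter (assay records)
# ---------------------------------------------------------------------------

PCHEMBL_MIN = 6.0


def affinity_filter(
    records: pd.DataFrame, pchembl_col: str = "pchembl", threshold: float = PCHEMBL_MIN
) -> tuple[pd.DataFrame, dict]:
    """Keep assay rows with pchembl strictly greater than the threshold.

    Rows with missing pchembl are dropped; the report counts both kinds of
    removal.  pchembl is -log10 of the measured potency, so > 6 keeps
    sub-micromolar binders.
    """
    if pchembl_col not in records.columns:
        raise ValueError(f"missing column {pchembl_col!r}")
    vals = pd.to_numeric(records[pchembl_col], errors="coerce")
    missing = vals.isna()
    kept = records[(~missing) & (vals > threshold)]
    report = {
        "n_input": len(records),
        "n_kept": len(kept),
        "n_missing_dropped": int(missing.sum()),
        "n_below_threshold": int(((~missing) & (vals <= threshold)).sum()),
    }
    return kept.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Z-scores
# ---------------------------------------------------------------------------

def zscore_table(records: Sequence[DockRecord]) -> tuple[list[ZRecord], dict]:
    """Normalise one receptor's ligand panel to energy/population Z-scores.

    z = (x - mean) / sd with the sample standard deviation (ddof = 1),
    computed over the receptor's full ligand panel.  Population is first
    converted to the fraction of runs so panels with different run counts
    are comparable.  A zero-spread axis yields all-zero Z-scores and a flag
    instead of a division error.
    """
    if len(records) < 2:
        raise ValueError("Z-scores need at least 2 ligands per receptor")
    receptors = {r.receptor for r in records}
    if len(receptors) != 1:
        raise ValueError(f"zscore_table expects one receptor, got {sorted(receptors)}")
    e = np.array([r.energy_kcal for r in records], dtype=float)
    p = np.array([r.population / r.runs for r in records], dtype=float)
    flags = {"energy_sd_zero": False, "population_sd_zero": False}

    def _z(x: np.ndarray, key: str) -> np.ndarray:
        sd = x.std(ddof=1)
        if sd == 0:
            flags[key] = True
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    ze = _z(e, "energy_sd_zero")
    zp = _z(p, "population_sd_zero")
    out = [
        ZRecord(record=r, z_energy=float(a), z_population=float(b))
        for r, a, b in zip(records, ze, zp)
    ]
    return out, flags


# ---------------------------------------------------------------------------
# Binder calling (0.9-of-true-positive rule)
# ---------------------------------------------------------------------------

def call_binders(
    zrecords: Sequence[ZRecord],
    true_positive: str,
    alpha: float = 0.9,
    mode: str = "per_axis",
) -> tuple[list[BinderCall], dict]:
    """Call binders relative to the known true ligand of a receptor.

    The true positive anchors the favourable corner of the (z_energy,
    z_population) plane: binders are at least ``alpha`` (default 0.9) as
    extreme as the true positive.  Three interpretations are exposed:

    - ``per_axis`` (default): z_energy <= alpha * z_TP_energy AND
      z_population >= alpha * z_TP_population;
    - ``product``: z_energy * z_population >= alpha * (TP product), with the
      sign constraints of the favourable quadrant;
    - ``norm``: Euclidean norm of (z_e, z_p) >= alpha * TP norm, restricted
      to the favourable quadrant.

    A panel whose true positive is not in the favourable quadrant
    (z_energy < 0, z_population > 0) is flagged degenerate; calls are still
    emitted and the true positive is always a binder.
    """
    tp = [z for z in zrecords if z.record.ligand == true_positive]
    if not tp:
        raise ValueError(f"true positive {true_positive!r} not in panel")
    tpz = tp[0]
    degenerate = not (tpz.z_energy < 0 and tpz.z_population > 0)
    if degenerate:
        warnings.warn(
            f"degenerate panel: true positive {true_positive!r} is not in the "
            f"favourable quadrant (z_E={tpz.z_energy:.2f}, z_P={tpz.z_population:.2f})"
        )

    def _ratio(x: float, ref: float) -> float:
        return x / ref if ref != 0 else np.inf if x == 0 else 0.0

    calls: list[BinderCall] = []
    for z in zrecords:
        me = _ratio(z.z_energy, tpz.z_energy)
        mp = _ratio(z.z_population, tpz.z_population)
        if z.record.ligand == true_positive:
            ok = True
        elif degenerate:
            ok = False
        elif mode == "per_axis":
            ok = (z.z_energy <= alpha * tpz.z_energy
                  and z.z_population >= alpha * tpz.z_population)
        elif mode == "product":
            # favourable products are negative; more extreme = smaller
            ok = (z.z_energy < 0 and z.z_population > 0
                  and z.z_energy * z.z_population
                  <= alpha * tpz.z_energy * tpz.z_population)
        elif mode == "norm":
            ok = (z.z_energy < 0 and z.z_population > 0
                  and np.hypot(z.z_energy, z.z_population)
                  >= alpha * np.hypot(tpz.z_energy, tpz.z_population))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        calls.append(
            BinderCall(
                receptor=z.record.receptor, ligand=z.record.ligand,
                group=z.record.group, is_binder=bool(ok),
                margin_energy=float(me), margin_population=float(mp),
            )
        )
    return calls, {"degenerate": degenerate, "alpha": alpha, "mode": mode}


# ---------------------------------------------------------------------------
# Selectivity / promiscuity
# ---------------------------------------------------------------------------

def selectivity_matrix(
    calls: Sequence[BinderCall],
    receptor_groups: Mapping[str, str],
    ligand_groups: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Receptor × ligand-group binder counts plus promiscuity summaries.

    ``receptor_groups`` maps each receptor to the ligand group of its known
    true ligand.  The promiscuity of a receptor is the number of ligand
    groups contributing at least one called binder; a receptor is selective
    when all its binders come from its own group.
    """
    groups = sorted(ligand_groups or {c.group for c in calls})
    if len(groups) < 2:
        raise ValueError("selectivity needs a panel covering >= 2 ligand groups")
    receptors = sorted({c.receptor for c in calls} | set(receptor_groups))
    mat = pd.DataFrame(0, index=receptors, columns=groups)
    for c in calls:
        if c.is_binder:
            mat.loc[c.receptor, c.group] += 1
    promiscuity = {r: int((mat.loc[r] > 0).sum()) for r in receptors}
    selective = {
        r: bool(mat.loc[r].sum() > 0
                and mat.loc[r].drop(receptor_groups.get(r, ""), errors="ignore").sum() == 0)
        for r in receptors
    }
    summary = {
        "promiscuity": promiscuity,
        "selective": selective,
        "n_highly_promiscuous": sum(1 for v in promiscuity.values() if v >= 5),
        "n_selective": sum(1 for v in selective.values() if v),
    }
    mat.index = [
        f"{r} ({receptor_groups[r]})" if r in receptor_groups else r
        for r in receptors
    ]
    return mat, summary


# ---------------------------------------------------------------------------
# Task enumeration and I/O
# ---------------------------------------------------------------------------

def enumerate_tasks(
    receptors: Sequence[str], ligand_panel: Sequence[str]
) -> list[tuple[str, str]]:
    """Full receptor × ligand cross product (the docking task list)."""
    if not receptors or not ligand_panel:
        raise ValueError("receptors and ligand panel must be non-empty")
    if len(set(ligand_panel)) != len(ligand_panel):
        dupes = [x for x in ligand_panel if ligand_panel.count(x) > 1]
        raise ValueError(f"duplicate ligand ids in panel: {sorted(set(dupes))}")
    if len(set(receptors)) != len(receptors):
        raise ValueError("duplicate receptor ids")
    return [(r, l) for r in receptors for l in ligand_panel]


def read_dock_table(path) -> dict[str, list[DockRecord]]:
    """Read a dock-score TSV (receptor, ligand, group, energy_kcal,
    population, runs) into per-receptor record lists."""
    df = pd.read_csv(path, sep="\t")
    required = {"receptor", "ligand", "group", "energy_kcal", "population", "runs"}
    if not required.issubset(df.columns):
        raise ValueError(f"dock table missing columns {required - set(df.columns)}")
    out: dict[str, list[DockRecord]] = {}
    for _, row in df.iterrows():
        rec = DockRecord(
            receptor=str(row.receptor), ligand=str(row.ligand),
            group=str(row.group), energy_kcal=float(row.energy_kcal),
            population=int(row.population), runs=int(row.runs),
        )
        out.setdefault(rec.receptor, []).append(rec)
    return out


def autodock_parameter_text(ga_runs: int = GA_RUNS_DEFAULT,
                            rmstol: float = RMSTOL_DEFAULT) -> str:
    """Docking engine parameter stanza (search runs and pose-cluster RMSD)."""
    return f"ga_run {ga_runs}\nrmstol {rmstol}\n"
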