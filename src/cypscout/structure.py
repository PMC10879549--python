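"""Structural model evaluation: superposition, RMSD reports, template tiers.

Structure models of P450s (homology or deep-learning models) are scored
against experimental references by optimal rigid-body superposition
(Kabsch) and RMSD at three granularities: all shared atoms of the domain,
alpha carbons only, and the active-site residues evaluated in the frame of
the whole-domain superposition — the last measures how well the model
places the pocket, not how well the pocket refits on its own.  Templates
for homology modelling are tiered by phylogenetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "CoordinateSet",
    "RMSDReport",
    "superpose",
    "rmsd_report",
    "template_tier",
    "select_best_model",
    "read_pdb",
    "read_xyz_tsv",
]


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    res_id: int
    atom_name: str
    xyz: tuple[float, float, float]
    element: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates at residue {self.res_id}")


@dataclass
class CoordinateSet:
    """An ordered list of atoms keyed by (residue id, atom name)."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        keys = [(a.res_id, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue, atom name) keys")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def index(self) -> dict[tuple[int, str], int]:
        return {(a.res_id, a.atom_name): i for i, a in enumerate(self.atoms)}

    def subset(self, predicate) -> "CoordinateSet":
        return CoordinateSet(atoms=[a for a in self.atoms if predicate(a)])


def _corresponding(
    mobile: CoordinateSet, reference: CoordinateSet
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    """Coordinates of atoms shared by key between the two sets, in ref order."""
    mi = mobile.index()
    keys = [(a.res_id, a.atom_name) for a in reference.atoms if (a.res_id, a.atom_name) in mi]
    if not keys:
        raise ValueError("no corresponding atoms between model and reference")
    ref_i = reference.index()
    m = mobile.coords()[[mi[k] for k in keys]]
    r = reference.coords()[[ref_i[k] for k in keys]]
    return m, r, keys


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transform:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile_xyz: np.ndarray, reference_xyz: np.ndarray
) -> tuple[Transform, float]:
    """Least-squares rigid superposition of mobile onto reference.

    Returns the proper rotation + translation minimising the RMSD over all
    rigid motions, and that minimal RMSD.  Reflections are never returned
    (the rotation determinant is +1 by construction and asserted).
    Requires at least 3 non-collinear point pairs.
    """
    m = np.asarray(mobile_xyz, dtype=float)
    r = np.asarray(reference_xyz, dtype=float)
    if m.shape != r.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = m.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 corresponding points")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    if np.linalg.matrix_rank(m0, tol=1e-9) < 2 or np.linalg.matrix_rank(r0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) geometry; superposition is ill-posed")
    rot, rssd = Rotation.align_vectors(r0, m0)
    R = rot.as_matrix()
    assert np.linalg.det(R) > 0.5, "reflection leaked from superposition"
    t = rc - R @ mc
    transform = Transform(rotation=R, translation=t)
    fitted = transform.apply(m)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return transform, rmsd


# ---------------------------------------------------------------------------
# RMSD report
# ---------------------------------------------------------------------------

@dataclass
class RMSDReport:
    domain_rmsd: float
    ca_rmsd: float
    active_site_rmsd: float | None
    n_atoms: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def rmsd_report(
    model: CoordinateSet,
    reference: CoordinateSet,
    active_site_residues: Sequence[int] = (),
) -> RMSDReport:
    """Whole-domain, CA, and active-site RMSD of a model vs its reference.

    The domain and CA metrics each get their own optimal superposition.
    The active-site metric is computed on the heavy atoms of the listed
    residues *after* the CA superposition — re-fitting the pocket alone
    would hide placement error, which is exactly what this metric reports.
    An empty residue list omits the metric with a flag.
    """
    flags: list[str] = []
    m_all, r_all, _ = _corresponding(model, reference)
    _, domain_rmsd = superpose(m_all, r_all)

    model_ca = model.subset(lambda a: a.atom_name == "CA")
    ref_ca = reference.subset(lambda a: a.atom_name == "CA")
    m_ca, r_ca, _ = _corresponding(model_ca, ref_ca)
    ca_transform, ca_rmsd = superpose(m_ca, r_ca)

    n_atoms = {"domain": len(m_all), "ca": len(m_ca)}
    active_rmsd: float | None = None
    if active_site_residues:
        site = set(active_site_residues)
        is_heavy = lambda a: not a.atom_name.startswith("H") and a.element != "H"
        model_site = model.subset(lambda a: a.res_id in site and is_heavy(a))
        ref_site = reference.subset(lambda a: a.res_id in site and is_heavy(a))
        m_s, r_s, _ = _corresponding(model_site, ref_site)
        fitted = ca_transform.apply(m_s)
        active_rmsd = float(np.sqrt(np.mean(np.sum((fitted - r_s) ** 2, axis=1))))
        n_atoms["active_site"] = len(m_s)
    else:
        flags.append("active_site_omitted")
    return RMSDReport(
        domain_rmsd=domain_rmsd, ca_rmsd=ca_rmsd,
        active_site_rmsd=active_rmsd, n_atoms=n_atoms, flags=flags,
    )


# ---------------------------------------------------------------------------
# Template tiers and model selection
# ---------------------------------------------------------------------------

def template_tier(phylo_distance: float) -> str:
    """Tier a modelling template by phylogenetic distance to the target.

    [0, 2] -> short, (2, 4] -> mid, > 4 -> long.  The published ranges
    touch at the integers; boundaries here close on the right so every
    distance lands in exactly one tier.
    """
    d = float(phylo_distance)
    if d < 0:
        raise ValueError(f"phylogenetic distance must be >= 0, got {d}")
    if d <= 2:
        return "short"
    if d <= 4:
        return "mid"
    return "long"


def select_best_model(
    scores: Mapping[str, float], direction: str
) -> str:
    """Pick the best model id by an external quality score.

    ``direction`` is ``lower_better`` (e.g. a statistical-potential energy)
    or ``higher_better`` (e.g. a predicted-confidence score).  Ties go to
    the lexicographically first id.
    """
    if not scores:
        raise ValueError("no models to select from")
    bad = {k: v for k, v in scores.items() if not np.isfinite(v)}
    if bad:
        raise ValueError(f"non-finite scores for models: {sorted(bad)}")
    if direction == "lower_better":
        return min(sorted(scores), key=lambda k: scores[k])
    if direction == "higher_better":
        return max(sorted(scores), key=lambda k: scores[k])
    raise ValueError(f"direction must be lower_better or higher_better, got {direction!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_pdb(path, chain: str | None = None) -> CoordinateSet:
    """Read ATOM records from a PDB file: first model, altloc 'A' or blank.

    ``chain`` selects one chain; None takes the first chain encountered.
    """
    atoms: list[Atom] = []
    picked_chain = chain
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break
            if not line.startswith("ATOM"):
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            ch = line[21]
            if picked_chain is None:
                picked_chain = ch
            if ch != picked_chain:
                continue
            atoms.append(
                Atom(
                    res_id=int(line[22:26]),
                    atom_name=line[12:16].strip(),
                    xyz=(float(line[30:38]), float(line[38:46]), float(line[46:54])),
                    element=line[76:78].strip(),
                )
            )
    if not atoms:
        raise ValueError(f"no ATOM records read from {path}")
    return CoordinateSet(atoms=atoms)


def read_xyz_tsv(path) -> CoordinateSet:
    """Read a plain coordinate TSV: res_id, atom_name, x, y, z."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"res_id", "atom_name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"xyz TSV missing columns {required - set(df.columns)}")
    atoms = [
        Atom(res_id=int(r.res_id), atom_name=str(r.atom_name),
             xyz=(float(r.x), float(r.y), float(r.z)))
        for r in df.itertuples()
    ]
    return CoordinateSet(atoms=atoms)
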