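"""Compound space: fingerprints, Tanimoto similarity, and Butina clustering.

Bacterial P450s (BacCYPs) act on a chemically very diverse set of small
molecules.  To make that diversity tractable, compounds are represented as
binary fingerprints, compared with the Tanimoto index
``TI(a, b) = |a ∩ b| / |a ∪ b|`` and partitioned into substrate groups with
sphere-exclusion (Butina) clustering.  The clustering cutoff is chosen by
balancing the number of multi-member clusters against the fraction of
compounds left unclustered, and the quality of a grouping is summarised by
the distributions of within-group versus between-group similarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "SimilarityMatrix",
    "ClusterAssignment",
    "CutoffScan",
    "FingerprintParams",
    "compute_fingerprint",
    "tanimoto",
    "similarity_matrix",
    "butina_cluster",
    "choose_cutoff",
    "intra_inter_distributions",
    "read_library",
    "write_clusters",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compound:
    """A small molecule: identifier, optional SMILES, binary fingerprint.

    ``fingerprint`` is a frozenset of set-bit positions; all fingerprints in
    one library must share the same ``n_bits``.  ``group`` is an optional
    substrate-group label (known for annotated compounds, planted for
    synthetic ones).
    """

    id: str
    fingerprint: frozenset[int]
    n_bits: int
    smiles: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError(f"n_bits must be positive, got {self.n_bits}")
        if self.fingerprint and max(self.fingerprint) >= self.n_bits:
            raise ValueError(
                f"compound {self.id!r}: bit {max(self.fingerprint)} outside "
                f"fingerprint length {self.n_bits}"
            )


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Tanimoto indices with an id order."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix is not symmetric")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("Tanimoto values must lie in [0, 1]")
        if n and not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal of a similarity matrix must be 1")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class ClusterAssignment:
    """A Butina partition: id -> cluster index, plus centroids and singletons.

    Cluster indices are contiguous from 0 in order of creation (largest
    neighbourhoods first).  Clusters of size one are recorded in
    ``singletons``; multi-member clusters have a designated centroid.
    """

    labels: dict[str, int]
    centroids: dict[int, str]
    singletons: set[str]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster: int) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v == cluster)

    def as_partition(self) -> set[frozenset[str]]:
        """Label-free view (a set of member sets) for comparing partitions."""
        out: dict[int, set[str]] = {}
        for cid, cl in self.labels.items():
            out.setdefault(cl, set()).add(cid)
        return {frozenset(v) for v in out.values()}


@dataclass
class CutoffScan:
    """Diagnostics of a cutoff scan and the selected cutoff."""

    chosen: float
    table: pd.DataFrame  # columns: cutoff, n_clusters_ge2, singleton_fraction
    floor_met: bool


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintParams:
    """Circular (Morgan) fingerprint parameters: radius 2, 2048 bits default."""

    radius: int = 2
    n_bits: int = 2048


def compute_fingerprint(
    smiles: str, params: FingerprintParams = FingerprintParams()
) -> frozenset[int]:
    """Circular fingerprint bit set for a SMILES string (requires RDKit).

    Deterministic: the same SMILES always yields the same bit set.

    Raises
    ------
    ValueError
        If the SMILES is empty or cannot be parsed; the offending string is
        named in the message.
    ImportError
        If RDKit is not installed (it is an optional dependency; the rest of
        the package operates on precomputed fingerprints).
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "compute_fingerprint requires rdkit (install the 'chem' extra)"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=params.radius, fpSize=params.n_bits
    )
    fp = gen.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


# ---------------------------------------------------------------------------
# Tanimoto
# ---------------------------------------------------------------------------

def tanimoto(a: frozenset[int] | set[int], b: frozenset[int] | set[int],
             n_bits: int | None = None) -> float:
    """Tanimoto index |a ∩ b| / |a ∪ b| of two bit sets.

    Both-empty input is degenerate (no molecule to compare); it returns 0.0
    with a warning rather than raising, so fragment SMILES do not abort a
    batch.  If ``n_bits`` is given, bits outside the range raise.
    """
    if n_bits is not None:
        for s in (a, b):
            if s and max(s) >= n_bits:
                raise ValueError("fingerprint bit outside declared length")
    if not a and not b:
        warnings.warn("Tanimoto of two empty fingerprints; returning 0.0")
        return 0.0
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union


def similarity_matrix(compounds: Sequence[Compound]) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix over a compound library."""
    if not compounds:
        return SimilarityMatrix(ids=[], values=np.zeros((0, 0)))
    n_bits = {c.n_bits for c in compounds}
    if len(n_bits) != 1:
        raise ValueError(f"mixed fingerprint lengths in library: {sorted(n_bits)}")
    ids = [c.id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in library")
    n = len(compounds)
    m = np.eye(n)
    fps = [c.fingerprint for c in compounds]
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(ids=ids, values=m)


# ---------------------------------------------------------------------------
# Butina sphere-exclusion clustering
# ---------------------------------------------------------------------------

def butina_cluster(matrix: SimilarityMatrix, cutoff: float) -> ClusterAssignment:
    """Sphere-exclusion clustering at a similarity cutoff.

    Each compound's neighbourhood is the set of compounds with TI >= cutoff.
    Repeatedly the unassigned compound with the most unassigned neighbours
    becomes a centroid and absorbs its unassigned neighbourhood; ties on the
    neighbour count are broken by lexicographic id.  Compounds that end up
    alone form singleton clusters.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    ids = matrix.ids
    n = len(ids)
    if n == 0:
        return ClusterAssignment(labels={}, centroids={}, singletons=set(), cutoff=cutoff)

    neigh: list[set[int]] = []
    v = matrix.values
    for i in range(n):
        s = {j for j in range(n) if j != i and v[i, j] >= cutoff}
        neigh.append(s)

    unassigned = set(range(n))
    labels: dict[str, int] = {}
    centroids: dict[int, str] = {}
    singletons: set[str] = set()
    cluster = 0
    while unassigned:
        # most unassigned neighbours; ties -> lexicographically smallest id
        best = min(unassigned, key=lambda i: (-len(neigh[i] & unassigned), ids[i]))
        members = (neigh[best] & unassigned) | {best}
        for i in members:
            labels[ids[i]] = cluster
        if len(members) == 1:
            singletons.add(ids[best])
        else:
            centroids[cluster] = ids[best]
        unassigned -= members
        cluster += 1
    return ClusterAssignment(
        labels=labels, centroids=centroids, singletons=singletons, cutoff=cutoff
    )


def choose_cutoff(
    matrix: SimilarityMatrix,
    candidate_cutoffs: Iterable[float],
    min_clusters: int = 2,
) -> CutoffScan:
    """Scan candidate cutoffs and pick one balancing clusters vs singletons.

    For each candidate, reports the number of clusters with >= 2 members and
    the fraction of compounds left as singletons.  The chosen cutoff
    minimises the singleton fraction among candidates yielding at least
    ``min_clusters`` multi-member clusters; ties go to the larger cutoff
    (tighter clusters).  If no candidate reaches the floor, the scan still
    returns the singleton-fraction argmin, flagged via ``floor_met=False``.
    """
    cands = sorted(set(candidate_cutoffs))
    if not cands:
        raise ValueError("need at least one candidate cutoff")
    n = max(len(matrix), 1)
    rows = []
    for c in cands:
        assign = butina_cluster(matrix, c)
        sizes = pd.Series(list(assign.labels.values())).value_counts()
        n_ge2 = int((sizes >= 2).sum()) if len(sizes) else 0
        rows.append(
            {
                "cutoff": c,
                "n_clusters_ge2": n_ge2,
                "singleton_fraction": len(assign.singletons) / n,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table.n_clusters_ge2 >= min_clusters]
    pool = ok if len(ok) else table
    floor_met = bool(len(ok))
    # minimal singleton fraction; ties -> largest cutoff
    best = pool.sort_values(
        ["singleton_fraction", "cutoff"], ascending=[True, False]
    ).iloc[0]
    return CutoffScan(chosen=float(best.cutoff), table=table, floor_met=floor_met)


# ---------------------------------------------------------------------------
# Intra/inter-group similarity distributions
# ---------------------------------------------------------------------------

def intra_inter_distributions(
    matrix: SimilarityMatrix, labels: Mapping[str, str]
) -> tuple[list[float], list[float]]:
    """Split all unordered pairwise TIs into same-group and cross-group lists.

    Returns ``(intra, inter)`` with ``len(intra) + len(inter) = n(n-1)/2``.
    With a single group the inter list is empty (warned).
    """
    missing = [i for i in matrix.ids if i not in labels]
    if missing:
        raise ValueError(f"no group label for ids: {missing[:5]}")
    groups = {labels[i] for i in matrix.ids}
    if len(groups) < 2:
        warnings.warn("only one group present; inter-group distribution is empty")
    intra: list[float] = []
    inter: list[float] = []
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ti = float(matrix.values[i, j])
            (intra if labels[ids[i]] == labels[ids[j]] else inter).append(ti)
    return intra, inter


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _fp_from_hex(hexstr: str, n_bits: int) -> frozenset[int]:
    """Decode a big-endian hex string into set-bit positions (bit 0 first)."""
    raw = bytes.fromhex(hexstr)
    bits = set()
    for byte_i, byte in enumerate(raw):
        for k in range(8):
            if byte >> (7 - k) & 1:
                bits.add(byte_i * 8 + k)
    if bits and max(bits) >= n_bits:
        raise ValueError("hex fingerprint longer than declared bit length")
    return frozenset(bits)


def _fp_to_hex(fp: frozenset[int], n_bits: int) -> str:
    nbytes = (n_bits + 7) // 8
    raw = bytearray(nbytes)
    for b in fp:
        raw[b // 8] |= 1 << (7 - b % 8)
    return raw.hex()


def read_library(
    path, n_bits: int = 2048, fp_params: FingerprintParams | None = None
) -> list[Compound]:
    """Read a compound library TSV/CSV: id, smiles?, fingerprint? (hex), group?.

    Fingerprints are taken from the ``fingerprint`` column when present,
    otherwise computed from SMILES (requiring RDKit).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "id" not in df.columns:
        raise ValueError("library file must have an 'id' column")
    params = fp_params or FingerprintParams(n_bits=n_bits)
    out = []
    for _, row in df.iterrows():
        fp_hex = row.get("fingerprint", "")
        smiles = row.get("smiles", "") or None
        if fp_hex:
            fp, bits = _fp_from_hex(fp_hex, n_bits), n_bits
        elif smiles:
            fp, bits = compute_fingerprint(smiles, params), params.n_bits
        else:
            raise ValueError(f"compound {row['id']!r}: neither fingerprint nor smiles")
        out.append(
            Compound(id=row["id"], fingerprint=fp, n_bits=bits, smiles=smiles,
                     group=row.get("group", "") or None)
        )
    return out


def write_library(compounds: Sequence[Compound], path) -> None:
    rows = [
        {
            "id": c.id,
            "smiles": c.smiles or "",
            "fingerprint": _fp_to_hex(c.fingerprint, c.n_bits),
            "group": c.group or "",
        }
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_clusters(assignment: ClusterAssignment, path, scan: CutoffScan | None = None) -> None:
    """Write id -> cluster TSV; optionally a JSON cutoff-scan table alongside."""
    df = pd.DataFrame(
        sorted(assignment.labels.items()), columns=["id", "cluster"]
    )
    df["singleton"] = df["id"].isin(assignment.singletons)
    df.to_csv(path, sep="\t", index=False)
    if scan is not None:
        diag = {
            "chosen_cutoff": scan.chosen,
            "floor_met": scan.floor_met,
            "scan": scan.table.to_dict(orient="records"),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(diag, fh, indent=2)
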