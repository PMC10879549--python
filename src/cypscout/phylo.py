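"""Phylogenetic grouping, motif scanning, and identity/substrate analyses.

BacCYP families are partitioned into groups by cutting a hierarchical
clustering of the cophenetic (path-length) distance matrix of a
phylogenetic tree, choosing the cut that maximises the number of "major"
groups — groups holding at least 1% of all leaves.  New sequences are
placed into groups by a 3-mer nearest-centroid classifier.  The module also
scans the family's conserved motifs (heme binding, EXXR, proton relay,
[N/H]RDP), checks group-diagnostic residues in domain numbering, and
supports the analysis of how protein sequence identity relates to substrate
chemical similarity.
"""

from __future__ import annotations

import io
import itertools
import re
import string
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import Align

__all__ = [
    "LabeledTree",
    "GroupingResult",
    "MotifHit",
    "DEFAULT_DIAGNOSTICS",
    "MOTIF_PATTERNS",
    "read_tree",
    "cophenetic_matrix",
    "cut_by_one_percent_rule",
    "kmer_profile",
    "assign_group",
    "scan_motifs",
    "check_diagnostics",
    "pairwise_identity",
    "identity_vs_substrate_ti",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_X_SLOT = AMINO_ACIDS + "BZX"  # ambiguity codes match only wildcard slots


# ---------------------------------------------------------------------------
# Trees and cophenetic distances
# ---------------------------------------------------------------------------

@dataclass
class LabeledTree:
    """A rooted or unrooted tree with branch lengths and unique leaf ids."""

    tree: dendropy.Tree

    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __post_init__(self) -> None:
        ids = self.leaf_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate leaf ids in tree")


def read_tree(source: str) -> LabeledTree:
    """Parse a Newick tree from a path or a literal Newick string."""
    if source.strip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    return LabeledTree(tree=tree)


def cophenetic_matrix(tree: LabeledTree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length (cophenetic) distance matrix.

    d(i, j) is the sum of branch lengths on the unique path between leaves
    i and j.  A missing branch length anywhere below the root is an error —
    silently defaulting it would corrupt every distance through that edge.
    """
    t = tree.tree
    leaves = list(t.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("cophenetic matrix needs at least 2 leaves")
    root = t.seed_node
    for node in t.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise ValueError(
                f"missing branch length above node "
                f"{node.taxon.label if node.taxon else '<internal>'}"
            )
    pdm = t.phylogenetic_distance_matrix()
    ids = [lf.taxon.label for lf in leaves]
    n = len(ids)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
        m[i, j] = m[j, i] = d
    return ids, m


# ---------------------------------------------------------------------------
# Cutting the hierarchy: the 1%-rule
# ---------------------------------------------------------------------------

def _group_letters(k: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... group letters."""
    letters = list(string.ascii_uppercase)
    out = list(letters)
    width = 2
    while len(out) < k:
        out.extend("".join(p) for p in itertools.product(letters, repeat=width))
        width += 1
    return out[:k]


@dataclass
class GroupingResult:
    """A cut of the cophenetic hierarchy into lettered groups."""

    k: int
    labels: dict[str, str]  # leaf id -> group letter
    fractions: dict[str, float]
    n_major: int  # groups holding >= 1% of leaves
    scan: dict[int, int] = field(default_factory=dict)  # k -> n_major(k)


def cut_by_one_percent_rule(
    ids: Sequence[str],
    matrix: np.ndarray,
    kmax: int,
    major_fraction: float = 0.01,
) -> GroupingResult:
    """Cut a complete-linkage hierarchy to maximise the number of major groups.

    For each k in 2..kmax the hierarchy is cut into k clusters and
    ``n_major(k)`` — the number of clusters containing at least
    ``major_fraction`` of all leaves — is computed; the returned cut
    maximises ``n_major`` with ties resolved to the smallest k.

    Group letters are assigned by decreasing group size (ties by first
    member id) so the labelling is deterministic.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 leaves to cut")
    if not 2 <= kmax <= n:
        raise ValueError(f"kmax must be in [2, {n}], got {kmax}")
    condensed = squareform(np.asarray(matrix, dtype=float), checks=False)
    z = linkage(condensed, method="complete")

    best_k, best_major, best_assign = None, -1, None
    scan: dict[int, int] = {}
    for k in range(2, kmax + 1):
        assign = fcluster(z, t=k, criterion="maxclust")
        sizes = Counter(assign)
        n_major = sum(1 for s in sizes.values() if s / n >= major_fraction)
        scan[k] = n_major
        if n_major > best_major:  # strict: ties keep the smallest k
            best_k, best_major, best_assign = k, n_major, assign

    # deterministic lettering: by size desc, then first-member id
    clusters: dict[int, list[str]] = {}
    for leaf, c in zip(ids, best_assign):
        clusters.setdefault(int(c), []).append(leaf)
    order = sorted(clusters, key=lambda c: (-len(clusters[c]), min(clusters[c])))
    letters = _group_letters(len(order))
    letter_of = {c: letters[i] for i, c in enumerate(order)}
    labels = {leaf: letter_of[int(c)] for leaf, c in zip(ids, best_assign)}
    fractions = {
        letter_of[c]: len(members) / n for c, members in clusters.items()
    }
    return GroupingResult(
        k=int(best_k), labels=labels, fractions=fractions,
        n_major=int(best_major), scan=scan,
    )


# ---------------------------------------------------------------------------
# Group assignment for new sequences (3-mer nearest centroid)
# ---------------------------------------------------------------------------

def kmer_profile(seq: str, k: int = 3) -> Counter:
    """Overlapping k-mer counts of a protein sequence (uppercased)."""
    s = seq.upper()
    return Counter(s[i : i + k] for i in range(len(s) - k + 1))


def _cosine(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    dot = sum(v * b.get(kk, 0.0) for kk, v in a.items())
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def assign_group(
    query: str,
    references: Mapping[str, str],
    labels: Mapping[str, str],
    k: int = 3,
) -> tuple[str, float, float]:
    """Assign a query sequence to a group by 3-mer nearest centroid.

    Each group's centroid is the mean k-mer count profile of its reference
    sequences; the query goes to the centroid with the highest cosine
    similarity.  Returns ``(group, score, margin)`` where margin is the gap
    to the runner-up (equal to score when only one group exists).
    """
    if not references:
        raise ValueError("no reference sequences")
    if len(query) < k:
        raise ValueError(f"query shorter than k-mer size {k}")
    centroids: dict[str, Counter] = {}
    counts: Counter = Counter()
    for rid, seq in references.items():
        g = labels[rid]
        prof = kmer_profile(seq, k)
        centroids.setdefault(g, Counter())
        centroids[g].update(prof)
        counts[g] += 1
    mean_profiles = {
        g: {kk: v / counts[g] for kk, v in prof.items()}
        for g, prof in centroids.items()
    }
    qprof = kmer_profile(query, k)
    scores = sorted(
        ((_cosine(qprof, p), g) for g, p in mean_profiles.items()),
        key=lambda t: (-t[0], t[1]),
    )
    best_score, best_group = scores[0]
    margin = best_score - scores[1][0] if len(scores) > 1 else best_score
    return best_group, float(best_score), float(margin)


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """One motif match: name, 1-based start, matched residues, variant flags."""

    motif: str
    start: int
    matched: str
    variants: tuple[tuple[str, str], ...] = ()

    @property
    def variant_dict(self) -> dict[str, str]:
        return dict(self.variants)


# P450 family motifs.  X slots accept any standard residue plus the
# ambiguity codes B/Z/X; fixed slots accept only the stated letters.  The
# heme motif's terminal G is relaxed to [G/A] (one family group carries A).
_X = f"[{_X_SLOT}]"
MOTIF_PATTERNS: dict[str, str] = {
    "heme_binding": f"F[GS]{_X}G{_X}[HR]{_X}C{_X}[GA]",
    "EXXR": f"E{_X}{_X}R",
    "proton_relay": f"[AG]G{_X}[DE]T[TS]",
    "NRDP": "[NH]RDP",
}

# (motif, 0-based offset within match, flag name) — the residue observed at
# these positions separates family groups (H vs R, D vs E, N vs H).
_VARIANT_SLOTS = {
    "heme_binding": [(5, "H/R"), (9, "G/A")],
    "proton_relay": [(3, "D/E")],
    "NRDP": [(0, "N/H")],
}


def scan_motifs(domain_seq: str) -> list[MotifHit]:
    """Scan a domain sequence for all family motifs.

    Returns non-overlapping matches per motif (motifs may overlap each
    other), with 1-based start positions local to the supplied sequence and
    variant flags at the group-separating slots.  Case-insensitive; no
    match yields an empty list.
    """
    seq = domain_seq.upper()
    hits: list[MotifHit] = []
    for name, pattern in MOTIF_PATTERNS.items():
        for m in re.finditer(pattern, seq):
            flags = tuple(
                (flag, m.group(0)[off])
                for off, flag in _VARIANT_SLOTS.get(name, [])
            )
            hits.append(
                MotifHit(motif=name, start=m.start() + 1, matched=m.group(0),
                         variants=flags)
            )
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


# ---------------------------------------------------------------------------
# Group-diagnostic residues (domain numbering)
# ---------------------------------------------------------------------------

# Group -> [(domain position, residue)].  Groups with no distinctive
# conserved feature map to empty lists.
DEFAULT_DIAGNOSTICS: dict[str, list[tuple[int, str]]] = {
    "A": [],
    "B": [(65, "L"), (171, "W"), (360, "E")],
    "C": [(121, "P"), (168, "T")],
    "D": [],
    "E": [],
    "F": [],
    "G": [(128, "A")],
    "H": [(155, "W")],
    "I": [(116, "G"), (128, "A"), (149, "D"), (155, "W")],
    "J": [(121, "D"), (128, "A"), (144, "P"), (155, "W")],
    "K": [(131, "P"), (132, "L"), (133, "P"), (137, "I"), (144, "P")],
    "L": [(131, "P"), (132, "L"), (133, "P"), (137, "I"), (144, "P"),
          (149, "R"), (155, "W"), (156, "S")],
    "M": [(162, "P")],
    "N": [],
}


@dataclass
class DiagnosticReport:
    """Per-group diagnostic-residue match fractions."""

    fractions: dict[str, float]
    no_diagnostics: set[str]  # groups with no diagnostic positions (flagged)
    out_of_range: dict[str, list[int]]  # group -> positions beyond the mapping


def check_diagnostics(
    domain_residues: Mapping[int, str] | str,
    profile: Mapping[str, list[tuple[int, str]]] | None = None,
) -> DiagnosticReport:
    """Fraction of each group's diagnostic residues matched by a sequence.

    ``domain_residues`` maps domain position (1-based) to the residue there,
    or is a string already laid out in domain numbering ('-' for gaps).
    Groups without diagnostics score 1.0 by convention and are flagged.
    Positions beyond the supplied mapping count as unmatched and are
    reported.
    """
    prof = profile if profile is not None else DEFAULT_DIAGNOSTICS
    if isinstance(domain_residues, str):
        residues = {
            i + 1: aa for i, aa in enumerate(domain_residues.upper()) if aa != "-"
        }
    else:
        residues = {int(p): aa.upper() for p, aa in domain_residues.items()}
    fractions: dict[str, float] = {}
    empty: set[str] = set()
    oor: dict[str, list[int]] = {}
    max_pos = max(residues) if residues else 0
    for group, diags in prof.items():
        if not diags:
            fractions[group] = 1.0
            empty.add(group)
            continue
        matched = 0
        for pos, aa in diags:
            if pos <= 0:
                raise ValueError(f"diagnostic position must be positive: {pos}")
            if pos > max_pos:
                oor.setdefault(group, []).append(pos)
                continue
            if residues.get(pos) == aa.upper():
                matched += 1
        fractions[group] = matched / len(diags)
    return DiagnosticReport(fractions=fractions, no_diagnostics=empty, out_of_range=oor)


# ---------------------------------------------------------------------------
# Pairwise identity and the identity-vs-substrate-similarity analysis
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment (match +1, mismatch 0, gap -1).

    The denominator is the number of alignment columns excluding terminal
    gap columns, so a domain fragment aligned inside a full-length sequence
    is not penalised for the overhang.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim columns where either row has a terminal gap run
    start = 0
    end = len(sa)
    for s in (sa, sb):
        m = re.match(r"-*", s)
        start = max(start, m.end())
        m = re.search(r"-*$", s)
        end = min(end, m.start())
    if end <= start:
        return 0.0
    matches = sum(1 for x, y in zip(sa[start:end], sb[start:end]) if x == y and x != "-")
    return 100.0 * matches / (end - start)


def identity_vs_substrate_ti(
    pairs: Sequence[tuple[float, float]],
    same_group: Sequence[bool] | None = None,
    high_identity_threshold: float = 70.0,
) -> dict[str, list[float]]:
    """Stratify substrate-similarity values by protein sequence identity.

    ``pairs`` holds (identity %, substrate TI) for protein pairs.  Returns
    TI lists for three strata: all pairs, same-phylogenetic-group pairs
    (when ``same_group`` flags are supplied), and pairs of proteins with
    identity strictly above the threshold ("over 70%" — the boundary itself
    is excluded).
    """
    for ident, ti in pairs:
        if not 0 <= ident <= 100:
            raise ValueError(f"identity out of [0, 100]: {ident}")
        if not 0 <= ti <= 1:
            raise ValueError(f"TI out of [0, 1]: {ti}")
    out: dict[str, list[float]] = {
        "all": [ti for _, ti in pairs],
        "same_group": [],
        "high_identity": [ti for ident, ti in pairs if ident > high_identity_threshold],
    }
    if same_group is not None:
        if len(same_group) != len(pairs):
            raise ValueError("same_group flags must align with pairs")
        out["same_group"] = [ti for (_, ti), sg in zip(pairs, same_group) if sg]
    for name in ("same_group", "high_identity"):
        if not out[name]:
            warnings.warn(f"stratum {name!r} is empty")
    return out
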