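"""Genomic-context substrate inference.

Bacterial metabolic pathways are frequently encoded in operons, so the
product of a gene adjacent to a P450 is often the P450's substrate.  This
module loads local genome annotation tables (GFF3 or TSV) together with a
gene → compound links table, retrieves the neighbours of a target gene up
to a genomic gap threshold, pools the neighbours' annotated reaction
compounds as candidate substrates ranked by Tanimoto similarity (or by
genomic proximity when no reference compounds are known), and measures
recovery of planted truths on benchmark sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .chemspace import Compound, tanimoto

__all__ = [
    "GeneRecord",
    "GenomeModel",
    "Neighborhood",
    "ContextPrediction",
    "load_annotations",
    "neighbors",
    "context_candidates",
    "context_recovery",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """One annotated gene with its genomic interval and linked compounds.

    Coordinates are 1-based and inclusive (GFF3 convention).  ``substrates``
    and ``products`` hold compound ids of the annotated reaction.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    genome_id: str = ""
    substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    ec_numbers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class GenomeModel:
    """Validated gene set with any unresolvable compound links reported."""

    genes: dict[str, GeneRecord]
    unknown_compounds: list[str] = field(default_factory=list)


@dataclass
class Neighbor:
    gene: GeneRecord
    gap_bp: int
    side: str  # upstream | downstream, relative to the target's strand
    adjacent: bool  # rank-1 nearest on its side


@dataclass
class Neighborhood:
    target: GeneRecord
    neighbors: list[Neighbor]
    max_gap_bp: int


@dataclass
class Candidate:
    compound_id: str
    source_gene: str
    role: str  # product | substrate
    gap_bp: int
    adjacent: bool
    ti: float | None = None  # best TI vs the reference set, when given


@dataclass
class ContextPrediction:
    """Ranked candidate substrates for one target, with provenance."""

    target_id: str
    candidates: list[Candidate]
    status: str  # "ok" | "no-information"

    @property
    def informative(self) -> bool:
        return self.status == "ok"


# ---------------------------------------------------------------------------
# Loading annotations
# ---------------------------------------------------------------------------

def _parse_gff3(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line[:80]!r}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype not in {"gene", "CDS"}:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("locus_tag")
            if gid is None:
                raise ValueError(f"GFF3 feature without ID: {line[:80]!r}")
            rows.append(
                {"gene_id": gid, "contig": contig, "start": start,
                 "end": end, "strand": strand}
            )
    return rows


def load_annotations(
    annotation_path,
    links_path=None,
    compound_library: Sequence[Compound] | None = None,
) -> GenomeModel:
    """Build a genome model from a GFF3 (or TSV) plus a gene-compound links TSV.

    The TSV form requires columns gene_id, contig, start, end, strand.  The
    links file maps gene_id -> compound_id with a role column (product or
    substrate).  Compound ids not present in the supplied library are kept
    but reported in ``unknown_compounds``.

    Raises on duplicate gene ids or missing coordinates.
    """
    path = str(annotation_path)
    if path.endswith((".gff", ".gff3")):
        rows = _parse_gff3(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "contig", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation TSV missing columns {required - set(df.columns)}")
        rows = df.to_dict(orient="records")

    genes: dict[str, GeneRecord] = {}
    for row in rows:
        gid = str(row["gene_id"])
        if gid in genes:
            raise ValueError(f"duplicate gene id: {gid}")
        if pd.isna(row["start"]) or pd.isna(row["end"]) or row["start"] == "" or row["end"] == "":
            raise ValueError(f"gene {gid}: missing coordinates")
        genes[gid] = GeneRecord(
            gene_id=gid,
            contig=str(row["contig"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
        )

    unknown: list[str] = []
    if links_path is not None:
        links = pd.read_csv(links_path, sep="\t", dtype=str)
        lib_ids = {c.id for c in compound_library} if compound_library else None
        for _, row in links.iterrows():
            gid, cid, role = row["gene_id"], row["compound_id"], row["role"]
            if gid not in genes:
                warnings.warn(f"links file references unknown gene {gid!r}")
                continue
            if role == "product":
                genes[gid].products.append(cid)
            elif role == "substrate":
                genes[gid].substrates.append(cid)
            else:
                raise ValueError(f"unknown role {role!r} for gene {gid}")
            if lib_ids is not None and cid not in lib_ids:
                unknown.append(cid)
    return GenomeModel(genes=genes, unknown_compounds=unknown)


# ---------------------------------------------------------------------------
# Neighborhood retrieval
# ---------------------------------------------------------------------------

def _gap(a: GeneRecord, b: GeneRecord) -> int:
    """Intervening bases between two intervals; overlap or abutment -> 0."""
    if b.start > a.end:
        return b.start - a.end - 1
    if a.start > b.end:
        return a.start - b.end - 1
    return 0


def neighbors(target_id: str, model: GenomeModel, max_gap_bp: int) -> Neighborhood:
    """Genes on the target's contig within ``max_gap_bp`` intervening bases.

    The gap is measured between the closest interval edges (inclusive
    threshold); overlapping or abutting genes have gap 0.  Eligibility is
    strand-agnostic; strand is carried on each record for downstream use.
    The nearest gene on each side is flagged adjacent.  Sides are oriented
    by the target's strand (for a minus-strand target, genes at lower
    coordinates are downstream).
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    if target_id not in model.genes:
        raise KeyError(f"unknown target gene: {target_id}")
    target = model.genes[target_id]
    found: list[Neighbor] = []
    for gid, gene in model.genes.items():
        if gid == target_id or gene.contig != target.contig:
            continue
        gap = _gap(target, gene)
        if gap > max_gap_bp:
            continue
        left_of_target = gene.start < target.start
        if target.strand == "+":
            side = "upstream" if left_of_target else "downstream"
        else:
            side = "downstream" if left_of_target else "upstream"
        found.append(Neighbor(gene=gene, gap_bp=gap, side=side, adjacent=False))
    # flag the rank-1 nearest neighbour on each side
    for side in ("upstream", "downstream"):
        on_side = [nb for nb in found if nb.side == side]
        if on_side:
            min(on_side, key=lambda nb: (nb.gap_bp, nb.gene.gene_id)).adjacent = True
    found.sort(key=lambda nb: (nb.gap_bp, nb.gene.gene_id))
    return Neighborhood(target=target, neighbors=found, max_gap_bp=max_gap_bp)


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------

_ROLE_RANK = {"product": 0, "substrate": 1}  # a neighbour's product first


def context_candidates(
    neighborhood: Neighborhood,
    library: Mapping[str, Compound],
    reference_ids: Sequence[str] | None = None,
) -> ContextPrediction:
    """Pool and rank substrate candidates from a neighbourhood.

    All substrates and products annotated on the neighbours are pooled
    (deduplicated per (compound, source gene) pair).  With a reference
    compound set, each candidate is scored by its best Tanimoto index
    against the references and ranked by TI descending; without one, by
    adjacency first and genomic gap ascending.  At equal rank a neighbour's
    product sorts before its substrate — in an operon the upstream enzyme's
    product is the likelier P450 substrate.

    Targets whose neighbours carry no compound annotation yield an empty
    prediction with status ``"no-information"`` rather than an error, so
    recovery statistics can separate "wrong" from "nothing to go on".
    """
    if not neighborhood.neighbors:
        return ContextPrediction(
            target_id=neighborhood.target.gene_id, candidates=[], status="no-information"
        )
    seen: set[tuple[str, str]] = set()
    cands: list[Candidate] = []
    for nb in neighborhood.neighbors:
        for role, comp_ids in (("product", nb.gene.products),
                               ("substrate", nb.gene.substrates)):
            for cid in comp_ids:
                key = (cid, nb.gene.gene_id)
                if key in seen:
                    continue
                seen.add(key)
                ti = None
                if reference_ids:
                    fps = [library[r].fingerprint for r in reference_ids if r in library]
                    if cid in library and fps:
                        ti = max(tanimoto(library[cid].fingerprint, fp) for fp in fps)
                cands.append(
                    Candidate(compound_id=cid, source_gene=nb.gene.gene_id,
                              role=role, gap_bp=nb.gap_bp, adjacent=nb.adjacent,
                              ti=ti)
                )
    if not cands:
        return ContextPrediction(
            target_id=neighborhood.target.gene_id, candidates=[], status="no-information"
        )
    if reference_ids:
        cands.sort(key=lambda c: (-(c.ti if c.ti is not None else -1.0),
                                  _ROLE_RANK[c.role], c.gap_bp, c.compound_id))
    else:
        cands.sort(key=lambda c: (not c.adjacent, c.gap_bp,
                                  _ROLE_RANK[c.role], c.compound_id))
    return ContextPrediction(
        target_id=neighborhood.target.gene_id, candidates=cands, status="ok"
    )


# ---------------------------------------------------------------------------
# Recovery benchmark
# ---------------------------------------------------------------------------

def context_recovery(
    predictions: Sequence[ContextPrediction],
    truth: Mapping[str, str],
    library: Mapping[str, Compound],
    ti_success: float = 0.85,
) -> tuple[float | None, dict]:
    """Fraction of informative targets whose top candidate matches the truth.

    A target counts as recovered when its rank-1 candidate has Tanimoto
    index >= ``ti_success`` against the true substrate.  The denominator is
    the number of targets with a non-empty prediction — targets for which
    the genome offers no compound information are excluded, matching the
    semantics of "cases where results are identified".  Returns
    ``(rate, detail)``; the rate is None when no target is informative.
    """
    missing = [p.target_id for p in predictions if p.target_id not in truth]
    if missing:
        raise ValueError(f"no truth entry for targets: {missing[:5]}")
    informative = [p for p in predictions if p.informative and p.candidates]
    if not informative:
        warnings.warn("no informative predictions; recovery undefined")
        return None, {"n_informative": 0, "n_total": len(predictions)}
    hits = 0
    for p in informative:
        top = p.candidates[0]
        true_cid = truth[p.target_id]
        if top.compound_id == true_cid:
            hits += 1
            continue
        if top.compound_id in library and true_cid in library:
            ti = tanimoto(library[top.compound_id].fingerprint,
                          library[true_cid].fingerprint)
            if ti >= ti_success:
                hits += 1
    rate = hits / len(informative)
    return rate, {
        "n_informative": len(informative),
        "n_total": len(predictions),
        "n_recovered": hits,
        "ti_success": ti_success,
    }
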