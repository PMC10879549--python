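"""Evidence integration: from a P450 sequence to a ranked substrate-group list.

The workflow runs the three information sources in order of increasing
specificity and combines them ordinally:

1. *Phylogeny* — the query is assigned to a group of the reference tree
   and the substrate groups historically seen in that group become a weak
   prior (phylogeny alone is the least informative source: similar
   sequences can bind very different compounds).
2. *Genomic context* — substrates/products annotated on the target's gene
   neighbours become candidate substrates (the operon signal).
3. *Docking* — ligand groups whose panel members are called binders
   against the query's structure.

Each candidate substrate group is tagged with an evidence tier —
context∧docking > docking-only > context-only > phylogeny-only — and
ranked by tier, then by docking margin, then by context similarity.  The
combination is deliberately ordinal rather than a fitted score: the
sources are incommensurable and the tiers encode which agreements matter.
Absent resources skip their stage explicitly rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chemspace import Compound
from .context import ContextPrediction, GenomeModel, context_candidates, neighbors
from .docking import BinderCall, DockRecord, call_binders, zscore_table
from .phylo import assign_group

__all__ = ["Resources", "RankedGroup", "EvidenceReport", "predict_substrate"]

TIER_ORDER = {
    "context+docking": 3,
    "docking": 2,
    "context": 1,
    "phylogeny": 0,
}


@dataclass
class Resources:
    """Everything the workflow may draw on; optional stages may be None."""

    references: Mapping[str, str]  # reference sequence id -> sequence
    reference_labels: Mapping[str, str]  # reference id -> phylogenetic group
    library: Mapping[str, Compound]  # compound id -> Compound (with group labels)
    # phylogenetic group -> substrate groups observed among its members
    group_substrate_prior: Mapping[str, Sequence[str]] | None = None
    genome: GenomeModel | None = None
    target_gene_id: str | None = None
    max_gap_bp: int = 2000
    context_reference_ids: Sequence[str] | None = None
    dock_records: Sequence[DockRecord] | None = None  # panel docked vs the query
    true_positive_ligand: str | None = None
    binder_alpha: float = 0.9


@dataclass
class RankedGroup:
    group: str
    tier: str
    evidence: list[str]
    docking_margin: float | None = None  # min of the two z-margin ratios
    context_ti: float | None = None
    context_compound: str | None = None

    @property
    def tier_rank(self) -> int:
        return TIER_ORDER[self.tier]


@dataclass
class EvidenceReport:
    query_id: str
    assigned_group: str | None
    assignment_score: float | None
    assignment_margin: float | None
    prior_groups: list[str]
    context: ContextPrediction | None
    docking_calls: list[BinderCall]
    ranking: list[RankedGroup]
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ran | skipped | ...

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "assigned_group": self.assigned_group,
            "assignment_score": self.assignment_score,
            "assignment_margin": self.assignment_margin,
            "prior_groups": self.prior_groups,
            "stages": self.stages,
            "context": None if self.context is None else {
                "status": self.context.status,
                "candidates": [
                    {"compound": c.compound_id, "source": c.source_gene,
                     "role": c.role, "gap_bp": c.gap_bp, "ti": c.ti}
                    for c in self.context.candidates
                ],
            },
            "docking_binders": [
                {"ligand": c.ligand, "group": c.group,
                 "margin_energy": c.margin_energy,
                 "margin_population": c.margin_population}
                for c in self.docking_calls if c.is_binder
            ],
            "ranking": [
                {"group": r.group, "tier": r.tier, "evidence": r.evidence,
                 "docking_margin": r.docking_margin, "context_ti": r.context_ti,
                 "context_compound": r.context_compound}
                for r in self.ranking
            ],
        }


def predict_substrate(
    query_id: str, query_seq: str, resources: Resources
) -> EvidenceReport:
    """Run the full workflow for one query sequence.

    Stages with missing resources are recorded as skipped; with nothing
    beyond the sequence the report still carries the phylogenetic
    assignment and its substrate-group prior.
    """
    res = resources
    stages: dict[str, str] = {}

    # --- stage 1: phylogenetic assignment + group prior -------------------
    group = score = margin = None
    prior: list[str] = []
    if res.references and res.reference_labels:
        group, score, margin = assign_group(
            query_seq, res.references, res.reference_labels
        )
        stages["phylogeny"] = "ran"
        if res.group_substrate_prior:
            prior = sorted(res.group_substrate_prior.get(group, []))
    else:
        stages["phylogeny"] = "skipped (no labelled references)"

    # --- stage 2: genomic context -----------------------------------------
    context_pred: ContextPrediction | None = None
    context_by_group: dict[str, tuple[float, str]] = {}  # group -> (score, compound)
    if res.genome is not None and res.target_gene_id is not None:
        nb = neighbors(res.target_gene_id, res.genome, res.max_gap_bp)
        context_pred = context_candidates(nb, res.library, res.context_reference_ids)
        stages["context"] = "ran" if context_pred.informative else "ran (no information)"
        for c in context_pred.candidates:
            comp = res.library.get(c.compound_id)
            if comp is None or comp.group is None:
                continue
            # proximity score stands in when no reference TI is available
            s = c.ti if c.ti is not None else 1.0 / (1.0 + c.gap_bp)
            if comp.group not in context_by_group or s > context_by_group[comp.group][0]:
                context_by_group[comp.group] = (s, c.compound_id)
    else:
        stages["context"] = "skipped (no genome annotations)"

    # --- stage 3: docking ---------------------------------------------------
    calls: list[BinderCall] = []
    docking_by_group: dict[str, float] = {}  # group -> best margin
    if res.dock_records and res.true_positive_ligand:
        zrecs, _ = zscore_table(list(res.dock_records))
        calls, info = call_binders(
            zrecs, res.true_positive_ligand, alpha=res.binder_alpha
        )
        stages["docking"] = "ran (degenerate panel)" if info["degenerate"] else "ran"
        for c in calls:
            if not c.is_binder:
                continue
            m = min(c.margin_energy, c.margin_population)
            if c.group not in docking_by_group or m > docking_by_group[c.group]:
                docking_by_group[c.group] = m
    else:
        stages["docking"] = "skipped (no docking table)"

    # --- combine ------------------------------------------------------------
    ranking: list[RankedGroup] = []
    all_groups = set(prior) | set(context_by_group) | set(docking_by_group)
    for g in all_groups:
        in_ctx = g in context_by_group
        in_dock = g in docking_by_group
        if in_ctx and in_dock:
            tier = "context+docking"
        elif in_dock:
            tier = "docking"
        elif in_ctx:
            tier = "context"
        else:
            tier = "phylogeny"
        evidence = []
        if in_ctx:
            evidence.append("context")
        if in_dock:
            evidence.append("docking")
        if g in prior:
            evidence.append("phylogeny-prior")
        ranking.append(
            RankedGroup(
                group=g, tier=tier, evidence=evidence,
                docking_margin=docking_by_group.get(g),
                context_ti=context_by_group.get(g, (None, None))[0],
                context_compound=context_by_group.get(g, (None, None))[1],
            )
        )
    ranking.sort(
        key=lambda r: (
            -r.tier_rank,
            -(r.docking_margin if r.docking_margin is not None else float("-inf")),
            -(r.context_ti if r.context_ti is not None else float("-inf")),
            r.group,
        )
    )
    return EvidenceReport(
        query_id=query_id, assigned_group=group, assignment_score=score,
        assignment_margin=margin, prior_groups=prior, context=context_pred,
        docking_calls=calls, ranking=ranking, stages=stages,
    )
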