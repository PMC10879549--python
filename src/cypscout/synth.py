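"""Synthetic benchmark worlds for every stage of the pipeline.

Each generator plants a known structure and returns the ground truth next
to the data, so parameter-recovery tests can score the pipeline without
any external download:

- compound libraries with planted substrate groups — high within-group and
  low between-group Tanimoto similarity;
- clade-structured trees with sequences evolved from per-clade ancestors;
- genomes where a producer gene adjacent to the target P450 makes the
  target's true substrate (the operon signal), buried among decoy genes;
- docking tables where planted binders are jointly extreme in energy and
  pose population;
- structure model/reference pairs related by a random rigid motion plus
  Gaussian coordinate noise of known scale.

All generators are deterministic in the configured seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .chemspace import Compound
from .context import GeneRecord, GenomeModel
from .docking import DockRecord
from .phylo import AMINO_ACIDS, LabeledTree, read_tree
from .structure import Atom, CoordinateSet

__all__ = [
    "WorldConfig",
    "SyntheticGenomes",
    "gen_compounds",
    "gen_tree_and_seqs",
    "gen_genomes",
    "default_binder_map",
    "panel_from_library",
    "gen_dock_table",
    "gen_structures",
    "run_end_to_end_benchmark",
]

# rng stream tags, one per generator, so worlds are independent per stage
_TAG_COMPOUNDS, _TAG_TREE, _TAG_GENOMES, _TAG_DOCK, _TAG_STRUCT = range(5)


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the synthetic world (one seed -> one world).

    Compound defaults mirror the observed separation of substrate groups
    (within-group TI above 0.6, between-group TI well under 0.35); the
    docking defaults mirror true binders sitting ~3 kcal/mol below and ~40
    runs above the decoy cloud out of 100 runs per docking.
    """

    seed: int = 0

    # compound library
    n_compound_groups: int = 17
    compounds_per_group: int = 8
    n_bits: int = 512
    scaffold_on_bits: int = 64
    intra_ti_range: tuple[float, float] = (0.6, 0.8)
    inter_ti_ceiling: float = 0.35
    design_cutoff: float = 0.45

    # tree / sequences
    n_clades: int = 6
    leaves_per_clade: int = 20
    divergence: float = 0.05  # expected substitutions/site, leaf from clade ancestor
    clade_divergence: float = 0.30
    seq_len: int = 300
    clade_depth: float = 0.40  # branch length root -> clade ancestor
    queries_per_clade: int = 5

    # genomes
    n_genomes: int = 200
    decoys_per_genome: int = 6
    planted_gap_bp: int = 800
    gene_len_bp: int = 900
    p_confuser: float = 0.02  # per genome: one decoy planted closer than the producer
    p_analog: float = 0.2  # producer makes a >=0.9-TI analog, not the substrate itself

    # docking
    n_receptors: int = 15
    binder_energy_offset: float = 3.0  # kcal/mol below the decoy mean
    binder_pop_offset: float = 0.4  # fraction of runs above the decoy mean
    energy_mu0: float = -6.0
    energy_sd: float = 1.0
    binder_energy_sd: float = 0.1
    pop_p0: float = 0.2
    binder_pop_sd: float = 1.0  # runs
    runs: int = 100
    n_promiscuous: int = 3
    promiscuous_extra_groups: int = 5  # bind own group plus this many others

    # structures
    n_residues: int = 200
    coord_noise_sd: float = 0.5  # Angstrom, per coordinate


def _rng(config: WorldConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


# ---------------------------------------------------------------------------
# Compounds
# ---------------------------------------------------------------------------

def gen_compounds(config: WorldConfig) -> list[Compound]:
    """Library with planted substrate groups in fingerprint space.

    Each group gets a random scaffold of ``scaffold_on_bits`` set bits;
    members replace a fixed number of scaffold bits with random off bits.
    The replacement count is derived from the midpoint of the intra-TI
    target range: two members differing from the scaffold in r bits each
    share at least (n_on - 2r) bits, so min intra-TI >= (n_on-2r)/(n_on+2r)
    deterministically.  Cross-group similarity stays near n_on/n_bits-level
    overlap and is asserted below the design cutoff after generation.
    """
    lo, hi = config.intra_ti_range
    if not 0 < lo < hi <= 1:
        raise ValueError(f"invalid intra-TI range {config.intra_ti_range}")
    if lo <= config.inter_ti_ceiling:
        raise ValueError(
            "infeasible design: intra-TI floor must exceed the inter-TI ceiling"
        )
    rng = _rng(config, _TAG_COMPOUNDS)
    n_on = config.scaffold_on_bits
    target = (lo + hi) / 2
    r = int(round(n_on * (1 - target) / (2 * (1 + target))))
    all_bits = np.arange(config.n_bits)
    compounds: list[Compound] = []
    for g in range(config.n_compound_groups):
        scaffold = set(rng.choice(all_bits, size=n_on, replace=False).tolist())
        off = np.array(sorted(set(range(config.n_bits)) - scaffold))
        for m in range(config.compounds_per_group):
            drop = set(rng.choice(sorted(scaffold), size=r, replace=False).tolist())
            add = set(rng.choice(off, size=r, replace=False).tolist())
            fp = frozenset((scaffold - drop) | add)
            compounds.append(
                Compound(
                    id=f"C_g{g + 1}_{m + 1}",
                    fingerprint=fp,
                    n_bits=config.n_bits,
                    group=f"g{g + 1}",
                )
            )
    _assert_separation(compounds, config)
    return compounds


def _assert_separation(compounds: Sequence[Compound], config: WorldConfig) -> None:
    """The generated world must satisfy its own design targets."""
    from .chemspace import tanimoto

    worst_inter = 0.0
    worst_intra = 1.0
    for a, b in itertools.combinations(compounds, 2):
        ti = tanimoto(a.fingerprint, b.fingerprint)
        if a.group == b.group:
            worst_intra = min(worst_intra, ti)
        else:
            worst_inter = max(worst_inter, ti)
    if worst_intra < config.design_cutoff:
        raise AssertionError(
            f"planted library violates design: min intra-TI {worst_intra:.3f} "
            f"< cutoff {config.design_cutoff}"
        )
    if worst_inter >= config.design_cutoff:
        raise AssertionError(
            f"planted library violates design: max inter-TI {worst_inter:.3f} "
            f">= cutoff {config.design_cutoff}"
        )


# ---------------------------------------------------------------------------
# Tree and sequences
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point substitutions at the given per-site probability."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_tree_and_seqs(
    config: WorldConfig,
) -> tuple[LabeledTree, dict[str, str], dict[str, str], dict[str, str], dict[str, str]]:
    """Clade-structured tree with evolved sequences and held-out queries.

    Returns ``(tree, leaf_seqs, leaf_labels, query_seqs, query_labels)``.
    Each clade descends from its own ancestor (diverged from a shared root
    sequence); leaves and queries are independent draws at the configured
    leaf divergence, so queries test assignment rather than memorisation.
    """
    rng = _rng(config, _TAG_TREE)
    letters = [chr(ord("A") + i) for i in range(config.n_clades)]
    root_seq = "".join(
        AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=config.seq_len)
    )
    clade_anc = {g: _mutate(root_seq, config.clade_divergence, rng) for g in letters}

    leaf_seqs: dict[str, str] = {}
    leaf_labels: dict[str, str] = {}
    clade_newicks = []
    for g in letters:
        parts = []
        for i in range(config.leaves_per_clade):
            lid = f"{g}{i + 1}"
            bl = config.divergence * rng.uniform(0.8, 1.2)
            parts.append(f"{lid}:{bl:.6f}")
            leaf_seqs[lid] = _mutate(clade_anc[g], config.divergence, rng)
            leaf_labels[lid] = g
        clade_newicks.append(f"({','.join(parts)}):{config.clade_depth:.6f}")
    newick = f"({','.join(clade_newicks)});"
    tree = read_tree(newick)

    query_seqs: dict[str, str] = {}
    query_labels: dict[str, str] = {}
    for g in letters:
        for i in range(config.queries_per_clade):
            qid = f"q{g}{i + 1}"
            query_seqs[qid] = _mutate(clade_anc[g], config.divergence, rng)
            query_labels[qid] = g
    return tree, leaf_seqs, leaf_labels, query_seqs, query_labels


# ---------------------------------------------------------------------------
# Genomes with planted operons
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomes:
    models: list[GenomeModel]
    target_ids: list[str]
    truth: dict[str, str]  # target gene id -> true substrate compound id
    analog_library: list[Compound]  # producer-product analogs added to the world


def gen_genomes(
    config: WorldConfig,
    library: Sequence[Compound],
    planted: bool = True,
) -> SyntheticGenomes:
    """Genomes whose target P450 sits next to the gene producing its substrate.

    Each genome carries one target gene, one producer neighbour within
    ``planted_gap_bp`` whose annotated product is the target's true
    substrate (or, with probability ``p_analog``, a >= 0.9-TI analog of
    it), and decoy genes with random compounds placed farther out.  With
    probability ``p_confuser`` a decoy lands closer than the producer —
    the irreducible noise of operon-based inference.  ``planted=False``
    drops the producer entirely (null world for base-rate controls).
    """
    rng = _rng(config, _TAG_GENOMES)
    lib = list(library)
    models: list[GenomeModel] = []
    targets: list[str] = []
    truth: dict[str, str] = {}
    analogs: list[Compound] = []
    glen = config.gene_len_bp
    for gi in range(config.n_genomes):
        contig = f"contig{gi + 1}"
        tid = f"t{gi + 1}_cyp"
        t_start = 50_000
        genes: dict[str, GeneRecord] = {
            tid: GeneRecord(gene_id=tid, contig=contig, start=t_start,
                            end=t_start + glen - 1, strand="+")
        }
        substrate = lib[rng.integers(len(lib))]
        truth[tid] = substrate.id
        used: list[tuple[int, int]] = [(t_start, t_start + glen - 1)]

        def place(gap: int, side: int) -> tuple[int, int]:
            # push outward until the interval is free on the chosen side
            while True:
                if side > 0:
                    s = t_start + glen + gap  # `gap` intervening bases after target end
                    e = s + glen - 1
                else:
                    e = t_start - gap - 1  # `gap` intervening bases before target start
                    s = e - glen + 1
                if all(e < a or s > b for a, b in used):
                    used.append((s, e))
                    return s, e
                gap += glen + 50

        producer_gap = None
        if planted:
            producer_gap = int(rng.integers(50, config.planted_gap_bp + 1))
            side = 1 if rng.random() < 0.5 else -1
            s, e = place(producer_gap, side)
            if rng.random() < config.p_analog:
                analog = _analog_of(substrate, rng, suffix=f"t{gi + 1}")
                analogs.append(analog)
                product_id = analog.id
            else:
                product_id = substrate.id
            pid = f"t{gi + 1}_producer"
            genes[pid] = GeneRecord(
                gene_id=pid, contig=contig, start=s, end=e,
                strand="+" if side > 0 else "-", products=[product_id],
            )
        confuser_idx = -1
        if planted and rng.random() < config.p_confuser:
            confuser_idx = int(rng.integers(config.decoys_per_genome))
        for d in range(config.decoys_per_genome):
            if d == confuser_idx:
                gap = int(rng.integers(0, max(producer_gap, 1)))
            else:
                base = (producer_gap or 0) + 200
                gap = int(rng.integers(base, base + 2600))
            side = 1 if rng.random() < 0.5 else -1
            s, e = place(gap, side)
            decoy_compound = lib[rng.integers(len(lib))]
            # a decoy annotated with the true substrate would not be a decoy
            while decoy_compound.group == substrate.group:
                decoy_compound = lib[rng.integers(len(lib))]
            did = f"t{gi + 1}_decoy{d + 1}"
            role = "products" if rng.random() < 0.5 else "substrates"
            rec = GeneRecord(gene_id=did, contig=contig, start=s, end=e,
                             strand="+" if side > 0 else "-")
            getattr(rec, role).append(decoy_compound.id)
            genes[did] = rec
        models.append(GenomeModel(genes=genes))
        targets.append(tid)
    return SyntheticGenomes(models=models, target_ids=targets, truth=truth,
                            analog_library=analogs)


def _analog_of(compound: Compound, rng: np.random.Generator, suffix: str) -> Compound:
    """A >= 0.9-TI analog: swap 2 on-bits for 2 off-bits."""
    on = sorted(compound.fingerprint)
    off = sorted(set(range(compound.n_bits)) - compound.fingerprint)
    drop = set(rng.choice(on, size=2, replace=False).tolist())
    add = set(rng.choice(off, size=2, replace=False).tolist())
    return Compound(
        id=f"{compound.id}_an_{suffix}",
        fingerprint=frozenset((set(on) - drop) | add),
        n_bits=compound.n_bits,
        group=compound.group,
    )


# ---------------------------------------------------------------------------
# Docking tables
# ---------------------------------------------------------------------------

def panel_from_library(library: Sequence[Compound]) -> list[Compound]:
    """Docking test panel: two ligands per group, plus a third in group g1.

    Mirrors the benchmark layout of two compounds per substrate group with
    one group contributing an extra ligand (17 groups -> a 35-ligand panel).
    """
    by_group: dict[str, list[Compound]] = {}
    for c in library:
        by_group.setdefault(c.group, []).append(c)
    panel: list[Compound] = []
    for g in sorted(by_group, key=lambda s: int(s.lstrip("g")) if s.lstrip("g").isdigit() else 0):
        take = 3 if g == "g1" else 2
        panel.extend(sorted(by_group[g], key=lambda c: c.id)[:take])
    return panel


def default_binder_map(
    config: WorldConfig, receptors: Sequence[str], panel: Sequence[Compound]
) -> tuple[dict[str, set[str]], dict[str, str], dict[str, str]]:
    """Planted binding truth: each receptor binds its own group's panel ligands.

    The first ``n_promiscuous`` receptors additionally bind the ligands of
    ``promiscuous_extra_groups`` further groups (so their planted group
    count matches the highly promiscuous regime of up to six groups).
    Returns ``(binder_map, receptor_group, true_positive)``.
    """
    groups = sorted({c.group for c in panel},
                    key=lambda s: int(s.lstrip("g")) if s.lstrip("g").isdigit() else 0)
    by_group: dict[str, list[str]] = {}
    for c in panel:
        by_group.setdefault(c.group, []).append(c.id)
    receptor_group: dict[str, str] = {}
    binder_map: dict[str, set[str]] = {}
    tp: dict[str, str] = {}
    for i, r in enumerate(receptors):
        g = groups[i % len(groups)]
        receptor_group[r] = g
        bound = set(by_group[g])
        if i < config.n_promiscuous:
            extra = [gg for gg in groups if gg != g][: config.promiscuous_extra_groups]
            for gg in extra:
                bound |= set(by_group[gg])
        binder_map[r] = bound
        tp[r] = sorted(by_group[g])[0]
    return binder_map, receptor_group, tp


def gen_dock_table(
    config: WorldConfig,
    receptors: Sequence[str],
    panel: Sequence[Compound],
    binder_map: Mapping[str, set[str]],
) -> list[DockRecord]:
    """Per-(receptor, ligand) best-pose energies and pose populations.

    Decoy pairs scatter widely (energy sd ~1 kcal/mol, binomial pose
    populations); planted binders sit ``binder_energy_offset`` kcal/mol
    lower and ``binder_pop_offset`` of the runs higher, with much smaller
    spread — true substrates dock reproducibly while decoys land in many
    shallow poses.
    """
    rng = _rng(config, _TAG_DOCK)
    records: list[DockRecord] = []
    for r in receptors:
        bound = binder_map.get(r, set())
        for c in panel:
            if c.id in bound:
                e = config.energy_mu0 - config.binder_energy_offset \
                    + rng.normal(0, config.binder_energy_sd)
                pop = (config.pop_p0 + config.binder_pop_offset) * config.runs \
                    + rng.normal(0, config.binder_pop_sd)
                pop = int(np.clip(round(pop), 0, config.runs))
            else:
                e = rng.normal(config.energy_mu0, config.energy_sd)
                pop = int(rng.binomial(config.runs, config.pop_p0))
            records.append(
                DockRecord(receptor=r, ligand=c.id, group=c.group,
                           energy_kcal=float(e), population=pop, runs=config.runs)
            )
    return records


# ---------------------------------------------------------------------------
# End-to-end benchmark
# ---------------------------------------------------------------------------

def run_end_to_end_benchmark(
    config: WorldConfig, n_queries: int = 60
) -> dict:
    """Full-workflow benchmark: is the planted substrate group ranked first?

    For each of ``n_queries`` synthetic targets, both evidence sources are
    available: the genome plants a producer of the true substrate next to
    the target, and a docking table for the query receptor plants binders
    from the true group (plus one unrelated group, mimicking partial
    promiscuity).  Returns the rank-1 rate and per-query details.
    """
    from .integrate import Resources, predict_substrate

    lib = gen_compounds(config)
    _, seqs, labels, qseqs, _ = gen_tree_and_seqs(config)
    genomes = gen_genomes(config, lib)
    libmap = {c.id: c for c in list(lib) + genomes.analog_library}
    panel = panel_from_library(lib)
    groups = sorted({c.group for c in panel})
    query_seq = next(iter(qseqs.values()))

    n = min(n_queries, len(genomes.models))
    n_rank1 = 0
    details = []
    for i in range(n):
        model, tid = genomes.models[i], genomes.target_ids[i]
        true_group = libmap[genomes.truth[tid]].group
        other = [g for g in groups if g != true_group]
        bound = {c.id for c in panel
                 if c.group == true_group or c.group == other[i % len(other)]}
        dock_cfg = replace(config, seed=(config.seed * 100_003 + i) % (2**31 - 1))
        records = gen_dock_table(dock_cfg, ["Q"], panel, {"Q": bound})
        tp = sorted(c.id for c in panel if c.group == true_group)[0]
        res = Resources(
            references=seqs, reference_labels=labels, library=libmap,
            genome=model, target_gene_id=tid,
            dock_records=records, true_positive_ligand=tp,
        )
        report = predict_substrate(tid, query_seq, res)
        top = report.ranking[0].group if report.ranking else None
        n_rank1 += top == true_group
        details.append({"target": tid, "true_group": true_group, "top": top})
    return {"rank1_rate": n_rank1 / n, "n": n, "details": details}


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def gen_structures(
    config: WorldConfig,
    noise: str = "whole",
    active_site_residues: Sequence[int] = (),
) -> tuple[CoordinateSet, CoordinateSet, dict]:
    """A reference CA trace and a model displaced by rigid motion + noise.

    The reference is a random walk with a 3.8 Å CA-CA step.  The model is
    the reference under a random proper rotation and translation, with
    Gaussian noise of sd ``coord_noise_sd`` per coordinate applied to the
    whole chain (``noise="whole"``), to the active-site residues only
    (``noise="active_site"``), or not at all (``noise="none"``).
    """
    from scipy.spatial.transform import Rotation

    rng = _rng(config, _TAG_STRUCT)
    n = config.n_residues
    steps = rng.normal(size=(n - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    reference = CoordinateSet(
        atoms=[Atom(res_id=i + 1, atom_name="CA", xyz=tuple(c)) for i, c in enumerate(coords)]
    )
    R = Rotation.random(random_state=np.random.RandomState(config.seed + 7)).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    moved = coords @ R.T + t
    if noise == "whole":
        moved = moved + rng.normal(0, config.coord_noise_sd, size=moved.shape)
    elif noise == "active_site":
        site = set(active_site_residues)
        mask = np.array([i + 1 in site for i in range(n)])
        moved[mask] += rng.normal(0, config.coord_noise_sd, size=(mask.sum(), 3))
    elif noise != "none":
        raise ValueError(f"unknown noise mode {noise!r}")
    model = CoordinateSet(
        atoms=[Atom(res_id=i + 1, atom_name="CA", xyz=tuple(c)) for i, c in enumerate(moved)]
    )
    return model, reference, {"noise_sd": config.coord_noise_sd, "mode": noise}
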