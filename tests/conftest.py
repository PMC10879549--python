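import numpy as np
import pytest

import cypscout as cs


@pytest.fixture(scope="session")
def world_cfg():
    return cs.WorldConfig(seed=1)


@pytest.fixture(scope="session")
def library(world_cfg):
    return cs.gen_compounds(world_cfg)


@pytest.fixture(scope="session")
def sim_matrix(library):
    # a 40-compound slice keeps the O(n^2) fixtures quick
    return cs.similarity_matrix(library[:40])


@pytest.fixture(scope="session")
def tree_world(world_cfg):
    tree, seqs, labels, qseqs, qlabels = cs.gen_tree_and_seqs(world_cfg)
    return {"tree": tree, "seqs": seqs, "labels": labels,
            "queries": qseqs, "query_labels": qlabels}


@pytest.fixture(scope="session")
def genome_world(world_cfg, library):
    genomes = cs.gen_genomes(world_cfg, library)
    libmap = {c.id: c for c in list(library) + genomes.analog_library}
    return {"genomes": genomes, "libmap": libmap}


@pytest.fixture(scope="session")
def dock_world(world_cfg, library):
    panel = cs.panel_from_library(library)
    receptors = [f"R{i + 1}" for i in range(world_cfg.n_receptors)]
    binder_map, receptor_group, tp = cs.default_binder_map(world_cfg, receptors, panel)
    records = cs.gen_dock_table(world_cfg, receptors, panel, binder_map)
    by_receptor = {}
    for r in records:
        by_receptor.setdefault(r.receptor, []).append(r)
    return {"panel": panel, "receptors": receptors, "binder_map": binder_map,
            "receptor_group": receptor_group, "tp": tp, "records": records,
            "by_receptor": by_receptor}
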