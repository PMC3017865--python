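"""Shared fixtures: synthetic panels and full pipeline runs.

The default panel (4 genomes x 500 proteins, 100 families, within-family
identity 0.8, seed 42) is expensive to generate and align, so it is built
once per session; the mini panel covers the same structure at a fraction
of the size for faster unit-level checks.
"""

from __future__ import annotations

import pytest

from lacogs.pipeline import run_pipeline
from lacogs.synthetic import SyntheticConfig, generate


def run_full(ds, config=None):
    return run_pipeline(
        ds.genomes,
        config,
        scl_table=ds.scl_table,
        domain_map=ds.domain_map,
        reference_hits=ds.reference_hits,
        surface_domains=ds.surface_domains,
    )


def partition_labels(ds, res):
    """(true, predicted) cluster labels over non-fragment proteins.

    Assembled pseudoproteins stand in for their consumed fragments and
    inherit the fragments' planted family; unclustered proteins get unique
    singleton labels on both sides.
    """
    truth = ds.truth
    mem = res.membership
    asm_fam = {
        a.assembly_id: truth.family_of[a.fragment_ids[0]] for a in res.assemblies
    }
    pids = [
        p.protein_id
        for p in ds.all_proteins()
        if p.protein_id not in res.consumed_fragments
    ]
    pids += [a.assembly_id for a in res.assemblies]
    lt = [truth.family_of.get(p) or asm_fam.get(p) or f"s{i}" for i, p in enumerate(pids)]
    lp = [mem.get(p, f"u{i}") for i, p in enumerate(pids)]
    return lt, lp


MINI = SyntheticConfig(
    n_genomes=4,
    proteins_per_genome=120,
    n_families=20,
    n_pseudogene_pairs=4,
    n_missing_one_families=3,
    n_niche_specific_families=2,
    n_species_specific_families=2,
    seed=7,
)


@pytest.fixture(scope="session")
def mini_dataset():
    return generate(MINI)


@pytest.fixture(scope="session")
def mini_result(mini_dataset):
    return run_full(mini_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return run_full(default_dataset)
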