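from __future__ import annotations

import numpy as np
import pytest

from unigroup.cli import PipelineInputs, run_stages
from unigroup.group_builder import GeneGroup, PipelineConfig
from unigroup import group_builder as gb
from unigroup.seqio import PeptideRecord
from unigroup.synthetic_data import SimConfig, SimulatedDataset, simulate_dataset

ACCEPT_SEED = 1729


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_inputs(ds: SimulatedDataset) -> PipelineInputs:
    return PipelineInputs(
        pepsets=ds.pepsets,
        ortholog_tables=ds.ortholog_tables,
        genomes=ds.genomes,
        annotations=ds.annotations,
        outgroup_panel=ds.outgroup_panel,
    )


def make_config(ds: SimulatedDataset, **overrides) -> PipelineConfig:
    return PipelineConfig(
        species_order=ds.config.species,
        reference_species=ds.config.reference_species,
        **overrides,
    )


def group_from_members(gid: str, members: dict[str, str], config: PipelineConfig,
                       status: str = "universal") -> GeneGroup:
    """Finalized group directly from {species: sequence} (test scaffolding)."""
    recs = {
        sp: PeptideRecord(pep_id=f"{gid}_{sp}", gene_id=f"{gid}_{sp}",
                          species=sp, sequence=seq)
        for sp, seq in members.items()
    }
    g = GeneGroup(group_id=gid, ref_record=recs[config.species_order[0]])
    g.members = recs
    gb._build_profile(g, config)
    gb._recompute_member_R(g)
    g.status = status
    return g


@pytest.fixture(scope="session")
def sim_small() -> SimulatedDataset:
    return simulate_dataset(
        SimConfig(seed=11, n_universal_families=10, n_decoy_families=4,
                  n_duplicated_families=1, annotation_dropout_fraction=0.1,
                  mean_peptide_length=200)
    )


@pytest.fixture(scope="session")
def small_config(sim_small) -> PipelineConfig:
    return make_config(sim_small)


@pytest.fixture(scope="session")
def small_result(sim_small, small_config):
    return run_stages(make_inputs(sim_small), small_config)


# --- shared full-scale acceptance fixtures (simulator defaults) ---


@pytest.fixture(scope="session")
def accept_dataset() -> SimulatedDataset:
    return simulate_dataset(SimConfig(seed=ACCEPT_SEED))


@pytest.fixture(scope="session")
def accept_config(accept_dataset) -> PipelineConfig:
    return make_config(accept_dataset)


@pytest.fixture(scope="session")
def accept_result(accept_dataset, accept_config):
    return run_stages(make_inputs(accept_dataset), accept_config)


@pytest.fixture(scope="session")
def nodrop_dataset() -> SimulatedDataset:
    return simulate_dataset(SimConfig(seed=ACCEPT_SEED, annotation_dropout_fraction=0.0))


@pytest.fixture(scope="session")
def nodrop_result(nodrop_dataset):
    return run_stages(make_inputs(nodrop_dataset), make_config(nodrop_dataset))


def group_to_family(group: GeneGroup, ds: SimulatedDataset) -> dict[str, int]:
    """How many of a group's members belong to each planted family.

    A member counts for a family when its pep_id or exact sequence matches
    the planted member for that species.
    """
    counts: dict[str, int] = {}
    for sp, rec in group.members.items():
        for fid, fam in ds.truth.families.items():
            m = fam.members.get(sp)
            if m is not None and (m.pep_id == rec.pep_id or m.sequence == rec.sequence):
                counts[fid] = counts.get(fid, 0) + 1
    return counts


def best_family(group: GeneGroup, ds: SimulatedDataset) -> str | None:
    counts = group_to_family(group, ds)
    if not counts:
        return None
    return max(sorted(counts), key=lambda fid: counts[fid])
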