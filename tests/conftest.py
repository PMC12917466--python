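import dendropy
import numpy as np
import pytest

from camtraits.drying import DryingCurveRecord, Environment


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted",
        preserve_underscores=True,
    )


@pytest.fixture
def three_tip_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return tree_from_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def five_tip_tree():
    return tree_from_newick("(((A:0.5,B:0.5):0.5,C:1.0):1.0,(D:1.5,E:1.5):0.5);")


def make_record(
    times, masses, mass_saturated=None, mass_dry=0.20, mass_wax=0.05,
    area_saturated=2e-3, env=None, leaf_id="L1", taxon="tx",
):
    """Hand-built drying record for arithmetic tests."""
    times = np.asarray(times, dtype=float)
    masses = np.asarray(masses, dtype=float)
    return DryingCurveRecord(
        leaf_id=leaf_id,
        taxon=taxon,
        times=times,
        masses=masses,
        mass_saturated=float(masses[0] if mass_saturated is None else mass_saturated),
        mass_dry=mass_dry,
        mass_wax=mass_wax,
        area_saturated=area_saturated,
        environment=env or Environment(),
    )


@pytest.fixture(scope="session")
def small_study():
    """One shared small synthetic study for pipeline-level tests."""
    from camtraits.simulate import simulate_study

    return simulate_study(
        n_taxa=12, n_singleton_taxa=3, replicates_per_group=3,
        leaves_per_taxon=2, seed=11,
    )
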