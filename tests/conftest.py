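import pytest

import weanflux as wf
from weanflux.synth import ArchetypeSpec, gen_taxon


def make_linear_taxon(taxon_id, substrate, yield_gdw, products=None, cofactors=None):
    """One-substrate linear fermenter: mu = yield * uptake."""
    spec = ArchetypeSpec(
        archetype="generalist",
        substrate_yields={substrate: (yield_gdw, dict(products or {}))},
        cofactor_requirements=dict(cofactors or {}),
    )
    return gen_taxon(spec, taxon_id)


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic screening scenario (10 genera, 12 foods, seed 7)."""
    return wf.gen_scenario(n_taxa=10, n_foods=12, seed=7)


@pytest.fixture(scope="session")
def scenario_community(scenario):
    profile = wf.renormalize(wf.filter_abundances(scenario.profile, 0.01))
    models = [scenario.models[t] for t in profile.entries]
    return wf.assemble_community(models, profile), profile


@pytest.fixture(scope="session")
def scenario_screen(scenario, scenario_community):
    """Full screen of the default scenario (12 singles + 66 pairs + control)."""
    community, profile = scenario_community
    results = wf.run_screen(
        scenario.foods, scenario.absorbable, community, profile, pairs=scenario.pairs
    )
    return results
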