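import numpy as np
import pytest

import gutcom as g

#: master seed for every randomized test artifact in the suite
MASTER_SEED = 123


@pytest.fixture(scope="session")
def toy3():
    models, diet, policy = g.toy3_fixture()
    return models, diet, policy


@pytest.fixture(scope="session")
def toy3_community(toy3):
    models, diet, policy = toy3
    return g.build_community(models, diet, policy)


@pytest.fixture(scope="session")
def toy3_opt(toy3_community):
    return g.maximize_community_growth(toy3_community)


@pytest.fixture(scope="session")
def demo8():
    return g.make_toy_community(g.demo8_spec())


@pytest.fixture(scope="session")
def demo8_community(demo8):
    models, diet, policy = demo8
    return g.build_community(models, diet, policy)


@pytest.fixture(scope="session")
def demo8_opt(demo8_community):
    return g.maximize_community_growth(demo8_community)


@pytest.fixture(scope="session")
def demo8_fva(demo8_community, demo8_opt):
    levels = sorted(g.tradeoff.DEFAULT_SCHEDULE)
    return {
        f: g.abundance_fva(demo8_community, f, demo8_opt.mu, keep_solutions=False)
        for f in levels
    }


@pytest.fixture(scope="session")
def demo8_campaign(demo8_community, demo8_opt, demo8_fva):
    """Reduced campaign: 9 levels x 10 cases, fixed master seed."""
    schedule = g.CampaignSchedule.reduced(10, master_seed=MASTER_SEED)
    cases = g.run_campaign(demo8_community, demo8_opt.mu, demo8_fva, schedule)
    return schedule, cases
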