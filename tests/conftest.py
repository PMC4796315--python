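import numpy as np
import pandas as pd
import pytest

from spongenet.io import ExpressionCohort, RunConfig
from spongenet.pipeline import infer_network
from spongenet.simulate import default_design, simulate_catalog_and_sites, simulate_expression
from spongenet.targets import MirnaFamily, profiles_from_site_table


@pytest.fixture(scope="session")
def tiny_catalog():
    """Three families with distinct seeds and known member counts."""
    return {
        MirnaFamily("f1", "AAGGCAC", frozenset({"miR-1a", "miR-1b"})),
        MirnaFamily("f2", "CTGTGAC", frozenset({"miR-2a", "miR-2b", "miR-2c"})),
        MirnaFamily("f3", "GGACTTA", frozenset({"miR-3"})),
    }


@pytest.fixture(scope="session")
def standard_truth():
    """One realisation of the standard recovery design (5 planted pairs)."""
    design = default_design(rng_seed=1)
    catalog, sites, truth = simulate_catalog_and_sites(design)
    return catalog, sites, truth


@pytest.fixture(scope="session")
def standard_cohorts(standard_truth):
    _, _, truth = standard_truth
    return simulate_expression(truth)


@pytest.fixture(scope="session")
def standard_network(standard_truth, standard_cohorts):
    catalog, sites, truth = standard_truth
    profiles = profiles_from_site_table(sites, truth.biotypes, catalog)
    lnc = {g: p for g, p in profiles.items() if truth.biotypes[g] == "lncRNA"}
    pcg = {g: p for g, p in profiles.items() if truth.biotypes[g] == "PCG"}
    pairs, network = infer_network(lnc, pcg, standard_cohorts, RunConfig(), catalog=catalog)
    return pairs, network


def make_cohort(cohort_id, values_by_gene, states, cn_status=None):
    """Small hand-built cohort from per-gene value lists."""
    n = len(states)
    sample_ids = [f"{cohort_id}_s{i}" for i in range(n)]
    values = pd.DataFrame(
        {s: [values_by_gene[g][i] for g in values_by_gene] for i, s in enumerate(sample_ids)},
        index=list(values_by_gene),
    )
    meta = pd.DataFrame(
        {"cohort": cohort_id, "state": list(states)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if cn_status is not None:
        meta["cn_status"] = list(cn_status)
    return ExpressionCohort(cohort_id=cohort_id, values=values, metadata=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
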