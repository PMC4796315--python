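"""Benchmark routines: planted-truth recovery, null calibration, matcher checks.

These run the whole pipeline on freshly simulated data and measure how
well it behaves: precision/recall against planted sponge pairs, the
false-edge rate under a decoupled (beta = 0) null, and the empirical
type-I error of the two primitive one-tailed tests under their
respective nulls.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .io import RunConfig
from .pipeline import SpongeNetwork, infer_network
from .simulate import (
    SimulationTruth,
    default_design,
    simulate_catalog_and_sites,
    simulate_expression,
)
from .stats import pearson_r_to_p_greater
from .targets import profiles_from_site_table

__all__ = [
    "run_standard_inference",
    "recovery_metrics",
    "recovery_benchmark",
    "null_benchmark",
    "share_test_type_i_error",
    "correlation_type_i_error",
]


def run_standard_inference(
    seed: int, beta: float = 0.8, config: RunConfig | None = None
) -> tuple[SimulationTruth, list, SpongeNetwork]:
    """Simulate the standard recovery design at one seed and infer the network."""
    design = default_design(rng_seed=seed, beta_repression=beta)
    catalog, sites, truth = simulate_catalog_and_sites(design)
    cohorts = simulate_expression(truth)
    profiles = profiles_from_site_table(sites, truth.biotypes, catalog)
    lnc = {g: p for g, p in profiles.items() if truth.biotypes[g] == "lncRNA"}
    pcg = {g: p for g, p in profiles.items() if truth.biotypes[g] == "PCG"}
    pairs, network = infer_network(lnc, pcg, cohorts, config or RunConfig(), catalog=catalog)
    return truth, pairs, network


def recovery_metrics(network: SpongeNetwork, truth: SimulationTruth) -> tuple[float, float]:
    """Precision and recall of inferred edges against the planted truth.

    Precision is defined as 1 when no edge is emitted (no false calls).
    """
    found = {(e.lnc_id, e.pcg_id) for e in network.edges}
    tp = len(found & truth.true_edges)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(truth.true_edges) if truth.true_edges else 1.0
    return precision, recall


def recovery_benchmark(n_seeds: int = 25, base_seed: int = 0, beta: float = 0.8) -> dict:
    """Median precision/recall over independent simulated studies."""
    precisions, recalls = [], []
    for i in range(n_seeds):
        truth, _, network = run_standard_inference(_derive_seed(base_seed, i), beta=beta)
        p, r = recovery_metrics(network, truth)
        precisions.append(p)
        recalls.append(r)
    return {
        "n_seeds": n_seeds,
        "precision_median": float(np.median(precisions)),
        "recall_median": float(np.median(recalls)),
        "precisions": precisions,
        "recalls": recalls,
    }


def null_benchmark(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Edge counts under the beta = 0 global null (expression decoupled)."""
    edge_counts = []
    for i in range(n_seeds):
        _, _, network = run_standard_inference(_derive_seed(base_seed, i), beta=0.0)
        edge_counts.append(len(network.edges))
    edge_counts = np.asarray(edge_counts)
    return {
        "n_seeds": n_seeds,
        "zero_edge_fraction": float(np.mean(edge_counts == 0)),
        "max_edges": int(edge_counts.max()),
        "edge_counts": edge_counts.tolist(),
    }


def _derive_seed(base_seed: int, i: int) -> int:
    return (int(base_seed) * 100_000 + i) % (2**31)


def share_test_type_i_error(
    alpha: float, n_replicates: int = 10_000, seed: int = 0, universe: int = 5000
) -> float:
    """Empirical type-I error of the shared-family enrichment test.

    Each replicate assigns every family of a large universe independently
    to two genes with probability 1/2 (random site assignment); the
    shared count is then hypergeometric under the null.  A large universe
    keeps the attainable p-value lattice dense; at small universe sizes
    the discrete test is conservative rather than calibrated.
    """
    rng = np.random.default_rng(seed)
    m = rng.binomial(universe, 0.5, size=n_replicates)
    n = rng.binomial(universe, 0.5, size=n_replicates)
    k = sps.hypergeom.rvs(universe, n, m, random_state=rng)
    p = sps.hypergeom.sf(k - 1, universe, n, m)
    p = np.where(k == 0, 1.0, p)  # the test reports exactly 1 for k = 0
    return float(np.mean(p <= alpha))


def correlation_type_i_error(
    alpha: float, n_replicates: int = 10_000, n: int = 100, seed: int = 0
) -> float:
    """Empirical type-I error of the one-tailed Pearson test on Gaussian noise."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_replicates, n))
    y = rng.standard_normal((n_replicates, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    p = pearson_r_to_p_greater(r, n)
    return float(np.mean(p <= alpha))
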