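"""The three-step sponge-lncRNA selection cascade.

For every lncRNA / protein-coding driver gene pair:

1. combine the shared-miRNA enrichment p-value (one-tailed Fisher's exact
   test over the seed-family universe, P1) with the one-tailed Pearson
   co-expression p-value in the discovery cohort (P2) via Fisher's
   method, and keep pairs whose BH-adjusted combined p-value (q) is at
   most the FDR threshold;
2. require at least ``min_shared_mirnas`` shared miRNAs and at least
   ``min_unique_sites`` unique targeting sites for the shared families
   (miRNAs sharing a seed target the same site, so sites are counted at
   family level);
3. require at least moderate positive co-expression (r >= 0.25 by
   default) in every cohort, so the signal replicates in an independent
   sample.

The FDR adjustment is computed once, jointly over all scored pairs; pairs
sharing no family enter the pool with P1 = 1 so the denominator is
well-defined.  Edges of the resulting bipartite network are the pairs
passing all three filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import ExpressionCohort, RunConfig
from .stats import (
    ConstantVectorError,
    bh_fdr,
    fisher_share_test,
    fishers_method,
    mann_whitney_two_tailed,
    pearson_one_tailed,
)
from .targets import GeneSiteProfile, MirnaFamily, shared_mre_summary

__all__ = ["PairStats", "SpongeNetwork", "select_driver_genes", "score_pair", "infer_network"]

logger = logging.getLogger(__name__)


@dataclass
class PairStats:
    """All per-pair statistics and filter flags for one lncRNA/PCG pair."""

    lnc_id: str
    pcg_id: str
    n_shared_mirnas: int
    n_shared_families: int
    unique_sites_lnc: int
    unique_sites_pcg: int
    p_share: float
    r_discovery: float
    p_corr: float
    chi2: float
    p_combined: float
    q_value: float = float("nan")
    r_by_cohort: dict[str, float] = field(default_factory=dict)
    pass_fdr: bool = False
    pass_counts: bool = False
    pass_replication: bool = False

    @property
    def r_replication(self) -> float:
        """Worst-case correlation over cohorts — the binding replication value."""
        if not self.r_by_cohort:
            return float("nan")
        return min(self.r_by_cohort.values())

    @property
    def is_edge(self) -> bool:
        return self.pass_fdr and self.pass_counts and self.pass_replication


@dataclass
class SpongeNetwork:
    """Bipartite sp-lncRNA -> driver-gene network of pairs passing all filters."""

    edges: list[PairStats]

    @property
    def lnc_nodes(self) -> set[str]:
        return {e.lnc_id for e in self.edges}

    @property
    def pcg_nodes(self) -> set[str]:
        return {e.pcg_id for e in self.edges}

    @property
    def per_pcg_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.pcg_id] = counts.get(e.pcg_id, 0) + 1
        return counts


def select_driver_genes(
    cohort: ExpressionCohort, driver_list: set[str], alpha: float = 0.01
) -> set[str]:
    """Keep driver genes differentially expressed across disease states.

    A driver qualifies if the two-tailed Mann-Whitney U test gives
    p <= alpha for normal vs primary or for primary vs metastatic.
    """
    by_state = {}
    for state in ("normal", "primary", "metastatic"):
        samples = cohort.samples_in_states([state])
        if not samples:
            raise ValueError(f"cohort {cohort.cohort_id!r} has no samples in state {state!r}")
        by_state[state] = samples

    selected: set[str] = set()
    for gene in sorted(driver_list):
        if gene not in cohort.values.index:
            logger.warning("driver gene %s absent from cohort %s; skipped", gene, cohort.cohort_id)
            continue
        for a_state, b_state in (("normal", "primary"), ("primary", "metastatic")):
            res = mann_whitney_two_tailed(
                cohort.expression(gene, by_state[a_state]),
                cohort.expression(gene, by_state[b_state]),
            )
            if res.p_value <= alpha:
                selected.add(gene)
                break
    return selected


def _passes_counts(stats: PairStats, config: RunConfig) -> bool:
    if config.shared_count_unit == "mirnas":
        enough_shared = stats.n_shared_mirnas >= config.min_shared_mirnas
    else:
        enough_shared = stats.n_shared_families >= config.min_shared_mirnas
    if config.site_count_rule == "min":
        sites = min(stats.unique_sites_lnc, stats.unique_sites_pcg)
    elif config.site_count_rule == "lnc":
        sites = stats.unique_sites_lnc
    else:
        sites = stats.unique_sites_lnc + stats.unique_sites_pcg
    return enough_shared and sites >= config.min_unique_sites


def score_pair(
    lnc: GeneSiteProfile,
    pcg: GeneSiteProfile,
    discovery: ExpressionCohort,
    universe: set[MirnaFamily] | int,
    config: RunConfig,
    catalog: set[MirnaFamily] | None = None,
) -> PairStats:
    """Score one lncRNA/PCG pair in the discovery cohort (q-value unset).

    ``universe`` is the usable family catalog conditioning the
    shared-miRNA enrichment test, or its size as a plain integer (in
    which case ``catalog`` must supply the family definitions for member
    expansion).  Correlation uses the samples whose disease state is in
    ``config.correlation_sample_states`` (tumours only by default).

    Raises
    ------
    ConstantVectorError
        If either gene's expression is constant over the correlation
        samples; callers skip the pair with a warning.
    """
    if isinstance(universe, int):
        universe_size = universe
        if catalog is None:
            raise ValueError("an integer universe size requires the family catalog")
        fam_map = {f.family_id: f for f in catalog if f.usable}
    else:
        usable = [f for f in universe if f.usable]
        universe_size = len(usable)
        fam_map = {f.family_id: f for f in usable}
    if not fam_map:
        raise ValueError("score_pair requires a non-empty usable family catalog")

    summary = shared_mre_summary(lnc, pcg, fam_map)
    m_lnc = len(lnc.families & fam_map.keys())
    n_pcg = len(pcg.families & fam_map.keys())
    k = len(summary.shared_families)
    share = fisher_share_test(k, m_lnc, n_pcg, universe_size)

    samples = discovery.samples_in_states(config.correlation_sample_states)
    corr = pearson_one_tailed(
        discovery.expression(lnc.gene_id, samples),
        discovery.expression(pcg.gene_id, samples),
    )
    chi2, p_combined = fishers_method(share.p_value, corr.p_value)
    return PairStats(
        lnc_id=lnc.gene_id,
        pcg_id=pcg.gene_id,
        n_shared_mirnas=summary.n_shared_mirnas,
        n_shared_families=k,
        unique_sites_lnc=summary.unique_sites_lnc,
        unique_sites_pcg=summary.unique_sites_pcg,
        p_share=share.p_value,
        r_discovery=corr.statistic,
        p_corr=corr.p_value,
        chi2=chi2,
        p_combined=p_combined,
    )


def infer_network(
    lnc_profiles: dict[str, GeneSiteProfile],
    pcg_profiles: dict[str, GeneSiteProfile],
    cohorts: list[ExpressionCohort],
    config: RunConfig,
    catalog: set[MirnaFamily] | None = None,
) -> tuple[list[PairStats], SpongeNetwork]:
    """Run the full selection cascade over all lncRNA x driver pairs.

    Returns every scored pair (with q-values and flags) and the network
    of pairs passing FDR, count and replication filters.  The combined
    p-value uses the discovery cohort only; every cohort (discovery
    included) must independently show r >= ``config.min_replication_r``.
    """
    if len(cohorts) < 2:
        raise ValueError("replication filtering requires at least 2 cohorts")
    by_id = {c.cohort_id: c for c in cohorts}
    discovery_id = config.discovery_cohort or cohorts[0].cohort_id
    if discovery_id not in by_id:
        raise ValueError(f"discovery cohort {discovery_id!r} not among {sorted(by_id)}")
    discovery = by_id[discovery_id]

    if catalog is None:
        raise ValueError("infer_network requires the miRNA family catalog")
    usable = {f for f in catalog if f.usable}

    pairs: list[PairStats] = []
    for lnc_id in sorted(lnc_profiles):
        for pcg_id in sorted(pcg_profiles):
            try:
                stats = score_pair(
                    lnc_profiles[lnc_id], pcg_profiles[pcg_id], discovery, usable, config
                )
            except ConstantVectorError:
                logger.warning(
                    "pair (%s, %s) skipped: constant expression in discovery cohort",
                    lnc_id,
                    pcg_id,
                )
                continue
            for cohort in cohorts:
                samples = cohort.samples_in_states(config.correlation_sample_states)
                try:
                    res = pearson_one_tailed(
                        cohort.expression(lnc_id, samples), cohort.expression(pcg_id, samples)
                    )
                except ConstantVectorError:
                    logger.warning(
                        "pair (%s, %s): constant expression in cohort %s; r set to nan",
                        lnc_id,
                        pcg_id,
                        cohort.cohort_id,
                    )
                    stats.r_by_cohort[cohort.cohort_id] = float("nan")
                    continue
                stats.r_by_cohort[cohort.cohort_id] = res.statistic
            pairs.append(stats)

    q_values = bh_fdr([p.p_combined for p in pairs])
    for stats, q in zip(pairs, q_values):
        stats.q_value = float(q)
        stats.pass_fdr = stats.q_value <= config.fdr_threshold
        stats.pass_counts = _passes_counts(stats, config)
        rep = stats.r_replication
        stats.pass_replication = bool(rep == rep and rep >= config.min_replication_r)

    network = SpongeNetwork(edges=[p for p in pairs if p.is_edge])
    logger.info(
        "scored %d pairs; %d edges pass FDR<=%g, counts and replication r>=%g",
        len(pairs),
        len(network.edges),
        config.fdr_threshold,
        config.min_replication_r,
    )
    return pairs, network
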