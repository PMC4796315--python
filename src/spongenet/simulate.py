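"""Synthetic two-cohort data with planted sponge (ceRNA) structure.

The generator emulates the study design the inference assumes: two
independent tumour cohorts of log2 expression over lncRNAs and
protein-coding genes, a conserved miRNA-family catalog, and transcript
sequences carrying canonical seed-match sites.  Selected lncRNA/PCG pairs
are "planted" with a block of shared seed families and enough unique
sites on both genes; all remaining gene/family assignments are sparse and
random, so non-planted pairs share families only by chance.

Co-expression of MRE-sharing genes arises through shared latent miRNA
activity: per cohort and sample, each family has an activity
``a[f, s] ~ N(0, 1)`` and every gene is repressed proportionally to its
(capped) site count for that family,

    x[g, s] = mu_g + state_shift * 1[state != normal] + cn_effect[g, s]
              - beta_repression * sum_f min(S[g, f], 4) * a[f, s] + eps,

with ``eps ~ N(0, noise_sd^2)``.  Activities are drawn independently per
cohort, so cross-cohort replication of a correlation is a genuine second
test.  Activities are latent: they are never written out as data.

All random draws are keyed per entity (gene, family, cohort), so adding
genes to a design does not perturb the draws of existing genes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ExpressionCohort,
    SiteTableRecord,
    TargetSiteTable,
    write_biotypes,
    write_expression_matrix,
    write_fasta,
    write_mirna_catalog,
    write_site_table,
)
from .targets import MirnaFamily, revcomp

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "default_design",
    "simulate_catalog_and_sites",
    "simulate_expression",
    "write_dataset",
    "SITE_CAP",
]

#: Site-count cap in the repression term (log2-scale saturation).
SITE_CAP = 4

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic two-cohort study."""

    n_families: int = 60
    members_per_family: tuple[int, int] = (1, 3)
    n_lnc: int = 30
    n_pcg: int = 10
    planted_pairs: tuple[tuple[str, str, int], ...] = ()
    beta_repression: float = 0.8
    noise_sd: float = 1.0
    n_samples_by_state: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 50, "primary": 50, "metastatic": 50}
    )
    n_cohorts: int = 2
    state_shift: float = 2.0
    cn_loss_fraction: float = 0.3
    cn_loss_effect: float = -1.5
    cn_gene: str | None = None
    min_unique_sites: int = 8
    bg_site_prob: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    spacer_len: int = 25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.beta_repression < 0:
            raise ValueError("beta_repression must be non-negative")
        if self.cn_loss_effect > 0:
            raise ValueError("cn_loss_effect must be <= 0")
        genes = set(self.lnc_ids) | set(self.pcg_ids)
        for lnc, pcg, k in self.planted_pairs:
            if lnc not in genes or pcg not in genes:
                raise ValueError(f"planted pair ({lnc}, {pcg}) references undeclared genes")
            if k > self.n_families:
                raise ValueError(
                    f"planted pair ({lnc}, {pcg}) requests {k} shared families, "
                    f"catalog has only {self.n_families}"
                )

    @property
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i + 1:03d}" for i in range(self.n_lnc)]

    @property
    def pcg_ids(self) -> list[str]:
        return [f"PCG{i + 1:03d}" for i in range(self.n_pcg)]

    @property
    def cohort_ids(self) -> list[str]:
        return [f"cohort{i + 1}" for i in range(self.n_cohorts)]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated study: who shares what, and why."""

    design: SimulationDesign
    site_counts: pd.DataFrame  # genes x families, planted+background site counts
    activities: dict[str, np.ndarray]  # cohort -> families x samples latent matrix
    true_edges: frozenset[tuple[str, str]]
    planted_sites: list[SiteTableRecord] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    biotypes: dict[str, str] = field(default_factory=dict)
    catalog: set = field(default_factory=set)
    site_table: TargetSiteTable = field(default_factory=TargetSiteTable)


def default_design(rng_seed: int = 0, **overrides) -> SimulationDesign:
    """The standard recovery design: 5 planted pairs, 12 shared families each."""
    planted = tuple((f"LNC{i + 1:03d}", f"PCG{i + 1:03d}", 12) for i in range(5))
    base = SimulationDesign(planted_pairs=planted, cn_gene="LNC001", rng_seed=rng_seed)
    return replace(base, **overrides) if overrides else base


def _rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic per-entity generator keyed by (seed, tags)."""
    key = zlib.crc32("|".join(str(t) for t in tags).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def simulate_catalog_and_sites(design: SimulationDesign):
    """Generate the miRNA catalog, transcript sequences and site table.

    Returns ``(catalog, site_table, truth)``.  Planted sites are embedded
    in the emitted sequences so that the canonical seed matcher
    rediscovers them exactly at their recorded coordinates.
    """
    seed = design.rng_seed

    # --- catalog: unique 7-nt seeds, members, all conserved and expressed
    rng_cat = _rng(seed, "catalog")
    seeds: list[str] = []
    seen: set[str] = set()
    while len(seeds) < design.n_families:
        s = _random_seq(rng_cat, 7)
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    lo, hi = design.members_per_family
    catalog: set[MirnaFamily] = set()
    fam_ids = [f"fam{i + 1:03d}" for i in range(design.n_families)]
    for fid, s in zip(fam_ids, seeds):
        n_members = int(rng_cat.integers(lo, hi + 1))
        members = frozenset(f"{fid}-miR{j + 1}" for j in range(n_members))
        catalog.add(MirnaFamily(family_id=fid, seed_2_8=s, member_mirnas=members))
    fam_by_id = {f.family_id: f for f in sorted(catalog, key=lambda f: f.family_id)}

    # --- allocate disjoint family blocks to planted pairs
    rng_plant = _rng(seed, "plant")
    shuffled = list(fam_ids)
    rng_plant.shuffle(shuffled)
    need = sum(k for _, _, k in design.planted_pairs)
    if need > design.n_families:
        raise ValueError(
            f"planted pairs request {need} disjoint shared families in total, "
            f"catalog has only {design.n_families}"
        )
    cursor = 0
    plan: dict[str, dict[str, int]] = {
        g: {} for g in design.lnc_ids + design.pcg_ids
    }  # gene -> family -> n planted sites
    true_edges = set()
    for lnc, pcg, k in design.planted_pairs:
        block = sorted(shuffled[cursor : cursor + k])
        cursor += k
        per_family = max(1, math.ceil(design.min_unique_sites / k))
        for fid in block:
            plan[lnc][fid] = plan[lnc].get(fid, 0) + per_family
            plan[pcg][fid] = plan[pcg].get(fid, 0) + per_family
        true_edges.add((lnc, pcg))

    # --- sparse random background assignment
    for gene in design.lnc_ids + design.pcg_ids:
        rng_bg = _rng(seed, "background", gene)
        draws = rng_bg.random(design.n_families)
        for fid, u in zip(fam_ids, draws):
            if u < design.bg_site_prob and fid not in plan[gene]:
                plan[gene][fid] = 1

    # --- build sequences with the planned sites embedded
    sequences: dict[str, str] = {}
    records: list[SiteTableRecord] = []
    biotypes = {g: "lncRNA" for g in design.lnc_ids}
    biotypes.update({g: "PCG" for g in design.pcg_ids})
    site_counts = pd.DataFrame(
        0, index=design.lnc_ids + design.pcg_ids, columns=fam_ids, dtype=int
    )
    for gene in design.lnc_ids + design.pcg_ids:
        rng_gene = _rng(seed, "gene", gene)
        chunks: list[str] = [_random_seq(rng_gene, design.spacer_len)]
        pos = design.spacer_len
        for fid in sorted(plan[gene]):
            fam = fam_by_id[fid]
            for _ in range(plan[gene][fid]):
                site_type = str(rng_gene.choice(["8mer", "7mer-m8", "7mer-A1"]))
                if site_type == "8mer":
                    motif = revcomp(fam.seed_2_8) + "A"
                elif site_type == "7mer-m8":
                    motif = revcomp(fam.seed_2_8)
                else:
                    motif = revcomp(fam.seed_2_8[:6]) + "A"
                spacer = _random_seq(rng_gene, design.spacer_len)
                # guard the site type against its flanks: a trailing A would
                # upgrade a 7mer-m8 to an 8mer, and a matching base before a
                # 7mer-A1 would absorb it into a longer site
                if site_type == "7mer-m8" and spacer[0] == "A":
                    spacer = "C" + spacer[1:]
                if site_type == "7mer-A1":
                    guard = revcomp(fam.seed_2_8)[0]
                    if chunks[-1][-1] == guard:
                        chunks[-1] = chunks[-1][:-1] + ("C" if guard != "C" else "G")
                start, end = pos, pos + len(motif)
                records.append(
                    SiteTableRecord(
                        gene_id=gene,
                        transcript_id=gene,
                        family_id=fid,
                        site_type=site_type,
                        start=start,
                        end=end,
                        source="predicted",
                    )
                )
                site_counts.at[gene, fid] += 1
                chunks.append(motif)
                chunks.append(spacer)
                pos = end + design.spacer_len
        sequences[gene] = "".join(chunks)

    site_table = TargetSiteTable(records=list(records))

    # --- latent miRNA activities, keyed per cohort and family
    n_samples = sum(design.n_samples_by_state.values())
    activities: dict[str, np.ndarray] = {}
    for cohort in design.cohort_ids:
        a = np.empty((design.n_families, n_samples))
        for i, fid in enumerate(fam_ids):
            a[i] = _rng(seed, "activity", cohort, fid).standard_normal(n_samples)
        activities[cohort] = a

    truth = SimulationTruth(
        design=design,
        site_counts=site_counts,
        activities=activities,
        true_edges=frozenset(true_edges),
        planted_sites=records,
        sequences=sequences,
        biotypes=biotypes,
        catalog=catalog,
        site_table=site_table,
    )
    return catalog, site_table, truth


def simulate_expression(truth: SimulationTruth) -> list[ExpressionCohort]:
    """Draw per-cohort log2 expression from the latent-activity model."""
    design = truth.design
    seed = design.rng_seed
    genes = design.lnc_ids + design.pcg_ids
    fam_ids = list(truth.site_counts.columns)
    load = np.minimum(truth.site_counts.loc[genes, fam_ids].to_numpy(dtype=float), SITE_CAP)

    states: list[str] = []
    for state in ("normal", "primary", "metastatic"):
        states.extend([state] * int(design.n_samples_by_state.get(state, 0)))
    state_arr = np.array(states)
    n_samples = len(states)
    is_tumour = (state_arr != "normal").astype(float)

    mu = np.array(
        [
            design.baseline_mean
            + design.baseline_sd * _rng(seed, "mu", g).standard_normal()
            for g in genes
        ]
    )

    cn_gene = design.cn_gene
    cohorts: list[ExpressionCohort] = []
    for cohort in design.cohort_ids:
        a = truth.activities[cohort]
        x = (
            mu[:, None]
            + design.state_shift * is_tumour[None, :]
            - design.beta_repression * (load @ a)
        )
        for gi, g in enumerate(genes):
            x[gi] += design.noise_sd * _rng(seed, "eps", cohort, g).standard_normal(n_samples)

        cn_status = np.array(["neutral"] * n_samples, dtype=object)
        if cn_gene is not None and design.cn_loss_fraction > 0:
            tumour_idx = np.flatnonzero(state_arr != "normal")
            rng_cn = _rng(seed, "cn", cohort)
            n_loss = int(round(design.cn_loss_fraction * tumour_idx.size))
            loss_idx = rng_cn.permutation(tumour_idx)[:n_loss]
            cn_status[loss_idx] = "loss"
            x[genes.index(cn_gene), loss_idx] += design.cn_loss_effect

        sample_ids = [f"{cohort}_s{i + 1:03d}" for i in range(n_samples)]
        values = pd.DataFrame(x, index=genes, columns=sample_ids)
        metadata = pd.DataFrame(
            {"cohort": cohort, "state": state_arr, "cn_status": cn_status},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        cohorts.append(ExpressionCohort(cohort_id=cohort, values=values, metadata=metadata))
    return cohorts


def write_dataset(truth: SimulationTruth, outdir: str | Path) -> dict[str, Path]:
    """Write a complete simulated dataset in the pipeline's input formats.

    Emits FASTA sequences, the miRNA catalog, the site table, biotypes,
    per-cohort expression and metadata TSVs, and the true planted edges.
    Returns a name -> path mapping of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "transcripts.fasta"
    write_fasta(truth.sequences, paths["fasta"])
    paths["catalog"] = outdir / "mirna_catalog.tsv"
    write_mirna_catalog(truth.catalog, paths["catalog"])
    paths["sites"] = outdir / "target_sites.tsv"
    write_site_table(truth.site_table, paths["sites"])
    paths["biotypes"] = outdir / "biotypes.tsv"
    write_biotypes(truth.biotypes, paths["biotypes"])

    for cohort in simulate_expression(truth):
        e = outdir / f"expression_{cohort.cohort_id}.tsv"
        m = outdir / f"metadata_{cohort.cohort_id}.tsv"
        write_expression_matrix(cohort, e, m)
        paths[f"expression_{cohort.cohort_id}"] = e
        paths[f"metadata_{cohort.cohort_id}"] = m

    paths["true_edges"] = outdir / "true_edges.tsv"
    with open(paths["true_edges"], "w") as fh:
        fh.write("lncRNA_id\tgene_id\n")
        for lnc, pcg in sorted(truth.true_edges):
            fh.write(f"{lnc}\t{pcg}\n")
    return paths
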