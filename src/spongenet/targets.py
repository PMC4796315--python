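"""Canonical miRNA seed-family target-site annotation and shared-MRE counts.

A miRNA family is the set of miRNAs sharing seed nucleotides 2-8; every
member recognises the same sites, so sites are annotated per family and
shared-miRNA counts are obtained by expanding families back to their
members.  Three canonical site types are called on the target strand
(5'->3'):

* ``8mer``    — reverse complement of seed 2-8 followed by an A opposite
  miRNA position 1 (8 nt);
* ``7mer-m8`` — reverse complement of seed 2-8 (7 nt);
* ``7mer-A1`` — reverse complement of seed 2-7 followed by an A (7 nt).

This is a deliberately simplified canonical matcher (no context scoring,
no conservation weighting, no 6mer or non-canonical sites); externally
predicted site tables can be imported instead and flow through the same
gene-profile representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MirnaFamily",
    "GeneSiteProfile",
    "SharedMreSummary",
    "revcomp",
    "find_seed_sites",
    "build_gene_profiles",
    "profiles_from_site_table",
    "shared_mre_summary",
    "SITE_TYPES",
]

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MirnaFamily:
    """A miRNA seed family: all miRNAs sharing seed nucleotides 2-8."""

    family_id: str
    seed_2_8: str
    member_mirnas: frozenset[str]
    conserved: bool = True
    expressed_top50: bool = True

    def __post_init__(self) -> None:
        if len(self.seed_2_8) != 7:
            raise ValueError(f"seed must be 7 nt, got {self.seed_2_8!r} for {self.family_id}")
        if any(c not in "ACGT" for c in self.seed_2_8):
            raise ValueError(f"invalid nucleotide in seed {self.seed_2_8!r} of {self.family_id}")
        if not self.member_mirnas:
            raise ValueError(f"family {self.family_id} has no member miRNAs")

    @property
    def usable(self) -> bool:
        """Whether the family enters the inference universe."""
        return self.conserved and self.expressed_top50


@dataclass
class GeneSiteProfile:
    """Per-gene MRE sites, keyed by family, with sites deduplicated by interval."""

    gene_id: str
    biotype: str  # "lncRNA" or "PCG"
    sites_by_family: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    region: str = "transcript"  # "transcript" (lncRNA) or "3utr" (PCG)

    @property
    def families(self) -> frozenset[str]:
        return frozenset(self.sites_by_family)

    def n_sites(self, families: Iterable[str] | None = None) -> int:
        """Number of unique site intervals, optionally restricted to families."""
        keys = self.sites_by_family.keys() if families is None else families
        return sum(len(self.sites_by_family[f]) for f in keys if f in self.sites_by_family)


@dataclass(frozen=True)
class SharedMreSummary:
    """Shared-MRE quantities for one lncRNA / protein-coding gene pair."""

    lnc_id: str
    pcg_id: str
    shared_families: frozenset[str]
    n_shared_mirnas: int
    unique_sites_lnc: int
    unique_sites_pcg: int


def find_seed_sites(sequence: str, family: MirnaFamily) -> list[tuple[str, int, int]]:
    """Find all canonical seed-match sites of a family on a sequence.

    Returns ``(site_type, start, end)`` tuples with 0-based half-open
    coordinates on the given (sense) strand.  Where an 8mer is present the
    nested 7mer-A1 call ending at the same position is suppressed, so each
    seed-match locus is reported once with its strongest type
    (8mer > 7mer-m8 > 7mer-A1).
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(f"sequence shorter than 8 nt ({len(seq)})")
    core7 = revcomp(family.seed_2_8)  # pairs miRNA positions 8..2
    core6 = revcomp(family.seed_2_8[:6])  # pairs miRNA positions 7..2
    sites: list[tuple[str, int, int]] = []
    eight_mer_ends: set[int] = set()

    i = seq.find(core7)
    while i != -1:
        if seq[i + 7 : i + 8] == "A":
            sites.append(("8mer", i, i + 8))
            eight_mer_ends.add(i + 8)
        else:
            sites.append(("7mer-m8", i, i + 7))
        i = seq.find(core7, i + 1)

    i = seq.find(core6)
    while i != -1:
        if seq[i + 6 : i + 7] == "A" and (i + 7) not in eight_mer_ends:
            sites.append(("7mer-A1", i, i + 7))
        i = seq.find(core6, i + 1)

    sites.sort(key=lambda s: (s[1], s[2]))
    return sites


def build_gene_profiles(
    sequences: Mapping[str, str],
    biotypes: Mapping[str, str],
    catalog: Iterable[MirnaFamily],
    transcript_to_gene: Mapping[str, str] | None = None,
) -> dict[str, GeneSiteProfile]:
    """Scan transcript sequences for seed sites and aggregate to gene level.

    Only conserved families in the top-50% expression tier are scanned.
    When a gene has several transcripts, the transcript with the maximum
    total site count represents the gene (a union across isoforms would
    double-count overlapping sites).  Genes whose transcripts carry no
    usable sites are excluded with a warning.

    Parameters
    ----------
    sequences
        transcript_id -> nucleotide sequence.
    biotypes
        gene_id -> "lncRNA" | "PCG".
    catalog
        The miRNA family universe.
    transcript_to_gene
        transcript_id -> gene_id; identity if omitted (one transcript per
        gene named after it).
    """
    usable = [f for f in catalog if f.usable]
    t2g = transcript_to_gene or {t: t for t in sequences}
    per_gene: dict[str, list[tuple[str, dict[str, set[tuple[int, int]]]]]] = {}
    for tid, seq in sequences.items():
        gene = t2g.get(tid)
        if gene is None:
            raise KeyError(f"transcript {tid!r} has no gene assignment")
        if gene not in biotypes:
            raise KeyError(f"gene {gene!r} has no biotype assignment")
        fam_sites: dict[str, set[tuple[int, int]]] = {}
        for fam in usable:
            hits = find_seed_sites(seq, fam)
            if hits:
                fam_sites[fam.family_id] = {(s, e) for _, s, e in hits}
        per_gene.setdefault(gene, []).append((tid, fam_sites))

    profiles: dict[str, GeneSiteProfile] = {}
    for gene, transcripts in per_gene.items():
        best_tid, best = max(
            transcripts, key=lambda item: (sum(len(v) for v in item[1].values()), item[0])
        )
        if not best:
            logger.warning("gene %s has no usable target sites on any transcript; excluded", gene)
            continue
        biotype = biotypes[gene]
        region = "transcript" if biotype == "lncRNA" else "3utr"
        profiles[gene] = GeneSiteProfile(
            gene_id=gene, biotype=biotype, sites_by_family=best, region=region
        )
    return profiles


def profiles_from_site_table(
    records: Iterable,
    biotypes: Mapping[str, str],
    catalog: Iterable[MirnaFamily],
) -> dict[str, GeneSiteProfile]:
    """Build gene profiles from an (imported or predicted) site table.

    ``records`` are objects with ``gene_id``, ``family_id``, ``start`` and
    ``end`` attributes (see :class:`spongenet.io.SiteTableRecord`).
    Families outside the usable universe are ignored, mirroring
    :func:`build_gene_profiles`.
    """
    usable_ids = {f.family_id for f in catalog if f.usable}
    profiles: dict[str, GeneSiteProfile] = {}
    for rec in records:
        if rec.family_id not in usable_ids:
            continue
        gene = rec.gene_id
        if gene not in biotypes:
            raise KeyError(f"gene {gene!r} has no biotype assignment")
        prof = profiles.get(gene)
        if prof is None:
            biotype = biotypes[gene]
            prof = GeneSiteProfile(
                gene_id=gene,
                biotype=biotype,
                region="transcript" if biotype == "lncRNA" else "3utr",
            )
            profiles[gene] = prof
        prof.sites_by_family.setdefault(rec.family_id, set()).add((rec.start, rec.end))
    return profiles


def shared_mre_summary(
    lnc: GeneSiteProfile,
    pcg: GeneSiteProfile,
    catalog: Mapping[str, MirnaFamily] | Iterable[MirnaFamily],
) -> SharedMreSummary:
    """Shared families, shared member-miRNA count and unique-site counts.

    ``n_shared_mirnas`` sums member miRNAs over shared families (distinct
    miRNAs: each miRNA belongs to exactly one family).  Unique-site counts
    are taken per gene over intervals of the shared families only.
    """
    fam_map = (
        dict(catalog) if isinstance(catalog, Mapping) else {f.family_id: f for f in catalog}
    )
    shared = lnc.families & pcg.families
    n_mirnas = sum(len(fam_map[f].member_mirnas) for f in shared)
    return SharedMreSummary(
        lnc_id=lnc.gene_id,
        pcg_id=pcg.gene_id,
        shared_families=frozenset(shared),
        n_shared_mirnas=n_mirnas,
        unique_sites_lnc=lnc.n_sites(shared),
        unique_sites_pcg=pcg.n_sites(shared),
    )
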