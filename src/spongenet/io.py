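"""Readers and writers for the pipeline's external formats.

Formats: FASTA (transcript sequences), TSV (expression matrix, sample
metadata, miRNA catalog, target-site table, edge list, count table),
GraphML (network export), plain text (driver-gene list) and a flat YAML
run configuration.  TSV is the only table dialect; all coordinates are
0-based half-open; sequences are normalised to the DNA alphabet (U -> T)
on input.  Floats are serialised with 12 significant digits so every
reader/writer pair round-trips.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ExpressionCohort",
    "SiteTableRecord",
    "TargetSiteTable",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_mirna_catalog",
    "write_mirna_catalog",
    "import_site_table",
    "write_site_table",
    "read_driver_list",
    "read_biotypes",
    "write_biotypes",
    "write_network",
    "read_edge_table",
    "write_count_table",
    "setup_logging",
    "EDGE_COLUMNS",
    "DISEASE_STATES",
    "FLOAT_FMT",
]

logger = logging.getLogger(__name__)

DISEASE_STATES = ("normal", "primary", "metastatic")
FLOAT_FMT = "%.12g"

# IUPAC nucleotide codes (DNA + U, normalised to T on input)
_IUPAC = set("ACGTUNRYSWKMBDHV")


def setup_logging(level: str = "INFO") -> None:
    """Configure structured logging to stderr for CLI runs."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        force=True,
    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: uppercase DNA sequence}`` mapping.

    IDs are the first whitespace-delimited token of the header.  U is
    normalised to T.  Duplicate IDs, empty sequences and non-IUPAC
    characters are hard errors.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            seq_id = header.split()[0] if header.split() else ""
            if not seq_id:
                raise ValueError(f"{path}: record with empty ID")
            if seq_id in out:
                raise ValueError(f"{path}: duplicate sequence ID {seq_id!r}")
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise ValueError(f"{path}: empty sequence for ID {seq_id!r}")
            for pos, ch in enumerate(seq):
                if ch not in _IUPAC:
                    raise ValueError(
                        f"{path}: non-IUPAC character {ch!r} at position {pos} in {seq_id!r}"
                    )
            out[seq_id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in sequences.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression cohorts


@dataclass
class ExpressionCohort:
    """A gene x sample log2 expression matrix with sample metadata.

    ``values`` is genes x samples; ``metadata`` is indexed by sample ID
    with a ``state`` column in {normal, primary, metastatic} and an
    optional ``cn_status`` column in {loss, neutral}.
    """

    cohort_id: str
    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError("expression columns and metadata rows must align")
        bad = set(self.metadata["state"]) - set(DISEASE_STATES)
        if bad:
            raise ValueError(f"unknown disease state(s): {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_states(self, states: Iterable[str]) -> list[str]:
        states = set(states)
        return [s for s in self.samples if self.metadata.at[s, "state"] in states]

    def expression(self, gene: str, samples: Sequence[str] | None = None):
        row = self.values.loc[gene]
        return (row if samples is None else row[list(samples)]).to_numpy(dtype=float)


def read_expression_matrix(path: str | Path, metadata_path: str | Path) -> ExpressionCohort:
    """Read a gene x sample TSV plus its sample-metadata TSV.

    Matrix and metadata must describe exactly the same samples; a
    mismatch is a hard error listing the symmetric difference.  Values
    are treated as log2-scale expression.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if mat.index.has_duplicates:
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dupes}")
    values = pd.DataFrame(index=mat.index.astype(str), columns=mat.columns.astype(str), dtype=float)
    for col in mat.columns:
        for gene, cell in mat[col].items():
            try:
                values.at[gene, col] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: {cell!r}"
                ) from None

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "cohort", "state"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing metadata column(s) {sorted(missing)}")
    meta = meta.set_index("sample_id")
    mat_samples, meta_samples = set(values.columns), set(meta.index)
    if mat_samples != meta_samples:
        diff = sorted(mat_samples ^ meta_samples)
        raise ValueError(
            f"sample mismatch between {path} and {metadata_path}: symmetric difference {diff}"
        )
    meta = meta.loc[values.columns]
    cohorts = meta["cohort"].unique()
    if len(cohorts) != 1:
        raise ValueError(f"{metadata_path}: expected one cohort per file, found {list(cohorts)}")
    return ExpressionCohort(cohort_id=str(cohorts[0]), values=values, metadata=meta)


def write_expression_matrix(
    cohort: ExpressionCohort, path: str | Path, metadata_path: str | Path
) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)
    cohort.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# miRNA catalog


def read_mirna_catalog(path: str | Path):
    """Read a miRNA catalog TSV into a set of :class:`~spongenet.targets.MirnaFamily`.

    Columns: mirna_id, family_id, seed_2_8, conserved (0/1),
    expressed_top50 (0/1).  All members of a family must agree on seed and
    flags.
    """
    from .targets import MirnaFamily

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "family_id", "seed_2_8", "conserved", "expressed_top50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalog column(s) {sorted(missing)}")
    families: set[MirnaFamily] = set()
    for fam_id, grp in df.groupby("family_id", sort=True):
        seeds = grp["seed_2_8"].unique()
        if len(seeds) != 1:
            raise ValueError(f"{path}: family {fam_id!r} has conflicting seeds {list(seeds)}")
        for col in ("conserved", "expressed_top50"):
            if len(grp[col].unique()) != 1:
                raise ValueError(f"{path}: family {fam_id!r} has conflicting {col} flags")
        families.add(
            MirnaFamily(
                family_id=str(fam_id),
                seed_2_8=str(seeds[0]).upper().replace("U", "T"),
                member_mirnas=frozenset(grp["mirna_id"].astype(str)),
                conserved=bool(int(grp["conserved"].iloc[0])),
                expressed_top50=bool(int(grp["expressed_top50"].iloc[0])),
            )
        )
    return families


def write_mirna_catalog(families, path: str | Path) -> None:
    rows = []
    for fam in sorted(families, key=lambda f: f.family_id):
        for mirna in sorted(fam.member_mirnas):
            rows.append(
                {
                    "mirna_id": mirna,
                    "family_id": fam.family_id,
                    "seed_2_8": fam.seed_2_8,
                    "conserved": int(fam.conserved),
                    "expressed_top50": int(fam.expressed_top50),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Target-site tables


@dataclass(frozen=True)
class SiteTableRecord:
    """One unique MRE site on a gene, called for a miRNA seed family."""

    gene_id: str
    transcript_id: str
    family_id: str
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1
    start: int  # 0-based, half-open
    end: int
    source: str = "predicted"  # predicted | imported

    def __post_init__(self) -> None:
        if self.site_type not in ("8mer", "7mer-m8", "7mer-A1"):
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end <= self.start:
            raise ValueError(f"site end must exceed start, got ({self.start}, {self.end})")
        length = self.end - self.start
        expected = 8 if self.site_type == "8mer" else 7
        if length != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, got {length}"
            )
        if self.source not in ("predicted", "imported"):
            raise ValueError(f"unknown site source {self.source!r}")


@dataclass
class TargetSiteTable:
    """A deduplicated collection of site records with a dropped-row counter."""

    records: list[SiteTableRecord] = field(default_factory=list)
    n_dropped_unknown_family: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_SITE_COLUMNS = ["gene_id", "transcript_id", "family_id", "site_type", "start", "end", "source"]


def import_site_table(path: str | Path, family_catalog) -> TargetSiteTable:
    """Import a precomputed (TargetScan-dialect) target-site TSV.

    Records whose family is absent from the catalog are dropped and
    counted (queryable as ``n_dropped_unknown_family``); duplicate
    (gene, family, start) rows are deduplicated; ``source`` is set to
    ``imported``.  An unparseable row is a hard error with its line number.
    """
    known = {f.family_id for f in family_catalog}
    table = TargetSiteTable()
    seen: set[tuple[str, str, int]] = set()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SITE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing site-table column(s) {sorted(missing)}")
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            rec = SiteTableRecord(
                gene_id=str(row["gene_id"]),
                transcript_id=str(row["transcript_id"]),
                family_id=str(row["family_id"]),
                site_type=str(row["site_type"]),
                start=int(row["start"]),
                end=int(row["end"]),
                source="imported",
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable row at line {line_no}: {exc}") from None
        if rec.family_id not in known:
            table.n_dropped_unknown_family += 1
            continue
        key = (rec.gene_id, rec.family_id, rec.start)
        if key in seen:
            continue
        seen.add(key)
        table.records.append(rec)
    if table.n_dropped_unknown_family:
        logger.warning(
            "%s: dropped %d site record(s) with unknown family IDs",
            path,
            table.n_dropped_unknown_family,
        )
    return table


def write_site_table(table: TargetSiteTable | Iterable[SiteTableRecord], path: str | Path) -> None:
    records = list(table)
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "transcript_id": r.transcript_id,
                "family_id": r.family_id,
                "site_type": r.site_type,
                "start": r.start,
                "end": r.end,
                "source": r.source,
            }
            for r in records
        ],
        columns=_SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Driver lists and biotypes


def read_driver_list(path: str | Path) -> set[str]:
    """Plain-text driver-gene list, one symbol per line; '#' starts a comment."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.split("#")[0].strip()
            if sym:
                out.add(sym)
    return out


def read_biotypes(path: str | Path) -> dict[str, str]:
    """TSV with columns gene_id, biotype in {lncRNA, PCG}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "biotype"} <= set(df.columns):
        raise ValueError(f"{path}: biotype table needs columns gene_id, biotype")
    bad = set(df["biotype"]) - {"lncRNA", "PCG"}
    if bad:
        raise ValueError(f"{path}: unknown biotype(s) {sorted(bad)}")
    return dict(zip(df["gene_id"], df["biotype"]))


def write_biotypes(biotypes: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(biotypes), "biotype": [biotypes[g] for g in biotypes]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export

EDGE_COLUMNS = [
    "lncRNA_id",
    "gene_id",
    "n_shared_mirnas",
    "n_shared_families",
    "unique_sites_lnc",
    "unique_sites_pcg",
    "p_share",
    "r_discovery",
    "p_corr",
    "p_combined",
    "q_value",
    "r_replication",
]


def write_network(network, edge_path: str | Path, graph_path: str | Path) -> None:
    """Write a sponge network as an edge TSV and a bipartite GraphML file.

    The GraphML carries a ``bipartite`` node attribute (0 = lncRNA,
    1 = protein-coding gene) and all edge statistics as edge attributes.
    """
    rows = []
    for e in network.edges:
        rows.append(
            {
                "lncRNA_id": e.lnc_id,
                "gene_id": e.pcg_id,
                "n_shared_mirnas": e.n_shared_mirnas,
                "n_shared_families": e.n_shared_families,
                "unique_sites_lnc": e.unique_sites_lnc,
                "unique_sites_pcg": e.unique_sites_pcg,
                "p_share": e.p_share,
                "r_discovery": e.r_discovery,
                "p_corr": e.p_corr,
                "p_combined": e.p_combined,
                "q_value": e.q_value,
                "r_replication": e.r_replication,
            }
        )
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    df.to_csv(edge_path, sep="\t", index=False, float_format=FLOAT_FMT)

    g = nx.Graph()
    for lnc in sorted(network.lnc_nodes):
        g.add_node(lnc, bipartite=0, biotype="lncRNA")
    for pcg in sorted(network.pcg_nodes):
        g.add_node(pcg, bipartite=1, biotype="PCG")
    for row in rows:
        attrs = {k: v for k, v in row.items() if k not in ("lncRNA_id", "gene_id")}
        clean = {
            k: (float(v) if isinstance(v, float) and math.isfinite(v) else v)
            for k, v in attrs.items()
        }
        g.add_edge(row["lncRNA_id"], row["gene_id"], **clean)
    nx.write_graphml(g, graph_path)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read back an edge TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing edge column(s) {sorted(missing)}")
    return df


def write_count_table(count_table, path: str | Path) -> None:
    """Write a per-gene sp-lncRNA count TSV with totals in a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# total_edges\t{count_table.total_edges}\n")
        fh.write(f"# n_pcgs\t{count_table.n_pcgs}\n")
        fh.write(f"# n_lncs\t{count_table.n_lncs}\n")
        fh.write("gene_symbol\tn_sp_lncRNAs\n")
        for gene in sorted(count_table.rows):
            fh.write(f"{gene}\t{count_table.rows[gene]}\n")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Thresholds and switches for the selection cascade.

    Defaults are the published operating point: differential-expression
    alpha 0.01, FDR 0.05, at least ten shared miRNAs, at least eight
    unique targeting sites and replication correlation r >= 0.25 in every
    cohort.
    """

    alpha_de: float = 0.01
    fdr_threshold: float = 0.05
    min_shared_mirnas: int = 10
    min_unique_sites: int = 8
    min_replication_r: float = 0.25
    discovery_cohort: str | None = None
    correlation_sample_states: tuple[str, ...] = ("primary", "metastatic")
    site_count_rule: str = "min"  # min | lnc | sum
    shared_count_unit: str = "mirnas"  # mirnas | families
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "fdr_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("min_shared_mirnas", "min_unique_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.site_count_rule not in ("min", "lnc", "sum"):
            raise ValueError(f"unknown site_count_rule {self.site_count_rule!r}")
        if self.shared_count_unit not in ("mirnas", "families"):
            raise ValueError(f"unknown shared_count_unit {self.shared_count_unit!r}")
        bad = set(self.correlation_sample_states) - set(DISEASE_STATES)
        if bad:
            raise ValueError(f"unknown correlation sample state(s): {sorted(bad)}")
        self.correlation_sample_states = tuple(self.correlation_sample_states)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key/value YAML config; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})

    def log_effective(self) -> None:
        """Log the full effective configuration at run start."""
        for f in fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))
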