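"""Network summaries and expression-group contrasts.

Per-driver-gene sp-lncRNA counts, network totals, and two-group
comparisons of a single gene's expression (primary vs metastatic/CRPC
tumours, or copy-number loss vs no loss) via the two-tailed Mann-Whitney
U test.

A reference per-gene count table for the published prostate-cancer
sponge network (17 driver genes, 96 edges) ships with the package as a
regression fixture for the summary path.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionCohort
from .stats import TestResult, mann_whitney_two_tailed

__all__ = [
    "CountTable",
    "ContrastResult",
    "summarize_network",
    "group_contrast",
    "load_reference_counts",
    "expand_counts_to_edges",
]

GROUPINGS = ("state_primary_vs_metastatic", "cn_loss_vs_no_loss")


@dataclass(frozen=True)
class CountTable:
    """Per-gene sp-lncRNA counts and network totals."""

    rows: dict[str, int]
    total_edges: int
    n_pcgs: int
    n_lncs: int


@dataclass(frozen=True)
class ContrastResult:
    """A two-group expression comparison with group medians."""

    gene_id: str
    grouping: str
    test: TestResult
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    group_a: str
    group_b: str


def summarize_network(edges: Iterable) -> CountTable:
    """Summarize an edge list into per-gene counts and totals.

    ``edges`` may be ``(lnc_id, pcg_id)`` tuples or any objects with
    ``lnc_id`` / ``pcg_id`` attributes.  Duplicate edges are a hard
    error.
    """
    pairs: list[tuple[str, str]] = []
    for e in edges:
        if isinstance(e, tuple):
            lnc, pcg = e[0], e[1]
        else:
            lnc, pcg = e.lnc_id, e.pcg_id
        pairs.append((str(lnc), str(pcg)))
    if len(set(pairs)) != len(pairs):
        seen: set[tuple[str, str]] = set()
        for p in pairs:
            if p in seen:
                raise ValueError(f"duplicate edge {p}")
            seen.add(p)
    rows: dict[str, int] = {}
    for _, pcg in pairs:
        rows[pcg] = rows.get(pcg, 0) + 1
    rows = dict(sorted(rows.items()))
    return CountTable(
        rows=rows,
        total_edges=len(pairs),
        n_pcgs=sum(1 for v in rows.values() if v > 0),
        n_lncs=len({lnc for lnc, _ in pairs}),
    )


def group_contrast(cohort: ExpressionCohort, gene: str, grouping: str) -> ContrastResult:
    """Compare a gene's expression between two sample groups.

    ``grouping`` is ``state_primary_vs_metastatic`` (primary tumours vs
    metastatic/CRPC) or ``cn_loss_vs_no_loss`` (tumours with copy-number
    loss vs without).  Returns the two-tailed Mann-Whitney result and the
    group medians.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    if gene not in cohort.values.index:
        raise KeyError(f"gene {gene!r} absent from cohort {cohort.cohort_id!r}")

    if grouping == "state_primary_vs_metastatic":
        name_a, name_b = "primary", "metastatic"
        group_a = cohort.samples_in_states(["primary"])
        group_b = cohort.samples_in_states(["metastatic"])
    else:
        if "cn_status" not in cohort.metadata.columns:
            raise ValueError(
                f"cohort {cohort.cohort_id!r} metadata lacks the cn_status column"
            )
        name_a, name_b = "loss", "no_loss"
        status = cohort.metadata["cn_status"]
        group_a = [s for s in cohort.samples if status[s] == "loss"]
        group_b = [s for s in cohort.samples if status[s] != "loss"]

    for name, group in ((name_a, group_a), (name_b, group_b)):
        if not group:
            raise ValueError(f"group {name!r} is empty for grouping {grouping!r}")

    a = cohort.expression(gene, group_a)
    b = cohort.expression(gene, group_b)
    return ContrastResult(
        gene_id=gene,
        grouping=grouping,
        test=mann_whitney_two_tailed(a, b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
        group_a=name_a,
        group_b=name_b,
    )


def load_reference_counts() -> pd.DataFrame:
    """Load the packaged published per-gene sp-lncRNA count table."""
    ref = resources.files("spongenet.data") / "prostate_driver_sp_lncrna_counts.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def expand_counts_to_edges(counts: pd.DataFrame) -> list[tuple[str, str]]:
    """Expand a (gene, count) table to an edge list with placeholder lncRNAs."""
    edges: list[tuple[str, str]] = []
    for _, row in counts.iterrows():
        gene = str(row["gene_symbol"])
        for i in range(int(row["n_sp_lncRNAs"])):
            edges.append((f"lnc-{gene}-{i + 1}", gene))
    return edges
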