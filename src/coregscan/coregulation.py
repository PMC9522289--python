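"""Integration of PRE maps, seed sites, expression sets and prediction lists.

Covers the cross-referencing of expressed miRs against target-prediction
lists, shared-targeter intersections between genes, PRE/miR-site proximity
(functional co-regulation is associated with PREs within ~50 nt of miR
sites), host-gene PRE annotation for miRs encoded inside other transcripts,
and pathway richness (fraction of a pathway's genes hit by the target set)
with a hypergeometric enrichment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .mir_sites import SeedSite
from .pre_scanner import DEFAULT_CONFIG, PREMatch, PREMotifConfig, scan_pres
from .smallrna_expr import bh_adjust
from .utr_io import UTRRecord


def normalize_mir_name(name: str) -> str:
    """Case-insensitive miR identity with the species prefix stripped."""
    name = name.strip().lower()
    if name.startswith("hsa-"):
        name = name[4:]
    return name


@dataclass(frozen=True)
class TargetPrediction:
    mir_name: str
    gene_id: str
    source: str = "external_list"  # or "seed_scan"


def read_predictions(path: str | Path) -> list[TargetPrediction]:
    """Prediction list TSV with columns mir, gene[, source]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    has_source = "source" in df.columns
    out = []
    for _, row in df.iterrows():
        src = row["source"] if has_source else "external_list"
        out.append(TargetPrediction(row["mir"], row["gene"], src))
    return out


def cross_reference(
    expressed: Iterable[str], predictions: Sequence[TargetPrediction], gene: str
) -> set[str]:
    """Expressed miRs that are also predicted to target ``gene``.

    Returns names as spelled in ``expressed``; matching is case-insensitive
    with the hsa- prefix ignored.
    """
    predicted = {
        normalize_mir_name(p.mir_name) for p in predictions if p.gene_id == gene
    }
    return {name for name in expressed if normalize_mir_name(name) in predicted}


def shared_targeters(
    predictions: Sequence[TargetPrediction], genes: Sequence[str]
) -> set[str]:
    """MiRs (normalized names) predicted to target every gene in ``genes``."""
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to intersect")
    shared: Optional[set[str]] = None
    for gene in genes:
        targeters = {
            normalize_mir_name(p.mir_name) for p in predictions if p.gene_id == gene
        }
        shared = targeters if shared is None else shared & targeters
    return shared or set()


@dataclass(frozen=True)
class ProximityPair:
    pre: PREMatch
    site: SeedSite
    gap_nt: int
    proximal: bool


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Nucleotides strictly between two 1-based inclusive intervals (0 if they overlap or abut)."""
    if a_start > b_start:
        a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
    return max(0, b_start - a_end - 1)


def proximity_pairs(
    pres: Sequence[PREMatch], sites: Sequence[SeedSite], max_gap: int = 50
) -> list[ProximityPair]:
    """All PRE x seed-site pairs on one record with their edge-to-edge gap.

    A pair is flagged proximal when the gap is at most ``max_gap`` nt
    (default 50, the spacing below which co-regulation is reported to
    accelerate decay).  Sorted by increasing gap.
    """
    record_ids = {p.record_id for p in pres} | {s.record_id for s in sites}
    if len(record_ids) > 1:
        raise ValueError(f"pres and sites span multiple records: {sorted(record_ids)}")
    pairs = [
        ProximityPair(
            pre=p,
            site=s,
            gap_nt=(gap := interval_gap(p.start, p.end, s.start, s.end)),
            proximal=gap <= max_gap,
        )
        for p in pres
        for s in sites
    ]
    return sorted(pairs, key=lambda pr: (pr.gap_nt, pr.pre.start, pr.site.start))


@dataclass(frozen=True)
class HostGeneAnnotation:
    """PRE content of the 3'UTR of the transcript a miR is processed from."""

    mir_name: str
    host_gene: str  # gene symbol, or "lncRNA" / "unknown"
    accession: str
    n_cpre: Optional[int]  # None when no sequence was supplied
    n_ncpre: Optional[int]


def annotate_host_genes(
    hosts: Sequence[tuple[str, str, str, Optional[UTRRecord]]],
    config: PREMotifConfig = DEFAULT_CONFIG,
) -> list[HostGeneAnnotation]:
    """Count canonical/non-canonical PREs in host-gene 3'UTRs.

    ``hosts`` rows are (mir_name, host label, accession, UTRRecord or None);
    hosts without a sequence (unknown/lncRNA-only labels) get undefined
    counts.
    """
    out = []
    for mir_name, host, accession, record in hosts:
        if record is None:
            out.append(HostGeneAnnotation(mir_name, host, accession, None, None))
            continue
        hits = scan_pres(record, config)
        n_c = sum(h.pre_class == "canonical" for h in hits)
        n_nc = sum(h.pre_class == "noncanonical" for h in hits)
        out.append(HostGeneAnnotation(mir_name, host, accession, n_c, n_nc))
    return out


@dataclass(frozen=True)
class PathwayRichness:
    pathway_id: str
    n_mapped: int
    n_total: int
    richness: float
    pvalue: float
    qvalue: float


def pathway_richness(
    target_genes: set[str],
    pathway_table: Mapping[str, set[str]],
    universe: set[str],
) -> list[PathwayRichness]:
    """Richness and hypergeometric enrichment per pathway.

    Richness = |targets ∩ pathway| / |pathway|.  The p-value is the upper
    tail of the hypergeometric distribution for the observed overlap given
    (|universe|, |pathway|, |targets ∩ universe|); q-values are BH across
    pathways.  Empty pathways are skipped with a warning.  Sorted by
    p-value.
    """
    targets = target_genes & universe
    rows = []
    for pid, genes in pathway_table.items():
        if not genes <= universe:
            raise ValueError(f"pathway {pid!r} contains genes outside the universe")
        if not genes:
            warnings.warn(f"pathway {pid!r} is empty; skipped")
            continue
        k = len(targets & genes)
        p = float(hypergeom.sf(k - 1, len(universe), len(genes), len(targets)))
        rows.append((pid, k, len(genes), k / len(genes), p))
    if not rows:
        return []
    qvals = bh_adjust([r[4] for r in rows])
    results = [
        PathwayRichness(pid, k, n, rich, p, q)
        for (pid, k, n, rich, p), q in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (r.pvalue, r.pathway_id))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: pathway, description, genes... per tab-separated line."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            table[fields[0]] = {g for g in fields[2:] if g}
    return table


def load_dem_reference() -> pd.DataFrame:
    """Bundled published reference table of miRs differentially expressed on
    PUM1/PUM2 knockdown in SH-SY5Y cells (plus non-differential controls),
    with host-gene identity and hand-annotated PRE counts per host 3'UTR.
    """
    with resources.files("coregscan.data").joinpath("pum_kd_dem_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def dem_reference_summary(table: Optional[pd.DataFrame] = None) -> dict[str, int]:
    """Row/threshold counts over the bundled knockdown reference table.

    Counts are restricted to the differentially expressed rows: how many are
    up-regulated, how many are hosted in named protein-coding genes, and how
    many of those hosts carry at least one canonical / non-canonical PRE.
    """
    df = load_dem_reference() if table is None else table
    dem = df[df["group"] == "dem"]
    coding = dem[dem["host_class"] == "protein_coding"]
    return {
        "n_dem": len(dem),
        "n_up": int((dem["log2_fold_change"] > 0).sum()),
        "n_down": int((dem["log2_fold_change"] < 0).sum()),
        "n_protein_coding_host": len(coding),
        "n_host_with_cpre": int((coding["n_cpre"] >= 1).sum()),
        "n_host_with_ncpre": int((coding["n_ncpre"] >= 1).sum()),
    }
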