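"""MicroRNA seed-match site prediction and site-inclusion filtering.

A miR's seed is mature-sequence positions 2-7 (extended 2-8).  A canonical
target site is a perfect Watson-Crick complement of the seed in the 3'UTR,
classified as:

* 8mer      -- complement of positions 2-8 followed by an A anchor (8 nt)
* 7mer-m8   -- complement of positions 2-8 alone (7 nt)
* 7mer-A1   -- complement of positions 2-7 followed by an A anchor (7 nt)
* 6mer      -- complement of positions 2-7 alone (6 nt; off by default)

The A1 anchor is an adenosine in the target regardless of the miR's own
position-1 base, matching the standard site-type taxonomy.  G:U wobbles are
not allowed.  By default each seed-match locus yields one call under the
precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CONSERVATION_CLASSES = frozenset(
    {"broadly_conserved", "conserved_mammals", "poorly_conserved", "poorly_conserved_confident"}
)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRRecord:
    name: str
    mature_seq: str  # 5'->3' RNA
    family: str = ""
    conservation_class: str = "broadly_conserved"

    def __post_init__(self) -> None:
        if len(self.mature_seq) < 8:
            raise ValueError(f"{self.name}: mature sequence shorter than 8 nt")
        if self.conservation_class not in CONSERVATION_CLASSES:
            raise ValueError(f"{self.name}: unknown conservation class {self.conservation_class!r}")


@dataclass(frozen=True)
class SeedSite:
    """A located seed-match site; 1-based inclusive coordinates."""

    record_id: str
    start: int
    end: int
    site_type: str
    mir_name: str

    @property
    def bed_name(self) -> str:
        return f"{self.site_type}:{self.mir_name}"


def seed_of(mir: MiRRecord, span: str = "2-7") -> str:
    """Seed subsequence of the mature miR (positions 2-7 or 2-8)."""
    if span == "2-7":
        return mir.mature_seq[1:7]
    if span == "2-8":
        return mir.mature_seq[1:8]
    raise ValueError(f"span must be '2-7' or '2-8', got {span!r}")


def target_sites(
    seq: str,
    mir: MiRRecord,
    include_6mer: bool = False,
    report_all_types: bool = False,
    record_id: str = "seq",
) -> list[SeedSite]:
    """All seed-match sites of ``mir`` in ``seq``, sorted by start.

    Every site contains the hexamer complementary to seed positions 2-7;
    each occurrence of that hexamer is classified by whether it is preceded
    by the complement of miR position 8 and/or followed by the A anchor.
    With ``report_all_types`` the negative conditions are dropped and every
    matching pattern is reported at each locus.
    """
    match6 = revcomp(seed_of(mir, "2-7"))  # core hexamer, present in all types
    c8 = _COMPLEMENT_CHAR(mir.mature_seq[7])
    sites: list[SeedSite] = []
    j = seq.find(match6)
    while j != -1:
        preceded = j > 0 and seq[j - 1] == c8
        followed = j + 6 < len(seq) and seq[j + 6] == "A"
        if report_all_types:
            if preceded and followed:
                sites.append(SeedSite(record_id, j, j + 7, "8mer", mir.name))
            if preceded:
                sites.append(SeedSite(record_id, j, j + 6, "7mer-m8", mir.name))
            if followed:
                sites.append(SeedSite(record_id, j + 1, j + 7, "7mer-A1", mir.name))
            if include_6mer:
                sites.append(SeedSite(record_id, j + 1, j + 6, "6mer", mir.name))
        else:
            if preceded and followed:
                sites.append(SeedSite(record_id, j, j + 7, "8mer", mir.name))
            elif preceded:
                sites.append(SeedSite(record_id, j, j + 6, "7mer-m8", mir.name))
            elif followed:
                sites.append(SeedSite(record_id, j + 1, j + 7, "7mer-A1", mir.name))
            elif include_6mer:
                sites.append(SeedSite(record_id, j + 1, j + 6, "6mer", mir.name))
        j = seq.find(match6, j + 1)
    return sorted(sites, key=lambda s: (s.start, s.site_type))


def _COMPLEMENT_CHAR(c: str) -> str:
    return c.translate(_COMPLEMENT)


def filter_sites(sites: list[SeedSite], mirs: list[MiRRecord]) -> list[SeedSite]:
    """Apply the site-inclusion criteria.

    A site is kept iff its type is 8mer or 7mer-m8 (a 2-8 seed match, any
    family conservation), or it is a 7mer-A1 site of a family broadly
    conserved among vertebrates.  6mers are always removed.
    """
    by_name = {m.name: m for m in mirs}
    kept = []
    for site in sites:
        if site.mir_name not in by_name:
            raise KeyError(f"unknown miR {site.mir_name!r}")
        mir = by_name[site.mir_name]
        if site.site_type in ("8mer", "7mer-m8"):
            kept.append(site)
        elif site.site_type == "7mer-A1" and mir.conservation_class == "broadly_conserved":
            kept.append(site)
    return kept


def read_mir_table(path: str | Path) -> list[MiRRecord]:
    """Read miR metadata TSV (name, mature_seq, family, conservation_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "mature_seq"}
    if not required <= set(df.columns):
        raise ValueError(f"miR table must contain columns {sorted(required)}")
    records = []
    for row in df.to_dict("records"):
        conservation = row.get("conservation_class") or "broadly_conserved"
        if not isinstance(conservation, str):
            conservation = "broadly_conserved"
        family = row.get("family")
        records.append(
            MiRRecord(
                name=row["name"],
                mature_seq=row["mature_seq"],
                family=family if isinstance(family, str) else "",
                conservation_class=conservation,
            )
        )
    return records
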