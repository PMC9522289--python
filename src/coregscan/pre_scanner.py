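"""Pumilio Response Element (PRE) discovery and conservation profiling.

Human PUM1/PUM2 bind an AU-rich element whose optimal 8-nt form is
UGUA(A/U)AUA; figure-level annotation practice also admits C at position 5,
so the canonical position-5 alphabet defaults to {A, U, C} and can be
narrowed.  Motifs that keep the UGUA core but diverge downstream may retain
function when the downstream region stays AU-rich; these are scanned as
non-canonical PREs under a configurable rule (AU fraction in a fixed window,
or a required downstream AUA).  Scanning is single-strand 5'->3' (the
substrate is mRNA), all overlapping windows are reported, and the ambiguity
code N never matches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .utr_io import UTRRecord

CANONICAL_LEN = 8
CORE = "UGUA"

GAP = "-"


@dataclass(frozen=True)
class PREMotifConfig:
    """Parameters of the PRE definitions.

    canonical_pos5_alphabet
        Admissible nucleotides at motif position 5 of the canonical
        UGUA(x)AUA; the permissive {A, U, C} is the default, {A, U} gives
        the strict optimal-element reading.
    noncanonical_window_len
        Length (nt) of the window immediately downstream of a UGUA anchor
        inspected by the non-canonical rule.
    noncanonical_min_AU
        Minimum number of A/U nucleotides in that window.
    noncanonical_require_AUA
        If true, the window must instead contain the literal trinucleotide
        AUA (stricter reading of "downstream AUA").
    """

    canonical_pos5_alphabet: frozenset[str] = frozenset("AUC")
    noncanonical_window_len: int = 4
    noncanonical_min_AU: int = 3
    noncanonical_require_AUA: bool = False

    def __post_init__(self) -> None:
        alphabet = frozenset(self.canonical_pos5_alphabet)
        if not alphabet or not alphabet <= frozenset("AUC"):
            raise ValueError("canonical_pos5_alphabet must be a non-empty subset of {A,U,C}")
        object.__setattr__(self, "canonical_pos5_alphabet", alphabet)
        if self.noncanonical_min_AU > self.noncanonical_window_len:
            raise ValueError("noncanonical_min_AU cannot exceed the window length")


DEFAULT_CONFIG = PREMotifConfig()


@dataclass(frozen=True)
class PREMatch:
    """A located PRE; 1-based inclusive coordinates on the scanned record."""

    record_id: str
    start: int
    end: int
    pre_class: str  # "canonical" | "noncanonical"
    matched_seq: str

    @property
    def bed_name(self) -> str:
        return f"PRE_{self.pre_class}"


def _canonical_at(seq: str, i: int, config: PREMotifConfig) -> bool:
    """True if a canonical PRE starts at 0-based offset i."""
    if i + CANONICAL_LEN > len(seq):
        return False
    return (
        seq[i : i + 4] == CORE
        and seq[i + 4] in config.canonical_pos5_alphabet
        and seq[i + 5 : i + 8] == "AUA"
    )


def scan_canonical(
    seq: str, config: PREMotifConfig = DEFAULT_CONFIG, record_id: str = "seq"
) -> list[PREMatch]:
    """All (possibly overlapping) canonical UGUA(x)AUA windows, sorted by start."""
    hits = []
    for i in range(len(seq) - CANONICAL_LEN + 1):
        if _canonical_at(seq, i, config):
            hits.append(
                PREMatch(record_id, i + 1, i + CANONICAL_LEN, "canonical", seq[i : i + CANONICAL_LEN])
            )
    return hits


def _noncanonical_at(seq: str, i: int, config: PREMotifConfig) -> bool:
    """True if a non-canonical PRE (and not a canonical one) anchors at offset i."""
    w = config.noncanonical_window_len
    if seq[i : i + 4] != CORE or i + 4 + w > len(seq):
        return False
    if _canonical_at(seq, i, config):
        return False
    window = seq[i + 4 : i + 4 + w]
    if config.noncanonical_require_AUA:
        return "AUA" in window
    return sum(c in "AU" for c in window) >= config.noncanonical_min_AU


def scan_noncanonical(
    seq: str, config: PREMotifConfig = DEFAULT_CONFIG, record_id: str = "seq"
) -> list[PREMatch]:
    """UGUA anchors with an AU-rich downstream window, canonical anchors excluded.

    The downstream window must lie fully within the sequence; an anchor too
    close to the 3' end is not called.
    """
    w = config.noncanonical_window_len
    hits = []
    for i in range(len(seq) - 4 - w + 1):
        if _noncanonical_at(seq, i, config):
            hits.append(
                PREMatch(record_id, i + 1, i + 4 + w, "noncanonical", seq[i : i + 4 + w])
            )
    return hits


def scan_pres(record: UTRRecord, config: PREMotifConfig = DEFAULT_CONFIG) -> list[PREMatch]:
    """Combined canonical + non-canonical PRE map of one UTR.

    Each UGUA anchor is reported at most once; canonical takes precedence.
    """
    hits = scan_canonical(record.sequence, config, record.gene_id) + scan_noncanonical(
        record.sequence, config, record.gene_id
    )
    return sorted(hits, key=lambda h: (h.start, h.pre_class))


@dataclass(frozen=True)
class ConservationSummary:
    """Cross-species conservation of one aligned motif window."""

    n_species: int
    fraction_intact: float
    per_column_identity: tuple[float, ...] = field(default=())


def conservation_profile(
    ortholog_windows: list[str], config: PREMotifConfig = DEFAULT_CONFIG
) -> ConservationSummary:
    """Summarize conservation of a motif window across aligned orthologs.

    ``fraction_intact`` is the fraction of species whose window (gaps
    removed) still contains an intact canonical or non-canonical PRE;
    ``per_column_identity`` is, per alignment column, the frequency of the
    modal non-gap character among non-gap entries (0 for all-gap columns).
    """
    if len(ortholog_windows) < 2:
        raise ValueError("need at least 2 species")
    windows = [w.upper() for w in ortholog_windows]
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("ortholog windows must be aligned to equal length")

    intact = 0
    for w in windows:
        degapped = w.replace(GAP, "")
        if scan_canonical(degapped, config) or scan_noncanonical(degapped, config):
            intact += 1

    identity = []
    for col in range(width):
        chars = [w[col] for w in windows if w[col] != GAP]
        if not chars:
            identity.append(0.0)
        else:
            identity.append(Counter(chars).most_common(1)[0][1] / len(chars))

    return ConservationSummary(
        n_species=len(windows),
        fraction_intact=intact / len(windows),
        per_column_identity=tuple(identity),
    )
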