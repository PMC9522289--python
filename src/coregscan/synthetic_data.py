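"""Synthetic fixtures with exact ground truth for every pipeline stage.

The generators emulate the study conditions the analysis modules expect:
3'UTRs with PREs and miR seed sites planted at known coordinates (with
rejection sampling of the background so the planted truth is exhaustive),
positionally aligned ortholog sets with tunable motif conservation,
negative-binomial miR count matrices for 3 WT vs 3 KD replicates with a
planted fraction of differential miRs, and CT tables with known condition
shifts.  Every generator is bit-reproducible under a fixed seed.

The negative binomial is parameterized by (mean mu, dispersion alpha) with
variance = mu + alpha * mu**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mir_sites import MiRRecord, revcomp, seed_of, target_sites
from .pre_scanner import DEFAULT_CONFIG, PREMotifConfig, scan_canonical, scan_noncanonical
from .smallrna_expr import KD, WT, CountMatrix
from .utr_io import UTRRecord

_BASES = np.array(list("ACGU"))


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    planted_pres: list[tuple[int, str]] = field(default_factory=list)  # (start, class)
    planted_sites: list[tuple[int, str, str]] = field(default_factory=list)  # (start, type, mir)
    dem_ids: set[str] = field(default_factory=set)
    dem_log2fc: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MotifSpec:
    """A motif to plant: kind is 'canonical', 'noncanonical' or a seed-site type."""

    position: int  # 1-based start
    kind: str
    mir: Optional[MiRRecord] = None  # required for seed-site kinds


def _motif_sequence(spec: MotifSpec, rng: np.random.Generator) -> str:
    if spec.kind == "canonical":
        return "UGUA" + str(rng.choice(list("AUC"))) + "AUA"
    if spec.kind == "noncanonical":
        # >=3 A/U and a contained AUA, but not the canonical xAUA form
        return "UGUA" + str(rng.choice(["AUAU", "AUAA", "GAUA"]))
    if spec.mir is None:
        raise ValueError(f"seed-site spec {spec.kind!r} needs a MiRRecord")
    match6 = revcomp(seed_of(spec.mir, "2-7"))
    c8 = revcomp(spec.mir.mature_seq[7])
    if spec.kind == "8mer":
        return c8 + match6 + "A"
    if spec.kind == "7mer-m8":
        return c8 + match6
    if spec.kind == "7mer-A1":
        return match6 + "A"
    if spec.kind == "6mer":
        return match6
    raise ValueError(f"unknown motif kind {spec.kind!r}")


def _draw_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def gen_utr(
    length: int,
    planted: Sequence[MotifSpec] = (),
    background_gc: float = 0.5,
    seed: int = 0,
    config: PREMotifConfig = DEFAULT_CONFIG,
    gene_id: str = "synthUTR",
    max_iter: int = 500,
) -> tuple[UTRRecord, SyntheticTruth]:
    """Random UTR with motifs planted at known positions and nowhere else.

    Background positions that accidentally create additional PREs, or seed
    sites for any planted miR, are redrawn until the planted truth is the
    exhaustive scan result.
    """
    rng = np.random.default_rng(seed)
    motifs = []
    occupied: set[int] = set()
    for spec in planted:
        seq = _motif_sequence(spec, rng)
        span = range(spec.position - 1, spec.position - 1 + len(seq))
        if spec.position < 1 or spec.position - 1 + len(seq) > length:
            raise ValueError(f"motif at {spec.position} does not fit in length {length}")
        if occupied & set(span):
            raise ValueError("planted motifs overlap")
        occupied |= set(span)
        motifs.append((spec, seq, span))

    arr = _draw_background(length, background_gc, rng)
    for _, seq, span in motifs:
        arr[list(span)] = list(seq)

    planted_pre_starts = {
        (m[0].position, m[0].kind) for m in motifs if m[0].kind in ("canonical", "noncanonical")
    }
    planted_site_keys = {
        (m[0].position, m[0].kind, m[0].mir.name)
        for m in motifs
        if m[0].mir is not None
    }
    mirs = {m[0].mir.name: m[0].mir for m in motifs if m[0].mir is not None}

    free = np.array(sorted(set(range(length)) - occupied), dtype=int)
    for _ in range(max_iter):
        seq = "".join(arr)
        bad: set[int] = set()
        for hit in scan_canonical(seq, config) + scan_noncanonical(seq, config):
            if (hit.start, hit.pre_class) not in planted_pre_starts:
                bad |= set(range(hit.start - 1, hit.end))
        for mir in mirs.values():
            for site in target_sites(seq, mir, include_6mer=True):
                if (site.start, site.site_type, site.mir_name) not in planted_site_keys:
                    bad |= set(range(site.start - 1, site.end))
        bad &= set(free.tolist())
        if not bad:
            truth = SyntheticTruth(
                planted_pres=sorted(planted_pre_starts),
                planted_sites=sorted(planted_site_keys),
                params={"length": length, "background_gc": background_gc, "seed": seed},
            )
            return UTRRecord(gene_id, "", seq), truth
        idx = sorted(bad)
        arr[idx] = _draw_background(len(idx), background_gc, rng)
    raise RuntimeError("could not place motifs without accidental matches; relax constraints")


def gen_ortholog_set(
    base: UTRRecord,
    n_species: int,
    subst_rate: float,
    protect_motifs: bool = True,
    seed: int = 0,
    motif_intervals: Sequence[tuple[int, int]] = (),
) -> tuple[dict[str, str], SyntheticTruth]:
    """Positionally aligned ortholog set (no indels) derived from ``base``.

    Species 1 is the unmutated base; each other species substitutes each
    position independently at ``subst_rate`` (to a different base).  With
    ``protect_motifs``, positions inside ``motif_intervals`` (1-based
    inclusive) are exempt.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not 0.0 <= subst_rate <= 1.0:
        raise ValueError("substitution rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    protected = np.zeros(base.length, dtype=bool)
    if protect_motifs:
        for start, end in motif_intervals:
            protected[start - 1 : end] = True
    base_arr = np.array(list(base.sequence))
    out = {"species_1": base.sequence}
    for k in range(2, n_species + 1):
        arr = base_arr.copy()
        hit = (rng.random(base.length) < subst_rate) & ~protected
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGU" if b != arr[i]]
            arr[i] = choices[rng.integers(len(choices))]
        out[f"species_{k}"] = "".join(arr)
    truth = SyntheticTruth(
        params={
            "seed": seed,
            "n_species": n_species,
            "subst_rate": subst_rate,
            "protect_motifs": protect_motifs,
            "motif_intervals": list(motif_intervals),
        }
    )
    return out, truth


def gen_counts(
    n_mirs: int = 2000,
    reps: int = 3,
    mean_log_range: tuple[float, float] = (0.5, 3.5),
    dispersion: float = 0.1,
    dem_fraction: float = 0.1,
    dem_log2fc: float = 1.5,
    library_factors: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB count matrix for WT/KD with a planted fraction of differential miRs.

    Baseline means are log10-uniform on ``mean_log_range``; planted DEMs get
    +/-``dem_log2fc`` in KD with alternating sign (a mix of up- and
    down-regulation); counts are NB(mean * library factor, dispersion).
    """
    if not 0.0 <= dem_fraction <= 1.0:
        raise ValueError("dem_fraction must lie in [0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    mir_ids = [f"mir_{i + 1:05d}" for i in range(n_mirs)]
    samples = [f"{WT}_{r + 1}" for r in range(reps)] + [f"{KD}_{r + 1}" for r in range(reps)]
    lib = np.ones(2 * reps) if library_factors is None else np.asarray(library_factors, float)
    if lib.shape != (2 * reps,) or (lib <= 0).any():
        raise ValueError("library_factors must be positive, one per sample")

    mu = 10.0 ** rng.uniform(*mean_log_range, size=n_mirs)
    n_dem = int(round(dem_fraction * n_mirs))
    dem_idx = rng.choice(n_mirs, size=n_dem, replace=False)
    lfc = np.zeros(n_mirs)
    lfc[dem_idx] = np.where(np.arange(n_dem) % 2 == 0, 1.0, -1.0) * dem_log2fc

    mean_by_cond = np.stack([mu, mu * 2.0**lfc], axis=1)  # WT, KD
    r = 1.0 / dispersion
    counts = np.empty((n_mirs, 2 * reps), dtype=np.int64)
    for s in range(2 * reps):
        m = mean_by_cond[:, 0 if s < reps else 1] * lib[s]
        counts[:, s] = rng.negative_binomial(r, r / (r + m))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=mir_ids, columns=samples),
        conditions=pd.Series([WT] * reps + [KD] * reps, index=samples),
    )
    truth = SyntheticTruth(
        dem_ids={mir_ids[i] for i in dem_idx},
        dem_log2fc={mir_ids[i]: float(lfc[i]) for i in dem_idx},
        params={
            "seed": seed,
            "n_mirs": n_mirs,
            "reps": reps,
            "dispersion": dispersion,
            "dem_fraction": dem_fraction,
            "dem_log2fc": dem_log2fc,
            "mean_log_range": mean_log_range,
        },
    )
    return cm, truth


def gen_ct(
    assays: Sequence[str],
    reps: int = 3,
    noise_sd: float = 0.2,
    shifts: Optional[Mapping[str, float]] = None,
    baselines: Optional[Mapping[str, float]] = None,
    tech_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """CT table: baseline + per-assay KD shift + Normal(0, noise_sd) noise.

    Technical replicates share the biological replicate's noisy CT plus
    independent noise of the same scale / 4 (instrument-level jitter).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    shifts = dict(shifts or {})
    baselines = dict(baselines or {})
    rows = []
    for cond in (WT, KD):
        for b in range(1, reps + 1):
            for assay in assays:
                base = baselines.get(assay, 20.0)
                ct_bio = base + (shifts.get(assay, 0.0) if cond == KD else 0.0)
                ct_bio += rng.normal(0.0, noise_sd)
                for t in range(1, tech_reps + 1):
                    ct = ct_bio + rng.normal(0.0, noise_sd / 4) if noise_sd else ct_bio
                    rows.append(
                        {
                            "sample_id": f"{cond}_{b}",
                            "biological_rep": b,
                            "technical_rep": t,
                            "assay": assay,
                            "ct": ct,
                            "condition": cond,
                        }
                    )
    return pd.DataFrame(rows)
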