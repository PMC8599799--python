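"""Labeled motif-site construction and reactivity feature extraction.

Positive sites are motif occurrences that overlap an occupancy peak for the
RBP (e.g. an eCLIP peak projected to transcript coordinates); negatives are
occurrences of the same motif whose full span is disjoint from every peak of
that RBP, sampled without replacement to match the positive count.  Each
surviving site contributes a fixed-width window of reactivity scores —
motif plus ``flank`` bases on each side (width 15 for a 5-mer with flank 5;
width 46 for the 6-mer polyadenylation signal with flank 20).  Windows
containing any null score, or running off a transcript end, are discarded
and counted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PeakInterval, TranscriptRecord, ValidationError, normalize_sequence
from .reactivity import ReactivityProfile


class SiteLabel(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class MotifSpec:
    """An exact-match binding motif; stored in the DNA alphabet."""

    rbp_name: str
    motif: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", normalize_sequence(self.motif))
        if len(self.motif) < 1:
            raise ValidationError("motif must be non-empty")

    @property
    def length(self) -> int:
        return len(self.motif)

    def ag_count(self) -> int:
        return sum(1 for b in self.motif if b in "AG")


def motif_has_min_ag(spec: MotifSpec, min_ag: int = 3) -> bool:
    """RBP-selection filter: motif must contain at least *min_ag* A/G residues
    (purines are what the solvent-accessibility probe reads out)."""
    return spec.ag_count() >= min_ag


@dataclass(frozen=True)
class MotifSite:
    transcript_id: str
    start: int
    motif: str
    label: SiteLabel
    source_peak: PeakInterval | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.motif)


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-width extraction window: motif of length m plus k flanking bases
    per side, total width m + 2k."""

    motif_length: int
    flank: int

    @property
    def width(self) -> int:
        return self.motif_length + 2 * self.flank


DISCARD = None  # sentinel: extract_window returns None for dropped windows


@dataclass
class FeatureMatrix:
    """Aligned per-reagent feature windows with labels.

    ``matrices`` maps reagent name -> (n_sites, width) float array with no
    NaNs; all reagents share the same row order given by ``sites``.
    ``discard_log`` counts windows dropped per reason.
    """

    sites: list[MotifSite]
    matrices: dict[str, np.ndarray]
    labels: np.ndarray
    discard_log: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def design_matrix(self, reagents: Sequence[str]) -> np.ndarray:
        """Row-wise concatenation of the requested reagents' windows."""
        return np.hstack([self.matrices[r] for r in reagents])


def scan_motif(transcript: TranscriptRecord, motif: str) -> list[int]:
    """All exact (possibly overlapping) motif start positions, ascending."""
    motif = normalize_sequence(motif)
    if not motif:
        raise ValidationError("motif must be non-empty")
    seq = transcript.sequence
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


def build_positive_sites(
    peaks: Iterable[PeakInterval],
    motif: MotifSpec,
    transcripts: Mapping[str, TranscriptRecord],
) -> tuple[list[MotifSite], int]:
    """Positive sites: motif occurrences overlapping each peak.

    Overlap means at least one motif base inside the peak.  Peaks containing
    no occurrence are dropped; the second return value counts them.
    Duplicate (transcript, start) pairs arising from overlapping peaks are
    collapsed, keeping the first peak encountered.
    """
    m = motif.length
    seen: dict[tuple[str, int], MotifSite] = {}
    dropped_peaks = 0
    for peak in peaks:
        tx = transcripts.get(peak.transcript_id)
        if tx is None:
            raise ValidationError(f"peak on unknown transcript {peak.transcript_id!r}")
        hits = [
            s
            for s in scan_motif(tx, motif.motif)
            if peak.overlaps(s, s + m)
        ]
        if not hits:
            dropped_peaks += 1
            continue
        for s in hits:
            seen.setdefault(
                (peak.transcript_id, s),
                MotifSite(peak.transcript_id, s, motif.motif, SiteLabel.POSITIVE, peak),
            )
    sites = sorted(seen.values(), key=lambda s: (s.transcript_id, s.start))
    return sites, dropped_peaks


def find_negative_pool(
    motif: MotifSpec,
    peaks: Iterable[PeakInterval],
    transcripts: Mapping[str, TranscriptRecord],
    buffer: int = 0,
) -> list[MotifSite]:
    """Motif occurrences whose full span (padded by *buffer*) avoids every peak."""
    peaks_by_tx: dict[str, list[PeakInterval]] = {}
    for p in peaks:
        peaks_by_tx.setdefault(p.transcript_id, []).append(p)
    m = motif.length
    pool = []
    for tid, tx in transcripts.items():
        tx_peaks = peaks_by_tx.get(tid, [])
        for s in scan_motif(tx, motif.motif):
            lo, hi = s - buffer, s + m + buffer
            if not any(p.overlaps(lo, hi) for p in tx_peaks):
                pool.append(MotifSite(tid, s, motif.motif, SiteLabel.NEGATIVE))
    return pool


def sample_negative_sites(
    pool: Sequence[MotifSite],
    n_positives: int,
    seed: int,
) -> list[MotifSite]:
    """Sample min(n_positives, |pool|) negatives without replacement, seeded."""
    if n_positives < 0:
        raise ValidationError("n_positives must be >= 0")
    if n_positives == 0:
        return []
    if len(pool) < n_positives:
        warnings.warn(
            f"negative pool ({len(pool)}) smaller than positive count ({n_positives})",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    k = min(n_positives, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    chosen = [pool[i] for i in sorted(idx)]
    return chosen


def extract_window(
    profile: ReactivityProfile,
    site: MotifSite,
    spec: WindowSpec,
) -> np.ndarray | None:
    """Reactivity over [start - k, start + m + k), or DISCARD (None).

    Discarded when the window leaves the transcript or contains a null score.
    Element j corresponds to transcript position ``site.start - k + j``.
    """
    lo = site.start - spec.flank
    hi = site.start + spec.motif_length + spec.flank
    if lo < 0 or hi > profile.length:
        return DISCARD
    window = profile.scores[lo:hi]
    if np.isnan(window).any():
        return DISCARD
    return window.copy()


def assemble_feature_matrix(
    sites: Sequence[MotifSite],
    profiles_by_reagent: Mapping[str, Mapping[str, ReactivityProfile]],
    spec: WindowSpec,
    mode: str = "combined",
) -> FeatureMatrix:
    """Extract windows for each site in each reagent and align them rowwise.

    ``profiles_by_reagent`` maps reagent name -> {transcript_id -> profile}.
    In ``combined`` mode (also used for single-reagent input) a site is kept
    only if its window survives in every requested reagent, so row counts
    agree across reagents and windows can be concatenated.
    """
    if mode not in ("combined", "single_reagent"):
        raise ValidationError(f"unknown mode {mode!r}")
    reagents = list(profiles_by_reagent)
    if not reagents:
        raise ValidationError("no reagents supplied")
    kept_sites: list[MotifSite] = []
    rows: dict[str, list[np.ndarray]] = {r: [] for r in reagents}
    log = {"boundary_or_null": 0, "missing_profile": 0}
    for site in sites:
        windows = {}
        ok = True
        for r in reagents:
            prof = profiles_by_reagent[r].get(site.transcript_id)
            if prof is None:
                log["missing_profile"] += 1
                ok = False
                break
            w = extract_window(prof, site, spec)
            if w is DISCARD:
                log["boundary_or_null"] += 1
                ok = False
                break
            windows[r] = w
        if not ok:
            continue
        kept_sites.append(site)
        for r in reagents:
            rows[r].append(windows[r])
    if not kept_sites:
        raise ValidationError(
            f"no sites survived window extraction (discards: {log})"
        )
    matrices = {r: np.vstack(rows[r]) for r in reagents}
    labels = np.array([1 if s.label == SiteLabel.POSITIVE else 0 for s in kept_sites])
    return FeatureMatrix(kept_sites, matrices, labels, log)


def filter_rbp_targets(
    transcripts: Mapping[str, TranscriptRecord],
    expression_rpkm: Mapping[str, float],
    min_rpkm: float = 5.0,
) -> dict[str, TranscriptRecord]:
    """Keep transcripts expressed at >= *min_rpkm* (inclusive); transcripts
    absent from the expression table are dropped with a warning."""
    missing = [tid for tid in transcripts if tid not in expression_rpkm]
    if missing:
        warnings.warn(f"{len(missing)} transcripts missing from RPKM table", stacklevel=2)
    return {
        tid: tx
        for tid, tx in transcripts.items()
        if tid in expression_rpkm and expression_rpkm[tid] >= min_rpkm
    }


def sites_to_bed(sites: Iterable[MotifSite], rbp_name: str) -> pd.DataFrame:
    """Site set as a BED6-shaped table (name=RBP, score=1/0 for label)."""
    rows = [
        (s.transcript_id, s.start, s.end, rbp_name, 1 if s.label == SiteLabel.POSITIVE else 0, "+")
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def feature_matrix_to_frame(fm: FeatureMatrix, spec: WindowSpec) -> pd.DataFrame:
    """Feature matrix as a TSV-ready table; columns name reagent and offset
    relative to the motif start (e.g. ``accessibility_probe_-5``)."""
    cols = {}
    offsets = range(-spec.flank, spec.motif_length + spec.flank)
    for r, mat in fm.matrices.items():
        for j, off in enumerate(offsets):
            cols[f"{r}_{off:+d}"] = mat[:, j]
    df = pd.DataFrame(cols)
    df.insert(0, "label", fm.labels)
    df.insert(0, "start", [s.start for s in fm.sites])
    df.insert(0, "transcript_id", [s.transcript_id for s in fm.sites])
    return df
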