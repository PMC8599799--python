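"""PolyA-site calling from 3'-end sequencing and PAS feature windows.

3'-end sequencing by polyA-tail priming localizes cleavage/polyadenylation
junctions as pileups of read 3' ends.  This module piles up read ends,
merges nearby high-count positions into called sites, anchors each site to
an upstream AAUAAA polyadenylation signal (PAS), stratifies sites into
active/inactive by read depth, and builds the 46-nt reactivity windows
(signal hexamer plus 20 nt per side) used to classify PAS usage from
structure probing alone.

Coordinate conventions: the cleavage position is the 0-based transcript
position of the read-inferred junction; ``signal_start`` is the first base
of the AAUAAA hexamer; ``signal_distance = cleavage_pos - (signal_start + 6)``
is the gap between the signal's 3' end and the cleavage site.  Plots and
metaprofiles are centered on the uridine of AAUAAA, i.e. ``signal_start + 2``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TranscriptRecord, ValidationError
from .reactivity import ReactivityProfile
from .sites import (
    FeatureMatrix,
    MotifSite,
    SiteLabel,
    WindowSpec,
    assemble_feature_matrix,
    scan_motif,
)

#: the canonical polyadenylation signal, DNA alphabet
PAS_MOTIF = "AATAAA"
#: offset of the uridine within AAUAAA — the metaprofile zero point
SIGNAL_U_OFFSET = 2


class Activity(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PASSite:
    transcript_id: str
    cleavage_pos: int
    read_count: int
    signal_start: int | None = None
    activity: Activity = Activity.UNASSIGNED

    @property
    def signal_distance(self) -> int | None:
        if self.signal_start is None:
            return None
        return self.cleavage_pos - (self.signal_start + len(PAS_MOTIF))


def pileup_3prime(end3_positions: Sequence[int], transcript_length: int) -> np.ndarray:
    """counts[i] = number of reads whose 3' end maps to position i."""
    pos = np.asarray(end3_positions, dtype=int)
    if pos.size and (pos.min() < 0 or pos.max() >= transcript_length):
        raise ValidationError("read 3' end outside transcript")
    return np.bincount(pos, minlength=transcript_length).astype(int)


def call_pas_sites(
    pileup: np.ndarray,
    transcript_id: str,
    min_reads: int = 5,
    cluster_distance: int = 10,
) -> list[PASSite]:
    """Cluster above-threshold pileup positions into called cleavage sites.

    Positions with count >= *min_reads* are merged greedily left-to-right
    while consecutive qualifying positions are within *cluster_distance* of
    each other.  Each cluster is reported at its modal position (ties broken
    toward the 3' end) with the cluster's summed read count.
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    pileup = np.asarray(pileup)
    qual = np.flatnonzero(pileup >= min_reads)
    sites: list[PASSite] = []
    if qual.size == 0:
        return sites
    cluster = [qual[0]]
    for p in qual[1:]:
        if p - cluster[-1] <= cluster_distance:
            cluster.append(p)
        else:
            sites.append(_finish_cluster(cluster, pileup, transcript_id))
            cluster = [p]
    sites.append(_finish_cluster(cluster, pileup, transcript_id))
    return sites


def _finish_cluster(cluster: list[int], pileup: np.ndarray, transcript_id: str) -> PASSite:
    counts = pileup[cluster]
    best = max(range(len(cluster)), key=lambda i: (counts[i], cluster[i]))
    return PASSite(transcript_id, int(cluster[best]), int(counts.sum()))


def anchor_to_signal(
    site: PASSite,
    transcript: TranscriptRecord,
    d_min: int = 10,
    d_max: int = 40,
) -> PASSite:
    """Attach the closest upstream AAUAAA whose 3' end lies d_min..d_max nt
    upstream of the cleavage position; unassignable sites keep
    ``signal_start=None`` and stay ``unassigned``."""
    m = len(PAS_MOTIF)
    best = None
    for s in scan_motif(transcript, PAS_MOTIF):
        dist = site.cleavage_pos - (s + m)
        if d_min <= dist <= d_max and (best is None or dist < best[0]):
            best = (dist, s)
    if best is None:
        return site
    return replace(site, signal_start=best[1])


def classify_activity(
    sites: Sequence[PASSite],
    high_quantile: float = 0.75,
    low_quantile: float = 0.25,
) -> list[PASSite]:
    """Stratify signal-assigned sites into active / inactive by read depth.

    Sites at or above the *high_quantile* of assigned-site read counts are
    active, at or below the *low_quantile* inactive; the middle band stays
    unassigned (excluded from training).  With all counts equal both
    thresholds coincide, so every site satisfies both bounds and the active
    label wins (checked first).
    """
    assigned = [s for s in sites if s.signal_start is not None]
    if not assigned:
        raise ValidationError("no signal-assigned sites to classify")
    counts = np.array([s.read_count for s in assigned], dtype=float)
    hi = np.quantile(counts, high_quantile)
    lo = np.quantile(counts, low_quantile)
    out = []
    for s in sites:
        if s.signal_start is None:
            out.append(s)
        elif s.read_count >= hi:
            out.append(replace(s, activity=Activity.ACTIVE))
        elif s.read_count <= lo:
            out.append(replace(s, activity=Activity.INACTIVE))
        else:
            out.append(replace(s, activity=Activity.UNASSIGNED))
    return out


def pas_training_sites(
    sites: Sequence[PASSite],
    transcripts: Mapping[str, TranscriptRecord],
    signal_buffer: int = 0,
) -> list[MotifSite]:
    """Positive/negative motif sites for the PAS classifier.

    Positives are the AAUAAA signals of active called sites.  Negatives are
    AAUAAA occurrences not assigned to any called site on their transcript
    (same motif, no cleavage evidence), padded by *signal_buffer* when
    deciding 'assigned'.
    """
    assigned_signals = {
        (s.transcript_id, s.signal_start) for s in sites if s.signal_start is not None
    }
    out: list[MotifSite] = []
    for s in sites:
        if s.activity == Activity.ACTIVE and s.signal_start is not None:
            out.append(
                MotifSite(s.transcript_id, s.signal_start, PAS_MOTIF, SiteLabel.POSITIVE)
            )
    for tid, tx in transcripts.items():
        for start in scan_motif(tx, PAS_MOTIF):
            near = any(
                t == tid and abs(start - ss) <= signal_buffer
                for t, ss in assigned_signals
            )
            if not near:
                out.append(MotifSite(tid, start, PAS_MOTIF, SiteLabel.NEGATIVE))
    # dedupe (a position can only carry one label; positives win)
    seen: dict[tuple[str, int], MotifSite] = {}
    for site in out:
        key = (site.transcript_id, site.start)
        if key not in seen or site.label == SiteLabel.POSITIVE:
            seen[key] = site
    return sorted(seen.values(), key=lambda s: (s.transcript_id, s.start))


def pas_feature_windows(
    profiles_by_reagent: Mapping[str, Mapping[str, ReactivityProfile]],
    training_sites: Sequence[MotifSite],
    flank: int = 20,
) -> FeatureMatrix:
    """46-nt reactivity windows centered on the PAS hexamer (flank 20)."""
    spec = WindowSpec(motif_length=len(PAS_MOTIF), flank=flank)
    return assemble_feature_matrix(training_sites, profiles_by_reagent, spec)


def pas_metaprofile(
    pileups: Mapping[str, np.ndarray],
    sites: Sequence[PASSite],
    flank_up: int = 30,
    flank_down: int = 60,
) -> pd.DataFrame:
    """Cumulative 3'-end read density around the signal uridine.

    Offsets are relative to ``signal_start + 2``; the value at each offset
    is the summed read count over all assigned sites, so total mass equals
    the reads contributed by in-window positions.
    """
    width = flank_up + flank_down + 1
    total = np.zeros(width)
    for s in sites:
        if s.signal_start is None:
            continue
        center = s.signal_start + SIGNAL_U_OFFSET
        pile = pileups[s.transcript_id]
        for j in range(width):
            p = center - flank_up + j
            if 0 <= p < len(pile):
                total[j] += pile[p]
    return pd.DataFrame(
        {"offset": np.arange(-flank_up, flank_down + 1), "read_count": total}
    )


def pas_sites_to_bed(sites: Iterable[PASSite]) -> pd.DataFrame:
    """Called sites as a BED6-shaped table (name=activity, score=read count)."""
    rows = [
        (s.transcript_id, s.cleavage_pos, s.cleavage_pos + 1, s.activity.value, s.read_count, "+")
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
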