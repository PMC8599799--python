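"""Per-nucleotide reactivity scoring from RT-stop counts.

Chemical probing reads out structure through reverse-transcriptase (RT)
stops: the polymerase terminates one nucleotide 3' of a chemical adduct, so
the 5' end of an aligned read marks the base after the modified one.  This
module converts paired treatment/control stop-count tracks into normalized
reactivity profiles in [0, 1], computes the in-cell minus in-vitro
difference track (VTD, "in vivo-to-in vitro difference"), and summarises
profiles as hexamer tables and anchor-aligned metaprofiles.

Scoring model
-------------
With treatment stop counts ``T_i``, control stop counts ``B_i``, control
base density (coverage) ``D_i``, and a library-size factor
``f = treatment.total_mapped / control.total_mapped``, the raw enrichment
score at position i is

    s_i = max(0, T_i - alpha * f * B_i) / max(f * D_i, epsilon)

i.e. background-subtracted stops per unit of background coverage.  Positions
failing the coverage filters (``T_i < T_min`` or ``f * D_i < t_min``) are
null; both thresholds default to 0 so nothing is filtered.  Raw scores are
then normalized per transcript by the mean of the values between two winsor
percentiles of the positive scores and clamped to [0, 1].

Null scores are represented as NaN throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TranscriptRecord, ValidationError


class Condition(str, enum.Enum):
    IN_CELL = "in_cell"
    IN_VITRO = "in_vitro"


class Reagent(str, enum.Enum):
    #: acylation probe reading 2'-OH flexibility (icSHAPE-class)
    FLEXIBILITY = "flexibility_probe"
    #: nicotinoyl-azide probe reading purine C8 solvent accessibility (LASER-class)
    ACCESSIBILITY = "accessibility_probe"
    CONTROL = "control"


@dataclass
class StopCountTrack:
    """RT-stop counts and base density for one library on one transcript."""

    transcript_id: str
    condition: Condition
    reagent: Reagent
    stops: np.ndarray
    density: np.ndarray
    total_mapped: float = 1.0

    def __post_init__(self) -> None:
        self.stops = np.asarray(self.stops, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.stops.shape != self.density.shape:
            raise ValidationError("stops and density must have equal length")
        if (self.stops < 0).any() or (self.density < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.total_mapped <= 0:
            raise ValidationError("total_mapped must be positive")

    @property
    def length(self) -> int:
        return len(self.stops)


@dataclass(frozen=True)
class ScoringParams:
    """Knobs of the enrichment scorer; defaults follow the pipeline's
    documented behaviour class with the final coverage filters disabled
    (``min_hit_coverage = min_background_density = 0``)."""

    alpha: float = 0.25
    epsilon: float = 1.0
    winsor_lo: float = 90.0
    winsor_hi: float = 99.0
    min_hit_coverage: float = 0.0  # -T
    min_background_density: float = 0.0  # -t

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must be in [0, 1]")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if not self.winsor_lo < self.winsor_hi:
            raise ValidationError("winsor_lo must be < winsor_hi")


@dataclass
class ReactivityProfile:
    """Normalized per-position reactivity; NaN marks null (filtered) positions."""

    transcript_id: str
    reagent: Reagent
    condition: Condition
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("non-null reactivities must lie in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.scores)


@dataclass
class VTDTrack:
    """Per-position in-cell minus in-vitro reactivity difference."""

    transcript_id: str
    reagent: Reagent
    diffs: np.ndarray


def stops_from_read_ends(read_5prime_positions: Sequence[int], transcript_length: int) -> np.ndarray:
    """Convert 5'-end read positions to per-position RT-stop counts.

    A read whose 5'-most aligned base is at p places the adduct (the stop) at
    p - 1; reads starting at position 0 have no upstream base and contribute
    nothing.
    """
    pos = np.asarray(read_5prime_positions, dtype=int)
    if pos.size and (pos.min() < 0 or pos.max() >= transcript_length):
        raise ValidationError("read position outside transcript")
    stops = np.bincount(pos[pos > 0] - 1, minlength=transcript_length)
    return stops.astype(float)


def enrichment_score(
    treatment: StopCountTrack,
    control: StopCountTrack,
    params: ScoringParams = ScoringParams(),
) -> np.ndarray:
    """Raw per-position enrichment scores (see module docstring for the model)."""
    if treatment.transcript_id != control.transcript_id:
        raise ValidationError("treatment and control must share a transcript")
    if treatment.length != control.length:
        raise ValidationError("track length mismatch")
    if treatment.reagent == Reagent.CONTROL:
        raise ValidationError("treatment track cannot carry the control reagent")
    f = treatment.total_mapped / control.total_mapped
    scaled_b = f * control.stops
    scaled_d = f * control.density
    if params.epsilon == 0 and not scaled_d.any():
        raise ValidationError("all-zero control density with epsilon=0")
    s = (treatment.stops - params.alpha * scaled_b) / np.maximum(scaled_d, params.epsilon)
    s = np.maximum(s, 0.0)
    null = (scaled_d < params.min_background_density) | (
        treatment.stops < params.min_hit_coverage
    )
    s[null] = np.nan
    return s


def normalize_profile(
    raw_scores: np.ndarray,
    params: ScoringParams = ScoringParams(),
    *,
    transcript_id: str = "",
    reagent: Reagent = Reagent.ACCESSIBILITY,
    condition: Condition = Condition.IN_CELL,
) -> ReactivityProfile:
    """Scale raw scores to [0, 1] by the winsorised-mean rule.

    The normalizer is the mean of the non-null positive scores lying between
    the ``winsor_lo`` and ``winsor_hi`` percentiles; values are divided by it
    and clamped to [0, 1].  All-null or all-zero input passes through
    unchanged (already within the contract range).
    """
    raw = np.asarray(raw_scores, dtype=float)
    pos = raw[~np.isnan(raw) & (raw > 0)]
    if pos.size == 0:
        scores = raw.copy()
    else:
        lo = np.percentile(pos, params.winsor_lo)
        hi = np.percentile(pos, params.winsor_hi)
        band = pos[(pos >= lo) & (pos <= hi)]
        norm = band.mean() if band.size else pos.max()
        scores = np.clip(raw / norm, 0.0, 1.0) if norm > 0 else raw.copy()
    return ReactivityProfile(transcript_id, reagent, condition, scores)


def score_track_pair(
    treatment: StopCountTrack,
    control: StopCountTrack,
    params: ScoringParams = ScoringParams(),
) -> ReactivityProfile:
    """enrichment_score followed by normalize_profile, keeping track metadata."""
    raw = enrichment_score(treatment, control, params)
    return normalize_profile(
        raw,
        params,
        transcript_id=treatment.transcript_id,
        reagent=treatment.reagent,
        condition=treatment.condition,
    )


def vtd(in_cell: ReactivityProfile, in_vitro: ReactivityProfile) -> VTDTrack:
    """In-cell minus in-vitro reactivity; NaN wherever either input is null.

    Negative values flag in-cell protection, e.g. a protein footprint.
    """
    if in_cell.transcript_id != in_vitro.transcript_id:
        raise ValidationError("transcript mismatch")
    if in_cell.reagent != in_vitro.reagent:
        raise ValidationError("reagent mismatch")
    if in_cell.condition != Condition.IN_CELL or in_vitro.condition != Condition.IN_VITRO:
        raise ValidationError("profiles must be (in_cell, in_vitro) in that order")
    return VTDTrack(in_cell.transcript_id, in_cell.reagent, in_cell.scores - in_vitro.scores)


def hexamer_vtd(
    vtd_tracks: Mapping[str, VTDTrack],
    transcripts: Mapping[str, TranscriptRecord],
    min_occurrences: int = 1,
) -> pd.DataFrame:
    """Mean VTD per hexamer over all fully-non-null occurrences.

    Each occurrence contributes the mean of its six per-position VTD values;
    the table averages those per-occurrence means.  Hexamers with fewer than
    *min_occurrences* usable occurrences are omitted.  Returns a DataFrame
    with columns ``hexamer``, ``n``, ``mean_vtd`` sorted by ``mean_vtd``.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for tid, track in vtd_tracks.items():
        seq = transcripts[tid].sequence
        d = track.diffs
        for start in range(len(seq) - 5):
            window = d[start : start + 6]
            if np.isnan(window).any():
                continue
            hexamer = seq[start : start + 6]
            if "N" in hexamer:
                continue
            sums[hexamer] = sums.get(hexamer, 0.0) + float(window.mean())
            counts[hexamer] = counts.get(hexamer, 0) + 1
    rows = [
        (h, counts[h], sums[h] / counts[h])
        for h in sums
        if counts[h] >= min_occurrences
    ]
    df = pd.DataFrame(rows, columns=["hexamer", "n", "mean_vtd"])
    return df.sort_values("mean_vtd", ignore_index=True)


def metaprofile(
    profiles: Mapping[str, ReactivityProfile],
    anchors: Iterable[tuple[str, int]],
    flank_up: int,
    flank_down: int,
) -> pd.DataFrame:
    """Average reactivity around anchor positions.

    Offsets run from ``-flank_up`` to ``+flank_down`` relative to each anchor;
    windows truncated by transcript ends contribute only their existing
    offsets, and null scores are excluded from the mean.  Returns a DataFrame
    with columns ``offset``, ``n``, ``mean`` (``mean`` NaN where n == 0).
    """
    width = flank_up + flank_down + 1
    total = np.zeros(width)
    n = np.zeros(width, dtype=int)
    for tid, pos in anchors:
        prof = profiles[tid]
        if not 0 <= pos < prof.length:
            raise ValidationError(f"anchor {pos} outside transcript {tid}")
        for j in range(width):
            p = pos - flank_up + j
            if 0 <= p < prof.length and not np.isnan(prof.scores[p]):
                total[j] += prof.scores[p]
                n[j] += 1
    mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {"offset": np.arange(-flank_up, flank_down + 1), "n": n, "mean": mean}
    )
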