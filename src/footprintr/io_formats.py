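"""Readers and writers for the on-disk formats the pipeline consumes and emits.

All coordinates are 0-based half-open throughout the package; BED-like files
match this convention natively and any 1-based input must be converted before
it reaches these functions.  Sequences are stored internally in the DNA
alphabet (T, not U); RNA input is converted on the way in, so motifs given as
RNA (e.g. ``AAUAAA``) and transcriptome FASTA files using T coexist safely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed content violated a semantic invariant (coordinates, alphabet...)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises :class:`ValidationError` on characters outside {A,C,G,T,U,N}.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValidationError(f"invalid sequence characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence in transcript coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.id:
            raise ValidationError("transcript id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeakInterval:
    """A half-open interval on a transcript, e.g. an eCLIP peak.

    ``name`` typically carries the RBP; ``score`` is optional metadata.
    """

    transcript_id: str
    start: int
    end: int
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """True if [start, end) shares at least one base with this interval."""
        return self.start < end and start < self.end


def read_transcripts(path) -> dict[str, TranscriptRecord]:
    """Read a multi-record FASTA into a mapping id -> TranscriptRecord.

    Duplicate IDs and out-of-alphabet characters are rejected.
    """
    records: dict[str, TranscriptRecord] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError on bad FASTA
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    for rec in parsed:
        if rec.id in records:
            raise ValidationError(f"duplicate transcript id {rec.id!r} in {path}")
        records[rec.id] = TranscriptRecord(rec.id, str(rec.seq))
    return records


def write_transcripts(transcripts: Mapping[str, TranscriptRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for tx in transcripts.values():
            fh.write(f">{tx.id}\n")
            for i in range(0, tx.length, width):
                fh.write(tx.sequence[i : i + width] + "\n")


def read_intervals(
    path,
    transcripts: Mapping[str, TranscriptRecord] | None = None,
    on_unknown: str = "error",
) -> list[PeakInterval]:
    """Read a BED3+ file of transcript-space intervals.

    Columns: transcript_id, start, end[, name[, score]].  Intervals are
    validated against *transcripts* when given; ``on_unknown`` chooses between
    ``"error"`` and ``"skip"`` for IDs missing from that set.
    """
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    out: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            tid, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            if transcripts is not None:
                tx = transcripts.get(tid)
                if tx is None:
                    if on_unknown == "skip":
                        continue
                    raise ValidationError(f"{path}:{lineno}: unknown transcript {tid!r}")
                if end > tx.length:
                    raise ValidationError(
                        f"{path}:{lineno}: interval end {end} beyond transcript length {tx.length}"
                    )
            out.append(PeakInterval(tid, start, end, name, score))
    return out


def write_intervals(intervals: Iterable[PeakInterval], path) -> None:
    """Write intervals as BED5 (score column '.' when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.transcript_id}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\n")


STOP_COUNT_COLUMNS = ["transcript_id", "position", "stop_count", "base_density"]


def read_stop_count_table(path, transcripts: Mapping[str, TranscriptRecord]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a sparse per-position stop-count TSV into dense per-transcript arrays.

    The file has a header line with columns ``transcript_id``, ``position``
    (0-based), ``stop_count``, ``base_density``; positions absent from the
    file are dense zeros.  Returns ``{transcript_id: (stops, density)}`` with
    float arrays of the full transcript length.  The caller attaches
    condition/reagent metadata (one library per file).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STOP_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df["stop_count"] < 0).any() or (df["base_density"] < 0).any():
        raise ValidationError(f"{path}: negative counts")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid, sub in df.groupby("transcript_id", sort=False):
        tx = transcripts.get(str(tid))
        if tx is None:
            raise ValidationError(f"{path}: unknown transcript {tid!r}")
        pos = sub["position"].to_numpy(dtype=int)
        if (pos < 0).any() or (pos >= tx.length).any():
            raise ValidationError(f"{path}: position outside [0, {tx.length}) for {tid}")
        stops = np.zeros(tx.length)
        dens = np.zeros(tx.length)
        stops[pos] = sub["stop_count"].to_numpy(dtype=float)
        dens[pos] = sub["base_density"].to_numpy(dtype=float)
        out[str(tid)] = (stops, dens)
    # transcripts never mentioned in the file are all-zero tracks
    for tid, tx in transcripts.items():
        out.setdefault(tid, (np.zeros(tx.length), np.zeros(tx.length)))
    return out


def write_stop_count_table(tracks: Mapping[str, tuple[np.ndarray, np.ndarray]], path) -> None:
    """Write dense tracks sparsely: only positions where stops or density is non-zero."""
    rows = []
    for tid, (stops, dens) in tracks.items():
        nz = np.nonzero((stops != 0) | (dens != 0))[0]
        for p in nz:
            rows.append((tid, int(p), stops[p], dens[p]))
    pd.DataFrame(rows, columns=STOP_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_reactivity_bedgraph(scores_by_transcript: Mapping[str, np.ndarray], path, track_name: str = "reactivity") -> None:
    """Write per-position scores as bedGraph, run-length compressed.

    NaN positions (null scores) are omitted; scores are printed to six
    decimal places so a write/read round trip restores them to 1e-6.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for tid, scores in scores_by_transcript.items():
            scores = np.asarray(scores, dtype=float)
            run_start = None
            run_val = None
            for i in range(len(scores) + 1):
                v = scores[i] if i < len(scores) else np.nan
                same = (
                    run_val is not None
                    and not np.isnan(v)
                    and f"{v:.6f}" == f"{run_val:.6f}"
                )
                if same:
                    continue
                if run_val is not None:
                    fh.write(f"{tid}\t{run_start}\t{i}\t{run_val:.6f}\n")
                run_start, run_val = (i, v) if (i < len(scores) and not np.isnan(v)) else (None, None)


def read_reactivity_bedgraph(path, transcripts: Mapping[str, TranscriptRecord]) -> dict[str, np.ndarray]:
    """Inverse of :func:`write_reactivity_bedgraph`; unlisted positions are NaN."""
    out = {tid: np.full(tx.length, np.nan) for tid, tx in transcripts.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            tid, start_s, end_s, val_s = line.split("\t")
            start, end, val = int(start_s), int(end_s), float(val_s)
            if tid not in out:
                raise ValidationError(f"{path}:{lineno}: unknown transcript {tid!r}")
            if not (0 <= start < end <= len(out[tid])):
                raise ValidationError(f"{path}:{lineno}: interval outside transcript")
            out[tid][start:end] = val
    return out


def read_run_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return cfg
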