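"""Synthetic transcriptome and probing experiment with known ground truth.

The generator emulates the full data-generating process the pipeline was
built for, end to end:

* random transcript sequences with planted RBP motif instances (a known
  subset bound by protein), start codons, and polyadenylation signals
  (AAUAAA) near the 3' end;
* smooth per-position ground-truth solvent accessibility and flexibility,
  identical between conditions except where a bound protein suppresses
  in-cell reactivity (the footprint);
* overdispersed (negative-binomial) RT-stop and coverage counts for two
  reagents x two conditions x treatment/control, with reagent base
  specificity (the accessibility probe reads A/G strongly; the acylation
  probe has a mild A/U preference);
* occupancy peak intervals covering exactly the bound motif instances;
* 3'-end reads piling up around the true cleavage position downstream of
  each active polyadenylation signal.

Every stage is deterministic given ``SimulationParams.seed``.  Footprints
at bound RBP sites are placed in either the accessibility or the
flexibility channel per site (the complementarity knob), so neither reagent
alone sees every bound site — combining reagents is genuinely informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import PeakInterval, TranscriptRecord, ValidationError
from .reactivity import Condition, Reagent, StopCountTrack
from .pas import PAS_MOTIF

# base-specificity weights: relative modification propensity per base
ACCESSIBILITY_BASE_WEIGHTS = {"A": 1.0, "G": 1.0, "C": 0.1, "T": 0.1}
FLEXIBILITY_BASE_WEIGHTS = {"A": 1.0, "T": 1.0, "C": 0.6, "G": 0.6}

# accessibility signature planted at polyadenylation signals: the first two
# adenosines solvent-exposed, the UAAA tail protein-protected
PAS_ACCESSIBILITY_PATTERN = np.array([0.9, 0.9, 0.08, 0.15, 0.15, 0.15])


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment.

    Defaults define the reference conditions used throughout the test
    suite: 100 transcripts of 500-800 nt; 5 bound and 5 unbound instances
    of a purine-rich 5-mer per transcript; mean coverage 200x; treatment
    modification rate 10x the background stop rate; 50% footprint
    suppression split evenly between the two reagent channels.
    """

    n_transcripts: int = 100
    length_min: int = 500
    length_max: int = 800
    seed: int = 0
    # probing counts
    coverage: float = 200.0  # mean per-position base density (lambda)
    background_stop_rate: float = 0.02  # beta0: stops per unit coverage, control
    modification_rate: float = 0.2  # beta1: added stop rate at full reactivity
    overdispersion: float = 50.0  # NB phi; variance = mu + mu^2/phi
    # RBP footprints
    rbp_motif: str = "AGGAC"
    bound_per_transcript: int = 5
    unbound_per_transcript: int = 5
    footprint_effect: float = 0.5  # delta: fractional in-cell suppression
    footprint_shoulder: int = 2  # extra suppressed nt each side of the motif
    shoulder_weight: float = 1.0
    accessibility_share: float = 0.5  # fraction of footprints in the accessibility channel
    peak_jitter: int = 5
    # start codons
    plant_start_codons: bool = True
    start_codon_boost: float = 0.95
    # polyadenylation
    pas_per_transcript: int = 2
    pas_decoys_per_transcript: int = 2  # unused AAUAAA occurrences (clean negatives)
    pas_active_fraction: float = 0.5
    pas_cleavage_gap: int = 18  # nt from signal 3' end to cleavage
    pas_cleavage_sd: float = 2.0  # spread of read 3' ends around cleavage
    pas_reads_per_active: float = 80.0  # mean reads at a strongly used site
    pas_reads_per_inactive: float = 20.0  # mean reads at a weakly used site
    pas_background_reads: float = 2.0  # mean stray reads per transcript
    pas_intrinsic_blend: float = 0.5  # sequence-intrinsic pattern weight (used PAS)

    def __post_init__(self) -> None:
        if not 0 <= self.footprint_effect <= 1:
            raise ValidationError("footprint_effect must be in [0, 1]")
        if self.length_min < 200 or self.length_min > self.length_max:
            raise ValidationError("need 200 <= length_min <= length_max")
        if not 0 <= self.accessibility_share <= 1:
            raise ValidationError("accessibility_share must be in [0, 1]")


@dataclass
class PlantedPAS:
    transcript_id: str
    signal_start: int
    cleavage_pos: int
    active: bool


@dataclass
class BoundSite:
    transcript_id: str
    start: int
    channel: str  # "accessibility_probe" or "flexibility_probe"


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    transcripts: dict[str, TranscriptRecord]
    bound_sites: list[BoundSite]
    unbound_sites: list[tuple[str, int]]  # planted, protein-free instances
    planted_pas: list[PlantedPAS]
    decoy_pas: list[tuple[str, int]]  # AAUAAA with no cleavage activity
    start_codons: list[tuple[str, int]]
    peaks: list[PeakInterval] = field(default_factory=list)
    # per condition -> transcript -> per-position truth in [0, 1]
    accessibility: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    flexibility: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def truth_for(self, reagent: Reagent, condition: Condition) -> dict[str, np.ndarray]:
        table = self.accessibility if reagent == Reagent.ACCESSIBILITY else self.flexibility
        return table[condition.value]

    def footprint_mask(self, params: SimulationParams) -> dict[str, np.ndarray]:
        """Boolean per-position mask of all footprinted positions (any channel)."""
        masks = {tid: np.zeros(tx.length, dtype=bool) for tid, tx in self.transcripts.items()}
        m = len(params.rbp_motif)
        for b in self.bound_sites:
            lo = max(0, b.start - params.footprint_shoulder)
            hi = min(len(masks[b.transcript_id]), b.start + m + params.footprint_shoulder)
            masks[b.transcript_id][lo:hi] = True
        return masks


_STAGE_IDS = {
    "sequences": 1,
    "truth": 2,
    "peaks": 3,
    "pas_reads": 4,
    "reads": 5,
}


def _stage_rng(params: SimulationParams, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([params.seed, _STAGE_IDS[stage], extra])
    )


def simulate_transcriptome(params: SimulationParams) -> GroundTruth:
    """Random sequences with planted motifs, start codons and PAS elements."""
    rng = _stage_rng(params, "sequences")
    bases = np.array(list("ACGT"))
    motif = params.rbp_motif.upper().replace("U", "T")
    m = len(motif)
    transcripts: dict[str, TranscriptRecord] = {}
    bound: list[BoundSite] = []
    unbound: list[tuple[str, int]] = []
    planted_pas: list[PlantedPAS] = []
    decoys: list[tuple[str, int]] = []
    start_codons: list[tuple[str, int]] = []
    for t in range(params.n_transcripts):
        tid = f"tx{t:04d}"
        L = int(rng.integers(params.length_min, params.length_max + 1))
        seq = rng.choice(bases, size=L)
        # 3' block: PAS elements every 80 nt walking upstream from L-60
        pas_positions = []
        for k in range(params.pas_per_transcript):
            sig = L - 60 - 80 * k
            if sig < 60:
                break
            pas_positions.append(sig)
        pas_zone_start = min(pas_positions) - 10 if pas_positions else L
        # planting slots: non-overlapping 20-nt slots clear of ends and the
        # PAS zone; RBP motif instances and decoy AAUAAA elements share them
        slot_hi = min(L - 20, pas_zone_start) - 20
        slots = np.arange(30, slot_hi, 20)
        n_motifs = params.bound_per_transcript + params.unbound_per_transcript
        n_needed = n_motifs + params.pas_decoys_per_transcript
        if len(slots) < n_needed:
            raise ValidationError(
                "transcripts too short for the requested number of planted elements"
            )
        chosen = rng.choice(slots, size=n_needed, replace=False)
        rng.shuffle(chosen)
        for j, s in enumerate(chosen):
            if j < params.bound_per_transcript:
                seq[s : s + m] = list(motif)
                channel = (
                    Reagent.ACCESSIBILITY.value
                    if rng.random() < params.accessibility_share
                    else Reagent.FLEXIBILITY.value
                )
                bound.append(BoundSite(tid, int(s), channel))
            elif j < n_motifs:
                seq[s : s + m] = list(motif)
                unbound.append((tid, int(s)))
            else:
                seq[s : s + 6] = list(PAS_MOTIF)
                decoys.append((tid, int(s)))
        for sig in pas_positions:
            seq[sig : sig + 6] = list(PAS_MOTIF)
            cleavage = sig + 6 + params.pas_cleavage_gap
            active = rng.random() < params.pas_active_fraction
            planted_pas.append(PlantedPAS(tid, int(sig), int(cleavage), active))
        if params.plant_start_codons:
            seq[20:23] = list("ATG")
            start_codons.append((tid, 20))
        transcripts[tid] = TranscriptRecord(tid, "".join(seq))
    return GroundTruth(
        transcripts=transcripts,
        bound_sites=bound,
        unbound_sites=unbound,
        planted_pas=planted_pas,
        decoy_pas=decoys,
        start_codons=start_codons,
    )


def _smooth_baseline(rng: np.random.Generator, length: int, window: int = 5) -> np.ndarray:
    """Locally correlated baseline: moving average of uniform noise."""
    raw = rng.uniform(0.05, 1.0, size=length + window - 1)
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="valid")


def simulate_truth_profiles(params: SimulationParams, truth: GroundTruth) -> GroundTruth:
    """Fill per-position accessibility/flexibility truth for both conditions.

    The in-vitro profile is the smooth baseline plus sequence-intrinsic
    features (start-codon exposure, the partial PAS signature).  The in-cell
    profile additionally carries protein footprints: multiplicative
    suppression ``(1 - delta * weight)`` over each bound RBP motif plus
    shoulders — in the site's assigned reagent channel only — and the full
    PAS accessibility signature with flexibility suppression at active PAS.
    """
    rng = _stage_rng(params, "truth")
    m = len(params.rbp_motif)
    for table in ("accessibility", "flexibility"):
        getattr(truth, table).clear()
        getattr(truth, table)[Condition.IN_CELL.value] = {}
        getattr(truth, table)[Condition.IN_VITRO.value] = {}
    for tid, tx in truth.transcripts.items():
        base_a = _smooth_baseline(rng, tx.length)
        base_f = _smooth_baseline(rng, tx.length)
        if params.plant_start_codons:
            for t2, pos in truth.start_codons:
                if t2 == tid:
                    # A and G of the AUG are exposed; intrinsic, both conditions
                    base_a[pos] = params.start_codon_boost
                    base_a[pos + 2] = params.start_codon_boost
        a_vitro, f_vitro = base_a.copy(), base_f.copy()
        a_cell, f_cell = base_a.copy(), base_f.copy()
        truth.accessibility[Condition.IN_VITRO.value][tid] = a_vitro
        truth.accessibility[Condition.IN_CELL.value][tid] = a_cell
        truth.flexibility[Condition.IN_VITRO.value][tid] = f_vitro
        truth.flexibility[Condition.IN_CELL.value][tid] = f_cell
    # RBP footprints: in-cell only, per assigned channel
    sh, w = params.footprint_shoulder, params.shoulder_weight
    for b in truth.bound_sites:
        weights = np.concatenate([np.full(sh, w), np.ones(m), np.full(sh, w)])
        lo = b.start - sh
        arr = (
            truth.accessibility[Condition.IN_CELL.value][b.transcript_id]
            if b.channel == Reagent.ACCESSIBILITY.value
            else truth.flexibility[Condition.IN_CELL.value][b.transcript_id]
        )
        for j, wt in enumerate(weights):
            p = lo + j
            if 0 <= p < len(arr):
                arr[p] *= 1.0 - params.footprint_effect * wt
    # PAS signatures: the sequence-intrinsic part (weight `blend`) is present
    # in both conditions at every planted signal; the protein-bound part
    # (scaled by the footprint effect) deepens the signature in-cell at
    # strongly used sites and rigidifies the hexamer
    blend = params.pas_intrinsic_blend
    for ps in truth.planted_pas:
        sl = slice(ps.signal_start, ps.signal_start + 6)
        w_cell = min(1.0, blend + params.footprint_effect) if ps.active else blend
        for cond, w in (
            (Condition.IN_VITRO.value, blend),
            (Condition.IN_CELL.value, w_cell),
        ):
            a = truth.accessibility[cond][ps.transcript_id]
            a[sl] = (1 - w) * a[sl] + w * PAS_ACCESSIBILITY_PATTERN
        if ps.active:
            f = truth.flexibility[Condition.IN_CELL.value][ps.transcript_id]
            f[sl] *= 1.0 - params.footprint_effect
    return truth


def base_specificity(sequence: str, reagent: Reagent) -> np.ndarray:
    weights = (
        ACCESSIBILITY_BASE_WEIGHTS
        if reagent == Reagent.ACCESSIBILITY
        else FLEXIBILITY_BASE_WEIGHTS
    )
    return np.array([weights.get(b, 0.5) for b in sequence])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial counts with mean *mean* and var mean + mean^2/phi,
    via the Gamma-Poisson mixture (phi -> inf recovers Poisson)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if not np.isfinite(phi):
        return rng.poisson(mean).astype(float)
    lam = rng.gamma(shape=phi, scale=np.ones_like(mean) / phi) * mean
    return rng.poisson(lam).astype(float)


def simulate_probing_reads(
    truth: GroundTruth,
    params: SimulationParams,
    reagent: Reagent,
    condition: Condition,
) -> tuple[dict[str, StopCountTrack], dict[str, StopCountTrack]]:
    """Treatment and control stop-count tracks for one reagent x condition.

    Per position: coverage ``D_i ~ NB(coverage, phi)`` independently per
    library; treatment stops have mean ``D_i * (beta0 + beta1 * truth_i *
    basespec_i)`` and control stops mean ``D_i * beta0``.  ``total_mapped``
    is the library's summed stop count over the whole transcriptome.
    """
    stage_extra = {"accessibility_probe": 0, "flexibility_probe": 10}[reagent.value] + {
        "in_cell": 0,
        "in_vitro": 1,
    }[condition.value]
    rng = _stage_rng(params, "reads", stage_extra)
    truth_tracks = truth.truth_for(reagent, condition)
    treat: dict[str, StopCountTrack] = {}
    ctrl: dict[str, StopCountTrack] = {}
    raw = {}
    for tid, tx in truth.transcripts.items():
        bs = base_specificity(tx.sequence, reagent)
        r = truth_tracks[tid]
        d_treat = _nb_draw(rng, np.full(tx.length, params.coverage), params.overdispersion)
        d_ctrl = _nb_draw(rng, np.full(tx.length, params.coverage), params.overdispersion)
        t_mean = d_treat * (params.background_stop_rate + params.modification_rate * r * bs)
        b_mean = d_ctrl * params.background_stop_rate
        t = _nb_draw(rng, t_mean, params.overdispersion)
        b = _nb_draw(rng, b_mean, params.overdispersion)
        raw[tid] = (t, d_treat, b, d_ctrl)
    total_t = max(sum(r[0].sum() for r in raw.values()), 1.0)
    total_b = max(sum(r[2].sum() for r in raw.values()), 1.0)
    for tid, (t, dt, b, dc) in raw.items():
        treat[tid] = StopCountTrack(tid, condition, reagent, t, dt, total_mapped=total_t)
        ctrl[tid] = StopCountTrack(tid, condition, Reagent.CONTROL, b, dc, total_mapped=total_b)
    return treat, ctrl


def simulate_eclip_peaks(truth: GroundTruth, params: SimulationParams) -> list[PeakInterval]:
    """One occupancy peak per bound site: the motif span plus jittered flanks."""
    rng = _stage_rng(params, "peaks")
    m = len(params.rbp_motif)
    peaks = []
    for b in truth.bound_sites:
        L = truth.transcripts[b.transcript_id].length
        lo = max(0, b.start - int(rng.integers(0, params.peak_jitter + 1)))
        hi = min(L, b.start + m + int(rng.integers(0, params.peak_jitter + 1)))
        peaks.append(PeakInterval(b.transcript_id, lo, hi, "synthRBP", None))
    truth.peaks = peaks
    return peaks


def simulate_pas_reads(truth: GroundTruth, params: SimulationParams) -> dict[str, np.ndarray]:
    """3'-end read positions per transcript, as arrays of 0-based positions.

    Active planted PAS receive ``NB(pas_reads_per_active)`` reads with ends
    normally scattered (sd ``pas_cleavage_sd``) around the true cleavage
    position; inactive PAS receive a trickle; a small uniform background is
    added per transcript.
    """
    rng = _stage_rng(params, "pas_reads")
    reads: dict[str, list[int]] = {tid: [] for tid in truth.transcripts}
    for ps in truth.planted_pas:
        L = truth.transcripts[ps.transcript_id].length
        mean = params.pas_reads_per_active if ps.active else params.pas_reads_per_inactive
        n = int(_nb_draw(rng, np.array([mean]), params.overdispersion)[0])
        if n == 0:
            continue
        offs = np.rint(rng.normal(0.0, params.pas_cleavage_sd, size=n)).astype(int)
        pos = np.clip(ps.cleavage_pos + offs, 0, L - 1)
        reads[ps.transcript_id].extend(pos.tolist())
    for tid, tx in truth.transcripts.items():
        n_bg = rng.poisson(params.pas_background_reads)
        if n_bg:
            reads[tid].extend(rng.integers(0, tx.length, size=n_bg).tolist())
    return {tid: np.array(sorted(v), dtype=int) for tid, v in reads.items()}


@dataclass
class SyntheticExperiment:
    """A full generated dataset: inputs for every pipeline stage plus truth."""

    params: SimulationParams
    truth: GroundTruth
    # (reagent, condition) -> (treatment tracks, control tracks)
    probing: dict[tuple[str, str], tuple[dict[str, StopCountTrack], dict[str, StopCountTrack]]]
    peaks: list[PeakInterval]
    pas_reads: dict[str, np.ndarray]


def simulate_experiment(
    params: SimulationParams, conditions: tuple[Condition, ...] = (Condition.IN_CELL, Condition.IN_VITRO)
) -> SyntheticExperiment:
    """Run every generation stage and bundle the results."""
    truth = simulate_transcriptome(params)
    simulate_truth_profiles(params, truth)
    peaks = simulate_eclip_peaks(truth, params)
    probing = {}
    for reagent in (Reagent.ACCESSIBILITY, Reagent.FLEXIBILITY):
        for cond in conditions:
            probing[(reagent.value, cond.value)] = simulate_probing_reads(
                truth, params, reagent, cond
            )
    pas_reads = simulate_pas_reads(truth, params)
    return SyntheticExperiment(params, truth, probing, peaks, pas_reads)
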