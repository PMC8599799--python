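import numpy as np
from scipy.stats import mannwhitneyu, spearmanr

from footprintr.pas import call_pas_sites, pileup_3prime
from footprintr.reactivity import Condition, Reagent, ScoringParams, enrichment_score
from footprintr.sites import MotifSpec, build_positive_sites, scan_motif
from footprintr.synthetic_data import (
    SimulationParams,
    base_specificity,
    simulate_eclip_peaks,
    simulate_experiment,
    simulate_pas_reads,
    simulate_probing_reads,
    simulate_transcriptome,
    simulate_truth_profiles,
)

TINY = dict(n_transcripts=8, length_min=500, length_max=560, seed=4)


class TestTranscriptome:
    def test_deterministic_given_seed(self):
        a = simulate_transcriptome(SimulationParams(**TINY))
        b = simulate_transcriptome(SimulationParams(**TINY))
        assert {t.id: t.sequence for t in a.transcripts.values()} == {
            t.id: t.sequence for t in b.transcripts.values()
        }

    def test_planted_element_bookkeeping_exact(self):
        params = SimulationParams(**TINY)
        truth = simulate_transcriptome(params)
        n = params.n_transcripts
        assert len(truth.bound_sites) == n * params.bound_per_transcript
        assert len(truth.unbound_sites) == n * params.unbound_per_transcript
        assert len(truth.planted_pas) == n * params.pas_per_transcript
        assert len(truth.decoy_pas) == n * params.pas_decoys_per_transcript
        for b in truth.bound_sites:
            seq = truth.transcripts[b.transcript_id].sequence
            assert seq[b.start : b.start + 5] == params.rbp_motif

    def test_scan_detects_planted_and_spontaneous_occurrences(self):
        params = SimulationParams(**TINY)
        truth = simulate_transcriptome(params)
        planted = {
            (b.transcript_id, b.start) for b in truth.bound_sites
        } | set(truth.unbound_sites)
        found = {
            (tid, s)
            for tid, tx in truth.transcripts.items()
            for s in scan_motif(tx, params.rbp_motif)
        }
        assert planted <= found  # spontaneous extras join the unbound pool


class TestTruthProfiles:
    def test_zero_effect_makes_conditions_identical(self):
        params = SimulationParams(**TINY, footprint_effect=0.0)
        truth = simulate_truth_profiles(params, simulate_transcriptome(params))
        for tid in truth.transcripts:
            np.testing.assert_array_equal(
                truth.accessibility["in_cell"][tid], truth.accessibility["in_vitro"][tid]
            )
            np.testing.assert_array_equal(
                truth.flexibility["in_cell"][tid], truth.flexibility["in_vitro"][tid]
            )

    def test_full_effect_zeroes_footprinted_channel(self):
        params = SimulationParams(**TINY, footprint_effect=1.0)
        truth = simulate_truth_profiles(params, simulate_transcriptome(params))
        for b in truth.bound_sites:
            table = truth.accessibility if b.channel == Reagent.ACCESSIBILITY.value else truth.flexibility
            window = table["in_cell"][b.transcript_id][b.start : b.start + 5]
            assert not window.any()

    def test_footprints_depress_in_cell_truth(self):
        params = SimulationParams(**TINY)
        truth = simulate_truth_profiles(params, simulate_transcriptome(params))
        diffs = []
        for b in truth.bound_sites:
            table = truth.accessibility if b.channel == Reagent.ACCESSIBILITY.value else truth.flexibility
            cell = table["in_cell"][b.transcript_id][b.start : b.start + 5]
            vitro = table["in_vitro"][b.transcript_id][b.start : b.start + 5]
            diffs.append((cell - vitro).mean())
        assert np.mean(diffs) < 0

    def test_pas_signature_high_at_first_two_adenosines(self):
        params = SimulationParams(**TINY)
        truth = simulate_truth_profiles(params, simulate_transcriptome(params))
        active = [p for p in truth.planted_pas if p.active]
        windows = np.array(
            [
                truth.accessibility["in_cell"][p.transcript_id][
                    p.signal_start : p.signal_start + 6
                ]
                for p in active
            ]
        )
        mean = windows.mean(axis=0)
        assert mean[:2].min() > mean[2:].max()


def tiny_truth(**over):
    params = SimulationParams(**{**TINY, **over})
    return params, simulate_truth_profiles(params, simulate_transcriptome(params))


class TestProbingReads:
    def test_stop_rate_distributions_match_when_modification_off(self):
        # with beta1 = 0 treatment and control stops are exchangeable
        rejections = 0
        for seed in range(6):
            params, truth = tiny_truth(seed=seed, modification_rate=0.0)
            treat, ctrl = simulate_probing_reads(
                truth, params, Reagent.ACCESSIBILITY, Condition.IN_CELL
            )
            t = np.concatenate([v.stops for v in treat.values()])
            b = np.concatenate([v.stops for v in ctrl.values()])
            if mannwhitneyu(t, b).pvalue < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_accessibility_probe_stops_enriched_at_purines(self):
        params, truth = tiny_truth()
        treat, _ = simulate_probing_reads(
            truth, params, Reagent.ACCESSIBILITY, Condition.IN_CELL
        )
        ag_stops = total_stops = ag_bases = total_bases = 0
        for tid, tx in truth.transcripts.items():
            is_ag = np.array([b in "AG" for b in tx.sequence])
            ag_stops += treat[tid].stops[is_ag].sum()
            total_stops += treat[tid].stops.sum()
            ag_bases += is_ag.sum()
            total_bases += len(is_ag)
        assert ag_stops / total_stops > ag_bases / total_bases

    def test_flexibility_probe_has_milder_au_skew(self):
        params, truth = tiny_truth()
        ratios = {}
        for reagent, pair in (
            (Reagent.FLEXIBILITY, "AT"),
            (Reagent.ACCESSIBILITY, "AG"),
        ):
            treat, _ = simulate_probing_reads(truth, params, reagent, Condition.IN_CELL)
            hits = base = 0
            for tid, tx in truth.transcripts.items():
                mask = np.array([c in pair for c in tx.sequence])
                hits += treat[tid].stops[mask].sum()
                base += treat[tid].stops.sum()
            frac = hits / base
            seq_frac = np.mean(
                [c in pair for tx in truth.transcripts.values() for c in tx.sequence]
            )
            ratios[reagent] = frac / seq_frac
        assert 1.0 < ratios[Reagent.FLEXIBILITY] < ratios[Reagent.ACCESSIBILITY]

    def test_mean_treatment_stops_recovered_by_moment_oracle(self):
        # E[T_i] = coverage * (beta0 + beta1 * truth_i * basespec_i)
        reps = []
        for seed in range(50):
            p2 = SimulationParams(**{**TINY, "n_transcripts": 2, "seed": seed})
            t2 = simulate_truth_profiles(p2, simulate_transcriptome(p2))
            treat, _ = simulate_probing_reads(t2, p2, Reagent.ACCESSIBILITY, Condition.IN_CELL)
            tid2 = next(iter(t2.transcripts))
            exp_i = p2.coverage * (
                p2.background_stop_rate
                + p2.modification_rate
                * t2.accessibility["in_cell"][tid2]
                * base_specificity(t2.transcripts[tid2].sequence, Reagent.ACCESSIBILITY)
            )
            reps.append((treat[tid2].stops - exp_i).mean())
        # mean residual within 3 standard errors of zero
        reps = np.array(reps)
        assert abs(reps.mean()) <= 3 * reps.std(ddof=1) / np.sqrt(len(reps))

    def test_score_recovers_planted_truth_ordering(self):
        params = SimulationParams(seed=0)
        truth = simulate_truth_profiles(params, simulate_transcriptome(params))
        for reagent in (Reagent.ACCESSIBILITY, Reagent.FLEXIBILITY):
            treat, ctrl = simulate_probing_reads(truth, params, reagent, Condition.IN_CELL)
            scores, eff = [], []
            for tid, tx in truth.transcripts.items():
                scores.append(enrichment_score(treat[tid], ctrl[tid], ScoringParams()))
                eff.append(
                    truth.truth_for(reagent, Condition.IN_CELL)[tid]
                    * base_specificity(tx.sequence, reagent)
                )
            rho = spearmanr(np.concatenate(scores), np.concatenate(eff)).statistic
            assert rho >= 0.6


class TestPeaks:
    def test_zero_jitter_peak_equals_motif_span(self):
        params, truth = tiny_truth(peak_jitter=0)
        peaks = simulate_eclip_peaks(truth, params)
        for peak, b in zip(peaks, truth.bound_sites):
            assert (peak.start, peak.end) == (b.start, b.start + 5)

    def test_bound_covered_unbound_disjoint(self):
        params, truth = tiny_truth()
        peaks = simulate_eclip_peaks(truth, params)
        by_tx = {}
        for p in peaks:
            by_tx.setdefault(p.transcript_id, []).append(p)
        for b in truth.bound_sites:
            assert any(p.overlaps(b.start, b.start + 5) for p in by_tx[b.transcript_id])
        for tid, s in truth.unbound_sites:
            assert not any(p.overlaps(s, s + 5) for p in by_tx.get(tid, []))

    def test_jittered_peaks_satisfy_positive_site_invariant(self):
        params, truth = tiny_truth(peak_jitter=5)
        peaks = simulate_eclip_peaks(truth, params)
        positives, dropped = build_positive_sites(
            peaks, MotifSpec("R", params.rbp_motif), truth.transcripts
        )
        assert dropped == 0
        planted = {(b.transcript_id, b.start) for b in truth.bound_sites}
        assert planted <= {(s.transcript_id, s.start) for s in positives}


class TestPASReads:
    def test_no_activity_and_no_background_means_no_reads(self):
        params, truth = tiny_truth(
            pas_active_fraction=0.0, pas_reads_per_inactive=0.0, pas_background_reads=0.0
        )
        reads = simulate_pas_reads(truth, params)
        assert all(len(v) == 0 for v in reads.values())

    def test_read_mass_concentrates_at_true_cleavage(self):
        params, truth = tiny_truth(pas_background_reads=0.0)
        reads = simulate_pas_reads(truth, params)
        near = total = 0
        for ps in truth.planted_pas:
            r = reads[ps.transcript_id]
            near += np.sum(np.abs(r - ps.cleavage_pos) <= 10)
        total = sum(len(v) for v in reads.values())
        assert near / total >= 0.95

    def test_calling_recovers_planted_active_sites(self):
        params, truth = tiny_truth(n_transcripts=20)
        reads = simulate_pas_reads(truth, params)
        recovered = 0
        active = [p for p in truth.planted_pas if p.active]
        for ps in active:
            pile = pileup_3prime(
                reads[ps.transcript_id], truth.transcripts[ps.transcript_id].length
            )
            sites = call_pas_sites(pile, ps.transcript_id, min_reads=5, cluster_distance=10)
            if any(abs(s.cleavage_pos - ps.cleavage_pos) <= 10 for s in sites):
                recovered += 1
        assert recovered / len(active) >= 0.95


class TestEndToEndDeterminism:
    def test_same_seed_same_counts_and_reads(self):
        p = SimulationParams(**TINY)
        a = simulate_experiment(p)
        b = simulate_experiment(p)
        key = (Reagent.ACCESSIBILITY.value, Condition.IN_CELL.value)
        for tid in a.truth.transcripts:
            np.testing.assert_array_equal(
                a.probing[key][0][tid].stops, b.probing[key][0][tid].stops
            )
            np.testing.assert_array_equal(a.pas_reads[tid], b.pas_reads[tid])


class TestPipelineLevelProperties:
    """Generator and downstream analyses are mutually consistent."""

    def test_footprinted_hexamer_has_depressed_vtd(self, small_experiment):
        from footprintr.pipeline import compute_profiles
        from footprintr.reactivity import hexamer_vtd, vtd

        exp = small_experiment
        profiles = compute_profiles(exp, conditions=(Condition.IN_CELL, Condition.IN_VITRO))
        # accessibility channel; hexamer = motif plus its following base varies,
        # use the motif's first 5 bases extended by the planted slot context
        tracks = {
            tid: vtd(profiles["accessibility_probe"]["in_cell"][tid],
                     profiles["accessibility_probe"]["in_vitro"][tid])
            for tid in exp.truth.transcripts
        }
        table = hexamer_vtd(tracks, exp.truth.transcripts, min_occurrences=3)
        motif = exp.params.rbp_motif
        inside = table[table["hexamer"].str.startswith(motif)]
        assert len(inside) > 0
        assert inside["mean_vtd"].mean() < table["mean_vtd"].mean()

    def test_start_codon_metaprofile_peaks_at_a_and_g(self, small_in_cell_experiment):
        from footprintr.pipeline import compute_profiles
        from footprintr.reactivity import metaprofile

        exp = small_in_cell_experiment
        profiles = compute_profiles(exp)["accessibility_probe"]["in_cell"]
        table = metaprofile(profiles, exp.truth.start_codons, 15, 17).set_index("offset")
        background = table.loc[[-15, -12, -9, 9, 12, 15], "mean"].mean()
        assert table.loc[0, "mean"] > background
        assert table.loc[2, "mean"] > background

    def test_classifier_auc_monotone_in_footprint_effect(self):
        from footprintr.pipeline import run_all

        smoke = dict(n_transcripts=30, length_min=500, length_max=600, coverage=120.0)
        medians = []
        for delta in (0.0, 0.2, 0.5, 0.8):
            vals = []
            for seed in range(5):
                out = run_all(
                    SimulationParams(**smoke, footprint_effect=delta),
                    seed=seed,
                    model_overrides={"C_grid": [1.0, 16.0], "gamma_grid": [0.25]},
                )
                vals.append(out["rbp"]["results"].set_index("design")["auc"]["combined"])
            medians.append(float(np.median(vals)))
        assert medians == sorted(medians)
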