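"""Ground-truth fidelity of the synthetic experiment generator."""
import numpy as np
import pytest
from scipy import stats

from m6akit import SimulationParams, generate_reference, simulate_libraries
from m6akit.pipeline import run_simulation
from m6akit.topology import STOP_REGION_NT


def small_params(**kw):
    base = dict(n_transcripts=60, depth=20_000, organs=("leaves",),
                replicates=1, te_fraction=0.0, seed=21)
    base.update(kw)
    return SimulationParams(**base)


class TestReference:
    def test_sites_carry_rrach(self):
        genome, models, truth = generate_reference(small_params())
        by_id = {m.transcript_id: m for m in models}
        for tid, positions in truth.sites.items():
            seq = by_id[tid].spliced_sequence(genome)
            for pos, motif in zip(positions, truth.site_motifs[tid]):
                kmer = seq[pos - 2 : pos + 3]
                assert kmer == motif
                assert kmer[0] in "AG" and kmer[1] in "AG"
                assert kmer[2] == "A" and kmer[3] == "C" and kmer[4] in "ACT"

    def test_same_seed_is_bit_identical(self):
        g1, m1, t1 = generate_reference(small_params())
        g2, m2, t2 = generate_reference(small_params())
        assert g1.fetch("chr1", 0, g1.length("chr1")) == \
            g2.fetch("chr1", 0, g2.length("chr1"))
        assert [m.exons for m in m1] == [m.exons for m in m2]
        assert t1.sites == t2.sites
        assert t1.expression.equals(t2.expression)

    def test_pure_stop_placement_confined_to_window(self):
        params = small_params(
            n_transcripts=100,
            placement_mass={"stop": 1.0, "cds": 0.0, "five_prime": 0.0})
        genome, models, truth = generate_reference(params)
        by_id = {m.transcript_id: m for m in models}
        n_sites = 0
        for tid, positions in truth.sites.items():
            stop = by_id[tid].stop_codon_tpos
            L = by_id[tid].spliced_length
            for pos in positions:
                n_sites += 1
                assert stop - STOP_REGION_NT <= pos < L
        assert n_sites >= 100

    def test_infeasible_layout_errors(self):
        with pytest.raises(ValueError, match="genome_length"):
            generate_reference(small_params(genome_length=1000))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(p_nonspecific=0.95, p_specific=0.9).validate()
        with pytest.raises(ValueError):
            SimulationParams(depth=0).validate()


class TestLibraries:
    def test_no_sites_no_background_means_no_m6a_fragments(self):
        params = small_params(p_nonspecific=0.0)
        genome, models, truth = generate_reference(params)
        # erase the sites of one well-expressed transcript
        tid = truth.expression["leaves"].idxmax()
        truth.sites[tid] = []
        libs = simulate_libraries(genome, models, truth, params, assays=("m6A",))
        from m6akit import TranscriptAssignment
        a = TranscriptAssignment(libs[0], models)
        assert a.count(tid) == 0

    def test_every_m6a_fragment_covers_the_single_site(self):
        params = small_params(n_transcripts=10, depth=2000, p_nonspecific=0.0,
                              p_specific=1.0, sites_probs={1: 1.0})
        genome, models, truth = generate_reference(params)
        libs = simulate_libraries(genome, models, truth, params, assays=("m6A",))
        from m6akit import TranscriptAssignment
        a = TranscriptAssignment(libs[0], models)
        for m in models:
            site = truth.sites[m.transcript_id][0]
            for ts, te in a.projected(m.transcript_id):
                assert ts <= site < te

    def test_background_fraction_below_two_percent(self):
        """Default capture parameters keep the non-specific share of the
        retained pool near the assay's sub-1% background."""
        params = SimulationParams(n_transcripts=200, depth=100_000,
                                  organs=("leaves",), replicates=1,
                                  te_fraction=0.0, seed=4)
        exp = run_simulation(params, assays=("m6A",))
        a = exp.assignment("leaves", 1, "m6A")
        n_bg = n_tot = 0
        for tid, (ts, te) in a.intervals.items():
            s = np.asarray(exp.truth.sites[tid])
            n_tot += len(ts)
            if len(s) == 0:
                n_bg += len(ts)
                continue
            idx = np.minimum(np.searchsorted(s, ts), len(s) - 1)
            n_bg += int((~((s[idx] >= ts) & (s[idx] < te))).sum())
        assert n_tot > 50_000
        assert n_bg / n_tot < 0.02

    def test_mrna_counts_track_expression_weights(self):
        params = SimulationParams(n_transcripts=250, depth=100_000,
                                  organs=("leaves",), replicates=1,
                                  te_fraction=0.0, de_fraction=0.0, seed=17)
        exp = run_simulation(params, assays=("mRNA",))
        a = exp.assignment("leaves", 1, "mRNA")
        counts = [a.count(t) for t in exp.truth.transcript_ids]
        weights = exp.truth.expression["leaves"].to_numpy()
        rho = stats.spearmanr(counts, weights).statistic
        assert rho >= 0.9

    def test_coverage_concentrates_at_sites(self):
        """Mean m6A depth within +-75 nt of planted sites is >=5x the mean
        elsewhere (specific:non-specific rate ratio is 900 here)."""
        params = SimulationParams(n_transcripts=100, depth=50_000,
                                  organs=("leaves",), replicates=1,
                                  te_fraction=0.0, seed=19)
        exp = run_simulation(params, assays=("m6A",))
        a = exp.assignment("leaves", 1, "m6A")
        near, near_n, far, far_n = 0.0, 0, 0.0, 0
        for m in exp.models:
            tid = m.transcript_id
            depth = a.depth(tid)
            mask = np.zeros(len(depth), dtype=bool)
            for s in exp.truth.sites[tid]:
                mask[max(0, s - 75): s + 76] = True
            near += depth[mask].sum(); near_n += int(mask.sum())
            far += depth[~mask].sum(); far_n += int((~mask).sum())
        assert (near / near_n) >= 5 * (far / far_n)

    def test_same_seed_same_libraries(self):
        params = small_params(n_transcripts=20, depth=3000)
        genome, models, truth = generate_reference(params)
        l1 = simulate_libraries(genome, models, truth, params)
        l2 = simulate_libraries(genome, models, truth, params)
        assert [(f.start, f.end) for f in l1[0].fragments] == \
            [(f.start, f.end) for f in l2[0].fragments]

    def test_te_fragments_confined_to_windows(self):
        params = small_params(n_transcripts=40, depth=20_000, te_fraction=0.5,
                              seed=23)
        genome, models, truth = generate_reference(params)
        libs = simulate_libraries(genome, models, truth, params, assays=("mRNA",))
        from m6akit import TranscriptAssignment
        a = TranscriptAssignment(libs[0], models)
        for tid, windows in truth.te_windows.items():
            for ts, te in a.projected(tid):
                assert any(ts >= w0 and te <= w1 for w0, w1 in windows)
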