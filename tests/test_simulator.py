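"""Donor genome synthesis, SV injection, library simulation and reads."""

import edlib
import numpy as np
import pytest

from fosjump import simulate as sim
from fosjump._seq import gc_fraction, revcomp


class TestMakeGenome:
    def test_length_and_determinism(self):
        g1 = sim.make_genome(1, [1_000_000], 0.4, 7)
        g2 = sim.make_genome(1, [1_000_000], 0.4, 7)
        assert len(g1["contig1"]) == 1_000_000
        assert g1 == g2

    def test_gc_content_close_to_requested(self):
        g = sim.make_genome(1, [1_000_000], 0.4, 8)
        assert abs(gc_fraction(g["contig1"]) - 0.4) < 0.01


class TestInjectSVs:
    def test_deletion_shrinks_genome_by_event_size(self):
        g = sim.make_genome(1, [1_000_000], 0.4, 9)
        donor, _ = sim.inject_svs(g, [sim.SVEvent("deletion", "contig1", 300_000, 58_435)])
        assert len(donor["contig1"]) == 1_000_000 - 58_435

    def test_inversion_conserves_length_and_reverses_segment(self):
        g = sim.make_genome(1, [100_000], 0.4, 10)
        donor, _ = sim.inject_svs(g, [sim.SVEvent("inversion", "contig1", 40_000, 8_091)])
        assert len(donor["contig1"]) == 100_000
        assert donor["contig1"][40_000 : 48_091] == revcomp(g["contig1"][40_000 : 48_091])

    def test_duplication_grows_genome(self):
        g = sim.make_genome(1, [200_000], 0.4, 11)
        donor, _ = sim.inject_svs(g, [sim.SVEvent("duplication", "contig1", 50_000, 33_248)])
        assert len(donor["contig1"]) == 200_000 + 33_248

    def test_translocation_swaps_tails(self):
        g = sim.make_genome(2, [100_000, 120_000], 0.4, 12)
        donor, _ = sim.inject_svs(
            g, [sim.SVEvent("translocation", "contig1", 60_000, None, "contig2", 70_000)]
        )
        assert donor["contig1"] == g["contig1"][:60_000] + g["contig2"][70_000:]
        assert donor["contig2"] == g["contig2"][:70_000] + g["contig1"][60_000:]

    def test_apply_then_revert_restores_original(self):
        g = sim.make_genome(2, [150_000, 150_000], 0.45, 13)
        events = [
            sim.SVEvent("deletion", "contig1", 20_000, 5_000),
            sim.SVEvent("duplication", "contig1", 60_000, 7_000),
            sim.SVEvent("inversion", "contig2", 30_000, 8_000),
            sim.SVEvent("translocation", "contig1", 100_000, None, "contig2", 90_000),
        ]
        donor, ledger = sim.inject_svs(g, events)
        assert sim.revert_svs(donor, ledger) == g

    def test_overlapping_events_rejected(self):
        g = sim.make_genome(1, [100_000], 0.4, 14)
        with pytest.raises(ValueError, match="overlap"):
            sim.inject_svs(
                g,
                [
                    sim.SVEvent("deletion", "contig1", 10_000, 5_000),
                    sim.SVEvent("inversion", "contig1", 12_000, 5_000),
                ],
            )

    def test_out_of_range_rejected(self):
        g = sim.make_genome(1, [50_000], 0.4, 15)
        with pytest.raises(ValueError, match="range"):
            sim.inject_svs(g, [sim.SVEvent("deletion", "contig1", 49_000, 5_000)])


class TestFosmidLibrary:
    def test_clone_count_matches_coverage_expectation(self, genome_1mb):
        params = sim.SimulationParams(coverage=10.0)
        clones = sim.simulate_fosmid_library(genome_1mb, params, np.random.default_rng(16))
        assert abs(len(clones) - 263) <= 3  # 10 x 1e6 / 38 kb

    def test_inserts_within_selection_window_and_mean(self, genome_1mb):
        params = sim.SimulationParams(coverage=20.0)
        clones = sim.simulate_fosmid_library(genome_1mb, params, np.random.default_rng(17))
        lens = np.array([c.insert_len for c in clones])
        assert lens.min() >= 30_000 and lens.max() <= 45_000
        se = lens.std(ddof=1) / np.sqrt(len(lens))
        assert abs(lens.mean() - 38_000) < 3 * se + 150  # truncation shifts mean slightly

    def test_contig_too_short_rejected(self):
        g = {"tiny": "ACGT" * 1000}
        with pytest.raises(ValueError):
            sim.simulate_fosmid_library(g, sim.SimulationParams(), np.random.default_rng(0))


class TestShearing:
    def test_categories_match_junction_overlap_oracle(self, genome_1mb, phz_vector):
        params = sim.SimulationParams()
        rng = np.random.default_rng(18)
        clones = sim.simulate_fosmid_library(genome_1mb, sim.SimulationParams(coverage=5.0), rng)
        n_checked = 0
        for c in clones:
            mol = sim.clone_molecule(c, genome_1mb, phz_vector)
            j1, j2 = mol.junctions
            for fr in sim.shear_and_select(mol, params, rng):
                covered = {(fr.start + i) % mol.length for i in range(fr.span)}
                # a junction is inside iff bases on both sides are covered
                inside = sum(
                    ((j - 1) % mol.length in covered) and (j % mol.length in covered)
                    for j in (j1, j2)
                )
                exp = {2: "paired_end", 1: "single_end"}.get(inside)
                if exp is None:
                    insert_positions = {p % mol.length for p in range(j1, j2)}
                    exp = "insert_only" if covered <= insert_positions else "vector_only"
                assert fr.category == exp
                n_checked += 1
        assert n_checked > 100

    def test_paired_to_single_ratio_higher_than_pcc2fos(self, genome_1mb, phz_vector, pcc_vector):
        """Placing oriV and CmR on opposite sides of the cloning site enriches
        selectable paired-end fragments relative to the ancestral layout."""
        params = sim.SimulationParams(coverage=15.0)

        def ratio(vector, seed):
            rng = np.random.default_rng(seed)
            clones = sim.simulate_fosmid_library(genome_1mb, params, rng, vector=vector)
            counts = {"paired_end": 0, "single_end": 0}
            for c in clones:
                for fr in sim.shear_and_select(sim.clone_molecule(c, genome_1mb, vector), params, rng):
                    if fr.selectable and fr.category in counts:
                        counts[fr.category] += 1
            return counts["paired_end"] / max(counts["single_end"], 1)

        assert ratio(phz_vector, 19) > ratio(pcc_vector, 19)


class TestPairedEndMolecules:
    def test_released_molecule_layout(self, errorfree_library, phz_vector):
        mols = [m for m in errorfree_library["molecules"] if m.end_b is not None]
        amp = sim.amp_tag_sequence()
        m = mols[0]
        seq = m.sequence(phz_vector)
        assert seq.startswith(phz_vector.ves1_seq)
        assert seq.endswith(phz_vector.ves2_seq)
        assert amp in seq
        assert seq == phz_vector.ves1_seq + m.end_a.seq + amp + m.end_b.seq + phz_vector.ves2_seq

    def test_truth_ends_map_to_donor_intervals(self, errorfree_library, genome_1mb):
        """Conservation: each genomic end equals its recorded donor slice."""
        for m in errorfree_library["molecules"][:50]:
            for end, emitted_rc in ((m.end_a, False), (m.end_b, True)):
                if end is None:
                    continue
                donor = genome_1mb[end.contig][end.start : end.end]
                emitted = end.seq if not emitted_rc else revcomp(end.seq)
                assert emitted in (donor, revcomp(donor))

    def test_truth_spans_match_insert_distribution(self, errorfree_library):
        spans = [m.truth_span for m in errorfree_library["molecules"] if m.end_b is not None]
        spans = np.array(spans)
        assert spans.min() >= 30_000 and spans.max() <= 45_000

    def test_direct_route_end_total_near_seven_kb(self, genome_1mb, phz_vector):
        params = sim.SimulationParams(coverage=20.0)
        rng = np.random.default_rng(21)
        clones = sim.simulate_fosmid_library(genome_1mb, params, rng)
        mols = sim.simulate_paired_ends(clones, genome_1mb, phz_vector, params, rng)
        totals = np.array([m.total_end_len for m in mols])
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - 7_000) < 3 * se + 100

    def test_chimaera_injection_fraction(self, genome_1mb, phz_vector):
        params = sim.SimulationParams(coverage=80.0)
        rng = np.random.default_rng(22)
        clones = sim.simulate_fosmid_library(genome_1mb, params, rng)
        mols = sim.simulate_paired_ends(clones, genome_1mb, phz_vector, params, rng)
        assert len(mols) >= 2000
        mols = sim.inject_chimaeras(mols, 0.2, rng)
        frac = np.mean([m.category == "chimaera" for m in mols])
        assert abs(frac - 0.2) < 0.03


class TestReads:
    def test_accuracy_one_is_verbatim(self, errorfree_library, phz_vector):
        m = errorfree_library["molecules"][0]
        reads = errorfree_library["reads"]
        assert reads[0][1] == m.sequence(phz_vector)

    def test_error_rate_matches_edit_distance(self, genome_1mb, phz_vector):
        params = sim.SimulationParams(read_accuracy=0.90)
        rng = np.random.default_rng(23)
        truth_seq = genome_1mb["contig1"][:10_000]
        noisy = sim._mutate(truth_seq, 0.90, rng)
        d = edlib.align(noisy, truth_seq, mode="NW")["editDistance"]
        # 1000 planted edits; the optimal path may be slightly cheaper
        assert 820 <= d <= 1100

    def test_fixed_seed_reproduces_fastq_and_truth(self, genome_1mb, phz_vector, tmp_path):
        def run():
            params = sim.SimulationParams(read_accuracy=0.9, coverage=2.0)
            rng = np.random.default_rng(24)
            clones = sim.simulate_fosmid_library(genome_1mb, params, rng)
            mols = sim.simulate_paired_ends(clones, genome_1mb, phz_vector, params, rng)
            return sim.simulate_reads(mols, phz_vector, params, rng)

        r1, t1 = run()
        r2, t2 = run()
        assert r1 == r2
        assert t1.equals(t2)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        sim.write_fastq(r1, str(p1))
        sim.write_fastq(r2, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_accuracy_rejected(self, genome_1mb, phz_vector):
        params = sim.SimulationParams(coverage=1.0)
        rng = np.random.default_rng(25)
        clones = sim.simulate_fosmid_library(genome_1mb, params, rng)
        mols = sim.simulate_paired_ends(clones, genome_1mb, phz_vector, params, rng)
        params.read_accuracy = 0.4
        with pytest.raises(ValueError):
            sim.simulate_reads(mols, phz_vector, params, rng)
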