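import numpy as np
import pytest

import spetkit as sk
from spetkit.config import RunConfig
from spetkit.formats_io import GenomeRef
from spetkit.genotyper import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AlleleDepthTable,
    GenotypeMatrix,
    Site,
    attach_reference,
    call_genotype,
    discover_sites,
    filter_high_confidence,
    recall_filter,
    tally_alleles,
)
from spetkit.simulate import Read, ReadBatch

CFG = RunConfig.for_mode("tomato-like")
B = {"A": 0, "C": 1, "G": 2, "T": 3}


@pytest.fixture
def tiny_setup():
    seq = ("ACGT" * 200)[:500]
    genome = GenomeRef(contigs={"chr1": seq}, anchored={"chr1": True})
    probe = sk.Probe(
        id="p1", contig="chr1", start=101, end=140,
        orientation="readout-right", target_pos=141,
        sequence=genome.fetch("chr1", 101, 140),
        readout_start=141, readout_end=250,
    )
    window = genome.fetch("chr1", 141, 250)
    return genome, probe, window


class TestTallyAlleles:
    def test_one_read_contributes_one_count_per_position(self, tiny_setup):
        genome, probe, window = tiny_setup
        batch = ReadBatch([Read("p1", "s1", 1, window)])
        table = tally_alleles(batch, [probe], genome)
        assert table.counts.sum() == 110
        assert table.depth("chr1", 141, 0) == 1
        assert table.depth("chr1", 250, 0) == 1

    def test_disagreeing_reads_split_the_count(self, tiny_setup):
        genome, probe, window = tiny_setup
        mutated = "G" + window[1:] if window[0] != "G" else "C" + window[1:]
        batch = ReadBatch([Read("p1", "s1", 1, window), Read("p1", "s1", 2, mutated)])
        table = tally_alleles(batch, [probe], genome)
        row = table.counts[table.row("chr1", 141), 0]
        assert sorted(row.tolist(), reverse=True)[:2] == [1, 1]

    def test_empty_batch_gives_empty_table(self, tiny_setup):
        genome, probe, _ = tiny_setup
        table = tally_alleles(ReadBatch([]), [probe], genome)
        assert table.counts.size == 0 and table.positions == []

    def test_unknown_probe_is_an_error(self, tiny_setup):
        genome, probe, window = tiny_setup
        with pytest.raises(KeyError, match="ghost"):
            tally_alleles(ReadBatch([Read("ghost", "s1", 1, window)]), [probe], genome)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "counts,state",
        [
            ({"A": 12}, "hom"),            # clean hom at >= 10 reads
            ({"A": 9}, "missing"),         # below the 10-read minimum
            ({"A": 12, "G": 8}, "het"),    # minor fraction 0.4
            ({"A": 24, "G": 1}, "hom"),    # minor fraction 0.04, inclusive
            ({"A": 18, "G": 2}, "missing"),  # 0.10: ambiguous band
            ({"A": 10, "G": 10}, "het"),   # minor fraction exactly 0.5
        ],
    )
    def test_call_states(self, counts, state):
        vec = np.zeros(4, dtype=int)
        for b, n in counts.items():
            vec[B[b]] = n
        assert call_genotype(vec, CFG).state == state

    def test_major_base_is_reported(self):
        vec = np.zeros(4, dtype=int)
        vec[B["G"]] = 15
        call = call_genotype(vec, CFG)
        assert (call.state, call.major) == ("hom", "G")


class TestDiscoverSites:
    def _run(self, tiny_setup, reads):
        genome, probe, _ = tiny_setup
        table = tally_alleles(ReadBatch(reads), [probe], genome)
        attach_reference(table, genome)
        return discover_sites(table, [probe], CFG)

    def test_variant_at_target_pos_is_a_target_site(self, tiny_setup):
        genome, probe, window = tiny_setup
        alt = "G" if window[0] != "G" else "C"
        reads = [Read("p1", "s1", 1, alt + window[1:]) for _ in range(12)]
        m = self._run(tiny_setup, reads)
        assert m.n_sites == 1
        site = m.sites[0]
        assert (site.pos, site.target, site.alt) == (141, True, alt)
        assert m.calls[0, 0] == HOM_ALT

    def test_variant_inside_readout_window_is_non_target(self, tiny_setup):
        genome, probe, window = tiny_setup
        alt = "G" if window[30] != "G" else "C"
        mutated = window[:30] + alt + window[31:]
        reads = [Read("p1", "s1", 1, mutated) for _ in range(12)]
        m = self._run(tiny_setup, reads)
        assert m.n_sites == 1
        assert (m.sites[0].pos, m.sites[0].target) == (171, False)

    def test_reference_only_reads_give_empty_matrix(self, tiny_setup):
        genome, probe, window = tiny_setup
        m = self._run(tiny_setup, [Read("p1", "s1", 1, window) for _ in range(12)])
        assert m.n_sites == 0

    def test_het_call_requires_balanced_fractions(self, tiny_setup):
        genome, probe, window = tiny_setup
        alt = "G" if window[0] != "G" else "C"
        reads = [Read("p1", "s1", 1, alt + window[1:]) for _ in range(8)]
        reads += [Read("p1", "s1", 2, window) for _ in range(12)]
        m = self._run(tiny_setup, reads)
        assert m.calls[0, 0] == HET

    def test_third_allele_carrier_set_missing(self, tiny_setup):
        genome, probe, window = tiny_setup
        ref = window[0]
        others = [b for b in "ACGT" if b != ref]
        # sample 1 hom for alt1 (drives the site), sample 2 hom for alt2
        reads = [Read("p1", "s1", 1, others[0] + window[1:]) for _ in range(12)]
        reads += [Read("p1", "s2", 1, others[1] + window[1:]) for _ in range(10)]
        m = self._run(tiny_setup, reads)
        assert m.n_sites == 1
        assert m.sites[0].alt == others[0]
        assert m.calls[0, 0] == HOM_ALT
        assert m.calls[0, 1] == MISSING


def _toy_table():
    """20 sites x 10 samples with hand-set calls and depths.

    Returns the matrix, the depth table, and the hand-computed indices that
    survive the high-confidence filter and then the re-call filter
    (tomato-like thresholds: mean depth >= 30, >= 80% called, >= 1 non-ref).
    """
    n_sites, n_samp = 20, 10
    calls = np.full((n_sites, n_samp), HOM_ALT, dtype=np.int8)
    depth = np.full((n_sites, n_samp), 40, dtype=np.int32)

    depth[0] = [30] * 9 + [29]          # mean 29.9 -> dropped
    depth[1] = [30] * 10                # mean 30.0 -> kept (boundary)
    calls[2, :2] = MISSING              # 8/10 called -> kept (80% boundary)
    calls[3, :3] = MISSING              # 7/10 called -> dropped
    calls[4] = HOM_REF                  # no non-ref allele -> dropped
    calls[5, 0] = HET                   # het counts as non-ref -> kept
    calls[5, 1:] = HOM_REF
    depth[6] = 0                        # no coverage -> dropped
    calls[6] = MISSING
    calls[7, :5] = MISSING              # 50% called -> dropped
    depth[8] = [100] * 5 + [0] * 5      # mean 50 -> kept
    # sites 9..19 stay clean hom-alt / depth 40 -> kept
    expected_hc = [1, 2, 5, 8] + list(range(9, 20))
    expected_recall = expected_hc  # no site between 80% boundaries differs

    sites = [Site("chr1", 10 * (i + 1), "A", "G", target=i < 10)
             for i in range(n_sites)]
    matrix = GenotypeMatrix(sites=sites, samples=[f"s{j}" for j in range(n_samp)],
                            calls=calls)
    counts = np.zeros((n_sites, n_samp, 4), dtype=np.int32)
    counts[:, :, 0] = depth  # depth parked on one base; filters only sum
    table = AlleleDepthTable(
        samples=matrix.samples,
        positions=[(s.contig, s.pos) for s in sites],
        counts=counts,
    )
    return matrix, table, expected_hc, expected_recall


class TestSiteFilters:
    def test_high_confidence_retains_exactly_the_hand_computed_set(self):
        matrix, table, expected_hc, _ = _toy_table()
        kept = filter_high_confidence(matrix, table, CFG)
        assert [s.pos for s in kept.sites] == [10 * (i + 1) for i in expected_hc]

    def test_recall_filter_retains_exactly_the_hand_computed_set(self):
        matrix, table, _, expected = _toy_table()
        hc = filter_high_confidence(matrix, table, CFG)
        final, report = recall_filter(hc, table, CFG)
        assert [s.pos for s in final.sites] == [10 * (i + 1) for i in expected]
        assert (report.retained, report.total) == (len(expected), len(expected))

    def test_recall_boundary_is_inclusive(self):
        matrix, table, _, _ = _toy_table()
        out, report = recall_filter(matrix, table, CFG)
        # site 2 (8/10 callable) survives, site 3 (7/10) does not
        positions = [s.pos for s in out.sites]
        assert 30 in positions and 40 not in positions

    def test_eggplant_max_missing_boundary(self):
        cfg = RunConfig.for_mode("eggplant-like")
        n = 50
        calls = np.full((2, n), HOM_ALT, dtype=np.int8)
        calls[0, :3] = MISSING  # 94% called -> dropped at max-missing 0.95
        calls[1, :2] = MISSING  # 96% called -> kept
        sites = [Site("chr1", 1, "A", "G", True), Site("chr1", 2, "A", "G", True)]
        matrix = GenotypeMatrix(sites, [f"s{j}" for j in range(n)], calls)
        counts = np.zeros((2, n, 4), dtype=np.int32)
        counts[:, :, 0] = 40
        table = AlleleDepthTable(matrix.samples, [("chr1", 1), ("chr1", 2)], counts)
        kept = filter_high_confidence(matrix, table, cfg)
        assert [s.pos for s in kept.sites] == [2]

    def test_filters_are_idempotent(self, demo_genotypes):
        matrix, depths, _ = demo_genotypes
        again = filter_high_confidence(matrix, depths, CFG)
        assert [s.pos for s in again.sites] == [s.pos for s in matrix.sites]
        final, _ = recall_filter(matrix, depths, CFG)
        assert final.n_sites == matrix.n_sites


class TestTargetPartition:
    def test_target_sites_coincide_with_probe_targets(self, demo_fixture,
                                                      demo_genotypes):
        matrix, _, _ = demo_genotypes
        targets = {(p.contig, p.target_pos) for p in demo_fixture.panel}
        observed = [(s.contig, s.pos) for s in matrix.sites if s.target]
        assert len(observed) <= len(demo_fixture.panel)
        assert set(observed) <= targets
        non_target = {(s.contig, s.pos) for s in matrix.sites if not s.target}
        assert not non_target & targets
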