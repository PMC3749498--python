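"""Marker scanning, densities and abundance rescaling."""

import numpy as np
import pytest

from ncldvscope.markers import (
    DensityRecord,
    MarkerProfile,
    absolute_abundance,
    correlate,
    encode_peptide,
    group_summary,
    load_marker_profile,
    marker_density,
    ncldv_prokaryote_ratio,
    profile_evalue,
    pssm_from_sequences,
    save_marker_profile,
    scan_markers,
)
from ncldvscope.model import CellCounts, SampleStats
from ncldvscope.qc import Peptide
from ncldvscope._align import pssm_best_window


@pytest.fixture(scope="module")
def marker(small_bundle):
    return next(m for m in small_bundle.markers if m.group == "ncldv")


@pytest.fixture(scope="module")
def profile(small_bundle, marker):
    return next(p for p in small_bundle.profiles if p.name == marker.name)


def _pep(seq, read_id="r0"):
    return Peptide(f"{read_id}|f+1|0", read_id, 1, 0, 3 * len(seq), seq)


class TestScan:
    def test_consensus_scores_best(self, small_bundle, profile, marker, rng):
        variant = next(iter(marker.variants.values()))
        random_pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        peps = [_pep(variant, "real"), _pep(random_pep, "rand")]
        hits = scan_markers(peps, [profile], small_bundle.db, "s1")
        assert [h.read_id for h in hits] == ["real"]
        assert hits[0].e_value < 1e-30

    def test_shuffled_peptides_miss(self, profile, marker, rng):
        variant = next(iter(marker.variants.values()))
        misses = 0
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(variant)))
            score = pssm_best_window(encode_peptide(shuffled), profile.pssm)
            if profile_evalue(score, len(shuffled), profile.ref_alignment_len) > 1e-3:
                misses += 1
        assert misses >= 99

    def test_one_hit_per_read_and_marker(self, small_bundle, profile, marker):
        variant = next(iter(marker.variants.values()))
        # two ORFs of the same read both matching the marker
        peps = [
            Peptide("r0|f+1|0", "r0", 1, 0, 300, variant),
            Peptide("r0|f+2|1", "r0", 2, 1, 271, variant[:90]),
        ]
        hits = scan_markers(peps, [profile], small_bundle.db, "s1")
        assert len(hits) == 1
        assert hits[0].e_value == min(
            profile_evalue(pssm_best_window(encode_peptide(p.seq), profile.pssm),
                           len(p.seq), profile.ref_alignment_len)
            for p in peps
        )

    def test_viral_marker_bins_ncldv(self, small_bundle, profile, marker):
        variant = next(iter(marker.variants.values()))
        hits = scan_markers([_pep(variant)], [profile], small_bundle.db, "s1")
        assert hits[0].bin == "NCLDV"

    def test_profile_tsv_roundtrip(self, tmp_path, profile):
        path = tmp_path / "prof.tsv"
        save_marker_profile(profile, path)
        loaded = load_marker_profile(path)
        assert loaded.name == profile.name and loaded.group == profile.group
        assert np.allclose(loaded.pssm, profile.pssm, atol=1e-5)


class TestDensity:
    def _stats(self, total_bp):
        return {"s1": SampleStats("s1", total_bp, total_bp // 300, "SRF")}

    def _profiles(self):
        pssm = pssm_from_sequences(["ACDEFGHIKW" * 10])
        return [
            MarkerProfile("m_n", "ncldv", pssm),
            MarkerProfile("m_c", "cellular", pssm),
        ]

    def _hit(self, marker, bin_, read_id):
        from ncldvscope.markers import MarkerHit

        return MarkerHit(marker, read_id, "s1", 1e-9, bin_)

    def test_density_arithmetic(self):
        profiles = self._profiles()
        hits = [self._hit("m_n", "NCLDV", f"r{i}") for i in range(2)]
        recs = marker_density(hits, self._stats(4_000_000), profiles)
        assert len(recs) == 1
        assert recs[0].density == pytest.approx(0.5)
        assert recs[0].normalized_density == pytest.approx(0.5 / 100)

    def test_zero_hits_zero_density(self):
        profiles = self._profiles()
        assert marker_density([], self._stats(1000), profiles) == []
        # and the group summary fills in the zero
        assert group_summary([], profiles, "ncldv", "mean") == 0.0

    def test_zero_total_bp_rejected(self):
        profiles = self._profiles()
        stats = {"s1": SampleStats("s1", 0, 0, "SRF")}
        with pytest.raises(ValueError):
            marker_density([self._hit("m_n", "NCLDV", "r0")], stats, profiles)

    def test_group_summary_modes(self):
        profiles = [
            MarkerProfile("a", "ncldv", pssm_from_sequences(["AC" * 50])),
            MarkerProfile("b", "ncldv", pssm_from_sequences(["DE" * 50])),
        ]
        recs = [
            DensityRecord("s1", "a", "NCLDV", 1, 0.1, 0.001),
            DensityRecord("s1", "b", "NCLDV", 3, 0.3, 0.003),
        ]
        assert group_summary(recs, profiles, "ncldv", "mean") == pytest.approx(0.2)
        assert group_summary(recs, profiles, "ncldv", "median") == pytest.approx(0.2)
        assert group_summary(recs[:1], profiles[:1], "ncldv", "mean") == pytest.approx(0.1)
        with pytest.raises(ValueError):
            group_summary(recs, profiles, "cellular")

    def test_appending_marker_free_sequence_rescales_exactly(self):
        profiles = self._profiles()
        hits = [self._hit("m_n", "NCLDV", f"r{i}") for i in range(4)]
        d_small = marker_density(hits, self._stats(1_000_000), profiles)[0].density
        d_big = marker_density(hits, self._stats(4_000_000), profiles)[0].density
        assert d_big == pytest.approx(d_small * 1_000_000 / 4_000_000)

    def test_ratio_uses_bins_not_profile_groups(self):
        # a cellular-marker hit binned NCLDV counts toward the viral side
        profiles = self._profiles()
        recs = [
            DensityRecord("s1", "m_c", "NCLDV", 1, 0.2, 0.002),
            DensityRecord("s1", "m_c", "Bacteria", 5, 1.0, 0.01),
            DensityRecord("s1", "m_n", "NCLDV", 1, 0.2, 0.002),
        ]
        r = ncldv_prokaryote_ratio(recs, profiles, sample_id="s1", mode="mean")
        assert r == pytest.approx(0.2 / 1.0)


class TestAbundance:
    def test_rescaling_arithmetic(self):
        cc = CellCounts("s1", fc_cells_per_ml=1e6)
        est = absolute_abundance(0.02, cc)
        assert len(est) == 1
        assert est[0].genomes_per_ml == pytest.approx(1.8e4)
        assert absolute_abundance(0.0, cc)[0].genomes_per_ml == 0.0

    def test_both_counts_reported_separately(self):
        cc = CellCounts("s1", fc_cells_per_ml=1e6, microscopy_cells_per_ml=8e5)
        est = absolute_abundance(0.01, cc)
        assert {e.count_source for e in est} == {"fc", "microscopy"}
        assert est[0].genomes_per_ml != est[1].genomes_per_ml

    def test_no_count_rejected(self):
        with pytest.raises(ValueError):
            absolute_abundance(0.01, CellCounts("s1"))


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_draws_near_zero(self):
        g = np.random.default_rng(99)
        r, _ = correlate(g.normal(size=1000), g.normal(size=1000))
        assert abs(r) < 0.1

    def test_planted_proportional_with_noise(self):
        g = np.random.default_rng(5)
        x = g.uniform(0.5, 2.0, size=17)
        y = x * (1 + 0.1 * g.normal(size=17))
        r, p = correlate(x, y)
        assert r > 0.9 and p < 1e-3

    def test_zero_variance_undefined(self):
        r, p = correlate(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)
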