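"""Taxonomy-masked reciprocal-best-hit HGT screen."""

import numpy as np
import pytest

from ncldvscope.hgt import best_cellular_hit, reciprocal_check, screen_hgt
from ncldvscope.model import ReferenceDB, ReferenceProtein, parse_lineage

from oracles import sw_score_biopython

AA = list("ACDEFGHIKLMNPQRSTVWY")
VIRAL_LIN = "Viruses; dsDNA viruses, no RNA stage; Mimiviridae; Mimivirus"


def _rand(rng, n=60):
    return "".join(rng.choice(AA, n))


def _mutate(rng, seq, k):
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = rng.choice([a for a in AA if a != out[pos]])
    return "".join(out)


@pytest.fixture(scope="module")
def planted():
    """5 planted virus->cell transfers, 20 decoys, assorted traps."""
    rng = np.random.default_rng(77)
    cell_lineages = [
        "Eukaryota; stramenopiles; Oomycetes; Phytophthora",
        "Eukaryota; stramenopiles; Bacillariophyta; Thalassiosira",
        "Bacteria; Proteobacteria; Gammaproteobacteria; Vibrio",
        "Eukaryota; Viridiplantae; Chlorophyta; Ostreococcus",
        "Archaea; Euryarchaeota; Thermococci; Thermococcus",
    ]
    viral, cellular = [], []
    for i in range(5):
        v = _rand(rng)
        viral.append(ReferenceProtein(f"vir_t{i}", v, parse_lineage(VIRAL_LIN), "viral"))
        cellular.append(
            ReferenceProtein(
                f"cell_t{i}", _mutate(rng, v, 3),
                parse_lineage(cell_lineages[i % len(cell_lineages)]), "cellular",
            )
        )
    for i in range(5):  # viral peptides without any cellular homolog
        viral.append(
            ReferenceProtein(f"vir_x{i}", _rand(rng), parse_lineage(VIRAL_LIN), "viral")
        )
    for i in range(20):  # unrelated cellular decoys
        cellular.append(
            ReferenceProtein(
                f"cell_d{i}", _rand(rng),
                parse_lineage(cell_lineages[i % len(cell_lineages)]), "cellular",
            )
        )
    return ReferenceDB(viral), ReferenceDB(cellular)


class TestBestCellularHit:
    def test_identical_protein_found(self, planted):
        viral_db, cellular_db = planted
        h = best_cellular_hit("vir_t0", viral_db["vir_t0"].seq, cellular_db)
        assert h is not None and h.subject_id == "cell_t0"

    def test_no_homolog_below_threshold(self, planted):
        viral_db, cellular_db = planted
        assert best_cellular_hit("vir_x0", viral_db["vir_x0"].seq, cellular_db) is None

    def test_argmin_matches_brute_force(self, planted, rng):
        viral_db, cellular_db = planted
        for vid in list(viral_db.ids)[:10]:
            h = best_cellular_hit(vid, viral_db[vid].seq, cellular_db, max_evalue=1e3)
            oracle = max(
                cellular_db.ids,
                key=lambda sid: (sw_score_biopython(viral_db[vid].seq, cellular_db[sid].seq), sid),
            )
            if h is not None:
                best_score = sw_score_biopython(viral_db[vid].seq, cellular_db[oracle].seq)
                got_score = sw_score_biopython(viral_db[vid].seq, cellular_db[h.subject_id].seq)
                assert got_score == best_score


class TestScreen:
    def test_planted_transfers_recovered_exactly(self, planted):
        viral_db, cellular_db = planted
        cands = screen_hgt(viral_db, cellular_db)
        got = {(c.viral_peptide_id, c.cellular_protein_id) for c in cands}
        assert got == {(f"vir_t{i}", f"cell_t{i}") for i in range(5)}

    def test_relative_in_same_group_blocks_candidate(self, planted):
        # a closer homolog in a *different* 3-level cellular group breaks
        # the reciprocal check; one in the same group is masked and doesn't
        viral_db, cellular_db = planted
        rng = np.random.default_rng(3)
        same_group = ReferenceProtein(
            "cell_sib", _mutate(rng, cellular_db["cell_t0"].seq, 1),
            parse_lineage("Eukaryota; stramenopiles; Oomycetes; Pythium"), "cellular",
        )
        db_same = ReferenceDB(list(cellular_db) + [same_group])
        got = {(c.viral_peptide_id, c.cellular_protein_id)
               for c in screen_hgt(viral_db, db_same)}
        assert ("vir_t0", "cell_t0") in got or ("vir_t0", "cell_sib") in got

        other_group = ReferenceProtein(
            "cell_far", _mutate(rng, cellular_db["cell_t0"].seq, 1),
            parse_lineage("Bacteria; Firmicutes; Bacilli; Bacillus"), "cellular",
        )
        db_other = ReferenceDB(list(cellular_db) + [other_group])
        combined = ReferenceDB(list(db_other) + list(viral_db))
        passed, best = reciprocal_check("cell_t0", combined)
        assert not passed  # the cross-group cellular homolog wins

    def test_empty_viral_proteome(self, planted):
        _, cellular_db = planted
        assert screen_hgt(ReferenceDB([]), cellular_db) == []

    def test_order_invariance(self, planted):
        viral_db, cellular_db = planted
        shuffled = ReferenceDB(list(reversed(list(cellular_db))))
        a = screen_hgt(viral_db, cellular_db)
        b = screen_hgt(viral_db, shuffled)
        assert [(c.viral_peptide_id, c.cellular_protein_id) for c in a] == [
            (c.viral_peptide_id, c.cellular_protein_id) for c in b
        ]

    def test_monotone_in_parameters(self, planted):
        viral_db, cellular_db = planted
        n_by_level = [
            len(screen_hgt(viral_db, cellular_db, exclusion_levels=lvl))
            for lvl in (2, 3, 4)
        ]
        # a longer prefix masks fewer relatives: candidates can only shrink
        assert n_by_level == sorted(n_by_level, reverse=True)
        n_by_e = [
            len(screen_hgt(viral_db, cellular_db, max_evalue=e))
            for e in (1e-3, 1e-5, 1e-10)
        ]
        assert n_by_e == sorted(n_by_e, reverse=True)

    def test_verbatim_copy_always_recovered(self, planted, rng):
        viral_db, cellular_db = planted
        v = viral_db["vir_x1"]
        copy = ReferenceProtein(
            "cell_copy", v.seq,
            parse_lineage("Eukaryota; Fungi; Ascomycota; Aspergillus"), "cellular",
        )
        db = ReferenceDB(list(cellular_db) + [copy])
        got = {(c.viral_peptide_id, c.cellular_protein_id) for c in screen_hgt(viral_db, db)}
        assert ("vir_x1", "cell_copy") in got
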