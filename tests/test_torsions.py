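"""Backbone torsions, Ramachandran classification, pairwise agreement."""

import copy

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nrgeom.rama_synthetic import classify, residue_class
from nrgeom.synthetic import make_ideal_helix, perturb_structure
from nrgeom.torsions import (
    TorsionRecord,
    backbone_torsions,
    ramachandran_classify,
    ramachandran_tally,
    torsion_comparison,
    wasserstein_1d,
    wrapped_difference,
)


class TestBackboneTorsions:
    def test_ideal_helix_recovers_phi_psi(self, helix20):
        records = backbone_torsions(helix20)
        for rec in records:
            if rec.phi is not None:
                assert rec.phi == pytest.approx(-57.0, abs=1e-6)
            if rec.psi is not None:
                assert rec.psi == pytest.approx(-47.0, abs=1e-6)

    def test_termini_undefined(self, helix20):
        records = backbone_torsions(helix20)
        assert records[0].phi is None
        assert records[-1].psi is None

    def test_chain_break_makes_flanking_angles_undefined(self, helix20):
        chain = copy.deepcopy(helix20)
        for res in chain.residues[10:]:
            for a in res.atoms:
                a.coords = a.coords + np.array([100.0, 0.0, 0.0])
        records = backbone_torsions(chain)
        by_seq = {r.auth_seq: r for r in records}
        assert by_seq[10].psi is None
        assert by_seq[11].phi is None
        assert by_seq[9].psi is not None

    def test_too_short_chain_errors(self, helix20):
        from nrgeom.io import ChainModel

        single = ChainModel("A", helix20.residues[:1])
        with pytest.raises(ValueError):
            backbone_torsions(single)


class TestWrapped:
    def test_wrap_rule_179_vs_minus_179(self):
        assert abs(wrapped_difference(179.0, -179.0)) == pytest.approx(2.0)

    @given(
        st.floats(-180, 180, allow_nan=False),
        st.floats(-180, 180, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        d1 = float(wrapped_difference(a, b))
        d2 = float(wrapped_difference(b, a))
        assert abs(d1) <= 180.0
        if abs(d1) != 180.0:
            assert d1 == pytest.approx(-d2, abs=1e-9)


class TestRamachandran:
    def _rec(self, phi, psi, res="LEU", cls=None):
        return TorsionRecord(1, res, phi, psi, cls or residue_class(res))

    def test_alpha_basin_favored(self):
        assert ramachandran_classify(self._rec(-63.0, -43.0)) == "favored"

    def test_far_from_all_basins_is_outlier(self):
        assert ramachandran_classify(self._rec(75.0, -65.0)) == "outlier"

    def test_classification_matches_table_oracle(self):
        # the shipped density table is its own oracle: classify == direct lookup
        probe = [(-63, -43), (-120, 130), (58, 42), (75, -65), (0, 0), (-100, 60)]
        for phi, psi in probe:
            assert ramachandran_classify(self._rec(phi, psi)) == classify("general", phi, psi)

    def test_glycine_routed_to_its_own_table(self):
        rec = self._rec(90.0, 0.0, res="GLY")
        assert rec.residue_class == "glycine"
        assert ramachandran_classify(rec) == classify("glycine", 90.0, 0.0)
        assert residue_class("ALA", "PRO") == "pre-proline"
        assert residue_class("ILE") == "isoleucine-valine"

    def test_undefined_angles_error(self):
        with pytest.raises(ValueError):
            ramachandran_classify(TorsionRecord(1, "ALA", None, -43.0, "general"))

    def test_tally_counts_sum(self, helix20):
        records = backbone_torsions(helix20)
        tally = ramachandran_tally(records)
        classifiable = [r for r in records if r.phi is not None and r.psi is not None]
        assert tally["n_classifiable"] == len(classifiable)
        assert tally["favored_pct"] == pytest.approx(100.0)  # ideal helix
        assert tally["outlier_count"] == 0

    def test_helix_self_classification_identical(self, helix20):
        a = backbone_torsions(helix20)
        b = backbone_torsions(copy.deepcopy(helix20))
        for ra, rb in zip(a, b):
            if ra.phi is not None and ra.psi is not None:
                assert ramachandran_classify(ra) == ramachandran_classify(rb)


class TestComparison:
    def test_identical_records_all_distances_zero(self):
        chain = make_ideal_helix(20)
        noisy = perturb_structure(chain, 0.15, seed=4)  # variance for Pearson
        recs = backbone_torsions(noisy)
        comp = torsion_comparison(recs, recs)
        assert comp.rmsd_phi == 0 and comp.rmsd_psi == 0
        assert comp.mae_phi == 0 and comp.wasserstein_phi == 0
        assert comp.pearson_phi == pytest.approx(1.0)
        assert comp.pearson_psi == pytest.approx(1.0)

    def test_constant_shift_gives_mae_and_wasserstein(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(-150, 100, 30)
        exp = [
            TorsionRecord(i, "ALA", float(p), float(p) * 0.5, "general")
            for i, p in enumerate(base)
        ]
        pred = [
            TorsionRecord(i, "ALA", float(p) + 10.0, float(p) * 0.5 + 10.0, "general")
            for i, p in enumerate(base)
        ]
        comp = torsion_comparison(exp, pred)
        assert comp.mae_phi == pytest.approx(10.0, abs=1e-9)
        assert comp.wasserstein_phi == pytest.approx(10.0, abs=1e-9)
        assert comp.rmsd_phi == pytest.approx(10.0, abs=1e-9)

    def test_minimum_pair_count_enforced(self):
        recs = [TorsionRecord(i, "ALA", -60.0, -45.0, "general") for i in range(5)]
        with pytest.raises(ValueError, match="pairs"):
            torsion_comparison(recs, recs)

    def test_numbering_offset_pairs_residues(self):
        exp = [TorsionRecord(i, "ALA", -60.0 + i, -45.0 - i, "general") for i in range(15)]
        pred = [
            TorsionRecord(i + 100, "ALA", -60.0 + i, -45.0 - i, "general") for i in range(15)
        ]
        comp = torsion_comparison(exp, pred, numbering_offset=100)
        assert comp.n_paired == 15
        assert comp.mae_phi == pytest.approx(0.0, abs=1e-12)


class TestWasserstein:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 5.0, 9.0])
        assert wasserstein_1d(x, x) == pytest.approx(0.0)

    def test_point_masses(self):
        assert wasserstein_1d([10.0], [25.0]) == pytest.approx(15.0)

    def test_shift_recovery(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-170, 170, 1000)
        b = np.clip(a + 7.0, -180, 180)
        assert wasserstein_1d(a, b) == pytest.approx(7.0, abs=0.5)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a, b, c = (rng.uniform(-180, 180, 40) for _ in range(3))
            dab = wasserstein_1d(a, b)
            assert dab == pytest.approx(wasserstein_1d(b, a), abs=1e-9)
            assert dab <= wasserstein_1d(a, c) + wasserstein_1d(c, b) + 1e-9

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])
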