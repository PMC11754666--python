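"""Junction segmentation, bend/underwinding reports, batch analysis."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import bendscan as bs


def apply_rigid(duplex, rotvec_deg, translation):
    R = Rotation.from_rotvec(np.asarray(rotvec_deg), degrees=True).as_matrix()
    t = np.asarray(translation, float)
    for bp in duplex.pairs:
        for nt in (bp.ts, bp.nts):
            for a in nt.atoms:
                a.position = R @ a.position + t
    return duplex


def flip_duplex(duplex, jdef):
    """Exchange strands and reverse direction: H2 becomes H1 and vice versa.

    Returns the reversed duplex (re-indexed from -3) plus the junction
    definition addressing the same physical base pairs from the other side.
    """
    from bendscan.core import from_ordinal, ordinal

    n = len(duplex)
    rev = list(reversed(duplex.pairs))
    new_idx = [from_ordinal(ordinal(-3) + k) for k in range(n)]
    old_pos = {idx: p for p, idx in enumerate(duplex.indices)}

    def mirror(indices):
        return tuple(sorted(new_idx[n - 1 - old_pos[i]] for i in indices))

    flipped = bs.Duplex(
        [bs.BasePair(ts=bp.nts, nts=bp.ts, pam_index=i)
         for bp, i in zip(rev, new_idx)]
    )
    mirrored = bs.JunctionDefinition(mirror(jdef.h2), mirror(jdef.j), mirror(jdef.h1))
    return flipped, mirrored


class TestJunctionDefinition:
    def test_defaults_match_pam_junction_spacer_layout(self):
        jdef = bs.JunctionDefinition()
        assert jdef.h1 == (-3, -2, -1)
        assert jdef.j == (1, 2)
        assert jdef.h2 == (3, 4, 5)
        assert jdef.n_junction == 2

    @pytest.mark.parametrize(
        "h1,j,h2",
        [
            ((-3, -2), (1, 2), (3, 4, 5)),  # H1 too short
            ((-3, -2, -1), (), (3, 4, 5)),  # empty junction
            ((-3, -2, -1), (1, 2), (4, 5, 6)),  # gap before H2
            ((-3, -2, -1), (2, 3), (4, 5, 6)),  # gap after H1
            ((-3, -1, 1), (2, 3), (4, 5, 6)),  # non-consecutive H1
        ],
    )
    def test_malformed_definitions_rejected(self, h1, j, h2):
        with pytest.raises(bs.UsageError):
            bs.JunctionDefinition(h1, j, h2)


class TestAnalyzeJunction:
    def test_undistorted_duplex_is_straight(self, ideal_duplex):
        r = bs.analyze_junction(ideal_duplex)
        assert r.beta_h < 1e-6
        assert abs(r.underwinding) < 1e-6
        assert r.zeta_h == pytest.approx(72.0, abs=1e-6)
        assert r.h1_fit_rmsd < 1e-9 and r.h2_fit_rmsd < 1e-9

    def test_injected_distortion_recovered_exactly(self, bent_duplex):
        duplex, truth = bent_duplex
        r = bs.analyze_junction(duplex)
        assert r.beta_h == pytest.approx(truth["beta_h"], abs=1e-6)
        assert r.underwinding == pytest.approx(truth["underwinding"], abs=1e-6)
        assert r.gamma_h == pytest.approx(truth["gamma_h"], abs=1e-6)
        assert r.zeta_h == pytest.approx(truth["zeta_h"], abs=1e-6)

    def test_report_internal_consistency(self, bent_duplex):
        duplex, _ = bent_duplex
        r = bs.analyze_junction(duplex)
        assert r.underwinding == pytest.approx(
            r.n_junction * 36.0 - r.zeta_h, abs=1e-12
        )
        assert "ZYZ" in r.convention

    def test_rigid_motion_invariance(self, sequence):
        spec = bs.DistortionSpec(bend=45, direction=-75, extra_untwist=19,
                                 noise_sigma=0.2, seed=3)
        duplex, _ = bs.generate_bent_duplex(sequence, spec)
        before = bs.analyze_junction(duplex)
        apply_rigid(duplex, [33, -12, 140], [10.0, -5.0, 2.5])
        after = bs.analyze_junction(duplex)
        assert after.beta_h == pytest.approx(before.beta_h, abs=1e-6)
        assert after.gamma_h == pytest.approx(before.gamma_h, abs=1e-6)
        assert after.underwinding == pytest.approx(before.underwinding, abs=1e-6)

    def test_bend_magnitude_symmetric_under_helix_exchange(self, sequence):
        spec = bs.DistortionSpec(bend=47, direction=20, extra_untwist=22)
        duplex, _ = bs.generate_bent_duplex(sequence, spec)
        fwd = bs.analyze_junction(duplex)
        flipped, mirrored = flip_duplex(duplex, bs.JunctionDefinition())
        rev = bs.analyze_junction(flipped, mirrored)
        assert rev.beta_h == pytest.approx(fwd.beta_h, abs=1e-6)
        assert rev.underwinding == pytest.approx(fwd.underwinding, abs=1e-6)

    def test_missing_indices_raise_segmentation_error(self):
        d = bs.build_ideal_duplex("ACGTAC")  # -3..+3 only
        with pytest.raises(bs.SegmentationError, match=r"\+5"):
            bs.analyze_junction(d)

    def test_nondefault_junction_sizes(self, sequence):
        for n in (1, 2, 3):
            spec = bs.DistortionSpec(bend=30, direction=10, extra_untwist=15,
                                     n_junction=n)
            duplex, truth = bs.generate_bent_duplex(sequence, spec)
            j = tuple(range(1, n + 1))
            jdef = bs.JunctionDefinition((-3, -2, -1), j, (n + 1, n + 2, n + 3))
            r = bs.analyze_junction(duplex, jdef)
            assert r.n_junction == n
            assert r.beta_h == pytest.approx(30.0, abs=1e-6)
            assert r.underwinding == pytest.approx(15.0, abs=1e-6)

    def test_zero_noise_recovery_over_parameter_grid(self, sequence):
        worst = 0.0
        for bend in (10, 30, 50, 80):
            for untwist in (0, 20, 40):
                spec = bs.DistortionSpec(bend=bend, direction=50,
                                         extra_untwist=untwist)
                duplex, _ = bs.generate_bent_duplex(sequence, spec)
                r = bs.analyze_junction(duplex)
                worst = max(worst, abs(r.beta_h - bend),
                            abs(r.underwinding - untwist))
        assert worst < 0.01


class TestAnalyzeBatch:
    def test_monotone_bend_progression(self, sequence):
        entries = []
        for bend, untwist in ((42, 18), (45, 19), (53, 28)):
            spec = bs.DistortionSpec(bend=bend, extra_untwist=untwist)
            duplex, _ = bs.generate_bent_duplex(sequence, spec)
            entries.append({"id": f"bend{bend}", "duplex": duplex})
        table = bs.analyze_batch(entries)
        assert list(table["id"]) == ["bend42", "bend45", "bend53"]
        assert table["beta_h"].is_monotonic_increasing
        assert table["underwinding"].is_monotonic_increasing
        assert table["error"].isna().all()

    def test_single_undistorted_entry(self, ideal_duplex):
        table = bs.analyze_batch([{"id": "ideal", "duplex": ideal_duplex}])
        assert len(table) == 1
        assert table.loc[0, "beta_h"] < 1e-6

    def test_failures_recorded_without_aborting(self, ideal_duplex):
        entries = [
            {"id": "ok", "duplex": ideal_duplex},
            {"id": "broken", "path": "no/such/file.pdb",
             "config": {"ts_chain": "A", "nts_chain": "B", "pairs": []}},
        ]
        table = bs.analyze_batch(entries)
        assert table.loc[0, "error"] is None
        assert "ParseError" in table.loc[1, "error"]

    def test_empty_batch_rejected(self):
        with pytest.raises(bs.UsageError):
            bs.analyze_batch([])

    def test_batch_over_written_structures(self, sequence, tmp_path):
        import json
        from conftest import pairing_map

        rows = []
        for bend, untwist in ((42, 18), (53, 28)):
            spec = bs.DistortionSpec(bend=bend, extra_untwist=untwist)
            duplex, _ = bs.generate_bent_duplex(sequence, spec)
            pdb = tmp_path / f"b{bend}.pdb"
            bs.write_duplex_pdb(duplex, pdb)
            cfg = {"ts_chain": "A", "nts_chain": "B",
                   "pairs": [list(t) for t in pairing_map(duplex)]}
            rows.append({"id": f"b{bend}", "path": str(pdb), "config": cfg})
        table = bs.analyze_batch(rows)
        assert table["error"].isna().all()
        assert table["beta_h"].tolist() == pytest.approx([42.0, 53.0], abs=0.01)
        assert table["underwinding"].tolist() == pytest.approx([18.0, 28.0], abs=0.01)
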