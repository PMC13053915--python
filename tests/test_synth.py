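"""Synthetic-study generator: geometry, planting rules, determinism."""

import filecmp

import numpy as np
import pytest

from nmrdyn.synth import (
    DEFAULT_SCHEDULE,
    StudyDesign,
    build_toy_structure,
    emit_study,
    make_ground_truth,
)


class TestToyStructure:
    def test_consecutive_ca_distance_is_helical(self, rng):
        sites = build_toy_structure(50, rng)
        coords = np.array([s.ca_coord for s in sites])
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert np.all(np.abs(steps - 3.8) < 0.1)

    def test_residue_count(self, rng):
        assert len(build_toy_structure(50, rng)) == 50

    def test_seed_determinism(self):
        a = build_toy_structure(30, np.random.default_rng(5))
        b = build_toy_structure(30, np.random.default_rng(5))
        assert all(np.array_equal(x.ca_coord, y.ca_coord) and
                   x.b_factor == y.b_factor for x, y in zip(a, b))

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            build_toy_structure(10, rng)


class TestPlantedEffects:
    def test_zero_effects_leave_states_identical(self):
        design = StudyDesign(effect_dh=0.0, effect_dn=0.0, effect_r1=0.0,
                             effect_r2=0.0, effect_noe=0.0,
                             exchange_pocket=(), exchange_network=(),
                             exchange_weak=(), disappeared=())
        gt = make_ground_truth(design, DEFAULT_SCHEDULE, rng_seed=3)
        apo, bound = gt.states["apo"], gt.states["bound"]
        for col in ("delta_h", "delta_n", "r1", "r2_0", "noe", "rex"):
            assert np.allclose(apo[col], bound[col])

    def test_distance_decay_of_local_effect(self, ground_truth):
        gt = ground_truth
        design = gt.design
        apo, bound = gt.states["apo"], gt.states["bound"]
        coords = {s.residue_id: s.ca_coord for s in gt.sites}
        site_xyz = np.array([coords[r] for r in design.ligand_site])
        # a pocket residue receives the full effect
        rid0 = design.ligand_site[0]
        assert bound.loc[rid0, "r2_0"] - apo.loc[rid0, "r2_0"] == pytest.approx(
            design.effect_r2, rel=1e-9
        )
        # a residue at distance d receives effect * exp(-d / decay_length)
        for rid in (80, 85):
            d = np.min(np.linalg.norm(site_xyz - coords[rid], axis=1))
            expected = design.effect_r2 * np.exp(-d / design.decay_length)
            got = bound.loc[rid, "r2_0"] - apo.loc[rid, "r2_0"]
            assert got == pytest.approx(expected, rel=1e-6)

    def test_network_residues_receive_full_effect_at_distance(self, ground_truth):
        gt = ground_truth
        apo, bound = gt.states["apo"], gt.states["bound"]
        for rid in gt.design.network_residues:
            got = bound.loc[rid, "r2_0"] - apo.loc[rid, "r2_0"]
            assert got == pytest.approx(gt.design.effect_r2, rel=1e-9)

    def test_planted_rex_set_respects_reporting_rule(self, ground_truth):
        gt = ground_truth
        above = gt.rex_above_cutoff("bound")
        assert above == set(gt.design.exchange_pocket) | set(
            gt.design.exchange_network
        )
        weak_rex = gt.states["bound"].loc[list(gt.design.exchange_weak), "rex"]
        assert (weak_rex < 5.0).all()
        assert (weak_rex > 0.0).all()

    def test_network_residue_outside_structure_rejected(self):
        with pytest.raises(ValueError, match="outside structure"):
            make_ground_truth(StudyDesign(network_residues=(12, 500)),
                              DEFAULT_SCHEDULE, rng_seed=1)


class TestEmitStudy:
    def test_same_seed_byte_identical(self, ground_truth, tmp_path):
        a = emit_study(ground_truth, tmp_path / "a", rng_seed=9)
        b = emit_study(ground_truth, tmp_path / "b", rng_seed=9)
        for key, path in a.files.items():
            assert filecmp.cmp(path, b.files[key], shallow=False), key

    def test_disappeared_absent_from_bound_outputs_only(self, study_zero_noise):
        import pandas as pd

        study = study_zero_noise
        gone = set(study.design.disappeared)
        bound = pd.read_csv(study.files["peaks_bound"], sep="\t")
        apo = pd.read_csv(study.files["peaks_apo"], sep="\t")
        assert gone.isdisjoint(set(bound["residue_id"]))
        assert gone <= set(apo["residue_id"])

    def test_default_study_total_size_under_5mb(self, study_default_noise):
        total = sum(p.stat().st_size for p in study_default_noise.files.values())
        assert total < 5 * 2**20

    def test_intensity_noise_is_gaussian(self, ground_truth, study_default_noise):
        # standardised residuals of every emitted plane against the planted
        # ideal intensity should follow the declared Gaussian noise model
        import pandas as pd
        import scipy.stats as stats

        from nmrdyn.exchange import carver_richards
        from nmrdyn.synth import gt_params

        gt = ground_truth
        study = study_default_noise
        sched = gt.schedule
        resid = []
        for state in ("apo", "bound"):
            tab = gt.states[state]
            cpmg = pd.read_csv(study.files[f"cpmg_{state}"], sep="\t")
            for rid, grp in cpmg.groupby("residue_id"):
                p = gt_params(tab, rid)
                for row in grp.itertuples():
                    if row.nu_cpmg_hz == 0:
                        ideal = 1.0
                    elif p is None:
                        ideal = np.exp(-tab.loc[rid, "r2_0"] * sched.t_relax)
                    else:
                        r2 = carver_richards(p, row.nu_cpmg_hz,
                                             t_relax=sched.t_relax)
                        ideal = np.exp(-r2 * sched.t_relax)
                    resid.append(row.intensity - ideal)
            r1 = pd.read_csv(study.files[f"r1_decay_{state}"], sep="\t")
            for row in r1.itertuples():
                ideal = np.exp(-tab.loc[row.residue_id, "r1"] * row.delay_s)
                resid.append(row.intensity - ideal)
        resid = np.asarray(resid)
        assert len(resid) >= 10_000
        z = resid / study.design.noise_intensity
        assert abs(z.std(ddof=1) - 1.0) < 0.05
        assert stats.kstest(z, "norm").pvalue > 0.01
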