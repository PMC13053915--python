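"""Structure reading, B-factor normalisation, spatial clustering, scoring."""

import numpy as np
import pytest

from nmrdyn.structure import (
    ResidueSite,
    cluster_residues,
    normalize_bfactors,
    read_structure,
    write_score_structure,
)
from nmrdyn.synth import _write_pdb, build_toy_structure

import pandas as pd


@pytest.fixture()
def helix_pdb(tmp_path, rng):
    sites = build_toy_structure(30, rng)
    path = tmp_path / "helix.pdb"
    _write_pdb(sites, pd.Series("ALA", index=range(1, 31)), path)
    return sites, path


ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 20.00           C
ATOM      2  CA BALA A   1       5.000   5.000   5.000  0.40 30.00           C
ATOM      3  CA  ALA A   2       0.000   0.000   3.800  1.00 25.00           C
END
"""

ICODE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 20.00           C
ATOM      2  CA  ALA A   1A      1.000   1.000   1.000  1.00 20.00           C
END
"""


class TestReadStructure:
    def test_round_trip_of_written_helix(self, helix_pdb):
        sites, path = helix_pdb
        back = read_structure(path, "A")
        assert len(back) == len(sites)
        for orig, rd in zip(sites, back):
            assert np.allclose(orig.ca_coord, rd.ca_coord, atol=1e-3)
            assert rd.b_factor == pytest.approx(orig.b_factor, abs=0.01)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        sites = read_structure(path, "A")
        assert np.allclose(sites[0].ca_coord, [0.0, 0.0, 0.0])
        assert sites[0].b_factor == pytest.approx(20.0)

    def test_insertion_code_rejected(self, tmp_path):
        path = tmp_path / "icode.pdb"
        path.write_text(ICODE_PDB)
        with pytest.raises(ValueError, match="insertion"):
            read_structure(path, "A")

    def test_missing_chain_rejected(self, helix_pdb):
        with pytest.raises(ValueError, match="chain"):
            read_structure(helix_pdb[1], "Z")


class TestNormalizeBfactors:
    def test_zscores_have_zero_mean_unit_sd(self, helix_pdb):
        z = np.array(list(normalize_bfactors(helix_pdb[0]).values()))
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_single_perturbed_site_carries_the_signal(self):
        sites = [ResidueSite(i, "A", [0, 0, float(i)], 20.0) for i in range(1, 11)]
        sites[4].b_factor = 26.0
        z = normalize_bfactors(sites)
        assert z[5] == max(z.values())
        assert z[5] > 2.5

    def test_zero_variance_rejected(self):
        sites = [ResidueSite(i, "A", [0, 0, float(i)], 20.0) for i in range(1, 11)]
        with pytest.raises(ValueError):
            normalize_bfactors(sites)


def sites_at(coords):
    return [ResidueSite(i + 1, "A", np.asarray(c, float), 20.0)
            for i, c in enumerate(coords)]


class TestClusterResidues:
    def test_singleton(self):
        clusters = cluster_residues({1}, sites_at([[0, 0, 0]]), cutoff=8.0)
        assert len(clusters) == 1 and clusters[0].members == {1}

    def test_pair_within_and_beyond_cutoff(self):
        near = cluster_residues({1, 2}, sites_at([[0, 0, 0], [5, 0, 0]]), 8.0)
        far = cluster_residues({1, 2}, sites_at([[0, 0, 0], [12, 0, 0]]), 8.0)
        assert len(near) == 1 and len(far) == 2

    def test_single_linkage_chains_through_intermediate(self):
        # endpoints 12 apart but each 6 from the middle: one component
        clusters = cluster_residues(
            {1, 2, 3}, sites_at([[0, 0, 0], [6, 0, 0], [12, 0, 0]]), 8.0
        )
        assert len(clusters) == 1
        assert clusters[0].members == {1, 2, 3}
        assert clusters[0].diameter == pytest.approx(12.0)

    def test_invariant_under_rigid_motion(self, rng):
        coords = rng.uniform(0, 30, size=(25, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1]])
        moved = coords @ rot.T + np.array([10.0, -5.0, 3.0])
        a = cluster_residues(set(range(1, 26)), sites_at(coords), 8.0)
        b = cluster_residues(set(range(1, 26)), sites_at(moved), 8.0)
        assert {frozenset(c.members) for c in a} == {frozenset(c.members)
                                                     for c in b}

    def test_cluster_count_monotone_in_cutoff(self, rng):
        coords = rng.uniform(0, 40, size=(30, 3))
        counts = [len(cluster_residues(set(range(1, 31)), sites_at(coords), c))
                  for c in (4.0, 8.0, 16.0, 100.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1

    def test_missing_coordinates_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="without coordinates"):
            clusters = cluster_residues({1, 99}, sites_at([[0, 0, 0]]), 8.0)
        assert clusters[0].members == {1}


class TestWriteScoreStructure:
    def test_scores_round_trip_at_column_precision(self, helix_pdb, tmp_path):
        sites, path = helix_pdb
        scores = {s.residue_id: 0.17 * s.residue_id for s in sites[:20]}
        out = tmp_path / "scored.pdb"
        write_score_structure(sites, scores, path, out)
        back = read_structure(out, "A")
        for s in back:
            expected = scores.get(s.residue_id, -1.0)
            assert s.b_factor == pytest.approx(expected, abs=0.005 + 1e-9)

    def test_sentinel_marks_unscored_residues(self, helix_pdb, tmp_path):
        sites, path = helix_pdb
        out = tmp_path / "scored.pdb"
        write_score_structure(sites, {1: 1.0}, path, out)
        back = read_structure(out, "A")
        assert back[1].b_factor == pytest.approx(-1.0)

    def test_fixed_width_columns(self, helix_pdb, tmp_path):
        sites, path = helix_pdb
        out = tmp_path / "scored.pdb"
        write_score_structure(sites, {1: 2.5}, path, out)
        atom_lines = [ln for ln in out.read_text().splitlines()
                      if ln.startswith("ATOM")]
        for ln in atom_lines:
            assert len(ln) >= 66
            float(ln[30:38]), float(ln[38:46]), float(ln[46:54])  # coords
            float(ln[54:60])  # occupancy
            float(ln[60:66])  # temperature factor
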