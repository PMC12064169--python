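import numpy as np
import pandas as pd
import pytest

from ppiscorekit import model_io, structure_analysis
from ppiscorekit.model_io import Residue
from ppiscorekit.structure_analysis import (
    compute_distance_matrix,
    interface_contacts,
    render_distogram,
)


def residue(num, name="ALA", **atoms):
    return Residue(number=num, name=name,
                   atoms={k: np.asarray(v, float) for k, v in atoms.items()})


class TestComputeDistanceMatrix:
    def test_3_4_5_triangle(self):
        structure = {
            "A": [residue(1, CA=(0, 0, 0))],
            "B": [residue(1, CA=(3, 4, 0))],
        }
        dm = compute_distance_matrix(structure, atom_mode="CA")
        assert dm.values[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, cohort):
        input_dir, manifest = cohort
        job_id, info = next(iter(manifest["jobs"].items()))
        chains = model_io.read_structure(
            input_dir / "models" / job_id / f"model_{info['best_model_index']}.pdb"
        )
        dm = compute_distance_matrix(chains)
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-6)
        assert np.all(np.diag(dm.values) == 0)

    def test_planted_distances_recovered(self, cohort):
        """CB distances match the generator's analytically placed contacts."""
        input_dir, manifest = cohort
        for job_id, info in manifest["jobs"].items():
            chains = model_io.read_structure(
                input_dir / "models" / job_id / f"model_{info['best_model_index']}.pdb"
            )
            dm = compute_distance_matrix(chains, atom_mode="CB")
            index = {(c, n): i for i, (c, n, _) in enumerate(dm.residue_labels)}
            for contact in info["planted_contacts"]:
                i = index[(contact["chain_a"], contact["resnum_a"])]
                j = index[(contact["chain_b"], contact["resnum_b"])]
                assert dm.values[i, j] == pytest.approx(contact["distance"], abs=1e-6)

    def test_cb_falls_back_to_ca_for_glycine(self):
        structure = {
            "A": [residue(1, "GLY", CA=(0, 0, 0))],
            "B": [residue(1, "ALA", CA=(6, 0, 0), CB=(5, 0, 0))],
        }
        dm = compute_distance_matrix(structure, atom_mode="CB")
        assert dm.values[0, 1] == pytest.approx(5.0)

    def test_missing_atom_and_fallback_rejected(self):
        structure = {"A": [residue(1, "ALA", O=(0, 0, 0))]}
        with pytest.raises(ValueError, match="residue 1"):
            compute_distance_matrix(structure, atom_mode="CB")

    def test_min_heavy_lower_bounds_ca(self, cohort):
        input_dir, manifest = cohort
        job_id, info = next(iter(manifest["jobs"].items()))
        chains = model_io.read_structure(
            input_dir / "models" / job_id / f"model_{info['best_model_index']}.pdb"
        )
        ca = compute_distance_matrix(chains, atom_mode="CA").values
        mh = compute_distance_matrix(chains, atom_mode="min-heavy").values
        assert np.all(mh <= ca + 1e-9)


class TestInterfaceContacts:
    def planted(self, d=4.0):
        return {
            "A": [residue(1, CA=(0, 0, 0), CB=(0, 1.5, 0))],
            "B": [residue(1, CA=(0, 1.5 + d + 1.5, 0), CB=(0, 1.5 + d, 0))],
        }

    def test_planted_pair_found(self):
        dm = compute_distance_matrix(self.planted(4.0))
        (c,) = interface_contacts(dm, 8.0)
        assert (c.chain_a, c.residue_a, c.chain_b, c.residue_b) == ("A", 1, "B", 1)
        assert c.distance == pytest.approx(4.0)

    def test_cutoff_zero_empty(self):
        dm = compute_distance_matrix(self.planted(4.0))
        assert interface_contacts(dm, 0.0) == []

    def test_single_chain_warns_empty(self):
        dm = compute_distance_matrix({"A": [residue(1, CA=(0, 0, 0), CB=(0, 1, 0))]})
        with pytest.warns(UserWarning):
            assert interface_contacts(dm, 8.0) == []

    def test_cohort_matches_brute_force_oracle(self, cohort):
        """Contact sets equal the generator's independent O(n^2) scan."""
        input_dir, manifest = cohort
        for job_id, info in manifest["jobs"].items():
            chains = model_io.read_structure(
                input_dir / "models" / job_id / f"model_{info['best_model_index']}.pdb"
            )
            dm = compute_distance_matrix(chains, atom_mode="CB")
            got = [
                (c.chain_a, c.residue_a, c.chain_b, c.residue_b, round(c.distance, 6))
                for c in interface_contacts(dm, manifest["contact_cutoff"])
            ]
            expected = [
                (e["chain_a"], e["resnum_a"], e["chain_b"], e["resnum_b"], e["distance"])
                for e in info["expected_contacts"]
            ]
            assert sorted(got) == sorted(expected)

    def test_monotone_in_cutoff(self, cohort):
        input_dir, manifest = cohort
        job_id, info = next(iter(manifest["jobs"].items()))
        chains = model_io.read_structure(
            input_dir / "models" / job_id / f"model_{info['best_model_index']}.pdb"
        )
        dm = compute_distance_matrix(chains)
        prev: set = set()
        for cutoff in (2.0, 5.0, 8.0, 12.0):
            cur = {(c.chain_a, c.residue_a, c.chain_b, c.residue_b)
                   for c in interface_contacts(dm, cutoff)}
            assert prev <= cur
            prev = cur

    def test_invariant_under_chain_relabeling(self):
        chains = self.planted(4.0)
        reordered = {"B": chains["B"], "A": chains["A"]}
        c1 = interface_contacts(compute_distance_matrix(chains), 8.0)
        c2 = interface_contacts(compute_distance_matrix(reordered), 8.0)
        assert c1 == c2

    def test_sorted_by_distance(self):
        chains = {
            "A": [residue(1, CA=(0, 0, 0), CB=(0, 1, 0)),
                  residue(2, CA=(20, 0, 0), CB=(20, 1, 0))],
            "B": [residue(1, CA=(0, 8, 0), CB=(0, 7, 0)),
                  residue(2, CA=(20, 5, 0), CB=(20, 4, 0))],
        }
        contacts = interface_contacts(compute_distance_matrix(chains), 8.0)
        dists = [c.distance for c in contacts]
        assert dists == sorted(dists)


class TestRenderDistogram:
    def test_image_and_matching_sidecar(self, tmp_path):
        chains = {
            "A": [residue(1, CA=(0, 0, 0), CB=(0, 1, 0)),
                  residue(2, CA=(3.8, 0, 0), CB=(3.8, 1, 0))],
            "B": [residue(1, CA=(0, 6, 0), CB=(0, 5, 0))],
        }
        dm = compute_distance_matrix(chains)
        sidecar = render_distogram(dm, tmp_path / "disto.png")
        assert (tmp_path / "disto.png").exists()
        back = pd.read_csv(sidecar, sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), dm.values, atol=1e-6)

    def test_single_chain_renders(self, tmp_path):
        chains = {"A": [residue(1, CA=(0, 0, 0), CB=(0, 1, 0)),
                        residue(2, CA=(3.8, 0, 0), CB=(3.8, 1, 0))]}
        dm = compute_distance_matrix(chains)
        sidecar = render_distogram(dm, tmp_path / "single.png")
        assert sidecar.exists() and dm.chain_boundaries == []

    def test_interchain_minimum_matches_planted(self, cohort, tmp_path):
        input_dir, manifest = cohort
        job_id, info = next(
            (j, i) for j, i in manifest["jobs"].items()
            if i["job_kind"] == "hetero-pair"
        )
        chains = model_io.read_structure(
            input_dir / "models" / job_id / f"model_{info['best_model_index']}.pdb"
        )
        dm = compute_distance_matrix(chains, atom_mode="CB")
        sidecar = render_distogram(dm, tmp_path / "d.png")
        back = pd.read_csv(sidecar, sep="\t", index_col=0).to_numpy()
        n_a = info["chain_lengths"][0]
        inter = back[:n_a, n_a:]
        expected_min = min(c["distance"] for c in info["expected_contacts"])
        assert inter.min() == pytest.approx(expected_min, abs=1e-6)
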