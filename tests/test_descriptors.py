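"""Featurization: property vectors, fingerprint provenance, many-body
descriptors and the solvent-mixture calculator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import Descriptors
from scipy.spatial.transform import Rotation

from yieldmap.chemdata import Structure3D
from yieldmap.descriptors import (
    SolventMixture,
    compute_fingerprint,
    compute_property_descriptors,
    coulomb_matrix_eigenvalues,
    derive_conceptual_dft,
    featurize_dataset,
    mbtr_spectrum,
    mixture_property,
    two_body_forces,
)
from yieldmap.exceptions import (
    ConfigurationError,
    DescriptorAvailabilityError,
    SingularGeometryError,
    ValidationError,
)


def random_structure(rng, n=5, elements=("C", "H", "O", "N")):
    els = [str(e) for e in rng.choice(elements, n)]
    coords = rng.normal(scale=2.0, size=(n, 3))
    return Structure3D(els, coords)


class TestPropertyDescriptors:
    def test_methane_molecular_weight(self):
        names, values = compute_property_descriptors("C")
        assert abs(values[names.index("MolWt")] - 16.04) < 0.01

    def test_deterministic(self):
        _, a = compute_property_descriptors("c1ccccc1O")
        _, b = compute_property_descriptors("c1ccccc1O")
        np.testing.assert_array_equal(a, b)

    def test_length_matches_toolkit_registry(self):
        names, values = compute_property_descriptors("CCO")
        assert len(names) == len(values) == len(Descriptors.descList)

    def test_invalid_smiles(self):
        with pytest.raises(ValidationError):
            compute_property_descriptors("not_a_smiles")


class TestFingerprints:
    def test_ethane_rdk_provenance_single_bond(self):
        fp = compute_fingerprint("CC", "rdk")
        assert fp.provenance  # ethane has exactly one bond path
        for occurrences in fp.provenance.values():
            for occ in occurrences:
                assert occ == (0,)

    def test_methane_rdk_no_on_bits(self):
        # no bond paths exist in a single-heavy-atom molecule
        fp = compute_fingerprint("C", "rdk")
        assert fp.on_bits.size == 0

    def test_provenance_keys_subset_of_on_bits(self):
        for kind in ("rdk", "morgan"):
            fp = compute_fingerprint("CC(=O)Nc1ccccc1", kind)
            on = set(fp.on_bits.tolist())
            assert set(fp.provenance) <= on

    def test_provenance_bonds_exist_in_molecule(self):
        smi = "CN(C)C(=O)c1nccs1"
        mol = Chem.MolFromSmiles(smi)
        for kind in ("rdk", "morgan"):
            fp = compute_fingerprint(smi, kind)
            for occurrences in fp.provenance.values():
                for occ in occurrences:
                    assert all(0 <= b < mol.GetNumBonds() for b in occ)

    def test_rdk_provenance_is_sound(self):
        """Fingerprinting the extracted substructure reproduces the claimed bit."""
        smi = "CCOC(=O)c1ccc(N)cc1"
        mol = Chem.MolFromSmiles(smi)
        fp = compute_fingerprint(smi, "rdk")
        checked = 0
        for bit, occurrences in fp.provenance.items():
            for occ in occurrences[:1]:
                frag = Chem.PathToSubmol(mol, list(occ))
                sub_fp = Chem.RDKFingerprint(frag, fpSize=fp.length)
                assert bit in set(sub_fp.GetOnBits())
                checked += 1
        assert checked > 10

    def test_maccs_provenance_empty(self):
        fp = compute_fingerprint("CCO", "maccs")
        assert fp.provenance == {} and fp.length == 167

    def test_morgan_radius0_has_empty_bond_tuple(self):
        fp = compute_fingerprint("CCO", "morgan")
        lengths = {len(occ) for occs in fp.provenance.values() for occ in occs}
        assert () in {occ for occs in fp.provenance.values() for occ in occs} or 0 in lengths

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            compute_fingerprint("CC", "daylight")


class TestCoulombMatrix:
    def test_single_hydrogen(self):
        s = Structure3D(["H"], [[0.0, 0.0, 0.0]])
        np.testing.assert_allclose(coulomb_matrix_eigenvalues(s, 1), [0.5])

    def test_h2_closed_form(self):
        # 2x2 matrix [[0.5, 1/d], [1/d, 0.5]] -> eigenvalues 0.5 +- 1/d
        s = Structure3D(["H", "H"], [[0, 0, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(coulomb_matrix_eigenvalues(s, 2), [1.5, -0.5], atol=1e-12)

    def test_padding(self):
        s = Structure3D(["H", "H"], [[0, 0, 0], [0, 0, 1.0]])
        out = coulomb_matrix_eigenvalues(s, 5)
        assert out.shape == (5,) and np.all(out[2:] == 0)

    def test_permutation_invariance(self, rng):
        s = random_structure(rng, 6)
        perm = rng.permutation(6)
        sp = Structure3D([s.elements[i] for i in perm], s.coordinates[perm])
        np.testing.assert_allclose(
            coulomb_matrix_eigenvalues(s, 6), coulomb_matrix_eigenvalues(sp, 6), atol=1e-9
        )

    def test_isometry_invariance(self, rng):
        s = random_structure(rng, 6)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = Structure3D(s.elements, s.coordinates @ rot.T + np.array([1.0, -2.0, 0.5]))
        np.testing.assert_allclose(
            coulomb_matrix_eigenvalues(s, 6), coulomb_matrix_eigenvalues(moved, 6), atol=1e-8
        )

    def test_coincident_nuclei(self):
        s = Structure3D(["H", "H"], [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(SingularGeometryError):
            coulomb_matrix_eigenvalues(s, 2)


class TestTwoBodyForces:
    def test_h2_inverse_distance(self):
        s = Structure3D(["H", "H"], [[0, 0, 0], [0, 0, 2.0]])
        np.testing.assert_allclose(two_body_forces(s, [("H", "H")]), [0.5])

    def test_absent_pair_is_zero(self):
        s = Structure3D(["H", "H"], [[0, 0, 0], [0, 0, 2.0]])
        out = two_body_forces(s, [("H", "H"), ("C", "H")])
        assert out[1] == 0.0

    def test_matches_brute_force(self, rng):
        s = random_structure(rng, 5)
        pairs = [("C", "C"), ("C", "H"), ("C", "O"), ("C", "N"), ("H", "H"),
                 ("H", "O"), ("H", "N"), ("N", "O"), ("O", "O"), ("N", "N")]
        expected = np.zeros(len(pairs))
        for i in range(5):
            for j in range(i + 1, 5):
                key = tuple(sorted((s.elements[i], s.elements[j])))
                r = np.linalg.norm(s.coordinates[i] - s.coordinates[j])
                expected[[tuple(sorted(p)) for p in pairs].index(key)] += 1.0 / r
        np.testing.assert_allclose(two_body_forces(s, pairs), expected, atol=1e-12)

    def test_isometry_invariance(self, rng):
        s = random_structure(rng, 6)
        pairs = [("C", "C"), ("C", "H"), ("H", "H"), ("C", "O"), ("H", "O"),
                 ("O", "O"), ("C", "N"), ("H", "N"), ("N", "N"), ("N", "O")]
        rot = Rotation.random(random_state=5).as_matrix()
        moved = Structure3D(s.elements, s.coordinates @ rot.T - 3.0)
        np.testing.assert_allclose(
            two_body_forces(s, pairs), two_body_forces(moved, pairs), atol=1e-10
        )

    @given(d=st.floats(min_value=0.5, max_value=5.0), shrink=st.floats(min_value=0.05, max_value=0.4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_distance(self, d, shrink):
        closer = Structure3D(["H", "H"], [[0, 0, 0], [0, 0, d * (1 - shrink)]])
        farther = Structure3D(["H", "H"], [[0, 0, 0], [0, 0, d]])
        assert two_body_forces(closer, [("H", "H")])[0] > two_body_forces(farther, [("H", "H")])[0]


class TestMBTR:
    def test_single_atom_k2_k3_zero(self):
        s = Structure3D(["C"], [[0, 0, 0]])
        names, vec = mbtr_spectrum(s, grid_points=20)
        k2k3 = [v for n, v in zip(names, vec) if "_k2_" in n or "_k3_" in n]
        assert np.allclose(k2k3, 0.0)

    def test_k1_integral_counts_atoms(self):
        s = Structure3D(["C", "C", "O"], [[0, 0, 0], [0, 0, 1.4], [0, 1.2, 0]])
        names, vec = mbtr_spectrum(s, grid_points=20)
        for el, count in (("C", 2), ("O", 1)):
            seg = np.array([v for n, v in zip(names, vec) if n.startswith(f"mbtr_k1_{el}_")])
            grid = np.linspace(-0.4, 1.4, 20)
            integral = np.trapezoid(seg, grid)
            assert abs(integral - count) < 1e-3

    def test_matches_direct_summation(self, rng):
        """Vectorized spectrum equals a naive pure-python Gaussian sum."""
        s = random_structure(rng, 3, elements=("C", "H"))
        grid_points = 20
        names, vec = mbtr_spectrum(s, grid_points=grid_points)

        from yieldmap.descriptors import MBTR_AXIS_RANGES, MBTR_DEFAULT_WIDTH, mbtr_layout

        els = sorted(set(s.elements))
        w = MBTR_DEFAULT_WIDTH
        lo_g, hi_g = -4 * w, 1 + 4 * w
        grid = [lo_g + (hi_g - lo_g) * i / (grid_points - 1) for i in range(grid_points)]

        def gauss_sum(centers):
            return [
                sum(
                    np.exp(-0.5 * ((g - c) / w) ** 2) / (w * np.sqrt(2 * np.pi))
                    for c in centers
                )
                for g in grid
            ]

        z = {e: Chem.GetPeriodicTable().GetAtomicNumber(e) for e in els}
        expected = {}
        for seg in mbtr_layout(els, grid_points):
            k = len(seg)
            lo, hi = MBTR_AXIS_RANGES[k]
            centers = []
            if k == 1:
                centers = [(z[e] - lo) / (hi - lo) for e in s.elements if e == seg[0]]
            elif k == 2:
                for i in range(3):
                    for j in range(i + 1, 3):
                        if tuple(sorted((s.elements[i], s.elements[j]))) == seg:
                            r = float(np.linalg.norm(s.coordinates[i] - s.coordinates[j]))
                            centers.append((1.0 / r - lo) / (hi - lo))
            else:
                for jc in range(3):
                    for i in range(3):
                        for kk in range(i + 1, 3):
                            if jc in (i, kk):
                                continue
                            a = s.coordinates[i] - s.coordinates[jc]
                            b = s.coordinates[kk] - s.coordinates[jc]
                            cos = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
                            flanks = sorted((s.elements[i], s.elements[kk]))
                            if (flanks[0], s.elements[jc], flanks[1]) == seg:
                                centers.append((cos - lo) / (hi - lo))
            expected[seg] = gauss_sum(centers)

        for seg, exp_vals in expected.items():
            prefix = f"mbtr_k{len(seg)}_{'-'.join(seg)}_"
            got = [v for n, v in zip(names, vec) if n.startswith(prefix)]
            np.testing.assert_allclose(got, exp_vals, atol=1e-9)

    def test_nonpositive_width_rejected(self):
        s = Structure3D(["C"], [[0, 0, 0]])
        with pytest.raises(ConfigurationError):
            mbtr_spectrum(s, widths={2: 0.0})


class TestConceptualDFT:
    def test_direct_arithmetic(self):
        chi, eta = derive_conceptual_dft(-0.3, -0.1)
        assert chi == pytest.approx(0.2) and eta == pytest.approx(0.1)

    def test_degenerate_limit(self):
        chi, eta = derive_conceptual_dft(-0.25, -0.25)
        assert chi == pytest.approx(0.25) and eta == 0.0

    @given(
        homo=st.floats(min_value=-1.0, max_value=0.0),
        gap=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_hardness_nonnegative(self, homo, gap):
        _, eta = derive_conceptual_dft(homo, homo + gap)
        assert eta >= 0

    def test_inverted_gap(self):
        with pytest.raises(ValidationError):
            derive_conceptual_dft(-0.1, -0.3)


class TestSolventMixture:
    DME_ETOAC = SolventMixture(components=((0.2, 7.20, 1.380), (0.8, 6.02, 1.372)))

    def test_dielectric_of_dme_etoac_blend(self):
        assert round(mixture_property(self.DME_ETOAC, "dielectric"), 2) == 6.26

    def test_refractive_index_of_dme_etoac_blend(self):
        assert round(mixture_property(self.DME_ETOAC, "refractive_index"), 3) == 1.374

    def test_single_component_identity(self):
        pure = SolventMixture(components=((1.0, 7.20, 1.380),))
        assert mixture_property(pure, "dielectric") == 7.20

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SolventMixture(components=((0.3, 7.20, 1.380), (0.3, 6.02, 1.372)))

    @given(f=st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linear_in_fractions_and_bounded(self, f):
        mix = SolventMixture(components=((f, 7.20, 1.380), (1 - f, 6.02, 1.372)))
        eps = mixture_property(mix, "dielectric")
        assert eps == pytest.approx(f * 7.20 + (1 - f) * 6.02)
        assert 6.02 <= eps <= 7.20


class TestFeaturizeDataset:
    def test_fingerprint_matrix_shape(self, small_library):
        matrix = featurize_dataset(small_library, "rdk", {"length": 2048})
        assert matrix.values.shape == (len(small_library), 2048)
        assert matrix.fingerprints is not None

    def test_row_order_matches_records(self, small_library):
        matrix = featurize_dataset(small_library, "rdk", {"length": 512})
        for record, fp in zip(small_library, matrix.fingerprints):
            assert fp.smiles == record.product_smiles

    def test_deterministic(self, small_library):
        a = featurize_dataset(small_library, "morgan", {"length": 512})
        b = featurize_dataset(small_library, "morgan", {"length": 512})
        np.testing.assert_array_equal(a.values, b.values)

    def test_qm_missing_record_named(self, small_library):
        from yieldmap.descriptors import QMPropertyRecord

        table = {
            r.key: QMPropertyRecord.from_frontier(-0.3, -0.1, 2.0, -12.0)
            for r in list(small_library)[:-1]
        }
        missing_key = small_library[len(small_library) - 1].key
        with pytest.raises(DescriptorAvailabilityError, match=missing_key):
            featurize_dataset(small_library, "qm", {"qm_table": table})

    def test_geometry_kind_without_geometries(self, small_library):
        with pytest.raises(DescriptorAvailabilityError):
            featurize_dataset(small_library, "coulomb_eigen", {})

    def test_unknown_kind(self, small_library):
        with pytest.raises(ConfigurationError):
            featurize_dataset(small_library, "no_such_descriptor")
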