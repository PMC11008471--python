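import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abclust import (
    EmbeddingRecord,
    ParatopeProfile,
    StratificationError,
    StructureModel,
    ValidationError,
    embedding_distance,
    extract_region,
    kabsch_rmsd,
    levenshtein_identity,
    paratope_distance,
    region_distance,
    structure_distance,
)

from conftest import make_record
from oracles import dp_levenshtein, random_rigid_motion

AA = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=25)


class TestLevenshteinIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ARDYW", "ARDYW", 1.0),
            ("ARDY", "ARGY", 0.75),
            ("", "AY", 0.0),
            ("AY", "", 0.0),
            ("", "", 1.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert levenshtein_identity(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(AA, AA)
    def test_matches_dp_oracle_and_symmetric(self, a, b):
        expected = 1.0 if not a and not b else (
            0.0 if not a or not b
            else 1.0 - dp_levenshtein(a, b) / max(len(a), len(b))
        )
        assert levenshtein_identity(a, b) == pytest.approx(expected)
        assert levenshtein_identity(a, b) == levenshtein_identity(b, a)

    def test_alphabet_agnostic(self):
        assert levenshtein_identity("AB1", "AB1") == 1.0


class TestRegionDistance:
    def test_identical_records_zero(self, toy_pair):
        a, _ = toy_pair
        for selector in ("cdrh3", "l3_h3", "heavy", "all"):
            assert region_distance(a, a, selector) == 0.0

    def test_single_substitution(self, toy_pair):
        a, b = toy_pair  # ARDYW vs ARDFW
        assert region_distance(a, b, "cdrh3") == pytest.approx(0.2)

    def test_heavy_selector_ignores_light(self):
        a = make_record("a", "ARDYW", cdrl3="QQYNSYPLT")
        b = make_record("b", "ARDYW", cdrl3="QQWWSYPLT")
        assert region_distance(a, b, "heavy") == 0.0
        assert region_distance(a, b, "light") > 0.0


def profile_for(rec, positions, others=()):
    probs = {pos: 0.9 for pos in positions}
    probs.update({pos: 0.1 for pos in others})
    return ParatopeProfile(record_id=rec.record_id, probabilities=probs)


class TestParatopeDistance:
    def test_identical_profiles_zero(self):
        rec = make_record("a", "ARDYW")
        start = rec.region_bounds["cdrh3"][0]
        prof = profile_for(rec, [("heavy", start + i) for i in range(3)])
        assert paratope_distance(rec, rec, prof, prof) == 0.0

    def test_disjoint_flags_distance_one(self):
        a = make_record("a", "ARDYW")
        b = make_record("b", "ARDYW")
        s = a.region_bounds["cdrh3"][0]
        pa = profile_for(a, [("heavy", s + 0)])
        pb = profile_for(b, [("heavy", s + 3)])
        assert paratope_distance(a, b, pa, pb) == 1.0

    def test_hand_enumerated_union(self):
        # flags {0,1,2} residues A,R,D vs {1,2,3} residues R,E,W; union of 4
        # index-aligned positions, only offset 1 flagged in both and matching
        a = make_record("a", "ARDYW")
        b = make_record("b", "AREWW")
        s = a.region_bounds["cdrh3"][0]
        pa = profile_for(a, [("heavy", s + i) for i in (0, 1, 2)])
        pb = profile_for(b, [("heavy", s + i) for i in (1, 2, 3)])
        assert paratope_distance(a, b, pa, pb) == pytest.approx(0.75)

    def test_empty_union_warns_and_returns_one(self, caplog):
        a = make_record("a", "ARDYW")
        pa = ParatopeProfile(record_id="a", probabilities={("heavy", 6): 0.1})
        with caplog.at_level(logging.WARNING, logger="abclust"):
            assert paratope_distance(a, a, pa, pa) == 1.0
        assert any("flagged" in m for m in caplog.messages)

    def test_profile_record_mismatch(self):
        a = make_record("a", "ARDYW")
        b = make_record("b", "ARDYW")
        prof = profile_for(a, [("heavy", 6)])
        with pytest.raises(ValidationError):
            paratope_distance(b, b, prof, prof)

    def test_probability_out_of_chain(self):
        a = make_record("a", "ARDYW")
        prof = ParatopeProfile(record_id="a", probabilities={("heavy", 999): 0.9})
        with pytest.raises(ValidationError):
            paratope_distance(a, a, prof, prof)

    def test_all_flagged_equals_region_distance_on_substituted_pair(self):
        """With every CDR3 position flagged, paratope identity reduces to
        positional identity, which equals Levenshtein identity for pure
        substitutions on length-matched records."""
        a = make_record("a", "ARDYWGQGTL", cdrl3="QQYNSYPLT")
        b = make_record("b", "ARDFWGQGTL", cdrl3="QQYNSYPLT")
        flags_a = [("heavy", i) for i in range(*a.region_bounds["cdrh3"])] + [
            ("light", i) for i in range(*a.region_bounds["cdrl3"])
        ]
        pa, pb = profile_for(a, flags_a), profile_for(b, flags_a)
        assert paratope_distance(a, b, pa, pb) == pytest.approx(
            region_distance(a, b, "l3_h3")
        )


class TestKabschRmsd:
    def test_identical_zero(self):
        coords = np.random.default_rng(0).normal(size=(5, 3))
        assert kabsch_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-10)

    def test_translation_and_rotation_invariance(self):
        coords = np.random.default_rng(1).normal(size=(6, 3))
        rot_z90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = coords @ rot_z90.T + np.array([5.0, 5.0, 5.0])
        assert kabsch_rmsd(coords, moved) == pytest.approx(0.0, abs=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(rng.integers(3, 12), 3)) * 4
        b = rng.normal(size=a.shape) * 4
        rot, trans = random_rigid_motion(rng)
        base = kabsch_rmsd(a, b)
        assert kabsch_rmsd(a @ rot.T + trans, b) == pytest.approx(base, abs=1e-8)
        assert kabsch_rmsd(a, b @ rot.T + trans) == pytest.approx(base, abs=1e-8)
        assert kabsch_rmsd(b, a) == pytest.approx(base, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=(7, 3)) * 3
            b = rng.normal(size=(7, 3)) * 3
            _, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            assert kabsch_rmsd(a, b) == pytest.approx(
                rssd / np.sqrt(len(a)), abs=1e-9
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_degenerate_flagged(self, caplog):
        with caplog.at_level(logging.WARNING, logger="abclust"):
            kabsch_rmsd(np.zeros((2, 3)), np.ones((2, 3)))
        assert any("degenerate" in m for m in caplog.messages)


def structure_for(rec, coords_by_chain):
    calpha = {}
    for chain, coords in coords_by_chain.items():
        for i, xyz in enumerate(coords):
            calpha[(chain, i)] = np.asarray(xyz, float)
    return StructureModel(record_id=rec.record_id, calpha=calpha)


class TestStructureDistance:
    def make_structured_pair(self, seed=0):
        a = make_record("a", "ARDYWGQGTL")
        b = make_record("b", "ARDFWGQGTL")
        rng = np.random.default_rng(seed)
        heavy = rng.normal(size=(len(a.heavy_seq), 3)) * 3
        light = rng.normal(size=(len(a.light_seq), 3)) * 3
        sa = structure_for(a, {"heavy": heavy, "light": light})
        sb = structure_for(b, {"heavy": heavy.copy(), "light": light.copy()})
        return a, b, sa, sb

    def test_identical_structures_zero(self):
        a, b, sa, sb = self.make_structured_pair()
        assert structure_distance(a, b, sa, sb, "cdrh3") == pytest.approx(0, abs=1e-9)

    def test_rigid_motion_zero(self):
        a, b, sa, sb = self.make_structured_pair()
        rot, trans = random_rigid_motion(np.random.default_rng(3))
        sb = StructureModel(
            record_id="b",
            calpha={k: v @ rot.T + trans for k, v in sb.calpha.items()},
        )
        for selector in ("cdrh3", "l3_h3", "heavy"):
            assert structure_distance(a, b, sa, sb, selector) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_known_displacement_closed_form(self):
        """Perturb k of n selector residues by a pure translation delta with
        the superposition region held fixed: RMSD = sqrt(k * delta^2 / n)."""
        a, b, sa, sb = self.make_structured_pair()
        start, end = b.region_bounds["cdrh3"]
        n = end - start
        k, delta = 3, 1.7
        for i in range(start, start + k):
            sb.calpha[("heavy", i)] = sb.calpha[("heavy", i)] + np.array(
                [0.0, 0.0, delta]
            )
        got = structure_distance(a, b, sa, sb, "cdrh3", superpose_on="light")
        assert got == pytest.approx(np.sqrt(k * delta**2 / n), abs=1e-6)

    def test_unequal_lengths_stratification_error(self):
        a = make_record("a", "ARDYW")
        b = make_record("b", "ARDYWW")
        sa = structure_for(a, {"heavy": np.zeros((len(a.heavy_seq), 3))})
        sb = structure_for(b, {"heavy": np.zeros((len(b.heavy_seq), 3))})
        with pytest.raises(StratificationError):
            structure_distance(a, b, sa, sb, "cdrh3")

    def test_missing_coordinates_listed(self):
        a = make_record("a", "ARDYW")
        sa = StructureModel(record_id="a", calpha={})
        with pytest.raises(ValidationError, match="missing"):
            structure_distance(a, a, sa, sa, "cdrh3")


def embedding_for(rec, vectors):
    return EmbeddingRecord(
        record_id=rec.record_id,
        per_residue={pos: np.asarray(v, float) for pos, v in vectors.items()},
    )


class TestEmbeddingDistance:
    def single_position_pair(self, vec_a, vec_b):
        a = make_record("a", "A")
        b = make_record("b", "A")
        s = a.region_bounds["cdrh3"][0]
        ea = embedding_for(a, {("heavy", s): vec_a})
        eb = embedding_for(b, {("heavy", s): vec_b})
        return ea, eb, a, b

    def test_identical_zero(self):
        ea, eb, a, b = self.single_position_pair([1.0, 2.0], [1.0, 2.0])
        assert embedding_distance(ea, eb, a, b, "cdrh3") == pytest.approx(0.0)

    def test_orthogonal_one(self):
        ea, eb, a, b = self.single_position_pair([1.0, 0.0], [0.0, 1.0])
        assert embedding_distance(ea, eb, a, b, "cdrh3") == pytest.approx(1.0)

    def test_hand_computed_cosine(self):
        ea, eb, a, b = self.single_position_pair([1.0, 0.0], [1.0, 1.0])
        assert embedding_distance(ea, eb, a, b, "cdrh3") == pytest.approx(
            1.0 - 1.0 / np.sqrt(2)
        )

    def test_positive_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        u, v = rng.normal(size=8), rng.normal(size=8)
        ea, eb, a, b = self.single_position_pair(u, v)
        ea2, eb2, _, _ = self.single_position_pair(3.5 * u, 0.2 * v)
        assert embedding_distance(ea, eb, a, b, "cdrh3") == pytest.approx(
            embedding_distance(ea2, eb2, a, b, "cdrh3")
        )

    def test_zero_norm_warns(self, caplog):
        ea, eb, a, b = self.single_position_pair([0.0, 0.0], [1.0, 0.0])
        with caplog.at_level(logging.WARNING, logger="abclust"):
            assert embedding_distance(ea, eb, a, b, "cdrh3") == 1.0

    def test_dimension_mismatch(self):
        ea, _, a, b = self.single_position_pair([1.0, 0.0], [0.0, 1.0])
        eb = embedding_for(b, {("heavy", b.region_bounds["cdrh3"][0]): [1.0, 0, 0]})
        with pytest.raises(ValueError):
            embedding_distance(ea, eb, a, b, "cdrh3")

    def test_euclidean_option(self):
        ea, eb, a, b = self.single_position_pair([1.0, 0.0], [0.0, 1.0])
        assert embedding_distance(
            ea, eb, a, b, "cdrh3", metric="euclidean"
        ) == pytest.approx(np.sqrt(2))


class TestMeasureContract:
    """All measures: symmetric, zero on identical inputs."""

    def test_symmetry_on_fixture(self, repertoire, aux):
        records, _ = repertoire
        a, b = records[0], records[9]
        assert region_distance(a, b, "l3_h3") == region_distance(b, a, "l3_h3")
        sa, sb = aux["structures"][a.record_id], aux["structures"][b.record_id]
        if len(a.heavy_seq) == len(b.heavy_seq):
            d1 = structure_distance(a, b, sa, sb, "cdrh3")
            d2 = structure_distance(b, a, sb, sa, "cdrh3")
            assert d1 == pytest.approx(d2, abs=1e-9)
        ea, eb = aux["embeddings"][a.record_id], aux["embeddings"][b.record_id]
        assert embedding_distance(ea, eb, a, b, "cdrs_all") == pytest.approx(
            embedding_distance(eb, ea, b, a, "cdrs_all")
        )
        pa, pb = aux["paratopes"][a.record_id], aux["paratopes"][b.record_id]
        assert paratope_distance(a, b, pa, pb) == paratope_distance(b, a, pb, pa)
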