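import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragpick import scoring
from fragpick.errors import ConfigurationError, ParseError
from fragpick.query_model import Query, Restraint, SSPrediction
from fragpick.scoring import (FuncSpec, ScoreMap, ScoreTermSpec, ScoringContext,
                              ScoringSystem, abego_bin, atom_pair_restraint_score,
                              build_rama_maps, dihedral_restraint_score,
                              fragment_crmsd, parse_score_config, profile_l1_score,
                              profile_submatrix_score, rama_score,
                              secondary_identity_score, secondary_similarity_score,
                              sequence_identity_score, torsion_bin_score,
                              total_score)
from fragpick.selection import FragmentCandidate


class TestScoreConfig:
    def test_basic_lines(self):
        specs = parse_score_config(
            "# score name priority wght max extras\n"
            "SecondarySimilarity 350 1.0 - predA\n"
            "RamaScore 400 2.0 - predA\n"
            "ProfileScoreL1 200 0.5 -\n"
            "FragmentCrmsd 0 0.0 -\n")
        assert [s.name for s in specs] == ["RamaScore", "SecondarySimilarity",
                                           "ProfileScoreL1", "FragmentCrmsd"]
        sims = [s for s in specs if s.name == "SecondarySimilarity"]
        assert sims[0].max_allowed is None and sims[0].extras == ["predA"]
        late = [s for s in specs if s.name == "FragmentCrmsd"][0]
        assert late.weight == 0.0 and late.is_late

    def test_three_tagged_instances_get_distinct_keys(self):
        specs = parse_score_config(
            "SecondarySimilarity 350 0.5 - psipred\n"
            "SecondarySimilarity 300 0.5 - sam\n"
            "SecondarySimilarity 250 0.5 - jufo\n")
        keys = scoring.score_term_keys(specs)
        assert len(set(keys)) == 3
        assert all("SecondarySimilarity" in k for k in keys)

    def test_unknown_term_lists_registered_names(self):
        with pytest.raises(ConfigurationError, match="ProfileScoreL1"):
            parse_score_config("NoSuchScore 100 1.0 -\n")

    def test_too_few_columns(self):
        with pytest.raises(ParseError):
            parse_score_config("ProfileScoreL1 200 0.5\n")


class TestTotalScore:
    def test_published_row_arithmetic(self):
        # weights 2.0/1.0/0.5/0.0 with term values 0.00/0.16/0.672/0.34
        # reproduce a printed total of 0.496
        specs = parse_score_config(
            "RamaScore 400 2.0 - predA\n"
            "SecondarySimilarity 350 1.0 - predA\n"
            "ProfileScoreL1 200 0.5 -\n"
            "FragmentCrmsd 0 0.0 -\n")
        sm = ScoreMap(values={"RamaScore": 0.0, "SecondarySimilarity": 0.16,
                              "ProfileScoreL1": 0.672, "FragmentCrmsd": 0.34})
        assert total_score(sm, specs) == pytest.approx(0.496, abs=1e-9)

    def test_single_term_linearity(self):
        specs = [ScoreTermSpec("ProfileScoreL1", 100, 2.0)]
        assert total_score(ScoreMap(values={"ProfileScoreL1": 1.0}), specs) == 2.0
        assert total_score(ScoreMap(values={"ProfileScoreL1": 0.0}), specs) == 0.0


class TestElementaryScores:
    def test_sequence_identity(self):
        assert sequence_identity_score("MKV", "MKV") == 0.0
        assert sequence_identity_score("MKV", "AAA") == 1.0
        assert sequence_identity_score("MKV", "MKA") == pytest.approx(1 / 3)

    def test_profile_l1(self):
        p = np.eye(20)[:3]
        assert profile_l1_score(p, p) == 0.0
        q = np.roll(p, 5, axis=1)  # disjoint one-hots at every position
        assert profile_l1_score(p, q) == 1.0
        a = np.zeros((1, 20)); a[0, 0] = a[0, 1] = 0.5
        b = np.zeros((1, 20)); b[0, 1] = b[0, 2] = 0.5
        assert profile_l1_score(a, b) == pytest.approx(0.5)

    def test_secondary_identity(self):
        assert secondary_identity_score("HHH", "HHH") == 0.0
        assert secondary_identity_score("HHH", "EEE") == 1.0
        assert secondary_identity_score("HHL", "HHE") == pytest.approx(1 / 3)

    def test_secondary_similarity_saturates_toward_the_likelier_state(self):
        # 51% helix / 49% strand: helical fragments must win on this term
        probs = np.array([[0.51, 0.49, 0.0]])
        helix = secondary_similarity_score(probs, "H")
        strand = secondary_similarity_score(probs, "E")
        assert helix == pytest.approx(0.49)
        assert strand == pytest.approx(0.51)
        assert helix < strand

    def test_secondary_similarity_extremes(self):
        probs = np.tile([1.0, 0.0, 0.0], (3, 1))
        assert secondary_similarity_score(probs, "HHH") == 0.0
        assert secondary_similarity_score(probs, "EEE") == 1.0

    def test_profile_submatrix_score(self):
        one_hot = np.eye(20)[[10, 8, 17]]  # M, K, V in alphabet order
        assert profile_submatrix_score(one_hot, "MKV") == pytest.approx(0.0)
        uniform = np.full((3, 20), 0.05)
        assert profile_submatrix_score(uniform, "MKV") == pytest.approx(0.95)

    def test_profile_submatrix_monotone_in_observed_probability(self, rng):
        base = rng.dirichlet(np.ones(20), size=3)
        s0 = profile_submatrix_score(base, "MKV")
        boosted = base.copy()
        from fragpick.constants import AA_INDEX
        for i, aa in enumerate("MKV"):
            boosted[i, AA_INDEX[aa]] += 0.2
            boosted[i] /= boosted[i].sum()
        assert profile_submatrix_score(boosted, "MKV") <= s0


class TestRama:
    def test_uniform_map_scores_zero_everywhere(self):
        maps = {s: np.full((36, 36), 1 / 1296) for s in "HEL"}
        probs = np.array([[1.0, 0.0, 0.0]])
        assert rama_score(probs, [(-60.0, -45.0)], maps) == pytest.approx(0.0)

    def test_modal_bin_scores_zero_and_empty_bin_scores_high(self):
        m = np.ones((36, 36)); m[12, 13] = 1000.0  # modal bin at (-60,-45)
        maps = {s: m / m.sum() for s in "HEL"}
        probs = np.array([[1.0, 0.0, 0.0]])
        assert rama_score(probs, [(-60.0, -45.0)], maps) == pytest.approx(0.0)
        far = rama_score(probs, [(100.0, 100.0)], maps)
        assert far == pytest.approx(1.0 - 1.0 / 1000.0)

    def test_undefined_torsions_contribute_one(self):
        maps = {s: np.full((36, 36), 1 / 1296) for s in "HEL"}
        probs = np.tile([1.0, 0.0, 0.0], (2, 1))
        s = rama_score(probs, [(float("nan"), 10.0), (-60.0, -45.0)], maps)
        assert s == pytest.approx(0.5)  # (1 + 0) / 2

    def test_build_maps_from_all_helix_database(self):
        from fragpick.fixtures import FixtureSpec, generate_vall
        spec = FixtureSpec(seed=2, n_chunks=4, chunk_length_range=(30, 40),
                           ss_composition={"H": 1.0, "E": 0.0, "L": 0.0},
                           torsion_noise=3.0)
        chunks, _ = generate_vall(spec)
        maps = build_rama_maps(chunks)
        for m in maps.values():
            assert m.sum() == pytest.approx(1.0)
            assert np.all(m > 0)  # smoothing keeps every bin populated
        # helix map concentrated around (-60, -45): phi bins 11-12, psi bin 13
        # (noise straddles the -60 bin edge)
        imax, jmax = np.unravel_index(np.argmax(maps["H"]), maps["H"].shape)
        assert imax in (11, 12) and jmax == 13
        # far above the uniform level of 1/1296 despite +1 smoothing
        assert maps["H"][11:13, 13].sum() > 50.0 / 1296.0


class TestCrmsd:
    def test_identical_and_rigidly_moved_coordinates(self, rng):
        x = rng.normal(size=(9, 3))
        assert fragment_crmsd(x, x) == pytest.approx(0.0, abs=1e-9)
        theta = np.radians(90.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = x @ rot.T + np.array([5.0, 0.0, 0.0])
        assert fragment_crmsd(x, moved) == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_clouds(self, rng):
        from MDAnalysis.analysis.rms import rmsd as qcp_rmsd
        for _ in range(100):
            x = rng.normal(size=(9, 3))
            y = rng.normal(size=(9, 3))
            expected = qcp_rmsd(x, y, center=True, superposition=True)
            assert fragment_crmsd(x, y) == pytest.approx(expected, abs=1e-6)


class TestRestraintScores:
    def test_harmonic_distance(self):
        func = FuncSpec("harmonic", x0=6.0, sd=1.0)
        r = Restraint("atom_pair", [(1, "CA"), (2, "CA")], func)
        coords = {(1, "CA"): np.zeros(3), (2, "CA"): np.array([6.0, 0, 0])}
        assert atom_pair_restraint_score(coords, r) == pytest.approx(0.0)
        coords[(2, "CA")] = np.array([8.0, 0, 0])
        assert atom_pair_restraint_score(coords, r) == pytest.approx(4.0)

    def test_bounded_inside_is_zero(self):
        func = FuncSpec("bounded", lb=4.0, ub=7.0, sd=1.0)
        r = Restraint("atom_pair", [(1, "CA"), (2, "CA")], func)
        coords = {(1, "CA"): np.zeros(3), (2, "CA"): np.array([5.0, 0, 0])}
        assert atom_pair_restraint_score(coords, r) == 0.0

    def test_missing_atom_means_not_applicable(self):
        func = FuncSpec("harmonic", x0=6.0, sd=1.0)
        r = Restraint("atom_pair", [(1, "CB"), (2, "CA")], func)
        assert atom_pair_restraint_score({(2, "CA"): np.zeros(3)}, r) is None

    def test_dihedral_trans_and_exact_match(self):
        pts = {(1, "N"): np.array([0.0, 1.0, 0.0]), (1, "CA"): np.zeros(3),
               (1, "C"): np.array([1.0, 0.0, 0.0]), (2, "N"): np.array([1.0, -1.0, 0.0])}
        from fragpick.geometry import dihedral
        measured = dihedral(pts[(1, "N")], pts[(1, "CA")], pts[(1, "C")], pts[(2, "N")])
        assert abs(measured) == pytest.approx(180.0)
        func = FuncSpec("circular_harmonic", x0=math.radians(measured), sd=0.5)
        r = Restraint("dihedral", [(1, "N"), (1, "CA"), (1, "C"), (2, "N")], func)
        assert dihedral_restraint_score(pts, r) == pytest.approx(0.0, abs=1e-12)

    def test_circular_harmonic_wraps_through_180(self):
        # measured -175 deg against x0 = +175 deg is a 10 deg violation
        func = FuncSpec("circular_harmonic", x0=math.radians(175.0), sd=math.radians(10.0))
        assert func.angle_value(-175.0) == pytest.approx(1.0, abs=1e-9)


class TestAbego:
    @pytest.mark.parametrize("phi,psi,omega,expected", [
        (-60.0, -45.0, 180.0, "A"),   # canonical alpha helix
        (-120.0, 130.0, 180.0, "B"),  # canonical beta strand
        (-60.0, -45.0, 10.0, "O"),    # cis omega wins over phi/psi
        (60.0, 30.0, 180.0, "G"),
        (60.0, 150.0, -175.0, "E"),
        (float("nan"), 0.0, 180.0, "-"),
    ])
    def test_bin_assignment(self, phi, psi, omega, expected):
        assert abego_bin(phi, psi, omega) == expected

    def test_torsion_bin_score_rules(self):
        all_ones = np.ones((1, 5))
        assert torsion_bin_score(all_ones, [(-120.0, 130.0, 180.0)]) == 0.0
        only_a = np.array([[1.0, 0.0, 0.0, 0.0, 0.0]])
        assert torsion_bin_score(only_a, [(-60.0, -45.0, 180.0)]) == 0.0
        assert torsion_bin_score(only_a, [(-120.0, 130.0, 180.0)]) == 1.0
        quarter = np.full((1, 5), 0.25)
        assert torsion_bin_score(quarter, [(-60.0, -45.0, 180.0)]) == pytest.approx(0.75)

    def test_undefined_torsions_use_best_available_bin(self):
        all_ones = np.ones((1, 5))
        assert torsion_bin_score(all_ones, [(float("nan"),) * 3]) == 0.0


class TestEvaluationOrder:
    def _system(self, tiny_world, config_text):
        chunks, planted, query, _ = tiny_world
        specs = parse_score_config(config_text)
        ctx = ScoringContext(rama_maps=build_rama_maps(chunks))
        return chunks, query, ScoringSystem(specs, query, [3, 9], ctx)

    def test_threshold_short_circuit_skips_lower_priority(self, tiny_world):
        chunks, query, system = self._system(
            tiny_world,
            "SecondarySimilarity 400 1.0 0.0 psipred\n"  # max 0: reject all mismatch
            "ProfileScoreL1 200 1.0 -\n")
        system.prepare_chunk(chunks[0])
        rejected = 0
        for offset in range(chunks[0].L_C - 9 + 1):
            cand = FragmentCandidate(1, chunks[0], offset, 9)
            sm = system.evaluate_candidate(cand)
            if sm.rejected_by == "SecondarySimilarity":
                rejected += 1
                assert "ProfileScoreL1" not in sm.values
                assert sm.total is None
        assert rejected > 0

    def test_zero_weight_term_deferred_to_late_scoring(self, tiny_world):
        chunks, query, system = self._system(
            tiny_world,
            "SecondarySimilarity 400 1.0 - psipred\n"
            "FragmentCrmsd 0 0.0 -\n")
        system.prepare_chunk(chunks[0])
        cand = FragmentCandidate(1, chunks[0], 0, 9)
        sm = system.evaluate_candidate(cand)
        assert "FragmentCrmsd" not in sm.values
        cand.score_map = sm
        system.late_score(cand)
        assert "FragmentCrmsd" in cand.score_map.values

    def test_cached_equals_direct_on_random_windows(self, tiny_world, rng):
        chunks, planted, query, _ = tiny_world
        query.set_torsion_bin_probs(rng.uniform(0.0, 1.0, size=(query.L_Q, 5)))
        from fragpick.scoring import load_substitution_matrix
        ctx = ScoringContext(rama_maps=build_rama_maps(chunks),
                             submatrix=load_substitution_matrix("BLOSUM62"))
        specs = parse_score_config(
            "SecondarySimilarity 400 1.0 - psipred\n"
            "RamaScore 350 1.0 - psipred\n"
            "TorsionBinSimilarity 300 1.0 -\n"
            "ProfileScoreL1 200 1.0 -\n"
            "ProfileScoreSubMatrix 100 1.0 -\n")
        system = ScoringSystem(specs, query, [3, 9], ctx)
        pred = query.ss_predictions["psipred"]
        derived = next(t for t in system.terms
                       if t.spec.name == "ProfileScoreSubMatrix").derived_profile
        for _ in range(100):
            chunk = chunks[int(rng.integers(len(chunks)))]
            L_F = int(rng.choice([3, 9]))
            if chunk.L_C < L_F:
                continue
            system.prepare_chunk(chunk)
            q0 = int(rng.integers(0, query.L_Q - L_F))
            off = int(rng.integers(0, chunk.L_C - L_F + 1))
            sm = system.evaluate_candidate(FragmentCandidate(q0 + 1, chunk, off, L_F))
            window = chunk.residues[off:off + L_F]
            expected = {
                "SecondarySimilarity": secondary_similarity_score(
                    pred.probs[q0:q0 + L_F], chunk.ss_string[off:off + L_F]),
                "RamaScore": rama_score(
                    pred.probs[q0:q0 + L_F], [(r.phi, r.psi) for r in window],
                    ctx.rama_maps),
                "TorsionBinSimilarity": torsion_bin_score(
                    query.torsion_bin_probs[q0:q0 + L_F],
                    [(r.phi, r.psi, r.omega) for r in window]),
                "ProfileScoreL1": profile_l1_score(
                    query.profile[q0:q0 + L_F],
                    chunk.profile_matrix()[off:off + L_F]),
                "ProfileScoreSubMatrix": profile_submatrix_score(
                    derived[q0:q0 + L_F], chunk.sequence[off:off + L_F]),
            }
            for key, exp in expected.items():
                assert sm.values[key] == pytest.approx(exp, abs=1e-9), key

    def test_missing_tag_is_startup_error(self, tiny_world):
        chunks, _, query, _ = tiny_world
        specs = parse_score_config("SecondarySimilarity 400 1.0 - nosuchtag\n")
        with pytest.raises(ConfigurationError, match="nosuchtag"):
            ScoringSystem(specs, query, [9])

    def test_crmsd_without_reference_is_startup_error(self, tiny_world):
        chunks, planted, _, _ = tiny_world
        bare = Query(sequence=planted.sequence)
        specs = parse_score_config("FragmentCrmsd 0 0.0 -\n")
        with pytest.raises(ConfigurationError, match="reference"):
            ScoringSystem(specs, bare, [9])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_nonrestraint_terms_are_normalized(seed):
    """Every non-restraint term lies in [0, 1] on randomized inputs."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(1, 10))
    q_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L))
    v_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L))
    assert 0.0 <= sequence_identity_score(q_seq, v_seq) <= 1.0
    p = rng.dirichlet(np.ones(20), size=L)
    v = rng.dirichlet(np.ones(20), size=L)
    assert 0.0 <= profile_l1_score(p, v) <= 1.0
    assert 0.0 <= profile_submatrix_score(p, v_seq) <= 1.0
    ss_probs = rng.dirichlet(np.ones(3), size=L)
    frag_ss = "".join(rng.choice(list("HEL"), L))
    assert 0.0 <= secondary_similarity_score(ss_probs, frag_ss) <= 1.0
    assert 0.0 <= secondary_identity_score(frag_ss, "".join(rng.choice(list("HEL"), L))) <= 1.0
    torsions = rng.uniform(-180.0, 180.0, size=(L, 3))
    maps = {s: (lambda m: m / m.sum())(rng.uniform(0.1, 5.0, size=(36, 36))) for s in "HEL"}
    assert 0.0 <= rama_score(ss_probs, torsions[:, :2], maps) <= 1.0
    bins = rng.uniform(0.0, 1.0, size=(L, 5))
    assert 0.0 <= torsion_bin_score(bins, torsions) <= 1.0
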