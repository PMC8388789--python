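"""Mixed-model equations, PEV/PEC, and the four connectedness statistics."""

import numpy as np
import pandas as pd
import pytest

from pedconnect import (
    FEMALE,
    MALE,
    Pedigree,
    PedigreeRecord,
    RecordsDesign,
    build_mme,
    cd_ind,
    classify_connectedness,
    connectedness,
    kinship,
    pev_pec,
    pevd_group,
    pevd_ind,
    r_individual,
    r_stat,
    summarize_connectedness,
)

from conftest import random_pedigree


def two_unit_founder_system(n_per_unit: int = 1, h2: float = 0.5):
    """Unrelated founders, one record each, split across two units."""
    records, animals, units = [], [], []
    for u in ("u1", "u2"):
        for k in range(n_per_unit):
            name = f"{u}a{k}"
            records.append(PedigreeRecord(name, sex=FEMALE))
            animals.append(name)
            units.append(u)
    ped = Pedigree(records)
    design = RecordsDesign(animals=tuple(animals), units=tuple(units))
    return ped, design, build_mme(ped, design, h2=h2)


def random_design(ped: Pedigree, rng, n_units: int = 3, n_records: int = 25) -> RecordsDesign:
    """Random records over the later (recorded) half of a pedigree."""
    pool = ped.ids[len(ped) // 2 :]
    animals = [pool[int(rng.integers(len(pool)))] for _ in range(n_records)]
    units = [f"u{int(rng.integers(n_units)) + 1}" for _ in range(n_records)]
    # every unit needs at least one record
    for k in range(n_units):
        animals.append(pool[int(rng.integers(len(pool)))])
        units.append(f"u{k + 1}")
    return RecordsDesign(animals=tuple(animals), units=tuple(units))


class TestBuildMME:
    def test_two_founder_closed_form(self):
        """2 units x 1 founder each, h2=0.5: hand-assembled 4x4 system."""
        _, _, mme = two_unit_founder_system()
        assert mme.lam == pytest.approx(1.0)
        M = mme.coefficient_matrix.toarray()
        expected = np.array(
            [
                [1.0, 0.0, 1.0, 0.0],
                [0.0, 1.0, 0.0, 1.0],
                [1.0, 0.0, 2.0, 0.0],
                [0.0, 1.0, 0.0, 2.0],
            ]
        )
        assert np.allclose(M, expected)

    def test_lambda_values(self):
        ped = Pedigree([PedigreeRecord("A", sex=FEMALE)])
        design = RecordsDesign(("A",), ("u1",))
        assert build_mme(ped, design, h2=0.5).lam == pytest.approx(1.0)
        assert build_mme(ped, design, h2=0.25).lam == pytest.approx(3.0)

    def test_pedigree_only_animal_enlarges_animal_block(self):
        ped1 = Pedigree([PedigreeRecord("A", sex=FEMALE)])
        ped2 = Pedigree([PedigreeRecord("A", sex=FEMALE), PedigreeRecord("B")])
        design = RecordsDesign(("A",), ("u1",))
        m1 = build_mme(ped1, design).coefficient_matrix
        m2 = build_mme(ped2, design).coefficient_matrix
        assert m2.shape[0] == m1.shape[0] + 1
        assert build_mme(ped2, design).n_units == 1

    def test_invalid_inputs(self):
        ped = Pedigree([PedigreeRecord("A", sex=FEMALE)])
        design = RecordsDesign(("A",), ("u1",))
        for h2 in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                build_mme(ped, design, h2=h2)
        with pytest.raises(ValueError):
            build_mme(ped, RecordsDesign(("Z",), ("u1",)))

    def test_repeated_records_allowed(self):
        ped = Pedigree([PedigreeRecord("A", sex=FEMALE), PedigreeRecord("B", sex=FEMALE)])
        design = RecordsDesign(("A", "A", "B"), ("u1", "u1", "u2"))
        mme = build_mme(ped, design)
        # Z'Z diagonal counts records per animal
        assert mme.coefficient_matrix.toarray()[2, 2] == pytest.approx(2 + mme.lam)


class TestPevPec:
    def test_uninformative_animal_has_prior_pev(self):
        """No record, no relatives: PEV equals the prior variance σu²."""
        ped = Pedigree([PedigreeRecord("A", sex=FEMALE), PedigreeRecord("Z")])
        design = RecordsDesign(("A",), ("u1",))
        mme = build_mme(ped, design, h2=0.3, sigma_e2=2.0)
        pp = pev_pec(mme, ["Z"])
        assert pp.values[0, 0] == pytest.approx(mme.sigma_u2)

    def test_pev_decreases_with_progeny_records(self):
        base = [
            PedigreeRecord("S", sex=MALE),
            PedigreeRecord("D1", sex=FEMALE),
            PedigreeRecord("D2", sex=FEMALE),
            PedigreeRecord("P1", sire="S", dam="D1", sex=FEMALE),
        ]
        ped1 = Pedigree(base)
        d1 = RecordsDesign(("P1",), ("u1",))
        pev1 = pev_pec(build_mme(ped1, d1), ["S"]).values[0, 0]
        ped2 = Pedigree(base + [PedigreeRecord("P2", sire="S", dam="D2", sex=FEMALE)])
        d2 = RecordsDesign(("P1", "P2"), ("u1", "u1"))
        pev2 = pev_pec(build_mme(ped2, d2), ["S"]).values[0, 0]
        assert pev2 < pev1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_dense_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n=10)
        design = random_design(ped, rng, n_units=2, n_records=8)
        mme = build_mme(ped, design, h2=0.4, sigma_e2=1.5)
        pp = pev_pec(mme)
        Minv = np.linalg.inv(mme.coefficient_matrix.toarray())
        idx = [mme.n_units + ped.index_of(a) for a in pp.ids]
        assert np.allclose(pp.values, Minv[np.ix_(idx, idx)] * 1.5, atol=1e-8)

    def test_constraint_invariance_with_redundant_intercept(self):
        """Adding an intercept makes the fixed block rank-deficient; the
        animal block of a generalized inverse is unchanged."""
        rng = np.random.default_rng(42)
        ped = random_pedigree(rng, n=12)
        design = random_design(ped, rng, n_units=3, n_records=10)
        mme = build_mme(ped, design, h2=0.3)
        pp = pev_pec(mme)
        # dense route with an explicit intercept column prepended to X
        X = np.hstack([np.ones((mme.X.shape[0], 1)), mme.X.toarray()])
        Z = mme.Z.toarray()
        from pedconnect import a_inverse

        Ainv = a_inverse(ped).toarray()
        M = np.block(
            [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + mme.lam * Ainv]]
        )
        Minv = np.linalg.pinv(M, hermitian=True)
        p = X.shape[1]
        idx = [p + ped.index_of(a) for a in pp.ids]
        assert np.allclose(pp.values, Minv[np.ix_(idx, idx)] * mme.sigma_e2, atol=1e-8)


class TestPevdInd:
    def test_unrelated_units_give_twice_pev(self):
        ped, design, mme = two_unit_founder_system(n_per_unit=2)
        pp = pev_pec(mme)
        m = pevd_ind(pp, design)
        pev = pp.values[0, 0]
        # unrelated units but shared unit effects: cross-unit PEC = 0
        assert m.loc["u1", "u2"] == pytest.approx(2 * pev - 2 * pp.values[0, 2])

    def test_three_unit_toy_vs_bruteforce(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(rng, n=15)
        design = random_design(ped, rng, n_units=3, n_records=12)
        pp = pev_pec(build_mme(ped, design, h2=0.35))
        m = pevd_ind(pp, design)
        members = design.unit_members()
        pos = {a: i for i, a in enumerate(pp.ids)}
        for ui in design.unit_labels:
            for uj in design.unit_labels:
                acc = [
                    pp.values[pos[a], pos[a]] + pp.values[pos[b], pos[b]]
                    - 2 * pp.values[pos[a], pos[b]]
                    for a in members[ui]
                    for b in members[uj]
                ]
                assert m.loc[ui, uj] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_symmetry_and_nonnegative_diagonal(self):
        rng = np.random.default_rng(9)
        ped = random_pedigree(rng, n=20)
        design = random_design(ped, rng)
        pp = pev_pec(build_mme(ped, design))
        m = pevd_ind(pp, design).to_numpy()
        assert np.allclose(m, m.T)
        assert (np.diag(m) >= -1e-12).all()


class TestPevdGroup:
    def test_quadratic_form_oracle(self):
        """Group PEVD equals w'Pw with w the signed unit-mean contrast."""
        rng = np.random.default_rng(4)
        ped = random_pedigree(rng, n=18)
        design = random_design(ped, rng, n_units=3, n_records=14)
        pp = pev_pec(build_mme(ped, design, h2=0.25))
        m = pevd_group(pp, design)
        members = design.unit_members()
        pos = {a: i for i, a in enumerate(pp.ids)}
        units = design.unit_labels
        for ui in units:
            for uj in units:
                w = np.zeros(len(pp.ids))
                for a in members[ui]:
                    w[pos[a]] += 1.0 / len(members[ui])
                for b in members[uj]:
                    w[pos[b]] -= 1.0 / len(members[uj])
                assert m.loc[ui, uj] == pytest.approx(w @ pp.values @ w, abs=1e-10)

    def test_identical_unit_gives_zero(self):
        """A unit paired with itself has no mean-difference error variance."""
        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, n=16)
        design = random_design(ped, rng)
        pp = pev_pec(build_mme(ped, design))
        m = pevd_group(pp, design).to_numpy()
        assert np.allclose(np.diag(m), 0.0, atol=1e-12)
        assert (m >= -1e-12).all()  # a variance

    def test_disconnected_single_animal_units(self):
        ped, design, mme = two_unit_founder_system(n_per_unit=1)
        pp = pev_pec(mme)
        m = pevd_group(pp, design)
        assert m.loc["u1", "u2"] == pytest.approx(
            pp.values[0, 0] + pp.values[1, 1] - 2 * pp.values[0, 1]
        )


class TestCD:
    def test_no_information_limit_gives_zero(self):
        """As h2 -> 0 records carry no genetic signal: PEV -> σu² and CD -> 0
        for unrelated units."""
        ped, design, _ = two_unit_founder_system(n_per_unit=1)
        mme = build_mme(ped, design, h2=1e-9)
        pp = pev_pec(mme)
        K = kinship(ped, list(pp.ids)).relationship
        m = cd_ind(pp, K, design, mme.lam)
        assert m.loc["u1", "u2"] == pytest.approx(0.0, abs=1e-6)

    def test_perfect_information_limit_gives_one(self):
        """With the units connected (one animal recorded in both) and h2 -> 1
        every EBV difference is estimable, PEVD -> 0 and CD -> 1."""
        ped = Pedigree(
            [
                PedigreeRecord("A", sex=FEMALE),
                PedigreeRecord("B", sex=FEMALE),
                PedigreeRecord("C", sex=FEMALE),
            ]
        )
        design = RecordsDesign(("A", "B", "C", "C"), ("u1", "u2", "u1", "u2"))
        mme = build_mme(ped, design, h2=1 - 1e-7)
        pp = pev_pec(mme)
        K = kinship(ped, list(pp.ids)).relationship
        m = cd_ind(pp, K, design, mme.lam)
        assert m.loc["u1", "u2"] == pytest.approx(1.0, abs=1e-5)

    def test_ratio_of_sums_equals_pevd_over_relationship_form(self):
        """The two printed forms of the unit-level CD — λ-scaled C²² sums and
        ΣPEVD/(σu²·ΣK-terms) — agree when computed independently."""
        rng = np.random.default_rng(6)
        ped = random_pedigree(rng, n=20)
        design = random_design(ped, rng, n_units=3, n_records=15)
        mme = build_mme(ped, design, h2=0.3, sigma_e2=2.0)
        pp = pev_pec(mme)
        K = kinship(ped, list(pp.ids)).relationship
        m = cd_ind(pp, K, design, mme.lam)
        members = design.unit_members()
        pos = {a: i for i, a in enumerate(pp.ids)}
        for ui in design.unit_labels:
            for uj in design.unit_labels:
                if ui == uj:
                    continue
                pevd_sum = sum(
                    pp.values[pos[a], pos[a]] + pp.values[pos[b], pos[b]]
                    - 2 * pp.values[pos[a], pos[b]]
                    for a in members[ui] for b in members[uj]
                )
                k_sum = sum(
                    K[pos[a], pos[a]] + K[pos[b], pos[b]] - 2 * K[pos[a], pos[b]]
                    for a in members[ui] for b in members[uj]
                )
                assert m.loc[ui, uj] == pytest.approx(
                    1.0 - pevd_sum / (mme.sigma_u2 * k_sum), abs=1e-10
                )

    def test_clone_units_rejected(self):
        """Units made of the same animal have zero relationship variance."""
        ped = Pedigree([PedigreeRecord("A", sex=FEMALE)])
        design = RecordsDesign(("A", "A"), ("u1", "u2"))
        mme = build_mme(ped, design)
        pp = pev_pec(mme)
        K = kinship(ped, list(pp.ids)).relationship
        with pytest.raises(ValueError, match="degenerate"):
            cd_ind(pp, K, design, mme.lam)


class TestRStat:
    def test_disconnected_units_have_zero_r(self):
        ped, design, mme = two_unit_founder_system(n_per_unit=2)
        pp = pev_pec(mme)
        m = r_stat(pp, design)
        assert m.loc["u1", "u2"] == pytest.approx(0.0, abs=1e-12)

    def test_unit_with_itself_is_one(self):
        rng = np.random.default_rng(8)
        ped = random_pedigree(rng, n=15)
        design = random_design(ped, rng)
        pp = pev_pec(build_mme(ped, design))
        m = r_stat(pp, design).to_numpy()
        assert np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()

    def test_individual_level_is_correlation(self):
        rng = np.random.default_rng(10)
        ped = random_pedigree(rng, n=12)
        design = random_design(ped, rng, n_units=2, n_records=8)
        pp = pev_pec(build_mme(ped, design))
        r = r_individual(pp)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1 + 1e-12).all()

    def test_shared_sire_link_increases_r_and_decreases_pevd(self):
        """A sire with recorded progeny in both units connects them."""
        base = [
            PedigreeRecord("S", sex=MALE),
            PedigreeRecord("D1", sex=FEMALE), PedigreeRecord("D2", sex=FEMALE),
            PedigreeRecord("D3", sex=FEMALE), PedigreeRecord("D4", sex=FEMALE),
            PedigreeRecord("S2", sex=MALE),
        ]
        def stats_for(sire_of_b):
            ped = Pedigree(
                base
                + [
                    PedigreeRecord("A1", sire="S", dam="D1", sex=FEMALE),
                    PedigreeRecord("A2", sire="S", dam="D2", sex=FEMALE),
                    PedigreeRecord("B1", sire=sire_of_b, dam="D3", sex=FEMALE),
                    PedigreeRecord("B2", sire=sire_of_b, dam="D4", sex=FEMALE),
                ]
            )
            design = RecordsDesign(("A1", "A2", "B1", "B2"), ("u1", "u1", "u2", "u2"))
            pp = pev_pec(build_mme(ped, design))
            return (
                r_stat(pp, design).loc["u1", "u2"],
                pevd_ind(pp, design).loc["u1", "u2"],
            )

        r_conn, pevd_conn = stats_for("S")
        r_disc, pevd_disc = stats_for("S2")
        assert r_conn > r_disc
        assert pevd_conn < pevd_disc


class TestSummaries:
    def _toy_result(self, seed=12):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n=25)
        design = random_design(ped, rng, n_units=3, n_records=20)
        return connectedness(ped, design, h2=0.3), design

    def test_two_units_overall_equals_single_offdiagonal(self):
        rng = np.random.default_rng(13)
        ped = random_pedigree(rng, n=15)
        design = random_design(ped, rng, n_units=2, n_records=10)
        res = connectedness(ped, design)
        for s, m in res.matrices.items():
            assert res.overall_means[s] == pytest.approx(m.iloc[0, 1])

    def test_identical_matrices_correlate_perfectly(self):
        res, design = self._toy_result()
        m = res.matrices["PEVD_ind"]
        matrices = {k: m for k in res.matrices}
        r = summarize_connectedness(matrices, design).cross_statistic_correlation()
        assert np.allclose(r.to_numpy(), 1.0)

    def test_unit_relabeling_and_record_order_invariance(self):
        rng = np.random.default_rng(14)
        ped = random_pedigree(rng, n=20)
        design = random_design(ped, rng, n_units=3, n_records=15)
        res1 = connectedness(ped, design)
        perm = rng.permutation(len(design.animals))
        relabel = {"u1": "x3", "u2": "x1", "u3": "x2"}
        design2 = RecordsDesign(
            animals=tuple(design.animals[k] for k in perm),
            units=tuple(relabel[design.units[k]] for k in perm),
        )
        res2 = connectedness(ped, design2)
        for s in res1.matrices:
            m1 = res1.matrices[s]
            m2 = res2.matrices[s]
            for ui, vi in relabel.items():
                for uj, vj in relabel.items():
                    assert m1.loc[ui, uj] == pytest.approx(
                        m2.loc[vi, vj], abs=1e-9
                    )

    def test_benchmark_classifier(self):
        assert classify_connectedness(0.01) == "insufficient"
        assert classify_connectedness(0.05) == "good"
        assert classify_connectedness(0.0999) == "good"
        assert classify_connectedness(0.10) == "superior"

    def test_diagonal_excluded_from_means(self):
        res, _ = self._toy_result()
        r = res.matrices["r"].to_numpy()
        # r diagonal is 1; the overall mean must come from off-diagonals only
        iu, ju = np.triu_indices(r.shape[0], k=1)
        assert res.overall_means["r"] == pytest.approx(r[iu, ju].mean())
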