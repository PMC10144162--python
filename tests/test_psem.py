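"""Path models, d-separation basis sets, Fisher's C, model selection."""

import math

import numpy as np
import pytest

from floralint import (
    ValidationError,
    basis_set,
    build_path_model,
    enumerate_candidate_models,
    fisher_c,
    fit_psem,
    load_model_family,
    select_best,
    simulate_tree,
)
from floralint.psem import PSEMFit
from floralint.synthetic_data import SyntheticTruth, causal_frame, simulate_species_means


def study_model():
    """The study system's best-supported path structure."""
    return build_path_model(
        [("PLa", "tube"), ("PLa", "stigma"), ("stigma", "upper")],
        [("tube", "stigma"), ("upper", "lower")],
        name="study",
    )


def brute_force_basis(model):
    """Independent pair scan applying the three exclusion rules."""
    exo = {v for v in model.vertices if not model.parents(v)}
    out = set()
    verts = sorted(model.vertices)
    for i, u in enumerate(verts):
        for v in verts[i + 1 :]:
            if (u, v) in model.edges or (v, u) in model.edges:
                continue
            if frozenset((u, v)) in model.correlated_errors:
                continue
            if u in exo and v in exo:
                continue
            cond = frozenset((model.parents(u) | model.parents(v)) - {u, v})
            out.add((frozenset((u, v)), cond))
    return out


def chi2_sf_even_df(c, df):
    """Survival function of chi-squared with even df, closed form:
    exp(-c/2) * sum_{i<df/2} (c/2)^i / i!"""
    k = df // 2
    half = c / 2.0
    return math.exp(-half) * sum(half**i / math.factorial(i) for i in range(k))


class TestPathModel:
    def test_study_model_structure(self):
        m = study_model()
        assert set(m.endogenous()) == {"tube", "stigma", "upper"}
        assert m.exogenous() == {"PLa", "lower"}

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            build_path_model([("A", "B"), ("B", "A")])

    def test_edge_plus_correlated_error_conflict(self):
        with pytest.raises(ValidationError, match="conflict"):
            build_path_model([("A", "B")], [("A", "B")])


class TestBasisSet:
    def test_chain_single_claim(self):
        m = build_path_model([("A", "B"), ("B", "C")])
        claims = basis_set(m)
        assert len(claims) == 1
        c = claims[0]
        assert {c.u, c.v} == {"A", "C"}
        assert c.conditioning == ("B",)
        assert c.response == "C"

    def test_correlated_error_excludes_claim(self):
        m = build_path_model([("A", "B"), ("B", "C")], [("A", "C")])
        assert basis_set(m) == []

    @pytest.mark.parametrize("model_factory", [study_model, None])
    def test_matches_brute_force_scan(self, model_factory):
        models = [model_factory()] if model_factory else enumerate_candidate_models()
        for m in models:
            got = {
                (frozenset((c.u, c.v)), frozenset(c.conditioning)) for c in basis_set(m)
            }
            assert got == brute_force_basis(m)

    def test_study_model_claims(self):
        claims = basis_set(study_model())
        got = {(tuple(sorted((c.u, c.v))), tuple(sorted(c.conditioning))) for c in claims}
        assert got == {
            (("PLa", "upper"), ("stigma",)),
            (("tube", "upper"), ("PLa", "stigma")),
            (("lower", "tube"), ("PLa",)),
            (("lower", "stigma"), ("PLa",)),
        }

    def test_response_is_always_endogenous(self):
        for m in enumerate_candidate_models():
            for c in basis_set(m):
                assert m.parents(c.response)


class TestFisherC:
    def test_additivity(self, rng):
        p = rng.uniform(0.01, 1.0, size=6)
        assert fisher_c(p) == pytest.approx(float(-2 * np.log(p).sum()), abs=1e-12)

    def test_df2_closed_form(self):
        from scipy.stats import chi2

        c = 0.338
        assert chi2.sf(c, 2) == pytest.approx(math.exp(-c / 2), abs=1e-12)

    def test_two_half_claims_oracle(self):
        """Two claims at p = 0.5: C = 2.773, chi2_4 survival = 0.597."""
        from scipy.stats import chi2

        c = fisher_c([0.5, 0.5])
        assert c == pytest.approx(2.773, abs=5e-4)
        p = chi2.sf(c, 4)
        assert p == pytest.approx(0.597, abs=5e-4)
        assert p == pytest.approx(chi2_sf_even_df(c, 4), abs=1e-10)

    def test_chi2_matches_independent_series(self, rng):
        from scipy.stats import chi2

        for df in (2, 4, 8, 12):
            for c in rng.uniform(0.1, 30, size=5):
                assert chi2.sf(c, df) == pytest.approx(chi2_sf_even_df(c, df), abs=1e-10)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            fisher_c([0.5, 0.0])


@pytest.fixture(scope="module")
def fitted():
    tree = simulate_tree(50, seed=13)
    truth = SyntheticTruth(seed=13, n_tips=50)
    means = simulate_species_means(truth, tree, seed=14)
    return fit_psem(study_model(), causal_frame(means), tree, evolutionary_models="BM")


class TestFitPSEM:
    def test_aic_bookkeeping(self, fitted):
        """AIC - C = 2K with K recounted independently from the structure."""
        m = fitted.model
        k_manual = sum(1 + len(m.parents(v)) for v in m.endogenous())
        k_manual += len(m.correlated_errors)
        assert fitted.n_params == k_manual
        assert fitted.aic - fitted.c_statistic == pytest.approx(2 * k_manual, abs=1e-12)

    def test_c_from_claim_pvalues(self, fitted):
        assert fitted.c_statistic == pytest.approx(
            fisher_c([c.p for c in fitted.claims]), abs=1e-12
        )
        assert fitted.df == 2 * len(fitted.claims)

    def test_structural_coefficients_near_truth(self, fitted):
        eq = fitted.equations
        assert eq["stigma"]["coefficients"]["PLa"] == pytest.approx(1.765, rel=0.25)
        assert eq["tube"]["coefficients"]["PLa"] == pytest.approx(0.207, rel=0.35)
        assert 0 < eq["stigma"]["r2"] <= 1

    def test_correlated_error_detected(self, fitted):
        tests = {tuple(t["pair"]): t for t in fitted.correlated_error_tests}
        assert tests[("stigma", "tube")]["r"] > 0.3
        assert tests[("stigma", "tube")]["p"] < 0.05

    def test_claim_power_against_missing_path(self, rng):
        """Omitting a genuinely strong path is caught by its claim."""
        wrong = build_path_model(
            [("PLa", "tube"), ("stigma", "upper")],  # drops PLa -> stigma
            [("upper", "lower")],
            name="missing-path",
        )
        hits = 0
        for i in range(20):
            tree = simulate_tree(100, seed=1000 + i)
            truth = SyntheticTruth(seed=1000 + i, n_tips=100)
            means = simulate_species_means(truth, tree, seed=2000 + i)
            fit = fit_psem(wrong, causal_frame(means), tree, evolutionary_models="BM")
            hits += fit.p <= 0.05
        assert hits >= 18


class TestCandidateFamily:
    def test_family_size_and_validity(self):
        family = enumerate_candidate_models()
        assert len(family) >= 7
        names = [m.name for m in family]
        assert len(set(names)) == len(names)
        for m in family:
            # revalidation through the constructor must succeed
            build_path_model(m.edges, m.correlated_errors, vertices=m.vertices)

    def test_every_module_reachable_from_predictor(self):
        import networkx as nx

        for m in enumerate_candidate_models():
            g = m.graph()
            reach = nx.descendants(g, "PLa")
            assert {"tube", "stigma", "upper"} <= reach

    def test_study_member_present(self):
        family = enumerate_candidate_models()
        target = {("PLa", "tube"), ("PLa", "stigma"), ("stigma", "upper")}
        assert sum(set(m.edges) == target for m in family) == 1

    def test_user_file_overrides(self, tmp_path):
        path = tmp_path / "family.txt"
        path.write_text(
            "# name: custom\nPLa -> tube\nPLa -> stigma\ntube ~~ stigma\n"
        )
        family = load_model_family(path)
        assert len(family) == 1
        assert family[0].name == "custom"
        assert frozenset(("tube", "stigma")) in family[0].correlated_errors


class TestSelectBest:
    def _fit(self, name, aic, c, passed, k=4):
        model = build_path_model([("A", "B")], name=name)
        return PSEMFit(
            model=model, equations={}, claims=[], c_statistic=c, df=2,
            p=0.5 if passed else 0.01, k_claims=1, n_params=k, aic=aic, passed=passed,
        )

    def test_filter_then_rank(self):
        fits = [
            self._fit("bad-low-aic", aic=10.0, c=9.0, passed=False),
            self._fit("good", aic=28.3, c=1.0, passed=True),
            self._fit("good-worse", aic=30.1, c=1.0, passed=True),
        ]
        best, table = select_best(fits)
        assert best.model.name == "good"
        assert table.loc[table["name"] == "good", "selected"].item()

    def test_no_admissible_model(self):
        fits = [self._fit("bad", aic=5.0, c=9.0, passed=False)]
        best, table = select_best(fits)
        assert best is None
        assert not table["selected"].any()

    def test_aic_tie_broken_by_parameter_count(self):
        fits = [
            self._fit("big", aic=20.0, c=1.0, passed=True, k=8),
            self._fit("small", aic=20.0, c=1.0, passed=True, k=6),
        ]
        best, _ = select_best(fits)
        assert best.model.name == "small"
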