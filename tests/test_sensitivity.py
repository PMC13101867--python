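"""Growth-sensitivity statistic, limitation protocol and filters."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from metaniche.classes import ORGANIC_CLASSES, CompoundClassMap
from metaniche.errors import ValidationError
from metaniche.fba import minimal_media, optimize_growth, replete_media
from metaniche.model import FluxSolution, MediaSpec
from metaniche.sensitivity import (
    build_profile,
    growth_sensitivity,
    import_flux_coverage,
    limitation_media,
    profiles_to_frame,
    select_substrates,
    variance_filter,
)
from metaniche.simulate import (
    ToyNetworkSpec,
    make_toy_model,
    perturb_ensemble,
    toy_class_map,
)


class TestGrowthSensitivityStatistic:
    def test_half_growth_drop_is_fully_limiting(self):
        assert growth_sensitivity(mu=1.0, mu_n=0.5, f=0.5) == 1.0

    def test_no_growth_change_is_insensitive(self):
        assert growth_sensitivity(mu=2.0, mu_n=2.0, f=0.5) == 0.0

    def test_forty_percent_drop_is_substantial(self):
        assert growth_sensitivity(mu=1.0, mu_n=0.6, f=0.5) == pytest.approx(0.8)

    def test_clipped_to_unit_interval(self):
        assert growth_sensitivity(1.0, 0.0, 0.5) == 1.0  # raw 2 → clipped
        assert growth_sensitivity(1.0, 1.0 + 1e-12, 0.5) == 0.0  # tiny negative

    def test_zero_replete_growth_raises(self):
        with pytest.raises(ValidationError):
            growth_sensitivity(0.0, 0.0, 0.5)

    def test_invariant_to_common_flux_rescaling(self):
        for scale in (0.1, 3.0, 100.0):
            assert growth_sensitivity(scale * 1.0, scale * 0.7, 0.5) == pytest.approx(
                growth_sensitivity(1.0, 0.7, 0.5)
            )


class TestSelectSubstrates:
    def _solutions(self, counts):
        # counts: compound -> number of solutions importing it
        n = max(counts.values())
        sols = []
        for i in range(n):
            fluxes = {c: -1.0 if i < k else 0.0 for c, k in counts.items()}
            sols.append(FluxSolution("optimal", 1.0, fluxes))
        return sols

    def test_threshold_excludes_rare_imports(self):
        sols = self._solutions({"glc": 12, "rare": 9})
        assert select_substrates(sols, min_models=10) == {"glc"}

    def test_threshold_one_keeps_everything(self):
        sols = self._solutions({"glc": 12, "rare": 9})
        assert select_substrates(sols, min_models=1) == {"glc", "rare"}


class TestImportFluxCoverage:
    def test_fully_classified_is_one(self):
        sol = FluxSolution("optimal", 1.0, {"EX_a": -3.0, "EX_b": -1.0})
        cov = import_flux_coverage(sol, {"a", "b"}, {"EX_a": "a", "EX_b": "b"})
        assert cov == 1.0

    def test_nine_to_one_split(self):
        sol = FluxSolution("optimal", 1.0, {"EX_a": -9.0, "EX_b": -1.0})
        assert import_flux_coverage(sol, {"a"}, {"EX_a": "a", "EX_b": "b"}) == pytest.approx(0.9)

    def test_zero_import_defaults_to_one(self):
        sol = FluxSolution("optimal", 0.0, {"EX_a": 0.0})
        assert import_flux_coverage(sol, set(), {"EX_a": "a"}) == 1.0


class TestLimitationMedia:
    def test_cap_is_fraction_of_replete_uptake(self, limited_model, limited_class_map):
        replete = replete_media(limited_model)
        sol = optimize_growth(limited_model, replete)
        minimal, _ = minimal_media(limited_model, sol.mu)
        media = limitation_media(
            limited_model, sol, minimal, "carboxylic_acids", limited_class_map, 0.5
        )
        ex = "EX_carboxylic_acids__s0"
        assert ex in minimal.active_imports()
        assert media.cap(ex) == pytest.approx(0.5 * sol.uptake(ex))
        # other classes stay fully open
        assert media.cap("EX_amino_acids__s0") == 1000.0

    def test_non_minimal_class_members_closed(self):
        spec = ToyNetworkSpec(
            classes=("carbohydrates",), n_substrates_per_class=2, biomass_cap=4.0
        )
        model = make_toy_model(spec)
        sol = optimize_growth(model, replete_media(model))
        minimal, _ = minimal_media(model, sol.mu)
        media = limitation_media(
            model, sol, minimal, "carbohydrates", toy_class_map(spec), 0.5
        )
        closed = [ex for ex in model.exchange_ids if media.cap(ex) == 0.0]
        # exactly one of the two redundant sugars is in the minimal media;
        # the other is made unavailable to prevent circumvention
        assert len(closed) == 1

    def test_unknown_class_raises(self, limited_model, limited_class_map):
        sol = optimize_growth(limited_model, replete_media(limited_model))
        minimal, _ = minimal_media(limited_model, sol.mu)
        with pytest.raises(ValidationError):
            limitation_media(limited_model, sol, minimal, "nonsense", limited_class_map)


def _brute_force_sensitivity(model, class_name, class_map, f=0.5):
    """Independent oracle: rebuild the limited LP from scratch with linprog."""
    S, _ = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    idx = {r: j for j, r in enumerate(model.reaction_ids)}
    # replete
    for ex in model.exchange_ids:
        lb[idx[ex]] = -1000.0
    c = np.zeros(len(lb))
    c[idx[model.biomass_id]] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    mu = -res.fun
    minimal, _ = minimal_media(model, mu)
    lb2 = lb.copy()
    for ex in model.exchange_ids:
        cpd = model.exchange_compound(ex)
        if class_map.class_of(cpd) == class_name:
            if ex in minimal.active_imports():
                lb2[idx[ex]] = min(0.0, f * res.x[idx[ex]])  # f × replete uptake
            else:
                lb2[idx[ex]] = 0.0
    res2 = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                   bounds=np.column_stack([lb2, ub]), method="highs")
    return float(np.clip((1 / f) * (1 - (-res2.fun) / mu), 0, 1))


class TestBuildProfile:
    def test_limiting_class_scores_one(self, limited_model, limited_spec, limited_class_map):
        ens = perturb_ensemble(limited_model, 0.0, 2, seed=1)
        profiles, failed = build_profile(ens, limited_class_map)
        assert failed == []
        values = dict(zip(ORGANIC_CLASSES, profiles[0].values))
        assert values["carboxylic_acids"] == pytest.approx(1.0, abs=1e-6)
        assert values["carbohydrates"] == 0.0  # class not even in the network

    def test_generalist_insensitive_everywhere(self, generalist_spec):
        ens = perturb_ensemble(make_toy_model(generalist_spec), 0.0, 1, seed=1)
        profiles, _ = build_profile(ens, toy_class_map(generalist_spec))
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in profiles[0].values)

    def test_identical_members_identical_profiles(self, limited_model, limited_class_map):
        ens = perturb_ensemble(limited_model, 0.0, 3, seed=1)
        profiles, _ = build_profile(ens, limited_class_map)
        assert profiles[0].values == profiles[1].values == profiles[2].values

    def test_limited_growth_never_exceeds_replete(self, limited_model, limited_class_map):
        # raw S ≥ 0 before clipping — checked through the clipped values
        ens = perturb_ensemble(limited_model, 0.3, 6, seed=5)
        profiles, _ = build_profile(ens, limited_class_map)
        for p in profiles:
            assert all(0.0 <= v <= 1.0 for v in p.values)

    @pytest.mark.parametrize("class_name", ["carboxylic_acids", "amino_acids"])
    def test_matches_scratch_lp_oracle(self, limited_model, limited_class_map, class_name):
        ens = perturb_ensemble(limited_model, 0.0, 1, seed=1)
        profiles, _ = build_profile(ens, limited_class_map)
        got = dict(zip(ORGANIC_CLASSES, profiles[0].values))[class_name]
        expected = _brute_force_sensitivity(limited_model, class_name, limited_class_map)
        assert got == pytest.approx(expected, abs=1e-6)


class TestVarianceFilter:
    def _frame(self, genome_values):
        rows = []
        for gid, vals in genome_values.items():
            for m, v in enumerate(vals):
                rows.append((gid, m, *([v] + [0.0] * 10)))
        return pd.DataFrame(rows, columns=["genome_id", "member", *ORGANIC_CLASSES])

    def test_identical_members_retained(self):
        frame = self._frame({"g1": [0.5] * 60})
        assert variance_filter(frame, 0.1) == set()

    def test_balanced_binary_split_excluded(self):
        frame = self._frame({"g1": [0, 1] * 30})
        # population variance of a balanced 0/1 split is 0.25 > 0.1
        assert variance_filter(frame, 0.1) == {"g1"}

    def test_infinite_cutoff_excludes_nothing(self):
        frame = self._frame({"g1": [0, 1] * 30})
        assert variance_filter(frame, np.inf) == set()

    def test_single_member_genome_never_excluded(self):
        frame = self._frame({"solo": [0.7]})
        assert variance_filter(frame, 1e-9) == set()


def test_class_map_tsv_roundtrip(tmp_path, limited_class_map):
    path = tmp_path / "classes.tsv"
    limited_class_map.to_tsv(path)
    assert CompoundClassMap.from_tsv(path).mapping == limited_class_map.mapping


def test_profiles_frame_layout(limited_model, limited_class_map):
    ens = perturb_ensemble(limited_model, 0.0, 2, seed=1)
    profiles, _ = build_profile(ens, limited_class_map)
    frame = profiles_to_frame(profiles)
    assert list(frame.columns) == ["genome_id", "member", *ORGANIC_CLASSES]
    assert len(frame) == 2
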