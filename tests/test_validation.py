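"""Validation bench: sole-carbon calls, rescue outcomes, permutation null."""
import numpy as np
import pandas as pd
import pytest

from metaniche.classes import ORGANIC_CLASSES
from metaniche.errors import ValidationError
from metaniche.simulate import (
    ToyNetworkSpec,
    make_toy_model,
    perturb_ensemble,
    toy_class_map,
)
from metaniche.validation import (
    call_ensemble_growth,
    matrix_agreement,
    pathway_present,
    permutation_null,
    rescue_and_classify,
    score_agreement,
    sole_carbon_media,
    OutcomeRecord,
)

TWO_SUGARS = ToyNetworkSpec(classes=("carbohydrates",), n_substrates_per_class=2)
VITAMIN_DEP = ToyNetworkSpec(
    classes=("carbohydrates", "b_vitamins"),
    limiting_classes=frozenset({"b_vitamins"}),
)


class TestSoleCarbonMedia:
    def test_only_target_organic_open(self):
        model = make_toy_model(TWO_SUGARS)
        media = sole_carbon_media(
            model, "carbohydrates__s0", toy_class_map(TWO_SUGARS)
        )
        assert media.cap("EX_carbohydrates__s0") == 10.0
        assert media.cap("EX_carbohydrates__s1") == 0.0

    def test_unknown_substrate_raises(self):
        model = make_toy_model(TWO_SUGARS)
        with pytest.raises(ValidationError):
            sole_carbon_media(model, "ribose", toy_class_map(TWO_SUGARS))


class TestCallEnsembleGrowth:
    def test_unanimous_growth(self):
        ens = perturb_ensemble(make_toy_model(TWO_SUGARS), 0.0, 4, seed=0)
        call = call_ensemble_growth(ens, "carbohydrates__s0", toy_class_map(TWO_SUGARS))
        assert call == "growth"

    def test_unanimous_no_growth(self):
        # vitamin-dependent model on sole sugar: vitamin exchange is closed
        ens = perturb_ensemble(make_toy_model(VITAMIN_DEP), 0.0, 4, seed=0)
        call = call_ensemble_growth(ens, "carbohydrates__s0", toy_class_map(VITAMIN_DEP))
        assert call == "no_growth"

    def test_minority_growth_is_indeterminate(self):
        model = make_toy_model(TWO_SUGARS)
        ens = perturb_ensemble(model, 0.0, 4, seed=0)
        j = ens.reaction_ids.index("T_carbohydrates__s0")
        ens.presence[[0, 1, 2], j] = 0  # only member 3 keeps the transporter
        call = call_ensemble_growth(ens, "carbohydrates__s0", toy_class_map(TWO_SUGARS))
        assert call == "indeterminate"


class TestPathwayPresence:
    def test_present_in_intact_model(self):
        model = make_toy_model(TWO_SUGARS)
        assert pathway_present(model, "carbohydrates__s0")

    def test_absent_when_transport_zeroed(self):
        ens = perturb_ensemble(make_toy_model(TWO_SUGARS), 0.0, 2, seed=0)
        j = ens.reaction_ids.index("T_carbohydrates__s0")
        ens.presence[0, j] = 0
        from metaniche.ensembles import instantiate_member

        member = instantiate_member(ens, 0)
        assert not pathway_present(member, "carbohydrates__s0")
        assert pathway_present(member, "carbohydrates__s1")


class TestRescueAndClassify:
    def test_perfect_agreement_both_ways(self):
        ens = perturb_ensemble(make_toy_model(TWO_SUGARS), 0.0, 3, seed=0)
        cmap = toy_class_map(TWO_SUGARS)
        rec = rescue_and_classify(ens, "carbohydrates__s0", 1, cmap)
        assert rec.category == "i"

    def test_vitamin_rescue_yields_category_ii(self):
        ens = perturb_ensemble(make_toy_model(VITAMIN_DEP), 0.0, 3, seed=0)
        cmap = toy_class_map(VITAMIN_DEP)
        rec = rescue_and_classify(
            ens, "carbohydrates__s0", 1, cmap, rescue_pool=["b_vitamins__s0"]
        )
        assert rec.category == "ii"

    def test_pathway_present_but_no_growth_is_iii(self):
        ens = perturb_ensemble(make_toy_model(VITAMIN_DEP), 0.0, 3, seed=0)
        cmap = toy_class_map(VITAMIN_DEP)
        rec = rescue_and_classify(ens, "carbohydrates__s0", 1, cmap, rescue_pool=[])
        assert rec.category == "iii"

    def test_pathway_absent_is_iv(self):
        ens = perturb_ensemble(make_toy_model(TWO_SUGARS), 0.0, 3, seed=0)
        j = ens.reaction_ids.index("T_carbohydrates__s0")
        ens.presence[:, j] = 0
        cmap = toy_class_map(TWO_SUGARS)
        rec = rescue_and_classify(ens, "carbohydrates__s0", 1, cmap)
        assert rec.category == "iv"

    def test_false_positive_is_v(self):
        ens = perturb_ensemble(make_toy_model(TWO_SUGARS), 0.0, 3, seed=0)
        cmap = toy_class_map(TWO_SUGARS)
        rec = rescue_and_classify(ens, "carbohydrates__s0", 0, cmap)
        assert rec.category == "v"


class TestScoreAgreement:
    def _rec(self, category, experiment, call="growth", substrate="s"):
        return OutcomeRecord("strain", substrate, category, experiment, call)

    def test_all_perfect(self):
        records = [self._rec("i", 1) for _ in range(5)]
        out = score_agreement(records)
        assert out["accuracy"] == 1.0
        assert out["precision"] == 1.0

    def test_hand_confusion_matrix(self):
        # 10 true positives, 9 true negatives, 1 false positive
        records = (
            [self._rec("i", 1) for _ in range(10)]
            + [self._rec("i", 0, call="no_growth") for _ in range(9)]
            + [self._rec("v", 0)]
        )
        out = score_agreement(records)
        assert out["accuracy"] == pytest.approx(19 / 20)
        assert out["precision"] == pytest.approx(10 / 11)

    def test_shares_sum_to_one(self):
        records = [
            self._rec(c, 1) for c in ("i", "ii", "iii", "iv", "v", "i", "ii")
        ]
        out = score_agreement(records)
        assert sum(out["shares"].values()) == pytest.approx(1.0)
        assert sum(out["counts"].values()) == len(records)

    def test_substrate_exclusion(self):
        records = [self._rec("i", 1), self._rec("v", 0, substrate="oxaloacetate")]
        out = score_agreement(records, exclude_substrates=["oxaloacetate"])
        assert out["accuracy"] == 1.0


class TestPermutationNull:
    def _random_matrix(self, n_strains=146, n_subs=77, density=0.3, seed=0):
        rng = np.random.default_rng(seed)
        m = (rng.random((n_strains, n_subs)) < density).astype(int)
        return pd.DataFrame(
            m,
            index=[f"s{i}" for i in range(n_strains)],
            columns=[f"c{j}" for j in range(n_subs)],
        )

    def test_perfect_predictions_significant(self):
        obs = self._random_matrix()
        out = permutation_null(obs, obs, n_boot=500, seed=1)
        assert out["real_accuracy"] == 1.0
        assert out["significant"]

    def test_random_predictions_not_significant(self):
        obs = self._random_matrix(seed=2)
        # random predictions built by the same row-sum-preserving scheme
        rng = np.random.default_rng(3)
        pred = obs.copy()
        for i in range(len(pred)):
            row = pred.iloc[i].to_numpy()
            rng.shuffle(row)
            pred.iloc[i] = row
        out = permutation_null(obs, pred, n_boot=500, seed=4)
        assert out["real_accuracy"] <= out["null_mean"] + 2 * out["null_sd"]

    def test_seed_reproducible(self):
        obs = self._random_matrix(20, 10)
        a = permutation_null(obs, obs, n_boot=50, seed=9)
        b = permutation_null(obs, obs, n_boot=50, seed=9)
        assert np.array_equal(a["null"], b["null"])

    def test_all_zero_matrix_degenerate(self):
        obs = pd.DataFrame(np.zeros((5, 4), dtype=int))
        out = permutation_null(obs, obs, n_boot=20, seed=0)
        assert out["null_mean"] == 1.0 and out["null_sd"] == 0.0
        assert not out["significant"]  # cannot beat a perfect null


def test_matrix_agreement_error_rate():
    rng = np.random.default_rng(5)
    truth = (rng.random((50, 40)) < 0.4).astype(int)
    flips = rng.random((50, 40)) < 0.1
    noisy = np.where(flips, 1 - truth, truth)
    acc = matrix_agreement(pd.DataFrame(truth), pd.DataFrame(noisy))
    assert acc == pytest.approx(0.9, abs=0.03)
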