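import numpy as np
import pandas as pd
import pytest

from fhresponse.errors import ConfigValidationError
from fhresponse.pipeline import compute_responses
from fhresponse.simulate import (
    DEFAULT_GROUP_PROPORTIONS,
    SimulationConfig,
    assign_variants,
    generate_cohort,
)
from fhresponse.variants import PVGroup, VariantRecord, classify_patient


def test_fixed_seed_reproduces_byte_identical_tables(tmp_path):
    c1 = generate_cohort(SimulationConfig(seed=7))
    c2 = generate_cohort(SimulationConfig(seed=7))
    for name in ("cohort", "variants", "genotypes", "truth"):
        pd.testing.assert_frame_equal(getattr(c1, name), getattr(c2, name))
    assert c1.cohort.to_csv(index=False) == c2.cohort.to_csv(index=False)


def test_different_seeds_differ():
    c1 = generate_cohort(SimulationConfig(seed=1))
    c2 = generate_cohort(SimulationConfig(seed=2))
    assert not c1.cohort["pre_ldl"].equals(c2.cohort["pre_ldl"])


@pytest.mark.parametrize("group", list(PVGroup))
def test_assigned_variants_classify_back_to_their_group(group):
    """Closure between the generator's variant pools and the classifier."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        variants = assign_variants(group, rng)
        assert classify_patient(variants).group is group
        if group is PVGroup.PV_NEGATIVE:
            assert variants == []
        elif group is PVGroup.COMPOUND_OR_HOMOZYGOUS:
            assert len(variants) == 2
        else:
            assert len(variants) == 1
        assert all(isinstance(v, VariantRecord) for v in variants)


def test_group_proportions_concentrate_at_large_n():
    cohort = generate_cohort(SimulationConfig(n_patients=4000, seed=5))
    observed = cohort.truth["pv_group"].value_counts(normalize=True)
    for group, expected in DEFAULT_GROUP_PROPORTIONS.items():
        assert observed.get(group, 0.0) == pytest.approx(expected, abs=0.02)


def test_genotype_frequencies_match_config():
    cfg = SimulationConfig(n_patients=4000, seed=9)
    cohort = generate_cohort(cfg)
    for rsid, freq in cfg.allele_freqs.items():
        assert cohort.genotypes[rsid].mean() / 2 == pytest.approx(freq, abs=0.02)


def test_noise_free_construction_recovers_group_medians_exactly():
    """With zero noise the achieved % of expected equals the group factor."""
    cfg = SimulationConfig(
        n_patients=400,
        seed=3,
        response_factor={g: (0.953 if g == "pv_negative" else 0.828) for g in DEFAULT_GROUP_PROPORTIONS},
        response_noise_sd=0.0,
        snp_effect_on_response=0.0,
    )
    cohort = generate_cohort(cfg)
    truth = cohort.truth
    neg = truth["pv_group"] == "pv_negative"
    assert truth.loc[neg, "achieved_pct_true"].median() == pytest.approx(95.3)
    assert truth.loc[~neg, "achieved_pct_true"].median() == pytest.approx(82.8)
    # and the pipeline recovers them from the written pre/post values
    responses, excl = compute_responses(cohort.cohort)
    assert excl.empty
    merged = responses.merge(truth, on="patient_id")
    neg = merged["pv_group"] == "pv_negative"
    assert merged.loc[neg, "achieved_pct"].median() == pytest.approx(95.3, abs=0.2)
    assert merged.loc[~neg, "achieved_pct"].median() == pytest.approx(82.8, abs=0.2)


def test_escalation_bias_shifts_pv_positive_to_intense_regimens():
    cohort = generate_cohort(SimulationConfig(n_patients=3000, seed=11))
    merged = cohort.cohort.merge(cohort.truth, on="patient_id")
    pos = merged["pv_group"] != "pv_negative"
    # moderate intensity = atorvastatin-equivalent 10-20 mg without ezetimibe
    moderate = (merged["expected_pct"] <= 46) & ~merged["ezetimibe"]
    assert moderate[~pos].mean() > moderate[pos].mean() + 0.1


def test_pv_structure_consistency():
    cohort = generate_cohort(SimulationConfig(seed=13))
    with_variants = set(cohort.variants["patient_id"])
    truth = cohort.truth.set_index("patient_id")
    for pid, row in truth.iterrows():
        if row["pv_group"] == "pv_negative":
            assert pid not in with_variants
        else:
            assert pid in with_variants


def test_evolocumab_patients_get_addon_columns():
    cohort = generate_cohort(SimulationConfig(seed=1, n_evolocumab=6)).cohort
    evo = cohort[cohort["evolocumab"]]
    assert len(evo) == 6
    assert evo["pre_evolocumab_ldl"].notna().all()
    assert (evo["pre_evolocumab_ldl"] == evo["post_ldl"]).all()
    assert cohort.loc[~cohort["evolocumab"], "pre_evolocumab_ldl"].isna().all()


@pytest.mark.parametrize(
    "bad",
    [
        {"group_proportions": {"pv_negative": 0.5, "ldlr_null": 0.4}},
        {"baseline_ldl_median": {"pv_negative": -1}},
        {"allele_freqs": {"rs651007": 1.5, "rs599839": 0.25, "rs12654264": 0.45, "rs2738446": 0.3}},
        {"n_patients": 0},
        {"escalation_policy_bias": 0},
    ],
)
def test_invalid_configs_rejected(bad):
    with pytest.raises(ConfigValidationError):
        SimulationConfig(**bad)
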