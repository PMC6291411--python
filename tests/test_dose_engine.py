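"""MIRD dose sums, mass rescaling, weighting schemes and effective dose."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirdose as m
from mirdose.biokinetics import GA68, TiacTable
from mirdose.dose_engine import SValueMatrix, TissueWeightingScheme


def identity_matrix(organs, phantom_id="male_2.0"):
    return SValueMatrix(
        pd.DataFrame(np.eye(len(organs)), index=organs, columns=organs), phantom_id
    )


def tiacs(mapping):
    return TiacTable(tiacs_h=dict(mapping), radionuclide=GA68)


class TestOrganDoses:
    def test_self_dose_only(self):
        report = m.compute_organ_doses(
            tiacs({"liver": 0.0379}), identity_matrix(["liver", "kidneys"])
        )
        assert report.dose("liver") == pytest.approx(0.0379, rel=1e-12)
        assert report.dose("kidneys") == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(2)
        organs = [f"o{i}" for i in range(5)]
        sm = SValueMatrix(
            pd.DataFrame(rng.uniform(0, 1, (5, 5)), index=organs, columns=organs),
            "male_2.0",
        )
        tau = {o: float(v) for o, v in zip(organs, rng.uniform(0, 0.1, 5))}
        d1 = m.compute_organ_doses(tiacs(tau), sm).organ_doses
        d2 = m.compute_organ_doses(tiacs({k: 2 * v for k, v in tau.items()}), sm).organ_doses
        for o in organs:
            assert d2[o] == pytest.approx(2 * d1[o], rel=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        organs = [f"o{i}" for i in range(5)]
        s = rng.uniform(0, 2, (5, 5))
        sm = SValueMatrix(pd.DataFrame(s, index=organs, columns=organs), "male_2.0")
        tau = dict(zip(organs, rng.uniform(0, 0.1, 5)))
        got = m.compute_organ_doses(tiacs(tau), sm).organ_doses
        for i, target in enumerate(organs):
            expected = sum(tau[src] * s[i, j] for j, src in enumerate(organs))
            assert got[target] == pytest.approx(expected, rel=1e-12)

    def test_alias_and_case_insensitive_matching(self):
        sm = identity_matrix(["urinary_bladder_wall", "liver"])
        report = m.compute_organ_doses(tiacs({"UB Wall": 0.1, "Liver": 0.2}), sm)
        assert report.dose("Urinary bladder wall") == pytest.approx(0.1)

    def test_missing_source_is_an_error(self):
        with pytest.raises(KeyError, match="pancreas"):
            m.compute_organ_doses(tiacs({"pancreas": 0.08}), identity_matrix(["liver"]))


class TestSValueCsv:
    def test_round_trip(self, tmp_path, svalues_male):
        path = tmp_path / "s.csv"
        svalues_male.to_csv(path)
        back = SValueMatrix.from_csv(path)
        assert back.phantom_id == svalues_male.phantom_id
        pd.testing.assert_frame_equal(back.table, svalues_male.table)

    def test_metadata_required(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("target,liver\nliver,1.0\n")
        with pytest.raises(ValueError, match="phantom_id"):
            SValueMatrix.from_csv(path)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            SValueMatrix(
                pd.DataFrame([[-1.0]], index=["liver"], columns=["liver"]), "male_2.0"
            )


class TestMassRescaling:
    def test_pancreas_between_phantom_generations(self):
        # 140 g -> 94.3 g inflates the self dose by the inverse mass ratio
        assert m.rescale_self_dose_for_mass(2.60e-1, 140.0, 94.3) == pytest.approx(
            3.86e-1, rel=1e-2
        )

    def test_identity_and_round_trip(self):
        assert m.rescale_self_dose_for_mass(0.1, 100.0, 100.0) == 0.1
        d = m.rescale_self_dose_for_mass(m.rescale_self_dose_for_mass(0.1, 140, 94.3), 94.3, 140)
        assert d == pytest.approx(0.1, rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            m.rescale_self_dose_for_mass(0.1, 0.0, 94.3)


def full_report(sex, value=None, rng=None):
    """A report covering every tissue both shipped schemes can ask for."""
    rng = rng if rng is not None else np.random.default_rng(0)
    organs = [
        "red_marrow", "right_colon", "left_colon", "rectum", "lungs",
        "stomach_wall", "breast", "urinary_bladder_wall", "esophagus", "liver",
        "thyroid", "bone_surfaces", "brain", "salivary_glands", "skin",
        "adrenals", "extrathoracic_region", "gallbladder_wall", "heart_wall",
        "kidneys", "lymphatic_nodes", "muscle", "oral_mucosa", "pancreas",
        "small_intestine", "spleen", "thymus", "total_body",
    ]
    organs.append("testes" if sex == "male" else "ovaries")
    organs.append("prostate" if sex == "male" else "uterus")
    if value is not None:
        doses = {o: value for o in organs}
    else:
        doses = {o: float(d) for o, d in zip(organs, rng.uniform(0.001, 0.3, len(organs)))}
    return m.DoseReport(organ_doses=doses, sex=sex)


class TestEffectiveDose:
    @pytest.mark.parametrize("scheme_id", ["ICRP103", "ICRP60"])
    def test_shipped_weights_sum_to_one(self, scheme_id):
        s = TissueWeightingScheme.shipped(scheme_id)
        assert sum(s.weights.values()) + s.remainder_weight == pytest.approx(1.0, abs=1e-9)

    def test_invalid_weight_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            TissueWeightingScheme("bad", {"liver": 0.5}, (), 0.4)

    @pytest.mark.parametrize("scheme_id", ["ICRP103", "ICRP60"])
    def test_uniform_doses_normalize(self, scheme_id):
        """With every tissue at dose d, ED = d because the weights sum to 1."""
        scheme = TissueWeightingScheme.shipped(scheme_id)
        male = full_report("male", value=0.0123)
        result = m.compute_effective_dose(male, None, scheme)
        assert result.per_sex["male"] == pytest.approx(0.0123, rel=1e-12)
        assert result.imputations == []

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(9)
        scheme = TissueWeightingScheme.shipped("ICRP103")
        for _ in range(5):
            male = full_report("male", rng=rng)
            result = m.compute_effective_dose(male, None, scheme)
            d = male.organ_doses
            expected = 0.0
            for tissue, w in scheme.weights.items():
                if tissue == "gonads":
                    h = d["testes"]
                elif tissue == "colon":
                    h = np.mean([d["right_colon"], d["left_colon"], d["rectum"]])
                else:
                    h = d[tissue]
                expected += w * h
            rem = [d[t] for t in scheme.remainder_tissues if t != "uterus"]
            expected += scheme.remainder_weight * np.mean(rem)
            assert result.per_sex["male"] == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_organ_permutation(self):
        rng = np.random.default_rng(10)
        scheme = TissueWeightingScheme.shipped("ICRP103")
        male = full_report("male", rng=rng)
        items = list(male.organ_doses.items())
        shuffled = m.DoseReport(dict(reversed(items)), sex="male")
        a = m.compute_effective_dose(male, None, scheme).per_sex["male"]
        b = m.compute_effective_dose(shuffled, None, scheme).per_sex["male"]
        assert a == pytest.approx(b, rel=1e-15)

    def test_reference_person_between_sexes(self):
        rng = np.random.default_rng(12)
        scheme = TissueWeightingScheme.shipped("ICRP103")
        for _ in range(5):
            male = full_report("male", rng=rng)
            female = full_report("female", rng=rng)
            res = m.compute_effective_dose(male, female, scheme)
            lo, hi = sorted(res.per_sex.values())
            assert lo - 1e-12 <= res.reference <= hi + 1e-12

    def test_missing_tissue_policies(self, caplog):
        scheme = TissueWeightingScheme.shipped("ICRP103")
        male = full_report("male")
        doses = {o: 0.01 for o in male.organ_doses}
        doses.pop("muscle")
        doses["total_body"] = 0.02
        partial = m.DoseReport(doses, sex="male")
        tb = m.compute_effective_dose(partial, None, scheme, "total_body")
        assert any("muscle" in msg for msg in tb.imputations)
        zero = m.compute_effective_dose(partial, None, scheme, "zero")
        assert tb.per_sex["male"] > zero.per_sex["male"]
        with pytest.raises(ValueError, match="policy"):
            m.compute_effective_dose(partial, None, scheme, "median")

    def test_most_exposed_remainder_split(self):
        """The historical rule gives a dominant remainder tissue half w_rem."""
        scheme = TissueWeightingScheme.shipped("ICRP60")
        male = full_report("male", value=0.01)
        male.organ_doses["pancreas"] = 0.26
        res = m.compute_effective_dose(male, None, scheme)
        # every other tissue at 0.01: ED = 0.95*0.01 + 0.025*0.26 + 0.025*0.01
        assert res.per_sex["male"] == pytest.approx(
            0.95 * 0.01 + 0.025 * 0.26 + 0.025 * 0.01, rel=1e-12
        )

    def test_no_reports_rejected(self):
        with pytest.raises(ValueError):
            m.compute_effective_dose(None, None, TissueWeightingScheme.shipped("ICRP103"))


class TestFemaleExtrapolation:
    def test_same_kernel_reproduces_male_doses(self, svalues_male):
        tau = tiacs({"liver": 0.0379, "kidneys": 0.0214})
        male = m.compute_organ_doses(tau, svalues_male)
        female = m.female_extrapolation(tau, svalues_male)
        assert female.organ_doses == pytest.approx(male.organ_doses)
        assert female.sex == "female"

    def test_male_only_sources_dropped(self, svalues_female):
        tau = tiacs({"liver": 0.0379, "prostate": 0.001, "testes": 0.002})
        report = m.female_extrapolation(tau, svalues_female)
        assert "prostate" not in report.organ_doses
        assert "ovaries" in report.organ_doses

    def test_matches_direct_dose_computation(self, svalues_female):
        tau = tiacs({"liver": 0.0379, "kidneys": 0.0214})
        via = m.female_extrapolation(tau, svalues_female)
        direct = m.compute_organ_doses(tau, svalues_female)
        assert via.organ_doses == pytest.approx(direct.organ_doses, rel=1e-12)


@settings(derandomize=True, max_examples=30)
@given(
    share=st.floats(1e-4, 0.3),
    dose=st.floats(1e-4, 1.0),
    ed=st.floats(1e-4, 0.1),
)
def test_tissue_ed_share_definition(share, dose, ed):
    assert m.tissue_ed_share(share, dose, ed) == pytest.approx(share * dose / ed)
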