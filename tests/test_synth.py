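"""Synthetic input generator: determinism, rate shapes, calibration, consistency."""

import dataclasses
import hashlib

import numpy as np
import pandas as pd
import pytest

from pamslt.synth import (
    DISEASES,
    ConfigurationError,
    MortalityParams,
    StrataSpec,
    SyntheticInputs,
    SyntheticScenario,
    adult_inactive_fraction,
    audit_disease_mortality,
    generate_costs_and_rr,
    generate_demography,
    generate_disease_epi,
    generate_inputs,
    generate_pa_distribution,
)


def _hash_dir(path):
    digest = hashlib.sha256()
    for f in sorted(path.iterdir()):
        digest.update(f.name.encode())
        digest.update(f.read_bytes())
    return digest.hexdigest()


class TestDemography:
    def test_mortality_monotone_from_age_35(self, default_inputs):
        for _, grp in default_inputs.demography.groupby(["sex", "ethnicity"]):
            q = grp.sort_values("age")["mortality"].to_numpy()
            assert np.all(np.diff(q[35:]) >= 0)

    def test_indigenous_mortality_at_least_reference(self, default_inputs):
        df = default_inputs.demography
        piv = df.pivot_table(index=["sex", "age"], columns="ethnicity", values="mortality")
        assert (piv["indigenous"] >= piv["other"]).all()

    def test_unit_ethnicity_multiplier_equalises_mortality(self):
        scenario = SyntheticScenario(
            mortality=MortalityParams(indigenous_multiplier=1.0)
        )
        df = generate_demography(StrataSpec(), scenario)
        piv = df.pivot_table(index=["sex", "age"], columns="ethnicity", values="mortality")
        np.testing.assert_allclose(piv["indigenous"], piv["other"])

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ConfigurationError):
            StrataSpec(age_band_edges=(0, 5, 5, 110))
        with pytest.raises(ConfigurationError):
            StrataSpec(age_band_edges=(10, 110))

    def test_rates_are_probabilities(self, default_inputs):
        df = default_inputs.demography
        assert df["mortality"].between(0, 1).all()
        assert df["pyld"].between(0, 1, inclusive="left").all()


class TestDiseaseEpi:
    def test_non_cancer_remission_is_zero(self, default_inputs):
        epi = default_inputs.disease_epi
        for name, d in DISEASES.items():
            rem = epi.loc[epi["disease"] == name, "remission"]
            if d.is_cancer:
                assert rem.max() > 0
            else:
                assert (rem == 0).all()

    def test_breast_cancer_absent_in_males(self, default_inputs):
        epi = default_inputs.disease_epi
        male_bc = epi[(epi["disease"] == "breast_cancer") & (epi["sex"] == "male")]
        assert (male_bc["incidence"] == 0).all()
        assert (male_bc["case_fatality"] == 0).all()

    def test_incidence_and_fatality_rise_with_age(self, default_inputs):
        epi = default_inputs.disease_epi
        for (name, sex, eth), grp in epi.groupby(["disease", "sex", "ethnicity"]):
            if DISEASES[name].female_only and sex != "female":
                continue
            grp = grp.sort_values("age")
            onset = DISEASES[name].onset_age
            assert np.all(np.diff(grp["incidence"].to_numpy()[onset:]) >= 0)
            assert np.all(np.diff(grp["case_fatality"].to_numpy()) >= 0)

    def test_implied_disease_mortality_within_all_cause(self):
        scenario = SyntheticScenario(seed=7)
        spec = StrataSpec()
        demog = generate_demography(spec, scenario)
        epi = generate_disease_epi(spec, scenario, demog)
        audit = audit_disease_mortality(demog, epi)
        assert (audit["excess"] <= 0).all()


class TestPaDistribution:
    def test_default_calibration_near_42_percent_inactive(self, default_inputs):
        frac = adult_inactive_fraction(
            default_inputs.demography, default_inputs.exposure, default_inputs.spec
        )
        assert 0.40 <= frac <= 0.44

    def test_different_seeds_differ_but_both_normalised(self):
        spec = StrataSpec()
        d3 = generate_pa_distribution(spec, SyntheticScenario(seed=3))
        d4 = generate_pa_distribution(spec, SyntheticScenario(seed=4))
        key = next(iter(d3))
        assert not np.allclose(d3[key].proportion, d4[key].proportion)
        for dists in (d3, d4):
            for dist in dists.values():
                assert abs(dist.proportion.sum() - 1.0) < 1e-12
                assert (dist.proportion >= 0).all()


class TestCostsAndRr:
    def test_relative_risk_monotone_for_all_diseases(self, default_inputs):
        mids = np.array([0.0, 75.0, 225.0, 450.0, 900.0, 1800.0, 3600.0, 6000.0])
        for name, rr in default_inputs.rr_funcs.items():
            vals = rr(mids)
            assert np.all(np.diff(vals) <= 0), name
            assert vals[0] == 1.0

    def test_zero_rr_scale_gives_null_risk(self):
        scenario = dataclasses.replace(
            SyntheticScenario(), rr=dataclasses.replace(SyntheticScenario().rr, scale=0.0)
        )
        _, _, rr_funcs = generate_costs_and_rr(StrataSpec(), scenario)
        for rr in rr_funcs.values():
            assert np.all(rr(np.linspace(0, 10_000, 50)) == 1.0)

    def test_terminal_phase_cost_dominates_subsequent_year(self):
        costs, unrelated, _ = generate_costs_and_rr(StrataSpec(), SyntheticScenario(seed=11))
        assert (costs["cost_last_6m"] >= costs["cost_subsequent_year"]).all()
        assert (costs[["cost_first_year", "cost_subsequent_year", "cost_last_6m"]] >= 0).all().all()
        assert (unrelated["cost"] > 0).all()


class TestDeterminismAndIo:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_inputs(scenario=SyntheticScenario(seed=42)).write_csvs(a)
        generate_inputs(scenario=SyntheticScenario(seed=42)).write_csvs(b)
        assert _hash_dir(a) == _hash_dir(b)

    def test_csv_roundtrip_preserves_values(self, default_inputs, tmp_path):
        default_inputs.write_csvs(tmp_path)
        first_line = (tmp_path / "population.csv").read_text().splitlines()[0]
        assert first_line.startswith("# schema=")
        back = SyntheticInputs.read_csvs(tmp_path)
        pd.testing.assert_frame_equal(
            back.demography.sort_index(axis=1),
            default_inputs.demography.sort_index(axis=1),
            check_dtype=False,
        )
        key = next(iter(default_inputs.exposure))
        np.testing.assert_allclose(
            back.exposure[key].proportion, default_inputs.exposure[key].proportion
        )
        assert set(back.rr_funcs) == set(default_inputs.rr_funcs)
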