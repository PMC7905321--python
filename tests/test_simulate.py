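"""Integration behaviour of full scenario runs and the CLI."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from polledsim import ScenarioConfig, Sector, Sex, run_replicate, run_scenario
from polledsim.cli import main
from tests.conftest import SUITE_SEED


class TestReproducibility:
    def test_same_seed_gives_bit_identical_series(self, tiny_cfg):
        a = run_replicate(tiny_cfg, 0)
        b = run_replicate(tiny_cfg, 0)
        pd.testing.assert_frame_equal(a, b)

    def test_different_replicates_differ(self, tiny_cfg):
        a = run_replicate(tiny_cfg, 0)
        b = run_replicate(tiny_cfg, 1)
        assert not a.drop(columns="replicate").equals(b.drop(columns="replicate"))


@pytest.fixture(scope="module")
def scheme_d_run():
    cfg = ScenarioConfig(scheme="D", years=8, replicates=1, seed=SUITE_SEED).scaled(0.1)
    return run_replicate(cfg, 0, return_state=True), cfg


class TestRunInvariants:
    def test_caps_and_ages_respected_at_year_end(self, scheme_d_run):
        (df, hb, reg), cfg = scheme_d_run
        final_year = cfg.burn_in_years + cfg.years
        age = hb.age(final_year)
        alive = hb.alive()
        assert (age[alive & (hb.sex == Sex.FEMALE)] < cfg.cow_cull_age).all()
        assert (age[alive & (hb.sex == Sex.MALE)] < cfg.bull_cull_age).all()
        for sector, fcap, bcap in (
            (Sector.SEEDSTOCK, cfg.seedstock_female_cap, cfg.seedstock_bull_cap),
            (Sector.COMMERCIAL, cfg.commercial_female_cap, cfg.commercial_bull_cap),
        ):
            females = alive & (hb.sex == Sex.FEMALE) & (hb.sector == sector)
            assert int(females.sum()) <= fcap
            bulls = alive & (hb.sex == Sex.MALE) & (hb.sector == sector)
            assert int((bulls & (age >= cfg.bull_service_age)).sum()) <= bcap

    def test_scheme_d_sires_are_always_homozygous_polled(self, scheme_d_run):
        (df, hb, reg), cfg = scheme_d_run
        # the obligatory-polled rule starts in scheme year 1 (year 0 is the
        # state left by the random-mating burn-in)
        used = df[(df["year"] >= 1) & (df["n_sires_used"] > 0)]
        assert (used["n_sires_hom_polled"] == used["n_sires_used"]).all()

    def test_scheme_d_commercial_frequency_declines(self, scheme_d_run):
        (df, hb, reg), cfg = scheme_d_run
        q = df[df.sector == "commercial"].sort_values("year")["horned_allele_freq"]
        diffs = np.diff(q.to_numpy())
        assert (diffs < 1e-3).all()  # monotone decline up to counting noise

    def test_pedigree_and_herdbook_stay_aligned(self, scheme_d_run):
        (df, hb, reg), cfg = scheme_d_run
        assert len(reg) == len(hb)
        np.testing.assert_allclose(reg.inbreeding_all, hb.f, atol=1e-12)

    def test_no_edited_animals_in_conventional_scenarios(self, scheme_d_run):
        (df, hb, reg), cfg = scheme_d_run
        assert not hb.edited.any()
        assert (df["n_sires_edited"] == 0).all()

    def test_editing_scenario_marks_only_seedstock_born_pp(self):
        cfg = ScenarioConfig(
            scheme="B", edit_fraction=0.10, years=4, replicates=1, seed=SUITE_SEED
        ).scaled(0.05)
        df, hb, reg = run_replicate(cfg, 0, return_state=True)
        edited = np.flatnonzero(hb.edited)
        assert edited.size > 0
        assert (hb.genotype[edited] == 2).all()
        assert (hb.origin_sector[edited] == Sector.SEEDSTOCK).all()
        assert (hb.sex[edited] == Sex.MALE).all()


class TestNeutralityControl:
    def test_scheme_a_without_dehorning_mortality_is_frequency_neutral(self):
        # genotype-blind selection + no differential mortality: expected
        # allele-frequency change is zero; test the replicate mean
        cfg = dataclasses.replace(
            ScenarioConfig(scheme="A", years=10, replicates=4, seed=SUITE_SEED).scaled(0.1),
            dehorning_mortality=0.0,
        )
        df = run_scenario(cfg)
        com = df[df.sector == "commercial"]
        q0 = com[com.year == 0].groupby("replicate")["horned_allele_freq"].mean()
        q10 = com[com.year == 10].groupby("replicate")["horned_allele_freq"].mean()
        assert (q10 - q0).mean() == pytest.approx(0.0, abs=0.06)


class TestCli:
    def test_run_writes_outputs_and_manifest(self, tmp_path):
        rc = main(
            [
                "run", "--scheme", "B", "--edit-pct", "0", "--years", "3",
                "--replicates", "2", "--seed", "5", "--scale", "0.04",
                "--out", str(tmp_path), "--quiet", "--write-pedigree",
            ]
        )
        assert rc == 0
        stats = pd.read_csv(tmp_path / "stats_B.csv")
        assert set(stats["year"]) == {0, 1, 2, 3}
        assert (tmp_path / "summary_B.csv").exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["master_seed"] == 5
        assert len(manifest["replicate_seeds"]) == 2
        ped = (tmp_path / "pedigree_B_rep0.txt").read_text().splitlines()
        assert all(len(line.split()) == 3 for line in ped[:10])

    def test_invalid_configuration_is_rejected(self, tmp_path):
        assert main(["run", "--scheme", "A", "--years", "-3", "--out", str(tmp_path), "--quiet"]) == 1
        with pytest.raises(SystemExit):
            main(["run", "--scheme", "E", "--out", str(tmp_path)])

    def test_config_file_roundtrip(self, tmp_path):
        cfg_file = tmp_path / "cfg.toml"
        cfg_file.write_text('scheme = "C"\nedit_fraction = 0.01\nyears = 2\n')
        cfg = ScenarioConfig.from_file(cfg_file)
        assert cfg.scheme == "C" and cfg.edit_fraction == 0.01 and cfg.years == 2
        cfg_file.write_text("unknown_knob = 1\n")
        with pytest.raises(ValueError):
            ScenarioConfig.from_file(cfg_file)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            ScenarioConfig(edit_fraction=1.5).validate()
        with pytest.raises(ValueError):
            ScenarioConfig(scheme="E").validate()
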