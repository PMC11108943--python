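"""Synthetic instrument emulator: protocols, noise, dynamics, and file I/O."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cutigas import FvCBParams, NoiseSpec
from cutigas.conductance import intercellular_co2, total_conductance_co2
from cutigas.synthetic import (
    SPECIES_PRESETS,
    EmptyChamberSpec,
    ProtocolSpec,
    SchemaError,
    StomatalModel,
    generate_curve,
    generate_empty_chamber,
    generate_redlight_run,
    read_li6800_csv,
    write_li6800_csv,
)


class TestProtocols:
    def test_racir_900_gives_270_records(self):
        df = generate_curve(ProtocolSpec.racir(start=100, end=900))
        assert len(df) == 270

    def test_racir_2000_gives_600_records(self):
        t, cref = ProtocolSpec.racir(start=100, end=2000).ramp_timeline()
        assert len(t) == 600
        assert cref[0] == 100.0 and cref[-1] == 2000.0

    def test_ss_protocol_is_16_setpoints(self):
        df = generate_curve(ProtocolSpec.steady_state())
        assert len(df) == 16
        assert list(df["CO2_r"][:6]) == [380, 285, 190, 145, 100, 50]

    def test_redlight_steady_window_is_42_records(self):
        df = generate_redlight_run()
        assert (df["phase"] == "steady").sum() == 42

    def test_ramp_is_monotone_between_pads(self):
        t, cref = ProtocolSpec.racir().ramp_timeline()
        core = cref[(t > 30) & (t < t[-1] - 30)]
        assert np.all(np.diff(core) > 0)


class TestGeneration:
    def test_seeded_determinism(self):
        kw = dict(
            protocol=ProtocolSpec.steady_state(),
            stomata=SPECIES_PRESETS["papaya"],
            noise=NoiseSpec(sd_glw=0.00415, sd_a=0.2),
            seed=11,
        )
        a, b = generate_curve(**kw), generate_curve(**kw)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            generate_curve(
                ProtocolSpec.steady_state(), noise=NoiseSpec(sd_glw=0.001), seed=None
            )

    def test_stored_ci_consistent_with_ternary_equation(self, clean_ss_frame):
        """The logged C_i must be exactly what the instrument would
        compute from the logged observables."""
        df = clean_ss_frame
        recomputed = [
            intercellular_co2(a, e, ca, total_conductance_co2(g))
            for a, e, ca, g in zip(df["A"], df["E"], df["Ca"], df["gsw"])
        ]
        assert np.max(np.abs(df["Ci"].to_numpy() - recomputed)) < 1e-9

    def test_instrument_ci_equals_model_ci_without_cuticle(self, clean_ss_frame):
        df = clean_ss_frame
        assert np.max(np.abs(df["Ci"] - df["Ci_true"])) < 1e-9

    def test_instrument_ci_overestimates_with_cuticle(self, rich_params):
        df = generate_curve(
            ProtocolSpec.steady_state(),
            params=rich_params,
            stomata=StomatalModel.static(0.05, 0.0056),
        )
        assimilating = df["A"] > 0
        assert assimilating.sum() >= 10
        assert np.all(df.loc[assimilating, "Ci"] > df.loc[assimilating, "Ci_true"])

    def test_stomata_close_at_high_co2(self):
        df = generate_curve(
            ProtocolSpec.racir(end=2000), stomata=SPECIES_PRESETS["citrus"]
        )
        high = df[df["CO2_r"] > 1500]["glw_true"].mean()
        low = df[df["CO2_r"] < 500]["glw_true"].mean()
        assert high < low

    def test_preset_conductances_match_species_means(self):
        # daylight g_lw targets at 400 ppm: stomatal share + cuticle
        for name, glw in [("magnolia", 0.09), ("citrus", 0.12), ("pepper", 0.33), ("papaya", 0.17)]:
            m = SPECIES_PRESETS[name]
            assert m.g_max + m.g_cw_true == pytest.approx(glw, abs=1e-4)


class TestEmptyChamber:
    def test_zero_spec_zero_noise_gives_zero_a(self):
        df = generate_empty_chamber(ProtocolSpec.empty())
        assert np.allclose(df["A"], 0.0)
        assert np.allclose(df["gsw"], 0.0)

    def test_linear_drift_evaluates_exactly(self):
        spec = EmptyChamberSpec(coeffs=(0.5, 0.001))
        df = generate_empty_chamber(ProtocolSpec.empty(), spec=spec)
        at_400 = df.loc[(df["CO2_r"] - 400).abs().idxmin(), "A"]
        assert at_400 == pytest.approx(0.9, abs=1e-6)

    def test_conductance_noise_sd_recovers_instrument_value(self):
        """Sample sd of reported g_lw over 270 records sits inside the
        99% chi-square band around the true 0.00415."""
        df = generate_empty_chamber(
            ProtocolSpec.empty(), noise=NoiseSpec(sd_glw=0.00415), seed=3
        )
        n = len(df)
        assert n == 270
        s = df["gsw"].std(ddof=1)
        lo = 0.00415 * np.sqrt(stats.chi2.ppf(0.005, n - 1) / (n - 1))
        hi = 0.00415 * np.sqrt(stats.chi2.ppf(0.995, n - 1) / (n - 1))
        assert lo < s < hi


class TestCsvRoundTrip:
    def test_write_then_read_is_lossless(self, clean_ss_frame, tmp_path):
        path = tmp_path / "run.csv"
        write_li6800_csv(clean_ss_frame, path)
        back = read_li6800_csv(path)
        pd.testing.assert_frame_equal(back, clean_ss_frame.reset_index(drop=True))

    def test_extra_vendor_columns_survive(self, clean_ss_frame, tmp_path):
        df = clean_ss_frame.copy()
        df["Flr_F"] = 123.4
        path = tmp_path / "run.csv"
        write_li6800_csv(df, path)
        back = read_li6800_csv(path)
        assert "Flr_F" in back.columns

    def test_missing_mandatory_column_names_it(self, clean_ss_frame, tmp_path):
        df = clean_ss_frame.drop(columns=["A"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="'A'"):
            read_li6800_csv(path)

    def test_glw_accepted_as_alias(self, clean_ss_frame, tmp_path):
        df = clean_ss_frame.rename(columns={"gsw": "glw"})
        path = tmp_path / "alias.csv"
        df.to_csv(path, index=False)
        back = read_li6800_csv(path)
        assert "gsw" in back.columns
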