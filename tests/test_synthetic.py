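"""Generator contracts: determinism, planted structure, closed-form moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bkgating as bk
from bkgating.synthetic import (
    default_amplitude,
    tm_positions,
    true_delta_v_table,
)


def _as_frame(records):
    return pd.DataFrame(
        [(r.mutation_id, r.delta_v_half, r.source, r.saturated, r.calcium_uM)
         for r in records],
        columns=["mutation", "dV", "source", "saturated", "ca"],
    )


class TestMutationDataset:
    def test_same_seed_identical_tables(self, small_cfg):
        a = _as_frame(bk.generate_mutation_dataset(small_cfg))
        b = _as_frame(bk.generate_mutation_dataset(small_cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, small_cfg):
        from dataclasses import replace
        other = replace(small_cfg, seed=small_cfg.seed + 1)
        a = _as_frame(bk.generate_mutation_dataset(small_cfg))
        b = _as_frame(bk.generate_mutation_dataset(other))
        assert not a.equals(b)

    def test_zero_saturated_fraction(self):
        cfg = bk.SyntheticConfig(n_positions=40, n_mutations=80, frac_saturated=0.0, seed=3)
        recs = bk.generate_mutation_dataset(cfg)
        assert all(r.saturated == "none" for r in recs)

    def test_too_many_mutations_rejected(self):
        cfg = bk.SyntheticConfig(n_positions=5, n_mutations=96, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            bk.generate_mutation_dataset(cfg)

    def test_tm_coverage_dominates(self, small_cfg, small_records):
        tm = set(tm_positions(small_cfg).tolist())
        frac_tm = np.mean([r.position in tm for r in small_records])
        assert frac_tm >= 0.70

    def test_large_shift_count_within_binomial_interval(self):
        # 473 mutations at 23% large-shift: 95% binomial interval around 109
        cfg = bk.SyntheticConfig(n_mutations=473, frac_large_shift=0.23, seed=0)
        table, _ = bk.curate_dataset(bk.generate_mutation_dataset(cfg))
        count = int(np.sum(np.abs(table["dV_mV"]) > 50))
        sd = np.sqrt(473 * 0.23 * 0.77)
        assert 108.79 - 1.96 * sd <= count <= 108.79 + 1.96 * sd

    def test_saturated_fraction_realized(self, small_cfg, small_records):
        n_sat = sum(r.saturated != "none" for r in small_records)
        n_base = small_cfg.n_mutations
        assert n_sat == round(small_cfg.frac_saturated * n_base)


class TestEnergyTables:
    def test_wt_self_mutation_zero_dddg(self, small_cfg):
        seq = bk.wt_sequence(small_cfg)
        mid = f"{seq[9]}10{seq[9]}"
        tables = bk.generate_energy_tables(small_cfg, [mid])
        df, _ = bk.dddg_matrix(tables, [mid])
        assert (df.loc[mid] == 0.0).all()

    def test_unknown_mutation_id_rejected(self, small_cfg):
        seq = bk.wt_sequence(small_cfg)
        wrong_wt = next(a for a in "ACDEFGHIKLMNPQRSTVWY" if a != seq[0])
        with pytest.raises(KeyError):
            bk.generate_energy_tables(small_cfg, [f"{wrong_wt}1A"])
        with pytest.raises(KeyError):
            bk.generate_energy_tables(small_cfg, [f"{seq[0]}999A"])

    def test_signal_terms_carry_the_planted_signal(self, small_cfg, small_records, small_curated):
        # Spearman correlation of each signal term's dddg with the true dV
        # exceeds that of every non-signal term.
        ids = small_curated["mutation"].tolist()
        tables = bk.generate_energy_tables(small_cfg, ids)
        dddg, _ = bk.dddg_matrix(tables, ids)
        truth = true_delta_v_table(small_cfg, small_records).loc[ids]
        rho = {
            t: abs(stats.spearmanr(dddg[t], truth).statistic)
            for t in small_cfg.terms if t != "ref"
        }
        signal = min(rho[t] for t in small_cfg.signal_features)
        noise = max(v for t, v in rho.items() if t not in small_cfg.signal_features)
        assert signal > noise

    def test_two_seeds_distinct_tables(self, small_cfg):
        from dataclasses import replace
        other = replace(small_cfg, seed=99)
        a = bk.generate_energy_tables(small_cfg, [f"{bk.wt_sequence(small_cfg)[0]}1A"
                                                  if bk.wt_sequence(small_cfg)[0] != "A"
                                                  else f"{bk.wt_sequence(small_cfg)[0]}1C"])
        b = bk.generate_energy_tables(other, [f"{bk.wt_sequence(other)[0]}1A"
                                              if bk.wt_sequence(other)[0] != "A"
                                              else f"{bk.wt_sequence(other)[0]}1C"])
        assert a[("WT", "open")].terms != b[("WT", "open")].terms


class TestEnsemble:
    def test_rmsf_converges_to_amplitude_profile(self):
        cfg = bk.SyntheticConfig(n_positions=12, n_mutations=20, n_frames=4000,
                                 n_chains=2, seed=5)
        ens, spec = bk.generate_ensemble(cfg)
        rmsf = bk.compute_rmsf(ens)
        # Gaussian closed form: E[RMSF] = amplitude; chain-averaged estimate
        assert np.allclose(rmsf.to_numpy(), spec.amplitude, rtol=0.08)

    def test_zero_amplitude_freezes_frames(self):
        cfg = bk.SyntheticConfig(n_positions=8, n_mutations=10, n_frames=5, seed=1)
        ens, _ = bk.generate_ensemble(cfg, amplitude=np.zeros(8), couplings=())
        assert np.allclose(ens.coords, ens.coords[0])

    def test_planted_coupling_appears_in_covariance(self):
        cfg = bk.SyntheticConfig(n_positions=10, n_mutations=10, n_frames=6000,
                                 n_chains=4, seed=2)
        amp = np.full(10, 1.2)
        ens, spec = bk.generate_ensemble(cfg, amplitude=amp, couplings=((2, 7, 0.6),))
        cov = bk.compute_anchor_covariance(ens, [2], mode="intra")
        expected = 0.6 * amp[1] * amp[6]  # rho * a_i * a_j
        assert cov.loc[2, 7] == pytest.approx(expected, rel=0.12)
        assert abs(cov.loc[2, 5]) < 0.1  # uncoupled residue

    def test_chain_label_symmetry(self, small_cfg):
        ens, _ = bk.generate_ensemble(small_cfg)
        by_chain = ens.positions_by_chain()
        assert len(by_chain) == small_cfg.n_chains
        ref = by_chain[ens.chains[0]]
        assert all(v == ref for v in by_chain.values())


class TestGVCurves:
    def test_zero_noise_points_on_curve(self, small_cfg):
        df = bk.generate_gv_curves(small_cfg, {"WT": (176.2, 29.0)})
        expected = bk.boltzmann(df["voltage_mV"].to_numpy(), 176.2, 29.0)
        assert np.allclose(df["g_over_gmax"], expected)

    def test_midpoint_is_half(self, small_cfg):
        v = np.array([100.0, 150.0, 176.2, 200.0, 250.0])
        df = bk.generate_gv_curves(small_cfg, {"WT": (176.2, 29.0)}, voltages=v,
                                   n_patches=1)
        at_mid = df.loc[df["voltage_mV"] == 176.2, "g_over_gmax"]
        assert float(at_mid.iloc[0]) == pytest.approx(0.5, abs=1e-12)

    def test_matches_hand_evaluated_boltzmann(self, small_cfg):
        # grid -100..300 step 20 against direct evaluation at the WT fit values
        df = bk.generate_gv_curves(small_cfg, {"WT": (176.2, 29.0)}, n_patches=1)
        for _, row in df.iterrows():
            hand = 1.0 / (1.0 + np.exp((176.2 - row["voltage_mV"]) / 29.0))
            assert row["g_over_gmax"] == pytest.approx(hand, abs=1e-12)

    def test_nonpositive_slope_rejected(self, small_cfg):
        with pytest.raises(ValueError, match="positive"):
            bk.generate_gv_curves(small_cfg, {"X": (100.0, 0.0)})


def test_enumerate_single_mutations_count():
    seq = bk.wt_sequence(bk.SyntheticConfig(n_positions=30, n_mutations=10, seed=0))
    muts = bk.enumerate_single_mutations(seq)
    assert len(muts) == 19 * 30
    assert len(set(muts)) == len(muts)


def test_annotations_cover_every_position(small_cfg):
    ann = bk.generate_annotations(small_cfg)
    assert list(ann["position"]) == list(range(1, small_cfg.n_positions + 1))
    assert set(ann["ss_class"]) <= {"H", "E", "C"}
    assert set(ann["exposure_class"]) <= {"WATER", "LIPID", "BORDER", "BURIED"}
    assert ann["sasa_pct"].between(0, 100).all()
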