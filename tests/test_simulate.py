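import numpy as np
import pandas as pd
import pytest

from leafflux.emu import decompose
from leafflux.measurement import predict_fragment
from leafflux.network import FluxState, parse_model
from leafflux.simulate import TracerProgram, mean_enrichment, simulate

from .conftest import uniform_flux
from .oracles import isotopomers_to_mid, simulate_isotopomers

TIMES = [0, 0.5, 1, 2, 5, 10, 30, 60]


class TestSinglePool:
    """One pool fed by fully labeled input: labeled fraction = 1 − e^{−vt/c}."""

    def setup_method(self):
        text = """
@met CO2.x carbons=1 source
@met B.c carbons=1
@met OUT carbons=1 sink
up: CO2.x (a) -> B.c (a)
out: B.c (a) -> OUT (a)
"""
        self.model = parse_model(text)
        self.system = decompose(self.model, [("B.c", (1,))])

    def test_closed_form(self):
        v, c = 3.0, 0.75  # turnover time 15 min
        fs = FluxState(
            pd.Series({"up": v, "out": v}), pd.Series(dtype=float),
            pd.Series({"B.c": c}), pd.Series(dtype=float),
        )
        t_star = 60.0 * c / v
        times = [0.0, t_star, 60.0]
        res = simulate(self.system, fs, TracerProgram(purity=1.0), times)
        labeled = 1.0 - res.mid("B.c", (1,))[:, 0]
        expect = 1.0 - np.exp(-np.array([0.0, 1.0, 60.0 / t_star]))
        assert np.allclose(labeled, expect, atol=1e-7)

    def test_washin_slows_initial_labeling(self):
        fs = FluxState(
            pd.Series({"up": 3.0, "out": 3.0}), pd.Series(dtype=float),
            pd.Series({"B.c": 0.05}), pd.Series(dtype=float),
        )
        step = simulate(self.system, fs, TracerProgram(purity=1.0), [0, 0.25, 60])
        wash = simulate(self.system, fs, TracerProgram(purity=1.0, tau_switch_s=5.0),
                        [0, 0.25, 60])
        assert wash.mid("B.c", (1,))[1, 1] < step.mid("B.c", (1,))[1, 1]
        assert wash.mid("B.c", (1,))[2, 1] == pytest.approx(
            step.mid("B.c", (1,))[2, 1], abs=1e-4
        )


class TestOracleEquivalence:
    """EMU cascade must match the brute-force positional-isotopomer ODE."""

    @pytest.mark.parametrize("purity", [1.0, 0.99])
    def test_split_join(self, split_model, purity):
        fs = uniform_flux(split_model, v=2.0)
        system = decompose(split_model, [("D.c", (1, 2, 3)), ("B.c", (1, 2))])
        res = simulate(system, fs, TracerProgram(purity=purity), TIMES,
                       method="ivp", rtol=1e-10, atol=1e-12)
        iso = simulate_isotopomers(split_model, fs, TIMES, purity=purity)
        for met, pos in [("D.c", (1, 2, 3)), ("B.c", (1, 2))]:
            expect = isotopomers_to_mid(iso[met], pos)
            assert np.abs(res.mid(met, pos) - expect).max() < 1e-6

    def test_reversible_and_scrambled(self):
        """Reversible step + symmetric (50/50 scrambled) 4-carbon metabolite."""
        text = """
@met CO2.x carbons=1 source
@met A.c carbons=2
@met S.c carbons=4
@met M.c carbons=4
@met OUT carbons=4 sink
up: CO2.x (a) + CO2.x (b) -> A.c (ab)
cond: A.c (ab) + A.c (cd) -> S.c (abcd|dcba)
iso: S.c (abcd) <-> M.c (abcd|dcba)
out: M.c (abcd) -> OUT (abcd)
"""
        model = parse_model(text)
        net = pd.Series({"up": 4.0, "cond": 2.0, "iso": 2.0, "out": 2.0})
        fs = FluxState(net, pd.Series({"iso": 1.5}),
                       pd.Series({"A.c": 0.3, "S.c": 1.0, "M.c": 0.8}),
                       pd.Series(dtype=float))
        system = decompose(model, [("M.c", (1, 2, 3, 4)), ("M.c", (1, 2))])
        res = simulate(system, fs, TracerProgram(purity=0.99), TIMES,
                       method="ivp", rtol=1e-10, atol=1e-12)
        iso = simulate_isotopomers(model, fs, TIMES, purity=0.99)
        for pos in [(1, 2, 3, 4), (1, 2)]:
            expect = isotopomers_to_mid(iso["M.c"], pos)
            assert np.abs(res.mid("M.c", pos) - expect).max() < 1e-6

    def test_block_path_matches_oracle(self, split_model):
        fs = uniform_flux(split_model, v=2.0)
        system = decompose(split_model, [("D.c", (1, 2, 3))])
        res = simulate(system, fs, TracerProgram(purity=1.0), TIMES,
                       method="block", n_grid=2000)
        iso = simulate_isotopomers(split_model, fs, TIMES, purity=1.0)
        expect = isotopomers_to_mid(iso["D.c"], (1, 2, 3))
        assert np.abs(res.mid("D.c", (1, 2, 3)) - expect).max() < 1e-6


class TestNumerics:
    def test_block_vs_ivp_on_fixture(self, camelina_system, camelina_truth):
        blk = simulate(camelina_system, camelina_truth, TracerProgram(), [0, 1, 10, 60])
        ivp = simulate(camelina_system, camelina_truth, TracerProgram(), [0, 1, 10, 60],
                       method="ivp", rtol=1e-9, atol=1e-11)
        err = max(np.abs(blk.mids[e] - ivp.mids[e]).max() for e in blk.mids)
        assert err < 5e-3  # fixed fit-resolution grid vs tight adaptive reference

    def test_ivp_tolerance_refinement(self, split_model):
        """Halving the adaptive tolerances changes target MIDs by < 1e-7."""
        fs = uniform_flux(split_model, v=2.0)
        system = decompose(split_model, [("D.c", (1, 2, 3))])
        a = simulate(system, fs, TracerProgram(), TIMES, method="ivp",
                     rtol=1e-8, atol=1e-10)
        b = simulate(system, fs, TracerProgram(), TIMES, method="ivp",
                     rtol=5e-9, atol=5e-11)
        assert np.abs(a.mid("D.c", (1, 2, 3)) - b.mid("D.c", (1, 2, 3))).max() < 1e-7

    def test_grid_refinement_second_order(self, camelina_system, camelina_truth):
        """Fixed-grid error shrinks by ~4x when the grid is doubled."""
        ref = simulate(camelina_system, camelina_truth, TracerProgram(), [0, 5, 60],
                       n_grid=2560, validate=False)

        def err(n):
            r = simulate(camelina_system, camelina_truth, TracerProgram(), [0, 5, 60],
                         n_grid=n, validate=False)
            return max(np.abs(r.mids[e] - ref.mids[e]).max() for e in ref.mids)

        assert err(640) < 0.4 * err(160)


class TestInvariants:
    def test_rows_normalized_and_initially_unlabeled(self, camelina_sim):
        for emu, arr in camelina_sim.mids.items():
            assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-6)
            assert arr.min() > -1e-9
            assert arr[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_m0_nonincreasing_on_fixture(self, camelina_sim):
        for emu, arr in camelina_sim.mids.items():
            m0 = arr[:, 0]
            assert (np.diff(m0) <= 1e-7).all(), f"M0 rose for {emu}"

    def test_asymptotic_labeling_pure_tracer(self, chain_model):
        """t → ∞ with pure tracer: M0 → (1−p)^size for every active EMU."""
        fs = uniform_flux(chain_model, v=5.0)
        system = decompose(chain_model, [("C.c", (1, 2, 3))])
        p = 0.99
        res = simulate(system, fs, TracerProgram(purity=p), [0, 600.0])
        assert res.mid("C.c", (1, 2, 3))[-1, 0] == pytest.approx((1 - p) ** 3, rel=1e-3)
        assert res.mid("C.c", (1, 2, 3))[-1, -1] == pytest.approx(p**3, rel=1e-3)

    def test_nonsteady_flux_rejected(self, chain_model):
        fs = uniform_flux(chain_model, v=2.0)
        fs.net_flux["ab"] = 3.0
        system = decompose(chain_model, [("C.c", (1, 2, 3))])
        with pytest.raises(ValueError, match="steady state"):
            simulate(system, fs, TracerProgram(), TIMES)


class TestFixturePhenomenology:
    """The fixture reproduces the study's labeling physiology."""

    def test_tca_slow_c3_fast(self, camelina_sim, camelina_truth, camelina_fragments):
        dil = camelina_truth.dilution_fraction.to_dict()
        frag = {f.id: f for f in camelina_fragments}
        e60 = {
            fid: mean_enrichment(predict_fragment(camelina_sim, frag[fid], dil)[-1])
            for fid in frag
        }
        for fid in ("cit_459", "mal_419", "suc4_289", "glu_432"):
            assert e60[fid] < 0.05, f"{fid} should label < 5% in 1 h"
        for fid in ("pga_185", "rubp_309", "s7p_289", "r5p_229", "e4p_199"):
            assert e60[fid] > 0.85, f"{fid} should label > 85% in 1 h"
        # S7P is the most highly labeled fragment, ~93 %
        assert max(e60, key=e60.get) == "s7p_289"
        assert e60["s7p_289"] == pytest.approx(0.93, abs=0.01)


class TestMeanEnrichment:
    @pytest.mark.parametrize(
        "mid,expect",
        [([1, 0, 0], 0.0), ([0, 0, 1], 1.0), ([0.25, 0.5, 0.25], 0.5)],
    )
    def test_examples(self, mid, expect):
        assert mean_enrichment(mid) == pytest.approx(expect)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            mean_enrichment([0.5, 0.4])
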