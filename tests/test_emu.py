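import numpy as np
import pytest

from instmfa.emu import (EMU, decompose, simulate_steady_state,
                         simulate_timecourse, subset_mid)
from instmfa.isotopomer import brute_force_isotopomer_simulate
from instmfa.network import FluxState, parse_model
from instmfa.synthetic import bundled_model

from conftest import TIMES

MINI_TRUTH = FluxState(
    dict(upt=1.0, glcv=0.162, pk=0.477, ana1=0.685, ana2=0.5, pdh=0.8,
         pyrout=0.177, malout=0.185, co2out=0.615),
    {"ana1": 0.2},
    {"PEP.c": 0.3, "PYR.c": 0.6, "MAL.c": 25.0, "CO2": 0.4})


class TestDecomposition:
    def test_linear_chain_traces_back_without_convolutions(self):
        m = parse_model("""
pool S 2 source
pool A 2
pool B 2
pool OUT 2 sink
rxn r1: S (ab) -> A (ab)
rxn r2: A (ab) -> B (ab)
rxn r3: B (ab) -> OUT (ab)
substrate S 0.4 0 0.6
measure B: B
""")
        net = decompose(m, ["B"])
        assert set(net.emus) == {EMU("A", (1, 2)), EMU("B", (1, 2))}
        assert all(len(t.parts) == 1 for e in net.emus
                   for t in net.production[e])

    def test_condensation_creates_convolution_node(self, condensation_model):
        net = decompose(condensation_model, ["C"])
        terms = net.production[EMU("C", (1, 2))]
        assert any(len(t.parts) == 2 for t in terms)

    def test_citrate_draws_on_acetyl_and_malate_convolution(self):
        core = bundled_model("arabidopsis_core")
        net = decompose(core, ["CIT"])
        cit = EMU("CIT", (1, 2, 3, 4, 5, 6))
        tca2 = [t for t in net.production[cit] if t.rxn_id == "tca2"]
        assert tca2, "citrate must be produced by citrate synthase"
        pools = {r[1].pool if r[0] == "x" else r[1]
                 for t in tca2 for r in t.parts}
        assert pools == {"AcCoA", "MAL"}
        assert all(len(t.parts) == 2 for t in tca2)

    def test_unreachable_target_reported(self):
        m = parse_model("""
pool S 1 source
pool A 1
pool B 1 source unlabelled
pool C 1
pool OUT 1 sink
rxn r1: S (a) -> A (a)
rxn r2: A (a) -> OUT (a)
rxn r3: B (a) -> C (a)
rxn r4: C (a) -> OUT (a)
substrate S 0.4 0.6
measure C: C
""")
        with pytest.raises(ValueError, match="unreachable"):
            decompose(m, ["C"])

    def test_subset_mid_is_hypergeometric_marginal(self):
        # 60% uniformly labelled hexose collapsed onto a 2-carbon fragment
        mol = np.array([0.4, 0, 0, 0, 0, 0, 0.6])
        assert np.allclose(subset_mid(mol, 2), [0.4, 0.0, 0.6])
        assert subset_mid(mol, 6) is not None
        assert np.allclose(subset_mid(np.array([0.5, 0.5]), 1), [0.5, 0.5])


class TestTimecourse:
    def test_washout_matches_closed_form(self, washout_model, washout_state):
        net = decompose(washout_model, ["A"])
        res = simulate_timecourse(net, washout_state, TIMES)
        exact = 0.6 * (1 - np.exp(-1.0 * TIMES / 2.0))
        assert np.max(np.abs(res["A"][:, 1] - exact)) < 1e-6

    def test_time_zero_is_unlabelled(self):
        net = decompose(bundled_model("mini_heterotroph"), ["PEP", "PYR", "MAL"])
        res = simulate_timecourse(net, MINI_TRUTH, TIMES)
        for mids in res.values():
            assert mids[0, 0] == pytest.approx(1.0)
            assert np.allclose(mids[0, 1:], 0.0)

    def test_normalization_preserved_at_every_time(self):
        net = decompose(bundled_model("mini_heterotroph"), ["PEP", "PYR", "MAL"])
        res = simulate_timecourse(net, MINI_TRUTH, TIMES)
        for mids in res.values():
            assert np.max(np.abs(mids.sum(axis=1) - 1.0)) < 1e-9
            assert mids.min() >= 0.0

    def test_uniform_labelling_limit_without_unlabelled_influx(self):
        # no unlabelled input: every balanced pool ends at substrate enrichment
        state = FluxState(
            dict(upt=1.0, glcv=0.0, pk=0.477, ana1=0.523, ana2=0.4,
                 pdh=0.6, pyrout=0.277, malout=0.123, co2out=0.477),
            {"ana1": 0.2},
            {"PEP.c": 0.3, "PYR.c": 0.6, "MAL.c": 5.0, "CO2": 0.4})
        m = bundled_model("mini_heterotroph")
        net = decompose(m, ["PEP", "PYR", "MAL"])
        ss = simulate_steady_state(net, state)
        for pool, mid in ss.items():
            n = len(mid) - 1
            enrich = np.dot(mid, np.arange(n + 1)) / n
            assert enrich == pytest.approx(0.6, abs=1e-9)

    def test_monotone_enrichment_on_irreversible_chain(self, washout_model,
                                                       washout_state):
        net = decompose(washout_model, ["A"])
        res = simulate_timecourse(net, washout_state, TIMES)
        assert np.all(np.diff(res["A"][:, 1]) >= -1e-8)  # integrator accuracy

    def test_time_rescaling_property(self):
        m = bundled_model("mini_heterotroph")
        net = decompose(m, ["PEP", "PYR", "MAL"])
        halved = FluxState({k: v / 2 for k, v in MINI_TRUTH.net.items()},
                           {k: v / 2 for k, v in MINI_TRUTH.exchange.items()},
                           {k: 2 * v for k, v in MINI_TRUTH.pools.items()})
        base = simulate_timecourse(net, MINI_TRUTH, TIMES)
        slow = simulate_timecourse(net, halved, 4 * TIMES)
        for pool in base:
            assert np.max(np.abs(base[pool] - slow[pool])) < 1e-7
        ss1 = simulate_steady_state(net, MINI_TRUTH)
        ss2 = simulate_steady_state(net, halved)
        for pool in ss1:
            assert np.allclose(ss1[pool], ss2[pool], atol=1e-10)

    def test_zero_pool_size_rejected(self, washout_model):
        bad = FluxState({"inflow": 1.0, "outflow": 1.0}, {}, {"A": 0.0})
        with pytest.raises(ValueError, match="positive"):
            simulate_timecourse(decompose(washout_model, ["A"]), bad, TIMES)


class TestSteadyState:
    def test_chain_passes_substrate_through(self, washout_model, washout_state):
        net = decompose(washout_model, ["A"])
        ss = simulate_steady_state(net, washout_state)
        assert np.allclose(ss["A"], [0.4, 0.6], atol=1e-12)

    def test_fifty_fifty_merge_halves_full_labelling(self):
        m = parse_model("""
pool S1 1 source
pool S2 1 source unlabelled
pool A 1
pool OUT 1 sink
rxn r1: S1 (a) -> A (a)
rxn r2: S2 (a) -> A (a)
rxn r3: A (a) -> OUT (a)
substrate S1 0 1
measure A: A
""")
        st = FluxState({"r1": 0.5, "r2": 0.5, "r3": 1.0}, {}, {"A": 1.0})
        ss = simulate_steady_state(decompose(m, ["A"]), st)
        assert np.allclose(ss["A"], [0.5, 0.5], atol=1e-12)

    def test_condensation_is_cauchy_product(self, condensation_model):
        st = FluxState({"ra": 1, "rb": 1, "rc": 1, "ro": 1}, {},
                       {"A": 1, "B": 1, "C": 1})
        ss = simulate_steady_state(decompose(condensation_model, ["C"]), st)
        assert np.allclose(ss["C"], [0.25, 0.5, 0.25], atol=1e-12)

    def test_matches_timecourse_limit(self):
        m = bundled_model("mini_heterotroph")
        net = decompose(m, ["PEP", "PYR", "MAL"])
        ss = simulate_steady_state(net, MINI_TRUTH)
        late = simulate_timecourse(net, MINI_TRUTH, np.array([0.0, 5000.0]))
        for pool in ss:
            assert np.max(np.abs(ss[pool] - late[pool][-1])) < 1e-6

    def test_zero_throughput_cycle_reported(self):
        m = parse_model("""
pool S 1 source
pool A 1
pool B 1
pool OUT 1 sink
rxn r1: S (a) -> A (a)
rxn r2: A (a) <-> B (a)
rxn r3: A (a) -> OUT (a)
substrate S 0.4 0.6
measure B: B
""")
        st = FluxState({"r1": 1.0, "r2": 0.0, "r3": 1.0}, {"r2": 0.0},
                       {"A": 1.0, "B": 1.0})
        with pytest.raises(ValueError, match="singular"):
            simulate_steady_state(decompose(m, ["B"]), st)


class TestIsotopomerOracle:
    """The EMU cascade against the exhaustive 2^n isotopomer integration."""

    def test_two_pool_network_agrees(self, washout_model, washout_state):
        emu = simulate_timecourse(decompose(washout_model, ["A"]),
                                  washout_state, TIMES, rtol=1e-10, atol=1e-12)
        bf = brute_force_isotopomer_simulate(washout_model, washout_state,
                                             TIMES, targets=["A"])
        assert np.max(np.abs(emu["A"] - bf["A"])) <= 1e-8

    def test_reduced_heterotroph_network_agrees(self):
        m = bundled_model("mini_heterotroph")
        emu = simulate_timecourse(decompose(m, ["PEP", "PYR", "MAL"]),
                                  MINI_TRUTH, TIMES, rtol=1e-10, atol=1e-12)
        bf = brute_force_isotopomer_simulate(
            m, MINI_TRUTH, TIMES, targets=["PEP", "PYR", "MAL"])
        for pool in emu:
            assert np.max(np.abs(emu[pool] - bf[pool])) <= 1e-8

    def test_washout_closed_form_on_both_paths(self, washout_model,
                                               washout_state):
        exact = 0.6 * (1 - np.exp(-TIMES / 2.0))
        emu = simulate_timecourse(decompose(washout_model, ["A"]),
                                  washout_state, TIMES, rtol=1e-10, atol=1e-12)
        bf = brute_force_isotopomer_simulate(washout_model, washout_state,
                                             TIMES, targets=["A"])
        assert np.max(np.abs(emu["A"][:, 1] - exact)) < 1e-6
        assert np.max(np.abs(bf["A"][:, 1] - exact)) < 1e-6

    def test_symmetric_scrambling_agrees_and_symmetrizes(self,
                                                         scrambling_model):
        st = FluxState({"ra": 1, "rb": 1, "rc": 1, "rd": 1, "ro": 1}, {},
                       {"A": 0.5, "B": 2.0, "S": 1.0, "C": 0.7})
        emu = simulate_timecourse(decompose(scrambling_model, ["C"]), st,
                                  TIMES, rtol=1e-10, atol=1e-12)
        bf = brute_force_isotopomer_simulate(scrambling_model, st, TIMES,
                                             targets=["C"])
        assert np.max(np.abs(emu["C"] - bf["C"])) <= 1e-8
        # positional isotopomers of the scrambled product are equal
        ss = simulate_steady_state(decompose(scrambling_model, ["C"]), st)
        c1 = simulate_steady_state(
            decompose(scrambling_model, ["C"]), st)  # full MID symmetric check
        m1_total = ss["C"][1]
        assert m1_total == pytest.approx(0.9 * 0.7 + 0.1 * 0.3, abs=1e-9)

    def test_state_space_guard(self):
        m = parse_model("""
pool S 13 source unlabelled
pool A 13
pool OUT 13 sink
rxn r1: S (abcdefghijklm) -> A (abcdefghijklm)
rxn r2: A (abcdefghijklm) -> OUT (abcdefghijklm)
""")
        st = FluxState({"r1": 1.0, "r2": 1.0}, {}, {"A": 1.0})
        with pytest.raises(ValueError, match="too large"):
            brute_force_isotopomer_simulate(m, st, TIMES, targets=["A"])


def test_timecourse_frame_is_tidy(washout_model, washout_state):
    from instmfa.emu import timecourse_frame
    net = decompose(washout_model, ["A"])
    res = simulate_timecourse(net, washout_state, TIMES)
    frame = timecourse_frame(res, TIMES)
    assert list(frame.columns) == ["observable", "time_min", "isotopologue",
                                   "fraction"]
    assert len(frame) == len(TIMES) * 2
    assert frame.groupby("time_min")["fraction"].sum().round(9).eq(1.0).all()
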