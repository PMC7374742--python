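import math

import numpy as np
import pytest

from netpharm.kinetics import (InhibitionSpec, KineticModel, Reaction,
                               add_inhibitor, concentration_at,
                               huang_ferrell_mapk_cascade, load_model,
                               parse_reaction_text, simulate)
from netpharm.sbml import read_sbml, write_sbml
from netpharm.synthetic_data import toy_cascade_model

DECAY = "A = 1.0\nA -> B ; kf=0.1\n"


def reaction_set(model):
    return {(frozenset(r.reactants.items()), frozenset(r.products.items()),
             r.kf, r.kr) for r in model.reactions}


class TestLoadModel:
    def test_toy_text_spec(self):
        m = load_model(DECAY)
        assert set(m.species) == {"A", "B"}
        assert len(m.reactions) == 1
        assert m.reactions[0].kf == 0.1

    def test_text_file_and_raw_text_agree(self, tmp_path):
        p = tmp_path / "decay.model"
        p.write_text(DECAY)
        assert reaction_set(load_model(p)) == reaction_set(load_model(DECAY))

    def test_sbml_round_trip_of_generated_model(self, tmp_path):
        rng = np.random.default_rng(12)
        m = KineticModel(name="gen")
        names = [f"S{i}" for i in range(6)]
        for n in names:
            m.species[n] = float(rng.uniform(0, 2))
        for i in range(5):
            a, b, c = rng.choice(names, size=3, replace=False)
            m.reactions.append(Reaction(
                reactants={a: 1, b: int(rng.integers(1, 3))}, products={c: 1},
                kf=float(rng.uniform(0.1, 2)),
                kr=float(rng.uniform(0.1, 2)) if i % 2 else None,
                rid=f"r{i}"))
        path = tmp_path / "gen.xml"
        write_sbml(m, path)
        back = read_sbml(path)
        assert back.species == m.species
        assert reaction_set(back) == reaction_set(m)

    def test_mapk_cascade_has_published_initial_conditions(self):
        m = huang_ferrell_mapk_cascade()
        assert m.species["MAPK"] == pytest.approx(1.2)
        assert m.species["MAPKK"] == pytest.approx(1.2)
        assert len(m.species) == 22
        assert len(m.reactions) == 20

    def test_non_mass_action_sbml_is_rejected_naming_the_reaction(self, tmp_path):
        m = load_model(DECAY)
        path = tmp_path / "bad.xml"
        write_sbml(m, path)
        # corrupt the kinetic law into a Michaelis-Menten-style expression
        text = path.read_text().replace("<ci>A</ci>",
                                        "<apply><power/><ci>A</ci><cn>0.5</cn></apply>")
        path.write_text(text)
        with pytest.raises(ValueError, match="r1"):
            read_sbml(path)

    def test_missing_model_file(self):
        with pytest.raises(FileNotFoundError):
            load_model("/nonexistent/model.xml")


class TestSimulate:
    def test_first_order_decay_matches_exponential(self):
        traj = simulate(load_model(DECAY), t_end=10.0, n_points=101)
        assert concentration_at(traj, "A", 10.0) == pytest.approx(
            math.exp(-1.0), abs=1e-5)
        assert concentration_at(traj, "B", 10.0) == pytest.approx(
            1 - math.exp(-1.0), abs=1e-5)

    def test_no_reactions_freezes_the_state(self):
        m = KineticModel(species={"X": 2.5, "Y": 0.1})
        traj = simulate(m, t_end=5.0, n_points=11)
        assert np.all(traj.series("X") == 2.5)
        assert np.all(traj.series("Y") == 0.1)

    def test_reversible_isomerization_reaches_half_half(self):
        m = load_model("A = 1.0\nA <-> B ; kf=1.0 kr=1.0\n")
        traj = simulate(m, t_end=20.0, n_points=201)
        assert concentration_at(traj, "A", 20.0) == pytest.approx(0.5, abs=1e-6)
        assert concentration_at(traj, "B", 20.0) == pytest.approx(0.5, abs=1e-6)

    def test_grid_includes_endpoints(self):
        traj = simulate(load_model(DECAY), t_end=3.0, n_points=31)
        assert traj.times[0] == 0.0 and traj.times[-1] == 3.0
        assert len(traj.times) == 31

    def test_non_negative_within_solver_tolerance(self):
        traj = simulate(huang_ferrell_mapk_cascade(), t_end=150.0,
                        n_points=301)
        assert traj.data.min() >= -1e-10

    def test_toy_cascade_moieties_conserved(self):
        traj = simulate(toy_cascade_model(), t_end=50.0, n_points=501)
        a_tot = sum(traj.series(s) for s in ("A", "EA", "Ap", "ApB"))
        e_tot = traj.series("E") + traj.series("EA")
        assert np.max(np.abs(a_tot - 1.0)) < 1e-6
        assert np.max(np.abs(e_tot - 0.1)) < 1e-6

    def test_cascade_moiety_conservation_and_intermediates(self):
        traj = simulate(huang_ferrell_mapk_cascade(), t_end=150.0)
        mapk_moiety = sum(traj.series(s) for s in
                          ("MAPK", "P_MAPK", "PP_MAPK", "PP_MAPKK_MAPK",
                           "PP_MAPKK_P_MAPK", "MAPK_Pase_P_MAPK",
                           "MAPK_Pase_PP_MAPK"))
        assert np.max(np.abs(mapk_moiety - 1.2)) < 1e-6
        end = traj.times[-1]
        assert (concentration_at(traj, "MAPK", end)
                + concentration_at(traj, "PP_MAPK", end)) < 1.2

    def test_tolerance_tightening_does_not_move_the_answer(self):
        m = huang_ferrell_mapk_cascade()
        loose = simulate(m, 150.0, rtol=1e-8, atol=1e-10)
        tight = simulate(m, 150.0, rtol=1e-9, atol=1e-11)
        for sp in ("MAPK", "PP_MAPK"):
            assert abs(concentration_at(loose, sp, 150.0)
                       - concentration_at(tight, sp, 150.0)) < 1e-4

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            simulate(load_model(DECAY), t_end=0.0)
        with pytest.raises(ValueError):
            simulate(load_model(DECAY), t_end=1.0, n_points=1)


class TestInhibitor:
    def test_zero_on_rate_is_a_null_perturbation(self):
        base = toy_cascade_model()
        spec = InhibitionSpec(inhibitor="drug", targets=("A",), k_on=0.0,
                              k_off=0.0, concentration=20.0)
        t0 = simulate(base, 30.0, n_points=301)
        t1 = simulate(add_inhibitor(base, spec), 30.0, n_points=301)
        for sp in base.species:
            assert np.allclose(t0.series(sp), t1.series(sp), atol=1e-8)

    def test_inhibitor_moiety_conserved(self):
        m = huang_ferrell_mapk_cascade()
        spec = InhibitionSpec(inhibitor="curcumin", targets=("MAPK",),
                              k_on=1.0, k_off=0.66255, concentration=20.0)
        traj = simulate(add_inhibitor(m, spec), 150.0)
        total = traj.series("curcumin") + traj.series("MAPK_curcumin")
        assert np.max(np.abs(total - 20.0)) < 1e-6

    def test_excess_irreversible_binding_depletes_the_target(self):
        m = KineticModel(species={"A": 1.0})
        spec = InhibitionSpec(inhibitor="I", targets=("A",), k_on=100.0,
                              k_off=0.0, concentration=20.0)
        traj = simulate(add_inhibitor(m, spec), 150.0)
        assert concentration_at(traj, "A", 150.0) < 1e-6

    def test_unknown_target_is_an_error(self):
        with pytest.raises(KeyError):
            add_inhibitor(toy_cascade_model(),
                          InhibitionSpec(inhibitor="I", targets=("NOPE",),
                                         k_on=1.0, k_off=1.0))

    def test_original_reactions_untouched(self):
        base = toy_cascade_model()
        spec = InhibitionSpec(inhibitor="I", targets=("A", "B"), k_on=1.0,
                              k_off=0.5)
        ext = add_inhibitor(base, spec)
        assert ext.reactions[:len(base.reactions)] == base.reactions
        assert len(ext.reactions) == len(base.reactions) + 2
        assert base.species.keys() != ext.species.keys()  # base unmodified


class TestConcentrationAt:
    def test_exact_at_time_zero(self):
        traj = simulate(toy_cascade_model(), 10.0, n_points=101)
        assert concentration_at(traj, "A", 0.0) == 1.0
        assert concentration_at(traj, "E", 0.0) == 0.1

    def test_midpoint_is_mean_of_grid_neighbours(self):
        traj = simulate(load_model(DECAY), 10.0, n_points=11)
        mid = 0.5 * (traj.series("A")[3] + traj.series("A")[4])
        t_mid = 0.5 * (traj.times[3] + traj.times[4])
        assert concentration_at(traj, "A", t_mid) == pytest.approx(mid)

    def test_dense_grid_tracks_the_closed_form(self):
        traj = simulate(load_model(DECAY), 10.0, n_points=1001)
        rng = np.random.default_rng(0)
        for t in rng.uniform(0, 10, size=20):
            assert concentration_at(traj, "A", t) == pytest.approx(
                math.exp(-0.1 * t), abs=1e-4)

    def test_errors(self):
        traj = simulate(load_model(DECAY), 10.0)
        with pytest.raises(KeyError):
            concentration_at(traj, "Z", 1.0)
        with pytest.raises(ValueError):
            concentration_at(traj, "A", 11.0)
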