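"""Tests for the Kawasaki-Ising membrane simulation."""

import math
from itertools import combinations

import numpy as np
import pytest

from lckcycle import ising, synth
from lckcycle.errors import ConfigError


def exact_energy_distribution(L, n_up, T):
    """Oracle: Boltzmann weights over every fixed-composition state.

    Enumerates all C(L*L, n_up) spin configurations, computing each
    energy from the bond list directly.
    """
    n = L * L
    bonds = []
    for i in range(L):
        for j in range(L):
            a = i * L + j
            bonds.append((a, ((i + 1) % L) * L + j))
            bonds.append((a, i * L + (j + 1) % L))
    weights = {}
    for ups in combinations(range(n), n_up):
        s = -np.ones(n, dtype=int)
        s[list(ups)] = 1
        e = -sum(s[a] * s[b] for a, b in bonds)
        weights[e] = weights.get(e, 0.0) + math.exp(-e / T)
    z = sum(weights.values())
    return {e: w / z for e, w in weights.items()}


class TestCriticalTemperature:
    def test_closed_form_value(self):
        tc = ising.critical_temperature()
        assert tc == pytest.approx(2.269185, abs=1e-5)
        assert tc == 2.0 / math.log(1.0 + math.sqrt(2.0))

    def test_below_simulation_temperature(self):
        assert ising.critical_temperature() < ising.SIM_TEMPERATURE

    def test_kramers_wannier_self_duality(self):
        tc = ising.critical_temperature()
        assert math.sinh(2.0 / tc) ** 2 == pytest.approx(1.0, abs=1e-12)


class TestKawasakiStep:
    def test_metropolis_factor_at_de_4(self):
        # closed form: exchange with dE = 4J at T = 2.28 accepted with
        # probability exp(-4/2.28) ~= 0.173
        assert math.exp(-4.0 / 2.28) == pytest.approx(0.1731, abs=1e-4)

    def test_exact_conservation(self):
        lat = synth.gen_ising_config(16, 0.5, seed=3)
        m0 = lat.mobile_magnetization()
        ising.metropolis_sweeps(lat, 400)  # 102,400 proposals
        assert lat.mobile_magnetization() == m0

    def test_single_step_runs(self):
        lat = synth.gen_ising_config(8, 0.5, seed=1)
        total = lat.spins.sum()
        ising.kawasaki_step(lat)
        assert lat.spins.sum() == total

    def test_zero_sweeps_identity(self):
        lat = synth.gen_ising_config(8, 0.5, seed=4)
        before = lat.spins.copy()
        res = ising.run(lat, 0)
        np.testing.assert_array_equal(res.lattice.spins, before)
        assert len(res.snapshots) == 0

    def test_determinism(self):
        a = synth.gen_ising_config(12, 0.5, seed=9)
        b = synth.gen_ising_config(12, 0.5, seed=9)
        ising.metropolis_sweeps(a, 50)
        ising.metropolis_sweeps(b, 50)
        np.testing.assert_array_equal(a.spins, b.spins)

    def test_zero_temperature_quench_energy_nonincreasing(self):
        lat = synth.gen_ising_config(12, 0.5, seed=5, T=1e-9)
        res = ising.run(lat, 400, sample_every=20)
        e = res.energies
        assert (np.diff(e) <= 0).all()

    def test_incremental_energy_matches_recompute(self):
        lat = synth.gen_ising_config(16, 0.5, seed=11)
        e0 = ising.total_energy(lat)
        res = ising.run(lat, 400, sample_every=400)  # 102,400 proposals
        assert res.energies[-1] == ising.total_energy(res.lattice)
        assert isinstance(e0, int)


class TestBoltzmannSampling:
    def test_4x4_energy_histogram_matches_enumeration(self):
        # exhaustive oracle over all C(16, 8) = 12,870 states
        expected = exact_energy_distribution(4, 8, ising.SIM_TEMPERATURE)
        assert sum(expected.values()) == pytest.approx(1.0)

        lat = synth.gen_ising_config(4, 0.5, seed=20)
        res = ising.run(lat, 400_000, sample_every=10, burn_in=2000)
        energies = res.energies
        n = len(energies)
        observed = {e: c / n for e, c in
                    zip(*map(np.ndarray.tolist,
                             np.unique(energies, return_counts=True)))}
        # thinned samples remain autocorrelated, so the SE of each level
        # frequency comes from batch means (100 blocks) rather than the
        # naive multinomial formula
        blocks = np.array_split(energies, 100)
        for e, p in expected.items():
            if p < 1e-3:
                continue
            freqs = np.array([(b == e).mean() for b in blocks])
            se = freqs.std(ddof=1) / math.sqrt(len(blocks))
            assert abs(observed.get(e, 0.0) - p) <= 3 * se + 1e-3, (e, p)

    def test_detailed_balance_pairwise_flows(self):
        # on a 3x3 lattice the stationary flow i->j must balance j->i
        lat = synth.gen_ising_config(3, 4 / 9, seed=6)
        ising.metropolis_sweeps(lat, 500)
        flows = {}
        prev = tuple(lat.spins.ravel())
        for _ in range(150_000):
            ising.kawasaki_step(lat)
            cur = tuple(lat.spins.ravel())
            if cur != prev:
                key = (prev, cur) if prev < cur else (cur, prev)
                sign = 1 if prev < cur else -1
                a, b = flows.get(key, (0, 0))
                flows[key] = (a + (sign > 0), b + (sign < 0))
                prev = cur
        checked = 0
        for (s1, s2), (n_ij, n_ji) in flows.items():
            tot = n_ij + n_ji
            if tot < 100:
                continue
            assert abs(n_ij - n_ji) <= 4 * math.sqrt(tot), (n_ij, n_ji)
            checked += 1
        assert checked >= 5


class TestDiscs:
    def test_tiny_disc_single_site(self):
        lat = synth.gen_ising_config(16, 0.5, seed=2)
        ising.place_disc(lat, ising.Disc((8, 8), 0.4, 1))
        assert lat.frozen.sum() == 1
        assert lat.spins[8, 8] == 1

    def test_frozen_count_matches_geometry_oracle(self):
        lat = synth.gen_ising_config(64, 0.5, seed=2)
        disc = ising.Disc((32, 32), 3.0, 1)
        ising.place_disc(lat, disc)
        count = sum(1 for y in range(64) for x in range(64)
                    if (y - 32) ** 2 + (x - 32) ** 2 <= 9.0)
        assert lat.frozen.sum() == count

    def test_frozen_sites_immutable_under_dynamics(self):
        lat = synth.gen_ising_config(16, 0.5, seed=2)
        disc = ising.Disc((8, 8), 2.0, -1)
        ising.place_disc(lat, disc)
        frozen = lat.frozen.copy()
        ising.metropolis_sweeps(lat, 500)
        assert (lat.spins[frozen] == -1).all()

    def test_composition_rebalanced(self):
        lat = synth.gen_ising_config(32, 0.5, seed=3)
        ising.place_disc(lat, ising.Disc((16, 16), 4.0, 1))
        mobile = ~lat.frozen
        n_plus = (lat.spins[mobile] == 1).sum()
        assert n_plus == round(0.5 * mobile.sum())

    def test_overlapping_discs_rejected(self):
        lat = synth.gen_ising_config(32, 0.5, seed=3)
        ising.place_disc(lat, ising.Disc((16, 16), 3.0, 1))
        with pytest.raises(ConfigError):
            ising.place_disc(lat, ising.Disc((17, 17), 3.0, 1))


class TestAnnulus:
    # near-critical Kawasaki domains decorrelate very slowly within one
    # trajectory, so enrichment statistics average over independent seeds
    def _shell_minus_bulk(self, T, seed, radius=3.0, L=48, n_snapshots=40,
                          with_disc=True):
        lat = synth.gen_ising_config(L, 0.5, seed=seed, T=T)
        disc = ising.Disc((L // 2, L // 2), radius, 1)
        if with_disc:
            ising.place_disc(lat, disc)
        res = ising.run(lat, n_snapshots * 10, sample_every=10, burn_in=500)
        prof = ising.radial_composition(res.snapshots, disc, lat.frozen)
        return float(prof.snapshot_means[:, 0].mean() - prof.bulk_mean), prof

    def _seed_stats(self, T, seeds, **kw):
        vals = np.array([self._shell_minus_bulk(T, s, **kw)[0] for s in seeds])
        return vals.mean(), vals.std(ddof=1) / math.sqrt(len(vals))

    def test_enrichment_near_critical(self):
        mean, se = self._seed_stats(2.28, range(31, 39))
        assert mean > 3 * se  # one-sided, well beyond alpha=0.01

    def test_no_enrichment_at_infinite_temperature(self):
        mean, se = self._seed_stats(np.inf, range(31, 37))
        assert abs(mean) <= 3 * se

    def test_profile_decays_from_edge(self):
        # enrichment decays strictly over the first shells; because the
        # order parameter is conserved, the enriched material is drawn
        # from nearby, leaving a shallow depletion trough before the
        # profile settles at bulk -- so monotonicity is only asserted up
        # to the trough
        profs = [self._shell_minus_bulk(2.28, s)[1] for s in range(61, 69)]
        prof = np.mean([p.mean_spin[:12] for p in profs], axis=0)
        assert (np.diff(prof[:4]) < 0).all()
        assert prof[0] == prof.max()
        assert (np.abs(prof[6:]) < 0.1).all()

    def test_translation_invariance_without_disc(self):
        # annulus machinery on an arbitrary reference point of a disc-free
        # lattice: no enrichment
        mean, se = self._seed_stats(2.28, range(71, 79), with_disc=False)
        assert abs(mean) <= 3 * se


class TestCorrelationLength:
    def _xi(self, T, seed, L=48, n_snapshots=100):
        lat = synth.gen_ising_config(L, 0.5, seed=seed, T=T)
        res = ising.run(lat, n_snapshots * 20, sample_every=20, burn_in=2000)
        return ising.correlation_length(res.snapshots)

    def _median_xi(self, T, seeds=range(43, 49)):
        return float(np.median([self._xi(T, s).xi for s in seeds]))

    def test_zero_separation_equals_variance(self):
        corr = self._xi(T=2.28, seed=41, n_snapshots=50)
        # spins are +-1 with zero mean at critical composition: var = 1
        assert corr.correlation[0] == pytest.approx(1.0, abs=1e-6)

    def test_high_temperature_short_range(self):
        assert self._median_xi(5.0) < 2.0

    def test_xi_grows_approaching_tc(self):
        # medians over a fixed seed panel; conserved composition caps the
        # positive-correlation range, so gaps near Tc are modest
        xi_228 = self._median_xi(2.28)
        xi_240 = self._median_xi(2.40)
        xi_500 = self._median_xi(5.00)
        assert xi_500 < xi_240 < xi_228


class TestPairContacts:
    def _stats(self, like, T, seed, L=20, n_sweeps=1500):
        # small box + long runs so the disc-separation distribution
        # equilibrates rather than reflecting the diffusive start
        lat = synth.gen_ising_config(L, 0.5, seed=seed, T=T)
        r = 2.0
        a = ising.Disc((L / 2, L / 2 - (r + 2)), r, 1)
        b = ising.Disc((L / 2, L / 2 + (r + 2)), r, 1 if like else -1)
        return ising.pair_contact_stats(lat, a, b, n_sweeps=n_sweeps,
                                        sample_every=5, burn_in=200,
                                        moves_per_sweep=8,
                                        contact_cutoff=1.5)

    def test_frozen_discs_point_mass(self):
        L = 32
        lat = synth.gen_ising_config(L, 0.5, seed=51)
        a = ising.Disc((L / 2, L / 4), 2.5, 1)
        b = ising.Disc((L / 2, 3 * L / 4), 2.5, -1)
        st = ising.pair_contact_stats(lat, a, b, n_sweeps=50, sample_every=5,
                                      burn_in=10, mobile=False)
        assert np.unique(st.separations).size == 1

    def test_overlapping_discs_rejected(self):
        lat = synth.gen_ising_config(32, 0.5, seed=52)
        a = ising.Disc((16, 14), 3.0, 1)
        b = ising.Disc((16, 18), 3.0, -1)
        with pytest.raises(ConfigError):
            ising.pair_contact_stats(lat, a, b)

    def test_like_discs_closer_than_unlike_near_critical(self):
        # sign property over seeds: like-preference pairs spend more time
        # in proximity than unlike pairs at T just above critical
        seps_like, seps_unlike = [], []
        cf_like, cf_unlike = [], []
        for seed in range(8):
            st = self._stats(True, 2.28, 100 + seed)
            seps_like.append(st.separations.mean())
            cf_like.append(st.contact_frequency)
            st = self._stats(False, 2.28, 200 + seed)
            seps_unlike.append(st.separations.mean())
            cf_unlike.append(st.contact_frequency)
        wins = sum(l < u for l, u in zip(seps_like, seps_unlike))
        assert np.mean(seps_unlike) - np.mean(seps_like) > 0
        assert np.mean(cf_like) > np.mean(cf_unlike)
        assert wins >= 6

    def test_athermal_limit_indistinguishable(self):
        seps_like, seps_unlike = [], []
        for seed in range(6):
            seps_like.append(self._stats(True, np.inf, 300 + seed,
                                         n_sweeps=600).separations.mean())
            seps_unlike.append(self._stats(False, np.inf, 400 + seed,
                                           n_sweeps=600).separations.mean())
        from scipy import stats as sps
        p = sps.mannwhitneyu(seps_like, seps_unlike,
                             alternative="two-sided").pvalue
        assert p > 0.01
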