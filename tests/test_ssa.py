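"""Stochastic engine: propensities, hybrid stepping, replication, partition."""

import numpy as np
import pytest

from budsim.cell_cycle import DIVISION, new_cycle
from budsim.gene_network import ConstantActivity
from budsim.ssa import (
    CHANNELS_PER_GENE,
    SimOptions,
    advance_cell,
    compute_propensities,
    effective_rates,
    partition_at_division,
    replicate_promoters,
    step,
)
from tests.conftest import frozen_cycle_params, make_cell, make_single_gene_network


def _stationary_run(net, cell, rng, total_min, chunk_min, burn_chunks=10):
    """Time series of (mrna, protein, pr_on) sampled every chunk_min."""
    rates = effective_rates(net.rate_table(), cell.noise)
    opts = SimOptions()
    n_chunks = int(total_min / chunk_min)
    samples = []
    t_end = 0.0
    for _ in range(n_chunks):
        t_end += chunk_min
        advance_cell(cell, net, 0.0, t_end, rng, rates=rates, options=opts)
        samples.append((cell.mrna[0], cell.protein[0], cell.pr_on[0]))
    arr = np.array(samples[burn_chunks:], dtype=float)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def _batch_se(x, n_batches=20):
    b = np.array_split(x, n_batches)
    means = np.array([bi.mean() for bi in b])
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestPropensities:
    def test_empty_cell_channels(self):
        net = make_single_gene_network(F=1.0, b_obs=0.1)
        cell = make_cell(net, frozen_cycle_params(), pr_on=0, pr_off=1)
        a = compute_propensities(cell, net, 0.0)
        # only promoter activation and basal transcription can fire
        assert a[0] > 0 and a[2] > 0
        assert a[1] == a[3] == a[4] == a[5] == a[6] == 0.0

    def test_reference_volume_scaling_is_unity(self):
        net = make_single_gene_network()
        cell = make_cell(net, frozen_cycle_params(), V=net.Vref, mrna=5, protein=10)
        rt = net.rate_table()
        a = compute_propensities(cell, net, 0.0)
        assert a[3] == pytest.approx(rt.rm_true[0] * 1)
        assert a[4] == pytest.approx(rt.d_m[0] * 5)
        assert a[6] == pytest.approx(rt.d_p[0] * 10)

    def test_doubling_volume_halves_scaled_channels(self):
        net = make_single_gene_network(b_obs=0.1)
        c1 = make_cell(net, frozen_cycle_params(), V=net.Vref, mrna=8, protein=20,
                       pr_on=1, pr_off=1)
        c2 = make_cell(net, frozen_cycle_params(), V=2 * net.Vref, mrna=8, protein=20,
                       pr_on=1, pr_off=1)
        a1 = compute_propensities(c1, net, 0.0)
        a2 = compute_propensities(c2, net, 0.0)
        for ch in (2, 3, 4, 5, 6):  # transcription, decay, translation
            assert a2[ch] == pytest.approx(a1[ch] / 2)
        for ch in (0, 1):           # promoter switching is volume-independent
            assert a2[ch] == pytest.approx(a1[ch])

    def test_conventional_decay_scaling_flag(self):
        net = make_single_gene_network()
        cell = make_cell(net, frozen_cycle_params(), V=2 * net.Vref, mrna=10)
        a_scaled = compute_propensities(cell, net, 0.0, options=SimOptions())
        a_conv = compute_propensities(
            cell, net, 0.0, options=SimOptions(scale_first_order="conventional")
        )
        assert a_conv[4] == pytest.approx(2 * a_scaled[4])  # no Vref/V on decay


class TestStep:
    def test_step_advances_time_and_state(self, rng):
        net = make_single_gene_network(F=1.0)
        cell = make_cell(net, frozen_cycle_params())
        counts0 = (cell.mrna.copy(), cell.protein.copy(), cell.pr_on.copy())
        _, elapsed, fired = step(cell, net, 0.0, rng)
        assert elapsed > 0
        assert cell.t == pytest.approx(elapsed)
        changed = (
            not np.array_equal(cell.mrna, counts0[0])
            or not np.array_equal(cell.protein, counts0[1])
            or not np.array_equal(cell.pr_on, counts0[2])
            or fired == CHANNELS_PER_GENE * net.n_genes  # volume channel
        )
        assert changed or isinstance(fired, str)

    def test_step_processes_scheduled_boundary(self, rng, base_params):
        net = make_single_gene_network(F=1.0, rm_obs=1e-6, r_p=0.0, r_act_max=1e-9)
        cell = make_cell(net, base_params, V=35.0, pr_on=0, pr_off=1)
        # T1 = T1min = 30 min; with negligible chemistry the first events
        # are the scheduled boundaries
        seen = []
        for _ in range(5000):
            _, _, fired = step(cell, net, 0.0, rng)
            if isinstance(fired, str):
                seen.append(fired)
                break
        assert seen == ["START_REACHED"]
        assert cell.position.block == "T2"
        assert cell.t == pytest.approx(cell.position.T1)


class TestStationaryMoments:
    def test_telegraph_and_birth_death_closed_forms(self, rng):
        """Fixed volume, F=1: ON fraction f, <R>=rm*phi*n/dm, <P>=rp<R>/dp."""
        net = make_single_gene_network(
            F=1.0, r_act_max=0.2, f_active=0.5, rm_obs=1.0, b_obs=0.0,
            r_p=0.5, d_m=0.1, d_p=0.02,
        )
        rt = net.rate_table()
        cell = make_cell(net, frozen_cycle_params(), pr_on=1, pr_off=0)
        mrna, protein, on = _stationary_run(net, cell, rng, 60_000, 30.0)
        f_exp = 0.5
        m_exp = rt.rm_true[0] * f_exp / 0.1
        p_exp = 0.5 * m_exp / 0.02
        assert abs(on.mean() - f_exp) < 3 * _batch_se(on)
        assert abs(mrna.mean() - m_exp) < 3 * _batch_se(mrna)
        assert abs(protein.mean() - p_exp) < 3 * _batch_se(protein)

    def test_count_distribution_invariant_in_growing_cell(self, rng):
        """The common Vref/V factor on synthesis and decay only stretches the
        timescale: the stationary mRNA count in a growing non-dividing cell
        stays at the fixed-volume prediction while volume increases 10-fold."""
        from budsim.cell_cycle import CellCycleParams

        params = CellCycleParams(
            Vi=30.0, r1=0.3, r2=0.3, r2m=0.3, T1min=1e9, T2=1e9, T3=1e9,
            k=0.0, b=20.0, c_inherit=0.25,
        )
        net = make_single_gene_network(F=1.0, f_active=1.0, rm_obs=2.0, b_obs=0.0,
                                       r_p=0.0, d_m=0.1, d_p=0.02)
        rates = effective_rates(net.rate_table(), np.ones(5))
        cell_means = []
        for i in range(10):
            cell = make_cell(net, params, V=30.0, pr_on=1, pr_off=0,
                             mrna=20, cell_id=i)
            counts = []
            t_end = 0.0
            for _ in range(100):
                t_end += 10.0
                advance_cell(cell, net, 0.0, t_end, rng, rates=rates)
                counts.append(cell.mrna[0])
            assert cell.V > 300.0  # the cell really grew ~10x
            cell_means.append(np.mean(counts[20:]))
        fixed_volume_prediction = 2.0 / 0.1
        assert np.mean(cell_means) == pytest.approx(fixed_volume_prediction, rel=0.05)

    def test_volume_trajectory_tracks_deterministic(self, rng, base_params):
        """Poisson volume increments stay within 2% RMS of the linear ramp."""
        net = make_single_gene_network(F=0.0, b_obs=0.0, r_act_max=1e-9)
        rel_dev = []
        for i in range(100):
            cell = make_cell(net, base_params, V=22.5, pr_on=0, pr_off=1, cell_id=i)
            res = advance_cell(cell, net, 0.0, 1000.0, rng)
            assert res == DIVISION
            v_det = 22.5 + base_params.r1 * (cell.position.T1 + base_params.T2) \
                + base_params.r2 * base_params.T3
            rel_dev.append((cell.V - v_det) / v_det)
        rms = float(np.sqrt(np.mean(np.square(rel_dev))))
        assert rms < 0.02


class TestReplication:
    def test_active_promoters_stay_active(self):
        net = make_single_gene_network()
        cell = make_cell(net, frozen_cycle_params(), pr_on=1, pr_off=0)
        replicate_promoters(cell)
        assert cell.pr_on[0] == 2 and cell.pr_off[0] == 0

    def test_inactive_promoters_stay_inactive(self):
        net = make_single_gene_network()
        cell = make_cell(net, frozen_cycle_params(), pr_on=0, pr_off=1)
        replicate_promoters(cell)
        assert cell.pr_on[0] == 0 and cell.pr_off[0] == 2

    def test_double_replication_rejected(self):
        net = make_single_gene_network()
        cell = make_cell(net, frozen_cycle_params(), pr_on=1, pr_off=0)
        replicate_promoters(cell)
        with pytest.raises(ValueError, match="already replicated"):
            replicate_promoters(cell)


class TestPartition:
    def test_species_conservation_over_many_divisions(self, rng, base_params):
        net = make_single_gene_network()
        for i in range(1000):
            mrna = int(rng.integers(0, 50))
            protein = int(rng.integers(0, 2000))
            cell = make_cell(net, base_params, V=60.0, pr_on=1, pr_off=0,
                             mrna=mrna, protein=protein, cell_id=i)
            replicate_promoters(cell)
            mother, daughter = partition_at_division(cell, 40.0, 20.0, rng)
            assert mother.mrna[0] + daughter.mrna[0] == mrna
            assert mother.protein[0] + daughter.protein[0] == protein
            assert mother.pr_on[0] + mother.pr_off[0] == 1
            assert daughter.pr_on[0] + daughter.pr_off[0] == 1
            assert mother.V + daughter.V == pytest.approx(60.0)

    def test_binomial_partition_moments(self, rng, base_params):
        net = make_single_gene_network()
        daughters = []
        for i in range(100):
            cell = make_cell(net, base_params, V=60.0, pr_on=1, pr_off=0,
                             mrna=0, protein=10_000, cell_id=i)
            replicate_promoters(cell)
            _, d = partition_at_division(cell, 30.0, 30.0, rng)
            daughters.append(d.protein[0])
        se = 50.0 / np.sqrt(100)  # sd of Binomial(1e4, .5) is 50
        assert abs(np.mean(daughters) - 5000.0) < 3 * se

    def test_zero_counts_partition_to_zero(self, rng, base_params):
        net = make_single_gene_network()
        cell = make_cell(net, base_params, V=60.0, pr_on=1, pr_off=0)
        replicate_promoters(cell)
        mother, daughter = partition_at_division(cell, 40.0, 20.0, rng)
        assert mother.mrna[0] == daughter.mrna[0] == 0

    def test_volume_mismatch_rejected(self, rng, base_params):
        net = make_single_gene_network()
        cell = make_cell(net, base_params, V=60.0)
        with pytest.raises(ValueError, match="pre-division volume"):
            partition_at_division(cell, 30.0, 20.0, rng)

    def test_lineage_fields(self, rng, base_params):
        net = make_single_gene_network()
        cell = make_cell(net, base_params, V=60.0, pr_on=1, pr_off=0, cell_id=7)
        cell.t = 123.0
        cell.generation = 2
        replicate_promoters(cell)
        mother, daughter = partition_at_division(cell, 40.0, 20.0, rng, daughter_id=99)
        assert mother.generation == 3
        assert daughter.generation == 0
        assert daughter.parent_id == 7
        assert daughter.cell_id == 99
        assert daughter.birth_time == 123.0
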