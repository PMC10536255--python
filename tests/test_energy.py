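"""Energy estimator: counting identities, formula checks, and machine-precision
agreement with a per-event enumeration simulator."""

import numpy as np
import pytest

import spikehar as sh
from spikehar.arch import Conv1D, Dense
from spikehar.energy import EnergyTable, LayerStats

from oracles import enumerate_energy_conv1d, enumerate_energy_dense


class TestSparsity:
    @pytest.mark.parametrize("arr,expected", [
        (np.zeros((2, 3, 2)), 1.0),
        (np.ones((2, 3, 2)), 0.0),
        (np.array([1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0], float), 0.75),
    ])
    def test_zero_fraction(self, arr, expected):
        assert sh.measure_sparsity(arr) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sh.measure_sparsity(np.empty(0))


class TestLayerStats:
    def test_dense_counting_example(self):
        """Input [1,0,1] into 4 units: 2 nonzeros, 4 connections each."""
        rng = np.random.default_rng(0)
        net = sh.Network(
            spec=sh.build_spike_cnn(3, 4),  # spec irrelevant to counting here
            layers=[Dense(3, 4, rng)],
        )
        x = np.array([[[1.0, 0.0, 1.0]]], np.float32)  # (N=1, T=1, D=3)
        stats = sh.collect_layer_stats(net, x)
        s = stats[0]
        assert s.input_nonzeros == 2 and s.input_total == 3
        assert s.macs_per_nonzero == 4.0
        assert s.macs_nonzero == 8 and s.macs_total == 12

    def test_lif_updates_and_spiking_flags(self, tiny_dataset):
        """SNN: every weighted layer fed by an LIF is flagged spiking and the
        LIF following each layer contributes neurons x time x batch updates;
        ANN twin: no LIF updates, nonzero reals counted."""
        X = tiny_dataset.windows[:8]
        snn = sh.build_network(sh.build_spike_cnn(3, 3), input_T=tiny_dataset.T,
                               rng=np.random.default_rng(0))
        stats = sh.collect_layer_stats(snn, X)
        assert [s.is_spiking for s in stats] == [False, True, True, True]
        # conv outputs have (batch, width, T) LIF updates at full time length
        assert stats[0].lif_updates == 8 * 32 * 64
        assert stats[1].lif_updates == 8 * 64 * 32
        assert stats[2].lif_updates == 8 * 64 * 16
        assert stats[3].lif_updates == 0  # readout head has no LIF

        ann = sh.build_network(sh.build_cnn(3, 3), input_T=tiny_dataset.T,
                               rng=np.random.default_rng(0))
        astats = sh.collect_layer_stats(ann, X)
        assert all(s.lif_updates == 0 for s in astats)
        assert all(not s.is_spiking for s in astats)
        assert 0 < astats[1].input_nonzeros <= astats[1].input_total

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            LayerStats(name="x", is_spiking=True, input_nonzeros=-1,
                       input_total=1, macs_nonzero=0, macs_total=0)


class TestEstimate:
    def test_all_zero_spike_layer_is_pure_lif_cost(self):
        """No spikes: the MAC term vanishes and compute = lif_updates * 0.383."""
        s = LayerStats(name="conv", is_spiking=True, input_nonzeros=0,
                       input_total=1000, macs_nonzero=0, macs_total=8000,
                       lif_updates=500, weight_count=100)
        rep = sh.estimate_energy([s])
        assert rep.compute_total == pytest.approx(500 * 0.383)

    def test_snn_equals_ann_plus_lif_overhead_at_zero_sparsity(self):
        """Identical dense-activity stats: SNN total = ANN total + LIF updates
        x 0.383 (term-by-term, the only differing term)."""
        kw = dict(name="d", input_nonzeros=4000, input_total=4000,
                  macs_nonzero=64000, macs_total=64000, weight_count=16,
                  lif_updates=2000)
        snn = sh.estimate_energy([LayerStats(is_spiking=True, **kw)])
        kw["lif_updates"] = 0
        ann = sh.estimate_energy([LayerStats(is_spiking=False, **kw)])
        assert snn.total == pytest.approx(ann.total + 2000 * 0.383)

    def test_higher_sparsity_strictly_cheaper(self):
        def stats(nnz):
            return [LayerStats(name="c", is_spiking=True, input_nonzeros=nnz,
                               input_total=1000, macs_nonzero=nnz * 8,
                               macs_total=8000, lif_updates=100, weight_count=10)]
        totals = [sh.estimate_energy(stats(nnz)).total for nnz in (900, 500, 100)]
        assert totals[0] > totals[1] > totals[2]

    def test_unit_normalization(self):
        """table=(1,0,0,0,0) at full density: ANN compute energy = MAC count."""
        t = EnergyTable(e_mac=1.0, e_spa=0.0, e_lif=0.0, e_ispad=0.0, e_wspad=0.0)
        s = LayerStats(name="d", is_spiking=False, input_nonzeros=700,
                       input_total=700, macs_nonzero=700 * 5, macs_total=700 * 5,
                       weight_count=5)
        rep = sh.estimate_energy([s], t)
        assert rep.compute_total == 3500.0 and rep.total == 3500.0

    def test_empty_stats_rejected(self):
        with pytest.raises(ValueError):
            sh.estimate_energy([])

    def test_table_default_values(self):
        t = EnergyTable()
        assert (t.e_mac, t.e_spa, t.e_lif, t.e_ispad, t.e_wspad) == \
               (0.175, 0.0, 0.383, 0.107, 1.712)


class TestEnumerationOracle:
    """estimate_energy must match a naive per-event loop to machine precision
    on small networks (a few hundred connections)."""

    @pytest.mark.parametrize("spiking", [True, False])
    def test_conv_dense_network(self, spiking):
        rng = np.random.default_rng(17)
        T, D = 12, 2
        conv = Conv1D(D, 3, kernel=5, rng=rng)
        dense = Dense(3, 4, rng)
        if spiking:
            x = (rng.random((4, D, T)) < 0.4).astype(np.float32)
        else:
            x = rng.normal(0, 1, (4, D, T)).astype(np.float32)
        mid = conv.forward(x)
        spikes = (mid > 0.5).astype(np.float32)
        head_in = spikes if spiking else mid

        net = sh.Network(spec=sh.build_spike_cnn(D, 4), layers=[conv, dense])
        # build stats by hand from the exact same tensors the oracle sees
        table = EnergyTable()
        lif_updates = spikes.size if spiking else 0
        stats = []
        for layer, inp, lif_u in ((conv, x, lif_updates), (dense, head_in, 0)):
            rec_net = sh.Network(spec=net.spec, layers=[layer])
            s = sh.collect_layer_stats(rec_net, inp.transpose(0, 2, 1))[0]
            stats.append(LayerStats(
                name=s.name, is_spiking=spiking and layer is dense,
                input_nonzeros=s.input_nonzeros, input_total=s.input_total,
                macs_nonzero=s.macs_nonzero, macs_total=s.macs_total,
                lif_updates=lif_u if layer is conv else 0,
                weight_count=s.weight_count))
        rep = sh.estimate_energy(stats, table)

        c1, m1 = enumerate_energy_conv1d(
            x, out_ch=3, kernel=5, pad_left=conv.pad_left,
            weight_count=conv.W.value.size + conv.b.value.size,
            table=table, skipping=False, lif_updates=lif_updates)
        c2, m2 = enumerate_energy_dense(
            head_in, out_dim=4, weight_count=dense.W.value.size + dense.b.value.size,
            table=table, skipping=spiking)
        assert rep.compute_total == pytest.approx(c1 + c2, rel=1e-12)
        assert rep.move_total == pytest.approx(m1 + m2, rel=1e-12)

    def test_skipping_conv_matches_oracle(self):
        """Spike input into a conv with skipping: boundary taps counted exactly."""
        rng = np.random.default_rng(23)
        conv = Conv1D(2, 3, kernel=5, rng=rng)
        x = (rng.random((2, 2, 9)) < 0.5).astype(np.float32)
        table = EnergyTable()
        net = sh.Network(spec=sh.build_spike_cnn(2, 3), layers=[conv])
        s = sh.collect_layer_stats(net, x.transpose(0, 2, 1))[0]
        s2 = LayerStats(name=s.name, is_spiking=True,
                        input_nonzeros=s.input_nonzeros, input_total=s.input_total,
                        macs_nonzero=s.macs_nonzero, macs_total=s.macs_total,
                        lif_updates=0, weight_count=s.weight_count)
        rep = sh.estimate_energy([s2], table)
        c, m = enumerate_energy_conv1d(x, 3, 5, conv.pad_left,
                                       conv.W.value.size + conv.b.value.size,
                                       table, skipping=True)
        assert rep.compute_total == pytest.approx(c, rel=1e-12)
        assert rep.move_total == pytest.approx(m, rel=1e-12)


class TestCompare:
    def _rep(self, total):
        s = LayerStats(name="d", is_spiking=False, input_nonzeros=1,
                       input_total=1, macs_nonzero=1, macs_total=1)
        rep = sh.estimate_energy([s])
        rep.total = total
        return rep

    def test_equal_totals_zero_reduction(self):
        assert sh.compare_models(self._rep(10.0), self._rep(10.0)) == 0.0

    def test_94_percent(self):
        assert sh.compare_models(self._rep(0.06), self._rep(1.0)) == pytest.approx(94.0)

    def test_negative_when_snn_costlier(self):
        assert sh.compare_models(self._rep(2.0), self._rep(1.0)) == pytest.approx(-100.0)

    def test_unit_mismatch_rejected(self):
        a, b = self._rep(1.0), self._rep(1.0)
        b.unit = "joules"
        with pytest.raises(ValueError, match="unit"):
            sh.compare_models(a, b)
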