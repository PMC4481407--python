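import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telofuse import (
    BiasModel,
    CountTable,
    FusionEvent,
    Metaphase,
    SimulationError,
    count_fused_telomeres,
    derive_structures,
    simulate_experiment,
    simulate_metaphase,
)


def telo(karyotype, arm_label, homolog=1):
    return next(
        t
        for t in karyotype.telomeres
        if t.arm_label == arm_label and t.homolog == homolog
    )


class TestBiasModel:
    def test_defaults_valid(self):
        b = BiasModel()
        assert b.het_weight == 1.0 and 0 <= b.p_g1 <= 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"het_weight": 0.0},
            {"het_weight": -2.0},
            {"p_g1": 1.5},
            {"events_per_cell_mean": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            BiasModel(**kwargs)


class TestFusionEvent:
    def test_distinct_ends_required(self, male):
        t = telo(male, "XL")
        with pytest.raises(SimulationError):
            FusionEvent(t, t)

    def test_canonical_end_order(self, male):
        a, b = telo(male, "2L"), telo(male, "XR")
        assert FusionEvent(a, b) == FusionEvent(b, a)

    def test_y_ring_flags(self, male):
        ring = FusionEvent(telo(male, "YL"), telo(male, "YS"))
        assert ring.is_ring and ring.is_y_ring and ring.involves_y
        mixed = FusionEvent(telo(male, "YL"), telo(male, "XR"))
        assert mixed.involves_y and not mixed.is_ring


class TestSimulateMetaphase:
    def test_zero_events_gives_eight_singletons(self, male):
        mp = simulate_metaphase(male, BiasModel(), 0, seed=0)
        assert mp.events == ()
        assert len(mp.structures) == 8
        assert all(s.kind == "chain" and len(s) == 1 for s in mp.structures)

    def test_saturation_consumes_all_telomeres(self, male):
        mp = simulate_metaphase(male, BiasModel(), 8, seed=1)
        used = [t for ev in mp.events for t in ev.ends]
        assert len(used) == 16 and len(set(used)) == 16
        n_events = sum(
            len(s) - 1 if s.kind == "chain" else len(s) for s in mp.structures
        )
        assert n_events == 8

    def test_too_many_events_rejected(self, male):
        with pytest.raises(SimulationError):
            simulate_metaphase(male, BiasModel(), 9, seed=0)
        with pytest.raises(SimulationError):
            simulate_metaphase(male, BiasModel(), -1, seed=0)

    def test_seed_determinism(self, male):
        a = simulate_metaphase(male, BiasModel(het_weight=3.0), 4, seed=99)
        b = simulate_metaphase(male, BiasModel(het_weight=3.0), 4, seed=99)
        assert a.events == b.events

    @given(seed=st.integers(0, 10_000), n_events=st.integers(0, 8))
    @settings(max_examples=25, deadline=None)
    def test_structure_accounting_invariant(self, male, seed, n_events):
        mp = simulate_metaphase(male, BiasModel(het_weight=2.0), n_events, seed=seed)
        chains = [s for s in mp.structures if s.kind == "chain"]
        rings = [s for s in mp.structures if s.kind == "ring"]
        assert sum(len(s) - 1 for s in chains) + sum(len(s) for s in rings) == n_events
        # every chromosome in exactly one structure
        members = [m for s in mp.structures for m in s.members]
        assert sorted(members) == sorted(
            {(t.chromosome, t.homolog) for t in male.telomeres}
        )


class TestDeriveStructures:
    def test_y_ring_topology(self, male):
        events = [FusionEvent(telo(male, "YL"), telo(male, "YS"))]
        structures = derive_structures(events, male)
        rings = [s for s in structures if s.kind == "ring"]
        assert len(rings) == 1 and rings[0].labels == ("Y",)
        assert sum(1 for s in structures if s.kind == "chain" and len(s) == 1) == 7

    def test_ring_autosome(self, female):
        events = [FusionEvent(telo(female, "2L", 1), telo(female, "2R", 1))]
        structures = derive_structures(events, female)
        rings = [s for s in structures if s.kind == "ring"]
        assert len(rings) == 1 and rings[0].members == (("2", 1),)

    def test_tricentric_4_y_x(self, male):
        events = [
            FusionEvent(telo(male, "4R"), telo(male, "YS")),
            FusionEvent(telo(male, "YL"), telo(male, "XR")),
        ]
        structures = derive_structures(events, male)
        chains = [s for s in structures if len(s) > 1]
        assert len(chains) == 1
        assert chains[0].kind == "chain" and chains[0].labels == ("4", "Y", "X")

    def test_four_autosome_chain(self, female):
        events = [
            FusionEvent(telo(female, "2R", 1), telo(female, "2L", 2)),
            FusionEvent(telo(female, "2R", 2), telo(female, "3L", 1)),
            FusionEvent(telo(female, "3R", 1), telo(female, "3L", 2)),
        ]
        structures = derive_structures(events, female)
        chains = [s for s in structures if len(s) > 1]
        assert len(chains) == 1 and len(chains[0]) == 4
        assert chains[0].labels == ("2", "2", "3", "3")

    def test_two_chromosome_ring(self, female):
        events = [
            FusionEvent(telo(female, "2L", 1), telo(female, "2L", 2)),
            FusionEvent(telo(female, "2R", 1), telo(female, "2R", 2)),
        ]
        structures = derive_structures(events, female)
        rings = [s for s in structures if s.kind == "ring"]
        assert len(rings) == 1 and rings[0].members == (("2", 1), ("2", 2))

    def test_telomere_reuse_rejected(self, male):
        xr = telo(male, "XR")
        events = [
            FusionEvent(xr, telo(male, "YL")),
            FusionEvent(xr, telo(male, "YS")),
        ]
        with pytest.raises(SimulationError):
            derive_structures(events, male)

    def test_canonical_ordering_is_deterministic(self, male):
        events = [
            FusionEvent(telo(male, "4R"), telo(male, "YS")),
            FusionEvent(telo(male, "YL"), telo(male, "XR")),
        ]
        assert derive_structures(events, male) == derive_structures(
            list(reversed(events)), male
        )


class TestCountFusedTelomeres:
    def test_single_event_counts(self, male):
        mp = Metaphase(male, (FusionEvent(telo(male, "XR"), telo(male, "4L")),))
        table = count_fused_telomeres([mp])
        assert table.ft_counts == {"A": 0, "XL": 0, "XR": 1, "Fourth": 1, "Y": 0}
        assert table.n_tfs == 1 and table.n_cells == 1

    def test_fig1_a4_configuration(self, female):
        events = (
            FusionEvent(telo(female, "XR", 1), telo(female, "4L", 1)),
            FusionEvent(telo(female, "2R", 1), telo(female, "2L", 2)),
            FusionEvent(telo(female, "2R", 2), telo(female, "3L", 1)),
            FusionEvent(telo(female, "3R", 1), telo(female, "3L", 2)),
        )
        table = count_fused_telomeres([Metaphase(female, events)])
        assert table.ft_counts == {"A": 6, "XL": 0, "XR": 1, "Fourth": 1}
        assert table.n_tfs == 4

    def test_empty_metaphases(self, male):
        table = count_fused_telomeres([Metaphase(male, ())] * 5)
        assert table.n_cells == 5 and table.n_tfs == 0
        assert all(v == 0 for v in table.ft_counts.values())

    def test_empty_list_rejected(self):
        with pytest.raises(SimulationError):
            count_fused_telomeres([])

    def test_sta_dta_and_y_tallies(self, male):
        events = (
            FusionEvent(telo(male, "YL"), telo(male, "YS"), "DTA"),
            FusionEvent(telo(male, "2L", 1), telo(male, "3L", 1), "STA"),
        )
        table = count_fused_telomeres([Metaphase(male, events)])
        assert table.sta_count == 1 and table.dta_count == 1
        assert table.y_fusion_count == 1 and table.y_ring_count == 1


class TestCountTableInvariants:
    def test_conservation_enforced(self):
        with pytest.raises(SimulationError):
            CountTable(
                ft_counts={"A": 3},
                n_cells=1,
                n_tfs=1,
                sta_count=0,
                dta_count=1,
                y_fusion_count=0,
                y_ring_count=0,
            )

    def test_ring_bound_enforced(self):
        with pytest.raises(SimulationError):
            CountTable(
                ft_counts={"Y": 2},
                n_cells=1,
                n_tfs=1,
                sta_count=0,
                dta_count=1,
                y_fusion_count=0,
                y_ring_count=1,
            )

    def test_negative_count_rejected(self):
        with pytest.raises(SimulationError):
            CountTable(
                ft_counts={"A": -2},
                n_cells=1,
                n_tfs=-1,
                sta_count=0,
                dta_count=-1,
                y_fusion_count=0,
                y_ring_count=0,
            )


class TestSimulateExperiment:
    def test_seed_determinism(self, male):
        bias = BiasModel(het_weight=2.0)
        assert simulate_experiment(male, bias, 500, seed=5) == simulate_experiment(
            male, bias, 500, seed=5
        )

    def test_different_seeds_differ(self, male):
        bias = BiasModel()
        assert simulate_experiment(male, bias, 500, seed=1) != simulate_experiment(
            male, bias, 500, seed=2
        )

    def test_conservation(self, male):
        table = simulate_experiment(male, BiasModel(), 300, seed=3)
        assert sum(table.ft_counts.values()) == 2 * table.n_tfs
        assert table.sta_count + table.dta_count == table.n_tfs

    def test_extreme_weight_saturates_het(self, male):
        # within het capacity (7 termini -> 3 het-het events) no Eu fusions
        for seed in range(20):
            mp = simulate_metaphase(male, BiasModel(het_weight=1e9), 3, seed=seed)
            assert all(t.het_associated for ev in mp.events for t in ev.ends)
        # in aggregate the Het FT fraction approaches 1
        table = simulate_experiment(
            male, BiasModel(het_weight=1e9, events_per_cell_mean=1.0), 500, seed=4
        )
        het = sum(table.ft_counts[c] for c in ("XR", "Fourth", "Y"))
        assert het / table.total_fts > 0.95

    def test_p_g1_extremes(self, male):
        all_dta = simulate_experiment(male, BiasModel(p_g1=1.0), 200, seed=6)
        assert all_dta.sta_count == 0
        all_sta = simulate_experiment(male, BiasModel(p_g1=0.0), 200, seed=6)
        assert all_sta.dta_count == 0

    def test_invalid_cells_rejected(self, male):
        with pytest.raises(SimulationError):
            simulate_experiment(male, BiasModel(), 0, seed=0)

    def test_marked_y_reduces_y_involvement(self, male, marked_y):
        bias = BiasModel(het_weight=5.0)
        wt = simulate_experiment(male, bias, 3000, seed=8)
        mk = simulate_experiment(marked_y, bias, 3000, seed=8)
        assert mk.y_fusion_count < wt.y_fusion_count
        assert mk.y_ring_count < wt.y_ring_count
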