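"""GRN dynamics: bootstrap, signaling, expression, translation, decay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wgdsim.genome import GeneKind, SignalingEquation, as_genome, scan_genes
from wgdsim.grn import (
    CompiledGRN,
    GRNState,
    apply_signaling,
    bootstrap_tfs,
    cis_lookup,
    draw_decay_rates,
    evaluate_signaling,
    expression_level,
    polymerase_identities,
    sensor_vector,
    step_grn,
)

from conftest import (
    CIS,
    W_POLYMERASE,
    W_REGULATORY,
    W_REPL_PLUS,
    W_SIGNALING,
    make_gene,
    make_signaling_payload,
)


def genes_of(s: str):
    return scan_genes(as_genome(s))


def reg_gene(target="2231", sign="0", ident_tail=""):
    return make_gene(W_REGULATORY, payload=target + sign + ident_tail)


class TestBootstrap:
    def test_first_twelve_regulatory_activated(self):
        # 20 regulatory genes with distinct payloads -> distinct identities
        targets = [f"2{x}{y}2" for x in range(4) for y in range(4)] + [
            f"3{x}32" for x in range(4)
        ]
        parts = [reg_gene(target=t, sign="1") for t in targets]
        genes = genes_of("".join(parts))
        assert len(genes) == 20
        conc = bootstrap_tfs(genes, value=10.0)
        assert len(conc) == 12
        assert set(conc) == {g.identity for g in genes[:12]}
        assert all(v == 10.0 for v in conc.values())

    def test_no_regulatory_genes_empty_table(self):
        genes = genes_of(make_gene(W_REPL_PLUS))
        assert bootstrap_tfs(genes) == {}

    def test_deterministic(self):
        genes = genes_of(reg_gene() + reg_gene(target="3333"))
        assert bootstrap_tfs(genes) == bootstrap_tfs(genes)


class TestSignaling:
    def test_hand_arithmetic_example(self):
        eq = SignalingEquation(((0, 5), (1, 2), (0, 1)))
        assert evaluate_signaling([eq], [2, 3, 0]) == [18]

    def test_zero_weights_give_identity_zero(self):
        eq = SignalingEquation(((0, 0), (1, 0), (2, 0)))
        assert evaluate_signaling([eq], [9, 9, 9]) == [0]

    def test_output_reduced_mod_1000(self):
        eq = SignalingEquation(((0, 1023), (0, 0), (0, 0)))
        assert evaluate_signaling([eq], [1, 0, 0]) == [23]

    def test_address_wraps_modulo_sensor_count(self):
        eq = SignalingEquation(((3, 1), (3, 0), (3, 0)))
        assert evaluate_signaling([eq], [7, 0, 0]) == [7]  # 3 % 3 == 0

    def test_increment_only_encoded_identities(self):
        conc = apply_signaling({}, [18, 42], encoded={18})
        assert conc == {18: 1.0}

    def test_repeated_identity_accumulates(self):
        conc = apply_signaling({18: 1.0}, [18, 18], encoded={18})
        assert conc == {18: 3.0}


class TestExpressionLevel:
    def _toy(self):
        # regulatory activator binding 2231; repressor binding 3333;
        # polymerase; one structural gene whose promoter carries both words
        s = (
            reg_gene(target="2231", sign="0")
            + reg_gene(target="3333", sign="1")
            + make_gene(W_POLYMERASE, payload="10100")
            + make_gene(W_REPL_PLUS, cis=["2231", "3333", "2222", "1111", "3210"])
        )
        genes = genes_of(s)
        assert [g.kind for g in genes] == [
            GeneKind.REGULATORY_ACTIVATOR,
            GeneKind.REGULATORY_REPRESSOR,
            GeneKind.POLYMERASE,
            GeneKind.STRUCT_REPL_PLUS,
        ]
        return genes

    def test_single_activator_term(self):
        genes = self._toy()
        act, rep, poly, target = genes
        conc = {act.identity: 5.0, poly.identity: 1.0}
        lvl = expression_level(
            target, conc, cis_lookup(genes), polymerase_identities(genes)
        )
        assert lvl == 5.0

    def test_polymerase_gating(self):
        genes = self._toy()
        act, rep, poly, target = genes
        conc = {act.identity: 5.0}  # no polymerase product
        assert (
            expression_level(
                target, conc, cis_lookup(genes), polymerase_identities(genes)
            )
            == 0.0
        )

    def test_signed_sum_with_repressor(self):
        genes = self._toy()
        act, rep, poly, target = genes
        conc = {act.identity: 5.0, rep.identity: 7.0, poly.identity: 1.0}
        lvl = expression_level(
            target, conc, cis_lookup(genes), polymerase_identities(genes)
        )
        assert lvl == -2.0

    def test_repeated_cis_counts_with_multiplicity(self):
        genes = genes_of(
            reg_gene(target="2231", sign="0")
            + make_gene(W_POLYMERASE, payload="10100")
            + make_gene(W_REPL_PLUS, cis=["2231", "2231", "2222", "1111", "3210"])
        )
        act = genes[0]
        poly = genes[1]
        conc = {act.identity: 4.0, poly.identity: 1.0}
        lvl = expression_level(
            genes[2], conc, cis_lookup(genes), polymerase_identities(genes)
        )
        assert lvl == 8.0


class TestStepGrn:
    def test_pure_decay_on_empty_genome(self):
        decay = np.zeros(1000)
        decay[7] = 0.1
        state = GRNState(concentrations={7: 10.0})
        out = step_grn([], state, sensor_vector(0, 0, 0), decay)
        assert out.concentrations == {7: 9.0}
        assert out.step == 1

    def test_below_threshold_only_decays(self):
        genes = genes_of(
            reg_gene(target="2231", sign="0")
            + make_gene(W_POLYMERASE, payload="10100")
            + make_gene(W_REPL_PLUS, cis=["2231", "2222", "1111", "3210", "2323"])
        )
        act, poly, target = genes
        decay = np.full(1000, 0.5)
        conc = {act.identity: 0.5, poly.identity: 2.0}  # level 0.25 < 1
        out = step_grn(genes, GRNState(concentrations=conc), sensor_vector(0, 0, 0), decay)
        assert out.concentrations[act.identity] == pytest.approx(0.25)
        assert target.identity not in out.concentrations or (
            out.concentrations[target.identity] == 0.0
        )

    def _fixed_point_genes(self):
        # activator A (decay 0) holds level L constant for gene G; the
        # polymerase product P (decay 0) keeps the gate open.
        neutral = ["2222", "1111", "3210", "2323", "1331"]
        s = (
            "1010" + "".join(neutral) + W_REGULATORY + "22310"  # A
            + "1010" + "".join(neutral) + W_POLYMERASE + "10100"  # P
            + make_gene(W_REPL_PLUS, cis=["2231", "2222", "1111", "3210", "2323"],
                        payload="30000")  # G
        )
        genes = genes_of(s)
        assert len(genes) == 3
        return genes

    def test_fixed_point_L_over_d(self):
        genes = self._fixed_point_genes()
        a, p, g = genes
        L, d = 2.0, 0.2
        decay = np.zeros(1000)
        decay[g.identity] = d
        state = GRNState(concentrations={a.identity: L, p.identity: 1.0})
        for _ in range(500):
            state = step_grn(genes, state, sensor_vector(0, 0, 0), decay)
        assert state.concentrations[g.identity] == pytest.approx(L / d, abs=1e-6)

    def test_concentrations_capped(self):
        genes = self._fixed_point_genes()
        a, p, g = genes
        decay = np.zeros(1000)
        decay[g.identity] = 0.01
        state = GRNState(concentrations={a.identity: 50.0, p.identity: 1.0})
        for _ in range(100):
            state = step_grn(genes, state, sensor_vector(0, 0, 0), decay, cap=100.0)
            assert all(0.0 <= v <= 100.0 for v in state.concentrations.values())
        assert state.concentrations[g.identity] == 100.0


class TestCompiledAgainstReference:
    """The vectorized GRN must match the dict-based reference step for step."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_equivalence_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        from wgdsim.genome import random_genome

        g = random_genome(6000, rng)
        genes = scan_genes(g)
        decay = draw_decay_rates(rng)
        compiled = CompiledGRN(genes, decay)
        compiled.bootstrap()
        state = GRNState(concentrations=compiled.concentrations())
        for step in range(5):
            sensors = sensor_vector(
                float(rng.integers(0, 30_000)),
                int(rng.integers(0, 10)),
                int(rng.integers(0, 10)),
            )
            compiled.step(sensors)
            state = step_grn(genes, state, sensors, decay)
            ref = {i: c for i, c in state.concentrations.items() if c != 0.0}
            assert compiled.concentrations() == pytest.approx(ref)

    def test_actuator_concentration_sums_kind_products(self):
        genes = genes_of(
            make_gene(W_REPL_PLUS, payload="00000")
            + make_gene(W_REPL_PLUS, payload="00001")
        )
        grn = CompiledGRN(genes, np.full(1000, 0.1))
        grn.conc[:] = [3.0, 4.0]
        assert grn.actuator_concentration(GeneKind.STRUCT_REPL_PLUS) == 7.0
        assert grn.actuator_concentration(GeneKind.STRUCT_REPL_MINUS) == 0.0


class TestInvariants:
    def test_decay_rates_in_range(self, rng):
        d = draw_decay_rates(rng, 0.05, 0.25)
        assert d.shape == (1000,)
        assert np.all((d >= 0.05) & (d <= 0.25))

    def test_decay_only_decline_is_monotone(self, rng):
        decay = draw_decay_rates(rng)
        state = GRNState(concentrations={5: 10.0, 900: 3.0})
        prev = dict(state.concentrations)
        for _ in range(20):
            state = step_grn([], state, sensor_vector(0, 0, 0), decay)
            for k, v in state.concentrations.items():
                assert v <= prev[k]
            prev = dict(state.concentrations)

    def test_sensor_vector_rejects_negative(self):
        with pytest.raises(ValueError):
            sensor_vector(-1.0, 0, 0)
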