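"""Genome alphabet, grammar parsing, and mutation operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wgdsim.genome import (
    GeneKind,
    GenomeGenerationError,
    apply_substitutions,
    as_genome,
    genome_to_str,
    identity_of,
    random_genome,
    random_viable_genome,
    read_genomes,
    scan_genes,
    whole_genome_duplicate,
    word_string,
    word_value,
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
from oracle import oracle_scan


class TestRandomGenome:
    def test_deterministic_given_seed(self):
        a = random_genome(8, np.random.default_rng(7))
        b = random_genome(8, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_digit_frequencies_uniform(self):
        g = random_genome(1_000_000, np.random.default_rng(0))
        freqs = np.bincount(g, minlength=4) / g.size
        # 3 binomial SE around 1/4
        se = np.sqrt(0.25 * 0.75 / g.size)
        assert np.all(np.abs(freqs - 0.25) < 3 * se)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            random_genome(0, np.random.default_rng(0))

    def test_typical_gene_density(self):
        counts = [
            len(scan_genes(random_genome(100_000, np.random.default_rng(s))))
            for s in range(10)
        ]
        # configured acceptance band bracketing the typical 150-200 genes
        assert 130 <= np.mean(counts) <= 230


class TestViableGenome:
    def test_empty_requirements_passthrough(self, rng):
        g = random_viable_genome(500, rng, requirements=set(), min_regulatory=0)
        g2 = random_genome(500, np.random.default_rng(12345))
        assert np.array_equal(g, g2)

    def test_default_requirements_satisfied(self, rng):
        g = random_viable_genome(50_000, rng, min_regulatory=5)
        kinds = {gene.kind for gene in scan_genes(g)}
        assert GeneKind.POLYMERASE in kinds
        assert GeneKind.SIGNALING in kinds
        assert GeneKind.STRUCT_REPL_PLUS in kinds
        assert GeneKind.STRUCT_MOVE_PLUS in kinds

    def test_impossible_requirement_fails(self, rng):
        with pytest.raises(GenomeGenerationError, match="polymerase"):
            random_viable_genome(10, rng, max_tries=5)


class TestGrammar:
    def test_single_regulatory_gene(self):
        g = make_gene(W_REGULATORY, payload="22310")  # target 2231, sign even
        genes = scan_genes(g)
        assert len(genes) == 1
        gene = genes[0]
        assert gene.kind is GeneKind.REGULATORY_ACTIVATOR
        assert word_string(gene.target_cis) == "2231"
        assert gene.sign == 1
        assert gene.span == (0, len(g))

    def test_repressor_sign_digit(self):
        genes = scan_genes(make_gene(W_REGULATORY, payload="22311"))
        assert genes[0].kind is GeneKind.REGULATORY_REPRESSOR
        assert genes[0].sign == -1

    def test_no_tata_no_genes(self):
        assert scan_genes("0" * 400) == []

    def test_cis_block_bounds(self):
        # 4 cis words: too few
        assert scan_genes(make_gene(W_REPL_PLUS, cis=CIS[:4])) == []
        # 5 is the minimum
        assert len(scan_genes(make_gene(W_REPL_PLUS, cis=CIS[:5]))) == 1
        # 50 is the maximum
        cis50 = (CIS * 8)[:50]
        assert len(scan_genes(make_gene(W_REPL_PLUS, cis=cis50))) == 1
        cis51 = (CIS * 8)[:51]
        assert scan_genes(make_gene(W_REPL_PLUS, cis=cis51)) == []

    def test_embedded_tata_aborts_parse(self):
        g = make_gene(W_REPL_PLUS, cis=[CIS[0], "1010", CIS[1], CIS[2], CIS[3]])
        assert scan_genes(g) == []

    def test_signaling_gene_elements(self):
        payload = make_signaling_payload([(0, 5), (1, 2), (0, 1)])
        genes = scan_genes(make_gene(W_SIGNALING, payload=payload))
        assert len(genes) == 1
        eq = genes[0].equation
        assert eq.elements == ((0, 5), (1, 2), (0, 1))

    def test_truncated_payload_fails(self):
        g = make_gene(W_REPL_PLUS, payload="000")  # needs 5 digits
        assert scan_genes(g) == []

    def test_scan_resumes_after_gene(self):
        g = make_gene(W_REGULATORY, payload="22310") + "00" + make_gene(
            W_POLYMERASE, payload="10100"
        )
        genes = scan_genes(g)
        assert [gene.kind for gene in genes] == [
            GeneKind.REGULATORY_ACTIVATOR,
            GeneKind.POLYMERASE,
        ]
        assert genes[1].motif == word_value("1010")

    def test_activator_fraction_near_half(self):
        g = random_genome(300_000, np.random.default_rng(3))
        reg = [x for x in scan_genes(g) if x.kind.value.startswith("regulatory")]
        frac = np.mean([x.kind is GeneKind.REGULATORY_ACTIVATOR for x in reg])
        se = np.sqrt(0.25 / len(reg))
        assert abs(frac - 0.5) < 4 * se


class TestOracleEquivalence:
    def _assert_matches(self, s: str):
        ours = scan_genes(s)
        ref = oracle_scan(s)
        assert len(ours) == len(ref)
        for a, b in zip(ours, ref):
            assert (a.start, a.end) == (b["start"], b["end"])
            assert a.kind.value == b["kind"]
            assert a.identity == b["identity"]
            assert [word_string(w) for w in a.cis_words] == b["cis"]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_oracle_on_random_genomes(self, seed):
        g = random_genome(2_000, np.random.default_rng(seed))
        self._assert_matches(genome_to_str(g))

    def test_matches_oracle_on_dense_handmade_string(self):
        parts = [
            make_gene(W_REGULATORY, payload="22310"),
            "10",  # partial TATA noise
            make_gene(W_SIGNALING, payload=make_signaling_payload([(2, -3)] * 4)),
            "1010",  # bare TATA, no gene
            make_gene(W_POLYMERASE, payload="10103"),
        ]
        self._assert_matches("".join(parts))


class TestIdentity:
    @pytest.mark.parametrize(
        "payload,expected",
        [("00000", 0), ("33333", 23), ("00001", 1), ("10000", 256)],
    )
    def test_base4_mod_1000(self, payload, expected):
        assert identity_of(payload) == expected

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            identity_of("0123")

    def test_identical_payload_prefix_identical_identity(self):
        assert identity_of("123130000") == identity_of("12313")


class TestSubstitutions:
    def test_rate_zero_is_identity(self, rng):
        g = random_genome(1000, rng)
        out, n = apply_substitutions(g, 0.0, rng)
        assert n == 0 and np.array_equal(out, g)

    def test_substituted_positions_differ(self, rng):
        g = random_genome(5000, rng)
        out, n = apply_substitutions(g, 0.05, rng)
        changed = np.flatnonzero(out != g)
        assert len(changed) == n > 0
        assert np.all(out[changed] != g[changed])
        assert np.all(out <= 3)

    def test_input_untouched(self, rng):
        g = random_genome(1000, rng)
        before = g.copy()
        apply_substitutions(g, 0.5, rng)
        assert np.array_equal(g, before)

    def test_mean_count_matches_binomial(self):
        rng = np.random.default_rng(11)
        g = random_genome(100_000, rng)
        counts = [apply_substitutions(g, 1e-4, rng)[1] for _ in range(1000)]
        se = np.sqrt(100_000 * 1e-4 / 1000)  # ~Poisson(10) mean SE
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_substitutions(random_genome(10, rng), 1.5, rng)

    def test_structure_preserved_at_rate_zero(self, rng):
        g = random_genome(3000, rng)
        out, _ = apply_substitutions(g, 0.0, rng)
        assert scan_genes(out) == scan_genes(g)


class TestWholeGenomeDuplication:
    def test_length_doubles(self, rng):
        g = random_genome(1000, rng)
        assert whole_genome_duplicate(g).size == 2000

    def test_empty_stays_empty(self):
        assert whole_genome_duplicate(as_genome("")).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_digit_multiset_conserved(self, seed):
        g = random_genome(500, np.random.default_rng(seed))
        dup = whole_genome_duplicate(g)
        assert np.array_equal(np.bincount(dup, minlength=4),
                              2 * np.bincount(g, minlength=4))

    def test_gene_list_doubles_with_clean_boundary(self, rng):
        # a TATA-word pad aborts any parse crossing the junction,
        # keeping the last gene clear of it
        g = as_genome(genome_to_str(random_genome(2000, rng)) + "1010" * 52)
        genes = scan_genes(g)
        dup_genes = scan_genes(whole_genome_duplicate(g))
        assert len(dup_genes) == 2 * len(genes)
        offset = g.size
        for a, b in zip(dup_genes[len(genes):], genes):
            assert (a.start, a.end) == (b.start + offset, b.end + offset)
            assert a.kind == b.kind and a.identity == b.identity


class TestGenomeFiles:
    def test_roundtrip(self, tmp_path, rng):
        from wgdsim.genome import write_genomes

        records = [
            ("founder", 1, random_genome(257, rng)),
            ("poly", 4, random_genome(64, rng)),
        ]
        path = tmp_path / "genomes.txt"
        write_genomes(path, records)
        back = read_genomes(path)
        assert [(n, p) for n, p, _ in back] == [("founder", 1), ("poly", 4)]
        for (_, _, a), (_, _, b) in zip(records, back):
            assert np.array_equal(a, b)
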