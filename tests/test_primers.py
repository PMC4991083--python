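"""Melting temperature, primer design and multiplex assembly tests."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from bchromkit.consensus import DiagnosticVariant, build_consensus
from bchromkit.io import load_table1_primers
from bchromkit.primers import (
    DesignFailure,
    Primer,
    assemble_multiplex,
    design_allele_specific_primer,
    design_control_pair,
    is_failure,
    melting_temp,
    three_prime_dimer_run,
)

BASES = np.array(list("ACGT"))


class TestMeltingTemp:
    @pytest.mark.parametrize("seq,expected", [("ACGT", 12.0), ("AAAA", 8.0)])
    def test_wallace_rule(self, seq, expected):
        assert melting_temp(seq, "wallace") == expected

    def test_nearest_neighbor_matches_independent_thermodynamic_oracle(self):
        """Every shipped multiplex primer agrees with biopython's NN model
        at the same parameter set (unified stacks, 50 mM Na+, 0.25 uM)."""
        table = load_table1_primers()
        for seq in table["sequence"]:
            mine = melting_temp(seq)
            oracle = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=250, dnac2=0, saltcorr=5)
            assert mine == pytest.approx(oracle, abs=2.0)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTNACGT")

    def test_too_short_for_nn_model(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACG")


def contig_with_variant(seed=7, length=200, pos=150):
    rng = np.random.default_rng(seed)
    contig = "".join(rng.choice(BASES, length))
    return contig, DiagnosticVariant(
        template_id="contig_1",
        position=pos,
        consensus_base="ACGT".replace(contig[pos], "")[0],
        b_base=contig[pos],
        flank_conservation=(50, 50),
        contig_pos=pos,
    )


class TestAlleleSpecificPrimer:
    def test_three_prime_base_is_b_allele(self):
        contig, variant = contig_with_variant()
        primer = design_allele_specific_primer(variant, contig)
        assert not is_failure(primer)
        assert primer.sequence[-1] == variant.b_base
        assert primer.three_prime == variant.position
        assert contig.endswith(primer.sequence[:-1] + variant.b_base) or primer.sequence in contig

    def test_low_complexity_upstream_fails_with_violations(self):
        # an all-G window melts far above any sane window -> no feasible length
        contig = "G" * 200
        variant = DiagnosticVariant(
            template_id="c", position=199, consensus_base="A", b_base="G",
            flank_conservation=(50, 50), contig_pos=199,
        )
        result = design_allele_specific_primer(variant, contig)
        assert is_failure(result)
        assert result.violations

    def test_selected_length_is_the_enumeration_optimum(self):
        """The chosen primer matches exhaustive enumeration of all lengths."""
        contig, variant = contig_with_variant(seed=8)
        lo, hi = 55.0, 65.0
        primer = design_allele_specific_primer(variant, contig, tm_window=(lo, hi))
        assert not is_failure(primer)
        mid = (lo + hi) / 2
        best = None
        for L in range(18, 41):
            seq = contig[variant.contig_pos - L + 1 : variant.contig_pos + 1]
            tm = melting_temp(seq)
            if lo <= tm <= hi and (best is None or (abs(tm - mid), L) < best[:2]):
                best = (abs(tm - mid), L, seq)
        assert best is not None
        assert primer.sequence == best[2]
        assert lo <= primer.tm <= hi


class TestControlPair:
    def test_fully_conserved_consensus_hosts_a_pair(self):
        rng = np.random.default_rng(9)
        cons = build_consensus(["".join(rng.choice(BASES, 600))] * 3)
        pair = design_control_pair(cons, b_site=200)
        assert not is_failure(pair)
        forward, reverse = pair
        rev_five = reverse.three_prime + reverse.length - 1
        product = rev_five - forward.template_start + 1
        assert 120 <= product <= 220
        assert reverse.three_prime > 200  # downstream of the variant site

    def test_primers_only_touch_conserved_columns(self):
        rng = np.random.default_rng(10)
        seqs = ["".join(rng.choice(BASES, 600))] * 3
        # poison every 40th column so candidate space is constrained
        poisoned = list(seqs[0])
        for i in range(0, 600, 40):
            poisoned[i] = "ACGT".replace(poisoned[i], "")[0]
        cons = build_consensus([seqs[0], seqs[1], "".join(poisoned)])
        pair = design_control_pair(cons, b_site=150)
        if not is_failure(pair):
            for primer in pair:
                for col in range(primer.template_start, primer.template_end):
                    assert cons.conserved_mask[col]

    def test_short_conserved_runs_fail(self):
        # alternating disagreement leaves no conserved run >= 18 nt
        a = "AC" * 300
        b = "".join(c if i % 10 else ("G" if c != "G" else "T") for i, c in enumerate(a))
        cons = build_consensus([a, a, b])
        assert is_failure(design_control_pair(cons, b_site=100))


def flat_primer(pid, strand, three_prime, length=20, tm=60.0, seq=None):
    seq = seq or ("AC" * length)[:length]
    return Primer(id=pid, sequence=seq, strand=strand, three_prime=three_prime, tm=tm, gc=0.5)


class TestAssembleMultiplex:
    def test_gel_resolvable_fragment_pair_accepted(self):
        # geometry reproducing a 163 bp control and 260 bp B product
        reverse = flat_primer("m-R", "-", 400)
        control = flat_primer("mC-F", "+", 419 - 163 + 20)  # start 257
        b_fwd = flat_primer("mB-F", "+", 419 - 260 + 20)  # start 160
        assay = assemble_multiplex(b_fwd, control, reverse, delta_gel=40)
        assert not is_failure(assay)
        assert assay.expected_control_length == 163
        assert assay.expected_b_length == 260
        assert assay.constraint_report["band_gap_bp"] == 97

    def test_equal_band_sizes_rejected(self):
        reverse = flat_primer("m-R", "-", 400)
        control = flat_primer("mC-F", "+", 276)
        b_fwd = flat_primer("mB-F", "+", 276, seq=("AG" * 10))
        result = assemble_multiplex(b_fwd, control, reverse)
        assert is_failure(result)
        assert any("gap" in v for v in result.violations)

    def test_three_prime_cross_dimer_rejected(self):
        # complement b's suffix position-by-position so the 3' ends anneal
        a_seq = "ACACACACACACACACACAC"
        b_seq = a_seq[:-6] + "".join({"A": "T", "C": "G"}[c] for c in a_seq[-6:])
        assert three_prime_dimer_run(a_seq, b_seq) >= 6
        reverse = flat_primer("m-R", "-", 400, seq=a_seq)
        control = flat_primer("mC-F", "+", 257 + 19, seq=b_seq)
        b_fwd = flat_primer("mB-F", "+", 160 + 19)
        result = assemble_multiplex(b_fwd, control, reverse)
        assert is_failure(result)
        assert any("dimer" in v for v in result.violations)

    def test_excessive_tm_span_rejected(self):
        reverse = flat_primer("m-R", "-", 400, tm=66.0)
        control = flat_primer("mC-F", "+", 276)
        b_fwd = flat_primer("mB-F", "+", 179)
        result = assemble_multiplex(b_fwd, control, reverse, tm_span_limit=5.0)
        assert is_failure(result)
        assert any("Tm span" in v for v in result.violations)


class TestPrimerInvariants:
    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            Primer("p", "ACGT", "+", 3, 60.0, 0.5)

    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            Primer("p", "ACGTN" * 4, "+", 19, 60.0, 0.5)
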