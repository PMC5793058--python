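"""Global alignment, reference-position mapping and residue rules."""

import pytest
from hypothesis import given, settings, strategies as st

import corallox as cx
from corallox.anchormap import AlignParams, LOX_RULES
from corallox.errors import BoundsError, ContractError

from oracles import brute_force_global_score

# A/C/G/T are all valid amino-acid codes (Ala/Cys/Gly/Thr), so a 4-letter
# alphabet keeps the exhaustive oracle tractable while exercising BLOSUM62.
FOUR = "ACGT"


class TestGlobalAlign:
    def test_identity_case(self):
        aln = cx.global_align("MWLLAKHD", "MWLLAKHD")
        assert aln.identity_pct == 100.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            cx.global_align("AAAA", "")

    def test_forced_mismatch_identity(self):
        assert cx.global_align("AAAA", "AAAT").identity_pct == 75.0

    def test_score_matches_exhaustive_enumeration(self, rng):
        """DP score equals brute-force enumeration over all monotone matchings."""
        for _ in range(120):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(list(FOUR), size=la))
            b = "".join(rng.choice(list(FOUR), size=lb))
            got = cx.global_align(a, b).score
            want = brute_force_global_score(a, b)
            assert got == pytest.approx(want, abs=1e-9), (a, b)

    def test_semiglobal_score_matches_oracle(self, rng):
        for _ in range(60):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(list(FOUR), size=la))
            b = "".join(rng.choice(list(FOUR), size=lb))
            got = cx.global_align(a, b, free_end_gaps=True).score
            want = brute_force_global_score(a, b, free_end_gaps=True)
            assert got == pytest.approx(want, abs=1e-9), (a, b)

    def test_score_symmetry(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACDEFGHIKL"), size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(list("ACDEFGHIKL"), size=int(rng.integers(5, 40))))
            assert cx.global_align(a, b).score == pytest.approx(
                cx.global_align(b, a).score
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_self_identity_is_always_100(self, a):
        assert cx.global_align(a, a).identity_pct == 100.0

    def test_invalid_params(self):
        with pytest.raises(ContractError):
            AlignParams(gap_open=5.0, gap_extend=6.0)


class TestMapPosition:
    def test_reference_maps_to_itself(self, reference):
        aln = cx.global_align(reference, reference)
        for pos in (757, 762, 943, 947, 1066):
            assert cx.map_position(aln, pos) == (pos, "aligned")

    def test_deletion_shifts_mapping(self, reference):
        # remove 10 query residues well upstream of the sites
        query = reference.residues[:100] + reference.residues[110:]
        aln = cx.global_align(reference, query, free_end_gaps=True)
        assert cx.map_position(aln, 757) == (747, "aligned")

    def test_truncated_query(self, reference):
        query = reference.residues[399:]  # covers reference 400..1066
        aln = cx.global_align(reference, query, free_end_gaps=True)
        pos, status = cx.map_position(aln, 66)
        assert status == "truncated" and pos is None

    def test_out_of_range(self, reference):
        aln = cx.global_align(reference, reference)
        with pytest.raises(BoundsError):
            cx.map_position(aln, 1067)

    def test_monotone_over_mapped_positions(self, reference, rng):
        query = reference.residues[:500] + reference.residues[520:]
        aln = cx.global_align(reference, query, free_end_gaps=True)
        mapped = [
            cx.map_position(aln, p)[0]
            for p in range(1, 1067)
            if cx.map_position(aln, p)[1] == "aligned"
        ]
        assert all(x < y for x, y in zip(mapped, mapped[1:]))


class TestCheckRules:
    def test_reference_self_check_all_match(self, reference, rules):
        checks = cx.check_rules(reference, reference, rules)
        assert all(c.status == "match" for c in checks)
        assert [c.query_pos for c in checks] == [c.rule.ref_pos for c in checks]

    def test_planted_substitution_recovered(self, reference, rules):
        mutated = list(reference.residues)
        mutated[756] = "K"  # first iron-coordinating His -> Lys
        checks = cx.check_rules("".join(mutated), reference, rules)
        by_pos = {c.rule.ref_pos: c for c in checks}
        assert by_pos[757].status == "substitution"
        assert by_pos[757].observed == "K"
        assert all(
            c.status == "match" for p, c in by_pos.items() if p != 757
        )

    def test_truncation_marks_downstream_rules(self, reference):
        query = reference.residues[:900]
        checks = cx.check_rules(query, reference, LOX_RULES)
        by_pos = {c.rule.ref_pos: c for c in checks}
        assert by_pos[757].status == "match"
        assert by_pos[943].status == "truncated"
        assert by_pos[947].status == "truncated"
        assert by_pos[1066].status == "truncated"

    def test_planted_mutation_set_recovered_exactly(self, reference, rules, rng):
        """check_rules recovers the full planted substitution set."""
        for _ in range(5):
            positions = rng.choice([757, 762, 943, 947, 66, 67, 349, 353], size=3, replace=False)
            mutated = list(reference.residues)
            planted = {}
            for p in positions:
                new = "K" if mutated[p - 1] != "K" else "Q"
                mutated[p - 1] = new
                planted[int(p)] = new
            checks = cx.check_rules("".join(mutated), reference, rules)
            found = {
                c.rule.ref_pos: c.observed
                for c in checks
                if c.status == "substitution"
            }
            assert found == planted


class TestCoffaAndActivity:
    @pytest.mark.parametrize(
        "observed,call",
        [("G", "R"), ("A", "S"), ("I", "indeterminate"), ("F", "indeterminate"),
         ("V", "indeterminate")],
    )
    def test_coffa_calls(self, observed, call, reference, synth_config):
        pos = synth_config.layout.coffa_pos
        mutated = list(reference.residues)
        mutated[pos - 1] = observed
        checks = cx.check_rules("".join(mutated), reference, [cx.coffa_rule(pos)])
        assert cx.coffa_call(checks[0]) == call

    def test_all_match_predicts_active(self, reference):
        checks = cx.check_rules(reference, reference, LOX_RULES)
        active, failures = cx.predict_activity(checks)
        assert active and failures == []

    def test_iron_ligand_substitution_fails_activity(self, reference):
        mutated = reference.residues[:756] + "K" + reference.residues[757:]
        checks = cx.check_rules(mutated, reference, LOX_RULES)
        active, failures = cx.predict_activity(checks)
        assert not active
        assert failures == ["iron_ligand@757:K"]

    def test_missing_cterm_fails_activity(self, reference):
        # partial sequence ending before the terminal residue
        checks = cx.check_rules(reference.residues[:1000], reference, LOX_RULES)
        active, failures = cx.predict_activity(checks)
        assert not active
        assert any("cterm@1066" in f for f in failures)

    def test_missing_rule_coverage_is_contract_error(self, reference):
        checks = cx.check_rules(reference, reference, LOX_RULES[:2])  # no cterm rule
        with pytest.raises(ContractError):
            cx.predict_activity(checks)


def test_rule_table_round_trip(tmp_path, rules):
    p = tmp_path / "rules.tsv"
    p.write_text(
        "ref_pos\texpected\trole\tdomain\n"
        + "\n".join(
            f"{r.ref_pos}\t{''.join(sorted(r.expected))}\t{r.role}\t{r.domain}"
            for r in rules
        )
        + "\n"
    )
    back = cx.anchormap.load_rule_table(p)
    assert sorted(back, key=lambda r: (r.domain, r.ref_pos)) == sorted(
        rules, key=lambda r: (r.domain, r.ref_pos)
    )
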