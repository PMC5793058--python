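"""Decision cascade, COX screen and identity clustering."""

import itertools

import numpy as np
import pytest

import corallox as cx
from corallox.errors import ConfigurationError, ContractError
from corallox.seqio import ProteinCandidate


def as_candidate(record):
    return cx.to_protein(record)[0]


class TestClassifySequence:
    def test_full_fusion_with_all_features(self, reference, reference_set, rules):
        c = cx.classify_sequence(reference, reference_set, rules)
        assert c.architecture == "AOS_LOX_fusion"
        assert c.completeness == "full_length"
        assert c.stereospecificity == "R"  # layout plants Gly at the determinant
        assert c.predicted_active

    def test_wllak_fragment_is_partial_lox(self, reference, reference_set, rules):
        core = cx.trim_core(reference)
        frag = ProteinCandidate("frag", core.residues, "as_is")
        c = cx.classify_sequence(frag, reference_set, rules)
        assert c.architecture == "LOX"
        assert c.completeness == "partial"

    def test_tolerated_aos_substitutions_keep_fusion_call(
        self, reference, reference_set, rules
    ):
        # two altered tetrad residues remain mappable: still a fusion
        mutated = list(reference.residues)
        mutated[65] = "D"  # Thr66 -> Asp
        mutated[348] = "Q"  # Arg349 -> Gln
        cand = ProteinCandidate("mut", "".join(mutated), "as_is")
        c = cx.classify_sequence(cand, reference_set, rules)
        assert c.architecture == "AOS_LOX_fusion"
        noted = " ".join(c.notes)
        assert "aos_catalytic@66" in noted and "aos_catalytic@349" in noted

    def test_cox_decoy_detected(self, cox_reference, reference_set, rules):
        c = cx.classify_sequence(cox_reference, reference_set, rules)
        assert c.architecture == "COX_like"
        assert c.completeness is None

    def test_random_sequence_is_non_dioxygenase(self, reference_set, rules, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=500))
        c = cx.classify_sequence(
            ProteinCandidate("rand", seq, "as_is"), reference_set, rules
        )
        assert c.architecture == "non_dioxygenase"
        assert not c.predicted_active

    def test_deterministic_and_order_independent(self, small_panel, reference_set, rules):
        records, _ = small_panel
        cands = [as_candidate(r) for r in records[:8]]
        first = [cx.classify_sequence(c, reference_set, rules) for c in cands]
        second = [cx.classify_sequence(c, reference_set, rules) for c in reversed(cands)]
        by_id = {c.seq_id: c for c in second}
        for c in first:
            again = by_id[c.seq_id]
            assert (c.architecture, c.completeness, c.stereospecificity,
                    c.predicted_active) == (
                again.architecture, again.completeness, again.stereospecificity,
                again.predicted_active,
            )

    def test_fusion_min_monotonicity(self, small_panel, reference_set, rules):
        """Raising fusion_min can only demote fusions to LOX, never promote."""
        records, _ = small_panel
        cands = [as_candidate(r) for r in records[:12]]
        low = cx.ClassifyConfig(fusion_min=900)
        high = cx.ClassifyConfig(fusion_min=1100)
        for cand in cands:
            a = cx.classify_sequence(cand, reference_set, rules, low).architecture
            b = cx.classify_sequence(cand, reference_set, rules, high).architecture
            if b == "AOS_LOX_fusion":
                assert a == "AOS_LOX_fusion"


class TestDetectCox:
    def test_self_similarity(self, cox_reference):
        is_cox, pid = cx.detect_cox(cox_reference, cox_reference)
        assert is_cox and pid == 100.0

    def test_missing_reference_is_config_error(self, reference):
        with pytest.raises(ConfigurationError):
            cx.detect_cox(reference, None)

    def test_lox_decoy_below_threshold(self, reference, cox_reference):
        is_cox, pid = cx.detect_cox(reference, cox_reference)
        assert not is_cox
        assert pid < 30.0

    def test_composition_preserving_shuffle_null(self, cox_reference, rng):
        """Shuffles of the COX reference itself stay below the identity cut."""
        residues = list(cox_reference.residues)
        pids = []
        for _ in range(8):
            rng.shuffle(residues)
            shuffled = ProteinCandidate("shuf", "".join(residues), "as_is")
            is_cox, pid = cx.detect_cox(shuffled, cox_reference)
            assert not is_cox
            pids.append(pid)
        assert max(pids) < 30.0


class TestGroupByIdentity:
    def _matrix(self, values, labels=None):
        values = np.asarray(values, dtype=float)
        labels = labels or [f"s{i}" for i in range(len(values))]
        return cx.IdentityMatrix(labels, values)

    def test_two_planted_blocks(self):
        v = np.full((4, 4), 30.0)
        v[:2, :2] = 85.0
        v[2:, 2:] = 90.0
        np.fill_diagonal(v, 100.0)
        clusters = cx.group_by_identity(self._matrix(v), cut=60.0)
        assert sorted(len(c.labels) for c in clusters) == [2, 2]
        for c in clusters:
            lo, hi = c.identity_range
            assert lo >= 80.0

    def test_cut_zero_gives_one_cluster(self):
        v = np.full((5, 5), 10.0)
        np.fill_diagonal(v, 100.0)
        clusters = cx.group_by_identity(self._matrix(v), cut=0.0)
        assert len(clusters) == 1
        assert len(clusters[0].labels) == 5

    def test_matches_connected_components_oracle(self, rng):
        """Clusters equal brute-force components of the thresholded graph."""
        for _ in range(20):
            n = 6
            v = rng.uniform(0, 100, size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 100.0)
            cut = float(rng.uniform(20, 80))
            clusters = cx.group_by_identity(self._matrix(v), cut)
            # oracle: transitive closure by edge expansion
            labels = [f"s{i}" for i in range(n)]
            comp = {lab: {lab} for lab in labels}
            changed = True
            while changed:
                changed = False
                for i, j in itertools.combinations(range(n), 2):
                    if v[i, j] >= cut and comp[labels[i]] is not comp[labels[j]]:
                        merged = comp[labels[i]] | comp[labels[j]]
                        for lab in merged:
                            comp[lab] = merged
                        changed = True
            want = {frozenset(s) for s in comp.values()}
            got = {frozenset(c.labels) for c in clusters}
            assert got == want

    def test_non_symmetric_rejected(self):
        v = np.full((3, 3), 50.0)
        np.fill_diagonal(v, 100.0)
        v[0, 1] = 10.0
        with pytest.raises(ContractError):
            self._matrix(v)
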