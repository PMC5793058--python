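"""Sequence-level verdicts: LOX vs AOS-LOX fusion vs COX-like vs neither.

The decision cascade mirrors how coral dioxygenase candidates are
curated by hand: motif evidence gates the LOX call; length plus
mappability of the AOS catalytic tetrad separates allene-oxide-synthase
fusion proteins from stand-alone lipoxygenases; a twilight-zone identity
screen against a cyclooxygenase reference catches COX-like sequences;
everything else is set aside.  Stereospecificity is a Coffa-determinant
prediction and catalytic competence an iron-ligand/terminal-residue
prediction — both are sequence-based hypotheses, not measured activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .anchormap import (
    AlignParams,
    DEFAULT_ALIGN_PARAMS,
    ResidueCheck,
    ResidueRule,
    check_rules,
    coffa_call,
    global_align,
    predict_activity,
)
from .errors import ConfigurationError
from .motifs import MotifDef, DEFAULT_MOTIFS, has_lox_signature
from .phylo import IdentityMatrix
from .seqio import ProteinCandidate, extract_domain

Architecture = Literal["LOX", "AOS_LOX_fusion", "COX_like", "non_dioxygenase"]

#: Caveat attached to every report row: these are sequence-based predictions.
PREDICTION_CAVEAT = (
    "sequence-based prediction only; catalytic activity and positional "
    "specificity require expression and product analysis"
)


@dataclass
class ClassifyConfig:
    """Thresholds of the decision cascade (all configurable).

    fusion_min: minimum length (aa) for the fusion call — full coral
    AOS-LOX fusions run ~1037-1081 aa while stand-alone LOX domains are
    ~700 aa, so 950 separates the regimes.  cox_min_identity /
    cox_min_overlap: twilight-zone homology convention (30% identity
    over >= 200 aligned residue pairs).  full_length_coverage: fraction
    of the relevant reference region the query alignment must span.
    """

    fusion_min: int = 950
    min_aos_mappable: int = 3
    cox_min_identity: float = 30.0
    cox_min_overlap: int = 200
    full_length_coverage: float = 0.90
    aos_domain_span: tuple[int, int] = (1, 373)
    lox_domain_span: tuple[int, int] = (374, 1066)
    align_params: AlignParams = field(default_factory=AlignParams)


@dataclass
class ReferenceSet:
    """Reference proteins the cascade aligns against.

    lox_reference: full-length AOS-LOX fusion carrying the canonical
    residue numbering (mandatory).  cox_reference: a cyclooxygenase for
    the COX screen (optional; without it no COX_like verdict is made).
    The AOS-domain reference is sliced from the fusion reference.
    """

    lox_reference: ProteinCandidate
    cox_reference: ProteinCandidate | None = None

    def aos_reference(self, span: tuple[int, int]) -> ProteinCandidate:
        return ProteinCandidate(
            self.lox_reference.parent_id + "|AOS", extract_domain(self.lox_reference, span), "as_is"
        )


@dataclass
class Classification:
    """The full verdict for one sequence, with its evidence."""

    seq_id: str
    architecture: Architecture
    completeness: Literal["full_length", "partial"] | None
    stereospecificity: Literal["R", "S", "indeterminate"]
    predicted_active: bool
    lox_checks: list[ResidueCheck] = field(default_factory=list)
    aos_checks: list[ResidueCheck] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    caveat: str = PREDICTION_CAVEAT

    def failed_rules(self) -> list[str]:
        out = []
        for c in self.lox_checks + self.aos_checks:
            if c.status != "match":
                what = c.observed if c.observed is not None else c.status
                out.append(f"{c.rule.role}@{c.rule.ref_pos}:{what}")
        return out


def detect_cox(
    protein: ProteinCandidate,
    cox_reference: ProteinCandidate | None,
    params: AlignParams = DEFAULT_ALIGN_PARAMS,
    min_identity: float = 30.0,
    min_overlap: int = 200,
) -> tuple[bool, float]:
    """Twilight-zone COX homology screen.

    True iff global-alignment identity is at least ``min_identity``
    percent and the alignment overlaps across at least ``min_overlap``
    aligned residue pairs.  Identity uses the all-columns denominator:
    under the gap-seeking optimal alignment, the identity of unrelated
    sequences over aligned pairs alone hovers near 30% even for random
    sequences, whereas the all-columns null sits near 16% — only the
    latter separates homology from noise at the twilight-zone cut.
    """
    if cox_reference is None:
        raise ConfigurationError("COX detection requires a cox_reference")
    aln = global_align(protein, cox_reference, params, free_end_gaps=True)
    pid = aln.identity_pct
    return (pid >= min_identity and aln.n_aligned_pairs >= min_overlap), pid


def _coverage(checks_alignment, span: tuple[int, int]) -> float:
    """Fraction of reference positions in ``span`` inside the query's aligned extent."""
    aligned_a, aligned_b = checks_alignment.aligned_a, checks_alignment.aligned_b
    # reference positions at the query's first/last residue columns
    first = last = None
    ref_count = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            ref_count += 1
        if cb != "-":
            if first is None and ca != "-":
                first = ref_count
            if ca != "-":
                last = ref_count
    if first is None or last is None:
        return 0.0
    lo, hi = span
    covered = max(0, min(hi, last) - max(lo, first) + 1)
    return covered / (hi - lo + 1)


def classify_sequence(
    protein: ProteinCandidate,
    references: ReferenceSet,
    rules: Sequence[ResidueRule],
    config: ClassifyConfig | None = None,
    motif_defs: Sequence[MotifDef] = DEFAULT_MOTIFS,
) -> Classification:
    """Run the full decision cascade on one protein candidate."""
    config = config or ClassifyConfig()
    if references.lox_reference is None:
        raise ConfigurationError("classification requires a LOX-numbering reference")
    lox_rules = [r for r in rules if r.domain == "LOX"]
    aos_rules = [r for r in rules if r.domain == "AOS"]
    if not lox_rules:
        raise ConfigurationError("rule table contains no LOX-domain rules")

    sig, evidence = has_lox_signature(protein, motif_defs)
    notes = list(evidence) if sig else []

    if sig:
        aln = global_align(
            references.lox_reference, protein, config.align_params, free_end_gaps=True
        )
        lox_checks = check_rules(
            protein, references.lox_reference, lox_rules, config.align_params, alignment=aln
        )
        architecture: Architecture = "LOX"
        aos_checks: list[ResidueCheck] = []
        if len(protein) >= config.fusion_min and aos_rules:
            aos_ref = references.aos_reference(config.aos_domain_span)
            aos_checks = check_rules(
                protein, aos_ref, aos_rules, config.align_params, free_end_gaps=True
            )
            n_mappable = sum(1 for c in aos_checks if c.mappable)
            if n_mappable >= config.min_aos_mappable:
                architecture = "AOS_LOX_fusion"
                notes.append(
                    "fusion architecture; AOS-LOX and HPL-LOX are not "
                    "sequence-distinguishable and share this label"
                )
            else:
                aos_checks = []
        truncated = any(c.status == "truncated" for c in lox_checks)
        span = (
            (1, len(references.lox_reference))
            if architecture == "AOS_LOX_fusion"
            else config.lox_domain_span
        )
        coverage = _coverage(aln, span)
        completeness = (
            "full_length"
            if not truncated and coverage >= config.full_length_coverage
            else "partial"
        )
        coffa_checks = [c for c in lox_checks if c.rule.role == "coffa"]
        stereo = coffa_call(coffa_checks[0]) if coffa_checks else "indeterminate"
        active, failures = predict_activity(lox_checks)
        for c in lox_checks + aos_checks:
            if c.status == "substitution":
                notes.append(
                    f"substitution {c.rule.role}@{c.rule.ref_pos}: "
                    f"expected {{{','.join(sorted(c.rule.expected))}}}, observed {c.observed}"
                )
        return Classification(
            protein.parent_id,
            architecture,
            completeness,
            stereo,
            active,
            lox_checks,
            aos_checks,
            notes,
        )

    if references.cox_reference is not None:
        is_cox, pid = detect_cox(
            protein,
            references.cox_reference,
            config.align_params,
            config.cox_min_identity,
            config.cox_min_overlap,
        )
        if is_cox:
            return Classification(
                protein.parent_id,
                "COX_like",
                None,
                "indeterminate",
                False,
                notes=[f"COX screen identity {pid:.1f}% over aligned pairs"],
            )
    return Classification(
        protein.parent_id,
        "non_dioxygenase",
        None,
        "indeterminate",
        False,
        notes=["no LOX motif signature; no COX similarity"],
    )


@dataclass
class Cluster:
    """A single-linkage component at the identity cut."""

    labels: list[str]
    identity_range: tuple[float, float] | None  # min-max off-diagonal; None for singletons


def group_by_identity(matrix: IdentityMatrix, cut: float) -> list[Cluster]:
    """Single-linkage clusters of the identity graph thresholded at ``cut``.

    Two sequences join the same cluster when a chain of pairwise
    identities >= cut connects them.  Each cluster reports its min-max
    off-diagonal identity.  cut = 0 yields one all-inclusive cluster.
    """
    n = len(matrix.labels)
    adj = (matrix.values >= cut) & ~np.eye(n, dtype=bool)
    n_comp, assignment = connected_components(csr_matrix(adj), directed=False)
    clusters = []
    for comp in range(n_comp):
        idx = np.flatnonzero(assignment == comp)
        labels = [matrix.labels[i] for i in idx]
        if len(idx) > 1:
            sub = matrix.values[np.ix_(idx, idx)]
            off = sub[~np.eye(len(idx), dtype=bool)]
            rng = (float(off.min()), float(off.max()))
        else:
            rng = None
        clusters.append(Cluster(labels, rng))
    clusters.sort(key=lambda c: matrix.labels.index(c.labels[0]))
    return clusters
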