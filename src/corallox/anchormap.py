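"""Reference-anchored alignment and catalytic-residue rule evaluation.

Catalytic positions of coral lipoxygenases are conventionally numbered
on the Gersemia fruticosa AOS-LOX fusion protein: iron ligands His757,
His762, His943, Asn947 and the terminal Ile1066 in the LOX domain, and
the catalytic tetrad Thr66, His67, Arg349, Tyr353 in the N-terminal
allene-oxide-synthase (AOS) domain.  This module aligns a query protein
globally to such a reference (affine-gap Needleman-Wunsch via
Biopython's PairwiseAligner), maps reference-numbered positions onto the
query, and evaluates declarative residue rules, including the single
Gly/Ala "Coffa" determinant that predicts R- versus S-stereospecificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import BoundsError, ContractError
from .seqio import ProteinCandidate

RuleRole = Literal["iron_ligand", "aos_catalytic", "coffa", "cterm"]
Domain = Literal["LOX", "AOS"]


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap alignment parameters.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  The
    defaults (BLOSUM62, open 10, extend 0.5) follow the Clustal W-era
    protein convention.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ContractError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ContractError("gap_extend must not exceed gap_open")


DEFAULT_ALIGN_PARAMS = AlignParams()


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment as two equal-length gapped strings.

    identity_pct divides identical residue-pair columns by the total
    number of alignment columns (global alignments have no dual-gap
    columns).  identity_over_pairs uses only columns where both rows
    carry a residue — the denominator used for homology screening.
    """

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ContractError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )

    @property
    def n_aligned_pairs(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x != "-" and y != "-"
        )

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.n_identical / self.n_columns

    @property
    def identity_over_pairs(self) -> float:
        pairs = self.n_aligned_pairs
        return 100.0 * self.n_identical / pairs if pairs else 0.0


@dataclass(frozen=True)
class ResidueRule:
    """A catalytic-residue expectation in reference numbering."""

    ref_pos: int
    expected: frozenset[str]
    role: RuleRole
    domain: Domain = "LOX"

    def __post_init__(self):
        if self.ref_pos < 1:
            raise ContractError("ref_pos must be >= 1")
        if not self.expected:
            raise ContractError("expected residue set must be non-empty")


@dataclass(frozen=True)
class ResidueCheck:
    """Outcome of evaluating one rule on one query.

    status: "match" (observed in the expected set), "substitution"
    (observed but unexpected), "unaligned" (reference column is a gap in
    the query), "truncated" (reference position lies beyond the query's
    aligned extent).
    """

    rule: ResidueRule
    query_pos: int | None
    observed: str | None
    status: Literal["match", "substitution", "unaligned", "truncated"]

    @property
    def mappable(self) -> bool:
        return self.status in ("match", "substitution")


def _rule(pos: int, expected: str, role: RuleRole, domain: Domain = "LOX") -> ResidueRule:
    return ResidueRule(pos, frozenset(expected), role, domain)


#: Iron ligands + terminal residue of the LOX domain, reference numbering.
LOX_RULES: tuple[ResidueRule, ...] = (
    _rule(757, "H", "iron_ligand"),
    _rule(762, "H", "iron_ligand"),
    _rule(943, "H", "iron_ligand"),
    _rule(947, "N", "iron_ligand"),
    _rule(1066, "ITS", "cterm"),
)

#: Position-947 tolerance observed across mammalian LOXs (Asn/His/Ser).
MAMMALIAN_947 = _rule(947, "NHS", "iron_ligand")

#: AOS catalytic tetrad, numbered on the AOS domain (aa 1-373 of the fusion).
AOS_RULES: tuple[ResidueRule, ...] = (
    _rule(66, "T", "aos_catalytic", "AOS"),
    _rule(67, "H", "aos_catalytic", "AOS"),
    _rule(349, "R", "aos_catalytic", "AOS"),
    _rule(353, "Y", "aos_catalytic", "AOS"),
)


def coffa_rule(ref_pos: int) -> ResidueRule:
    """Build the Coffa-determinant rule at a caller-supplied position.

    The determinant's coordinate in reference numbering is deliberately
    not shipped as a biological default: it must be declared by the
    caller (configs and the synthetic reference layout declare theirs).
    """
    return _rule(ref_pos, "GA", "coffa")


def default_rule_table(coffa_pos: int | None = None) -> list[ResidueRule]:
    rules = list(LOX_RULES) + list(AOS_RULES)
    if coffa_pos is not None:
        rules.append(coffa_rule(coffa_pos))
    return rules


def _aligner(params: AlignParams, free_end_gaps: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if free_end_gaps:
        aligner.end_gap_score = 0.0
    return aligner


def global_align(
    a: str | ProteinCandidate,
    b: str | ProteinCandidate,
    params: AlignParams = DEFAULT_ALIGN_PARAMS,
    free_end_gaps: bool = False,
) -> AlignmentResult:
    """Optimal global affine-gap alignment of two protein sequences.

    ``free_end_gaps=True`` switches to semiglobal scoring (terminal gaps
    free), the right mode for mapping partial sequences onto a longer
    reference.  The traceback is deterministic (the aligner's first
    optimal alignment is always taken).
    """
    sa = a if isinstance(a, str) else a.residues
    sb = b if isinstance(b, str) else b.residues
    if not sa or not sb:
        raise ContractError("cannot align an empty sequence")
    aligner = _aligner(params, free_end_gaps)
    alignments = aligner.align(sa, sb)
    aln = alignments[0]
    return AlignmentResult(str(aln[0]), str(aln[1]), float(alignments.score))


def map_position(aln: AlignmentResult, ref_pos: int) -> tuple[int | None, str]:
    """Map a reference position (row a) onto the query (row b).

    Returns ``(query_pos, status)`` with status "match"-eligible
    ("aligned"), "unaligned" (query gap at that column) or "truncated"
    (column outside the query's aligned extent).
    """
    ref_len = sum(1 for c in aln.aligned_a if c != "-")
    if not 1 <= ref_pos <= ref_len:
        raise BoundsError(f"ref_pos {ref_pos} outside reference of length {ref_len}")
    # column index carrying the ref_pos-th reference residue
    count = 0
    col = -1
    for i, c in enumerate(aln.aligned_a):
        if c != "-":
            count += 1
            if count == ref_pos:
                col = i
                break
    q_before = sum(1 for c in aln.aligned_b[: col + 1] if c != "-")
    if aln.aligned_b[col] != "-":
        return q_before, "aligned"
    # query gap: truncated if outside the query's residue extent
    first_q = next((i for i, c in enumerate(aln.aligned_b) if c != "-"), None)
    last_q = next(
        (len(aln.aligned_b) - 1 - i for i, c in enumerate(reversed(aln.aligned_b)) if c != "-"),
        None,
    )
    if first_q is None or col < first_q or col > last_q:
        return None, "truncated"
    return None, "unaligned"


def check_rules(
    protein: str | ProteinCandidate,
    reference: str | ProteinCandidate,
    rules: Sequence[ResidueRule],
    params: AlignParams = DEFAULT_ALIGN_PARAMS,
    free_end_gaps: bool = True,
    alignment: AlignmentResult | None = None,
) -> list[ResidueCheck]:
    """Evaluate residue rules on a query aligned to a numbered reference.

    One alignment (reference as row a) serves all rules; a precomputed
    alignment may be passed to avoid re-aligning.
    """
    seq = protein if isinstance(protein, str) else protein.residues
    aln = alignment or global_align(reference, protein, params, free_end_gaps)
    checks = []
    for rule in rules:
        qpos, status = map_position(aln, rule.ref_pos)
        if status == "aligned":
            observed = seq[qpos - 1]
            st = "match" if observed in rule.expected else "substitution"
            checks.append(ResidueCheck(rule, qpos, observed, st))
        else:
            checks.append(ResidueCheck(rule, None, None, status))
    return checks


def coffa_call(check: ResidueCheck) -> Literal["R", "S", "indeterminate"]:
    """Predict oxygenation stereochemistry from the Coffa determinant.

    Gly predicts R-stereospecificity, Ala predicts S; any other residue
    (Ile/Phe/Val/Leu variants are observed in corals) or an unmapped
    position is indeterminate — the effect of such alterations on
    product chirality is unknown.
    """
    if check.rule.role != "coffa":
        raise ContractError("coffa_call requires a check with role 'coffa'")
    if check.observed == "G":
        return "R"
    if check.observed == "A":
        return "S"
    return "indeterminate"


def predict_activity(checks: Sequence[ResidueCheck]) -> tuple[bool, list[str]]:
    """Catalytic-competence prediction from iron-ligand and terminal checks.

    True iff every iron_ligand and cterm check matches; the failure list
    names each non-match with its role, reference position and what was
    observed (or why nothing was).
    """
    relevant = [c for c in checks if c.rule.role in ("iron_ligand", "cterm")]
    roles = {c.rule.role for c in relevant}
    if "iron_ligand" not in roles or "cterm" not in roles:
        raise ContractError(
            "predict_activity requires coverage of iron_ligand and cterm rules"
        )
    failures = []
    for c in relevant:
        if c.status != "match":
            what = c.observed if c.observed is not None else c.status
            failures.append(f"{c.rule.role}@{c.rule.ref_pos}:{what}")
    return not failures, failures


def load_rule_table(path) -> list[ResidueRule]:
    """Read a rule table (TSV: ref_pos, expected, role, domain)."""
    rules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("ref_pos"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ContractError(f"{path}:{lineno}: expected 4 tab-separated fields")
            pos, expected, role, domain = parts
            rules.append(_rule(int(pos), expected.upper(), role, domain))  # type: ignore[arg-type]
    if not rules:
        raise ContractError(f"{path}: empty rule table")
    return rules
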