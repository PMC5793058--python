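"""Conserved-motif detection and core trimming for lipoxygenase curation.

Lipoxygenase catalytic domains carry short, nearly invariant sequence
motifs — WLLAK, YRDD, HAAVN — and a characteristic C-terminal stretch
(PNGTAI in soft-coral AOS-LOX fusions; the PNSIAI spelling variant is
also accepted) ending in the iron-coordinating terminal residue
(Ile/Thr, exceptionally Ser).  These literal motifs act as presence
filters and as the trimming anchor: partial sequences are cut from the
WLLAK anchor to the C-terminus before identity and tree analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import ContractError, TrimError
from .seqio import ProteinCandidate

MotifName = Literal["WLLAK", "YRDD", "HAAVN", "CTERM"]

#: Residues accepted as the final (iron-coordinating) amino acid.
TERMINAL_RESIDUES = frozenset("ITS")
#: Window (from the C-terminus) within which a CTERM motif must fall.
CTERM_WINDOW = 15
#: Core lengths outside this window are flagged with a warning note (not filtered).
EXPECTED_CORE_WINDOW = (280, 400)


@dataclass(frozen=True)
class MotifDef:
    """A literal motif with a Hamming-mismatch budget and a role.

    Roles: "anchor" motifs define the trim start (WLLAK), "support"
    motifs are corroborating evidence (YRDD, HAAVN), "terminal" motifs
    must sit near the C-terminus (CTERM patterns).
    """

    name: MotifName
    pattern: str
    max_mismatch: int = 0
    role: Literal["anchor", "support", "terminal"] = "support"

    def __post_init__(self):
        if len(self.pattern) < 4:
            raise ContractError(f"motif {self.name}: pattern shorter than 4 residues")
        if not 0 <= self.max_mismatch < len(self.pattern):
            raise ContractError(f"motif {self.name}: max_mismatch out of range")


# WLLAK is the hard filter (exact); the others tolerate one substitution.
# Both printed spellings of the soft-coral C-terminal motif are accepted.
DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("WLLAK", "WLLAK", 0, "anchor"),
    MotifDef("YRDD", "YRDD", 1, "support"),
    MotifDef("HAAVN", "HAAVN", 1, "support"),
    MotifDef("CTERM", "PNGTAI", 1, "terminal"),
    MotifDef("CTERM", "PNSIAI", 1, "terminal"),
)


@dataclass(frozen=True)
class MotifHit:
    motif: MotifName
    start: int  # 1-based inclusive
    end: int
    observed: str
    n_mismatch: int


@dataclass(frozen=True)
class CoreRegion:
    """The WLLAK-to-C-terminus core used for partial-sequence analyses."""

    parent_id: str
    span: tuple[int, int]
    residues: str

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


def _residues(protein: ProteinCandidate | str) -> str:
    return protein if isinstance(protein, str) else protein.residues


def scan_motifs(
    protein: ProteinCandidate | str, defs: Sequence[MotifDef] = DEFAULT_MOTIFS
) -> list[MotifHit]:
    """All windows within each motif's Hamming budget, sorted by start."""
    seq = _residues(protein)
    if not seq:
        raise ContractError("empty protein")
    hits: list[MotifHit] = []
    for d in defs:
        k = len(d.pattern)
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            mm = sum(1 for a, b in zip(window, d.pattern) if a != b)
            if mm <= d.max_mismatch:
                hits.append(MotifHit(d.name, i + 1, i + k, window, mm))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def _best_near_miss(seq: str, d: MotifDef) -> MotifHit | None:
    k = len(d.pattern)
    best = None
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mm = sum(1 for a, b in zip(window, d.pattern) if a != b)
        if best is None or mm < best.n_mismatch:
            best = MotifHit(d.name, i + 1, i + k, window, mm)
    return best


def trim_core(
    protein: ProteinCandidate | str, defs: Sequence[MotifDef] = DEFAULT_MOTIFS
) -> CoreRegion:
    """Trim from the selected WLLAK anchor to the sequence end.

    When several anchor hits exist the rightmost exact hit wins, else the
    rightmost inexact hit: the catalytic-domain copy of the motif lies in
    the final third of a full-length fusion, so upstream matches are
    treated as decoys.  Re-trimming a core is a no-op.
    """
    seq = _residues(protein)
    parent_id = "<anonymous>" if isinstance(protein, str) else protein.parent_id
    anchors = [d for d in defs if d.role == "anchor"]
    if not anchors:
        raise ContractError("no anchor motif in the motif table")
    hits = [h for h in scan_motifs(seq, anchors)]
    if not hits:
        near = _best_near_miss(seq, anchors[0])
        raise TrimError(
            f"{parent_id}: no {anchors[0].name} anchor found "
            f"(best near-miss {near.observed!r} at {near.start} with "
            f"{near.n_mismatch} mismatches)" if near else f"{parent_id}: sequence shorter than anchor",
            best_near_miss=near,
        )
    exact = [h for h in hits if h.n_mismatch == 0]
    chosen = max(exact or hits, key=lambda h: h.start)
    return CoreRegion(parent_id, (chosen.start, len(seq)), seq[chosen.start - 1 :])


def has_lox_signature(
    protein: ProteinCandidate | str, defs: Sequence[MotifDef] = DEFAULT_MOTIFS
) -> tuple[bool, list[str]]:
    """LOX presence filter: anchor motif + C-terminal motif + terminal residue.

    True iff a WLLAK (anchor) hit exists, a terminal-role motif matches
    within the final ``CTERM_WINDOW`` residues, and the final residue is
    one of Ile/Thr/Ser.  The evidence list explains every passed and
    failed clause; it is stable for reporting.
    """
    seq = _residues(protein)
    if not seq:
        raise ContractError("empty protein")
    hits = scan_motifs(seq, defs)
    evidence: list[str] = []
    anchor_hits = [h for h in hits if any(d.name == h.motif and d.role == "anchor" for d in defs)]
    ok = True
    if anchor_hits:
        best = max(anchor_hits, key=lambda h: (h.n_mismatch == 0, h.start))
        evidence.append(f"anchor {best.motif} at {best.start}-{best.end} ({best.n_mismatch} mm)")
    else:
        ok = False
        evidence.append("anchor motif WLLAK absent")
    term_names = {d.name for d in defs if d.role == "terminal"}
    term_hits = [
        h for h in hits if h.motif in term_names and h.end > len(seq) - CTERM_WINDOW
    ]
    if term_hits:
        h = term_hits[-1]
        evidence.append(f"C-terminal motif {h.observed!r} at {h.start}-{h.end} ({h.n_mismatch} mm)")
    else:
        ok = False
        evidence.append(f"no C-terminal motif within final {CTERM_WINDOW} residues")
    if seq[-1] in TERMINAL_RESIDUES:
        evidence.append(f"terminal residue {seq[-1]} in allowed set")
    else:
        ok = False
        evidence.append(
            f"terminal residue {seq[-1]} not in allowed set "
            f"{{{','.join(sorted(TERMINAL_RESIDUES))}}}"
        )
    return ok, evidence


def load_motif_table(path) -> list[MotifDef]:
    """Read a motif table (TSV: name, pattern, max_mismatch, role)."""
    defs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ContractError(f"{path}:{lineno}: expected 4 tab-separated fields")
            name, pattern, mm, role = parts
            defs.append(MotifDef(name, pattern.upper(), int(mm), role))  # type: ignore[arg-type]
    if not defs:
        raise ContractError(f"{path}: empty motif table")
    return defs
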