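"""Sequence input/output, translation and domain slicing.

Records are read from FASTA or GenBank flat files into lightweight
:class:`SeqRecord` containers (Biopython does the parsing; a strict
pre-scan attaches line numbers to FASTA format errors).  Nucleotide
records are turned into :class:`ProteinCandidate` objects either through
their annotated CDS or through a six-frame longest-ORF search with the
standard genetic code.

Coordinates are 1-based inclusive throughout, matching the residue
numbering convention used for catalytic-site annotation (e.g. "His 757").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import BoundsError, ContractError, FormatError

Moltype = Literal["nucleotide", "protein"]

#: IUPAC nucleotide codes (incl. ambiguity) accepted in nucleotide records.
NUCLEOTIDE_ALPHABET = set("ACGTUNRYSWKMBDHV")
#: Amino-acid codes (incl. X/B/Z ambiguity and * stop) accepted in protein records.
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZUO*")

DEFAULT_MIN_ORF_AA = 100


@dataclass
class SeqRecord:
    """A raw input sequence with provenance.

    cds_features holds 1-based inclusive (start, end, strand) spans taken
    from GenBank annotation; strand is "+" or "-".
    """

    id: str
    residues: str
    moltype: Moltype
    organism: str | None = None
    description: str = ""
    cds_features: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.residues:
            raise ContractError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()
        alphabet = NUCLEOTIDE_ALPHABET if self.moltype == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise ContractError(
                f"record {self.id!r}: characters {sorted(bad)} not in {self.moltype} alphabet"
            )
        if self.cds_features and self.moltype != "nucleotide":
            raise ContractError(f"record {self.id!r}: cds_features on a protein record")
        for start, end, strand in self.cds_features:
            if not (1 <= start <= end <= len(self.residues)):
                raise ContractError(
                    f"record {self.id!r}: CDS span ({start},{end}) outside sequence "
                    f"of length {len(self.residues)}"
                )
            if strand not in "+-":
                raise ContractError(f"record {self.id!r}: bad strand {strand!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteinCandidate:
    """A protein sequence derived from a :class:`SeqRecord`.

    provenance records how the protein was obtained: "as_is" for protein
    input, "annotated_cds" for a translated annotated CDS, "longest_orf"
    for a six-frame ORF search.  frame is 0 for non-translated input,
    otherwise +1..+3 / -1..-3.  parent_span is the 1-based inclusive
    nucleotide span on the parent (forward-strand coordinates).
    """

    parent_id: str
    residues: str
    provenance: Literal["annotated_cds", "longest_orf", "as_is"]
    frame: int = 0
    parent_span: tuple[int, int] | None = None

    def __post_init__(self):
        if "*" in self.residues:
            raise ContractError(f"{self.parent_id}: internal stop in protein candidate")
        if not self.residues:
            raise ContractError(f"{self.parent_id}: empty protein candidate")

    def __len__(self) -> int:
        return len(self.residues)


def guess_moltype(residues: str) -> Moltype:
    """Call a sequence nucleotide when >= 95% of its letters are ACGTUN."""
    seq = residues.upper()
    nuc = sum(1 for c in seq if c in "ACGTUN")
    return "nucleotide" if nuc >= 0.95 * len(seq) else "protein"


def _validate_fasta_lines(path) -> None:
    allowed = NUCLEOTIDE_ALPHABET | PROTEIN_ALPHABET | {"-", "."}
    n_records = 0
    have_seq = False
    header_line = 0
    any_line = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            any_line = True
            if line.startswith(">"):
                if n_records and not have_seq:
                    raise FormatError(
                        "record with no sequence lines", path=path, line=header_line
                    )
                if len(line) == 1:
                    raise FormatError("empty FASTA header", path=path, line=lineno)
                n_records += 1
                header_line = lineno
                have_seq = False
            else:
                if n_records == 0:
                    raise FormatError(
                        "sequence data before first '>' header", path=path, line=lineno
                    )
                bad = set(line.upper()) - allowed
                if bad:
                    raise FormatError(
                        f"illegal sequence characters {sorted(bad)}", path=path, line=lineno
                    )
                have_seq = True
    if not any_line:
        raise FormatError("empty file", path=path)
    if n_records == 0:
        raise FormatError("no FASTA records found", path=path)
    if not have_seq:
        raise FormatError("record with no sequence lines", path=path, line=header_line)


def read_fasta(path, moltype: Moltype | Literal["auto"] = "auto") -> list[SeqRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    The record id is the first whitespace-delimited token of the header;
    the remainder becomes the description.  Format problems raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    _validate_fasta_lines(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("-", "").replace(".", "")
        mt = guess_moltype(residues) if moltype == "auto" else moltype
        records.append(
            SeqRecord(
                id=rec.id,
                residues=residues,
                moltype=mt,
                description=rec.description[len(rec.id) :].strip(),
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord | ProteinCandidate], path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round trips with :func:`read_fasta`."""
    with open(path, "w") as fh:
        for rec in records:
            rec_id = rec.id if isinstance(rec, SeqRecord) else rec.parent_id
            desc = rec.description if isinstance(rec, SeqRecord) else ""
            header = f">{rec_id}" + (f" {desc}" if desc else "")
            fh.write(header + "\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genbank(path) -> list[SeqRecord]:
    """Read a GenBank/GenPept flat file; CDS feature spans are retained.

    The accession.version is used as the record id when present.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on truncation
        raise FormatError(f"not a readable GenBank file ({exc})", path=path) from exc
    if not parsed:
        raise FormatError("no GenBank records found", path=path)
    records = []
    for rec in parsed:
        residues = str(rec.seq).upper()
        if not residues:
            raise FormatError(f"record {rec.id}: missing ORIGIN sequence", path=path)
        mt = guess_moltype(residues)
        if rec.annotations.get("molecule_type", "").lower().startswith("protein"):
            mt = "protein"
        cds = []
        if mt == "nucleotide":
            for feat in rec.features:
                if feat.type == "CDS":
                    start = int(feat.location.start) + 1  # Biopython is 0-based half-open
                    end = int(feat.location.end)
                    strand = "-" if feat.location.strand == -1 else "+"
                    cds.append((start, end, strand))
        records.append(
            SeqRecord(
                id=rec.id,
                residues=residues,
                moltype=mt,
                organism=rec.annotations.get("organism"),
                description=rec.description,
                cds_features=cds,
            )
        )
    return records


def _translate(nt: str) -> str:
    # trailing partial codon dropped; ambiguity codons become X
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate(table=1))


def _orfs_in_frame(nt: str, frame_offset: int):
    """Yield (aa_seq, nt_start0, nt_end0) for start-to-stop ORFs in one frame."""
    aa = _translate(nt[frame_offset:])
    i = 0
    while i < len(aa):
        if aa[i] == "M":
            j = aa.find("*", i)
            end = j if j != -1 else len(aa)
            yield aa[i:end], frame_offset + 3 * i, frame_offset + 3 * end
            i = end + 1
        else:
            i += 1


def to_protein(
    record: SeqRecord, min_length: int = DEFAULT_MIN_ORF_AA
) -> list[ProteinCandidate]:
    """Derive protein candidates from a record.

    Protein input passes through as a single "as_is" candidate.  A
    nucleotide record with CDS annotation translates each annotated CDS
    (standard genetic code, terminal stop stripped).  An unannotated
    nucleotide record is scanned in all six frames for the longest
    start-to-stop ORF of at least ``min_length`` amino acids; ties break
    by earliest start in frame order +1, +2, +3, -1, -2, -3.  An empty
    list (no qualifying ORF) is a valid, non-fatal outcome.
    """
    if record.moltype == "protein":
        return [ProteinCandidate(record.id, record.residues.rstrip("*"), "as_is")]

    if record.cds_features:
        out = []
        for start, end, strand in record.cds_features:
            nt = record.residues[start - 1 : end]
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            aa = _translate(nt).rstrip("*")
            if "*" in aa:
                aa = aa[: aa.index("*")]  # annotated frame with premature stop: keep 5' part
            if not aa:
                continue
            frame = (start - 1) % 3 + 1 if strand == "+" else -(((len(record) - end) % 3) + 1)
            out.append(
                ProteinCandidate(record.id, aa, "annotated_cds", frame=frame, parent_span=(start, end))
            )
        return out

    seq = record.residues.replace("U", "T")
    rc = str(Seq(seq).reverse_complement())
    best = None  # (length, order_rank, start_in_frame, candidate)
    for rank, (frame, template) in enumerate(
        [(1, seq), (2, seq), (3, seq), (-1, rc), (-2, rc), (-3, rc)]
    ):
        off = abs(frame) - 1
        for aa, s0, e0 in _orfs_in_frame(template, off):
            if len(aa) < min_length:
                continue
            if frame > 0:
                span = (s0 + 1, min(e0 + 3, len(seq)))  # include stop codon if present
            else:
                span = (len(seq) - min(e0 + 3, len(seq)) + 1, len(seq) - s0)
            key = (-len(aa), rank, s0)
            if best is None or key < best[0]:
                best = (key, ProteinCandidate(record.id, aa, "longest_orf", frame=frame, parent_span=span))
    return [best[1]] if best else []


def extract_domain(protein: ProteinCandidate | str, span: tuple[int, int]) -> str:
    """Slice a 1-based inclusive span; e.g. (1, 373) is an N-terminal domain."""
    residues = protein if isinstance(protein, str) else protein.residues
    start, end = span
    if not (1 <= start <= end <= len(residues)):
        raise BoundsError(
            f"span ({start},{end}) outside sequence of length {len(residues)}"
        )
    return residues[start - 1 : end]
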