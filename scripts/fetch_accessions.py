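#!/usr/bin/env python
"""Optional helper: download the real reference accessions from NCBI.

Fetches the GenBank records commonly used as references and queries for
coral AOS-LOX curation (e.g. EU082210.1, KF000373.1, AF003692.1,
AAF93169.1) so they can be fed to `corallox annotate` as --lox-reference
/ --cox-reference.  Requires network access; nothing in the library or
test suite depends on this script.

Usage:  python scripts/fetch_accessions.py --email you@example.org --out refs/
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

DEFAULT_ACCESSIONS = [
    "EU082210.1",   # Gersemia fruticosa AOS-8R-LOX (numbering reference)
    "KF000373.1",   # Capnella imbricata AOS-8R-LOXa
    "KF000374.1",   # Capnella imbricata HPL-8R-LOX
    "AF003692.1",   # Plexaura homomalla AOS-8R-LOX
    "AB188528.1",   # Clavularia viridis putative AOS-LOX
    "AAF93169.1",   # Plexaura homomalla COX
]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact email")
    parser.add_argument("--out", type=Path, default=Path("refs"))
    parser.add_argument("--accessions", nargs="*", default=DEFAULT_ACCESSIONS)
    args = parser.parse_args()

    Entrez.email = args.email
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in args.accessions:
        db = "protein" if acc[:2].isalpha() and acc[2].isdigit() is False else "nuccore"
        for attempt_db in (db, "nuccore", "protein"):
            try:
                with Entrez.efetch(
                    db=attempt_db, id=acc, rettype="gb", retmode="text"
                ) as handle:
                    record = SeqIO.read(handle, "genbank")
                break
            except Exception:
                record = None
        if record is None:
            print(f"FAILED {acc}")
            continue
        dest = args.out / f"{acc}.gb"
        SeqIO.write(record, dest, "genbank")
        print(f"fetched {acc} -> {dest} ({len(record.seq)} residues/bases)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
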