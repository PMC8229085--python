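#!/usr/bin/env python
"""Optional helper: download the deposited COI sequences from GenBank.

Fetches accessions MW604141-MW604196 (the survey's deposited MEAM1 and MED
COI amplicons) into data/deposited/med_coi.fasta, which enables the
deposited-data test tier.  Requires network access; nothing in the build
or the default test run depends on it.

Usage:  python scripts/fetch_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

ACCESSIONS = [f"MW{604141 + i}" for i in range(56)]
OUT = Path(__file__).parent.parent / "data" / "deposited" / "med_coi.fasta"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="anonymous@example.org",
                        help="identity reported to NCBI Entrez")
    args = parser.parse_args()
    Entrez.email = args.email
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with Entrez.efetch(
        db="nucleotide", id=",".join(ACCESSIONS), rettype="fasta",
        retmode="text",
    ) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != len(ACCESSIONS):
        raise SystemExit(
            f"expected {len(ACCESSIONS)} records, got {len(records)}"
        )
    SeqIO.write(records, OUT, "fasta")
    print(f"wrote {len(records)} records to {OUT}")


if __name__ == "__main__":
    main()
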