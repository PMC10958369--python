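"""Download the four Fannia mitogenome GenBank records used by the
published-number acceptance tests into data/accessions/.

Requires network access to NCBI E-utilities:

    python scripts/fetch_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

ACCESSIONS = ("OQ692989", "NC_053661", "NC_068710", "MT628564")
OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "accessions"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="mitocompare@example.org",
                        help="Contact email passed to NCBI Entrez.")
    args = parser.parse_args()

    from Bio import Entrez

    Entrez.email = args.email
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = OUT_DIR / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        print(f"{acc}: fetching ...")
        with Entrez.efetch(db="nuccore", id=acc, rettype="gb",
                           retmode="text") as handle:
            dest.write_text(handle.read())
        print(f"{acc}: wrote {dest}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
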