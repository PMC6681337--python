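#!/usr/bin/env python
"""Download the deposited reference structures and sequences (network needed).

Populates data/reference/ with:

* 6jf2.pdb — crystal structure of the FlgG core fragment (two chains/ASU)
* 6jzr.cif — distal-rod assembly model
* 6jzt.cif — hook assembly model
* 5jxl.cif — Campylobacter FlgE (D0 + l-stretch + D1 donor)
* 3a69.pdb — Salmonella FlgE D0/D1 model
* P0A1J3.fasta / P0A1J1.fasta — FlgG and FlgE sequences

The tests in tests/test_acceptance.py that exercise deposited data skip
until this script has been run.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "reference"

FILES = {
    "6jf2.pdb": "https://files.rcsb.org/download/6JF2.pdb",
    "6jzr.cif": "https://files.rcsb.org/download/6JZR.cif",
    "6jzt.cif": "https://files.rcsb.org/download/6JZT.cif",
    "5jxl.cif": "https://files.rcsb.org/download/5JXL.cif",
    "3a69.pdb": "https://files.rcsb.org/download/3A69.pdb",
    "P0A1J3.fasta": "https://rest.uniprot.org/uniprotkb/P0A1J3.fasta",
    "P0A1J1.fasta": "https://rest.uniprot.org/uniprotkb/P0A1J1.fasta",
}


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for name, url in FILES.items():
        dest = DATA_DIR / name
        if dest.exists():
            print(f"{name}: already present")
            continue
        print(f"{name}: downloading from {url}")
        urllib.request.urlretrieve(url, dest)
    print(f"done; files in {DATA_DIR}")


if __name__ == "__main__":
    main()
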