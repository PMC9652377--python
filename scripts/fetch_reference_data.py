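#!/usr/bin/env python
"""Download the reference inputs used by the two external-data acceptance tests.

Fetches into data/reference/:
  * 3ODU.pdb              — antagonist-bound CXCR4 homodimer crystal structure
  * cxcr4_human.fasta     — human CXCR4 (UniProt P61073)
  * us28_hcmv.fasta       — HCMV US28 (UniProt P69332)
  * arrb2_human.fasta     — human β-arrestin-2 (UniProt P32121)
  * arrestin1_human.fasta — human visual arrestin-1 / S-antigen (UniProt P10523)

Requires network access; the rest of the package never does.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

TARGETS = {
    "3ODU.pdb": "https://files.rcsb.org/download/3ODU.pdb",
    "cxcr4_human.fasta": "https://rest.uniprot.org/uniprotkb/P61073.fasta",
    "us28_hcmv.fasta": "https://rest.uniprot.org/uniprotkb/P69332.fasta",
    "arrb2_human.fasta": "https://rest.uniprot.org/uniprotkb/P32121.fasta",
    "arrestin1_human.fasta": "https://rest.uniprot.org/uniprotkb/P10523.fasta",
}


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "reference"
    out_dir.mkdir(parents=True, exist_ok=True)
    failures = 0
    for name, url in TARGETS.items():
        dest = out_dir / name
        if dest.exists():
            print(f"{name}: already present")
            continue
        try:
            with urllib.request.urlopen(url, timeout=60) as response:
                dest.write_bytes(response.read())
            print(f"{name}: fetched from {url}")
        except OSError as exc:
            failures += 1
            print(f"{name}: FAILED ({exc})", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
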