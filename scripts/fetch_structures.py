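#!/usr/bin/env python
"""Download the deposited PDB structures used by the acceptance targets.

Run on a machine with network access:

    python scripts/fetch_structures.py

Files are written as plain-text PDB under data/structures/.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ("4WIS", "6OY3", "6QMA")
DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "structures"


def main() -> int:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = DATA_DIR / f"{acc.lower()}.pdb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = f"https://files.rcsb.org/download/{acc}.pdb"
        print(f"fetching {url} ...")
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                dest.write_bytes(resp.read())
        except Exception as exc:
            print(f"failed to fetch {acc}: {exc}", file=sys.stderr)
            return 1
        print(f"wrote {dest} ({dest.stat().st_size} bytes)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
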