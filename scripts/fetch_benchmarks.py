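#!/usr/bin/env python
"""Optional: download the benchmark GPCR:G-protein structures from the PDB.

The six complexes commonly used to benchmark static-structure interface
contacts are 3SN6 (beta2AR:Gs), 6GDG (A2AR:mini-Gs), 6D9H (A1R:Gi2),
6G79 (5HT1BR:Go), 7DFL (H1R:Gq) and 7F6G (AT1R:Gq).  This script only
fetches coordinates; the generic-numbering mapping tables (BW / CGN) must
be supplied separately by the user, e.g. exported from GPCRdb — the library
deliberately never fetches them itself.

Usage:  python scripts/fetch_benchmarks.py --outdir scratch/benchmarks
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

PDB_IDS = ("3SN6", "6GDG", "6D9H", "6G79", "7DFL", "7F6G")
URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("scratch/benchmarks"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for pdb_id in PDB_IDS:
        dest = args.outdir / f"{pdb_id}.pdb"
        if dest.exists():
            print(f"{pdb_id}: already present")
            continue
        print(f"{pdb_id}: downloading ...")
        urllib.request.urlretrieve(URL.format(pdb_id=pdb_id), dest)
    print(f"done -> {args.outdir}")


if __name__ == "__main__":
    main()
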