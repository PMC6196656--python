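#!/usr/bin/env python
"""Download the deposited CaSR ECD crystal structures (mmCIF) used by the
structural worked examples into data/structures/. Requires network access.

Usage: python scripts/fetch_structures.py [--entries 5K5S 5K5T 5FBK 5FBH]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

DEFAULT_ENTRIES = ("5K5S", "5K5T", "5FBK", "5FBH")
DEST = Path(__file__).resolve().parents[1] / "data" / "structures"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--entries", nargs="+", default=list(DEFAULT_ENTRIES))
    args = parser.parse_args()
    DEST.mkdir(parents=True, exist_ok=True)
    for entry in args.entries:
        url = f"https://files.rcsb.org/download/{entry.upper()}.cif"
        dest = DEST / f"{entry.lower()}.cif"
        print(f"fetching {url} -> {dest}")
        urllib.request.urlretrieve(url, dest)
    print("done")


if __name__ == "__main__":
    main()
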