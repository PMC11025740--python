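#!/usr/bin/env python
"""Download the deposited chick SEG measurement tables (network required).

Fetches every file of Figshare article 22341070 (DOI
10.6084/m9.figshare.22341070) into ``data/figshare/raw/``.  The deposit's
exact schema is not standardized, so after downloading, normalize the
tables into a single canonical CSV at ``data/figshare/measurements.csv``
with columns ``embryo_id, operator, time_min, seg_length_um`` — writing a
``data/figshare/colmap.yaml`` column map (see
:class:`somite_staircase.ColumnMap`) if renaming/unit conversion or
per-embryo start-somite assignment (late windows start at somite 14) is
needed.  The deposited-data tests in tests/test_acceptance.py then run
against that file.

Usage:  python scripts/fetch_figshare.py [--dest data/figshare]
"""

from __future__ import annotations

import argparse
import json
import urllib.request
from pathlib import Path

API = "https://api.figshare.com/v2/articles/22341070"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dest", type=Path, default=Path("data/figshare"))
    args = ap.parse_args()

    raw_dir = args.dest / "raw"
    raw_dir.mkdir(parents=True, exist_ok=True)

    with urllib.request.urlopen(API, timeout=60) as resp:
        article = json.load(resp)

    for f in article.get("files", []):
        target = raw_dir / f["name"]
        print(f"downloading {f['name']} ({f['size']} bytes) ...")
        urllib.request.urlretrieve(f["download_url"], target)

    print(f"done; files in {raw_dir}")
    print(
        "next: normalize the tables to "
        f"{args.dest / 'measurements.csv'} (canonical columns: "
        "embryo_id, operator, time_min, seg_length_um)"
    )


if __name__ == "__main__":
    main()
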