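"""Fetch the Ramilowski et al. (2015) human ligand-receptor resource.

Downloads the FANTOM5 pair table (708 ligands, 691 receptors, 2557
literature-supported interactions), keeps the ligand/receptor gene-symbol
columns, and writes data/ramilowski_lr.csv in the two-column format the
package loads.  Network access required; the table is third-party data and
is deliberately not shipped with the package.

An alternative resource in the same two-column format can be substituted
anywhere a database path is accepted.

Usage:  python scripts/fetch_lr_database.py [--out data/ramilowski_lr.csv]
"""

from __future__ import annotations

import argparse
import io
import urllib.request
from pathlib import Path

import pandas as pd

URL = (
    "https://fantom.gsc.riken.jp/5/suppl/Ramilowski_et_al_2015/data/"
    "PairsLigRec.txt"
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("data/ramilowski_lr.csv"))
    ap.add_argument("--url", default=URL)
    args = ap.parse_args()

    with urllib.request.urlopen(args.url, timeout=60) as resp:
        raw = resp.read().decode("utf-8", errors="replace")
    table = pd.read_csv(io.StringIO(raw), sep="\t")
    pairs = table[["Ligand.ApprovedSymbol", "Receptor.ApprovedSymbol"]].rename(
        columns={
            "Ligand.ApprovedSymbol": "ligand",
            "Receptor.ApprovedSymbol": "receptor",
        }
    )
    pairs = pairs.drop_duplicates().reset_index(drop=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(args.out, index=False)
    print(
        f"wrote {len(pairs)} pairs "
        f"({pairs.ligand.nunique()} ligands, {pairs.receptor.nunique()} receptors) "
        f"to {args.out}"
    )


if __name__ == "__main__":
    main()
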