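#!/usr/bin/env python
"""Optional reproduction on the deposited cohort data.

The preprocessed expression matrix and clinical annotations of the
study cohort are public (Zenodo, https://doi.org/10.5281/zenodo.17437183;
raw spectra under ProteomeXchange PXD071328).  This script is NOT part
of the test suite: it requires the user to download those files and
convert them to the package's formats (expression TSV, clinical CSV,
GMT, matrisome TSV).  Given them, it reruns the full pipeline and
prints the benchmark quantities to compare with the publication:
the number of differentially expressed proteins between AJ groups
(2299 of 4492), the AJ-subset distance medians (3.19 / 3.79 / 3.45)
and the whole-proteome distance medians (85.81 / 87.59 / 91.78).

Usage:
    python scripts/reproduce_deposited.py \
        --expression expr.tsv --clinical clinical.csv \
        --gmt keg_sets.gmt --matrisome matrisome.tsv --out results/deposited
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from ajstrat import RunConfig, run_full_pipeline
from ajstrat.io import read_clinical, read_expression, read_gmt, read_matrisome


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--expression", type=Path, required=True)
    parser.add_argument("--clinical", type=Path, required=True)
    parser.add_argument("--gmt", type=Path, required=True)
    parser.add_argument("--matrisome", type=Path, default=None)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/deposited"))
    args = parser.parse_args(argv)

    missing = [p for p in (args.expression, args.clinical, args.gmt)
               if not p.exists()]
    if missing:
        parser.error(
            "input file(s) not found: "
            + ", ".join(str(p) for p in missing)
            + " — download the deposited data first (see module docstring)"
        )

    expr = read_expression(args.expression)
    clinical = read_clinical(args.clinical)
    gene_sets = read_gmt(args.gmt)
    matrisome = None
    if args.matrisome is not None:
        matrisome = set(read_matrisome(args.matrisome)["protein_id"])

    bundle = run_full_pipeline(
        expr, clinical, gene_sets, matrisome, RunConfig(seed=args.seed)
    )
    bundle.write_reports(args.out)

    s = bundle.summary
    print(f"proteins tested: {s.get('n_de_tested')}")
    print(f"differentially expressed: {s.get('n_de_significant')}")
    for key, value in sorted(s.items()):
        if key.startswith("median_"):
            print(f"{key}: {value:.2f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
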