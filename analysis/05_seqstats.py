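#!/usr/bin/env python
"""Fragment sequence statistics.

Always computes the published-coordinate fragment lengths (coordinates are
inputs; no sequence needed).  When the GenBank FASTA files are present under
data/accessions/, additionally computes per-fragment A+T / G+C content, the
asymmetric identity matrix over the three oyster species (upper triangle 5'
fragments, lower triangle 3' fragments), and the circular separation of the
*C. virginica* fragments.

Writes TSV/JSON under results/seqstats/.
"""

import argparse
import json
from pathlib import Path

from oysterlsu.accessions import (
    AccessionDataMissing,
    FRAGMENTS,
    cv_fragment_separation,
    fragment_base_content,
    fragment_lengths,
    oyster_similarity_matrix,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data-dir", type=Path, default=Path("data/accessions"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/seqstats"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    lengths = fragment_lengths()
    (out / "fragment_lengths.json").write_text(json.dumps(lengths, indent=1))
    for acc, vals in lengths.items():
        print(f"{acc} ({FRAGMENTS[acc]['species']}):",
              ", ".join(f"{k}={v} nt" for k, v in vals.items()))

    try:
        content = {
            acc: fragment_base_content(acc, args.data_dir)
            for acc in ("AY905542", "AF177226", "EU672834")
        }
    except AccessionDataMissing as exc:
        print(f"\naccession sequences not available ({exc}); "
              "sequence-derived statistics skipped")
        return

    matrix = oyster_similarity_matrix(args.data_dir)
    matrix.to_csv(out / "similarity_matrix.tsv", sep="\t", na_rep="-")
    gap_a, gap_b = cv_fragment_separation(args.data_dir)
    (out / "base_content.json").write_text(json.dumps(content, indent=1))
    print("\nA+T% per fragment:", content)
    print("identity matrix (upper 5', lower 3'):")
    print(matrix.to_string(na_rep="-"))
    print(f"C. virginica fragment separation: {gap_a} nt forward")


if __name__ == "__main__":
    main()
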