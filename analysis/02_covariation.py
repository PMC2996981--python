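#!/usr/bin/env python
"""Covariation analysis of the simulated alignment: mutual information and
chi-square per column pair, greedy pair prediction, and scoring against the
generating structure.

Reads results/simulate/ (run 01_simulate.py first, same seed); writes the
statistics TSV, the predicted structure, and a score summary.
"""

import argparse
import json
from pathlib import Path

from oysterlsu.covariation import (
    RnaAlignment,
    covariation_matrix,
    predict_pairs,
    write_stats_tsv,
)
from oysterlsu.formats import read_ct, to_dotbracket, write_ct


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--in-dir", type=Path, default=Path("results/simulate"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/covariation"))
    parser.add_argument("--mi-threshold", type=float, default=0.3)
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    aln = RnaAlignment.from_fasta(args.in_dir / "alignment.fasta")
    truth = read_ct(args.in_dir / "structure.ct")
    stats = covariation_matrix(aln)
    write_stats_tsv(stats, out / "pair_stats.tsv")
    predicted = predict_pairs(stats, mi_threshold=args.mi_threshold)
    write_ct(predicted, out / "predicted.ct", title="predicted")
    (out / "predicted.dbn").write_text(to_dotbracket(predicted) + "\n")

    tp = len(predicted.pairs & truth.pairs)
    ppv = tp / len(predicted.pairs) if predicted.pairs else 0.0
    recall = tp / len(truth.pairs)
    summary = {"n_true": len(truth.pairs), "n_predicted": len(predicted.pairs),
               "true_positives": tp, "ppv": ppv, "recall": recall}
    (out / "scores.json").write_text(json.dumps(summary, indent=1))
    print(f"{len(stats)} column pairs scored; "
          f"{len(predicted.pairs)} pairs predicted")
    print(f"PPV {ppv:.3f}, recall {recall:.3f} against the true structure")


if __name__ == "__main__":
    main()
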