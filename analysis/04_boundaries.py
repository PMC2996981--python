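#!/usr/bin/env python
"""EST-driven boundary inference: map the simulated ESTs back to the genome,
call the 5'/3' boundaries of the transcribed fragment, score exact recovery
over 20 independent simulations, and report the circular separation between
the two fragments — the synthetic analogue of locating a fragmented gene's
halves from transcript evidence on a mitochondrial genome.

Writes the boundary call and the recovery summary under results/boundaries/.
"""

import argparse
import json
from pathlib import Path

from oysterlsu.boundaries import fragment_separation
from oysterlsu.pipeline import boundary_recovery_experiment, boundary_recovery_rate
from oysterlsu.synthetic import SimConfig


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/boundaries"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    call, interval = boundary_recovery_experiment(seed=args.seed)
    rate = boundary_recovery_rate(n_runs=20, base_seed=args.seed)
    config = SimConfig(seed=args.seed)
    gap_a, gap_b = fragment_separation(
        config.genome_length, config.frag5, config.frag3
    )

    payload = {
        "call": {"start": call.start, "end": call.end,
                 "start_evidence": call.start_evidence,
                 "end_fraction": call.end_fraction},
        "truth": list(interval),
        "exact": (call.start, call.end) == interval,
        "recovery_rate_20_runs": rate,
        "fragment_separation": {"forward_gap": gap_a, "complement_gap": gap_b},
    }
    (out / "boundary_report.json").write_text(json.dumps(payload, indent=1))
    print(f"call ({call.start}, {call.end}) vs truth {interval}; "
          f"modal poly(A) fraction {call.end_fraction:.2f}")
    print(f"exact recovery in {rate:.0%} of 20 runs")
    print(f"circular gaps between fragments: {gap_a} nt forward, {gap_b} nt back")


if __name__ == "__main__":
    main()
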