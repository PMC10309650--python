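#!/usr/bin/env python
"""External benchmark reproduction (requires user-supplied data).

Runs the full 20-repetition held-out-pair cross-validation on a
user-provided gold-standard dataset — e.g. one family of the four-part
Yamanishi drug-target benchmark, with descriptor tables exported from
ChemDes/BioTriangle — and writes per-repetition metrics.  None of this
data ships with the package; download and descriptor extraction are up
to the user.

    python scripts/reproduce_benchmark.py \
        --drugs drug_features.tsv --targets target_features.tsv \
        --interactions interactions.tsv --out metrics.tsv --seed 0

Expect hours of runtime at the full settings (100 trees, 20 nets,
100 epochs, 20 repetitions).
"""

from __future__ import annotations

import argparse

from engdd.config import RunConfig
from engdd.data_io import read_feature_table, read_interactions
from engdd.pipeline import evaluate_repeated


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--drugs", required=True)
    ap.add_argument("--targets", required=True)
    ap.add_argument("--interactions", required=True)
    ap.add_argument("--scheme", default="pair",
                    choices=["pair", "drug", "target"])
    ap.add_argument("--repetitions", type=int, default=20)
    ap.add_argument("--config", default=None)
    ap.add_argument("--out", required=True)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = RunConfig.from_yaml(args.config) if args.config else RunConfig()
    drugs = read_feature_table(args.drugs, "drug")
    targets = read_feature_table(args.targets, "target")
    interactions = read_interactions(args.interactions, drugs, targets)
    report = evaluate_repeated(drugs, targets, interactions, cfg,
                               scheme=args.scheme,
                               repetitions=args.repetitions,
                               base_seed=args.seed)
    report.to_tsv(args.out)
    print(report.summary_frame().round(4))


if __name__ == "__main__":
    main()
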