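#!/usr/bin/env python
"""Optional validation against the published full-scale network.

Runs the complete pipeline at its default operating point (100 clusters,
1000 K-means initializations, 500 vbsr restarts, alpha = 0.05) on a local
copy of the Dehalococcoides microarray log-ratio matrix (NCBI GEO series
GSE26288, genes x samples TSV) and its condition table, then compares the
resulting network statistics against the published values within a +/-10%
tolerance band. Clustering and restart stochasticity mean this is a
tolerance-band check, not an exact reproduction; it requires the externally
downloaded data and is therefore not part of the test suite.

Usage:
    python scripts/validate_full_study.py \
        --expression ratios.tsv --conditions conditions.tsv --out results/full
"""
from __future__ import annotations

import argparse
import json
import sys

REFERENCE = {
    "n_connected_nodes": 118.0,
    "mean_degree": 4.37,
    "n_isolated_variables": 24.0,
    "condition_mean_degree": 1.50,
    "cluster_mean_r2": 0.73,
    "cluster_median_size": 12.0,
}


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--expression", required=True,
                        help="genes x samples log-ratio TSV (GSE26288-derived)")
    parser.add_argument("--conditions", required=True,
                        help="samples x condition-variables TSV")
    parser.add_argument("--out", required=True, help="output directory")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--tolerance", type=float, default=0.10,
                        help="relative tolerance band (default 10%%)")
    args = parser.parse_args(argv)

    from spinet.cli import RunConfig, run_pipeline

    stats = run_pipeline(
        args.expression, args.conditions, args.out,
        config=RunConfig(seed=args.seed), heatmap=True,
    )
    report = {}
    ok = True
    for key, expected in REFERENCE.items():
        observed = stats.get(key)
        if observed is None:
            report[key] = {"expected": expected, "observed": None, "within_band": False}
            ok = False
            continue
        within = abs(observed - expected) <= args.tolerance * abs(expected)
        report[key] = {
            "expected": expected,
            "observed": float(observed),
            "within_band": bool(within),
        }
        ok = ok and within
    print(json.dumps(report, indent=2))
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
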