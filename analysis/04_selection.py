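#!/usr/bin/env python
"""Sequential trait-category selection of optimum predictors per habitat.

Runs the hierarchical exhaustive-AIC search — morphology, then anatomy with
morphology's winners as covariates, then physiology — separately for steppe
and alpine pools, and on the full species set.  Reports per-stage best
subsets, delta-AIC-when-omitted importances, near-ties, and the adjusted-R^2
staircase.

Reads results/data/ and results/optima.csv; writes results/ledger_<pool>.json
and results/report_<pool>.txt.
"""

from pathlib import Path

import pandas as pd

from elevtrait import io as eio
from elevtrait.selection import DEFAULT_CATEGORIES, sequential_selection

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tree = eio.read_tree(ROOT / "data" / "tree.nwk")
    traits = eio.read_traits(ROOT / "data" / "traits.csv")
    optima = pd.read_csv(ROOT / "optima.csv").set_index("species")["optimum_m"]
    analysis = traits.join(optima.rename("optimum"), how="inner")

    pools = {"steppe": analysis[analysis["habitat"] == "steppe"],
             "alpine": analysis[analysis["habitat"] == "alpine"],
             "all": analysis}
    for name, pool in pools.items():
        ledger = sequential_selection(pool.dropna(subset=["optimum"]), tree,
                                      DEFAULT_CATEGORIES)
        ledger.to_json(ROOT / f"ledger_{name}.json")
        report = ledger.report()
        (ROOT / f"report_{name}.txt").write_text(report + "\n")
        print(f"--- {name} (n={len(pool)}) ---")
        print(report)


if __name__ == "__main__":
    main()
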