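#!/usr/bin/env python
"""Phylogenetic PCA of traits and elevational distribution per habitat.

Ordinates the continuous traits together with each species' estimated
elevational optimum, minimum, and maximum (correlation mode, multivariate
ML lambda), then passively projects the growth-form categories as centroids
on the first two components.

Reads results/data/ and results/optima.csv; writes results/ppca_<habitat>.json.
"""

import json
from pathlib import Path

import pandas as pd

from elevtrait import io as eio
from elevtrait.ppca import phylo_pca, project_categories
from elevtrait.screen import PUBLISHED_TABLE

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tree = eio.read_tree(ROOT / "data" / "tree.nwk")
    traits = eio.read_traits(ROOT / "data" / "traits.csv")
    opt = pd.read_csv(ROOT / "optima.csv").set_index("species")

    cont = [t for t in PUBLISHED_TABLE["trait"]
            if t in traits.columns and t != "growth_form"]
    for hab in ("steppe", "alpine"):
        pool = traits[traits["habitat"] == hab]
        mat = pool[cont].join(opt[["optimum_m", "min_m", "max_m"]],
                              how="inner").dropna()
        res = phylo_pca(mat, tree)
        cent = project_categories(res.scores, pool.loc[mat.index, "growth_form"])
        payload = res.to_dict()
        payload["centroids"] = {i: r.drop("flag").to_dict()
                                for i, r in cent.iterrows()}
        with open(ROOT / f"ppca_{hab}.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        print(f"{hab}: n={len(mat)}, lambda={res.lambda_hat:.3f}, "
              f"PC1 {res.percent_variance[0]:.1f}% + "
              f"PC2 {res.percent_variance[1]:.1f}% "
              f"= {res.percent_variance[:2].sum():.1f}% of variance")
        ordered = cent["PC1"].sort_values()
        print(f"  growth-form centroids along PC1: "
              f"{' < '.join(ordered.index)}")


if __name__ == "__main__":
    main()
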