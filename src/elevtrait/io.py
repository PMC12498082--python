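"""Readers, writers, and input validation.

Formats: Newick for trees, RFC-4180 CSV for trait / occurrence / optima
tables, JSON for ledgers and ordinations, YAML for configs.  Species name
matching is exact after whitespace/underscore normalization; no fuzzy
matching.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from elevtrait.pgls import normalize_label

__all__ = [
    "read_tree", "write_tree", "read_traits", "write_traits",
    "read_occurrences", "write_occurrences", "read_config", "write_config",
    "ValidationReport", "validate_inputs", "config_hash",
]

OCC_COLUMNS = ("locality", "elevation_m", "species", "present")


def read_tree(path) -> dendropy.Tree:
    """Parse a rooted Newick tree; labels are de-quoted and normalized.

    Zero-length terminal branches are rejected (they would make the
    Brownian covariance singular); polytomies are accepted.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    bad = []
    for leaf in tree.leaf_node_iter():
        if not leaf.edge.length or leaf.edge.length <= 0:
            bad.append(leaf.taxon.label if leaf.taxon else "<unlabeled>")
    if bad:
        raise ValueError(f"zero/negative-length terminal branches for: {bad}")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaf.taxon.label = normalize_label(leaf.taxon.label)
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("traits CSV needs a 'species' column")
    df["species"] = df["species"].map(normalize_label)
    dup = df["species"][df["species"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate species rows: {sorted(dup.unique())}")
    return df.set_index("species")


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="species")


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {missing}")
    df["species"] = df["species"].map(normalize_label)
    if df.duplicated(["locality", "species"]).any():
        raise ValueError("duplicate (locality, species) records")
    if not set(pd.unique(df["present"])) <= {0, 1}:
        raise ValueError("present must be binary 0/1")
    return df


def write_occurrences(occ: pd.DataFrame, path) -> None:
    occ.to_csv(path, index=False, columns=list(OCC_COLUMNS))


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:12]


@dataclass
class ValidationReport:
    failures: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def __str__(self) -> str:
        lines = [f"FAIL: {m}" for m in self.failures]
        lines += [f"warn: {m}" for m in self.warnings]
        return "\n".join(lines) or "all checks passed"


_PERCENT_TRAITS = ("Mechanical tissue", "Storage tissue", "LNC", "LPC", "LCC",
                   "RNC", "RPC", "Starch", "Fructan", "Free sugar")
_NONNEG_TRAITS = ("Height", "Longevity", "Ring width")


def validate_inputs(tree, traits: pd.DataFrame | None = None,
                    occurrences: pd.DataFrame | None = None,
                    elev_range: tuple | None = None) -> ValidationReport:
    """Cross-check species sets and table invariants.

    Hard failures (species in traits but not in the tree, out-of-bound trait
    values, non-binary presence) halt the pipeline; soft issues (tree tips
    without trait rows, elevations outside the configured gradient) are
    warnings.
    """
    rep = ValidationReport()
    tips = {normalize_label(l.taxon.label) for l in tree.leaf_node_iter()
            if l.taxon is not None}
    if traits is not None:
        sp = set(traits.index.map(normalize_label))
        missing = sorted(sp - tips)
        if missing:
            rep.failures.append(f"species in traits but not in tree: {missing}")
        extra = sorted(tips - sp)
        if extra:
            rep.warnings.append(f"tree tips without trait rows: {extra[:10]}"
                                + ("..." if len(extra) > 10 else ""))
        for col in _PERCENT_TRAITS:
            if col in traits.columns:
                v = traits[col].dropna()
                if ((v < 0) | (v > 100)).any():
                    rep.failures.append(f"{col} outside [0, 100]")
        for col in _NONNEG_TRAITS:
            if col in traits.columns and (traits[col].dropna() < 0).any():
                rep.failures.append(f"{col} has negative values")
        if "habitat" in traits.columns:
            bad = set(traits["habitat"].dropna().astype(str)) - {"steppe", "alpine"}
            if bad:
                rep.failures.append(f"unknown habitat labels: {sorted(bad)}")
    if occurrences is not None:
        osp = set(occurrences["species"].map(normalize_label))
        missing = sorted(osp - tips)
        if missing and traits is not None:
            rep.warnings.append(
                f"occurrence species not in tree (ignored in PGLS stages): "
                f"{missing[:10]}" + ("..." if len(missing) > 10 else ""))
        if not set(pd.unique(occurrences["present"])) <= {0, 1}:
            rep.failures.append("presence is not binary")
        if elev_range is not None:
            lo, hi = elev_range
            out = occurrences[(occurrences["elevation_m"] < lo)
                              | (occurrences["elevation_m"] > hi)]
            if len(out):
                rep.warnings.append(
                    f"{len(out)} records outside configured gradient "
                    f"({lo:g}, {hi:g})")
    return rep
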