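"""Hypergeometric over-representation analysis against GMT gene sets.

For a test set of n genes drawn from a reference universe of N genes, the
overlap k with a gene set of size K (within the reference) is tested with
the upper-tail hypergeometric probability P(X >= k); p-values are BH
adjusted across all tested sets.  Increased and decreased core genes are
analysed separately; genes without a clear direction are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import SchemaError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content) with members deduplicated per set."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        deduped = {}
        for name, members in self.sets.items():
            seen: set[str] = set()
            clean = [g for g in members if not (g in seen or seen.add(g))]
            deduped[name] = clean
        self.sets = deduped

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def merge(cls, collections: list["GeneSetCollection"]) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        for coll in collections:
            for name, members in coll.sets.items():
                if name in sets:
                    raise SchemaError(f"duplicate gene-set name {name!r} across collections")
                sets[name] = members
        tag = "+".join(c.source_tag for c in collections if c.source_tag)
        return cls(sets, source_tag=tag)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def ora(
    test_set: set[str] | list[str],
    collection: GeneSetCollection,
    reference: set[str] | list[str],
    min_size: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    Test genes outside the reference are dropped with a warning.  Sets with
    fewer than ``min_size`` members inside the reference are skipped (listed
    in the ``skipped`` attribute of the result).  BH adjustment runs across
    all tested sets jointly.
    """
    reference = set(reference)
    if not reference:
        raise ValueError("empty reference universe")
    test = set(test_set)
    outside = test - reference
    if outside:
        logger.warning("dropping %d test genes outside the reference", len(outside))
        test &= reference
    if not test:
        raise ValueError("test set empty after intersection with reference")
    N, n = len(reference), len(test)
    rows, skipped = [], []
    for name, members in collection.sets.items():
        in_ref = set(members) & reference
        K = len(in_ref)
        if K < min_size:
            skipped.append(name)
            continue
        k = len(test & in_ref)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p_raw": p})
    if not rows:
        raise ValueError("no gene set passed the minimum-size filter")
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out = out.sort_values(["p_adj", "p_raw", "set_name"], kind="mergesort").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


def direction_split(core: pd.DataFrame) -> tuple[set[str], set[str], set[str]]:
    """Partition core features into increased / decreased / excluded (mixed).

    The three sets are disjoint and their union is the core set; features
    without a consistent fold-change direction across their core time points
    are excluded from enrichment.
    """
    core = core[core["is_core"]]
    increased = set(core.loc[core["direction"] == "increased", "feature_id"])
    decreased = set(core.loc[core["direction"] == "decreased", "feature_id"])
    excluded = set(core.loc[core["direction"] == "mixed", "feature_id"])
    return increased, decreased, excluded
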