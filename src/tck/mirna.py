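"""Inverse-correlation matching of deregulated miRNAs to putative targets.

For every miRNA/gene pair, the Pearson correlation of the two per-timepoint
median-log2FC (PD vs HC) profiles is computed; a pair is a putative
regulatory match when the correlation is at or below a negative threshold
(default -0.5) and the gene's fold-change profile moves opposite to the
miRNA's direction by at least a gate (default 0.3 log2 units) at one or
more time points.  Matches can then be flagged against a table of
experimentally validated miRNA targets ("strong" evidence tier).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import SchemaError

logger = logging.getLogger(__name__)


def fc_profiles(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a differential table into feature x time median-log2FC profiles."""
    prof = table.pivot(index="feature_id", columns="time_h", values="median_log2fc")
    return prof.sort_index(axis=1)


def fc_profile(table: pd.DataFrame, feature_id: str) -> pd.Series:
    """Time-ordered median-log2FC profile of one feature."""
    sub = table[table["feature_id"] == feature_id]
    if sub.empty:
        raise SchemaError(f"feature {feature_id!r} absent from differential table")
    return sub.sort_values("time_h").set_index("time_h")["median_log2fc"]


def _pairwise_pcc(m: np.ndarray, G: np.ndarray, min_shared: int) -> np.ndarray:
    """PCC of one miRNA profile against each row of G, NaN-aware.

    Pairs with fewer than ``min_shared`` shared finite points or with a
    zero-variance profile get NaN.
    """
    valid = np.isfinite(G) & np.isfinite(m)[None, :]
    n_sh = valid.sum(axis=1)
    Mv = np.where(valid, m[None, :], 0.0)
    Gv = np.where(valid, G, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = Mv.sum(1) / n_sh
        gm = Gv.sum(1) / n_sh
        mc = np.where(valid, Mv - mm[:, None], 0.0)
        gc = np.where(valid, Gv - gm[:, None], 0.0)
        num = (mc * gc).sum(1)
        den = np.sqrt((mc**2).sum(1) * (gc**2).sum(1))
        pcc = num / den
    pcc[(n_sh < min_shared) | (den == 0)] = np.nan
    return pcc


def match_targets(
    mirna_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    mirna_directions: pd.Series | dict[str, str],
    theta_pcc: float = -0.5,
    theta_fc: float = 0.3,
    min_shared: int = 3,
    return_all: bool = False,
) -> pd.DataFrame:
    """Match miRNAs to putative targets by inverse FC-profile correlation.

    ``mirna_directions`` labels each miRNA ``increased`` or ``decreased``
    (its deregulation direction in the PD group).  A pair matches when
    PCC <= ``theta_pcc`` and the gene shows a median log2FC of at most
    ``-theta_fc`` (miRNA increased) or at least ``+theta_fc`` (miRNA
    decreased) at one or more time points.  By default only pairs passing
    the PCC gate are returned; ``return_all=True`` returns every scored pair.
    Pairs whose correlation is undefined (zero variance, < ``min_shared``
    shared time points) are skipped.
    """
    dirs = pd.Series(mirna_directions)
    mirna_profiles = mirna_profiles.sort_index(axis=1)
    gene_profiles = gene_profiles.sort_index(axis=1)
    if not mirna_profiles.columns.equals(gene_profiles.columns):
        raise SchemaError("miRNA and gene profiles cover different time points")
    G = gene_profiles.to_numpy(dtype=float)
    gene_ids = gene_profiles.index
    with np.errstate(invalid="ignore"):
        gene_min = np.nanmin(np.where(np.isfinite(G), G, np.inf), axis=1)
        gene_max = np.nanmax(np.where(np.isfinite(G), G, -np.inf), axis=1)
    frames = []
    n_skipped = 0
    for mid in mirna_profiles.index:
        if mid not in dirs.index:
            raise SchemaError(f"no direction label for miRNA {mid!r}")
        direction = dirs[mid]
        if direction not in ("increased", "decreased"):
            raise SchemaError(
                f"direction for {mid!r} must be 'increased' or 'decreased', got {direction!r}"
            )
        m = mirna_profiles.loc[mid].to_numpy(dtype=float)
        pcc = _pairwise_pcc(m, G, min_shared)
        defined = np.isfinite(pcc)
        n_skipped += int((~defined).sum())
        passes_pcc = defined & (pcc <= theta_pcc)
        if direction == "increased":
            passes_fc = gene_min <= -theta_fc
        else:
            passes_fc = gene_max >= theta_fc
        keep = defined if return_all else passes_pcc
        frames.append(
            pd.DataFrame(
                {
                    "mirna_id": mid,
                    "gene_id": gene_ids[keep],
                    "pcc": pcc[keep],
                    "passes_pcc": passes_pcc[keep],
                    "passes_fc_gate": passes_fc[keep],
                }
            )
        )
    if n_skipped:
        logger.info("skipped %d pairs with undefined correlation", n_skipped)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["mirna_id", "gene_id", "pcc", "passes_pcc", "passes_fc_gate"]
    )
    out["match"] = out["passes_pcc"] & out["passes_fc_gate"]
    return out


def intersect_validated(
    matches: pd.DataFrame, target_table: pd.DataFrame
) -> pd.DataFrame:
    """Flag matches present in a validated-target table with strong evidence.

    ``target_table`` needs columns ``mirna_id``, ``gene_id``, ``evidence``;
    rows with missing fields are skipped and counted.  All matches are
    retained; a ``validated`` flag (evidence tier "strong", case-insensitive)
    and the evidence string are added.
    """
    required = {"mirna_id", "gene_id", "evidence"}
    missing = required - set(target_table.columns)
    if missing:
        raise SchemaError(f"target table missing columns: {sorted(missing)}")
    tab = target_table.dropna(subset=["mirna_id", "gene_id", "evidence"])
    n_bad = len(target_table) - len(tab)
    if n_bad:
        logger.warning("skipped %d malformed target-table rows", n_bad)
    evidence = {
        (str(r.mirna_id), str(r.gene_id)): str(r.evidence)
        for r in tab.itertuples(index=False)
    }
    out = matches.copy()
    keys = list(zip(out["mirna_id"].astype(str), out["gene_id"].astype(str)))
    out["evidence"] = [evidence.get(k, "") for k in keys]
    out["validated"] = [evidence.get(k, "").strip().lower() == "strong" for k in keys]
    return out
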