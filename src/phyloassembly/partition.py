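"""Five-process assembly classification from (betaNTI, RCbray) pairs.

Decision rule per sample pair:

* betaNTI > +2            -> variable selection
* betaNTI < -2            -> homogeneous selection
* else RCbray > +0.95     -> dispersal limitation
* else RCbray < -0.95     -> homogenizing dispersal
* else (|RCbray| <= 0.95) -> undominated (ecological drift)

Boundary values (betaNTI exactly +/-2, RCbray exactly +/-0.95) fall to
the stochastic / undominated side: the thresholds are read as strict
exceedances. "Stochastic" aggregates dispersal limitation, homogenizing
dispersal and undominated (|betaNTI| < 2).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .matrices import PairwiseMatrix

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

STOCHASTIC_PROCESSES = (
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def classify_pair(bnti: float, rc: float) -> str:
    """Assembly process for one sample pair; inputs must be finite."""
    if not (math.isfinite(bnti) and math.isfinite(rc)):
        raise ValueError(f"non-finite input: bnti={bnti}, rc={rc}")
    if bnti > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def classify_pairs(bnti: PairwiseMatrix, rc: PairwiseMatrix) -> pd.DataFrame:
    """Long-form classification of every sample pair.

    Pairs where betaNTI or RCbray is undefined (NaN, e.g. a degenerate
    null) are kept with ``process = NaN`` and ``flagged = True`` so that
    downstream summaries can report how many were excluded.
    """
    if bnti.sample_ids != rc.sample_ids:
        raise ValueError("betaNTI and RCbray matrices have different samples")
    df = bnti.pair_frame().rename(columns={bnti.metric_name: "bnti"})
    df["rc"] = rc.condensed()
    finite = np.isfinite(df["bnti"]) & np.isfinite(df["rc"])
    df["process"] = [
        classify_pair(b, r) if ok else None
        for b, r, ok in zip(df["bnti"], df["rc"], finite)
    ]
    df["flagged"] = ~finite
    return df


def partition_fractions(
    pairs: pd.DataFrame,
    grouping: dict[str, str] | pd.Series | None = None,
    scheme: str = "within_group",
) -> pd.DataFrame:
    """Per-group percentage of sample pairs assigned to each process.

    ``grouping`` maps sample id to group label (e.g. soil layer or
    elevation). ``scheme="within_group"`` counts only pairs whose two
    samples share a group; ``"all_pairs"`` pools every classified pair
    into a single group ``"all"``. Flagged pairs are excluded, with the
    excluded count reported per group. Percentages over classified pairs
    sum to 100; ``stochastic_pct`` is the sum over the non-selection
    processes (equivalently the share of pairs with |betaNTI| < 2).
    """
    if scheme not in ("within_group", "all_pairs"):
        raise ValueError(f"unknown scheme {scheme!r}")
    pairs = pairs.copy()
    if scheme == "all_pairs" or grouping is None:
        pairs["group"] = "all"
    else:
        grouping = dict(grouping) if not isinstance(grouping, dict) else grouping
        missing = (set(pairs["sample_a"]) | set(pairs["sample_b"])) - set(grouping)
        if missing:
            raise ValueError(f"samples missing from grouping: {sorted(missing)[:5]}")
        ga = pairs["sample_a"].map(grouping)
        gb = pairs["sample_b"].map(grouping)
        pairs["group"] = ga.where(ga == gb)
        pairs = pairs.dropna(subset=["group"])

    rows = []
    for group, sub in pairs.groupby("group", sort=True):
        n_flagged = int(sub["flagged"].sum())
        ok = sub[~sub["flagged"]]
        n = len(ok)
        rec = {"group": group, "n_pairs": n, "n_excluded": n_flagged}
        for proc in PROCESSES:
            rec[f"{proc}_pct"] = 100.0 * (ok["process"] == proc).sum() / n if n else float("nan")
        rec["stochastic_pct"] = (
            sum(rec[f"{p}_pct"] for p in STOCHASTIC_PROCESSES) if n else float("nan")
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("group")


def between_group_pairs(
    pairs: pd.DataFrame, grouping: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Subset of pairs whose two samples belong to different groups."""
    grouping = dict(grouping) if not isinstance(grouping, dict) else grouping
    ga = pairs["sample_a"].map(grouping)
    gb = pairs["sample_b"].map(grouping)
    return pairs[ga.ne(gb)].copy()
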