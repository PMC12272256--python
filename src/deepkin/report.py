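"""Scan-scale significance filtering and cohort/network summaries.

Operates on a pair table (columns ID1, ID2, THETA, P) as produced by the
kinship scan plus inference annotation, and on an optional cohort
assignment (sample ID -> label, optional grid x/y coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .infer import deepest_significant

__all__ = [
    "significant_pairs",
    "relative_networks",
    "cohort_summary",
]


def significant_pairs(
    pairs: pd.DataFrame,
    me: float,
    n_comparisons: int | None = None,
    alpha_policy: str = "bonferroni",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Filter a pair table to significant pairs and report the threshold.

    With the default 'bonferroni' policy the per-pair level is
    alpha / N over all N comparisons in the scan (N defaults to the
    number of rows, correct only if the table holds every scanned
    pair); with 'fixed' the level is alpha as given.  The returned
    header records alpha, theta_delta, delta and me.
    """
    if alpha_policy == "bonferroni":
        N = n_comparisons if n_comparisons is not None else len(pairs)
        alpha_eff = alpha / N
    elif alpha_policy == "fixed":
        alpha_eff = alpha
    else:
        raise ValueError(f"unknown alpha policy {alpha_policy!r}")
    deepest = deepest_significant(me, alpha_eff)
    kept = pairs[pairs["P"] < alpha_eff].copy()
    header = {
        "alpha": alpha_eff,
        "theta_delta": deepest.theta_delta,
        "delta": deepest.delta,
        "me": me,
        "n_comparisons": n_comparisons if n_comparisons is not None else len(pairs),
        "n_significant": len(kept),
    }
    return kept, header


def relative_networks(
    sig_pairs: pd.DataFrame,
) -> tuple[list[list[str]], dict[int, int]]:
    """Connected components of the significant-pair graph.

    Returns components as lists of sample IDs (each sorted, components
    ordered by smallest member) and a histogram {component size: count}.
    """
    g = nx.Graph()
    if len(sig_pairs):
        g.add_edges_from(zip(sig_pairs["ID1"].astype(str),
                             sig_pairs["ID2"].astype(str)))
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    hist: dict[int, int] = {}
    for c in components:
        hist[len(c)] = hist.get(len(c), 0) + 1
    return components, hist


def cohort_summary(
    pairs: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within- and cross-cohort relatedness summaries.

    ``pairs`` must contain every scanned pair (THETA and P per row);
    ``labels`` maps ID -> COHORT with optional X, Y grid coordinates.
    Means over theta include negative estimates.  Within-cohort rows
    report N = n(n-1)/2 comparisons; cross-cohort rows N = n_a * n_b
    and, when coordinates are given, the straight-line grid distance.

    Raises
    ------
    ValueError
        If any sample in the pair table has no cohort label.
    """
    lab = dict(zip(labels["ID"].astype(str), labels["COHORT"]))
    ids = pd.unique(pd.concat([pairs["ID1"], pairs["ID2"]]).astype(str))
    unlabeled = [s for s in ids if s not in lab]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {', '.join(sorted(unlabeled)[:10])}")

    has_xy = {"X", "Y"}.issubset(labels.columns)
    counts = labels[labels["ID"].astype(str).isin(ids)]["COHORT"].value_counts()

    c1 = pairs["ID1"].astype(str).map(lab)
    c2 = pairs["ID2"].astype(str).map(lab)
    key = pd.DataFrame(
        {"a": np.minimum(c1, c2), "b": np.maximum(c1, c2),
         "theta": pairs["THETA"], "sig": pairs["P"] < alpha}
    )

    within_rows, cross_rows = [], []
    for (a, b), grp in key.groupby(["a", "b"], sort=True):
        n_sig = int(grp["sig"].sum())
        theta_sig = grp.loc[grp["sig"], "theta"]
        if a == b:
            n = int(counts[a])
            N = n * (n - 1) // 2
            within_rows.append(
                {
                    "cohort": a, "n": n, "N": N, "N_sig": n_sig,
                    "P": n_sig / N if N else np.nan,
                    "theta_bar": float(grp["theta"].mean()),
                    "theta_bar_sig": (
                        float(theta_sig.mean()) if n_sig else np.nan
                    ),
                }
            )
        else:
            N = int(counts[a]) * int(counts[b])
            dist = np.nan
            if has_xy:
                xa = labels.loc[labels["COHORT"] == a, ["X", "Y"]].iloc[0]
                xb = labels.loc[labels["COHORT"] == b, ["X", "Y"]].iloc[0]
                dist = float(np.hypot(xa["X"] - xb["X"], xa["Y"] - xb["Y"]))
            cross_rows.append(
                {
                    "cohort_a": a, "cohort_b": b, "N": N, "N_sig": n_sig,
                    "P": n_sig / N if N else np.nan,
                    "theta_bar": float(grp["theta"].mean()),
                    "distance": dist,
                }
            )
    within = pd.DataFrame(within_rows)
    if has_xy and len(within):
        cx = {c: labels.loc[labels["COHORT"] == c, "X"].iloc[0] for c in within["cohort"]}
        cy = {c: labels.loc[labels["COHORT"] == c, "Y"].iloc[0] for c in within["cohort"]}
        within["x"] = within["cohort"].map(cx)
        within["y"] = within["cohort"].map(cy)
    elif len(within):
        within["x"] = np.nan
        within["y"] = np.nan
    return within, pd.DataFrame(cross_rows)
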