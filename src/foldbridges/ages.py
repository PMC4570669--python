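"""Fold-age projections: age differences on bridges, central vs peripheral ages.

Fold ages are normalized evolutionary age estimates in [0, 1] (1 = a
structural ancestor at the last universal common ancestor, 0 = recent).
Two analyses are supported: the distribution of absolute age differences
|age_A - age_B| across fold pairs binned by edge multiplicity (how many
alignment methods display the pair as a bridge; multiplicity 0 is the
background of unconnected pairs), and Mann-Whitney comparisons of the age
distributions of central versus peripheral folds per network and centrality
measure.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from foldbridges.analysis import MEASURES


def validate_ages(ages: pd.DataFrame) -> pd.Series:
    """Check and index an AgeTable (columns ``fold, age``; ages in [0, 1])."""
    if not {"fold", "age"} <= set(ages.columns):
        raise ValueError("age table needs columns 'fold' and 'age'")
    s = ages.set_index("fold")["age"].astype(float)
    if s.index.duplicated().any():
        raise ValueError("age table has duplicate folds")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("ages must lie in [0, 1]")
    return s


def edge_age_differences(
    multiplicity: pd.DataFrame, ages: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """|age| differences per fold pair, binned by edge multiplicity.

    ``multiplicity`` is the exhaustive pair table from
    :func:`foldbridges.networks.edge_multiplicity` (bin 0 = unconnected
    pairs).  Pairs with an endpoint missing from the age table are excluded
    and logged.  Returns the per-pair frame, a per-bin summary (count,
    median, quartiles) and the exclusion log.
    """
    age_of = validate_ages(ages)
    a = multiplicity["group_a"].map(age_of)
    b = multiplicity["group_b"].map(age_of)
    missing_mask = a.isna() | b.isna()
    excluded = sorted(
        set(multiplicity.loc[a.isna(), "group_a"]).union(
            multiplicity.loc[b.isna(), "group_b"]
        )
    )
    frame = multiplicity[~missing_mask].copy()
    frame["abs_age_diff"] = (a - b).abs()[~missing_mask]
    summary = (
        frame.groupby("multiplicity")["abs_age_diff"]
        .agg(
            count="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return frame, summary, excluded


def compare_ages(set_a, set_b, ages: pd.DataFrame) -> dict:
    """Two-sided Mann-Whitney U comparison of two folds' age samples.

    Exact null distribution for small untied samples, normal approximation
    with tie correction otherwise.  Returns the U statistic (first sample),
    the p-value and the group means/sizes.
    """
    age_of = validate_ages(ages)
    x = age_of.loc[sorted(set_a)].to_numpy()
    y = age_of.loc[sorted(set_b)].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        warnings.warn("all ages tied across both groups; p = 1")
        return {
            "U": float(x.size * y.size / 2.0),
            "p_value": 1.0,
            "mean_a": float(x.mean()),
            "mean_b": float(y.mean()),
            "n_a": int(x.size),
            "n_b": int(y.size),
        }
    method = "exact" if (x.size <= 20 and y.size <= 20 and np.unique(np.concatenate([x, y])).size == x.size + y.size) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_a": float(x.mean()),
        "mean_b": float(y.mean()),
        "n_a": int(x.size),
        "n_b": int(y.size),
    }


def central_peripheral_age_report(
    partitions_by_network: Mapping[str, Mapping[str, Mapping[str, set]]],
    ages: pd.DataFrame,
    alpha: float = 0.01,
    min_group: int = 1,
) -> pd.DataFrame:
    """Central-vs-peripheral age comparison per network and measure.

    For every (network, measure) with both sets of size >= ``min_group``,
    runs the two-sided Mann-Whitney test and flags ``central_older`` when
    p < alpha and the central mean age exceeds the peripheral mean.
    """
    age_of = validate_ages(ages)
    rows = []
    for network_id, partitions in partitions_by_network.items():
        for measure in MEASURES:
            central = {n for n in partitions[measure]["central"] if n in age_of.index}
            peripheral = {n for n in partitions[measure]["peripheral"] if n in age_of.index}
            if len(central) < min_group or len(peripheral) < min_group:
                rows.append(
                    {
                        "network": network_id,
                        "measure": measure,
                        "n_central": len(central),
                        "n_peripheral": len(peripheral),
                        "mean_central": np.nan,
                        "mean_peripheral": np.nan,
                        "U": np.nan,
                        "p_value": np.nan,
                        "central_older": False,
                        "tested": False,
                    }
                )
                continue
            res = compare_ages(central, peripheral, ages)
            rows.append(
                {
                    "network": network_id,
                    "measure": measure,
                    "n_central": res["n_a"],
                    "n_peripheral": res["n_b"],
                    "mean_central": res["mean_a"],
                    "mean_peripheral": res["mean_b"],
                    "U": res["U"],
                    "p_value": res["p_value"],
                    "central_older": bool(
                        res["p_value"] < alpha and res["mean_a"] > res["mean_b"]
                    ),
                    "tested": True,
                }
            )
    return pd.DataFrame(rows)
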