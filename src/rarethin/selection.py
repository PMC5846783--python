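"""Baseline-model construction: collinearity screen and exhaustive
GCV-ranked search over 1-4 variable smooth combinations.

Variable selection is only run to build baseline models; thinned refits
reuse the baseline's variables so the thinning effect is isolated from
specification changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .gam import CountGAM, ModelSpec
from .survey import SurveyDataset

__all__ = ["correlation_screen", "enumerate_candidates", "select_best", "SelectionResult"]


def correlation_screen(covariates: pd.DataFrame, threshold: float = 0.7):
    """Forbidden pairs: |Pearson r| strictly above ``threshold``."""
    if covariates.shape[1] < 2 or len(covariates) < 3:
        raise ValueError("need at least 2 covariates and 3 rows")
    if (covariates.std() == 0).any():
        bad = covariates.columns[covariates.std() == 0].tolist()
        raise ValueError(f"constant covariates have undefined correlation: {bad}")
    corr = covariates.corr()
    pairs = []
    cols = list(covariates.columns)
    for a, b in combinations(cols, 2):
        # strict inequality, with a round-off guard at the boundary
        if abs(corr.loc[a, b]) > threshold + 1e-12:
            pairs.append((a, b))
    return pairs


def enumerate_candidates(variables, forbidden_pairs=(), max_size: int = 4):
    """All subsets of size 1..max_size avoiding forbidden pairs, in
    deterministic lexicographic order."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    variables = list(variables)
    if not variables:
        raise ValueError("need at least one variable")
    forbidden = {frozenset(p) for p in forbidden_pairs}
    out = []
    for size in range(1, max_size + 1):
        for combo in combinations(sorted(variables), size):
            if any(frozenset(p) <= set(combo) for p in forbidden):
                continue
            out.append(tuple(combo))
    return out


@dataclass
class SelectionResult:
    """Ranked candidate table and the winning specification."""

    table: pd.DataFrame
    best_spec: ModelSpec
    best_fit: object
    forbidden_pairs: list


def select_best(
    dataset: SurveyDataset,
    combinations_list,
    family: str,
    taxon: str,
    df: int = 3,
) -> SelectionResult:
    """Fit every candidate and rank by GCV (ascending).

    Ties break toward fewer variables, then lexicographic order.
    Non-converged fits are ranked after all converged ones and flagged.
    """
    if not combinations_list:
        raise ValueError("empty combination list")
    rows, fits = [], {}
    for combo in combinations_list:
        try:
            model = CountGAM.from_survey(
                dataset, taxon=taxon, family=family, variables=combo, df=df
            )
            res = model.fit()
            expl = res.deviance_explained
            rows.append(
                {
                    "variables": combo,
                    "gcv": res.gcv,
                    "deviance": res.deviance,
                    "deviance_explained": expl,
                    "converged": res.converged,
                }
            )
            fits[combo] = res
        except ValueError as err:
            rows.append(
                {
                    "variables": combo,
                    "gcv": np.inf,
                    "deviance": np.nan,
                    "deviance_explained": np.nan,
                    "converged": False,
                    "error": str(err),
                }
            )
    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise ValueError("all candidate fits failed")
    # near-exact GCV ties (within round-off) resolve by the deterministic
    # rules: fewer variables first, then lexicographic order
    def _sig(g):
        return float(f"{g:.10g}") if np.isfinite(g) else np.inf

    table["_rank_key"] = [
        (not c, _sig(g), len(v), v)
        for c, g, v in zip(table["converged"], table["gcv"], table["variables"])
    ]
    table = table.sort_values("_rank_key").drop(columns="_rank_key").reset_index(drop=True)
    best_combo = table.iloc[0]["variables"]
    return SelectionResult(
        table=table,
        best_spec=ModelSpec(family=family, variables=best_combo, df=df),
        best_fit=fits[best_combo],
        forbidden_pairs=[],
    )
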