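"""The sighting-thinning experiment engine.

Sightings are randomly deleted (sampled without replacement) at scheduled
rates while every effort segment is kept, which simulates an increasingly
rare species under constant survey effort.  Models refitted to each thinned
replicate (with the baseline's variables) are scored against the baseline:

* count GAMs by the mean squared difference between prediction maps (MSE),
  judged against MSE_ref -- the MSE between the baseline map and the map of
  an intercept-plus-offset-only model of the same family (a homogeneous
  spatial distribution);
* MaxEnt by AUC of its logistic map scores against the full dataset's
  presence/absence segments, judged against 0.5.

Everything is reproducible from a master seed: replicate (rate r, index j)
uses the seed stream ``SeedSequence(master_seed, spawn_key=(r, j))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import CountGAM, ModelSpec
from .grids import (
    DailyPredictions,
    DensityMap,
    PredictionGrid,
    average_predictions,
    prediction_mse,
    uncertainty_cv,
)
from .maxent import HingeFeatureSet, MaxentModel, auc_score
from .survey import SurveyDataset, round_half_up

__all__ = [
    "ThinningPlan",
    "thin_sightings",
    "retained_count",
    "reference_mse",
    "ExperimentResult",
    "run_experiment",
    "summarize_experiment",
]

DOLPHIN_RATES = (0.25, 0.50, 0.75, 0.90, 0.92, 0.95)
AUK_RATES = (0.25, 0.50, 0.75, 0.90, 0.92, 0.95, 0.97, 0.99)


@dataclass(frozen=True)
class ThinningPlan:
    """Thinning rates, replication and the master seed."""

    rates: tuple = DOLPHIN_RATES
    n_replicates: int = 100
    master_seed: int = 0

    def __post_init__(self):
        rates = tuple(float(r) for r in self.rates)
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ValueError("rates must lie in [0, 1)")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("rates must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "rates", rates)

    def rng_for(self, rate_index: int, replicate: int) -> np.random.Generator:
        """Independent substream for one (rate, replicate) cell."""
        ss = np.random.SeedSequence(self.master_seed, spawn_key=(rate_index, replicate))
        return np.random.Generator(np.random.PCG64(ss))


def retained_count(n_sightings: int, rate: float) -> int:
    """Sightings kept at a thinning rate: round-half-up((1 - rate) * n).

    Computed in decimal arithmetic so e.g. a 90% rate on 1,455 sightings
    yields exactly 145.5 -> 146 (binary floats would give 145.4999...).
    """
    import decimal

    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    kept = (1 - decimal.Decimal(repr(float(rate)))) * n_sightings
    return int(kept.quantize(decimal.Decimal(1), rounding=decimal.ROUND_HALF_UP))


def thin_sightings(
    dataset: SurveyDataset, rate: float, rng: np.random.Generator, taxon=None
) -> SurveyDataset:
    """Randomly delete a fraction of sightings; effort is untouched.

    Removal is a random sample without replacement of the sighting records
    (optionally of one taxon); their segments become, or stay, zeros.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    sig = dataset.sightings
    if taxon is not None:
        pool = sig.index[sig["taxon"] == taxon].to_numpy()
    else:
        pool = sig.index.to_numpy()
    if len(pool) == 0:
        raise ValueError("dataset has no sightings to thin")
    keep_n = retained_count(len(pool), rate)
    kept = np.sort(rng.permutation(pool)[:keep_n])
    keep_mask = sig.index.isin(kept) | (
        ~sig.index.isin(pool)
    )  # other taxa are untouched
    return dataset.with_sightings(sig[keep_mask])


def _fit_and_map(dataset, spec: ModelSpec, taxon, grid) -> tuple:
    model = CountGAM.from_survey(
        dataset, taxon=taxon, family=spec.family, variables=spec.variables, df=spec.df
    )
    res = model.fit()
    daily = res.predict_daily(grid, with_variance=False)
    return res, average_predictions(daily)


def reference_mse(
    dataset: SurveyDataset, spec: ModelSpec, taxon: str, grid: PredictionGrid,
    baseline_map: DensityMap,
) -> float:
    """MSE between the baseline map and the homogeneous (null) model map.

    The null model is the intercept-plus-offset-only fit of the same family
    on the full dataset.
    """
    null_spec = ModelSpec(family=spec.family, variables=(), df=spec.df)
    _, null_map = _fit_and_map(dataset, null_spec, taxon, grid)
    return prediction_mse(null_map, baseline_map, standardise=True)


class _MapAccumulator:
    """Running cellwise sums for averaged replicate maps and their CV."""

    def __init__(self, n_cells):
        self.n = 0
        self.s = np.zeros(n_cells)
        self.s2 = np.zeros(n_cells)
        self.valid = np.ones(n_cells, dtype=bool)

    def add(self, dmap: DensityMap):
        vals = np.where(dmap.valid, dmap.values, 0.0)
        self.n += 1
        self.s += vals
        self.s2 += vals**2
        self.valid &= dmap.valid

    def mean_map(self, template: DensityMap) -> DensityMap:
        mean = self.s / max(self.n, 1)
        return DensityMap(
            cell_ids=template.cell_ids,
            lon=template.lon,
            lat=template.lat,
            values=np.where(self.valid, mean, np.nan),
            valid=self.valid.copy(),
        )

    def cv_map(self, template: DensityMap) -> DensityMap:
        mean = self.s / max(self.n, 1)
        var = self.s2 / max(self.n, 1) - mean**2
        ok = self.valid & (mean > 0)
        cv = np.where(ok, 100.0 * np.sqrt(np.maximum(var, 0.0)) / np.where(ok, mean, 1.0), np.nan)
        return DensityMap(
            cell_ids=template.cell_ids,
            lon=template.lon,
            lat=template.lat,
            values=cv,
            valid=ok,
        )


@dataclass
class ExperimentResult:
    """Raw per-replicate outcomes plus baseline references and map sums."""

    outcomes: pd.DataFrame
    references: dict  # model name -> MSE_ref (or 0.5 for maxent AUC)
    baseline_maps: dict
    accumulators: dict  # (model, rate) -> _MapAccumulator


def run_experiment(
    dataset: SurveyDataset,
    taxon: str,
    specs: dict,
    plan: ThinningPlan,
    grid: PredictionGrid,
    include_maxent: bool = False,
    maxent_reg: float = 1.5,
) -> ExperimentResult:
    """Thin, refit and score every (rate, replicate, model type).

    ``specs`` maps family name -> :class:`ModelSpec` (the baseline variable
    sets).  Per-replicate fit failures are recorded, never raised.
    """
    baseline_maps, references = {}, {}
    for name, spec in specs.items():
        _, bmap = _fit_and_map(dataset, spec, taxon, grid)
        baseline_maps[name] = bmap
        references[name] = reference_mse(dataset, spec, taxon, grid, bmap)

    presence_labels = (dataset.counts(taxon) > 0).to_numpy().astype(int)
    maxent_vars = None
    if include_maxent:
        maxent_vars = tuple(next(iter(specs.values())).variables)
        references["maxent"] = 0.5

    rows = []
    acc = {}
    for name in list(specs) + (["maxent"] if include_maxent else []):
        for rate in plan.rates:
            acc[(name, rate)] = _MapAccumulator(grid.n_cells)

    for ri, rate in enumerate(plan.rates):
        for rep in range(plan.n_replicates):
            rng = plan.rng_for(ri, rep)
            thinned = thin_sightings(dataset, rate, rng, taxon=taxon)
            retained = int((thinned.sightings["taxon"] == taxon).sum())
            for name, spec in specs.items():
                row = {
                    "rate": rate,
                    "replicate": rep,
                    "model": name,
                    "retained": retained,
                    "converged": False,
                    "score": np.nan,
                }
                try:
                    res, emap = _fit_and_map(thinned, spec, taxon, grid)
                    row["converged"] = bool(res.converged)
                    if res.converged:
                        row["score"] = prediction_mse(
                            emap, baseline_maps[name], standardise=True
                        )
                        acc[(name, rate)].add(emap)
                except (ValueError, np.linalg.LinAlgError):
                    pass
                rows.append(row)
            if include_maxent:
                row = {
                    "rate": rate,
                    "replicate": rep,
                    "model": "maxent",
                    "retained": retained,
                    "converged": False,
                    "score": np.nan,
                }
                try:
                    counts = thinned.counts(taxon)
                    pres = thinned.segments[counts.to_numpy() > 0][list(maxent_vars)]
                    bg = thinned.segments[list(maxent_vars)]
                    mres = MaxentModel(pres, bg, reg_multiplier=maxent_reg).fit()
                    scores = mres.predict(dataset.segments[list(maxent_vars)])
                    row["converged"] = bool(mres.converged)
                    if mres.converged:
                        row["score"] = auc_score(scores, presence_labels)
                except ValueError:
                    pass
                rows.append(row)
    return ExperimentResult(
        outcomes=pd.DataFrame(rows),
        references=references,
        baseline_maps=baseline_maps,
        accumulators=acc,
    )


def summarize_experiment(result: ExperimentResult) -> pd.DataFrame:
    """Per rate x model: MSE_mean (or AUC_mean), its standard error, and the
    proportion of converged replicates beating the reference.

    GAM replicates beat the reference when MSE < MSE_ref; MaxEnt replicates
    when AUC > 0.5.  Non-converged replicates are excluded from the mean and
    from the proportion's denominator, and counted in ``n_failed``.
    """
    out = []
    df = result.outcomes
    if len(df) == 0:
        raise ValueError("empty outcome set")
    for (model, rate), sub in df.groupby(["model", "rate"], sort=True):
        scores = sub.loc[sub["converged"], "score"].to_numpy(dtype=float)
        ref = result.references[model]
        n_ok = len(scores)
        if model == "maxent":
            better = float(np.mean(scores > ref)) if n_ok else np.nan
        else:
            better = float(np.mean(scores < ref)) if n_ok else np.nan
        out.append(
            {
                "model": model,
                "rate": rate,
                "retained": int(sub["retained"].iloc[0]),
                "n_converged": n_ok,
                "n_failed": int(len(sub) - n_ok),
                "score_mean": float(np.mean(scores)) if n_ok else np.nan,
                "score_median": float(np.median(scores)) if n_ok else np.nan,
                "score_se": float(np.std(scores, ddof=1) / np.sqrt(n_ok))
                if n_ok > 1
                else 0.0 if n_ok == 1 else np.nan,
                "reference": ref,
                "proportion_better": better,
            }
        )
    return pd.DataFrame(out)
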