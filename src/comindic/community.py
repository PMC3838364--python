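"""Community-level aggregation of species scores.

A sampling occasion (one site in one year) is summarized by the
abundance-weighted mean of the per-species scores of the species caught:
CSI_t = sum(a_it * SSI_i) / sum(a_it) for specialization, COI_t likewise
for originality, with a_it the species densities.  Species without a
score are dropped from both numerator and denominator and accounted for
through a coverage fraction, so partially-scored communities are flagged
rather than silently distorted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .originality import SpeciesScoreVector
from .specialization import validate_survey

logger = logging.getLogger(__name__)


def community_index(
    survey: pd.DataFrame,
    scores: SpeciesScoreVector,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Abundance-weighted mean score per sampling occasion.

    Returns a long-format frame with one row per (site_id, year):
    ``index`` (NaN when no scored species was caught), ``coverage``
    (fraction of total density carried by scored species) and
    ``flagged`` (True when coverage < ``min_coverage`` or the index is
    undefined).  Metric and trait-set tags are carried in ``df.attrs``.
    """
    survey = validate_survey(survey)
    if len(survey) == 0:
        raise ValueError("empty survey table")
    if len(scores.species_ids) == 0:
        raise ValueError("empty score vector")
    score_map = scores.as_series()
    unscored = set(survey["species_id"]) - set(scores.species_ids)
    if unscored:
        logger.warning(
            "%d surveyed species without scores (e.g. %s)",
            len(unscored),
            sorted(unscored)[:5],
        )

    df = survey.copy()
    df["score"] = df["species_id"].map(score_map)
    df["scored_density"] = np.where(df["score"].notna(), df["density"], 0.0)
    df["weighted"] = df["scored_density"] * df["score"].fillna(0.0)

    g = df.groupby(["site_id", "year"], sort=True)
    agg = g.agg(
        total=("density", "sum"),
        scored=("scored_density", "sum"),
        weighted=("weighted", "sum"),
    ).reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["index"] = agg["weighted"] / agg["scored"]
        agg["coverage"] = np.where(
            agg["total"] > 0, agg["scored"] / agg["total"], 0.0
        )
    agg.loc[agg["scored"] == 0, "index"] = np.nan
    agg["flagged"] = (agg["coverage"] < min_coverage) | agg["index"].isna()
    n_flagged = int(agg["flagged"].sum())
    if n_flagged:
        logger.warning(
            "%d occasion(s) flagged (coverage < %.2f or no scored species)",
            n_flagged,
            min_coverage,
        )
    out = agg[["site_id", "year", "index", "coverage", "flagged"]].copy()
    out.attrs["metric"] = scores.metric
    out.attrs["trait_set"] = scores.trait_set
    return out


def write_index_csv(series: pd.DataFrame, path) -> None:
    """Long-format CSV: site, year, metric, trait_set, index, coverage."""
    out = series.copy()
    out.insert(2, "metric", series.attrs.get("metric", "custom"))
    out.insert(3, "trait_set", series.attrs.get("trait_set", "custom"))
    out.to_csv(path, index=False)


def read_index_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    attrs = {}
    for col in ("metric", "trait_set"):
        if col in df.columns:
            vals = df[col].unique()
            attrs[col] = vals[0] if len(vals) == 1 else "mixed"
            df = df.drop(columns=col)
    df.attrs.update(attrs)
    return df
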