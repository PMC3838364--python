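"""Habitat specialization from survey densities.

Specialization is measured without expert habitat typologies: sampling
sites are clustered on four abiotic descriptors (summed January-June air
temperature, position along the upstream-downstream longitudinal
gradient, log elevation, slope) into k habitat classes of roughly equal
size, which also corrects the over-sampling of headwaters typical of
electrofishing networks.  A species' Specialization Index (SSI) is then
the coefficient of variation (sd/mean) of its average density across the
classes: 0 for a perfect generalist, sqrt(k) for a species confined to a
single class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .originality import SpeciesScoreVector

logger = logging.getLogger(__name__)

ABIOTIC_VARS = ("temperature_sum", "longitudinal_gradient", "log_elevation", "slope")


class SpecializationError(ValueError):
    pass


def validate_abiotic(table: pd.DataFrame) -> pd.DataFrame:
    """Check the abiotic site table (site_id + four complete variables)."""
    if "site_id" not in table.columns:
        raise SpecializationError("abiotic table needs a 'site_id' column")
    if table["site_id"].duplicated().any():
        dup = table.loc[table["site_id"].duplicated(), "site_id"].tolist()
        raise SpecializationError(f"duplicate site id(s): {dup}")
    missing = [v for v in ABIOTIC_VARS if v not in table.columns]
    if missing:
        raise SpecializationError(f"missing abiotic variable(s): {missing}")
    sub = table[list(ABIOTIC_VARS)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise SpecializationError(f"missing values in abiotic variable(s): {bad}")
    return table


@dataclass
class HabitatAssignment:
    """site_id -> habitat class label in 1..k."""

    assignment: pd.Series  # index: site_id, values: int class labels
    k: int
    method: str
    seed: int

    def __post_init__(self) -> None:
        if self.assignment.index.has_duplicates:
            raise SpecializationError("duplicate site ids in assignment")
        bad = set(self.assignment.unique()) - set(range(1, self.k + 1))
        if bad:
            raise SpecializationError(f"class labels outside 1..{self.k}: {bad}")

    def class_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def to_csv(self, path) -> None:
        df = self.assignment.rename("habitat_class").rename_axis("site_id")
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\n# method={self.method}\n# seed={self.seed}\n")
            df.to_csv(fh)


def balanced_habitat_classes(
    abiotic: pd.DataFrame, k: int = 7, slack: int = 0, seed: int = 0
) -> HabitatAssignment:
    """Cluster sites into k habitat classes of near-equal size.

    The four abiotic variables are standardized to zero mean / unit
    variance and clustered by k-means; sites are then moved from over-full
    to under-full classes, nearest centroid first, until no class exceeds
    ceil(n/k) + slack.  Deterministic for a fixed seed.
    """
    abiotic = validate_abiotic(abiotic)
    n = len(abiotic)
    if n < k:
        raise SpecializationError(f"{n} sites < {k} classes")
    X = abiotic[list(ABIOTIC_VARS)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    const = [v for v, s in zip(ABIOTIC_VARS, sd) if s == 0]
    if const:
        raise SpecializationError(f"constant abiotic variable(s): {const}")
    Z = (X - X.mean(axis=0)) / sd

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(Z)
    centroids = km.cluster_centers_
    dist = np.linalg.norm(Z[:, None, :] - centroids[None, :, :], axis=2)

    cap = math.ceil(n / k) + slack
    counts = np.bincount(labels, minlength=k)
    while counts.max() > cap:
        over = int(np.argmax(counts))
        members = np.flatnonzero(labels == over)
        under = np.flatnonzero(counts < cap)
        # move the member with the cheapest switch to an under-full class
        extra = dist[np.ix_(members, under)] - dist[members, over][:, None]
        mi, ui = np.unravel_index(np.argmin(extra), extra.shape)
        site, target = members[mi], under[ui]
        labels[site] = target
        counts[over] -= 1
        counts[target] += 1

    assignment = pd.Series(
        labels + 1, index=pd.Index(abiotic["site_id"], name="site_id")
    )
    return HabitatAssignment(
        assignment, k=k, method="kmeans+capacity", seed=seed
    )


def validate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Check a survey table of (site_id, year, species_id, density) rows."""
    needed = ["site_id", "year", "species_id", "density"]
    missing = [c for c in needed if c not in survey.columns]
    if missing:
        raise SpecializationError(f"survey table missing column(s): {missing}")
    if (survey["density"] < 0).any():
        raise SpecializationError("negative densities in survey table")
    if survey.duplicated(["site_id", "year", "species_id"]).any():
        raise SpecializationError(
            "duplicate (site, year, species) rows in survey table"
        )
    return survey


def ssi(
    survey: pd.DataFrame,
    habitat: HabitatAssignment,
    ddof: int = 1,
) -> SpeciesScoreVector:
    """Species Specialization Index: CV of class-mean density per species.

    For each species, density is averaged over every sampling occasion
    (site-year pair) within each habitat class, counting absences as zero
    density, and the SSI is the standard deviation of the k class means
    divided by their mean.  ``ddof=1`` (sample sd) by default; set
    ``ddof=0`` for the population convention.
    """
    survey = validate_survey(survey)
    unknown = set(survey["site_id"]) - set(habitat.assignment.index)
    if unknown:
        raise SpecializationError(
            f"surveyed site(s) without habitat class: {sorted(unknown)[:5]}"
        )
    occ = survey[["site_id", "year"]].drop_duplicates()
    occ_class = habitat.assignment.loc[occ["site_id"]].to_numpy()
    occ_per_class = pd.Series(occ_class).value_counts().sort_index()
    if len(occ_per_class) < 2:
        raise SpecializationError(
            "only one habitat class represented in the survey"
        )

    df = survey.copy()
    df["habitat_class"] = habitat.assignment.loc[df["site_id"]].to_numpy()
    # total density per (species, class); absences enter via the occasion count
    totals = (
        df.groupby(["species_id", "habitat_class"])["density"].sum().unstack(fill_value=0.0)
    )
    totals = totals.reindex(columns=occ_per_class.index, fill_value=0.0)
    class_means = totals / occ_per_class.to_numpy()[None, :]

    values, ids = [], []
    for sp, row in class_means.iterrows():
        m = row.to_numpy(dtype=float)
        if m.sum() == 0:
            logger.warning("species %s has zero total density; SSI undefined", sp)
            continue
        mean = m.mean()
        sd = m.std(ddof=ddof)
        ids.append(sp)
        values.append(sd / mean)
    return SpeciesScoreVector(
        ids, np.array(values), metric="ssi", trait_set="habitat", normalized=False
    )
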