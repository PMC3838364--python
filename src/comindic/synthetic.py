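"""Synthetic survey scenarios with controllable statistical structure.

Real electrofishing monitoring data (multi-site, multi-year catch
densities with trait compilations and land-cover context) cannot be
redistributed, so every input the pipeline consumes can be generated
here: mixed-type trait tables, ultrametric trees, abiotic site
descriptors with headwater oversampling, land-use class tables, and
survey tables whose expected community-weighted index shifts by a
configured amount in each land-use class relative to the natural
reference.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .originality import SpeciesScoreVector
from .sensitivity import REFERENCE_CLASS, VARIANTS, LandUseTable, SiteContext
from .traits import TraitTable
from .trees import Node, RootedTree


@dataclass
class ScenarioConfig:
    """Knobs for a full synthetic monitoring scenario.

    Defaults emulate a national river-fish survey reduced to desk scale:
    26 common species, a few hundred sites revisited over 5 years,
    lognormal catch densities, and a site-level random effect on the
    community index of about 0.01 index units.
    """

    n_species: int = 26
    n_sites: int = 300
    n_years: int = 5
    year_start: int = 1990
    # trait schema: columns per kind
    n_quantitative: int = 7
    n_ordinal: int = 3
    n_nominal: int = 2
    n_binary: int = 2
    missingness: float = 0.0
    # survey generative model
    sigma_site: float = 0.01  # sd of site random effect, index units
    sigma_obs: float = 0.5  # sd of log-density noise per occasion x species
    occupancy: float = 0.9  # per occasion x species presence probability
    log_abundance_mean: float = 2.0
    log_abundance_sd: float = 1.0
    # land use
    landuse_variant: str = "CLC5"
    class_effects: dict = field(default_factory=dict)  # class -> index shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_sites < 1 or self.n_years < 1:
            raise ValueError("need at least 1 site and 1 year")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        if self.sigma_site < 0 or self.sigma_obs < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")
        if self.landuse_variant not in VARIANTS:
            raise ValueError(f"unknown land-use variant {self.landuse_variant!r}")
        bad = set(self.class_effects) - set(VARIANTS[self.landuse_variant])
        if bad:
            raise ValueError(f"effects for unknown class(es): {sorted(bad)}")

    def species_ids(self) -> list:
        return [f"sp{i:02d}" for i in range(1, self.n_species + 1)]


def gen_trait_table(cfg: ScenarioConfig, seed: int | None = None) -> TraitTable:
    """Mixed-type trait table with latent functional structure.

    Each species occupies a position in a two-axis latent functional
    space (think habitat-use vs diet axes); every trait is a noisy
    readout of that position — normal or lognormal for quantitative
    traits, binned levels for ordinal scores, latent-quadrant categories
    for nominal traits, thresholds for binary ones.  Correlated traits
    give the dendrogram a reproducible shape, as real functional trait
    compilations do; fully independent traits would make originality
    rankings unstable noise.
    """
    n_traits = (
        cfg.n_quantitative + cfg.n_ordinal + cfg.n_nominal + cfg.n_binary
    )
    if n_traits == 0:
        raise ValueError("trait schema declares zero traits")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = cfg.species_ids()
    n = cfg.n_species
    z = rng.normal(0.0, 1.0, (n, 2))  # latent functional positions
    noise = 0.5  # per-trait readout noise relative to the latent signal

    def latent_combo():
        a = rng.normal(0.0, 1.0, 2)
        a /= np.linalg.norm(a)
        return z @ a + rng.normal(0.0, noise, n)

    cols, kinds = {}, {}
    for j in range(cfg.n_quantitative):
        name = f"q{j+1}"
        v = latent_combo()
        # half plain, half exponentiated (body-size-like traits)
        cols[name] = v if j % 2 == 0 else np.exp(0.5 * v)
        kinds[name] = "quantitative"
    for j in range(cfg.n_ordinal):
        name = f"o{j+1}"
        v = latent_combo()
        cols[name] = np.clip(np.round(3.0 + 1.2 * v), 1, 5).astype(float)
        kinds[name] = "ordinal"
    letters = list(string.ascii_uppercase[:4])
    for j in range(cfg.n_nominal):
        name = f"n{j+1}"
        u1, u2 = latent_combo(), latent_combo()
        quadrant = (u1 > 0).astype(int) * 2 + (u2 > 0).astype(int)
        cols[name] = np.array(letters)[quadrant]
        kinds[name] = "nominal"
    for j in range(cfg.n_binary):
        name = f"b{j+1}"
        cols[name] = (latent_combo() > 0.25).astype(int)
        kinds[name] = "binary"
    df = pd.DataFrame(cols, index=pd.Index(ids, name="species"), dtype=object)
    if cfg.missingness > 0:
        mask = rng.random(df.shape) < cfg.missingness
        # never blank out a full column
        for j in range(df.shape[1]):
            if mask[:, j].all():
                mask[rng.integers(0, n), j] = False
        df = df.mask(mask)
    for name, kind in kinds.items():
        if kind in ("quantitative", "ordinal"):
            df[name] = pd.to_numeric(df[name])
    return TraitTable(df, kinds)


def gen_ultrametric_tree(n_tips: int, seed: int = 0) -> RootedTree:
    """Random sequential-coalescence tree; ultrametric by construction."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    clusters = [
        {"node": Node(label=f"t{i+1:02d}"), "height": 0.0} for i in range(n_tips)
    ]
    height = 0.0
    while len(clusters) > 1:
        k = len(clusters)
        height += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = clusters[i], clusters[j]
        parent = Node()
        for c in (a, b):
            c["node"].length = height - c["height"]
            parent.add_child(c["node"])
        clusters[i] = {"node": parent, "height": height}
        clusters.pop(j)
    return RootedTree(clusters[0]["node"])


def gen_abiotic(site_ids, seed: int = 0) -> pd.DataFrame:
    """Abiotic site table along an upstream-downstream latent axis.

    A Beta-skewed upstream factor oversamples headwaters (as field
    networks do): upstream sites are colder, higher, steeper and sit low
    on the longitudinal gradient.
    """
    rng = np.random.default_rng(seed)
    n = len(site_ids)
    u = rng.beta(0.8, 1.6, n)  # skew toward upstream (small u)
    return pd.DataFrame(
        {
            "site_id": list(site_ids),
            "temperature_sum": 45 + 40 * u + rng.normal(0, 4, n),
            "longitudinal_gradient": np.clip(u + rng.normal(0, 0.08, n), 0, 1),
            "log_elevation": np.log(2500) - 2.5 * u + rng.normal(0, 0.3, n),
            "slope": np.exp(1.0 - 2.0 * u + rng.normal(0, 0.4, n)),
        }
    )


#: Default class shares per variant (natural -> urban order).
DEFAULT_PROPORTIONS = {
    "CLC5": [0.30, 0.20, 0.30, 0.05, 0.15],
    "EUROWATER6": [0.30, 0.20, 0.30, 0.05, 0.10, 0.05],
    "ONEMA7": [0.30, 0.20, 0.15, 0.15, 0.05, 0.10, 0.05],
}


def gen_landuse(
    site_ids,
    variant: str = "CLC5",
    proportions=None,
    seed: int = 0,
) -> LandUseTable:
    """Multinomial land-use assignment; reference class kept non-empty."""
    classes = VARIANTS.get(variant)
    if classes is None:
        raise ValueError(f"unknown variant {variant!r}")
    if proportions is None:
        proportions = DEFAULT_PROPORTIONS[variant]
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size != len(classes):
        raise ValueError(
            f"{proportions.size} proportions for {len(classes)} classes"
        )
    if abs(proportions.sum() - 1.0) > 1e-9 or (proportions < 0).any():
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(classes, size=len(site_ids), p=proportions)
    if REFERENCE_CLASS not in labels:
        labels[rng.integers(0, len(labels))] = REFERENCE_CLASS
    return LandUseTable(
        pd.Series(labels, index=pd.Index(site_ids, name="site_id")),
        variant=variant,
    )


def _expected_index(
    log_w: np.ndarray, x: np.ndarray, t: float, noise_factor: float
) -> float:
    """Second-order expectation of the ratio index under tilt t.

    The occasion index is a ratio of sums of noisy densities; a
    delta-method correction accounts for the lognormal noise and
    occupancy thinning (``noise_factor`` = exp(sigma_obs^2)/occupancy - 1
    is the variance inflation of each density relative to its mean):
    E[sum(uX)/sum(u)] ~ m - noise_factor * sum(p_i^2 (x_i - m)) with
    p_i the normalized mean weights and m their weighted mean of x.
    """
    w = np.exp(log_w + t * x)
    p = w / w.sum()
    m = float(p @ x)
    return m - noise_factor * float((p**2) @ (x - m))


def _solve_tilt(
    log_w: np.ndarray, x: np.ndarray, target: float, noise_factor: float = 0.0
) -> float:
    """Tilt t such that the expected ratio index hits ``target``."""
    lo, hi = -1.0, 1.0
    f = lambda t: _expected_index(log_w, x, t, noise_factor) - target
    for _ in range(60):
        if f(lo) < 0 < f(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise ValueError("target index unreachable by tilting")
    return brentq(f, lo, hi, xtol=1e-12)


def gen_survey(
    cfg: ScenarioConfig,
    scores: SpeciesScoreVector,
    landuse: LandUseTable,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SiteContext]:
    """Survey table + site context with injected land-use effects.

    Species log-densities get a site-specific exponential tilt along the
    score axis so that the *expected* community-weighted index at a site
    equals the reference-class baseline plus the configured class effect
    plus a Normal(0, sigma_site^2) site random intercept.  Lognormal
    occasion noise and Bernoulli occupancy sit on top.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = list(scores.species_ids)
    x = scores.values.astype(float)
    if np.ptp(x) <= 0:
        raise ValueError("scores are constant; no index gradient to inject")
    sites = list(landuse.assignment.index)
    n_sites, n_sp = len(sites), len(ids)

    mu = rng.normal(cfg.log_abundance_mean, cfg.log_abundance_sd, n_sp)
    # density variance inflation seen by the ratio index (lognormal noise
    # plus Bernoulli occupancy thinning)
    noise_factor = float(np.exp(cfg.sigma_obs**2) / cfg.occupancy - 1.0)
    m0 = _expected_index(mu, x, 0.0, noise_factor)
    lo, hi = x.min(), x.max()
    for cls, eff in cfg.class_effects.items():
        if not lo < m0 + eff < hi:
            raise ValueError(
                f"effect {eff} for class {cls!r} pushes the expected index "
                f"outside the score range ({lo:.4g}, {hi:.4g})"
            )

    # spatial layout: unit-square grid, watershed = quadrant, region = watershed
    side = int(np.ceil(np.sqrt(n_sites)))
    gx = (np.arange(n_sites) % side) / max(side - 1, 1)
    gy = (np.arange(n_sites) // side) / max(side - 1, 1)
    gx = np.clip(gx + rng.normal(0, 0.01, n_sites), 0, 1)
    gy = np.clip(gy + rng.normal(0, 0.01, n_sites), 0, 1)
    ws = np.where(gx < 0.5, "W", "E")
    ws = np.char.add(ws, np.where(gy < 0.5, "S", "N"))
    ctx = SiteContext(
        pd.DataFrame(
            {
                "site_id": sites,
                "x": gx,
                "y": gy,
                "watershed": ws,
                "region": ws,
            }
        )
    )

    b_site = rng.normal(0.0, cfg.sigma_site, n_sites)
    effects = np.array(
        [cfg.class_effects.get(landuse.assignment.loc[s], 0.0) for s in sites]
    )
    # a weighted-mean index is bounded by the score range, so site targets
    # are truncated just inside it (binds only in extreme tails)
    margin = 0.02 * (hi - lo)
    targets = np.clip(m0 + effects + b_site, lo + margin, hi - margin)
    tilts = np.array(
        [_solve_tilt(mu, x, t, noise_factor) for t in targets]
    )

    years = np.arange(cfg.year_start, cfg.year_start + cfg.n_years)
    rows = []
    for si, site in enumerate(sites):
        log_base = mu + tilts[si] * x
        for yr in years:
            present = rng.random(n_sp) < cfg.occupancy
            if not present.any():
                present[rng.integers(0, n_sp)] = True
            dens = np.exp(log_base + rng.normal(0, cfg.sigma_obs, n_sp))
            for sp, p, d in zip(ids, present, dens):
                if p:
                    rows.append((site, int(yr), sp, float(d)))
    survey = pd.DataFrame(
        rows, columns=["site_id", "year", "species_id", "density"]
    )
    return survey, ctx


#: How finer classification variants collapse into coarser ones.
_COARSEN = {
    ("ONEMA7", "EUROWATER6"): {"Intensive Farming": "Farming"},
    ("EUROWATER6", "CLC5"): {"Intensive Urban": "Urban"},
    ("ONEMA7", "CLC5"): {
        "Intensive Farming": "Farming",
        "Intensive Urban": "Urban",
    },
}


def coarsen_landuse(lu: LandUseTable, to_variant: str) -> LandUseTable:
    """Collapse a fine land-use classification into a coarser variant.

    The 6- and 5-class variants are nested groupings of the 7-class one
    (intensive farming folds into farming, intensive urban into urban),
    so the same sites can be analyzed under alternative classifications.
    """
    key = (lu.variant, to_variant)
    if key not in _COARSEN:
        raise ValueError(f"no coarsening from {lu.variant} to {to_variant}")
    mapping = _COARSEN[key]
    labels = lu.assignment.map(lambda c: mapping.get(c, c))
    return LandUseTable(labels, variant=to_variant, reference=lu.reference)
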