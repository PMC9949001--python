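"""Synthetic Cell Painting feature tables.

Generates single-cell, site-level morphological feature tables with the
statistical structure the downstream profiling analysis assumes — replicate
wells look alike, same-MOA compounds look alike to a tunable degree, plates
carry row/column gradients, and the cells-per-site count depends on simulated
magnification — so every stage of the pipeline is testable without images.

Model sketch
------------
Each compound ``c`` of MOA ``m`` gets an effect vector over features

    beta_c = a * (sqrt(rho) * u_m + sqrt(1 - rho) * v_c)

with ``u_m`` / ``v_c`` seeded unit directions shared per MOA / private per
compound, ``a`` the effect magnitude for a seeded active subset of compounds
(fraction ``f``; inactive compounds get beta = 0) and ``rho`` the MOA-sharing
weight: the expected cosine similarity between two active same-MOA compounds.
A cell in well ``w`` at site ``s`` then measures, per feature,

    x = beta_c(w) + row_effect + col_effect + site_effect + cell_noise

where cell noise is Gaussian with a shared latent factor per channel per cell
(loading sqrt(r_chan)) so features of one channel are correlated, making
correlation-threshold feature selection non-trivial.  Cells per site are
Poisson with a magnification-dependent mean, lower at higher magnification
(smaller field of view).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .plate import PlateMap, ROLE_TREATMENT

logger = logging.getLogger(__name__)

__all__ = [
    "BRIGHTFIELD",
    "ChannelRegistry",
    "FeatureSchema",
    "SimConfig",
    "EffectLibrary",
    "build_feature_schema",
    "build_effect_library",
    "simulate_plate",
    "simulate_experiment_plate",
    "desk_scale_config",
]

BRIGHTFIELD = "Brightfield"
_FIVE = ("DNA", "ER", "RNA", "AGP", "Mito")
_SIX = ("DNA", "ER", "RNA", "Actin", "Golgi", "Mito")

# (compartment, group, measure) templates cycled to name single-channel features
_SINGLE_TEMPLATES = [
    ("Cells", "Intensity", "MeanIntensity"),
    ("Cytoplasm", "Intensity", "IntegratedIntensity"),
    ("Nuclei", "Intensity", "StdIntensity"),
    ("Cells", "Granularity", "Granularity3"),
    ("Cytoplasm", "Texture", "Contrast"),
    ("Nuclei", "Texture", "Entropy"),
    ("Cells", "Intensity", "UpperQuartileIntensity"),
    ("Cytoplasm", "Granularity", "Granularity5"),
    ("Nuclei", "RadialDistribution", "MeanFrac"),
    ("Cells", "Texture", "SumAverage"),
]
_FREE_MEASURES = [
    "Area", "Perimeter", "Eccentricity", "Solidity", "Extent",
    "FormFactor", "MajorAxisLength", "MinorAxisLength", "Compactness",
    "MaxFeretDiameter",
]


@dataclasses.dataclass(frozen=True)
class ChannelRegistry:
    """Ordered registry of imaging-channel tokens usable in feature names."""

    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channel registry must not be empty")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel tokens must be unique")
        for tok in self.channels:
            if not tok or "_" in tok or not tok.isalnum():
                raise ValueError(f"invalid channel token {tok!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.channels

    def __iter__(self):
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    @classmethod
    def five_channel(cls, brightfield: bool = False) -> "ChannelRegistry":
        """DNA, ER, RNA, AGP, Mito — the standard five effective channels."""
        ch = _FIVE + ((BRIGHTFIELD,) if brightfield else ())
        return cls(ch)

    @classmethod
    def six_channel(cls, brightfield: bool = False) -> "ChannelRegistry":
        """Variant with AGP split into Actin and Golgi (+ plasma membrane)."""
        ch = _SIX + ((BRIGHTFIELD,) if brightfield else ())
        return cls(ch)


class FeatureSchema:
    """Named morphological features plus their channel attribution.

    Feature names follow the ``Compartment_Group_Measure[_Channel[_Channel2]]``
    convention, so the channel set of every feature is recoverable by name
    parsing alone.
    """

    def __init__(self, names, channel_map, slots):
        self.names: tuple[str, ...] = tuple(names)
        self._channel_map: dict[str, frozenset[str]] = dict(channel_map)
        # slot index (position within its channel's single-feature block) for
        # single-channel features; used to share effect structure across channels
        self.slots: dict[str, int] = dict(slots)

    def __len__(self) -> int:
        return len(self.names)

    def channels_of(self, name: str) -> frozenset[str]:
        return self._channel_map[name]

    def features_of_channel(self, token: str) -> list[str]:
        return [n for n in self.names if token in self._channel_map[n]]

    @property
    def channel_free(self) -> list[str]:
        return [n for n in self.names if not self._channel_map[n]]


@dataclasses.dataclass
class SimConfig:
    """All simulator parameters.

    Scales are in robust-z-comparable units (cell noise has unit variance by
    default); ``effect_magnitude`` is the norm of an active compound's effect
    vector, spread across all features.
    """

    n_features_per_channel: int = 10
    n_channel_free_features: int = 8
    active_fraction: float = 0.9
    effect_magnitude: float = 1.0
    moa_sharing: float = 0.5  # rho: expected cosine between same-MOA effects
    channel_effect_sharing: float = 0.5  # effect redundancy across channels
    sigma_cell: float = 1.0
    sigma_site: float = 0.1
    sigma_plate: float = 0.1
    channel_corr: float = 0.3  # within-channel noise correlation r_chan
    cells_per_site: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"10X": 600.0, "20X": 150.0, "40X": 40.0}
    )
    magnification: str = "20X"
    sites_per_well: int = 9
    brightfield_effect_loading: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features_per_channel < 0 or self.n_channel_free_features < 0:
            raise ValueError("feature counts must be >= 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.effect_magnitude < 0:
            raise ValueError("effect_magnitude must be >= 0")
        if not 0.0 <= self.moa_sharing <= 1.0:
            raise ValueError("moa_sharing must be in [0, 1]")
        if not 0.0 <= self.channel_effect_sharing <= 1.0:
            raise ValueError("channel_effect_sharing must be in [0, 1]")
        if not 0.0 <= self.channel_corr < 1.0:
            raise ValueError("channel_corr must be in [0, 1)")
        for name in ("sigma_cell", "sigma_site", "sigma_plate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sites_per_well < 1:
            raise ValueError("sites_per_well must be >= 1")
        if any(v <= 0 for v in self.cells_per_site.values()):
            raise ValueError("cells-per-site means must be > 0")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    @property
    def lam(self) -> float:
        """Poisson mean cells per site at the configured magnification."""
        try:
            return float(self.cells_per_site[self.magnification])
        except KeyError:
            raise ValueError(
                f"no cells-per-site mean for magnification {self.magnification!r}"
            ) from None


def desk_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced-size configuration for fast desk-scale runs.

    Keeps the structural knobs (effects, MOA sharing, noise layers) at their
    defaults but shrinks feature counts, sites and cell counts so a full
    plate simulates in well under a second; the inverse magnification /
    cell-count ordering is preserved.
    """
    params = dict(
        n_features_per_channel=6,
        n_channel_free_features=6,
        sites_per_well=3,
        cells_per_site={"10X": 160.0, "20X": 40.0, "40X": 10.0},
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def build_feature_schema(registry: ChannelRegistry, config: SimConfig) -> FeatureSchema:
    """Build the feature-name schema for a channel registry.

    Per channel: ``n_features_per_channel`` single-channel features; one
    correlation feature per unordered channel pair; plus
    ``n_channel_free_features`` shape features with no channel attribution.
    """
    if config.n_features_per_channel == 0 and config.n_channel_free_features == 0:
        raise ValueError("zero features requested")
    names: list[str] = []
    channel_map: dict[str, frozenset[str]] = {}
    slots: dict[str, int] = {}
    for ch in registry:
        for i in range(config.n_features_per_channel):
            comp, group, measure = _SINGLE_TEMPLATES[i % len(_SINGLE_TEMPLATES)]
            suffix = f"{i // len(_SINGLE_TEMPLATES)}" if i >= len(_SINGLE_TEMPLATES) else ""
            name = f"{comp}_{group}_{measure}{suffix}_{ch}"
            names.append(name)
            channel_map[name] = frozenset({ch})
            slots[name] = i
    for c1, c2 in itertools.combinations(registry, 2):
        name = f"Cytoplasm_Correlation_Pearson_{c1}_{c2}"
        names.append(name)
        channel_map[name] = frozenset({c1, c2})
    for i in range(config.n_channel_free_features):
        measure = _FREE_MEASURES[i % len(_FREE_MEASURES)]
        suffix = f"{i // len(_FREE_MEASURES)}" if i >= len(_FREE_MEASURES) else ""
        name = f"Nuclei_AreaShape_{measure}{suffix}"
        names.append(name)
        channel_map[name] = frozenset()
        slots.setdefault(name, -1)
    return FeatureSchema(names, channel_map, {k: v for k, v in slots.items() if v >= 0})


@dataclasses.dataclass
class EffectLibrary:
    """Per-MOA and per-compound effect directions and effect vectors.

    ``betas`` holds one row per treatment compound (zeros for inactive
    compounds); ``moa_directions`` / ``compound_directions`` are unit vectors.
    """

    betas: pd.DataFrame
    moa_directions: pd.DataFrame
    compound_directions: pd.DataFrame
    active: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.betas.columns)


def _structured_direction(rng: np.random.Generator, schema: FeatureSchema,
                          config: SimConfig) -> np.ndarray:
    """Draw a unit effect direction with cross-channel slot sharing.

    Single-channel features in the same slot (e.g. MeanIntensity of DNA and of
    RNA) share a latent component with weight ``channel_effect_sharing``, so a
    perturbation that brightens one channel's intensity tends to move the
    analogous features of other channels too — the redundancy that makes
    dropping one channel nearly information-neutral.
    """
    n = len(schema)
    x = rng.standard_normal(n)
    s = config.channel_effect_sharing
    if s > 0 and schema.slots:
        n_slots = max(schema.slots.values()) + 1
        shared = rng.standard_normal(n_slots)
        for i, name in enumerate(schema.names):
            slot = schema.slots.get(name)
            if slot is not None:
                x[i] = np.sqrt(1.0 - s) * x[i] + np.sqrt(s) * shared[slot]
    norm = np.linalg.norm(x)
    return x / norm if norm > 0 else x


def build_effect_library(platemap: PlateMap, schema: FeatureSchema,
                         config: SimConfig) -> EffectLibrary:
    """Draw the seeded effect library for a plate map.

    Active compounds (a seeded subset of fraction ``active_fraction``) get
    ``beta_c = a * (sqrt(rho) u_m + sqrt(1-rho) v_c)``; Brightfield features
    are down-weighted by ``brightfield_effect_loading``.  Deterministic for a
    fixed seed.
    """
    compound_moa = platemap.compound_moa()
    if any(pd.isna(m) for m in compound_moa.values()):
        raise ValueError("all treatment compounds must carry an MOA label")
    compounds = sorted(compound_moa)
    moas = sorted(set(compound_moa.values()))
    rng = np.random.default_rng([int(config.seed), 0x5EED])

    u = {m: _structured_direction(rng, schema, config) for m in moas}
    v = {c: _structured_direction(rng, schema, config) for c in compounds}

    n_active = int(round(config.active_fraction * len(compounds)))
    active_idx = rng.choice(len(compounds), size=n_active, replace=False)
    active = pd.Series(False, index=compounds)
    active.iloc[np.sort(active_idx)] = True

    mask = np.ones(len(schema))
    for i, name in enumerate(schema.names):
        if BRIGHTFIELD in schema.channels_of(name):
            mask[i] = config.brightfield_effect_loading

    rho, a = config.moa_sharing, config.effect_magnitude
    rows = []
    for c in compounds:
        if active[c] and a > 0:
            beta = a * (np.sqrt(rho) * u[compound_moa[c]]
                        + np.sqrt(1.0 - rho) * v[c]) * mask
        else:
            beta = np.zeros(len(schema))
        rows.append(beta)
    betas = pd.DataFrame(rows, index=compounds, columns=schema.names)
    return EffectLibrary(
        betas=betas,
        moa_directions=pd.DataFrame([u[m] for m in moas], index=moas,
                                    columns=schema.names),
        compound_directions=pd.DataFrame([v[c] for c in compounds],
                                         index=compounds, columns=schema.names),
        active=active,
    )


def _noise_loadings(schema: FeatureSchema, registry: ChannelRegistry,
                    r_chan: float) -> tuple[np.ndarray, np.ndarray]:
    """Channel-factor loading matrix A (n_channels x F) and idiosyncratic
    weights w (F,) such that every feature has unit noise variance."""
    n_ch, n_f = len(registry), len(schema)
    order = {ch: k for k, ch in enumerate(registry)}
    A = np.zeros((n_ch, n_f))
    w = np.ones(n_f)
    for j, name in enumerate(schema.names):
        chans = schema.channels_of(name)
        if not chans:
            continue
        share = r_chan / len(chans)
        for ch in chans:
            A[order[ch], j] = np.sqrt(share)
        w[j] = np.sqrt(1.0 - r_chan)
    return A, w


def simulate_plate(
    platemap: PlateMap,
    library: EffectLibrary,
    schema: FeatureSchema,
    config: SimConfig,
    setting_label: str = "base",
    registry: ChannelRegistry | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a single-cell feature table for one plate.

    Returns one row per cell with metadata columns ``Metadata_Plate``,
    ``Metadata_Well``, ``Metadata_Site``, ``Metadata_Compound``,
    ``Metadata_MOA``, ``Metadata_Setting`` followed by the schema's feature
    columns.  Wells that draw zero cells contribute zero rows (a warning is
    logged).  Deterministic for a fixed seed (``seed`` overrides
    ``config.seed`` for the noise stream; the effect library is unaffected).
    """
    if registry is None:
        tokens = sorted({t for n in schema.names for t in schema.channels_of(n)})
        registry = ChannelRegistry(tuple(tokens)) if tokens else ChannelRegistry(("DNA",))
    if len(platemap.wells) == 0:
        raise ValueError("empty plate")
    lam = config.lam
    noise_seed = config.seed if seed is None else seed
    rng = np.random.default_rng([int(noise_seed), 0xCE11])

    n_f = len(schema)
    n_rows, n_cols = platemap.plate_dims
    row_eff = rng.normal(0.0, config.sigma_plate, size=(n_rows, n_f))
    col_eff = rng.normal(0.0, config.sigma_plate, size=(n_cols, n_f))
    A, w = _noise_loadings(schema, registry, config.channel_corr)

    wells = platemap.wells
    well_labels = list(wells.index)
    s = config.sites_per_well
    n_units = len(well_labels) * s
    counts = rng.poisson(lam, size=n_units)

    # per-(well, site) deterministic base = beta + row + col + site effect
    base = np.empty((n_units, n_f))
    meta_well, meta_site, meta_comp, meta_moa = [], [], [], []
    from .plate import parse_well  # local import to avoid cycle at module load

    unit = 0
    zero_wells = []
    for wlab in well_labels:
        r, c = parse_well(wlab, platemap.plate_dims)
        comp = wells.at[wlab, "compound_id"]
        moa = wells.at[wlab, "moa"]
        beta = (library.betas.loc[comp].to_numpy()
                if comp in library.betas.index else np.zeros(n_f))
        well_base = beta + row_eff[r] + col_eff[c]
        if counts[unit:unit + s].sum() == 0:
            zero_wells.append(wlab)
        for site in range(1, s + 1):
            base[unit] = well_base + rng.normal(0.0, config.sigma_site, size=n_f)
            meta_well.append(wlab)
            meta_site.append(site)
            meta_comp.append(comp)
            meta_moa.append(moa)
            unit += 1
    if zero_wells:
        logger.warning("wells with zero simulated cells: %s", zero_wells)

    total = int(counts.sum())
    # cell noise: shared per-channel factor + idiosyncratic, unit variance
    Z = rng.standard_normal((total, A.shape[0]))
    E = rng.standard_normal((total, n_f))
    values = np.repeat(base, counts, axis=0)
    values += config.sigma_cell * (Z @ A + E * w)

    df = pd.DataFrame(values, columns=list(schema.names))
    df.insert(0, "Metadata_Plate", platemap.plate_id)
    df.insert(1, "Metadata_Well", np.repeat(meta_well, counts))
    df.insert(2, "Metadata_Site", np.repeat(meta_site, counts))
    df.insert(3, "Metadata_Compound", np.repeat(meta_comp, counts))
    df.insert(4, "Metadata_MOA", np.repeat(np.asarray(meta_moa, dtype=object), counts))
    df.insert(5, "Metadata_Setting", setting_label)
    return df


def simulate_experiment_plate(
    config: SimConfig,
    registry: ChannelRegistry | None = None,
    platemap: PlateMap | None = None,
    setting_label: str = "base",
    seed: int | None = None,
):
    """Convenience wiring: layout -> schema -> effect library -> cells.

    Returns ``(platemap, schema, library, cells)``.  The plate layout and
    effect library derive from ``config.seed``; ``seed`` (if given) only
    re-rolls the measurement noise, which is the right comparison when
    sweeping acquisition settings over the same underlying biology.
    """
    from .plate import generate_jumpmoa_layout

    if registry is None:
        registry = ChannelRegistry.five_channel(brightfield=True)
    if platemap is None:
        platemap = generate_jumpmoa_layout(seed=config.seed)
    schema = build_feature_schema(registry, config)
    library = build_effect_library(platemap, schema, config)
    cells = simulate_plate(platemap, library, schema, config,
                           setting_label=setting_label, registry=registry,
                           seed=seed)
    return platemap, schema, library, cells
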