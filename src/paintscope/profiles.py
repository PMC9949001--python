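"""Well-profile construction: aggregation, normalization, feature selection.

Turns single-cell / site-level feature tables into analysis-ready well
profiles: per-well arithmetic-mean aggregation, per-plate robust
standardization (median / 1.4826*MAD), removal of missing, near-constant and
redundant features, and channel-feature dropping for channel-dropout
experiments.  Tables follow the ``Metadata_`` column-prefix convention; every
non-metadata column is a feature.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .simulate import ChannelRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "METADATA_PREFIX",
    "Profile",
    "ProfilingError",
    "feature_columns",
    "metadata_columns",
    "aggregate",
    "mad_robustize",
    "feature_select",
    "channels_of_feature",
    "drop_channel_features",
]

METADATA_PREFIX = "Metadata_"
MAD_CONSISTENCY = 1.4826  # makes the robust scale match an SD for Gaussian data


class ProfilingError(ValueError):
    pass


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if not c.startswith(METADATA_PREFIX)]


def metadata_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(METADATA_PREFIX)]


@dataclasses.dataclass
class Profile:
    """A well-level feature table plus its processing provenance.

    ``data`` has one row per (plate, well); ``provenance`` accumulates the
    processing history: aggregation level, per-well cell counts, normalization
    state, feature-selection trace, dropped channels, subsampled sites.
    """

    data: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return feature_columns(self.data)

    def with_data(self, data: pd.DataFrame, **updates) -> "Profile":
        prov = dict(self.provenance)
        prov.update(updates)
        return Profile(data=data, provenance=prov)


def aggregate(
    cells: pd.DataFrame,
    level: str = "well",
    expected_wells: list[str] | None = None,
) -> Profile:
    """Mean-aggregate a cell table to site or well level.

    The well mean is the arithmetic mean over all cells of the well (a
    cell-weighted mean over sites, not a mean of site means).  Per-group cell
    counts are recorded both in a ``Metadata_Object_Count`` column and in
    provenance.  ``expected_wells`` (labels) adds all-missing rows for wells
    that produced no cells; those are flagged in provenance and excluded from
    metrics downstream.
    """
    keys = ["Metadata_Plate", "Metadata_Well"]
    if level == "site":
        keys.append("Metadata_Site")
    elif level != "well":
        raise ValueError(f"level must be 'site' or 'well', got {level!r}")
    missing_keys = [k for k in keys if k not in cells.columns]
    if missing_keys:
        raise ProfilingError(f"missing grouping metadata: {missing_keys}")

    feats = feature_columns(cells)
    carry = [c for c in ("Metadata_Compound", "Metadata_MOA", "Metadata_Setting")
             if c in cells.columns]
    grouped = cells.groupby(keys, sort=True, dropna=False)
    agg = grouped[feats].mean()
    counts = grouped.size().rename("Metadata_Object_Count")
    meta = grouped[carry].first() if carry else None

    out = pd.concat([x for x in (meta, counts, agg) if x is not None], axis=1)
    out = out.reset_index()

    empty_wells: list[str] = []
    if expected_wells is not None and level == "well":
        plates = out["Metadata_Plate"].unique()
        have = set(zip(out["Metadata_Plate"], out["Metadata_Well"]))
        rows = []
        for p in plates:
            for wlab in expected_wells:
                if (p, wlab) not in have:
                    empty_wells.append(wlab)
                    rows.append({"Metadata_Plate": p, "Metadata_Well": wlab,
                                 "Metadata_Object_Count": 0})
        if rows:
            logger.warning("wells with no cells, emitting missing rows: %s",
                           empty_wells)
            out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
            out = out.sort_values(["Metadata_Plate", "Metadata_Well"],
                                  ignore_index=True)

    cell_counts = {
        (p, wlab): int(n)
        for (p, wlab), n in out.groupby(["Metadata_Plate", "Metadata_Well"])
        ["Metadata_Object_Count"].sum().items()
    }
    plate_counts = {p: int(n) for p, n in
                    out.groupby("Metadata_Plate")["Metadata_Object_Count"]
                    .sum().items()}
    prov = {
        "level": level,
        "cell_counts": cell_counts,
        "plate_cell_counts": plate_counts,
        "empty_wells": empty_wells,
        "normalized": None,
        "feature_selection": [],
        "dropped_channels": [],
    }
    if "Metadata_Setting" in out.columns:
        settings = out["Metadata_Setting"].dropna().unique().tolist()
        prov["setting_label"] = settings[0] if len(settings) == 1 else settings
    if "Metadata_Site" in cells.columns and level == "well":
        prov["sites_used"] = {
            (p, wlab): sorted(g["Metadata_Site"].unique().tolist())
            for (p, wlab), g in cells.groupby(["Metadata_Plate", "Metadata_Well"])
        }
    return Profile(data=out, provenance=prov)


def mad_robustize(profile: Profile, epsilon: float = 1e-18) -> Profile:
    """Robust per-plate standardization: ``(x - median) / (1.4826 * MAD + eps)``.

    Applied per feature within each plate.  Features whose MAD is exactly zero
    (constant over the plate) become all-missing for that plate and are left
    for feature selection to remove.  Idempotent up to ``eps`` on
    already-robustized data.
    """
    df = profile.data.copy()
    feats = profile.features
    df[feats] = df[feats].astype(float)
    if df.groupby("Metadata_Plate").size().min() < 2:
        raise ProfilingError("robustize needs at least 2 wells per plate")
    for _, idx in df.groupby("Metadata_Plate").groups.items():
        block = df.loc[idx, feats]
        med = block.median(axis=0, skipna=True)
        mad = (block - med).abs().median(axis=0, skipna=True)
        scaled = (block - med) / (MAD_CONSISTENCY * mad + epsilon)
        scaled.loc[:, mad == 0] = np.nan
        df.loc[idx, feats] = scaled
    return profile.with_data(df, normalized="mad_robustize")


def _near_zero_variance(col: pd.Series, freq_ratio: float,
                        unique_fraction: float) -> bool:
    x = col.dropna()
    if len(x) == 0:
        return False  # handled by drop_na
    vc = x.value_counts()
    ratio = np.inf if len(vc) < 2 else vc.iloc[0] / vc.iloc[1]
    uniq = x.nunique() / len(x)
    return bool(ratio > freq_ratio and uniq < unique_fraction)


def feature_select(
    profile: Profile,
    ops: tuple[str, ...] = ("drop_na", "variance_threshold", "correlation_threshold"),
    corr_cutoff: float = 0.9,
    na_cutoff: float = 0.05,
    freq_ratio: float = 19.0,
    unique_fraction: float = 0.01,
) -> Profile:
    """Ordered feature selection with a recorded removal trace.

    * ``drop_na`` — remove features whose missing fraction exceeds ``na_cutoff``.
    * ``variance_threshold`` — remove near-zero-variance features (ratio of the
      most to second-most common value > ``freq_ratio`` AND unique-value
      fraction < ``unique_fraction``).
    * ``correlation_threshold`` — while any |Pearson r| > ``corr_cutoff``
      remains, greedily remove the involved feature with the largest mean
      absolute correlation to all remaining features; ties drop the
      lexicographically later name.  Deterministic and order-independent.
    """
    df = profile.data
    feats = list(profile.features)
    trace = list(profile.provenance.get("feature_selection", []))

    for op in ops:
        if op == "drop_na":
            frac = df[feats].isna().mean()
            removed = sorted(frac[frac > na_cutoff].index)
        elif op == "variance_threshold":
            removed = sorted(
                f for f in feats
                if _near_zero_variance(df[f], freq_ratio, unique_fraction)
            )
        elif op == "correlation_threshold":
            removed = _correlation_removals(df[feats], corr_cutoff)
        else:
            raise ValueError(f"unknown feature-selection op {op!r}")
        feats = [f for f in feats if f not in set(removed)]
        trace.append({"op": op, "removed": removed})
        if not feats:
            raise ProfilingError(f"all features removed (last op: {op})")

    keep = metadata_columns(df) + feats
    return profile.with_data(df[keep].copy(), feature_selection=trace)


def _correlation_removals(block: pd.DataFrame, cutoff: float) -> list[str]:
    if block.shape[1] < 2:
        return []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = block.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)
    removed: list[str] = []
    while True:
        over = corr.gt(cutoff)
        if not over.to_numpy().any():
            break
        involved = corr.columns[over.any(axis=0)]
        mean_abs = corr.loc[involved].mean(axis=1)
        top = mean_abs.max()
        # ties: drop the lexicographically later name
        victim = sorted(mean_abs.index[mean_abs == top])[-1]
        removed.append(victim)
        corr = corr.drop(index=victim, columns=victim)
    return sorted(removed)


def channels_of_feature(name: str, registry: ChannelRegistry) -> frozenset[str]:
    """Channel tokens referenced by a feature name (by underscore parsing).

    Unknown tokens are ignored; channel-free features return the empty set.
    """
    return frozenset(tok for tok in name.split("_") if tok in registry)


def drop_channel_features(
    profile: Profile, channel: str, registry: ChannelRegistry
) -> Profile:
    """Remove every feature referencing ``channel`` (incl. two-channel
    correlation features).  Must run before feature selection, mirroring the
    drop-then-select order of channel-dropout analyses."""
    if channel not in registry:
        raise ProfilingError(f"channel {channel!r} not in registry {tuple(registry)}")
    done = [t for t in profile.provenance.get("feature_selection", []) if t["removed"]]
    if done:
        raise ProfilingError("channel dropping must precede feature selection")
    removed = [f for f in profile.features
               if channel in channels_of_feature(f, registry)]
    keep = [c for c in profile.data.columns if c not in set(removed)]
    dropped = list(profile.provenance.get("dropped_channels", [])) + [channel]
    return profile.with_data(profile.data[keep].copy(), dropped_channels=dropped)
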