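"""Setting-perturbation experiments.

Orchestrates the analyses used to grade imaging configurations end to end:
site subsampling (cell-count curves), channel and brightfield feature
dropout, channel-correlation summaries, and reproducible experiment runs
that emit profiles, metric results, a normalized leaderboard and a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_profile
from .metrics import (
    MetricConfig,
    ProfileStrength,
    ProfileStrengthResults,
    normalize_leaderboard,
)
from .plate import PlateMap
from .profiles import (
    Profile,
    aggregate,
    channels_of_feature,
    drop_channel_features,
    feature_select,
    mad_robustize,
)
from .simulate import (
    ChannelRegistry,
    SimConfig,
    simulate_experiment_plate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentSpec",
    "ExperimentError",
    "profile_pipeline",
    "subsample_sites",
    "cellcount_curve",
    "channel_dropout_experiment",
    "DropoutResult",
    "channel_correlation_summary",
    "run_experiment",
]


class ExperimentError(ValueError):
    pass


@dataclasses.dataclass
class ExperimentSpec:
    """A base simulation plus the perturbations to grade against it."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    metric: MetricConfig = dataclasses.field(default_factory=MetricConfig)
    registry: ChannelRegistry = dataclasses.field(
        default_factory=lambda: ChannelRegistry.five_channel(brightfield=True)
    )
    setting_label: str = "base"
    subsample_sites: tuple[int, ...] = ()
    drop_channels: tuple[str, ...] = ()
    magnifications: tuple[str, ...] = ()
    effect_sweep: tuple[float, ...] = ()
    n_seeds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.subsample_sites:
            if t < 1 or t > self.sim.sites_per_well:
                raise ExperimentError(
                    f"subsample target {t} outside 1..{self.sim.sites_per_well}"
                )
        for ch in self.drop_channels:
            if ch not in self.registry:
                raise ExperimentError(f"drop channel {ch!r} not in registry")


def profile_pipeline(
    cells: pd.DataFrame,
    drop_channel: str | None = None,
    registry: ChannelRegistry | None = None,
    **select_kwargs,
) -> Profile:
    """cells -> well means -> robustize -> (optional channel drop) -> select."""
    prof = aggregate(cells, level="well")
    prof = mad_robustize(prof)
    if drop_channel is not None:
        if registry is None:
            raise ExperimentError("registry required to drop channel features")
        prof = drop_channel_features(prof, drop_channel, registry)
    return feature_select(prof, **select_kwargs)


def subsample_sites(
    cells: pd.DataFrame, target_sites: int, seed=None
) -> Profile:
    """Keep a seeded random subset of sites per well, then aggregate to wells.

    Draws are independent per well (no shared site index across the plate).
    Errors if any well has fewer sites than requested.  Provenance records
    the sites used and the new cell counts.
    """
    if "Metadata_Site" not in cells.columns:
        raise ExperimentError("cells table lacks Metadata_Site")
    rng = np.random.default_rng(seed)
    masks = []
    sites_used: dict[tuple, list] = {}
    for (plate, well), grp in cells.groupby(["Metadata_Plate", "Metadata_Well"]):
        avail = sorted(grp["Metadata_Site"].unique())
        if len(avail) < target_sites:
            raise ExperimentError(
                f"well {well}: {len(avail)} sites available, "
                f"{target_sites} requested"
            )
        chosen = sorted(rng.choice(avail, size=target_sites, replace=False).tolist())
        sites_used[(plate, well)] = chosen
        masks.append(grp.index[grp["Metadata_Site"].isin(chosen)])
    keep = cells.loc[np.concatenate([m.to_numpy() for m in masks])]
    prof = aggregate(keep.sort_index(), level="well")
    prof.provenance["sites_used"] = sites_used
    prof.provenance["subsampled_to_sites"] = target_sites
    return prof


def _fit(profile: Profile, platemap: PlateMap, metric: MetricConfig,
         seed) -> ProfileStrengthResults:
    return ProfileStrength(profile, platemap, metric).fit(seed=seed)


def cellcount_curve(spec: ExperimentSpec) -> pd.DataFrame:
    """Profile strength versus plate cell count.

    For each magnification and each subsampled site count, simulates (or
    reuses) the plate, runs the full pipeline and metrics, and emits one row
    per condition and seed: (magnification, sites, plate_cell_count,
    percent_replicating, percent_matching, percent_score, seed).
    """
    mags = spec.magnifications or (spec.sim.magnification,)
    targets = tuple(sorted(spec.subsample_sites)) or (spec.sim.sites_per_well,)
    rows = []
    for mag in mags:
        cfg = spec.sim.replace(magnification=mag)
        for k in range(spec.n_seeds):
            noise_seed = spec.seed + k
            platemap, _, _, cells = simulate_experiment_plate(
                cfg, registry=spec.registry,
                setting_label=f"{mag}-seed{noise_seed}", seed=noise_seed,
            )
            for target in targets:
                if target == cfg.sites_per_well:
                    prof = profile_pipeline(cells)
                else:
                    sub = subsample_sites(cells, target, seed=[noise_seed, target])
                    sub = mad_robustize(sub)
                    prof = feature_select(sub)
                res = _fit(prof, platemap, spec.metric, seed=noise_seed)
                n_cells = int(sum(prof.provenance["plate_cell_counts"].values()))
                rows.append({
                    "magnification": mag,
                    "sites": target,
                    "plate_cell_count": n_cells,
                    "percent_replicating": res.percent_replicating,
                    "percent_matching": res.percent_matching,
                    "percent_score": res.percent_score,
                    "seed": noise_seed,
                })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class DropoutResult:
    """Paired metric results with and without one channel's features."""

    channel: str
    with_channel: ProfileStrengthResults
    without_channel: ProfileStrengthResults

    @property
    def delta_percent_score(self) -> float:
        """without - with: positive means dropping the channel helped."""
        return (self.without_channel.percent_score
                - self.with_channel.percent_score)

    @property
    def delta(self) -> dict:
        return {
            "percent_replicating": (self.without_channel.percent_replicating
                                    - self.with_channel.percent_replicating),
            "percent_matching": (self.without_channel.percent_matching
                                 - self.with_channel.percent_matching),
            "percent_score": self.delta_percent_score,
        }


def channel_dropout_experiment(
    spec: ExperimentSpec, channel: str, seed=None
) -> DropoutResult:
    """Run the pipeline twice from the same simulated cells, dropping one
    channel's features before feature selection in the second run."""
    if channel not in spec.registry:
        raise ExperimentError(f"channel {channel!r} not in registry")
    noise_seed = spec.seed if seed is None else seed
    platemap, _, _, cells = simulate_experiment_plate(
        spec.sim, registry=spec.registry, setting_label=spec.setting_label,
        seed=noise_seed,
    )
    prof_with = profile_pipeline(cells)
    prof_without = profile_pipeline(cells, drop_channel=channel,
                                    registry=spec.registry)
    return DropoutResult(
        channel=channel,
        with_channel=_fit(prof_with, platemap, spec.metric, noise_seed),
        without_channel=_fit(prof_without, platemap, spec.metric, noise_seed),
    )


def channel_correlation_summary(
    profile: Profile, registry: ChannelRegistry
) -> pd.DataFrame:
    """Channel x channel matrix of mean |Pearson r| between feature groups.

    Features are grouped by channel membership (two-channel correlation
    features belong to both groups); correlations are computed across wells.
    The diagonal is the within-channel mean |r| excluding self-pairs; a
    channel with no features yields a missing row/column.
    """
    feats = profile.features
    groups = {
        ch: [f for f in feats if ch in channels_of_feature(f, registry)]
        for ch in registry
    }
    if sum(1 for g in groups.values() if g) < 2:
        raise ExperimentError("need >= 2 channels with >= 1 feature each")
    X = profile.data[feats].to_numpy(dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    with np.errstate(invalid="ignore"):
        corr = pd.DataFrame(np.abs(np.corrcoef(X.T)), index=feats, columns=feats)
    out = pd.DataFrame(np.nan, index=list(registry), columns=list(registry))
    for c1 in registry:
        for c2 in registry:
            f1, f2 = groups[c1], groups[c2]
            if not f1 or not f2:
                continue
            block = corr.loc[f1, f2].to_numpy()
            if c1 == c2:
                n = len(f1)
                if n < 2:
                    continue
                mask = ~np.eye(n, dtype=bool)
                out.loc[c1, c2] = float(block[mask].mean())
            else:
                same = np.equal.outer(np.asarray(f1, object),
                                      np.asarray(f2, object))
                out.loc[c1, c2] = float(block[~same].mean())
    return out


def _config_hash(spec: ExperimentSpec) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, ChannelRegistry):
            return list(o.channels)
        return str(o)

    blob = json.dumps(dataclasses.asdict(spec), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(spec: ExperimentSpec, out_dir: str | Path) -> Path:
    """Run a full experiment: base condition plus every perturbation.

    Writes well profiles, per-setting metric JSONs (+ null CSVs), a
    normalized leaderboard CSV, a log file and a ``manifest.json`` recording
    the config hash, seed, package version and every artifact.  A failing
    stage is recorded in the manifest (status ``failed``) before the error
    propagates, so interrupted runs are identifiable.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("paintscope")
    root.addHandler(handler)

    settings = [("base", None, None)]
    settings += [(f"sites-{t}", "subsample", t) for t in spec.subsample_sites]
    settings += [(f"drop-{ch}", "drop", ch) for ch in spec.drop_channels]

    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": spec.seed,
        "config_hash": _config_hash(spec),
        "version": __version__,
        "stages": {name: {"status": "pending"} for name, _, _ in
                   [("simulate", None, None)] + settings + [("leaderboard", None, None)]},
    }

    def save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    save_manifest()
    scores = []
    try:
        try:
            platemap, _, _, cells = simulate_experiment_plate(
                spec.sim, registry=spec.registry,
                setting_label=spec.setting_label, seed=spec.seed,
            )
            manifest["stages"]["simulate"] = {"status": "complete"}
            save_manifest()
        except Exception as exc:
            manifest["stages"]["simulate"] = {"status": "failed",
                                              "error": str(exc)}
            save_manifest()
            raise

        for name, kind, arg in settings:
            try:
                if kind == "subsample":
                    prof = subsample_sites(cells, arg, seed=[spec.seed, arg])
                    prof = feature_select(mad_robustize(prof))
                elif kind == "drop":
                    prof = profile_pipeline(cells, drop_channel=arg,
                                            registry=spec.registry)
                else:
                    prof = profile_pipeline(cells)
                prof.data = prof.data.assign(Metadata_Setting=name)
                prof_path = out / f"profiles_{name}.csv"
                write_profile(prof, prof_path)
                res = _fit(prof, platemap, spec.metric, spec.seed)
                res_path = out / f"metrics_{name}.json"
                res.save(res_path, null_csv=out / f"null_{name}.csv")
                scores.append({
                    "setting": name,
                    "percent_replicating": res.percent_replicating,
                    "percent_matching": res.percent_matching,
                    "percent_score": res.percent_score,
                })
                manifest["stages"][name] = {
                    "status": "complete",
                    "artifacts": [str(prof_path), str(res_path)],
                }
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed",
                                            "error": str(exc)}
                save_manifest()
                raise
            save_manifest()

        try:
            board = normalize_leaderboard(pd.DataFrame(scores))
            board_path = out / "leaderboard.csv"
            board.to_csv(board_path, index=False)
            manifest["stages"]["leaderboard"] = {
                "status": "complete", "artifacts": [str(board_path)],
            }
        except Exception as exc:
            manifest["stages"]["leaderboard"] = {"status": "failed",
                                                 "error": str(exc)}
            save_manifest()
            raise
        save_manifest()
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
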