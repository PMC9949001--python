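"""Profile-strength metrics: percent replicating, percent matching, leaderboards.

Percent replicating asks: for what fraction of compounds does the profile
correlation among its replicate wells exceed what chance would produce?
Percent matching asks the same for compounds annotated with the same
mechanism of action (MOA).  Chance is quantified by a resampled null
distribution — many random groups of non-matching wells, each summarized by
its median pairwise Pearson correlation across features — and the decision
threshold is a high percentile (default the 95th) of that null.  Percent
score is the arithmetic mean of the two metrics and is what setting
leaderboards rank.

The model-object surface is :class:`ProfileStrength` (built from a well
profile plus a plate map) whose :meth:`~ProfileStrength.fit` returns a
:class:`ProfileStrengthResults` carrying the estimates, null distributions,
thresholds, per-compound statistics and a ``summary()`` table; the
module-level functions expose each step individually.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .plate import PlateMap, ROLE_TREATMENT
from .profiles import Profile, feature_columns

__all__ = [
    "MetricConfig",
    "MetricError",
    "MetricFragment",
    "median_replicate_correlation",
    "median_moa_matching_correlation",
    "sample_null",
    "percentile",
    "percent_replicating",
    "percent_matching",
    "percent_score",
    "mean_aggregate_duplicates",
    "normalize_leaderboard",
    "ProfileStrength",
    "ProfileStrengthResults",
]


class MetricError(ValueError):
    pass


@dataclasses.dataclass
class MetricConfig:
    """Configuration of the resampling metrics.

    ``null_unit`` selects how a null draw is formed: ``"group"`` (default)
    mirrors the foreground statistic — groups of replicate-count wells with
    all-distinct compounds for replicating, pairs of distinct-MOA compounds
    (median cross-well correlation) for matching — making null and foreground
    exchangeable under the no-signal model; ``"pair"`` uses single random
    well pairs.  ``foreground_aggregate`` selects per-compound medians
    (default) or pooling of all foreground pairs into one distribution.
    """

    null_size: int = 10_000
    threshold_percentile: float = 95.0
    correlation: str = "pearson"
    null_unit: str = "group"
    foreground_aggregate: str = "median"
    include_controls_in_null: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.null_size < 1:
            raise ValueError("null_size must be >= 1")
        if not 0.0 < self.threshold_percentile < 100.0:
            raise ValueError("threshold_percentile must be in (0, 100)")
        if self.correlation != "pearson":
            raise ValueError("only Pearson correlation is supported")
        if self.null_unit not in ("group", "pair"):
            raise ValueError("null_unit must be 'group' or 'pair'")
        if self.foreground_aggregate not in ("median", "pooled"):
            raise ValueError("foreground_aggregate must be 'median' or 'pooled'")


# ---------------------------------------------------------------------------
# well matrix preparation


@dataclasses.dataclass
class _Wells:
    """Usable profile rows with their compound/MOA labels and correlations."""

    wells: list[tuple[str, str]]  # (plate, well)
    compounds: np.ndarray  # object array
    moas: np.ndarray
    corr: np.ndarray  # well x well Pearson correlation across features

    def compound_rows(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.compounds):
            out.setdefault(c, []).append(i)
        return {c: np.asarray(v) for c, v in out.items()}


def _prepare_wells(
    profile: Profile | pd.DataFrame,
    platemap: PlateMap,
    include_controls: bool = False,
) -> _Wells:
    df = profile.data if isinstance(profile, Profile) else profile
    feats = feature_columns(df)
    feats = [f for f in feats if f != "Metadata_Object_Count"]
    if not feats:
        raise MetricError("profile has no feature columns")
    roles = platemap.wells["role"]
    comp = platemap.wells["compound_id"]
    moa = platemap.wells["moa"]

    if "Metadata_Well" not in df.columns:
        raise MetricError("profile lacks a Metadata_Well column")
    wlabs = df["Metadata_Well"].tolist()
    plates = (df["Metadata_Plate"].tolist() if "Metadata_Plate" in df.columns
              else ["plate"] * len(df))
    keep_idx, wells, comps, moas = [], [], [], []
    for i, (plate, wlab) in enumerate(zip(plates, wlabs)):
        if wlab not in roles.index:
            continue
        if not include_controls and roles[wlab] != ROLE_TREATMENT:
            continue
        keep_idx.append(i)
        wells.append((plate, wlab))
        comps.append(comp[wlab])
        moas.append(moa[wlab])

    X = df.iloc[keep_idx][feats].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} wells with missing feature values",
            stacklevel=2,
        )
    sd = X.std(axis=1)
    flat = ok & (sd == 0)
    if flat.any():
        warnings.warn(
            f"excluding {int(flat.sum())} zero-variance profile rows "
            "(correlation undefined)",
            stacklevel=2,
        )
        ok &= sd > 0
    X = X[ok]
    if X.shape[0] < 2:
        raise MetricError("fewer than 2 usable profile rows")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    return _Wells(
        wells=[w for w, k in zip(wells, ok) if k],
        compounds=np.asarray([c for c, k in zip(comps, ok) if k], dtype=object),
        moas=np.asarray([m for m, k in zip(moas, ok) if k], dtype=object),
        corr=corr,
    )


def _median_pairwise(corr: np.ndarray, idx: np.ndarray) -> float:
    pairs = [corr[i, j] for i, j in itertools.combinations(idx, 2)]
    return float(np.median(pairs))


# ---------------------------------------------------------------------------
# foreground statistics


def median_replicate_correlation(
    profile: Profile | pd.DataFrame, platemap: PlateMap
) -> tuple[pd.Series, list[str]]:
    """Per-compound median pairwise Pearson correlation among replicate wells.

    Returns ``(r_c, excluded)`` where ``excluded`` lists compounds with fewer
    than 2 usable wells.
    """
    w = _prepare_wells(profile, platemap)
    rows = w.compound_rows()
    vals, excluded = {}, []
    for c in sorted(rows):
        if len(rows[c]) < 2:
            excluded.append(c)
        else:
            vals[c] = _median_pairwise(w.corr, rows[c])
    if not vals:
        raise MetricError("no compound has >= 2 profiled replicate wells")
    return pd.Series(vals, name="median_replicate_correlation"), excluded


def median_moa_matching_correlation(
    profile: Profile | pd.DataFrame, platemap: PlateMap
) -> tuple[pd.Series, list[str]]:
    """Per-compound median Pearson correlation with same-MOA *other* compounds.

    For compound ``c``, the median over all (well of c) x (well of a
    different compound sharing c's MOA) pairs.  Returns ``(m_c, excluded)``
    with singleton-MOA compounds excluded and reported.
    """
    w = _prepare_wells(profile, platemap)
    rows = w.compound_rows()
    comp_moa = {c: m for c, m in zip(w.compounds, w.moas)}
    moa_comps: dict[str, list[str]] = {}
    for c, m in comp_moa.items():
        moa_comps.setdefault(m, []).append(c)
    vals, excluded = {}, []
    for c in sorted(rows):
        partners = [p for p in moa_comps[comp_moa[c]] if p != c]
        if not partners:
            excluded.append(c)
            continue
        mine = rows[c]
        theirs = np.concatenate([rows[p] for p in partners])
        pairs = w.corr[np.ix_(mine, theirs)].ravel()
        vals[c] = float(np.median(pairs))
    if not vals:
        raise MetricError("no MOA class has >= 2 distinct compounds")
    return pd.Series(vals, name="median_moa_matching_correlation"), excluded


# ---------------------------------------------------------------------------
# null distributions


def _reject_sample(rng, n_entities: int, labels: np.ndarray, K: int,
                   g: int) -> np.ndarray:
    """K index groups of size g, distinct entities and distinct labels."""
    codes = pd.factorize(labels)[0]
    if len(np.unique(codes)) < g:
        raise MetricError(
            f"cannot draw groups of {g} with distinct labels from "
            f"{len(np.unique(codes))} label classes"
        )
    out = np.empty((K, g), dtype=np.intp)
    filled = 0
    while filled < K:
        need = K - filled
        cand = rng.integers(0, n_entities, size=(need, g))
        s_ent = np.sort(cand, axis=1)
        ok = (np.diff(s_ent, axis=1) != 0).all(axis=1)
        s_lab = np.sort(codes[cand], axis=1)
        ok &= (np.diff(s_lab, axis=1) != 0).all(axis=1)
        good = cand[ok]
        take = min(len(good), need)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def sample_null(
    profile: Profile | pd.DataFrame,
    platemap: PlateMap,
    group_size: int,
    K: int = 10_000,
    mode: str = "non-replicate",
    seed=None,
    null_unit: str = "group",
    include_controls: bool = False,
) -> np.ndarray:
    """Draw the resampled null distribution of median profile correlations.

    mode="non-replicate"
        Each draw: ``group_size`` wells, all from distinct compounds;
        statistic = median pairwise correlation.  This is the percent-
        replicating null.
    mode="non-matching-moa"
        Each draw: ``group_size`` compounds with all-distinct MOAs;
        statistic = median correlation over all cross-compound well pairs,
        mirroring the foreground matching statistic.  With
        ``null_unit="pair"`` a draw is instead a single pair of wells from
        distinct MOAs and the statistic their correlation.

    Draws are without replacement within a group and with replacement across
    groups; rejection sampling enforces distinctness.  Deterministic per seed.
    """
    w = _prepare_wells(profile, platemap, include_controls=include_controls)
    rng = np.random.default_rng(seed)
    if mode == "non-replicate":
        g = 2 if null_unit == "pair" else group_size
        draws = _reject_sample(rng, len(w.compounds), w.compounds, K, g)
        pi, pj = np.triu_indices(g, k=1)
        return np.median(w.corr[draws[:, pi], draws[:, pj]], axis=1)
    if mode == "non-matching-moa":
        if null_unit == "pair":
            draws = _reject_sample(rng, len(w.moas), w.moas, K, 2)
            return w.corr[draws[:, 0], draws[:, 1]]
        rows = w.compound_rows()
        comps = sorted(rows)
        comp_moa = {c: m for c, m in zip(w.compounds, w.moas)}
        moa_labels = np.asarray([comp_moa[c] for c in comps], dtype=object)
        draws = _reject_sample(rng, len(comps), moa_labels, K, group_size)
        counts = {c: len(rows[c]) for c in comps}
        if len(set(counts.values())) == 1:
            # uniform replicate counts: fully vectorized cross-pair medians
            r = next(iter(counts.values()))
            W = np.stack([rows[c] for c in comps])  # (n_comp, r)
            flat = W[draws].reshape(K, group_size * r)
            block = np.repeat(np.arange(group_size), r)
            pi, pj = np.triu_indices(group_size * r, k=1)
            cross = block[pi] != block[pj]
            pi, pj = pi[cross], pj[cross]
            return np.median(w.corr[flat[:, pi], flat[:, pj]], axis=1)
        out = np.empty(K)
        for k in range(K):
            groups = [rows[comps[i]] for i in draws[k]]
            vals = [
                w.corr[np.ix_(a, b)].ravel()
                for a, b in itertools.combinations(groups, 2)
            ]
            out[k] = np.median(np.concatenate(vals))
        return out
    raise ValueError(f"unknown null mode {mode!r}")


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile with inclusive endpoints.

    The convention is NumPy's ``method="linear"``: the p-th percentile of n
    sorted values interpolates between the two order statistics bracketing
    rank ``(n - 1) * p / 100``; q=0 is the minimum and q=100 the maximum.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise MetricError("percentile of an empty list")
    return float(np.percentile(arr, q, method="linear"))


# ---------------------------------------------------------------------------
# the metrics


@dataclasses.dataclass
class MetricFragment:
    """One metric's result: the estimate plus everything used to compute it."""

    metric: str
    value: float
    per_compound: pd.Series
    null: np.ndarray
    threshold: float
    n_evaluated: int
    excluded: list[str]
    group_size: int

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "metric": self.metric,
            "value": self.value,
            "threshold": self.threshold,
            "n_evaluated": self.n_evaluated,
            "n_excluded": len(self.excluded),
            "excluded": list(self.excluded),
            "group_size": self.group_size,
            "null_size": int(len(self.null)),
            "per_compound": {k: float(v) for k, v in self.per_compound.items()},
        }
        if include_null:
            d["null"] = [float(x) for x in self.null]
        return d


def _pooled_foreground(profile, platemap, which: str) -> np.ndarray:
    w = _prepare_wells(profile, platemap)
    rows = w.compound_rows()
    vals = []
    if which == "replicating":
        for c, idx in rows.items():
            vals.extend(
                w.corr[i, j] for i, j in itertools.combinations(idx, 2)
            )
    else:
        comp_moa = {c: m for c, m in zip(w.compounds, w.moas)}
        for c1, c2 in itertools.combinations(sorted(rows), 2):
            if comp_moa[c1] == comp_moa[c2]:
                vals.extend(w.corr[np.ix_(rows[c1], rows[c2])].ravel())
    return np.asarray(vals)


def _modal_group_size(sizes) -> int:
    vc = pd.Series(list(sizes)).value_counts()
    return int(vc.index[0])


def percent_replicating(
    profile: Profile | pd.DataFrame,
    platemap: PlateMap,
    config: MetricConfig | None = None,
    seed=None,
) -> MetricFragment:
    """Fraction (in %) of compounds whose replicate-well median correlation
    strictly exceeds the null's threshold percentile."""
    config = config or MetricConfig()
    if seed is None:
        seed = config.seed
    r_c, excluded = median_replicate_correlation(profile, platemap)
    w = _prepare_wells(profile, platemap)
    rows = w.compound_rows()
    g = _modal_group_size(len(v) for v in rows.values() if len(v) >= 2)
    null = sample_null(
        profile, platemap, group_size=g, K=config.null_size,
        mode="non-replicate", seed=_substream(seed, 1),
        null_unit=config.null_unit,
        include_controls=config.include_controls_in_null,
    )
    t = percentile(null, config.threshold_percentile)
    if config.foreground_aggregate == "pooled":
        pooled = _pooled_foreground(profile, platemap, "replicating")
        value = 100.0 * float(np.mean(pooled > t))
    else:
        value = 100.0 * float(np.mean(r_c.to_numpy() > t))
    return MetricFragment(
        metric="percent_replicating", value=value, per_compound=r_c,
        null=null, threshold=t, n_evaluated=len(r_c), excluded=excluded,
        group_size=g,
    )


def percent_matching(
    profile: Profile | pd.DataFrame,
    platemap: PlateMap,
    config: MetricConfig | None = None,
    seed=None,
) -> MetricFragment:
    """Fraction (in %) of compounds whose same-MOA cross-compound median
    correlation strictly exceeds the null's threshold percentile.

    The null pairs compounds with distinct MOAs (see :func:`sample_null`);
    singleton-MOA compounds are excluded and reported.
    """
    config = config or MetricConfig()
    if seed is None:
        seed = config.seed
    m_c, excluded = median_moa_matching_correlation(profile, platemap)
    null = sample_null(
        profile, platemap, group_size=2, K=config.null_size,
        mode="non-matching-moa", seed=_substream(seed, 2),
        null_unit=config.null_unit,
        include_controls=config.include_controls_in_null,
    )
    t = percentile(null, config.threshold_percentile)
    if config.foreground_aggregate == "pooled":
        pooled = _pooled_foreground(profile, platemap, "matching")
        value = 100.0 * float(np.mean(pooled > t))
    else:
        value = 100.0 * float(np.mean(m_c.to_numpy() > t))
    return MetricFragment(
        metric="percent_matching", value=value, per_compound=m_c,
        null=null, threshold=t, n_evaluated=len(m_c), excluded=excluded,
        group_size=2,
    )


def _substream(seed, tag: int):
    """Derive an independent, reproducible RNG seed for a metric's null."""
    if seed is None:
        return None
    return [int(seed), int(tag)]


def percent_score(pr: float, pm: float) -> float:
    """Arithmetic mean of percent replicating and percent matching."""
    for v in (pr, pm):
        if not 0.0 <= v <= 100.0:
            raise MetricError(f"percent value {v} outside [0, 100]")
    return (pr + pm) / 2.0


def mean_aggregate_duplicates(
    scores: pd.DataFrame,
    setting_col: str = "setting",
    score_cols: tuple[str, ...] = ("percent_score",),
) -> pd.DataFrame:
    """Mean-aggregate rows sharing a setting label before ranking."""
    cols = [c for c in score_cols if c in scores.columns]
    return scores.groupby(setting_col, as_index=False)[cols].mean()


def normalize_leaderboard(
    scores: pd.DataFrame,
    setting_col: str = "setting",
    score_col: str = "percent_score",
) -> pd.DataFrame:
    """Rank settings with the best normalized to 100.

    Duplicate setting labels are mean-aggregated first; output is sorted by
    descending score (ties ordered by setting label) with columns ``place``
    and ``normalized_score``.
    """
    agg = mean_aggregate_duplicates(scores, setting_col, (score_col,))
    best = agg[score_col].max()
    if not best > 0:
        raise MetricError("all scores are zero; leaderboard undefined")
    agg = agg.sort_values(
        [score_col, setting_col], ascending=[False, True], ignore_index=True
    )
    agg["normalized_score"] = 100.0 * agg[score_col] / best
    agg.insert(0, "place", np.arange(1, len(agg) + 1))
    return agg


# ---------------------------------------------------------------------------
# model / results facade


class ProfileStrength:
    """Profile-strength model for one well profile and its plate map.

    Parameters
    ----------
    profile : Profile or DataFrame
        Well-level profile table (one row per well, ``Metadata_`` columns
        plus features), normally the output of the profiling pipeline.
    platemap : PlateMap
        Maps wells to compounds and MOA classes; negative-control wells are
        excluded from both foreground and null by default.
    config : MetricConfig, optional

    Examples
    --------
    >>> model = ProfileStrength(profile, platemap)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, profile, platemap: PlateMap,
                 config: MetricConfig | None = None):
        self.profile = profile
        self.platemap = platemap
        self.config = config or MetricConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, platemap: PlateMap,
                       **config_kwargs) -> "ProfileStrength":
        return cls(df, platemap, MetricConfig(**config_kwargs))

    def fit(self, seed=None) -> "ProfileStrengthResults":
        """Compute both metrics and their shared score."""
        if seed is None:
            seed = self.config.seed
        rep = percent_replicating(self.profile, self.platemap, self.config,
                                  seed=seed)
        mat = percent_matching(self.profile, self.platemap, self.config,
                               seed=seed)
        label = None
        data = self.profile.data if isinstance(self.profile, Profile) else self.profile
        if "Metadata_Setting" in data.columns:
            vals = data["Metadata_Setting"].dropna().unique()
            label = vals[0] if len(vals) == 1 else None
        return ProfileStrengthResults(
            replicating=rep, matching=mat, config=self.config,
            setting_label=label, model=self,
        )


@dataclasses.dataclass
class ProfileStrengthResults:
    """Fitted profile-strength estimates with their resampling diagnostics."""

    replicating: MetricFragment
    matching: MetricFragment
    config: MetricConfig
    setting_label: str | None = None
    model: ProfileStrength | None = None

    @property
    def percent_replicating(self) -> float:
        return self.replicating.value

    @property
    def percent_matching(self) -> float:
        return self.matching.value

    @property
    def percent_score(self) -> float:
        return percent_score(self.percent_replicating, self.percent_matching)

    def to_dict(self, include_null: bool = False) -> dict:
        return {
            "setting": self.setting_label,
            "percent_replicating": self.percent_replicating,
            "percent_matching": self.percent_matching,
            "percent_score": self.percent_score,
            "config": dataclasses.asdict(self.config),
            "replicating": self.replicating.to_dict(include_null),
            "matching": self.matching.to_dict(include_null),
        }

    def save(self, path, include_null: bool = False,
             null_csv: str | Path | None = None) -> Path:
        """Write results as JSON; optionally the nulls as a separate CSV."""
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(include_null), indent=2))
        if null_csv is not None:
            pd.DataFrame({
                "null_replicating": pd.Series(self.replicating.null),
                "null_matching": pd.Series(self.matching.null),
            }).to_csv(null_csv, index=False)
        return path

    def summary(self) -> str:
        """Plain-text summary table."""
        rep, mat = self.replicating, self.matching
        lines = [
            "Profile Strength".center(58),
            "=" * 58,
            f"Setting:                {self.setting_label or '-'}",
            f"Null size / percentile: {len(rep.null)} / "
            f"{self.config.threshold_percentile:g}",
            f"Replicating: {rep.n_evaluated} compounds evaluated, "
            f"{len(rep.excluded)} excluded (group size {rep.group_size})",
            f"Matching:    {mat.n_evaluated} compounds evaluated, "
            f"{len(mat.excluded)} excluded (singleton MOA)",
            "-" * 58,
            f"Percent replicating  {rep.value:7.1f}   "
            f"(null threshold r > {rep.threshold:.4f})",
            f"Percent matching     {mat.value:7.1f}   "
            f"(null threshold r > {mat.threshold:.4f})",
            f"Percent score        {self.percent_score:7.1f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_null(self, which: str = "replicating", ax=None, bins: int = 50):
        """Histogram of a null distribution with the threshold and the
        per-compound foreground statistics overlaid."""
        import matplotlib.pyplot as plt

        frag = self.replicating if which == "replicating" else self.matching
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(frag.null, bins=bins, density=True, alpha=0.6,
                label=f"null (n={len(frag.null)})")
        for v in frag.per_compound:
            ax.axvline(v, color="0.3", alpha=0.15, lw=0.8)
        ax.axvline(frag.threshold, color="crimson", lw=1.5,
                   label=f"{self.config.threshold_percentile:g}th pct")
        ax.set_xlabel("median profile correlation")
        ax.set_ylabel("density")
        ax.set_title(frag.metric.replace("_", " "))
        ax.legend()
        return ax
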