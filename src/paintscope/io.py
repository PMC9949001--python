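"""Table and profile IO: CSV/Parquet feature tables with JSON provenance sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .profiles import Profile

__all__ = ["read_table", "write_table", "read_profile", "write_profile"]


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            ("|".join(map(str, k)) if isinstance(k, tuple) else str(k)):
                _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_profile(profile: Profile, path: str | Path) -> Path:
    """Write profile data plus a ``<stem>.provenance.json`` sidecar."""
    path = Path(path)
    write_table(profile.data, path)
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(_jsonable(profile.provenance), indent=2))
    return path


def read_profile(path: str | Path) -> Profile:
    path = Path(path)
    data = read_table(path)
    sidecar = path.with_suffix(".provenance.json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Profile(data=data, provenance=prov)
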