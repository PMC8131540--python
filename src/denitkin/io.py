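"""Readers/writers for tidy bottle observation tables, packaged fixtures and
run manifests.

The interchange format is a delimited text table, one row per (bottle, time):

    time_d, strain, replicate, acetate_mM, no3_mM, no2_mM, od600, ph,
    ta_meqL, co2_gas_mM, n2o_gas_mM, n2_gas_mM

"ND" is accepted as a value token in concentration columns and maps to 0 with
a below-detection flag.  Every write is accompanied by a JSON RunManifest
(version, config hash, seed, input digests) so deterministic commands can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_COLUMNS = [
    "time_d", "strain", "replicate", "acetate_mM", "no3_mM", "no2_mM",
    "od600", "ph", "ta_meqL", "co2_gas_mM", "n2o_gas_mM", "n2_gas_mM",
]
CONCENTRATION_COLUMNS = [
    "acetate_mM", "no3_mM", "no2_mM", "co2_gas_mM", "n2o_gas_mM", "n2_gas_mM",
]
ND_TOKEN = "ND"


class SchemaError(ValueError):
    """Observation table does not match the tidy schema."""


@dataclass(frozen=True)
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int | None
    input_digests: dict[str, str]
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def make_manifest(
    config: dict | None = None,
    seed: int | None = None,
    inputs: dict[str, str | Path] | None = None,
) -> RunManifest:
    from . import __version__

    config_blob = json.dumps(config or {}, sort_keys=True, default=str)
    digests = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for name, p in (inputs or {}).items()
    }
    return RunManifest(
        tool_version=__version__,
        config_hash=hashlib.sha256(config_blob.encode()).hexdigest(),
        seed=seed,
        input_digests=digests,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def read_observations(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Parse a tidy observation table; "ND" becomes 0 with a *_nd flag column.

    Raises SchemaError listing missing/extra columns, and a ValueError naming
    the replicate for non-increasing time within a (strain, replicate) series.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if missing or extra:
        raise SchemaError(f"schema mismatch in {path.name}: missing {missing}, extra {extra}")
    out = df[SCHEMA_COLUMNS].copy()
    for col in SCHEMA_COLUMNS:
        if col in ("strain", "replicate"):
            continue
        raw = out[col].astype(str).str.strip()
        nd = raw.eq(ND_TOKEN)
        if nd.any():
            if col not in CONCENTRATION_COLUMNS:
                raise SchemaError(f"'ND' token not allowed in column {col}")
            out[f"{col.removesuffix('_mM')}_nd"] = nd
        try:
            out[col] = pd.to_numeric(raw.mask(nd, "0"))
        except ValueError as err:
            bad = raw[pd.to_numeric(raw.mask(nd, "0"), errors="coerce").isna()]
            lines = ", ".join(str(i + 2) for i in bad.index[:5])
            raise SchemaError(f"malformed values in {col} at line(s) {lines}") from err
    for (strain, rep), group in out.groupby(["strain", "replicate"], sort=False):
        t = group["time_d"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"time not strictly increasing for strain={strain}, replicate={rep}"
            )
    return out


def write_observations(
    df: pd.DataFrame,
    path: str | Path,
    nd_flags: bool = True,
    manifest: RunManifest | None = None,
) -> None:
    """Write a tidy table, rendering censored zeros (flag columns or exact 0
    in concentration columns) as "ND"; optionally drop a manifest sidecar."""
    path = Path(path)
    out = df.copy()
    flag_cols = [c for c in out.columns if c.endswith("_nd")]
    rendered = out.drop(columns=flag_cols)
    rendered = rendered[[c for c in SCHEMA_COLUMNS if c in rendered.columns]]
    as_text = rendered.astype(object)
    for col in CONCENTRATION_COLUMNS:
        if col not in rendered.columns:
            continue
        flag = f"{col.removesuffix('_mM')}_nd"
        if flag in out.columns:
            censored = out[flag].astype(bool)
        elif nd_flags:
            censored = rendered[col] == 0.0
        else:
            censored = pd.Series(False, index=rendered.index)
        as_text.loc[censored, col] = ND_TOKEN
    as_text.to_csv(path, index=False)
    if manifest is not None:
        manifest.write(path.with_suffix(path.suffix + ".manifest.json"))


def load_fixture(name: str) -> pd.DataFrame:
    """Packaged machine-readable transcriptions of the printed batch tables."""
    with resources.files("denitkin.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")
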