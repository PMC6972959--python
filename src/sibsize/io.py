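"""Kinship-table input and result serialization.

Two TSV dialects are accepted for observed kinship data, both with a
header line:

* ``offspring_id<TAB>mother_id`` — one row per sampled offspring; H_obs is
  computed as sum_j C(m_j, 2) over the multiplicity m_j of each mother ID.
* ``id1<TAB>id2<TAB>is_mhs`` — the complete enumeration of the C(n, 2)
  offspring pairs with a 0/1 maternal-half-sib flag (full-sib pairs must be
  flagged 1: FS counts as MHS); H_obs = sum(is_mhs).

Summaries are written as JSON embedding the seed and a hash of the
configuration that produced them; tables go to CSV at full precision.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .estimators import SampleObservation, n_pairs

__all__ = ["read_kinship_table", "write_results", "config_hash"]


class KinshipTableError(ValueError):
    """Malformed kinship table (bad columns, duplicate IDs, bad flags...)."""


def _count_pairs_from_mothers(mothers: pd.Series) -> int:
    counts = mothers.value_counts().to_numpy()
    return int((counts * (counts - 1) // 2).sum())


def read_kinship_table(source) -> SampleObservation:
    """Parse a kinship TSV (path or DataFrame) into a SampleObservation.

    Raises :class:`KinshipTableError` with the offending line where
    possible.  Duplicate offspring IDs are rejected; in the pairwise
    dialect the table must enumerate all C(n, 2) pairs exactly once.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        origin = "<dataframe>"
    else:
        path = Path(source)
        if not path.exists():
            raise KinshipTableError(f"{path}: no such file")
        if path.stat().st_size == 0:
            raise KinshipTableError(f"{path}: empty file")
        df = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=True)
        origin = str(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols

    if set(cols) == {"offspring_id", "mother_id"}:
        if df["offspring_id"].isna().any() or df["mother_id"].isna().any():
            bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # 1-based + header
            raise KinshipTableError(f"{origin}: line {bad}: missing field")
        dup = df["offspring_id"].duplicated()
        if dup.any():
            bad = int(df.index[dup][0]) + 2
            raise KinshipTableError(
                f"{origin}: line {bad}: duplicate offspring_id "
                f"{df['offspring_id'][dup].iloc[0]!r}"
            )
        n = len(df)
        if n < 2:
            raise KinshipTableError(f"{origin}: need at least 2 offspring, got {n}")
        return SampleObservation(n=n, h_obs=_count_pairs_from_mothers(df["mother_id"]))

    if set(cols) == {"id1", "id2", "is_mhs"}:
        flags = pd.to_numeric(df["is_mhs"], errors="coerce")
        if flags.isna().any() or not flags.isin([0, 1]).all():
            bad = int(df.index[~flags.isin([0, 1])][0]) + 2
            raise KinshipTableError(f"{origin}: line {bad}: is_mhs must be 0 or 1")
        ids = pd.concat([df["id1"], df["id2"]])
        if ids.isna().any():
            raise KinshipTableError(f"{origin}: missing pair member ID")
        pair_keys = df.apply(lambda r: tuple(sorted((r["id1"], r["id2"]))), axis=1)
        if pair_keys.duplicated().any():
            bad = int(df.index[pair_keys.duplicated()][0]) + 2
            raise KinshipTableError(f"{origin}: line {bad}: duplicate pair")
        if (df["id1"] == df["id2"]).any():
            bad = int(df.index[df["id1"] == df["id2"]][0]) + 2
            raise KinshipTableError(f"{origin}: line {bad}: self-pair")
        n = ids.nunique()
        if n < 2 or len(df) != n_pairs(n):
            raise KinshipTableError(
                f"{origin}: pairwise dialect must enumerate all C(n,2) pairs of the "
                f"{n} distinct offspring; got {len(df)} rows"
            )
        return SampleObservation(n=int(n), h_obs=int(flags.sum()))

    raise KinshipTableError(
        f"{origin}: unknown columns {cols!r}; expected "
        "[offspring_id, mother_id] or [id1, id2, is_mhs]"
    )


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    return obj


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping (for provenance stamps)."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    summary: Mapping[str, Any] | None,
    prefix: str | Path,
    table: pd.DataFrame | None = None,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write a summary JSON (and optionally a per-replicate CSV) at ``prefix``.

    The JSON embeds ``seed`` and a hash of ``config`` so outputs are
    traceable to the run that produced them.  Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if summary is not None:
        payload = dict(_jsonable(summary))
        if config is not None:
            payload["config_hash"] = config_hash(config)
            payload["config"] = _jsonable(config)
        if seed is not None:
            payload["seed"] = int(seed)
        path = prefix.with_suffix(".json")
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written["summary"] = path
    if table is not None:
        path = prefix.with_suffix(".csv")
        table.to_csv(path, index=False, float_format="%.17g")
        written["table"] = path
    return written
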