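"""Plain-text readers/writers for every pipeline table.

All tables round-trip through TSV/CSV with full float precision (write
then read reproduces numeric columns to better than 1e-12); results are
serialised as JSON.  Readers validate schemas up front and fail with the
offending column or row rather than propagating NaNs downstream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .effects import EffectMap
from .spin import SpinSet
from .synth import EmbeddingTable, Lexicon, TrialActivationTable

__all__ = [
    "write_lexicon", "read_lexicon",
    "write_embeddings", "read_embeddings",
    "write_events", "read_events",
    "write_atlas", "read_atlas",
    "write_features", "read_features",
    "write_effect_map", "read_effect_map",
    "write_spins", "read_spins",
    "write_trials", "read_trials",
    "write_series", "read_series",
    "write_results", "read_results",
]

_FLOAT = "%.17g"
PathLike = Union[str, Path]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def _no_nan(df: pd.DataFrame, columns, what: str) -> None:
    for c in columns:
        bad = df[c].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{what}: NaN in required column {c!r} at row {row}")


# --- lexicon ---------------------------------------------------------------

def write_lexicon(lex: Lexicon, path: PathLike) -> None:
    lex.table.to_csv(path, sep="\t", index=False)


def read_lexicon(path: PathLike) -> Lexicon:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["word", "count"], "lexicon")
    _no_nan(df, ["word", "count"], "lexicon")
    return Lexicon(df)


# --- embeddings ------------------------------------------------------------

def write_embeddings(emb: EmbeddingTable, path: PathLike) -> None:
    emb.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_embeddings(path: PathLike) -> EmbeddingTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["word", "occurrence_id"], "embedding table")
    return EmbeddingTable(df)


# --- events / features -----------------------------------------------------

_EVENT_COLS = [
    "sentence_id", "order", "is_complex", "word", "position",
    "pos_tag", "is_content", "onset", "duration", "occurrence_id",
]


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    events.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_events(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, _EVENT_COLS, "event table")
    _no_nan(df, ["word", "onset", "duration", "position"], "event table")
    df["is_content"] = df["is_content"].astype(bool)
    df.index.name = "event"
    return df


def write_features(features: pd.DataFrame, path: PathLike) -> None:
    features.to_csv(path, sep="\t", index=True, index_label="event", float_format=_FLOAT)


def read_features(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="event", float_precision="round_trip")
    _require(df, ["included", "length", "position", "pos_tag"], "feature table")
    df["included"] = df["included"].astype(bool)
    return df


# --- atlas -----------------------------------------------------------------

def write_atlas(atlas: ParcelAtlas, path: PathLike) -> None:
    atlas.table.to_csv(path, index=False, float_format=_FLOAT)


def read_atlas(path: PathLike) -> ParcelAtlas:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["parcel_id", "hemisphere", "x", "y", "z", "gradient"], "atlas")
    _no_nan(df, ["x", "y", "z", "gradient"], "atlas")
    return ParcelAtlas(df)  # centroid norms validated by the container


# --- effect maps -----------------------------------------------------------

_MAP_COLS = [
    "parcel_id", "hemisphere", "parameter", "modality",
    "window", "value", "se", "included", "sign_inverted",
]


def write_effect_map(em: EffectMap, atlas: ParcelAtlas, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": atlas.table["parcel_id"],
            "hemisphere": atlas.hemispheres,
            "parameter": em.parameter,
            "modality": em.modality,
            "window": em.window if em.window is not None else "",
            "value": em.values,
            "se": em.se if em.se is not None else np.nan,
            "included": em.included.astype(int),
            "sign_inverted": int(em.sign_inverted),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_effect_map(path: PathLike) -> EffectMap:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""], float_precision="round_trip")
    _require(df, _MAP_COLS, "effect map")
    window = df["window"].iloc[0]
    se = df["se"].to_numpy(float)
    return EffectMap(
        parameter=str(df["parameter"].iloc[0]),
        modality=str(df["modality"].iloc[0]),
        window=None if (pd.isna(window) or window == "") else str(window),
        values=df["value"].to_numpy(float),
        se=None if np.isnan(se).all() else se,
        included=df["included"].to_numpy().astype(bool),
        sign_inverted=bool(int(df["sign_inverted"].iloc[0])),
    )


# --- spin sets -------------------------------------------------------------

def write_spins(spins: SpinSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={spins.seed} n_perm={spins.n_perm} n_parcels={spins.n_parcels}\n")
        np.savetxt(fh, spins.perms, fmt="%d", delimiter="\t")


def read_spins(path: PathLike) -> SpinSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("spin set file lacks its metadata header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        perms = np.loadtxt(fh, dtype=int, delimiter="\t", ndmin=2)
    n_parcels = int(meta["n_parcels"])
    if perms.shape[1] != n_parcels:
        raise ValueError("spin set column count does not match recorded n_parcels")
    return SpinSet(
        perms=perms,
        seed=int(meta["seed"]),
        quaternions=np.full((len(perms), 4), np.nan),
        n_parcels=n_parcels,
    )


# --- trials / series -------------------------------------------------------

def write_trials(trials: TrialActivationTable, path: PathLike) -> None:
    trials.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_trials(path: PathLike) -> TrialActivationTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["subject", "trial", "parcel_id", "window", "activation"], "trial table")
    _no_nan(df, ["activation"], "trial table")
    return TrialActivationTable.from_frame(df)


def write_series(series: np.ndarray, tr: float, path: PathLike) -> None:
    df = pd.DataFrame(series, columns=[f"parcel_{j}" for j in range(series.shape[1])])
    df.insert(0, "time", np.arange(len(df)) * tr)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_series(path: PathLike) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["time"], "parcel time series")
    t = df.pop("time").to_numpy(float)
    tr = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return df.to_numpy(float), tr


# --- results ---------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(results: Dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path: PathLike) -> Dict:
    with open(path) as fh:
        return json.load(fh)
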