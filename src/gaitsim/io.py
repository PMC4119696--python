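"""CSV/JSON round-tripping for every artifact the package produces.

Conventions: comma-separated UTF-8, ``.`` decimal, mandatory header row,
floats at 9 significant digits. Provenance (seed, config hash, ...) is
embedded as leading ``# key: value`` comment lines in CSV outputs and as a
sidecar ``.meta.json`` for gait recordings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortError, ParseError
from .fuzzy import FuzzySet
from .metrics import DataVector, SimilarityMatrix
from .nonoverlap import SingletonSample
from .pipeline import BEHAVIORS, BehaviorProfile, GaitRecording

__all__ = [
    "FLOAT_FORMAT",
    "read_fuzzy_set",
    "write_fuzzy_set",
    "read_pointsets",
    "write_pointsets",
    "read_data_vectors",
    "write_data_vectors",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_recording",
    "write_recording",
    "read_cohort",
    "write_cohort",
]

FLOAT_FORMAT = "%.9g"


def _write_csv(df: pd.DataFrame, path: Path, metadata: Mapping | None, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, float_format=FLOAT_FORMAT, index=index)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_metadata(path: Path) -> dict:
    """Parse the leading ``# key: value`` comment block of a CSV file."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


# -- fuzzy sets -------------------------------------------------------------

def write_fuzzy_set(fs: FuzzySet, path: Path, metadata: Mapping | None = None) -> None:
    df = pd.DataFrame(
        {"element_id": list(fs.support), "membership": fs.memberships}
    )
    _write_csv(df, path, metadata, index=False)


def read_fuzzy_set(path: Path) -> FuzzySet:
    df = _read_csv(path)
    for col in ("element_id", "membership"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    mu = df["membership"].to_numpy(dtype=float)
    bad = np.flatnonzero((mu < 0) | (mu > 1) | ~np.isfinite(mu))
    if bad.size:
        raise ParseError(
            f"{path}: membership out of [0, 1] at row {int(bad[0]) + 2} "
            f"(column 'membership')"
        )
    return FuzzySet(tuple(df["element_id"].astype(str)), mu)


# -- labeled point sets -----------------------------------------------------

def write_pointsets(
    samples: Sequence[SingletonSample], path: Path, metadata: Mapping | None = None
) -> None:
    rows = [(s.label, v) for s in samples for v in s.values]
    df = pd.DataFrame(rows, columns=["label", "value"])
    _write_csv(df, path, metadata, index=False)


def read_pointsets(path: Path) -> list[SingletonSample]:
    """Read labeled point heights; one sample per distinct label, order kept."""
    df = _read_csv(path)
    for col in ("label", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    values = df["value"].to_numpy(dtype=float)
    bad = np.flatnonzero((values < 0) | (values > 1) | ~np.isfinite(values))
    if bad.size:
        raise ParseError(
            f"{path}: value out of [0, 1] at row {int(bad[0]) + 2} (column 'value')"
        )
    samples = []
    for label in df["label"].astype(str).drop_duplicates():
        vals = df.loc[df["label"].astype(str) == label, "value"]
        samples.append(SingletonSample(label, tuple(float(v) for v in vals)))
    return samples


# -- data vectors -----------------------------------------------------------

def write_data_vectors(
    vectors: Sequence[DataVector], path: Path, metadata: Mapping | None = None
) -> None:
    dim = vectors[0].dim
    df = pd.DataFrame(
        [[v.id, *v.components] for v in vectors],
        columns=["id", *(f"d{k + 1}" for k in range(dim))],
    )
    _write_csv(df, path, metadata, index=False)


def read_data_vectors(path: Path) -> list[DataVector]:
    df = _read_csv(path)
    if "id" not in df.columns:
        raise ParseError(f"{path}: missing column 'id'")
    comp_cols = [c for c in df.columns if c != "id"]
    if not comp_cols:
        raise ParseError(f"{path}: no component columns")
    return [
        DataVector(str(row["id"]), row[comp_cols].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ]


# -- similarity matrices ----------------------------------------------------

def write_similarity_matrix(
    mat: SimilarityMatrix, path: Path, metadata: Mapping | None = None
) -> None:
    df = mat.to_dataframe()
    df.index.name = "id"
    _write_csv(df, path, metadata, index=True)


def read_similarity_matrix(path: Path) -> SimilarityMatrix:
    df = _read_csv(path, index_col=0)
    ids = tuple(str(i) for i in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise ParseError(f"{path}: row and column ids differ")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float))


# -- gait recordings and cohorts -------------------------------------------

def _meta_path(csv_path: Path) -> Path:
    csv_path = Path(csv_path)
    return csv_path.with_suffix(".meta.json")


def write_recording(
    rec: GaitRecording, path: Path, metadata: Mapping | None = None
) -> None:
    """Wide CSV (``time_s`` + one column per channel) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for name in rec.channel_names:
        df[name] = rec.channels[name]
    df.to_csv(path, float_format=FLOAT_FORMAT, index=False)
    meta = {
        "subject_id": rec.subject_id,
        "behavior": rec.behavior,
        "sampling_rate": rec.sampling_rate,
    }
    meta.update(metadata or {})
    with open(_meta_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_recording(path: Path) -> GaitRecording:
    path = Path(path)
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise ParseError(f"{path}: sidecar {meta_file.name} not found")
    with open(meta_file, encoding="utf-8") as fh:
        meta = json.load(fh)
    df = _read_csv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing column 'time_s'")
    channels = {
        str(c): df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"
    }
    return GaitRecording(
        subject_id=str(meta["subject_id"]),
        behavior=str(meta["behavior"]),
        sampling_rate=float(meta["sampling_rate"]),
        channels=channels,
    )


def _recording_filename(subject_id: str, behavior: str) -> str:
    return f"{subject_id}_{behavior}.csv"


def write_cohort(
    cohort: Sequence[BehaviorProfile], out_dir: Path, metadata: Mapping | None = None
) -> list[Path]:
    """Write every recording of every profile into *out_dir*; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for prof in cohort:
        for behavior in BEHAVIORS:
            p = out_dir / _recording_filename(prof.subject_id, behavior)
            write_recording(prof.recordings[behavior], p, metadata)
            paths.append(p)
    return paths


def read_cohort(cohort_dir: Path) -> list[BehaviorProfile]:
    """Load all ``<subject>_<behavior>.csv`` recordings into complete profiles.

    Raises :class:`CohortError` with an explicit list of the missing
    (subject, behavior) combinations when any profile is incomplete.
    """
    cohort_dir = Path(cohort_dir)
    recs: dict[str, dict[str, GaitRecording]] = {}
    for csv_path in sorted(cohort_dir.glob("*.csv")):
        if not _meta_path(csv_path).exists():
            continue  # not a recording (e.g. an emitted table)
        rec = read_recording(csv_path)
        recs.setdefault(rec.subject_id, {})[rec.behavior] = rec
    if not recs:
        raise CohortError(f"no recordings found in {cohort_dir}")
    missing = [
        (sid, b)
        for sid, by_behavior in sorted(recs.items())
        for b in BEHAVIORS
        if b not in by_behavior
    ]
    if missing:
        raise CohortError(f"incomplete cohort; missing (subject, behavior): {missing}")
    return [
        BehaviorProfile(sid, by_behavior) for sid, by_behavior in sorted(recs.items())
    ]
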