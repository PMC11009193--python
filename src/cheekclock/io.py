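"""Readers and writers for matrices, manifests, surveys, and clocks.

File conventions
----------------
* Methylation matrix: TSV/CSV, first column ``probe_id``, one column per
  sample; blank cells are missing.
* Probe manifest: TSV with columns ``probe_id``, ``chrom``, ``pos``,
  ``island_relation``, ``genes`` (semicolon-joined symbols, possibly empty).
* Survey: CSV keyed by ``sample_id`` with an ``age`` column, optional
  ``replicate_group``, and role-prefixed columns ``lifestyle__*``,
  ``demo__*``, ``cat__*``, ``tech__*``.
* Ensemble clock: versioned JSON; floats use the shortest round-trip
  representation, so save/load is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annealing import ClockModel
from .datatypes import MethylationMatrix, ProbeManifest, SurveyTable
from .ensemble import EnsembleClock

__all__ = [
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_survey",
    "write_survey",
    "save_ensemble",
    "load_ensemble",
    "SchemaVersionError",
    "ENSEMBLE_SCHEMA_VERSION",
]

ENSEMBLE_SCHEMA_VERSION = "cheekclock-ensemble-1"


class SchemaVersionError(ValueError):
    """Raised when a serialized clock uses an incompatible schema version."""


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_methylation_matrix(path, scale_hint: str = "beta") -> MethylationMatrix:
    """Read a probes × samples TSV/CSV into a validated matrix.

    Blank cells become missing; any non-numeric cell is reported with its row
    and column; duplicate probe or sample ids are rejected.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe id(s): {dups[:5]}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s): {dups[:5]}")
    probe = raw.replace("", np.nan).apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & (raw != "")
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at probe {raw.index[r]!r}, sample "
            f"{raw.columns[c]!r}: {raw.iloc[r, c]!r}"
        )
    # python float() is correctly rounded, so write/read is bit-exact
    values = raw.map(lambda s: np.nan if s == "" else float(s))
    return MethylationMatrix(values, scale=scale_hint)


def write_methylation_matrix(matrix: MethylationMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path))


def read_probe_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"probe_id": str, "chrom": str},
                     keep_default_na=False)
    df = df.set_index("probe_id")
    genes = df["genes"].map(lambda s: [g for g in str(s).split(";") if g])
    table = pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "pos": df["pos"].astype(int),
         "island_relation": df["island_relation"], "genes": genes},
        index=df.index,
    )
    return ProbeManifest(table)


def write_probe_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.table.copy()
    df["genes"] = df["genes"].map(";".join)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def read_survey(path) -> SurveyTable:
    df = pd.read_csv(path, index_col="sample_id")
    pick = lambda pre: df[[c for c in df.columns if c.startswith(pre)]].rename(
        columns=lambda c: c[len(pre):]
    )
    df = df.rename_axis(index=None)
    rg = df["replicate_group"] if "replicate_group" in df.columns else None
    if rg is not None:
        rg = rg.where(rg.notna() & (rg.astype(str) != ""))
    return SurveyTable(
        age=df["age"].astype(float),
        lifestyle=pick("lifestyle__").astype(float),
        demographics=pick("demo__").astype(float),
        categorical=pick("cat__"),
        technical=pick("tech__"),
        replicate_group=rg,
    )


def write_survey(survey: SurveyTable, path) -> None:
    parts = [survey.age.rename("age")]
    for pre, df in (("lifestyle__", survey.lifestyle), ("demo__", survey.demographics),
                    ("cat__", survey.categorical), ("tech__", survey.technical)):
        if len(df.columns):
            parts.append(df.add_prefix(pre))
    out = pd.concat(parts, axis=1)
    if survey.replicate_group is not None:
        out["replicate_group"] = survey.replicate_group
    out.index.name = "sample_id"
    out.to_csv(path)


def save_ensemble(clock: EnsembleClock, path) -> None:
    """Serialize a clock to versioned JSON (bit-exact round trip)."""
    payload = {
        "schema_version": ENSEMBLE_SCHEMA_VERSION,
        "models": [m.to_dict() for m in clock.models],
        "ensemble_weights": [float(w) for w in clock.ensemble_weights],
        "rotation": (list(map(float, clock.rotation))
                     if clock.rotation is not None else None),
        "cluster_means": (
            {k: float(v) for k, v in clock.cluster_means.items()}
            if clock.cluster_means is not None else None
        ),
        "provenance": clock.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ensemble(path) -> EnsembleClock:
    """Load a serialized clock; refuses incompatible schema versions and
    raises (never returns a partial clock) on malformed files."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt or truncated ensemble file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != ENSEMBLE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"cannot read schema {version!r}; this build reads "
            f"{ENSEMBLE_SCHEMA_VERSION!r}"
        )
    means = payload.get("cluster_means")
    return EnsembleClock(
        models=[ClockModel.from_dict(d) for d in payload["models"]],
        ensemble_weights=np.asarray(payload["ensemble_weights"], dtype=float),
        rotation=tuple(payload["rotation"]) if payload.get("rotation") else None,
        cluster_means=pd.Series(means, dtype=float) if means is not None else None,
        provenance=payload.get("provenance", {}),
    )
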