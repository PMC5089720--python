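"""Reading and writing clamp records and run artifacts.

Clamp records travel as plain CSV with a commented metadata header — a
portable, diff-able format:

    # clamptrace_record: v1
    # weight_kg: 28.5
    # insulin_rate_mU_kg_min: 1.0
    # insulin_start_min: 120.0
    # sa_inf_dpm_mg: 5994.0
    # diet: lean
    # state: conscious
    # animal_id: lean_conscious_000
    time_min,glucose_mg_dl,tracer_dpm_ml,insulin_uU_ml,ginf_mg_kg_min,fstar_dpm_kg_min
    0.0,95.1,8851.2,0.0,0.0,19473.7
    ...

Tracer columns may alternatively be declared in microcuries with
``# tracer_units: uCi_per_ml`` / ``# fstar_units: uCi_per_kg_min``; they are
converted to dpm (x 2.22e6) on ingest, so everything downstream is in dpm.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import DPM_PER_UCI, ClampRecord

__all__ = ["read_clamp_csv", "write_clamp_csv", "write_ground_truth_json"]

_COLUMNS = ["time_min", "glucose_mg_dl", "tracer_dpm_ml", "insulin_uU_ml",
            "ginf_mg_kg_min", "fstar_dpm_kg_min"]
_REQUIRED_META = ["weight_kg", "insulin_rate_mU_kg_min", "insulin_start_min"]


def write_clamp_csv(record: ClampRecord, path: str | Path) -> Path:
    """Write a :class:`ClampRecord` as a metadata-headed CSV."""
    path = Path(path)
    meta = {
        "clamptrace_record": "v1",
        "weight_kg": repr(record.weight),
        "insulin_rate_mU_kg_min": repr(record.insulin_rate),
        "insulin_start_min": repr(record.insulin_start),
        "sa_inf_dpm_mg": "" if record.SA_inf is None else repr(record.SA_inf),
        "diet": record.diet,
        "state": record.state,
        "animal_id": record.animal_id,
    }
    df = pd.DataFrame({
        "time_min": record.time,
        "glucose_mg_dl": record.G,
        "tracer_dpm_ml": record.Gstar,
        "insulin_uU_ml": record.I,
        "ginf_mg_kg_min": record.GINF,
        "fstar_dpm_kg_min": record.Fstar,
    })
    buf = _io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())
    return path


def _parse_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_clamp_csv(path: str | Path) -> ClampRecord:
    """Read and validate a clamp-record CSV (see module docstring)."""
    path = Path(path)
    meta = _parse_meta(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    for key in _REQUIRED_META:
        if key not in meta or meta[key] == "":
            raise ValueError(f"missing required metadata '{key}' in header")

    gstar = df["tracer_dpm_ml"].to_numpy(dtype=float)
    fstar = df["fstar_dpm_kg_min"].to_numpy(dtype=float)
    if meta.get("tracer_units", "dpm_per_ml") == "uCi_per_ml":
        gstar = gstar * DPM_PER_UCI
    if meta.get("fstar_units", "dpm_per_kg_min") == "uCi_per_kg_min":
        fstar = fstar * DPM_PER_UCI

    sa_raw = meta.get("sa_inf_dpm_mg", "")
    sa_inf = None if sa_raw == "" else float(sa_raw)
    if sa_inf is not None and meta.get("sa_inf_units", "dpm_per_mg") == "uCi_per_mg":
        sa_inf *= DPM_PER_UCI

    time = df["time_min"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        raise ValueError(f"unsorted input: time not increasing at row {bad[0] + 1}")

    return ClampRecord(
        time=time,
        G=df["glucose_mg_dl"].to_numpy(dtype=float),
        Gstar=gstar,
        I=df["insulin_uU_ml"].to_numpy(dtype=float),
        GINF=df["ginf_mg_kg_min"].to_numpy(dtype=float),
        Fstar=fstar,
        SA_inf=sa_inf,
        weight=float(meta["weight_kg"]),
        insulin_rate=float(meta["insulin_rate_mU_kg_min"]),
        insulin_start=float(meta["insulin_start_min"]),
        diet=meta.get("diet", "lean"),
        state=meta.get("state", "conscious"),
        animal_id=meta.get("animal_id", path.stem),
    )


def write_ground_truth_json(truth, path: str | Path) -> Path:
    """Persist a :class:`GroundTruth` sidecar (scalars + coarse arrays)."""
    path = Path(path)
    payload = {
        "SI_P": truth.SI_P, "SI_H": truth.SI_H, "MCR": truth.MCR,
        "Rd_basal": truth.Rd_basal, "EGP_basal": truth.EGP_basal,
        "Rd_SS": truth.Rd_SS, "EGP_SS": truth.EGP_SS,
        "G_SS": truth.G_SS, "I_SS": truth.I_SS, "dIns": truth.dIns,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path
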