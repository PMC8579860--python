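"""CSV/JSON dialects for landmarks, targets, leads, variability and models.

All coordinates are stored in millimetres.  Files may declare either the
PC-origin or the MCP-origin convention per row (``frame`` column plus the
patient's ``acpc_length``); everything is converted to the canonical
PC-origin frame on load.  Schema violations raise :class:`SchemaError`
naming the file line (header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Frame, FrameOrigin, convert_frame
from .landmarks import (
    AXES,
    LANDMARK_NAMES,
    LandmarkSet,
    ObserverVariabilityModel,
)
from .metamodels import (
    DNNConfig,
    DNNModel,
    DNNRegressor,
    RKHSModel,
    RKHSRegressor,
    SVRAxisModel,
    SVRRegressor,
    Standardizer,
)

__all__ = [
    "SchemaError",
    "read_landmarks",
    "write_landmarks",
    "read_targets",
    "write_targets",
    "read_leads",
    "write_leads",
    "read_variability",
    "write_variability",
    "save_model",
    "load_model",
    "write_json_report",
]

LANDMARK_COLUMNS = ["patient_id", "hemisphere", "rater_id", "session_id",
                    "landmark", "x", "y", "z", "frame", "acpc_length"]
TARGET_COLUMNS = ["patient_id", "hemisphere", "x", "y", "z", "frame", "acpc_length"]
LEAD_COLUMNS = ["patient_id", "hemisphere", "ax", "ay", "az",
                "jx", "jy", "jz", "frame", "acpc_length"]


class SchemaError(ValueError):
    """A file does not conform to its documented dialect."""


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _line(idx: int) -> int:
    """CSV line number of a dataframe row (header is line 1)."""
    return int(idx) + 2


def _to_pc(row: pd.Series, x: float, y: float, z: float, path) -> np.ndarray:
    frame_name = str(row["frame"]).upper()
    if frame_name not in ("PC", "MCP"):
        raise SchemaError(
            f"{path} line {_line(row.name)}: unknown frame {row['frame']!r}"
        )
    acpc = float(row["acpc_length"])
    if not acpc > 0:
        raise SchemaError(
            f"{path} line {_line(row.name)}: acpc_length must be > 0, got {acpc}"
        )
    src = Frame(FrameOrigin(frame_name), acpc)
    dst = Frame(FrameOrigin.PC, acpc)
    return convert_frame((x, y, z), src, dst)


def read_landmarks(path: str | Path, tolerance_tau: float = 1.0) -> list[LandmarkSet]:
    """Load a long-form landmarks CSV into landmark sets.

    One set per (patient, hemisphere, rater, session); coordinates converted
    to PC origin.  Raises :class:`SchemaError` for unknown landmark names,
    duplicate entries or frame problems, naming the offending line.
    """
    df = _read_csv(path, LANDMARK_COLUMNS)
    bad = df[~df["landmark"].isin(LANDMARK_NAMES)]
    if not bad.empty:
        row = bad.iloc[0]
        raise SchemaError(
            f"{path} line {_line(row.name)}: unknown landmark {row['landmark']!r}"
        )
    sets: list[LandmarkSet] = []
    keys = ["patient_id", "hemisphere", "rater_id", "session_id"]
    df[["rater_id", "session_id"]] = df[["rater_id", "session_id"]].fillna("")
    for (pid, hemi, rater, session), group in df.groupby(keys, sort=True):
        dup = group["landmark"].duplicated()
        if dup.any():
            row = group[dup].iloc[0]
            raise SchemaError(
                f"{path} line {_line(row.name)}: duplicate landmark "
                f"{row['landmark']!r} for {pid}/{hemi}"
            )
        points = {}
        for _, row in group.iterrows():
            points[row["landmark"]] = _to_pc(
                row, float(row["x"]), float(row["y"]), float(row["z"]), path
            )
        sets.append(
            LandmarkSet(
                patient_id=str(pid), hemisphere=str(hemi), points=points,
                tolerance_tau=tolerance_tau,
                rater_id=str(rater) or None, session_id=str(session) or None,
            )
        )
    return sets


def write_landmarks(
    sets: Iterable[LandmarkSet],
    path: str | Path,
    acpc_length: Mapping[str, float] | float,
) -> None:
    """Write landmark sets in the long-form dialect (canonical PC frame)."""
    rows = []
    for s in sets:
        acpc = acpc_length if isinstance(acpc_length, (int, float)) else acpc_length[s.patient_id]
        for name in LANDMARK_NAMES:
            if name not in s.points:
                continue
            p = s[name]
            rows.append(
                {
                    "patient_id": s.patient_id, "hemisphere": s.hemisphere,
                    "rater_id": s.rater_id or "", "session_id": s.session_id or "",
                    "landmark": name,
                    "x": p[0], "y": p[1], "z": p[2],
                    "frame": "PC", "acpc_length": float(acpc),
                }
            )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_targets(path: str | Path) -> pd.DataFrame:
    """Load a targets CSV; returns patient_id, hemisphere, x, y, z (PC frame)."""
    df = _read_csv(path, TARGET_COLUMNS)
    dup = df.duplicated(subset=["patient_id", "hemisphere"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"{path} line {_line(row.name)}: duplicate target for "
            f"{row['patient_id']}/{row['hemisphere']}"
        )
    out = []
    for _, row in df.iterrows():
        p = _to_pc(row, float(row["x"]), float(row["y"]), float(row["z"]), path)
        out.append({"patient_id": str(row["patient_id"]),
                    "hemisphere": str(row["hemisphere"]),
                    "x": p[0], "y": p[1], "z": p[2],
                    "acpc_length": float(row["acpc_length"])})
    return pd.DataFrame(out)


def write_targets(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "frame" not in out.columns:
        out["frame"] = "PC"
    out[TARGET_COLUMNS].to_csv(path, index=False)


def read_leads(path: str | Path) -> pd.DataFrame:
    """Load a leads CSV (tip A and proximal point J per row, PC frame on return)."""
    df = _read_csv(path, LEAD_COLUMNS)
    out = []
    for _, row in df.iterrows():
        a = _to_pc(row, float(row["ax"]), float(row["ay"]), float(row["az"]), path)
        j = _to_pc(row, float(row["jx"]), float(row["jy"]), float(row["jz"]), path)
        rec = {"patient_id": str(row["patient_id"]),
               "hemisphere": str(row["hemisphere"]),
               "ax": a[0], "ay": a[1], "az": a[2],
               "jx": j[0], "jy": j[1], "jz": j[2],
               "acpc_length": float(row["acpc_length"])}
        if "active_contact_index" in df.columns:
            rec["active_contact_index"] = int(row["active_contact_index"])
        out.append(rec)
    return pd.DataFrame(out)


def write_leads(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "frame" not in out.columns:
        out["frame"] = "PC"
    cols = LEAD_COLUMNS + (
        ["active_contact_index"] if "active_contact_index" in out.columns else []
    )
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# variability JSON


def write_variability(model: ObserverVariabilityModel, path: str | Path) -> None:
    payload = {
        "provenance": model.provenance,
        "entries": [
            {"landmark": n, "axis": a, "sigma_mm": model.sigma[(n, a)]}
            for n in LANDMARK_NAMES for a in AXES
        ],
        "grand_mean_mm": model.grand_mean_mm,
        "grand_sd_mm": model.grand_sd_mm,
        "n_pairs": model.n_pairs,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_variability(path: str | Path) -> ObserverVariabilityModel:
    payload = json.loads(Path(path).read_text())
    sigma = {
        (e["landmark"], e["axis"]): float(e["sigma_mm"]) for e in payload["entries"]
    }
    missing = [
        (n, a) for n in LANDMARK_NAMES for a in AXES if (n, a) not in sigma
    ]
    if missing:
        raise SchemaError(f"{path}: variability table lacks entries for {missing[:3]} ...")
    return ObserverVariabilityModel(
        provenance=payload["provenance"],
        sigma=sigma,
        grand_mean_mm=float(payload.get("grand_mean_mm", float("nan"))),
        grand_sd_mm=float(payload.get("grand_sd_mm", float("nan"))),
        n_pairs=int(payload.get("n_pairs", 0)),
    )


# ---------------------------------------------------------------------------
# model JSON


def _std_to_json(s: Standardizer) -> dict:
    return {"center": s.center.tolist(), "scale": s.scale.tolist()}


def _std_from_json(d: dict) -> Standardizer:
    return Standardizer(center=np.array(d["center"]), scale=np.array(d["scale"]))


def save_model(model, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize a fitted metamodel to JSON (numbers round-trip bit-exactly)."""
    payload: dict = {"format_version": 1, "software_version": __version__,
                     "metadata": metadata or {}}
    if isinstance(model, RKHSRegressor):
        m = model.model_
        payload.update(
            kind="rkhs",
            sigma=m.kernel_sigma, ridge_lambda=m.ridge_lambda,
            training_inputs=m.training_inputs.tolist(),
            alpha=np.asarray(m.coefficients_alpha).tolist(),
            x_standardizer=_std_to_json(m.x_standardizer),
            y_standardizer=_std_to_json(m.y_standardizer),
        )
    elif isinstance(model, SVRRegressor):
        payload.update(
            kind="svr", sigma=model.sigma, epsilon=model.epsilon, C=model.C,
            axes=[
                {
                    "support_inputs": am.support_inputs.tolist(),
                    "dual_coefficients": am.dual_coefficients.tolist(),
                    "bias_b": am.bias_b,
                    "x_standardizer": _std_to_json(am.x_standardizer),
                    "y_standardizer": _std_to_json(am.y_standardizer),
                    "kkt_residuals": am.kkt_residuals,
                }
                for am in model.axis_models_
            ],
        )
    elif isinstance(model, DNNRegressor):
        m = model.model_
        payload.update(
            kind="dnn",
            config={
                "hidden_sizes": list(m.config.hidden_sizes),
                "learning_rate": m.config.learning_rate,
                "epochs": m.config.epochs,
                "batch_size": m.config.batch_size,
                "seed": m.config.seed,
                "l2_alpha": m.config.l2_alpha,
            },
            layers=[{"A": A.tolist(), "b": b.tolist()} for A, b in m.layers],
            final_loss=m.final_loss,
            x_standardizer=_std_to_json(m.x_standardizer),
            y_standardizer=_std_to_json(m.y_standardizer),
        )
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; returns a fitted regressor."""
    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "rkhs":
        reg = RKHSRegressor(payload["sigma"], payload["ridge_lambda"])
        reg.model_ = RKHSModel(
            training_inputs=np.array(payload["training_inputs"]),
            coefficients_alpha=np.array(payload["alpha"]),
            kernel_sigma=payload["sigma"],
            ridge_lambda=payload["ridge_lambda"],
            x_standardizer=_std_from_json(payload["x_standardizer"]),
            y_standardizer=_std_from_json(payload["y_standardizer"]),
        )
        return reg
    if kind == "svr":
        reg = SVRRegressor(payload["sigma"], payload["epsilon"], payload["C"])
        reg.axis_models_ = [
            SVRAxisModel(
                support_inputs=np.array(ax["support_inputs"]),
                dual_coefficients=np.array(ax["dual_coefficients"]),
                bias_b=float(ax["bias_b"]),
                kernel_sigma=payload["sigma"],
                epsilon_tube=payload["epsilon"],
                cost_C=payload["C"],
                x_standardizer=_std_from_json(ax["x_standardizer"]),
                y_standardizer=_std_from_json(ax["y_standardizer"]),
                kkt_residuals=ax.get("kkt_residuals", {}),
            )
            for ax in payload["axes"]
        ]
        return reg
    if kind == "dnn":
        cfg = payload["config"]
        config = DNNConfig(
            hidden_sizes=tuple(cfg["hidden_sizes"]),
            learning_rate=cfg["learning_rate"],
            epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            seed=cfg["seed"],
            l2_alpha=cfg["l2_alpha"],
        )
        reg = DNNRegressor(config)
        reg.model_ = DNNModel(
            layers=tuple(
                (np.array(layer["A"]), np.array(layer["b"]))
                for layer in payload["layers"]
            ),
            config=config,
            x_standardizer=_std_from_json(payload["x_standardizer"]),
            y_standardizer=_std_from_json(payload["y_standardizer"]),
            final_loss=float(payload["final_loss"]),
        )
        return reg
    raise SchemaError(f"{path}: unknown model kind {kind!r}")


def write_json_report(payload: dict, path: str | Path, seed: int | None = None,
                      config_echo: dict | None = None) -> None:
    """Write a JSON report embedding the config echo, seed and software version."""
    body = dict(payload)
    body["_audit"] = {
        "software_version": __version__,
        "seed": seed,
        "config": config_echo or {},
    }
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True))
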