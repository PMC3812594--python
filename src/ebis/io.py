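"""File formats: spectrum/fit/feature CSV dialects, tree and report JSON, config YAML.

All tabular artifacts are plain CSV (UTF-8, '.' decimal, header required) so
they can be inspected and diffed.  Frequencies are stored in Hz in files;
hemispheres are written as single letters L/R and parsed back to the internal
"left"/"right" strings.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .cole import (
    ColeParameters,
    FrequencyGrid,
    ImpedanceSpectrum,
    MeasurementMeta,
)
from .crossval import LoocvReport
from .errors import ParseError, ValidationError
from .features import FeatureVector
from .fitting import FitResult
from .simulate import DamageEffect, Dataset, GeneratorConfig, SubjectProfile
from .tree import NodeSpec, TreeSpec

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_fits",
    "read_fits",
    "write_features",
    "read_features",
    "write_tree",
    "read_tree",
    "write_report",
    "write_profiles",
    "read_profiles",
    "load_generator_config",
]

SPECTRUM_COLUMNS = [
    "subject_id",
    "hemisphere",
    "electrode_set",
    "repeat",
    "frequency_hz",
    "resistance_ohm",
    "reactance_ohm",
]

_HEMI_TO_LETTER = {"left": "L", "right": "R"}
_LETTER_TO_HEMI = {"L": "left", "R": "right", "left": "left", "right": "right"}


def write_spectra(dataset: Union[Dataset, Sequence[ImpedanceSpectrum]], path) -> None:
    """Write spectra to the spectrum CSV dialect (one row per frequency point).

    A trailing ``label`` column records the tissue label when known; readers
    that only need the measured values may ignore it.
    """
    spectra = dataset.spectra if isinstance(dataset, Dataset) else list(dataset)
    frames = []
    for s in spectra:
        m = s.meta
        if m is None:
            raise ValidationError("cannot write a spectrum without metadata")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": m.subject_id,
                    "hemisphere": _HEMI_TO_LETTER[m.hemisphere],
                    "electrode_set": m.electrode_set,
                    "repeat": m.repeat,
                    "frequency_hz": s.grid.frequencies_hz,
                    "resistance_ohm": s.resistance,
                    "reactance_ohm": s.reactance,
                    "label": m.label if m.label is not None else "",
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SPECTRUM_COLUMNS + ["label"])
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra(path) -> List[ImpedanceSpectrum]:
    """Read spectra back from the spectrum CSV dialect.

    Raises `ParseError` naming the missing column or offending rows for
    malformed files; an empty file with a valid header yields an empty list.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file, header required") from exc
    for col in SPECTRUM_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    if df.empty:
        return []
    for col in ("frequency_hz", "resistance_ohm", "reactance_ohm"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ParseError(f"{path}: non-numeric value in column '{col}', row {row}")
        df[col] = numeric

    has_label = "label" in df.columns
    spectra: List[ImpedanceSpectrum] = []
    keys = ["subject_id", "hemisphere", "electrode_set", "repeat"]
    grid_cache: Dict[bytes, FrequencyGrid] = {}
    for key, group in df.groupby(keys, sort=False):
        subject_id, hemi, eset, repeat = key
        if hemi not in _LETTER_TO_HEMI:
            raise ParseError(f"{path}: unknown hemisphere code '{hemi}'")
        freqs = group["frequency_hz"].to_numpy()
        order = np.argsort(freqs)
        freqs = freqs[order]
        try:
            grid = grid_cache.setdefault(freqs.tobytes(), FrequencyGrid(freqs))
        except ValidationError as exc:
            raise ParseError(
                f"{path}: invalid frequency grid for measurement {key}: {exc}"
            ) from exc
        label: Optional[str] = None
        if has_label:
            raw = group["label"].iloc[0]
            if isinstance(raw, str) and raw:
                label = raw
        meta = MeasurementMeta(
            subject_id=str(subject_id),
            hemisphere=_LETTER_TO_HEMI[hemi],
            electrode_set=str(eset),
            repeat=int(repeat),
            label=label,
        )
        spectra.append(
            ImpedanceSpectrum(
                grid=grid,
                resistance=group["resistance_ohm"].to_numpy()[order],
                reactance=group["reactance_ohm"].to_numpy()[order],
                meta=meta,
            )
        )
    return spectra


FIT_COLUMNS = [
    "subject_id",
    "hemisphere",
    "electrode_set",
    "repeat",
    "r0_ohm",
    "rinf_ohm",
    "alpha",
    "fc_hz",
    "residual_rms",
    "converged",
]


def write_fits(fits: Sequence[FitResult], path) -> None:
    rows = []
    for f in fits:
        m = f.meta
        rows.append(
            {
                "subject_id": m.subject_id,
                "hemisphere": _HEMI_TO_LETTER[m.hemisphere],
                "electrode_set": m.electrode_set,
                "repeat": m.repeat,
                "r0_ohm": f.params.r0,
                "rinf_ohm": f.params.r_inf,
                "alpha": f.params.alpha,
                "fc_hz": f.params.fc,
                "residual_rms": f.residual_rms,
                "converged": f.converged,
                "label": m.label if m.label is not None else "",
            }
        )
    pd.DataFrame(rows, columns=FIT_COLUMNS + ["label"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_fits(path) -> List[FitResult]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file, header required") from exc
    for col in FIT_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    fits: List[FitResult] = []
    for _, row in df.iterrows():
        label = row.get("label")
        label = label if isinstance(label, str) and label else None
        meta = MeasurementMeta(
            subject_id=str(row["subject_id"]),
            hemisphere=_LETTER_TO_HEMI[str(row["hemisphere"])],
            electrode_set=str(row["electrode_set"]),
            repeat=int(row["repeat"]),
            label=label,
        )
        params = ColeParameters(
            r0=float(row["r0_ohm"]),
            r_inf=float(row["rinf_ohm"]),
            alpha=float(row["alpha"]),
            fc=float(row["fc_hz"]),
        )
        fits.append(
            FitResult(
                params=params,
                residual_rms=float(row["residual_rms"]),
                n_iterations=0,
                converged=bool(row["converged"]),
                initial=params,
                meta=meta,
            )
        )
    return fits


FEATURE_COLUMNS = ["subject_id", "hemisphere", "repeat", "f1", "f2", "f3", "label"]


def write_features(vectors: Sequence[FeatureVector], path) -> None:
    rows = [
        {
            "subject_id": v.subject_id,
            "hemisphere": _HEMI_TO_LETTER.get(v.hemisphere, v.hemisphere),
            "repeat": v.repeat,
            "f1": v.f1,
            "f2": v.f2,
            "f3": v.f3,
            "label": v.label if v.label is not None else "",
        }
        for v in vectors
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_features(path) -> List[FeatureVector]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file, header required") from exc
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    out: List[FeatureVector] = []
    for _, row in df.iterrows():
        label = row["label"]
        label = label if isinstance(label, str) and label else None
        out.append(
            FeatureVector(
                f1=float(row["f1"]),
                f2=float(row["f2"]),
                f3=float(row["f3"]),
                subject_id=str(row["subject_id"]),
                hemisphere=_LETTER_TO_HEMI.get(str(row["hemisphere"])),
                repeat=int(row["repeat"]),
                label=label,
            )
        )
    return out


def write_tree(tree: TreeSpec, path) -> None:
    """Serialise a tree: {"nodes": [...], "final": {"below": ..., "above": ...}}."""
    doc = {
        "nodes": [
            {
                "feature": n.feature,
                "threshold": n.threshold,
                "direction": n.direction,
                "exit_label": n.exit_label,
            }
            for n in tree.nodes
        ],
        "final": {"below": tree.final_below, "above": tree.final_above},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_tree(path) -> TreeSpec:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    try:
        nodes = tuple(
            NodeSpec(
                feature=n["feature"],
                threshold=float(n["threshold"]),
                direction=n["direction"],
                exit_label=n["exit_label"],
            )
            for n in doc["nodes"]
        )
        final = doc["final"]
        return TreeSpec(nodes=nodes, final_below=final["below"], final_above=final["above"])
    except (KeyError, TypeError, ValidationError) as exc:
        raise ParseError(f"{path}: malformed tree specification: {exc}") from exc


def write_report(report: LoocvReport, path) -> None:
    doc = {
        "n_subjects": report.n_subjects,
        "overall_error_percent": report.overall_error_percent,
        "per_subject": [
            {
                "subject_id": r.subject_id,
                "error_percent": r.error_percent,
                "n_vectors": r.n_vectors,
                "valid": r.valid,
                "tuned_thresholds": list(r.tuned_thresholds)
                if r.tuned_thresholds
                else None,
                "note": r.note,
            }
            for r in report.per_subject
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def write_profiles(profiles: Sequence[SubjectProfile], path) -> None:
    """Ground-truth sidecar: the generating Cole parameters per montage."""
    doc = [
        {
            "subject_id": p.subject_id,
            "stroke_hemisphere": p.stroke_hemisphere,
            "params": {
                f"{hemi}/{eset}": asdict(cp) for (hemi, eset), cp in p.params.items()
            },
        }
        for p in profiles
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_profiles(path) -> List[SubjectProfile]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for entry in doc:
        params = {}
        for key, cp in entry["params"].items():
            hemi, eset = key.split("/")
            params[(hemi, eset)] = ColeParameters(**cp)
        out.append(
            SubjectProfile(
                subject_id=entry["subject_id"],
                stroke_hemisphere=entry["stroke_hemisphere"],
                params=params,
            )
        )
    return out


def load_generator_config(path) -> GeneratorConfig:
    """Build a `GeneratorConfig` from a YAML (or JSON) mapping.

    Recognised keys mirror the dataclass fields; ``damage_effects`` is a list
    of ``{f1_shift, f2_shift, f3_shift}`` mappings and ``grid`` may specify
    ``{f_min_hz, f_max_hz, n_points}``.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return GeneratorConfig()
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a mapping at the top level")
    kwargs = dict(raw)
    if "damage_effects" in kwargs:
        kwargs["damage_effects"] = tuple(
            DamageEffect(**e) for e in kwargs["damage_effects"]
        )
    if "grid" in kwargs:
        g = kwargs["grid"]
        kwargs["grid"] = FrequencyGrid(
            np.logspace(
                np.log10(float(g["f_min_hz"])),
                np.log10(float(g["f_max_hz"])),
                int(g["n_points"]),
            )
        )
    try:
        return GeneratorConfig(**kwargs)
    except (TypeError, ValidationError) as exc:
        raise ParseError(f"{path}: invalid generator configuration: {exc}") from exc
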