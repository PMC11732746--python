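"""Readers and writers for the long-format concentration and flux tables.

The canonical interchange format is a tidy CSV with one row per measured
fraction::

    cruise,station,occupation,deployment_id,depth_m,substance,fraction,
    concentration,concentration_sd,v_tray_star_l,flags

``fraction`` is one of t0/top/base/tray/tray_star; units are implied by
the substance (µg l⁻¹ for CHL/POC, µmol l⁻¹ for BSI); ``flags`` is a
semicolon-separated quality-marker list. A spreadsheet import adapter
normalizes supplementary-style workbooks into the same layout via fuzzy
header matching.

Malformed rows are never silently dropped: readers return a rejects
table with one reason per rejected row, and duplicate
(deployment_id, substance, fraction) keys are a hard error.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .attenuation import AttenuationFit
from .errors import ValidationError
from .fluxes import FluxRecord
from .partition import MSCDeployment, SUBSTANCES

logger = logging.getLogger(__name__)

CONCENTRATION_COLUMNS = [
    "cruise", "station", "occupation", "deployment_id", "depth_m",
    "substance", "fraction", "concentration", "concentration_sd",
    "v_tray_star_l", "flags",
]

FRACTION_CODES = ("t0", "top", "base", "tray", "tray_star")

FLUX_COLUMNS = [
    "cruise", "station", "occupation", "deployment_id", "depth_m",
    "substance", "f_slow", "f_fast", "f_total",
    "sd_slow", "sd_fast", "sd_total", "v_fast_used", "method_fast",
]

_FRACTION_FIELD = {
    "t0": ("p_t0", "sd_t0"),
    "top": ("p_top", "sd_top"),
    "base": ("p_base", "sd_base"),
    "tray": ("p_tray", "sd_tray"),
    "tray_star": ("p_tray_star", "sd_tray_star"),
}


def _nan_to_none(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_concentrations(path) -> tuple[list[MSCDeployment], pd.DataFrame]:
    """Read a long-format concentration CSV into deployments.

    Returns ``(deployments, rejects)`` where ``rejects`` has the
    offending rows plus a ``reject_reason`` column. Duplicate
    (deployment_id, substance, fraction) keys and unknown substances are
    hard errors.
    """
    frame = pd.read_csv(
        path, dtype={"occupation": str, "flags": str}, float_precision="round_trip"
    )
    missing = set(CONCENTRATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        logger.warning("%s: empty data section", path)
        return [], frame.assign(reject_reason=pd.Series(dtype=str))

    unknown = set(frame["substance"].unique()) - SUBSTANCES
    if unknown:
        raise ValidationError(f"{path}: unknown substances {sorted(unknown)}")
    dup_mask = frame.duplicated(["deployment_id", "substance", "fraction"], keep=False)
    if dup_mask.any():
        offenders = frame.loc[
            dup_mask, ["deployment_id", "substance", "fraction"]
        ].drop_duplicates()
        raise ValidationError(
            f"{path}: duplicate (deployment_id, substance, fraction) keys:\n"
            f"{offenders.to_string(index=False)}"
        )

    reject_rows, reject_reasons = [], []

    def reject(row: pd.Series, reason: str) -> None:
        reject_rows.append(row)
        reject_reasons.append(reason)

    good_rows = []
    for _, row in frame.iterrows():
        if row["fraction"] not in FRACTION_CODES:
            reject(row, f"unknown fraction {row['fraction']!r}")
        elif not row["depth_m"] > 0:
            reject(row, "depth_m must be > 0")
        elif row["fraction"] == "tray_star" and _nan_to_none(row["v_tray_star_l"]) is None:
            reject(row, "fraction=tray_star requires v_tray_star_l")
        elif _nan_to_none(row["concentration"]) is None:
            reject(row, "missing concentration")
        else:
            good_rows.append(row)

    deployments = []
    if good_rows:
        good = pd.DataFrame(good_rows)
        keys = ["cruise", "station", "occupation", "deployment_id", "depth_m", "substance"]
        for key_vals, sub in good.groupby(keys, sort=True, dropna=False):
            kw: dict = dict(zip(keys, key_vals))
            occ = kw["occupation"]
            kw["occupation"] = None if (occ is None or (isinstance(occ, float) and np.isnan(occ))) else str(occ)
            flags: set[str] = set()
            for _, row in sub.iterrows():
                conc_field, sd_field = _FRACTION_FIELD[row["fraction"]]
                kw[conc_field] = float(row["concentration"])
                kw[sd_field] = _nan_to_none(row["concentration_sd"])
                if row["fraction"] == "tray_star":
                    kw["v_tray_star_l"] = float(row["v_tray_star_l"])
                if isinstance(row.get("flags"), str) and row["flags"]:
                    flags.update(row["flags"].split(";"))
            kw["flags"] = frozenset(flags)
            deployments.append(MSCDeployment(**kw))

    rejects = pd.DataFrame(reject_rows)
    rejects["reject_reason"] = reject_reasons if reject_rows else pd.Series(dtype=str)
    logger.info(
        "read_concentrations: %d rows in, %d deployments, %d rejected",
        len(frame), len(deployments), len(rejects),
    )
    return deployments, rejects


def deployments_to_frame(deployments: Iterable[MSCDeployment]) -> pd.DataFrame:
    """Long-format frame (the canonical CSV layout) from deployments."""
    rows = []
    for dep in deployments:
        for fraction, (conc_field, sd_field) in _FRACTION_FIELD.items():
            conc = getattr(dep, conc_field)
            if conc is None:
                continue
            rows.append(
                {
                    "cruise": dep.cruise,
                    "station": dep.station,
                    "occupation": dep.occupation,
                    "deployment_id": dep.deployment_id,
                    "depth_m": dep.depth_m,
                    "substance": dep.substance,
                    "fraction": fraction,
                    "concentration": conc,
                    "concentration_sd": getattr(dep, sd_field),
                    "v_tray_star_l": dep.v_tray_star_l if fraction == "tray_star" else None,
                    "flags": ";".join(sorted(dep.flags)),
                }
            )
    return pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS)


def write_concentrations(
    deployments_or_frame, path, full_precision: bool = True
) -> None:
    """Write the canonical concentration CSV.

    ``full_precision=False`` rounds numerics to 6 significant digits for
    human-facing output; the default keeps full precision so write→read
    round trips are bit-exact.
    """
    frame = (
        deployments_or_frame
        if isinstance(deployments_or_frame, pd.DataFrame)
        else deployments_to_frame(deployments_or_frame)
    )
    _write_csv(frame, path, full_precision)


def flux_records_to_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {col: getattr(r, col) for col in FLUX_COLUMNS}
            for r in records
        ],
        columns=FLUX_COLUMNS,
    )


def write_fluxes(records: Iterable[FluxRecord], path, full_precision: bool = True) -> None:
    _write_csv(flux_records_to_frame(records), path, full_precision)


def fits_to_frame(fits: Iterable[AttenuationFit]) -> pd.DataFrame:
    rows = []
    for fit in fits:
        lo, hi = fit.b_ci95
        rows.append(
            {
                "group": fit.group,
                "substance": fit.substance,
                "scheme": fit.scheme,
                "v_fast": fit.v_fast,
                "b": fit.b,
                "b_se": fit.b_se,
                "b_ci95_lo": lo,
                "b_ci95_hi": hi,
                "ln_f0": fit.ln_f0,
                "ln_f0_se": fit.ln_f0_se,
                "z0": fit.z0,
                "n_points": fit.n_points,
                "n_excluded_nonpositive": fit.n_excluded_nonpositive,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(rows)


def _write_csv(frame: pd.DataFrame, path, full_precision: bool) -> None:
    if full_precision:
        frame.to_csv(path, index=False)
    else:
        frame.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Spreadsheet import
# ---------------------------------------------------------------------------

#: Canonical column → header synonyms, matched after lower-casing and
#: stripping everything that is not a letter or digit.
_HEADER_SYNONYMS: Mapping[str, tuple[str, ...]] = {
    "cruise": ("cruise",),
    "station": ("station", "site"),
    "occupation": ("occupation", "visit"),
    "deployment_id": ("deploymentid", "deployment", "mscid", "mscdeployment"),
    "depth_m": ("depthm", "depth", "deploymentdepthm"),
    "substance": ("substance", "parameter", "variable", "compound"),
    "fraction": ("fraction", "particlefraction", "sample"),
    "concentration": ("concentration", "conc", "value"),
    "concentration_sd": ("concentrationsd", "sd", "stdev", "standarddeviation"),
    "v_tray_star_l": ("vtraystarl", "vtraystar", "syphonedvolumel"),
    "flags": ("flags", "flag", "qualityflags"),
}

_REQUIRED_HEADERS = (
    "station", "depth_m", "substance", "fraction", "concentration",
)


def _normalize(header: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(header).lower())


def _map_headers(
    columns: Sequence[str], mapping_override: Mapping[str, str] | None
) -> dict[str, str]:
    """Map raw workbook headers to canonical names; returns
    {raw_header: canonical}. Unmatched raw headers are ignored (logged);
    a missing *required* canonical header raises."""
    override = {str(k): v for k, v in (mapping_override or {}).items()}
    result: dict[str, str] = {}
    for raw in columns:
        if raw in override:
            result[raw] = override[raw]
            continue
        norm = _normalize(raw)
        for canonical, synonyms in _HEADER_SYNONYMS.items():
            if norm in synonyms and canonical not in result.values():
                result[raw] = canonical
                break
        else:
            logger.info("workbook import: ignoring unmatched column %r", raw)
    for required in _REQUIRED_HEADERS:
        if required not in result.values():
            raise ValidationError(
                f"workbook sheet: no column matched required header {required!r} "
                f"(headers seen: {list(columns)})"
            )
    return result


_SUBSTANCE_ALIASES = {
    "chl": "CHL", "chla": "CHL", "chlorophylla": "CHL", "chlorophyll": "CHL",
    "poc": "POC", "particulateorganiccarbon": "POC",
    "bsi": "BSI", "biogenicsilica": "BSI", "opal": "BSI",
}


def import_supplementary_workbook(
    path,
    mapping_override: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Normalize a supplementary-style xlsx workbook into the canonical
    long-format tables.

    Sheets whose name contains "concentration" feed the concentration
    table; sheets containing "flux" feed an optional flux table (returned
    raw with canonicalized metadata columns, for cross-validation against
    recomputed fluxes). Headers are matched fuzzily; ``mapping_override``
    maps raw header → canonical name where fuzzy matching is wrong.
    """
    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    conc_frames, flux_frames = [], []
    for name, sheet in sheets.items():
        lname = name.lower()
        if "concentration" in lname:
            header_map = _map_headers(sheet.columns, mapping_override)
            sub = sheet[list(header_map)].rename(columns=header_map)
            sub["substance"] = [
                _SUBSTANCE_ALIASES.get(_normalize(s), str(s).upper())
                for s in sub["substance"]
            ]
            for col in CONCENTRATION_COLUMNS:
                if col not in sub.columns:
                    sub[col] = None
            conc_frames.append(sub[CONCENTRATION_COLUMNS])
        elif "flux" in lname:
            flux_frames.append(sheet)
        else:
            logger.info("workbook import: skipping sheet %r", name)
    if not conc_frames:
        raise ValidationError(f"{path}: no sheet with 'concentration' in its name")
    concentrations = pd.concat(conc_frames, ignore_index=True)
    fluxes = pd.concat(flux_frames, ignore_index=True) if flux_frames else None
    return concentrations, fluxes


def cross_validate_fluxes(
    recomputed: pd.DataFrame, reported: pd.DataFrame, on: Sequence[str], column: str
) -> pd.DataFrame:
    """Relative-difference report between recomputed and reported flux
    tables, joined on ``on``. No tolerance is asserted — this is an
    audit artefact."""
    merged = recomputed.merge(reported, on=list(on), suffixes=("_recomputed", "_reported"))
    a = merged[f"{column}_recomputed"]
    b = merged[f"{column}_reported"]
    merged["rel_diff"] = (a - b).abs() / b.abs().replace(0, np.nan)
    return merged
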