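"""BSi:POC molar ratios of particle pools.

Biogenic silica is measured in molar units (µmol l⁻¹) and particulate
organic carbon in mass units (µg l⁻¹), so POC is divided by the standard
atomic weight of carbon (12.011 g mol⁻¹) before any ratio is formed.

For *total sinking* material the slow and fast pools are summed first.
Where a computed slow-pool concentration is negative (an upward flux of
material, usually measurement noise), its **magnitude** is added to the
fast-sinking concentration — the magnitude rule. Per-fraction ratios
(suspended / slow / fast) and time-zero ratios are computed without the
rule; a negative per-fraction ratio is flagged rather than hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .geometry import MSCGeometry
from .partition import FractionSet, MSCDeployment, partition

logger = logging.getLogger(__name__)

#: Standard atomic weight of carbon, g mol⁻¹.
CARBON_MOLAR_MASS = 12.011

FRACTION_NAMES = ("time_zero", "suspended", "slow", "fast", "total_sinking")


def poc_mass_to_mol(poc_ug_l: float) -> float:
    """Convert a POC mass concentration (µg l⁻¹) to µmol l⁻¹."""
    return poc_ug_l / CARBON_MOLAR_MASS


def magnitude_rule_sum(slow: float, fast: float) -> float:
    """Total-sinking concentration with the magnitude rule: a negative
    slow pool contributes its absolute value to the fast pool."""
    return abs(slow) + fast if slow < 0 else slow + fast


def total_sinking_ratio(
    bsi_slow: float, bsi_fast: float, poc_slow: float, poc_fast: float
) -> float:
    """BSi:POC molar ratio of total sinking material (mol mol⁻¹).

    Raises :class:`UndefinedRatioError` when the POC denominator is zero
    or negative after the magnitude rule.
    """
    numerator = magnitude_rule_sum(bsi_slow, bsi_fast)
    denominator = poc_mass_to_mol(magnitude_rule_sum(poc_slow, poc_fast))
    if denominator <= 0:
        raise UndefinedRatioError(
            f"total-sinking POC concentration {denominator:.4g} µmol l⁻¹ is not positive"
        )
    return numerator / denominator


@dataclass(frozen=True)
class MolarRatioRecord:
    """One BSi:POC molar ratio (mol mol⁻¹) for one particle fraction at
    one depth, possibly aggregated over several deployments."""

    group: str
    depth_m: float
    fraction: str
    ratio: float
    sd: float | None = None
    n_deployments: int = 1
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.fraction not in FRACTION_NAMES:
            raise ValidationError(f"unknown fraction {self.fraction!r}")
        if self.n_deployments < 1:
            raise ValidationError("n_deployments must be >= 1")


def _group_label(dep: MSCDeployment) -> str:
    occ = dep.occupation if dep.occupation else "-"
    return f"{dep.cruise}/{dep.station}/{occ}"


def _pair_by_deployment(
    deployments: Iterable[MSCDeployment],
) -> list[tuple[MSCDeployment, MSCDeployment]]:
    """Pair BSI and POC deployments sharing a deployment_id."""
    by_id: dict[str, dict[str, MSCDeployment]] = {}
    for dep in deployments:
        if dep.substance in ("BSI", "POC"):
            by_id.setdefault(dep.deployment_id, {})[dep.substance] = dep
    pairs = []
    for dep_id, subs in sorted(by_id.items()):
        if "BSI" in subs and "POC" in subs:
            pairs.append((subs["BSI"], subs["POC"]))
        else:
            logger.info("ratios: deployment %s lacks a BSI/POC partner, skipped", dep_id)
    return pairs


def molar_ratio_records(
    deployments: Iterable[MSCDeployment],
    geom: MSCGeometry,
    fractions: Sequence[str] = ("total_sinking", "time_zero"),
) -> list[MolarRatioRecord]:
    """Per-deployment BSi:POC ratios for the requested fractions.

    BSI and POC deployments are paired by ``deployment_id``. The
    magnitude rule applies only to ``total_sinking``; a deployment whose
    total-sinking denominator is non-positive yields a record flagged
    ``undefined_ratio`` with a NaN ratio rather than being dropped.
    """
    unknown = set(fractions) - set(FRACTION_NAMES)
    if unknown:
        raise ValidationError(f"unknown fractions: {sorted(unknown)}")
    records: list[MolarRatioRecord] = []
    for bsi, poc in _pair_by_deployment(deployments):
        group, depth = _group_label(bsi), bsi.depth_m
        need_pools = {"suspended", "slow", "fast", "total_sinking"} & set(fractions)
        fb = fp = None
        if need_pools:
            fb, fp = partition(bsi, geom), partition(poc, geom)
        for fraction in fractions:
            if fraction == "time_zero":
                if bsi.p_t0 is None or poc.p_t0 is None:
                    continue
                pair = (bsi.p_t0, poc.p_t0)
            elif fraction == "total_sinking":
                try:
                    ratio = total_sinking_ratio(fb.p_slow, fb.p_fast, fp.p_slow, fp.p_fast)
                except UndefinedRatioError as exc:
                    logger.warning("ratios: %s: %s", bsi.deployment_id, exc)
                    records.append(
                        MolarRatioRecord(group, depth, fraction, float("nan"),
                                         flags=frozenset({"undefined_ratio"}))
                    )
                    continue
                records.append(MolarRatioRecord(group, depth, fraction, ratio))
                continue
            else:
                attr = {"suspended": "p_susp", "slow": "p_slow", "fast": "p_fast"}[fraction]
                pair = (getattr(fb, attr), getattr(fp, attr))
            bsi_c, poc_c = pair
            poc_mol = poc_mass_to_mol(poc_c)
            if poc_mol == 0:
                records.append(
                    MolarRatioRecord(group, depth, fraction, float("nan"),
                                     flags=frozenset({"undefined_ratio"}))
                )
                continue
            ratio = bsi_c / poc_mol
            flags = frozenset({"negative_ratio"}) if ratio < 0 else frozenset()
            records.append(MolarRatioRecord(group, depth, fraction, ratio, flags=flags))
    return records


def aggregate_ratios(
    records: Sequence[MolarRatioRecord],
    group_keys: Sequence[str] = ("group", "depth_m", "fraction"),
) -> list[MolarRatioRecord]:
    """Mean ± sample standard deviation of ratios per group.

    The sd is the n−1 sample standard deviation and is ``None`` for
    singleton groups. Records flagged ``undefined_ratio`` are excluded
    (with a log entry); input order does not affect the result.
    """
    if not records:
        raise ValidationError("aggregate_ratios: empty input")
    usable = [r for r in records if not np.isnan(r.ratio)]
    n_dropped = len(records) - len(usable)
    if n_dropped:
        logger.info("aggregate_ratios: %d undefined ratios excluded", n_dropped)
    frame = pd.DataFrame(
        {
            "group": [r.group for r in usable],
            "depth_m": [r.depth_m for r in usable],
            "fraction": [r.fraction for r in usable],
            "ratio": [r.ratio for r in usable],
        }
    )
    out: list[MolarRatioRecord] = []
    for keys, sub in frame.groupby(list(group_keys), sort=True):
        keys = dict(zip(group_keys, keys if isinstance(keys, tuple) else (keys,)))
        n = len(sub)
        out.append(
            MolarRatioRecord(
                group=str(keys.get("group", "pooled")),
                depth_m=float(keys.get("depth_m", np.nan)),
                fraction=str(keys.get("fraction", "total_sinking")),
                ratio=float(sub["ratio"].mean()),
                sd=float(sub["ratio"].std(ddof=1)) if n > 1 else None,
                n_deployments=n,
            )
        )
    return out


def ratio_records_to_frame(records: Sequence[MolarRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in records],
            "depth_m": [r.depth_m for r in records],
            "fraction": [r.fraction for r in records],
            "ratio_mol_mol": [r.ratio for r in records],
            "ratio_sd": [r.sd for r in records],
            "n_deployments": [r.n_deployments for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )
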