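"""Phenotype derivation: estimated pre-treatment LDLC (eLDLC), the Dutch
Lipid Clinic Network (DLCN) score without genetic items, and group labels.

Lipids are handled in mg/dL; the DLCN LDLC band is evaluated on eLDLC
converted to mmol/L with the conventional factor 38.67 mg/dL per mmol/L.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MGDL_PER_MMOL = 38.67

DLCN_CATEGORIES = ("unlikely", "possible", "probable", "definite")


def mgdl_to_mmol(x):
    return np.asarray(x, dtype=float) / MGDL_PER_MMOL


def mmol_to_mgdl(x):
    return np.asarray(x, dtype=float) * MGDL_PER_MMOL


class UnknownStatinError(KeyError):
    """Raised when a statin type/dose has no entry in the correction table."""


@dataclass(frozen=True)
class StatinCorrectionTable:
    """Map (statin type, daily dose mg) -> expected fractional LDLC reduction."""

    factors: dict[str, dict[float, float]]

    def __post_init__(self) -> None:
        for statin, doses in self.factors.items():
            for dose, r in doses.items():
                if not 0.0 <= r < 1.0:
                    raise ValueError(f"{statin} {dose} mg: reduction {r} outside [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "StatinCorrectionTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({s: {float(d): float(r) for d, r in doses.items()}
                    for s, doses in raw.items()})

    @classmethod
    def default(cls) -> "StatinCorrectionTable":
        ref = resources.files("ldlprs.config") / "statin_correction.yaml"
        raw = yaml.safe_load(ref.read_text())
        return cls({s: {float(d): float(r) for d, r in doses.items()}
                    for s, doses in raw.items()})

    def reduction(self, statin: str | None, dose: float | None) -> float:
        if statin is None or (isinstance(statin, float) and np.isnan(statin)) or statin == "":
            return 0.0
        key = statin.lower()
        if "+" in key:  # combination therapy: statin-only factor unless configured
            if key not in self.factors:
                base = key.split("+", 1)[0].strip()
                logger.warning("no combination entry for %r; using statin-only %r", statin, base)
                key = base
        if key not in self.factors or float(dose) not in self.factors[key]:
            raise UnknownStatinError(f"no correction factor for {statin!r} at {dose} mg")
        return self.factors[key][float(dose)]


def estimate_pretreatment_ldlc(
    measured_ldlc: float,
    statin: str | None = None,
    dose: float | None = None,
    table: StatinCorrectionTable | None = None,
) -> float:
    """Back-calculate pre-treatment LDLC: eLDLC = measured / (1 - r).

    r is the expected fractional reduction for the statin type and dose;
    untreated individuals have r = 0 so eLDLC equals the measurement.
    """
    if measured_ldlc <= 0:
        raise ValueError("measured LDLC must be positive")
    table = table or StatinCorrectionTable.default()
    r = table.reduction(statin, dose)
    return float(measured_ldlc / (1.0 - r))


@dataclass(frozen=True)
class DlcnTable:
    """DLCN point values per item, band edges, and category bounds."""

    family_history: dict[str, int]
    clinical_history: dict[str, int]
    physical_exam: dict[str, int]
    ldl_bands_mmol: list[tuple[float, int]]
    categories: dict[str, tuple[int, int | None]]

    @classmethod
    def from_yaml(cls, path) -> "DlcnTable":
        with open(path) as fh:
            return cls._build(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "DlcnTable":
        ref = resources.files("ldlprs.config") / "dlcn.yaml"
        return cls._build(yaml.safe_load(ref.read_text()))

    @classmethod
    def _build(cls, raw: dict) -> "DlcnTable":
        return cls(
            family_history={k: int(v) for k, v in raw["family_history"]["items"].items()},
            clinical_history={k: int(v) for k, v in raw["clinical_history"]["items"].items()},
            physical_exam={k: int(v) for k, v in raw["physical_exam"]["items"].items()},
            ldl_bands_mmol=sorted(
                ((float(lo), int(pts)) for lo, pts in raw["ldl_bands_mmol"]), reverse=True
            ),
            categories={k: (int(v[0]), None if v[1] is None else int(v[1]))
                        for k, v in raw["categories"].items()},
        )

    def ldl_band_points(self, eldlc_mmol: float) -> int:
        for lo, pts in self.ldl_bands_mmol:
            if eldlc_mmol >= lo:
                return pts
        return 0

    def category(self, points: int) -> str:
        for name, (lo, hi) in self.categories.items():
            if points >= lo and (hi is None or points <= hi):
                return name
        raise ValueError(f"no DLCN category for {points} points")


@dataclass
class DlcnResult:
    points: int
    category: str


def dlcn_score(
    items: dict[str, bool],
    eldlc_mgdl: float,
    table: DlcnTable | None = None,
) -> DlcnResult:
    """DLCN score (genetic items excluded) from clinical item flags + eLDLC.

    Family-history and physical-exam sections contribute the maximum of
    their present items; clinical-history items are summed; the LDLC band
    is scored on eLDLC in mmol/L. Absent items score 0.
    """
    if eldlc_mgdl < 0:
        raise ValueError("eLDLC must be non-negative")
    table = table or DlcnTable.default()

    def section(points_map: dict[str, int], combine_max: bool) -> int:
        present = [pts for item, pts in points_map.items() if items.get(item, False)]
        if not present:
            return 0
        return max(present) if combine_max else sum(present)

    pts = (
        section(table.family_history, combine_max=True)
        + section(table.clinical_history, combine_max=False)
        + section(table.physical_exam, combine_max=True)
        + table.ldl_band_points(float(mgdl_to_mmol(eldlc_mgdl)))
    )
    return DlcnResult(int(pts), table.category(int(pts)))


def dlcn_score_frame(df: pd.DataFrame, eldlc_col: str = "eLDLC",
                     table: DlcnTable | None = None) -> pd.DataFrame:
    """Vectorized DLCN scoring over a phenotype table.

    Item columns are looked up by the names in the DLCN config; missing
    columns are treated as all-absent.
    """
    table = table or DlcnTable.default()
    n = len(df)

    def flags(item: str) -> np.ndarray:
        if item in df:
            return df[item].fillna(False).astype(bool).to_numpy()
        return np.zeros(n, dtype=bool)

    def section(points_map: dict[str, int], combine_max: bool) -> np.ndarray:
        pts = np.zeros(n, dtype=int)
        for item, p in points_map.items():
            present = flags(item) * p
            pts = np.maximum(pts, present) if combine_max else pts + present
        return pts

    eldlc_mmol = mgdl_to_mmol(df[eldlc_col].to_numpy(float))
    if (eldlc_mmol < 0).any():
        raise ValueError("eLDLC must be non-negative")
    band = np.zeros(n, dtype=int)
    for lo, p in sorted(table.ldl_bands_mmol):  # ascending so higher bands overwrite
        band = np.where(eldlc_mmol >= lo, p, band)
    total = (section(table.family_history, True)
             + section(table.clinical_history, False)
             + section(table.physical_exam, True)
             + band)
    cats = pd.Series([table.category(int(p)) for p in total], index=df.index)
    return pd.DataFrame({"dlcn_points": total, "dlcn_category": cats}, index=df.index)


def assign_groups(df: pd.DataFrame, group_col: str = "group",
                  dlcn_col: str = "dlcn_points") -> pd.Series:
    """Split PCHD cases into dFH (DLCN > 8) and nFH (DLCN <= 8); HC unchanged."""
    out = df[group_col].astype(str).copy()
    is_case = out == "PCHD"
    out[is_case & (df[dlcn_col] > 8)] = "dFH"
    out[is_case & (df[dlcn_col] <= 8)] = "nFH"
    return out
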