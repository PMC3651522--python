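"""Western-blot densitometry normalization.

Lane-level band intensities (arbitrary densitometry units) are converted to
per-species protein-level summaries in two stages:

1. each target band is divided by its lane's loading-control (beta-actin)
   band, removing lane-to-lane loading differences;
2. each gel is rescaled to a reference species run on every gel, removing
   gel-level effects (transfer efficiency, exposure, scan brightness).

The cross-gel factor for a gel is (grand mean of reference lanes across all
gels) / (mean of that gel's reference lanes), so the reference species ends
up with the same rescaled value on every gel and the adjustment is a pure
gel effect. Species-level summaries are then the arithmetic mean, sample
standard deviation (n - 1) and replicate count of the rescaled lanes.

A serial-dilution linearity check is included as QC: it finds the widest
contiguous loading range over which band intensity is proportional to
protein loaded, mirroring the standard practice of confirming the assay's
linear region before quantitative comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensitometryError",
    "GelMeasurement",
    "LinearRange",
    "MEASUREMENT_COLUMNS",
    "normalize_lane",
    "actin_normalize",
    "cross_gel_normalize",
    "summarize_species",
    "check_linear_range",
    "read_measurements",
    "write_measurements",
]

MEASUREMENT_COLUMNS = (
    "gel_id",
    "lane",
    "species",
    "organ",
    "target_intensity",
    "control_intensity",
)


class DensitometryError(ValueError):
    """Invalid densitometry input (bad lane, missing reference, ...)."""


@dataclass(frozen=True)
class GelMeasurement:
    """One gel lane: raw target and loading-control band intensities."""

    gel_id: str
    lane: str
    species: str
    organ: str
    target_intensity: float
    control_intensity: float
    is_reference: bool = False


@dataclass(frozen=True)
class LinearRange:
    """Outcome of the serial-dilution linearity QC."""

    ok: bool
    low: float | None
    high: float | None
    n_points: int

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "low": self.low,
            "high": self.high,
            "n_points": self.n_points,
        }


def normalize_lane(measurement: GelMeasurement) -> float:
    """Loading-control ratio for one lane: target / control intensity."""
    if not measurement.control_intensity > 0:
        raise DensitometryError(
            f"gel {measurement.gel_id} lane {measurement.lane}: "
            f"control intensity must be positive, got {measurement.control_intensity}"
        )
    return measurement.target_intensity / measurement.control_intensity


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DensitometryError(f"measurement table lacks columns: {missing}")


def actin_normalize(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio`` column (target / control) to a measurement table."""
    _require_columns(df=measurements, cols=MEASUREMENT_COLUMNS)
    bad = measurements[~(measurements["control_intensity"] > 0)]
    if len(bad):
        row = bad.iloc[0]
        raise DensitometryError(
            f"gel {row['gel_id']} lane {row['lane']}: control intensity must be "
            f"positive, got {row['control_intensity']}"
        )
    out = measurements.copy()
    out["ratio"] = out["target_intensity"] / out["control_intensity"]
    return out


def cross_gel_normalize(
    lanes: pd.DataFrame,
    reference_species: str,
    value_column: str = "ratio",
) -> pd.DataFrame:
    """Rescale per-gel values to a common reference species.

    Every gel must contain at least one lane of ``reference_species`` with a
    positive value. Each gel's lanes are multiplied by
    (grand mean of reference lanes) / (mean of this gel's reference lanes),
    which equalizes the per-gel reference statistic across gels and
    preserves within-gel ordering.
    """
    if value_column not in lanes.columns:
        raise DensitometryError(f"no {value_column!r} column; run actin_normalize first")
    out = lanes.copy()
    is_ref = out["species"] == reference_species
    ref = out[is_ref]
    gels = out["gel_id"].unique()
    missing = sorted(set(gels) - set(ref["gel_id"].unique()))
    if missing:
        raise DensitometryError(
            f"no {reference_species!r} reference lane on gel(s): {', '.join(map(str, missing))}"
        )
    if not (ref[value_column] > 0).all():
        bad = ref[~(ref[value_column] > 0)].iloc[0]
        raise DensitometryError(
            f"non-positive reference value on gel {bad['gel_id']} lane {bad['lane']}"
        )
    grand = ref[value_column].mean()
    per_gel = ref.groupby("gel_id")[value_column].mean()
    factors = grand / out["gel_id"].map(per_gel)
    out["level"] = out[value_column] * factors
    out["is_reference"] = is_ref
    return out


def summarize_species(
    lanes: pd.DataFrame,
    organ: str | None = None,
    value_column: str = "level",
) -> pd.DataFrame:
    """Per-species mean, sample SD and replicate count of normalized lanes.

    Species with no lane for the requested organ are simply absent from the
    output (they are not zero-filled). SD is NaN for singleton species.
    """
    if value_column not in lanes.columns:
        raise DensitometryError(f"no {value_column!r} column in lane table")
    sub = lanes if organ is None else lanes[lanes["organ"] == organ]
    if not len(sub):
        raise DensitometryError(
            f"no lanes to summarize" + (f" for organ {organ!r}" if organ else "")
        )
    grouped = sub.groupby("species")[value_column]
    out = pd.DataFrame(
        {
            "mean_level": grouped.mean(),
            "sd_level": grouped.std(ddof=1),
            "n": grouped.count(),
        }
    ).reset_index()
    if organ is not None:
        out.insert(1, "organ", organ)
    return out.sort_values("species", ignore_index=True)


def check_linear_range(
    loaded_protein: Sequence[float],
    band_intensity: Sequence[float],
    tolerance: float = 0.10,
) -> LinearRange:
    """Find the widest contiguous dilution range with proportional response.

    Points are sorted by protein loaded; every contiguous run of >= 3 points
    is fitted with a through-origin line, and a run qualifies when every
    point's relative deviation from the fit is within ``tolerance``. The
    longest qualifying run (ties broken toward the wider mass range) gives
    the reported (low, high) endpoints in the units of ``loaded_protein``.
    """
    x = np.asarray(loaded_protein, dtype=float)
    y = np.asarray(band_intensity, dtype=float)
    if x.size != y.size:
        raise DensitometryError("loaded_protein and band_intensity lengths differ")
    if x.size < 3:
        raise DensitometryError(f"need >= 3 dilution points, got {x.size}")
    if not np.all(x > 0):
        raise DensitometryError("protein loadings must be strictly positive")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        raise DensitometryError("duplicate protein loadings in dilution series")

    best: tuple[int, float, int, int] | None = None  # (length, span, i, j)
    n = x.size
    for i in range(n):
        for j in range(i + 3, n + 1):
            xs, ys = x[i:j], y[i:j]
            slope = float(np.dot(xs, ys) / np.dot(xs, xs))
            if slope <= 0:
                continue
            rel = np.abs(ys - slope * xs) / (slope * xs)
            if np.max(rel) <= tolerance:
                cand = (j - i, float(xs[-1] - xs[0]), i, j)
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is None:
        return LinearRange(ok=False, low=None, high=None, n_points=0)
    _, _, i, j = best
    return LinearRange(ok=True, low=float(x[i]), high=float(x[j - 1]), n_points=j - i)


def read_measurements(path) -> pd.DataFrame:
    """Read a lane-level measurement table from CSV/TSV (sniffed by suffix)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, MEASUREMENT_COLUMNS)
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
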