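"""Data model and I/O for segmented transect surveys.

A survey is a set of effort segments (nominally 10 km of transect flown in
homogeneous observation conditions) and a set of sightings, each sighting
being one group of animals tied to a segment.  Effort enters downstream
models through the searched area of a segment: ``length_km * 2 * half_width``
where the half-width is the effective strip width (ESW) for line-transect
protocols or the physical half-strip for strip-transect protocols.
"""

from __future__ import annotations

import decimal
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROTOCOLS",
    "SEGMENT_BASE_COLUMNS",
    "SIGHTING_COLUMNS",
    "SurveyDataset",
    "Bookkeeping",
    "effort_area",
    "round_half_up",
    "read_survey_tables",
]

PROTOCOLS = ("line", "strip")

#: required leading columns of a segment table; covariates follow.
SEGMENT_BASE_COLUMNS = (
    "segment_id",
    "transect_id",
    "day_index",
    "length_km",
    "protocol",
    "half_width_km",
)

SIGHTING_COLUMNS = ("sighting_id", "segment_id", "taxon", "group_size")


class SurveyValidationError(ValueError):
    """Raised when a survey table violates the data contract."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from the lower value (0.5 -> 1), decimal-exact."""
    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def effort_area(length_km: float, half_width_km: float) -> float:
    """Searched area of a segment in km^2: ``length * 2 * half_width``.

    The same formula applies to both protocols; for line transects the
    half-width is the ESW, for strip transects the physical half-strip
    (0.2 km in the aerial seabird protocol this package emulates).
    """
    if not (length_km > 0):
        raise SurveyValidationError(f"segment length must be > 0, got {length_km}")
    if not (half_width_km > 0):
        raise SurveyValidationError(f"half width must be > 0, got {half_width_km}")
    return float(length_km) * 2.0 * float(half_width_km)


class Bookkeeping(NamedTuple):
    """Sighting/zero-segment bookkeeping for one taxon."""

    n_sigh: int
    n_z: int
    pct_z: float


@dataclass
class SurveyDataset:
    """Effort segments plus sightings, validated on construction.

    Parameters
    ----------
    segments : DataFrame with :data:`SEGMENT_BASE_COLUMNS` then covariates.
    sightings : DataFrame with :data:`SIGHTING_COLUMNS`.
    schema : ordered covariate names; inferred from extra segment columns
        when omitted.
    """

    segments: pd.DataFrame
    sightings: pd.DataFrame
    schema: tuple = ()

    def __post_init__(self) -> None:
        seg = self.segments.reset_index(drop=True).copy()
        sig = self.sightings.reset_index(drop=True).copy()
        for col in SEGMENT_BASE_COLUMNS:
            if col not in seg.columns:
                raise SurveyValidationError(f"segment table misses column {col!r}")
        for col in SIGHTING_COLUMNS:
            if col not in sig.columns:
                raise SurveyValidationError(f"sighting table misses column {col!r}")
        if not self.schema:
            extra = [
                c
                for c in seg.columns
                if c not in SEGMENT_BASE_COLUMNS and c != "region"
            ]
            self.schema = tuple(extra)
        else:
            self.schema = tuple(self.schema)
        for cov in self.schema:
            if cov not in seg.columns:
                raise SurveyValidationError(f"missing covariate column {cov!r}")
            vals = pd.to_numeric(seg[cov], errors="coerce")
            if vals.isna().any():
                raise SurveyValidationError(
                    f"covariate {cov!r} has missing or non-numeric values"
                )
            seg[cov] = vals.astype(float)
        if len(seg) == 0:
            raise SurveyValidationError("empty segment table")
        if seg["segment_id"].duplicated().any():
            raise SurveyValidationError("duplicated segment_id")
        seg["length_km"] = pd.to_numeric(seg["length_km"])
        seg["half_width_km"] = pd.to_numeric(seg["half_width_km"])
        seg["day_index"] = pd.to_numeric(seg["day_index"]).astype(int)
        if (seg["length_km"] <= 0).any():
            raise SurveyValidationError("nonpositive segment length")
        if (seg["half_width_km"] <= 0).any():
            raise SurveyValidationError("nonpositive half width")
        bad = ~seg["protocol"].isin(PROTOCOLS)
        if bad.any():
            raise SurveyValidationError(
                f"unknown protocol values: {sorted(seg.loc[bad, 'protocol'].unique())}"
            )
        if len(sig):
            if sig["sighting_id"].duplicated().any():
                raise SurveyValidationError("duplicated sighting_id")
            sig["group_size"] = pd.to_numeric(sig["group_size"])
            if (sig["group_size"] < 1).any():
                raise SurveyValidationError("group_size < 1")
            if not np.array_equal(sig["group_size"], sig["group_size"].astype(int)):
                raise SurveyValidationError("non-integer group_size")
            sig["group_size"] = sig["group_size"].astype(int)
            unknown = ~sig["segment_id"].isin(seg["segment_id"])
            if unknown.any():
                missing = sorted(sig.loc[unknown, "segment_id"].unique())[:5]
                raise SurveyValidationError(
                    f"sightings reference unknown segments: {missing}"
                )
        object.__setattr__(self, "segments", seg)
        object.__setattr__(self, "sightings", sig)

    # -- basic views -----------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def taxa(self) -> tuple:
        if len(self.sightings) == 0:
            return ()
        return tuple(sorted(self.sightings["taxon"].unique()))

    def effort_area_km2(self) -> pd.Series:
        """Searched area per segment (km^2), indexed by segment_id."""
        area = self.segments["length_km"].to_numpy() * 2.0 * self.segments[
            "half_width_km"
        ].to_numpy()
        return pd.Series(area, index=self.segments["segment_id"].to_numpy())

    def counts(self, taxon: str, strict: bool = False) -> pd.Series:
        """Per-segment individual counts for ``taxon`` (0 where unseen)."""
        if strict and taxon not in self.taxa:
            raise SurveyValidationError(f"unknown taxon {taxon!r}")
        base = pd.Series(0, index=self.segments["segment_id"].to_numpy(), dtype=int)
        if len(self.sightings):
            sub = self.sightings[self.sightings["taxon"] == taxon]
            if len(sub):
                summed = sub.groupby("segment_id")["group_size"].sum()
                base.loc[summed.index] = summed.astype(int)
        return base

    def bookkeeping(self, taxon: str) -> Bookkeeping:
        """(n_sigh, n_z, pct_z): sightings, zero segments, % zeros (1 dp)."""
        if self.n_segments == 0:  # pragma: no cover - construction forbids it
            raise SurveyValidationError("empty segment table")
        n_sigh = int((self.sightings["taxon"] == taxon).sum()) if len(self.sightings) else 0
        c = self.counts(taxon)
        n_z = int((c == 0).sum())
        pct = round_half_up(100.0 * n_z / self.n_segments, 1)
        return Bookkeeping(n_sigh=n_sigh, n_z=n_z, pct_z=pct)

    def with_sightings(self, sightings: pd.DataFrame) -> "SurveyDataset":
        """New dataset sharing this effort table with replaced sightings."""
        return SurveyDataset(self.segments, sightings, schema=self.schema)

    # -- I/O -------------------------------------------------------------
    def write(self, segment_stream, sighting_stream) -> None:
        """Write the two delimited tables (CSV with header rows)."""
        self.segments.to_csv(segment_stream, index=False)
        self.sightings.to_csv(sighting_stream, index=False)

    def to_strings(self) -> tuple:
        seg, sig = io.StringIO(), io.StringIO()
        self.write(seg, sig)
        return seg.getvalue(), sig.getvalue()


def read_survey_tables(segment_stream, sighting_stream, schema=None) -> SurveyDataset:
    """Read and validate the segment/sighting CSV pair.

    ``schema`` restricts which covariate columns are required; when omitted
    all non-reserved segment columns are taken as covariates.
    """
    seg = pd.read_csv(segment_stream, dtype={"segment_id": str, "transect_id": str})
    sig = pd.read_csv(sighting_stream, dtype={"segment_id": str, "sighting_id": str})
    return SurveyDataset(seg, sig, schema=tuple(schema) if schema else ())
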