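"""Event-level flow-cytometry reduction: blast gating and percent-positive.

Events arrive as an :class:`EventMatrix` (events x channels with a
channel -> marker map).  The blast gate is a rectangle in (CD45, SSC):
CD45-dim, side-scatter low/intermediate mononuclear events.  All
per-patient quantities downstream of the gate are simple counting
statistics: percent of gated blasts above a positivity cutoff per marker,
and the CD34+CD38-CD123+ leukemic-stem-cell fraction.

Positivity is strict: an event exactly at a cutoff counts as negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Markers the classifier requires, in canonical order.
CORE_MARKERS: tuple[str, ...] = ("CD34", "CD117", "CD13", "CD33", "MPO", "HLA-DR")

#: Markers needed for the leukemic-stem-cell fraction.
LSC_MARKERS: tuple[str, ...] = ("CD34", "CD38", "CD123")

#: Minimum acquired blasts before the low-count warning fires.
MIN_BLASTS: int = 10_000


class ChannelError(KeyError):
    """A required channel/marker is absent from the event matrix."""


class EventMatrix:
    """Per-cell intensities for one specimen.

    Parameters
    ----------
    intensities:
        events x channels array of non-negative values; no NaN allowed.
    channels:
        channel identifiers, one per column.
    channel_map:
        channel identifier -> marker name.  Identity entries may be omitted:
        a channel whose identifier is itself a marker name maps to itself.
    specimen_id:
        opaque specimen identifier.
    """

    def __init__(
        self,
        intensities: np.ndarray,
        channels: Sequence[str],
        channel_map: Mapping[str, str] | None = None,
        specimen_id: str = "",
    ) -> None:
        arr = np.asarray(intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError("intensities must be a 2-D events x channels array")
        if arr.shape[1] != len(channels):
            raise ValueError("channel count does not match intensity columns")
        if np.isnan(arr).any():
            raise ValueError("intensities contain NaN")
        self.intensities = arr
        self.channels = list(channels)
        cmap = dict(channel_map or {})
        for ch in self.channels:
            cmap.setdefault(ch, ch)
        self.channel_map = cmap
        self.specimen_id = specimen_id
        self._marker_to_col = {}
        for j, ch in enumerate(self.channels):
            self._marker_to_col.setdefault(self.channel_map[ch], j)

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    @property
    def markers(self) -> list[str]:
        return list(self._marker_to_col)

    def has_marker(self, marker: str) -> bool:
        return marker in self._marker_to_col

    def marker_values(self, marker: str) -> np.ndarray:
        """Intensity column for ``marker`` (resolved through the channel map)."""
        try:
            return self.intensities[:, self._marker_to_col[marker]]
        except KeyError:
            raise ChannelError(f"marker {marker!r} not present in event matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities,
                            columns=[self.channel_map[c] for c in self.channels])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, specimen_id: str = "") -> "EventMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.columns),
                   specimen_id=specimen_id)


def read_events_csv(path, specimen_id: str = "",
                    channel_map: Mapping[str, str] | None = None) -> EventMatrix:
    """Read a tabular event file (one column per channel/marker)."""
    frame = pd.read_csv(path)
    return EventMatrix(frame.to_numpy(dtype=float), list(frame.columns),
                       channel_map=channel_map, specimen_id=specimen_id or str(path))


def read_events_fcs(path, channel_map: Mapping[str, str],
                    specimen_id: str = "") -> EventMatrix:
    """Read an FCS 3.0/3.1 file.  Requires the optional ``fcsparser`` extra."""
    try:
        import fcsparser
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "FCS input requires the optional dependency 'fcsparser' "
            "(pip install slaml[fcs]); CSV event files need no extra."
        ) from exc
    _, data = fcsparser.parse(str(path), reformat_meta=True)
    return EventMatrix(np.asarray(data, dtype=float), list(data.columns),
                       channel_map=channel_map, specimen_id=specimen_id or str(path))


@dataclass(frozen=True)
class GateParams:
    """Rectangular blast gate in (CD45, SSC).

    Defaults bracket a CD45-dim population between the unstained floor and
    the CD45-bright lymphocyte mode of the synthetic intensity model; real
    data should supply instrument-appropriate bounds.
    """

    cd45_low: float = 20.0
    cd45_high: float = 2_000.0
    ssc_low: float = 0.0
    ssc_high: float = 50_000.0
    min_blasts: int = MIN_BLASTS

    def __post_init__(self) -> None:
        if self.cd45_low >= self.cd45_high:
            raise ValueError("cd45_low must be below cd45_high")
        if self.ssc_low >= self.ssc_high:
            raise ValueError("ssc_low must be below ssc_high")


@dataclass(frozen=True)
class GateResult:
    indices: np.ndarray
    gate: GateParams
    fraction_retained: float
    low_count_warning: bool

    @property
    def n_retained(self) -> int:
        return int(self.indices.size)


def gate_blasts(events: EventMatrix, gate_params: GateParams | None = None) -> GateResult:
    """Select CD45-dim x SSC-low/intermediate events (the blast gate).

    Sets ``low_count_warning`` when fewer than ``gate_params.min_blasts``
    events are retained.
    """
    gp = gate_params or GateParams()
    if not events.has_marker("CD45"):
        raise ChannelError("CD45 channel required for blast gating")
    cd45 = events.marker_values("CD45")
    if events.has_marker("SSC"):
        ssc = events.marker_values("SSC")
        in_ssc = (ssc >= gp.ssc_low) & (ssc <= gp.ssc_high)
    else:
        in_ssc = np.ones(events.n_events, dtype=bool)
    mask = (cd45 >= gp.cd45_low) & (cd45 <= gp.cd45_high) & in_ssc
    idx = np.flatnonzero(mask)
    frac = idx.size / events.n_events if events.n_events else 0.0
    return GateResult(indices=idx, gate=gp, fraction_retained=float(frac),
                      low_count_warning=idx.size < gp.min_blasts)


def percent_positive(
    events: EventMatrix,
    marker: str,
    cutoff: float,
    gate: GateResult | None = None,
) -> float:
    """Percent of (gated) events with intensity strictly above ``cutoff``.

    An empty gate yields NaN (undefined), never a division error.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    values = events.marker_values(marker)
    if gate is not None:
        values = values[gate.indices]
    if values.size == 0:
        return float("nan")
    return 100.0 * float(np.count_nonzero(values > cutoff)) / values.size


def cutoff_from_negative_control(control: np.ndarray, q: float = 99.5) -> float:
    """Positivity cutoff as the ``q``-th percentile of a negative population."""
    control = np.asarray(control, dtype=float)
    if control.size == 0:
        raise ValueError("empty negative-control population")
    return float(np.percentile(control, q))


@dataclass(frozen=True)
class MarkerProfile:
    """Per-patient percent-of-blasts-positive summary."""

    patient_id: str
    percentages: dict[str, float] = field(default_factory=dict)
    n_blasts: int = 0

    def __post_init__(self) -> None:
        if self.n_blasts < 0:
            raise ValueError("n_blasts must be >= 0")
        for marker, v in self.percentages.items():
            if not np.isnan(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"percentage for {marker} out of [0, 100]: {v}")

    def has_core_markers(self) -> bool:
        return all(m in self.percentages and not np.isnan(self.percentages[m])
                   for m in CORE_MARKERS)


def marker_profile_from_events(
    events: EventMatrix,
    cutoffs: Mapping[str, float],
    gate_params: GateParams | None = None,
    patient_id: str | None = None,
) -> MarkerProfile:
    """Gate, then compute percent-positive for every marker with a cutoff.

    Markers without a cutoff entry are skipped.  An empty matrix yields a
    profile with undefined (NaN) percentages and ``n_blasts == 0``.
    """
    if events.n_events == 0:
        return MarkerProfile(
            patient_id=patient_id or events.specimen_id,
            percentages={m: float("nan") for m in cutoffs if m != "CD45"},
            n_blasts=0,
        )
    gate = gate_blasts(events, gate_params)
    percentages = {
        marker: percent_positive(events, marker, cut, gate)
        for marker, cut in cutoffs.items()
        if marker != "CD45" and events.has_marker(marker)
    }
    return MarkerProfile(patient_id=patient_id or events.specimen_id,
                         percentages=percentages, n_blasts=gate.n_retained)


def lsc_fraction(
    events: EventMatrix,
    cutoffs: Mapping[str, float],
    gate: GateResult | None = None,
) -> float:
    """Percent of gated blasts that are CD34+ CD38- CD123+.

    ``cutoffs`` must provide entries for CD34, CD38 and CD123.  Positivity is
    strict (> cutoff); CD38-negative means intensity <= cutoff.
    """
    for marker in LSC_MARKERS:
        if not events.has_marker(marker):
            raise ChannelError(f"LSC quantification requires channel {marker!r}")
        if marker not in cutoffs:
            raise ValueError(f"missing cutoff for {marker!r}")
    sel = gate.indices if gate is not None else slice(None)
    cd34 = events.marker_values("CD34")[sel]
    cd38 = events.marker_values("CD38")[sel]
    cd123 = events.marker_values("CD123")[sel]
    if cd34.size == 0:
        return float("nan")
    lsc = (cd34 > cutoffs["CD34"]) & (cd38 <= cutoffs["CD38"]) & (cd123 > cutoffs["CD123"])
    return 100.0 * float(np.count_nonzero(lsc)) / cd34.size


def profiles_to_frame(profiles: Sequence[MarkerProfile]) -> pd.DataFrame:
    """MarkerProfile list -> tidy table (one row per patient)."""
    markers = sorted({m for p in profiles for m in p.percentages})
    rows = []
    for p in profiles:
        row = {"patient_id": p.patient_id, "n_blasts": p.n_blasts}
        row.update({m: p.percentages.get(m, float("nan")) for m in markers})
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(frame: pd.DataFrame) -> list[MarkerProfile]:
    """Tidy table -> MarkerProfile list (inverse of :func:`profiles_to_frame`)."""
    meta = {"patient_id", "n_blasts"}
    markers = [c for c in frame.columns if c not in meta]
    out = []
    for _, row in frame.iterrows():
        out.append(MarkerProfile(
            patient_id=str(row["patient_id"]),
            percentages={m: float(row[m]) for m in markers},
            n_blasts=int(row["n_blasts"]) if "n_blasts" in frame.columns else 0,
        ))
    return out
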