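"""Rule-based stage-of-leukemia-arrest (SLA) classification.

A specimen's marker profile (percent of blasts positive for CD34, CD117,
CD13, CD33, cytoplasmic MPO and HLA-DR) is mapped to exactly one of six
stages mirroring normal myeloid maturation:

* CD34-positive branch (>=20% of blasts CD34+):
    - HSC-L : CD13 and CD33 both negative, MPO < low tier
    - MPP-L : MPO < low tier (myeloid markers detectable)
    - CMP-L : MPO within [low, high] tier
    - GMP-L : MPO above the high tier
* CD34-negative branch:
    - MP-L : HLA-DR positive (>=20%)
    - GP-L : HLA-DR negative

Boundary ties: a percentage equal to the positivity threshold counts as
positive; MPO exactly at a tier bound falls in the CMP-L tier.

CD117 is recorded but non-discriminative; a CD34+ profile with CD117
negative is flagged atypical rather than reclassified.  Likewise a CD34+
profile whose myeloid markers (CD13/CD33) are both negative while MPO is
expressed fires the atypical flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from slaml._report import round_half_away
from slaml.gating import CORE_MARKERS, MarkerProfile

#: Canonical label order, from least to most mature arrest stage.
SLA_LABELS: tuple[str, ...] = ("HSC-L", "MPP-L", "CMP-L", "GMP-L", "GP-L", "MP-L")


class ClassificationError(ValueError):
    """A profile cannot be classified (missing/undefined core marker)."""


class DegenerateDecompositionError(ValueError):
    """PCA input carries no variance."""


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the decision scheme, as percent-of-blasts values."""

    positivity: float = 20.0     # marker "+" means >= this percent of blasts
    mpo_low: float = 10.0        # below: MPO-negative tier (HSC-L / MPP-L)
    mpo_high: float = 70.0       # above: MPO-high tier (GMP-L)
    hladr_split: float = 20.0    # >= : MP-L, < : GP-L

    def __post_init__(self) -> None:
        for name in ("positivity", "mpo_low", "mpo_high", "hladr_split"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must lie strictly between 0 and 100, got {v}")
        if self.mpo_low >= self.mpo_high:
            raise ValueError("mpo_low must be below mpo_high")


@dataclass(frozen=True)
class SLALabel:
    """Classification outcome for one profile."""

    label: str
    atypical: bool = False
    rationale: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.label not in SLA_LABELS:
            raise ValueError(f"unknown SLA label {self.label!r}")


ProfileLike = Union[MarkerProfile, Mapping[str, float]]


def _core_percentages(profile: ProfileLike) -> dict[str, float]:
    if isinstance(profile, MarkerProfile):
        values = profile.percentages
    else:
        values = dict(profile)
    out: dict[str, float] = {}
    for marker in CORE_MARKERS:
        if marker not in values:
            raise ClassificationError(f"core marker {marker!r} missing from profile")
        v = float(values[marker])
        if np.isnan(v):
            raise ClassificationError(f"core marker {marker!r} is undefined (NaN)")
        out[marker] = v
    return out


def classify_sla(profile: ProfileLike, params: ClassifierParams | None = None) -> SLALabel:
    """Assign one SLA label to a marker profile.

    Raises :class:`ClassificationError` when a core marker is missing or
    undefined — there is no silent default class.
    """
    params = params or ClassifierParams()
    p = _core_percentages(profile)
    rules: list[str] = []
    atypical = False

    cd34_pos = p["CD34"] >= params.positivity
    cd13_pos = p["CD13"] >= params.positivity
    cd33_pos = p["CD33"] >= params.positivity
    cd117_pos = p["CD117"] >= params.positivity

    if cd34_pos:
        rules.append("CD34+")
        if p["MPO"] < params.mpo_low:
            if not cd13_pos and not cd33_pos:
                rules.append("CD13-/CD33-/MPO-low->HSC-L")
                label = "HSC-L"
            else:
                rules.append("MPO-low->MPP-L")
                label = "MPP-L"
        else:
            if not cd13_pos and not cd33_pos:
                # MPO expressed but classic myeloid markers absent
                atypical = True
                rules.append("atypical:CD13-/CD33-with-MPO")
            if p["MPO"] <= params.mpo_high:
                rules.append("MPO-mid->CMP-L")
                label = "CMP-L"
            else:
                rules.append("MPO-high->GMP-L")
                label = "GMP-L"
        # secondary expectation: CD34+ myeloid-committed stages are CD117+
        if label != "HSC-L" and not cd117_pos:
            atypical = True
            rules.append("atypical:CD117-")
    else:
        rules.append("CD34-")
        if p["HLA-DR"] >= params.hladr_split:
            rules.append("HLA-DR+->MP-L")
            label = "MP-L"
        else:
            rules.append("HLA-DR-->GP-L")
            label = "GP-L"

    return SLALabel(label=label, atypical=atypical, rationale=tuple(rules))


def classify_cohort(
    profiles: Iterable[ProfileLike],
    params: ClassifierParams | None = None,
) -> tuple[list[SLALabel], pd.DataFrame]:
    """Classify every profile and tabulate cohort SLA frequencies.

    Returns (labels, frequency table).  The table has one row per SLA in
    canonical order with columns ``count``, ``percent`` (full precision) and
    ``percent_rounded`` (one decimal, half-away-from-zero), plus the
    atypical count as a DataFrame attribute ``attrs['n_atypical']``.
    """
    profiles = list(profiles)
    if not profiles:
        raise ClassificationError("empty cohort: no profiles to classify")
    labels = [classify_sla(pr, params) for pr in profiles]
    return labels, frequency_table([lab.label for lab in labels],
                                   n_atypical=sum(lab.atypical for lab in labels))


def frequency_table(labels: Sequence[str], n_atypical: int = 0) -> pd.DataFrame:
    """SLA frequency table from bare label strings (already-classified records)."""
    if len(labels) == 0:
        raise ClassificationError("empty cohort: no labels to tabulate")
    counts = pd.Series(labels).value_counts()
    total = int(counts.sum())
    rows = []
    for lab in SLA_LABELS:
        c = int(counts.get(lab, 0))
        pct = 100.0 * c / total
        rows.append({"label": lab, "count": c, "percent": pct,
                     "percent_rounded": round_half_away(pct, 1)})
    table = pd.DataFrame(rows).set_index("label")
    table.attrs["n_atypical"] = int(n_atypical)
    return table


def project_pca(
    matrix: pd.DataFrame | np.ndarray,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component projection of a patients x markers percentage matrix.

    Columns are centered (optionally scaled to unit variance) and decomposed
    by SVD.  Returns ``(coordinates, variance_explained)`` where
    ``coordinates`` is patients x components and ``variance_explained`` is
    non-negative and sums to 1.

    Raises :class:`DegenerateDecompositionError` for a constant matrix and
    ``ValueError`` for fewer than 2 patients/markers or undefined entries.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA requires a 2-D matrix with >=2 patients and >=2 markers")
    if np.isnan(x).any():
        raise ValueError("PCA input contains undefined (NaN) values")
    centered = x - x.mean(axis=0, keepdims=True)
    if standardize:
        sd = centered.std(axis=0, ddof=1, keepdims=True)
        nonzero = sd > 0
        centered = np.where(nonzero, centered / np.where(nonzero, sd, 1.0), centered)
    total_var = float((centered ** 2).sum())
    if total_var <= 0.0:
        raise DegenerateDecompositionError("constant matrix: no variance to decompose")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coordinates = u * s
    variance_explained = (s ** 2) / total_var
    return coordinates, variance_explained
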