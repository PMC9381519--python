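"""Genotype-phenotype association screen.

One-vs-rest 2x2 tables per (SLA, lesion) over tested patients, relative
risks with a Haldane-Anscombe zero-cell correction, two-sided Fisher exact
p-values (point-probability rule), secondary-AML labelling, and functional
mutation-module tallies.

Raw p-values are reported without multiplicity adjustment by default; a
Benjamini-Hochberg column is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from slaml._report import round_half_away

SLA_LABELS = ("HSC-L", "MPP-L", "CMP-L", "GMP-L", "GP-L", "MP-L")


class UndefinedRRError(ValueError):
    """Relative risk undefined: an exposure margin is empty."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = lesion+ within SLA, b = lesion- within SLA,
    c = lesion+ outside, d = lesion- outside (tested patients only)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    sla: str
    lesion: str
    table: ContingencyTable2x2
    rr: float
    p: float
    continuity_corrected: bool

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("relative risk must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def relative_risk(t: ContingencyTable2x2) -> tuple[float, bool]:
    """RR = [a/(a+b)] / [c/(c+d)].

    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe) and
    the correction flag is returned True.  Empty margins raise
    :class:`UndefinedRRError`.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise UndefinedRRError("cannot compute RR with an empty exposure margin")
    corrected = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = ((t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5) if corrected
                  else (t.a, t.b, t.c, t.d))
    rr = (a / (a + b)) / (c / (c + d))
    return float(rr), corrected


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (point-probability rule).

    Sums hypergeometric probabilities of all tables, at the observed
    margins, whose probability does not exceed that of the observed table.
    """
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


def association_screen(
    genotypes: pd.DataFrame,
    sla_labels: Sequence[str],
    lesions: Iterable[str] | None = None,
    adjust: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """One-vs-rest association screen across SLA x lesions.

    ``genotypes`` carries one 0/1 column per lesion plus an optional
    ``<lesion>_tested`` 0/1 column (all-tested assumed when absent).
    Returns a volcano-ready table (one row per SLA x lesion with counts,
    RR, p, log2 RR, -log10 p) and the list of skipped lesions (absent from
    the table or untested for every patient).
    """
    labels = np.asarray(sla_labels)
    if len(labels) != len(genotypes):
        raise ValueError("sla_labels length must match genotype rows")
    if lesions is None:
        lesions = [c for c in genotypes.columns
                   if c != "patient_id" and not c.endswith("_tested")]
    rows: list[dict] = []
    skipped: list[str] = []
    for lesion in lesions:
        if lesion not in genotypes.columns:
            skipped.append(lesion)
            continue
        tested_col = f"{lesion}_tested"
        tested = (genotypes[tested_col].to_numpy(dtype=bool)
                  if tested_col in genotypes.columns
                  else np.ones(len(genotypes), dtype=bool))
        if not tested.any():
            skipped.append(lesion)
            continue
        mutated = genotypes[lesion].to_numpy(dtype=bool) & tested
        for sla in SLA_LABELS:
            in_s = (labels == sla) & tested
            out_s = (labels != sla) & tested
            t = ContingencyTable2x2(
                a=int(np.count_nonzero(mutated & in_s)),
                b=int(np.count_nonzero(~mutated & in_s)),
                c=int(np.count_nonzero(mutated & out_s)),
                d=int(np.count_nonzero(~mutated & out_s)),
            )
            if t.a + t.b == 0 or t.c + t.d == 0:
                continue  # no tested patients on one side: RR undefined
            rr, corrected = relative_risk(t)
            p = fisher_exact_2x2(t)
            rows.append({
                "sla": sla, "lesion": lesion,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "rr": rr, "rr_rounded": round_half_away(rr, 2),
                "p": p, "continuity_corrected": corrected,
                "log2_rr": float(np.log2(rr)),
                "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
            })
    volcano = pd.DataFrame(rows)
    if adjust and not volcano.empty:
        volcano["p_bh"] = _benjamini_hochberg(volcano["p"].to_numpy())
    return volcano, skipped


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Secondary AML labelling
# ---------------------------------------------------------------------------

def _load_resource_genes(name: str) -> list[str]:
    text = resources.files("slaml.resources").joinpath(name).read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def default_mds_gene_set() -> list[str]:
    """The eight-gene MDS-pattern mutation set (editable resource)."""
    return _load_resource_genes("mds_genes.txt")


@dataclass(frozen=True)
class SecondaryAMLLabel:
    """Tri-state flags: True/False/None (None = unknown inputs)."""

    clinical: bool | None
    molecular: bool | None
    karyotypic: bool | None

    @property
    def overall(self) -> bool | None:
        flags = (self.clinical, self.molecular, self.karyotypic)
        if any(f is True for f in flags):
            return True
        if all(f is False for f in flags):
            return False
        return None


def classify_secondary_aml(
    record: Mapping[str, object],
    mds_gene_set: Sequence[str] | None = None,
) -> SecondaryAMLLabel:
    """Clinical / molecular / karyotypic secondary-AML flags for one patient.

    ``record`` supplies ``history_mds``/``history_mpn`` (0/1, may be missing),
    0/1 mutation flags keyed by gene name, and ``mrc_karyotype`` (0/1, may be
    missing).  Missing inputs yield an explicit unknown (None), never a
    silent False.
    """
    genes = list(mds_gene_set) if mds_gene_set is not None else default_mds_gene_set()

    def _flag(key: str) -> bool | None:
        v = record.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return bool(int(v))

    mds = _flag("history_mds")
    mpn = _flag("history_mpn")
    if mds is None and mpn is None:
        clinical: bool | None = None
    else:
        clinical = bool(mds) or bool(mpn)

    known = [g for g in genes if g in record and record.get(g) is not None
             and not (isinstance(record.get(g), float) and np.isnan(record[g]))]
    if not known:
        molecular: bool | None = None
    else:
        molecular = any(int(record[g]) == 1 for g in known)

    karyotypic = _flag("mrc_karyotype")
    return SecondaryAMLLabel(clinical=clinical, molecular=molecular,
                             karyotypic=karyotypic)


# ---------------------------------------------------------------------------
# Functional mutation modules
# ---------------------------------------------------------------------------

def default_module_map() -> dict[str, str]:
    """Gene -> functional-category map for the 46-gene panel (editable CSV)."""
    text = resources.files("slaml.resources").joinpath("gene_modules.csv").read_text()
    out: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        line = line.strip()
        if not line:
            continue
        gene, module = line.split(",", 1)
        out[gene] = module
    return out


def functional_module_tally(
    genotypes: pd.DataFrame,
    sla_labels: Sequence[str],
    module_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse gene mutations into functional modules, then screen.

    A patient counts once for a module if any gene of that module is
    mutated.  Returns the module-level volcano table and the list of
    mutated-but-unmapped genes.
    """
    module_map = dict(module_map) if module_map is not None else default_module_map()
    gene_cols = [c for c in genotypes.columns
                 if c != "patient_id" and not c.endswith("_tested")]
    unmapped = [g for g in gene_cols
                if g not in module_map and genotypes[g].to_numpy(dtype=bool).any()]
    modules = sorted({module_map[g] for g in gene_cols if g in module_map})
    collapsed = {"patient_id": genotypes.get("patient_id",
                                             pd.Series(range(len(genotypes))))}
    for module in modules:
        members = [g for g in gene_cols if module_map.get(g) == module]
        flag = np.zeros(len(genotypes), dtype=bool)
        tested = np.zeros(len(genotypes), dtype=bool)
        for g in members:
            tcol = f"{g}_tested"
            t = (genotypes[tcol].to_numpy(dtype=bool) if tcol in genotypes.columns
                 else np.ones(len(genotypes), dtype=bool))
            flag |= genotypes[g].to_numpy(dtype=bool) & t
            tested |= t
        collapsed[module] = flag.astype(int)
        collapsed[f"{module}_tested"] = tested.astype(int)
    volcano, _ = association_screen(pd.DataFrame(collapsed), sla_labels)
    return volcano, unmapped
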