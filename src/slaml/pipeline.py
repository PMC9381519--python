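"""End-to-end orchestration: simulate/load -> classify -> associate -> survive.

A :class:`RunConfig` names either input tables or a simulation config
(never both), the classifier thresholds, and analysis toggles.  The run
emits a :class:`ReportBundle` whose manifest (seed, version, config hash)
is sufficient to reproduce the bundle bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from slaml import __version__
from slaml._report import percent, ratio
from slaml.classifier import (
    SLA_LABELS,
    ClassifierParams,
    classify_cohort,
    project_pca,
)
from slaml.gating import profiles_from_frame
from slaml.genotype import association_screen, classify_secondary_aml
from slaml.outcomes import (
    cir_inputs_from_outcomes,
    compare_cir,
    cumulative_incidence,
    km_estimate,
    logrank_test,
    survival_table,
)
from slaml.synthetic import CohortConfig, simulate_cohort

log = logging.getLogger("slaml.pipeline")


class SchemaError(ValueError):
    """An input table violates the documented schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    simulate: CohortConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    pca: bool = False
    association: bool = True
    survival: bool = True
    saml: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (not self.inputs):
            raise ValueError(
                "exactly one of a simulation config or input paths must be supplied")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        sim = None
        if raw.get("simulate") is not None:
            sim_kwargs = dict(raw["simulate"])
            sim_kwargs.setdefault("seed", raw.get("seed", 0))
            sim = CohortConfig(**sim_kwargs)
        clf = ClassifierParams(**raw.get("classifier", {}))
        toggles = raw.get("analyses", {})
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir"),
            simulate=sim,
            inputs=dict(raw.get("inputs", {})),
            classifier=clf,
            pca=bool(toggles.get("pca", False)),
            association=bool(toggles.get("association", True)),
            survival=bool(toggles.get("survival", True)),
            saml=bool(toggles.get("saml", False)),
        )

    def canonical(self) -> dict:
        d: dict[str, Any] = {
            "seed": self.seed,
            "simulate": asdict(self.simulate) if self.simulate else None,
            "inputs": dict(sorted(self.inputs.items())),
            "classifier": asdict(self.classifier),
            "analyses": {"pca": self.pca, "association": self.association,
                         "survival": self.survival, "saml": self.saml},
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    frequency_table: pd.DataFrame
    labels: pd.DataFrame
    summary: pd.DataFrame | None = None
    volcano: pd.DataFrame | None = None
    skipped_lesions: list[str] = field(default_factory=list)
    survival_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    test_results: dict[str, dict] = field(default_factory=dict)
    saml_labels: pd.DataFrame | None = None
    pca_variance: list[float] | None = None
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.frequency_table.to_csv(out / "sla_frequencies.csv")
        self.labels.to_csv(out / "sla_labels.csv", index=False)
        if self.summary is not None:
            self.summary.to_csv(out / "cohort_summary.csv")
        if self.volcano is not None:
            self.volcano.to_csv(out / "volcano.csv", index=False)
        for name, table in self.survival_tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        if self.saml_labels is not None:
            self.saml_labels.to_csv(out / "saml_labels.csv", index=False)
        payload = dict(self.manifest)
        payload["tests"] = self.test_results
        (out / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def validate_genotypes(genotypes: pd.DataFrame) -> None:
    """0/1 flags only; raises :class:`SchemaError` naming the bad column."""
    for col in genotypes.columns:
        if col == "patient_id":
            continue
        vals = pd.unique(genotypes[col].dropna())
        try:
            ok = set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise SchemaError(
                f"genotype column {col!r} must contain only 0/1 flags")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (SchemaError, ValueError, KeyError) as exc:
                raise StageError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def summarize_cohort(records: pd.DataFrame, by: str = "sla") -> pd.DataFrame:
    """Per-SLA clinical summary: median (IQR) for numeric fields, n (%) for
    0/1 flags.  Denominators are per-field non-missing counts; percentages
    are rounded to one decimal at report time."""
    if records.empty:
        raise ValueError("at least one record required")
    groups = [("all", records)] + [(s, records[records[by] == s])
                                   for s in SLA_LABELS if (records[by] == s).any()]
    numeric = [c for c in records.columns
               if c not in (by, "patient_id") and pd.api.types.is_numeric_dtype(records[c])]
    rows = {}
    for name, sub in groups:
        row: dict[str, object] = {"n": len(sub)}
        for col in numeric:
            vals = sub[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                row[f"{col}_median"] = np.nan
                continue
            uniq = np.unique(vals)
            if set(uniq) <= {0.0, 1.0}:
                row[f"{col}_n"] = int(vals.sum())
                row[f"{col}_pct"] = percent(vals.sum(), vals.size)
            else:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])  # type-7 linear
                row[f"{col}_median"] = med
                row[f"{col}_iqr_low"] = q1
                row[f"{col}_iqr_high"] = q3
        rows[name] = row
    return pd.DataFrame(rows).T


def ratio_summary(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Report-rounded plain ratio (e.g. mice per sample)."""
    return ratio(numerator, denominator, ndigits)


@_stage("load")
def _load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    tables = {}
    for key, path in config.inputs.items():
        tables[key] = pd.read_csv(path)
    if "profiles" not in tables:
        raise SchemaError("inputs must include a 'profiles' table")
    if "genotypes" in tables:
        validate_genotypes(tables["genotypes"])
    return tables


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in order; identical config+seed gives an
    identical bundle.  Stage failures abort with a stage-tagged error."""
    if config.simulate is not None:
        sim_cfg = config.simulate
        if sim_cfg.seed != config.seed:
            sim_cfg = CohortConfig(**{**asdict(sim_cfg), "seed": config.seed})
        cohort = simulate_cohort(sim_cfg)
        log.info("simulate: %d patients", len(cohort.profiles))
        tables = {"profiles": cohort.profiles, "genotypes": cohort.genotypes,
                  "outcomes": cohort.outcomes}
    else:
        tables = _load_tables(config)
        log.info("load: %d patients", len(tables["profiles"]))

    profiles = tables["profiles"]
    marker_profiles = profiles_from_frame(profiles)

    @_stage("classify")
    def _classify():
        return classify_cohort(marker_profiles, config.classifier)

    labels, freq = _classify()
    labels_df = pd.DataFrame({
        "patient_id": profiles["patient_id"],
        "label": [lab.label for lab in labels],
        "atypical": [int(lab.atypical) for lab in labels],
        "rationale": ["|".join(lab.rationale) for lab in labels],
    })
    log.info("classify: %d labelled, %d atypical",
             len(labels_df), int(labels_df["atypical"].sum()))

    bundle = ReportBundle(frequency_table=freq, labels=labels_df)
    sla = labels_df["label"].to_numpy()

    if config.pca:
        @_stage("pca")
        def _pca():
            meta = {"patient_id", "n_blasts"}
            cols = [c for c in profiles.columns if c not in meta
                    and pd.api.types.is_numeric_dtype(profiles[c])]
            _, var = project_pca(profiles[cols].to_numpy())
            return [float(v) for v in var]
        bundle.pca_variance = _pca()

    summary_src = profiles.drop(columns=["patient_id"], errors="ignore").copy()
    summary_src["sla"] = sla
    bundle.summary = summarize_cohort(summary_src.assign(patient_id=profiles["patient_id"]))

    if config.association and "genotypes" in tables:
        @_stage("association")
        def _assoc():
            validate_genotypes(tables["genotypes"])
            return association_screen(tables["genotypes"], sla)
        bundle.volcano, bundle.skipped_lesions = _assoc()
        log.info("association: %d rows, %d skipped lesions",
                 0 if bundle.volcano is None else len(bundle.volcano),
                 len(bundle.skipped_lesions))

    if config.saml and "genotypes" in tables:
        @_stage("saml")
        def _saml():
            geno = tables["genotypes"]
            clinical = tables.get("clinical")
            rows = []
            for i in range(len(geno)):
                record = dict(geno.iloc[i])
                if clinical is not None:
                    record.update(dict(clinical.iloc[i]))
                lab = classify_secondary_aml(record)
                rows.append({
                    "patient_id": record.get("patient_id", i),
                    "clinical": lab.clinical, "molecular": lab.molecular,
                    "karyotypic": lab.karyotypic, "overall": lab.overall,
                })
            return pd.DataFrame(rows)
        bundle.saml_labels = _saml()

    if config.survival and "outcomes" in tables:
        @_stage("survival")
        def _survival():
            outcomes = tables["outcomes"]
            t = outcomes["os_months"].to_numpy(dtype=float)
            e = outcomes["os_event"].to_numpy(dtype=int)
            bundle.survival_tables["os_km_all"] = survival_table(km_estimate(t, e))
            present = [s for s in SLA_LABELS if (sla == s).any()]
            for s in present:
                m = sla == s
                bundle.survival_tables[f"os_km_{s}"] = survival_table(
                    km_estimate(t[m], e[m]))
            if len(present) >= 2:
                lr = logrank_test(t, e, sla)
                bundle.test_results["os_logrank"] = {
                    "statistic": lr.statistic, "df": lr.df, "p": lr.p}
            if {"cr", "relapse_months", "relapse_event",
                    "death_prior_relapse"} <= set(outcomes.columns):
                rt, causes, mask = cir_inputs_from_outcomes(outcomes)
                if rt.size:
                    cr_res = cumulative_incidence(rt, causes)
                    bundle.survival_tables["cir_all"] = pd.DataFrame({
                        "time": cr_res.times,
                        "cif_relapse": cr_res.cif_relapse,
                        "cif_death": cr_res.cif_death,
                        "event_free": cr_res.event_free,
                    })
                    cr_groups = sla[mask]
                    if np.unique(cr_groups).size >= 2:
                        gr = compare_cir(rt, causes, cr_groups,
                                         n_permutations=200, seed=config.seed)
                        bundle.test_results["cir_gray_permutation"] = {
                            "statistic": gr.statistic, "df": gr.df, "p": gr.p}
        _survival()

    bundle.manifest = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_patients": int(len(profiles)),
        "n_atypical": int(labels_df["atypical"].sum()),
    }
    if config.outdir:
        bundle.write(config.outdir)
    return bundle
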