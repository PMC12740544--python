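"""Readers, writers and run configuration.

Interchange format is plain CSV.  A cohort file has one row per
observation with columns ``subject_id, time_h, activity_fraction`` and
optional ``sd, tp_label``; TIA tables and accuracy/precision reports are
written with frozen column orders so identical inputs give byte-identical
files.  Percentages in the report tables are rendered to one decimal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import AccuracyReport, CVSummary
from .nlmem import CohortDataset, FitConfig, PopulationFit, PopulationModel, SubjectRecord
from .simulate import SimulationConfig, TruthRecord
from .workflow import TIAEstimate, WorkflowConfig, assign_timepoint_labels

__all__ = [
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "write_truth",
    "read_tia_table",
    "write_tia_table",
    "write_fit_json",
    "read_fit_json",
    "write_report",
    "write_manifest",
]

COHORT_COLUMNS = ("subject_id", "time_h", "activity_fraction")


class CohortFormatError(ValueError):
    """Malformed cohort file (row context in the message)."""


def read_cohort(
    path, nominal_times=(1.8, 18.7, 42.6, 66.3, 160.3)
) -> CohortDataset:
    """Read a time-activity cohort CSV, validating and labelling sessions.

    Samples without a ``tp_label`` column are assigned to the nearest
    nominal session mean.  Validation failures name the offending row
    (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    for col in ("time_h", "activity_fraction"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise CohortFormatError(
                f"{path}: non-numeric {col} at row {int(bad[0]) + 1}"
            )
        df[col] = vals
    neg = df.index[df["time_h"] <= 0]
    if len(neg):
        raise CohortFormatError(
            f"{path}: non-positive time_h at row {int(neg[0]) + 1}"
        )
    neg = df.index[df["activity_fraction"] < 0]
    if len(neg):
        raise CohortFormatError(
            f"{path}: negative activity_fraction at row {int(neg[0]) + 1}"
        )
    has_sd = "sd" in df.columns
    has_label = "tp_label" in df.columns
    if has_label:
        dup = df.duplicated(subset=["subject_id", "tp_label"])
        if dup.any():
            raise CohortFormatError(
                f"{path}: duplicate (subject_id, tp_label) at row "
                f"{int(df.index[dup][0]) + 1}"
            )
    subjects = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise CohortFormatError(
                f"{path}: duplicate times for subject {sid}"
            )
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                times=grp["time_h"].to_numpy(),
                activity=grp["activity_fraction"].to_numpy(),
                sd=grp["sd"].to_numpy() if has_sd else None,
                tp_labels=tuple(grp["tp_label"]) if has_label else None,
            )
        )
    n_sessions = len(nominal_times)
    dataset = CohortDataset(
        subjects, session_labels=tuple(f"TP{k + 1}" for k in range(n_sessions))
    )
    if not has_label:
        dataset = assign_timepoint_labels(dataset, nominal_times)
    return dataset


def write_cohort(dataset: CohortDataset, path) -> None:
    rows = []
    for s in dataset.subjects:
        for i in range(s.n_obs):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "time_h": s.times[i],
                    "activity_fraction": s.activity[i],
                    "sd": s.sd[i] if s.sd is not None else "",
                    "tp_label": s.tp_labels[i] if s.tp_labels else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_truth(truths: list[TruthRecord], path) -> None:
    rows = []
    for t in truths:
        row = {"subject_id": t.subject_id}
        row.update(dict(zip(
            ("A1", "A2", "A3", "lambda1", "lambda2", "lambda3"),
            t.true_params.as_array(),
        )))
        row["true_tia_h"] = t.true_tia
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_tia_table(estimates: list[TIAEstimate], path) -> None:
    rows = [
        {
            "subject_id": e.subject_id,
            "method": e.method,
            "role": e.role,
            "tia_h": e.value,
            "sd_h": e.sd,
            "cv": e.cv,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_tia_table(path) -> list[TIAEstimate]:
    df = pd.read_csv(path)
    return [
        TIAEstimate(
            subject_id=str(r.subject_id), value=float(r.tia_h),
            sd=float(r.sd_h), method=str(r.method), role=str(r.role),
        )
        for r in df.itertuples()
    ]


def write_fit_json(fit: PopulationFit, path) -> None:
    doc = {
        "theta": fit.model.theta.tolist(),
        "omega": fit.model.omega.tolist(),
        "sigma": fit.model.sigma,
        "error_model": fit.model.error_model,
        "ofv": fit.ofv,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_subjects,
        "est_cov": None if fit.est_cov is None else fit.est_cov.tolist(),
        "se": None if fit.se is None else fit.se.tolist(),
        "start_ofvs": fit.start_ofvs,
        "best_start": fit.best_start,
        "messages": fit.messages,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_fit_json(path) -> PopulationFit:
    doc = json.loads(Path(path).read_text())
    model = PopulationModel(
        theta=np.asarray(doc["theta"]),
        omega=np.asarray(doc["omega"]),
        sigma=doc["sigma"],
        error_model=doc.get("error_model", "proportional"),
    )
    return PopulationFit(
        model=model,
        ofv=doc["ofv"],
        converged=doc["converged"],
        n_obs=doc["n_obs"],
        n_subjects=doc["n_subjects"],
        est_cov=None if doc.get("est_cov") is None else np.asarray(doc["est_cov"]),
        se=None if doc.get("se") is None else np.asarray(doc["se"]),
        start_ofvs=doc.get("start_ofvs", []),
        best_start=doc.get("best_start", 0),
        messages=doc.get("messages", []),
    )


def _pct(x: float) -> str:
    return f"{100.0 * x:.1f}"


def _accuracy_frame(reports: dict[str, AccuracyReport]) -> pd.DataFrame:
    if not reports:
        raise ValueError("no accuracy reports to write")
    rows = []
    for name in sorted(reports, key=lambda n: (len(n), n)):
        r = reports[name]
        rows.append(
            {
                "method": r.method,
                "n": r.n,
                "rd_median_pct": _pct(r.rd_median),
                "rd_min_pct": _pct(r.rd_min),
                "rd_max_pct": _pct(r.rd_max),
                "rmse_pct": _pct(r.rmse),
                "rmse_sd_pct": _pct(r.rmse_sd),
                "mape_pct": f"{r.mape:.1f}",
                "mape_sd_pct": f"{r.mape_sd:.1f}",
                "rd10": r.rd10_count,
                "rd10_pct": r.rd10_pct,
                "rd20": r.rd20_count,
                "rd20_pct": r.rd20_pct,
                "slope": "" if r.slope is None else f"{r.slope:.4f}",
                "p_slope": "" if r.p_slope is None else f"{r.p_slope:.3g}",
            }
        )
    return pd.DataFrame(rows)


def _precision_frame(summaries: dict[str, CVSummary]) -> pd.DataFrame:
    rows = []
    for name in sorted(summaries, key=lambda n: (len(n), n)):
        s = summaries[name]
        rows.append(
            {
                "method": s.method,
                "n": s.n,
                "cv_mean_pct": _pct(s.mean),
                "cv_sd_pct": _pct(s.sd),
                "cv_median_pct": _pct(s.median),
                "cv_min_pct": _pct(s.min),
                "cv_max_pct": _pct(s.max),
            }
        )
    return pd.DataFrame(rows)


def write_report(
    reports: dict[str, AccuracyReport],
    path,
    format: str = "csv",
    cv_summaries: dict[str, CVSummary] | None = None,
) -> None:
    """Write the per-method accuracy (and optionally precision) tables.

    ``format`` is "csv" or "markdown".  With ``cv_summaries`` given, a
    precision table is written alongside (suffix ``_precision``).
    """
    path = Path(path)
    acc = _accuracy_frame(reports)
    if format == "csv":
        acc.to_csv(path, index=False)
    elif format == "markdown":
        path.write_text(_to_markdown(acc) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    if cv_summaries:
        prec = _precision_frame(cv_summaries)
        ppath = path.with_name(path.stem + "_precision" + path.suffix)
        if format == "csv":
            prec.to_csv(ppath, index=False)
        else:
            ppath.write_text(_to_markdown(prec) + "\n")


def _to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One serialisable document holding all pipeline settings."""

    seed: int = 0
    outdir: str = "results"
    fit: FitConfig = field(default_factory=FitConfig)
    workflow: WorkflowConfig = field(default_factory=WorkflowConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        def build(dc_type, sub):
            names = {f.name for f in fields(dc_type)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(
                    f"unknown {dc_type.__name__} keys: {sorted(unknown)}"
                )
            return dc_type(**sub)

        names = {f.name for f in fields(cls)}
        unknown = set(doc) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "seed" in doc:
            kwargs["seed"] = int(doc["seed"])
        if "outdir" in doc:
            kwargs["outdir"] = str(doc["outdir"])
        if "fit" in doc:
            kwargs["fit"] = build(FitConfig, doc["fit"] or {})
        if "simulation" in doc:
            sub = dict(doc["simulation"] or {})
            for key in ("nominal_times", "time_jitter_sd", "time_window",
                        "theta_true", "omega_true"):
                if key in sub:
                    sub[key] = tuple(sub[key])
            names_s = {f.name for f in fields(SimulationConfig)}
            unknown = set(sub) - names_s
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
            kwargs["simulation"] = SimulationConfig(**sub)
        if "workflow" in doc:
            sub = dict(doc["workflow"] or {})
            names_w = {f.name for f in fields(WorkflowConfig)}
            unknown = set(sub) - names_w
            if unknown:
                raise ValueError(f"unknown workflow keys: {sorted(unknown)}")
            if "fit" in sub:
                sub["fit"] = build(FitConfig, sub["fit"] or {})
            kwargs["workflow"] = WorkflowConfig(**sub)
        cfg = cls(**kwargs)
        # one seed drives everything unless sub-seeds are set explicitly
        cfg.simulation.seed = cfg.simulation.seed or cfg.seed
        return cfg

    def to_dict(self) -> dict:
        def clean(obj):
            if is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        doc = {
            "seed": self.seed,
            "outdir": self.outdir,
            "fit": clean(self.fit),
            "workflow": {
                k: v for k, v in clean(self.workflow).items() if k != "consts"
            },
            "simulation": clean(self.simulation),
        }
        doc["workflow"]["fit"] = clean(self.workflow.fit)
        return doc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def write_manifest(config: RunConfig, path) -> None:
    """Reproducibility manifest: config hash, seed and package version."""
    from . import __version__

    doc = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config_sha256": digest,
        "seed": config.seed,
        "dosim_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
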