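"""Evaluation protocol for few-time-point dosimetry.

The protocol compares TIA estimates from reduced imaging schedules against
an all-session reference:

1. *Reference (rTIA)*: one population fit on the full cohort with all
   sessions; each subject's empirical-Bayes parameters give rTIA, its
   delta-method SD, and CV.
2. *Few-time-point (eTIA)*: for every proper subset of the sessions and
   every subject, leave-one-out estimation — the population model is
   re-fitted on the remaining subjects' all-session data (cached per
   left-out subject, reused across subsets) and the left-out subject's
   parameters are estimated empirically-Bayes from the subset's samples
   only, with the population model held fixed.
3. *No-time-point surrogates (NTPme/NTPmd)*: the componentwise mean or
   median of the reference individual parameters is assigned to every
   subject, mimicking a fixed-activity strategy with no individual imaging.

Accuracy (RD/RMSE/MAPE with propagated SDs, RD>10%/20% counts, eTIA-rTIA
regression) and precision (CV) are summarised per method.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import (
    DEFAULT_CONSTANTS,
    PhysicalConstants,
    SOEFParameters,
    soef_tia,
    tia_sd_delta,
)
from .metrics import AccuracyReport, CVSummary, build_accuracy_report, cv_summary
from .nlmem import (
    CohortDataset,
    FitConfig,
    IndividualEstimate,
    PopulationFit,
    PopulationModel,
    SubjectRecord,
    estimate_individual,
    fit_population,
    initial_model_heuristic,
)

__all__ = [
    "SubsetLabel",
    "TIAEstimate",
    "WorkflowConfig",
    "ReferenceResult",
    "EvaluationResult",
    "enumerate_subsets",
    "atp_label",
    "assign_timepoint_labels",
    "reference_tias",
    "JackknifeRunner",
    "ftp_tias_jackknife",
    "ntp_tias",
    "best_subset",
    "run_full_evaluation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsetLabel:
    """An ordered set of imaging-session indices (1-based)."""

    sessions: tuple[int, ...]
    n_sessions: int = 5

    def __post_init__(self) -> None:
        s = self.sessions
        if len(s) == 0:
            raise ValueError("subset must be nonempty")
        if list(s) != sorted(set(s)):
            raise ValueError("session indices must be unique and ascending")
        if s[0] < 1 or s[-1] > self.n_sessions:
            raise ValueError(f"session indices must lie in 1..{self.n_sessions}")

    @property
    def name(self) -> str:
        if len(self.sessions) == self.n_sessions:
            return "ATP"
        return "TP" + "".join(str(k) for k in self.sessions)

    @property
    def size(self) -> int:
        return len(self.sessions)

    @property
    def tp_labels(self) -> tuple[str, ...]:
        return tuple(f"TP{k}" for k in self.sessions)


def atp_label(n_sessions: int = 5) -> SubsetLabel:
    return SubsetLabel(tuple(range(1, n_sessions + 1)), n_sessions)


def enumerate_subsets(n_sessions: int) -> list[SubsetLabel]:
    """All nonempty proper session subsets, sorted by (size, lexicographic)."""
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    out = []
    for size in range(1, n_sessions):
        for combo in itertools.combinations(range(1, n_sessions + 1), size):
            out.append(SubsetLabel(combo, n_sessions))
    return out


@dataclass(frozen=True)
class TIAEstimate:
    """A TIA value with uncertainty, tagged by producing method."""

    subject_id: str
    value: float
    sd: float
    method: str
    role: str  # "reference" | "estimated"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"TIA must be > 0 (subject {self.subject_id})")
        if self.sd < 0:
            raise ValueError("TIA SD must be >= 0")
        if self.role not in ("reference", "estimated"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def cv(self) -> float:
        return self.sd / self.value


def assign_timepoint_labels(
    dataset: CohortDataset, nominal_times=(1.8, 18.7, 42.6, 66.3, 160.3)
) -> CohortDataset:
    """Label each sample with the nearest nominal session mean.

    Two samples of one subject mapping to the same session is a collision
    and raises, since the evaluation assumes at most one sample per session.
    """
    mu = np.asarray(nominal_times, dtype=float)
    subjects = []
    for s in dataset.subjects:
        idx = np.argmin(np.abs(s.times[:, None] - mu[None, :]), axis=1)
        if len(set(idx.tolist())) != len(idx):
            dup = [int(k) + 1 for k in idx]
            raise ValueError(
                f"subject {s.subject_id}: two samples map to the same session "
                f"(assignments {dup} for times {s.times.tolist()})"
            )
        labels = tuple(f"TP{int(k) + 1}" for k in idx)
        subjects.append(replace(s, tp_labels=labels))
    labels_all = tuple(f"TP{k + 1}" for k in range(mu.size))
    return CohortDataset(subjects, session_labels=labels_all)


@dataclass
class WorkflowConfig:
    """Settings of the evaluation protocol."""

    fit: FitConfig = field(default_factory=FitConfig)
    #: "exclude": leave-one-out training fits without the evaluated subject
    #: (default); "include": reuse the full-cohort fit as everyone's prior.
    jackknife: str = "exclude"
    #: multi-start count for the leave-one-out training fits (these start
    #: from the fold's own heuristic, never from the full-cohort fit, so a
    #: left-out subject cannot influence its own prior even via the start)
    training_n_starts: int = 3
    #: subjects missing sessions stay in training folds; they enter the
    #: reference only with at least this many sessions present
    min_sessions_reference: int = 4
    consts: PhysicalConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if self.jackknife not in ("exclude", "include"):
            raise ValueError(f"unknown jackknife mode {self.jackknife!r}")


@dataclass
class ReferenceResult:
    """All-session population fit with per-subject reference TIAs."""

    pop_fit: PopulationFit
    individual: list[IndividualEstimate]
    tias: list[TIAEstimate]

    def tia_of(self, subject_id: str) -> TIAEstimate:
        for t in self.tias:
            if t.subject_id == subject_id:
                return t
        raise KeyError(subject_id)


def _tia_estimate(est: IndividualEstimate, method: str, role: str,
                  consts: PhysicalConstants) -> TIAEstimate:
    value = soef_tia(est.params, consts)
    sd = tia_sd_delta(est.params, est.param_cov, consts)
    return TIAEstimate(
        subject_id=est.subject_id, value=value, sd=sd, method=method, role=role
    )


def reference_tias(
    dataset: CohortDataset,
    config: WorkflowConfig | None = None,
    init: PopulationModel | None = None,
    pop_fit: PopulationFit | None = None,
) -> ReferenceResult:
    """Reference (all-session) TIAs from one full-cohort population fit."""
    config = config or WorkflowConfig()
    init = init or initial_model_heuristic(dataset, config.consts)
    if pop_fit is None:
        pop_fit = fit_population(dataset, init, config.fit)
    estimates = []
    tias = []
    for s in dataset.subjects:
        n_sessions = len(set(s.tp_labels)) if s.tp_labels else s.n_obs
        if n_sessions < dataset.n_sessions:
            if n_sessions < config.min_sessions_reference:
                log.warning(
                    "subject %s has %d sessions (<%d); excluded from reference",
                    s.subject_id, n_sessions, config.min_sessions_reference,
                )
                continue
            log.warning(
                "subject %s missing sessions; reference uses %d sessions",
                s.subject_id, n_sessions,
            )
        est = estimate_individual(
            pop_fit.model, s, subset=None,
            eta0=pop_fit.eta_hat.get(s.subject_id),
            floor=config.fit.floor,
        )
        estimates.append(est)
        tias.append(_tia_estimate(est, "ATP", "reference", config.consts))
    return ReferenceResult(pop_fit=pop_fit, individual=estimates, tias=tias)


class JackknifeRunner:
    """Caches leave-one-out training fits: at most one per subject.

    The training fit for subject ``m`` is a population fit on the other
    subjects' all-session data, initialised from that fold's own peeling
    heuristic, so it is fully determined by the training data — the
    left-out subject's observations cannot influence its own prior.  It is
    computed lazily on first use and reused for every session subset.
    """

    def __init__(
        self,
        dataset: CohortDataset,
        config: WorkflowConfig,
        reference: ReferenceResult | None = None,
    ):
        self.dataset = dataset
        self.config = config
        self.reference = reference
        self._training: dict[str, PopulationFit] = {}
        self.n_training_fits = 0

    def training_fit(self, subject_id: str) -> PopulationFit:
        if self.config.jackknife == "include":
            if self.reference is None:
                raise ValueError("jackknife mode 'include' needs a reference fit")
            return self.reference.pop_fit
        if subject_id not in self._training:
            fold = self.dataset.drop_subject(subject_id)
            init = initial_model_heuristic(fold, self.config.consts)
            fit_cfg = replace(
                self.config.fit,
                n_starts=self.config.training_n_starts,
                compute_cov=False,
            )
            self._training[subject_id] = fit_population(fold, init, fit_cfg)
            self.n_training_fits += 1
        return self._training[subject_id]

    def etia(self, subject: SubjectRecord, subset: SubsetLabel) -> TIAEstimate:
        pop = self.training_fit(subject.subject_id)
        est = estimate_individual(
            pop.model, subject, subset=subset.tp_labels, floor=self.config.fit.floor
        )
        return _tia_estimate(est, subset.name, "estimated", self.config.consts)


def ftp_tias_jackknife(
    dataset: CohortDataset,
    subset: SubsetLabel,
    config: WorkflowConfig | None = None,
    runner: JackknifeRunner | None = None,
    subjects: list[str] | None = None,
) -> list[TIAEstimate]:
    """Leave-one-out estimated TIAs for one session subset.

    Pass a shared ``runner`` when evaluating several subsets so the N
    training fits are computed once.  ``subjects`` restricts evaluation to
    the named subjects (all by default).
    """
    config = config or WorkflowConfig()
    if runner is None:
        reference = reference_tias(dataset, config)
        runner = JackknifeRunner(dataset, config, reference)
    wanted = set(subjects) if subjects is not None else None
    out = []
    for s in dataset.subjects:
        if wanted is not None and s.subject_id not in wanted:
            continue
        if s.tp_labels is None or not set(subset.tp_labels) <= set(s.tp_labels):
            log.warning(
                "subject %s lacks sessions %s; skipped for subset %s",
                s.subject_id, subset.tp_labels, subset.name,
            )
            continue
        try:
            out.append(runner.etia(s, subset))
        except Exception as exc:  # noqa: BLE001 - flagged subject, not fatal
            log.warning(
                "subject %s excluded from subset %s: %s", s.subject_id,
                subset.name, exc,
            )
    return out


def ntp_tias(
    dataset: CohortDataset,
    mode: str,
    reference: ReferenceResult,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[TIAEstimate]:
    """No-time-point surrogate: one representative parameter set for everyone.

    ``mode`` is "mean" (NTPme) or "median" (NTPmd) of the reference
    individual parameters.  The TIA SD reflects the cohort spread of the
    individual parameters, propagated through the TIA gradient.
    """
    if mode not in ("mean", "median"):
        raise ValueError("mode must be 'mean' or 'median'")
    pmat = np.array([e.params.as_array() for e in reference.individual])
    rep = np.mean(pmat, axis=0) if mode == "mean" else np.median(pmat, axis=0)
    params = SOEFParameters.from_array(rep)
    value = soef_tia(params, consts)
    if pmat.shape[0] > 1:
        cov = np.cov(pmat, rowvar=False)
        sd = tia_sd_delta(params, cov, consts)
    else:
        sd = 0.0
    method = "NTPme" if mode == "mean" else "NTPmd"
    return [
        TIAEstimate(subject_id=e.subject_id, value=value, sd=sd,
                    method=method, role="estimated")
        for e in reference.individual
    ]


@dataclass(frozen=True)
class BestChoice:
    name: str
    rmse: float
    mape: float
    rmse_mape_disagree: bool


def best_subset(
    reports: dict[str, AccuracyReport], subsets: list[SubsetLabel]
) -> dict[int, BestChoice]:
    """Lowest-RMSE subset per subset size (ties by lexicographic name).

    If the MAPE minimiser differs from the RMSE minimiser for a size, the
    RMSE choice wins and the disagreement flag is set.
    """
    if not reports:
        raise ValueError("no reports")
    by_size: dict[int, list[SubsetLabel]] = {}
    for lab in subsets:
        if lab.name in reports:
            by_size.setdefault(lab.size, []).append(lab)
    out = {}
    for size, labs in sorted(by_size.items()):
        key_rmse = min(labs, key=lambda l: (reports[l.name].rmse, l.name))
        key_mape = min(labs, key=lambda l: (reports[l.name].mape, l.name))
        out[size] = BestChoice(
            name=key_rmse.name,
            rmse=reports[key_rmse.name].rmse,
            mape=reports[key_rmse.name].mape,
            rmse_mape_disagree=key_rmse.name != key_mape.name,
        )
    return out


@dataclass
class EvaluationResult:
    """Full protocol output: reference, per-method estimates and summaries."""

    reference: ReferenceResult
    etias: dict[str, list[TIAEstimate]]
    reports: dict[str, AccuracyReport]
    cv_summaries: dict[str, CVSummary]
    best: dict[int, BestChoice]
    subsets: list[SubsetLabel]


def _report_for(
    method: str, estimates: list[TIAEstimate], reference: ReferenceResult
) -> AccuracyReport | None:
    pairs = []
    for e in estimates:
        try:
            r = reference.tia_of(e.subject_id)
        except KeyError:
            continue
        pairs.append((e, r))
    if not pairs:
        return None
    etia = np.array([e.value for e, _ in pairs])
    sd_e = np.array([e.sd for e, _ in pairs])
    rtia = np.array([r.value for _, r in pairs])
    sd_r = np.array([r.sd for _, r in pairs])
    return build_accuracy_report(method, etia, sd_e, rtia, sd_r)


def run_full_evaluation(
    dataset: CohortDataset,
    config: WorkflowConfig | None = None,
    subsets: list[SubsetLabel] | None = None,
    include_ntp: bool = True,
    include_atp: bool = True,
    init: PopulationModel | None = None,
) -> EvaluationResult:
    """Run the whole protocol: reference fit, jackknife subsets, NTP, summaries."""
    config = config or WorkflowConfig()
    if subsets is None:
        subsets = enumerate_subsets(dataset.n_sessions)
    reference = reference_tias(dataset, config, init=init)
    runner = JackknifeRunner(dataset, config, reference)
    etias: dict[str, list[TIAEstimate]] = {}
    eval_subsets = list(subsets)
    if include_atp:
        eval_subsets.append(atp_label(dataset.n_sessions))
    for lab in eval_subsets:
        etias[lab.name] = ftp_tias_jackknife(dataset, lab, config, runner=runner)
    if include_ntp:
        etias["NTPme"] = ntp_tias(dataset, "mean", reference, config.consts)
        etias["NTPmd"] = ntp_tias(dataset, "median", reference, config.consts)
    reports = {}
    cv_summaries = {"ATP_reference": cv_summary(
        "ATP_reference", np.array([t.cv for t in reference.tias])
    )}
    for name, ests in etias.items():
        rep = _report_for(name, ests, reference)
        if rep is not None:
            reports[name] = rep
        if ests:
            cv_summaries[name] = cv_summary(name, np.array([t.cv for t in ests]))
    best = best_subset(
        {k: v for k, v in reports.items() if k.startswith("TP")}, list(subsets)
    )
    return EvaluationResult(
        reference=reference,
        etias=etias,
        reports=reports,
        cv_summaries=cv_summaries,
        best=best,
        subsets=list(subsets),
    )
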