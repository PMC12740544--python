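"""Evaluation protocol: subsets, labels, reference/FTP/NTP estimates."""

import dataclasses

import numpy as np
import pytest

from dosim.kinetics import SOEFParameters, soef_tia
from dosim.metrics import build_accuracy_report
from dosim.nlmem import FitConfig, IndividualEstimate, SubjectRecord
from dosim.simulate import SimulationConfig, generate_cohort
from dosim.workflow import (
    JackknifeRunner,
    ReferenceResult,
    SubsetLabel,
    TIAEstimate,
    WorkflowConfig,
    assign_timepoint_labels,
    atp_label,
    best_subset,
    enumerate_subsets,
    ntp_tias,
    reference_tias,
)


class TestSubsetLabel:
    def test_names(self):
        assert SubsetLabel((3,)).name == "TP3"
        assert SubsetLabel((1, 3, 5)).name == "TP135"
        assert SubsetLabel((1, 2, 3, 4, 5)).name == "ATP"
        assert atp_label(5).name == "ATP"

    @pytest.mark.parametrize("bad", [(), (2, 1), (1, 1), (0,), (6,)])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            SubsetLabel(tuple(bad))


class TestEnumerateSubsets:
    def test_five_sessions_give_thirty(self):
        subs = enumerate_subsets(5)
        assert len(subs) == 30  # C(5,1)+C(5,2)+C(5,3)+C(5,4)
        sizes = [s.size for s in subs]
        assert sizes == sorted(sizes)
        assert [s.size for s in subs].count(1) == 5
        assert [s.size for s in subs].count(2) == 10
        full = set(range(1, 6))
        for s in subs:
            assert set(s.sessions) < full

    def test_two_sessions(self):
        subs = enumerate_subsets(2)
        assert [s.name for s in subs] == ["TP1", "TP2"]

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            enumerate_subsets(1)


class TestAssignLabels:
    def _cohort(self, times):
        from dosim.nlmem import CohortDataset

        sub = SubjectRecord("S1", np.asarray(times), np.full(len(times), 0.01))
        return CohortDataset([sub])

    def test_nearest_session(self):
        ds = assign_timepoint_labels(self._cohort([43.1]))
        assert ds.subjects[0].tp_labels == ("TP3",)

    def test_midpoint_arithmetic(self):
        # |100-66.3| < |100-160.3| so a 100 h sample belongs to session 4
        ds = assign_timepoint_labels(self._cohort([100.0]))
        assert ds.subjects[0].tp_labels == ("TP4",)

    def test_collision_is_error(self):
        with pytest.raises(ValueError, match="same session"):
            assign_timepoint_labels(self._cohort([42.0, 43.0]))


def _reference_from_params(params_list):
    """Build a ReferenceResult directly from given per-subject parameters."""
    individual = []
    tias = []
    for i, p in enumerate(params_list):
        sid = f"S{i + 1}"
        individual.append(
            IndividualEstimate(
                subject_id=sid,
                eta=np.zeros(6),
                params=p,
                param_cov=np.zeros((6, 6)),
                source_subset=("TP1", "TP2", "TP3", "TP4", "TP5"),
            )
        )
        tias.append(
            TIAEstimate(
                subject_id=sid, value=soef_tia(p), sd=0.0,
                method="ATP", role="reference",
            )
        )
    return ReferenceResult(pop_fit=None, individual=individual, tias=tias)


class TestNTP:
    def test_identical_cohort_zero_deviation(self):
        p = SOEFParameters(0.02, 0.01, 0.025, 0.005, 0.05, 2.0)
        ref = _reference_from_params([p, p, p])
        ests = ntp_tias(None, "mean", ref)
        for e, r in zip(ests, ref.tias):
            assert e.value == pytest.approx(r.value, rel=1e-12)
            assert e.method == "NTPme"

    def test_mean_and_median_of_two(self):
        p = SOEFParameters(0.02, 0.01, 0.025, 0.005, 0.05, 2.0)
        p3 = SOEFParameters.from_array(3.0 * p.as_array())
        expected = soef_tia(SOEFParameters.from_array(2.0 * p.as_array()))
        for mode in ("mean", "median"):
            ests = ntp_tias(None, mode, _reference_from_params([p, p3]))
            assert all(e.value == pytest.approx(expected, rel=1e-12) for e in ests)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ntp_tias(None, "mode", _reference_from_params([]))


class TestBestSubset:
    def _report(self, method, rds):
        n = len(rds)
        rtia = np.full(n, 2.0)
        etia = rtia * (1.0 + np.asarray(rds))
        return build_accuracy_report(method, etia, np.zeros(n), rtia, np.zeros(n))

    def test_minimum_rmse_per_size(self):
        subsets = [SubsetLabel((1,)), SubsetLabel((3,)), SubsetLabel((1, 3))]
        reports = {
            "TP1": self._report("TP1", [0.2, 0.2, 0.2]),
            "TP3": self._report("TP3", [0.05, 0.05, 0.05]),
            "TP13": self._report("TP13", [0.01, 0.01, 0.01]),
        }
        best = best_subset(reports, subsets)
        assert best[1].name == "TP3"
        assert best[2].name == "TP13"
        assert not best[1].rmse_mape_disagree

    def test_tie_breaks_lexicographically(self):
        subsets = [SubsetLabel((2,)), SubsetLabel((4,))]
        reports = {
            "TP2": self._report("TP2", [0.1, -0.1]),
            "TP4": self._report("TP4", [-0.1, 0.1]),
        }
        assert best_subset(reports, subsets)[1].name == "TP2"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_subset({}, [])


@pytest.fixture(scope="module")
def workflow_setup(small_cohort, small_fit):
    dataset, truths, _ = small_cohort
    config = WorkflowConfig(
        fit=FitConfig(n_starts=2, seed=0), training_n_starts=1
    )
    ref = reference_tias(dataset, config, pop_fit=small_fit)
    return dataset, truths, config, ref


class TestReferenceAndJackknife:
    """End-to-end pieces on the shared ten-subject cohort."""

    def test_reference_tracks_truth(self, workflow_setup):
        dataset, truths, _, ref = workflow_setup
        from scipy import stats

        truth = {t.subject_id: t.true_tia for t in truths}
        r = np.array([t.value for t in ref.tias])
        tt = np.array([truth[t.subject_id] for t in ref.tias])
        assert len(ref.tias) == dataset.n_subjects
        assert stats.spearmanr(r, tt).statistic > 0.85
        assert all(t.value > 0 and t.sd >= 0 for t in ref.tias)

    def test_homogeneous_cohort_reference_uniform(self):
        cfg = SimulationConfig(
            n_subjects=8, omega_true=(0.0,) * 6, sigma_true=1e-3, seed=21
        )
        ds, truths = generate_cohort(cfg)
        config = WorkflowConfig(
            fit=FitConfig(n_starts=2, seed=0, fix_omega=(1e-8,) * 6)
        )
        ref = reference_tias(ds, config)
        vals = np.array([t.value for t in ref.tias])
        assert np.all(np.abs(vals / truths[0].true_tia - 1.0) < 0.005)

    def test_jackknife_caching_contract(self, workflow_setup):
        dataset, _, config, ref = workflow_setup
        runner = JackknifeRunner(dataset, config, ref)
        ids = [s.subject_id for s in dataset.subjects[:3]]
        for lab in (SubsetLabel((3,)), SubsetLabel((2, 5)), SubsetLabel((1, 3, 5))):
            for sid in ids:
                runner.etia(dataset.subject(sid), lab)
        # one training fit per subject, reused across every subset
        assert runner.n_training_fits == len(ids)

    def test_ftp_estimates_valid_and_atp_consistent(self, workflow_setup):
        dataset, _, config, ref = workflow_setup
        runner = JackknifeRunner(dataset, config, ref)
        sid = dataset.subjects[0].subject_id
        est_atp = runner.etia(dataset.subject(sid), atp_label(5))
        est_stp = runner.etia(dataset.subject(sid), SubsetLabel((3,)))
        rtia = ref.tia_of(sid)
        assert est_atp.value > 0 and est_stp.value > 0
        # all-session jackknife estimate stays close to the reference;
        # the single-session one is less certain
        assert abs(est_atp.value / rtia.value - 1.0) < 0.15
        assert est_stp.sd >= est_atp.sd

    def test_leave_one_out_excludes_subject(self, workflow_setup):
        dataset, _, config, ref = workflow_setup
        runner = JackknifeRunner(dataset, config, ref)
        sid = dataset.subjects[0].subject_id
        fold_fit = runner.training_fit(sid)
        assert fold_fit.n_subjects == dataset.n_subjects - 1

    def test_leakage_invariance(self, workflow_setup):
        """Perturbing a left-out subject's excluded sessions cannot change
        its few-time-point estimate."""
        dataset, _, config, ref = workflow_setup
        sid = dataset.subjects[0].subject_id
        lab = SubsetLabel((3,))
        runner = JackknifeRunner(dataset, config, None)
        base = runner.etia(dataset.subject(sid), lab)

        perturbed_subjects = []
        for s in dataset.subjects:
            if s.subject_id == sid:
                y = s.activity.copy()
                y[[0, 1, 3, 4]] *= 1.3  # distort every session except TP3
                s = dataclasses.replace(s, activity=y)
            perturbed_subjects.append(s)
        perturbed = dataclasses.replace(dataset, subjects=perturbed_subjects)
        runner2 = JackknifeRunner(perturbed, config, None)
        out = runner2.etia(perturbed.subject(sid), lab)
        assert out.value == base.value
        assert out.sd == base.sd
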