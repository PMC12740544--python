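#!/usr/bin/env python
"""Leave-one-out few-time-point evaluation over all 30 session subsets.

For each subject of the 20-subject evaluation cohort, the population model
is refitted on the remaining subjects' all-session data (one cached
training fit per subject) and the subject's TIA is re-estimated
empirically-Bayes from every proper subset of its sessions, plus the
all-session case and the no-imaging mean/median surrogates.

Outputs: results/estimated_tias.csv, results/reference_tias_eval.csv
"""

from pathlib import Path

from dosim.io import read_cohort, write_tia_table
from dosim.nlmem import FitConfig
from dosim.workflow import WorkflowConfig, run_full_evaluation

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    dataset = read_cohort(OUT / "cohort_eval.csv")
    config = WorkflowConfig(fit=FitConfig(n_starts=3, seed=SEED))
    result = run_full_evaluation(dataset, config)
    write_tia_table(result.reference.tias, OUT / "reference_tias_eval.csv")
    all_ests = [e for group in result.etias.values() for e in group]
    write_tia_table(all_ests, OUT / "estimated_tias.csv")
    print(f"{len(all_ests)} estimates over {len(result.etias)} methods")
    for size, choice in sorted(result.best.items()):
        flag = " (RMSE/MAPE disagree)" if choice.rmse_mape_disagree else ""
        print(
            f"best {size}-session subset: {choice.name} — "
            f"RMSE {100 * choice.rmse:.1f}%, MAPE {choice.mape:.1f}%{flag}"
        )


if __name__ == "__main__":
    main()
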