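"""Fit CPTs and validate the candidate structures predictively.

Keeps each structure fixed, refits parameters per cross-validation fold, and
scores held-out food-security predictions with the Brier score, information
reward and Bayesian information reward; also reports the 90/10 split
confusion matrix (positive = food insecure).  Lower Brier and higher rewards
are better; a Bayesian information reward above zero means the network beats
the food-insecurity base rate.
"""

import json
from dataclasses import asdict
from pathlib import Path

from foodsecbn import confusion_split, cross_validate, fit_cpts
from foodsecbn.io import load_structure, load_table, save_network, write_manifest

SEED = 77
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = load_table(RESULTS / "households.csv")
    reports = {}
    for label in ("data", "prior"):
        structure = load_structure(RESULTS / f"structure_{label}.json")
        fitted = fit_cpts(structure, data)
        save_network(fitted, RESULTS / f"network_{label}.json")
        report = cross_validate(structure, data, k=10, seed=SEED)
        cm = confusion_split(structure, data, train_fraction=0.9, seed=SEED)
        reports[label] = {
            "scores": asdict(report),
            "confusion": asdict(cm),
        }
        print(
            f"{label}: S_B={report.S_B:.4f}  S_IR={report.S_IR:.4f}  "
            f"S_BIR={report.S_BIR:.4f}  "
            f"confusion tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn}"
        )
    (RESULTS / "validation.json").write_text(json.dumps(reports, indent=1) + "\n")
    write_manifest(
        RESULTS / "validate.manifest.json", "03_fit_and_validate", seed=SEED, k=10
    )


if __name__ == "__main__":
    main()
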