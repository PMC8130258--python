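"""Learn network structures from the synthetic households.

Two structure-learning runs mirror the study design: MMPC with the
stratified Jonckheere-Terpstra test alone, and the same learner seeded with
an expert network as a prior (here the ground truth plays the expert, so the
prior is as good as an expert could be).  Both are oriented by the causal
ordering and compared against the true skeleton.
"""

from pathlib import Path

from foodsecbn import learn_structure
from foodsecbn.io import (
    export_dot,
    load_network,
    load_ordering,
    load_table,
    save_structure,
    write_manifest,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def f1(learned, truth) -> float:
    tp = len(learned & truth)
    fp = len(learned - truth)
    fn = len(truth - learned)
    return 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 1.0


def main() -> None:
    data = load_table(RESULTS / "households.csv")
    ordering = load_ordering(RESULTS / "ordering.yaml")
    truth = load_network(RESULTS / "truth_network.json")
    truth_edges = {frozenset(e) for e in truth.structure.edges}

    data_only = learn_structure(data, ordering, alpha=0.05, max_conditioning=3)
    with_prior = learn_structure(
        data,
        ordering,
        alpha=0.05,
        max_conditioning=3,
        expert_prior=truth.structure,
        alpha_keep=0.20,
    )

    save_structure(data_only, RESULTS / "structure_data.json", ordering)
    save_structure(with_prior, RESULTS / "structure_prior.json", ordering)
    export_dot(data_only, RESULTS / "structure_data.dot")
    export_dot(with_prior, RESULTS / "structure_prior.dot")
    write_manifest(
        RESULTS / "learn.manifest.json",
        "02_learn_structures",
        alpha=0.05,
        max_conditioning=3,
        alpha_keep=0.20,
    )

    for label, s in (("data-only", data_only), ("data+prior", with_prior)):
        edges = {frozenset(e) for e in s.edges}
        print(
            f"{label}: {len(s.edges)} edges, skeleton F1 vs truth = "
            f"{f1(edges, truth_edges):.3f}"
        )


if __name__ == "__main__":
    main()
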