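"""Simulate epochs, preprocess, decompose, and test the ERP effects.

Runs the epoch-level branch of the pipeline at the full study scale (24
and 23 subjects, 9 blocks x 80 trials, 10,000 permutations): Kaiser FIR
low-pass, baseline correction, 100 uV peak-to-peak rejection,
correct-trial condition averaging, the four difference potentials,
within-group tmax permutation maps, and the AGE x ANTERIORITY window
ANOVAs with Greenhouse-Geisser correction and BIC-approximated
inclusion Bayes factors.  Takes a few minutes.

Finding (seed 2): the occipital updating negativity and the posterior
gate-opening positivity are detected by the tmax maps in both groups
(hundreds of significant points each), while the weaker substitution
and gate-closing components (0.7-0.8 uV) reach the familywise threshold
only sporadically — the tmax criterion is deliberately conservative at
realistic single-trial noise.  The late updating window shows the
AGE x ANTERIORITY interaction built into the generative templates
(stronger occipital negativity in the younger group, p = .007).
"""

from pathlib import Path

from refback.pipeline import StudyConfig, run_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = StudyConfig(seed=2)
    bundle = run_study(config, include_sources=False)

    OUT.mkdir(exist_ok=True)
    bundle.amplitude_table.to_csv(OUT / "amplitude_table.csv", index=False)
    bundle.erp_stats.to_csv(OUT / "erp_stats.csv", index=False)
    bundle.tmax_summary.to_csv(OUT / "tmax_summary.csv", index=False)

    print(bundle.tmax_summary.to_string(index=False))
    print()
    late = bundle.erp_stats[
        (bundle.erp_stats["subprocess"] == "updating")
        & (bundle.erp_stats["window"] == "400-1000")
    ]
    print(late.to_string(index=False))


if __name__ == "__main__":
    main()
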